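"""Trait computation and drought-tolerance-coefficient construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germscreen import (
    SimConfig,
    ValidationError,
    build_dc_matrix,
    drought_coefficient,
    drought_tolerance_index,
    generate_screen,
    germination_fractions,
    hypocotyl_length,
    trait_table,
    water_absorption_rate,
)
from germscreen.simulate import DC_COLUMNS


def _raw_row(accession="A", biorep=1, treatment="CK", techrep=1, m0=1.0,
             m20=1.4, n_sown=40, g2=4, g3=12, g4=20, g7=36, fw=0.6,
             sl=16.0, rl=10.0):
    return dict(accession=accession, biorep=biorep, treatment=treatment,
                techrep=techrep, m0=m0, m20=m20, n_sown=n_sown, g2=g2,
                g3=g3, g4=g4, g7=g7, fw=fw, sl=sl, rl=rl)


class TestUnitOperations:
    @pytest.mark.parametrize("m0,m20,expected", [
        (1.00, 1.47, 0.47),
        (2.0, 2.0, 0.0),
        (1.0, 0.94, -0.06),  # mass loss under osmotic stress is legal
    ])
    def test_water_absorption(self, m0, m20, expected):
        assert water_absorption_rate(m20, m0) == pytest.approx(expected)

    def test_water_absorption_rejects_nonpositive_mass(self):
        with pytest.raises(ValidationError):
            water_absorption_rate(1.2, 0.0)

    def test_germination_fractions(self):
        f = germination_fractions(4, 12, 20, 36, 40)
        assert f["GP"] == pytest.approx(12 / 40)
        assert f["GR"] == pytest.approx(36 / 40)
        assert f == {"GP": 0.3, "GR": 0.9, "GR2": 0.1, "GR4": 0.5, "GR7": 0.9}

    @pytest.mark.parametrize("counts", [(0, 0, 0, 0), (40, 40, 40, 40)])
    def test_germination_extremes(self, counts):
        f = germination_fractions(*counts, 40)
        assert f["GP"] == f["GR"] == counts[0] / 40

    def test_nonmonotone_counts_rejected(self):
        with pytest.raises(ValidationError, match="g4=10"):
            germination_fractions(2, 12, 10, 36, 40)

    @pytest.mark.parametrize("mode,expected", [("sum", 0.3), ("mean", 0.1)])
    def test_drought_tolerance_index_modes(self, mode, expected):
        assert drought_tolerance_index(0.1, 0.1, 0.1, dt_mode=mode) == \
            pytest.approx(expected)
        assert drought_tolerance_index(0, 0, 0, dt_mode=mode) == 0

    def test_dt_mean_is_third_of_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = np.sort(rng.uniform(0, 1, 3))
            s = drought_tolerance_index(*a, dt_mode="sum")
            m = drought_tolerance_index(*a, dt_mode="mean")
            assert m == pytest.approx(s / 3)

    def test_hypocotyl_length(self):
        assert hypocotyl_length(16.0, 10.0) == pytest.approx(6.0)
        assert hypocotyl_length(10.0, 10.0) == 0.0
        assert hypocotyl_length(18.8, 14.9) == pytest.approx(3.9)
        with pytest.raises(ValidationError):
            hypocotyl_length(9.0, 10.0)

    def test_drought_coefficient(self):
        assert drought_coefficient(0.5, 0.5) == 1.0
        assert drought_coefficient(0.0, 0.5) == 0.0
        assert drought_coefficient(1.9, 1.0) == pytest.approx(1.9)
        assert np.isnan(drought_coefficient(0.3, 0.0))
        with pytest.raises(ValidationError):
            drought_coefficient(0.3, -1.0)


class TestDCMatrix:
    def test_identical_treatments_give_unit_row(self):
        rows = [_raw_row(treatment=t, techrep=k)
                for t in ("CK", "DS") for k in (1, 2, 3)]
        dc = build_dc_matrix(pd.DataFrame(rows), 1)
        assert np.allclose(dc.loc["A"].to_numpy(), 1.0)

    def test_total_germination_failure_zeroes_dcs(self):
        ck = [_raw_row(techrep=k) for k in (1, 2, 3)]
        ds = [_raw_row(treatment="DS", techrep=k, g2=0, g3=0, g4=0, g7=0,
                       fw=0.0, sl=0.0, rl=0.0, m20=1.1) for k in (1, 2, 3)]
        dc = build_dc_matrix(pd.DataFrame(ck + ds), 1)
        zeroed = ["RGP", "RGR", "RDT", "RFW", "RSL", "RHL", "RRL"]
        assert (dc.loc["A", zeroed] == 0).all()
        assert dc.loc["A", "RAR"] > 0

    def test_zero_control_flags_missing(self):
        ck = [_raw_row(g2=0, g3=0, g4=0, g7=0, fw=0.0, sl=0.0, rl=0.0)]
        ds = [_raw_row(treatment="DS")]
        dc = build_dc_matrix(pd.DataFrame(ck + ds), 1)
        assert dc.loc["A", ["RGP", "RGR", "RFW"]].isna().all()
        assert dc.loc["A", "RAR"] == pytest.approx(1.0)

    def test_accession_missing_treatment_is_excluded(self):
        rows = [_raw_row(accession="A", treatment=t) for t in ("CK", "DS")]
        rows += [_raw_row(accession="B", treatment="CK")]
        dc = build_dc_matrix(pd.DataFrame(rows), 1)
        assert list(dc.index) == ["A"]
        assert dc.attrs["excluded"] == ["B"]

    def test_flat_screen_recovers_base_dc(self):
        cfg = SimConfig(n_accessions=20, latent_sd=0.0, noise_sd=0.0,
                        trait_loadings={c: 0.0 for c in DC_COLUMNS},
                        trait_sensitivity={c: 1.0 for c in DC_COLUMNS},
                        stress_severity=0.4, rng_seed=11)
        dc = build_dc_matrix(generate_screen(cfg), 1)
        # Per-trait means recover the baseline; individual entries vary
        # with roll-level binomial/measurement noise.
        assert np.allclose(dc.mean(), 0.6, atol=0.05)
        assert np.allclose(dc.to_numpy(), 0.6, atol=0.25)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_dc_scale_invariance(self, c):
        # Rescaling both treatments leaves every DC unchanged.
        base = [_raw_row(treatment=t) if t == "CK"
                else _raw_row(treatment=t, fw=0.3, sl=8.0, rl=6.0, m20=1.2)
                for t in ("CK", "DS")]
        df = pd.DataFrame(base)
        scaled = df.copy()
        scaled[["fw", "sl", "rl"]] *= c
        a = build_dc_matrix(df, 1)[["RFW", "RSL", "RHL", "RRL"]]
        b = build_dc_matrix(scaled, 1)[["RFW", "RSL", "RHL", "RRL"]]
        pd.testing.assert_frame_equal(a, b, check_exact=False)

    def test_gp_never_exceeds_gr(self, default_screen):
        tab = trait_table(default_screen)
        assert (tab["GP"] <= tab["GR"] + 1e-12).all()
        assert np.allclose(tab["HL"], tab["SL"] - tab["RL"])

    def test_stress_depresses_dt_on_average(self, default_screen):
        tab = trait_table(default_screen)
        wide = tab.pivot_table(index=["accession", "biorep"],
                               columns="treatment", values="DT")
        assert wide["DS"].mean() < wide["CK"].mean()
        # DT is bounded by three times the day-7 rate in sum mode.
        assert (tab["DT"] <= 3 * tab["GR"] + 1e-12).all()
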