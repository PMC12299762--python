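"""Germination-stage phenotypes and drought-tolerance coefficients.

Eight traits are computed per (accession, biological replicate,
treatment), aggregating technical replicates by their arithmetic mean:

========  =====================================================
AR        seed water-absorption rate, (m20 − m0)/m0
GP        germination potential, day-3 germinated fraction
GR        germination rate, day-7 germinated fraction
DT        drought-tolerance index from day-2/4/7 rates
FW        day-7 seedling fresh weight (g)
SL        day-7 seedling length (cm)
HL        hypocotyl length, SL − RL (cm)
RL        day-7 root length (cm)
========  =====================================================

The drought-tolerance coefficient (DC) of a trait is the stressed value
divided by the control value for the same accession, kept on the
fractional scale (1.0 = no stress response).  A zero control makes the
DC undefined and it is carried as missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import DC_COLUMNS, TRAITS, drop_hidden


class ValidationError(ValueError):
    """Raised when raw measurements violate the screen's invariants."""


def water_absorption_rate(m20, m0):
    """Fractional mass gain after 20 h imbibition, (m20 − m0)/m0.

    Negative values are legal (mass loss during imbibition is observed
    under osmotic stress); a non-positive dry mass is not.
    """
    m0 = np.asarray(m0, dtype=float)
    m20 = np.asarray(m20, dtype=float)
    if (m0 <= 0).any():
        raise ValidationError("dry seed mass m0 must be positive")
    out = (m20 - m0) / m0
    return float(out) if out.ndim == 0 else out


def germination_fractions(g2, g3, g4, g7, n_sown) -> dict[str, float]:
    """Cumulative germinated fractions {GP, GR, GR2, GR4, GR7}.

    GP is the day-3 fraction, GR the day-7 fraction; counts must be
    non-decreasing and bounded by the seeds sown.
    """
    if n_sown <= 0:
        raise ValidationError("n_sown must be positive")
    if not 0 <= g2 <= g3 <= g4 <= g7 <= n_sown:
        raise ValidationError(
            f"non-monotone germination counts (g2={g2}, g3={g3}, "
            f"g4={g4}, g7={g7}, n_sown={n_sown})")
    n = float(n_sown)
    return {"GP": g3 / n, "GR": g7 / n,
            "GR2": g2 / n, "GR4": g4 / n, "GR7": g7 / n}


def drought_tolerance_index(gr2: float, gr4: float, gr7: float,
                            dt_mode: str = "sum") -> float:
    """Drought-tolerance index from day-2/4/7 germination rates.

    ``sum`` (default) is the plain GR2 + GR4 + GR7; ``mean`` divides by
    three, which keeps the index on the same [0, 1] scale as the rates.
    """
    for v in (gr2, gr4, gr7):
        if not 0.0 <= v <= 1.0:
            raise ValidationError("germination rates must lie in [0, 1]")
    total = gr2 + gr4 + gr7
    if dt_mode == "sum":
        return total
    if dt_mode == "mean":
        return total / 3.0
    raise ValueError(f"dt_mode must be 'sum' or 'mean', got {dt_mode!r}")


def hypocotyl_length(sl: float, rl: float) -> float:
    """Hypocotyl length = seedling length − root length (cm)."""
    if rl < 0 or sl < rl:
        raise ValidationError(
            f"need seedling length >= root length >= 0 (sl={sl}, rl={rl})")
    return sl - rl


def drought_coefficient(treat, control):
    """DC = stressed value / control value, on the fractional scale.

    A zero control yields NaN (missing DC); a negative control is a
    measurement error and is rejected.
    """
    treat = np.asarray(treat, dtype=float)
    control = np.asarray(control, dtype=float)
    if (control < 0).any():
        raise ValidationError("control trait value must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(control == 0, np.nan, treat / np.where(control == 0, 1, control))
    return float(out) if out.ndim == 0 else out


def trait_table(raw: pd.DataFrame, dt_mode: str = "sum") -> pd.DataFrame:
    """Per-(accession, biorep, treatment) trait vectors.

    Technical replicates are aggregated by arithmetic mean before any
    ratio is formed (the roll is the observational unit; each roll's
    morphometrics are already pooled-seedling means).
    """
    raw = drop_hidden(raw)
    required = {"accession", "biorep", "treatment", "techrep", "m0", "m20",
                "n_sown", "g2", "g3", "g4", "g7", "fw", "sl", "rl"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"raw table missing columns: {sorted(missing)}")

    counts = raw[["g2", "g3", "g4", "g7"]].to_numpy()
    bad = (np.diff(counts, axis=1) < 0).any(axis=1) | \
        (raw["g7"] > raw["n_sown"]) | (raw["g2"] < 0)
    if bad.any():
        idx = raw.index[bad][0]
        r = raw.loc[idx]
        raise ValidationError(
            "non-monotone germination counts in record "
            f"(accession={r['accession']}, biorep={r['biorep']}, "
            f"treatment={r['treatment']}, techrep={r['techrep']})")

    rows = []
    for (acc, rep, trt), grp in raw.groupby(
            ["accession", "biorep", "treatment"], sort=True):
        ar = float(np.mean(water_absorption_rate(grp["m20"], grp["m0"])))
        n = float(grp["n_sown"].mean())
        g2, g3, g4, g7 = (float(grp[c].mean()) for c in ("g2", "g3", "g4", "g7"))
        gp, gr = g3 / n, g7 / n
        dt = drought_tolerance_index(g2 / n, g4 / n, g7 / n, dt_mode=dt_mode)
        fw = float(grp["fw"].mean())
        sl = float(grp["sl"].mean())
        rl = float(grp["rl"].mean())
        hl = hypocotyl_length(sl, rl)
        rows.append((acc, rep, trt, ar, gp, gr, dt, fw, sl, hl, rl))
    return pd.DataFrame(
        rows, columns=["accession", "biorep", "treatment", *TRAITS])


def build_dc_matrix(raw: pd.DataFrame, biorep: int,
                    dt_mode: str = "sum") -> pd.DataFrame:
    """Accessions × 8 DC matrix for one biological replicate.

    Accessions missing either treatment are excluded (a list of the
    dropped ids is attached as ``.attrs['excluded']``); a zero control
    trait leaves that accession's DC missing (NaN).
    """
    traits = trait_table(raw[raw["biorep"] == biorep], dt_mode=dt_mode)
    if traits.empty:
        raise ValidationError(f"no records for biorep {biorep}")
    for trt in ("CK", "DS"):
        if trt not in set(traits["treatment"]):
            raise ValidationError(f"treatment {trt} absent from biorep {biorep}")
    wide = traits.pivot(index="accession", columns="treatment", values=list(TRAITS))
    ck = wide.xs("CK", axis=1, level=1)
    ds = wide.xs("DS", axis=1, level=1)
    complete = ck.notna().all(axis=1) & ds.notna().all(axis=1)
    excluded = list(wide.index[~complete])
    ck, ds = ck[complete], ds[complete]
    dc = pd.DataFrame(
        {rc: drought_coefficient(ds[t].to_numpy(), ck[t].to_numpy())
         for rc, t in zip(DC_COLUMNS, TRAITS)},
        index=ck.index)
    dc.index.name = "accession"
    dc.attrs["biorep"] = biorep
    dc.attrs["excluded"] = excluded
    return dc
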