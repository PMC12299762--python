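"""Synthetic germination-screen generator.

Emulates a paper-roll germination assay: accessions of a seed crop are
germinated under a control treatment (CK, plain water) and an osmotic
drought-stress treatment (DS, PEG-6000), in biological replicates each
containing several technical replicates (rolls of 40 seeds).  Germinated
seeds are counted on days 2, 3, 4 and 7; seed mass is recorded dry and at
20 h imbibition; day-7 seedlings yield fresh weight, seedling length and
root length.

The generative model is a single latent drought-tolerance score per
accession.  Each trait's drought-tolerance coefficient (DC = DS/CK) is a
trait-specific baseline — set by the stress severity — shifted by the
latent score through a signed loading (water-absorption rate loads
negatively, every other trait positively) plus replicate-level noise.
Control trait values are drawn around configurable population means;
stressed values are the control values thinned by the realized DC.
Germination counts are produced by sequential binomial thinning so the
day-2/3/4/7 trajectory is monotone by construction, and complete
germination failure under stress zeroes the seedling morphometrics, as a
real screen records.

The latent score is written to the output as ``true_tolerance``, a hidden
bookkeeping column used only by recovery tests; pipeline readers drop it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical trait order used across the whole package.
TRAITS: tuple[str, ...] = ("AR", "GP", "GR", "DT", "FW", "SL", "HL", "RL")

#: Drought-tolerance-coefficient column names, one per trait.
DC_COLUMNS: tuple[str, ...] = ("RAR", "RGP", "RGR", "RDT", "RFW", "RSL", "RHL", "RRL")

#: Columns of the raw-screen table, in output order.
RAW_COLUMNS: tuple[str, ...] = (
    "accession",
    "biorep",
    "treatment",
    "techrep",
    "m0",
    "m20",
    "n_sown",
    "g2",
    "g3",
    "g4",
    "g7",
    "fw",
    "sl",
    "rl",
    "true_tolerance",
)

#: Hidden column carrying the simulation's latent truth; excluded by
#: every pipeline reader, read only by recovery tests.
HIDDEN_COLUMNS: tuple[str, ...] = ("true_tolerance",)

# Control-population trait means and SDs (AR as a fraction, GP/GR as
# fractions of seeds sown, lengths in cm, fresh weight in g).  DT is
# derived from the germination trajectory, so its entries are recorded
# for completeness but not sampled directly.
_DEFAULT_CK_MEANS = {
    "AR": 0.47, "GP": 0.82, "GR": 0.95, "DT": 0.35,
    "FW": 0.63, "SL": 16.29, "HL": 6.25, "RL": 10.05,
}
_DEFAULT_CK_SDS = {
    "AR": 0.15, "GP": 0.15, "GR": 0.06, "DT": 0.05,
    "FW": 0.07, "SL": 1.78, "HL": 0.90, "RL": 1.36,
}

# Signed effect of the latent tolerance score on each trait's DC.
_DEFAULT_LOADINGS = {
    "RAR": -0.15, "RGP": 0.20, "RGR": 0.18, "RDT": 0.19,
    "RFW": 0.16, "RSL": 0.17, "RHL": 0.16, "RRL": 0.18,
}

# Relative sensitivity of each trait's DC baseline to the stress
# severity: baseline DC = 1 - severity * sensitivity.  At the default
# severity of 0.75 the baselines sit near observed mean DCs of a
# PEG-6000 germination screen (root length buffered, hypocotyl and
# germination potential hit hardest).
_DEFAULT_SENSITIVITY = {
    "RAR": 0.72, "RGP": 1.00, "RGR": 0.88, "RDT": 0.97,
    "RFW": 0.81, "RSL": 0.60, "RHL": 1.00, "RRL": 0.32,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic screen.

    Parameters
    ----------
    n_accessions, n_bioreps, n_techreps
        Design counts: germplasm lines, biological replicates (full
        independent repeats of the screen) and technical replicates
        (rolls per treatment).
    seeds_per_roll
        Seeds sown per technical replicate.
    latent_sd
        SD of the per-accession latent tolerance score (dimensionless).
    trait_loadings
        Signed effect of the latent score on each trait's DC, keyed by
        DC column name; the water-absorption loading is negative.
    ck_means, ck_sds
        Between-accession mean and SD of each control-treatment trait.
    trait_sensitivity
        Relative severity response of each trait's DC baseline.
    stress_severity
        Fraction in [0, 1]; 0 means DS is indistinguishable from CK.
    noise_sd
        SD of replicate-level DC noise (dimensionless).
    rng_seed
        Seed for the generator; identical configs give identical tables.
    """

    n_accessions: int = 200
    n_bioreps: int = 2
    n_techreps: int = 3
    seeds_per_roll: int = 40
    latent_sd: float = 1.0
    trait_loadings: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS))
    ck_means: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CK_MEANS))
    ck_sds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CK_SDS))
    trait_sensitivity: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SENSITIVITY))
    stress_severity: float = 0.75
    noise_sd: float = 0.05
    rng_seed: int = 0
    # Control germination fraction on day 2 and the day-4 position
    # between the day-3 and day-7 fractions.
    ck_day2_frac: float = 0.10
    day4_progress: float = 0.6
    dc_clip: float = 2.5

    def __post_init__(self) -> None:
        for name in ("n_accessions", "n_bioreps", "n_techreps", "seeds_per_roll"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.stress_severity <= 1.0:
            raise ValueError("stress_severity must lie in [0, 1]")
        if self.noise_sd < 0 or self.latent_sd < 0:
            raise ValueError("latent_sd and noise_sd must be non-negative")
        for m, keys in ((self.trait_loadings, DC_COLUMNS),
                        (self.trait_sensitivity, DC_COLUMNS),
                        (self.ck_means, TRAITS),
                        (self.ck_sds, TRAITS)):
            if set(m) != set(keys):
                missing = set(keys) - set(m)
                extra = set(m) - set(keys)
                raise ValueError(
                    f"trait map must configure exactly {keys}; "
                    f"missing={sorted(missing)} extra={sorted(extra)}")
        if any(v < 0 for v in self.ck_sds.values()):
            raise ValueError("ck_sds must be non-negative")
        # Expected DS germination probabilities must be valid before any
        # clamping: baseline DC times the control fraction.
        for trait, dc in (("GP", "RGP"), ("GR", "RGR")):
            p = self.ck_means[trait] * self.baseline_dc(dc)
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"expected DS germination probability for {trait} is {p:.3f}, "
                    "outside [0, 1]; adjust ck_means or stress parameters")

    def baseline_dc(self, dc_column: str) -> float:
        """Expected DC of a trait at latent score 0, before clamping."""
        return 1.0 - self.stress_severity * self.trait_sensitivity[dc_column]

    def with_seed(self, rng_seed: int) -> "SimConfig":
        return replace(self, rng_seed=rng_seed)


def _thin_counts(rng: np.random.Generator, n_sown: int,
                 targets: np.ndarray) -> np.ndarray:
    """Draw a monotone cumulative count trajectory.

    ``targets`` are cumulative germination fractions per recording day;
    increments are binomial draws from the seeds still ungerminated, so
    counts are non-decreasing and bounded by ``n_sown`` by construction.
    """
    targets = np.clip(np.maximum.accumulate(targets), 0.0, 1.0)
    counts = np.empty(targets.shape, dtype=int)
    g = 0
    prev = 0.0
    for d, p in enumerate(targets):
        remaining = n_sown - g
        cond = 0.0 if prev >= 1.0 else (p - prev) / (1.0 - prev)
        g += rng.binomial(remaining, np.clip(cond, 0.0, 1.0))
        counts[d] = g
        prev = p
    return counts


def generate_screen(config: SimConfig) -> pd.DataFrame:
    """Generate a raw screen table for the configured design.

    Returns one row per (accession, biorep, treatment, techrep) with the
    measurement columns in :data:`RAW_COLUMNS`.  Deterministic for a
    given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_accessions
    tolerance = rng.normal(0.0, config.latent_sd, n)
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]

    rows: list[tuple] = []
    for b in range(1, config.n_bioreps + 1):
        # Accession-level control trait values for this biological
        # replicate (independent re-run of the screen).
        ck = {}
        for trait in ("AR", "FW", "HL", "RL"):
            ck[trait] = np.clip(
                rng.normal(config.ck_means[trait], config.ck_sds[trait], n),
                0.0, None)
        # Control seeds imbibing plain water always gain mass; keep the
        # accession-level AR clear of zero so roll-level measurement
        # noise cannot push a control mean negative.
        ck["AR"] = np.clip(ck["AR"], 0.05, None)
        gr = np.clip(rng.normal(config.ck_means["GR"], config.ck_sds["GR"], n),
                     0.0, 1.0)
        gp = np.minimum(
            np.clip(rng.normal(config.ck_means["GP"], config.ck_sds["GP"], n),
                    0.0, 1.0),
            gr)
        g2f = np.clip(rng.normal(config.ck_day2_frac, 0.03, n), 0.0, 1.0)
        g2f = np.minimum(g2f, gp)
        g4f = gp + config.day4_progress * (gr - gp)

        # Replicate-level DC realizations: baseline + loading * latent
        # score + noise, clamped to the supported DC range.
        dc = {}
        for col in DC_COLUMNS:
            raw = (config.baseline_dc(col)
                   + config.trait_loadings[col] * tolerance
                   + rng.normal(0.0, config.noise_sd, n))
            dc[col] = np.clip(raw, 0.0, config.dc_clip)

        for i in range(n):
            ck_targets = np.array([g2f[i], gp[i], g4f[i], gr[i]])
            ds_targets = np.clip(
                ck_targets * np.array([dc["RDT"][i], dc["RGP"][i],
                                       dc["RDT"][i], dc["RGR"][i]]),
                0.0, 1.0)
            for treatment in ("CK", "DS"):
                if treatment == "CK":
                    targets = ck_targets
                    ar = ck["AR"][i]
                    fw, hl, rl = ck["FW"][i], ck["HL"][i], ck["RL"][i]
                else:
                    targets = ds_targets
                    ar = ck["AR"][i] * dc["RAR"][i]
                    fw = ck["FW"][i] * dc["RFW"][i]
                    hl = ck["HL"][i] * dc["RHL"][i]
                    rl = ck["RL"][i] * dc["RRL"][i]
                for tr in range(1, config.n_techreps + 1):
                    m0 = max(rng.normal(0.55, 0.03), 1e-3)
                    m20 = m0 * (1.0 + ar + rng.normal(0.0, 0.01))
                    counts = _thin_counts(rng, config.seeds_per_roll, targets)
                    if counts[-1] == 0:
                        fw_t = sl_t = rl_t = 0.0
                    else:
                        jitter = rng.normal(1.0, 0.03, 3).clip(0.0)
                        fw_t = fw * jitter[0]
                        hl_t = hl * jitter[1]
                        rl_t = rl * jitter[2]
                        sl_t = hl_t + rl_t
                    rows.append((accessions[i], b, treatment, tr,
                                 m0, m20, config.seeds_per_roll,
                                 *counts, fw_t, sl_t, rl_t, tolerance[i]))

    table = pd.DataFrame(rows, columns=RAW_COLUMNS)
    _assert_valid(table)
    return table


def _assert_valid(table: pd.DataFrame) -> None:
    """Internal consistency checks on every generated table."""
    counts = table[["g2", "g3", "g4", "g7"]].to_numpy()
    if (np.diff(counts, axis=1) < 0).any():
        raise AssertionError("non-monotone germination trajectory generated")
    if (counts[:, -1] > table["n_sown"].to_numpy()).any():
        raise AssertionError("germinated count exceeds seeds sown")
    if (table["m0"] <= 0).any():
        raise AssertionError("non-positive dry seed mass generated")
    if (table["sl"] < table["rl"]).any() or (table["rl"] < 0).any():
        raise AssertionError("seedling/root length inconsistency generated")


def drop_hidden(table: pd.DataFrame) -> pd.DataFrame:
    """Return the table without simulator-internal columns."""
    return table.drop(columns=[c for c in HIDDEN_COLUMNS if c in table])


def true_tolerance(table: pd.DataFrame) -> pd.Series:
    """Per-accession latent tolerance (test use only)."""
    return table.groupby("accession", sort=True)["true_tolerance"].first()


def write_screen(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_screen(path, keep_hidden: bool = False) -> pd.DataFrame:
    table = pd.read_csv(path)
    return table if keep_hidden else drop_hidden(table)
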