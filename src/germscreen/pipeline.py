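"""End-to-end orchestration: raw screen table → evaluation reports.

Runs traits → descriptive tables → PCA → D/WDC/CDC evaluation →
grade classification → stepwise models → cross-replicate BLUP, writing
one CSV per stage plus a structured run log.  Every stage is also
runnable standalone through the library functions it wraps.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blup as blup_mod
from . import classify as classify_mod
from . import descriptive, evaluation, regression, traits
from .pca import pca_table
from .simulate import DC_COLUMNS, TRAITS, drop_hidden
from .traits import ValidationError

log = logging.getLogger("germscreen")

_DT_MODES = ("sum", "mean")
_NORMALIZATIONS = ("minmax", "none")
_DELTA_SCOPES = ("global", "per_comparison")
_RETAIN_POLICIES = ("fixed", "cumulative", "kaiser")
_BLUP_TARGETS = ("per_rep", "rep_mean")


@dataclass
class PipelineConfig:
    """Options for a full pipeline run; flags mirror these one-to-one."""

    input_path: str = "screen.csv"
    output_dir: str = "results"
    dt_mode: str = "sum"
    pca_retain: str = "fixed"
    pca_k: int = 3
    pca_cum_threshold: float = 85.0
    gra_rho: float = 0.5
    gra_normalization: str = "minmax"
    gra_delta_scope: str = "global"
    cluster_k: int = 5
    stepwise_entry_p: float = 0.05
    stepwise_removal_p: float = 0.10
    blup_error_against: str = "per_rep"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [("dt_mode", _DT_MODES), ("pca_retain", _RETAIN_POLICIES),
                  ("gra_normalization", _NORMALIZATIONS),
                  ("gra_delta_scope", _DELTA_SCOPES),
                  ("blup_error_against", _BLUP_TARGETS)]
        for name, allowed in checks:
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"{name}={getattr(self, name)!r} not in {allowed}")
        if not 0 < self.gra_rho <= 1:
            raise ValueError("gra_rho must lie in (0, 1]")
        if self.cluster_k < 1 or self.pca_k < 1:
            raise ValueError("cluster_k and pca_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def validate_input(table: pd.DataFrame) -> list[str]:
    """Validate a raw screen table; returns a list of violations.

    Checks column presence, germination-count monotonicity, dry-mass
    positivity, length consistency and CK/DS treatment completeness.
    Each violation names the offending rows.
    """
    violations: list[str] = []
    required = ["accession", "biorep", "treatment", "techrep", "m0", "m20",
                "n_sown", "g2", "g3", "g4", "g7", "fw", "sl", "rl"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        violations.append(f"missing columns: {missing}")
        return violations

    def where(mask) -> str:
        rows = table.loc[mask, ["accession", "biorep", "treatment", "techrep"]]
        return "; ".join(
            f"(accession={r.accession}, biorep={r.biorep}, "
            f"treatment={r.treatment}, techrep={r.techrep})"
            for r in rows.itertuples())

    counts = table[["g2", "g3", "g4", "g7"]].to_numpy()
    bad = (np.diff(counts, axis=1) < 0).any(axis=1) | (table["g2"] < 0)
    if bad.any():
        violations.append(f"non-monotone germination counts: {where(bad)}")
    over = table["g7"] > table["n_sown"]
    if over.any():
        violations.append(f"germinated count exceeds seeds sown: {where(over)}")
    nonpos = table["m0"] <= 0
    if nonpos.any():
        violations.append(f"non-positive dry mass m0: {where(nonpos)}")
    shorter = table["sl"] < table["rl"]
    if shorter.any():
        violations.append(f"seedling length below root length: {where(shorter)}")
    neg = (table[["rl", "fw"]] < 0).any(axis=1)
    if neg.any():
        violations.append(f"negative length or weight: {where(neg)}")

    for (acc, rep), grp in table.groupby(["accession", "biorep"]):
        missing_trt = {"CK", "DS"} - set(grp["treatment"])
        if missing_trt:
            violations.append(
                f"accession {acc} biorep {rep} lacks treatment(s) "
                f"{sorted(missing_trt)}")
    return violations


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, **kwargs)
    log.info("wrote %s (%d rows)", path.name, len(df))


def run_pipeline(config: PipelineConfig,
                 raw: pd.DataFrame | None = None) -> dict:
    """Execute every stage and write all report CSVs.

    Returns a bundle dict with the per-replicate stage outputs and the
    run log entries.  ``raw`` can be passed directly (e.g. fresh from
    the simulator); otherwise ``config.input_path`` is read.
    """
    if raw is None:
        raw = pd.read_csv(config.input_path)
    raw = drop_hidden(raw)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    violations = validate_input(raw)
    if violations:
        raise ValidationError(
            "input validation failed:\n" + "\n".join(violations))

    runlog: list[dict] = []
    bioreps = sorted(raw["biorep"].unique())
    bundle: dict = {"bioreps": {}, "log": runlog}
    d_by_rep = {}

    for rep in bioreps:
        stage = {"biorep": rep}
        trait_tab = traits.trait_table(raw[raw["biorep"] == rep],
                                       dt_mode=config.dt_mode)
        _write(trait_tab, outdir / f"traits_rep{rep}.csv", index=False)

        summaries = []
        for trt in ("CK", "DS"):
            sub = trait_tab[trait_tab["treatment"] == trt]
            s = descriptive.summary_table(sub[list(TRAITS)])
            s.insert(0, "treatment", trt)
            summaries.append(s)
        summary = pd.concat(summaries)
        change = pd.DataFrame({
            t: descriptive.treatment_change(
                summary.loc[summary["treatment"] == "CK", "mean"][t],
                summary.loc[summary["treatment"] == "DS", "mean"][t])
            for t in TRAITS}).T
        change.index.name = "trait"
        _write(summary, outdir / f"trait_summary_rep{rep}.csv")
        _write(change, outdir / f"treatment_change_rep{rep}.csv")

        dc = traits.build_dc_matrix(raw, rep, dt_mode=config.dt_mode)
        if dc.attrs["excluded"]:
            log.warning("rep %s: excluded accessions without both "
                        "treatments: %s", rep, dc.attrs["excluded"])
        _write(dc, outdir / f"dc_matrix_rep{rep}.csv")
        dc_summary = descriptive.summary_table(dc)
        _write(dc_summary, outdir / f"dc_summary_rep{rep}.csv")
        r, p, flags = descriptive.dc_correlations(dc)
        _write(r, outdir / f"dc_correlations_rep{rep}.csv")
        _write(descriptive.correlations_long(r, p, flags),
               outdir / f"dc_correlations_long_rep{rep}.csv", index=False)

        ev = evaluation.evaluate(
            dc, rho=config.gra_rho,
            normalization=config.gra_normalization,
            delta_scope=config.gra_delta_scope,
            retain=config.pca_retain, k=config.pca_k)
        _write(pca_table(ev.pca), outdir / f"pca_rep{rep}.csv")
        _write(ev.pca.scores, outdir / f"pca_scores_rep{rep}.csv")
        scores = ev.scores.copy()
        for col in ("D", "WDC", "CDC"):
            scores[f"{col}_rank"] = scores[col].rank(
                ascending=False, method="min").astype(int)
        _write(scores, outdir / f"evaluation_scores_rep{rep}.csv")
        ranking = evaluation.indicator_ranking(
            dc, ev.scores, rho=config.gra_rho,
            normalization=config.gra_normalization,
            delta_scope=config.gra_delta_scope)
        _write(ranking, outdir / f"indicator_ranking_rep{rep}.csv")

        grades = classify_mod.classify_grades(ev.scores["D"],
                                              k=config.cluster_k)
        _write(grades.assignments, outdir / f"grades_rep{rep}.csv",
               index=False)
        _write(grades.summary, outdir / f"grade_summary_rep{rep}.csv",
               index=False)

        models = []
        accuracy_frames = []
        for resp in ("D", "WDC", "CDC"):
            m = regression.stepwise_fit(
                ev.scores[resp], dc.loc[ev.scores.index, list(DC_COLUMNS)],
                entry_p=config.stepwise_entry_p,
                removal_p=config.stepwise_removal_p, response_name=resp)
            models.append({"response": resp, "equation": m.equation(),
                           "r": m.r, "r_squared": m.r_squared,
                           "n_terms": len(m.terms)})
            if resp == "D":
                acc = regression.prediction_accuracy(
                    ev.scores["D"], m.predict(dc.loc[ev.scores.index]))
                acc.insert(0, "accession", acc.index)
                accuracy_frames.append(acc)
                stage["d_model"] = m
                stage["accuracy_min"] = acc.attrs["min"]
                stage["accuracy_mean"] = acc.attrs["mean"]
        rcorr, _, _ = regression.score_correlations(ev.scores)
        _write(pd.DataFrame(models), outdir / f"stepwise_models_rep{rep}.csv",
               index=False)
        _write(rcorr, outdir / f"score_correlations_rep{rep}.csv")
        _write(accuracy_frames[0],
               outdir / f"prediction_accuracy_rep{rep}.csv", index=False)

        stage.update({"traits": trait_tab, "dc": dc, "evaluation": ev,
                      "grades": grades, "correlations": r})
        bundle["bioreps"][rep] = stage
        d_by_rep[rep] = ev.scores["D"]
        runlog.append({"stage": f"rep{rep}", "accessions": len(dc),
                       "excluded": dc.attrs["excluded"]})

    if len(bioreps) >= 2:
        d_table = pd.DataFrame(d_by_rep).dropna()
        d_table.columns = [f"rep{c}" for c in d_table.columns]
        blup_res = blup_mod.fit_blup(d_table)
        err = blup_mod.prediction_error(
            pd.Series(blup_res.predictions["blup_d"].to_numpy(),
                      index=d_table.index),
            d_table, against=config.blup_error_against)
        _write(blup_res.predictions, outdir / "blup_predictions.csv",
               index=False)
        bundle["blup"] = blup_res
        bundle["blup_error_pct"] = err
        runlog.append({"stage": "blup", "accessions": len(d_table),
                       "repeatability": blup_res.repeatability,
                       "mean_prediction_error_pct": err})

    pd.DataFrame(runlog).to_csv(outdir / "run_log.csv", index=False)
    return bundle


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s:%(levelname)s] %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
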