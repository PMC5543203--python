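"""End-to-end validation pipeline with REMARK-style flow accounting.

Stages: simulate a cohort, score the surgical and month-1 specimens by the
SOP for two blinded raters, compute concordance at the 2.7% and 10%
cut-points, classify PEPI status, and run Kaplan-Meier / log-rank analyses
per stratum plus the ROC cut-point derivation on baseline Ki-67. All outputs
are deterministic for a fixed seed and carry seed + config-hash provenance.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._seeds import child_rng
from .concordance import agreement_stats, bland_altman, correlations
from .cutpoint import roc_curve, youden_j_at
from .errors import FlowConservationError, UndefinedScoreError
from .io import provenance, write_json
from .pepi import classify_cohort, modified_pepi0
from .image_scoring import SOPConfig, sop_score
from .survival import km_estimate, km_median, logrank, median_followup
from .synthetic import (
    CohortConfig,
    DEFAULT_SCENARIO_PROBS,
    HistologyConfig,
    generate_cohort,
    sample_histology_config,
)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_cases: int = 200
    cohort: CohortConfig = field(default_factory=CohortConfig)
    histology: HistologyConfig = field(default_factory=HistologyConfig)
    scenario_probs: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIO_PROBS))
    sop: SOPConfig = field(default_factory=SOPConfig)
    sigma_field: float = 0.20
    fields_per_case: int = 3
    cutpoints: tuple[float, float] = (2.7, 10.0)

    def __post_init__(self):
        for cp in self.cutpoints:
            if not 0.0 < cp < 100.0:
                raise ValueError("cut-points must lie in (0, 100)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig(**d["cohort"])
        if "histology" in d:
            d["histology"] = HistologyConfig(**d["histology"])
        if "sop" in d:
            d["sop"] = SOPConfig(**d["sop"])
        if "cutpoints" in d:
            d["cutpoints"] = tuple(d["cutpoints"])
        return cls(**d)


# ---------------------------------------------------------------------------
# REMARK flow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageFlow:
    name: str
    n_in: int
    exclusions: tuple[tuple[str, int], ...]
    n_out: int


@dataclass(frozen=True)
class RemarkFlow:
    stages: tuple[StageFlow, ...]


def remark_flow(stages) -> RemarkFlow:
    """Validate conservation (in = out + excluded) at every stage."""
    checked = []
    for s in stages:
        stage = StageFlow(
            name=s.name if isinstance(s, StageFlow) else s["name"],
            n_in=s.n_in if isinstance(s, StageFlow) else s["n_in"],
            exclusions=tuple(
                tuple(e) for e in (s.exclusions if isinstance(s, StageFlow) else s["exclusions"])
            ),
            n_out=s.n_out if isinstance(s, StageFlow) else s["n_out"],
        )
        n_excl = sum(c for _, c in stage.exclusions)
        if stage.n_in != stage.n_out + n_excl:
            raise FlowConservationError(
                f"stage {stage.name!r}: {stage.n_in} in != {stage.n_out} out "
                f"+ {n_excl} excluded"
            )
        checked.append(stage)
    return RemarkFlow(stages=tuple(checked))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _generate_case_maps(cfg, theta, rng, n_fields):
    from .synthetic import generate_cellmap

    maps = []
    for _ in range(n_fields):
        seed = int(rng.integers(0, 2**31 - 1))
        maps.append(generate_cellmap(replace(cfg, theta=theta), seed=seed))
    return maps


def score_specimen(
    cohort: pd.DataFrame, column: str, specimen: str, config: PipelineConfig
) -> tuple[pd.DataFrame, StageFlow]:
    """Two-rater SOP scoring of one specimen column for every case.

    With ``sigma_field == 0`` both raters share one stream, hence identical
    fields and identical scores (the zero-rater-noise limit).
    """
    rows = []
    n_excluded = 0
    for _, case in cohort.iterrows():
        case_id = case["case_id"]
        theta = float(np.clip(case[column] / 100.0, 0.0, 1.0))
        rng_case = child_rng(config.seed, "pipeline", specimen, case_id)
        hist_cfg, scenario = sample_histology_config(
            config.histology, rng_case, config.scenario_probs
        )
        for rater in ("a", "b"):
            stream = rater if config.sigma_field > 0 else "shared"
            rng = child_rng(config.seed, "pipeline", specimen, case_id, "rater", stream)
            if 0.0 < theta < 1.0 and config.sigma_field > 0:
                theta_r = float(expit(logit(theta) + rng.normal(0.0, config.sigma_field)))
            else:
                theta_r = theta
            maps = _generate_case_maps(hist_cfg, theta_r, rng, config.fields_per_case)
            vpc_seed = int(rng.integers(0, 2**31 - 1))
            try:
                res = sop_score(
                    case_id, maps, hist_cfg.stain_contrast, config.sop, seed=vpc_seed
                )
            except UndefinedScoreError:
                n_excluded += 1
                rows.append(
                    {
                        "case_id": case_id,
                        "rater": rater,
                        "specimen": specimen,
                        "scenario": scenario,
                        "route": "NONE",
                        "flags": "no_tumor_cells",
                        "percent": np.nan,
                        "total": 0,
                        "positive": 0,
                        "fields_used": 0,
                        "exhaustive": False,
                    }
                )
                continue
            rows.append(
                {
                    "case_id": case_id,
                    "rater": rater,
                    "specimen": specimen,
                    "scenario": scenario,
                    "route": res.route,
                    "flags": "|".join(res.flags),
                    "percent": res.score.percent,
                    "total": res.score.total,
                    "positive": res.score.positive,
                    "fields_used": res.score.fields_used,
                    "exhaustive": res.score.exhaustive,
                }
            )
    scores = pd.DataFrame(rows)
    flow = StageFlow(
        name=f"sop_{specimen}",
        n_in=2 * len(cohort),
        exclusions=(("no_tumor_cells", n_excluded),) if n_excluded else (),
        n_out=2 * len(cohort) - n_excluded,
    )
    return scores, flow


def pair_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Pivot long per-rater scores into case_id / score_a / score_b pairs."""
    wide = scores.pivot(index="case_id", columns="rater", values="percent")
    wide = wide.rename(columns={"a": "score_a", "b": "score_b"}).reset_index()
    return wide[["case_id", "score_a", "score_b"]].sort_values("case_id").reset_index(drop=True)


def _stats_row(pairs: pd.DataFrame, cutpoint: float, method: str, sample_set: str) -> dict:
    complete = pairs.dropna(subset=["score_a", "score_b"])
    stats = agreement_stats(complete, cutpoint)
    pearson, spearman = correlations(complete)
    ba = bland_altman(complete)
    return {
        "sample_set": sample_set,
        "cutpoint": cutpoint,
        "method": method,
        "n": stats.n,
        "ppa": None if stats.ppa is None else {
            "estimate": stats.ppa.estimate,
            "lower": stats.ppa.lower,
            "upper": stats.ppa.upper,
            "successes": stats.ppa.successes,
            "trials": stats.ppa.trials,
        },
        "npa": None if stats.npa is None else {
            "estimate": stats.npa.estimate,
            "lower": stats.npa.lower,
            "upper": stats.npa.upper,
            "successes": stats.npa.successes,
            "trials": stats.npa.trials,
        },
        "kappa": None if stats.kappa is None else {
            "estimate": stats.kappa.estimate,
            "lower": stats.kappa.lower,
            "upper": stats.kappa.upper,
        },
        "pearson": pearson,
        "spearman": spearman,
        "bland_altman_bias": ba.bias,
        "bland_altman_loa": [ba.loa_lower, ba.loa_upper],
    }


def _km_payload(times, events) -> dict:
    curve = km_estimate(times, events)
    return {
        "n": curve.n,
        "n_events": int(np.asarray(events, bool).sum()),
        "times": curve.times,
        "n_at_risk": curve.n_at_risk,
        "survival": curve.survival,
        "median": km_median(curve),
    }


def _survival_analysis(cohort: pd.DataFrame, mask: pd.Series, name: str) -> dict:
    times = cohort["rfs_months"].to_numpy(float)
    events = cohort["relapse_event"].to_numpy(bool)
    mask = np.asarray(mask, dtype=bool)
    out = {
        "stratum": name,
        "group_true": _km_payload(times[mask], events[mask]) if mask.any() else None,
        "group_false": _km_payload(times[~mask], events[~mask]) if (~mask).any() else None,
    }
    if mask.any() and (~mask).any():
        lr = logrank(times, events, mask)
        out["logrank"] = {"statistic": lr.statistic, "p_value": lr.p_value, "df": lr.df}
    else:
        out["logrank"] = None
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full validation pipeline and write its artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def log(msg):
        print(f"[ki67 {time.time() - t0:7.1f}s] {msg}", file=sys.stderr)

    stages = []
    cohort_cfg = replace(config.cohort, n_cases=config.n_cases, seed=config.seed)
    cohort = generate_cohort(cohort_cfg)
    stages.append(StageFlow("cohort", config.n_cases, (), config.n_cases))
    cohort.to_csv(outdir / "cohort.csv", index=False)
    log(f"simulated cohort of {len(cohort)} cases")

    cp_pepi, cp_early = config.cutpoints
    concordance_rows = []
    score_tables = {}
    for specimen, column, cutpoint in (
        ("surgical", "ki67_surgical", cp_pepi),
        ("month1", "ki67_month1", cp_early),
    ):
        scores, flow = score_specimen(cohort, column, specimen, config)
        stages.append(flow)
        scores.to_csv(outdir / f"sop_{specimen}.csv", index=False)
        score_tables[specimen] = scores
        pairs = pair_scores(scores)
        n_pairs = len(pairs.dropna(subset=["score_a", "score_b"]))
        stages.append(
            StageFlow(
                f"concordance_{specimen}",
                len(cohort),
                (("incomplete_pair", len(cohort) - n_pairs),)
                if n_pairs < len(cohort)
                else (),
                n_pairs,
            )
        )
        concordance_rows.append(
            _stats_row(pairs, cutpoint, "Ki-67 SOP", f"synthetic {specimen}")
        )
        log(f"scored {specimen} specimens (n pairs = {n_pairs})")

    # PEPI classification: cohort truth plus each rater's surgical scores
    pepi_truth = classify_cohort(cohort)
    rater_calls = {}
    surgical = score_tables["surgical"]
    for rater in ("a", "b"):
        sub = surgical[surgical["rater"] == rater].set_index("case_id")["percent"]
        rater_calls[rater] = pd.array(
            [
                modified_pepi0(r["pT"], r["nodal"], sub.get(r["case_id"], np.nan))
                for _, r in cohort.iterrows()
            ],
            dtype="boolean",
        )
    pepi_out = pepi_truth.copy()
    pepi_out["modified_pepi0_rater_a"] = rater_calls["a"]
    pepi_out["modified_pepi0_rater_b"] = rater_calls["b"]
    pepi_out.to_csv(outdir / "pepi.csv", index=False)
    log("classified PEPI status")

    survival_results = [
        _survival_analysis(
            cohort, pepi_truth["modified_pepi0"].fillna(False).to_numpy(bool),
            "modified_pepi0_truth",
        ),
        _survival_analysis(
            cohort, rater_calls["a"].fillna(False).to_numpy(bool), "modified_pepi0_rater_a"
        ),
        _survival_analysis(
            cohort, rater_calls["b"].fillna(False).to_numpy(bool), "modified_pepi0_rater_b"
        ),
        _survival_analysis(
            cohort, (cohort["ki67_month1"] > cp_early).to_numpy(bool), "month1_gt10_truth"
        ),
    ]
    followup = median_followup(
        cohort["rfs_months"].to_numpy(float), cohort["relapse_event"].to_numpy(bool)
    )
    log("survival analyses done")

    roc = roc_curve(
        cohort["ki67_baseline"].to_numpy(float),
        (cohort["luminal_label"] == "B").to_numpy(bool),
    )
    roc_summary = {
        "auc": roc.auc,
        "youden_cut": roc.youden_cut,
        "j_at_10": youden_j_at(roc, 10.0),
        "j_at_14": youden_j_at(roc, 14.0),
        "n": int(len(cohort)),
    }
    log("ROC cut-point derivation done")

    triage = {
        specimen: float(
            (tbl["route"] == "VPC").sum() / max((tbl["route"] != "NONE").sum(), 1)
        )
        for specimen, tbl in score_tables.items()
    }

    flow = remark_flow(stages)
    summary = {
        "provenance": provenance(config.seed, config),
        "n_cases": config.n_cases,
        "cutpoints": list(config.cutpoints),
        "concordance": concordance_rows,
        "survival": survival_results,
        "median_followup_months": followup,
        "roc": roc_summary,
        "triage_rate": triage,
        "flow": flow,
    }
    write_json(outdir / "concordance.json", concordance_rows)
    write_json(outdir / "survival.json", {"analyses": survival_results,
                                          "median_followup_months": followup})
    write_json(outdir / "roc.json", roc_summary)
    write_json(outdir / "flow.json", flow)
    write_json(outdir / "summary.json", summary)
    log("pipeline complete")
    return summary
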