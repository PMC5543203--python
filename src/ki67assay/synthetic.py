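"""Synthetic histology fields, patient cohorts and paired rater scores.

Cell maps hold ground-truth nuclei (class, position, Ki-67 status) for a single
microscopic field; :func:`render_field` turns a map into an RGB image using the
hematoxylin/DAB Beer-Lambert color model, so the image-analysis stand-in can be
validated against known truth. Cohorts carry staging, ER, serial Ki-67 values
and relapse-free survival drawn from per-stratum exponential hazards.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from skimage.color import hed2rgb
from skimage.draw import disk as _disk

from ._seeds import child_rng

CELL_CLASSES = (
    "invasive_tumor",
    "dcis",
    "lymphocyte",
    "fibroblast",
    "endothelial",
    "necrotic_debris",
)

# Nuclear radius range (pixels) per cell class. Invasive tumor and DCIS nuclei
# are large epithelial nuclei; the stromal/inflammatory classes are small, which
# is what the detector's size filter exploits.
CLASS_RADIUS = {
    "invasive_tumor": (4.0, 7.0),
    "dcis": (4.0, 6.5),
    "lymphocyte": (2.2, 3.0),
    "fibroblast": (2.4, 3.2),
    "endothelial": (2.2, 3.0),
    "necrotic_debris": (1.8, 2.8),
}

#: Minimum DAB optical density of a Ki-67-positive nucleus.
POSITIVE_OD_FLOOR = 0.6
_POSITIVE_DAB = (0.7, 1.5)
_NEGATIVE_DAB = (0.0, 0.15)
#: Hematoxylin counterstain OD applied to every nucleus.
HEMATOXYLIN_OD = 0.85


@dataclass(frozen=True)
class Nucleus:
    """One nucleus: position, size, class, Ki-67 status and DAB density."""

    id: int
    center: tuple[float, float]  # (x, y), pixels, origin top-left
    radius: float
    cell_class: str
    ki67_positive: bool
    stain_od: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if not 0.0 <= self.stain_od <= 3.0:
            raise ValueError("stain_od must be in [0, 3]")
        if self.ki67_positive and self.stain_od < POSITIVE_OD_FLOOR:
            raise ValueError("positive nuclei must have stain_od >= floor")


@dataclass
class CellMap:
    """Ground truth for one field; ``degenerate`` flags an empty tumor compartment."""

    width: int
    height: int
    microns_per_pixel: float
    nuclei: list[Nucleus]
    seed: int
    degenerate: bool = False

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        for n in self.nuclei:
            x, y = n.center
            if not (0 <= x < self.width and 0 <= y < self.height):
                raise ValueError(f"nucleus {n.id} center outside field extent")
        has_tumor = any(n.cell_class == "invasive_tumor" for n in self.nuclei)
        if self.degenerate == has_tumor:
            raise ValueError("degenerate flag inconsistent with tumor content")

    @property
    def tumor_nuclei(self) -> list[Nucleus]:
        return [n for n in self.nuclei if n.cell_class == "invasive_tumor"]

    @property
    def true_ki67_fraction(self) -> float | None:
        """Positive fraction over invasive tumor only; None when degenerate."""
        tumor = self.tumor_nuclei
        if not tumor:
            return None
        return sum(n.ki67_positive for n in tumor) / len(tumor)

    @property
    def area_mm2(self) -> float:
        return (self.width * self.microns_per_pixel / 1000.0) * (
            self.height * self.microns_per_pixel / 1000.0
        )

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "microns_per_pixel": self.microns_per_pixel,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "nuclei": [
                {
                    "id": n.id,
                    "x": n.center[0],
                    "y": n.center[1],
                    "radius": n.radius,
                    "cell_class": n.cell_class,
                    "ki67_positive": bool(n.ki67_positive),
                    "stain_od": n.stain_od,
                }
                for n in self.nuclei
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellMap":
        nuclei = [
            Nucleus(
                id=int(r["id"]),
                center=(float(r["x"]), float(r["y"])),
                radius=float(r["radius"]),
                cell_class=r["cell_class"],
                ki67_positive=bool(r["ki67_positive"]),
                stain_od=float(r["stain_od"]),
            )
            for r in d["nuclei"]
        ]
        return cls(
            width=int(d["width"]),
            height=int(d["height"]),
            microns_per_pixel=float(d["microns_per_pixel"]),
            nuclei=nuclei,
            seed=int(d["seed"]),
            degenerate=bool(d["degenerate"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "CellMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class HistologyConfig:
    """Parameters of one simulated field scenario."""

    tumor_density: float = 1700.0  # invasive tumor cells per mm^2
    confounder_prevalences: dict = field(
        default_factory=lambda: {
            "dcis": 0.03,
            "lymphocyte": 0.08,
            "fibroblast": 0.10,
            "endothelial": 0.04,
            "necrotic_debris": 0.02,
        }
    )
    lymphocyte_infiltration_level: float = 0.0
    stroma_streaming_prob: float = 0.0
    fibroblast_stained_fraction: float = 0.02
    stain_contrast: float = 1.0
    width: int = 512
    height: int = 512
    microns_per_pixel: float = 0.5
    theta: float = 0.10  # target Ki-67 positive fraction

    def validate(self) -> None:
        if self.tumor_density < 0:
            raise ValueError("tumor_density must be >= 0")
        for name, p in (
            ("lymphocyte_infiltration_level", self.lymphocyte_infiltration_level),
            ("stroma_streaming_prob", self.stroma_streaming_prob),
            ("fibroblast_stained_fraction", self.fibroblast_stained_fraction),
            ("theta", self.theta),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.stain_contrast <= 1.0:
            raise ValueError("stain_contrast must be in (0, 1]")
        for c, v in self.confounder_prevalences.items():
            if c not in CELL_CLASSES or c == "invasive_tumor":
                raise ValueError(f"bad confounder class {c!r}")
            if v < 0:
                raise ValueError("prevalences must be >= 0")


def generate_cellmap(config: HistologyConfig, seed: int) -> CellMap:
    """Draw one field: tumor Ki-67 flags are i.i.d. Bernoulli(theta).

    Placement uses a jittered occupancy grid, giving near-uniform positions
    with no overlapping nuclei. Zero realized tumor cells yields a map with
    ``degenerate=True`` rather than a silent empty score downstream.
    """
    config.validate()
    rng = child_rng(seed, "cellmap")

    area = (config.width * config.microns_per_pixel / 1000.0) * (
        config.height * config.microns_per_pixel / 1000.0
    )
    expected_tumor = config.tumor_density * area
    n_tumor = int(rng.poisson(expected_tumor))

    rates = dict(config.confounder_prevalences)
    rates["lymphocyte"] = rates.get("lymphocyte", 0.0) + 3.0 * config.lymphocyte_infiltration_level
    counts = {c: int(rng.poisson(expected_tumor * r)) for c, r in rates.items()}

    classes: list[str] = ["invasive_tumor"] * n_tumor
    for c in sorted(counts):
        classes += [c] * counts[c]
    total = len(classes)

    max_r = max(hi for _, hi in CLASS_RADIUS.values())
    cell = int(math.ceil(2 * max_r + 2))
    nx, ny = config.width // cell, config.height // cell
    n_slots = nx * ny
    if total > n_slots:
        raise ValueError(
            f"field too small: {total} nuclei requested, {n_slots} placement slots"
        )

    streaming = rng.random() < config.stroma_streaming_prob
    slot_ids = np.arange(n_slots)
    if streaming and ny >= 3:
        # confine tumor to the central third of rows; confounders anywhere
        rows = slot_ids // nx
        band = slot_ids[(rows >= ny // 3) & (rows < 2 * ny // 3)]
        if n_tumor <= band.size:
            tumor_slots = rng.choice(band, size=n_tumor, replace=False)
            rest = np.setdiff1d(slot_ids, tumor_slots)
            other_slots = rng.choice(rest, size=total - n_tumor, replace=False)
            slots = np.concatenate([tumor_slots, other_slots])
        else:
            slots = rng.choice(slot_ids, size=total, replace=False)
    else:
        slots = rng.choice(slot_ids, size=total, replace=False)

    radii = np.empty(total)
    for c in set(classes):
        idx = [i for i, cc in enumerate(classes) if cc == c]
        lo, hi = CLASS_RADIUS[c]
        radii[idx] = rng.uniform(lo, hi, size=len(idx))

    margin = cell / 2.0 - radii - 0.5
    margin = np.clip(margin, 0.0, None)
    cx = (slots % nx + 0.5) * cell + rng.uniform(-1, 1, total) * margin
    cy = (slots // nx + 0.5) * cell + rng.uniform(-1, 1, total) * margin
    cx = np.clip(cx, 0.0, config.width - 1e-6)
    cy = np.clip(cy, 0.0, config.height - 1e-6)

    positive = np.zeros(total, dtype=bool)
    is_tumor_like = np.array([c in ("invasive_tumor", "dcis") for c in classes], dtype=bool)
    positive[is_tumor_like] = rng.random(int(is_tumor_like.sum())) < config.theta
    is_fibro = np.array([c == "fibroblast" for c in classes], dtype=bool)
    positive[is_fibro] = rng.random(int(is_fibro.sum())) < config.fibroblast_stained_fraction

    od = rng.uniform(*_NEGATIVE_DAB, size=total)
    od[positive] = rng.uniform(*_POSITIVE_DAB, size=int(positive.sum()))

    nuclei = [
        Nucleus(
            id=i,
            center=(float(cx[i]), float(cy[i])),
            radius=float(radii[i]),
            cell_class=classes[i],
            ki67_positive=bool(positive[i]),
            stain_od=float(od[i]),
        )
        for i in range(total)
    ]
    return CellMap(
        width=config.width,
        height=config.height,
        microns_per_pixel=config.microns_per_pixel,
        nuclei=nuclei,
        seed=seed,
        degenerate=(n_tumor == 0),
    )


def render_field(cellmap: CellMap, stain_contrast: float = 1.0) -> np.ndarray:
    """Render a map to an RGB uint8 image via the HED Beer-Lambert model.

    Every nucleus gets the hematoxylin counterstain; DAB density is the
    nucleus' ``stain_od`` scaled by ``stain_contrast``. Deterministic: the
    same map and contrast always give a bit-identical image.
    """
    if stain_contrast <= 0:
        raise ValueError("stain_contrast must be > 0")
    h_od = np.zeros((cellmap.height, cellmap.width))
    d_od = np.zeros_like(h_od)
    for n in cellmap.nuclei:
        rr, cc = _disk((n.center[1], n.center[0]), n.radius, shape=h_od.shape)
        h_od[rr, cc] = HEMATOXYLIN_OD
        d_od[rr, cc] = n.stain_od * stain_contrast
    hed = np.stack([h_od, np.zeros_like(h_od), d_od], axis=-1)
    rgb = hed2rgb(hed)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# Field scenarios: the confounder mix that drives the SOP triage rate.
# ---------------------------------------------------------------------------

#: Default per-case probabilities of each complex-histology scenario; the
#: remainder is clean. Sums to 0.17, the target VPC triage rate.
DEFAULT_SCENARIO_PROBS = {
    "lymphocyte_rich": 0.06,
    "sparse_streaming": 0.05,
    "fibroblast_marking": 0.03,
    "faint_stain": 0.03,
}


def sample_histology_config(
    base: HistologyConfig,
    rng: np.random.Generator,
    scenario_probs: dict | None = None,
) -> tuple[HistologyConfig, str]:
    """Draw a per-case field scenario and the config realizing it."""
    probs = DEFAULT_SCENARIO_PROBS if scenario_probs is None else scenario_probs
    names = sorted(probs)
    p = np.array([probs[k] for k in names])
    if p.sum() > 1.0 + 1e-9:
        raise ValueError("scenario probabilities exceed 1")
    u = rng.random()
    edges = np.cumsum(p)
    scenario = "clean"
    for name, edge in zip(names, edges):
        if u < edge:
            scenario = name
            break
    if scenario == "clean":
        return base, scenario
    if scenario == "lymphocyte_rich":
        cfg = replace(base, lymphocyte_infiltration_level=float(rng.uniform(0.3, 0.6)))
    elif scenario == "sparse_streaming":
        cfg = replace(
            base,
            tumor_density=float(rng.uniform(10.0, 30.0)),
            stroma_streaming_prob=1.0,
        )
    elif scenario == "fibroblast_marking":
        prev = dict(base.confounder_prevalences)
        prev["fibroblast"] = 0.30
        cfg = replace(
            base,
            confounder_prevalences=prev,
            fibroblast_stained_fraction=float(rng.uniform(0.3, 0.6)),
        )
    elif scenario == "faint_stain":
        cfg = replace(base, stain_contrast=float(rng.uniform(0.10, 0.25)))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return cfg, scenario


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "case_id",
    "pT",
    "nodal",
    "er_allred",
    "luminal_label",
    "ki67_baseline",
    "ki67_month1",
    "ki67_surgical",
    "rfs_months",
    "relapse_event",
]


@dataclass(frozen=True)
class CohortConfig:
    """Mixture, suppression, hazard and censoring parameters for a cohort."""

    n_cases: int = 200
    # baseline Ki-67 (%) mixture: two lognormals; the B median of 20 puts the
    # density crossing -- hence the Youden-optimal cut -- at 10%.
    weight_a: float = 0.55
    meanlog_a: float = math.log(5.0)
    sdlog_a: float = 0.55
    meanlog_b: float = math.log(20.0)
    sdlog_b: float = 0.55
    # multiplicative on-treatment suppression of Ki-67 (surgical specimen);
    # month-1 values sit halfway on the log scale.
    suppression_meanlog_a: float = math.log(0.12)
    suppression_meanlog_b: float = math.log(0.45)
    suppression_sdlog: float = 0.5
    # monthly exponential relapse hazards per stratum
    hazard_modified_pepi0: float = 0.0
    hazard_le10: float = 0.002
    hazard_gt10: float = 0.008
    censoring_rate: float = 0.10  # probability of early loss to follow-up
    followup_range: tuple[float, float] = (48.0, 84.0)  # admin censoring, months
    p_pt: tuple[float, float, float, float] = (0.35, 0.45, 0.15, 0.05)
    p_n0: float = 0.60
    p_er_positive: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0.0 <= self.weight_a <= 1.0:
            raise ValueError("weight_a must be in [0, 1]")
        for h in (self.hazard_modified_pepi0, self.hazard_le10, self.hazard_gt10):
            if h < 0:
                raise ValueError("hazards must be >= 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if abs(sum(self.p_pt) - 1.0) > 1e-9:
            raise ValueError("pT probabilities must sum to 1")


def _case_hazard(cfg: CohortConfig, pt: int, nodal: str, ki67_surgical: float,
                 ki67_month1: float) -> float:
    if pt in (1, 2) and nodal == "N0" and ki67_surgical <= 2.7:
        return cfg.hazard_modified_pepi0
    return cfg.hazard_gt10 if ki67_month1 > 10.0 else cfg.hazard_le10


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort of case records with stratum-specific relapse hazards.

    Relapse times are exponential per stratum; a case is lost to follow-up
    early with probability ``censoring_rate`` and is otherwise followed to an
    administrative horizon drawn uniformly from ``followup_range``. With the
    default hazard of 0 for modified-PEPI-0 cases that stratum has no events.
    """
    config.validate()
    rng = child_rng(config.seed, "cohort")
    n = config.n_cases

    is_b = rng.random(n) >= config.weight_a
    baseline = np.where(
        is_b,
        rng.lognormal(config.meanlog_b, config.sdlog_b, n),
        rng.lognormal(config.meanlog_a, config.sdlog_a, n),
    )
    baseline = np.clip(baseline, 0.1, 95.0)

    supp_meanlog = np.where(is_b, config.suppression_meanlog_b, config.suppression_meanlog_a)
    suppression = np.minimum(
        rng.lognormal(supp_meanlog, config.suppression_sdlog, n), 1.0
    )
    surgical = np.clip(baseline * suppression, 0.0, 100.0)
    month1 = np.clip(baseline * np.sqrt(suppression), 0.0, 100.0)

    pt = rng.choice([1, 2, 3, 4], size=n, p=list(config.p_pt))
    nodal = np.where(rng.random(n) < config.p_n0, "N0", "N+")
    er = np.where(
        rng.random(n) < config.p_er_positive,
        rng.integers(3, 9, size=n),
        rng.integers(0, 3, size=n),
    )

    followup = rng.uniform(*config.followup_range, size=n)
    lost = rng.random(n) < config.censoring_rate
    rfs = np.empty(n)
    event = np.zeros(n, dtype=bool)
    for i in range(n):
        h = _case_hazard(config, int(pt[i]), str(nodal[i]), float(surgical[i]), float(month1[i]))
        t_event = rng.exponential(1.0 / h) if h > 0 else math.inf
        if lost[i]:
            rfs[i] = rng.uniform(0.0, min(t_event, followup[i]))
            event[i] = False
        elif t_event <= followup[i]:
            rfs[i] = t_event
            event[i] = True
        else:
            rfs[i] = followup[i]
            event[i] = False

    return pd.DataFrame(
        {
            "case_id": [f"case{i:04d}" for i in range(n)],
            "pT": pt.astype(int),
            "nodal": nodal,
            "er_allred": er.astype(int),
            "luminal_label": np.where(is_b, "B", "A"),
            "ki67_baseline": baseline,
            "ki67_month1": month1,
            "ki67_surgical": surgical,
            "rfs_months": rfs,
            "relapse_event": event,
        },
        columns=COHORT_COLUMNS,
    )


def expected_event_rate(config: CohortConfig, hazard: float) -> float:
    """Closed-form P(event) for a case with the given monthly hazard."""
    if hazard == 0:
        return 0.0
    a, b = config.followup_range
    # E over followup ~ U(a, b) of 1 - exp(-h * fu), times P(not lost early)
    mean_surv = (math.exp(-hazard * a) - math.exp(-hazard * b)) / (hazard * (b - a))
    return (1.0 - config.censoring_rate) * (1.0 - mean_surv)


# ---------------------------------------------------------------------------
# Paired rater scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RaterModel:
    """Logit-normal field-selection noise plus binomial counting noise."""

    sigma_field: float = 0.20
    cells_counted: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.sigma_field < 0:
            raise ValueError("sigma_field must be >= 0")
        if self.cells_counted < 1:
            raise ValueError("cells_counted must be >= 1")


def rater_score(theta: float, model: RaterModel, rng: np.random.Generator) -> float:
    """One rater's percent for a case with true positive fraction ``theta``."""
    if theta in (0.0, 1.0):
        return 100.0 * theta
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in [0, 1]")
    p = expit(logit(theta) + rng.normal(0.0, model.sigma_field))
    return 100.0 * rng.binomial(model.cells_counted, p) / model.cells_counted


def generate_paired_scores(
    thetas: Sequence[float],
    model_a: RaterModel,
    model_b: RaterModel,
) -> pd.DataFrame:
    """Independent blinded-rater scores for each case's true fraction."""
    rng_a = child_rng(model_a.seed, "rater", "A")
    rng_b = child_rng(model_b.seed, "rater", "B")
    model_a.validate()
    model_b.validate()
    rows = []
    for i, theta in enumerate(thetas):
        rows.append(
            {
                "case_id": f"case{i:04d}",
                "score_a": rater_score(float(theta), model_a, rng_a),
                "score_b": rater_score(float(theta), model_b, rng_b),
            }
        )
    return pd.DataFrame(rows, columns=["case_id", "score_a", "score_b"])


def default_theta_mixture(n: int, rng: np.random.Generator,
                          config: CohortConfig | None = None) -> np.ndarray:
    """Per-case true Ki-67 fractions from the default luminal A/B mixture."""
    cfg = config or CohortConfig()
    is_b = rng.random(n) >= cfg.weight_a
    x = np.where(
        is_b,
        rng.lognormal(cfg.meanlog_b, cfg.sdlog_b, n),
        rng.lognormal(cfg.meanlog_a, cfg.sdlog_a, n),
    )
    return np.clip(x, 0.1, 95.0) / 100.0
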