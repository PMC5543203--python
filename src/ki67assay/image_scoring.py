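"""Automated scoring pathway: AOI selection, nuclei detection, triage, SOP.

The detector is a transparent stand-in for commercial image-analysis software:
color deconvolution into hematoxylin/DAB densities, thresholding, connected
components and a size filter; a component is Ki-67 positive iff its mean DAB
density clears ``od_threshold``. The SOP routes a case to VPC whenever any
complex-histology flag fires (or AOI selection fails), otherwise scores it by
image analysis over the selected AOIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hed

from .errors import AoiSelectionError
from .synthetic import CellMap, POSITIVE_OD_FLOOR, render_field
from .vpc import GridSpec, Ki67Score, vpc_score

TRIAGE_FLAGS = (
    "lymphocyte_rich",
    "sparse_streaming_tumor",
    "fibroblast_marking",
    "faint_diffuse_stain",
)


@dataclass(frozen=True)
class AOI:
    """Axis-aligned candidate window in field coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int
    tumor_count: int
    exclusions: tuple[str, ...] = ()

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


def _window_census(cellmap: CellMap, window: int):
    nx = cellmap.width // window
    ny = cellmap.height // window
    census = {}
    for n in cellmap.nuclei:
        ix = min(int(n.center[0] // window), nx - 1)
        iy = min(int(n.center[1] // window), ny - 1)
        if ix < 0 or iy < 0:
            continue
        key = (ix, iy)
        census.setdefault(key, {}).setdefault(n.cell_class, 0)
        census[key][n.cell_class] += 1
    return nx, ny, census


def select_aois(
    cellmap: CellMap,
    min_aois: int = 3,
    max_aois: int = 10,
    window: int = 128,
) -> list[AOI]:
    """Greedy AOI tiling: rank windows by invasive-tumor count, reject dirty ones.

    Windows containing necrotic debris, or dominated by DCIS, lymphocytes or
    endothelium (vessels), or with no invasive tumor at all, are rejected.
    Raises :class:`AoiSelectionError` when fewer than ``min_aois`` survive.
    """
    nx, ny, census = _window_census(cellmap, window)
    if nx < 1 or ny < 1:
        raise AoiSelectionError("field smaller than one AOI window")
    accepted = []
    for iy in range(ny):
        for ix in range(nx):
            counts = census.get((ix, iy), {})
            tumor = counts.get("invasive_tumor", 0)
            flags = []
            if counts.get("necrotic_debris", 0) >= 1:
                flags.append("necrotic")
            if counts.get("dcis", 0) > tumor:
                flags.append("dcis")
            if counts.get("lymphocyte", 0) > tumor:
                flags.append("lymphocyte_zone")
            if counts.get("endothelial", 0) > tumor:
                flags.append("vessel")
            if tumor == 0:
                flags.append("no_tumor")
            if not flags:
                accepted.append(
                    AOI(
                        x0=ix * window,
                        y0=iy * window,
                        x1=(ix + 1) * window,
                        y1=(iy + 1) * window,
                        tumor_count=tumor,
                    )
                )
    if len(accepted) < min_aois:
        raise AoiSelectionError(
            f"only {len(accepted)} clean AOI windows, need {min_aois}"
        )
    accepted.sort(key=lambda a: (-a.tumor_count, a.y0, a.x0))
    return accepted[:max_aois]


@dataclass(frozen=True)
class DetectedNucleus:
    center: tuple[float, float]  # (x, y)
    area: int
    mean_dab_od: float
    positive: bool


def detect_nuclei(
    image: np.ndarray,
    od_threshold: float = 0.30,
    nuclear_threshold: float = 0.50,
    min_area: int = 38,
) -> list[DetectedNucleus]:
    """Detect nuclei on a rendered RGB field and classify Ki-67 positivity.

    Deconvolves the image into HED densities, masks pixels with appreciable
    hematoxylin or DAB signal, labels connected components and drops the small
    (non-epithelial) ones. A nucleus is positive iff its mean DAB density is at
    least ``od_threshold``. A blank image yields an empty list.
    """
    hed = rgb2hed(np.asarray(image, dtype=float) / 255.0)
    mask = (hed[..., 0] > nuclear_threshold) | (hed[..., 2] > od_threshold)
    labels, n_labels = ndimage.label(mask)
    if n_labels == 0:
        return []
    idx = np.arange(1, n_labels + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    dab = ndimage.mean(hed[..., 2], labels, index=idx)
    centroids = ndimage.center_of_mass(mask, labels, index=idx)
    out = []
    for a, d, (cy, cx) in zip(areas, dab, centroids):
        if a < min_area:
            continue
        out.append(
            DetectedNucleus(
                center=(float(cx), float(cy)),
                area=int(a),
                mean_dab_od=float(d),
                positive=bool(d >= od_threshold),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriageThresholds:
    max_lymphocyte_fraction: float = 0.30
    min_tumor_density: float = 50.0  # cells per mm^2
    max_stained_fibroblast_fraction: float = 0.20
    min_stain_contrast: float = 0.30


@dataclass(frozen=True)
class FieldStats:
    """Case-level statistics the triage rules compare against thresholds."""

    lymphocyte_fraction: float
    tumor_density: float
    stained_fibroblast_fraction: float
    stain_contrast: float

    @classmethod
    def from_cellmaps(cls, maps: Sequence[CellMap], stain_contrast: float) -> "FieldStats":
        n_total = n_lymph = n_tumor = n_fibro = n_fibro_stained = 0
        area = 0.0
        for m in maps:
            area += m.area_mm2
            for n in m.nuclei:
                n_total += 1
                if n.cell_class == "lymphocyte":
                    n_lymph += 1
                elif n.cell_class == "invasive_tumor":
                    n_tumor += 1
                elif n.cell_class == "fibroblast":
                    n_fibro += 1
                    if n.stain_od >= POSITIVE_OD_FLOOR:
                        n_fibro_stained += 1
        return cls(
            lymphocyte_fraction=n_lymph / n_total if n_total else 0.0,
            tumor_density=n_tumor / area if area else 0.0,
            stained_fibroblast_fraction=n_fibro_stained / n_fibro if n_fibro else 0.0,
            stain_contrast=stain_contrast,
        )


@dataclass(frozen=True)
class TriageDecision:
    flags: tuple[str, ...]
    route: str  # IMAGE | VPC

    def __post_init__(self):
        if (self.route == "VPC") != bool(self.flags):
            raise ValueError("route must be VPC iff any flag is set")


def triage_flags(
    stats: FieldStats, thresholds: TriageThresholds | None = None
) -> TriageDecision:
    """Pure threshold comparison; route is VPC iff any flag fires."""
    t = thresholds or TriageThresholds()
    flags = []
    if stats.lymphocyte_fraction > t.max_lymphocyte_fraction:
        flags.append("lymphocyte_rich")
    if stats.tumor_density < t.min_tumor_density:
        flags.append("sparse_streaming_tumor")
    if stats.stained_fibroblast_fraction > t.max_stained_fibroblast_fraction:
        flags.append("fibroblast_marking")
    if stats.stain_contrast < t.min_stain_contrast:
        flags.append("faint_diffuse_stain")
    return TriageDecision(flags=tuple(flags), route="VPC" if flags else "IMAGE")


# ---------------------------------------------------------------------------
# SOP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SOPConfig:
    thresholds: TriageThresholds = field(default_factory=TriageThresholds)
    od_threshold: float = 0.30
    nuclear_threshold: float = 0.50
    min_detect_area: int = 38
    aoi_window: int = 128
    min_aois: int = 3
    max_aois: int = 10
    grid_spacing: float = 12.0
    grid_count_every: int = 1
    min_cells: int = 200
    n_fields: int = 3


@dataclass(frozen=True)
class SOPResult:
    case_id: str
    route: str
    score: Ki67Score
    aois: tuple[AOI, ...] | None
    flags: tuple[str, ...]

    def __post_init__(self):
        if self.score.method != self.route:
            raise ValueError("score method must match the route taken")


def image_score(
    cellmap: CellMap,
    stain_contrast: float,
    config: SOPConfig,
    image: np.ndarray | None = None,
) -> tuple[Ki67Score, tuple[AOI, ...]]:
    """Score one field by AOI selection plus the stand-in detector."""
    aois = select_aois(
        cellmap, min_aois=config.min_aois, max_aois=config.max_aois,
        window=config.aoi_window,
    )
    if image is None:
        image = render_field(cellmap, stain_contrast)
    detections = detect_nuclei(
        image,
        od_threshold=config.od_threshold,
        nuclear_threshold=config.nuclear_threshold,
        min_area=config.min_detect_area,
    )
    total = positive = 0
    for d in detections:
        if any(a.contains(*d.center) for a in aois):
            total += 1
            positive += int(d.positive)
    if total == 0:
        raise AoiSelectionError("no detections within the selected AOIs")
    score = Ki67Score(
        percent=100.0 * positive / total,
        method="IMAGE",
        total=total,
        positive=positive,
        fields_used=1,
        exhaustive=False,
        provenance={"n_aois": len(aois), "od_threshold": config.od_threshold},
    )
    return score, tuple(aois)


def sop_score(
    case_id: str,
    maps: Sequence[CellMap],
    stain_contrast: float,
    config: SOPConfig | None = None,
    seed: int = 0,
) -> SOPResult:
    """Run the scoring SOP for one case: triage, then image analysis or VPC.

    AOI or detector failure on the image route falls through to VPC; a case
    with no tumor cells anywhere raises :class:`UndefinedScoreError`.
    """
    cfg = config or SOPConfig()
    stats = FieldStats.from_cellmaps(maps, stain_contrast)
    decision = triage_flags(stats, cfg.thresholds)
    flags = list(decision.flags)
    route = decision.route

    if route == "IMAGE":
        try:
            score, aois = image_score(maps[0], stain_contrast, cfg)
            return SOPResult(case_id, "IMAGE", score, aois, tuple(flags))
        except AoiSelectionError:
            flags.append("aoi_failure")
            route = "VPC"

    score = vpc_score(
        maps,
        spec=GridSpec(line_spacing=cfg.grid_spacing, count_every=cfg.grid_count_every),
        min_cells=cfg.min_cells,
        n_fields=cfg.n_fields,
        seed=seed,
    )
    return SOPResult(case_id, "VPC", score, None, tuple(flags))
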