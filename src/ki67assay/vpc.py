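"""Visual point counting: systematic grid-line sampling of tumor nuclei.

A horizontal line grid is laid over each field; a nucleus is counted iff its
disk intersects a counting line (``|y_center - line| <= radius``, tangency
counts). Counting runs on every ``count_every``-th line starting at the grid
offset. Fields are accumulated until at least ``min_cells`` tumor cells have
been counted; if the available fields cannot supply that many, every cell is
counted exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._seeds import child_rng
from .errors import UndefinedScoreError
from .synthetic import CellMap


@dataclass(frozen=True)
class GridSpec:
    line_spacing: float
    offset: float = 0.0
    count_every: int = 3
    orientation: str = "horizontal"

    def __post_init__(self):
        if self.line_spacing <= 0:
            raise ValueError("line_spacing must be > 0")
        if not 0 <= self.offset < self.line_spacing:
            raise ValueError("offset must be in [0, line_spacing)")
        if self.count_every < 1:
            raise ValueError("count_every must be >= 1")
        if self.orientation != "horizontal":
            raise ValueError("only horizontal grids are supported")


@dataclass(frozen=True)
class CountResult:
    total_tumor: int
    positive_tumor: int
    fields_used: int = 1
    exhaustive: bool = False

    def __post_init__(self):
        if not 0 <= self.positive_tumor <= self.total_tumor:
            raise ValueError("need 0 <= positive_tumor <= total_tumor")
        if self.fields_used < 1:
            raise ValueError("fields_used must be >= 1")


@dataclass(frozen=True)
class Ki67Score:
    """A Ki-67 percentage with counting provenance."""

    percent: float
    method: str  # VPC | IMAGE | SOP
    total: int | None = None
    positive: int | None = None
    fields_used: int | None = None
    exhaustive: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError("percent must be in [0, 100]")
        if self.method not in ("VPC", "IMAGE", "SOP"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.total is not None:
            if self.total <= 0:
                raise ValueError("total must be positive when present")
            if abs(self.percent - 100.0 * self.positive / self.total) > 1e-9:
                raise ValueError("percent inconsistent with counts")


def grid_lines(extent: tuple[int, int], spec: GridSpec) -> np.ndarray:
    """Counted line ordinates: offset, offset + count_every*spacing, ... < height."""
    _, height = extent
    step = spec.count_every * spec.line_spacing
    if spec.offset >= height:
        return np.array([])
    n = int(np.floor((height - spec.offset) / step)) + 1
    lines = spec.offset + step * np.arange(n)
    return lines[lines < height]


def count_on_lines(cellmap: CellMap, lines: Sequence[float]) -> CountResult:
    """Count invasive tumor nuclei whose disks intersect any counting line.

    Each nucleus is counted at most once even if it touches several lines.
    """
    lines = np.asarray(lines, dtype=float)
    tumor = cellmap.tumor_nuclei
    if not tumor or lines.size == 0:
        return CountResult(0, 0)
    ys = np.array([n.center[1] for n in tumor])
    rs = np.array([n.radius for n in tumor])
    hit = (np.abs(ys[:, None] - lines[None, :]) <= rs[:, None]).any(axis=1)
    pos = np.array([n.ki67_positive for n in tumor])
    total = int(hit.sum())
    return CountResult(
        total_tumor=total,
        positive_tumor=int((hit & pos).sum()),
        exhaustive=(total == len(tumor)),
    )


def count_all(cellmap: CellMap) -> CountResult:
    """Exhaustive count of every invasive tumor nucleus in the field."""
    tumor = cellmap.tumor_nuclei
    return CountResult(
        total_tumor=len(tumor),
        positive_tumor=sum(n.ki67_positive for n in tumor),
        exhaustive=True,
    )


def default_grid_spec(maps: Sequence[CellMap]) -> GridSpec:
    """Spacing of four median tumor-nucleus diameters, counting every third line."""
    radii = [n.radius for m in maps for n in m.tumor_nuclei]
    diameter = 2.0 * float(np.median(radii)) if radii else 10.0
    return GridSpec(line_spacing=4.0 * diameter, count_every=3)


def vpc_score(
    maps: Sequence[CellMap],
    spec: GridSpec | None = None,
    min_cells: int = 200,
    n_fields: int = 3,
    seed: int = 0,
) -> Ki67Score:
    """Score a case by visual point counting over randomly selected fields.

    ``n_fields`` fields are drawn without replacement; further fields are added
    while the accumulated tumor count is below ``min_cells``. If all fields are
    exhausted first, every cell in every field is counted (``exhaustive``).
    The grid offset is re-randomized per field to avoid periodic aliasing.
    """
    if not maps:
        raise ValueError("at least one field is required")
    if spec is None:
        spec = default_grid_spec(maps)
    rng = child_rng(seed, "vpc")
    order = rng.permutation(len(maps))

    total = positive = 0
    used = 0
    for idx in order:
        if used >= n_fields and total >= min_cells:
            break
        m = maps[int(idx)]
        offset = float(rng.uniform(0.0, spec.line_spacing))
        res = count_on_lines(m, grid_lines((m.width, m.height), replace(spec, offset=offset)))
        total += res.total_tumor
        positive += res.positive_tumor
        used += 1

    exhaustive = False
    if total < min_cells:
        total = positive = 0
        for m in maps:
            res = count_all(m)
            total += res.total_tumor
            positive += res.positive_tumor
        used = len(maps)
        exhaustive = True

    if total == 0:
        raise UndefinedScoreError("no tumor cells available in any field")
    return Ki67Score(
        percent=100.0 * positive / total,
        method="VPC",
        total=total,
        positive=positive,
        fields_used=used,
        exhaustive=exhaustive,
        provenance={
            "line_spacing": spec.line_spacing,
            "count_every": spec.count_every,
            "min_cells": min_cells,
            "n_fields": n_fields,
            "seed": seed,
        },
    )
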