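"""Cut-point classification and (modified) PEPI-0 status.

The boundary is favorable: a value exactly at the cut-point is ``at_or_below``.
Modified PEPI-0 requires pT1/2, N0 and surgical Ki-67 <= 2.7%; full PEPI-0
additionally requires retained ER (Allred 3-8). Missing inputs propagate as
``None`` (undetermined) rather than raising, so fulvestrant-style cohorts with
uninterpretable ER can still be classified on the modified rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

KI67_PEPI_CUTPOINT = 2.7
KI67_EARLY_TRIAGE_CUTPOINT = 10.0


def _missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class CutpointCall:
    value: float
    cutpoint: float
    call: str  # at_or_below | above

    def __post_init__(self):
        expected = "at_or_below" if self.value <= self.cutpoint else "above"
        if self.call != expected:
            raise ValueError("call inconsistent with value and cutpoint")


def classify_cutpoint(value: float | None, cutpoint: float) -> CutpointCall | None:
    """Dichotomize a Ki-67 percent at a cut-point; boundary goes at_or_below."""
    if _missing(value):
        return None
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise ValueError("value must be in [0, 100]")
    call = "at_or_below" if value <= cutpoint else "above"
    return CutpointCall(value=value, cutpoint=cutpoint, call=call)


def modified_pepi0(pt, nodal, ki67_surgical) -> bool | None:
    """True iff pT1/2, N0 and surgical Ki-67 <= 2.7%; None if any input missing."""
    if _missing(pt) or _missing(nodal) or _missing(ki67_surgical):
        return None
    return int(pt) in (1, 2) and str(nodal) == "N0" and float(ki67_surgical) <= KI67_PEPI_CUTPOINT


def pepi0(pt, nodal, ki67_surgical, er_allred) -> bool | None:
    """Modified PEPI-0 plus retained ER (Allred 3-8); ER missing -> undetermined.

    A case that already fails the modified rule is False regardless of ER,
    which preserves the implication pepi0 => modified_pepi0.
    """
    base = modified_pepi0(pt, nodal, ki67_surgical)
    if base is None:
        return None
    if not base:
        return False
    if _missing(er_allred):
        return None
    er = int(er_allred)
    if not 0 <= er <= 8:
        raise ValueError("er_allred must be in 0..8")
    return 3 <= er <= 8


@dataclass(frozen=True)
class PepiStatus:
    case_id: str
    modified_pepi0: bool
    pepi0: bool | None

    def __post_init__(self):
        if self.pepi0 is True and not self.modified_pepi0:
            raise ValueError("pepi0 implies modified_pepi0")


def classify_cohort(cohort: pd.DataFrame, ki67_column: str = "ki67_surgical") -> pd.DataFrame:
    """Add ``modified_pepi0`` / ``pepi0`` columns (nullable boolean) to a cohort."""
    out = cohort.copy()
    out["modified_pepi0"] = pd.array(
        [
            modified_pepi0(r["pT"], r["nodal"], r[ki67_column])
            for _, r in cohort.iterrows()
        ],
        dtype="boolean",
    )
    out["pepi0"] = pd.array(
        [
            pepi0(r["pT"], r["nodal"], r[ki67_column], r.get("er_allred"))
            for _, r in cohort.iterrows()
        ],
        dtype="boolean",
    )
    return out
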