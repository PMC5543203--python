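"""Two-rater agreement statistics.

Contingency tables are 2x2 cross-classifications at a cut-point with rater A
as the reference (rows); "positive" means above the cut-point. PPA/NPA carry
exact Clopper-Pearson intervals; Cohen's kappa carries a large-sample
(Fleiss-Cohen-Everitt) Wald interval truncated to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pepi import classify_cutpoint


@dataclass(frozen=True)
class ContingencyTable:
    """a: both above; b: A above, B at/below; c: A at/below, B above; d: both at/below."""

    a: int
    b: int
    c: int
    d: int
    n_excluded: int = 0

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")
        if self.n < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        """Swap raters (b and c exchange roles)."""
        return ContingencyTable(self.a, self.c, self.b, self.d, self.n_excluded)

    @classmethod
    def from_pairs(
        cls,
        pairs: pd.DataFrame,
        cutpoint: float,
        score_a: str = "score_a",
        score_b: str = "score_b",
    ) -> "ContingencyTable":
        if len(pairs) == 0:
            raise ValueError("no score pairs provided")
        a = b = c = d = excluded = 0
        for _, row in pairs.iterrows():
            ca = classify_cutpoint(row[score_a], cutpoint)
            cb = classify_cutpoint(row[score_b], cutpoint)
            if ca is None or cb is None:
                excluded += 1
                continue
            if ca.call == "above":
                if cb.call == "above":
                    a += 1
                else:
                    b += 1
            else:
                if cb.call == "above":
                    c += 1
                else:
                    d += 1
        return cls(a, b, c, d, n_excluded=excluded)


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    lower: float
    upper: float
    successes: int
    trials: int


@dataclass(frozen=True)
class KappaCI:
    estimate: float
    lower: float
    upper: float


@dataclass(frozen=True)
class AgreementStats:
    ppa: ProportionCI | None
    npa: ProportionCI | None
    kappa: KappaCI | None
    n: int


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval from beta quantiles."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    alpha = (1.0 - level) / 2.0
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - alpha, successes + 1, trials - successes)
    )
    return lower, upper


def ppa_npa(
    table: ContingencyTable, level: float = 0.95
) -> tuple[ProportionCI | None, ProportionCI | None]:
    """Percent positive and negative agreement, rater A as reference.

    PPA = a/(a+b) and NPA = d/(c+d), each with its exact interval; a
    proportion with an empty margin is reported as None.
    """
    ppa = npa = None
    if table.a + table.b >= 1:
        lo, hi = clopper_pearson(table.a, table.a + table.b, level)
        ppa = ProportionCI(table.a / (table.a + table.b), lo, hi, table.a, table.a + table.b)
    if table.c + table.d >= 1:
        lo, hi = clopper_pearson(table.d, table.c + table.d, level)
        npa = ProportionCI(table.d / (table.c + table.d), lo, hi, table.d, table.c + table.d)
    return ppa, npa


def cohen_kappa(table: ContingencyTable, level: float = 0.95) -> KappaCI | None:
    """Unweighted Cohen's kappa with a large-sample Wald interval.

    Returns None when the chance agreement is degenerate (p_e = 1). The
    standard error follows Fleiss, Cohen & Everitt (1969).
    """
    n = table.n
    if n < 2:
        raise ValueError("kappa needs at least two pairs")
    p = np.array([[table.a, table.b], [table.c, table.d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = p[0, 0] + p[1, 1]
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-12:
        return None
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt asymptotic variance
    term_a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2)
    )
    term_b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term_c = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (term_a + term_b - term_c) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return KappaCI(
        estimate=float(kappa),
        lower=float(max(-1.0, kappa - z * se)),
        upper=float(min(1.0, kappa + z * se)),
    )


def agreement_stats(
    pairs: pd.DataFrame, cutpoint: float, level: float = 0.95
) -> AgreementStats:
    """Table-1-style summary for one cut-point."""
    table = ContingencyTable.from_pairs(pairs, cutpoint)
    ppa, npa = ppa_npa(table, level)
    kappa = cohen_kappa(table, level) if table.n >= 2 else None
    return AgreementStats(ppa=ppa, npa=npa, kappa=kappa, n=table.n)


def correlations(
    pairs: pd.DataFrame, score_a: str = "score_a", score_b: str = "score_b"
) -> tuple[float, float]:
    """(Pearson r, Spearman rho) over complete pairs; ties are mid-ranked."""
    df = pairs[[score_a, score_b]].dropna()
    if len(df) < 3:
        raise ValueError("correlations need at least 3 complete pairs")
    x = df[score_a].to_numpy(float)
    y = df[score_b].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlations undefined for constant scores")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(
    pairs: pd.DataFrame, score_a: str = "score_a", score_b: str = "score_b"
) -> BlandAltman:
    """Bias (mean A-B) and 1.96-sd limits of agreement, with plot coordinates."""
    df = pairs[[score_a, score_b]].dropna()
    if len(df) < 2:
        raise ValueError("Bland-Altman needs at least 2 complete pairs")
    diff = df[score_a].to_numpy(float) - df[score_b].to_numpy(float)
    mean = (df[score_a].to_numpy(float) + df[score_b].to_numpy(float)) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        means=mean,
        differences=diff,
    )
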