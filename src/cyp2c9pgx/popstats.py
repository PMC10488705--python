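"""Population-genetic and categorical statistics.

Allele frequencies from diplotype counts, Hardy-Weinberg chi-square tests,
r x c contingency chi-square, Cramér's V effect size with a Cohen-style
interpretation scaled by degrees of freedom, census-weighted aggregation
of subcohort frequency vectors, and fold-range summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .star_model import DataError

__all__ = [
    "ContingencyResult",
    "EffectSizeResult",
    "CensusWeights",
    "allele_freqs_from_diplotypes",
    "hwe_chisq",
    "contingency_chisq",
    "cramers_v",
    "weighted_aggregate",
    "fold_range",
]

#: Brazilian census race/Color proportions; the three groups cover 98.8%
#: of the population, so analyses renormalise them to sum to 1.
RAW_CENSUS_WEIGHTS = {"White": 0.431, "Brown": 0.465, "Black": 0.093}

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square outcome for an r x c table (df = (r-1)(c-1))."""

    chi2: float
    df: int
    p_value: float
    n: int
    r: int
    c: int


@dataclass(frozen=True)
class EffectSizeResult:
    """Cramér's V = sqrt(chi2 / (n * min(r-1, c-1))) with a Cohen label."""

    V: float
    df_min: int
    cohen_label: str


@dataclass(frozen=True)
class CensusWeights:
    """Per-subcohort weights, renormalised to the simplex."""

    weights: dict
    renormalized: bool = True

    @classmethod
    def brazilian_census(cls) -> "CensusWeights":
        total = sum(RAW_CENSUS_WEIGHTS.values())
        return cls({k: v / total for k, v in RAW_CENSUS_WEIGHTS.items()})

    def __post_init__(self):
        if self.renormalized and abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise DataError("renormalized weights must sum to 1")


def _split_pair(category: str):
    parts = category.split("/")
    if len(parts) != 2:
        raise DataError(f"category {category!r} is not a star-allele pair")
    return parts[0], parts[1]


def allele_freqs_from_diplotypes(counts: Mapping, n: int | None = None) -> dict:
    """Star-allele frequencies from diplotype category counts.

    freq(a) = (count of heterozygotes carrying a + 2 * count of a-homozygotes)
    over 2n; output sums to 1.
    """
    allele_counts: dict = {}
    total = 0
    for category, count in counts.items():
        a, b = _split_pair(str(category))
        allele_counts[a] = allele_counts.get(a, 0) + count
        allele_counts[b] = allele_counts.get(b, 0) + count
        total += count
    if n is None:
        n = total
    elif n != total:
        raise DataError(f"counts sum to {total}, expected n={n}")
    if n == 0:
        raise DataError("no individuals")
    return {a: c / (2.0 * n) for a, c in allele_counts.items()}


def hwe_chisq(genotype_counts: Sequence[int]) -> ContingencyResult:
    """Hardy-Weinberg chi-square at one biallelic locus.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa).  Expected counts are the
    HWE proportions (p^2, 2pq, q^2) * N from the observed allele frequency;
    df = 1.  A monomorphic locus returns chi2 = 0, p = 1 by convention.
    """
    obs = np.asarray(genotype_counts, dtype=float)
    if obs.shape != (3,) or (obs < 0).any():
        raise DataError("genotype counts must be three non-negative numbers")
    N = obs.sum()
    if N <= 0:
        raise DataError("no observations")
    p = (2 * obs[0] + obs[1]) / (2 * N)
    q = 1.0 - p
    if p <= 0 or q <= 0:
        return ContingencyResult(chi2=0.0, df=1, p_value=1.0, n=int(N), r=1, c=3)
    expected = np.array([p * p, 2 * p * q, q * q]) * N
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, 1))
    return ContingencyResult(chi2=chi2, df=1, p_value=p_value, n=int(N), r=1, c=3)


def contingency_chisq(table) -> ContingencyResult:
    """Pearson chi-square test of independence for an r x c count table.

    No continuity correction is applied; p-values come from the asymptotic
    chi-square distribution with (r-1)(c-1) df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("table must be at least 2 x 2")
    if (obs < 0).any():
        raise DataError("counts must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise DataError("degenerate table: all-zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    r, c = obs.shape
    return ContingencyResult(
        chi2=float(chi2), df=int(df), p_value=float(p), n=int(obs.sum()), r=r, c=c
    )


#: Cohen (1988) small/medium/large thresholds at one degree of freedom;
#: scaled by sqrt(df_min) for wider tables.
COHEN_THRESHOLDS = (0.10, 0.30, 0.50)


def cramers_v(res: ContingencyResult, thresholds=COHEN_THRESHOLDS) -> EffectSizeResult:
    """Cramér's V for a contingency result, with a Cohen-scale label."""
    df_min = min(res.r - 1, res.c - 1)
    if df_min <= 0:
        raise DataError("Cramér's V requires at least a 2 x 2 table")
    if res.n <= 0:
        raise DataError("n must be positive")
    V = float(np.sqrt(res.chi2 / (res.n * df_min)))
    small, medium, large = (t / np.sqrt(df_min) for t in thresholds)
    if V >= large:
        label = "large"
    elif V >= medium:
        label = "medium"
    elif V >= small:
        label = "small"
    else:
        label = "negligible"
    return EffectSizeResult(V=V, df_min=df_min, cohen_label=label)


def weighted_aggregate(subcohort_freqs: Mapping, weights: CensusWeights) -> dict:
    """Census-weighted convex combination of subcohort frequency vectors.

    All vectors must share the same categories; the output sums to 1
    whenever the inputs do.
    """
    labels = list(weights.weights)
    missing = [lab for lab in labels if lab not in subcohort_freqs]
    if missing:
        raise DataError(f"no frequency vector for subcohort(s) {missing}")
    categories = list(subcohort_freqs[labels[0]])
    for lab in labels[1:]:
        if list(subcohort_freqs[lab]) != categories:
            raise DataError("subcohort frequency vectors have mismatched categories")
    out = {}
    for cat in categories:
        out[cat] = sum(
            weights.weights[lab] * subcohort_freqs[lab][cat] for lab in labels
        )
    return out


def fold_range(values) -> float:
    """Max/min ratio of a collection of positive values.

    A zero value makes the ratio undefined; infinity is returned with a
    warning.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0 or (vals < 0).any():
        raise DataError("fold_range needs non-negative, non-empty values")
    if (vals == 0).any():
        warnings.warn("zero value in fold_range; ratio is infinite", stacklevel=2)
        return float("inf")
    return float(vals.max() / vals.min())
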