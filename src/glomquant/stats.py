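"""Statistical summaries and tests used in the phenotype analyses.

Penetrance with exact (Clopper-Pearson) binomial intervals, one-sample t
against zero, tie-corrected Kruskal-Wallis with Bonferroni-adjusted
pairwise follow-up, and geometric-mean group summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError


@dataclass
class PenetranceResult:
    k: int
    n: int
    percent: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "percent": self.percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass
class GroupComparison:
    H: float
    df: int
    omnibus_p: float
    pairwise: List[dict]  # {pair: (label, label), raw_p, adjusted_p}
    posthoc: str = "mannwhitney"

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "df": self.df,
            "omnibus_p": self.omnibus_p,
            "posthoc": self.posthoc,
            "pairwise": [
                {
                    "pair": list(e["pair"]),
                    "raw_p": e["raw_p"],
                    "adjusted_p": e["adjusted_p"],
                }
                for e in self.pairwise
            ],
        }


@dataclass
class GroupSummary:
    geometric_mean: float
    q25: float
    q75: float
    zeros_replaced: bool = False

    def to_dict(self) -> dict:
        return {
            "geometric_mean": self.geometric_mean,
            "q25": self.q25,
            "q75": self.q75,
            "zeros_replaced": self.zeros_replaced,
        }


def penetrance(k: int, n: int, confidence: float = 0.95) -> PenetranceResult:
    """Phenotype penetrance 100*k/n with an exact binomial CI.

    The Clopper-Pearson bounds come from the beta-quantile form of exact
    binomial tail inversion.
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return PenetranceResult(
        k=int(k), n=int(n), percent=100.0 * k / n, ci_low=100.0 * lo, ci_high=100.0 * hi
    )


def one_sample_t(
    values: Sequence[float], mu0: float = 0.0
) -> Tuple[float, int, float]:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise DegenerateSampleError(f"need >= 2 observations, got {x.size}")
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateSampleError("zero sample variance")
    n = x.size
    t = (x.mean() - mu0) / (s / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    H is computed from joint mid-ranks and divided by the tie-correction
    factor 1 - sum(t^3 - t)/(N^3 - N).
    """
    if len(groups) < 2:
        raise DegenerateSampleError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DegenerateSampleError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise DegenerateSampleError("all values identical")
    n_total = pooled.size
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        start += a.size
        h += a.size * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    h /= correction
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return float(h), int(df), p


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value, normal approximation with tie and
    continuity corrections."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.pvalue)


def _dunn_pvalues(
    arrays: List[np.ndarray], pairs: List[Tuple[int, int]]
) -> List[float]:
    """Dunn's rank-based post hoc z-tests on the joint ranking."""
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = _midranks(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    pvals = []
    for i, j in pairs:
        ni, nj = arrays[i].size, arrays[j].size
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pvals.append(float(2.0 * sps.norm.sf(abs(z))))
    return pvals


def pairwise_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    posthoc: str = "mannwhitney",
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus Bonferroni-adjusted pairwise comparisons.

    ``posthoc`` selects the pairwise procedure: ``"mannwhitney"`` (default)
    or ``"dunn"``; the choice is echoed in the output.
    """
    if posthoc not in ("mannwhitney", "dunn"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    if len(labels) != len(groups):
        raise ValueError("labels and groups must align")
    h, df, p = kruskal_wallis(groups)
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    if posthoc == "dunn":
        raw = _dunn_pvalues(arrays, pairs)
    else:
        raw = [_mannwhitney_p(arrays[i], arrays[j]) for i, j in pairs]
    pairwise = [
        {
            "pair": (labels[i], labels[j]),
            "raw_p": float(rp),
            "adjusted_p": float(min(1.0, rp * m)),
        }
        for (i, j), rp in zip(pairs, raw)
    ]
    return GroupComparison(H=h, df=df, omnibus_p=p, pairwise=pairwise, posthoc=posthoc)


def geometric_mean(values: Sequence[float], zero_policy: str = "replace") -> float:
    """exp(mean(log v)); zeros handled by policy.

    ``"replace"`` substitutes half the smallest positive value for each
    zero; ``"strict"`` raises on any zero.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    if (x < 0).any():
        raise ValueError("values must be non-negative")
    if zero_policy not in ("replace", "strict"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    zeros = x == 0
    if zeros.any():
        if zero_policy == "strict":
            raise ValueError("zero values under strict policy")
        positive = x[~zeros]
        if positive.size == 0:
            raise ValueError("all values are zero; geometric mean undefined")
        x = np.where(zeros, positive.min() / 2.0, x)
    return float(np.exp(np.mean(np.log(x))))


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Geometric mean (zero policy "replace") with 25th/75th percentiles
    (linear interpolation)."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    gm = geometric_mean(x, zero_policy="replace")
    q25, q75 = np.percentile(x, [25, 75])  # linear interpolation default
    return GroupSummary(
        geometric_mean=gm,
        q25=float(q25),
        q75=float(q75),
        zeros_replaced=bool((x == 0).any()),
    )
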