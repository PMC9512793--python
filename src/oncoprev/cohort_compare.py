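"""Cohort comparison: gene ranking, top-k overlap, TP53 patterns, statistics.

Comparison conventions follow common practice for population mutation
profiles: ranked gene lists are compared by the common rate
2*(T - U)/T (T = summed list sizes, U = union size; for equal-size lists this
reduces to |intersection| / k); per-cancer mutational patterns are labelled
by where TP53 sits relative to the top rate cluster; mean rate vectors are
compared by an F-test-gated unpaired t test (Welch's correction when the
variances differ at p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NumericError

__all__ = [
    "RankedGeneList",
    "PatternLabel",
    "rank_top_k",
    "overlap_rate",
    "classify_tp53_pattern",
    "pearson_r",
    "compare_rates",
    "CompareResult",
]


@dataclass(slots=True)
class RankedGeneList:
    """Genes ordered by nonincreasing mutation rate; tie rule recorded."""

    genes: list[str]
    rates: list[float]
    tie_rule: str = "alphabetical"
    truncated: bool = False  # True when fewer nonzero-rate genes than k

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.rates):
            raise ValueError("genes and rates differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if any(a < b for a, b in zip(self.rates, self.rates[1:])):
            raise ValueError("rates are not nonincreasing")

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


@dataclass(slots=True)
class PatternLabel:
    """Per-cancer mutational pattern by TP53 rank: TP53-Top/TP53-Plus/Non-TP53."""

    label: str
    cluster: list[str]
    delta: float


def rank_top_k(rates: Mapping[str, float] | pd.Series, k: int = 50) -> RankedGeneList:
    """Top-k genes by rate, descending; ties broken alphabetically.

    Genes with zero rate are not ranked; if fewer than k genes have nonzero
    rate the list is shorter and flagged (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = [(g, float(r)) for g, r in dict(rates).items() if r > 0]
    items.sort(key=lambda gr: (-gr[1], gr[0]))
    truncated = len(items) < k
    if truncated:
        warnings.warn(
            f"only {len(items)} genes with nonzero rate (requested top {k})",
            stacklevel=2,
        )
    top = items[:k]
    return RankedGeneList(
        genes=[g for g, _ in top],
        rates=[r for _, r in top],
        truncated=truncated,
    )


def overlap_rate(list_a: RankedGeneList | Iterable[str],
                 list_b: RankedGeneList | Iterable[str]) -> float:
    """Common rate of two gene lists: 2*(T - U)/T.

    T is the summed list size, U the union size; for equal-size deduplicated
    lists this equals |A intersect B| / k.
    """
    a = list_a.as_set() if isinstance(list_a, RankedGeneList) else set(list_a)
    b = list_b.as_set() if isinstance(list_b, RankedGeneList) else set(list_b)
    t = len(a) + len(b)
    if t == 0:
        raise NumericError("overlap of two empty lists is undefined")
    u = len(a | b)
    return 2.0 * (t - u) / t


def classify_tp53_pattern(ranked: RankedGeneList, delta: float = 0.10,
                          gene: str = "TP53") -> PatternLabel:
    """Label a cancer's profile by TP53's position in the top rate cluster.

    The cluster is every gene whose rate is within ``delta`` of the top rate.
    TP53 alone in the cluster -> 'TP53-Top'; TP53 clustered with one or two
    other genes -> 'TP53-Plus'; anything else (TP53 absent from the cluster,
    or a cluster of four or more) -> 'Non-TP53'.
    """
    if len(ranked) == 0:
        raise NumericError("cannot classify an empty ranked list")
    r1 = ranked.rates[0]
    cluster = [g for g, r in zip(ranked.genes, ranked.rates) if r >= r1 - delta]
    if cluster == [gene]:
        label = f"{gene}-Top"
    elif gene in cluster and len(cluster) in (2, 3):
        label = f"{gene}-Plus"
    else:
        label = f"Non-{gene}"
    return PatternLabel(label=label, cluster=cluster, delta=delta)


def _align(rates_a: Mapping[str, float] | pd.Series,
           rates_b: Mapping[str, float] | pd.Series,
           exclude: Iterable[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Align two gene->rate maps on the union of genes, imputing 0 for
    unobserved genes (they were screened and not mutated, not missing)."""
    a, b = dict(rates_a), dict(rates_b)
    genes = sorted(set(a) | set(b))
    if exclude:
        drop = set(exclude)
        genes = [g for g in genes if g not in drop]
    xa = np.array([a.get(g, 0.0) for g in genes], dtype=float)
    xb = np.array([b.get(g, 0.0) for g in genes], dtype=float)
    return xa, xb


def pearson_r(rates_a: Mapping[str, float] | pd.Series,
              rates_b: Mapping[str, float] | pd.Series,
              exclude: Iterable[str] | None = None) -> tuple[float, float]:
    """Pearson correlation of two aligned gene-rate vectors; returns (r, p).

    ``exclude`` removes dominant genes (e.g. TP53) before correlating.
    """
    xa, xb = _align(rates_a, rates_b, exclude)
    if len(xa) < 2 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise NumericError("correlation undefined: constant or too-short vector")
    res = stats.pearsonr(xa, xb)
    return float(res.statistic), float(res.pvalue)


@dataclass(slots=True)
class CompareResult:
    """F-test-gated two-sample comparison of mean rates (mirrors a figure-legend
    statistics block: F, its dfs and p; the chosen t test with t, df, p;
    group means with SE; and the 95% CI of the difference in means a-b)."""

    f: float
    dfn: int
    dfd: int
    f_p: float
    test: str  # "welch-t" or "pooled-t"
    t: float
    df: float
    p: float
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    ci_low: float
    ci_high: float


def compare_rates(rates_a: Sequence[float], rates_b: Sequence[float],
                  alpha_f: float = 0.05) -> CompareResult:
    """Compare two rate vectors: F test on variances, then unpaired t.

    If the two-sided F test rejects equal variances at ``alpha_f``, Welch's
    t test (Welch-Satterthwaite df) is used; otherwise the pooled-variance
    unpaired t test. The F statistic puts the larger sample variance in the
    numerator, as variance-ratio tests conventionally report it.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise NumericError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 and vb <= 0:
        raise NumericError("both groups have zero variance")
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    f_p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    welch = f_p < alpha_f
    tt = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(tt.df)
    mean_a, mean_b = a.mean(), b.mean()
    se_a = a.std(ddof=1) / np.sqrt(len(a))
    se_b = b.std(ddof=1) / np.sqrt(len(b))
    if welch:
        se_diff = np.sqrt(va / len(a) + vb / len(b))
    else:
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
        se_diff = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    tcrit = stats.t.ppf(0.975, df)
    diff = mean_a - mean_b
    return CompareResult(
        f=float(f), dfn=dfn, dfd=dfd, f_p=float(f_p),
        test="welch-t" if welch else "pooled-t",
        t=float(tt.statistic), df=df, p=float(tt.pvalue),
        mean_a=float(mean_a), se_a=float(se_a),
        mean_b=float(mean_b), se_b=float(se_b),
        ci_low=float(diff - tcrit * se_diff),
        ci_high=float(diff + tcrit * se_diff),
    )
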