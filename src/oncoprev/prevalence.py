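"""Weighted mutation-proportion estimation with Poisson-simulation CIs.

The estimator is a conditional-probability matrix (genes x sites, entry =
fraction of the site's cohort mutated in the gene, each sample counted at
most once) combined with the epidemiological weight vector v by a scalar
product per gene: P_i = sum_j prob[i, j] * v_j. Confidence intervals come
from a parametric bootstrap: mutated-sample counts are resimulated as
Poisson draws with the observed count as mean (clamped at the cohort size
so resimulated proportions stay <= 1), the weighted proportion is recomputed
for each replicate, and the empirical 2.5/97.5 percentiles are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, NumericError
from .epidemiology import WeightVector
from .filtering import GeneSampleTable

__all__ = [
    "ConditionalMatrix",
    "conditional_matrix",
    "weighted_proportions",
    "poisson_ci",
    "accumulated_rate",
]


@dataclass(slots=True)
class ConditionalMatrix:
    """m genes x n sites conditional mutation probabilities with raw counts.

    ``counts[i, j]`` is the number of samples in site j's cohort with >=1
    qualifying mutation in gene i; ``n_samples[j]`` the cohort size; the
    probability entries are ``counts / n_samples`` (never stored separately,
    so the invariant cannot drift).
    """

    genes: list[str]
    sites: list[str]
    counts: np.ndarray      # int, shape (m, n)
    n_samples: np.ndarray   # int, shape (n,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.n_samples = np.asarray(self.n_samples, dtype=np.int64)
        m, n = self.counts.shape
        if m != len(self.genes) or n != len(self.sites):
            raise AlignmentError("counts shape does not match gene/site labels")
        if (self.n_samples < 1).any():
            bad = [self.sites[j] for j in np.where(self.n_samples < 1)[0]]
            raise NumericError(f"sites with empty cohorts: {bad}")
        if (self.counts < 0).any() or (self.counts > self.n_samples).any():
            raise NumericError("mutated-sample counts outside [0, N]")

    @property
    def prob(self) -> np.ndarray:
        """Conditional probabilities P(gene mutated | site), shape (m, n)."""
        return self.counts / self.n_samples.astype(float)


def conditional_matrix(site_tables: Mapping[str, GeneSampleTable],
                       genes: Sequence[str],
                       site_order: Sequence[str] | None = None
                       ) -> ConditionalMatrix:
    """Assemble the gene x site matrix from per-site tabulations.

    Rows cover the full ``genes`` panel; genes never observed in a cohort get
    a zero row. Column order follows ``site_order`` (default: sorted site
    codes) so it can be aligned with a weight vector.
    """
    sites = list(site_order) if site_order is not None else sorted(site_tables)
    missing = [s for s in sites if s not in site_tables]
    if missing:
        raise AlignmentError(f"no tabulation for sites: {missing}")
    genes = list(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(genes), len(sites)), dtype=np.int64)
    n = np.zeros(len(sites), dtype=np.int64)
    for j, site in enumerate(sites):
        table = site_tables[site]
        n[j] = table.n_samples
        for gene, samples in table.mutated_samples.items():
            i = gene_idx.get(gene)
            if i is not None:
                counts[i, j] = len(samples)
    return ConditionalMatrix(genes=genes, sites=sites, counts=counts, n_samples=n)


def _aligned_weights(matrix: ConditionalMatrix, v: WeightVector) -> np.ndarray:
    if set(matrix.sites) != set(v.sites):
        only_m = sorted(set(matrix.sites) - set(v.sites))
        only_v = sorted(set(v.sites) - set(matrix.sites))
        raise AlignmentError(
            f"site mismatch between matrix and weights; matrix-only: {only_m}, "
            f"weights-only: {only_v}"
        )
    return v.weights.reindex(matrix.sites).to_numpy(dtype=float)


def weighted_proportions(matrix: ConditionalMatrix, v: WeightVector) -> pd.Series:
    """Per-gene weighted mutation proportion: P_i = sum_j prob[i, j] * v_j."""
    w = _aligned_weights(matrix, v)
    est = matrix.prob @ w
    return pd.Series(est, index=matrix.genes, name="weighted_proportion")


def poisson_ci(matrix: ConditionalMatrix, v: WeightVector,
               n_reps: int = 2000, seed: int = 0,
               chunk: int = 250) -> pd.DataFrame:
    """Parametric-bootstrap 95% CI of the weighted proportions.

    For each replicate, every cell's mutated-sample count is redrawn as
    Poisson(mean = observed count) and clamped at the cohort size; the full
    weighted-proportion pipeline is reapplied to the resimulated counts.
    Returns a DataFrame (index gene) with point estimate, simulation mean,
    and empirical 2.5/97.5 percentile bounds. One RNG stream seeded once,
    replicate-major draw order, so results are reproducible bit-for-bit.
    """
    if n_reps < 2:
        raise NumericError("n_reps must be >= 2")
    w = _aligned_weights(matrix, v)
    rng = np.random.default_rng(seed)
    m = len(matrix.genes)
    lam = matrix.counts.astype(float)
    cap = matrix.n_samples.astype(np.int64)
    inv_n = 1.0 / matrix.n_samples.astype(float)
    reps = np.empty((n_reps, m), dtype=float)
    for start in range(0, n_reps, chunk):
        stop = min(start + chunk, n_reps)
        draws = rng.poisson(lam=lam, size=(stop - start, *lam.shape))
        np.minimum(draws, cap[np.newaxis, np.newaxis, :], out=draws)
        reps[start:stop] = (draws * inv_n) @ w
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    point = matrix.prob @ w
    return pd.DataFrame(
        {
            "point": point,
            "sim_mean": reps.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def accumulated_rate(table: GeneSampleTable, gene: str) -> float:
    """Total qualifying mutation events in ``gene`` per patient (may exceed 1).

    Unlike the prevalence (<=1 count per sample), every record counts, so a
    patient with two distinct EGFR mutations contributes 2.
    """
    if table.n_samples == 0:
        raise NumericError("empty cohort")
    return table.record_counts.get(gene, 0) / table.n_samples
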