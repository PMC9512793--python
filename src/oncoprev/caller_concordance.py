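"""Variant-caller concordance on gene/patient call sets.

Different somatic callers run on the same cohort produce different call
sets; for gene-level prevalence the relevant question is how often they
agree on *which genes are mutated in which patients*. Metrics here operate
on deduplicated gene -> patient-set maps: the multiway shared-gene rate
(|intersection| / |union| of the gene lists), all pairwise rates, a per-gene
patient-count table, and a scale-free maximum-error rate built from summed
absolute pairwise count differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import NumericError
from .filtering import GeneSampleTable
from .mutation_io import MutationRecord

__all__ = [
    "CallerCallSet",
    "callset_from_records",
    "callset_from_table",
    "multiway_shared_rate",
    "pairwise_shared_rates",
    "max_error_rate",
    "per_gene_count_table",
]


@dataclass(slots=True)
class CallerCallSet:
    """One caller's calls: gene -> set of patients with >=1 qualifying call."""

    caller_id: str
    calls: dict[str, set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {g for g, pats in self.calls.items() if pats}

    def count(self, gene: str) -> int:
        return len(self.calls.get(gene, ()))


def callset_from_records(caller_id: str,
                         records: Iterable[MutationRecord]) -> CallerCallSet:
    """Build a call set from (already filtered) records, deduplicating patients."""
    calls: dict[str, set[str]] = {}
    for rec in records:
        calls.setdefault(rec.gene, set()).add(rec.sample_id)
    return CallerCallSet(caller_id=caller_id, calls=calls)


def callset_from_table(caller_id: str, table: GeneSampleTable) -> CallerCallSet:
    return CallerCallSet(
        caller_id=caller_id,
        calls={g: set(s) for g, s in table.mutated_samples.items()},
    )


def multiway_shared_rate(callsets: Sequence[CallerCallSet]) -> dict:
    """Fraction of the union gene list called by every caller.

    Returns ``{"shared_genes": |intersection|, "union_genes": |union|,
    "rate": shared/union}``.
    """
    if len(callsets) < 2:
        raise NumericError("need at least two call sets")
    gene_lists = [cs.genes for cs in callsets]
    union = set().union(*gene_lists)
    if not union:
        raise NumericError("all call sets are empty")
    shared = set.intersection(*gene_lists)
    return {
        "shared_genes": len(shared),
        "union_genes": len(union),
        "rate": len(shared) / len(union),
    }


def pairwise_shared_rates(callsets: Sequence[CallerCallSet]) -> pd.DataFrame:
    """Symmetric matrix of pairwise shared-gene rates (diagonal 1.0)."""
    if len(callsets) < 2:
        raise NumericError("need at least two call sets")
    ids = [cs.caller_id for cs in callsets]
    mat = np.ones((len(callsets), len(callsets)))
    for i, j in combinations(range(len(callsets)), 2):
        a, b = callsets[i].genes, callsets[j].genes
        union = a | b
        rate = len(a & b) / len(union) if union else float("nan")
        mat[i, j] = mat[j, i] = rate
    return pd.DataFrame(mat, index=ids, columns=ids)


def per_gene_count_table(callsets: Sequence[CallerCallSet]) -> pd.DataFrame:
    """Gene x caller table of deduplicated patient counts, sorted by the
    per-gene maximum count, descending (ties alphabetical)."""
    genes = sorted(set().union(*(cs.genes for cs in callsets)) if callsets else set())
    data = {cs.caller_id: [cs.count(g) for g in genes] for cs in callsets}
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    if len(df):
        order = df.max(axis=1).sort_values(ascending=False, kind="stable")
        df = df.loc[order.index]
    return df


def max_error_rate(callsets: Sequence[CallerCallSet]) -> float:
    """Summed absolute pairwise per-gene patient-count difference, normalized.

    E = [sum_g sum_{pairs (a,b)} |n_a(g) - n_b(g)|]
        / [n_pairs * sum_g max_c n_c(g)]

    over the union gene universe; 0 iff all callers report identical per-gene
    patient counts, and bounded above by 1.
    """
    if len(callsets) < 2:
        raise NumericError("need at least two call sets")
    table = per_gene_count_table(callsets)
    if table.empty:
        raise NumericError("all call sets are empty")
    counts = table.to_numpy(dtype=float)
    denom_mass = counts.max(axis=1).sum()
    if denom_mass <= 0:
        raise NumericError("all per-gene counts are zero")
    n_pairs = len(callsets) * (len(callsets) - 1) // 2
    num = 0.0
    for i, j in combinations(range(len(callsets)), 2):
        num += np.abs(counts[:, i] - counts[:, j]).sum()
    return num / (n_pairs * denom_mass)
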