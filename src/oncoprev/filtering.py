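"""Two-tier mutation filtering and per-gene mutated-sample tabulation.

Tier 1 restricts records to a cancer-gene census panel; tier 2 retains only
protein-altering consequences (missense, nonsense, frameshift, inframe indel,
splice). Tabulation counts a gene as mutated at most once per sample, while
keeping total qualifying record counts for accumulated-rate analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._tables import QUALIFYING_CLASSES
from .exceptions import ConfigurationError, EmptyCohortWarning, IntegrityError, NumericError
from .mutation_io import CohortProfile, GenePanel, MutationRecord

__all__ = [
    "GeneSampleTable",
    "tier1_filter",
    "tier2_filter",
    "dedup_records",
    "tabulate",
    "stratify",
]


@dataclass(slots=True)
class GeneSampleTable:
    """Per-cohort tabulation: gene -> mutated-sample set, plus record totals.

    ``mutated_samples[g]`` is the set of samples with >=1 qualifying call in
    gene ``g`` (the <=1-per-sample rule); ``record_counts[g]`` is the raw
    qualifying record total, used for accumulated rates.
    """

    cohort_id: str
    n_samples: int
    mutated_samples: dict[str, set[str]] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)

    def mutated_count(self, gene: str) -> int:
        return len(self.mutated_samples.get(gene, ()))

    def proportion(self, gene: str) -> float:
        """Fraction of samples mutated in ``gene`` (each sample counted once)."""
        return self.mutated_count(gene) / self.n_samples


def tier1_filter(records: Iterable[MutationRecord], panel: GenePanel
                 ) -> list[MutationRecord]:
    """Keep records whose (synonym-resolved) gene is in the census panel."""
    if not panel.official_symbols:
        raise ConfigurationError("tier-1 filter requires a non-empty panel")
    return [r for r in records if r.gene in panel.official_symbols]


def tier2_filter(records: Iterable[MutationRecord],
                 retained_classes: frozenset[str] = QUALIFYING_CLASSES
                 ) -> list[MutationRecord]:
    """Keep protein-altering consequences; drop silent/noncoding/SV/fusion/other.

    ``retained_classes`` is configurable so frameshift inclusion under the
    truncating umbrella can be toggled for sensitivity analysis.
    """
    return [r for r in records if r.variant_class in retained_classes]


def dedup_records(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Collapse byte-identical calls (same sample, gene, site, alleles).

    Guards against duplication when profiles merged from several repositories
    contain the same call twice. Order of first occurrence is preserved.
    """
    seen: set[tuple] = set()
    out: list[MutationRecord] = []
    for r in records:
        key = (r.sample_id, r.gene, r.chrom, r.pos, r.ref, r.alt)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def tabulate(cohort: CohortProfile) -> GeneSampleTable:
    """Build the per-gene mutated-sample table for an already-filtered cohort.

    A gene counts as mutated at most once per sample; the raw record totals
    are tabulated separately. Records whose sample is outside the roster are
    an integrity error; an empty cohort is rejected because downstream
    proportions would be undefined.
    """
    if cohort.n_samples == 0:
        raise NumericError(f"cohort {cohort.cohort_id!r} has no samples")
    table = GeneSampleTable(cohort_id=cohort.cohort_id, n_samples=cohort.n_samples)
    roster = cohort.samples.keys()
    for rec in cohort.records:
        if rec.sample_id not in roster:
            raise IntegrityError(
                f"record sample {rec.sample_id!r} not in roster of "
                f"cohort {cohort.cohort_id!r}"
            )
        table.mutated_samples.setdefault(rec.gene, set()).add(rec.sample_id)
        table.record_counts[rec.gene] = table.record_counts.get(rec.gene, 0) + 1
    return table


def stratify(cohort: CohortProfile, gender: str | None = None,
             smoking: str | None = None) -> CohortProfile:
    """Restrict a cohort to samples matching the requested strata.

    Samples with 'unknown' for a requested attribute are excluded unless
    'unknown' is explicitly requested. An empty result triggers an
    :class:`EmptyCohortWarning` rather than failing silently downstream.
    """

    def keep(info) -> bool:
        if gender is not None and info.gender != gender:
            return False
        if smoking is not None and info.smoking != smoking:
            return False
        return True

    samples = {sid: info for sid, info in cohort.samples.items() if keep(info)}
    records = [r for r in cohort.records if r.sample_id in samples]
    parts = [p for p in (gender, smoking) if p is not None]
    sub_id = cohort.cohort_id + ("|" + "|".join(parts) if parts else "")
    if not samples:
        warnings.warn(
            f"stratum {parts} of cohort {cohort.cohort_id!r} is empty",
            EmptyCohortWarning,
            stacklevel=2,
        )
    return CohortProfile(
        cohort_id=sub_id,
        subtype_code=cohort.subtype_code,
        samples=samples,
        records=records,
        icd10_site=cohort.icd10_site,
    )
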