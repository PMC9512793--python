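"""MAF-style mutation table I/O, sample annotations, and gene-synonym resolution.

The on-disk formats follow the cBioPortal/TCGA conventions: a tab-separated
mutation table with one row per variant call per sample (1-based coordinates),
and a separate sample-annotation TSV joined on sample ID. Column headers are
configurable through :class:`MafDialect` so exports from different portals can
be read without preprocessing.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._tables import DEFAULT_SYNONYMS, MAF_CLASS_MAP, VARIANT_CLASSES
from .exceptions import ConfigurationError, FormatError

__all__ = [
    "MutationRecord",
    "SampleInfo",
    "CohortProfile",
    "GenePanel",
    "MafDialect",
    "LoadReport",
    "read_maf",
    "write_profile",
    "read_annotations",
    "write_annotations",
    "read_gene_panel",
    "read_synonym_table",
    "resolve_synonyms",
]


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One somatic variant call in one sample (the MAF row abstraction)."""

    sample_id: str
    gene: str
    variant_class: str
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "T"
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")


@dataclass(frozen=True, slots=True)
class SampleInfo:
    """Per-sample clinical attributes; missing values are 'unknown'."""

    gender: str = "unknown"
    smoking: str = "unknown"


@dataclass(slots=True)
class CohortProfile:
    """A named cancer cohort: sample roster plus its mutation records.

    ``samples`` maps sample_id -> :class:`SampleInfo`; every record's
    sample_id must be in the roster (checked by :meth:`validate`).
    """

    cohort_id: str
    subtype_code: str
    samples: dict[str, SampleInfo]
    records: list[MutationRecord] = field(default_factory=list)
    icd10_site: str | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        roster = self.samples.keys()
        for rec in self.records:
            if rec.sample_id not in roster:
                from .exceptions import IntegrityError

                raise IntegrityError(
                    f"record sample {rec.sample_id!r} not in roster of "
                    f"cohort {self.cohort_id!r}"
                )


@dataclass(slots=True)
class GenePanel:
    """A cancer-gene census panel with an alias -> official-symbol map."""

    official_symbols: frozenset[str]
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.official_symbols:
            raise ConfigurationError("gene panel is empty")
        for alias, target in self.synonym_map.items():
            if alias in self.official_symbols:
                raise ConfigurationError(
                    f"alias {alias!r} is itself an official panel symbol"
                )
        # no alias maps to two targets by dict construction; loaders check
        # duplicates before building the dict

    def canonical(self, symbol: str) -> str:
        """Official symbol for ``symbol`` (identity if not an alias)."""
        return self.synonym_map.get(symbol, symbol)

    def __contains__(self, symbol: str) -> bool:
        return self.canonical(symbol) in self.official_symbols


@dataclass(slots=True)
class MafDialect:
    """Column-name aliases and variant-class vocabulary of a MAF flavour."""

    sample_cols: tuple[str, ...] = ("Tumor_Sample_Barcode", "Sample_ID", "sample_id")
    gene_cols: tuple[str, ...] = ("Hugo_Symbol", "gene", "Gene")
    class_cols: tuple[str, ...] = ("Variant_Classification", "variant_class")
    chrom_cols: tuple[str, ...] = ("Chromosome", "chrom")
    pos_cols: tuple[str, ...] = ("Start_Position", "Start_position", "pos")
    ref_cols: tuple[str, ...] = ("Reference_Allele", "ref")
    alt_cols: tuple[str, ...] = ("Tumor_Seq_Allele2", "Tumor_Allele", "alt")
    protein_cols: tuple[str, ...] = ("HGVSp_Short", "Protein_Change", "protein_change")
    class_map: Mapping[str, str] = field(default_factory=lambda: dict(MAF_CLASS_MAP))


DEFAULT_DIALECT = MafDialect()


@dataclass(slots=True)
class LoadReport:
    """Accounting of a MAF read: rows seen, parsed, remapped, skipped."""

    path: str = ""
    n_rows: int = 0
    n_parsed: int = 0
    n_unmapped_class: int = 0
    n_skipped: int = 0
    unmapped_tokens: Counter = field(default_factory=Counter)
    skipped_rows: list[str] = field(default_factory=list)


def _pick_column(header: Sequence[str], candidates: tuple[str, ...],
                 what: str, required: bool = True) -> str | None:
    for name in candidates:
        if name in header:
            return name
    if required:
        raise FormatError(
            f"mandatory column for {what} not found; expected one of {candidates}"
        )
    return None


def read_maf(path: str | Path, dialect: MafDialect = DEFAULT_DIALECT
             ) -> tuple[list[MutationRecord], LoadReport]:
    """Read a MAF-style TSV into :class:`MutationRecord` objects.

    Variant classes are mapped through ``dialect.class_map``; rows whose class
    token is not in the map get ``variant_class='other'`` and are counted in
    the report. Unreadable rows are skipped and recorded, never silently lost.
    """
    path = Path(path)
    report = LoadReport(path=str(path))
    records: list[MutationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        header = reader.fieldnames
        c_sample = _pick_column(header, dialect.sample_cols, "sample ID")
        c_gene = _pick_column(header, dialect.gene_cols, "gene symbol")
        c_class = _pick_column(header, dialect.class_cols, "variant classification")
        c_chrom = _pick_column(header, dialect.chrom_cols, "chromosome", required=False)
        c_pos = _pick_column(header, dialect.pos_cols, "position", required=False)
        c_ref = _pick_column(header, dialect.ref_cols, "reference allele", required=False)
        c_alt = _pick_column(header, dialect.alt_cols, "alternate allele", required=False)
        c_prot = _pick_column(header, dialect.protein_cols, "protein change", required=False)
        for row in reader:
            report.n_rows += 1
            try:
                raw_class = (row[c_class] or "").strip()
                vclass = dialect.class_map.get(raw_class)
                if vclass is None:
                    vclass = "other"
                    report.n_unmapped_class += 1
                    report.unmapped_tokens[raw_class] += 1
                rec = MutationRecord(
                    sample_id=row[c_sample].strip(),
                    gene=row[c_gene].strip(),
                    variant_class=vclass,
                    chrom=(row[c_chrom].strip() if c_chrom else "1") or "1",
                    pos=int(row[c_pos]) if c_pos and row[c_pos] else 1,
                    ref=(row[c_ref].strip() if c_ref else "A") or "A",
                    alt=(row[c_alt].strip() if c_alt else "T") or "T",
                    protein_change=(row[c_prot].strip() or None) if c_prot else None,
                )
            except (ValueError, KeyError, TypeError) as exc:
                report.n_skipped += 1
                report.skipped_rows.append(f"row {report.n_rows}: {exc}")
                continue
            records.append(rec)
            report.n_parsed += 1
    return records, report


_WRITE_HEADER = [
    "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
    "Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2",
    "HGVSp_Short",
]


def write_profile(cohort: CohortProfile, path: str | Path) -> None:
    """Write a cohort's records as a MAF-style TSV (read back by `read_maf`)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_WRITE_HEADER)
        for r in cohort.records:
            writer.writerow(
                [r.gene, r.sample_id, r.variant_class, r.chrom, r.pos,
                 r.ref, r.alt, r.protein_change or ""]
            )


def write_annotations(cohort: CohortProfile, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "cohort_id", "subtype_code", "gender", "smoking"])
        for sid, info in cohort.samples.items():
            writer.writerow([sid, cohort.cohort_id, cohort.subtype_code,
                             info.gender, info.smoking])


def read_annotations(path: str | Path) -> dict[str, SampleInfo]:
    """Read a sample-annotation TSV; missing attributes become 'unknown'."""
    out: dict[str, SampleInfo] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise FormatError(f"{path}: annotation file needs a sample_id column")
        for row in reader:
            out[row["sample_id"]] = SampleInfo(
                gender=(row.get("gender") or "unknown").strip() or "unknown",
                smoking=(row.get("smoking") or "unknown").strip() or "unknown",
            )
    return out


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Read a two-column alias<TAB>official TSV; ambiguous aliases are errors."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{i}: expected two tab-separated columns")
            alias, official = parts[0].strip(), parts[1].strip()
            if alias == "alias":  # optional header
                continue
            if alias in mapping and mapping[alias] != official:
                raise ConfigurationError(
                    f"{path}: alias {alias!r} maps to both "
                    f"{mapping[alias]!r} and {official!r}"
                )
            mapping[alias] = official
    return mapping


def read_gene_panel(panel_path: str | Path,
                    synonym_path: str | Path | None = None) -> GenePanel:
    """Read a gene panel (one symbol per line or first TSV column).

    With no synonym file the bundled default alias table is used, restricted
    to aliases whose target is in the panel.
    """
    symbols: set[str] = set()
    with open(panel_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym = line.split("\t")[0].strip()
            if sym and sym.lower() not in ("gene", "hugo_symbol", "symbol"):
                symbols.add(sym)
    if not symbols:
        raise ConfigurationError(f"{panel_path}: no gene symbols found")
    if synonym_path is not None:
        synonyms = read_synonym_table(synonym_path)
    else:
        synonyms = {a: t for a, t in DEFAULT_SYNONYMS.items() if t in symbols}
    synonyms = {a: t for a, t in synonyms.items() if a not in symbols}
    return GenePanel(official_symbols=frozenset(symbols), synonym_map=synonyms)


def resolve_synonyms(records: Iterable[MutationRecord], panel: GenePanel
                     ) -> tuple[list[MutationRecord], Counter]:
    """Rewrite alias gene symbols to official symbols.

    Returns the rewritten records and a Counter of substitutions by alias.
    Idempotent: official symbols (and unknown symbols) pass through unchanged.
    """
    substitutions: Counter = Counter()
    out: list[MutationRecord] = []
    for rec in records:
        official = panel.synonym_map.get(rec.gene)
        if official is not None and official != rec.gene:
            substitutions[rec.gene] += 1
            rec = replace(rec, gene=official)
        out.append(rec)
    return out, substitutions
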