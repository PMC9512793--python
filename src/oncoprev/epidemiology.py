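"""Registry incidence weights, subtype->site aggregation, and ICD re-weighting.

The weight vector v gives each tumor site's fractional contribution to total
cancer incidence. Sites present in the registry but lacking sequencing data
contribute their combined incidence fraction Q; the weights of the sequenced
sites are rescaled by 1/(1-Q) so they again sum to one. Incidence recorded
under ICD-O-3 categories is first re-allocated onto ICD-10 major sites by a
many-to-one site map, conserving incidence mass, before the same rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, NumericError
from .mutation_io import CohortProfile

__all__ = [
    "WeightVector",
    "load_incidence",
    "validate_incidence",
    "load_site_map",
    "aggregate_profiles",
    "preliminary_weights",
    "rescale_for_coverage",
    "convert_icdo3",
]

_TOL = 1e-9


@dataclass(slots=True)
class WeightVector:
    """Per-site epidemiological weights with provenance.

    ``kind`` is 'preliminary' (all registry sites, sums to 1) or 'final'
    (sequenced sites only, rescaled by 1/(1-Q), sums to 1). ``q`` is the
    incidence fraction of sites without sequencing data.
    """

    weights: pd.Series  # index: site codes, values: fractions
    kind: str = "preliminary"
    q: float | None = None

    def __post_init__(self) -> None:
        if (self.weights < -_TOL).any():
            raise NumericError("negative weight")
        total = float(self.weights.sum())
        if abs(total - 1.0) > 1e-6:
            raise NumericError(f"weights sum to {total}, expected 1")

    @property
    def sites(self) -> list[str]:
        return list(self.weights.index)

    def __getitem__(self, site: str) -> float:
        return float(self.weights[site])


def validate_incidence(incidence: pd.DataFrame) -> pd.DataFrame:
    """Check an incidence table (columns site, year, cases) and return it."""
    for col in ("site", "year", "cases"):
        if col not in incidence.columns:
            raise ConfigurationError(f"incidence table missing column {col!r}")
    if (incidence["cases"] < 0).any():
        raise NumericError("negative case count in incidence table")
    if incidence.duplicated(subset=["site", "year"]).any():
        dup = incidence[incidence.duplicated(subset=["site", "year"], keep=False)]
        raise ConfigurationError(
            f"duplicate (site, year) rows in incidence table: "
            f"{sorted(set(map(tuple, dup[['site', 'year']].values)))[:5]}"
        )
    return incidence


def load_incidence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    return validate_incidence(df)


def load_site_map(path: str | Path) -> dict[str, str]:
    """Read a two-column subtype<TAB>icd10_site TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: site map needs two columns")
    sub_col, site_col = df.columns[0], df.columns[1]
    mapping = dict(zip(df[sub_col], df[site_col]))
    return mapping


def aggregate_profiles(profiles: Sequence[CohortProfile],
                       site_map: Mapping[str, str]) -> list[CohortProfile]:
    """Merge subtype cohorts into per-site cohorts (e.g. 94 subtypes -> 23 sites).

    Sample rosters and records are concatenated per target site; the total
    sample count is conserved. Unmapped subtype codes are an error listing
    every offending code.
    """
    missing = sorted({p.subtype_code for p in profiles} - set(site_map))
    if missing:
        raise ConfigurationError(f"unmapped subtype codes: {missing}")
    merged: dict[str, CohortProfile] = {}
    for p in profiles:
        site = site_map[p.subtype_code]
        tgt = merged.get(site)
        if tgt is None:
            tgt = CohortProfile(
                cohort_id=site, subtype_code=site, samples={}, records=[],
                icd10_site=site,
            )
            merged[site] = tgt
        overlap = tgt.samples.keys() & p.samples.keys()
        if overlap:
            raise ConfigurationError(
                f"sample IDs shared between subtypes mapping to {site}: "
                f"{sorted(overlap)[:5]}"
            )
        tgt.samples.update(p.samples)
        tgt.records.extend(p.records)
    return [merged[s] for s in sorted(merged)]


def preliminary_weights(incidence: pd.DataFrame) -> WeightVector:
    """Per-site incidence fractions: sum cases over years, divide by the total."""
    validate_incidence(incidence)
    per_site = incidence.groupby("site")["cases"].sum().astype(float)
    total = float(per_site.sum())
    if total <= 0:
        raise NumericError("incidence table has no cases")
    return WeightVector(weights=per_site / total, kind="preliminary", q=None)


def rescale_for_coverage(prelim: WeightVector,
                         sequenced_sites: Iterable[str]) -> WeightVector:
    """Drop unsequenced sites and renormalize: final = preliminary / (1 - Q).

    Q is the summed preliminary weight of sites without sequencing data.
    Sites sequenced but absent from the registry are ignored here (they carry
    zero incidence weight); the caller is expected to warn about them.
    """
    sequenced = set(sequenced_sites)
    if not sequenced:
        raise NumericError("no sequenced sites")
    kept = [s for s in prelim.sites if s in sequenced]
    if not kept:
        raise NumericError("no overlap between incidence sites and sequenced sites")
    q = float(prelim.weights[~prelim.weights.index.isin(sequenced)].sum())
    if q >= 1.0 - _TOL:
        raise NumericError(f"Q = {q}: all incidence mass is unsequenced")
    final = prelim.weights[kept] / (1.0 - q)
    final = final / float(final.sum())  # exact renormalization
    return WeightVector(weights=final, kind="final", q=q)


def convert_icdo3(weights_icdo3: Mapping[str, float],
                  site_map: Mapping[str, str],
                  sequenced_sites: Iterable[str] | None = None) -> WeightVector:
    """Re-allocate ICD-O-3 category weights onto ICD-10 sites (mass conserved).

    Each ICD-10 site's weight is the sum of its mapped ICD-O-3 categories.
    If ``sequenced_sites`` is given, coverage rescaling is applied afterwards.
    """
    missing = sorted(set(weights_icdo3) - set(site_map))
    if missing:
        raise ConfigurationError(f"unmapped ICD-O-3 categories: {missing}")
    acc: dict[str, float] = {}
    for cat, w in weights_icdo3.items():
        site = site_map[cat]
        acc[site] = acc.get(site, 0.0) + float(w)
    series = pd.Series(acc).sort_index()
    total = float(series.sum())
    if total <= 0:
        raise NumericError("ICD-O-3 weights sum to zero")
    prelim = WeightVector(weights=series / total, kind="preliminary", q=None)
    if sequenced_sites is None:
        return prelim
    return rescale_for_coverage(prelim, sequenced_sites)
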