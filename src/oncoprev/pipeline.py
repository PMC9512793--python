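"""End-to-end orchestration: read -> resolve -> filter -> weight -> estimate.

`run_pipeline` wires the stages together exactly once, persists every
intermediate artifact, and logs per-stage record counts so filtration
accounting is auditable. The CLI wraps this module thinly.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import epidemiology, filtering, prevalence
from .exceptions import ConfigurationError
from .mutation_io import (
    CohortProfile,
    SampleInfo,
    read_gene_panel,
    read_maf,
    resolve_synonyms,
)

logger = logging.getLogger("oncoprev")

__all__ = ["RunConfig", "run_pipeline", "load_profiles"]


@dataclass(slots=True)
class RunConfig:
    """Validated inputs and parameters of one pipeline run."""

    profiles_dir: Path
    panel_path: Path
    incidence_path: Path
    site_map_path: Path
    outdir: Path
    synonyms_path: Path | None = None
    n_reps: int = 2000
    seed: int = 0
    top_k: int = 50
    delta: float = 0.10
    retained_classes: frozenset[str] = field(
        default_factory=lambda: frozenset(filtering.QUALIFYING_CLASSES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def p(key: str, required: bool = True) -> Path | None:
            val = raw.get(key)
            if val is None:
                if required:
                    raise ConfigurationError(f"config missing key {key!r}")
                return None
            q = Path(val)
            return q if q.is_absolute() else base / q

        cfg = cls(
            profiles_dir=p("profiles_dir"),
            panel_path=p("panel"),
            incidence_path=p("incidence"),
            site_map_path=p("site_map"),
            outdir=p("outdir"),
            synonyms_path=p("synonyms", required=False),
            n_reps=int(raw.get("n_reps", 2000)),
            seed=int(raw.get("seed", 0)),
            top_k=int(raw.get("top_k", 50)),
            delta=float(raw.get("delta", 0.10)),
        )
        if "retained_classes" in raw:
            cfg.retained_classes = frozenset(raw["retained_classes"])
        return cfg

    def validate(self) -> None:
        for name in ("profiles_dir", "panel_path", "incidence_path", "site_map_path"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigurationError(f"{name} does not exist: {path}")
        if self.synonyms_path is not None and not self.synonyms_path.exists():
            raise ConfigurationError(f"synonyms_path does not exist: {self.synonyms_path}")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")


def load_profiles(profiles_dir: str | Path) -> list[CohortProfile]:
    """Load every `<stem>.maf.tsv` + `<stem>.samples.tsv` pair in a directory.

    The annotation file supplies the roster, the subtype code and the
    gender/smoking attributes; samples with records but no annotation row
    are an integrity error surfaced by tabulation later.
    """
    profiles_dir = Path(profiles_dir)
    mafs = sorted(profiles_dir.glob("*.maf.tsv"))
    if not mafs:
        raise ConfigurationError(f"no *.maf.tsv files in {profiles_dir}")
    cohorts: list[CohortProfile] = []
    for maf in mafs:
        stem = maf.name[: -len(".maf.tsv")]
        ann = profiles_dir / f"{stem}.samples.tsv"
        records, _ = read_maf(maf)
        samples: dict[str, SampleInfo] = {}
        subtype = stem
        if ann.exists():
            with open(ann, newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    samples[row["sample_id"]] = SampleInfo(
                        gender=row.get("gender") or "unknown",
                        smoking=row.get("smoking") or "unknown",
                    )
                    subtype = row.get("subtype_code") or subtype
        else:
            samples = {r.sample_id: SampleInfo() for r in records}
        cohorts.append(
            CohortProfile(
                cohort_id=stem, subtype_code=subtype,
                samples=samples, records=records,
            )
        )
    return cohorts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full estimation pipeline and persist all artifacts.

    Returns a dict with the in-memory results (matrix, weights, prevalence
    table) and the paths written, for programmatic use and testing.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = read_gene_panel(config.panel_path, config.synonyms_path)
    cohorts = load_profiles(config.profiles_dir)
    site_map = epidemiology.load_site_map(config.site_map_path)
    incidence = epidemiology.load_incidence(config.incidence_path)

    stage_counts: list[dict] = []
    filtered: list[CohortProfile] = []
    for cohort in cohorts:
        n0 = len(cohort.records)
        recs, subs = resolve_synonyms(cohort.records, panel)
        recs = filtering.dedup_records(recs)
        n_dedup = len(recs)
        recs = filtering.tier1_filter(recs, panel)
        n1 = len(recs)
        recs = filtering.tier2_filter(recs, config.retained_classes)
        n2 = len(recs)
        stage_counts.append(
            {
                "cohort": cohort.cohort_id, "records_in": n0,
                "after_dedup": n_dedup, "after_tier1": n1, "after_tier2": n2,
                "synonym_substitutions": int(sum(subs.values())),
                "n_samples": cohort.n_samples,
            }
        )
        logger.info(
            "cohort %s: %d records -> dedup %d -> tier1 %d -> tier2 %d",
            cohort.cohort_id, n0, n_dedup, n1, n2,
        )
        filtered.append(
            CohortProfile(
                cohort_id=cohort.cohort_id, subtype_code=cohort.subtype_code,
                samples=cohort.samples, records=recs,
                icd10_site=cohort.icd10_site,
            )
        )

    site_cohorts = epidemiology.aggregate_profiles(filtered, site_map)
    total_in = sum(c.n_samples for c in filtered)
    total_out = sum(c.n_samples for c in site_cohorts)
    assert total_in == total_out, "sample count not conserved by aggregation"

    tables = {c.icd10_site: filtering.tabulate(c) for c in site_cohorts}

    prelim = epidemiology.preliminary_weights(incidence)
    sequenced = set(tables)
    uncovered = sorted(sequenced - set(prelim.sites))
    if uncovered:
        warnings.warn(
            f"sequenced sites absent from the incidence table get weight 0: "
            f"{uncovered}"
        )
        sequenced -= set(uncovered)
    final_w = epidemiology.rescale_for_coverage(prelim, sequenced)

    genes = sorted(panel.official_symbols)
    matrix = prevalence.conditional_matrix(
        tables, genes, site_order=final_w.sites
    )
    ci_table = prevalence.poisson_ci(
        matrix, final_w, n_reps=config.n_reps, seed=config.seed
    )
    ranked = ci_table.copy()
    ranked["_gene"] = ranked.index
    ranked = ranked.sort_values(["point", "_gene"],
                                ascending=[False, True]).drop(columns="_gene")

    # persisted artifacts
    per_site = pd.DataFrame(matrix.prob, index=matrix.genes, columns=matrix.sites)
    prev_out = ranked.join(per_site)
    prev_path = outdir / "prevalence.tsv"
    prev_out.to_csv(prev_path, sep="\t")
    weights_path = outdir / "weights.tsv"
    wdf = final_w.weights.rename("final_weight").to_frame()
    wdf["preliminary_weight"] = prelim.weights.reindex(wdf.index)
    wdf["n_samples"] = [tables[s].n_samples for s in wdf.index]
    wdf.to_csv(weights_path, sep="\t", index_label="site")
    filter_path = outdir / "filter_report.tsv"
    pd.DataFrame(stage_counts).to_csv(filter_path, sep="\t", index=False)
    manifest = {
        "seed": config.seed,
        "n_reps": config.n_reps,
        "q": final_w.q,
        "n_genes": len(genes),
        "n_sites": len(final_w.sites),
        "n_samples_total": int(total_out),
        "panel_sha256": _sha256(Path(config.panel_path)),
        "incidence_sha256": _sha256(Path(config.incidence_path)),
        "retained_classes": sorted(config.retained_classes),
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "panel": panel,
        "site_tables": tables,
        "matrix": matrix,
        "weights": final_w,
        "preliminary_weights": prelim,
        "prevalence": ci_table,
        "stage_counts": stage_counts,
        "paths": {
            "prevalence": prev_path,
            "weights": weights_path,
            "filter_report": filter_path,
            "manifest": manifest_path,
        },
    }
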