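"""Synthetic multi-cohort mutation studies with known ground truth.

Every downstream stage (filtering, weighting, prevalence, comparison,
concordance) is exercised against cohorts generated from a known
:class:`TruthModel`: per-site per-gene mutation probabilities, registry-style
incidence counts (including sites with no sequencing data, to exercise the
coverage rescaling), a controllable fraction of non-qualifying noise records
(silent/noncoding/SV/fusion or off-panel genes), and synonym-aliased gene
symbols drawn from the bundled alias table.

The generative model per sample: each panel gene mutates independently with
its site's true probability; a mutated sample-gene pair yields
1 + Poisson(lambda_extra) distinct records (so accumulated rates can exceed
prevalence), each with a protein-altering consequence class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._tables import DEFAULT_SYNONYMS, ICD10_MAJOR_SITES, KNOWN_CANCER_GENES
from .caller_concordance import CallerCallSet, callset_from_records
from .epidemiology import WeightVector, preliminary_weights, rescale_for_coverage
from .mutation_io import (
    CohortProfile,
    GenePanel,
    MutationRecord,
    SampleInfo,
    write_annotations,
    write_profile,
)

__all__ = [
    "TruthModel",
    "gen_truth",
    "gen_cohort_profiles",
    "gen_caller_calls",
    "true_weight_vector",
    "true_weighted_proportions",
    "write_study",
]

# Consequence-class frequencies among qualifying somatic calls (roughly the
# proportions seen in public pan-cancer MAFs).
_QUAL_CLASSES = ("missense", "nonsense", "frameshift", "inframe_indel", "splice")
_QUAL_WEIGHTS = (0.62, 0.12, 0.12, 0.04, 0.10)

_NOISE_CLASSES = ("silent", "noncoding", "SV", "fusion")

_GENDERS = ("female", "male")
_GENDER_P = (0.5, 0.5)
_SMOKING = ("smoker", "non-smoker", "unknown")
_SMOKING_P = (0.3, 0.6, 0.1)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(slots=True)
class TruthModel:
    """Ground truth for a simulated study.

    ``true_prob`` has shape (n_genes, n_sites) over ``gene_ids`` x
    ``site_ids`` (the sequenced sites). ``site_incidence`` may contain extra
    site codes with no sequencing cohort; their incidence mass becomes Q.
    """

    gene_ids: list[str]
    site_ids: list[str]
    true_prob: np.ndarray
    site_incidence: dict[str, int]
    noise: float = 0.05
    alias_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_prob = np.asarray(self.true_prob, dtype=float)
        if self.true_prob.shape != (len(self.gene_ids), len(self.site_ids)):
            raise ValueError("true_prob shape does not match gene/site ids")
        if ((self.true_prob < 0) | (self.true_prob > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if any(c < 0 for c in self.site_incidence.values()):
            raise ValueError("incidence counts must be nonnegative")
        for frac, name in ((self.noise, "noise"), (self.alias_rate, "alias_rate")):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    def panel(self) -> GenePanel:
        """Census panel over the truth's genes, with bundled aliases attached."""
        symbols = frozenset(self.gene_ids)
        synonyms = {a: t for a, t in DEFAULT_SYNONYMS.items()
                    if t in symbols and a not in symbols}
        return GenePanel(official_symbols=symbols, synonym_map=synonyms)


def _gene_names(n: int) -> list[str]:
    names = list(KNOWN_CANCER_GENES[:n])
    names += [f"G{i:04d}" for i in range(len(names), n)]
    return names


def _site_names(n: int) -> list[str]:
    names = list(ICD10_MAJOR_SITES[:n])
    names += [f"S{i:02d}" for i in range(len(names), n)]
    return names


def gen_truth(n_genes: int, n_sites: int, seed: int, *,
              noise: float = 0.05, alias_rate: float = 0.05,
              n_unsequenced_sites: int = 2) -> TruthModel:
    """Draw a reproducible TruthModel.

    Mutation probabilities are a two-component mixture: most genes draw
    near-zero rates (Beta(1.1, 30), mean ~3.5%) while a small "driver"
    subset — always including the first gene, the TP53 analogue — draws
    Beta(2.5, 4) (mean ~38%), reproducing the dominance of a few highly
    mutated genes over a long low-frequency tail. Incidence counts are
    lognormal (median ~2e4 cases/site); ``n_unsequenced_sites`` extra sites
    receive incidence but no cohort, to exercise Q-rescaling.
    """
    if n_genes < 1 or n_sites < 1:
        raise ValueError("n_genes and n_sites must be >= 1")
    if n_unsequenced_sites < 0:
        raise ValueError("n_unsequenced_sites must be >= 0")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    sites = _site_names(n_sites)
    hot = np.zeros(n_genes, dtype=bool)
    hot[0] = True
    hot |= rng.random(n_genes) < 0.08
    prob = rng.beta(1.1, 30.0, size=(n_genes, n_sites))
    prob[hot] = rng.beta(2.5, 4.0, size=(int(hot.sum()), n_sites))
    incidence = {
        s: int(max(1, round(c)))
        for s, c in zip(sites, rng.lognormal(mean=10.0, sigma=0.8, size=n_sites))
    }
    for i in range(n_unsequenced_sites):
        incidence[f"U{i:02d}"] = int(
            max(1, round(rng.lognormal(mean=9.0, sigma=0.8)))
        )
    return TruthModel(
        gene_ids=genes, site_ids=sites, true_prob=prob,
        site_incidence=incidence, noise=noise, alias_rate=alias_rate, seed=seed,
    )


def _random_record(rng: np.random.Generator, sample_id: str, gene: str,
                   variant_class: str) -> MutationRecord:
    pos = int(rng.integers(1, 250_000_000))
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    protein = None
    if variant_class == "missense":
        a, b = rng.choice(list(_AA), size=2)
        protein = f"{a}{int(rng.integers(1, 1200))}{b}"
    return MutationRecord(
        sample_id=sample_id, gene=gene, variant_class=variant_class,
        chrom=str(int(rng.integers(1, 23))), pos=pos, ref=str(ref), alt=str(alt),
        protein_change=protein,
    )


def gen_cohort_profiles(truth: TruthModel, samples_per_site: int, seed: int, *,
                        subtypes_per_site: int = 1,
                        lambda_extra: float = 0.15) -> list[CohortProfile]:
    """Generate one cohort per (site, subtype) under the truth model.

    Each site's ``samples_per_site`` samples are split evenly across
    ``subtypes_per_site`` subtype cohorts (codes ``<site>.<t>``), so the
    subtype -> site aggregation step has real work to do. Noise records and
    synonym aliases are injected at the truth's configured rates.
    """
    if samples_per_site < 1:
        raise ValueError("samples_per_site must be >= 1")
    if subtypes_per_site < 1:
        raise ValueError("subtypes_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    alias_of: dict[str, list[str]] = {}
    for alias, official in DEFAULT_SYNONYMS.items():
        if official in truth.gene_ids and alias not in truth.gene_ids:
            alias_of.setdefault(official, []).append(alias)
    panel_genes = truth.gene_ids
    cohorts: list[CohortProfile] = []
    for j, site in enumerate(truth.site_ids):
        p_site = truth.true_prob[:, j]
        # even split; earlier subtypes take the remainder
        base, rem = divmod(samples_per_site, subtypes_per_site)
        sizes = [base + (1 if t < rem else 0) for t in range(subtypes_per_site)]
        offset = 0
        for t, size in enumerate(sizes):
            if size == 0:
                continue
            subtype = f"{site}.{t}"
            samples: dict[str, SampleInfo] = {}
            for s in range(size):
                sid = f"{site}-{offset + s:05d}"
                samples[sid] = SampleInfo(
                    gender=str(rng.choice(_GENDERS, p=_GENDER_P)),
                    smoking=str(rng.choice(_SMOKING, p=_SMOKING_P)),
                )
            sids = list(samples)
            hits = rng.random((size, len(panel_genes))) < p_site[np.newaxis, :]
            records: list[MutationRecord] = []
            for s_idx, g_idx in zip(*np.nonzero(hits)):
                gene = panel_genes[g_idx]
                n_rec = 1 + int(rng.poisson(lambda_extra))
                for _ in range(n_rec):
                    vclass = str(rng.choice(_QUAL_CLASSES, p=_QUAL_WEIGHTS))
                    records.append(
                        _random_record(rng, sids[s_idx], gene, vclass)
                    )
            # alias a fraction of qualifying records (resolvable by the panel)
            if truth.alias_rate > 0 and alias_of:
                from dataclasses import replace as _replace

                for i, rec in enumerate(records):
                    if rec.gene in alias_of and rng.random() < truth.alias_rate:
                        alias = str(rng.choice(alias_of[rec.gene]))
                        records[i] = _replace(rec, gene=alias)
            # noise records so that they are ~`noise` of the final total
            if truth.noise > 0 and records:
                n_noise = int(round(len(records) * truth.noise / (1 - truth.noise)))
                for _ in range(n_noise):
                    sid = sids[int(rng.integers(size))]
                    if rng.random() < 0.5:
                        gene = panel_genes[int(rng.integers(len(panel_genes)))]
                        vclass = str(rng.choice(_NOISE_CLASSES))
                    else:  # off-panel gene with an otherwise qualifying class
                        gene = f"NPG{int(rng.integers(500)):03d}"
                        vclass = "missense"
                    records.append(_random_record(rng, sid, gene, vclass))
            offset += size
            cohorts.append(
                CohortProfile(
                    cohort_id=subtype, subtype_code=subtype,
                    samples=samples, records=records, icd10_site=site,
                )
            )
    return cohorts


def gen_caller_calls(base_cohort: CohortProfile, n_callers: int,
                     drop_rate: float | Sequence[float], seed: int
                     ) -> list[CallerCallSet]:
    """Simulate caller call sets by independently thinning the base records.

    Caller k misses each true record with probability ``drop_rate[k]``
    (a scalar applies to every caller).
    """
    if n_callers < 2:
        raise ValueError("n_callers must be >= 2")
    rates = np.broadcast_to(np.asarray(drop_rate, dtype=float), (n_callers,))
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("drop_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    callsets = []
    for k in range(n_callers):
        keep = rng.random(len(base_cohort.records)) >= rates[k]
        kept = [r for r, ok in zip(base_cohort.records, keep) if ok]
        callsets.append(callset_from_records(f"caller{k + 1}", kept))
    return callsets


def incidence_frame(truth: TruthModel, year: int = 2010) -> pd.DataFrame:
    """The truth's incidence as a registry-style (site, year, cases) table."""
    return pd.DataFrame(
        {
            "site": list(truth.site_incidence),
            "year": year,
            "cases": list(truth.site_incidence.values()),
        }
    )


def true_weight_vector(truth: TruthModel) -> WeightVector:
    """Final (coverage-rescaled) weights implied by the truth's incidence."""
    prelim = preliminary_weights(incidence_frame(truth))
    return rescale_for_coverage(prelim, truth.site_ids)


def true_weighted_proportions(truth: TruthModel) -> pd.Series:
    """Ground-truth weighted proportions: sum_j true_prob[i, j] * v_j."""
    v = true_weight_vector(truth)
    w = v.weights.reindex(truth.site_ids).to_numpy(dtype=float)
    return pd.Series(truth.true_prob @ w, index=truth.gene_ids,
                     name="true_weighted_proportion")


def write_study(truth: TruthModel, cohorts: Sequence[CohortProfile],
                outdir: str | Path) -> dict[str, Path]:
    """Persist a simulated study as the pipeline's expected plain-text inputs.

    Writes one MAF + annotation TSV per cohort, the incidence TSV, the
    subtype -> site map TSV, the panel and synonym TSVs, and the truth as
    YAML (probabilities as TSV alongside). Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    maf_dir = outdir / "profiles"
    maf_dir.mkdir(exist_ok=True)
    for cohort in cohorts:
        stem = cohort.subtype_code.replace("/", "_")
        write_profile(cohort, maf_dir / f"{stem}.maf.tsv")
        write_annotations(cohort, maf_dir / f"{stem}.samples.tsv")
    paths["profiles"] = maf_dir
    inc = outdir / "incidence.tsv"
    incidence_frame(truth).to_csv(inc, sep="\t", index=False)
    paths["incidence"] = inc
    smap = outdir / "site_map.tsv"
    with open(smap, "w") as fh:
        fh.write("subtype_code\ticd10_site\n")
        for cohort in cohorts:
            fh.write(f"{cohort.subtype_code}\t{cohort.icd10_site}\n")
    paths["site_map"] = smap
    panel_path = outdir / "panel.tsv"
    panel_path.write_text("\n".join(truth.gene_ids) + "\n")
    paths["panel"] = panel_path
    syn_path = outdir / "synonyms.tsv"
    panel = truth.panel()
    with open(syn_path, "w") as fh:
        fh.write("alias\tofficial\n")
        for alias, official in sorted(panel.synonym_map.items()):
            fh.write(f"{alias}\t{official}\n")
    paths["synonyms"] = syn_path
    truth_yaml = outdir / "truth.yaml"
    with open(truth_yaml, "w") as fh:
        yaml.safe_dump(
            {
                "gene_ids": truth.gene_ids,
                "site_ids": truth.site_ids,
                "site_incidence": {k: int(v) for k, v in truth.site_incidence.items()},
                "noise": truth.noise,
                "alias_rate": truth.alias_rate,
                "seed": truth.seed,
                "true_prob_tsv": "true_prob.tsv",
            },
            fh,
        )
    pd.DataFrame(truth.true_prob, index=truth.gene_ids,
                 columns=truth.site_ids).to_csv(outdir / "true_prob.tsv", sep="\t")
    paths["truth"] = truth_yaml
    return paths
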