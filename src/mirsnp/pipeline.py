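"""Orchestration of the discovery and association runs.

``run_discovery`` executes the stepwise integration: publication-count
classification -> seed-site scan of the surviving genes' UTRs -> variant
intersection and allele scoring -> GO-term filter -> MAF ranking.  Its
funnel report records the count surviving each step, at both the variant
and the gene level.

``run_association`` computes miRNA-target expression correlations, the
nested lymph-node ANOVA for both node terms, reduced-model residuals, and
a grid of additive-model power calculations.

Two runs with identical configuration and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .association import (
    PowerSpec,
    log2_counts,
    nested_anova_lymph,
    pearson_corr,
    power_closed_form,
    reduced_model_residuals,
)
from .litmine import (
    classify_cancer_genes,
    compute_publication_cutoff,
    read_publication_counts,
    write_gene_list,
)
from .target_sites import (
    CONSERVED_SITE_TYPES,
    map_sites,
    read_mirna_fasta,
    read_utr_fasta,
    write_sites_bed,
)
from .variant_overlap import (
    CandidateRow,
    filter_by_go,
    intersect_sites_variants,
    rank_candidates,
    read_go_annotations,
    read_maf_sidecar,
    read_variants_vcf,
    score_variant_site,
    write_candidates_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DiscoveryResult", "run_discovery", "run_association",
           "simulate_full_study"]


@dataclass
class RunConfig:
    """Validated configuration of a full run; serialized into the report."""

    # discovery inputs
    counts_tsv: Optional[str] = None
    utr_fasta: Optional[str] = None
    mirna_fasta: Optional[str] = None
    vcf: Optional[str] = None
    maf_sidecar: Optional[str] = None
    go_tsv: Optional[str] = None
    # association inputs
    expression_tsv: Optional[str] = None
    clinical_tsv: Optional[str] = None
    pairs: Sequence[Sequence[str]] = field(default_factory=list)
    # parameters
    publication_cutoff: object = "auto"  # "auto" (nonzero median) or int
    maf_floor: float = 0.01
    site_types: Sequence[str] = tuple(CONSERVED_SITE_TYPES)
    go_term: str = "GO:0007010"
    log_transform: bool = True
    power_grid: Sequence[dict] = field(default_factory=list)
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        if self.publication_cutoff != "auto":
            self.publication_cutoff = int(self.publication_cutoff)
            if self.publication_cutoff < 1:
                raise ValueError("publication_cutoff must be >= 1 or 'auto'")
        if not 0.0 <= self.maf_floor <= 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5]")
        from .target_sites import SITE_TYPE_RANK

        for st in self.site_types:
            if st not in SITE_TYPE_RANK:
                raise ValueError(f"unknown site type {st!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DiscoveryResult:
    candidates: list
    funnel: dict
    cutoff: int


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_discovery(config: RunConfig) -> DiscoveryResult:
    """Execute the discovery funnel and write candidate table, BED and
    funnel report under ``config.outdir``."""
    for name in ("counts_tsv", "utr_fasta", "mirna_fasta", "vcf"):
        if getattr(config, name) is None:
            raise ValueError(f"discovery stage: config.{name} is required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # step 1: literature classification
    records = read_publication_counts(config.counts_tsv)
    cutoff = (
        compute_publication_cutoff(records)
        if config.publication_cutoff == "auto"
        else config.publication_cutoff
    )
    cancer_genes = classify_cancer_genes(records, cutoff)
    write_gene_list(cancer_genes, outdir / "cancer_genes.txt")

    # step 2: seed-site scan of the surviving genes' UTRs
    mirnas = read_mirna_fasta(config.mirna_fasta)
    utrs = read_utr_fasta(config.utr_fasta)
    utrs_cancer = [u for u in utrs if u.gene in cancer_genes]
    min_type = min(config.site_types, key=lambda s: _type_rank(s))
    mapped = [
        m
        for m in map_sites(mirnas, utrs_cancer, min_site_type=min_type)
        if m.site_type in config.site_types
    ]
    genes_with_sites = {m.gene for m in mapped}

    # step 3: common variants inside sites
    sidecar = read_maf_sidecar(config.maf_sidecar) if config.maf_sidecar else None
    variants = read_variants_vcf(config.vcf, sidecar=sidecar)
    common = [v for v in variants if v.maf is not None and v.maf >= config.maf_floor]
    pairs = intersect_sites_variants(mapped, common)

    candidates = []
    for ms, variant in pairs:
        report = score_variant_site(
            _mirna_by_name(mirnas, ms.mirna), ms.utr, ms.site, variant
        )
        candidates.append(
            CandidateRow(
                gene=ms.gene,
                variant_id=variant.id,
                maf=variant.maf,
                mirna=ms.mirna,
                site_type=ms.site_type,
                mismatches_ref=report.mismatches_by_allele[variant.ref],
                mismatches_alt=report.mismatches_by_allele[variant.alt],
                effect=report.effect,
            )
        )
    genes_with_variants = {c.gene for c in candidates}
    snps_in_sites = {c.variant_id for c in candidates}

    # GO step (gene-level), then MAF ranking
    if config.go_tsv:
        annotations = read_go_annotations(config.go_tsv)
        filtered = filter_by_go(candidates, config.go_term, annotations)
    else:
        filtered = candidates
    ranked = rank_candidates(filtered)

    funnel = {
        "publication_cutoff": cutoff,
        "genes_total": len(records),
        "genes_with_publications": sum(1 for r in records if r.n_publications >= 1),
        "genes_cancer": len(cancer_genes),
        "genes_with_sites": len(genes_with_sites),
        "sites_total": len(mapped),
        "variants_total": len(variants),
        "variants_common": len(common),
        "site_variant_pairs": len(candidates),
        "snps_in_sites": len(snps_in_sites),
        "genes_with_site_variants": len(genes_with_variants),
        "candidates_after_go": len(ranked),
        "snps_after_go": len({c.variant_id for c in ranked}),
        "genes_after_go": len({c.gene for c in ranked}),
    }

    write_candidates_tsv(ranked, outdir / "candidates.tsv")
    write_sites_bed(mapped, outdir / "sites.bed")
    _write_json(funnel, outdir / "funnel.json")
    _write_json(
        {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "funnel": funnel,
        },
        outdir / "discovery_report.json",
    )
    return DiscoveryResult(candidates=ranked, funnel=funnel, cutoff=cutoff)


def _type_rank(site_type: str) -> int:
    from .target_sites import SITE_TYPE_RANK

    return SITE_TYPE_RANK[site_type]


def _mirna_by_name(mirnas, name):
    for m in mirnas:
        if m.name == name:
            return m
    raise KeyError(name)


def run_association(config: RunConfig) -> dict:
    """Correlations, nested ANOVA (both node terms), residuals, and power
    grid; writes a JSON report plus residuals TSV under ``config.outdir``."""
    import pandas as pd

    if config.expression_tsv is None or config.clinical_tsv is None:
        raise ValueError("association stage: expression_tsv and clinical_tsv required")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expression = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
    clinical = pd.read_csv(
        config.clinical_tsv, sep="\t", dtype={"pathologic_M": str}, keep_default_na=False
    )
    required = {"sample", "pathologic_T", "pathologic_N", "henodes", "pathologic_M"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table lacks column(s): {sorted(missing)}")
    for col in ("pathologic_T", "pathologic_N", "henodes"):
        clinical[col] = pd.to_numeric(clinical[col], errors="raise")
    samples = [s for s in expression.columns if s in set(clinical["sample"])]
    clinical = clinical.set_index("sample").loc[samples].reset_index()

    def _values(feature):
        if feature not in expression.index:
            raise ValueError(f"feature {feature!r} not in expression table")
        vals = expression.loc[feature, samples].to_numpy(dtype=float)
        return log2_counts(vals) if config.log_transform else vals

    correlations = {}
    for mirna, gene in config.pairs:
        res = pearson_corr(_values(mirna), _values(gene))
        correlations[f"{mirna}~{gene}"] = {"r": res.r, "p": res.p, "n": res.n}

    target = config.pairs[0][1] if config.pairs else expression.index[0]
    y = _values(target)
    anova = {}
    for term in ("N_stage", "henodes"):
        res = nested_anova_lymph(y, clinical, node_term=term)
        anova[term] = {
            "F": res.F, "p": res.p, "df_num": res.df_num,
            "df_den": res.df_den, "n": res.n,
        }
    residuals = reduced_model_residuals(y, clinical)
    residuals.rename("std_residual").to_csv(
        outdir / "reduced_model_residuals.tsv", sep="\t", index_label="sample",
        float_format="%.6f",
    )

    power = []
    for cell in config.power_grid:
        spec = PowerSpec(**cell)
        power.append({**cell, "power": power_closed_form(spec)})

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "target_feature": str(target),
        "correlations": correlations,
        "anova": anova,
        "power": power,
    }
    _write_json(report, outdir / "association_report.json")
    return report


def simulate_full_study(
    outdir,
    seed: int = 0,
    n_genes: int = 1000,
    n_samples: int = 1000,
    planted_maf: float = 0.43,
    density: float = 0.022,
    planted_site_rate: float = 0.5,
    go_term: str = "GO:0007010",
) -> dict:
    """Generate every pipeline input with consistent planted truth.

    Writes UTR/miRNA FASTA, VCF, publication-count TSV, GO TSV, expression
    and clinical TSVs, a luciferase table, and a combined truth JSON under
    ``outdir``; returns the truth dictionary.  The planted disruptor gene
    is forced through the publication and GO filters so end-to-end recovery
    is scored against a known answer.
    """
    from .refdata import HSA_MIR_182, HSA_MIR_96
    from .synthetic import (
        _child_seeds,
        gen_expression_clinical,
        gen_go_annotations,
        gen_litmine_counts,
        gen_luciferase,
        gen_utr_set,
        gen_variant_table,
        write_clinical_tsv,
        write_counts_tsv,
        write_expression_tsv,
        write_go_tsv,
        write_vcf,
    )
    from .target_sites import write_utr_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed, 6)
    mirnas = (HSA_MIR_96, HSA_MIR_182)

    utrs, utr_truth = gen_utr_set(
        n_genes=n_genes,
        planted_site_rate=planted_site_rate,
        mirnas=mirnas,
        seed=seeds[0],
    )
    variants, var_truth = gen_variant_table(
        utrs, utr_truth, density=density,
        planted_disruptor=(None, planted_maf), seed=seeds[1],
    )
    planted_gene = var_truth["planted_disruptor"]["gene"]
    genes = [u.gene for u in utrs]
    counts, lit_truth = gen_litmine_counts(
        genes, forced_genes=[planted_gene], seed=seeds[2]
    )
    annotations, go_truth = gen_go_annotations(
        genes, term=go_term, forced_genes=[planted_gene], seed=seeds[3]
    )
    expression, clinical, cohort_truth = gen_expression_clinical(
        n_samples=n_samples, seed=seeds[4]
    )
    luciferase, luc_truth = gen_luciferase(seed=seeds[5])

    write_utr_fasta(utrs, outdir / "utrs.fasta")
    with open(outdir / "mirnas.fasta", "w") as fh:
        for m in mirnas:
            fh.write(f">{m.name} {m.species}\n{m.mature_seq}\n")
    write_vcf(variants, utrs, outdir / "variants.vcf")
    write_counts_tsv(counts, outdir / "publication_counts.tsv")
    write_go_tsv(annotations, outdir / "go_annotations.tsv")
    write_expression_tsv(expression, outdir / "expression.tsv")
    write_clinical_tsv(clinical, outdir / "clinical.tsv")
    luciferase.to_csv(outdir / "luciferase.tsv", sep="\t", index=False,
                      float_format="%.5f")

    truth = {
        "seed": seed,
        "utr": utr_truth.data,
        "variants": var_truth.data,
        "litmine": lit_truth.data,
        "go": go_truth.data,
        "cohort": cohort_truth.data,
        "luciferase": luc_truth.data,
    }
    _write_json(truth, outdir / "truth.json")
    return truth
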