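"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameters, seed) -- regeneration
with the same seed is byte-identical -- and returns machine-readable
ground truth sufficient to score any pipeline stage exactly.

The defaults emulate the statistical structure of the study's real data
sources rather than their content: sparse publication counts whose nonzero
median is 4; i.i.d.-background UTRs with planted seed sites; background
common SNVs plus one high-MAF site-disrupting SNP planted at frequency
0.43 with a fully complementary ancestral allele; miRNA-target expression
correlations of -0.3 and -0.2; ordinal T/N staging with a planted
expression->node-stage effect; rare (~2%) M1 status; and luciferase-style
reporter repression of 30%/70% under the permissive allele.

Background minor-allele frequencies default to Uniform(0.01, 0.40), below
the planted disruptor's 0.43: the generator's contract is that the planted
SNP is the cohort's top-frequency candidate, which is the condition the
MAF-ranked discovery step presumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sequences import DNA_BASES, complement_base, reverse_complement
from .target_sites import MiRNA, UTRAnnotation, seed_of
from .variant_overlap import Variant

__all__ = [
    "SyntheticTruth",
    "gen_utr_set",
    "gen_variant_table",
    "gen_litmine_counts",
    "gen_go_annotations",
    "gen_expression_clinical",
    "gen_luciferase",
    "write_vcf",
    "write_counts_tsv",
    "write_go_tsv",
    "write_expression_tsv",
    "write_clinical_tsv",
    "expected_chance_site_count",
]

_CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5")
_GENE_GAP = 1000  # bp between consecutive synthetic UTRs on a chromosome


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(json.load(fh))

    def __getitem__(self, key):
        return self.data[key]


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


# ---------------------------------------------------------------------------
# UTR set with planted seed sites

def _planted_site_seq(mirna: MiRNA, site_type: str) -> tuple[str, int]:
    """(sequence to write, core offset within it) for a planted site."""
    seed = seed_of(mirna)
    core = reverse_complement(seed[:6], "DNA")
    m8 = complement_base(seed[6], "DNA")
    if site_type == "8mer":
        return m8 + core + "A", 1
    if site_type == "7mer-m8":
        return m8 + core, 1
    if site_type == "7mer-A1":
        return core + "A", 0
    if site_type == "6mer":
        return core, 0
    raise ValueError(f"unknown site_type {site_type!r}")


def _guard_base(rng, exclude: str) -> str:
    choices = [b for b in DNA_BASES if b != exclude]
    return choices[rng.integers(len(choices))]


def gen_utr_set(
    n_genes: int = 1000,
    length_range: tuple[int, int] = (150, 300),
    planted_site_rate: float = 0.5,
    mirnas: Sequence[MiRNA] = (),
    site_type: str = "8mer",
    seed: int = 0,
) -> tuple[list[UTRAnnotation], SyntheticTruth]:
    """I.i.d. uniform-background UTRs with seed sites planted at recorded
    offsets.

    Each (gene, miRNA) pair receives one planted site with probability
    ``planted_site_rate``, at a position that does not overlap previously
    planted sites; one flanking base on each side is set so the planted
    match scans as exactly the requested type.  Genes are laid out on five
    synthetic chromosomes with alternating random strand.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    max_span = 8 + 2  # longest planted site plus guard bases
    if lo < max_span:
        raise ValueError(f"minimum UTR length {lo} cannot hold a planted site")
    utrs: list[UTRAnnotation] = []
    planted: list[dict] = []
    offsets = {c: 0 for c in _CHROMS}
    for i in range(n_genes):
        gene = f"SYNG{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(list(DNA_BASES), size=length)
        occupied: list[tuple[int, int]] = []
        for mi in mirnas:
            if rng.random() >= planted_site_rate:
                continue
            site_seq, _core_off = _planted_site_seq(mi, site_type)
            span = len(site_seq)
            # reserve one guard base each side
            for _attempt in range(50):
                start = int(rng.integers(1, length - span))
                if all(start - 1 >= e or start + span + 1 <= s for s, e in occupied):
                    break
            else:
                continue
            seq[start : start + span] = list(site_seq)
            # guards keep the scanned type equal to the planted type
            if site_type in ("7mer-A1", "6mer"):
                m8 = complement_base(seed_of(mi)[6], "DNA")
                if seq[start - 1] == m8:
                    seq[start - 1] = _guard_base(rng, m8)
            if site_type in ("7mer-m8", "6mer") and start + span < length:
                if seq[start + span] == "A":
                    seq[start + span] = _guard_base(rng, "A")
            occupied.append((start - 1, start + span + 1))
            planted.append(
                {
                    "gene": gene,
                    "mirna": mi.name,
                    "utr_start": start,
                    "utr_end": start + span,
                    "site_type": site_type,
                }
            )
        chrom = _CHROMS[i % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = offsets[chrom]
        offsets[chrom] = gstart + length + _GENE_GAP
        utrs.append(
            UTRAnnotation(gene, "".join(seq), chrom, gstart, gstart + length, strand)
        )
    truth = SyntheticTruth(
        {
            "seed": seed,
            "params": {
                "n_genes": n_genes,
                "length_range": list(length_range),
                "planted_site_rate": planted_site_rate,
                "site_type": site_type,
                "mirnas": [
                    {"name": m.name, "mature_seq": m.mature_seq} for m in mirnas
                ],
            },
            "planted_sites": planted,
        }
    )
    return utrs, truth


def expected_chance_site_count(
    utrs: Iterable[UTRAnnotation], n_mirnas: int
) -> float:
    """Analytic expectation of chance hexamer-core matches in uniform
    i.i.d. sequence: (L - 5) * 4^-6 per UTR per miRNA."""
    return sum(max(len(u) - 5, 0) for u in utrs) * n_mirnas * 0.25**6


# ---------------------------------------------------------------------------
# Variant table

def _draw_maf(rng, dist: tuple) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "beta":
        lo, hi = dist[3], dist[4]
        return float(lo + (hi - lo) * rng.beta(dist[1], dist[2]))
    raise ValueError(f"unknown MAF distribution {dist!r}")


def gen_variant_table(
    utrs: Sequence[UTRAnnotation],
    utr_truth: SyntheticTruth,
    density: float = 0.022,
    maf_distribution: tuple = ("uniform", 0.01, 0.40),
    planted_disruptor: tuple[Optional[str], float] = (None, 0.43),
    disruptor_mirna: Optional[str] = None,
    seed: int = 0,
) -> tuple[list[Variant], SyntheticTruth]:
    """Background SNVs scattered uniformly plus one planted disruptor.

    The disruptor is placed inside a planted seed site of the requested
    gene (default: the first gene, in symbol order, that carries a planted
    site), with the ancestral/reference allele left fully complementary to
    the seed and the alternate allele breaking one pairing -- the pattern
    of the worked PALLD example.  ``density`` is the per-base probability
    of a background SNV.
    """
    rng = np.random.default_rng(seed)
    by_gene = {u.gene: u for u in utrs}
    sites_by_gene: dict[str, list[dict]] = {}
    for s in utr_truth["planted_sites"]:
        sites_by_gene.setdefault(s["gene"], []).append(s)

    target_gene, planted_maf = planted_disruptor
    if target_gene is None:
        candidates = sorted(sites_by_gene)
        if not candidates:
            raise ValueError("no planted site available for the disruptor")
        target_gene = candidates[0]
    if target_gene not in sites_by_gene:
        raise ValueError(f"gene {target_gene!r} has no planted site")
    gene_sites = sorted(sites_by_gene[target_gene], key=lambda s: (s["mirna"], s["utr_start"]))
    if disruptor_mirna is not None:
        gene_sites = [s for s in gene_sites if s["mirna"] == disruptor_mirna]
        if not gene_sites:
            raise ValueError(f"no planted site for {disruptor_mirna!r} in {target_gene!r}")
    site = gene_sites[0]
    utr = by_gene[target_gene]
    core_start = (
        site["utr_start"] + 1 if site["site_type"] in ("8mer", "7mer-m8") else site["utr_start"]
    )
    snp_off = core_start + int(rng.integers(6))
    ref_sense = utr.seq[snp_off]
    alt_sense = _guard_base(rng, ref_sense)
    if utr.strand == "+":
        snp_pos = utr.genomic_start + snp_off
        ref_g, alt_g = ref_sense, alt_sense
    else:
        snp_pos = utr.genomic_end - 1 - snp_off
        ref_g = complement_base(ref_sense, "DNA")
        alt_g = complement_base(alt_sense, "DNA")

    # miRNAs of the generated panel whose scanned site on the reference UTR
    # covers the SNP: miRNAs sharing the hexamer core (as miR-96/miR-182 do)
    # are all disrupted by one core SNP, so the truth lists every one.
    from .target_sites import find_seed_sites

    affected = []
    for m in utr_truth["params"].get("mirnas", []):
        mi = MiRNA(m["name"], m["mature_seq"]) if isinstance(m, dict) else None
        if mi is None:
            continue
        for s in find_seed_sites(mi, utr, min_site_type="6mer"):
            if s.utr_start <= snp_off < s.utr_end:
                affected.append(mi.name)
                break

    raw: list[tuple[str, int, str, str, float, bool]] = [
        (utr.chrom, snp_pos, ref_g, alt_g, float(planted_maf), True)
    ]
    if density > 0:
        for u in utrs:
            hits = np.flatnonzero(rng.random(len(u)) < density)
            for off in hits:
                off = int(off)
                if u.gene == target_gene and off == snp_off:
                    continue
                sense = u.seq[off]
                alt_s = _guard_base(rng, sense)
                if u.strand == "+":
                    pos, r, a = u.genomic_start + off, sense, alt_s
                else:
                    pos = u.genomic_end - 1 - off
                    r = complement_base(sense, "DNA")
                    a = complement_base(alt_s, "DNA")
                raw.append((u.chrom, pos, r, a, _draw_maf(rng, maf_distribution), False))

    raw.sort(key=lambda t: (t[0], t[1]))
    variants = []
    planted_id = None
    for i, (chrom, pos, r, a, maf, is_planted) in enumerate(raw):
        vid = f"rs{100000 + i}"
        if is_planted:
            planted_id = vid
        variants.append(Variant(vid, chrom, pos, r, a, maf))
    truth = SyntheticTruth(
        {
            "seed": seed,
            "params": {
                "density": density,
                "maf_distribution": list(maf_distribution),
            },
            "planted_disruptor": {
                "id": planted_id,
                "gene": target_gene,
                "mirna": site["mirna"],
                "affected_mirnas": sorted(affected) or [site["mirna"]],
                "chrom": utr.chrom,
                "pos0": int(snp_pos),
                "maf": float(planted_maf),
                "utr_offset": int(snp_off),
                "site": site,
            },
            "n_background": len(variants) - 1,
        }
    )
    return variants, truth


def write_vcf(variants: Sequence[Variant], utrs: Sequence[UTRAnnotation], path) -> None:
    """Plain-text VCFv4.2 with contig lines and a MAF INFO field."""
    contig_len: dict[str, int] = {}
    for u in utrs:
        contig_len[u.chrom] = max(contig_len.get(u.chrom, 0), u.genomic_end + 1)
    for v in variants:
        contig_len[v.chrom] = max(contig_len.get(v.chrom, 0), v.pos0 + 2)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(contig_len):
            fh.write(f"##contig=<ID={chrom},length={contig_len[chrom]}>\n")
        fh.write(
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos0)):
            info = f"MAF={v.maf:.4f}" if v.maf is not None else "."
            fh.write(
                f"{v.chrom}\t{v.pos0 + 1}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Publication counts

def gen_litmine_counts(
    genes,
    zero_fraction: float = 0.6,
    nonzero_median: int = 4,
    forced_genes: Sequence[str] = (),
    seed: int = 0,
) -> tuple[dict[str, int], SyntheticTruth]:
    """Zero-inflated geometric publication counts.

    A gene has zero publications with probability ``zero_fraction``;
    otherwise its count is a shifted geometric calibrated so the
    theoretical (and, for realistically large gene sets, the realized)
    nonzero median equals ``nonzero_median``.  ``forced_genes`` always
    receive counts above the median, guaranteeing they pass the cutoff.
    """
    if isinstance(genes, int):
        genes = [f"SYNG{i:04d}" for i in range(genes)]
    genes = list(genes)
    m = int(nonzero_median)
    if m < 1:
        raise ValueError("nonzero_median must be >= 1")
    # shifted-geometric success prob with median m: q = (1-p) in the open
    # interval (0.5^(1/(m-1)), 0.5^(1/m)); take the midpoint in exponent
    q = 0.5 ** (1.0 / (m - 0.5)) if m > 1 else 0.25
    p = 1.0 - q
    rng = np.random.default_rng(seed)
    forced = set(forced_genes)
    counts = {}
    for g in genes:
        if g in forced:
            counts[g] = m + int(rng.geometric(p))
        elif rng.random() < zero_fraction:
            counts[g] = 0
        else:
            counts[g] = int(rng.geometric(p))
    truth = SyntheticTruth(
        {
            "seed": seed,
            "params": {
                "zero_fraction": zero_fraction,
                "nonzero_median": m,
                "geometric_p": p,
            },
            "forced_genes": sorted(forced),
        }
    )
    return counts, truth


def write_counts_tsv(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tn_publications\n")
        for g in sorted(counts):
            fh.write(f"{g}\t{counts[g]}\n")


# ---------------------------------------------------------------------------
# GO annotations

def gen_go_annotations(
    genes: Sequence[str],
    term: str = "GO:0007010",
    annotation_probability: float = 0.1,
    forced_genes: Sequence[str] = (),
    decoy_terms: Sequence[str] = ("GO:0008150", "GO:0009987"),
    seed: int = 0,
) -> tuple[dict[str, set], SyntheticTruth]:
    """Annotate each gene with the query term with the given probability;
    ``forced_genes`` are always annotated.  Decoy terms are sprinkled in so
    term sets are not degenerate."""
    rng = np.random.default_rng(seed)
    forced = set(forced_genes)
    annotations: dict[str, set] = {}
    annotated = []
    for g in genes:
        terms = set()
        if g in forced or rng.random() < annotation_probability:
            terms.add(term)
            annotated.append(g)
        for d in decoy_terms:
            if rng.random() < 0.3:
                terms.add(d)
        annotations[g] = terms
    truth = SyntheticTruth(
        {
            "seed": seed,
            "params": {
                "term": term,
                "annotation_probability": annotation_probability,
            },
            "annotated_genes": sorted(annotated),
            "forced_genes": sorted(forced),
        }
    )
    return annotations, truth


def write_go_tsv(annotations: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for g in sorted(annotations):
            for t in sorted(annotations[g]):
                fh.write(f"{g}\t{t}\n")


# ---------------------------------------------------------------------------
# Expression + clinical cohort

def gen_expression_clinical(
    n_samples: int = 1000,
    true_corr_mirna96: float = -0.3,
    true_corr_mirna182: float = -0.2,
    mirna_mirna_corr: float = 0.5,
    node_effect: float = 0.3,
    t_probs: Sequence[float] = (0.25, 0.45, 0.20, 0.10),
    n_probs: Sequence[float] = (0.55, 0.25, 0.13, 0.07),
    m1_rate: float = 0.02,
    m_missing_rate: float = 0.01,
    log2_mean: float = 8.0,
    log2_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Cohort with planted expression correlations and node-stage effect.

    Target-gene and miRNA expression are drawn from a latent trivariate
    normal with the requested correlations and mapped to a normalized-count
    scale as 2**(mean + sd*z) - 1, so a log2(x+1) analysis recovers the
    latent correlations.  Pathologic T is drawn independently of
    expression; the node stage N is an ordinal discretization of a latent
    combining T, the target-expression latent scaled by ``node_effect``,
    and unit noise, so ``node_effect`` = 0 makes N conditionally
    independent of expression given T (an exact null).  H&E-positive node
    counts are Poisson with an N-dependent rate; M1 status is rare.

    Returns (expression features x samples, clinical table, truth).
    """
    rng = np.random.default_rng(seed)
    corr = np.array(
        [
            [1.0, true_corr_mirna96, true_corr_mirna182],
            [true_corr_mirna96, 1.0, mirna_mirna_corr],
            [true_corr_mirna182, mirna_mirna_corr, 1.0],
        ]
    )
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_samples, 3)) @ chol.T
    expr_vals = np.maximum(2.0 ** (log2_mean + log2_sd * z) - 1.0, 0.0)
    samples = [f"S{i:05d}" for i in range(n_samples)]
    expression = pd.DataFrame(
        expr_vals.T,
        index=["PALLD", "hsa-miR-96-5p", "hsa-miR-182-5p"],
        columns=samples,
    )

    t_stage = rng.choice([1, 2, 3, 4], size=n_samples, p=np.asarray(t_probs))
    zt = (t_stage - t_stage.mean()) / max(t_stage.std(), 1e-9)
    eta = 0.4 * zt + node_effect * z[:, 0] + rng.standard_normal(n_samples)
    cuts = np.quantile(eta, np.cumsum(n_probs)[:-1])
    n_stage = np.searchsorted(cuts, eta, side="right")
    henodes = rng.poisson(np.array([0.2, 1.5, 4.0, 9.0])[n_stage])
    u = rng.random(n_samples)
    m_status = np.where(u < m1_rate, "M1", np.where(u < m1_rate + m_missing_rate, "NA", "M0"))
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "pathologic_T": t_stage,
            "pathologic_N": n_stage,
            "henodes": henodes,
            "pathologic_M": m_status,
        }
    )
    truth = SyntheticTruth(
        {
            "seed": seed,
            "params": {
                "n_samples": n_samples,
                "true_corr_mirna96": true_corr_mirna96,
                "true_corr_mirna182": true_corr_mirna182,
                "mirna_mirna_corr": mirna_mirna_corr,
                "node_effect": node_effect,
                "m1_rate": m1_rate,
                "log2_mean": log2_mean,
                "log2_sd": log2_sd,
            },
        }
    )
    return expression, clinical, truth


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="feature", float_format="%.4f")


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Luciferase-style reporter simulation

DEFAULT_REPRESSION = {
    ("C-allele", "miR-96"): 0.30,
    ("C-allele", "miR-182"): 0.70,
}


def gen_luciferase(
    constructs: Sequence[str] = ("C-allele", "G-allele", "target-deletion"),
    mirnas: Sequence[str] = ("miR-96", "miR-182", "control"),
    repression_by_condition: Optional[Mapping[tuple[str, str], float]] = None,
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Replicate normalized reporter ratios per (construct, miRNA).

    The mean ratio relative to the control-miRNA condition is
    1 - repression; unspecified conditions (the disrupted G allele, the
    target-deletion construct, control miRNA) have repression 0.  Gaussian
    replicate noise, truncated positive.
    """
    if repression_by_condition is None:
        repression_by_condition = DEFAULT_REPRESSION
    rng = np.random.default_rng(seed)
    rows = []
    for construct in constructs:
        for mirna in mirnas:
            rep = 0.0 if mirna == "control" else repression_by_condition.get(
                (construct, mirna), 0.0
            )
            ratios = 1.0 - rep + noise_sd * rng.standard_normal(replicates)
            ratios = np.maximum(ratios, 1e-6)
            for k, ratio in enumerate(ratios):
                rows.append(
                    {
                        "construct": construct,
                        "mirna": mirna,
                        "replicate": k,
                        "ratio": float(ratio),
                    }
                )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        {
            "seed": seed,
            "params": {"noise_sd": noise_sd, "replicates": replicates},
            "repression": {
                f"{c}|{m}": v for (c, m), v in repression_by_condition.items()
            },
        }
    )
    return table, truth
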