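"""Intersection of SNVs with seed sites, allele-aware scoring, candidate
prioritization, and repaired-miRNA design.

The central operation scores each allele of a variant against the seed of a
miRNA whose site it falls in.  A site-disrupting variant is one whose
ancestral allele leaves the seed fully paired while the other allele breaks
pairing -- the pattern of rs1071738 in the PALLD 3'-UTR, where the
ancestral C allele permits miR-96/miR-182 binding and the alternate G
allele abolishes it.  The "repaired" miRNA mirrors the published rescue
construct: the miRNA base opposite the SNP is substituted so the seed fully
complements the otherwise-escaping allele.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .sequences import complement_base, normalize_dna
from .target_sites import (
    MappedSite,
    MiRNA,
    SeedSite,
    UTRAnnotation,
    genomic_to_utr_offset,
    seed_of,
)

logger = logging.getLogger(__name__)

EFFECTS = ("site_preserving", "site_disrupting", "site_creating", "neutral")

__all__ = [
    "Variant",
    "AlleleSiteReport",
    "CandidateRow",
    "RepairedMiRNA",
    "NotRepairableError",
    "intersect_sites_variants",
    "apply_allele",
    "seed_mismatch_count",
    "classify_allele_effect",
    "score_variant_site",
    "filter_by_go",
    "rank_candidates",
    "design_repaired_mirna",
    "read_variants_vcf",
    "read_maf_sidecar",
    "read_go_annotations",
    "write_candidates_tsv",
]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with a population minor-allele frequency.

    ``ancestral`` defaults to the reference allele; an explicit ancestral
    allele (e.g. from a sidecar table) may differ from it, as it does for
    rs1071738 in Europeans.
    """

    id: str
    chrom: str
    pos0: int  # 0-based genomic position
    ref: str
    alt: str
    maf: Optional[float] = None
    ancestral: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "ref", normalize_dna(self.ref))
        object.__setattr__(self, "alt", normalize_dna(self.alt))
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"{self.id}: only single-nucleotide variants are supported "
                f"(ref={self.ref!r}, alt={self.alt!r})"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.id}: MAF {self.maf} outside [0, 0.5]")
        if self.ancestral is not None:
            anc = normalize_dna(self.ancestral)
            if anc not in (self.ref, self.alt):
                raise ValueError(
                    f"{self.id}: ancestral allele {anc!r} is neither ref nor alt"
                )
            object.__setattr__(self, "ancestral", anc)

    @property
    def ancestral_allele(self) -> str:
        return self.ancestral if self.ancestral is not None else self.ref

    @property
    def derived_allele(self) -> str:
        return self.alt if self.ancestral_allele == self.ref else self.ref


@dataclass(frozen=True)
class AlleleSiteReport:
    """Per-allele seed-mismatch counts for one (miRNA, site, SNP) triple."""

    variant: Variant
    site: SeedSite
    gene: str
    mismatches_by_allele: Mapping[str, int]
    effect: str

    def __post_init__(self):
        keys = set(self.mismatches_by_allele)
        if keys != {self.variant.ref, self.variant.alt}:
            raise ValueError(
                f"{self.variant.id}: mismatch map keys {sorted(keys)} must be "
                f"exactly the two variant alleles"
            )
        for allele, k in self.mismatches_by_allele.items():
            if not 0 <= k <= 7:
                raise ValueError(f"mismatch count {k} for allele {allele} not in [0,7]")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass
class CandidateRow:
    """One prioritized output record, per (miRNA, site, SNP) triple."""

    gene: str
    variant_id: str
    maf: Optional[float]
    mirna: str
    site_type: str
    mismatches_ref: int
    mismatches_alt: int
    effect: str
    go_matched: bool = False


@dataclass(frozen=True)
class RepairedMiRNA:
    """An engineered miRNA with the SNP-opposing base substituted."""

    parent: str
    sequence: str
    substituted_position: int  # 1-based position on the miRNA
    target_allele: str


class NotRepairableError(ValueError):
    """The SNP does not oppose a seed position, or the repair is a no-op."""


def intersect_sites_variants(
    genomic_sites: Sequence[MappedSite], variants: Sequence[Variant]
) -> list[tuple[MappedSite, Variant]]:
    """All (site, variant) pairs with site.start <= pos0 < site.end on the
    same chromosome, sorted by (chrom, pos0, site start, miRNA name)."""
    trees: dict[str, IntervalTree] = {}
    for ms in genomic_sites:
        trees.setdefault(ms.chrom, IntervalTree()).addi(ms.start, ms.end, ms)
    pairs = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for iv in tree.at(v.pos0):
            pairs.append((iv.data, v))
    pairs.sort(key=lambda p: (p[1].chrom, p[1].pos0, p[0].start, p[0].mirna))
    return pairs


def apply_allele(utr: UTRAnnotation, variant: Variant, allele: str) -> str:
    """UTR sense sequence with the variant position set to ``allele``.

    Alleles are given on the genomic plus strand; for minus-strand genes the
    substituted sense base is the complement.  The input UTR is not mutated.
    """
    allele = normalize_dna(allele)
    if allele not in (variant.ref, variant.alt):
        raise ValueError(
            f"allele {allele!r} is neither ref ({variant.ref}) nor alt "
            f"({variant.alt}) of {variant.id}"
        )
    off = genomic_to_utr_offset(utr, variant.pos0)
    base = allele if utr.strand == "+" else complement_base(allele, "DNA")
    return utr.seq[:off] + base + utr.seq[off + 1 :]


def seed_mismatch_count(
    mirna: MiRNA, utr_seq: str, site: SeedSite, span: str = "site"
) -> int:
    """Count seed positions not Watson-Crick paired at the site.

    With ``span="site"`` (default) the count runs over the seed positions
    the site type claims to pair: miRNA bases 2-8 for 8mer/7mer-m8 sites,
    bases 2-7 for 7mer-A1/6mer sites (whose position 8 is unpaired by
    definition).  With ``span="m8"`` the count always runs over bases 2-8,
    in which case 0 means the 7-nt window equals the reverse complement of
    the seed.
    """
    if span not in ("site", "m8"):
        raise ValueError("span must be 'site' or 'm8'")
    seq = normalize_dna(utr_seq)
    seed = seed_of(mirna)  # bases 2-8, RNA
    core_start = site.core_start
    if not (0 <= core_start and core_start + 6 <= len(seq)):
        raise ValueError(
            f"site core [{core_start},{core_start + 6}) outside sequence of "
            f"length {len(seq)}"
        )
    # seed position p (2..8) aligns at sequence offset core_start + 7 - p
    positions = range(2, 9) if span == "m8" or site.pairs_m8 else range(2, 8)
    mismatches = 0
    for p in positions:
        off = core_start + 7 - p
        expected = complement_base(seed[p - 2], "DNA")
        if off < 0 or off >= len(seq) or seq[off] != expected:
            mismatches += 1
    return mismatches


def classify_allele_effect(mm_ancestral: int, mm_derived: int) -> str:
    """Four-rule classification of an allele pair's effect on the site."""
    if mm_ancestral == 0 and mm_derived == 0:
        return "site_preserving"
    if mm_ancestral == 0:
        return "site_disrupting"
    if mm_derived == 0:
        return "site_creating"
    return "neutral"


def score_variant_site(
    mirna: MiRNA,
    utr: UTRAnnotation,
    site: SeedSite,
    variant: Variant,
    span: str = "site",
) -> AlleleSiteReport:
    """Score both alleles of a variant against a site's seed pairing."""
    mm = {
        allele: seed_mismatch_count(mirna, apply_allele(utr, variant, allele), site, span)
        for allele in (variant.ref, variant.alt)
    }
    effect = classify_allele_effect(
        mm[variant.ancestral_allele], mm[variant.derived_allele]
    )
    return AlleleSiteReport(variant, site, utr.gene, mm, effect)


def filter_by_go(
    candidates: Iterable[CandidateRow],
    term: str,
    annotations: Mapping[str, set],
) -> list[CandidateRow]:
    """Keep rows whose gene is annotated with ``term`` (exact identifier
    match, no ontology-graph propagation).  Genes absent from the annotation
    map are dropped with a logged warning."""
    kept = []
    missing = set()
    for row in candidates:
        if row.gene not in annotations:
            missing.add(row.gene)
            continue
        if term in annotations[row.gene]:
            row.go_matched = True
            kept.append(row)
    if missing:
        logger.warning(
            "filter_by_go: %d gene(s) without annotations dropped: %s",
            len(missing),
            ", ".join(sorted(missing)[:10]),
        )
    return kept


def rank_candidates(candidates: Sequence[CandidateRow]) -> list[CandidateRow]:
    """Descending by MAF; ties broken lexicographically by (variant id,
    miRNA name).  Stable and deterministic."""
    for row in candidates:
        if row.maf is None:
            raise ValueError(f"candidate {row.variant_id} has no MAF")
    return sorted(candidates, key=lambda r: (-r.maf, r.variant_id, r.mirna))


def design_repaired_mirna(
    mirna: MiRNA,
    utr: UTRAnnotation,
    site: SeedSite,
    variant: Variant,
    target_allele: str,
) -> RepairedMiRNA:
    """Substitute the SNP-opposing miRNA base so the seed complements
    ``target_allele`` -- the engineered-rescue design in which the G
    opposite the SNP is replaced by a C to restore full pairing.

    Raises NotRepairableError if the SNP does not oppose a seed position
    (miRNA bases 2-8 of the site) or if the parent already pairs the target
    allele (no-op repair).
    """
    target_allele = normalize_dna(target_allele)
    if target_allele not in (variant.ref, variant.alt):
        raise ValueError(
            f"target allele {target_allele!r} is neither ref nor alt of {variant.id}"
        )
    off = genomic_to_utr_offset(utr, variant.pos0)
    # seed position opposite the SNP: sequence offset core_start + 7 - p
    pos = site.core_start + 7 - off
    if not 2 <= pos <= 8:
        raise NotRepairableError(
            f"{variant.id} does not oppose a seed base of {mirna.name} "
            f"(would be miRNA position {pos})"
        )
    sense_base = (
        target_allele if utr.strand == "+" else complement_base(target_allele, "DNA")
    )
    new_base = complement_base(sense_base, "RNA")
    parent_seq = mirna.mature_seq
    if parent_seq[pos - 1] == new_base:
        raise NotRepairableError(
            f"{mirna.name} already pairs allele {target_allele} at position "
            f"{pos}; repair would be a no-op"
        )
    repaired = parent_seq[: pos - 1] + new_base + parent_seq[pos:]
    return RepairedMiRNA(mirna.name, repaired, pos, target_allele)


# ---------------------------------------------------------------------------
# I/O

def read_variants_vcf(path, sidecar: Optional[Mapping] = None, strict: bool = True) -> list[Variant]:
    """Read SNVs from a VCF 4.x file via pysam.

    MAF is taken from the ``MAF`` INFO field (falling back to ``AF``), or
    from a sidecar mapping id -> (maf, ancestral); frequencies are inputs,
    never recomputed.  Indels are rejected with an error (``strict=True``)
    or skipped with a warning.
    """
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref
            alts = rec.alts or ()
            for alt in alts:
                if len(ref) != 1 or len(alt) != 1:
                    msg = f"indel/MNV record {rec.id or rec.pos} ({ref}>{alt}) is not supported"
                    if strict:
                        raise ValueError(msg)
                    logger.warning("skipping %s", msg)
                    continue
                maf = None
                for key in ("MAF", "AF"):
                    if key in rec.info:
                        val = rec.info[key]
                        # round away float32 representation noise from htslib
                        maf = round(float(val[0] if isinstance(val, tuple) else val), 6)
                        break
                ancestral = None
                vid = rec.id or f"{rec.chrom}:{rec.pos}"
                if sidecar and vid in sidecar:
                    maf, ancestral = sidecar[vid]
                variants.append(
                    Variant(vid, rec.chrom, rec.pos - 1, ref, alt, maf, ancestral)
                )
    return variants


def read_maf_sidecar(path) -> dict[str, tuple[float, Optional[str]]]:
    """Sidecar TSV ``id<TAB>maf[<TAB>ancestral]`` (header required)."""
    out = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0].lower() != "id":
            raise ValueError("sidecar TSV must have a header starting with 'id'")
        for row in reader:
            if not row:
                continue
            anc = row[2] if len(row) > 2 and row[2] else None
            out[row[0]] = (float(row[1]), anc)
    return out


def read_go_annotations(path) -> dict[str, set]:
    """Gene -> GO-term-id sets, from a two-column TSV (gene, term) or a
    GAF 2.x file (columns 2 and 5, 1-based)."""
    annotations: dict[str, set] = {}
    with open(path) as fh:
        first = fh.readline()
        is_gaf = first.startswith("!")
        fh.seek(0)
        for line in fh:
            if line.startswith(("!", "#")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if is_gaf or len(fields) >= 15:
                gene, term = fields[2], fields[4]
            else:
                if fields[0].lower() in ("gene", "symbol"):
                    continue
                gene, term = fields[0], fields[1]
            annotations.setdefault(gene, set()).add(term)
    return annotations


CANDIDATE_COLUMNS = [
    "gene", "variant_id", "maf", "mirna", "site_type",
    "mismatches_ref", "mismatches_alt", "effect", "go_matched",
]


def write_candidates_tsv(candidates: Iterable[CandidateRow], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for r in candidates:
            writer.writerow(
                [r.gene, r.variant_id, f"{r.maf:.6g}" if r.maf is not None else "",
                 r.mirna, r.site_type, r.mismatches_ref, r.mismatches_alt,
                 r.effect, int(r.go_matched)]
            )
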