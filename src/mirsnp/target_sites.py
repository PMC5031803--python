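"""Seed-site scanning of 3'-UTR sequences and genomic coordinate mapping.

The scanner implements the canonical seed-match site classes used for
conserved target-site prediction:

* ``8mer``     -- complement of miRNA bases 2-8, followed (3'-ward on the
                  mRNA) by an A opposite miRNA position 1;
* ``7mer-m8``  -- complement of bases 2-8;
* ``7mer-A1``  -- complement of bases 2-7 plus the A opposite position 1;
* ``6mer``     -- complement of bases 2-7.

Pairing is strict Watson-Crick: G:U wobbles count as mismatches.  Every
maximal match is reported once with its strongest type, keyed by the locus
of the hexamer core (the bases opposite miRNA positions 2-7).

Coordinates are 0-based half-open throughout; 1-based conventions appear
only at VCF/BED boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import SeqIO

from .sequences import complement_base, normalize_dna, normalize_rna, reverse_complement

SITE_TYPE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}
#: site classes treated as "conserved-class" sites (the 7-8mer classes that
#: populate conserved-site databases); 6mers are excluded by default.
CONSERVED_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

__all__ = [
    "MiRNA",
    "UTRAnnotation",
    "SeedSite",
    "MappedSite",
    "seed_of",
    "find_seed_sites",
    "site_to_genomic",
    "genomic_to_utr_offset",
    "read_mirna_fasta",
    "read_utr_fasta",
    "write_utr_fasta",
    "write_sites_bed",
    "SITE_TYPE_RANK",
    "CONSERVED_SITE_TYPES",
]


@dataclass(frozen=True)
class MiRNA:
    """A named mature miRNA. The sequence is stored 5'->3' in RNA."""

    name: str
    mature_seq: str
    species: str = "hsa"

    def __post_init__(self):
        object.__setattr__(self, "mature_seq", normalize_rna(self.mature_seq))
        if len(self.mature_seq) < 8:
            raise ValueError(
                f"mature sequence of {self.name!r} is shorter than 8 nt"
            )

    @property
    def seed(self) -> str:
        return seed_of(self)


def seed_of(mirna: MiRNA) -> str:
    """The 7-nt seed: bases 2-8 from the miRNA 5' end (1-based, inclusive)."""
    return mirna.mature_seq[1:8]


@dataclass
class UTRAnnotation:
    """A 3'-UTR: sense-strand (mRNA-orientation) sequence plus genomic placement.

    ``conserved`` is an optional per-position boolean track imported from a
    conserved-site database; conservation is never computed here.
    """

    gene: str
    seq: str
    chrom: str
    genomic_start: int  # 0-based inclusive
    genomic_end: int  # exclusive
    strand: str
    conserved: Optional[Sequence[bool]] = None

    def __post_init__(self):
        self.seq = normalize_dna(self.seq)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.genomic_end - self.genomic_start != len(self.seq):
            raise ValueError(
                f"{self.gene}: genomic interval length "
                f"{self.genomic_end - self.genomic_start} != sequence length "
                f"{len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SeedSite:
    """A located seed match on a UTR (offsets on the sense sequence)."""

    mirna: str
    utr_start: int  # 0-based inclusive
    utr_end: int  # exclusive
    site_type: str

    def __post_init__(self):
        if self.site_type not in SITE_TYPE_RANK:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        span = self.utr_end - self.utr_start
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if span != expected:
            raise ValueError(
                f"{self.site_type} span must be {expected}, got {span}"
            )

    @property
    def core_start(self) -> int:
        """Offset of the hexamer core (bases opposite miRNA positions 2-7)."""
        if self.site_type in ("8mer", "7mer-m8"):
            return self.utr_start + 1
        return self.utr_start

    @property
    def pairs_m8(self) -> bool:
        """Whether the site type claims pairing at miRNA position 8."""
        return self.site_type in ("8mer", "7mer-m8")


class MappedSite(NamedTuple):
    """A seed site lifted to genomic coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene: str
    mirna: str
    site_type: str
    site: SeedSite
    utr: UTRAnnotation


def find_seed_sites(
    mirna: MiRNA,
    utr: UTRAnnotation,
    min_site_type: str = "7mer-A1",
    require_conserved_flag: bool = False,
) -> list[SeedSite]:
    """Scan a UTR for seed sites of ``mirna``, strongest type per core locus.

    Matches weaker than ``min_site_type`` are suppressed.  With
    ``require_conserved_flag`` and a conservation track on the UTR, only
    sites whose whole span is flagged conserved are returned.
    """
    if min_site_type not in SITE_TYPE_RANK:
        raise ValueError(f"unknown min_site_type {min_site_type!r}")
    if not utr.seq:
        raise ValueError(f"{utr.gene}: empty UTR sequence")
    seed = seed_of(mirna)
    core = reverse_complement(seed[:6], "DNA")  # opposite miRNA positions 2-7
    m8_base = complement_base(seed[6], "DNA")  # opposite miRNA position 8
    seq = utr.seq
    min_rank = SITE_TYPE_RANK[min_site_type]

    sites: list[SeedSite] = []
    j = seq.find(core)
    while j != -1:
        has_m8 = j > 0 and seq[j - 1] == m8_base
        has_a1 = j + 6 < len(seq) and seq[j + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(mirna.name, j - 1, j + 7, "8mer")
        elif has_m8:
            site = SeedSite(mirna.name, j - 1, j + 6, "7mer-m8")
        elif has_a1:
            site = SeedSite(mirna.name, j, j + 7, "7mer-A1")
        else:
            site = SeedSite(mirna.name, j, j + 6, "6mer")
        keep = SITE_TYPE_RANK[site.site_type] >= min_rank
        if keep and require_conserved_flag and utr.conserved is not None:
            keep = all(utr.conserved[k] for k in range(site.utr_start, site.utr_end))
        if keep:
            sites.append(site)
        j = seq.find(core, j + 1)
    sites.sort(key=lambda s: s.utr_start)
    return sites


def site_to_genomic(site: SeedSite, utr: UTRAnnotation) -> tuple[str, int, int, str]:
    """Map a UTR-relative site to a genomic 0-based half-open interval.

    For minus-strand genes the UTR sense sequence is the reverse complement
    of the genomic plus strand, so the mapping mirrors the interval:
    genomic_start = utr.genomic_end - site.utr_end.
    """
    if not (0 <= site.utr_start < site.utr_end <= len(utr)):
        raise ValueError(
            f"site [{site.utr_start},{site.utr_end}) outside UTR of length {len(utr)}"
        )
    if utr.strand == "+":
        return (
            utr.chrom,
            utr.genomic_start + site.utr_start,
            utr.genomic_start + site.utr_end,
            "+",
        )
    return (
        utr.chrom,
        utr.genomic_end - site.utr_end,
        utr.genomic_end - site.utr_start,
        "-",
    )


def genomic_to_utr_offset(utr: UTRAnnotation, pos0: int) -> int:
    """Sense-sequence offset of a genomic position (inverse of site_to_genomic)."""
    if not (utr.genomic_start <= pos0 < utr.genomic_end):
        raise ValueError(
            f"genomic position {pos0} outside {utr.gene} "
            f"[{utr.genomic_start},{utr.genomic_end})"
        )
    if utr.strand == "+":
        return pos0 - utr.genomic_start
    return utr.genomic_end - 1 - pos0


def map_sites(
    mirnas: Iterable[MiRNA],
    utrs: Iterable[UTRAnnotation],
    min_site_type: str = "7mer-A1",
    require_conserved_flag: bool = False,
) -> list[MappedSite]:
    """Scan every (miRNA, UTR) pair and lift the hits to genomic coordinates."""
    mapped = []
    for utr in utrs:
        for mi in mirnas:
            for site in find_seed_sites(
                mi, utr, min_site_type, require_conserved_flag
            ):
                chrom, start, end, strand = site_to_genomic(site, utr)
                mapped.append(
                    MappedSite(chrom, start, end, strand, utr.gene, mi.name,
                               site.site_type, site, utr)
                )
    mapped.sort(key=lambda m: (m.chrom, m.start, m.end, m.mirna))
    return mapped


# ---------------------------------------------------------------------------
# I/O. UTR FASTA description lines carry "gene|chrom|start|end|strand";
# miRNA FASTA ids are the mature names, with an optional species tag in the
# description.

def read_mirna_fasta(path) -> list[MiRNA]:
    mirnas = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        species = parts[1] if len(parts) > 1 else rec.id.split("-")[0]
        mirnas.append(MiRNA(rec.id, str(rec.seq), species=species))
    return mirnas


def read_utr_fasta(path) -> list[UTRAnnotation]:
    utrs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()[0].split("|")
        if len(fields) != 5:
            raise ValueError(
                f"UTR FASTA header must be 'gene|chrom|start|end|strand', "
                f"got {rec.description!r}"
            )
        gene, chrom, start, end, strand = fields
        utrs.append(
            UTRAnnotation(gene, str(rec.seq), chrom, int(start), int(end), strand)
        )
    return utrs


def write_utr_fasta(utrs: Iterable[UTRAnnotation], path) -> None:
    with open(path, "w") as fh:
        for u in utrs:
            fh.write(
                f">{u.gene}|{u.chrom}|{u.genomic_start}|{u.genomic_end}|{u.strand}\n"
            )
            for i in range(0, len(u.seq), 70):
                fh.write(u.seq[i : i + 70] + "\n")


def write_sites_bed(mapped: Iterable[MappedSite], path) -> None:
    """BED6, 0-based half-open, name = 'miRNA:site_type'."""
    with open(path, "w") as fh:
        for m in mapped:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.mirna}:{m.site_type}\t0\t{m.strand}\n"
            )
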