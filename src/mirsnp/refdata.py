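"""Reference sequences for the worked example.

Mature miRNA sequences are the canonical miRBase entries for miR-96-5p and
miR-182-5p in human and mouse.  The mouse miR-96 sequence is identical to
the human one; mouse miR-182 differs at two nucleotides at the 3' end.

``PALLD_UTR_FRAGMENT_*`` is a SYNTHETIC reconstruction of the PALLD 3'-UTR
fragment spanning the shared miR-96/miR-182 binding site around the common
C/G SNP rs1071738: the flanking sequence and genomic coordinates are
placeholders, but the binding-site core reproduces the published structure
-- overlapping sites for both miRNAs whose seeds are fully complementary to
the ancestral C allele and carry exactly one mismatch against the alternate
G allele, with the SNP opposite a seed G nucleotide of both miRNAs (the
position substituted G->C in the "repaired" miRNAs).  miR-182, the stronger
repressor in reporter assays, is assigned the 8mer register and miR-96 the
overlapping 7mer-A1.
"""

from .target_sites import MiRNA, UTRAnnotation
from .variant_overlap import Variant

HSA_MIR_96 = MiRNA("hsa-miR-96-5p", "UUUGGCACUAGCACAUUUUUGCU", species="hsa")
HSA_MIR_182 = MiRNA("hsa-miR-182-5p", "UUUGGCAAUGGUAGAACUCACACU", species="hsa")
MMU_MIR_96 = MiRNA("mmu-miR-96-5p", "UUUGGCACUAGCACAUUUUUGCU", species="mmu")
MMU_MIR_182 = MiRNA("mmu-miR-182-5p", "UUUGGCAAUGGUAGAACUCACACCG", species="mmu")

# Synthetic 40-nt PALLD 3'-UTR fragment (sense strand; PALLD is a
# plus-strand gene).  The rs1071738 SNP sits at fragment offset 19: C in
# the ancestral allele, G in the alternate.
_LEFT = "CTCTAGAGTCACTTCA"
_RIGHT = "GTCTCATTGAGACTCC"
PALLD_SITE_C_ALLELE = "TTGCCAAA"  # miR-182 8mer; miR-96 7mer-A1 at offset +1
PALLD_SITE_G_ALLELE = "TTGGCAAA"
PALLD_SNP_FRAGMENT_OFFSET = len(_LEFT) + 3

_CHROM = "chr4"
_START = 169_000_000  # synthetic placeholder coordinate


def _fragment(core: str) -> UTRAnnotation:
    seq = _LEFT + core + _RIGHT
    return UTRAnnotation(
        gene="PALLD",
        seq=seq,
        chrom=_CHROM,
        genomic_start=_START,
        genomic_end=_START + len(seq),
        strand="+",
    )


PALLD_UTR_FRAGMENT_C = _fragment(PALLD_SITE_C_ALLELE)
PALLD_UTR_FRAGMENT_G = _fragment(PALLD_SITE_G_ALLELE)

#: rs1071738 with the ancestral C as reference allele and the published
#: >43% minor-allele frequency; population frequencies of the two alleles
#: vary widely, and the ancestral C is the minor allele in Europeans.
RS1071738 = Variant(
    id="rs1071738",
    chrom=_CHROM,
    pos0=_START + PALLD_SNP_FRAGMENT_OFFSET,
    ref="C",
    alt="G",
    maf=0.43,
    ancestral="C",
)
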