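import numpy as np
import pytest

from mirsnp.refdata import (
    HSA_MIR_182,
    HSA_MIR_96,
    PALLD_UTR_FRAGMENT_C,
    PALLD_UTR_FRAGMENT_G,
    RS1071738,
)
from mirsnp.sequences import complement_base, reverse_complement
from mirsnp.target_sites import MappedSite, MiRNA, SeedSite, UTRAnnotation, find_seed_sites
from mirsnp.variant_overlap import (
    CandidateRow,
    NotRepairableError,
    Variant,
    apply_allele,
    classify_allele_effect,
    design_repaired_mirna,
    filter_by_go,
    intersect_sites_variants,
    rank_candidates,
    read_maf_sidecar,
    read_variants_vcf,
    score_variant_site,
    seed_mismatch_count,
)


def make_utr(seq, strand="+", start=1000, gene="G1", chrom="chr1"):
    return UTRAnnotation(gene, seq, chrom, start, start + len(seq), strand)


def mapped(chrom, start, end, mirna="mirA", gene="G1"):
    site = SeedSite(mirna, 0, end - start, {6: "6mer", 7: "7mer-m8", 8: "8mer"}[end - start])
    utr = make_utr("A" * (end - start), start=start, gene=gene, chrom=chrom)
    return MappedSite(chrom, start, end, "+", gene, mirna, site.site_type, site, utr)


# ---------------------------------------------------------------------------
# Variant validation

def test_variant_rejects_indels_and_bad_maf():
    with pytest.raises(ValueError, match="single-nucleotide"):
        Variant("rs1", "chr1", 10, "AT", "A")
    with pytest.raises(ValueError, match="identical"):
        Variant("rs1", "chr1", 10, "A", "A")
    with pytest.raises(ValueError, match="MAF"):
        Variant("rs1", "chr1", 10, "A", "C", maf=0.7)
    v = Variant("rs1", "chr1", 10, "A", "C", maf=0.1, ancestral="C")
    assert v.ancestral_allele == "C" and v.derived_allele == "A"


# ---------------------------------------------------------------------------
# intersection

def test_intersection_half_open_boundary():
    sites = [mapped("chr1", 100, 107)]
    inside = Variant("rs_in", "chr1", 106, "A", "C")
    outside = Variant("rs_out", "chr1", 107, "A", "C")
    at_start = Variant("rs_start", "chr1", 100, "A", "C")
    pairs = intersect_sites_variants(sites, [inside, outside, at_start])
    assert [v.id for _, v in pairs] == ["rs_start", "rs_in"]
    assert intersect_sites_variants(sites, []) == []


def test_intersection_matches_double_loop_oracle(rng):
    sites = [
        mapped(f"chr{rng.integers(1, 4)}", int(s), int(s) + 7, mirna=f"m{i % 5}",
               gene=f"G{i}")
        for i, s in enumerate(rng.integers(0, 5000, size=500))
    ]
    variants = [
        Variant(f"rs{i}", f"chr{rng.integers(1, 4)}", int(p), "A", "C")
        for i, p in enumerate(rng.integers(0, 5200, size=2000))
    ]
    got = intersect_sites_variants(sites, variants)
    expected = [
        (s, v)
        for v in variants
        for s in sites
        if s.chrom == v.chrom and s.start <= v.pos0 < s.end
    ]
    expected.sort(key=lambda p: (p[1].chrom, p[1].pos0, p[0].start, p[0].mirna))
    assert got == expected


# ---------------------------------------------------------------------------
# allele application

def test_apply_allele_identity_and_substitution():
    utr = make_utr("AAGTGCCAAAT", start=1000)
    v = Variant("rs1", "chr1", 1005, "C", "G")
    assert apply_allele(utr, v, "C") == utr.seq
    assert apply_allele(utr, v, "G") == "AAGTGGCAAAT"
    assert utr.seq == "AAGTGCCAAAT"  # input never mutated
    with pytest.raises(ValueError, match="neither ref"):
        apply_allele(utr, v, "T")


def test_apply_allele_minus_strand_complements():
    # minus-strand gene: genomic allele G appears as sense-strand C
    utr = make_utr("AAGTGCCAAAT", strand="-", start=1000)
    off = 4  # sense offset to substitute
    pos0 = utr.genomic_end - 1 - off
    sense_ref = utr.seq[off]
    v = Variant("rs1", "chr1", pos0, complement_base(sense_ref), "G")
    out = apply_allele(utr, v, "G")
    assert out[off] == "C"
    assert out == utr.seq[:off] + "C" + utr.seq[off + 1 :]


def test_apply_allele_outside_utr_raises():
    utr = make_utr("ACGTACGT", start=100)
    v = Variant("rs1", "chr1", 99, "A", "C")
    with pytest.raises(ValueError, match="outside"):
        apply_allele(utr, v, "A")


# ---------------------------------------------------------------------------
# seed mismatch counting

def test_palld_mismatch_counts_per_allele():
    for mir in (HSA_MIR_96, HSA_MIR_182):
        site = find_seed_sites(mir, PALLD_UTR_FRAGMENT_C)[0]
        assert seed_mismatch_count(mir, PALLD_UTR_FRAGMENT_C.seq, site) == 0
        assert seed_mismatch_count(mir, PALLD_UTR_FRAGMENT_G.seq, site) == 1


def test_mismatch_count_strict_m8_span():
    """Over the full 2-8 window the A1-register miRNA shows its unpaired
    position 8: zero only when the 7-mer equals the seed's complement."""
    site96 = find_seed_sites(HSA_MIR_96, PALLD_UTR_FRAGMENT_C)[0]
    site182 = find_seed_sites(HSA_MIR_182, PALLD_UTR_FRAGMENT_C)[0]
    assert seed_mismatch_count(HSA_MIR_182, PALLD_UTR_FRAGMENT_C.seq, site182, span="m8") == 0
    assert seed_mismatch_count(HSA_MIR_96, PALLD_UTR_FRAGMENT_C.seq, site96, span="m8") == 1


def test_planted_mismatches_are_counted_exactly(rng):
    for _ in range(100):
        mir = MiRNA("m", "".join(rng.choice(list("ACGU"), size=22)))
        window = reverse_complement(mir.mature_seq[1:8])  # opposite bases 2-8
        k = int(rng.integers(0, 8))
        positions = rng.choice(7, size=k, replace=False)
        w = list(window)
        for p in positions:
            w[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[w[p]]
        seq = "GG" + "".join(w) + "CC"
        site = SeedSite(mir.name, 2, 9, "7mer-m8")
        assert seed_mismatch_count(mir, seq, site) == k


# ---------------------------------------------------------------------------
# effect classification

def test_effect_truth_table_exhaustive():
    for a in range(8):
        for b in range(8):
            effect = classify_allele_effect(a, b)
            if a == 0 and b == 0:
                assert effect == "site_preserving"
            elif a == 0:
                assert effect == "site_disrupting"
            elif b == 0:
                assert effect == "site_creating"
            else:
                assert effect == "neutral"


def test_rs1071738_scored_as_site_disrupting():
    for mir in (HSA_MIR_96, HSA_MIR_182):
        site = find_seed_sites(mir, PALLD_UTR_FRAGMENT_C)[0]
        report = score_variant_site(mir, PALLD_UTR_FRAGMENT_C, site, RS1071738)
        assert report.mismatches_by_allele == {"C": 0, "G": 1}
        assert report.effect == "site_disrupting"


def test_ancestral_override_flips_classification():
    """When the ancestral allele is the one that breaks pairing, the derived
    allele creates the site."""
    mir = HSA_MIR_182
    site = find_seed_sites(mir, PALLD_UTR_FRAGMENT_C)[0]
    v = Variant(RS1071738.id, RS1071738.chrom, RS1071738.pos0, "C", "G",
                maf=0.43, ancestral="G")
    report = score_variant_site(mir, PALLD_UTR_FRAGMENT_C, site, v)
    assert report.effect == "site_creating"


# ---------------------------------------------------------------------------
# GO filter and ranking

def row(gene="G1", vid="rs1", maf=0.1, mirna="mirA"):
    return CandidateRow(gene, vid, maf, mirna, "8mer", 0, 1, "site_disrupting")


def test_go_filter_keeps_exactly_annotated_genes(rng):
    genes = [f"G{i}" for i in range(50)]
    chosen = set(rng.choice(genes, size=12, replace=False))
    annotations = {g: ({"GO:1"} if g in chosen else set()) for g in genes}
    candidates = [row(gene=g, vid=f"rs{i}") for i, g in enumerate(genes)]
    kept = filter_by_go(candidates, "GO:1", annotations)
    assert {r.gene for r in kept} == chosen
    assert all(r.go_matched for r in kept)


def test_go_filter_drops_unknown_gene_with_warning(caplog):
    candidates = [row(gene="KNOWN"), row(gene="UNKNOWN")]
    with caplog.at_level("WARNING"):
        kept = filter_by_go(candidates, "GO:1", {"KNOWN": {"GO:1"}})
    assert [r.gene for r in kept] == ["KNOWN"]
    assert "UNKNOWN" in caplog.text


def test_ranking_descending_maf_with_lexicographic_ties(rng):
    rows = [row(vid="rs2", maf=0.10), row(vid="rs1", maf=0.43), row(vid="rs3", maf=0.25)]
    assert [r.maf for r in rank_candidates(rows)] == [0.43, 0.25, 0.10]
    tied = [row(vid="rsB", maf=0.2), row(vid="rsA", maf=0.2, mirna="mirB"),
            row(vid="rsA", maf=0.2, mirna="mirA")]
    assert [(r.variant_id, r.mirna) for r in rank_candidates(tied)] == [
        ("rsA", "mirA"), ("rsA", "mirB"), ("rsB", "mirA")
    ]
    # oracle on random rows
    rows = [row(vid=f"rs{i}", maf=float(m)) for i, m in
            enumerate(rng.uniform(0, 0.5, size=1000).round(3))]
    expected = sorted(rows, key=lambda r: (-r.maf, r.variant_id, r.mirna))
    assert rank_candidates(rows) == expected


def test_ranking_requires_maf():
    with pytest.raises(ValueError, match="no MAF"):
        rank_candidates([row(maf=None)])


# ---------------------------------------------------------------------------
# repaired miRNA design

def test_repaired_mir96_matches_published_design():
    """WT miR-96/182 carry a G opposite the SNP; the engineered rescue
    replaces it with a C, restoring full pairing with the G allele."""
    for mir in (HSA_MIR_96, HSA_MIR_182):
        site = find_seed_sites(mir, PALLD_UTR_FRAGMENT_C)[0]
        rep = design_repaired_mirna(mir, PALLD_UTR_FRAGMENT_C, site, RS1071738, "G")
        assert rep.substituted_position == 5
        assert mir.mature_seq[4] == "G" and rep.sequence[4] == "C"
        assert sum(a != b for a, b in zip(rep.sequence, mir.mature_seq)) == 1
        repaired = MiRNA(rep.parent + "-MUT", rep.sequence)
        assert seed_mismatch_count(repaired, PALLD_UTR_FRAGMENT_G.seq, site) == 0


def test_repair_toward_already_matched_allele_is_flagged():
    mir = HSA_MIR_182
    site = find_seed_sites(mir, PALLD_UTR_FRAGMENT_C)[0]
    with pytest.raises(NotRepairableError, match="no-op"):
        design_repaired_mirna(mir, PALLD_UTR_FRAGMENT_C, site, RS1071738, "C")


def test_repair_outside_seed_span_rejected():
    mir = HSA_MIR_182
    site = find_seed_sites(mir, PALLD_UTR_FRAGMENT_C)[0]
    v = Variant("rs_far", RS1071738.chrom, PALLD_UTR_FRAGMENT_C.genomic_start + 2,
                PALLD_UTR_FRAGMENT_C.seq[2], "A")
    with pytest.raises(NotRepairableError, match="seed"):
        design_repaired_mirna(mir, PALLD_UTR_FRAGMENT_C, site, v, "A")


# ---------------------------------------------------------------------------
# VCF / sidecar I/O

def test_vcf_round_trip_and_sidecar(tmp_path, rng):
    from mirsnp.synthetic import write_vcf

    utr = make_utr("ACGT" * 25, start=0, chrom="chr9")
    variants = [
        Variant("rs10", "chr9", 4, "A", "G", maf=0.21),
        Variant("rs11", "chr9", 17, "C", "T", maf=0.05),
    ]
    path = tmp_path / "v.vcf"
    write_vcf(variants, [utr], path)
    back = read_variants_vcf(path)
    assert [(v.id, v.chrom, v.pos0, v.ref, v.alt, v.maf) for v in back] == [
        ("rs10", "chr9", 4, "A", "G", 0.21),
        ("rs11", "chr9", 17, "C", "T", 0.05),
    ]
    sidecar = tmp_path / "maf.tsv"
    sidecar.write_text("id\tmaf\tancestral\nrs10\t0.43\tG\n")
    side = read_maf_sidecar(sidecar)
    back = read_variants_vcf(path, sidecar=side)
    assert back[0].maf == 0.43 and back[0].ancestral_allele == "G"
    assert back[1].maf == 0.05


def test_indel_records_rejected_or_skipped(tmp_path):
    path = tmp_path / "indel.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t5\trs_indel\tAT\tA\t.\tPASS\t.\n"
        "chr1\t9\trs_snv\tA\tC\t.\tPASS\t.\n"
    )
    with pytest.raises(ValueError, match="indel"):
        read_variants_vcf(path)
    kept = read_variants_vcf(path, strict=False)
    assert [v.id for v in kept] == ["rs_snv"]
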