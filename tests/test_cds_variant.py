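import numpy as np
import pytest

from plantsurvey import seqcodes, simdata
from plantsurvey.cds_variant import (
    DELETION,
    FRAMESHIFT,
    IN_FRAME_INDEL,
    INSERTION,
    MISSENSE,
    PREMATURE_STOP,
    SNV,
    SYNONYMOUS,
    align_cds,
    apply_variants,
    call_and_classify,
    call_cds_variants,
    classify_effect,
    locate_allele,
    write_variants_tsv,
    write_vcf,
)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS with a start codon and no internal stop codons."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def test_identical_sequences_have_no_variants():
    cds = _random_cds(np.random.default_rng(1), 50)
    aln = align_cds(cds, cds)
    assert aln.column_counts() == (0, 0)
    assert call_cds_variants(aln) == []


def test_synonymous_third_position_snv():
    rng = np.random.default_rng(2)
    cds = _random_cds(rng, 40)
    # force codon 38 to CCT (Pro); change its third base to A -> CCA (still Pro)
    cds = cds[: 3 * 37] + "CCT" + cds[3 * 38 :]
    alt = cds[:113] + "A" + cds[114:]
    variants = call_and_classify(cds, alt)
    assert len(variants) == 1
    v = variants[0]
    assert (v.cds_pos, v.type, v.effect) == (114, SNV, SYNONYMOUS)
    assert v.aa_change == (38, "Pro", "Pro")


def test_his_to_gln_missense_at_codon_532():
    rng = np.random.default_rng(3)
    cds = _random_cds(rng, 533)
    cds = cds[: 3 * 531] + "CAT" + cds[3 * 532 :]  # codon 532 = CAT (His)
    assert len(cds) == 1599
    alt = cds[:1595] + "A" + cds[1596:]  # position 1596 T -> A: CAT -> CAA
    variants = call_and_classify(cds, alt)
    assert len(variants) == 1
    v = variants[0]
    assert v.cds_pos == 1596 and v.effect == MISSENSE
    assert v.aa_change == (532, "His", "Gln")


def test_nonsense_snv_is_premature_stop():
    # TGG (Trp) -> TGA (stop)
    cds = "ATG" + "TGG" + "GGA" * 10
    alt = cds[:5] + "A" + cds[6:]
    v = call_and_classify(cds, alt)[0]
    assert v.effect == PREMATURE_STOP
    assert v.aa_change == (2, "Trp", "Ter")


def test_single_base_deletion_frameshifts_to_early_stop():
    # deleting one base of codon 2 shifts the frame onto a TAA at codon 3
    cds = "ATG" + "AAG" + "CTA" + "ACC" + "GGG" + "CAC" * 4
    alt = cds[:4] + cds[5:]
    variants = call_and_classify(cds, alt)
    assert len(variants) == 1
    v = variants[0]
    assert v.type == DELETION and v.length == 1
    assert v.effect == FRAMESHIFT
    assert v.premature_stop_codon is not None
    # verify the reported stop codon against the shifted sequence
    shifted = apply_variants(cds, [v])
    cn = v.premature_stop_codon
    assert shifted[3 * (cn - 1) : 3 * cn] in {"TAA", "TAG", "TGA"}


def test_74_base_deletion_is_frameshift():
    rng = np.random.default_rng(4)
    cds = _random_cds(rng, 550)
    alt = cds[:1574] + cds[1648:]  # remove bases 1575..1648 inclusive
    variants = call_and_classify(cds, alt)
    assert len(variants) == 1
    v = variants[0]
    assert v.type == DELETION and v.length == 74
    # equivalent placements may shift by a base or two at matching junctions
    assert abs(v.cds_pos - 1575) <= 3
    assert v.cds_end == v.cds_pos + 73
    assert v.length % 3 == 2
    assert v.effect == FRAMESHIFT


def test_in_frame_deletion_and_insertion():
    cds = _random_cds(np.random.default_rng(5), 30)
    del3 = cds[:30] + cds[33:]
    assert call_and_classify(cds, del3)[0].effect == IN_FRAME_INDEL
    ins3 = cds[:30] + "AAA" + cds[30:]
    v = call_and_classify(cds, ins3)[0]
    assert v.type == INSERTION and v.effect == IN_FRAME_INDEL


def test_classify_requires_codon_aligned_reference():
    v = call_cds_variants(align_cds("ATGCA", "ATGCC"))[0]
    with pytest.raises(ValueError):
        classify_effect(v, "ATGCA")


def test_variant_round_trip_random_mutations(rng):
    for trial in range(200):
        cds = _random_cds(rng, int(rng.integers(20, 120)))
        alt = list(cds)
        for _ in range(int(rng.integers(0, 6))):
            kind = int(rng.integers(0, 3))
            if not alt:
                break
            p = int(rng.integers(0, len(alt)))
            if kind == 0:
                alt[p] = "ACGT"[("ACGT".index(alt[p]) + int(rng.integers(1, 4))) % 4]
            elif kind == 1 and len(alt) > 10:
                del alt[p : p + int(rng.integers(1, 4))]
            else:
                alt.insert(p, "ACGT"[int(rng.integers(0, 4))])
        alt_seq = "".join(alt)
        aln = align_cds(cds, alt_seq)
        variants = call_cds_variants(aln)
        assert apply_variants(cds, variants) == alt_seq, f"trial {trial}"


def test_locate_allele_on_both_strands(rng):
    genome = simdata.make_organelle_genome(60_000, seed=31)
    gene = _random_cds(rng, 400)  # 1200 bp
    target = genome[:20_000] + gene + genome[20_000:]
    hit = locate_allele(gene, [("chr1", target)])
    assert hit is not None
    assert (hit.chrom_id, hit.start, hit.end, hit.strand) == ("chr1", 20_001, 20_000 + len(gene), "+")
    assert hit.identity == 1.0

    flipped = genome[:20_000] + seqcodes.revcomp(gene) + genome[20_000:]
    hit2 = locate_allele(gene, [("chr1", flipped)])
    assert hit2 is not None and hit2.strand == "-"
    assert (hit2.start, hit2.end) == (20_001, 20_000 + len(gene))


def test_locate_allele_tolerates_divergence_and_rejects_unrelated(rng):
    genome = simdata.make_organelle_genome(50_000, seed=32)
    gene = _random_cds(rng, 350)
    target = genome[:10_000] + gene + genome[10_000:]
    query = simdata.make_diploid(gene, 0.02, seed=34)[1]  # ~2% diverged allele
    hit = locate_allele(query, [("c", target)])
    assert hit is not None and hit.identity > 0.95

    unrelated = _random_cds(np.random.default_rng(99), 350)
    assert locate_allele(unrelated, [("c", genome)]) is None


def test_locate_allele_rejects_short_query():
    with pytest.raises(ValueError):
        locate_allele("ACGT" * 10, [("c", "ACGT" * 1000)])


def test_vcf_and_tsv_output(tmp_path):
    from plantsurvey.cds_variant import VariantRecord

    cds = "ATGCATCCTGGG"  # codons ATG CAT CCT GGG
    v_snv = classify_effect(VariantRecord(6, "T", "A", SNV, 1), cds)
    v_del = classify_effect(VariantRecord(7, "CC", "", DELETION, 2), cds)
    v_ins = classify_effect(VariantRecord(9, "", "AAA", INSERTION, 3), cds)
    variants = [v_snv, v_del, v_ins]
    vcf = tmp_path / "out.vcf"
    write_vcf(variants, cds, "cds1", vcf)
    lines = vcf.read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    data = [l.split("\t") for l in lines if not l.startswith("#")]
    assert len(data) == 3
    # SNV reported in place; indels anchored on the preceding reference base
    assert data[0][:5] == ["cds1", "6", ".", "T", "A"]
    assert "AA=His2Gln" in data[0][7]
    assert data[1][:5] == ["cds1", "6", ".", "TCC", "T"]
    assert data[2][:5] == ["cds1", "9", ".", "T", "TAAA"]
    tsv = tmp_path / "out.tsv"
    write_variants_tsv(variants, tsv)
    assert len(tsv.read_text().splitlines()) == len(variants) + 1


def test_alignment_scoring_prefers_single_gap():
    # one 2-base gap should beat two separate 1-base gaps under affine costs
    ref = "AAACCCGGGTTTACGTACGT"
    alt = "AAACCCGGGACGTACGT"  # TTT -> (drop 3)
    aln = align_cds(ref, alt)
    mm, gaps = aln.column_counts()
    assert (mm, gaps) == (0, 3)
    assert "---" in aln.alt_aligned
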