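import numpy as np
import pytest

from plantsurvey import seqcodes, simdata
from plantsurvey.organelle_filter import (
    ORGANELLE,
    NUCLEAR,
    AcceptanceRule,
    build_organelle_index,
    classify_batch,
    classify_read,
    organelle_pileup,
    partition_reads,
    partition_readsets,
)
from plantsurvey.reads import ReadSet

from .oracles import oracle_is_organelle, plant_edited_read

L = 140


def test_rule_truth_table():
    rule = AcceptanceRule()
    # (mismatches, gap bases) -> accepted?
    cases = {
        (0, 0): True,
        (3, 0): True,
        (4, 0): False,
        (0, 2): True,
        (0, 3): False,
        (1, 1): True,
        (2, 1): False,
        (1, 2): False,
    }
    for (mm, g), expect in cases.items():
        assert rule.satisfies(mm, g) is expect, (mm, g)
    assert rule.max_gap_bases == 2
    assert rule.max_edits == 3


def test_rule_rejects_negative_limits():
    with pytest.raises(ValueError):
        AcceptanceRule(max_mismatch_only=-1)


def _mutate(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def test_classifier_edge_cases(organelle_30k, organelle_index_30k):
    org, index = organelle_30k, organelle_index_30k
    sub = org[1000 : 1000 + L]

    # exact substring
    label, hit = classify_read(sub, index)
    assert label == ORGANELLE
    assert hit.ref_start == 1001 and hit.strand == "+"
    assert hit.n_mismatch == 0 and hit.n_gap_bases == 0

    # exactly at the mismatch limit, then one over
    label, hit = classify_read(_mutate(sub, [5, 60, 120]), index)
    assert label == ORGANELLE and hit.n_mismatch == 3
    assert classify_read(_mutate(sub, [5, 60, 100, 120]), index)[0] == NUCLEAR

    # 1-base deletion -> 1 gap base
    src = org[2000 : 2000 + L + 1]
    label, hit = classify_read(src[:70] + src[71:], index)
    assert label == ORGANELLE and hit.n_gap_bases == 1

    # 1 deletion + 1 mismatch accepted; 1 deletion + 2 mismatches rejected
    one_del = src[:70] + src[71:]
    assert classify_read(_mutate(one_del, [10]), index)[0] == ORGANELLE
    assert classify_read(_mutate(one_del, [10, 120]), index)[0] == NUCLEAR

    # 2-base deletion, mismatch-free
    src2 = org[3000 : 3000 + L + 2]
    label, hit = classify_read(src2[:50] + src2[52:], index)
    assert label == ORGANELLE and hit.n_gap_bases == 2

    # 1-base insertion
    ins = org[4000 : 4000 + L - 1]
    assert classify_read(ins[:80] + "A" + ins[80:], index)[0] == ORGANELLE

    # reverse strand
    label, hit = classify_read(seqcodes.revcomp(sub), index)
    assert label == ORGANELLE and hit.strand == "-"

    # read spanning the circular origin
    wrap = (org + org)[len(org) - 50 : len(org) - 50 + L]
    label, hit = classify_read(wrap, index)
    assert label == ORGANELLE
    assert hit.ref_start == len(org) - 50 + 1

    # N counts as a mismatch: 3 Ns pass, 4 Ns fail
    with_n = lambda k: "N" * k + sub[k:]
    assert classify_read(with_n(3), index)[0] == ORGANELLE
    assert classify_read(with_n(4), index)[0] == NUCLEAR

    # unrelated random read
    rng = np.random.default_rng(0)
    rand = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
    assert classify_read(rand, index)[0] == NUCLEAR


def test_batch_and_single_read_classification_agree(organelle_30k, organelle_index_30k, rng):
    reads, seqs = [], []
    ref_ext_len = organelle_index_30k.cat.size
    for i in range(60):
        seq, _ = plant_edited_read(
            rng, organelle_index_30k.cat, L,
            n_sub=int(rng.integers(0, 5)),
            n_del=int(rng.integers(0, 3)),
            n_ins=int(rng.integers(0, 3)),
            revcomp=bool(rng.random() < 0.5),
        )
        seqs.append(seq)
    mat = seqcodes.encode_matrix(seqs)
    labels, _ = classify_batch(mat, organelle_index_30k)
    for i, seq in enumerate(seqs):
        single, _ = classify_read(seq, organelle_index_30k)
        assert labels[i] == (single == ORGANELLE)


def test_classifier_agrees_with_exhaustive_oracle_small(organelle_index_30k, rng):
    index = organelle_index_30k
    rule = AcceptanceRule()
    for i in range(120):
        if i % 12 == 0:
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, L))
            pos = 0
        else:
            seq, pos = plant_edited_read(
                rng, index.cat, L,
                n_sub=int(rng.integers(0, 6)),
                n_del=int(rng.integers(0, 3)),
                n_ins=int(rng.integers(0, 3)),
                revcomp=bool(rng.random() < 0.5),
            )
        got = classify_read(seq, index)[0] == ORGANELLE
        want = oracle_is_organelle(seq, index.cat, pos, rule)
        assert got == want, f"case {i}"


def test_partition_conserves_reads_and_stats(organelle_30k, organelle_index_30k):
    cfg = simdata.SimConfig(
        nuclear_size=100_000, repeat_fraction=0.0, organelle_sizes=(30_000,),
        depth_nuclear=4.0, organelle_read_fraction=0.2, read_len=140,
        insert_mean=280.0, seed=9,
    )
    out = simdata.simulate_survey(cfg)
    sets = [out["reads1"], out["reads2"]]
    index = build_organelle_index([("org0", out["organelles"][0])], read_len=140)
    masks, _, stats = partition_readsets(sets, index)
    total = sum(rs.n_reads for rs in sets)
    removed = sum(int(m.sum()) for m in masks)
    assert stats.reads_in == total
    assert stats.reads_removed == removed
    assert stats.bases_removed == removed * 140
    assert 0 < stats.removed_read_fraction < 1
    # labels agree well with simulation truth for both mates
    truth = out["truth"].origin == 1
    for m in masks:
        assert (m == truth).mean() > 0.99


def test_file_level_partition_writes_both_classes(tmp_path, organelle_30k,
                                                  organelle_index_30k, rng):
    org = organelle_30k
    seqs = [org[i * 150 : i * 150 + 140] for i in range(20)]
    seqs += ["".join("ACGT"[j] for j in rng.integers(0, 4, 140)) for _ in range(10)]
    rs = ReadSet(seqcodes.encode_matrix(seqs), 30)
    fin = tmp_path / "in.fastq"
    rs.to_fastq(fin)
    stats = partition_reads(
        [fin], organelle_index_30k, tmp_path / "nuc.fastq", tmp_path / "org.fastq"
    )
    nuc = ReadSet.from_fastq(tmp_path / "nuc.fastq")
    orgs = ReadSet.from_fastq(tmp_path / "org.fastq")
    assert nuc.n_reads + orgs.n_reads == 30
    assert orgs.n_reads == stats.reads_removed == 20


def test_pileup_depth_breadth_and_het(organelle_30k, organelle_index_30k):
    org, index = organelle_30k, organelle_index_30k
    n = len(org)
    # perfect tiling at step 10 -> uniform depth 14, full breadth, no het
    ext = org + org
    seqs = [ext[p : p + L] for p in range(0, n, 10)]
    rs = ReadSet(seqcodes.encode_matrix(seqs), 30)
    _, hits = classify_batch(rs, index)
    rep = organelle_pileup(rs, hits, index)
    assert rep.breadth == 1.0
    assert rep.mean_depth == pytest.approx(L / 10)
    assert rep.het_sites == []

    # 50/50 mixture of two templates differing at one site -> one het site
    site = 5_000
    alt = org[:site] + {"A": "C", "C": "G", "G": "T", "T": "A"}[org[site]] + org[site + 1 :]
    ext_alt = alt + alt
    seqs2 = seqs + [ext_alt[p : p + L] for p in range(0, n, 10)]
    rs2 = ReadSet(seqcodes.encode_matrix(seqs2), 30)
    _, hits2 = classify_batch(rs2, index)
    rep2 = organelle_pileup(rs2, hits2, index)
    assert [p for p, _ in rep2.het_sites] == [site + 1]
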