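import numpy as np
import pytest

from plantsurvey import readqc
from plantsurvey.reads import ReadRecord, ReadSet
from plantsurvey.readqc import QCParams, filter_read, filtering_rate, trim_read


def _rec(seq: str, qual_char: str = "I") -> ReadRecord:
    return ReadRecord("r", seq, qual_char * len(seq))


def test_trim_removes_front_and_tail():
    read = _rec("A" * 8 + "C" * 140 + "G" * 2)
    trimmed = trim_read(read, QCParams())
    assert trimmed.seq == "C" * 140
    assert len(trimmed.qual) == 140


def test_trim_collapses_too_short_read():
    trimmed = trim_read(_rec("ACGTACGT"), QCParams(front_trim=5, tail_trim=5))
    assert trimmed.seq == ""


def test_filter_reason_order_is_length_then_n_then_quality():
    params = QCParams(front_trim=0, tail_trim=0, min_len=10)
    # too short AND has N: length reported first
    assert filter_read(_rec("ACGNT"), params) == readqc.REASON_LENGTH
    # long enough, has N AND bad quality: N reported first
    bad = ReadRecord("r", "ACGTNACGTA", "!" * 10)
    assert filter_read(bad, params) == readqc.REASON_N_COUNT
    # only bad quality
    lowq = ReadRecord("r", "ACGTACGTAC", "!" * 10)
    assert filter_read(lowq, params) == readqc.REASON_QUALITY
    assert filter_read(_rec("ACGTACGTAC"), params) is None


def test_quality_fraction_threshold_is_exact():
    params = QCParams(front_trim=0, tail_trim=0, min_len=140)
    # 140 bases, max unqualified fraction 0.20 -> at most 28 bases below Q20
    for n_bad, expect in [(28, None), (29, readqc.REASON_QUALITY)]:
        qual = "!" * n_bad + "I" * (140 - n_bad)
        assert filter_read(ReadRecord("r", "A" * 140, qual), params) == expect


def test_vectorized_qc_matches_record_level_reference(rng):
    params = QCParams()
    n, L = 300, 150
    codes = rng.integers(0, 4, size=(n, L)).astype(np.uint8)
    # sprinkle Ns into some reads
    rows = rng.integers(0, n, size=40)
    cols = rng.integers(0, L, size=40)
    codes[rows, cols] = 4
    quals = rng.choice([2, 25, 38], size=(n, L), p=[0.15, 0.35, 0.5]).astype(np.int16)
    rs = ReadSet(codes, quals)
    keep, trimmed = readqc.qc_readset(rs, params)
    for i, rec in enumerate(rs.records()):
        t = trim_read(rec, params)
        expect_keep = filter_read(t, params) is None
        assert keep[i] == expect_keep, f"read {i}"
    # trimmed matrix matches string-level trimming
    rec0 = next(iter(rs.records()))
    assert next(iter(trimmed.records())).seq == trim_read(rec0, params).seq


def test_pairs_are_dropped_symmetrically(rng):
    params = QCParams(front_trim=0, tail_trim=0, min_len=10,
                      max_unqualified_fraction=0.2)
    good = np.full((4, 10), 30, dtype=np.int16)
    bad = good.copy()
    bad[1] = 5  # whole read below Q20 -> fails
    r1 = ReadSet(rng.integers(0, 4, (4, 10)).astype(np.uint8), good)
    r2 = ReadSet(rng.integers(0, 4, (4, 10)).astype(np.uint8), bad)
    c1, c2, stats, keep = readqc.qc_pairs(r1, r2, params)
    assert keep.tolist() == [True, False, True, True]
    assert c1.n_reads == c2.n_reads == 3
    assert stats.reads_in == 8 and stats.reads_out == 6


def test_file_level_qc_stats_consistency(tmp_path, rng):
    n, L = 50, 150
    codes = rng.integers(0, 4, (n, L)).astype(np.uint8)
    quals = rng.choice([12, 35], size=(n, L), p=[0.15, 0.85]).astype(np.int16)
    rs = ReadSet(codes, quals)
    fin, fout = tmp_path / "in.fastq", tmp_path / "out.fastq"
    rs.to_fastq(fin)
    stats = readqc.run_qc(fin, fout, QCParams())
    assert stats.raw_bases == n * L
    assert stats.reads_in == n
    assert stats.clean_bases == stats.reads_out * 140
    assert stats.filtering_rate == pytest.approx(
        100 * (1 - stats.clean_bases / stats.raw_bases)
    )
    kept = ReadSet.from_fastq(fout)
    assert kept.n_reads == stats.reads_out
    assert kept.read_len == 140


def test_file_and_memory_qc_agree(tmp_path, rng):
    n, L = 200, 150
    codes = rng.integers(0, 4, (n, L)).astype(np.uint8)
    codes[rng.integers(0, n, 10), rng.integers(0, L, 10)] = 4
    quals = rng.choice([10, 30], size=(n, L), p=[0.12, 0.88]).astype(np.int16)
    r1, r2 = ReadSet(codes[:100], quals[:100]), ReadSet(codes[100:], quals[100:])
    _, _, mem_stats, _ = readqc.qc_pairs(r1, r2, QCParams())
    p = {k: tmp_path / f"{k}.fastq" for k in ("i1", "i2", "o1", "o2")}
    r1.to_fastq(p["i1"])
    r2.to_fastq(p["i2"])
    file_stats = readqc.run_qc(p["i1"], p["o1"], QCParams(), p["i2"], p["o2"])
    assert file_stats.reads_out == mem_stats.reads_out
    assert file_stats.clean_bases == mem_stats.clean_bases
    assert file_stats.q20_pct == pytest.approx(mem_stats.q20_pct)


def test_filtering_rate_formula_and_errors():
    assert filtering_rate(100.0, 87.0) == pytest.approx(13.0)
    with pytest.raises(ValueError):
        filtering_rate(0, 0)


def test_negative_params_rejected():
    with pytest.raises(ValueError):
        QCParams(front_trim=-1).validate()
    with pytest.raises(ValueError):
        QCParams(max_unqualified_fraction=1.5).validate()
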