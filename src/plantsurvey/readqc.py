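"""Read cleaning: fixed front/tail trimming plus length, N-count and
low-quality-fraction filters, with summary statistics.

The defaults mirror a fastp-style invocation used for survey data: trim 8
bases from the front and 2 from the tail of each 150 bp read, then discard
reads shorter than 140 bp, reads containing any N, and reads in which more
than 20% of bases fall below Q20.  Pairs are dropped symmetrically: if one
mate fails, both are removed, which keeps mate files synchronized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .reads import ReadRecord, ReadSet, iter_fastq_records, write_fastq_records

# reason codes, checked in this fixed order
REASON_LENGTH = "length"
REASON_N_COUNT = "n_count"
REASON_QUALITY = "quality"


@dataclass
class QCParams:
    front_trim: int = 8
    tail_trim: int = 2
    min_len: int = 140
    qual_threshold: int = 20
    max_unqualified_fraction: float = 0.20
    max_n: int = 0

    def validate(self) -> None:
        if min(self.front_trim, self.tail_trim, self.min_len, self.max_n) < 0:
            raise ValueError("QC parameters must be non-negative")
        if not 0.0 <= self.max_unqualified_fraction <= 1.0:
            raise ValueError("max_unqualified_fraction must be in [0, 1]")


@dataclass
class QCStats:
    raw_bases: int = 0
    clean_bases: int = 0
    reads_in: int = 0
    reads_out: int = 0
    q20_pct: float = 0.0
    q30_pct: float = 0.0
    raw_q20_pct: float = 0.0
    raw_q30_pct: float = 0.0

    @property
    def filtering_rate(self) -> float:
        """Percentage of raw bases removed by trimming and filtering."""
        if self.raw_bases == 0:
            return 0.0
        return 100.0 * (1.0 - self.clean_bases / self.raw_bases)

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["filtering_rate"] = self.filtering_rate
        text = json.dumps(d, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def filtering_rate(raw_bases: float, clean_bases: float) -> float:
    """100 * (1 - clean/raw); the headline QC number of a survey run."""
    if raw_bases <= 0:
        raise ValueError("raw_bases must be positive")
    return 100.0 * (1.0 - clean_bases / raw_bases)


def trim_read(read: ReadRecord, params: QCParams) -> ReadRecord:
    """Remove the first front_trim and last tail_trim bases (and qualities).

    A read shorter than the combined trim lengths collapses to an empty
    read, which the length filter then discards.
    """
    if len(read.seq) <= params.front_trim + params.tail_trim:
        return ReadRecord(read.id, "", "")
    end = len(read.seq) - params.tail_trim
    return ReadRecord(
        read.id, read.seq[params.front_trim : end], read.qual[params.front_trim : end]
    )


def filter_read(read: ReadRecord, params: QCParams) -> str | None:
    """Return None to keep the read, or the first failing rule's reason code.

    Rules are applied in a fixed order (length, then N count, then
    unqualified-base fraction) so reason codes are reproducible.
    """
    n = len(read.seq)
    if n < params.min_len:
        return REASON_LENGTH
    if read.seq.count("N") > params.max_n:
        return REASON_N_COUNT
    if n > 0:
        unqualified = int((read.phred() < params.qual_threshold).sum())
        if unqualified / n > params.max_unqualified_fraction:
            return REASON_QUALITY
    return None


def _q_pcts(quals: np.ndarray) -> tuple[float, float]:
    if quals.size == 0:
        return 0.0, 0.0
    q20 = 100.0 * float((quals >= 20).mean())
    q30 = 100.0 * float((quals >= 30).mean())
    return q20, q30


def qc_readset(rs: ReadSet, params: QCParams) -> tuple[np.ndarray, ReadSet]:
    """Vectorized trim+filter of a uniform-length batch.

    Returns (keep mask over input reads, trimmed ReadSet of all input reads).
    Callers combine masks across mates before subsetting.
    """
    params.validate()
    L = rs.read_len
    f, t = params.front_trim, params.tail_trim
    if L <= f + t:
        trimmed = ReadSet(rs.codes[:, :0], 0 if np.isscalar(rs.quals) else rs.quals[:, :0], rs.ids)
        return np.zeros(rs.n_reads, dtype=bool), trimmed
    codes = rs.codes[:, f : L - t]
    quals = rs.quals if np.isscalar(rs.quals) else rs.quals[:, f : L - t]
    trimmed = ReadSet(codes, quals, rs.ids)
    n = codes.shape[1]
    keep = np.full(rs.n_reads, n >= params.min_len)
    if keep.any():
        n_count = (codes >= 4).sum(axis=1)
        keep &= n_count <= params.max_n
    if keep.any():
        if np.isscalar(quals):
            if (int(quals) < params.qual_threshold) and params.max_unqualified_fraction < 1.0:
                keep[:] = False
        else:
            unq = (quals < params.qual_threshold).sum(axis=1)
            keep &= unq / n <= params.max_unqualified_fraction
    return keep, trimmed


def qc_pairs(
    r1: ReadSet, r2: ReadSet, params: QCParams
) -> tuple[ReadSet, ReadSet, QCStats, np.ndarray]:
    """Trim and filter mate pairs in memory; a pair survives only if both
    mates pass.  Returns (clean1, clean2, stats, keep mask over pairs)."""
    keep1, t1 = qc_readset(r1, params)
    keep2, t2 = qc_readset(r2, params)
    keep = keep1 & keep2
    c1, c2 = t1.subset(keep), t2.subset(keep)
    stats = QCStats(
        raw_bases=r1.n_bases + r2.n_bases,
        clean_bases=c1.n_bases + c2.n_bases,
        reads_in=r1.n_reads + r2.n_reads,
        reads_out=c1.n_reads + c2.n_reads,
    )
    raw_q = np.concatenate([r1.qual_matrix().ravel(), r2.qual_matrix().ravel()])
    clean_q = np.concatenate([c1.qual_matrix().ravel(), c2.qual_matrix().ravel()])
    stats.raw_q20_pct, stats.raw_q30_pct = _q_pcts(raw_q)
    stats.q20_pct, stats.q30_pct = _q_pcts(clean_q)
    return c1, c2, stats, keep


def run_qc(
    fastq_in: str | Path,
    fastq_out: str | Path,
    params: QCParams | None = None,
    fastq_in2: str | Path | None = None,
    fastq_out2: str | Path | None = None,
) -> QCStats:
    """File-level QC.  Single-end, or paired when the second in/out paths are
    given (pairs are dropped if either mate fails)."""
    params = params or QCParams()
    params.validate()
    stats = QCStats()
    raw_q_hits = np.zeros(2, dtype=np.int64)  # >=Q20, >=Q30 in raw bases
    clean_q_hits = np.zeros(2, dtype=np.int64)

    def process(read: ReadRecord) -> ReadRecord | None:
        stats.reads_in += 1
        stats.raw_bases += len(read)
        q = read.phred()
        raw_q_hits[0] += int((q >= 20).sum())
        raw_q_hits[1] += int((q >= 30).sum())
        trimmed = trim_read(read, params)
        if filter_read(trimmed, params) is not None:
            return None
        return trimmed

    if fastq_in2 is None:
        kept = []
        for read in iter_fastq_records(fastq_in):
            out = process(read)
            if out is not None:
                kept.append(out)
        write_fastq_records(kept, fastq_out)
    else:
        kept1, kept2 = [], []
        it2 = iter_fastq_records(fastq_in2)
        for read1 in iter_fastq_records(fastq_in):
            read2 = next(it2)
            out1, out2 = process(read1), process(read2)
            if out1 is not None and out2 is not None:
                kept1.append(out1)
                kept2.append(out2)
        write_fastq_records(kept1, fastq_out)
        write_fastq_records(kept2, fastq_out2)
        kept = kept1 + kept2

    for read in kept:
        stats.reads_out += 1
        stats.clean_bases += len(read)
        q = read.phred()
        clean_q_hits[0] += int((q >= 20).sum())
        clean_q_hits[1] += int((q >= 30).sum())
    if stats.raw_bases:
        stats.raw_q20_pct = 100.0 * raw_q_hits[0] / stats.raw_bases
        stats.raw_q30_pct = 100.0 * raw_q_hits[1] / stats.raw_bases
    if stats.clean_bases:
        stats.q20_pct = 100.0 * clean_q_hits[0] / stats.clean_bases
        stats.q30_pct = 100.0 * clean_q_hits[1] / stats.clean_bases
    return stats
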