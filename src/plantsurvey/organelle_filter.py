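"""Organelle-read classification by seed-and-extend alignment under an
explicit acceptance rule.

A read is labelled ORGANELLE when it has an end-to-end alignment, on either
strand, to one of the organelle references with

* no gaps and at most 3 mismatches, or
* no mismatches and at most 2 gap bases, or
* 1 gap base and at most 1 mismatch

(defaults; every limit is configurable).  Insertions and deletions both
count toward the gap-base total, and N in a read counts as a mismatch
against any base.

The engine finds candidates with non-overlapping exact seeds packed into
64-bit integers: with ``n_seeds = max_edits + 1`` disjoint seeds, any
alignment within the edit budget must contain at least one exact seed
(pigeonhole), so no qualifying alignment is missed.  Candidates are first
verified gaplessly (vectorized); only candidates that fail gaplessly fall
back to a small banded dynamic program that tracks the minimum mismatch
count for every gap-base budget.

Circular references are indexed with their origin-spanning windows by
concatenating the first read_len-1 bases onto the end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seqcodes
from .reads import ReadRecord, ReadSet, read_fasta

ORGANELLE = "ORGANELLE"
NUCLEAR = "NUCLEAR"

_INF = 1 << 30


@dataclass
class AcceptanceRule:
    max_mismatch_only: int = 3  # gapless alignments
    max_gap_only: int = 2  # gap bases when mismatch-free
    mixed_max_gap: int = 1
    mixed_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if min(
            self.max_mismatch_only,
            self.max_gap_only,
            self.mixed_max_gap,
            self.mixed_max_mismatch,
        ) < 0:
            raise ValueError("rule limits must be non-negative")

    def satisfies(self, n_mismatch: int, n_gap_bases: int) -> bool:
        if n_gap_bases == 0 and n_mismatch <= self.max_mismatch_only:
            return True
        if n_mismatch == 0 and n_gap_bases <= self.max_gap_only:
            return True
        if (
            n_gap_bases <= self.mixed_max_gap
            and n_mismatch <= self.mixed_max_mismatch
        ):
            return True
        return False

    @property
    def max_gap_bases(self) -> int:
        return max(self.max_gap_only, self.mixed_max_gap)

    @property
    def max_edits(self) -> int:
        return max(
            self.max_mismatch_only,
            self.max_gap_only,
            self.mixed_max_gap + self.mixed_max_mismatch,
        )


@dataclass
class AlignmentHit:
    """A read placement: 1-based start on the (possibly circular) reference."""

    ref_id: str
    ref_start: int
    strand: str  # '+' or '-'
    n_mismatch: int
    n_gap_bases: int


class ReferenceIndex:
    """Exact-seed index over one or more reference sequences.

    Seeds are ``seed_len``-mers (max 32, packed 2 bits/base into uint64)
    taken at every position of each reference; circular references are
    extended by ``wrap_ext`` bases so origin-spanning placements are found.
    Lookup is by binary search in the sorted seed-code array.
    """

    def __init__(
        self,
        refs: list[tuple[str, str]],
        seed_len: int = 32,
        read_len: int = 150,
        circular: bool = True,
    ):
        if not refs:
            raise ValueError("no reference sequences given")
        if not 1 <= seed_len <= 32:
            raise ValueError("seed_len must be in 1..32")
        self.seed_len = seed_len
        self.circular = circular
        self.ref_ids = [r[0] for r in refs]
        self.ref_lens = np.array([len(r[1]) for r in refs], dtype=np.int64)
        if (self.ref_lens == 0).any():
            raise ValueError("empty reference sequence")
        wrap_ext = (read_len - 1 + 2) if circular else 0  # +2: room for deletions
        ext_parts = []
        for _, seq in refs:
            codes = seqcodes.encode(seq)
            if circular:
                ext = np.concatenate([codes, codes[: min(wrap_ext, codes.size)]])
            else:
                ext = codes
            ext_parts.append(ext)
        self.ext_lens = np.array([e.size for e in ext_parts], dtype=np.int64)
        self.ref_offsets = np.concatenate([[0], np.cumsum(self.ext_lens)])[:-1]
        self.cat = np.concatenate(ext_parts)

        codes_all, pos_all = [], []
        for i, ext in enumerate(ext_parts):
            kc = seqcodes.kmer_codes(ext, seed_len)
            valid = ~seqcodes.window_has_n(ext, seed_len)
            pos = np.flatnonzero(valid).astype(np.int64) + self.ref_offsets[i]
            codes_all.append(kc[valid])
            pos_all.append(pos)
        codes_cat = np.concatenate(codes_all)
        pos_cat = np.concatenate(pos_all)
        order = np.argsort(codes_cat, kind="stable")
        self.sorted_codes = codes_cat[order]
        self.sorted_pos = pos_cat[order]

    def ref_index_of(self, global_pos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.ref_offsets, global_pos, side="right") - 1

    def lookup(self, seed_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Start/count of matching positions for each query seed code."""
        lo = np.searchsorted(self.sorted_codes, seed_codes, side="left")
        hi = np.searchsorted(self.sorted_codes, seed_codes, side="right")
        return lo, hi - lo


def build_organelle_index(
    refs: list[tuple[str, str]] | str | Path,
    seed_len: int = 32,
    read_len: int = 150,
    circular: bool = True,
) -> ReferenceIndex:
    """Index organelle reference genomes (FASTA path or (id, seq) pairs)."""
    if isinstance(refs, (str, Path)):
        refs = read_fasta(refs)
    return ReferenceIndex(refs, seed_len=seed_len, read_len=read_len, circular=circular)


def _pack_seed(mat: np.ndarray, offset: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack columns [offset, offset+s) of a code matrix into uint64 codes;
    also return the mask of rows whose window contains a non-ACGT code."""
    out = np.zeros(mat.shape[0], dtype=np.uint64)
    bad = np.zeros(mat.shape[0], dtype=bool)
    for j in range(offset, offset + s):
        col = mat[:, j]
        bad |= col >= 4
        out = (out << np.uint64(2)) | (col.astype(np.uint64) & np.uint64(3))
    return out, bad


def _expand_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Flat indices covering [starts[i], starts[i]+counts[i]) for all i."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    rep_starts = np.repeat(starts, counts)
    ends = np.cumsum(counts)
    intra = np.arange(total, dtype=np.int64) - np.repeat(ends - counts, counts)
    return rep_starts + intra


def _gapped_rule_check(
    read: np.ndarray, ref: np.ndarray, start: int, rule: AcceptanceRule
) -> tuple[int, int] | None:
    """Banded DP around a candidate diagonal.

    Tracks, for every gap-base budget g and diagonal offset, the minimum
    mismatch count of an end-to-end alignment of the read.  Deletions
    (reference base skipped) are internal only; a gap at the very start is
    equivalent to shifting the start, which the outer loop covers.
    Returns the best (n_mismatch, n_gap_bases) satisfying the rule, or None.
    """
    band = rule.max_gap_bases
    if band == 0:
        return None
    L = read.size
    width = 2 * band + 1
    best: tuple[int, int] | None = None
    for s0 in range(start - band, start + band + 1):
        if s0 < 0 or s0 + L - band > ref.size:
            continue
        dp = [[_INF] * width for _ in range(band + 1)]
        dp[0][band] = 0
        for i in range(L):
            if i > 0:
                # deletion closure: skip reference bases between read
                # positions; ascending g so multi-base skips chain through
                # the freshly updated budgets
                for g in range(band):
                    for oi in range(width - 1):
                        v = dp[g][oi]
                        if v < dp[g + 1][oi + 1]:
                            dp[g + 1][oi + 1] = v
            ndp = [[_INF] * width for _ in range(band + 1)]
            ri = int(read[i])
            for g in range(band + 1):
                row = dp[g]
                for oi in range(width):
                    v = row[oi]
                    if v >= _INF:
                        continue
                    j = s0 + i + (oi - band)
                    if 0 <= j < ref.size:
                        cost = 0 if (ri == int(ref[j]) and ri < 4) else 1
                        if v + cost < ndp[g][oi]:
                            ndp[g][oi] = v + cost
                    if g < band and oi >= 1 and v < ndp[g + 1][oi - 1]:
                        ndp[g + 1][oi - 1] = v  # insertion: read base unaligned
            dp = ndp
        for g in range(band + 1):
            for oi in range(width):
                mm = dp[g][oi]
                if mm < _INF and rule.satisfies(mm, g):
                    cand = (mm, g)
                    if best is None or (cand[0] + cand[1], cand[1]) < (
                        best[0] + best[1],
                        best[1],
                    ):
                        best = cand
    return best


@dataclass
class BatchHits:
    """Best accepted placement per classified read (parallel arrays over the
    subset of reads labelled ORGANELLE)."""

    read_idx: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    ref_idx: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    pos: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))  # 0-based
    strand: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint8))
    n_mismatch: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    n_gap_bases: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


def classify_batch(
    rs: ReadSet | np.ndarray,
    index: ReferenceIndex,
    rule: AcceptanceRule | None = None,
    chunk_size: int = 500_000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, BatchHits]:
    """Classify a batch of uniform-length reads.

    Returns (boolean array: True where the read matches an organelle
    reference under the rule, best hits for those reads).  ``rng``, when
    given, breaks ties between equally good placements at random instead of
    preferring the lowest coordinate / + strand (used for depth mapping).
    """
    rule = rule or AcceptanceRule()
    codes = rs.codes if isinstance(rs, ReadSet) else rs
    n_reads, L = codes.shape
    s = index.seed_len
    n_seeds = min(rule.max_edits + 1, max(1, L // s))
    if L < s:
        raise ValueError("reads shorter than the seed length")
    offsets = [int(round(i * (L - s) / max(1, n_seeds - 1))) for i in range(n_seeds)]

    labels = np.zeros(n_reads, dtype=bool)
    all_hits: list[tuple] = []

    for c0 in range(0, n_reads, chunk_size):
        mat = codes[c0 : c0 + chunk_size]
        n = mat.shape[0]
        rc = seqcodes.revcomp_codes(mat)
        cand_read, cand_strand, cand_start = [], [], []
        for strand, m in ((0, mat), (1, rc)):
            for off in offsets:
                q, bad = _pack_seed(m, off, s)
                lo, cnt = index.lookup(q)
                cnt = np.where(bad, 0, cnt)
                hit_reads = np.repeat(np.arange(n, dtype=np.int64), cnt)
                flat = _expand_ranges(lo, cnt)
                starts = index.sorted_pos[flat] - off
                cand_read.append(hit_reads)
                cand_strand.append(np.full(hit_reads.size, strand, dtype=np.uint8))
                cand_start.append(starts)
        r_idx = np.concatenate(cand_read)
        strd = np.concatenate(cand_strand)
        start = np.concatenate(cand_start)

        # drop placements that run outside their reference's extended span
        ok = start >= 0
        ref_i = index.ref_index_of(np.maximum(start, 0))
        span_end = index.ref_offsets[ref_i] + index.ext_lens[ref_i]
        ok &= start + L <= span_end
        ok &= start >= index.ref_offsets[ref_i]
        r_idx, strd, start, ref_i = r_idx[ok], strd[ok], start[ok], ref_i[ok]

        if r_idx.size:
            key = (r_idx * 2 + strd) * np.int64(index.cat.size + 1) + start
            _, uniq = np.unique(key, return_index=True)
            r_idx, strd, start, ref_i = (
                r_idx[uniq],
                strd[uniq],
                start[uniq],
                ref_i[uniq],
            )

        # vectorized gapless verification
        mm = np.empty(r_idx.size, dtype=np.int64)
        for v0 in range(0, r_idx.size, 200_000):
            sl = slice(v0, v0 + 200_000)
            windows = index.cat[start[sl, None] + np.arange(L)]
            reads_fwd = mat[r_idx[sl]]
            reads_rc = rc[r_idx[sl]]
            q = np.where(strd[sl, None] == 1, reads_rc, reads_fwd)
            mm[sl] = np.count_nonzero((windows != q) | (q >= 4), axis=1)
        gapless_ok = mm <= rule.max_mismatch_only

        acc_r = [r_idx[gapless_ok]]
        acc_strd = [strd[gapless_ok]]
        acc_start = [start[gapless_ok]]
        acc_ref = [ref_i[gapless_ok]]
        acc_mm = [mm[gapless_ok]]
        acc_g = [np.zeros(int(gapless_ok.sum()), dtype=np.int64)]

        if rule.max_gap_bases > 0:
            resolved = np.zeros(n, dtype=bool)
            resolved[acc_r[0]] = True
            todo = np.flatnonzero(~gapless_ok & ~resolved[r_idx])
            for t in todo:
                ri = int(r_idx[t])
                read_arr = rc[ri] if strd[t] else mat[ri]
                res = _gapped_rule_check(read_arr, index.cat, int(start[t]), rule)
                if res is not None:
                    acc_r.append(np.array([ri]))
                    acc_strd.append(np.array([strd[t]], dtype=np.uint8))
                    acc_start.append(np.array([start[t]]))
                    acc_ref.append(np.array([ref_i[t]]))
                    acc_mm.append(np.array([res[0]]))
                    acc_g.append(np.array([res[1]]))

        a_r = np.concatenate(acc_r)
        a_strd = np.concatenate(acc_strd).astype(np.uint8)
        a_start = np.concatenate(acc_start)
        a_ref = np.concatenate(acc_ref)
        a_mm = np.concatenate(acc_mm)
        a_g = np.concatenate(acc_g)
        labels[c0 : c0 + n][np.unique(a_r)] = True

        if a_r.size:
            pos_in_ref = (a_start - index.ref_offsets[a_ref]) % index.ref_lens[a_ref]
            if rng is not None:
                tie = rng.random(a_r.size)
                order = np.lexsort((tie, a_mm + a_g, a_r))
            else:
                order = np.lexsort((pos_in_ref, a_strd, a_g, a_mm + a_g, a_r))
            a_r, a_strd, pos_in_ref, a_ref, a_mm, a_g = (
                x[order] for x in (a_r, a_strd, pos_in_ref, a_ref, a_mm, a_g)
            )
            _, first = np.unique(a_r, return_index=True)
            all_hits.append(
                (
                    a_r[first] + c0,
                    a_ref[first],
                    pos_in_ref[first],
                    a_strd[first],
                    a_mm[first],
                    a_g[first],
                )
            )

    if all_hits:
        hits = BatchHits(*[np.concatenate(cols) for cols in zip(*all_hits)])
    else:
        hits = BatchHits()
    return labels, hits


def classify_read(
    read: ReadRecord | str,
    index: ReferenceIndex,
    rule: AcceptanceRule | None = None,
) -> tuple[str, AlignmentHit | None]:
    """Classify one read; returns (ORGANELLE or NUCLEAR, best hit or None)."""
    seq = read.seq if isinstance(read, ReadRecord) else read
    mat = seqcodes.encode(seq)[None, :]
    labels, hits = classify_batch(mat, index, rule)
    if not labels[0]:
        return NUCLEAR, None
    hit = AlignmentHit(
        ref_id=index.ref_ids[int(hits.ref_idx[0])],
        ref_start=int(hits.pos[0]) + 1,
        strand="-" if hits.strand[0] else "+",
        n_mismatch=int(hits.n_mismatch[0]),
        n_gap_bases=int(hits.n_gap_bases[0]),
    )
    return ORGANELLE, hit


@dataclass
class RemovalStats:
    reads_in: int
    reads_removed: int
    bases_in: int
    bases_removed: int

    @property
    def removed_read_fraction(self) -> float:
        return self.reads_removed / self.reads_in if self.reads_in else 0.0

    @property
    def removed_base_fraction(self) -> float:
        return self.bases_removed / self.bases_in if self.bases_in else 0.0

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "reads_in": self.reads_in,
            "reads_removed": self.reads_removed,
            "bases_in": self.bases_in,
            "bases_removed": self.bases_removed,
            "removed_read_fraction": self.removed_read_fraction,
            "removed_base_fraction": self.removed_base_fraction,
        }
        text = json.dumps(d, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def partition_readsets(
    readsets: list[ReadSet],
    index: ReferenceIndex,
    rule: AcceptanceRule | None = None,
) -> tuple[list[np.ndarray], list[BatchHits], RemovalStats]:
    """Classify each read independently (mates are not kept paired).

    Returns per-readset organelle masks and hits, plus removal statistics;
    every read lands in exactly one class.
    """
    masks, hits_list = [], []
    reads_in = bases_in = removed = bases_removed = 0
    for rs in readsets:
        mask, hits = classify_batch(rs, index, rule)
        masks.append(mask)
        hits_list.append(hits)
        reads_in += rs.n_reads
        bases_in += rs.n_bases
        removed += int(mask.sum())
        bases_removed += int(mask.sum()) * rs.read_len
    stats = RemovalStats(reads_in, removed, bases_in, bases_removed)
    return masks, hits_list, stats


def partition_reads(
    fastq_in: list[str | Path],
    index: ReferenceIndex,
    out_nuclear: str | Path,
    out_organelle: str | Path,
    rule: AcceptanceRule | None = None,
) -> RemovalStats:
    """File-level partition: all input FASTQs are classified read-by-read and
    written to a nuclear and an organelle FASTQ."""
    readsets = [ReadSet.from_fastq(p) for p in fastq_in]
    masks, _, stats = partition_readsets(readsets, index, rule)
    first = True
    for rs, mask in zip(readsets, masks):
        nuc, org = rs.subset(~mask), rs.subset(mask)
        mode = "w" if first else "a"
        _append_fastq(nuc, out_nuclear, mode)
        _append_fastq(org, out_organelle, mode)
        first = False
    return stats


def _append_fastq(rs: ReadSet, path: str | Path, mode: str) -> None:
    tmp = Path(str(path) + ".part")
    rs.to_fastq(tmp)
    with open(path, mode) as out, open(tmp) as src:
        for line in src:
            out.write(line)
    tmp.unlink()


@dataclass
class PileupReport:
    ref_id: str
    depth: np.ndarray
    breadth: float
    mean_depth: float
    het_sites: list[tuple[int, tuple[int, int, int, int]]]  # (1-based pos, ACGT counts)
    counts: np.ndarray  # (ref_len, 4)

    def to_tsv(self, path: str | Path) -> None:
        het_pos = {p for p, _ in self.het_sites}
        with open(path, "w") as fh:
            fh.write("pos\tdepth\tA\tC\tG\tT\thet\n")
            for i in range(self.depth.size):
                a, c, g, t = self.counts[i]
                fh.write(
                    f"{i + 1}\t{self.depth[i]}\t{a}\t{c}\t{g}\t{t}\t"
                    f"{1 if i + 1 in het_pos else 0}\n"
                )


def organelle_pileup(
    rs: ReadSet,
    hits: BatchHits,
    index: ReferenceIndex,
    ref_idx: int = 0,
    min_depth: int = 10,
    het_maf: float = 0.2,
) -> PileupReport:
    """Stack gapless organelle placements into per-site allele counts.

    A site is called heterozygous when its depth reaches ``min_depth`` and
    the second most frequent allele reaches frequency ``het_maf``.  Reads
    whose best placement involves gap bases are excluded from the stack
    (their per-column coordinates are ambiguous at survey precision).
    """
    if ref_idx >= len(index.ref_ids):
        raise ValueError("reference index out of range for this index")
    ref_len = int(index.ref_lens[ref_idx])
    L = rs.read_len
    sel = (hits.ref_idx == ref_idx) & (hits.n_gap_bases == 0)
    counts = np.zeros((ref_len, 5), dtype=np.int64)
    if sel.any():
        ridx = hits.read_idx[sel]
        pos = hits.pos[sel]
        strand = hits.strand[sel]
        reads = rs.codes[ridx]
        rc = seqcodes.revcomp_codes(reads)
        aligned = np.where(strand[:, None] == 1, rc, reads)
        cols = (pos[:, None] + np.arange(L)) % ref_len
        np.add.at(counts, (cols.ravel(), aligned.ravel().astype(np.int64)), 1)
    acgt = counts[:, :4]
    depth = acgt.sum(axis=1)
    breadth = float((depth >= 1).mean()) if ref_len else 0.0
    mean_depth = float(depth.mean()) if ref_len else 0.0
    het_sites = []
    covered = np.flatnonzero(depth >= min_depth)
    if covered.size:
        part = np.sort(acgt[covered], axis=1)
        second = part[:, -2]
        het = second >= het_maf * depth[covered]
        for i in covered[het]:
            het_sites.append((int(i) + 1, tuple(int(x) for x in acgt[i])))
    return PileupReport(
        ref_id=index.ref_ids[ref_idx],
        depth=depth,
        breadth=breadth,
        mean_depth=mean_depth,
        het_sites=het_sites,
        counts=acgt,
    )
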