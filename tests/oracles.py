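"""Independent reference implementations used only to check the package.

These are deliberately written in a different style from the production
code (full scans and exhaustive dynamic programs instead of seed-and-extend)
so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np

from plantsurvey import seqcodes
from plantsurvey.organelle_filter import AcceptanceRule

_BIG = 10**9


def gapless_min_mismatches(read: np.ndarray, ref: np.ndarray) -> int:
    """Minimum mismatch count of the read over every gapless end-to-end
    placement on the reference (one strand), by direct full scan."""
    L = read.size
    n_starts = ref.size - L + 1
    if n_starts <= 0:
        return _BIG
    mm = np.zeros(n_starts, dtype=np.int32)
    for j in range(L):
        col = ref[j : j + n_starts]
        mm += (col != read[j]) | (read[j] >= 4)
    return int(mm.min())


def semi_global_rule_satisfiable(
    read: np.ndarray, window: np.ndarray, rule: AcceptanceRule
) -> bool:
    """Exhaustive semi-global DP: is there an end-to-end alignment of the
    read anywhere inside the window whose (mismatches, gap bases) satisfy
    the rule?  Gap bases count insertion and deletion columns; flanking
    reference bases are free (they are outside the alignment)."""
    L, W = read.size, window.size
    maxg = rule.max_gap_bases
    # dp[g][j]: min mismatches aligning a read prefix, ending at window pos j
    dp = np.full((maxg + 1, W + 1), _BIG, dtype=np.int32)
    dp[0, :] = 0  # free alignment start anywhere
    for i in range(L):
        ndp = np.full_like(dp, _BIG)
        ri = int(read[i])
        sub = ((window != ri) | (ri >= 4)).astype(np.int32)
        for g in range(maxg + 1):
            # diagonal: consume read[i] and window[j]
            ndp[g, 1:] = np.minimum(ndp[g, 1:], dp[g, :-1] + sub)
            # insertion: read base aligned to nothing
            if g + 1 <= maxg:
                ndp[g + 1, :] = np.minimum(ndp[g + 1, :], dp[g, :])
        # deletions: skip window bases between read bases (internal only)
        if 0 < i + 1 < L:
            for g in range(maxg):
                for _ in range(maxg - g):
                    ndp[g + 1, 1:] = np.minimum(ndp[g + 1, 1:], ndp[g, :-1])
        dp = ndp
    for g in range(maxg + 1):
        mm = int(dp[g].min())
        if mm < _BIG and rule.satisfies(mm, g):
            return True
    return False


def oracle_is_organelle(
    read_seq: str,
    ref_ext: np.ndarray,
    approx_pos: int,
    rule: AcceptanceRule,
) -> bool:
    """Rule evaluation for one read: exhaustive gapless scan over the whole
    extended reference (both strands) plus an exhaustive gapped DP in a
    window around the position the read was generated from."""
    read = seqcodes.encode(read_seq)
    rc = seqcodes.revcomp_codes(read)
    for r in (read, rc):
        if rule.satisfies(gapless_min_mismatches(r, ref_ext), 0):
            return True
    if rule.max_gap_bases > 0:
        lo = max(0, approx_pos - 15)
        hi = min(ref_ext.size, approx_pos + read.size + 15)
        window = ref_ext[lo:hi]
        for r in (read, rc):
            if semi_global_rule_satisfiable(r, window, rule):
                return True
    return False


def plant_edited_read(
    rng: np.random.Generator,
    ref_ext: np.ndarray,
    length: int,
    n_sub: int = 0,
    n_del: int = 0,
    n_ins: int = 0,
    revcomp: bool = False,
) -> tuple[str, int]:
    """Draw a read of the requested length from the reference and plant the
    requested numbers of deletions, insertions and substitutions.  Returns
    (read sequence, 0-based source position on the extended reference)."""
    src_len = length + n_del - n_ins
    pos = int(rng.integers(0, ref_ext.size - src_len + 1))
    frag = list(seqcodes.decode(ref_ext[pos : pos + src_len]))
    for _ in range(n_del):
        del frag[int(rng.integers(0, len(frag)))]
    for _ in range(n_ins):
        frag.insert(int(rng.integers(0, len(frag) + 1)), "ACGT"[int(rng.integers(0, 4))])
    for _ in range(n_sub):
        i = int(rng.integers(0, len(frag)))
        frag[i] = "ACGT"[("ACGT".index(frag[i]) + int(rng.integers(1, 4))) % 4]
    seq = "".join(frag)
    if revcomp:
        seq = seqcodes.revcomp(seq)
    return seq, pos


def nx_bruteforce(lengths: list[int], frac: float) -> int:
    """Sort-and-accumulate N50/N90 oracle."""
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= frac * total:
            return length
    return min(lengths)


def canonical_kmer_counts_bruteforce(seqs: list[str], k: int) -> dict[str, int]:
    """String-level canonical k-mer counting."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) - set("ACGT"):
                continue
            rc = w.translate(comp)[::-1]
            canon = min(w, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts
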