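"""Canonical k-mer counting and spectrum-based survey estimation.

The survey logic is the classical one: count canonical 17-mers in the clean
(and organelle-filtered) reads, find the error trough and the main coverage
peak of the depth histogram, and derive

* genome size  = (k-mer volume above the error cutoff) / main peak depth,
* repeat fraction = 1 - (unique-species volume) / (total volume), with the
  unique component fitted as A * Poisson(d; c) around the main peak,
* heterozygosity from the excess k-mer species at half the main peak depth
  (two haplotype alleles per heterozygous locus, each sequenced at c/2).

Counting is vectorized: 17-mers are packed into 64-bit integers chunk by
chunk, counted with sorts, and merged into a running (code, count) table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats as sps

from . import seqcodes
from .reads import ReadSet

DEFAULT_K = 17
DEPTH_CAP = 10_000  # histogram tail bin; deeper k-mers accumulate here


@dataclass
class KmerHistogram:
    """Depth histogram of distinct canonical k-mers."""

    k: int
    bins: dict[int, int]

    @property
    def total_volume(self) -> int:
        return sum(d * c for d, c in self.bins.items())

    @property
    def total_species(self) -> int:
        return sum(self.bins.values())

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(depths 1..max_depth, counts) as dense arrays."""
        if not self.bins:
            return np.array([1]), np.array([0])
        max_d = max(self.bins)
        counts = np.zeros(max_d, dtype=np.int64)
        for d, c in self.bins.items():
            counts[d - 1] = c
        return np.arange(1, max_d + 1), counts

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for d in sorted(self.bins):
                fh.write(f"{d}\t{self.bins[d]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = DEFAULT_K) -> "KmerHistogram":
        bins: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d, c = line.split()[:2]
                bins[int(d)] = int(c)
        return cls(k=k, bins=bins)


@dataclass
class SpectrumFit:
    """Fitted survey estimates from one k-mer histogram."""

    k: int
    d_min: int
    c_peak: int
    repeat_peak: int | None
    genome_size: int
    repeat_fraction: float
    het_half_peak_present: bool
    het_rate: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _merge_counts(
    acc: tuple[np.ndarray, np.ndarray], new: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    codes = np.concatenate([acc[0], new[0]])
    counts = np.concatenate([acc[1], new[1]])
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    boundary = np.empty(codes.size, dtype=bool)
    if codes.size:
        boundary[0] = True
        boundary[1:] = codes[1:] != codes[:-1]
        group = np.cumsum(boundary) - 1
        summed = np.zeros(int(group[-1]) + 1, dtype=np.int64)
        np.add.at(summed, group, counts)
        return codes[boundary], summed
    return codes, counts


def _canonical_codes_matrix(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed k-mer codes of every window of every row; windows
    containing non-ACGT codes are dropped."""
    n, L = mat.shape
    w = L - k + 1
    if w <= 0 or n == 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros((n, w), dtype=np.uint64)
    c = mat.astype(np.uint64)
    for j in range(k):
        fwd <<= np.uint64(2)
        fwd |= c[:, j : j + w] & np.uint64(3)
    rcm = seqcodes.revcomp_codes(mat).astype(np.uint64)
    rev = np.zeros((n, w), dtype=np.uint64)
    for j in range(k):
        rev <<= np.uint64(2)
        rev |= rcm[:, j : j + w] & np.uint64(3)
    rev = rev[:, ::-1]  # window i of the rc read is window w-1-i of the read
    canon = np.minimum(fwd, rev)
    if (mat >= 4).any():
        bad = np.zeros((n, w), dtype=bool)
        is_n = (mat >= 4).astype(np.int32)
        cum = np.concatenate([np.zeros((n, 1), np.int32), np.cumsum(is_n, axis=1)], axis=1)
        bad = (cum[:, k:] - cum[:, :w]) > 0
        return canon[~bad]
    return canon.ravel()


def count_kmers(
    reads: ReadSet | np.ndarray | Iterable[str],
    k: int = DEFAULT_K,
    cap: int = DEPTH_CAP,
    chunk_kmers: int = 40_000_000,
) -> KmerHistogram:
    """Count canonical k-mers (lexicographic min of window and its reverse
    complement) and histogram them by depth.

    k must be odd (an even k admits self-complementary k-mers whose
    canonical form is ambiguous between strands) and at most 31.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not 1 < k <= 31:
        raise ValueError("k must be in 3..31")

    if isinstance(reads, ReadSet):
        mat = reads.codes
    elif isinstance(reads, np.ndarray):
        mat = reads
    else:
        mat = None

    acc = (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    if mat is not None:
        n, L = mat.shape
        w = max(L - k + 1, 0)
        rows_per_chunk = max(1, chunk_kmers // max(w, 1))
        for r0 in range(0, n, rows_per_chunk):
            canon = _canonical_codes_matrix(mat[r0 : r0 + rows_per_chunk], k)
            u, c = np.unique(canon, return_counts=True)
            acc = _merge_counts(acc, (u, c.astype(np.int64)))
    else:
        buf: list[str] = []
        buf_len = 0
        for seq in reads:
            buf.append(seq.upper())
            buf_len += len(seq)
            if buf_len >= chunk_kmers:
                acc = _flush_strings(acc, buf, k)
                buf, buf_len = [], 0
        acc = _flush_strings(acc, buf, k)

    counts = acc[1]
    if counts.size == 0:
        return KmerHistogram(k=k, bins={})
    clipped = np.minimum(counts, cap)
    depths, species = np.unique(clipped, return_counts=True)
    return KmerHistogram(
        k=k, bins={int(d): int(s) for d, s in zip(depths, species)}
    )


def _flush_strings(acc, seqs: list[str], k: int):
    parts = []
    for seq in seqs:
        codes = seqcodes.encode(seq)
        if codes.size < k:
            continue
        kc = seqcodes.kmer_codes(codes, k)
        rc = seqcodes.kmer_codes(seqcodes.revcomp_codes(codes), k)[::-1]
        canon = np.minimum(kc, rc)
        good = ~seqcodes.window_has_n(codes, k)
        parts.append(canon[good])
    if not parts:
        return acc
    allc = np.concatenate(parts)
    u, c = np.unique(allc, return_counts=True)
    return _merge_counts(acc, (u, c.astype(np.int64)))


def _smooth(counts: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with shrinking edges."""
    kernel = np.ones(window)
    num = np.convolve(counts.astype(float), kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / den


def detect_peaks(hist: KmerHistogram) -> tuple[int, int, int | None]:
    """Locate the error trough (d_min), the main coverage peak and, when
    present, a repeat peak near twice the main peak depth.

    The error component of a read k-mer spectrum dominates depths 1..few;
    d_min is the first local minimum of the smoothed distinct-count curve.
    Histograms with no interior minimum (no error blob) give d_min = 1 with
    a warning.
    """
    if not hist.bins:
        raise ValueError("empty histogram")
    depths, counts = hist.arrays()
    s = _smooth(counts)
    n = s.size
    d_min = None
    if n >= 2 and s[1] >= s[0]:
        d_min = 1  # rising from depth 1: no error blob
    else:
        for i in range(1, n - 1):
            if s[i] <= s[i - 1] and s[i] <= s[i + 1]:
                d_min = i + 1
                break
        if d_min is None:
            d_min = 1
            warnings.warn(
                "k-mer histogram has no interior minimum; using d_min = 1",
                stacklevel=2,
            )
    main_region = s[d_min - 1 :]
    c_peak = d_min + int(np.argmax(main_region))

    repeat_peak = None
    main_height = s[c_peak - 1]
    lo = c_peak + max(2, c_peak // 4)
    local_max = [
        i + 1
        for i in range(max(1, lo - 1), n - 1)
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and s[i] >= 0.01 * main_height
    ]
    if local_max:
        repeat_peak = min(local_max, key=lambda d: abs(d - 2 * c_peak))
    return d_min, c_peak, repeat_peak


def estimate_genome_size(hist: KmerHistogram, d_min: int, c_peak: int) -> int:
    """Usable k-mer volume divided by the main peak depth, in bases."""
    if not 1 <= d_min <= c_peak:
        raise ValueError("need 1 <= d_min <= c_peak")
    volume = sum(d * c for d, c in hist.bins.items() if d >= d_min)
    if volume == 0:
        raise ValueError("no k-mer volume above the error cutoff")
    return int(round(volume / c_peak))


def _fit_unique_species(
    hist: KmerHistogram, c_peak: int, lo_frac: float = 0.5, hi_frac: float = 1.5
) -> float:
    """Least-squares amplitude of A * Poisson(d; c_peak) against the
    histogram over d in [lo_frac*c, hi_frac*c]."""
    lo = int(np.ceil(lo_frac * c_peak))
    hi = int(np.floor(hi_frac * c_peak))
    ds = np.array([d for d in range(lo, hi + 1) if d >= 1])
    if ds.size == 0:
        raise ValueError("empty fit window")
    b = np.array([hist.bins.get(int(d), 0) for d in ds], dtype=float)
    p = sps.poisson.pmf(ds, c_peak)
    denom = float((p * p).sum())
    if denom == 0:
        raise ValueError("degenerate fit window")
    return float((b * p).sum() / denom)


def estimate_repeat_fraction(hist: KmerHistogram, d_min: int, c_peak: int) -> float:
    """1 minus the fitted unique-species volume over the total usable volume."""
    if not 1 <= d_min <= c_peak:
        raise ValueError("need 1 <= d_min <= c_peak")
    a = _fit_unique_species(hist, c_peak)
    volume = sum(d * c for d, c in hist.bins.items() if d >= d_min)
    if volume == 0:
        raise ValueError("no k-mer volume above the error cutoff")
    return max(0.0, 1.0 - a * c_peak / volume)


def assess_heterozygosity(
    hist: KmerHistogram, d_min: int, c_peak: int
) -> tuple[bool, float]:
    """Detect a half-depth heterozygosity peak and convert it to a per-base rate.

    The unique homozygous component is fitted tightly around the main peak
    (A * Poisson(d; c)); the species excess over that model in a window
    centred on c/2 is attributed to heterozygous alleles.  Two alleles of
    one het locus each contribute k k-mer species at c/2, so the het locus
    fraction is f = (E/2) / (E/2 + A) and the per-base rate solves
    f = 1 - (1 - r)^k.  Reported as (False, 0.0) when the excess volume is
    below 5% of the fitted main-peak volume or the window is empty.
    """
    half = c_peak / 2.0
    lo = max(d_min, int(round(0.35 * c_peak)))
    hi = int(round(0.65 * c_peak))
    if hi < lo:
        return False, 0.0
    try:
        a = _fit_unique_species(hist, c_peak, lo_frac=0.75, hi_frac=1.25)
    except ValueError:
        return False, 0.0
    ds = np.arange(lo, hi + 1)
    model = a * sps.poisson.pmf(ds, c_peak)
    observed = np.array([hist.bins.get(int(d), 0) for d in ds], dtype=float)
    excess = np.maximum(observed - model, 0.0)
    excess_volume = float((ds * excess).sum())
    main_volume = a * c_peak
    if main_volume <= 0 or excess_volume < 0.05 * main_volume:
        return False, 0.0
    e_species = float(excess.sum())
    f = (e_species / 2.0) / (e_species / 2.0 + a)
    het_rate = 1.0 - (1.0 - f) ** (1.0 / hist.k)
    return True, het_rate


def fit_spectrum(hist: KmerHistogram) -> SpectrumFit:
    """Run the full spectrum analysis on one histogram."""
    d_min, c_peak, repeat_peak = detect_peaks(hist)
    size = estimate_genome_size(hist, d_min, c_peak)
    repeat = estimate_repeat_fraction(hist, d_min, c_peak)
    present, het = assess_heterozygosity(hist, d_min, c_peak)
    return SpectrumFit(
        k=hist.k,
        d_min=d_min,
        c_peak=c_peak,
        repeat_peak=repeat_peak,
        genome_size=size,
        repeat_fraction=repeat,
        het_half_peak_present=present,
        het_rate=het,
    )


def plot_spectrum(
    hist: KmerHistogram, fit: SpectrumFit | None, path: str | Path
) -> None:
    """Depth vs distinct-k-mer-count plot with the fitted peaks annotated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depths, counts = hist.arrays()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(depths, counts, lw=1, color="#2a6f97")
    if fit is not None:
        ax.axvline(fit.c_peak, color="#c1121f", ls="--", lw=1, label=f"main peak {fit.c_peak}x")
        ax.axvline(fit.d_min, color="#999999", ls=":", lw=1, label=f"error cutoff {fit.d_min}")
        if fit.repeat_peak:
            ax.axvline(fit.repeat_peak, color="#e36414", ls="--", lw=1,
                       label=f"repeat peak {fit.repeat_peak}x")
    ax.set_xlabel(f"{hist.k}-mer depth")
    ax.set_ylabel("distinct k-mers")
    ax.set_xlim(0, min(depths.max(), (fit.c_peak * 4) if fit else depths.max()))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
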