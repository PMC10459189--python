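"""Per-contig GC content vs coverage depth screening.

After a preliminary assembly, each contig of at least 5 kb is summarized by
its GC fraction and its mean read depth; the 2-D density of (GC, depth)
should form a single enrichment center for a clean single-organism sample.
Additional centers at high GC (> 60% by default) indicate contamination;
depth-separated centers at similar GC suggest heterozygosity or copy-number
structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .organelle_filter import AcceptanceRule, ReferenceIndex, classify_batch
from .reads import ReadSet

RELAXED_RULE = AcceptanceRule(
    max_mismatch_only=5, max_gap_only=2, mixed_max_gap=2, mixed_max_mismatch=3
)


@dataclass
class ContigStat:
    contig_id: str
    length: int
    gc: float
    mean_depth: float


@dataclass
class CenterReport:
    centers: list[tuple[float, float, float]]  # (gc bin center, depth bin center, density)
    contamination_flag: bool
    flags_reason: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "centers": [list(c) for c in self.centers],
            "contamination_flag": self.contamination_flag,
            "flags_reason": self.flags_reason,
        }
        text = json.dumps(d, indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def contig_gc(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N and ambiguity codes are excluded entirely."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def map_depths(
    readsets: list[ReadSet],
    contigs: list[tuple[str, str]],
    rule: AcceptanceRule = RELAXED_RULE,
    seed: int = 0,
) -> dict[str, float]:
    """Mean aligned-base depth per contig.

    Reads are placed end-to-end with the seed-and-extend engine under a
    relaxed rule (up to 5 edits); each read contributes its best placement
    only, with ties between equally good placements broken at random under
    a fixed seed so repeat copies share depth evenly.
    """
    if not contigs:
        return {}
    read_len = readsets[0].read_len if readsets else 150
    index = ReferenceIndex(contigs, seed_len=32, read_len=read_len, circular=False)
    rng = np.random.default_rng(seed)
    aligned_bases = np.zeros(len(contigs), dtype=np.int64)
    for rs in readsets:
        _, hits = classify_batch(rs, index, rule, rng=rng)
        np.add.at(aligned_bases, hits.ref_idx, rs.read_len)
    return {
        contigs[i][0]: aligned_bases[i] / len(contigs[i][1])
        for i in range(len(contigs))
    }


def gc_depth_table(
    contigs: list[tuple[str, str]],
    depths: dict[str, float],
    min_len: int = 5000,
) -> list[ContigStat]:
    """GC/depth summary restricted to contigs of at least ``min_len`` bases."""
    table = []
    for cid, seq in contigs:
        if len(seq) < min_len:
            continue
        table.append(
            ContigStat(
                contig_id=cid,
                length=len(seq),
                gc=contig_gc(seq),
                mean_depth=float(depths.get(cid, 0.0)),
            )
        )
    return table


def table_to_frame(table: list[ContigStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [t.contig_id for t in table],
            "length": [t.length for t in table],
            "gc": [t.gc for t in table],
            "mean_depth": [t.mean_depth for t in table],
        }
    )


def detect_centers(
    table: list[ContigStat],
    gc_bin_width: float = 0.01,
    depth_bin_width: float = 5.0,
    min_cluster_fraction: float = 0.02,
    gc_flag_threshold: float = 0.60,
) -> CenterReport:
    """Find enrichment centers of the (GC, depth) density.

    Contigs are binned on a (gc_bin_width x depth_bin_width) grid; occupied
    bins are grouped into 8-connected components, and each component holding
    at least ``min_cluster_fraction`` of the contigs yields one center (its
    densest bin, after 3x3 smoothing).  The contamination flag is raised
    when any center sits above ``gc_flag_threshold`` GC.
    """
    if not table:
        raise ValueError("empty contig table")
    gc = np.array([t.gc for t in table])
    depth = np.array([t.mean_depth for t in table])
    n = len(table)

    gc_edges = np.arange(0.0, 1.0 + gc_bin_width, gc_bin_width)
    dmax = max(depth.max(), depth_bin_width)
    depth_edges = np.arange(0.0, dmax + 2 * depth_bin_width, depth_bin_width)
    h, _, _ = np.histogram2d(gc, depth, bins=[gc_edges, depth_edges])

    smooth = ndimage.uniform_filter(h, size=3, mode="constant")
    labels, n_comp = ndimage.label(h > 0, structure=np.ones((3, 3), dtype=int))
    centers = []
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        count = h[mask].sum()
        if count < min_cluster_fraction * n:
            continue
        masked = np.where(mask, smooth, -1.0)
        gi, di = np.unravel_index(int(np.argmax(masked)), masked.shape)
        centers.append(
            (
                float((gc_edges[gi] + gc_edges[gi + 1]) / 2),
                float((depth_edges[di] + depth_edges[di + 1]) / 2),
                float(count / n),
            )
        )
    centers.sort(key=lambda c: -c[2])

    flag = any(c[0] > gc_flag_threshold for c in centers)
    reasons = []
    if flag:
        flagged = [c for c in centers if c[0] > gc_flag_threshold]
        reasons.append(
            "enrichment center(s) above "
            f"{100 * gc_flag_threshold:.0f}% GC at "
            + ", ".join(f"(GC {100 * c[0]:.0f}%, depth {c[1]:.0f}x)" for c in flagged)
            + ": possible contamination"
        )
    similar_gc_pairs = [
        (a, b)
        for i, a in enumerate(centers)
        for b in centers[i + 1 :]
        if abs(a[0] - b[0]) <= 0.05 and abs(a[1] - b[1]) > depth_bin_width
    ]
    if similar_gc_pairs:
        reasons.append(
            "multiple depth-separated centers at similar GC: possible "
            "heterozygosity or copy-number signal"
        )
    if not reasons:
        reasons.append("single enrichment center; no contamination signal")
    return CenterReport(
        centers=centers, contamination_flag=flag, flags_reason="; ".join(reasons)
    )


def plot_gc_depth(table: list[ContigStat], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table_to_frame(table)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(100 * df["gc"], df["mean_depth"], s=4, alpha=0.4, color="#2a6f97")
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("mean depth (x)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
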