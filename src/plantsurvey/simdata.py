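"""Synthetic genome-survey data with known ground truth.

Generates, deterministically from a seed:

* a nuclear genome with a controlled fraction of exact-copy repeats and a
  target GC content,
* circular organelle genomes (plastid / mitochondrion stand-ins),
* nuclear insertions of diverged organelle fragments (NUMT/NUPT mimics),
* paired-end reads with substitution errors, a controlled nuclear depth and
  a controlled fraction of organelle-derived read pairs.

The defaults emulate a desk-scale version of a typical plant survey design:
150 bp paired-end reads from ~300 bp inserts, ~35% GC, a strongly repetitive
nuclear genome and a ~10% organellar read fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import seqcodes
from .reads import ReadSet

NUCLEAR = "NUCLEAR"
ORGANELLE = "ORGANELLE"


@dataclass
class SimConfig:
    """Parameters of one simulated survey experiment."""

    nuclear_size: int = 5_000_000
    repeat_fraction: float = 0.30
    repeat_unit_len: int = 500
    gc_target: float = 0.35
    organelle_sizes: tuple[int, ...] = (150_000,)
    norg_count: int = 0
    norg_len: int = 2_000
    norg_divergence: float = 0.10
    read_len: int = 150
    depth_nuclear: float = 100.0
    organelle_read_fraction: float = 0.10
    error_rate: float = 0.001
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.nuclear_size <= 0 or self.repeat_unit_len <= 0 or self.read_len <= 0:
            raise ValueError("all sizes must be positive")
        for frac_name in ("repeat_fraction", "gc_target", "organelle_read_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if any(s <= 0 for s in self.organelle_sizes):
            raise ValueError("organelle sizes must be positive")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if self.organelle_read_fraction >= 1.0:
            raise ValueError("organelle_read_fraction must be < 1")


@dataclass
class Insertion:
    """One organelle fragment inserted into the nuclear sequence."""

    start: int  # 0-based, in the final nuclear sequence
    end: int  # exclusive
    source: str
    divergence: float


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated genome and/or read set."""

    nuclear_size: int | None = None
    realized_repeat_fraction: float | None = None
    insertions: list[Insertion] = field(default_factory=list)
    # per read-pair arrays (parallel):
    origin: np.ndarray | None = None  # 0 = NUCLEAR, 1 = ORGANELLE
    source_id: list[str] | None = None
    frag_start: np.ndarray | None = None
    strand: np.ndarray | None = None  # strand of mate 1: 0 = '+', 1 = '-'

    def origin_labels(self) -> np.ndarray:
        return np.where(self.origin == 1, ORGANELLE, NUCLEAR)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\torigin\tsource_id\tstart\tstrand\n")
            if self.origin is None:
                return
            labels = self.origin_labels()
            for i in range(self.origin.size):
                fh.write(
                    f"read{i}\t{labels[i]}\t{self.source_id[i]}\t"
                    f"{int(self.frag_start[i])}\t{'-' if self.strand[i] else '+'}\n"
                )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """i.i.d. base codes with P(G) = P(C) = gc/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    u = rng.random(n)
    return np.searchsorted(np.cumsum(p), u).astype(np.uint8)


def mutate_codes(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Substitute bases independently at the given per-base rate.

    Returns the mutated copy and the number of substitutions applied.
    Substituted bases are always changed to a different base.
    """
    out = codes.copy()
    if rate <= 0:
        return out, 0
    mask = rng.random(codes.shape) < rate
    mask &= codes < 4
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n, dtype=np.uint8)
        out[mask] = (out[mask] + shift) % 4
    return out, n


def make_nuclear_genome(cfg: SimConfig) -> tuple[str, TruthRecord]:
    """Background i.i.d. sequence with exact-copy repeat units planted in it.

    Repeat content is realized by sampling a small library of repeat units
    (each reused ~10 times) and copying them onto non-overlapping random
    positions until the target repeat fraction is reached.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    size = cfg.nuclear_size
    genome = _random_bases(rng, size, cfg.gc_target)

    target_bases = round(cfg.repeat_fraction * size)
    if cfg.repeat_fraction > 0 and target_bases < cfg.repeat_unit_len:
        raise ValueError("repeat unit does not fit")
    n_copies = target_bases // cfg.repeat_unit_len
    placed = 0
    if n_copies > 0:
        n_units = max(1, n_copies // 10)
        units = [
            _random_bases(rng, cfg.repeat_unit_len, cfg.gc_target)
            for _ in range(n_units)
        ]
        occupied = np.zeros(size, dtype=bool)
        attempts = 0
        max_attempts = 50 * n_copies
        while placed < n_copies and attempts < max_attempts:
            attempts += 1
            start = int(rng.integers(0, size - cfg.repeat_unit_len + 1))
            sl = slice(start, start + cfg.repeat_unit_len)
            if occupied[sl].any():
                continue
            genome[sl] = units[int(rng.integers(0, n_units))]
            occupied[sl] = True
            placed += 1
    truth = TruthRecord(
        nuclear_size=size,
        realized_repeat_fraction=placed * cfg.repeat_unit_len / size,
    )
    return seqcodes.decode(genome), truth


def make_organelle_genome(size: int, gc_target: float = 0.35, seed: int = 0) -> str:
    """Circular organelle genome stand-in of the exact requested length."""
    if size <= 0:
        raise ValueError("organelle genome size must be positive")
    rng = np.random.default_rng(seed)
    return seqcodes.decode(_random_bases(rng, size, gc_target))


def make_diploid(template: str, het_rate: float, seed: int = 0) -> tuple[str, str, int]:
    """Two haplotypes from one template: hap1 = template, hap2 diverged at
    the given per-base substitution rate.  Returns (hap1, hap2, n_het_sites)."""
    rng = np.random.default_rng(seed)
    codes = seqcodes.encode(template)
    hap2, n = mutate_codes(codes, het_rate, rng)
    return template, seqcodes.decode(hap2), n


def insert_organelle_fragments(
    nuclear: str,
    organelle: str,
    n: int,
    frag_len: int,
    divergence: float,
    seed: int = 0,
    source: str = "organelle",
) -> tuple[str, TruthRecord]:
    """Plant n diverged organelle fragments into the nuclear sequence
    (NUMT/NUPT mimics).  Output length grows by exactly n * frag_len."""
    if n < 0:
        raise ValueError("number of insertions must be non-negative")
    if frag_len > len(organelle):
        raise ValueError("fragment longer than organelle genome")
    rng = np.random.default_rng(seed)
    org = seqcodes.encode(organelle)
    org_ext = np.concatenate([org, org[: frag_len - 1]])  # circular source
    nuc = seqcodes.encode(nuclear)
    insert_at = np.sort(rng.integers(0, len(nuclear) + 1, size=n))
    pieces = []
    insertions = []
    prev = 0
    offset = 0
    for i in range(n):
        src_start = int(rng.integers(0, len(organelle)))
        frag = org_ext[src_start : src_start + frag_len]
        frag, _ = mutate_codes(frag, divergence, rng)
        pieces.append(nuc[prev : insert_at[i]])
        pieces.append(frag)
        start = int(insert_at[i]) + offset
        insertions.append(
            Insertion(start=start, end=start + frag_len, source=source, divergence=divergence)
        )
        offset += frag_len
        prev = int(insert_at[i])
    pieces.append(nuc[prev:])
    out = np.concatenate(pieces) if pieces else nuc
    truth = TruthRecord(nuclear_size=out.size, insertions=insertions)
    return seqcodes.decode(out), truth


@dataclass
class ReadSource:
    """One template sequence reads can be drawn from."""

    name: str
    seq: str
    circular: bool
    weight: float
    origin: str = NUCLEAR  # NUCLEAR or ORGANELLE


def constant_quality(error_rate: float) -> int:
    """Phred score consistent with the simulated substitution rate."""
    return round(-10.0 * math.log10(max(error_rate, 1e-4)))


def simulate_reads(
    sources: Sequence[ReadSource], cfg: SimConfig
) -> tuple[ReadSet, ReadSet, TruthRecord]:
    """Draw paired-end reads from weighted sources.

    The number of pairs is round(total_bases / (2 * read_len)) with
    total_bases = nuclear_size * depth_nuclear / (1 - organelle_read_fraction),
    so that nuclear templates see the requested fold-coverage when the
    organelle weight equals ``organelle_read_fraction``.

    Each pair is drawn from an insert of length ~ Normal(insert_mean,
    insert_sd) truncated at read_len; mate 1 reads one end forward, mate 2
    the other end reverse-complemented, with the orientation of the pair
    flipped uniformly at random.  Substitution errors are applied per base;
    qualities are constant at the Phred score matching the error rate.
    """
    cfg.validate()
    if not sources:
        raise ValueError("no read sources given")
    weights = np.array([s.weight for s in sources], dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("source weights must sum to 1")

    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_len
    total_bases = cfg.nuclear_size * cfg.depth_nuclear / (1.0 - cfg.organelle_read_fraction)
    n_pairs = int(round(total_bases / (2 * rl)))
    counts = rng.multinomial(n_pairs, weights)

    r1_parts, r2_parts = [], []
    origin_parts, start_parts, strand_parts = [], [], []

    for src, n in zip(sources, counts):
        if n == 0:
            continue
        codes = seqcodes.encode(src.seq)
        L = codes.size
        if L < rl:
            raise ValueError(f"source {src.name!r} shorter than read length")
        ins = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)).astype(np.int64)
        ins = np.clip(ins, rl, None)
        if src.circular:
            ins = np.minimum(ins, L)  # cannot exceed the genome itself
            starts = rng.integers(0, L, size=n)
            ext = np.concatenate([codes, codes[: int(ins.max())]])
        else:
            ins = np.minimum(ins, L)
            starts = np.floor(rng.random(n) * (L - ins + 1)).astype(np.int64)
            ext = codes
        idx = np.arange(rl)
        fwd = ext[starts[:, None] + idx]
        rev = seqcodes.revcomp_codes(ext[(starts + ins - rl)[:, None] + idx])
        flip = rng.random(n) < 0.5
        m1 = np.where(flip[:, None], rev, fwd)
        m2 = np.where(flip[:, None], fwd, rev)
        m1, _ = mutate_codes(m1, cfg.error_rate, rng)
        m2, _ = mutate_codes(m2, cfg.error_rate, rng)
        r1_parts.append(m1)
        r2_parts.append(m2)
        origin_parts.append(
            np.full(n, 1 if src.origin == ORGANELLE else 0, dtype=np.uint8)
        )
        start_parts.append(starts % L if src.circular else starts)
        strand_parts.append(flip.astype(np.uint8))

    r1 = np.concatenate(r1_parts) if r1_parts else np.empty((0, rl), np.uint8)
    r2 = np.concatenate(r2_parts) if r2_parts else np.empty((0, rl), np.uint8)
    origin = np.concatenate(origin_parts) if origin_parts else np.empty(0, np.uint8)
    frag_start = np.concatenate(start_parts) if start_parts else np.empty(0, np.int64)
    strand = np.concatenate(strand_parts) if strand_parts else np.empty(0, np.uint8)
    names: list[str] = []
    for src, n in zip(sources, counts):
        names.extend([src.name] * int(n))

    # shuffle pairs so sources are interleaved as in a real run
    perm = rng.permutation(r1.shape[0])
    r1, r2 = r1[perm], r2[perm]
    origin, frag_start, strand = origin[perm], frag_start[perm], strand[perm]
    names = [names[int(i)] for i in perm]

    q = constant_quality(cfg.error_rate)
    truth = TruthRecord(
        origin=origin, source_id=names, frag_start=frag_start, strand=strand
    )
    return ReadSet(r1, q), ReadSet(r2, q), truth


def simulate_survey(
    cfg: SimConfig,
    diploid_het: float = 0.0,
) -> dict:
    """Build a complete synthetic survey: genomes, NUMT/NUPT insertions and
    paired reads.  Returns a dict with the sequences, read sets and truth.

    With ``diploid_het > 0`` the nuclear template is split into two
    haplotypes diverged at that per-base rate and reads are drawn from both
    in equal proportion (total nuclear depth unchanged).
    """
    cfg.validate()
    nuclear, genome_truth = make_nuclear_genome(cfg)
    organelles = [
        make_organelle_genome(s, cfg.gc_target, seed=cfg.seed + 101 + i)
        for i, s in enumerate(cfg.organelle_sizes)
    ]
    if cfg.norg_count > 0 and organelles:
        nuclear, ins_truth = insert_organelle_fragments(
            nuclear,
            organelles[0],
            cfg.norg_count,
            cfg.norg_len,
            cfg.norg_divergence,
            seed=cfg.seed + 202,
            source="organelle0",
        )
        genome_truth.insertions = ins_truth.insertions
        genome_truth.nuclear_size = len(nuclear)

    org_w = cfg.organelle_read_fraction
    sources: list[ReadSource] = []
    if diploid_het > 0:
        hap1, hap2, _ = make_diploid(nuclear, diploid_het, seed=cfg.seed + 303)
        nuc_w = (1.0 - org_w) / 2
        sources.append(ReadSource("hap1", hap1, False, nuc_w, NUCLEAR))
        sources.append(ReadSource("hap2", hap2, False, nuc_w, NUCLEAR))
    else:
        sources.append(ReadSource("nuclear", nuclear, False, 1.0 - org_w, NUCLEAR))
    for i, org in enumerate(organelles):
        sources.append(
            ReadSource(f"organelle{i}", org, True, org_w / len(organelles), ORGANELLE)
        )
    if not organelles and org_w > 0:
        raise ValueError("organelle_read_fraction > 0 but no organelle genomes")

    r1, r2, read_truth = simulate_reads(sources, cfg)
    read_truth.nuclear_size = genome_truth.nuclear_size
    read_truth.realized_repeat_fraction = genome_truth.realized_repeat_fraction
    read_truth.insertions = genome_truth.insertions
    return {
        "nuclear": nuclear,
        "organelles": organelles,
        "reads1": r1,
        "reads2": r2,
        "truth": read_truth,
        "config": cfg,
    }


def write_manifest(cfg: SimConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["organelle_sizes"] = list(d["organelle_sizes"])
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
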