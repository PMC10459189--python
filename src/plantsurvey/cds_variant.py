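"""CDS variant detection and coding-effect classification.

Workflow: locate the allele of a query gene in a target genome by seed
matching (31-mers, diagonal chaining), align the reference CDS to the
candidate allele CDS with a global affine-gap aligner, call variants from
the alignment columns, and classify each variant's coding effect under the
standard genetic code.

Coordinates are 1-based over the intron-free CDS with the first base of the
start codon at position 1; genomic intervals are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from . import seqcodes
from .reads import read_fasta

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
FRAMESHIFT = "frameshift"
IN_FRAME_INDEL = "in_frame_indel"
PREMATURE_STOP = "premature_stop"

_NEG_INF = -(1 << 28)


@dataclass
class LocusHit:
    chrom_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    identity: float


@dataclass
class VariantRecord:
    """One CDS difference relative to the reference CDS.

    ``cds_pos`` is the substituted base for SNVs, the first deleted
    reference base for deletions, and the reference base immediately before
    the inserted sequence for insertions (0 when inserting before base 1).
    """

    cds_pos: int
    ref_allele: str
    alt_allele: str
    type: str
    length: int
    effect: str | None = None
    aa_change: tuple[int, str, str] | None = None
    premature_stop_codon: int | None = None

    @property
    def cds_end(self) -> int:
        if self.type == DELETION:
            return self.cds_pos + self.length - 1
        return self.cds_pos


@dataclass
class Alignment:
    ref_aligned: str
    alt_aligned: str
    score: int

    def column_counts(self) -> tuple[int, int]:
        """(mismatch columns, gap columns)."""
        mm = gaps = 0
        for a, b in zip(self.ref_aligned, self.alt_aligned):
            if a == "-" or b == "-":
                gaps += 1
            elif a != b:
                mm += 1
        return mm, gaps


def align_cds(
    ref_cds: str,
    alt_cds: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> Alignment:
    """Global alignment with affine gaps (Gotoh), deterministic trace-back
    preferring diagonal, then up (gap in the alt), then left (gap in the ref).

    The first base of a gap costs ``gap_open``; each further base
    ``gap_extend``.
    """
    if not ref_cds or not alt_cds:
        raise ValueError("both sequences must be non-empty")
    x = ref_cds.upper()
    y = alt_cds.upper()
    n, m = len(x), len(y)
    xa = np.frombuffer(x.encode(), dtype=np.uint8)
    ya = np.frombuffer(y.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)
    X = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)  # gap in alt (up)
    Y = np.full((n + 1, m + 1), _NEG_INF, dtype=np.int32)  # gap in ref (left)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend

    js = np.arange(m, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(ya == xa[i - 1], match, mismatch).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i, 1:] = np.maximum(
            X[i - 1, 1:] + gap_extend,
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + gap_open,
        )
        X[i, 0] = gap_open + (i - 1) * gap_extend
        # Y has an in-row dependency; solve with a max-prefix scan:
        # Y[i,j] = max_{j'<j} (A[j'] - j'*ge) + go + (j-1)*ge,  A = max(M, X)
        a = np.maximum(M[i, :-1], X[i, :-1]).astype(np.int64) - js * gap_extend
        run = np.maximum.accumulate(a)
        Y[i, 1:] = (run + gap_open + js * gap_extend).astype(np.int32)

    # trace-back
    ref_out: list[str] = []
    alt_out: list[str] = []
    i, j = n, m
    score = int(max(M[n, m], X[n, m], Y[n, m]))
    if M[n, m] >= X[n, m] and M[n, m] >= Y[n, m]:
        state = "M"
    elif X[n, m] >= Y[n, m]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            ref_out.append(x[i - 1])
            alt_out.append(y[j - 1])
            target = M[i, j] - (match if x[i - 1] == y[j - 1] else mismatch)
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            ref_out.append(x[i - 1])
            alt_out.append("-")
            if i == 1 and j == 0:
                i = 0
                continue
            if X[i - 1, j] + gap_extend == X[i, j] and i > 1:
                i -= 1
                state = "X"
            else:
                target = X[i, j] - gap_open
                i -= 1
                state = "M" if M[i, j] == target else "Y"
        else:
            ref_out.append("-")
            alt_out.append(y[j - 1])
            if j == 1 and i == 0:
                j = 0
                continue
            if Y[i, j - 1] + gap_extend == Y[i, j] and j > 1:
                j -= 1
                state = "Y"
            else:
                target = Y[i, j] - gap_open
                j -= 1
                state = "M" if M[i, j] == target else "X"
    return Alignment("".join(reversed(ref_out)), "".join(reversed(alt_out)), score)


def call_cds_variants(alignment: Alignment) -> list[VariantRecord]:
    """Variants from alignment columns, in reference CDS coordinates.

    Each mismatch column yields one SNV; each maximal gap run yields one
    insertion or deletion record.  Applying the records to the reference
    reconstructs the alternate sequence exactly.
    """
    ra, aa = alignment.ref_aligned, alignment.alt_aligned
    variants: list[VariantRecord] = []
    ref_pos = 0  # last consumed reference base (1-based after increment)
    i = 0
    ncols = len(ra)
    while i < ncols:
        if ra[i] != "-" and aa[i] != "-":
            ref_pos += 1
            if ra[i] != aa[i]:
                variants.append(
                    VariantRecord(
                        cds_pos=ref_pos,
                        ref_allele=ra[i],
                        alt_allele=aa[i],
                        type=SNV,
                        length=1,
                    )
                )
            i += 1
        elif aa[i] == "-":  # deletion: ref bases absent from alt
            start = ref_pos + 1
            run = []
            while i < ncols and aa[i] == "-" and ra[i] != "-":
                run.append(ra[i])
                ref_pos += 1
                i += 1
            variants.append(
                VariantRecord(
                    cds_pos=start,
                    ref_allele="".join(run),
                    alt_allele="",
                    type=DELETION,
                    length=len(run),
                )
            )
        else:  # insertion: alt bases anchored after the previous ref base
            run = []
            while i < ncols and ra[i] == "-" and aa[i] != "-":
                run.append(aa[i])
                i += 1
            variants.append(
                VariantRecord(
                    cds_pos=ref_pos,
                    ref_allele="",
                    alt_allele="".join(run),
                    type=INSERTION,
                    length=len(run),
                )
            )
    return variants


def apply_variants(ref_cds: str, variants: list[VariantRecord]) -> str:
    """Reconstruct the alternate sequence from the reference and variants."""
    events = sorted(variants, key=lambda v: (v.cds_pos, 0 if v.type != INSERTION else 1))
    out: list[str] = []
    pos = 0  # number of ref bases consumed
    for v in events:
        if v.type == SNV:
            out.append(ref_cds[pos : v.cds_pos - 1])
            out.append(v.alt_allele)
            pos = v.cds_pos
        elif v.type == DELETION:
            out.append(ref_cds[pos : v.cds_pos - 1])
            pos = v.cds_pos - 1 + v.length
        else:
            out.append(ref_cds[pos : v.cds_pos])
            out.append(v.alt_allele)
            pos = v.cds_pos
    out.append(ref_cds[pos:])
    return "".join(out)


def _translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop."""
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table.get(codon, "X")


def _aa3(aa1: str) -> str:
    return "Ter" if aa1 == "*" else seq3(aa1)


def classify_effect(variant: VariantRecord, ref_cds: str) -> VariantRecord:
    """Fill in the coding effect of a variant (returns the same record).

    SNVs compare the reference and alternate codon; indels are frameshifts
    unless their length is a multiple of three.  For frameshifts the shifted
    frame is scanned for the first stop codon, reported as a codon number in
    the alternate sequence.
    """
    if len(ref_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    ref_cds = ref_cds.upper()
    if variant.type == SNV:
        codon_number = (variant.cds_pos + 2) // 3
        cstart = 3 * (codon_number - 1)
        ref_codon = ref_cds[cstart : cstart + 3]
        offset = variant.cds_pos - 1 - cstart
        alt_codon = (
            ref_codon[:offset] + variant.alt_allele + ref_codon[offset + 1 :]
        )
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        variant.aa_change = (codon_number, _aa3(ref_aa), _aa3(alt_aa))
        if ref_aa == alt_aa:
            variant.effect = SYNONYMOUS
        elif alt_aa == "*":
            variant.effect = PREMATURE_STOP
        else:
            variant.effect = MISSENSE
        return variant

    if variant.length % 3 == 0:
        variant.effect = IN_FRAME_INDEL
        return variant
    variant.effect = FRAMESHIFT
    alt = apply_variants(ref_cds, [variant])
    first_codon = (variant.cds_pos + 2) // 3 if variant.type == DELETION else (
        variant.cds_pos // 3 + 1
    )
    for cn in range(first_codon, len(alt) // 3 + 1):
        codon = alt[3 * (cn - 1) : 3 * cn]
        if _translate_codon(codon) == "*":
            variant.premature_stop_codon = cn
            break
    return variant


def call_and_classify(ref_cds: str, alt_cds: str) -> list[VariantRecord]:
    """Align, call and classify in one step."""
    aln = align_cds(ref_cds, alt_cds)
    variants = call_cds_variants(aln)
    return [classify_effect(v, ref_cds) for v in variants]


def locate_allele(
    gene_seq: str,
    genome: list[tuple[str, str]] | str | Path,
    seed_len: int = 31,
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
) -> LocusHit | None:
    """Best-identity locus of a query gene in a genome.

    Non-overlapping 31-mer seeds of the query (both strands) are matched
    against every window of each chromosome; seed hits vote for a diagonal,
    and the winning diagonal is scored by direct base identity over the full
    query span.  Returns None when no locus reaches the identity and
    coverage thresholds.
    """
    if len(gene_seq) < 100:
        raise ValueError("query gene must be at least 100 bp")
    if isinstance(genome, (str, Path)):
        genome = read_fasta(genome)
    qlen = len(gene_seq)
    queries = {
        "+": seqcodes.encode(gene_seq),
        "-": seqcodes.encode(seqcodes.revcomp(gene_seq)),
    }
    offsets = list(range(0, qlen - seed_len + 1, seed_len))
    seed_tab = {}
    for strand, q in queries.items():
        codes = np.array(
            [seqcodes.kmer_codes(q[o : o + seed_len], seed_len)[0] for o in offsets],
            dtype=np.uint64,
        )
        order = np.argsort(codes)
        seed_tab[strand] = (codes[order], np.array(offsets, dtype=np.int64)[order])

    best: LocusHit | None = None
    for chrom_id, chrom_seq in genome:
        chrom = seqcodes.encode(chrom_seq)
        if chrom.size < seed_len:
            continue
        wins = seqcodes.kmer_codes(chrom, seed_len)
        for strand, (codes, offs) in seed_tab.items():
            idx = np.searchsorted(codes, wins)
            idx = np.minimum(idx, codes.size - 1)
            hit = codes[idx] == wins
            if not hit.any():
                continue
            positions = np.flatnonzero(hit)
            diags = positions - offs[idx[positions]]
            vals, counts = np.unique(diags, return_counts=True)
            diag = int(vals[np.argmax(counts)])
            start = max(0, diag)
            end = min(chrom.size, diag + qlen)
            if end - start < min_coverage * qlen:
                continue
            q = queries[strand][start - diag : end - diag]
            window = chrom[start:end]
            ident = float((q == window).mean())
            if ident >= min_identity:
                cand = LocusHit(
                    chrom_id=chrom_id,
                    start=start + 1,
                    end=end,
                    strand=strand,
                    identity=ident,
                )
                if best is None or cand.identity > best.identity:
                    best = cand
    return best


def write_vcf(
    variants: list[VariantRecord], ref_cds: str, cds_id: str, path: str | Path
) -> None:
    """Minimal VCF v4.2 against the CDS as the reference sequence.

    Indels follow VCF convention (anchored on the preceding reference base).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cds_id},length={len(ref_cds)}>\n")
        fh.write(
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">\n'
        )
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Amino acid change">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"EFFECT={v.effect or '.'}"
            if v.aa_change:
                cn, raa, aaa = v.aa_change
                info += f";AA={raa}{cn}{aaa}"
            if v.premature_stop_codon:
                info += f";STOP_CODON={v.premature_stop_codon}"
            if v.type == SNV:
                pos, ref, alt = v.cds_pos, v.ref_allele, v.alt_allele
            elif v.type == DELETION:
                anchor_pos = v.cds_pos - 1
                if anchor_pos >= 1:
                    anchor = ref_cds[anchor_pos - 1]
                    pos, ref, alt = anchor_pos, anchor + v.ref_allele, anchor
                else:  # deletion at position 1: anchor on the following base
                    nxt = ref_cds[v.cds_pos - 1 + v.length]
                    pos, ref, alt = 1, v.ref_allele + nxt, nxt
            else:
                anchor = ref_cds[v.cds_pos - 1] if v.cds_pos >= 1 else ref_cds[0]
                pos = max(v.cds_pos, 1)
                ref, alt = anchor, anchor + v.alt_allele
            fh.write(f"{cds_id}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")


def write_variants_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cds_pos\tcds_end\ttype\tref\talt\teffect\taa_change\tstop_codon\n")
        for v in variants:
            aa = ""
            if v.aa_change:
                cn, raa, aaa = v.aa_change
                aa = f"{raa}{cn}{aaa}"
            fh.write(
                f"{v.cds_pos}\t{v.cds_end}\t{v.type}\t{v.ref_allele or '-'}\t"
                f"{v.alt_allele or '-'}\t{v.effect or ''}\t{aa}\t"
                f"{v.premature_stop_codon or ''}\n"
            )
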