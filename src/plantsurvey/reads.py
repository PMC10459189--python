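"""Read containers and FASTQ input/output.

Two representations are used throughout the package:

* :class:`ReadRecord` — a single read as plain strings, convenient for the
  record-level operations (trimming, filtering, classification of one read).
* :class:`ReadSet` — a batch of equal-length reads stored as a 2-bit code
  matrix, the production representation for survey-scale work (millions of
  short reads of one length, as produced by the simulator and by fixed-trim
  QC).

FASTQ parsing goes through Biopython's ``FastqGeneralIterator``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import seqcodes

PHRED_OFFSET = 33


@dataclass
class ReadRecord:
    """One sequencing read: identifier, bases over {A,C,G,T,N}, Phred+33 quality."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.qual)})"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def phred(self) -> np.ndarray:
        """Quality as integer Phred scores."""
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8).astype(
            np.int16
        ) - PHRED_OFFSET


class ReadSet:
    """A batch of equal-length reads as a (n, L) uint8 code matrix.

    ``quals`` holds integer Phred scores, either an (n, L) matrix or a scalar
    (constant quality, as produced by the simulator).  ``ids`` may be None,
    in which case sequential identifiers are generated on output.
    """

    def __init__(
        self,
        codes: np.ndarray,
        quals: np.ndarray | int,
        ids: list[str] | None = None,
    ):
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        self.codes = codes
        self.quals = quals
        self.ids = ids
        if ids is not None and len(ids) != codes.shape[0]:
            raise ValueError("ids length does not match read count")

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_len(self) -> int:
        return self.codes.shape[1]

    @property
    def n_bases(self) -> int:
        return self.codes.size

    def __len__(self) -> int:
        return self.n_reads

    def id_of(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"read{i}"

    def qual_matrix(self) -> np.ndarray:
        if np.isscalar(self.quals):
            return np.full(self.codes.shape, self.quals, dtype=np.int16)
        return self.quals

    def subset(self, mask_or_index: np.ndarray) -> "ReadSet":
        idx = np.asarray(mask_or_index)
        codes = self.codes[idx]
        quals = self.quals if np.isscalar(self.quals) else self.quals[idx]
        ids = None
        if self.ids is not None:
            pos = np.flatnonzero(idx) if idx.dtype == bool else idx
            ids = [self.ids[int(i)] for i in pos]
        return ReadSet(codes, quals, ids)

    def records(self) -> Iterator[ReadRecord]:
        qm = self.qual_matrix()
        for i in range(self.n_reads):
            seq = seqcodes.decode(self.codes[i])
            qual = (qm[i] + PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")
            yield ReadRecord(self.id_of(i), seq, qual)

    @classmethod
    def from_records(cls, records: Iterable[ReadRecord]) -> "ReadSet":
        records = list(records)
        ids = [r.id for r in records]
        codes = seqcodes.encode_matrix([r.seq for r in records])
        if records:
            qbytes = "".join(r.qual for r in records).encode("ascii")
            quals = (
                np.frombuffer(qbytes, dtype=np.uint8)
                .reshape(codes.shape)
                .astype(np.int16)
                - PHRED_OFFSET
            )
        else:
            quals = np.empty((0, 0), dtype=np.int16)
        return cls(codes, quals, ids)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        """Load a FASTQ file of uniform-length reads.

        Survey short-read data is uniform-length by construction (fixed-cycle
        sequencing followed by fixed front/tail trimming); variable-length
        input raises.
        """
        ids: list[str] = []
        seqs: list[str] = []
        quals: list[str] = []
        for title, seq, qual in _iter_fastq(path):
            ids.append(title.split()[0])
            seqs.append(seq.upper())
            quals.append(qual)
        codes = seqcodes.encode_matrix(seqs)
        if seqs:
            qarr = (
                np.frombuffer("".join(quals).encode("ascii"), dtype=np.uint8)
                .reshape(codes.shape)
                .astype(np.int16)
                - PHRED_OFFSET
            )
        else:
            qarr = np.empty((0, 0), dtype=np.int16)
        return cls(codes, qarr, ids)

    def to_fastq(self, path: str | Path) -> None:
        with _open_write(path) as fh:
            chars = seqcodes._DECODE[self.codes]
            if np.isscalar(self.quals):
                qline = chr(int(self.quals) + PHRED_OFFSET) * self.read_len
                for i in range(self.n_reads):
                    fh.write(
                        f"@{self.id_of(i)}\n{chars[i].tobytes().decode()}\n+\n{qline}\n"
                    )
            else:
                qchars = (self.quals + PHRED_OFFSET).astype(np.uint8)
                for i in range(self.n_reads):
                    fh.write(
                        f"@{self.id_of(i)}\n{chars[i].tobytes().decode()}\n"
                        f"+\n{qchars[i].tobytes().decode()}\n"
                    )


def _open_read(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _open_write(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def _iter_fastq(path: str | Path):
    with _open_read(path) as fh:
        try:
            yield from FastqGeneralIterator(fh)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def iter_fastq_records(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file as :class:`ReadRecord` objects (any lengths)."""
    for i, (title, seq, qual) in enumerate(_iter_fastq(path)):
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record index {i} in {path}")
        yield ReadRecord(title.split()[0], seq.upper(), qual)


def write_fastq_records(records: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_write(path) as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as 60-column FASTA."""
    with _open_write(path) as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with _open_read(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
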