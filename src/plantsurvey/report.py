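"""Assembly summary statistics and survey report assembly."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .gc_depth import CenterReport
from .kmer_survey import SpectrumFit
from .organelle_filter import RemovalStats
from .readqc import QCStats
from .reads import read_fasta


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    longest_bp: int
    n50_bp: int
    n90_bp: int
    gc_pct: float


def _nx(sorted_lengths_desc: list[int], total: int, frac: float) -> int:
    """Largest length L such that sequences of length >= L sum to >= frac*total."""
    cum = 0
    for length in sorted_lengths_desc:
        cum += length
        if cum >= frac * total:
            return length
    return sorted_lengths_desc[-1]


def assembly_stats(fasta: str | Path | list[tuple[str, str]]) -> AssemblyStats:
    """Contig count, total size, longest contig, N50/N90 and GC percentage."""
    if isinstance(fasta, (str, Path)):
        entries = read_fasta(fasta)
    else:
        entries = fasta
    if not entries:
        raise ValueError("no sequences")
    lengths = sorted((len(s) for _, s in entries), reverse=True)
    total = sum(lengths)
    gc_bases = 0
    acgt_bases = 0
    for _, s in entries:
        su = s.upper()
        g = su.count("G") + su.count("C")
        a = su.count("A") + su.count("T")
        gc_bases += g
        acgt_bases += g + a
    gc_pct = 100.0 * gc_bases / acgt_bases if acgt_bases else 0.0
    return AssemblyStats(
        n_sequences=len(lengths),
        total_bp=total,
        longest_bp=lengths[0],
        n50_bp=_nx(lengths, total, 0.5),
        n90_bp=_nx(lengths, total, 0.9),
        gc_pct=gc_pct,
    )


def annotation_coverage(n_annotated: int, n_total: int) -> float:
    """Percentage of genes with a functional annotation, rounded half-up to
    two decimals (printed-report precision)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_annotated <= n_total:
        raise ValueError("need 0 <= n_annotated <= n_total")
    pct = Decimal(100 * n_annotated) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SurveyReport:
    qc: QCStats | None = None
    organelle_removal: RemovalStats | None = None
    spectrum: SpectrumFit | None = None
    gc_depth: CenterReport | None = None
    assembly: AssemblyStats | None = None
    annotation: list[tuple[str, int, int, float]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def enc(x):
            if x is None:
                return None
            if hasattr(x, "__dataclass_fields__"):
                d = asdict(x)
                if isinstance(x, QCStats):
                    d["filtering_rate"] = x.filtering_rate
                return d
            return x

        d = {
            "qc": enc(self.qc),
            "organelle_removal": None,
            "spectrum": enc(self.spectrum),
            "gc_depth": enc(self.gc_depth),
            "assembly": enc(self.assembly),
            "annotation": [list(row) for row in self.annotation],
            "notes": list(self.notes),
        }
        if self.organelle_removal is not None:
            r = self.organelle_removal
            d["organelle_removal"] = {
                "reads_in": r.reads_in,
                "reads_removed": r.reads_removed,
                "bases_in": r.bases_in,
                "bases_removed": r.bases_removed,
                "removed_read_fraction": r.removed_read_fraction,
                "removed_base_fraction": r.removed_base_fraction,
            }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "SurveyReport":
        from .gc_depth import CenterReport as CR

        d = json.loads(text)
        rep = cls()
        if d.get("qc"):
            q = dict(d["qc"])
            q.pop("filtering_rate", None)
            rep.qc = QCStats(**q)
        if d.get("organelle_removal"):
            r = d["organelle_removal"]
            rep.organelle_removal = RemovalStats(
                r["reads_in"], r["reads_removed"], r["bases_in"], r["bases_removed"]
            )
        if d.get("spectrum"):
            rep.spectrum = SpectrumFit(**d["spectrum"])
        if d.get("gc_depth"):
            g = d["gc_depth"]
            rep.gc_depth = CR(
                centers=[tuple(c) for c in g["centers"]],
                contamination_flag=g["contamination_flag"],
                flags_reason=g["flags_reason"],
            )
        if d.get("assembly"):
            rep.assembly = AssemblyStats(**d["assembly"])
        rep.annotation = [tuple(row) for row in d.get("annotation", [])]
        rep.notes = list(d.get("notes", []))
        return rep

    def render_text(self) -> str:
        """Human-readable summary table (deterministic section order)."""
        lines = ["Genome survey report", "=" * 40]

        def section(title: str) -> None:
            lines.append("")
            lines.append(title)
            lines.append("-" * len(title))

        section("Read quality control")
        if self.qc is None:
            lines.append("not run")
        else:
            q = self.qc
            lines.append(f"raw bases\t{q.raw_bases}")
            lines.append(f"clean bases\t{q.clean_bases}")
            lines.append(f"filtering rate (%)\t{q.filtering_rate:.2f}")
            lines.append(f"Q20 (%)\t{q.q20_pct:.2f}")
            lines.append(f"Q30 (%)\t{q.q30_pct:.2f}")

        section("Organelle read removal")
        if self.organelle_removal is None:
            lines.append("not run")
        else:
            r = self.organelle_removal
            lines.append(f"reads removed (%)\t{100 * r.removed_read_fraction:.2f}")
            lines.append(f"bases removed (%)\t{100 * r.removed_base_fraction:.2f}")

        section("k-mer spectrum")
        if self.spectrum is None:
            lines.append("not run")
        else:
            s = self.spectrum
            lines.append(f"k\t{s.k}")
            lines.append(f"main peak depth (x)\t{s.c_peak}")
            lines.append(f"genome size (bp)\t{s.genome_size}")
            lines.append(f"repeat fraction (%)\t{100 * s.repeat_fraction:.2f}")
            lines.append(
                f"heterozygous half-peak\t{'yes' if s.het_half_peak_present else 'no'}"
            )
            lines.append(f"heterozygosity (%)\t{100 * s.het_rate:.3f}")

        section("GC-depth screen")
        if self.gc_depth is None:
            lines.append("not run")
        else:
            lines.append(f"enrichment centers\t{len(self.gc_depth.centers)}")
            lines.append(
                f"contamination flag\t{'yes' if self.gc_depth.contamination_flag else 'no'}"
            )
            lines.append(f"reason\t{self.gc_depth.flags_reason}")

        section("Assembly statistics")
        if self.assembly is None:
            lines.append("not run")
        else:
            a = self.assembly
            lines.append(f"sequences\t{a.n_sequences}")
            lines.append(f"total (bp)\t{a.total_bp}")
            lines.append(f"longest (bp)\t{a.longest_bp}")
            lines.append(f"N50 (bp)\t{a.n50_bp}")
            lines.append(f"N90 (bp)\t{a.n90_bp}")
            lines.append(f"GC content (%)\t{a.gc_pct:.2f}")

        section("Annotation coverage")
        if not self.annotation:
            lines.append("not run")
        else:
            for name, n_ann, n_tot, pct in self.annotation:
                lines.append(f"{name}\t{n_ann}/{n_tot}\t{pct:.2f}%")

        for note in self.notes:
            lines.append("")
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def build_report(
    qc: QCStats | None = None,
    organelle_removal: RemovalStats | None = None,
    spectrum: SpectrumFit | None = None,
    gc_depth: CenterReport | None = None,
    assembly: AssemblyStats | None = None,
    annotation: list[tuple[str, int, int]] | None = None,
    notes: list[str] | None = None,
) -> SurveyReport:
    """Assemble components (any subset may be missing) into one report."""
    rows = []
    for name, n_ann, n_tot in annotation or []:
        rows.append((name, n_ann, n_tot, annotation_coverage(n_ann, n_tot)))
    return SurveyReport(
        qc=qc,
        organelle_removal=organelle_removal,
        spectrum=spectrum,
        gc_depth=gc_depth,
        assembly=assembly,
        annotation=rows,
        notes=list(notes or []),
    )
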