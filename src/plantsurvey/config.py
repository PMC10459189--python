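"""Pipeline configuration: a plain YAML mapping with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .organelle_filter import AcceptanceRule
from .readqc import QCParams


@dataclass
class PipelineConfig:
    qc: QCParams = field(default_factory=QCParams)
    rule: AcceptanceRule = field(default_factory=AcceptanceRule)
    k: int = 17
    seed: int = 0
    outdir: str = "survey_out"
    min_contig_len: int = 5000
    gc_bin_width: float = 0.01
    depth_bin_width: float = 5.0
    min_cluster_fraction: float = 0.02
    gc_flag_threshold: float = 0.60
    pileup_min_depth: int = 10
    pileup_het_maf: float = 0.2
    threads: int = 1  # accepted for interface symmetry; execution is
    # single-threaded and results are identical for any value

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "qc" in d and isinstance(d["qc"], dict):
            _check_keys(d["qc"], QCParams, "qc")
            d["qc"] = QCParams(**d["qc"])
        if "rule" in d and isinstance(d["rule"], dict):
            _check_keys(d["rule"], AcceptanceRule, "rule")
            d["rule"] = AcceptanceRule(**d["rule"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)


def _check_keys(d: dict, cls, section: str) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys in {section}: {sorted(unknown)}")
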