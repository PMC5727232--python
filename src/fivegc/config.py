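"""Run configuration: one name per concept across config file, CLI flags
and report."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters of a full enrichment run.

    Defaults are the analysis's canonical values: 200 bp windows, TSS
    windows extending 1000 bp upstream, 500 baseline regions, cluster
    threshold 3, both strands. ``seed`` governs baseline sampling and must
    be set explicitly. The config round-trips through YAML unchanged.
    """

    genome: str = ""
    peaks: str = ""
    tss: str = ""
    exclude: list[str] = field(default_factory=list)
    outdir: str = "fivegc_out"
    width: int = 200
    max_upstream: int = 1000
    baseline_n: int = 500
    cluster_threshold: int = 3
    strands: str = "both"
    seed: int | None = None
    promoter_mode: str = "upstream_only"
    use_summit: bool = False
    max_n_fraction: float = 0.1
    mask: str = "include"
    panels: str = ""  # optional YAML panel file; empty = built-in panels

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate_inputs(self) -> None:
        """Fail before any output is written if an input is missing."""
        problems = []
        for label, p in (("genome", self.genome), ("peaks", self.peaks),
                         ("tss", self.tss)):
            if not p:
                problems.append(f"{label}: not set")
            elif not Path(p).exists():
                problems.append(f"{label}: {p} does not exist")
        for p in self.exclude:
            if not Path(p).exists():
                problems.append(f"exclude: {p} does not exist")
        if self.panels and not Path(self.panels).exists():
            problems.append(f"panels: {self.panels} does not exist")
        if self.seed is None:
            problems.append("seed: required (baseline sampling)")
        if self.strands not in ("+", "-", "both"):
            problems.append(f"strands: invalid selector {self.strands!r}")
        if problems:
            raise FileNotFoundError(
                "invalid run configuration: " + "; ".join(problems)
            )
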