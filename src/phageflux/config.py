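"""Pipeline thresholds, with the study's published values as defaults.

Every decision rule in the pipeline reads its threshold from here (or
takes it as a keyword argument); the config file format is plain
``key = value`` lines with ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # curation
    phage_marker_floor: float = 30.0      # bits
    euk_marker_floor: float = 30.0        # bits
    ani_threshold: float = 95.0           # %
    coverage_threshold: float = 0.5       # fraction of the candidate
    coverage_on: str = "candidate"        # cd-hit -aS convention
    min_length_bp: int = 10_000
    dtr_min_bp: int = 20
    dtr_max_bp: int = 5_000
    dtr_end_window_bp: int = 200
    chimera_min_bp: int = 5_000
    # host linking
    crispr_min_repeats: int = 3
    crispr_repeat_min: int = 21
    crispr_repeat_max: int = 48
    crispr_spacer_min: int = 18
    crispr_spacer_max: int = 72
    repeat_match_min_bp: int = 23         # stands in for blastn e <= 1e-10
    aai_floor: float = 60.0               # %
    aai_fraction_floor: float = 0.5
    # lifestyle
    temperate_marker_floor: float = 30.0  # bits
    flank_excess_bp: int = 10_000
    # read filters
    virus_read_min_identity: float = 95.0
    virus_read_min_aln_bp: int = 45
    mag_read_min_identity: float = 97.0
    mag_read_min_aln_bp: int = 45
    export_read_min_identity: float = 95.0
    export_read_min_fraction: float = 0.8
    crispr_read_min_identity: float = 97.0
    crispr_read_min_fraction: float = 0.75
    # flux analysis
    sep_factor: float = 1.5               # >= 150% of the reference mean
    wgcna_power: float = 6.0
    cut_height: float = 0.988
    min_module_size: int = 10
    alpha: float = 0.05

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise ValueError(f"line {lineno}: unknown config key {key!r}")
                current = getattr(defaults, key)
                kwargs[key] = type(current)(value)
        return cls(**kwargs)
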