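"""Pipeline configuration: a flat TOML file with one global seed.

The single ``seed`` fans out to per-stage seeds by a fixed derivation
(``SeedSequence([seed, stage_index])``), so one knob reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from trnaswitch.errors import InputError

# stage indices for seed derivation — order is part of the file contract
STAGE_REFERENCE = 0
STAGE_SIMULATE = 1
STAGE_CDS = 2

FOCAL_CODONS = ("TCC", "AGC", "CTG", "TTG")


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0])


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults give the focal-four demo scenario.

    The demo truth makes the tRNAs decoding TCC/AGC/CTG/TTG lose the most
    methylation in the knockout and the Ser-TCG / Leu-CTT tRNAs the least,
    and enriches the generated CDS in the focal codons. Stoichiometries are
    free parameters of the simulation, not measured values.
    """

    seed: int = 0
    # simulated truth: aligned per-tRNA lists
    trna_codons: list[str] = field(
        default_factory=lambda: [
            "TCC", "AGC", "CTG", "TTG",  # focal, most affected
            "TCG", "CTT",                # escape codons, least affected
            "GCC", "GAG", "AAG", "GAC", "TTC", "ATC",
        ]
    )
    s_wt: list[float] = field(
        default_factory=lambda: [
            0.92, 0.88, 0.85, 0.80,
            0.30, 0.25,
            0.60, 0.55, 0.50, 0.45, 0.40, 0.35,
        ]
    )
    s_ko: list[float] = field(
        default_factory=lambda: [
            0.05, 0.05, 0.05, 0.05,
            0.28, 0.24,
            0.35, 0.32, 0.30, 0.28, 0.26, 0.24,
        ]
    )
    n_reads: int = 10000
    # error model
    p_mis: float = 0.5
    p_stop: float = 0.2
    e_bg: float = 0.001
    # quantification
    min_coverage: int = 100
    metric: str = "s_hat"
    k_top: int = 4
    k_bottom: int = 4
    # codon analysis
    freq_cutoff: int = 10
    wobble_policy: str = "strict"
    # CDS input: synthesized unless cds_path points at a FASTA
    cds_path: str = ""
    n_codons: int = 300
    cds_boost_codons: list[str] = field(default_factory=lambda: list(FOCAL_CODONS))
    cds_boost: float = 8.0

    def validate(self) -> None:
        if not len(self.trna_codons) == len(self.s_wt) == len(self.s_ko):
            raise InputError("trna_codons, s_wt, s_ko must have equal lengths")
        if self.metric not in ("s_hat", "mismatch_rate", "stop_rate"):
            raise InputError(f"unknown metric {self.metric!r}")
        if self.wobble_policy not in ("strict", "crick"):
            raise InputError(f"unknown wobble policy {self.wobble_policy!r}")

    def save(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {_toml_value(getattr(self, f.name))}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise InputError(f"cannot serialize config value {value!r}")
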