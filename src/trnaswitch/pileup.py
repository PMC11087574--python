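"""Per-position base-count pileups and their TSV dialect.

A pileup records, for one tRNA in one condition, the number of reads calling
A/C/G/T at each 0-based position plus the number of reverse-transcription stop
events recorded at that position. The TSV dialect has columns
``tRNA_id, position, count_A, count_C, count_G, count_T, count_stop`` and, in
combined files, an optional leading ``condition`` column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from trnaswitch.errors import InputError, ValidationError

BASE_ORDER = ("A", "C", "G", "T")
PILEUP_COLUMNS = (
    "tRNA_id",
    "position",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "count_stop",
)


@dataclass
class Pileup:
    """Base and stop counts over one tRNA; ``counts`` is (length, 5) int64."""

    trna_id: str
    counts: np.ndarray  # columns A, C, G, T, stop

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 5:
            raise ValidationError("pileup counts must have shape (length, 5)")
        if (self.counts < 0).any():
            raise ValidationError("pileup counts must be nonnegative")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def base_coverage(self, position: int) -> int:
        """Reads contributing a base call at ``position``."""
        return int(self.counts[position, :4].sum())

    def reads_entering(self, position: int) -> int:
        """Reads covering ``position`` including those terminating there."""
        return int(self.counts[position, :].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[f"count_{b}" for b in BASE_ORDER] + ["count_stop"])
        df.insert(0, "position", np.arange(len(self), dtype=np.int64))
        df.insert(0, "tRNA_id", self.trna_id)
        return df


def write_pileups(pileups: list[Pileup], path: str | Path, *, condition: str | None = None) -> None:
    """Write pileups to a single TSV, optionally tagged with a condition."""
    frames = [p.to_frame() for p in pileups]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PILEUP_COLUMNS)
    if condition is not None:
        df.insert(0, "condition", condition)
    df.to_csv(path, sep="\t", index=False)


def read_pileups(path: str | Path) -> dict[str, Pileup]:
    """Read a pileup TSV (single- or combined-condition) into per-tRNA pileups."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"pileup file {path} missing columns {sorted(missing)}")
    out: dict[str, Pileup] = {}
    for trna_id, grp in df.groupby("tRNA_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(len(grp))):
            raise InputError(f"pileup for {trna_id!r} has non-contiguous positions")
        counts = grp[[f"count_{b}" for b in BASE_ORDER] + ["count_stop"]].to_numpy()
        out[str(trna_id)] = Pileup(trna_id=str(trna_id), counts=counts)
    return out
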