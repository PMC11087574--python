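"""Codon-frequency profiling of a CDS and cross-referencing with tRNA deltas."""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from trnaswitch.errors import FrameError, InputError
from trnaswitch.quant import rank_trnas
from trnaswitch.reference import STOP_CODONS, DecodingMap, normalize_dna

USAGE_COLUMNS = ("codon", "count", "frequency")
REPORT_COLUMNS = (
    "codon",
    "frequency",
    "frequency_rank",
    "trna_ids",
    "delta",
    "vulnerable",
)

DEFAULT_FREQUENCY_CUTOFF = 10


@dataclass
class CodonUsageTable:
    """Per-codon counts/frequencies of one CDS; terminal stop excluded."""

    cds_id: str
    table: pd.DataFrame  # columns: codon, count, frequency
    total: int

    def frequency_of(self, codon: str) -> float:
        sel = self.table.loc[self.table["codon"] == normalize_dna(codon), "frequency"]
        return float(sel.iloc[0]) if len(sel) else 0.0


def codon_frequency(cds: str, *, cds_id: str = "cds") -> CodonUsageTable:
    """Count every in-frame codon of a CDS.

    The terminal stop codon is excluded from counts and frequencies
    (frequency denominator = number of sense codons); internal stops trigger a
    warning naming their nucleotide positions but are still excluded from the
    sense-codon totals.
    """
    seq = normalize_dna(cds)
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    internal_stops = [i * 3 for i, c in enumerate(codons) if c in STOP_CODONS]
    if internal_stops:
        warnings.warn(
            f"{cds_id}: internal stop codon(s) at nucleotide position(s) "
            f"{internal_stops}",
            stacklevel=2,
        )
        codons = [c for c in codons if c not in STOP_CODONS]
    counts = Counter(codons)
    total = sum(counts.values())
    rows = [
        {"codon": c, "count": n, "frequency": n / total}
        for c, n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=list(USAGE_COLUMNS))
    return CodonUsageTable(cds_id=cds_id, table=table, total=total)


def vulnerability_report(
    usage: CodonUsageTable,
    delta: pd.DataFrame,
    decoding_map: DecodingMap,
    *,
    k_top: int = 4,
    m: int = DEFAULT_FREQUENCY_CUTOFF,
) -> pd.DataFrame:
    """Flag codons that are both frequent and decoded by most-affected tRNAs.

    A codon is vulnerable when (a) at least one of its decoding tRNAs is among
    the ``k_top`` most affected by the knockout, and (b) its frequency rank in
    the CDS is at most ``m``. Unmapped codons are listed with empty tRNA ids,
    never fatal. Sorted by frequency descending, ties by codon.
    """
    if delta.empty:
        raise InputError("delta table is empty")
    most_affected, _ = rank_trnas(delta, min(k_top, len(delta)), 0)
    affected = set(most_affected)
    delta_by_id = dict(zip(delta["tRNA_id"], delta["delta"]))

    table = usage.table.sort_values(
        ["frequency", "codon"], ascending=[False, True]
    ).reset_index(drop=True)
    # competition ranking on frequency: tied codons share a rank
    freq_rank = (
        table["frequency"].rank(method="min", ascending=False).astype(int)
    )
    rows = []
    for (_, row), rank in zip(table.iterrows(), freq_rank):
        codon = row["codon"]
        decoders = decoding_map.trnas_for(codon)
        deltas = [delta_by_id[t] for t in decoders if t in delta_by_id]
        rows.append(
            {
                "codon": codon,
                "frequency": row["frequency"],
                "frequency_rank": rank,
                "trna_ids": ";".join(decoders),
                "delta": max(deltas) if deltas else float("nan"),
                "vulnerable": bool(affected.intersection(decoders)) and rank <= m,
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
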