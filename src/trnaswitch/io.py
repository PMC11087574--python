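"""File-format adapters: tRNA reference FASTA+TSV and CDS FASTA."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from trnaswitch.errors import InputError
from trnaswitch.reference import TRNASpecies

REFERENCE_TSV_COLUMNS = ("id", "amino_acid", "anticodon", "decoded_codons", "pos58")


def write_trna_reference(
    trnas: list[TRNASpecies], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Write a tRNA reference as FASTA (sequences) plus TSV (metadata)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description=f"anticodon={t.anticodon}")
        for t in trnas
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "id": t.id,
            "amino_acid": t.amino_acid,
            "anticodon": t.anticodon,
            "decoded_codons": ";".join(t.decoded_codons),
            "pos58": "" if t.pos58 is None else t.pos58,
        }
        for t in trnas
    ]
    pd.DataFrame(rows, columns=list(REFERENCE_TSV_COLUMNS)).to_csv(
        tsv_path, sep="\t", index=False
    )


def read_trna_reference(
    fasta_path: str | Path, tsv_path: str | Path
) -> list[TRNASpecies]:
    """Read FASTA+TSV back into validated ``TRNASpecies`` records."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(tsv_path, sep="\t", dtype={"pos58": "Int64"})
    missing = set(REFERENCE_TSV_COLUMNS) - set(meta.columns)
    if missing:
        raise InputError(f"reference TSV missing columns {sorted(missing)}")
    trnas: list[TRNASpecies] = []
    for row in meta.itertuples(index=False):
        if row.id not in seqs:
            raise InputError(f"tRNA {row.id!r} has metadata but no FASTA sequence")
        pos58 = None if pd.isna(row.pos58) else int(row.pos58)
        trna = TRNASpecies(
            id=str(row.id),
            decoded_codons=tuple(str(row.decoded_codons).split(";")),
            anticodon=str(row.anticodon),
            amino_acid=str(row.amino_acid),
            sequence=seqs[row.id],
            pos58=pos58,
        )
        trna.validate()
        trnas.append(trna)
    return trnas


def write_cds(sequence: str, path: str | Path, *, cds_id: str = "cds") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=cds_id, description="")], str(path), "fasta")


def read_cds(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA; returns ``(id, sequence)``."""
    for rec in SeqIO.parse(str(path), "fasta"):
        return rec.id, str(rec.seq)
    raise InputError(f"no FASTA records in {path}")
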