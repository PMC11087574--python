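import numpy as np
import pandas as pd
import pytest

from trnaswitch.reference import TRNASpecies, reverse_complement
from trnaswitch.simulate import ErrorModel, generate_trna_reference

DEMO_CODONS = [
    "TCC", "AGC", "CTG", "TTG",
    "TCG", "CTT",
    "GCC", "GAG", "AAG", "GAC", "TTC", "ATC",
]


@pytest.fixture(scope="session")
def demo_trnas():
    """12 tRNA families: the focal four, the two escapes, six fillers."""
    return generate_trna_reference(len(DEMO_CODONS), 11, codons=DEMO_CODONS)


@pytest.fixture(scope="session")
def focal_trnas(demo_trnas):
    return demo_trnas[:4]


@pytest.fixture
def default_model():
    return ErrorModel()


def make_delta_frame(codon_delta: dict[str, float]) -> pd.DataFrame:
    """Delta table keyed by decoded codon, using the generated id scheme."""
    from trnaswitch.reference import GENETIC_CODE

    rows = [
        {
            "tRNA_id": f"tRNA-{GENETIC_CODE[c]}-{c}",
            "decoded_codons": c,
            "delta": d,
        }
        for c, d in codon_delta.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["delta", "tRNA_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = df["delta"].rank(method="dense", ascending=False).astype(int)
    return df


def trna_for_anticodon(anticodon: str, ident: str | None = None) -> TRNASpecies | None:
    """Minimal valid species for an anticodon, or None if it decodes a stop."""
    from trnaswitch.reference import GENETIC_CODE

    codon = reverse_complement(anticodon)
    aa = GENETIC_CODE[codon]
    if aa == "*":
        return None
    return TRNASpecies(
        id=ident or f"tRNA-{aa}-{codon}",
        decoded_codons=(codon,),
        anticodon=anticodon,
        amino_acid=aa,
        sequence="ACGT" * 10,
        pos58=None,
    )


def random_trna_set(rng: np.random.Generator, n: int) -> list[TRNASpecies]:
    """Random distinct-anticodon tRNA set of size <= n (stops excluded)."""
    bases = "ACGT"
    anticodons = set()
    while len(anticodons) < n:
        anticodons.add("".join(rng.choice(list(bases), size=3)))
    out = []
    for ac in sorted(anticodons):
        trna = trna_for_anticodon(ac)
        if trna is not None:
            out.append(trna)
    return out
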