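"""Genetic code, tRNA reference records, T-loop conventions, and codon decoding.

Internally the alphabet is DNA (``ACGT``); RNA input is mapped ``U -> T`` on
read. tRNA species are identified publicly by the codon they decode, with the
anticodon stored alongside. The m1A site is located operationally by the
T-loop nonamer ``GTTCNANNC`` (the lone fixed ``A``, sixth base of the match),
not by an absolute coordinate, so references of any length are supported;
"position 58" is the conventional label for that site.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from trnaswitch.errors import AlphabetError, FrameError, InputError, ValidationError

__all__ = [
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "AMINO_ACIDS",
    "TLOOP_MOTIF",
    "TRNASpecies",
    "DecodingMap",
    "GeneticCode",
    "locate_position58",
    "build_decoding_map",
    "translate",
    "reverse_complement",
    "normalize_dna",
    "synonymous_codons",
]

_BASES = "TCAG"
# NCBI translation table 1 in TCAG order.
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

GENETIC_CODE: dict[str, str] = {
    b1 + b2 + b3: aa
    for (b1, b2, b3), aa in zip(
        ((x, y, z) for x in _BASES for y in _BASES for z in _BASES), _AA_STRING
    )
}
STOP_CODONS: frozenset[str] = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
AMINO_ACIDS: frozenset[str] = frozenset(GENETIC_CODE.values()) - {"*"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# T-loop consensus; the fixed A at offset 5 is the methylated adenosine.
TLOOP_MOTIF = re.compile("GTTC[ACGT]A[ACGT][ACGT]C")
_MOTIF_A_OFFSET = 5

# Anticodon position 34 pairing partners for codon position 3.  Watson-Crick
# partner first; extra entries are the wobble expansions ("crick" policy).
# Inosine (I) has no Watson-Crick partner, so it decodes nothing under the
# strict policy.
_WC_PARTNER_34 = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CRICK_PARTNERS_34 = {"A": "T", "C": "G", "G": "CT", "T": "AG", "I": "TCA"}

WOBBLE_POLICIES = ("strict", "crick")


def normalize_dna(seq: str, *, allow_inosine: bool = False) -> str:
    """Uppercase and map RNA to DNA (U->T); reject foreign characters."""
    out = seq.upper().replace("U", "T")
    allowed = set("ACGT") | ({"I"} if allow_inosine else set())
    bad = set(out) - allowed
    if bad:
        raise AlphabetError(f"invalid characters in sequence: {sorted(bad)!r}")
    return out


def reverse_complement(seq: str) -> str:
    return normalize_dna(seq).translate(_COMPLEMENT)[::-1]


def locate_position58(sequence: str) -> int | None:
    """Return the 0-based index of the m1A adenosine in the first T-loop match.

    Scans 5'->3' for ``GTTCNANNC`` (``GUUCNANNC`` in RNA) and returns the index
    of the fixed ``A`` (sixth base of the nonamer), or ``None`` if the motif is
    absent. U and T are treated as equivalent.
    """
    seq = normalize_dna(sequence)
    if len(seq) < 9:
        raise InputError("sequence shorter than the 9-base T-loop motif")
    m = TLOOP_MOTIF.search(seq)
    if m is None:
        return None
    return m.start() + _MOTIF_A_OFFSET


@dataclass(frozen=True)
class TRNASpecies:
    """One tRNA family, named by the codon it decodes.

    ``decoded_codons`` lists the codon(s) this species is annotated to decode;
    the first entry is the primary codon and must be the exact reverse
    complement of the anticodon at codon positions 1-2 (wobble is allowed only
    at codon position 3). ``pos58`` is the 0-based index of the m1A adenosine
    within the T-loop motif, or ``None`` when the species carries no site.
    """

    id: str
    decoded_codons: tuple[str, ...]
    anticodon: str
    amino_acid: str
    sequence: str
    pos58: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "decoded_codons", tuple(normalize_dna(c) for c in self.decoded_codons)
        )
        object.__setattr__(
            self, "anticodon", normalize_dna(self.anticodon, allow_inosine=True)
        )
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))

    @property
    def primary_codon(self) -> str:
        return self.decoded_codons[0]

    def validate(self) -> None:
        if not self.decoded_codons:
            raise ValidationError(f"{self.id}: no decoded codons")
        if len(self.anticodon) != 3:
            raise ValidationError(f"{self.id}: anticodon must be a 3-mer")
        for codon in self.decoded_codons:
            if len(codon) != 3:
                raise ValidationError(f"{self.id}: codon {codon!r} is not a 3-mer")
            if GENETIC_CODE.get(codon) != self.amino_acid:
                raise ValidationError(
                    f"{self.id}: codon {codon} translates to "
                    f"{GENETIC_CODE.get(codon)!r}, not {self.amino_acid!r}"
                )
        # Codon positions 1-2 pair with anticodon positions 36-35 (Watson-Crick
        # only); position 3 pairs with anticodon position 34, wobble allowed.
        primary = self.primary_codon
        for i, (cbase, abase) in enumerate(zip(primary[:2], self.anticodon[::-1][:2])):
            if _WC_PARTNER_34.get(abase) != cbase:
                raise ValidationError(
                    f"{self.id}: codon position {i + 1} ({cbase}) does not "
                    f"Watson-Crick pair with anticodon ({abase})"
                )
        if primary[2] not in _CRICK_PARTNERS_34.get(self.anticodon[0], ""):
            raise ValidationError(
                f"{self.id}: codon position 3 ({primary[2]}) cannot pair with "
                f"anticodon position 34 ({self.anticodon[0]})"
            )
        if self.pos58 is not None:
            if not 0 <= self.pos58 < len(self.sequence):
                raise ValidationError(f"{self.id}: pos58 outside sequence")
            if self.sequence[self.pos58] != "A":
                raise ValidationError(f"{self.id}: base at pos58 is not A")
            start = self.pos58 - _MOTIF_A_OFFSET
            window = self.sequence[start : start + 9]
            if start < 0 or TLOOP_MOTIF.fullmatch(window) is None:
                raise ValidationError(
                    f"{self.id}: pos58 is not the m1A position of a T-loop motif"
                )

    def decoded_codons_under_policy(self, wobble_policy: str) -> tuple[str, ...]:
        """Codons reachable from this anticodon under a wobble policy.

        Expansions that would change the amino acid are dropped — decoding is
        only ever synonymous.
        """
        if wobble_policy not in WOBBLE_POLICIES:
            raise InputError(f"unknown wobble policy {wobble_policy!r}")
        stem = reverse_complement(self.anticodon[1:])  # codon positions 1-2
        if wobble_policy == "strict":
            wc = _WC_PARTNER_34.get(self.anticodon[0])
            third = wc if wc is not None else ""
        else:
            third = _CRICK_PARTNERS_34.get(self.anticodon[0], "")
        return tuple(
            stem + b for b in third if GENETIC_CODE.get(stem + b) == self.amino_acid
        )


@dataclass(frozen=True)
class GeneticCode:
    """The standard genetic code (NCBI table 1) as a small value object."""

    table: dict[str, str] = field(default_factory=lambda: dict(GENETIC_CODE))
    stop_codons: frozenset[str] = STOP_CODONS

    def amino_acid(self, codon: str) -> str:
        return self.table[normalize_dna(codon)]

    def synonymous(self, amino_acid: str) -> tuple[str, ...]:
        return synonymous_codons(amino_acid)


def synonymous_codons(amino_acid: str) -> tuple[str, ...]:
    """All sense codons translating to ``amino_acid``, lexicographic order."""
    return tuple(c for c in SENSE_CODONS if GENETIC_CODE[c] == amino_acid)


@dataclass(frozen=True)
class DecodingMap:
    """Codon -> decoding tRNA ids under a named wobble policy."""

    mapping: dict[str, tuple[str, ...]]
    wobble_policy: str

    def trnas_for(self, codon: str) -> tuple[str, ...]:
        return self.mapping.get(normalize_dna(codon), ())

    def codons_for(self, trna_ids) -> frozenset[str]:
        wanted = set(trna_ids)
        return frozenset(
            c for c, ids in self.mapping.items() if wanted.intersection(ids)
        )

    def __len__(self) -> int:
        return len(self.mapping)


def build_decoding_map(
    trnas: list[TRNASpecies], wobble_policy: str = "strict"
) -> DecodingMap:
    """Build the codon->tRNA map reachable from a reference set.

    ``strict`` admits only the exact reverse complement of each anticodon;
    ``crick`` adds the classical position-34 wobble expansions (G34:U/C,
    U34:A/G, I34:U/C/A). Deterministic for a fixed input order.
    """
    if not trnas:
        raise InputError("empty tRNA reference set")
    if wobble_policy not in WOBBLE_POLICIES:
        raise InputError(f"unknown wobble policy {wobble_policy!r}")
    seen: set[str] = set()
    mapping: dict[str, list[str]] = {}
    for trna in trnas:
        if trna.id in seen:
            raise InputError(f"duplicate tRNA id {trna.id!r}")
        seen.add(trna.id)
        trna.validate()
        for codon in trna.decoded_codons_under_policy(wobble_policy):
            mapping.setdefault(codon, []).append(trna.id)
    return DecodingMap(
        mapping={c: tuple(ids) for c, ids in sorted(mapping.items())},
        wobble_policy=wobble_policy,
    )


def translate(cds: str, *, warn_internal_stop: bool = True) -> str:
    """Translate a frame-0 CDS under the standard code.

    The trailing stop codon (if present) is dropped from the protein; internal
    stops are kept as ``*`` and reported with a warning.
    """
    seq = normalize_dna(cds)
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    protein = "".join(GENETIC_CODE[c] for c in codons)
    if warn_internal_stop and "*" in protein:
        pos = [i * 3 for i, aa in enumerate(protein) if aa == "*"]
        warnings.warn(
            f"internal stop codon(s) at nucleotide position(s) {pos}", stacklevel=2
        )
    return protein
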