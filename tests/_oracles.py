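"""Independent brute-force oracles, deliberately written without reusing the
package's own lookup tables or traversal logic wherever a second route exists.
"""

from Bio.Seq import Seq

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_ALL_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]


def translate_oracle(cds: str) -> str:
    """Second, independently sourced translation route (Biopython table 1)."""
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def codon_count_oracle(cds: str) -> dict[str, int]:
    """Stride-3 counting loop; terminal and internal stops excluded."""
    counts: dict[str, int] = {}
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def _pairs_at_34(anticodon34: str, codon3: str, policy: str) -> bool:
    if policy == "strict":
        return _WC.get(anticodon34) == codon3
    allowed = {"A": "T", "C": "G", "G": "CT", "T": "AG", "I": "TCA"}
    return codon3 in allowed.get(anticodon34, "")


def decoding_map_oracle(trnas, policy: str) -> dict[str, list[str]]:
    """Exhaustive codon x tRNA pairing enumeration.

    A tRNA decodes a codon iff codon positions 1-2 Watson-Crick pair with
    anticodon positions 36-35, position 3 pairs with anticodon position 34
    under the policy, and the codon still encodes the tRNA's amino acid.
    """
    mapping: dict[str, list[str]] = {}
    for codon in _ALL_CODONS:
        for trna in trnas:
            ac = trna.anticodon
            if _WC.get(ac[2]) != codon[0] or _WC.get(ac[1]) != codon[1]:
                continue
            if not _pairs_at_34(ac[0], codon[2], policy):
                continue
            if str(Seq(codon).translate()) != trna.amino_acid:
                continue
            mapping.setdefault(codon, []).append(trna.id)
    return mapping


def recoding_plan_oracle(delta_df, mapping: dict[str, list[str]], k_top: int):
    """Per-amino-acid argmin over synonymous escape codons.

    Returns {amino_acid: (sorted source codons, replacement codon)}.
    """
    ordered = sorted(
        zip(delta_df["delta"], delta_df["tRNA_id"]), key=lambda t: (-t[0], t[1])
    )
    top = {tid for _, tid in ordered[:k_top]}
    deltas = dict(zip(delta_df["tRNA_id"], delta_df["delta"]))

    sources_by_aa: dict[str, set[str]] = {}
    for codon, tids in mapping.items():
        if top.intersection(tids):
            sources_by_aa.setdefault(str(Seq(codon).translate()), set()).add(codon)

    plan = {}
    for aa, sources in sources_by_aa.items():
        candidates = []
        for codon in sorted(_ALL_CODONS):
            if str(Seq(codon).translate()) != aa or codon in sources:
                continue
            ds = [deltas[t] for t in mapping.get(codon, []) if t in deltas]
            if ds:
                candidates.append((min(ds), codon))
        if candidates:
            plan[aa] = (sorted(sources), min(candidates)[1])
    return plan


def recode_oracle(cds: str, codon_map: dict[str, str]) -> tuple[str, int]:
    """Loop-based recoding; returns (sequence, substitution count)."""
    out = []
    n_subs = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in codon_map:
            out.append(codon_map[codon])
            n_subs += 1
        else:
            out.append(codon)
    return "".join(out), n_subs
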