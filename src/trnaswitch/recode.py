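"""Synonymous codon-switch redesign of a CDS.

Codons decoded by the tRNAs most affected by the knockout are replaced, amino
acid by amino acid, with the synonymous codon whose decoding tRNA lost the
least modification — rendering translation of the recoded CDS independent of
the methylation while preserving the protein exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from trnaswitch.errors import FrameError, InputError, ValidationError
from trnaswitch.quant import rank_trnas
from trnaswitch.reference import (
    GENETIC_CODE,
    STOP_CODONS,
    DecodingMap,
    GeneticCode,
    normalize_dna,
    translate,
)

logger = logging.getLogger(__name__)

SUBSTITUTION_COLUMNS = ("position", "from_codon", "to_codon")


@dataclass(frozen=True)
class RecodingRule:
    """One amino acid's source codons and their shared replacement."""

    amino_acid: str
    source_codons: frozenset[str]
    replacement_codon: str
    note: str = ""

    def validate(self) -> None:
        if GENETIC_CODE.get(self.replacement_codon) != self.amino_acid:
            raise ValidationError(
                f"replacement {self.replacement_codon} does not encode "
                f"{self.amino_acid}"
            )
        for codon in self.source_codons:
            if GENETIC_CODE.get(codon) != self.amino_acid:
                raise ValidationError(
                    f"source {codon} does not encode {self.amino_acid}"
                )
        if self.replacement_codon in self.source_codons:
            raise ValidationError(
                f"replacement {self.replacement_codon} is also a source codon"
            )


@dataclass(frozen=True)
class RecodingPlan:
    """At most one rule per amino acid; rules are functions on codons."""

    rules: tuple[RecodingRule, ...]

    def validate(self) -> None:
        seen = set()
        for rule in self.rules:
            if rule.amino_acid in seen:
                raise ValidationError(f"multiple rules for {rule.amino_acid}")
            seen.add(rule.amino_acid)
            rule.validate()

    def codon_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rule in self.rules:
            for codon in rule.source_codons:
                out[codon] = rule.replacement_codon
        return out

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "amino_acid": r.amino_acid,
                "source_codons": sorted(r.source_codons),
                "replacement_codon": r.replacement_codon,
                "note": r.note,
            }
            for r in self.rules
        ]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RecodingPlan":
        payload = json.loads(Path(path).read_text())
        plan = cls(
            rules=tuple(
                RecodingRule(
                    amino_acid=r["amino_acid"],
                    source_codons=frozenset(r["source_codons"]),
                    replacement_codon=r["replacement_codon"],
                    note=r.get("note", ""),
                )
                for r in payload
            )
        )
        plan.validate()
        return plan


@dataclass
class RecodedCDS:
    cds_id: str
    sequence: str
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)

    def substitution_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.substitutions, columns=list(SUBSTITUTION_COLUMNS))


def build_recoding_plan(
    delta: pd.DataFrame,
    decoding_map: DecodingMap,
    code: GeneticCode,
    k_top: int,
) -> RecodingPlan:
    """Derive replacement rules from the WT-KO delta ranking.

    For each amino acid with codons decoded by a top-``k_top`` tRNA, the
    source set is exactly those codons and the replacement is the synonymous
    codon whose decoding tRNA has the smallest delta (codon-lexicographic tie
    break), restricted to codons outside the source set whose decoders carry a
    known delta. Amino acids with no escape codon (e.g. Met, Trp) are skipped
    with a warning — a protein-changing substitution is never emitted.
    """
    most_affected, _ = rank_trnas(delta, k_top, 0)
    affected = set(most_affected)
    delta_by_id = dict(zip(delta["tRNA_id"], delta["delta"]))

    source_codons = sorted(decoding_map.codons_for(affected))
    by_aa: dict[str, list[str]] = {}
    for codon in source_codons:
        by_aa.setdefault(code.amino_acid(codon), []).append(codon)

    rules = []
    for amino_acid in sorted(by_aa):
        sources = frozenset(by_aa[amino_acid])
        best: tuple[float, str] | None = None
        for codon in code.synonymous(amino_acid):
            if codon in sources:
                continue
            decoders = [t for t in decoding_map.trnas_for(codon) if t in delta_by_id]
            if not decoders:
                continue
            codon_delta = min(delta_by_id[t] for t in decoders)
            if best is None or (codon_delta, codon) < best:
                best = (codon_delta, codon)
        if best is None:
            logger.warning(
                "%s: no synonymous escape codon with a quantified tRNA — rule "
                "skipped",
                amino_acid,
            )
            continue
        rules.append(
            RecodingRule(
                amino_acid=amino_acid,
                source_codons=sources,
                replacement_codon=best[1],
                note=(
                    f"sources decoded by top-{k_top} most-affected tRNAs; "
                    f"replacement tRNA delta {best[0]:.4g}"
                ),
            )
        )
    plan = RecodingPlan(rules=tuple(rules))
    plan.validate()
    return plan


def recode_cds(cds: str, plan: RecodingPlan, *, cds_id: str = "cds") -> RecodedCDS:
    """Apply a recoding plan to every in-frame codon of a CDS.

    Stop codons are never rewritten (plans cannot target them by
    construction); internal stops only warn. The substitution log records the
    0-based nucleotide position of each rewritten codon's first base, sorted.
    """
    seq = normalize_dna(cds)
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} is not a multiple of 3")
    plan.validate()
    mapping = plan.codon_map()
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    internal = [i * 3 for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
    if internal:
        logger.warning(
            "%s: internal stop codon(s) at position(s) %s — left untouched",
            cds_id,
            internal,
        )
    out = []
    substitutions: list[tuple[int, str, str]] = []
    for i, codon in enumerate(codons):
        replacement = mapping.get(codon)
        if replacement is None:
            out.append(codon)
        else:
            out.append(replacement)
            substitutions.append((i * 3, codon, replacement))
    return RecodedCDS(cds_id=cds_id, sequence="".join(out), substitutions=substitutions)


@dataclass
class VerificationReport:
    protein_identical: bool
    no_residual_sources: bool
    log_consistent: bool
    first_offense: int | None = None  # 0-based nt position of first failure

    @property
    def passed(self) -> bool:
        return self.protein_identical and self.no_residual_sources and self.log_consistent


def verify_recoding(
    original: str, recoded: RecodedCDS, plan: RecodingPlan
) -> VerificationReport:
    """Check protein identity, source-codon elimination, and log consistency.

    Failures are findings, not exceptions; the first offending codon position
    is reported. Log consistency requires that replaying the log on the
    original reproduces the recoded sequence, that every logged substitution
    matches a plan rule, and that no unlogged difference exists.
    """
    original = normalize_dna(original)
    first_offense: int | None = None

    protein_identical = translate(original, warn_internal_stop=False) == translate(
        recoded.sequence, warn_internal_stop=False
    )
    if not protein_identical:
        orig_p = translate(original, warn_internal_stop=False)
        reco_p = translate(recoded.sequence, warn_internal_stop=False)
        for i, (a, b) in enumerate(zip(orig_p, reco_p)):
            if a != b:
                first_offense = i * 3
                break

    sources = set(plan.codon_map())
    residuals = [
        i
        for i in range(0, len(recoded.sequence) - 2, 3)
        if recoded.sequence[i : i + 3] in sources
    ]
    no_residual_sources = not residuals
    if residuals and first_offense is None:
        first_offense = residuals[0]

    mapping = plan.codon_map()
    log_consistent = len(original) == len(recoded.sequence)
    replayed = list(original)
    logged_positions = set()
    if log_consistent:
        for pos, from_codon, to_codon in recoded.substitutions:
            ok = (
                pos % 3 == 0
                and original[pos : pos + 3] == from_codon
                and mapping.get(from_codon) == to_codon
            )
            if not ok:
                log_consistent = False
                first_offense = pos if first_offense is None else first_offense
                break
            replayed[pos : pos + 3] = to_codon
            logged_positions.add(pos)
    if log_consistent:
        replayed_seq = "".join(replayed)
        if replayed_seq != recoded.sequence:
            log_consistent = False
            diff = next(
                i for i in range(len(replayed_seq)) if replayed_seq[i] != recoded.sequence[i]
            )
            pos = diff - diff % 3
            first_offense = pos if first_offense is None else first_offense

    return VerificationReport(
        protein_identical=protein_identical,
        no_residual_sources=no_residual_sources,
        log_consistent=log_consistent,
        first_offense=first_offense,
    )
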