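"""Synthetic tRNA references, RT-signature pileups, and coding sequences.

The generative read model: reverse transcription proceeds 3'->5' along the
tRNA. At the m1A site (pos58), a read drawn from the modified fraction ``s``
terminates with probability ``p_stop`` or miscalls a non-A base with
probability ``p_mis`` (split uniformly over C/G/T); otherwise, and at every
other position, each base call errs independently with background rate
``e_bg``. A stop at pos58 removes coverage from all positions 5' of it.

Pileups are sampled column-wise with multinomial draws, which is
distributionally identical to simulating independent reads one at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from trnaswitch.errors import InputError, ValidationError
from trnaswitch.pileup import BASE_ORDER, Pileup, write_pileups
from trnaswitch.reference import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    TRNASpecies,
    locate_position58,
    reverse_complement,
)

CONDITIONS = ("WT", "KO")

TRUTH_COLUMNS = ("tRNA_id", "condition", "stoichiometry", "n_reads", "seed")

_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class ErrorModel:
    """RT misincorporation/stop parameters plus background error rate."""

    p_mis: float = 0.5
    p_stop: float = 0.2
    e_bg: float = 0.001

    def __post_init__(self) -> None:
        for name in ("p_mis", "p_stop", "e_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.p_mis + self.p_stop > 1.0 + 1e-12:
            raise ValidationError("p_mis + p_stop must not exceed 1")

    def expected_rates(self, s: float) -> tuple[float, float]:
        """Closed-form (mismatch_rate, stop_rate) at the m1A site.

        stop_rate is per read entering the site; mismatch_rate is per read
        contributing a base call (stopped reads call no base).
        """
        p_stop_obs = s * self.p_stop
        p_mismatch = s * self.p_mis + (1.0 - s * (self.p_stop + self.p_mis)) * self.e_bg
        mismatch_rate = p_mismatch / (1.0 - p_stop_obs) if p_stop_obs < 1.0 else 0.0
        return mismatch_rate, p_stop_obs


@dataclass(frozen=True)
class SimulationTruth:
    """Known per-(tRNA, condition) stoichiometries and depths, plus the seed."""

    seed: int
    rows: tuple[tuple[str, str, float, int], ...]  # (tRNA_id, condition, s, n_reads)

    def __post_init__(self) -> None:
        for trna_id, condition, s, n_reads in self.rows:
            if condition not in CONDITIONS:
                raise ValidationError(f"unknown condition {condition!r}")
            if not 0.0 <= s <= 1.0:
                raise ValidationError(f"{trna_id}/{condition}: stoichiometry {s} outside [0, 1]")
            if n_reads < 1:
                raise ValidationError(f"{trna_id}/{condition}: n_reads must be >= 1")
        by_id = self.by_condition()
        for trna_id, conds in by_id.items():
            if set(conds) == set(CONDITIONS) and conds["KO"][0] > conds["WT"][0] + 1e-12:
                warnings.warn(
                    f"{trna_id}: KO stoichiometry exceeds WT — the simulated "
                    "knockout should only remove methylation",
                    stacklevel=2,
                )

    def by_condition(self) -> dict[str, dict[str, tuple[float, int]]]:
        out: dict[str, dict[str, tuple[float, int]]] = {}
        for trna_id, condition, s, n_reads in self.rows:
            out.setdefault(trna_id, {})[condition] = (s, n_reads)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=list(TRUTH_COLUMNS[:4]))
        df["seed"] = self.seed
        return df


def make_truth(
    trna_ids: list[str],
    s_wt: list[float],
    s_ko: list[float],
    n_reads: int,
    seed: int,
) -> SimulationTruth:
    """Assemble a paired WT/KO truth table from aligned stoichiometry lists."""
    if not len(trna_ids) == len(s_wt) == len(s_ko):
        raise InputError("trna_ids, s_wt, and s_ko must have equal lengths")
    rows = [(t, "WT", float(sw), int(n_reads)) for t, sw in zip(trna_ids, s_wt)]
    rows += [(t, "KO", float(sk), int(n_reads)) for t, sk in zip(trna_ids, s_ko)]
    return SimulationTruth(seed=seed, rows=tuple(rows))


def _random_trna_sequence(
    rng: np.random.Generator, codon: str, length: int = 76
) -> tuple[str, int]:
    """Random tRNA-like sequence whose FIRST T-loop motif sits at a fixed spot.

    The anticodon occupies indices 33-35 and the motif nonamer indices 52-60,
    putting the m1A adenosine at index 57 (the canonical position-58 label for
    a 76-mer). Regenerates until no spurious earlier motif match exists.
    """
    anticodon = reverse_complement(codon)
    target = 57
    motif_start = target - 5
    for _ in range(1000):
        seq = rng.choice(list("ACGT"), size=length)
        seq[33:36] = list(anticodon)
        n5, n7, n8 = rng.choice(list("ACGT"), size=3)
        seq[motif_start : motif_start + 9] = list(f"GTTC{n5}A{n7}{n8}C")
        sequence = "".join(seq)
        if locate_position58(sequence) == target:
            return sequence, target
    raise RuntimeError("failed to place a unique T-loop motif")  # pragma: no cover


def generate_trna_reference(
    n_families: int,
    seed: int,
    *,
    codons: list[str] | None = None,
    length: int = 76,
) -> list[TRNASpecies]:
    """Generate ``n_families`` tRNA species with distinct decoded codons.

    Each carries a valid T-loop window whose m1A adenosine is recorded as
    ``pos58``. ``codons`` pins the decoded codons (e.g. the focal
    TCC/AGC/CTG/TTG set); otherwise they are drawn without replacement from
    the 61 sense codons. Reproducible for a fixed seed.
    """
    if not 1 <= n_families <= len(SENSE_CODONS):
        raise InputError(f"n_families must be in [1, {len(SENSE_CODONS)}]")
    rng = np.random.default_rng(seed)
    if codons is None:
        chosen = list(rng.choice(SENSE_CODONS, size=n_families, replace=False))
    else:
        chosen = [c.upper().replace("U", "T") for c in codons]
        if len(chosen) != n_families:
            raise InputError("len(codons) must equal n_families")
        if len(set(chosen)) != len(chosen):
            raise InputError("decoded codons must be distinct across families")
        bad = [c for c in chosen if c not in SENSE_CODONS]
        if bad:
            raise InputError(f"not sense codons: {bad}")
    trnas = []
    for codon in chosen:
        sequence, pos58 = _random_trna_sequence(rng, codon, length=length)
        aa = GENETIC_CODE[codon]
        trna = TRNASpecies(
            id=f"tRNA-{aa}-{codon}",
            decoded_codons=(codon,),
            anticodon=reverse_complement(codon),
            amino_acid=aa,
            sequence=sequence,
            pos58=pos58,
        )
        trna.validate()
        trnas.append(trna)
    return trnas


def _background_column(
    rng: np.random.Generator, coverage: int, ref_base: str, e_bg: float
) -> np.ndarray:
    """Multinomial base-call counts for one column under background error."""
    probs = np.full(4, e_bg / 3.0)
    probs[_BASE_INDEX[ref_base]] = 1.0 - e_bg
    return rng.multinomial(coverage, probs)


def simulate_pileup(
    trna: TRNASpecies,
    s: float,
    n_reads: int,
    model: ErrorModel,
    seed: int | np.random.SeedSequence,
) -> Pileup:
    """Simulate one pileup at methylation stoichiometry ``s``.

    Every read enters pos58 (reads run full-length from the 3' end until a
    stop), so base counts plus stop count there always total ``n_reads``;
    positions 5' of pos58 lose the stopped reads.
    """
    if not 0.0 <= s <= 1.0:
        raise InputError(f"stoichiometry {s} outside [0, 1]")
    if n_reads < 1:
        raise InputError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    seq = trna.sequence
    length = len(seq)
    counts = np.zeros((length, 5), dtype=np.int64)

    pos58 = trna.pos58
    n_stop = 0
    if pos58 is not None:
        n_mod = rng.binomial(n_reads, s)
        n_stop, n_mis, n_thru = rng.multinomial(
            n_mod, [model.p_stop, model.p_mis, 1.0 - model.p_stop - model.p_mis]
        )
        col = np.zeros(5, dtype=np.int64)
        # misincorporations split uniformly over the three non-A bases
        alt = [i for i, b in enumerate(BASE_ORDER) if b != seq[pos58]]
        col[alt] += rng.multinomial(n_mis, [1 / 3] * 3)
        col[:4] += _background_column(
            rng, n_thru + (n_reads - n_mod), seq[pos58], model.e_bg
        )
        col[4] = n_stop
        counts[pos58] = col

    for i in range(length):
        if i == pos58:
            continue
        coverage = n_reads if (pos58 is None or i > pos58) else n_reads - n_stop
        counts[i, :4] = _background_column(rng, coverage, seq[i], model.e_bg)
    return Pileup(trna_id=trna.id, counts=counts)


def simulate_experiment(
    trnas: list[TRNASpecies],
    truth: SimulationTruth,
    model: ErrorModel,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write paired WT/KO pileup TSVs plus the ground-truth table.

    One combined TSV per condition (``pileups_WT.tsv`` / ``pileups_KO.tsv``)
    with a condition column, and ``truth.tsv`` mirroring the truth. Fully
    reproducible from ``truth.seed``.
    """
    by_id = truth.by_condition()
    if not by_id:
        raise InputError("truth covers no tRNAs")
    trna_index = {t.id: t for t in trnas}
    for trna_id, conds in by_id.items():
        if trna_id not in trna_index:
            raise InputError(f"truth references unknown tRNA {trna_id!r}")
        missing = set(CONDITIONS) - set(conds)
        if missing:
            raise InputError(f"{trna_id}: missing condition(s) {sorted(missing)}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ordered_ids = list(by_id)
    for ci, condition in enumerate(CONDITIONS):
        pileups = []
        for ti, trna_id in enumerate(ordered_ids):
            s, n_reads = by_id[trna_id][condition]
            child_seed = np.random.SeedSequence([truth.seed, ci, ti])
            pileups.append(
                simulate_pileup(trna_index[trna_id], s, n_reads, model, child_seed)
            )
        path = outdir / f"pileups_{condition}.tsv"
        write_pileups(pileups, path, condition=condition)
        paths[condition] = path

    truth_path = outdir / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def generate_cds(
    codon_weights: dict[str, float], n_codons: int, seed: int
) -> str:
    """Random CDS of ``n_codons`` sense codons plus a terminal TAA stop.

    Codons are drawn i.i.d. with probability proportional to their weights, so
    expected codon frequencies match the normalized weights; no internal stops
    can occur because stop codons carry no weight.
    """
    if n_codons < 1:
        raise InputError("n_codons must be >= 1")
    weights = {c.upper().replace("U", "T"): w for c, w in codon_weights.items()}
    for codon, w in weights.items():
        if w < 0:
            raise InputError(f"negative weight for codon {codon}")
        if codon in STOP_CODONS and w > 0:
            raise InputError(f"stop codon {codon} cannot carry weight")
        if codon not in GENETIC_CODE:
            raise InputError(f"unknown codon {codon!r}")
    codons = sorted(c for c, w in weights.items() if w > 0 and c in SENSE_CODONS)
    if not codons:
        raise InputError("need at least one positive sense-codon weight")
    probs = np.array([weights[c] for c in codons], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    body = rng.choice(codons, size=n_codons, p=probs)
    return "".join(body) + "TAA"
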