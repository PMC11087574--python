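"""Per-tRNA m1A58 level estimation and WT-KO delta ranking.

The "level" is operationalized two ways and both are reported: the raw
mismatch rate at the m1A site, and a method-of-moments stoichiometry that
inverts the stated generative model using mismatch and stop signals jointly.
With q = stop_rate + mismatch_rate * (1 - stop_rate) — i.e. the fraction of
reads entering the site that either stopped or miscalled —

    E[q] = s * (p_mis + p_stop) * (1 - e_bg) + e_bg

so  s_hat = clip((q - e_bg) / ((p_mis + p_stop) * (1 - e_bg)), 0, 1).

No significance testing is performed: the WT-KO delta is a magnitude
ranking, not a hypothesis test.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from trnaswitch.errors import InputError
from trnaswitch.pileup import BASE_ORDER, Pileup
from trnaswitch.reference import TRNASpecies
from trnaswitch.simulate import ErrorModel

logger = logging.getLogger(__name__)

LEVEL_COLUMNS = (
    "tRNA_id",
    "condition",
    "mismatch_rate",
    "stop_rate",
    "s_hat",
    "coverage",
)
DELTA_COLUMNS = ("tRNA_id", "decoded_codons", "delta", "rank")

DEFAULT_MIN_COVERAGE = 100


def misincorporation_rate(
    pileup: Pileup,
    position: int,
    *,
    ref_base: str = "A",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> tuple[float, float, int] | None:
    """(mismatch_rate, stop_rate, coverage) at one position, or None if thin.

    mismatch_rate = non-reference base calls / base-calling reads;
    stop_rate = stops recorded at the position / reads entering it.
    Positions whose entering coverage is below ``min_coverage`` are flagged
    and excluded (returns None) rather than raising.
    """
    entering = pileup.reads_entering(position)
    if entering < min_coverage:
        logger.warning(
            "%s position %d: coverage %d below threshold %d — excluded",
            pileup.trna_id,
            position,
            entering,
            min_coverage,
        )
        return None
    base_cov = pileup.base_coverage(position)
    ref_idx = BASE_ORDER.index(ref_base)
    mismatches = base_cov - int(pileup.counts[position, ref_idx])
    mismatch_rate = mismatches / base_cov if base_cov > 0 else 0.0
    stop_rate = int(pileup.counts[position, 4]) / entering
    return mismatch_rate, stop_rate, entering


def estimate_stoichiometry(
    mismatch_rate: float, stop_rate: float, model: ErrorModel
) -> float:
    """Method-of-moments inversion of the RT signature; clipped to [0, 1].

    Returns NaN (with a warning) when the model carries no signal channel
    (p_mis + p_stop = 0) yet the observed rates exceed background —
    stoichiometry is then unidentifiable.
    """
    q = stop_rate + mismatch_rate * (1.0 - stop_rate)
    denom = (model.p_mis + model.p_stop) * (1.0 - model.e_bg)
    if denom == 0.0:
        if q > model.e_bg + 1e-12:
            logger.warning(
                "p_mis + p_stop = 0 but combined signal %.4g exceeds background "
                "%.4g: stoichiometry unidentifiable",
                q,
                model.e_bg,
            )
            return math.nan
        return 0.0
    s_hat = (q - model.e_bg) / denom
    logger.debug(
        "s_hat = clip((q - e_bg) / ((p_mis + p_stop)(1 - e_bg))) = "
        "clip((%.6g - %.6g) / %.6g) = %.6g",
        q,
        model.e_bg,
        denom,
        s_hat,
    )
    return min(1.0, max(0.0, s_hat))


def level_table(
    pileups: dict[str, Pileup],
    trnas: list[TRNASpecies],
    model: ErrorModel,
    condition: str,
    *,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-tRNA m1A level table for one condition.

    tRNAs without an annotated m1A site, without a pileup, or below the
    coverage threshold are logged and skipped.
    """
    rows = []
    for trna in trnas:
        if trna.pos58 is None:
            logger.info("%s: no m1A site annotated — skipped", trna.id)
            continue
        pileup = pileups.get(trna.id)
        if pileup is None:
            logger.warning("%s: no pileup in condition %s — skipped", trna.id, condition)
            continue
        ref_base = trna.sequence[trna.pos58]
        rates = misincorporation_rate(
            pileup, trna.pos58, ref_base=ref_base, min_coverage=min_coverage
        )
        if rates is None:
            continue
        mismatch_rate, stop_rate, coverage = rates
        rows.append(
            {
                "tRNA_id": trna.id,
                "condition": condition,
                "mismatch_rate": mismatch_rate,
                "stop_rate": stop_rate,
                "s_hat": estimate_stoichiometry(mismatch_rate, stop_rate, model),
                "coverage": coverage,
            }
        )
    return pd.DataFrame(rows, columns=list(LEVEL_COLUMNS))


def delta_m1a(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    *,
    metric: str = "s_hat",
    trnas: list[TRNASpecies] | None = None,
) -> pd.DataFrame:
    """WT minus KO m1A level per tRNA, densely ranked by decreasing delta.

    ``metric`` selects the level column ("s_hat" default, "mismatch_rate" the
    model-free fallback). tRNAs present in only one condition are excluded and
    logged; an empty intersection is an error.
    """
    if metric not in ("s_hat", "mismatch_rate", "stop_rate"):
        raise InputError(f"unknown metric {metric!r}")
    merged = wt.merge(ko, on="tRNA_id", suffixes=("_wt", "_ko"), how="inner")
    dropped = (set(wt["tRNA_id"]) | set(ko["tRNA_id"])) - set(merged["tRNA_id"])
    for trna_id in sorted(dropped):
        logger.warning("%s present in only one condition — excluded from delta", trna_id)
    if merged.empty:
        raise InputError("WT and KO level tables share no tRNA ids")
    codon_map = (
        {t.id: ";".join(t.decoded_codons) for t in trnas} if trnas is not None else {}
    )
    out = pd.DataFrame(
        {
            "tRNA_id": merged["tRNA_id"],
            "decoded_codons": merged["tRNA_id"].map(lambda i: codon_map.get(i, "")),
            "delta": merged[f"{metric}_wt"] - merged[f"{metric}_ko"],
        }
    )
    out = out.sort_values(["delta", "tRNA_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    out["rank"] = out["delta"].rank(method="dense", ascending=False).astype(int)
    return out


def rank_trnas(
    delta: pd.DataFrame, k_top: int, k_bottom: int
) -> tuple[list[str], list[str]]:
    """Top-k most-affected and bottom-k least-affected tRNA ids.

    Ties in delta break by tRNA id lexicographic order; the two lists are
    guaranteed disjoint because k_top + k_bottom may not exceed the table.
    """
    n = len(delta)
    if k_top < 0 or k_bottom < 0 or k_top + k_bottom > n:
        raise InputError(
            f"k_top={k_top}, k_bottom={k_bottom} out of range for table of size {n}"
        )
    ordered = delta.sort_values(["delta", "tRNA_id"], ascending=[False, True])
    top = list(ordered["tRNA_id"].iloc[:k_top])
    tail = ordered.iloc[n - k_bottom :] if k_bottom else ordered.iloc[:0]
    bottom = list(
        tail.sort_values(["delta", "tRNA_id"], ascending=[True, True])["tRNA_id"]
    )
    return top, bottom
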