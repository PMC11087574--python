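"""End-to-end orchestration: simulate -> quantify -> rank -> profile -> switch.

Each stage writes its outputs into the run directory; the manifest records
the configuration, seed, package version, and a sha256 per output file (no
timestamps, so identical configs yield byte-identical manifests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from trnaswitch import __version__, io
from trnaswitch.config import (
    STAGE_CDS,
    STAGE_REFERENCE,
    STAGE_SIMULATE,
    PipelineConfig,
    stage_seed,
)
from trnaswitch.errors import TrnaswitchError
from trnaswitch.pileup import read_pileups
from trnaswitch.quant import delta_m1a, level_table, rank_trnas
from trnaswitch.recode import build_recoding_plan, recode_cds, verify_recoding
from trnaswitch.reference import SENSE_CODONS, GeneticCode, build_decoding_map
from trnaswitch.simulate import (
    CONDITIONS,
    ErrorModel,
    generate_cds,
    generate_trna_reference,
    make_truth,
    simulate_experiment,
)
from trnaswitch.usage import codon_frequency, vulnerability_report

logger = logging.getLogger(__name__)


class StageError(TrnaswitchError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunResult:
    outdir: Path
    manifest: dict


def demo_cds_weights(config: PipelineConfig) -> dict[str, float]:
    """Uniform sense-codon weights with the focal codons boosted."""
    weights = {c: 1.0 for c in SENSE_CODONS}
    for codon in config.cds_boost_codons:
        weights[codon] = config.cds_boost
    return weights


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunResult:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = ErrorModel(p_mis=config.p_mis, p_stop=config.p_stop, e_bg=config.e_bg)
    files: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("reference"):
        trnas = generate_trna_reference(
            len(config.trna_codons),
            stage_seed(config.seed, STAGE_REFERENCE),
            codons=config.trna_codons,
        )
        files["reference_fasta"] = outdir / "reference.fasta"
        files["reference_tsv"] = outdir / "reference.tsv"
        io.write_trna_reference(trnas, files["reference_fasta"], files["reference_tsv"])

    with stage("simulate"):
        truth = make_truth(
            [t.id for t in trnas],
            config.s_wt,
            config.s_ko,
            config.n_reads,
            stage_seed(config.seed, STAGE_SIMULATE),
        )
        sim_paths = simulate_experiment(trnas, truth, model, outdir)
        files["pileups_WT"] = sim_paths["WT"]
        files["pileups_KO"] = sim_paths["KO"]
        files["truth"] = sim_paths["truth"]

    with stage("quantify"):
        levels = {}
        for condition in CONDITIONS:
            pileups = read_pileups(files[f"pileups_{condition}"])
            levels[condition] = level_table(
                pileups, trnas, model, condition, min_coverage=config.min_coverage
            )
            path = outdir / f"levels_{condition}.tsv"
            levels[condition].to_csv(path, sep="\t", index=False)
            files[f"levels_{condition}"] = path

    with stage("delta"):
        delta = delta_m1a(levels["WT"], levels["KO"], metric=config.metric, trnas=trnas)
        files["delta"] = outdir / "delta.tsv"
        delta.to_csv(files["delta"], sep="\t", index=False)
        top, bottom = rank_trnas(delta, config.k_top, config.k_bottom)
        ranked = pd.DataFrame(
            [{"tRNA_id": t, "group": "most_affected"} for t in top]
            + [{"tRNA_id": t, "group": "least_affected"} for t in bottom],
            columns=["tRNA_id", "group"],
        )
        files["ranked"] = outdir / "ranked.tsv"
        ranked.to_csv(files["ranked"], sep="\t", index=False)

    with stage("cds"):
        if config.cds_path:
            cds_id, cds = io.read_cds(config.cds_path)
        else:
            cds_id, cds = "synthetic_cds", generate_cds(
                demo_cds_weights(config),
                config.n_codons,
                stage_seed(config.seed, STAGE_CDS),
            )
        files["cds"] = outdir / "cds.fasta"
        io.write_cds(cds, files["cds"], cds_id=cds_id)

    with stage("usage"):
        decoding_map = build_decoding_map(trnas, config.wobble_policy)
        usage = codon_frequency(cds, cds_id=cds_id)
        files["usage"] = outdir / "usage.tsv"
        usage.table.to_csv(files["usage"], sep="\t", index=False)
        report = vulnerability_report(
            usage, delta, decoding_map, k_top=config.k_top, m=config.freq_cutoff
        )
        files["vulnerability"] = outdir / "vulnerability.tsv"
        report.to_csv(files["vulnerability"], sep="\t", index=False)

    with stage("plan"):
        plan = build_recoding_plan(delta, decoding_map, GeneticCode(), config.k_top)
        files["plan"] = outdir / "plan.json"
        plan.to_json(files["plan"])

    with stage("switch"):
        recoded = recode_cds(cds, plan, cds_id=cds_id)
        files["recoded"] = outdir / "recoded.fasta"
        io.write_cds(recoded.sequence, files["recoded"], cds_id=f"{cds_id}_recoded")
        files["substitutions"] = outdir / "substitutions.tsv"
        recoded.substitution_frame().to_csv(files["substitutions"], sep="\t", index=False)

    with stage("verify"):
        report = verify_recoding(cds, recoded, plan)
        files["verify"] = outdir / "verify.json"
        files["verify"].write_text(
            json.dumps(dataclasses.asdict(report), indent=2, sort_keys=True) + "\n"
        )
        if not report.passed:
            raise TrnaswitchError(
                f"recoding verification failed at position {report.first_offense}"
            )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "files": {
            name: _sha256(path) for name, path in sorted(files.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(outdir=outdir, manifest=manifest)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
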