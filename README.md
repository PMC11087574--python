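# trnaswitch

Toolkit linking tRNA m¹A58 methylation to codon decoding of an mRNA:

1. **m¹A58 quantification** — estimates the per-tRNA methylation level at the
   T-loop m¹A site from reverse-transcription-signature pileups (mismatch +
   stop read-out), and ranks tRNAs by their wild-type minus knockout decrease.
2. **Codon-usage profiling** — computes the codon-frequency table of a CDS and
   flags "vulnerable" codons: frequent in the CDS *and* decoded by the tRNAs
   that lose the most methylation.
3. **Codon-switch redesign** — rewrites the CDS, replacing codons decoded by
   methylation-sensitive tRNAs with synonymous codons decoded by insensitive
   ones, preserving the protein exactly and emitting a verifiable
   substitution log.
4. **Synthetic data** — generates tRNA references with valid `GUUCNANNC`
   T-loop motifs, paired WT/KO pileups under a configurable RT
   misincorporation/stop error model with known ground-truth stoichiometry,
   and coding sequences with controllable codon composition.

In the bundled demo scenario the tRNAs decoding TCC/AGC (Ser) and CTG/TTG
(Leu) carry the largest methylation losses and the Ser-TCG / Leu-CTT tRNAs
the smallest, so the derived plan is `TCC/AGC → TCG` and `CTG/TTG → CTT`.

## CLI

Every stage is a subcommand; `run-all` chains them:

```sh
# full demo pipeline into ./run (reference → pileups → levels → delta →
# usage → plan → recoded CDS → verification + checksummed manifest)
trnaswitch run-all --seed 1 --out run

# or stage by stage
trnaswitch simulate --seed 1 --out run
trnaswitch quantify --pileups run/pileups_WT.tsv --ref-fasta run/reference.fasta \
    --ref-tsv run/reference.tsv --condition WT --out run/levels_WT.tsv
trnaswitch delta --wt run/levels_WT.tsv --ko run/levels_KO.tsv \
    --ref-fasta run/reference.fasta --ref-tsv run/reference.tsv --out run/delta.tsv
trnaswitch usage --cds run/cds.fasta --out run/usage.tsv
trnaswitch plan --delta run/delta.tsv --ref-fasta run/reference.fasta \
    --ref-tsv run/reference.tsv --k-top 4 --out run/plan.json
trnaswitch switch --in run/cds.fasta --plan run/plan.json \
    --out run/recoded.fasta --log run/substitutions.tsv
trnaswitch verify --original run/cds.fasta --recoded run/recoded.fasta \
    --log run/substitutions.tsv --plan run/plan.json
```

Configuration is a flat TOML file (see `trnaswitch.config.PipelineConfig` for
all keys and defaults); one global `seed` fans out deterministically to every
stage, and reruns with the same config are byte-identical, including the
manifest. A user-supplied CDS FASTA can replace the synthetic one via
`cds_path`.

### File formats

All formats are plain text: FASTA for sequences, TSV for tables
(pileups: `condition, tRNA_id, position, count_A..count_T, count_stop`;
levels: `tRNA_id, condition, mismatch_rate, stop_rate, s_hat, coverage`;
delta: `tRNA_id, decoded_codons, delta, rank`), JSON for recoding plans,
verification reports, and the run manifest.

## Method notes

- The m¹A site is located by the first `GUUCNANNC` T-loop motif match (the
  fixed A, sixth base of the nonamer), not by a hard-coded coordinate.
- Stoichiometry is estimated by method-of-moments inversion of the generative
  model using mismatch and stop signals jointly; the raw mismatch rate is
  retained as a model-free alternative (`--metric mismatch_rate`).
- Codon→tRNA decoding supports a `strict` (exact reverse-complement, default)
  and a `crick` wobble policy (G34:U/C, U34:A/G, I34:U/C/A); wobble
  expansions are always synonymous.
- Replacement codons are chosen per amino acid as the synonymous codon whose
  decoding tRNA has the smallest WT−KO delta; amino acids without a
  synonymous escape (Met, Trp) are never rewritten.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(protein preservation, motif U/T invariance), brute-force oracle comparisons
(decoding map, recoding plan, recoding, codon counting, translation), and
`tests/test_acceptance.py` with one test per acceptance criterion.

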