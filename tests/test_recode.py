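import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import recode_oracle, recoding_plan_oracle, translate_oracle
from conftest import make_delta_frame, trna_for_anticodon
from trnaswitch.errors import FrameError, ValidationError
from trnaswitch.recode import (
    RecodedCDS,
    RecodingPlan,
    RecodingRule,
    build_recoding_plan,
    recode_cds,
    verify_recoding,
)
from trnaswitch.reference import (
    SENSE_CODONS,
    GeneticCode,
    build_decoding_map,
    reverse_complement,
    synonymous_codons,
    translate,
)

FOCAL_DELTAS = {
    "TCC": 0.85, "AGC": 0.80, "CTG": 0.75, "TTG": 0.70,
    "TCG": 0.02, "CTT": 0.01,
    "GCC": 0.30, "GAG": 0.25, "AAG": 0.20, "GAC": 0.15, "TTC": 0.10, "ATC": 0.05,
}

PAPER_PLAN = RecodingPlan(
    rules=(
        RecodingRule("L", frozenset({"TTG", "CTG"}), "CTT"),
        RecodingRule("S", frozenset({"TCC", "AGC"}), "TCG"),
    )
)


@pytest.fixture
def demo_map(demo_trnas):
    return build_decoding_map(demo_trnas, "strict")


class TestRecodingPlanObject:
    def test_paper_plan_valid(self):
        PAPER_PLAN.validate()
        assert PAPER_PLAN.codon_map() == {
            "TTG": "CTT", "CTG": "CTT", "TCC": "TCG", "AGC": "TCG",
        }

    def test_replacement_in_sources_rejected(self):
        rule = RecodingRule("S", frozenset({"TCG"}), "TCG")
        with pytest.raises(ValidationError):
            rule.validate()

    def test_non_synonymous_rule_rejected(self):
        rule = RecodingRule("S", frozenset({"CTG"}), "TCG")
        with pytest.raises(ValidationError):
            rule.validate()

    def test_duplicate_amino_acid_rejected(self):
        plan = RecodingPlan(
            rules=(
                RecodingRule("S", frozenset({"TCC"}), "TCG"),
                RecodingRule("S", frozenset({"AGC"}), "TCT"),
            )
        )
        with pytest.raises(ValidationError):
            plan.validate()

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "plan.json"
        PAPER_PLAN.to_json(path)
        loaded = RecodingPlan.from_json(path)
        assert loaded.codon_map() == PAPER_PLAN.codon_map()


class TestBuildRecodingPlan:
    def test_reproduces_paper_rules(self, demo_map):
        delta = make_delta_frame(FOCAL_DELTAS)
        plan = build_recoding_plan(delta, demo_map, GeneticCode(), k_top=4)
        rules = {r.amino_acid: (set(r.source_codons), r.replacement_codon) for r in plan.rules}
        assert rules == {
            "S": ({"TCC", "AGC"}, "TCG"),
            "L": ({"TTG", "CTG"}, "CTT"),
        }

    def test_empty_top_set_empty_plan(self, demo_map):
        delta = make_delta_frame(FOCAL_DELTAS)
        plan = build_recoding_plan(delta, demo_map, GeneticCode(), k_top=0)
        assert plan.rules == ()

    def test_no_escape_codon_skipped(self, caplog):
        # Met has a single codon: an affected Met tRNA can never be escaped
        trna = trna_for_anticodon("CAT")  # decodes ATG
        dmap = build_decoding_map([trna], "strict")
        delta = make_delta_frame({"ATG": 0.9})
        with caplog.at_level("WARNING"):
            plan = build_recoding_plan(delta, dmap, GeneticCode(), k_top=1)
        assert plan.rules == ()
        assert "no synonymous escape" in caplog.text

    def test_matches_argmin_oracle_on_random_deltas(self):
        trnas = [trna_for_anticodon(reverse_complement(c)) for c in SENSE_CODONS]
        dmap = build_decoding_map(trnas, "strict")
        mapping = {c: list(ids) for c, ids in dmap.mapping.items()}
        rng = np.random.default_rng(21)
        for _ in range(30):
            deltas = {c: float(np.round(rng.uniform(-0.1, 1.0), 4)) for c in SENSE_CODONS}
            delta = make_delta_frame(deltas)
            k_top = int(rng.integers(1, 12))
            plan = build_recoding_plan(delta, dmap, GeneticCode(), k_top)
            expected = recoding_plan_oracle(delta, mapping, k_top)
            got = {
                r.amino_acid: (sorted(r.source_codons), r.replacement_codon)
                for r in plan.rules
            }
            assert got == expected


class TestRecodeCds:
    def test_paper_example(self):
        recoded = recode_cds("ATGTCCAGCTTGCTGTAA", PAPER_PLAN)
        assert recoded.sequence == "ATGTCGTCGCTTCTTTAA"
        assert len(recoded.substitutions) == 4
        assert recoded.substitutions[0] == (3, "TCC", "TCG")

    def test_identity_without_sources(self):
        recoded = recode_cds("ATGGGGAAATAA", PAPER_PLAN)
        assert recoded.sequence == "ATGGGGAAATAA"
        assert recoded.substitutions == []

    def test_frame_error(self):
        with pytest.raises(FrameError):
            recode_cds("ATGT", PAPER_PLAN)

    def test_random_cds_against_oracles(self):
        rng = np.random.default_rng(5)
        cds = "".join(rng.choice(SENSE_CODONS, size=2000)) + "TAA"
        recoded = recode_cds(cds, PAPER_PLAN)
        assert translate(recoded.sequence) == translate_oracle(cds)
        oracle_seq, oracle_n = recode_oracle(cds, PAPER_PLAN.codon_map())
        assert recoded.sequence == oracle_seq
        assert len(recoded.substitutions) == oracle_n

    def test_stop_codons_never_rewritten(self, caplog):
        with caplog.at_level("WARNING"):
            recoded = recode_cds("ATGTAATCCTAA", PAPER_PLAN)  # internal stop
        assert recoded.sequence == "ATGTAATCGTAA"
        assert "internal stop" in caplog.text


def _plans():
    multi = sorted({translate(c) for c in SENSE_CODONS if len(synonymous_codons(translate(c))) >= 2})

    @st.composite
    def plan_strategy(draw):
        aas = draw(st.sets(st.sampled_from(multi), min_size=1, max_size=5))
        rules = []
        for aa in sorted(aas):
            syn = synonymous_codons(aa)
            repl = draw(st.sampled_from(syn))
            others = [c for c in syn if c != repl]
            sources = draw(
                st.sets(st.sampled_from(others), min_size=1, max_size=len(others))
            )
            rules.append(RecodingRule(aa, frozenset(sources), repl))
        return RecodingPlan(tuple(rules))

    return plan_strategy()


_cds_strategy = st.lists(st.sampled_from(SENSE_CODONS), min_size=0, max_size=80).map(
    lambda codons: "".join(codons) + "TAA"
)


class TestRecodingProperties:
    @settings(max_examples=150, deadline=None)
    @given(cds=_cds_strategy, plan=_plans())
    def test_protein_preserved_complete_idempotent(self, cds, plan):
        recoded = recode_cds(cds, plan)
        assert translate(recoded.sequence) == translate(cds)
        sources = set(plan.codon_map())
        body = [recoded.sequence[i : i + 3] for i in range(0, len(recoded.sequence), 3)]
        assert not set(body) & sources
        again = recode_cds(recoded.sequence, plan)
        assert again.sequence == recoded.sequence
        assert again.substitutions == []


class TestVerifyRecoding:
    def test_paper_recoding_passes(self):
        cds = "ATGTCCAGCTTGCTGGGGTAA"
        recoded = recode_cds(cds, PAPER_PLAN)
        report = verify_recoding(cds, recoded, PAPER_PLAN)
        assert report.passed
        assert report.first_offense is None

    def test_tampered_codon_detected(self):
        cds = "ATGTCCAGCTTGCTGGGGTAA"
        recoded = recode_cds(cds, PAPER_PLAN)
        seq = list(recoded.sequence)
        seq[15:18] = "CTG"  # overwrite the GGG codon at nt 15 with a source codon
        tampered = RecodedCDS(
            cds_id=recoded.cds_id, sequence="".join(seq),
            substitutions=recoded.substitutions,
        )
        report = verify_recoding(cds, tampered, PAPER_PLAN)
        assert not report.passed
        assert not report.log_consistent
        assert report.first_offense == 15  # names the tampered codon position

    def test_protein_change_detected(self):
        cds = "ATGTCCTAA"
        recoded = recode_cds(cds, PAPER_PLAN)
        mutant = RecodedCDS(
            cds_id="cds", sequence="ATGGCGTAA", substitutions=recoded.substitutions
        )
        report = verify_recoding(cds, mutant, PAPER_PLAN)
        assert not report.protein_identical

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for trial in range(100):
            codons = rng.choice(SENSE_CODONS, size=int(rng.integers(1, 40)))
            cds = "".join(codons) + "TAA"
            recoded = recode_cds(cds, PAPER_PLAN)
            if trial % 3 == 0 and recoded.substitutions:
                # tamper: flip one substituted codon back
                pos, from_codon, _ = recoded.substitutions[
                    int(rng.integers(len(recoded.substitutions)))
                ]
                seq = list(recoded.sequence)
                seq[pos : pos + 3] = from_codon
                recoded = RecodedCDS(
                    cds_id="cds", sequence="".join(seq),
                    substitutions=recoded.substitutions,
                )
            report = verify_recoding(cds, recoded, PAPER_PLAN)
            # independent diff-based checker
            mapping = PAPER_PLAN.codon_map()
            expected_seq, _ = recode_oracle(cds, mapping)
            ok = (
                expected_seq == recoded.sequence
                and translate_oracle(recoded.sequence) == translate_oracle(cds)
            )
            assert report.passed == ok
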