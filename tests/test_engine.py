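"""PM5 prediction engine: lookup, rules a-e, bands, leave-one-out."""

from __future__ import annotations

import itertools

import pytest

from conftest import make_record
from oracle import brute_force_band, brute_force_predict
from pm5calib.curation import Dichotomous
from pm5calib.engine import (
    Band,
    LookupSet,
    Source,
    assign_band,
    colocated_del,
    definition,
    predict,
    run_predictions,
)
from pm5calib.errors import ConfigurationError
from pm5calib.insilico import annotate_physiochemical
from pm5calib.model import Cohort
from pm5calib.simulate import CohortConfig, generate_cohort


def _lookup(records, source=Source.MAVE):
    return LookupSet.build(Cohort(records), source)


class TestColocatedDel:
    def test_leave_one_out_at_substitution_level(self):
        lookup = _lookup(
            [
                make_record(codon=42, ref="A", alt="D", functional="DEL"),
                make_record(codon=42, ref="A", alt="W", functional="DEL"),
            ]
        )
        exam = make_record(codon=42, ref="A", alt="W")
        assert [r.alt_aa for r in colocated_del(exam, lookup)] == ["D"]

    def test_no_codon_entry_gives_empty_list(self):
        exam = make_record(codon=99)
        assert colocated_del(exam, _lookup([])) == []

    def test_distinct_substitutions_all_returned(self):
        lookup = _lookup(
            [
                make_record(codon=42, ref="A", alt="D", functional="DEL"),
                make_record(codon=42, ref="A", alt="G", functional="DEL"),
            ]
        )
        exam = make_record(codon=42, ref="A", alt="W")
        assert len(colocated_del(exam, lookup)) == 2


class TestPredict:
    def test_no_colocated_del_always_tol(self):
        exam = make_record(codon=10)
        lookup = _lookup([])
        for letter in "abcde":
            tool = None if letter in "ab" else "BLOSUM62"
            assert predict(exam, lookup, definition(letter, tool)) is Dichotomous.TOL

    def test_blosum62_comparison_hand_case(self):
        # reference A->D scores -2 on BLOSUM62; exam A->W scores -3: more damaging
        ref = make_record(codon=42, ref="A", alt="D", functional="DEL")
        exam = make_record(codon=42, ref="A", alt="W")
        annotate_physiochemical(Cohort([ref, exam]))
        assert exam.tool_scores["BLOSUM62"] == -3
        assert ref.tool_scores["BLOSUM62"] == -2
        lookup = _lookup([ref])
        assert predict(exam, lookup, definition("c", "BLOSUM62")) is Dichotomous.DEL

    def test_rule_e_needs_two_comparisons_met(self):
        refs = [
            make_record(codon=9, ref="A", alt="D", functional="DEL", tools={"REVEL": 0.2}),
            make_record(codon=9, ref="A", alt="G", functional="DEL", tools={"REVEL": 0.9}),
        ]
        exam = make_record(codon=9, ref="A", alt="W", tools={"REVEL": 0.5})
        lookup = _lookup(refs)
        assert predict(exam, lookup, definition("d", "REVEL")) is Dichotomous.DEL
        assert predict(exam, lookup, definition("e", "REVEL")) is Dichotomous.TOL

    def test_missing_reference_score_counts_colocated_but_never_met(self):
        refs = [
            make_record(codon=9, ref="A", alt="D", functional="DEL", tools={}),
            make_record(codon=9, ref="A", alt="G", functional="DEL", tools={}),
        ]
        exam = make_record(codon=9, ref="A", alt="W", tools={"REVEL": 0.9})
        lookup = _lookup(refs)
        assert predict(exam, lookup, definition("b")) is Dichotomous.DEL
        assert predict(exam, lookup, definition("d", "REVEL")) is Dichotomous.TOL


class TestAssignBand:
    def test_exhaustive_over_n_del_and_n_met(self):
        """Band rule against enumeration over all (n_del, n_met) pairs."""
        for n_del, n_met in itertools.product(range(4), range(4)):
            if n_met > n_del:
                continue
            refs = [
                make_record(
                    codon=5, ref="A", alt=alt, functional="DEL",
                    tools={"REVEL": 0.2 if i < n_met else 0.9},
                )
                for i, alt in enumerate("DGHK"[:n_del])
            ]
            exam = make_record(codon=5, ref="A", alt="W", tools={"REVEL": 0.5})
            band = assign_band(exam, _lookup(refs), "REVEL").band
            if n_del == 1 and n_met == 1:
                assert band is Band.X
            elif n_del >= 2 and n_met >= 1:
                assert band is Band.Y
            else:
                assert band is Band.BASELINE


def _synthetic(n_codons=12, seed=0, sparse=False):
    config = CohortConfig(
        n_codons=n_codons,
        seed=seed,
        variants_per_codon=(1, 4),
        p_clinical_label_given_del=0.2 if sparse else 0.8,
        p_clinical_label_given_tol=0.05 if sparse else 0.3,
    )
    return annotate_physiochemical(generate_cohort(config))


class TestRunPredictions:
    def test_unsupported_combination_rejected(self, toy_cohort):
        with pytest.raises(ConfigurationError, match="MAVE/CLINVAR"):
            run_predictions(toy_cohort, "MAVE", "CLINVAR", [definition("a")])

    def test_no_clinical_labels_means_all_tol(self):
        cohort = Cohort(
            [make_record(codon=10 + i, functional="DEL") for i in range(5)]
        )
        table = run_predictions(cohort, "CLINVAR", "MAVE", [definition("a")])
        assert (table["prediction"] == "TOL").all()

    def test_own_del_label_not_own_evidence_when_sources_shared(self):
        # one DEL at a codon: under MAVE/MAVE lookup it must not see itself
        cohort = Cohort(
            [
                make_record(codon=7, ref="A", alt="V", functional="DEL"),
                make_record(codon=8, ref="R", alt="Q", functional="TOL"),
            ]
        )
        table = run_predictions(cohort, "MAVE", "MAVE", [definition("a")])
        assert (table["prediction"] == "TOL").all()

    def test_stringency_nesting_on_fixtures(self):
        """DEL(e) <= DEL(d) <= DEL(b) and DEL(d) <= DEL(c) <= DEL(a), per tool."""
        for seed in range(3):
            cohort = _synthetic(seed=seed)
            defs = {
                "a": definition("a"),
                "b": definition("b"),
                "c": definition("c", "REVEL"),
                "d": definition("d", "REVEL"),
                "e": definition("e", "REVEL"),
            }
            table = run_predictions(cohort, "CLINVAR", "MAVE", defs.values())
            del_sets = {
                letter: set(
                    table[(table["definition"] == letter) & (table["prediction"] == "DEL")][
                        "substitution"
                    ]
                )
                for letter in defs
            }
            assert del_sets["e"] <= del_sets["d"] <= del_sets["b"] <= del_sets["a"]
            assert del_sets["d"] <= del_sets["c"] <= del_sets["a"]

    def test_band_partition_exhaustive_and_exclusive(self):
        cohort = _synthetic(seed=4)
        table = run_predictions(
            cohort, "CLINVAR", "MAVE", [], band_tools=("REVEL", "BLOSUM62")
        )
        for _, group in table.groupby("tool"):
            assert set(group["band"]) <= {"x", "y", "baseline"}
            assert group["substitution"].is_unique

    @pytest.mark.parametrize("lookup_source", ["CLINVAR", "MAVE"])
    def test_engine_matches_brute_force_oracle(self, lookup_source):
        """Equivalence with direct enumeration on cohorts of <= 50 variants."""
        rules = [
            ("a", 1, 0, None),
            ("b", 2, 0, None),
            ("c", 1, 1, "REVEL"),
            ("c", 1, 1, "BLOSUM62"),
            ("d", 2, 1, "REVEL"),
            ("e", 2, 2, "BLOSUM62"),
        ]
        truth = "MAVE" if lookup_source == "MAVE" else "MAVE"
        for seed in range(5):
            cohort = _synthetic(n_codons=10, seed=seed)
            assert len(cohort) <= 50
            defs = [definition(letter, tool) for letter, _, _, tool in rules]
            table = run_predictions(
                cohort, lookup_source, truth, defs, band_tools=("REVEL",)
            )
            for row in table.itertuples():
                variant = next(
                    r for r in cohort if r.label == row.substitution
                )
                if row.kind == "definition":
                    letter = row.definition
                    matching = [
                        r for r in rules
                        if r[0] == letter and (r[3] or "-") == row.tool
                    ]
                    _, min_del, n_met, tool = matching[0]
                    expected = brute_force_predict(
                        variant, cohort.records, lookup_source, min_del, n_met, tool
                    )
                    assert row.prediction == expected, (row.substitution, letter)
                else:
                    expected = brute_force_band(
                        variant, cohort.records, lookup_source, row.tool
                    )
                    assert row.band == expected
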