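"""Confusion matrices, Haldane-Anscombe correction, likelihood ratios."""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pm5calib.errors import ValidationError
from pm5calib.evaluate import (
    ConfusionMatrix,
    Strength,
    build_confusion,
    evaluate_all,
    evidence_points,
    haldane_anscombe,
    negative_lr,
    positive_lr,
    round1,
)


def _corrected(tp, fn, fp, tn):
    return haldane_anscombe(ConfusionMatrix(tp, fn, fp, tn))


class TestHaldaneAnscombe:
    def test_adds_half_to_each_cell(self):
        cm = _corrected(245, 556, 244, 6496)
        assert cm.cells() == (245.5, 556.5, 244.5, 6496.5)
        assert cm.corrected

    def test_rescues_all_zero_matrix(self):
        assert _corrected(0, 0, 0, 0).cells() == (0.5, 0.5, 0.5, 0.5)

    def test_double_correction_rejected(self):
        with pytest.raises(ValidationError):
            haldane_anscombe(_corrected(1, 2, 3, 4))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestPositiveLr:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((245, 556, 244, 6496), 8.4),  # sensitivity/FP-rate on corrected cells
            ((10, 10, 10, 10), 1.0),
            ((83, 662, 10, 6698), 71.5),
        ],
    )
    def test_point_estimates(self, cells, expected):
        assert round1(positive_lr(_corrected(*cells)).estimate) == expected

    def test_ci_log_method(self):
        result = positive_lr(_corrected(245, 556, 244, 6496))
        assert result.rounded() == (8.4, 7.2, 9.9)

    def test_uncorrected_matrix_rejected(self):
        with pytest.raises(ValidationError):
            positive_lr(ConfusionMatrix(1, 2, 3, 4))

    def test_swapping_cells_inverts_plr(self):
        a = positive_lr(_corrected(30, 70, 5, 95)).estimate
        b = positive_lr(_corrected(5, 95, 30, 70)).estimate
        assert a * b == pytest.approx(1.0)

    def test_monotone_in_tn_and_fp_mass(self):
        base = positive_lr(_corrected(30, 70, 5, 95)).estimate
        assert positive_lr(_corrected(30, 70, 5, 195)).estimate > base
        assert positive_lr(_corrected(30, 70, 15, 95)).estimate < base


class TestNegativeLr:
    def test_symmetric_matrix_is_one(self):
        assert negative_lr(_corrected(10, 10, 10, 10)).estimate == pytest.approx(1.0)

    def test_printed_orientation_specificity_over_fn_rate(self):
        # (6496.5/6741)/(556.5/802) by hand
        result = negative_lr(_corrected(245, 556, 244, 6496))
        assert result.estimate == pytest.approx(1.3888, abs=1e-3)

    def test_perfect_classifier(self):
        result = negative_lr(_corrected(50, 0, 0, 50))
        assert result.estimate == pytest.approx((50.5 / 51) / (0.5 / 51))
        assert round(result.estimate) == 101


@given(
    st.tuples(
        st.integers(1, 400), st.integers(1, 400), st.integers(1, 400), st.integers(1, 400)
    ),
    st.integers(2, 10),
)
def test_ci_contains_estimate_and_narrows_with_scale(cells, factor):
    cm = _corrected(*cells)
    result = positive_lr(cm)
    assert result.ci_low <= result.estimate <= result.ci_high
    scaled = positive_lr(_corrected(*(c * factor for c in cells)))
    log_width = math.log(result.ci_high / result.ci_low)
    scaled_width = math.log(scaled.ci_high / scaled.ci_low)
    assert scaled_width < log_width


class TestEvidencePoints:
    def test_unit_lr_gives_zero_points(self):
        points, label = evidence_points(1.0)
        assert points == 0
        assert label is Strength.NONE

    def test_band_level_lrs_map_to_moderate_and_strong(self):
        points_x, label_x = evidence_points(16.3)
        assert points_x > 3 and label_x is Strength.MODERATE
        points_y, label_y = evidence_points(71.5)
        assert points_y > 5 and label_y is Strength.STRONG

    def test_bin_edges(self):
        # odds of 350^(k/8) sit exactly on the k-point boundaries
        for k, label in [(1, Strength.SUPPORTING), (2, Strength.MODERATE),
                         (4, Strength.STRONG), (8, Strength.VERY_STRONG)]:
            points, got = evidence_points(350.0 ** (k / 8))
            assert points == pytest.approx(k)
            assert got is label

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            evidence_points(0.0)


def _prediction_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "codon", "substitution", "kind", "definition", "tool",
                 "n_colocated_del", "n_met", "prediction", "band", "truth"],
    )


class TestBuildConfusion:
    def test_perfect_predictor_has_no_errors(self):
        rows = [
            ("G1", i, f"A{i}V", "definition", "a", "-", 1, None, t, None, t)
            for i, t in enumerate(["DEL"] * 8 + ["TOL"] * 12)
        ]
        cm = build_confusion(_prediction_frame(rows))
        assert (cm.fp, cm.fn) == (0, 0)
        assert cm.total == 20

    def test_all_tol_predictor(self):
        rows = [
            ("G1", i, f"A{i}V", "definition", "a", "-", 0, None, "TOL", None, t)
            for i, t in enumerate(["DEL"] * 4 + ["TOL"] * 6)
        ]
        cm = build_confusion(_prediction_frame(rows))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 4, 6)

    def test_band_cell_excludes_other_band(self):
        rows = [
            ("G1", 1, "A1V", "band", None, "REVEL", 1, 1, None, "x", "DEL"),
            ("G1", 2, "A2V", "band", None, "REVEL", 3, 2, None, "y", "DEL"),
            ("G1", 3, "A3V", "band", None, "REVEL", 0, 0, None, "baseline", "TOL"),
            ("G1", 4, "A4V", "band", None, "REVEL", 0, 0, None, "baseline", "DEL"),
        ]
        x = build_confusion(_prediction_frame(rows), band="x")
        assert (x.tp, x.fn, x.fp, x.tn) == (1, 1, 0, 1)  # the y row is excluded
        y = build_confusion(_prediction_frame(rows), band="y")
        assert (y.tp, y.fn, y.fp, y.tn) == (1, 1, 0, 1)

    def test_non_dichotomous_truth_rejected(self):
        rows = [("G1", 1, "A1V", "definition", "a", "-", 0, None, "TOL", None, "MISSING")]
        with pytest.raises(ValidationError):
            build_confusion(_prediction_frame(rows))


class TestEvaluateAll:
    @staticmethod
    def _table():
        rows = []
        for gene, n_del in (("G1", 5), ("G2", 3)):
            for i in range(12):
                truth = "DEL" if i < n_del else "TOL"
                pred = "DEL" if (i % 2 == 0 and i < 8) else "TOL"
                band = "x" if i == 0 else ("y" if i == 2 else "baseline")
                rows.append((gene, i + 2, f"A{i+2}V", "definition", "a", "-",
                             1, None, pred, None, truth))
                rows.append((gene, i + 2, f"A{i+2}V", "band", None, "REVEL",
                             1, 1, None, band, truth))
        return _prediction_frame(rows)

    def test_combined_scope_is_cellwise_sum(self):
        results = evaluate_all(self._table())
        binary = results[results["analysis"] == "a"].set_index("scope")
        for cell in ("tp", "fn", "fp", "tn"):
            assert (
                binary.loc["combined", cell]
                == binary.loc["G1", cell] + binary.loc["G2", cell]
            )

    def test_band_rows_share_baseline_fn_tn(self):
        results = evaluate_all(self._table())
        banded = results[results["analysis"].str.startswith("band_")]
        for (_, _), group in banded.groupby(["scope", "tool"]):
            assert group["fn"].nunique() == 1
            assert group["tn"].nunique() == 1

    def test_all_baseline_cohort_has_empty_band_cells(self):
        rows = [
            ("G1", i, f"A{i}V", "band", None, "REVEL", 0, 0, None, "baseline",
             "DEL" if i % 3 == 0 else "TOL")
            for i in range(2, 12)
        ]
        results = evaluate_all(_prediction_frame(rows))
        assert (results["tp"] == 0).all()
        assert (results["fp"] == 0).all()
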