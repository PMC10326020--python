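"""Variance filtering, centering/normalization, group dropping, stratification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crosslasso.containers import StratificationRule
from crosslasso.preprocess import (
    drop_condition_group,
    preprocess,
    stratify_samples,
    variance_filter,
)

from conftest import make_matrix, make_pair


class TestVarianceFilter:
    def test_keeps_highest_variance_rows(self, rng):
        values = np.outer(np.arange(10), [0.0, 1.0, 2.0])  # variance grows with row idx
        m = make_matrix(values)
        out, report = variance_filter(m, 0.2)
        assert out.analyte_ids == ["a8", "a9"]
        assert report.n_input_rows == 10 and report.n_retained_rows == 2

    def test_fraction_one_is_identity(self, rng):
        m = make_matrix(rng.standard_normal((6, 4)))
        out, _ = variance_filter(m, 1.0)
        assert np.array_equal(out.values, m.values)
        assert out.analyte_ids == m.analyte_ids

    def test_ties_broken_by_input_order(self):
        m = make_matrix(np.tile([1.0, 2.0, 3.0], (4, 1)))  # identical variances
        out, _ = variance_filter(m, 0.5)
        assert out.analyte_ids == ["a0", "a1"]

    def test_ceil_keeps_at_least_one_row(self):
        m = make_matrix(np.random.default_rng(0).standard_normal((7, 3)))
        out, _ = variance_filter(m, 0.01)
        assert out.n_analytes == 1

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.2])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            variance_filter(make_matrix([[1.0, 2.0]]), fraction)

    def test_composition_matches_combined_fraction(self, rng):
        # without ties crossing the cut, filtering at f1 then f2 == filtering at f1*f2
        m = make_matrix(rng.standard_normal((20, 6)))
        once, _ = variance_filter(m, 0.5 * 0.4)
        step1, _ = variance_filter(m, 0.5)
        step2, _ = variance_filter(step1, 0.4)
        assert step2.analyte_ids == once.analyte_ids


class TestPreprocess:
    def test_hand_computed_two_by_two(self):
        # col-center -> [[-2,-.5],[2,.5]]; row-center -> [[-.75,.75],[.75,-.75]];
        # row norm 1.06066 -> +-0.70711
        pair = make_pair([[1, 2], [5, 3]], [[1, 2], [5, 3]])
        out = preprocess(pair)
        expect = np.array([[-1, 1], [1, -1]]) / np.sqrt(2)
        np.testing.assert_allclose(out.left.values, expect, atol=1e-12)

    def test_constant_offset_rows_dropped_and_reported(self):
        # [[1,3],[2,4]]: both rows identical up to an offset -> zero after centering
        pair = make_pair([[1, 3], [2, 4]], [[1, 0], [0, 1]])
        out, report = preprocess(pair, return_report=True)
        assert out.left.n_analytes == 0
        assert report["left"] == ["y0", "y1"]
        assert report["right"] == []

    def test_rows_have_zero_mean_unit_norm(self, rng):
        pair = make_pair(rng.standard_normal((5, 8)), rng.standard_normal((7, 8)))
        out = preprocess(pair)
        for m in (out.left, out.right):
            np.testing.assert_allclose(m.values.sum(axis=1), 0, atol=1e-12)
            np.testing.assert_allclose(np.linalg.norm(m.values, axis=1), 1, atol=1e-12)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            preprocess(make_pair([[1.0]], [[2.0]]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_invariants_hold_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        pair = make_pair(rng.standard_normal((4, 6)) * 10 + 5,
                         rng.standard_normal((5, 6)))
        out = preprocess(pair)
        for m in (out.left, out.right):
            assert np.all(np.isfinite(m.values))
            np.testing.assert_allclose(m.values.sum(axis=1), 0, atol=1e-10)
            np.testing.assert_allclose(np.linalg.norm(m.values, axis=1), 1, atol=1e-12)


class TestDropConditionGroup:
    def _pair(self):
        groups = {"c0": "TGFB1", "c1": "TGFB1", "c2": "EGF", "c3": "EGF",
                  "c4": "OSM", "c5": "OSM", "c6": "OSM", "c7": "OSM"}
        rng = np.random.default_rng(0)
        return make_pair(rng.standard_normal((3, 8)), rng.standard_normal((3, 8)),
                         condition_groups=groups)

    def test_drop_removes_group_columns_from_both(self):
        out = drop_condition_group(self._pair(), "TGFB1")
        assert out.n_conditions == 6
        assert all(not c.startswith("c0") and c != "c1" for c in out.condition_ids)
        assert out.left.condition_ids == out.right.condition_ids

    def test_column_conservation(self):
        pair = self._pair()
        out = drop_condition_group(pair, "OSM")
        assert out.n_conditions == pair.n_conditions - 4

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            drop_condition_group(self._pair(), "BMP2")

    def test_too_few_remaining_columns_rejected(self):
        groups = {"c0": "A", "c1": "A", "c2": "A"}
        pair = make_pair(np.ones((1, 3)) * [[1, 2, 3]], [[4, 5, 6]],
                         condition_groups=groups)
        with pytest.raises(ValueError, match="fewer than 2"):
            drop_condition_group(pair, "A")


class TestStratifySamples:
    def _expr(self):
        # samples s0..s3, markers HER2/ER/PR in FPKM-like units
        values = np.array([
            [2**7.5 - 1, 2**6.0 - 1, 0.0, 2**7.8 - 1],  # HER2
            [0.0, 2**4.0 - 1, 0.5, 2**3.5 - 1],          # ER
            [0.0, 2**3.6 - 1, 0.2, 0.1],                 # PR
        ])
        return make_matrix(values, analyte_ids=["HER2", "ER", "PR"],
                           condition_ids=["s0", "s1", "s2", "s3"], assay="rnaseq")

    def test_receptor_amplified_rule(self):
        hits = stratify_samples(self._expr(), [StratificationRule("HER2", "log2p1", ">", 7)])
        assert hits == ["s0", "s3"]

    def test_triple_low_conjunction(self):
        rules = [
            StratificationRule("HER2", "log2p1", "<", 7),
            StratificationRule("ER", "log2p1", "<", 1),
            StratificationRule("PR", "log2p1", "<", 1),
        ]
        assert stratify_samples(self._expr(), rules) == ["s2"]

    def test_empty_rules_select_all(self):
        assert stratify_samples(self._expr(), []) == ["s0", "s1", "s2", "s3"]

    def test_missing_marker_rejected(self):
        with pytest.raises(ValueError, match="EGFR"):
            stratify_samples(self._expr(), [StratificationRule("EGFR", "identity", ">", 0)])
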