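"""NRD statistic and ratio-vs-expression correlation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slofe.io import ExpressionTable
from slofe.ratio import GeneRatio, RatioPrediction
from slofe.validate import correlate, nrd, validate_sls

from .test_ratio import control, operon


class TestNRD:
    def test_worked_values(self):
        """The two printed read-depth pairs: 0.976 (~97%) and 0.871 (~87%)."""
        assert nrd(3094, 74) == pytest.approx(0.97608, abs=1e-4)
        assert nrd(18300, 2367) == pytest.approx(0.87066, abs=1e-4)

    def test_equal_depths_give_zero(self):
        for x in (1.0, 7.0, 1e6):
            assert nrd(x, x) == 0.0

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValueError):
            nrd(0.0, 0.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            nrd(-1.0, 5.0)

    @given(
        st.floats(0, 1e9, allow_nan=False),
        st.floats(0, 1e9, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        if max(a, b) == 0:
            return
        v = nrd(a, b)
        assert -1.0 <= v <= 1.0
        assert nrd(b, a) == pytest.approx(-v, abs=1e-12)

    def test_zero_downstream_depth_saturates(self):
        assert nrd(123.0, 0.0) == 1.0


class TestValidateSLs:
    def _op(self):
        return operon(3, [control(-30.0, 0, "SSL"), control(-20.0, 1, "STSL"),
                          control(-12.0, 2, "TSL", terminal=True)])

    def test_records_only_for_stabilizers(self):
        depths = ExpressionTable({"g1": 1000, "g2": 100, "g3": 10})
        records = validate_sls([self._op()], depths)
        assert len(records) == 2  # the terminal TSL is not assessed

    def test_threshold_and_status(self):
        depths = ExpressionTable({"g1": 1000, "g2": 400, "g3": 10})
        records = validate_sls([self._op()], depths)
        assert [r.passed for r in records] == [True, True]
        tight = validate_sls([self._op()], depths, threshold=0.7)
        assert [r.passed for r in tight] == [False, True]

    def test_near_one_threshold_requires_zero_downstream(self):
        # passing is strict (nrd > threshold), so at a threshold just under 1
        # only a saturated record (rd3 = 0, nrd = 1) can pass
        depths = ExpressionTable({"g1": 1000, "g2": 0, "g3": 10})
        records = validate_sls([self._op()], depths, threshold=0.999)
        assert records[0].passed is True  # rd3 == 0
        assert records[1].passed is False

    def test_missing_depth_reported_as_no_data(self):
        depths = ExpressionTable({"g1": 1000})
        records = validate_sls([self._op()], depths)
        assert [r.status for r in records] == ["no_data", "no_data"]

    def test_both_zero_flagged_undefined(self):
        depths = ExpressionTable({"g1": 0, "g2": 0, "g3": 0})
        records = validate_sls([self._op()], depths)
        assert records[0].status == "undefined"

    def test_dg_rescue_flag(self):
        # depths ordered with |dG| but the first step is shallow (<0.5 NRD)
        depths = ExpressionTable({"g1": 1000, "g2": 700, "g3": 100})
        plain = validate_sls([self._op()], depths)
        rescued = validate_sls([self._op()], depths, dg_rescue=True)
        assert plain[0].passed is False
        assert rescued[0].passed is True and rescued[0].status == "rescued"

    def test_fixture_planted_stabilizers_all_pass(self, fixture, pipeline_result):
        """Depths generated from the planted |dG| put every stabilizer SL
        above the 0.5 NRD threshold at noise sigma 0.1."""
        records = pipeline_result.validations
        stab = fixture.truth_sls[
            (~fixture.truth_sls.terminal)
            & fixture.truth_sls.uclass.isin(["SSL", "STSL"])
        ]
        assert len(records) == len(stab)
        assert all(r.passed for r in records)


def pred_from_values(values):
    return RatioPrediction(
        1, tuple(GeneRatio(f"g{i+1}", "sl", -10.0, v) for i, v in enumerate(values))
    )


class TestCorrelate:
    def test_affine_match_is_perfect(self):
        pred = pred_from_values([1.0, 0.8, 0.5, 0.2])
        expr = ExpressionTable(
            {f"g{i+1}": 10 ** (3 + 2 * v) for i, v in enumerate([1.0, 0.8, 0.5, 0.2])}
        )
        assert correlate(pred, expr).r == pytest.approx(1.0)

    def test_anti_ordered_is_minus_one(self):
        pred = pred_from_values([1.0, 0.6, 0.2])
        expr = ExpressionTable({"g1": 10, "g2": 1000, "g3": 100000})
        assert correlate(pred, expr).r == pytest.approx(-1.0)

    def test_scale_invariance(self):
        pred = pred_from_values([1.0, 0.7, 0.4, 0.1])
        expr = {f"g{i+1}": v for i, v in enumerate([900.0, 300.0, 80.0, 4.0])}
        r1 = correlate(pred, ExpressionTable(expr)).r
        r2 = correlate(pred, ExpressionTable({g: 50 * v for g, v in expr.items()})).r
        assert r1 == pytest.approx(r2)

    def test_fewer_than_three_genes_not_computed(self):
        pred = pred_from_values([1.0, 0.5])
        expr = ExpressionTable({"g1": 10, "g2": 5})
        rep = correlate(pred, expr)
        assert rep.r is None and "fewer" in rep.reason

    def test_zero_variance_not_computed(self):
        pred = pred_from_values([1.0, 1.0, 1.0])
        expr = ExpressionTable({"g1": 10, "g2": 20, "g3": 30})
        assert correlate(pred, expr).r is None

    def test_zero_abundance_excluded_unless_pseudocount(self):
        pred = pred_from_values([1.0, 0.6, 0.3, 0.0])
        expr = ExpressionTable({"g1": 1000, "g2": 100, "g3": 10, "g4": 0})
        assert correlate(pred, expr).n_genes == 3
        assert correlate(pred, expr, pseudocount=1.0).n_genes == 4

    def test_noisy_simulation_recovers_high_correlation(self):
        """Ratio vs log10 expression with sigma=0.1 noise: r > 0.9 in at
        least 95 of 100 replicates."""
        rng = np.random.default_rng(2024)
        truth = [1.0, 0.7, 0.45, 0.2]
        pred = pred_from_values(truth)
        wins = 0
        for _ in range(100):
            expr = ExpressionTable(
                {
                    f"g{i+1}": 10 ** (2 + 2 * v + rng.normal(0, 0.1))
                    for i, v in enumerate(truth)
                }
            )
            if correlate(pred, expr).r > 0.9:
                wins += 1
        assert wins >= 95
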