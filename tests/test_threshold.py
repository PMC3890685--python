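import math

import numpy as np
import pytest

from closematch import (
    FittingError,
    fit_re_curve,
    leave_one_out,
    metrics_at_threshold,
    pairwise_matrix,
    solve_adhoc_threshold,
    sweep,
    sweep_table,
    threshold_grid,
)
from closematch.threshold import UNREACHABLE_MESSAGE

import oracle


def loo(lib, model="p"):
    return leave_one_out(lib, pairwise_matrix(lib, model))


class TestThresholdGrid:
    def test_three_point_grid(self):
        np.testing.assert_allclose(threshold_grid(0.75, 3), [0, 0.375, 0.75])

    def test_default_30_points_even_spacing(self):
        g = threshold_grid(0.29, 30)
        assert len(g) == 30
        assert g[0] == 0 and g[-1] == pytest.approx(0.29)
        np.testing.assert_allclose(np.diff(g), 0.01)

    def test_sorted_and_duplicate_free(self):
        g = threshold_grid(0.123, 30)
        assert np.all(np.diff(g) > 0)

    def test_degenerate_zero_tmax_warns(self):
        with pytest.warns(UserWarning):
            g = threshold_grid(0.0)
        np.testing.assert_array_equal(g, [0.0])

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            threshold_grid(-0.1)
        with pytest.raises(ValueError):
            threshold_grid(0.5, 1)


class TestMetrics:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (0.0, dict(tp=2, fn=1, tn=1, re=0.0, oe=0.25, accuracy=0.75, precision=1.0)),
            (0.5, dict(tp=3, tn=1, re=0.0, oe=0.0, accuracy=1.0, precision=1.0)),
            (1.0, dict(tp=3, fp=1, re=0.25, oe=0.25, accuracy=0.75, precision=0.75)),
        ],
    )
    def test_toy_hand_metrics(self, toylib1, t, expected):
        m = metrics_at_threshold(loo(toylib1), t, "incorrect")
        for key, val in expected.items():
            assert getattr(m, key) == pytest.approx(val), key

    def test_undefined_re_when_nothing_accepted(self, toylib1):
        # t=0 accepts only the two identical Alphas -> RE defined there,
        # but a library with no zero-distance pairs has RE undefined at 0
        lib_res = loo(toylib1)
        shifted = [r for r in lib_res if r.bm_distance > 0]
        m = metrics_at_threshold(shifted, 0.0)
        assert math.isnan(m.re) and math.isnan(m.precision)

    def test_ambiguity_modes_on_tie_fixture(self, toylib2):
        res = loo(toylib2)
        inc = metrics_at_threshold(res, 0.25, "incorrect")
        cor = metrics_at_threshold(res, 0.25, "correct")
        ign = metrics_at_threshold(res, 0.25, "ignored")
        # raw counts identical; the mode only changes the formulas
        assert inc.fp_ambiguous == cor.fp_ambiguous == ign.fp_ambiguous == 1
        assert cor.accuracy > inc.accuracy
        assert inc.re > cor.re
        # ignored drops the ambiguous query; the identical cross-species
        # pair (mutual FP best matches) is all that remains
        assert ign.n_queries - ign.fp_ambiguous == 2
        assert ign.re == pytest.approx(1.0)
        assert inc.re == pytest.approx(1.0) and cor.re == pytest.approx(2 / 3)

    def test_unknown_mode_rejected(self, toylib1):
        with pytest.raises(ValueError):
            metrics_at_threshold(loo(toylib1), 0.1, "strict")

    def test_metrics_match_formula_oracle(self, random_library):
        for seed in range(6):
            lib, _ = random_library(seed, n_rate=0.05)
            recs = [(r.id, r.species, r.residues) for r in lib]
            res = loo(lib, "k2p")
            t_max = max((r.bm_distance for r in res if r.defined), default=0.0)
            for t in np.linspace(0, t_max, 5):
                labels = oracle.classify_all(recs, "k2p", t)
                for mode in ("incorrect", "ignored", "correct"):
                    m = metrics_at_threshold(res, t, mode)
                    exp = oracle.metrics(labels, mode)
                    got = (m.re, m.oe, m.accuracy, m.precision)
                    for g, e in zip(got, exp):
                        assert (math.isnan(g) and math.isnan(e)) or g == pytest.approx(e)


class TestSweep:
    def test_toy_re_sequence(self, toylib1):
        res = loo(toylib1)
        metrics = sweep(res, np.array([0, 0.375, 0.75]))
        assert [m.re for m in metrics] == [0.0, 0.0, 0.25]

    def test_counts_sum_to_n_at_every_point(self, random_library):
        lib, _ = random_library(7, n_rate=0.1)
        res = loo(lib, "k2p")
        t_max = max(r.bm_distance for r in res if r.defined)
        for m in sweep(res, threshold_grid(t_max, 12)):
            assert m.n_queries == len(lib)

    def test_last_point_equals_best_match_metrics(self, random_library):
        lib, _ = random_library(8)
        res = loo(lib, "k2p")
        t_max = max(r.bm_distance for r in res if r.defined)
        last = sweep(res, threshold_grid(t_max, 10))[-1]
        assert last.tn == 0 and last.fn == 0

    def test_sweep_table_shape(self, toylib1):
        tab = sweep_table(sweep(loo(toylib1), threshold_grid(0.75, 30)))
        assert len(tab) == 30
        assert list(tab.columns[:6]) == ["t", "TP", "FP", "FP_ambiguous", "TN", "FN"]


class TestFitRECurve:
    def test_two_point_linear_fit_is_exact(self):
        model = fit_re_curve([0.0, 0.1], [0.01, 0.11], "linear")
        assert model.coefficients[0] == pytest.approx(0.01, abs=1e-12)
        assert model.coefficients[1] == pytest.approx(1.0, abs=1e-12)

    def test_exact_parabola_interpolated(self):
        t = np.linspace(0, 1, 7)
        re = 0.02 + 0.3 * t + 0.5 * t**2
        model = fit_re_curve(t, re, "polynomial", degree=2)
        np.testing.assert_allclose(model.predict(t), re, atol=1e-10)

    def test_undefined_points_excluded_from_fit(self):
        t = np.array([0.0, 0.1, 0.2, 0.3])
        re = np.array([np.nan, 0.1, 0.2, 0.3])
        model = fit_re_curve(t, re, "linear")
        assert len(model.fit_points) == 3
        assert not model.fit_points["RE"].isna().any()

    def test_too_few_points_raises_fitting_error(self):
        with pytest.raises(FittingError, match="denser"):
            fit_re_curve([0.0, 0.1, 0.2], [np.nan, np.nan, 0.1], "linear")

    def test_unknown_fit_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_re_curve([0, 1], [0, 1], "spline")


class TestSolveAdhoc:
    def test_linear_inversion(self):
        model = fit_re_curve([0.0, 0.1], [0.01, 0.11], "linear")
        result = solve_adhoc_threshold(model, 0.05)
        assert result.reachable
        assert result.threshold == pytest.approx(0.04, abs=1e-12)
        assert "for a RE of 0.05 use a threshold of 0.0400" in result.message

    def test_re_already_above_target_is_unreachable(self):
        model = fit_re_curve([0.0, 0.1], [0.10, 0.20], "linear")
        result = solve_adhoc_threshold(model, 0.05)
        assert not result.reachable
        assert result.threshold is None
        assert UNREACHABLE_MESSAGE in result.message

    def test_no_extrapolation_beyond_domain(self):
        # root at t=0.5, but swept domain ends at 0.2
        model = fit_re_curve([0.0, 0.2], [0.0, 0.02], "linear")
        result = solve_adhoc_threshold(model, 0.05)
        assert not result.reachable

    def test_smaller_of_two_in_range_roots_returned(self):
        # parabola 0.05 + (t-0.2)(t-0.6) crosses 0.05 at t=0.2 and t=0.6
        t = np.linspace(0, 1, 9)
        re = 0.05 + (t - 0.2) * (t - 0.6)
        model = fit_re_curve(t, re, "polynomial", degree=2)
        result = solve_adhoc_threshold(model, 0.05)
        assert result.threshold == pytest.approx(0.2, abs=1e-9)

    def test_invalid_target_rejected(self):
        model = fit_re_curve([0.0, 0.1], [0.0, 0.1], "linear")
        with pytest.raises(ValueError):
            solve_adhoc_threshold(model, 1.5)


class TestPartitionIdentities:
    def test_accuracy_plus_oe_is_one_without_ambiguity(self, random_library):
        for seed in range(4):
            lib, _ = random_library(seed, n_rate=0.0)
            res = loo(lib, "p")
            t_max = max(r.bm_distance for r in res if r.defined)
            for m in sweep(res, threshold_grid(t_max, 8)):
                assert m.accuracy + m.oe == pytest.approx(1.0)

    def test_re_plus_precision_is_one_where_defined(self, random_library):
        lib, _ = random_library(12)
        res = loo(lib, "k2p")
        t_max = max(r.bm_distance for r in res if r.defined)
        for m in sweep(res, threshold_grid(t_max, 8)):
            if not math.isnan(m.re):
                assert m.re + m.precision == pytest.approx(1.0)
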