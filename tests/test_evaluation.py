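"""Tests of evaluation metrics, the sweep helpers, and validation checks."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hbrnorm import evaluation
from hbrnorm.evaluation import (
    LeakageError,
    _pooled_t,
    area_metric_correlation,
    evaluate,
    explained_variance,
    first_negative_msll_size,
    msll,
    overlap_range_comparison,
    plateau_size,
    smse,
    within_subject_stability,
)

from conftest import small_generator_config
from hbrnorm.synthetic import generate_target
from test_deviation import model_from_truth


# --------------------------------------------------------------------------
# metric formulas against independent brute-force oracles
# --------------------------------------------------------------------------

def brute_ev(y, pred):
    resid = [yi - pi for yi, pi in zip(y, pred)]
    rbar = sum(resid) / len(resid)
    var_r = sum((r - rbar) ** 2 for r in resid) / len(resid)
    ybar = sum(y) / len(y)
    var_y = sum((yi - ybar) ** 2 for yi in y) / len(y)
    return 1 - var_r / var_y


def brute_smse(y, pred):
    mse = sum((yi - pi) ** 2 for yi, pi in zip(y, pred)) / len(y)
    ybar = sum(y) / len(y)
    var_y = sum((yi - ybar) ** 2 for yi in y) / len(y)
    return mse / var_y


def brute_msll(y, pred, sd, bmean, bsd):
    import math
    total = 0.0
    for yi, pi, si in zip(y, pred, sd):
        total += (0.5 * math.log(2 * math.pi * si ** 2)
                  + (yi - pi) ** 2 / (2 * si ** 2))
        total -= (0.5 * math.log(2 * math.pi * bsd ** 2)
                  + (yi - bmean) ** 2 / (2 * bsd ** 2))
    return total / len(y)


class TestMetricFormulas:
    def test_ev_direct_arithmetic(self):
        assert explained_variance([0, 2, 4], [1, 2, 3]) == \
            pytest.approx(0.75)

    def test_ev_perfect_and_trivial(self):
        y = np.array([1.0, 2.0, 5.0])
        assert explained_variance(y, y) == pytest.approx(1.0)
        assert explained_variance(y, np.full(3, y.mean())) == \
            pytest.approx(0.0)

    def test_smse_direct_arithmetic(self):
        assert smse([0, 2, 4], [1, 2, 3]) == pytest.approx(0.25)
        y = np.array([1.0, 2.0, 5.0])
        assert smse(y, y) == pytest.approx(0.0)
        assert smse(y, np.full(3, y.mean())) == pytest.approx(1.0)

    def test_msll_plug_in_values(self):
        y = np.array([1.0, 2.0, 3.0])
        # predictive identical to the baseline: loss difference is zero
        assert msll(y, np.full(3, 2.0), np.full(3, 0.5), 2.0, 0.5) == \
            pytest.approx(0.0)
        # exact mean, baseline one SD off on a single point
        val = msll(np.array([1.0]), np.array([1.0]), np.array([0.5]),
                   baseline_mean=1.5, baseline_sd=0.5)
        assert val == pytest.approx(-0.5)

    def test_msll_sharper_correct_prediction_improves(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 0.01, size=200)
        wide = msll(y, np.zeros(200), np.full(200, 1.0), 0.0, 1.0)
        narrow = msll(y, np.zeros(200), np.full(200, 0.5), 0.0, 1.0)
        assert narrow < wide

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            msll([1.0, 2.0], [1.0, 2.0], [0.5, -0.1], 0.0, 1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            out = explained_variance([1.0, 1.0, 1.0], [1.0, 1.1, 0.9])
        assert np.isnan(out)

    def test_brute_force_equivalence_on_random_fixtures(self):
        """EV/SMSE/MSLL match naive loop implementations to 1e-10 on 100
        random fixtures."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 40)
            y = rng.normal(2.5, 0.3, size=n)
            pred = y + rng.normal(0, 0.2, size=n)
            sd = rng.uniform(0.05, 0.5, size=n)
            bmean, bsd = rng.normal(2.5, 0.2), rng.uniform(0.1, 0.6)
            assert explained_variance(y, pred) == pytest.approx(
                brute_ev(y, pred), abs=1e-10)
            assert smse(y, pred) == pytest.approx(
                brute_smse(y, pred), abs=1e-10)
            assert msll(y, pred, sd, bmean, bsd) == pytest.approx(
                brute_msll(y, pred, sd, bmean, bsd), abs=1e-10)

    def test_smse_complements_ev_for_unbiased_predictions(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, size=500)
        resid = rng.normal(0, 0.5, size=500)
        resid -= resid.mean()  # exactly mean-unbiased residuals
        pred = y - resid
        assert smse(y, pred) == pytest.approx(
            1 - explained_variance(y, pred), abs=1e-12)


class TestEvaluate:
    def test_leakage_detected(self, small_adapted):
        model, aset, remainder = small_adapted
        with pytest.raises(LeakageError):
            evaluate(model, pd.concat([remainder, aset.table.head(3)]),
                     aset.table)

    def test_report_shape_and_determinism(self, small_adapted):
        model, aset, remainder = small_adapted
        r1 = evaluate(model, remainder, aset.table)
        r2 = evaluate(model, remainder, aset.table)
        assert len(r1) == len(model.rois) + 1
        assert "mean" in r1.index
        pd.testing.assert_frame_equal(r1, r2)

    def test_training_rows_score_better_than_heldout(self, small_adapted):
        """Evaluating on the adaptation rows themselves shows the
        overfitting direction relative to held-out rows."""
        model, aset, remainder = small_adapted
        # baseline must not overlap test: use remainder as baseline source
        on_train = evaluate(model, aset.table, remainder)
        on_test = evaluate(model, remainder, aset.table)
        assert on_train.loc["mean", "ev"] >= on_test.loc["mean", "ev"] - 0.1


class TestSweepHelpers:
    def _toy_sweep(self, mslls):
        rows = []
        for size, val in mslls.items():
            rows.append({"n_per_batch": size, "replicate": 0, "seed": 0,
                         "roi": "mean", "ev": 0.1, "smse": 0.9,
                         "msll": val})
        return pd.DataFrame(rows)

    def test_plateau_is_first_size_within_tolerance(self):
        sweep = self._toy_sweep({5: -0.1, 25: -0.28, 100: -0.295,
                                 300: -0.30})
        assert plateau_size(sweep, tol=0.01) == 100
        assert plateau_size(sweep, tol=0.03) == 25

    def test_better_than_final_counts_as_plateaued(self):
        sweep = self._toy_sweep({5: -0.35, 300: -0.30})
        assert plateau_size(sweep, tol=0.01) == 5

    def test_first_negative_msll(self):
        sweep = self._toy_sweep({5: 0.05, 25: -0.01, 300: -0.2})
        assert first_negative_msll_size(sweep) == 25
        allpos = self._toy_sweep({5: 0.3, 300: 0.1})
        assert first_negative_msll_size(allpos) is None

    def test_single_cell_sweep_runs(self, small_model, small_target):
        cohort, _ = small_target
        from hbrnorm.hbr import SamplerConfig
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sweep = evaluation.sweep_adaptation_size(
                small_model, cohort, sizes=(15,), replicates=1, seed=5,
                sampler_config=SamplerConfig(draws=250, warmup=250))
        assert set(sweep["n_per_batch"]) == {15}
        assert (sweep["replicate"] == 0).all()
        assert "mean" in set(sweep["roi"])


class TestWithinSubjectStability:
    def _dev(self, z_by_wave):
        rows = []
        for subj, zs in z_by_wave.items():
            for w, z in enumerate(zs):
                rows.append({"subject_id": subj, "wave": f"wave{w+1}",
                             "z_a": z})
        return pd.DataFrame(rows)

    def _raw(self, y_by_wave):
        rows = []
        for subj, ys in y_by_wave.items():
            for w, y in enumerate(ys):
                rows.append({"subject_id": subj, "wave": f"wave{w+1}",
                             "roi_a": y})
        return pd.DataFrame(rows)

    def test_constant_z_gives_zero_sd(self):
        dev = self._dev({"s1": [0.7, 0.7, 0.7]})
        raw = self._raw({"s1": [2.5, 2.4, 2.3]})
        per_subject, summary = within_subject_stability(dev, raw)
        assert per_subject["z_sd"].iloc[0] == pytest.approx(0.0)

    def test_wave_permutation_invariant(self):
        dev1 = self._dev({"s1": [0.2, 0.9, -0.3]})
        dev2 = self._dev({"s1": [-0.3, 0.2, 0.9]})
        raw = self._raw({"s1": [2.5, 2.4, 2.3]})
        _, s1 = within_subject_stability(dev1, raw)
        _, s2 = within_subject_stability(dev2, raw)
        pd.testing.assert_frame_equal(s1, s2)

    def test_no_longitudinal_subjects_flagged(self):
        dev = self._dev({"s1": [0.5]})
        raw = self._raw({"s1": [2.5]})
        with pytest.warns(RuntimeWarning):
            per_subject, summary = within_subject_stability(dev, raw)
        assert per_subject.empty

    def test_subject_intercepts_make_within_z_spread_small(self):
        """With omega >> sigma, a subject's z travels with them across
        waves: within-subject z-SD is well below the cross-sectional ~1."""
        cfg = small_generator_config(omega=0.4,
                                     sigma0=np.full(4, 0.05),
                                     longitudinal_fraction=0.5,
                                     preterm_fraction=0.0)
        cohort, truth = generate_target(cfg, seed=13)
        model = model_from_truth(truth, cfg.roi_names)
        from hbrnorm.deviation import compute_zscores
        dev = compute_zscores(model, cohort)
        per_subject, summary = within_subject_stability(dev, cohort)
        assert summary.loc["median", "z_sd"] < 0.5


class TestOverlapComparison:
    def test_identical_samples_t_zero_p_one(self):
        t, df, p = _pooled_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_separated_scanners_detected_in_raw_not_z(self):
        cfg = small_generator_config(scanner_offsets={"scannerB": 0.15},
                                     tau_alpha=0.0,
                                     longitudinal_fraction=0.0,
                                     preterm_fraction=0.0)
        cohort, truth = generate_target(cfg, seed=29)
        model = model_from_truth(truth, cfg.roi_names)
        from hbrnorm.deviation import compute_zscores
        dev = compute_zscores(model, cohort)
        report = overlap_range_comparison(cohort, dev)
        # truth model knows each wave's own intercept: z differences gone
        assert (report["raw_p"] < 0.05).all()
        assert (report["z_t"].abs() < 3).all()
        n1 = ((cohort["wave"] == "wave1")
              & cohort["age"].between(8.6, 10.7)).sum()
        n2 = ((cohort["wave"] == "wave2")
              & cohort["age"].between(8.6, 10.7)).sum()
        assert (report["df"] == n1 + n2 - 2).all()

    def test_too_few_rows_rejected(self):
        dev = pd.DataFrame({"wave": ["wave1"], "age": [9.0], "z_a": [0.1]})
        raw = pd.DataFrame({"wave": ["wave1"], "age": [9.0],
                            "roi_a": [2.5]})
        with pytest.raises(ValueError):
            overlap_range_comparison(raw, dev)


class TestAreaCorrelation:
    def test_perfect_alignment_r_one(self):
        report = pd.DataFrame({
            "ev": [0.1, 0.2, 0.3, 0.4], "smse": [0.9, 0.8, 0.7, 0.6],
            "msll": [-0.1, -0.2, -0.3, -0.4]},
            index=["a", "b", "c", "d"])
        areas = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = area_metric_correlation(report, areas)
        assert out.loc["ev", "r"] == pytest.approx(1.0)
        assert out.loc["smse", "r"] == pytest.approx(-1.0)

    def test_constant_metric_flagged(self):
        report = pd.DataFrame({
            "ev": [0.2, 0.2, 0.2], "smse": [0.8, 0.7, 0.6],
            "msll": [-0.1, -0.2, -0.3]}, index=["a", "b", "c"])
        areas = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.warns(RuntimeWarning):
            out = area_metric_correlation(report, areas)
        assert np.isnan(out.loc["ev", "r"])

    def test_too_few_rois_rejected(self):
        report = pd.DataFrame({"ev": [0.1], "smse": [0.9],
                               "msll": [-0.1]}, index=["a"])
        with pytest.raises(ValueError):
            area_metric_correlation(report, pd.Series({"a": 1.0}))
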