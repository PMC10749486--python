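"""Z scores, composite panels, ROC/AUC, DeLong and bootstrap comparisons."""

import numpy as np
import pandas as pd
import pytest

from seropanel.errors import ConfigError, StandardizationError
from seropanel.positivity import CutoffModel, fit_cutoff
from seropanel.roc import (
    auc_mann_whitney,
    bootstrap_auc_test,
    composite_score,
    delong_auc_variance,
    delong_test,
    panel_sweep,
    roc_curve,
    zscore,
    zscore_table,
)

MODEL = CutoffModel("M", hd_mean=100.0, hd_sd=25.0, cutoff=150.0, n_hd=10)


def _labels(n_pos, n_neg):
    return np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])


class TestZScore:
    def test_reference_points(self):
        assert zscore(np.array([100.0]), MODEL)[0] == 0.0
        # the positivity cutoff (mean + 2 SD) sits exactly at z = 2
        assert zscore(np.array([150.0]), MODEL)[0] == 2.0

    def test_flip_option(self):
        assert zscore(np.array([150.0]), MODEL, flip=True)[0] == -2.0

    def test_zero_sd_raises(self):
        flat = CutoffModel("F", 1.0, 0.0, 1.0, 5, zero_sd=True)
        with pytest.raises(StandardizationError):
            zscore(np.array([1.0]), flat)

    def test_hd_scores_standardized_on_generator(self, crc_cohort, crc_models):
        zt = zscore_table(crc_cohort, crc_models, include_clinical=False)
        hd = zt.loc[crc_cohort.hd_ids()]
        n = len(hd)
        for m in crc_cohort.markers:
            assert abs(hd[m].mean()) < 3 / np.sqrt(n)
            assert abs(hd[m].std(ddof=1) - 1.0) < 3 / np.sqrt(n)


class TestComposite:
    def test_singleton_identity(self, crc_cohort, crc_models):
        zt = zscore_table(crc_cohort, crc_models)
        pd.testing.assert_series_equal(
            composite_score(zt, ["FIRdexon2"]), zt["FIRdexon2"], check_names=False
        )

    def test_order_invariance_and_loop_oracle(self, rng):
        zt = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        s1 = composite_score(zt, ["a", "b", "c"])
        s2 = composite_score(zt, ["c", "a", "b"])
        loop = np.array([sum(zt.iloc[i][m] for m in "abc") for i in range(30)])
        np.testing.assert_allclose(s1, s2)
        np.testing.assert_allclose(s1, loop)

    def test_missing_component_blanks_composite(self, rng):
        zt = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
        zt.iloc[2, 0] = np.nan
        s = composite_score(zt, ["a", "b"])
        assert np.isnan(s.iloc[2]) and np.isfinite(s.drop(s.index[2])).all()

    def test_empty_subset_raises(self, rng):
        zt = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
        with pytest.raises(ConfigError):
            composite_score(zt, [])


class TestROC:
    def test_perfect_separation(self):
        res = roc_curve([3.0, 4.0, 1.0, 2.0], _labels(2, 2))
        assert res.auc == 1.0

    def test_all_tied_scores(self):
        res = roc_curve([5.0] * 6, _labels(3, 3))
        assert res.auc == pytest.approx(0.5)

    def test_curve_shape_invariants(self, rng):
        scores = rng.integers(0, 5, 40).astype(float)
        res = roc_curve(scores, rng.random(40) < 0.5)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr))

    def test_one_class_absent_raises(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_trapezoid_equals_mann_whitney_with_ties(self, rng):
        """Dual routes agree: threshold-sweep trapezoid vs midrank U."""
        for _ in range(60):
            n1, n0 = rng.integers(3, 40, size=2)
            scores = rng.integers(0, 6, n1 + n0).astype(float)
            y = _labels(n1, n0)
            assert roc_curve(scores, y).auc == pytest.approx(
                auc_mann_whitney(scores, y), abs=1e-12
            )

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(60)
        y = rng.random(60) < 0.4
        if not (y.any() and (~y).any()):
            y[0] = True
            y[1] = False
        a1 = auc_mann_whitney(scores, y)
        a2 = auc_mann_whitney(np.exp(3 * scores), y)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_string_labels_accepted(self):
        res = roc_curve([1.0, 2.0, 3.0], ["HD", "HD", "CANCER"])
        assert res.auc == 1.0 and res.n_pos == 1 and res.n_neg == 2


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        s = rng.standard_normal(50)
        y = _labels(25, 25)
        res = delong_test(s, s.copy(), y)
        assert res.z_statistic == 0.0 and res.p == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal((2, 60))
        y = _labels(30, 30)
        r1 = delong_test(a, b, y)
        r2 = delong_test(b, a, y)
        assert r1.z_statistic == pytest.approx(-r2.z_statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_single_auc_variance_matches_brute_force(self, rng):
        """Placement components recomputed by explicit double loops."""
        for _ in range(10):
            m, n = 7, 9
            s = rng.integers(0, 5, m + n).astype(float)
            y = _labels(m, n)
            auc, var = delong_auc_variance(s, y)
            pos, neg = s[:m], s[m:]
            v10 = np.array(
                [np.mean((p > neg) + 0.5 * (p == neg)) for p in pos]
            )
            v01 = np.array(
                [np.mean((pos > c) + 0.5 * (pos == c)) for c in neg]
            )
            assert auc == pytest.approx(v10.mean())
            assert var == pytest.approx(v10.var(ddof=1) / m + v01.var(ddof=1) / n)

    def test_zero_variance_unequal_auc_raises(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        y = _labels(2, 2)
        with pytest.raises(ValueError):
            delong_test(a, b, y)

    def test_agrees_with_bootstrap_on_fixed_pair(self, rng):
        n = 60
        y = _labels(n, n)
        signal = y * 0.8
        a = signal + rng.standard_normal(2 * n)
        b = 0.5 * a + rng.standard_normal(2 * n)
        p_delong = delong_test(a, b, y).p
        p_boot = bootstrap_auc_test(a, b, y, reps=4000, seed=1)
        assert p_boot == pytest.approx(p_delong, abs=0.05)


class TestBootstrap:
    def test_identical_vectors_p_one(self, rng):
        s = rng.standard_normal(40)
        assert bootstrap_auc_test(s, s.copy(), _labels(20, 20), seed=0) == 1.0

    def test_deterministic_given_seed(self, rng):
        a, b = rng.standard_normal((2, 50))
        y = _labels(25, 25)
        p1 = bootstrap_auc_test(a, b, y, reps=500, seed=42)
        p2 = bootstrap_auc_test(a, b, y, reps=500, seed=42)
        assert p1 == p2

    def test_too_few_reps_rejected(self, rng):
        a, b = rng.standard_normal((2, 20))
        with pytest.raises(ValueError):
            bootstrap_auc_test(a, b, _labels(10, 10), reps=50, seed=0)

    def test_signflip_method_valid_p(self, rng):
        a, b = rng.standard_normal((2, 40))
        p = bootstrap_auc_test(a, b, _labels(20, 20), reps=500, seed=3,
                               method="signflip")
        assert 0.0 <= p <= 1.0


class TestPanelSweep:
    def test_singletons_match_roc_curve(self, crc_results, crc_cohort):
        zt = crc_results["ztable"]
        labels = crc_cohort.samples["group"]
        sweep = panel_sweep(zt, labels, "FIRdexon2", ["CEA", "CA19-9"])
        row = sweep[sweep["panel"] == "FIRdexon2"].iloc[0]
        assert row["auc"] == pytest.approx(
            roc_curve(zt["FIRdexon2"], labels).auc
        )

    def test_unknown_marker_rejected(self, crc_results, crc_cohort):
        with pytest.raises(ConfigError):
            panel_sweep(
                crc_results["ztable"], crc_cohort.samples["group"], "nope", []
            )

    def test_noise_marker_dilutes_auc_only_slightly(self, rng):
        """Adding a pure-noise marker to a panel barely moves a large-n AUC."""
        n = 2000
        y = _labels(n, n)
        # marker strength typical of a serum panel (true AUC ~0.64)
        informative = y * 0.5 + rng.standard_normal(2 * n)
        noise = rng.standard_normal(2 * n)
        zt = pd.DataFrame({"inf": informative, "noise": noise})
        sweep = panel_sweep(zt, y, "inf", ["noise"])
        auc_single = float(sweep.loc[sweep["panel"] == "inf", "auc"].iloc[0])
        auc_both = float(sweep.loc[sweep["panel"] == "inf + noise", "auc"].iloc[0])
        assert abs(auc_both - auc_single) < 0.05

    def test_dominant_marker_ranks_first(self, rng):
        """A constructed dominant marker tops the ranking in every panel."""
        n = 300
        y = _labels(n, n)
        strong = y * 2.0 + rng.standard_normal(2 * n)
        weak = y * 0.2 + rng.standard_normal(2 * n)
        zt = pd.DataFrame({"A": strong, "B": weak})
        sweep = panel_sweep(zt, y, "A", ["B"])
        top = sweep.iloc[0]["panel"]
        assert "A" in top
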