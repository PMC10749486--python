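"""Net signal, HD cutoffs, positivity calls, and the group-level tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seropanel.errors import ConfigError, FitError
from seropanel.positivity import (
    call_matrix,
    call_positive,
    fit_cutoff,
    fit_cutoffs,
    mann_whitney_u,
    net_alpha,
    pearson_chisq,
    positivity_table,
)


class TestNetAlpha:
    def test_subtraction_and_identity(self):
        assert net_alpha(5000.0, 2000.0) == 3000.0
        assert net_alpha(1234.5, 1234.5) == 0.0

    def test_negative_preserved_and_missing_propagates(self):
        assert net_alpha(100.0, 300.0) == -200.0
        assert np.isnan(net_alpha(np.nan, 10.0))

    def test_vectorized_equals_elementwise_loop(self, rng):
        fusion = rng.gamma(2.0, 1000.0, size=(184, 5))
        gst = rng.gamma(2.0, 400.0, size=(184, 5))
        vec = net_alpha(fusion, gst)
        loop = np.empty_like(vec)
        for i in range(fusion.shape[0]):
            for j in range(fusion.shape[1]):
                loop[i, j] = fusion[i, j] - gst[i, j]
        np.testing.assert_array_equal(vec, loop)


class TestFitCutoff:
    def test_hand_arithmetic(self):
        m = fit_cutoff([0.0, 2.0])
        assert m.hd_mean == 1.0
        assert m.hd_sd == pytest.approx(np.sqrt(2.0))
        assert m.cutoff == pytest.approx(1.0 + 2.0 * np.sqrt(2.0))
        assert m.n_hd == 2

    def test_constant_reference_warns_and_cutoff_is_mean(self):
        with pytest.warns(UserWarning, match="constant"):
            m = fit_cutoff([7.0, 7.0, 7.0])
        assert m.cutoff == 7.0 and m.zero_sd

    def test_too_few_values_raises(self):
        with pytest.raises(FitError):
            fit_cutoff([1.0])
        with pytest.raises(FitError):
            fit_cutoff([1.0, np.nan])

    def test_two_sd_rule_on_normal_draws(self, rng):
        """mean + 2 SD of many N(0,1) draws sits near 2 with ~97.7% below."""
        x = rng.standard_normal(10_000)
        m = fit_cutoff(x)
        assert 1.9 < m.cutoff < 2.1
        frac_below = np.mean(x <= m.cutoff)
        assert frac_below == pytest.approx(0.9772, abs=0.005)


class TestCallPositive:
    def test_boundary_is_strict(self):
        m = fit_cutoff([0.0, 2.0])
        calls = call_positive([m.cutoff, np.nextafter(m.cutoff, np.inf)], m)
        assert calls.tolist() == [False, True]

    def test_missing_value_gives_missing_call(self):
        m = fit_cutoff([0.0, 2.0])
        calls = call_positive([np.nan, 100.0], m)
        assert pd.isna(calls.iloc[0]) and calls.iloc[1] == True  # noqa: E712

    def test_hd_positivity_near_normal_tail(self, rng):
        """On a calibrated normal HD cohort the call rate is ~2.3%."""
        x = rng.standard_normal(20_000)
        m = fit_cutoff(x[:10_000])
        rate = call_positive(x[10_000:], m).mean()
        # binomial 95% band around the 2.28% normal tail at n = 10000
        assert 0.018 < rate < 0.028

    def test_monotonicity_raising_value_never_unflips(self, rng):
        m = fit_cutoff(rng.standard_normal(100))
        v = rng.standard_normal(50)
        base = call_positive(v, m).to_numpy()
        raised = call_positive(v + abs(rng.standard_normal(50)), m).to_numpy()
        assert not np.any(base & ~raised)

    @given(
        scale=st.floats(0.1, 100.0),
        offset=st.floats(-1000.0, 1000.0),
    )
    def test_affine_equivariance(self, scale, offset):
        """a*x+b (a>0) transforms the cutoff identically, calls unchanged."""
        x = np.array([1.0, 2.0, 3.0, 8.0, 2.5, 0.5])
        probes = np.array([0.9, 2.4, 5.0, 9.0])
        m1 = fit_cutoff(x)
        m2 = fit_cutoff(scale * x + offset)
        assert m2.cutoff == pytest.approx(scale * m1.cutoff + offset, rel=1e-9, abs=1e-9)
        c1 = call_positive(probes, m1).tolist()
        c2 = call_positive(scale * probes + offset, m2).tolist()
        # ignore probes that the affine map lands on the cutoff within float noise
        tol = 1e-9 * (abs(scale * m1.cutoff) + abs(offset) + 1)
        near = np.abs(scale * probes + offset - m2.cutoff) < tol
        assert all(a == b for a, b, skip in zip(c1, c2, near) if not skip)


class TestPositivityTable:
    def test_counts_match_brute_force_recount(self, crc_cohort, crc_models):
        table = positivity_table(crc_cohort, crc_models)
        calls = call_matrix(crc_cohort, crc_models)
        for m in crc_cohort.markers:
            k_cancer = sum(
                bool(calls.loc[s, m])
                for s in crc_cohort.cancer_ids()
                if not pd.isna(calls.loc[s, m])
            )
            assert table.loc[m, "n_positive_cancer"] == k_cancer

    def test_percent_is_exact_ratio(self):
        from seropanel.cohort import cohort_from_frames

        n_hd, n_ca = 94, 90
        ids = [f"H{i}" for i in range(n_hd)] + [f"C{i}" for i in range(n_ca)]
        samples = pd.DataFrame(
            {
                "group": ["HD"] * n_hd + ["CANCER"] * n_ca,
                "sex": "unknown",
                "age": pd.array([None] * 184, dtype="Int64"),
                "dukes_stage": pd.NA,
                "cea_positive": pd.NA,
                "ca199_positive": pd.NA,
                "p53ab_positive": pd.NA,
                "cea_value": np.nan,
                "ca199_value": np.nan,
            },
            index=pd.Index(ids, name="sample_id"),
        )
        # HD flat at 0..93 -> cutoff fixed; wire exactly 11 cancer positives
        hd_vals = np.linspace(0.0, 10.0, n_hd)
        cutoff = hd_vals.mean() + 2 * hd_vals.std(ddof=1)
        ca_vals = np.full(n_ca, 1.0)
        ca_vals[:11] = cutoff + 5.0
        net = pd.DataFrame({"M1": np.concatenate([hd_vals, ca_vals])}, index=samples.index)
        cohort = cohort_from_frames(samples, net)
        table = positivity_table(cohort, fit_cutoffs(cohort))
        assert table.loc["M1", "n_positive_cancer"] == 11
        assert table.loc["M1", "pct_cancer"] == pytest.approx(100 * 11 / 90)
        assert round(table.loc["M1", "pct_cancer"]) == 12

    def test_all_negative_cohort_is_zero_everywhere(self, crc_cohort, crc_models):
        from seropanel.positivity import CutoffModel

        huge = {
            m: CutoffModel(m, mod.hd_mean, mod.hd_sd, 1e18, mod.n_hd)
            for m, mod in crc_models.items()
        }
        table = positivity_table(crc_cohort, huge)
        assert (table["n_positive_cancer"] == 0).all()
        assert (table["pct_hd"] == 0).all()

    def test_marker_without_model_is_config_error(self, crc_cohort, crc_models):
        partial = dict(list(crc_models.items())[:-1])
        with pytest.raises(ConfigError):
            positivity_table(crc_cohort, partial)


class TestMannWhitney:
    def test_identical_multisets(self):
        a = [1.0, 2.0, 2.0, 5.0]
        u, p = mann_whitney_u(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    def test_fully_separated_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/20, exact enumeration

    def test_u_equals_pairwise_win_fraction(self, rng):
        for _ in range(20):
            a = rng.integers(0, 10, size=rng.integers(3, 30)).astype(float)
            b = rng.integers(0, 10, size=rng.integers(3, 30)).astype(float)
            u, _ = mann_whitney_u(a, b)
            wins = sum(
                1.0 if x > yv else (0.5 if x == yv else 0.0) for x in a for yv in b
            )
            assert u == pytest.approx(wins)

    def test_complementary_orientations_sum(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=17)
        ua, _ = mann_whitney_u(a, b)
        ub, _ = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(12 * 17)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearsonChisq:
    def test_balanced_table_is_null(self):
        stat, p = pearson_chisq([[5, 5], [5, 5]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_perfect_diagonal(self):
        stat, _ = pearson_chisq([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_matches_direct_formula_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2)).astype(float)
            stat, _ = pearson_chisq(t)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            expected = 0.0
            for i in range(2):
                for j in range(2):
                    e = row[i] * col[j] / n
                    expected += (t[i, j] - e) ** 2 / e
            assert stat == pytest.approx(expected)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            pearson_chisq([[0, 0], [3, 4]])
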