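import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from resistex import (
    TwoColorArray,
    ValidationError,
    aquantile_normalise,
    bh_adjust,
    loess_normalise,
    moderated_t,
    to_ma,
)
from resistex.dea import estimate_variance_prior, read_raw_signals, write_raw_signals


def make_arrays(M, A, swapped=None, probe_ids=None):
    """Build arrays from target M/A matrices (probe x array)."""
    M, A = np.asarray(M, float), np.asarray(A, float)
    n, k = M.shape
    if probe_ids is None:
        probe_ids = np.array([f"P{i}" for i in range(n)])
    swapped = swapped or [False] * k
    arrays = []
    for j in range(k):
        raw_m = -M[:, j] if swapped[j] else M[:, j]
        arrays.append(
            TwoColorArray(
                array_id=f"a{j}",
                probe_ids=probe_ids,
                red=2.0 ** (A[:, j] + raw_m / 2),
                green=2.0 ** (A[:, j] - raw_m / 2),
                dye_swapped=swapped[j],
            )
        )
    return arrays


class TestToMA:
    def test_log2_arithmetic(self):
        a = TwoColorArray("a", np.array(["p"]), np.array([4.0]), np.array([2.0]))
        ma = to_ma([a])
        assert ma.M[0, 0] == pytest.approx(1.0)
        assert ma.A[0, 0] == pytest.approx(1.5)

    def test_dye_swap_negates_m_keeps_a(self):
        a = TwoColorArray("a", np.array(["p"]), np.array([4.0]), np.array([2.0]),
                          dye_swapped=True)
        ma = to_ma([a])
        assert ma.M[0, 0] == pytest.approx(-1.0)
        assert ma.A[0, 0] == pytest.approx(1.5)

    def test_channel_swap_involution(self):
        rng = np.random.default_rng(0)
        arrays = make_arrays(rng.normal(0, 1, (50, 3)), rng.uniform(6, 14, (50, 3)))
        swapped = [a.swapped_copy() for a in arrays]
        np.testing.assert_allclose(to_ma(swapped).M, -to_ma(arrays).M, atol=1e-12)
        np.testing.assert_allclose(to_ma(swapped).A, to_ma(arrays).A, atol=1e-12)

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValidationError):
            TwoColorArray("a", np.array(["p"]), np.array([0.0]), np.array([2.0]))

    def test_rejects_mismatched_probe_lists(self):
        a = TwoColorArray("a", np.array(["p", "q"]), np.array([1.0, 2]), np.array([2.0, 1]))
        b = TwoColorArray("b", np.array(["q", "p"]), np.array([1.0, 2]), np.array([2.0, 1]))
        with pytest.raises(ValidationError):
            to_ma([a, b])


def _wls_loess_oracle(y, x, frac):
    """Independent local-linear fit: direct tricube-weighted least squares at
    every point (no robustifying passes)."""
    n = len(x)
    k = max(2, int(np.ceil(frac * n)))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="mergesort")[:k]
        dmax = d[idx].max()
        w = np.clip(1 - (d[idx] / dmax) ** 3, 0, None) ** 3
        design = np.vstack([np.ones(len(idx)), x[idx] - x[i]]).T
        beta = np.linalg.lstsq(design * w[:, None], y[idx] * w, rcond=None)[0]
        out[i] = beta[0]
    return out


class TestLoess:
    def test_removes_planted_linear_trend(self):
        rng = np.random.default_rng(0)
        A = np.sort(rng.uniform(6, 14, (500, 1)), axis=0)
        M = 0.5 * A
        ma = to_ma(make_arrays(M, A))
        out = loess_normalise(ma)
        # interior points are fit exactly; linear extrapolation at the edges
        # of a noise-free linear trend is also exact
        assert np.max(np.abs(out.M)) < 1e-6
        np.testing.assert_array_equal(out.A, ma.A)

    def test_constant_m_maps_to_zero(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(6, 14, (200, 1))
        M = np.full((200, 1), 0.7)
        out = loess_normalise(to_ma(make_arrays(M, A)))
        assert np.max(np.abs(out.M)) < 1e-9

    def test_trend_free_m_barely_changes(self):
        # with M independent of A the fitted trend is pure noise, so the
        # change stays within the fit's own standard error (estimated by
        # refitting independent replicate noise draws at the same A)
        rng = np.random.default_rng(2)
        n = 1000
        A = rng.uniform(6, 14, (n, 1))
        M = rng.normal(0, 0.5, (n, 1))
        ma = to_ma(make_arrays(M, A))
        out = loess_normalise(ma)
        change = np.abs(out.M[:, 0] - ma.M[:, 0])
        replicate_fits = []
        for _ in range(30):
            rep = to_ma(make_arrays(rng.normal(0, 0.5, (n, 1)), A))
            rep_out = loess_normalise(rep)
            replicate_fits.append(rep.M[:, 0] - rep_out.M[:, 0])
        se = np.std(replicate_fits, axis=0, ddof=1)
        assert np.all(change < 5 * se)
        assert np.sqrt(np.mean(change**2)) < 2 * np.median(se)

    def test_matches_direct_wls_oracle_on_smooth_signal(self):
        rng = np.random.default_rng(3)
        n = 400
        A = rng.uniform(6, 14, (n, 1))
        M = 0.5 * np.sin(A) + rng.normal(0, 0.3, (n, 1))
        ma = to_ma(make_arrays(M, A))
        out = loess_normalise(ma, iterations=0)
        fitted = ma.M[:, 0] - out.M[:, 0]
        oracle = _wls_loess_oracle(ma.M[:, 0], ma.A[:, 0], 0.4)
        assert np.max(np.abs(fitted - oracle)) < 0.1
        # both estimates track the planted sine trend
        assert np.sqrt(np.mean((fitted - 0.5 * np.sin(A[:, 0])) ** 2)) < 0.1

    def test_small_arrays_fall_back_to_median_centering(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(6, 14, (20, 1))
        M = rng.normal(2.0, 0.1, (20, 1))
        with pytest.warns(UserWarning, match="median-centering"):
            out = loess_normalise(to_ma(make_arrays(M, A)))
        assert abs(np.median(out.M)) < 1e-12

    def test_invalid_span(self):
        rng = np.random.default_rng(5)
        ma = to_ma(make_arrays(rng.normal(0, 1, (60, 1)), rng.uniform(6, 14, (60, 1))))
        with pytest.raises(ValidationError):
            loess_normalise(ma, span=1.5)


class TestAquantile:
    def test_shifted_arrays_meet_at_rankwise_mean(self):
        # brute-force oracle at n=10: sorted target is the rank-wise mean
        rng = np.random.default_rng(0)
        base = np.sort(rng.uniform(6, 14, 10))
        A = np.column_stack([base, base + 1.0])
        M = rng.normal(0, 1, (10, 2))
        out = aquantile_normalise(to_ma(make_arrays(M, A)))
        target = (np.sort(A[:, 0]) + np.sort(A[:, 1])) / 2
        np.testing.assert_allclose(np.sort(out.A[:, 0]), target, atol=1e-12)
        np.testing.assert_allclose(np.sort(out.A[:, 1]), target, atol=1e-12)
        ma = to_ma(make_arrays(M, A))
        np.testing.assert_array_equal(out.M, ma.M)  # M untouched

    def test_idempotent_on_identical_distributions(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 30)
        A = np.column_stack([a, rng.permutation(a)])
        ma = to_ma(make_arrays(rng.normal(0, 1, (30, 2)), A))
        out = aquantile_normalise(ma)
        np.testing.assert_allclose(out.A, ma.A, atol=1e-12)

    def test_postcondition_sorted_a_equal(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(6, 14, (40, 4))
        out = aquantile_normalise(to_ma(make_arrays(rng.normal(0, 1, (40, 4)), A)))
        for j in range(1, 4):
            np.testing.assert_allclose(
                np.sort(out.A[:, 0]), np.sort(out.A[:, j]), atol=1e-9
            )

    def test_single_array_warns_and_passes_through(self):
        rng = np.random.default_rng(3)
        ma = to_ma(make_arrays(rng.normal(0, 1, (10, 1)), rng.uniform(6, 14, (10, 1))))
        with pytest.warns(UserWarning):
            out = aquantile_normalise(ma)
        np.testing.assert_array_equal(out.A, ma.A)


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(0)
        M = rng.normal(0, 1, (100, 6))
        res = moderated_t(M, prior_df=0)
        mean = M.mean(axis=1)
        sd = M.std(axis=1, ddof=1)
        t_ref = mean / (sd / np.sqrt(6))
        np.testing.assert_allclose([r.t_mod for r in res], t_ref, atol=1e-10)
        assert all(r.df_total == 5 for r in res)

    def test_infinite_prior_pools_all_variances(self):
        rng = np.random.default_rng(1)
        M = rng.normal(0, 1, (50, 4))
        res = moderated_t(M, prior_df=np.inf, prior_s2=0.8)
        t_ref = M.mean(axis=1) / np.sqrt(0.8 / 4)
        np.testing.assert_allclose([r.t_mod for r in res], t_ref, atol=1e-10)

    def test_shrinkage_fixed_point(self):
        # a probe whose sample variance equals the prior keeps it exactly
        d0, s0_2 = 4.0, 0.25
        M = np.array([[0.1, -0.1, 0.3, -0.3]])  # var chosen below via prior_s2
        s2 = M.var(ddof=1)
        res = moderated_t(M, prior_df=d0, prior_s2=s2)
        post = (d0 * s2 + 3 * s2) / (d0 + 3)
        assert post == pytest.approx(s2)
        t_expected = M.mean() / np.sqrt(s2 / 4)
        assert res[0].t_mod == pytest.approx(t_expected, abs=1e-12)

    def test_prior_estimation_recovers_known_hyperparameters(self):
        # variances drawn from the scaled-F model with known d0, s0^2
        rng = np.random.default_rng(2)
        d0_true, s0_true, df = 6.0, 0.3, 5
        s2 = (
            s0_true
            * (stats.chi2.rvs(df, size=30000, random_state=rng) / df)
            / (stats.chi2.rvs(d0_true, size=30000, random_state=rng) / d0_true)
        )
        d0, s0_2 = estimate_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.1)
        assert s0_2 == pytest.approx(s0_true, rel=0.05)

    def test_single_array_rejected(self):
        with pytest.raises(ValidationError):
            moderated_t(np.zeros((10, 1)))


class TestBHAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_defining_properties(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_step_up_oracle_and_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            q = bh_adjust(p)
            # O(m^2) literal transcription of the step-up definition
            m = len(p)
            ranks = {}
            for i, pi in enumerate(p):
                candidates = [
                    m * pj / (np.sum(p <= pj)) for pj in p if pj >= pi
                ]
                ranks[i] = min(1.0, min(candidates))
            np.testing.assert_allclose(q, [ranks[i] for i in range(m)], atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestRawSignalIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        arrays = make_arrays(
            rng.normal(0, 1, (5, 2)), rng.uniform(6, 14, (5, 2)), swapped=[False, True]
        )
        path = tmp_path / "signals.tsv"
        write_raw_signals(arrays, path)
        back = read_raw_signals(path)
        assert [a.array_id for a in back] == [a.array_id for a in arrays]
        for a, b in zip(arrays, back):
            np.testing.assert_allclose(a.red, b.red)
            np.testing.assert_allclose(a.green, b.green)
            assert a.dye_swapped == b.dye_swapped
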