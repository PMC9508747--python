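"""Spatial correlations, stratified bootstrap, and the edge model."""

import numpy as np
import pandas as pd
import pytest
from itertools import permutations

from scipy.stats import rankdata

import mtspread as mt
from mtspread.datatypes import EdgeMatrix
from mtspread.exceptions import (
    CollinearityError,
    SampleSizeError,
    UndefinedCorrelationError,
    ValidationError,
)


def _sym(values, semantics="fisher_z_spearman_cov"):
    v = np.asarray(values, dtype=float)
    ids = np.arange(1, v.shape[0] + 1)
    return EdgeMatrix(v, ids, semantics)


def _edge_setup(n=12, seed=0, density=1.0):
    rng = np.random.default_rng(seed)
    mwf = rng.uniform(0.05, 0.25, n)
    fc, counts, fiber = mt.generate_connectome(n, density, mwf, seed=seed + 1)
    return rng, fc, counts, fiber


class TestSpatialCorrelation:
    def test_perfect_discordance(self):
        rho, p = mt.spatial_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_small_n_matches_exhaustive_permutation(self):
        rng = np.random.default_rng(1)
        mwf = rng.random(8)
        tau = rng.random(8)
        tau[2] = tau[5]  # introduce a tie
        rho, p = mt.spatial_correlation(mwf, tau)
        r_m, r_t = rankdata(mwf), rankdata(tau)
        obs = abs(np.corrcoef(r_m, r_t)[0, 1])
        assert rho == pytest.approx(np.corrcoef(r_m, r_t)[0, 1], abs=1e-10)
        count = 0
        total = 0
        for perm in permutations(range(8)):
            r = abs(np.corrcoef(r_m, r_t[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_null_rho_small_at_large_n(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            rho, _ = mt.spatial_correlation(rng.random(200), rng.random(200))
            hits += abs(rho) < 0.2
        assert hits >= 38  # |rho| < 0.2 in >= 95% of null draws

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            mt.spatial_correlation(np.ones(10), np.arange(10.0))

    def test_too_few_rois(self):
        with pytest.raises(SampleSizeError):
            mt.spatial_correlation([1, 2, 3], [3, 2, 1])


class TestPartialSpatialCorrelation:
    def test_constant_control_equals_plain(self):
        rng = np.random.default_rng(2)
        mwf, tau = rng.random(50), rng.random(50)
        rho0, _ = mt.spatial_correlation(mwf, tau)
        rho1, _ = mt.partial_spatial_correlation(mwf, tau, np.ones(50))
        assert rho1 == pytest.approx(rho0, abs=1e-10)

    def test_control_identical_to_tau(self):
        rng = np.random.default_rng(3)
        mwf, tau = rng.random(50), rng.random(50)
        rho, _ = mt.partial_spatial_correlation(mwf, tau, tau)
        assert abs(rho) < 1e-8

    def test_matches_recursive_formula(self):
        rng = np.random.default_rng(4)
        mwf, tau, ctrl = rng.random(50), rng.random(50), rng.random(50)
        tau = tau + 0.8 * ctrl  # planted confounding
        rho, _ = mt.partial_spatial_correlation(mwf, tau, ctrl)
        rm, rt, rc = rankdata(mwf), rankdata(tau), rankdata(ctrl)
        r_mt = np.corrcoef(rm, rt)[0, 1]
        r_mc = np.corrcoef(rm, rc)[0, 1]
        r_tc = np.corrcoef(rt, rc)[0, 1]
        expected = (r_mt - r_mc * r_tc) / np.sqrt((1 - r_mc**2) * (1 - r_tc**2))
        assert rho == pytest.approx(expected, abs=1e-10)


class TestStratifiedBootstrap:
    def _scores(self, n=30, n_rois=20, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.random((n, n_rois)) + 1.0
        return pd.DataFrame(
            vals, index=[f"s{i}" for i in range(n)], columns=np.arange(1, n_rois + 1)
        )

    def test_single_iteration_degenerate_ci(self):
        df = self._scores()
        mwf = np.random.default_rng(1).random(20)
        strata = {f"s{i}": "all" for i in range(30)}
        res = mt.stratified_bootstrap_rho(df, strata, mwf, B=1, seed=5)
        s = res.strata["all"]
        assert s.ci_low == s.ci_high

    def test_identical_strata_identical_cis(self):
        df = self._scores(n=40)
        mwf = np.random.default_rng(2).random(20)
        # two labels partitioning identical data: same rows duplicated
        df2 = pd.concat([df, df.set_index(df.index + "_b")])
        strata = {s: ("A" if not s.endswith("_b") else "B") for s in df2.index}
        res = mt.stratified_bootstrap_rho(df2, strata, mwf, B=50, seed=3)
        a, b = res.strata["A"], res.strata["B"]
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert res.cis_overlap is True

    def test_seeded_determinism(self):
        df = self._scores()
        mwf = np.random.default_rng(3).random(20)
        strata = {f"s{i}": ("A" if i < 15 else "B") for i in range(30)}
        r1 = mt.stratified_bootstrap_rho(df, strata, mwf, B=30, seed=9)
        r2 = mt.stratified_bootstrap_rho(df, strata, mwf, B=30, seed=9)
        for label in r1.strata:
            assert r1.strata[label] == r2.strata[label]

    def test_small_stratum_rejected(self):
        df = self._scores(n=12)
        mwf = np.random.default_rng(4).random(20)
        strata = {f"s{i}": ("A" if i < 5 else "B") for i in range(12)}
        with pytest.raises(SampleSizeError):
            mt.stratified_bootstrap_rho(df, strata, mwf, B=10, seed=0)


class TestVectorizeEdges:
    def test_full_mask_counts(self):
        m = _sym(np.zeros((4, 4)))
        counts = _sym(np.ones((4, 4)), "streamline_count")
        vals, (ii, jj) = mt.vectorize_edges(m, counts)
        assert len(vals) == 6  # C(4, 2)

    def test_empty_mask_rejected(self):
        m = _sym(np.zeros((4, 4)))
        counts = _sym(np.zeros((4, 4)), "streamline_count")
        with pytest.raises(ValidationError):
            mt.vectorize_edges(m, counts)

    def test_scatter_round_trip(self, rng):
        v = rng.standard_normal((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = _sym(v)
        vals, (ii, jj) = mt.vectorize_edges(m)
        back = np.zeros((5, 5))
        back[ii, jj] = vals
        assert np.allclose(back, np.triu(v, 1))


class TestEdgeInteractionModel:
    def test_exact_recovery_zero_noise(self):
        """An outcome constructed exactly as 0.1 + 0.5 FC* - 0.4 FC* MWF*
        is recovered to machine precision with beta_mwf = 0."""
        _, fc, counts, fiber = _edge_setup(n=12, seed=0)
        iu, ju = np.triu_indices(12, 1)
        f = fc.values[iu, ju]
        m = fiber.values[iu, ju]
        f_std = (f - f.mean()) / f.std(ddof=1)
        m_std = (m - m.mean()) / m.std(ddof=1)
        y = 0.1 + 0.5 * f_std - 0.4 * f_std * m_std
        ym = np.zeros((12, 12))
        ym[iu, ju] = y
        ym += ym.T
        outcome = _sym(ym)
        res = mt.edge_interaction_model(outcome, fc, fiber)
        # outcome is z-scored internally: rescale expectations accordingly
        sd_y = y.std(ddof=1)
        assert res.coefficients["beta_fc"] == pytest.approx(0.5 / sd_y, abs=1e-8)
        assert res.coefficients["beta_mwf"] == pytest.approx(0.0, abs=1e-8)
        assert res.coefficients["beta_interaction"] == pytest.approx(
            -0.4 / sd_y, abs=1e-8
        )
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations(self):
        rng, fc, counts, fiber = _edge_setup(n=10, seed=5)
        iu, ju = np.triu_indices(10, 1)
        noise = np.zeros((10, 10))
        noise[iu, ju] = rng.standard_normal(iu.size)
        noise += noise.T
        outcome = _sym(noise)
        res = mt.edge_interaction_model(outcome, fc, fiber, mask=counts)
        y = noise[iu, ju]
        keep = counts.values[iu, ju] > 0
        y = y[keep]
        f = fc.values[iu, ju][keep]
        m = fiber.values[iu, ju][keep]
        ys = (y - y.mean()) / y.std(ddof=1)
        fs = (f - f.mean()) / f.std(ddof=1)
        ms = (m - m.mean()) / m.std(ddof=1)
        X = np.column_stack([np.ones_like(ys), fs, ms, fs * ms])
        beta = np.linalg.solve(X.T @ X, X.T @ ys)
        assert np.abs(res.coefficients.to_numpy() - beta).max() < 1e-10

    def test_constant_fiber_mwf_collinear(self):
        _, fc, counts, _ = _edge_setup(n=10, seed=2)
        const = EdgeMatrix(np.full((10, 10), 0.2), np.arange(1, 11), "fiber_mwf")
        noise = np.random.default_rng(0).standard_normal((10, 10))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        with pytest.raises(CollinearityError):
            mt.edge_interaction_model(_sym(noise), fc, const)

    def test_roi_order_permutation_invariance(self):
        rng, fc, counts, fiber = _edge_setup(n=9, seed=7)
        noise = rng.standard_normal((9, 9))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        outcome = _sym(noise)
        res1 = mt.edge_interaction_model(outcome, fc, fiber, mask=counts)
        perm = rng.permutation(9)
        def permute(m):
            return EdgeMatrix(m.values[np.ix_(perm, perm)], m.roi_ids, m.semantics)
        res2 = mt.edge_interaction_model(
            permute(outcome), permute(fc), permute(fiber), mask=permute(counts)
        )
        assert np.allclose(
            res1.coefficients.to_numpy(), res2.coefficients.to_numpy(), atol=1e-12
        )
        assert np.allclose(
            res1.p_values.to_numpy(), res2.p_values.to_numpy(), atol=1e-12
        )

    def test_joint_sign_flip_preserves_fc_and_interaction(self):
        rng, fc, counts, fiber = _edge_setup(n=10, seed=8)
        noise = rng.standard_normal((10, 10))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        outcome = _sym(noise)
        res1 = mt.edge_interaction_model(outcome, fc, fiber, mask=counts)
        flipped_fc = EdgeMatrix(-fc.values, fc.roi_ids, "fisher_z_fc")
        res2 = mt.edge_interaction_model(
            _sym(-noise), flipped_fc, fiber, mask=counts
        )
        assert res2.coefficients["beta_fc"] == pytest.approx(
            res1.coefficients["beta_fc"], abs=1e-12
        )
        assert res2.coefficients["beta_interaction"] == pytest.approx(
            res1.coefficients["beta_interaction"], abs=1e-12
        )

    def test_permutation_p_option(self):
        rng, fc, counts, fiber = _edge_setup(n=10, seed=9)
        noise = rng.standard_normal((10, 10))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        res = mt.edge_interaction_model(
            _sym(noise), fc, fiber, mask=counts, n_permutations=200, seed=1
        )
        assert res.permutation_p is not None
        assert 0 < res.permutation_p <= 1
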