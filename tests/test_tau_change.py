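"""Annualized change and covariance-in-change matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import mtspread as mt
from mtspread.connectome import FISHER_CLIP
from mtspread.datatypes import ChangeTable, SuvrTable, TauScoreTable
from mtspread.exceptions import CollinearityError, KindMismatchError, SampleSizeError


def _suvr(values, subjects, rois, timepoint="baseline"):
    frame = pd.DataFrame(values, index=subjects, columns=rois)
    return SuvrTable(frame, timepoint, "flortaucipir", "inferior_cerebellar_gm")


def _change_table(values, rois=None, intervals=None):
    values = np.asarray(values, dtype=float)
    subjects = [f"s{i}" for i in range(values.shape[0])]
    rois = rois or list(range(1, values.shape[1] + 1))
    iv = pd.Series(intervals if intervals is not None else 1.0, index=subjects)
    return ChangeTable(
        pd.DataFrame(values, index=subjects, columns=rois), iv, "score"
    )


def _covariates(n, seed=0):
    return mt.generate_cohort({"CN_Abpos": n}, seed=seed).assign(
        subject_id=[f"s{i}" for i in range(n)]
    )


class TestAnnualChange:
    def test_simple_arithmetic(self):
        bl = _suvr([[1.5]], ["s1"], [1])
        fu = _suvr([[1.8]], ["s1"], [1], "followup")
        ch = mt.annual_change(bl, fu, pd.Series({"s1": 1.5}))
        assert ch.annual_change.loc["s1", 1] == pytest.approx(0.2)

    def test_no_change_is_zero(self):
        bl = _suvr([[1.4, 1.6]], ["s1"], [1, 2])
        fu = _suvr([[1.4, 1.6]], ["s1"], [1, 2], "followup")
        ch = mt.annual_change(bl, fu, pd.Series({"s1": 2.0}))
        assert (ch.annual_change.to_numpy() == 0).all()

    def test_kind_mismatch(self):
        bl = _suvr([[1.5]], ["s1"], [1])
        prob = pd.DataFrame([[0.5]], index=["s1"], columns=[1])
        fu = TauScoreTable(prob, prob * 1.5, "followup")
        with pytest.raises(KindMismatchError):
            mt.annual_change(bl, fu, pd.Series({"s1": 1.0}))

    def test_subject_missing_timepoint_dropped(self):
        bl = _suvr([[1.5], [1.4]], ["s1", "s2"], [1])
        fu = _suvr([[1.8]], ["s1"], [1], "followup")
        ch = mt.annual_change(bl, fu, pd.Series({"s1": 1.0, "s2": 1.0}))
        assert list(ch.subjects) == ["s1"]


class TestChangeCovariance:
    def test_perfect_concordance_clipped(self):
        ch = _change_table(np.column_stack([
            [1, 2, 3] * 4, [1, 2, 3] * 4, np.random.default_rng(0).random(12)
        ]))
        m = mt.change_covariance(ch)
        assert m.values[0, 1] == pytest.approx(np.arctanh(FISHER_CLIP))

    def test_perfect_discordance(self):
        ch = _change_table(np.column_stack([
            [1, 2, 3] * 4, [3, 2, 1] * 4, np.random.default_rng(0).random(12)
        ]))
        m = mt.change_covariance(ch)
        assert m.values[0, 1] == pytest.approx(-np.arctanh(FISHER_CLIP))

    def test_matches_brute_force_rank_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.random((15, 6))
        m = mt.change_covariance(_change_table(x))
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert m.values[i, j] == 0.0
                    continue
                ri, rj = rankdata(x[:, i]), rankdata(x[:, j])
                r = np.corrcoef(ri, rj)[0, 1]
                z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
                assert abs(m.values[i, j] - z) < 1e-12

    def test_constant_roi_missing_with_warning(self):
        rng = np.random.default_rng(4)
        x = rng.random((12, 3))
        x[:, 1] = 0.7
        with pytest.warns(UserWarning):
            m = mt.change_covariance(_change_table(x))
        assert np.isnan(m.values[0, 1]) and np.isnan(m.values[1, 2])
        assert np.isfinite(m.values[0, 2])

    def test_too_few_subjects(self):
        with pytest.raises(SampleSizeError):
            mt.change_covariance(_change_table(np.random.default_rng(0).random((5, 3))))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.random((20, 4))
        m1 = mt.change_covariance(_change_table(x))
        y = x.copy()
        y[:, 0] = np.exp(3 * y[:, 0])  # strictly increasing transform
        m2 = mt.change_covariance(_change_table(y))
        assert np.allclose(m1.values, m2.values, atol=1e-10)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.random((20, 4))
        m1 = mt.change_covariance(_change_table(x))
        perm = rng.permutation(20)
        m2 = mt.change_covariance(_change_table(x[perm]))
        assert np.allclose(m1.values, m2.values, atol=1e-12)


class TestPartialChangeCovariance:
    def test_constant_controls_equal_plain(self):
        rng = np.random.default_rng(7)
        x = rng.random((30, 4))
        ch = _change_table(x)
        cov = _covariates(30)
        cov["site"] = "site1"  # constant categorical: no indicator columns
        plain = mt.change_covariance(ch)
        partial = mt.partial_change_covariance(ch, cov, ["site"])
        assert np.allclose(plain.values, partial.values, atol=1e-10)

    def test_control_equal_to_roi_ranks_zeroes_its_edges(self):
        rng = np.random.default_rng(8)
        x = rng.random((30, 3))
        ch = _change_table(x)
        cov = _covariates(30)
        cov["age"] = rankdata(x[:, 0])
        m = mt.partial_change_covariance(ch, cov, ["age"])
        assert abs(m.values[0, 1]) < 1e-8
        assert abs(m.values[0, 2]) < 1e-8
        assert abs(m.values[1, 2]) > 0  # other edges unaffected

    def test_matches_recursive_formula_one_control(self):
        """Partial Spearman via residualized ranks equals the recursion
        rho_xy.z = (rho_xy - rho_xz*rho_yz)/sqrt((1-rho_xz^2)(1-rho_yz^2))."""
        rng = np.random.default_rng(9)
        x = rng.random((30, 3))
        ch = _change_table(x)
        cov = _covariates(30)
        z = rng.random(30)
        cov["age"] = z
        m = mt.partial_change_covariance(ch, cov, ["age"])
        rz = rankdata(z)
        for i in range(3):
            for j in range(i + 1, 3):
                ri, rj = rankdata(x[:, i]), rankdata(x[:, j])
                r_ij = np.corrcoef(ri, rj)[0, 1]
                r_iz = np.corrcoef(ri, rz)[0, 1]
                r_jz = np.corrcoef(rj, rz)[0, 1]
                expected = (r_ij - r_iz * r_jz) / np.sqrt(
                    (1 - r_iz**2) * (1 - r_jz**2)
                )
                assert abs(np.tanh(m.values[i, j]) - expected) < 1e-10

    def test_collinear_controls_named(self):
        rng = np.random.default_rng(10)
        x = rng.random((30, 3))
        ch = _change_table(x)
        cov = _covariates(30)
        cov["education"] = cov["age"] * 2.0  # exactly collinear
        with pytest.raises(CollinearityError, match="education"):
            mt.partial_change_covariance(ch, cov, ["age", "education"])

    def test_semantics_tag(self):
        rng = np.random.default_rng(11)
        m = mt.change_covariance(_change_table(rng.random((12, 3))))
        assert m.semantics == "fisher_z_spearman_cov"
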