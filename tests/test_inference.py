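import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalnet.inference import (GroupDesign, cluster_extent_correct, glm_tmap,
                               make_group_design, one_sample_design,
                               permutation_test, tfce)
from thalnet.volume_io import Mask


def _mask(shape=(6, 6, 6)):
    return Mask(data=np.ones(shape, dtype=bool), affine=np.diag([3.0, 3, 3, 1]))


def _two_sample_design(n1, n2, covariates=()):
    tab = pd.DataFrame({"group": ["control"] * n1 + ["patient"] * n2})
    for name, values in covariates:
        tab[name] = values
    return make_group_design(tab, covariates=tuple(n for n, _ in covariates))


class TestGlmTmap:
    def test_identical_groups_give_zero_t(self):
        base = np.random.default_rng(0).standard_normal((4, 4, 4))
        data = np.repeat(base[..., None], 8, axis=3)
        sm = glm_tmap(data, _two_sample_design(4, 4), _mask((4, 4, 4)))
        np.testing.assert_allclose(sm.t, 0.0, atol=1e-8)

    def test_pooled_two_sample_t_hand_value(self):
        # {1,2,3} vs {4,5,6}: classic pooled t = -3.674
        data = np.array([1, 2, 3, 4, 5, 6], float).reshape(1, 1, 1, 6)
        sm = glm_tmap(data, _two_sample_design(3, 3), _mask((1, 1, 1)))
        assert sm.t[0, 0, 0] == pytest.approx(-3.674, abs=1e-3)
        assert sm.df == 4

    def test_orthogonal_covariate_leaves_t_unchanged(self, rng):
        # covariate orthogonal to group, intercept and the data leaves the
        # contrast estimate and residuals untouched; t moves only through
        # the lost degree of freedom, vanishing for long designs
        n = 60
        y = rng.standard_normal(n)
        data = y.reshape(1, 1, 1, n)
        d0 = _two_sample_design(n // 2, n // 2)
        sm0 = glm_tmap(data, d0, _mask((1, 1, 1)))
        cov = rng.standard_normal(n)
        basis = np.column_stack([d0.matrix, y])
        cov -= basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
        d1 = GroupDesign(matrix=np.column_stack([d0.matrix, cov]),
                         contrast=np.array([0.0, 1.0, 0.0]))
        sm1 = glm_tmap(data, d1, _mask((1, 1, 1)))
        t0, t1 = sm0.t[0, 0, 0], sm1.t[0, 0, 0]
        assert sm1.df == sm0.df - 1
        # exact df-rescaling relation, hence approximate invariance
        assert t1 == pytest.approx(t0 * np.sqrt(sm1.df / sm0.df), abs=1e-8)
        assert t1 == pytest.approx(t0, rel=0.02)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            GroupDesign(matrix=X, contrast=np.array([0.0, 1.0]))


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert (tfce(np.zeros((5, 5, 5))) == 0).all()

    def test_isolated_voxel_integral_oracle(self):
        # integral of h^2 dh from 0 to 2 = 8/3 (E=0.5, H=2, unit extent)
        m = np.zeros((7, 7, 7))
        m[3, 3, 3] = 2.0
        val = tfce(m, E=0.5, H=2.0, dh=0.01)[3, 3, 3]
        assert val == pytest.approx(8.0 / 3.0, rel=0.01)

    def test_cluster_size_ratio_power_law(self):
        h = 1.5
        two = np.zeros((7, 7, 7))
        two[3, 3, 3] = two[3, 3, 4] = h
        one = np.zeros((7, 7, 7))
        one[3, 3, 3] = h
        r = tfce(two, dh=0.005)[3, 3, 3] / tfce(one, dh=0.005)[3, 3, 3]
        assert r == pytest.approx(2**0.5, abs=1e-9)

    def test_negative_tail_antisymmetric(self, rng):
        m = rng.standard_normal((6, 6, 6))
        np.testing.assert_allclose(tfce(-m, dh=0.02), -tfce(m, dh=0.02),
                                   atol=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_background_shift_below_dh_is_invisible(self, s):
        rng = np.random.default_rng(s)
        m = np.zeros((6, 6, 6))
        m[2:4, 2:4, 2:4] = rng.uniform(1.0, 3.0, (2, 2, 2))
        dh = 0.05
        base = tfce(m, dh=dh)
        shift = m.copy()
        shift[m == 0] = 0.04  # constant below dh on the background
        np.testing.assert_allclose(tfce(shift, dh=dh), base, atol=1e-12)

    @pytest.mark.parametrize("conn", [6, 18, 26])
    def test_connectivity_levels_accepted(self, conn):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = 1.0
        tfce(m, connectivity=conn)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            tfce(np.zeros((3, 3, 3)), connectivity=4)


class TestPermutationTest:
    def test_saturated_one_sample_minimum_p(self, rng):
        data = 5.0 + 0.1 * rng.standard_normal((5, 5, 5, 12))
        res = permutation_test(data, one_sample_design(12), _mask((5, 5, 5)),
                               enhancement="tfce", n_perm=300, seed=1)
        assert res.corrected_p.min() == pytest.approx(1.0 / 301.0)

    def test_exhaustive_sign_flip_matches_enumeration_oracle(self, rng):
        # n=4: 16 sign patterns; compare against brute-force enumeration
        data = rng.standard_normal((3, 3, 3, 4)) + 1.0
        mask = _mask((3, 3, 3))
        res = permutation_test(data, one_sample_design(4), mask,
                               enhancement="voxel", n_perm=500, seed=0)
        assert res.exhaustive and res.n_permutations == 16

        Y = data.reshape(-1, 4)
        null_max = []
        for signs in itertools.product([1.0, -1.0], repeat=4):
            Yp = Y * np.array(signs)
            mean = Yp.mean(axis=1)
            se = Yp.std(axis=1, ddof=1) / 2.0
            null_max.append(np.abs(mean / se).max())
        null_max = np.array(null_max)
        mean = Y.mean(axis=1)
        se = Y.std(axis=1, ddof=1) / 2.0
        obs = np.abs(mean / se)
        expected_p = np.array([(null_max >= o).sum() / 16.0 for o in obs])
        np.testing.assert_allclose(res.corrected_p.ravel(), expected_p,
                                   atol=1e-12)

    def test_p_monotone_in_enhanced_statistic(self, rng):
        data = rng.standard_normal((5, 5, 5, 16))
        data[..., :8] += 0.7
        res = permutation_test(data, _two_sample_design(8, 8), _mask((5, 5, 5)),
                               enhancement="tfce", n_perm=150, seed=3)
        enh = np.abs(res.enhanced).ravel()
        p = res.corrected_p.ravel()
        order = np.argsort(enh)
        assert (np.diff(p[order]) <= 1e-12).all()

    def test_freedman_lane_reduces_to_label_permutation(self, rng):
        # no covariates: residualizing against the intercept and permuting
        # is numerically identical to permuting raw labels
        n = 10
        data = rng.standard_normal((4, 4, 4, n))
        design = _two_sample_design(5, 5)
        mask = _mask((4, 4, 4))
        res = permutation_test(data, design, mask, enhancement="voxel",
                               n_perm=120, seed=9)

        Y = data.reshape(-1, n).T
        X = design.matrix
        rng2 = np.random.default_rng(9)
        perms = np.array([rng2.permutation(n) for _ in range(120)])
        null_max = []
        for p in perms:
            pinv = np.linalg.pinv(X)
            beta = pinv @ Y[p]
            resid = Y[p] - X @ beta
            sigma2 = (resid**2).sum(axis=0) / (n - 2)
            cvar = design.contrast @ np.linalg.inv(X.T @ X) @ design.contrast
            t = (design.contrast @ beta) / np.sqrt(sigma2 * cvar)
            null_max.append(np.abs(t).max())
        null_max = np.array(null_max)
        obs = np.abs(glm_tmap(data, design, mask).t.ravel())
        expected_p = (1.0 + (null_max[None] >= obs[:, None]).sum(1)) / 121.0
        np.testing.assert_allclose(res.corrected_p.ravel(), expected_p,
                                   atol=1e-12)

    def test_sign_flip_with_group_regressor_rejected(self):
        X = np.column_stack([np.ones(8), [1] * 4 + [0] * 4])
        with pytest.raises(ValueError, match="sign_flip"):
            GroupDesign(matrix=X, contrast=np.array([0.0, 1.0]),
                        scheme="sign_flip")

    def test_small_n_perm_rejected(self, rng):
        data = rng.standard_normal((3, 3, 3, 8))
        with pytest.raises(ValueError):
            permutation_test(data, _two_sample_design(4, 4), _mask((3, 3, 3)),
                             n_perm=50)


class TestClusterExtent:
    def test_no_suprathreshold_voxels_empty_table(self, rng):
        data = 0.01 * rng.standard_normal((4, 4, 4, 12))
        res = cluster_extent_correct(data, _two_sample_design(6, 6),
                                     _mask((4, 4, 4)), forming_t=50.0,
                                     n_perm=120, seed=0)
        assert len(res.cluster_table) == 0

    def test_planted_cluster_detected(self, rng):
        # ~30-voxel strong effect in 6 vs 6
        data = rng.standard_normal((6, 6, 6, 12))
        effect = np.zeros((6, 6, 6))
        effect[1:4, 1:4, 1:4] = 2.5
        data[..., :6] += effect[..., None]
        res = cluster_extent_correct(data, _two_sample_design(6, 6),
                                     _mask((6, 6, 6)), forming_t=2.3,
                                     n_perm=500, seed=2)
        assert len(res.cluster_table) >= 1
        top = res.cluster_table.iloc[0]
        assert top["corrected_p"] < 0.05
        assert effect[int(top.peak_i), int(top.peak_j), int(top.peak_k)] > 0

    def test_covariates_handled(self, rng):
        ages = rng.normal(25, 5, 12).round(1)
        design = _two_sample_design(6, 6, covariates=[("age", ages)])
        data = rng.standard_normal((4, 4, 4, 12))
        res = cluster_extent_correct(data, design, _mask((4, 4, 4)),
                                     n_perm=120, seed=1)
        assert res.observed.df == 12 - 3
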