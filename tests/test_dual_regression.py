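import numpy as np
import pytest

from thalnet.dual_regression import (SubjectTimecourses, dual_regress,
                                     stage1_timecourses, stage2_subdivisions)
from thalnet.spatial_ica import ICADecomposition
from thalnet.synthetic_data import make_ground_truth, simulate_subject
from thalnet.volume_io import Mask, Volume4D


def _decomposition_from_maps(maps, brain):
    """Wrap known spatial maps as a decomposition for regression tests."""
    maps = np.asarray(maps, dtype=float)
    flat = maps.reshape(len(maps), -1)[:, brain.data.ravel()]
    scaled = np.zeros_like(maps)
    for k in range(len(maps)):
        sd = flat[k].std()
        scaled[k] = maps[k] / (sd if sd > 0 else 1.0)
    return ICADecomposition(maps=scaled, zmaps=scaled, mixing=np.zeros((1, len(maps))),
                            brain=brain, seed=0, n_iter=0, retained_variance=1.0)


@pytest.fixture
def planted(rng):
    """Noiseless bold = maps x timecourses with near-orthogonal blobs."""
    shape = (8, 8, 8)
    brain = Mask(data=np.ones(shape, dtype=bool), affine=np.eye(4))
    maps = np.zeros((2,) + shape)
    maps[0, 1:4, 1:4, 1:4] = 1.5
    maps[1, 5:8, 5:8, 5:8] = 1.0
    T = 80
    tc = rng.standard_normal((T, 2))
    data = np.einsum("kxyz,tk->xyzt", maps, tc)
    bold = Volume4D(data=data, affine=np.eye(4))
    return bold, maps, tc, brain


class TestStage1:
    def test_noiseless_reconstruction(self, planted):
        bold, maps, tc, brain = planted
        dec = _decomposition_from_maps(maps, brain)
        est = stage1_timecourses(bold, dec, brain)
        for k in range(2):
            r = np.corrcoef(est.tc[:, k], tc[:, k])[0, 1]
            assert abs(r) > 0.999

    def test_pure_noise_gives_null_timecourses(self, rng, planted):
        _, maps, tc, brain = planted
        dec = _decomposition_from_maps(maps, brain)
        noise = Volume4D(data=rng.standard_normal(brain.shape3d + (200,)),
                         affine=np.eye(4))
        est = stage1_timecourses(noise, dec, brain)
        planted_tc = rng.standard_normal((200, 2))
        for k in range(2):
            assert abs(np.corrcoef(est.tc[:, k], planted_tc[:, k])[0, 1]) < 0.2

    def test_constant_bold_gives_zero_weights(self, planted):
        _, maps, _, brain = planted
        dec = _decomposition_from_maps(maps, brain)
        bold = Volume4D(data=np.full(brain.shape3d + (10,), 3.0), affine=np.eye(4))
        est = stage1_timecourses(bold, dec, brain)
        np.testing.assert_allclose(est.tc, 0.0, atol=1e-9)


class TestStage2:
    def test_joint_solution_matches_lstsq_oracle(self, rng):
        # correlated timecourses: joint betas must equal the direct
        # multiple-regression solution, not per-component simple fits
        T = 60
        base = rng.standard_normal(T)
        tcs = np.column_stack([base + 0.3 * rng.standard_normal(T),
                               base + 0.3 * rng.standard_normal(T)])
        tc = SubjectTimecourses(tc=tcs)
        shape = (3, 3, 3)
        data = rng.standard_normal(shape + (T,))
        thal = Mask(data=np.ones(shape, dtype=bool), affine=np.eye(4))
        sub = stage2_subdivisions(Volume4D(data=data, affine=np.eye(4)), tc, thal)
        norm = tc.variance_normalized().tc
        X = np.column_stack([np.ones(T), norm])
        for v in [(0, 0, 0), (1, 2, 1)]:
            beta = np.linalg.lstsq(X, data[v], rcond=None)[0]
            marginal = [np.linalg.lstsq(
                np.column_stack([np.ones(T), norm[:, k]]), data[v], rcond=None
            )[0][1] for k in range(2)]
            np.testing.assert_allclose(sub.thal_betas[:, v[0], v[1], v[2]],
                                       beta[1:], atol=1e-10)
            assert not np.allclose(beta[1:], marginal, atol=1e-3)

    def test_collinear_timecourses_rejected(self, rng):
        T = 40
        x = rng.standard_normal(T)
        tc = SubjectTimecourses(tc=np.column_stack([x, x * 2.0]))
        thal = Mask(data=np.ones((2, 2, 2), dtype=bool), affine=np.eye(4))
        bold = Volume4D(data=rng.standard_normal((2, 2, 2, T)), affine=np.eye(4))
        with pytest.raises(ValueError, match="components 0 and 1"):
            stage2_subdivisions(bold, tc, thal)

    def test_row_mismatch_rejected(self, rng):
        tc = SubjectTimecourses(tc=rng.standard_normal((30, 2)))
        thal = Mask(data=np.ones((2, 2, 2), dtype=bool), affine=np.eye(4))
        bold = Volume4D(data=rng.standard_normal((2, 2, 2, 40)), affine=np.eye(4))
        with pytest.raises(ValueError):
            stage2_subdivisions(bold, tc, thal)


class TestEndToEndDualRegression:
    def test_noiseless_subject_recovers_thalamic_weights(self, gt_noiseless):
        gt = gt_noiseless
        brain = gt.brain
        vol, _ = simulate_subject(gt, "control", seed=11, confound_leak=0.0)
        dec = _decomposition_from_maps(gt.network_maps, brain)
        _, sub = dual_regress(vol, dec, brain, gt.thalamus)
        for k in range(gt.n_components):
            w = gt.thalamic_weights[k][gt.thalamus.data]
            b = sub.thal_betas[k][gt.thalamus.data]
            r = np.corrcoef(w, b)[0, 1]
            assert abs(r) > 0.999

    def test_component_with_zero_thalamic_weight_gives_null_betas(self, rng):
        gt = make_ground_truth(seed=6, noise_sd=0.0, n_components=3,
                               group_effect={0: 1.0})
        gt.thalamic_weights[2][:] = 0.0  # silence one component in the thalamus
        vol, _ = simulate_subject(gt, "control", seed=2, confound_leak=0.0)
        dec = _decomposition_from_maps(gt.network_maps, gt.brain)
        _, sub = dual_regress(vol, dec, gt.brain, gt.thalamus)
        active = np.abs(sub.thal_betas[0][gt.thalamus.data]).mean()
        silent = np.abs(sub.thal_betas[2][gt.thalamus.data]).mean()
        assert silent < 0.05 * active

    def test_patient_factor_lowers_mean_affected_beta(self, gt):
        # Monte-Carlo direction check at reduced replicate count
        dec = _decomposition_from_maps(gt.network_maps, gt.brain)
        k = 0  # planted factor 0.5
        diffs = []
        for rep in range(15):
            vc, _ = simulate_subject(gt, "control", seed=3000 + rep)
            vp, _ = simulate_subject(gt, "patient", seed=3000 + rep)
            _, sc = dual_regress(vc, dec, gt.brain, gt.thalamus)
            _, sp = dual_regress(vp, dec, gt.brain, gt.thalamus)
            sup = gt.thalamic_weights[k] > 0.5
            diffs.append(sc.thal_betas[k][sup].mean() - sp.thal_betas[k][sup].mean())
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.9

    def test_group_average_support_dice(self, gt, cortex):
        """Group-averaged subdivision maps reproduce the planted thalamic
        weight support at Dice > 0.7 (matched threshold)."""
        from thalnet.preprocess import preprocess_subject
        from thalnet.seedmaps import concatenate_group, thalamic_seed_maps
        from thalnet.spatial_ica import fit_spatial_ica, match_components

        subs = []
        mapsets = []
        vols = []
        for i in range(12):
            vol, conf = simulate_subject(gt, "control", seed=700 + i)
            clean = preprocess_subject(vol, conf)
            vols.append(clean)
            mapsets.append(thalamic_seed_maps(clean, gt.thalamus, gt.brain, f"s{i}"))
        dec = fit_spatial_ica(concatenate_group(mapsets), cortex,
                              n_components=gt.n_components, seed=0)
        matches = match_components(dec, gt.network_maps, brain=cortex)
        for v in vols:
            _, sub = dual_regress(v, dec, gt.brain, gt.thalamus)
            subs.append(sub)
        for comp, ref, r in matches:
            mean_beta = np.sign(r) * np.mean(
                [s.thal_betas[comp] for s in subs], axis=0)
            w = gt.thalamic_weights[ref]
            truth = w > 0.5
            # matched threshold: keep the same number of top voxels
            thal_vals = mean_beta[gt.thalamus.data]
            thr = np.sort(thal_vals)[-truth.sum()]
            pred = (mean_beta >= thr) & gt.thalamus.data
            dice = 2 * (pred & truth).sum() / (pred.sum() + truth.sum())
            assert dice > 0.7
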