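"""Source-based morphometry: order selection, infomax ICA, z-maps, selection."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from errtsem.cohort import CohortConfig, generate_gm, sample_demographics
from errtsem.sbm import (
    GMMatrix,
    InfomaxICA,
    estimate_order,
    infomax_ica,
    select_components,
    stack_to_matrix,
    zscore_threshold,
)


def _phantom(seed=5, n=200, k=4, grid=(14, 14, 14), noise=0.1):
    cfg = CohortConfig(
        n_subjects=n,
        seed=seed,
        gm_age_r2={f"s{i}": 0.2 for i in range(k)},
        gm_corr=np.eye(k) * 0.7 + 0.3,
    )
    demo = sample_demographics(cfg)
    stack, truth = generate_gm(demo, cfg, grid_shape=grid, noise_sd=noise)
    return stack, truth


class TestOrderEstimation:
    def test_planted_rank_recovered(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            L = rng.normal(size=(40, 5))
            M = rng.normal(size=(5, 6000)) ** 2
            X = L @ M + 0.01 * rng.normal(size=(40, 6000))
            k, curve = estimate_order(GMMatrix(data=X))
            assert k == 5
            assert len(curve) == 39  # one value per candidate order

    def test_white_noise_gives_low_order(self):
        low = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(20, 8000))
            k, _ = estimate_order(GMMatrix(data=X))
            low += k <= 2
        assert low >= 9

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3|variance"):
            estimate_order(GMMatrix(data=np.zeros((10, 100))))


class TestInfomax:
    def test_recovers_planted_blobs(self):
        stack, truth = _phantom()
        ica = InfomaxICA(n_components=4, random_state=0).fit(stack)
        S, T = ica.sources_, truth.gm_source_maps.reshape(4, -1)
        C = np.abs(np.corrcoef(np.vstack([S, T]))[:4, 4:])
        ri, ci = linear_sum_assignment(-C)
        assert np.all(C[ri, ci] > 0.9)
        M = ica.mixing_
        Cm = np.abs(
            np.array(
                [
                    [np.corrcoef(M[:, i], truth.gm_loadings[:, j])[0, 1] for j in range(4)]
                    for i in range(4)
                ]
            )
        )
        ri, ci = linear_sum_assignment(-Cm)
        assert Cm[ri, ci].mean() > 0.9

    def test_rank_one_identity(self):
        rng = np.random.default_rng(1)
        load = rng.normal(size=50)
        src = rng.normal(size=400) ** 2
        X = np.outer(load, src)
        ica = InfomaxICA(n_components=1, random_state=0).fit(X)
        r = np.corrcoef(ica.sources_[0], src - src.mean())[0, 1]
        assert abs(r) > 0.999999

    def test_whitened_reconstruction_identity(self):
        stack, _ = _phantom(seed=6)
        ica = InfomaxICA(n_components=4, random_state=0).fit(stack)
        # unmixing is invertible in the whitened space: mixing @ sources
        # reproduces the whitened data exactly (up to PCA truncation)
        Xc = stack.reshape(stack.shape[0], -1) - ica.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        Xk = (U[:, :4] * s[:4]) @ Vt[:4]
        rec = ica.mixing_ @ ica.sources_
        assert np.linalg.norm(Xk - rec) / np.linalg.norm(Xk) < 1e-6

    def test_determinism(self):
        stack, _ = _phantom(seed=7, n=80, grid=(10, 10, 10))
        a = InfomaxICA(n_components=3, random_state=3).fit(stack)
        b = InfomaxICA(n_components=3, random_state=3).fit(stack)
        assert np.array_equal(a.sources_, b.sources_)
        assert np.array_equal(a.mixing_, b.mixing_)

    def test_sources_have_positive_skew(self):
        stack, _ = _phantom(seed=8)
        sset = infomax_ica(stack_to_matrix(stack), k=4)
        from scipy.stats import skew

        assert np.all(skew(sset.sources, axis=1) >= 0)

    def test_k_exceeding_subjects_rejected(self):
        stack, _ = _phantom(seed=9, n=10, grid=(8, 8, 8))
        with pytest.raises(ValueError):
            InfomaxICA(n_components=11).fit(stack)


class TestZMaps:
    def test_gaussian_tail_survival_fraction(self):
        rng = np.random.default_rng(0)
        V = 100000
        z = zscore_threshold(rng.normal(size=V))
        frac = np.mean(z != 0)
        p = 0.0026998  # 2 * P(Z > 3)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / V)

    def test_single_spike_survives_alone(self):
        x = np.zeros(1000)
        x[13] = 50.0
        z = zscore_threshold(x)
        assert np.flatnonzero(z).tolist() == [13]

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        assert np.allclose(zscore_threshold(x), zscore_threshold(5.0 * x + 3.0))

    def test_constant_source_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_threshold(np.ones(100))


class TestSelection:
    def test_phantom_rois_select_exactly_matching_components(self):
        stack, truth = _phantom(seed=10, n=150, k=6, grid=(12, 12, 12), noise=0.05)
        ica = InfomaxICA(n_components=6, random_state=0).fit(stack)
        sset = ica.source_set()
        masks = {
            f"roi{i}": (truth.gm_source_maps[i].reshape(-1) > 0.5)
            for i in range(3)
        }
        chosen = select_components(sset, masks)
        # exactly the three components matching the masked blobs
        assert len(chosen) == 3
        for comp in chosen:
            overlaps = [
                np.sum((sset.z_maps[comp] != 0) & m) / max(np.sum((sset.z_maps[comp] != 0) | m), 1)
                for m in masks.values()
            ]
            assert max(overlaps) >= 0.2

    def test_empty_masks_select_nothing(self):
        stack, _ = _phantom(seed=11, n=80, grid=(10, 10, 10))
        sset = InfomaxICA(n_components=4, random_state=0).fit(stack).source_set()
        assert select_components(sset, {}) == []

    def test_grid_mismatch_rejected(self):
        stack, _ = _phantom(seed=12, n=80, grid=(10, 10, 10))
        sset = InfomaxICA(n_components=4, random_state=0).fit(stack).source_set()
        with pytest.raises(ValueError, match="grid"):
            select_components(sset, {"bad": np.ones(17, dtype=bool)})


class TestNiftiRoundTrip:
    def test_stack_written_and_reloaded(self, tmp_path):
        import nibabel as nib

        from errtsem.sbm import load_nifti_stack

        stack, _ = _phantom(seed=13, n=12, grid=(6, 6, 6))
        vol = np.moveaxis(stack, 0, -1)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "stack.nii.gz")
        gm = load_nifti_stack(tmp_path / "stack.nii.gz")
        assert gm.data.shape == (12, 216)
        assert np.allclose(gm.data, stack.reshape(12, -1))
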