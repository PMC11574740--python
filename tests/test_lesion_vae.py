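"""Lesion scoring: histogram matching, VAE training/backprop, score maps,
median filtering, one-class binarization, ROI volumes."""

import numpy as np
import pytest

from ptemark import lesion_vae as lv
from ptemark import synthetic_cohort as sc


class TestHistogramMatch:
    def test_identity_within_quantization(self, rng):
        v = np.zeros((12, 12, 4))
        mask = np.zeros_like(v, dtype=bool)
        mask[2:10, 2:10, 1:3] = True
        v[mask] = rng.random(mask.sum())
        out = lv.histogram_match(v, v, mask=mask, reference_mask=mask)
        assert np.abs(out[mask] - v[mask]).max() <= 1.0 / mask.sum()

    def test_matched_quantiles_equal_reference(self, rng):
        mask = np.ones((2000,), dtype=bool)
        v = rng.gamma(2.0, 1.0, 2000)
        ref = rng.normal(5.0, 2.0, 2000)
        out = lv.histogram_match(v, ref, mask=mask, reference_mask=mask)
        for q in np.arange(0.1, 0.95, 0.1):
            lo, hi = np.quantile(ref, [max(q - 0.01, 0), min(q + 0.01, 1)])
            assert lo - 1e-9 <= np.quantile(out[mask], q) <= hi + 1e-9

    def test_monotone_transform_recovered(self, rng):
        mask = np.ones(1500, dtype=bool)
        v = rng.random(1500)
        warped = v**3 + 0.5 * v  # strictly increasing
        out = lv.histogram_match(warped, v, mask=mask, reference_mask=mask)
        assert np.abs(np.sort(out) - np.sort(v)).max() <= 1.0 / v.size
        # ranks preserved => pointwise recovery
        assert np.abs(out - v).max() <= 2.0 / v.size + 1e-6

    def test_constant_input_maps_to_reference_median(self, rng):
        v = np.full(100, 0.3)
        ref = rng.random(100)
        out = lv.histogram_match(v, ref, mask=np.ones(100, bool),
                                 reference_mask=np.ones(100, bool))
        assert np.allclose(out, np.median(np.sort(ref)))

    def test_background_untouched(self, rng):
        v = rng.random((8, 8, 2))
        mask = np.zeros_like(v, bool)
        mask[2:6, 2:6, :] = True
        ref = rng.random((8, 8, 2))
        out = lv.histogram_match(v, ref, mask=mask, reference_mask=mask)
        assert np.array_equal(out[~mask], v[~mask])


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 3.5)
        assert np.array_equal(lv.median_filter(img, 7), img)

    def test_single_hot_pixel_removed(self):
        img = np.full((21, 21), 1.0)
        img[10, 10] = 50.0
        out = lv.median_filter(img, 7)
        assert np.array_equal(out, np.full((21, 21), 1.0))

    def test_matches_brute_force_neighborhood_median(self, rng):
        """9x9 hot block survives; every pixel equals the brute-force median
        of its reflect-padded 7x7 neighborhood."""
        img = rng.random((16, 16))
        img[4:13, 4:13] += 10.0
        out = lv.median_filter(img, 7)
        # edge-inclusive reflection, i.e. numpy's "symmetric" padding
        padded = np.pad(img, 3, mode="symmetric")
        for i in range(16):
            for j in range(16):
                expect = np.median(padded[i : i + 7, j : j + 7])
                assert out[i, j] == pytest.approx(expect)
        assert np.all(out[6:11, 6:11] > 5.0)  # block interior survives

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            lv.median_filter(np.zeros((5, 5)), size=4)


class TestVAETraining:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients of the full evidence-bound loss agree with
        central finite differences on a tiny float64 network."""
        arch = lv.VAEArchitecture(input_size=8, channels=(2, 3, 4), latent_dim=2)
        model = lv.build_vae(arch, seed=0, dtype=np.float64)
        x = rng.random((3, 1, 8, 8))
        eps = rng.standard_normal((3, 2))

        def loss():
            val, _, _ = model.loss_and_grads(x, eps, kl_weight=0.7, train=True)
            return val

        loss()
        grads = [g.copy() for g in model.gradients()]
        params = model.parameters()
        h = 1e-6
        picker = np.random.default_rng(2)
        for pi, p in enumerate(params):
            flat = p.reshape(-1)
            for idx in picker.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss()
                flat[idx] = orig - h
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = grads[pi].reshape(-1)[idx]
                if abs(num) < 1e-6 and abs(ana) < 1e-6:
                    continue  # true-zero gradient (e.g. conv bias before BN)
                assert abs(num - ana) / max(abs(num), abs(ana)) < 1e-4

    def test_loss_decreases_on_fixture(self, vae_fixture):
        losses = vae_fixture["model"].epoch_losses
        assert losses[-1] < losses[0]

    def test_training_is_seed_deterministic(self, vae_fixture):
        slices = vae_fixture["train_slices"][:32]
        cfg = lv.TrainConfig(epochs=1, batch_size=16, seed=3)
        m1 = lv.train_vae(slices, vae_fixture["arch"], cfg)
        m2 = lv.train_vae(slices, vae_fixture["arch"], cfg)
        assert m1.final_loss == m2.final_loss

    def test_zero_kl_weight_reduces_to_plain_autoencoder(self, vae_fixture, rng):
        model = lv.build_vae(vae_fixture["arch"], seed=0)
        x = vae_fixture["train_slices"][:4][:, None].astype(np.float32)
        eps = rng.standard_normal((4, model.architecture.latent_dim)).astype(np.float32)
        total, recon, kl = model.loss_and_grads(x, eps, kl_weight=0.0)
        assert total == pytest.approx(recon)
        assert kl >= 0  # KL computed but not contributing

    def test_nonfinite_loss_aborts_with_location(self, vae_fixture):
        slices = vae_fixture["train_slices"][:16].copy()
        slices[0, 0, 0] = np.nan
        with pytest.raises(RuntimeError, match="epoch 0"):
            lv.train_vae(slices, vae_fixture["arch"],
                         lv.TrainConfig(epochs=1, batch_size=16, seed=0))


class TestReconstructAndScore:
    def test_output_shape_and_determinism(self, vae_fixture):
        sl = vae_fixture["train_slices"][0]
        r1 = lv.reconstruct(vae_fixture["model"], sl)
        r2 = lv.reconstruct(vae_fixture["model"], sl)
        assert r1.shape == sl.shape
        assert np.array_equal(r1, r2)

    def test_shape_mismatch_rejected(self, vae_fixture):
        with pytest.raises(ValueError):
            lv.reconstruct(vae_fixture["model"], np.zeros((16, 16)))

    def test_lesioned_slices_reconstruct_worse_than_clean(self, vae_fixture):
        model = vae_fixture["model"]
        errs = {"clean": [], "lesioned": []}
        for key in errs:
            for vol in vae_fixture[key]:
                for sl in lv.extract_brain_slices([vol], 32):
                    errs[key].append(np.mean((sl - lv.reconstruct(model, sl)) ** 2))
        assert np.mean(errs["lesioned"]) > np.mean(errs["clean"])

    def test_identical_pair_scores_zero(self, rng):
        v = rng.random((16, 16))
        assert np.all(lv.score_from_difference(v, v) == 0)

    def test_score_map_nonnegative_and_localized(self, vae_fixture):
        """Median-filtered reconstruction error concentrates inside the
        planted lesions (mean in-lesion score > 2x mean outside)."""
        model, parc = vae_fixture["model"], vae_fixture["parc"]
        ratios = []
        for vol, mask in zip(vae_fixture["lesioned"], vae_fixture["masks"]):
            if not mask.any():
                continue
            smap = lv.lesion_score_map(model, vol)
            assert smap.min() >= 0
            inb = parc.brain_mask
            ratios.append(smap[mask].mean() / smap[inb & ~mask].mean())
        assert np.mean(ratios) > 2.0

    def test_checkpoint_roundtrip(self, vae_fixture, tmp_path):
        model = vae_fixture["model"]
        path = tmp_path / "vae.npz"
        lv.save_model(model, path)
        loaded = lv.load_model(path)
        sl = vae_fixture["train_slices"][1]
        assert np.array_equal(lv.reconstruct(model, sl), lv.reconstruct(loaded, sl))
        assert loaded.epoch_losses == model.epoch_losses


class TestBinarize:
    def test_identical_maps_give_empty_masks(self):
        assert not lv.binarize_lesions(np.ones((10, 20)), nu=0.1).any()

    def test_gaussian_flagged_fraction_near_nu(self, rng):
        scores = rng.normal(1.0, 0.3, size=(100, 30))
        frac = lv.binarize_lesions(scores, nu=0.1).mean(axis=0)
        assert frac.min() >= 0.02 and frac.max() <= 0.30

    def test_extreme_subject_flagged(self):
        for rep in range(5):
            r = np.random.default_rng(100 + rep)
            x = r.normal(0.05, 0.01, size=(20, 4))
            x[7, 2] = 0.05 + 10 * 0.01
            assert lv.binarize_lesions(x, nu=0.1)[7, 2]

    def test_subject_permutation_equivariance(self, rng):
        scores = rng.normal(0.0, 1.0, size=(30, 25))
        perm = rng.permutation(30)
        m1 = lv.binarize_lesions(scores, nu=0.1)
        m2 = lv.binarize_lesions(scores[perm], nu=0.1)
        assert np.array_equal(m1[perm], m2)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            lv.binarize_lesions(rng.random((5, 10)), nu=0.1)  # too few subjects
        with pytest.raises(ValueError):
            lv.binarize_lesions(rng.random((10, 10)), nu=1.5)


class TestRoiLesionVolumes:
    def test_empty_mask_gives_zero_vector(self, parc_small):
        vols = lv.roi_lesion_volumes(
            np.zeros_like(parc_small.label_volume, bool), parc_small
        )
        assert vols.shape == (15,) and not vols.any()

    def test_full_roi_counted_at_its_position(self, parc_small):
        mask = parc_small.label_volume == 3
        vols = lv.roi_lesion_volumes(mask, parc_small)
        expect = np.zeros(15, dtype=int)
        expect[2] = mask.sum()
        assert np.array_equal(vols, expect)

    def test_hand_placed_straddling_mask(self, parc_small):
        mask = np.zeros_like(parc_small.label_volume, bool)
        roi1 = np.argwhere(parc_small.label_volume == 1)[:3]
        roi2 = np.argwhere(parc_small.label_volume == 2)[:2]
        mask[tuple(roi1.T)] = True
        mask[tuple(roi2.T)] = True
        vols = lv.roi_lesion_volumes(mask, parc_small)
        assert vols[0] == 3 and vols[1] == 2 and vols[2:].sum() == 0

    def test_volume_conservation(self, vae_fixture):
        parc = vae_fixture["parc"]
        mask = vae_fixture["masks"][0] & parc.brain_mask
        vols = lv.roi_lesion_volumes(mask, parc)
        assert vols.sum() == mask.sum()


def test_architecture_validation():
    with pytest.raises(ValueError):
        lv.VAEArchitecture(input_size=30)  # not divisible by 8
    with pytest.raises(ValueError):
        lv.VAEArchitecture(latent_dim=0)
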