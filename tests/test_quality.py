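"""Natural-scene-statistics quality scoring, gating, and stationarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as gamma_fn
from scipy.stats import spearmanr

from octriage.exceptions import (
    DegenerateInputError,
    DomainError,
    ModelFitError,
)
from octriage.io import CohortManifest
from octriage.quality import (
    Niqe,
    compute_mscn,
    fit_aggd,
    gate_frames,
    stationarity,
)
from octriage.synth import apply_quality_drift, default_profiles, generate_bscan


class TestMscn:
    def test_constant_image_gives_zero_field(self):
        assert np.all(compute_mscn(np.full((64, 64), 0.4)) == 0.0)

    def test_normalizes_iid_noise_locally(self):
        rng = np.random.default_rng(0)
        mscn = compute_mscn(rng.random((128, 128)), scale=2.5)
        interior = mscn[16:-16, 16:-16]
        assert abs(interior.mean()) < 0.1
        assert abs(interior.std() - 1.0) < 0.1

    def test_contrast_invariance_up_to_stabilizer(self):
        rng = np.random.default_rng(1)
        img = rng.random((96, 96))  # full contrast keeps C effects small
        delta = np.abs(compute_mscn(2 * img) - compute_mscn(img)).max()
        assert delta < 0.05

    def test_small_image_rejected(self):
        with pytest.raises(DomainError):
            compute_mscn(np.zeros((16, 16)))


def _ml_aggd_alpha(x: np.ndarray) -> float:
    """Brute-force grid-search ML fit of the AGGD shape (test oracle)."""
    best, best_ll = None, -np.inf
    for alpha in np.arange(0.3, 4.0, 0.01):
        for frac in (0.35, 0.5, 0.65):  # crude asymmetry grid
            left, right = x[x < 0], x[x >= 0]
            conv = np.sqrt(gamma_fn(1 / alpha) / gamma_fn(3 / alpha))
            bl = max(np.sqrt(np.mean(left**2)) * conv, 1e-9) * (frac / 0.5)
            br = max(np.sqrt(np.mean(right**2)) * conv, 1e-9) * ((1 - frac) / 0.5)
            norm = alpha / ((bl + br) * gamma_fn(1 / alpha))
            ll = (
                x.size * np.log(norm)
                - np.sum((np.abs(left) / bl) ** alpha)
                - np.sum((right / br) ** alpha)
            )
            if ll > best_ll:
                best, best_ll = alpha, ll
    return best


class TestAggd:
    def test_recovers_gaussian_shape(self):
        x = np.random.default_rng(0).normal(size=100_000)
        p = fit_aggd(x)
        assert 1.8 <= p.alpha <= 2.2
        assert abs(p.beta_l - p.beta_r) / p.beta_l < 0.1

    def test_recovers_laplace_shape(self):
        x = np.random.default_rng(0).laplace(size=100_000)
        p = fit_aggd(x)
        assert 0.85 <= p.alpha <= 1.15

    def test_right_skew_gives_larger_right_scale(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([-np.abs(rng.normal(0, 0.5, 5000)), np.abs(rng.normal(0, 1.5, 5000))])
        p = fit_aggd(x)
        assert p.beta_r > p.beta_l

    def test_agrees_with_ml_grid_search(self):
        rng = np.random.default_rng(3)
        x = rng.laplace(size=10_000)
        moment_alpha = fit_aggd(x).alpha
        ml_alpha = _ml_aggd_alpha(x)
        assert abs(moment_alpha - ml_alpha) / ml_alpha < 0.10

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(DegenerateInputError):
            fit_aggd(np.full(500, 1.3))
        with pytest.raises(DomainError):
            fit_aggd(np.arange(50.0))


class TestNiqe:
    def test_refit_is_deterministic(self, cfg):
        imgs = [
            np.random.default_rng(i).random((128, 192)) for i in range(20)
        ]
        m1 = Niqe(min_images=20).fit(imgs)
        m2 = Niqe(min_images=20).fit(imgs)
        assert np.array_equal(m1.nu_, m2.nu_)
        assert np.array_equal(m1.sigma_, m2.sigma_)

    def test_zero_distance_when_features_match_model(self, example_scan):
        model = Niqe(min_images=1)
        feats = model._image_patch_features(example_scan.intensity, select_sharp=False)
        model.nu_ = feats.mean(axis=0)
        model.sigma_ = np.cov(feats, rowvar=False)
        assert model.score_image(example_scan.intensity) == pytest.approx(0.0, abs=1e-8)

    def test_blur_monotonically_raises_score(self, niqe_model, example_scan):
        img = example_scan.intensity
        s0 = niqe_model.score_image(img)
        s1 = niqe_model.score_image(gaussian_filter(img, 1.0))
        s3 = niqe_model.score_image(gaussian_filter(img, 3.0))
        assert s3 > s1 > s0

    def test_additive_noise_raises_score_20_of_20(self, niqe_model):
        profiles = default_profiles()
        rng = np.random.default_rng(0)
        names = sorted(profiles)
        for i in range(20):
            model = profiles[names[i % 6]].sample_tissue_model("buccal", rng)
            img = generate_bscan(model, seed=500 + i).intensity
            noisy = np.clip(img + np.random.default_rng(i).normal(0, 0.1, img.shape), 0, 1)
            assert niqe_model.score_image(noisy) > niqe_model.score_image(img)

    def test_intensity_scaling_leaves_score_nearly_unchanged(
        self, niqe_model, example_scan
    ):
        img = 0.5 * example_scan.intensity
        assert abs(
            niqe_model.score_image(img) - niqe_model.score_image(example_scan.intensity)
        ) <= 0.05

    def test_dropout_raises_score(self, niqe_model, example_scan):
        img = example_scan.intensity.copy()
        mask = np.random.default_rng(0).random(img.shape) < 0.1
        img[mask] = 0.0
        assert niqe_model.score_image(img) > niqe_model.score_image(
            example_scan.intensity
        )

    def test_single_patch_corpus_is_rank_deficient(self):
        img = np.random.default_rng(0).random((96, 96))
        with pytest.raises(ModelFitError):
            Niqe(min_images=1).fit([img])

    def test_image_below_two_patches_cannot_be_scored(self, niqe_model):
        with pytest.raises(DomainError):
            niqe_model.score_image(np.random.default_rng(0).random((96, 96)))

    def test_corpus_smaller_than_minimum_rejected(self):
        with pytest.raises(DomainError):
            Niqe(min_images=20).fit([np.zeros((96, 192))] * 5)


def _mini_manifest(n_sites=3, n_frames=14):
    rows = []
    for s in range(n_sites):
        for f in range(n_frames):
            rows.append(
                {
                    "subject_id": f"subj{s}",
                    "site_id": f"site{s}",
                    "anatomic_site": "buccal",
                    "frame_index": f,
                    "image_path": f"{s}_{f}.png",
                    "diagnosis": "normal",
                    "split": "none",
                }
            )
    return CohortManifest(pd.DataFrame(rows))


class TestGateFrames:
    def test_infinite_threshold_is_identity(self):
        m = _mini_manifest()
        scores = np.linspace(1, 5, len(m))
        kept, report = gate_frames(m, scores, np.inf)
        assert len(kept) == len(m)
        assert not report["all_dropped"].any()

    def test_negative_threshold_drops_everything_and_flags(self):
        m = _mini_manifest()
        kept, report = gate_frames(m, np.ones(len(m)), -1.0)
        assert len(kept) == 0
        assert report["all_dropped"].all()

    def test_drift_increases_drop_fraction_with_frame_index(self, niqe_model):
        """Later frames of a drifting site fail the gate more often."""
        profiles = default_profiles()
        rng = np.random.default_rng(0)
        frac_dropped = []
        per_idx = {i: [] for i in range(14)}
        for s in range(3):
            model = profiles["normal"].sample_tissue_model("buccal", rng)
            base = generate_bscan(model, seed=700 + s).intensity
            for idx in range(14):
                img = apply_quality_drift(base, idx, 0.03, noise_seed=900 + idx)
                per_idx[idx].append(
                    niqe_model.score_image(img) > niqe_model.gate_threshold_
                )
        idxs = sorted(per_idx)
        frac_dropped = [np.mean(per_idx[i]) for i in idxs]
        rho, _ = spearmanr(idxs, frac_dropped)
        assert rho > 0


class TestStationarity:
    def test_trend_rejected_by_kpss(self):
        rng = np.random.default_rng(0)
        x = 0.01 * np.arange(200) + rng.normal(0, 0.05, 200)
        _, _, _, kpss_p = stationarity(x)
        assert kpss_p <= 0.05

    def test_iid_noise_rejects_unit_root(self):
        x = np.random.default_rng(0).normal(size=200)
        _, adf_p, _, _ = stationarity(x)
        assert adf_p <= 0.05

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            stationarity(np.arange(10.0))

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateInputError):
            stationarity(np.full(50, 2.0))
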