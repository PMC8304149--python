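"""No-reference frame quality: natural-scene-statistics scoring and gating.

The quality score follows the NIQE recipe: compute mean-subtracted
contrast-normalized (MSCN) coefficients, summarize them and their four
orientation pairwise products with (asymmetric) generalized Gaussian fits on
sharp patches at two scales, model the pristine corpus as a multivariate
Gaussian over those 36 features, and score a test frame by the Mahalanobis
distance between its feature statistics and the corpus model (pooled
covariance, pseudo-inverse). Larger = worse. The pristine corpus here is
high-quality synthetic output: the pipeline needs a quality *ranking* for
gating, not an absolute perceptual scale.

Stationarity of the per-acquisition quality series is assessed with the
standard complementary pair: ADF (unit-root null) and KPSS (stationarity
null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom
from scipy.special import gamma as gamma_fn
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateInputError,
    DomainError,
    ModelFitError,
)
from .io import CohortManifest

_ALPHA_GRID = np.arange(0.05, 10.0, 0.001)
_RHO_GRID = (gamma_fn(2.0 / _ALPHA_GRID) ** 2) / (
    gamma_fn(1.0 / _ALPHA_GRID) * gamma_fn(3.0 / _ALPHA_GRID)
)


@dataclass(frozen=True)
class AggdParams:
    """Asymmetric generalized Gaussian parameters from moment matching."""

    alpha: float
    beta_l: float
    beta_r: float
    eta: float


def compute_mscn(
    image: np.ndarray, scale: float = 7.0 / 6.0, c: float = 1.0 / 255.0
) -> np.ndarray:
    """Locally mean-subtracted, contrast-normalized coefficients.

    ``(I - mu) / (sd + C)`` with Gaussian-weighted local moments at the given
    window scale. A constant image yields an all-zero field.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 32:
        raise DomainError("image must be 2-D and at least 32x32")
    if c <= 0 or scale <= 0:
        raise DomainError("scale and stabilizer C must be positive")
    if np.ptp(image) == 0:  # degenerate constant image -> exact zero field
        return np.zeros_like(image)
    mu = gaussian_filter(image, scale, mode="nearest")
    sigma = np.sqrt(
        np.maximum(gaussian_filter(image * image, scale, mode="nearest") - mu * mu, 0.0)
    )
    return (image - mu) / (sigma + c)


def fit_aggd(samples: np.ndarray) -> AggdParams:
    """Fit an asymmetric generalized Gaussian by the moment-ratio inversion.

    Left/right scales come from the one-sided second moments; the shape is
    read off the generalized-Gaussian moment-ratio function on a fine grid
    and clamped to [0.05, 10].
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise DomainError(f"need >= 100 finite samples, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all samples identical; AGGD fit is degenerate")

    left = x[x < 0]
    right = x[x >= 0]
    # epsilon guards one-sided moments when a side is (nearly) empty
    sigma_l = np.sqrt(np.mean(left**2)) if left.size else 1e-12
    sigma_r = np.sqrt(np.mean(right**2)) if right.size else 1e-12
    sigma_l = max(sigma_l, 1e-12)
    sigma_r = max(sigma_r, 1e-12)
    gamma_ratio = sigma_l / sigma_r
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x**2)
    big_r = r_hat * (gamma_ratio**3 + 1.0) * (gamma_ratio + 1.0) / (
        (gamma_ratio**2 + 1.0) ** 2
    )
    alpha = float(_ALPHA_GRID[np.argmin((_RHO_GRID - big_r) ** 2)])
    conv = np.sqrt(gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha))
    beta_l = float(sigma_l * conv)
    beta_r = float(sigma_r * conv)
    eta = float((beta_r - beta_l) * gamma_fn(2.0 / alpha) / gamma_fn(1.0 / alpha))
    return AggdParams(alpha=alpha, beta_l=beta_l, beta_r=beta_r, eta=eta)


def _fit_ggd(samples: np.ndarray) -> tuple[float, float]:
    """Symmetric generalized Gaussian (shape, variance) via moment matching."""
    x = np.asarray(samples, dtype=float).ravel()
    var = np.mean(x**2)
    if var <= 0:
        return 2.0, 0.0
    rho = np.mean(np.abs(x)) ** 2 / var
    alpha = float(_ALPHA_GRID[np.argmin((_RHO_GRID - rho) ** 2)])
    return alpha, float(var)


_SHIFTS = ((0, 1), (1, 0), (1, 1), (1, -1))  # H, V, D1, D2 neighbours


def _patch_features(mscn: np.ndarray) -> np.ndarray:
    """18 features of one patch: GGD of MSCN + AGGD of 4 pairwise products."""
    feats = list(_fit_ggd(mscn))
    for dr, dc in _SHIFTS:
        if dc >= 0:
            prod = mscn[dr:, dc:] * mscn[: mscn.shape[0] - dr, : mscn.shape[1] - dc]
        else:
            prod = mscn[dr:, :dc] * mscn[: mscn.shape[0] - dr, -dc:]
        try:
            p = fit_aggd(prod)
            feats.extend([p.alpha, p.eta, p.beta_l, p.beta_r])
        except DegenerateInputError:
            feats.extend([2.0, 0.0, 0.0, 0.0])
    return np.array(feats)


class Niqe(BaseEstimator):
    """Pristine-corpus natural-scene-statistics quality model.

    Parameters
    ----------
    patch_size : int
        Full-scale patch edge (halved at the second scale).
    sharpness_fraction : float
        Corpus patches are kept when their mean local contrast reaches this
        fraction of the sharpest patch's.
    c : float
        MSCN contrast stabilizer, on the [0, 1] intensity scale.
    window_sigma : float
        Gaussian window scale for the local MSCN moments.
    min_images : int
        Minimum pristine corpus size.
    gate_percentile : float
        Percentile of the corpus self-scores stored as ``gate_threshold_``.

    Attributes
    ----------
    nu_ : ndarray of shape (36,)
        Corpus feature mean.
    sigma_ : ndarray of shape (36, 36)
        Corpus feature covariance.
    gate_threshold_ : float
        Default quality gate calibrated on the corpus self-scores.
    """

    def __init__(
        self,
        patch_size: int = 96,
        sharpness_fraction: float = 0.75,
        c: float = 1.0 / 255.0,
        window_sigma: float = 7.0 / 6.0,
        min_images: int = 20,
        gate_percentile: float = 97.5,
    ):
        self.patch_size = patch_size
        self.sharpness_fraction = sharpness_fraction
        self.c = c
        self.window_sigma = window_sigma
        self.min_images = min_images
        self.gate_percentile = gate_percentile

    def _image_patch_features(
        self, image: np.ndarray, select_sharp: bool
    ) -> np.ndarray:
        """(n_patches, 36) feature rows for one image, two scales.

        The image is min-max normalized first, so the score is exactly
        invariant to global intensity scaling and offset.
        """
        image = np.asarray(image, dtype=float)
        span = np.ptp(image)
        if span > 0:
            image = (image - image.min()) / span
        p = self.patch_size
        n_r, n_c = image.shape[0] // p, image.shape[1] // p
        if n_r * n_c < 1:
            raise DomainError(
                f"image {image.shape} holds no {p}x{p} patch; too small to score"
            )
        half = zoom(image, 0.5, order=1, mode="nearest", grid_mode=True)
        mscn1 = compute_mscn(image, self.window_sigma, self.c)
        mscn2 = compute_mscn(half, self.window_sigma, self.c)

        mu = gaussian_filter(image, self.window_sigma, mode="nearest")
        sd = np.sqrt(
            np.maximum(
                gaussian_filter(image * image, self.window_sigma, mode="nearest")
                - mu * mu,
                0.0,
            )
        )

        rows = []
        sharpness = []
        for i in range(n_r):
            for j in range(n_c):
                sl1 = np.s_[i * p : (i + 1) * p, j * p : (j + 1) * p]
                h = p // 2
                sl2 = np.s_[i * h : (i + 1) * h, j * h : (j + 1) * h]
                rows.append(
                    np.concatenate([_patch_features(mscn1[sl1]), _patch_features(mscn2[sl2])])
                )
                sharpness.append(float(sd[sl1].mean()))
        feats = np.array(rows)
        if select_sharp and len(rows) > 1:
            sharp = np.array(sharpness)
            feats = feats[sharp >= self.sharpness_fraction * sharp.max()]
            if feats.shape[0] == 0:
                raise ModelFitError("no patch passes the sharpness threshold")
        return feats

    def fit(self, images: list[np.ndarray], y: object = None) -> "Niqe":
        """Fit the corpus Gaussian over sharp-patch features of ``images``."""
        if len(images) < self.min_images:
            raise DomainError(
                f"pristine corpus needs >= {self.min_images} images, got {len(images)}"
            )
        blocks = [self._image_patch_features(img, select_sharp=True) for img in images]
        feats = np.vstack(blocks)
        if feats.shape[0] < 2:
            raise ModelFitError(
                "corpus yields a single patch; covariance is rank-deficient"
            )
        nu = feats.mean(axis=0)
        sigma = np.cov(feats, rowvar=False)
        if not np.any(sigma):
            raise ModelFitError("corpus patches are identical; covariance is zero")
        self.nu_ = nu
        self.sigma_ = sigma
        self.n_patches_ = feats.shape[0]
        self.self_scores_ = np.array([self.score_image(img) for img in images])
        self.gate_threshold_ = float(
            np.percentile(self.self_scores_, self.gate_percentile)
        )
        return self

    def score_image(self, image: np.ndarray) -> float:
        """Quality distance of one frame to the pristine model (0 = pristine)."""
        if not hasattr(self, "nu_"):
            raise ModelFitError("model is not fitted")
        feats = self._image_patch_features(np.asarray(image, float), select_sharp=False)
        if feats.shape[0] < 2:
            raise DomainError("image is smaller than 2 patches; cannot score")
        nu2 = feats.mean(axis=0)
        sigma2 = np.cov(feats, rowvar=False)
        d = self.nu_ - nu2
        pooled = (self.sigma_ + sigma2) / 2.0
        val = float(d @ np.linalg.pinv(pooled) @ d)
        return float(np.sqrt(max(val, 0.0)))

    def score_images(self, images: list[np.ndarray]) -> np.ndarray:
        return np.array([self.score_image(img) for img in images])


def niqe_score(image: np.ndarray, model: Niqe) -> float:
    """Functional wrapper over :meth:`Niqe.score_image`."""
    return model.score_image(image)


def gate_frames(
    manifest: CohortManifest,
    scores: pd.Series | np.ndarray,
    threshold: float,
) -> tuple[CohortManifest, pd.DataFrame]:
    """Drop frames whose quality score exceeds the gate threshold.

    Returns the filtered manifest plus a per-site report with kept/dropped
    frame counts; sites losing every frame are flagged for review.
    """
    df = manifest.df.copy()
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(df):
        raise DomainError("need exactly one score per manifest frame")
    df["niqe_score"] = scores
    df["pass"] = df["niqe_score"] <= threshold
    kept = df[df["pass"]].drop(columns=["pass"])
    report = (
        df.groupby("site_id", sort=False)
        .agg(n_frames=("frame_index", "size"), n_kept=("pass", "sum"))
        .reset_index()
    )
    report["n_dropped"] = report["n_frames"] - report["n_kept"]
    report["all_dropped"] = report["n_kept"] == 0
    filtered = CohortManifest(kept.drop(columns=["niqe_score"]))
    return filtered, report


def stationarity(series: np.ndarray) -> tuple[float, float, float, float]:
    """ADF and KPSS statistics/p-values of an acquisition-order quality series.

    ADF tests the unit-root null (lag order by AIC); KPSS tests the
    level-stationarity null with its default bandwidth. KPSS p-values are
    table-clipped to [0.01, 0.10] by the underlying implementation.
    """
    from statsmodels.tsa.stattools import adfuller, kpss

    x = np.asarray(series, dtype=float).ravel()
    if x.size < 20:
        raise DomainError(f"series must have length >= 20, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no stationarity content")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adf_stat, adf_p, *_ = adfuller(x, autolag="AIC")
        kpss_stat, kpss_p, *_ = kpss(x, regression="c", nlags="auto")
    return float(adf_stat), float(adf_p), float(kpss_stat), float(kpss_p)
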