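"""Synthetic oral-mucosa OCT B-scan and cohort generator.

The forward model is deliberately minimal: a layered mean intensity profile
(air gap, optional bright keratin band, epithelium with exponential depth
decay ``exp(-2 * mu_epi * dz)``, a 2-px bright basement-membrane line scaled
by a contrast parameter, stroma decaying with its own coefficient) multiplied
by unit-mean multiplicative gamma speckle and clipped to ``[0, 1]``. No
polarization, refraction or wave optics. Dorsal-tongue frames additionally
carry a keratin cap and vertical shadow stripes mimicking papillae.

Class profiles encode what distinguishes the diagnostic groups in this model:
carcinoma has the shallowest depth decay and a destroyed basement membrane,
dysplasia intermediate decay and weakened membrane contrast, normal/benign
tissue the steepest decay and a crisp membrane. Epithelial thickness scales
with anatomic site (floor of mouth thinnest, buccal mucosa thickest). Frame
quality degrades linearly with acquisition order (Gaussian blur plus additive
noise), giving the quality-gating stage real signal to act on.
"""

from __future__ import annotations

import math
from collections.abc import Iterator
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .bscan import AXIAL_PITCH_UM, LATERAL_PITCH_UM, BScan, DeviceFrame
from .config import SynthConfig
from .exceptions import DomainError
from .io import ANATOMIC_SITES, DIAGNOSES, CohortManifest, write_image

#: d(log10 I)/d(row) = -SLOPE_PER_MU * mu  for decay exp(-2 * mu * pitch * row).
SLOPE_PER_MU = 2.0 * AXIAL_PITCH_UM * math.log10(math.e)

#: Multiplier applied to the class-level epithelial thickness per anatomic
#: site; encodes the floor-of-mouth < ventral tongue < ... < buccal ordering.
SITE_THICKNESS_FACTOR = {
    "floor_of_mouth": 0.60,
    "tongue_ventral": 0.80,
    "labial": 0.90,
    "gingiva": 0.95,
    "palate": 1.00,
    "other": 1.00,
    "tongue_dorsal": 1.05,
    "buccal": 1.25,
}

DEFAULT_SITE_MIX = {
    "buccal": 0.35,
    "labial": 0.15,
    "tongue_dorsal": 0.08,
    "tongue_ventral": 0.08,
    "floor_of_mouth": 0.08,
    "palate": 0.08,
    "gingiva": 0.10,
    "other": 0.08,
}

_SURFACE_FRACTION = 0.15
_SURFACE_WOBBLE_PX = 2.5
_BACKGROUND = 0.02
_SURFACE_I0 = 0.85
_KERATIN_BRIGHTNESS = 0.90
_BM_ROWS = 2
_BM_BRIGHTNESS = 0.60
_DORSAL_KERATIN_UM = 35.0
_SPECKLE_NOISELESS = 1.0e6


@dataclass(frozen=True)
class TissueModel:
    """Per-site ground-truth tissue parameters of the forward model."""

    epithelial_thickness_um: float
    basement_membrane_contrast: float
    epithelium_attenuation_per_um: float
    stroma_attenuation_per_um: float
    keratin_layer_um: float = 0.0
    papillae_shadowing: bool = False
    speckle_shape: float = 9.0

    def __post_init__(self) -> None:
        if self.epithelial_thickness_um <= 0:
            raise DomainError("epithelial_thickness_um must be > 0")
        if self.epithelial_thickness_um < AXIAL_PITCH_UM:
            raise DomainError("epithelial thickness truncates below 1 axial pixel")
        if not 0.0 <= self.basement_membrane_contrast <= 1.0:
            raise DomainError("basement_membrane_contrast must be in [0, 1]")
        if self.epithelium_attenuation_per_um <= 0 or self.stroma_attenuation_per_um <= 0:
            raise DomainError("attenuation coefficients must be > 0")
        if self.keratin_layer_um < 0:
            raise DomainError("keratin_layer_um must be >= 0")
        if self.speckle_shape <= 0:
            raise DomainError("speckle_shape must be > 0")


@dataclass(frozen=True)
class FieldDist:
    """Clipped-normal sampling distribution for one tissue parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), self.lo, self.hi))


def _mu_dist(target_score: float, sd_score: float = 0.0025) -> FieldDist:
    """Attenuation distribution whose ideal decay slope equals a score target."""
    mu = abs(target_score) / SLOPE_PER_MU
    sd = sd_score / SLOPE_PER_MU
    return FieldDist(mu, sd, mu - 5 * sd, mu + 5 * sd)


@dataclass(frozen=True)
class ClassProfile:
    """Sampling distributions for one diagnosis class plus its quality drift."""

    diagnosis: str
    epithelial_thickness_um: FieldDist
    basement_membrane_contrast: FieldDist
    epithelium_attenuation_per_um: FieldDist
    stroma_attenuation_per_um: FieldDist
    keratin_layer_um: FieldDist = FieldDist(0.0, 0.0, 0.0, 0.0)
    speckle_shape: float = 9.0
    #: Blur sigma added per acquisition index; additive noise sd grows at
    #: rate / SynthConfig.drift_noise_divisor per index.
    quality_drift_rate: float = 0.03

    def sample_tissue_model(
        self, anatomic_site: str, rng: np.random.Generator
    ) -> TissueModel:
        if anatomic_site not in SITE_THICKNESS_FACTOR:
            raise DomainError(f"unknown anatomic site {anatomic_site!r}")
        thickness = self.epithelial_thickness_um.sample(rng)
        thickness *= SITE_THICKNESS_FACTOR[anatomic_site]
        keratin = self.keratin_layer_um.sample(rng)
        if anatomic_site == "tongue_dorsal":
            keratin += _DORSAL_KERATIN_UM
        return TissueModel(
            epithelial_thickness_um=max(thickness, AXIAL_PITCH_UM),
            basement_membrane_contrast=self.basement_membrane_contrast.sample(rng),
            epithelium_attenuation_per_um=self.epithelium_attenuation_per_um.sample(rng),
            stroma_attenuation_per_um=self.stroma_attenuation_per_um.sample(rng),
            keratin_layer_um=max(keratin, 0.0),
            papillae_shadowing=anatomic_site == "tongue_dorsal",
            speckle_shape=self.speckle_shape,
        )


#: Published class-mean score targets on the device's score scale.
CLASS_SCORE_TARGETS = {
    "oscc": -0.0651,
    "dysplasia": -0.0828,
    "normal_benign": -0.0943,
}


def score_group(diagnosis: str) -> str:
    """Map a diagnosis label onto its score-band group."""
    if diagnosis == "oscc":
        return "oscc"
    if diagnosis.endswith("_dysplasia"):
        return "dysplasia"
    return "normal_benign"


def default_profiles() -> dict[str, ClassProfile]:
    """Calibrated per-diagnosis profiles (six classes, one profile each)."""

    def thick(mean: float, sd: float) -> FieldDist:
        return FieldDist(mean, sd, 120.0, 450.0)

    def bm(mean: float) -> FieldDist:
        return FieldDist(mean, 0.05, 0.0, 1.0) if mean > 0 else FieldDist(0, 0, 0, 0)

    mu_norm = _mu_dist(CLASS_SCORE_TARGETS["normal_benign"])
    mu_dys = _mu_dist(CLASS_SCORE_TARGETS["dysplasia"])
    mu_oscc = _mu_dist(CLASS_SCORE_TARGETS["oscc"])

    spec = {
        "normal": (thick(230, 18), bm(0.65), mu_norm),
        "benign": (thick(240, 18), bm(0.60), mu_norm),
        "mild_dysplasia": (thick(270, 20), bm(0.45), mu_dys),
        "moderate_dysplasia": (thick(285, 22), bm(0.40), mu_dys),
        "severe_dysplasia": (thick(300, 24), bm(0.35), mu_dys),
        "oscc": (thick(330, 28), bm(0.0), mu_oscc),
    }
    return {
        dx: ClassProfile(
            diagnosis=dx,
            epithelial_thickness_um=t,
            basement_membrane_contrast=b,
            epithelium_attenuation_per_um=mu,
            stroma_attenuation_per_um=mu,
        )
        for dx, (t, b, mu) in spec.items()
    }


def generate_bscan(
    model: TissueModel,
    height: int = 256,
    width: int = 384,
    seed: int = 0,
    surface_wobble_px: float = _SURFACE_WOBBLE_PX,
) -> BScan:
    """Render one noiseless-layer-profile-times-speckle B-scan.

    Identical ``(model, height, width, seed)`` produce bit-identical grids.
    Speckle shapes >= 1e6 are treated as the noise-free limit and skipped.
    """
    if height < 64 or width < 64:
        raise DomainError(f"dimensions must be >= 64, got {height}x{width}")
    rng = np.random.default_rng(seed)

    base_row = int(round(_SURFACE_FRACTION * height))
    phase = rng.uniform(0, 2 * math.pi)
    cols = np.arange(width)
    surface = base_row + np.rint(
        surface_wobble_px * np.sin(2 * math.pi * cols / width + phase)
    ).astype(int)
    surface = np.clip(surface, 1, height // 2)

    k_px = int(round(model.keratin_layer_um / AXIAL_PITCH_UM))
    t_px = max(1, int(round(model.epithelial_thickness_um / AXIAL_PITCH_UM)))
    mu_e = model.epithelium_attenuation_per_um
    mu_s = model.stroma_attenuation_per_um

    rows = np.arange(height)[:, None]
    epi_top = surface[None, :] + k_px
    depth = rows - epi_top  # rows below the epithelium top, in pixels

    img = np.full((height, width), _BACKGROUND)
    in_keratin = (rows >= surface[None, :]) & (rows < epi_top)
    img[in_keratin] = _KERATIN_BRIGHTNESS

    decay_e = _SURFACE_I0 * np.exp(-2.0 * mu_e * AXIAL_PITCH_UM * np.maximum(depth, 0))
    in_epi = (depth >= 0) & (depth < t_px)
    img[in_epi] = decay_e[in_epi]

    boundary_val = _SURFACE_I0 * math.exp(-2.0 * mu_e * AXIAL_PITCH_UM * t_px)
    decay_s = boundary_val * np.exp(
        -2.0 * mu_s * AXIAL_PITCH_UM * np.maximum(depth - t_px, 0)
    )
    in_stroma = depth >= t_px
    img[in_stroma] = decay_s[in_stroma]

    if model.basement_membrane_contrast > 0:
        in_bm = (depth >= t_px) & (depth < t_px + _BM_ROWS)
        img[in_bm] = np.maximum(
            img[in_bm], _BM_BRIGHTNESS * model.basement_membrane_contrast
        )

    if model.papillae_shadowing:
        shade = np.ones(width)
        for _ in range(int(rng.integers(2, 6))):
            center = int(rng.integers(0, width))
            half = int(rng.integers(2, 6))
            strength = rng.uniform(0.3, 0.7)
            lo, hi = max(0, center - half), min(width, center + half + 1)
            shade[lo:hi] = np.minimum(shade[lo:hi], 1.0 - strength)
        shade = gaussian_filter1d(shade, sigma=1.0, mode="nearest")
        below = rows >= surface[None, :]
        img = np.where(below, img * shade[None, :], img)

    if model.speckle_shape < _SPECKLE_NOISELESS:
        speckle = rng.gamma(model.speckle_shape, 1.0 / model.speckle_shape, img.shape)
        img = img * speckle

    img = np.clip(img, 0.0, 1.0)
    meta: dict[str, Any] = {
        "truth": {
            "surface_rows": surface,
            "epithelial_thickness_px": t_px,
            "keratin_px": k_px,
            "mu_epi_per_um": mu_e,
            "mu_stroma_per_um": mu_s,
        }
    }
    return BScan(img, meta=meta)


def compose_device_frame(
    scan: BScan, separator_rows: int = 3, separator_value: float = 1.0
) -> DeviceFrame:
    """Stack [upper scan; constant separator; vertically mirrored copy]."""
    if separator_rows < 1:
        raise DomainError("separator_rows must be >= 1")
    sep = np.full((separator_rows, scan.n_cols), float(separator_value))
    grid = np.vstack([scan.intensity, sep, scan.intensity[::-1]])
    return DeviceFrame(grid, separator_rows=separator_rows, meta=dict(scan.meta))


def apply_quality_drift(
    image: np.ndarray,
    frame_index: int,
    drift_rate: float,
    noise_seed: int,
    noise_divisor: float = 1500.0,
) -> np.ndarray:
    """Degrade a frame per its acquisition order: blur + additive noise."""
    out = np.asarray(image, dtype=float)
    sigma = drift_rate * frame_index
    if sigma > 0:
        out = gaussian_filter(out, sigma=sigma, mode="reflect")
    noise_sd = drift_rate * frame_index / noise_divisor
    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0)


def iter_cohort_frames(
    profiles: dict[str, ClassProfile],
    n_sites_per_class: int,
    frames_per_site: tuple[int, int] = (10, 15),
    site_mix: dict[str, float] | None = None,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> Iterator[tuple[dict[str, Any], DeviceFrame, TissueModel]]:
    """Lazily yield ``(manifest row, device frame, tissue model)`` triples.

    Deterministic under ``seed`` at every granularity; `generate_cohort`
    writes exactly this stream to disk.
    """
    if n_sites_per_class < 1:
        raise DomainError("n_sites_per_class must be >= 1")
    lo, hi = frames_per_site
    if not (1 <= lo <= hi <= 50):
        raise DomainError("frames_per_site must lie within [1, 50]")
    cfg = config or SynthConfig()
    mix = dict(DEFAULT_SITE_MIX if site_mix is None else site_mix)
    sites = [s for s in ANATOMIC_SITES if mix.get(s, 0.0) > 0]
    weights = np.array([mix[s] for s in sites], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise DomainError(f"site_mix weights sum to {weights.sum()!r}, expected 1")

    rng = np.random.default_rng(seed)
    for dx in [d for d in DIAGNOSES if d in profiles]:
        profile = profiles[dx]
        for i in range(n_sites_per_class):
            site_id = f"{dx}_{i:03d}"
            anatomic = str(rng.choice(sites, p=weights))
            model = profile.sample_tissue_model(anatomic, rng)
            n_frames = int(rng.integers(lo, hi + 1))
            for idx in range(n_frames):
                scan_seed = int(rng.integers(2**31))
                noise_seed = int(rng.integers(2**31))
                scan = generate_bscan(model, cfg.height, cfg.width, scan_seed)
                degraded = apply_quality_drift(
                    scan.intensity,
                    idx,
                    profile.quality_drift_rate,
                    noise_seed,
                    cfg.drift_noise_divisor,
                )
                scan = scan.with_intensity(
                    degraded,
                    subject_id=f"subj_{site_id}",
                    site_id=site_id,
                    anatomic_site=anatomic,
                    frame_index=idx,
                    diagnosis=dx,
                )
                frame = compose_device_frame(
                    scan, cfg.separator_rows, cfg.separator_value
                )
                row = {
                    "subject_id": f"subj_{site_id}",
                    "site_id": site_id,
                    "anatomic_site": anatomic,
                    "frame_index": idx,
                    "image_path": f"{site_id}_f{idx:02d}.png",
                    "diagnosis": dx,
                    "split": "none",
                }
                yield row, frame, model


def generate_cohort(
    profiles: dict[str, ClassProfile],
    n_sites_per_class: int,
    out_dir: str | Path,
    frames_per_site: tuple[int, int] = (10, 15),
    site_mix: dict[str, float] | None = None,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> CohortManifest:
    """Write a full synthetic cohort (16-bit PNGs + manifest.csv) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for row, frame, _model in iter_cohort_frames(
        profiles, n_sites_per_class, frames_per_site, site_mix, seed, config
    ):
        write_image(frame.intensity, out / row["image_path"], depth=16)
        row = dict(row)
        row["image_path"] = str(out / row["image_path"])
        rows.append(row)
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.df.to_csv(out / "manifest.csv", index=False)
    return manifest


def noiseless_model(model: TissueModel) -> TissueModel:
    """Copy of ``model`` in the speckle-free limit."""
    return replace(model, speckle_shape=_SPECKLE_NOISELESS)
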