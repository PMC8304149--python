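"""Run configuration: every tunable of the pipeline, with defaults.

The configuration serializes to YAML and reloads losslessly, so a run is a
pure function of (config, inputs, seed).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .exceptions import ConfigurationError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthConfig(_Section):
    """Synthetic cohort generator settings."""

    height: int = 256
    width: int = 384
    separator_rows: int = 3
    separator_value: float = 1.0
    frames_per_site_min: int = 10
    frames_per_site_max: int = 15
    #: Additive-noise drift sd per acquisition index = blur drift rate / this.
    drift_noise_divisor: float = 1500.0


class QualityConfig(_Section):
    """No-reference quality model (natural-scene-statistics) settings."""

    patch_size: int = 96
    sharpness_fraction: float = 0.75
    n_scales: int = 2
    #: Contrast stabiliser C for MSCN, on the [0, 1] intensity scale.
    stabilizer: float = 1.0 / 255.0
    window_sigma: float = 7.0 / 6.0
    min_corpus_images: int = 20
    #: Size of the default synthetic pristine corpus.
    corpus_images: int = 60
    #: Gate threshold = this percentile of the pristine corpus self-scores.
    gate_percentile: float = 97.5


class PreprocessConfig(_Section):
    """Mirror-pair segmentation settings."""

    smoothing_sigma: float = 1.0
    ncc_accept_threshold: float = 0.6
    #: Pixels trimmed from each edge of the template halves.
    template_trim: int = 4


class ScoreBandsConfig(_Section):
    """Published class bands for the scalar OCT score.

    Contiguous and ordered; each shared endpoint belongs to the
    more-negative (less severe) band, and the malignant upper endpoint
    itself is out of range.
    """

    normal_low: float = -0.1280
    normal_high: float = -0.0918
    dysplastic_high: float = -0.0780
    malignant_high: float = -0.0580


class OctScoreConfig(_Section):
    """Edge detection and decay-slope scoring settings."""

    edge_sigma: float = 2.0
    lateral_sigma: float = 4.0
    edge_threshold: float = 0.5
    #: Boundary is reported only when the sub-surface edge response reaches
    #: this fraction of the column's overall peak response.
    boundary_min_rel: float = 0.30
    fit_window_px: int = 40
    fit_start_offset_px: int = 5
    min_fit_rows: int = 8
    min_valid_columns: int = 32
    log_floor: float = 1.0e-4
    #: Calibration constants mapping the raw median log10-decay slope to the
    #: published score scale; fixed once by scripts/calibrate.py.
    calibration_gain: float = 1.014234
    calibration_offset: float = 0.001289
    bands: ScoreBandsConfig = ScoreBandsConfig()


class CascadeConfig(_Section):
    """Sequential classifier cascade settings."""

    train_fraction: float = 0.7
    regularization_c: float = 1.0
    include_mirror: bool = True
    #: Combined sensitivity counts a site as detected when ANY stage flags it.
    combined_or_rule: bool = True
    backend: str = "default"


class MetricsConfig(_Section):
    ci_level: float = 0.95


class RunConfig(_Section):
    """Top-level configuration for all pipeline stages."""

    seed: int = 0
    synth: SynthConfig = SynthConfig()
    quality: QualityConfig = QualityConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    octscore: OctScoreConfig = OctScoreConfig()
    cascade: CascadeConfig = CascadeConfig()
    metrics: MetricsConfig = MetricsConfig()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path!s} does not hold a mapping")
        return cls.model_validate(raw)
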