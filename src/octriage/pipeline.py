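"""End-to-end orchestration helpers shared by the CLI, scripts and tests.

The stages compose as: simulate (or load) device frames -> quality gate on
the upper half -> mirror-pair split by template matching -> (a) attenuation
scoring of the raw upper scan and (b) embedding features of the
normalized/smoothed halves feeding the classifier cascade. The attenuation
score path works on raw intensities (its calibration depends on absolute
decay); the feature path works on enhanced images, as each stage's own
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .bscan import BScan, DeviceFrame
from .cascade import TriageCascade
from .config import RunConfig
from .embed import EmbeddingBackend, get_backend
from .octscore import classify_score, score_scan, score_site
from .preprocess import Template, make_template, normalize_and_smooth, split_pair
from .quality import Niqe
from .synth import ClassProfile, default_profiles, iter_cohort_frames


def simulate_records(
    n_sites_per_class: int,
    frames_per_site: tuple[int, int],
    seed: int,
    config: RunConfig | None = None,
    profiles: dict[str, ClassProfile] | None = None,
) -> list[tuple[dict[str, Any], DeviceFrame]]:
    """Materialize an in-memory synthetic cohort (manifest rows + frames)."""
    cfg = config or RunConfig()
    profs = profiles or default_profiles()
    return [
        (row, frame)
        for row, frame, _model in iter_cohort_frames(
            profs, n_sites_per_class, frames_per_site, seed=seed, config=cfg.synth
        )
    ]


def pristine_corpus(
    n_images: int = 30, seed: int = 42, config: RunConfig | None = None
) -> list[np.ndarray]:
    """High-quality (drift-free) frames spanning classes and sites."""
    cfg = config or RunConfig()
    profs = default_profiles()
    names = sorted(profs)
    from .synth import DEFAULT_SITE_MIX, generate_bscan

    sites = list(DEFAULT_SITE_MIX)
    weights = list(DEFAULT_SITE_MIX.values())
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        profile = profs[names[i % len(names)]]
        site = str(rng.choice(sites, p=weights))
        model = profile.sample_tissue_model(site, rng)
        out.append(
            generate_bscan(
                model, cfg.synth.height, cfg.synth.width, seed=int(rng.integers(2**31))
            ).intensity
        )
    return out


def fit_quality_model(config: RunConfig | None = None, seed: int = 42) -> Niqe:
    """Fit the no-reference quality model on the default pristine corpus."""
    cfg = config or RunConfig()
    q = cfg.quality
    model = Niqe(
        patch_size=q.patch_size,
        sharpness_fraction=q.sharpness_fraction,
        c=q.stabilizer,
        window_sigma=q.window_sigma,
        min_images=q.min_corpus_images,
        gate_percentile=q.gate_percentile,
    )
    return model.fit(pristine_corpus(max(q.min_corpus_images, q.corpus_images), seed, cfg))


def quality_gate_records(
    records: Iterable[tuple[dict[str, Any], DeviceFrame]],
    niqe: Niqe,
    threshold: float | None = None,
) -> tuple[list[tuple[dict[str, Any], DeviceFrame]], pd.DataFrame]:
    """Score each frame's upper half and drop those above the gate."""
    thr = niqe.gate_threshold_ if threshold is None else threshold
    kept, rows = [], []
    for row, frame in records:
        score = niqe.score_image(frame.upper)
        ok = score <= thr
        rows.append(dict(row, niqe_score=score, passed=ok))
        if ok:
            kept.append((row, frame))
    return kept, pd.DataFrame(rows)


def default_template(config: RunConfig | None = None, seed: int = 0) -> Template:
    """Template pair from a noiseless mid-range (normal mucosa) model."""
    cfg = config or RunConfig()
    model = default_profiles()["normal"].sample_tissue_model(
        "buccal", np.random.default_rng(seed)
    )
    return make_template(
        model,
        cfg.synth.height,
        cfg.synth.width,
        cfg.synth.separator_rows,
        cfg.preprocess.template_trim,
        seed=seed,
    )


@dataclass
class SplitRecord:
    """A frame after mirror-pair segmentation."""

    row: dict[str, Any]
    upper: BScan
    lower: BScan
    peak_upper: float
    peak_lower: float


def split_records(
    records: Iterable[tuple[dict[str, Any], DeviceFrame]],
    template: Template,
    accept_threshold: float = 0.6,
    smoothing_sigma: float = 1.0,
) -> tuple[list[SplitRecord], list[dict[str, Any]]]:
    """Split every device frame; collect rejects separately.

    Matching runs on the normalized/smoothed frame; halves are extracted
    from the raw frame so downstream intensity measurements stay exact.
    """
    out, rejects = [], []
    for row, frame in records:
        enhanced = normalize_and_smooth(frame.intensity, smoothing_sigma)
        pair = split_pair(frame, template, accept_threshold, match_image=enhanced)
        if pair is None:
            rejects.append(dict(row))
            continue
        out.append(
            SplitRecord(
                row=dict(row),
                upper=pair.upper,
                lower=pair.lower_unmirrored,
                peak_upper=pair.ncc_peak_upper,
                peak_lower=pair.ncc_peak_lower,
            )
        )
    return out, rejects


def score_records(
    split: Iterable[SplitRecord], config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame and per-site attenuation-score tables."""
    cfg = config or RunConfig()
    frame_rows = []
    for rec in split:
        row = dict(rec.row)
        try:
            s = score_scan(rec.upper, cfg.octscore)
        except Exception as exc:  # noqa: BLE001 - per-frame error policy
            row.update(score=np.nan, band="error", error=str(exc))
        else:
            row.update(
                score=s.score,
                band=classify_score(s.score, cfg.octscore.bands),
                epithelial_thickness_um=s.epithelial_thickness_um,
                n_columns_used=s.n_columns_used,
                error="",
            )
        frame_rows.append(row)
    frames = pd.DataFrame(frame_rows)
    site_rows = []
    for site_id, grp in frames.groupby("site_id", sort=False):
        usable = grp[grp["band"].isin(["malignant", "dysplastic", "normal"])]
        row = {
            "site_id": site_id,
            "diagnosis": grp["diagnosis"].iloc[0],
            "n_frames": len(grp),
            "n_used": len(usable),
        }
        if len(usable):
            site = score_site(usable["score"].to_numpy())
            row["score"] = site.score
            row["band"] = classify_score(site.score, cfg.octscore.bands)
            row["flag"] = ""
        else:
            row["score"] = np.nan
            row["band"] = "out_of_range"
            row["flag"] = "all_frames_out_of_range"
        site_rows.append(row)
    return frames, pd.DataFrame(site_rows)


def feature_table(
    split: Iterable[SplitRecord],
    backend: EmbeddingBackend | str = "default",
    include_mirror: bool = True,
    smoothing_sigma: float = 1.0,
) -> pd.DataFrame:
    """Embedding features of the enhanced halves, one row per image."""
    if isinstance(backend, str):
        backend = get_backend(backend)
    rows = []
    for rec in split:
        halves = [("upper", rec.upper.intensity)]
        if include_mirror:
            halves.append(("lower", rec.lower.intensity))
        for half, img in halves:
            enhanced = normalize_and_smooth(img, smoothing_sigma)
            vec = backend(enhanced)
            row = dict(rec.row, half=half, backend=backend.name)
            for k, v in enumerate(vec):
                row[f"f{k:03d}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def class_mean_scores(
    seed: int,
    n_sites_per_class: int = 60,
    frames_per_site: tuple[int, int] = (3, 5),
    config: RunConfig | None = None,
    quality_seed: int = 42,
) -> dict[str, list[float]]:
    """Per-site mean attenuation scores grouped by score-band class.

    The canonical simulate -> quality gate -> split -> score protocol used
    for score-scale calibration: returns ``{oscc | dysplasia | normal_benign:
    [site mean scores]}`` over the gated, successfully split frames.
    """
    from .synth import score_group

    cfg = config or RunConfig()
    records = simulate_records(n_sites_per_class, frames_per_site, seed, cfg)
    niqe = fit_quality_model(cfg, seed=quality_seed)
    kept, _report = quality_gate_records(records, niqe)
    template = default_template(cfg, seed=0)
    split, _rejects = split_records(
        kept, template, cfg.preprocess.ncc_accept_threshold,
        cfg.preprocess.smoothing_sigma,
    )
    _frames, sites = score_records(split, cfg)
    groups: dict[str, list[float]] = {"oscc": [], "dysplasia": [], "normal_benign": []}
    for _, row in sites.iterrows():
        if np.isfinite(row["score"]):
            groups[score_group(row["diagnosis"])].append(float(row["score"]))
    return groups


def fit_cascade(
    features: pd.DataFrame, config: RunConfig | None = None
) -> TriageCascade:
    cfg = config or RunConfig()
    cascade = TriageCascade(
        train_fraction=cfg.cascade.train_fraction,
        c=cfg.cascade.regularization_c,
        seed=cfg.seed,
        backend=cfg.cascade.backend,
    )
    return cascade.fit(features)


def cascade_experiment(
    seed: int,
    n_sites_per_class: int = 60,
    frames_per_site: tuple[int, int] = (3, 5),
    config: RunConfig | None = None,
    quality_seed: int = 42,
):
    """Full train-and-evaluate cascade run on a fresh synthetic cohort.

    simulate -> quality gate -> split -> embed -> fit cascade -> predict ->
    evaluate on the surviving sites. Returns the
    :class:`~octriage.cascade.CascadeEvaluation`.
    """
    from .cascade import evaluate_cascade

    cfg = config or RunConfig()
    cfg = cfg.model_copy(deep=True)
    cfg.seed = seed
    records = simulate_records(n_sites_per_class, frames_per_site, seed, cfg)
    niqe = fit_quality_model(cfg, seed=quality_seed)
    kept, _ = quality_gate_records(records, niqe)
    template = default_template(cfg, seed=0)
    split, _ = split_records(
        kept, template, cfg.preprocess.ncc_accept_threshold,
        cfg.preprocess.smoothing_sigma,
    )
    features = feature_table(
        split, cfg.cascade.backend, cfg.cascade.include_mirror,
        cfg.preprocess.smoothing_sigma,
    )
    cascade = fit_cascade(features, cfg)
    predictions = cascade.predict(features)
    truth = pd.Series({r["site_id"]: r["diagnosis"] for r, _ in records})
    truth = truth.loc[[p.site_id for p in predictions]]
    return evaluate_cascade(predictions, truth, cfg.cascade.combined_or_rule)
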