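"""The scalar "algorithm score": surface tracing, decay slope, class bands.

Per A-line (depth column) the tissue surface is the dominant rising edge of
the depth profile (the peak of the depth-directed derivative-of-Gaussian
response), and the epithelial lower boundary is the strongest sub-surface
rising edge — the bright basement-membrane line — reported only when strong
enough relative to the surface edge, so a destroyed membrane (carcinoma)
yields no boundary. The score is the calibrated median across columns of the
robust least-squares slope of log10 intensity versus depth, fitted from just
below the surface down to the detected boundary (or a fixed window when no
boundary is found). Lower-attenuation tissue (carcinoma) decays more slowly,
so its score is less negative; the published bands stratify the score into
malignant / dysplastic / normal ranges:

    malignant   (-0.0780, -0.0580)
    dysplastic  (-0.0918, -0.0780]
    normal      [-0.1280, -0.0918]

Each shared endpoint belongs to the more-negative (less severe) band, and the
malignant upper endpoint itself is out of range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bscan import AXIAL_PITCH_UM, BScan
from .config import OctScoreConfig, ScoreBandsConfig
from .exceptions import DomainError, ScoreFailureError, TraceFailureError


@dataclass
class SurfaceTrace:
    """Per-column surface / epithelial-boundary rows with a validity mask."""

    surface: np.ndarray  # int rows; -1 where invalid
    boundary: np.ndarray  # int rows; -1 where absent
    valid: np.ndarray  # bool per column

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class OctScore:
    """Scalar score plus the measurements it came from."""

    score: float
    epithelial_thickness_um: float | None
    n_columns_used: int


def detect_surface(
    scan: BScan | np.ndarray,
    edge_sigma: float = 2.0,
    edge_threshold: float = 0.5,
    lateral_sigma: float = 4.0,
    boundary_min_rel: float = 0.30,
) -> SurfaceTrace:
    """Trace the first-layer edge (and, where present, the epithelial base).

    The edge response is a depth-directed derivative-of-Gaussian, smoothed
    laterally to suppress speckle. Per column the surface is the peak of the
    first (and dominant) response lobe exceeding ``edge_threshold`` times the
    column peak; the boundary is the strongest rising edge deeper than the
    surface lobe (search starts ``3 * edge_sigma`` px below the surface, and
    always at least 3 px below it), reported only when it reaches
    ``boundary_min_rel`` of the column's peak response.
    """
    img = scan.intensity if isinstance(scan, BScan) else np.asarray(scan, float)
    if img.ndim != 2 or img.shape[0] < 64:
        raise DomainError("scan must be 2-D with at least 64 depth rows")
    resp = gaussian_filter1d(img, sigma=edge_sigma, axis=0, order=1, mode="nearest")
    if lateral_sigma > 0:
        resp = gaussian_filter1d(resp, sigma=lateral_sigma, axis=1, mode="nearest")

    n_rows, n_cols = img.shape
    # the bottom edge cannot hold the tissue surface (and may carry frame
    # furniture such as the separator line after an off-by-one split)
    bottom_margin = max(8, int(round(3 * edge_sigma)) + 2)
    search = resp[: n_rows - bottom_margin]
    col_peak = search.max(axis=0)
    valid = col_peak > 1e-9
    # dominant rising edge: within the first suprathreshold lobe the response
    # peak is the global column maximum (the surface step dwarfs every deeper
    # edge in this imaging geometry)
    surface = np.where(valid, search.argmax(axis=0), -1)

    off = max(3, int(round(3 * edge_sigma)))
    cols = np.arange(n_cols)
    deep_start = np.clip(surface + off, 0, n_rows - 1)
    rel = np.arange(n_rows)[:, None]
    idx = np.clip(deep_start[None, :] + rel, 0, n_rows - 1)
    in_range = deep_start[None, :] + rel < n_rows - bottom_margin
    deep = np.where(in_range, resp[idx, cols[None, :]], -np.inf)
    deep_peak = deep.max(axis=0)
    deep_arg = deep.argmax(axis=0)
    has_boundary = valid & (deep_peak >= boundary_min_rel * col_peak)
    boundary = np.where(has_boundary, deep_start + deep_arg, -1)

    if valid.sum() < 0.5 * n_cols:
        raise TraceFailureError(
            f"only {int(valid.sum())}/{n_cols} columns produced a surface edge"
        )
    return SurfaceTrace(
        surface=surface.astype(int), boundary=boundary.astype(int), valid=valid
    )


def _masked_slopes(y: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column least-squares slope/intercept of y vs row under a mask."""
    x = np.arange(y.shape[0], dtype=float)[:, None]
    m = mask.astype(float)
    n = m.sum(axis=0)
    n_safe = np.maximum(n, 2.0)
    sx = (m * x).sum(axis=0)
    sy = (m * y).sum(axis=0)
    sxx = (m * x * x).sum(axis=0)
    sxy = (m * x * y).sum(axis=0)
    denom = n_safe * sxx - sx * sx
    denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
    slope = (n_safe * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n_safe
    return slope, intercept


def compute_score(
    scan: BScan | np.ndarray,
    trace: SurfaceTrace,
    config: OctScoreConfig | None = None,
) -> OctScore:
    """Calibrated median log10-decay slope below the detected surface.

    Per valid column the slope of ``log10(max(I, eps))`` versus depth row is
    fitted over ``[surface + offset, min(surface + window, boundary - 1))``;
    rows deviating more than 3.5 robust sigmas from the first fit (e.g. an
    undetected bright basement-membrane line) are discarded and the line
    refitted. The site-level thickness is the median boundary-to-surface
    distance times the axial pitch. Deterministic; the median across columns
    makes the score robust to a minority of corrupted A-lines.
    """
    cfg = config or OctScoreConfig()
    img = scan.intensity if isinstance(scan, BScan) else np.asarray(scan, float)
    n_rows, n_cols = img.shape
    logi = np.log10(np.maximum(img, cfg.log_floor))

    surface = trace.surface
    start = surface + cfg.fit_start_offset_px
    stop = np.minimum(surface + cfg.fit_window_px, n_rows)
    has_b = trace.boundary >= 0
    stop = np.where(has_b, np.minimum(stop, trace.boundary - 1), stop)
    length = stop - start
    usable = trace.valid & (length >= cfg.min_fit_rows)

    max_len = cfg.fit_window_px - cfg.fit_start_offset_px
    rel = np.arange(max_len)[:, None]
    cols = np.arange(n_cols)[None, :]
    idx = np.clip(start[None, :] + rel, 0, n_rows - 1)
    y = logi[idx, cols]
    mask = (rel < length[None, :]) & usable[None, :]

    slope, intercept = _masked_slopes(y, mask)
    resid = np.where(mask, y - (intercept[None, :] + slope[None, :] * rel), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-masked columns
        mad = np.nanmedian(np.abs(resid), axis=0)
    sigma = np.maximum(1.4826 * mad, 0.02)  # floor keeps exact fits intact
    keep = mask & (np.abs(np.nan_to_num(resid, nan=np.inf)) <= 3.5 * sigma[None, :])
    enough = keep.sum(axis=0) >= cfg.min_fit_rows
    slope2, _ = _masked_slopes(y, keep & enough[None, :])

    good = usable & enough & np.isfinite(slope2)
    slopes = slope2[good]
    if slopes.size < cfg.min_valid_columns:
        raise ScoreFailureError(
            f"only {slopes.size} columns produced a finite slope "
            f"(need >= {cfg.min_valid_columns})"
        )
    raw = float(np.median(slopes))
    score = cfg.calibration_gain * raw + cfg.calibration_offset

    d = (trace.boundary - surface)[has_b & trace.valid]
    thickness = float(np.median(d)) * AXIAL_PITCH_UM if d.size else None
    return OctScore(
        score=score,
        epithelial_thickness_um=thickness,
        n_columns_used=int(slopes.size),
    )


def score_scan(
    scan: BScan | np.ndarray, config: OctScoreConfig | None = None
) -> OctScore:
    """Convenience: trace the surface then compute the score in one call."""
    cfg = config or OctScoreConfig()
    trace = detect_surface(
        scan,
        edge_sigma=cfg.edge_sigma,
        edge_threshold=cfg.edge_threshold,
        lateral_sigma=cfg.lateral_sigma,
        boundary_min_rel=cfg.boundary_min_rel,
    )
    return compute_score(scan, trace, cfg)


def classify_score(score: float, bands: ScoreBandsConfig | None = None) -> str:
    """Band lookup: malignant / dysplastic / normal / out_of_range."""
    b = bands or ScoreBandsConfig()
    if not (b.normal_low < b.normal_high < b.dysplastic_high < b.malignant_high):
        raise DomainError("score bands must be ordered and non-overlapping")
    if score < b.normal_low or score >= b.malignant_high:
        return "out_of_range"
    if score <= b.normal_high:
        return "normal"
    if score <= b.dysplastic_high:
        return "dysplastic"
    return "malignant"


def score_site(frame_scores: list[float] | np.ndarray) -> OctScore:
    """Site-level score: arithmetic mean of the per-frame scores."""
    arr = np.asarray(frame_scores, dtype=float)
    if arr.size == 0:
        raise DomainError("a site needs at least one frame score")
    return OctScore(
        score=float(arr.mean()), epithelial_thickness_um=None, n_columns_used=arr.size
    )
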