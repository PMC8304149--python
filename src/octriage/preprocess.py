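"""Device-frame preprocessing: normalization, smoothing, mirror-pair split.

Each raw device frame holds the acquired B-scan twice (an upper original and
a vertically mirrored lower copy, separated by a bright line). The two halves
are located by zero-normalized 2D cross-correlation against a high-quality
template pair; frames whose best match falls below an acceptance threshold
are rejected as unusable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import match_template

from .bscan import BScan, DeviceFrame
from .exceptions import DegenerateInputError, DomainError
from .synth import TissueModel, compose_device_frame, generate_bscan, noiseless_model


@dataclass
class Template:
    """Matched pair of upper/lower reference patches.

    The patches cover the high-signal surface band of each half rather than
    the whole half (deep rows are speckle-dominated and decorrelate across
    tissue models). A match of the upper patch at frame offset ``(r, c)``
    places the full upper half at ``(r - row_offset_upper, c - col_offset)``;
    analogously for the lower (mirrored) patch via ``row_offset_lower``.
    """

    upper: np.ndarray
    lower: np.ndarray
    row_offset_upper: int
    row_offset_lower: int
    col_offset: int
    half_shape: tuple[int, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, arr in (("upper", self.upper), ("lower", self.lower)):
            if np.ptp(arr) == 0:
                raise DegenerateInputError(f"{name} template is constant")


def normalize_and_smooth(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Min-max rescale to [0, 1], then Gaussian-filter (reflect boundary).

    A constant frame is returned unchanged (no division blow-up); sigma = 0
    performs normalization only.
    """
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    frame = np.asarray(frame, dtype=float)
    lo, hi = frame.min(), frame.max()
    if hi > lo:
        frame = (frame - lo) / (hi - lo)
    if sigma > 0:
        frame = gaussian_filter(frame, sigma=sigma, mode="reflect")
    return frame


def ncc_match(frame: np.ndarray, template: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Peak zero-normalized cross-correlation over all valid placements.

    Ties break to the smallest row, then the smallest column.
    """
    frame = np.asarray(frame, dtype=float)
    template = np.asarray(template, dtype=float)
    if template.shape[0] >= frame.shape[0] or template.shape[1] >= frame.shape[1]:
        raise DomainError(
            f"template {template.shape} must be strictly smaller than frame {frame.shape}"
        )
    if np.ptp(template) == 0:
        raise DegenerateInputError("constant template carries no structure")
    ncc = match_template(frame, template, pad_input=False)
    idx = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    return float(ncc[idx]), (int(idx[0]), int(idx[1]))


def _banded_match(
    search: np.ndarray, template: np.ndarray, expected_row: int, margin: int
) -> tuple[float, tuple[int, int]]:
    """NCC restricted to placements within ``margin`` rows of the expected one."""
    r0 = max(0, expected_row - margin)
    r1 = min(search.shape[0], expected_row + margin + template.shape[0])
    if r1 - r0 <= template.shape[0]:
        r0, r1 = 0, search.shape[0]
    peak, (dr, dc) = ncc_match(search[r0:r1], template)
    return peak, (dr + r0, dc)


@dataclass
class SegmentedPair:
    """Result of splitting one device frame into its two half scans."""

    upper: BScan
    lower_unmirrored: BScan
    ncc_peak_upper: float
    ncc_peak_lower: float
    offset_upper: tuple[int, int]
    offset_lower: tuple[int, int]


def make_template(
    model: TissueModel,
    height: int = 256,
    width: int = 384,
    separator_rows: int = 3,
    trim: int = 4,
    seed: int = 0,
    band: tuple[int, int] | None = None,
    smoothing_sigma: float = 1.0,
) -> Template:
    """Build the default template pair from a noiseless simulator frame.

    ``band`` gives the half-open row window of the upper half used as the
    template (default: from just above the surface through the strongly
    scattering layers); the lower template is its mirror image.
    """
    scan = generate_bscan(noiseless_model(model), height, width, seed, surface_wobble_px=0.0)
    frame = compose_device_frame(scan, separator_rows)
    h = frame.half_height
    if band is None:
        base = int(round(0.15 * height))
        band = (max(base - 18, 0), min(base + 30, h))
    b0, b1 = band
    upper_half = normalize_and_smooth(frame.intensity, smoothing_sigma)[:h]
    upper = upper_half[b0:b1, trim : width - trim]
    lower = upper[::-1]
    return Template(
        upper=upper,
        lower=lower,
        row_offset_upper=b0,
        row_offset_lower=h - b1,
        col_offset=trim,
        half_shape=(h, width),
        provenance="noiseless simulator default",
    )


def split_pair(
    frame: DeviceFrame | np.ndarray,
    template: Template,
    accept_threshold: float = 0.6,
    match_image: np.ndarray | None = None,
) -> SegmentedPair | None:
    """Locate both halves by template matching; reject unmatchable frames.

    Matching may run on an enhanced copy (``match_image``, e.g. the
    normalized/smoothed frame) while the halves are extracted from the raw
    frame at the matched offsets. Returns ``None`` when
    ``min(peak_upper, peak_lower) < accept_threshold``.
    """
    if isinstance(frame, DeviceFrame):
        grid = frame.intensity
        meta = dict(frame.meta)
    else:
        grid = np.asarray(frame, dtype=float)
        meta = {}
    search = grid if match_image is None else np.asarray(match_image, dtype=float)
    if search.shape != grid.shape:
        raise DomainError("match_image must share the frame's shape")
    h, w = template.half_shape
    if grid.shape[0] < 2 * template.upper.shape[0]:
        raise DomainError(
            "frame is shorter than two template heights; cannot hold a pair"
        )
    # the halves sit at known approximate rows in a well-formed frame, so the
    # search is restricted to a band around each expected placement
    margin = 16
    exp_u = template.row_offset_upper
    exp_l = grid.shape[0] - h + template.row_offset_lower
    peak_u, off_u = _banded_match(search, template.upper, exp_u, margin)
    peak_l, off_l = _banded_match(search, template.lower, exp_l, margin)
    if min(peak_u, peak_l) < accept_threshold:
        return None

    def _extract(offset: tuple[int, int], row_offset: int) -> np.ndarray:
        r0 = int(np.clip(offset[0] - row_offset, 0, grid.shape[0] - h))
        c0 = int(np.clip(offset[1] - template.col_offset, 0, grid.shape[1] - w))
        return grid[r0 : r0 + h, c0 : c0 + w]

    upper = _extract(off_u, template.row_offset_upper)
    lower = _extract(off_l, template.row_offset_lower)[::-1]
    return SegmentedPair(
        upper=BScan(upper, meta=dict(meta, half="upper")),
        lower_unmirrored=BScan(lower, meta=dict(meta, half="lower")),
        ncc_peak_upper=peak_u,
        ncc_peak_lower=peak_l,
        offset_upper=off_u,
        offset_lower=off_l,
    )


@dataclass(frozen=True)
class RoiSpec:
    """Half-open row/column crop window."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int


def extract_roi(scan: BScan, roi: RoiSpec) -> BScan:
    """Crop a scan to the region of interest, keeping depth bookkeeping."""
    if not (
        0 <= roi.row_start < roi.row_stop <= scan.n_rows
        and 0 <= roi.col_start < roi.col_stop <= scan.n_cols
    ):
        raise DomainError(f"ROI {roi} is outside scan of shape {scan.shape}")
    sub = scan.intensity[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop]
    prev = scan.meta.get("roi_offset", (0, 0))
    return scan.with_intensity(
        sub, roi_offset=(prev[0] + roi.row_start, prev[1] + roi.col_start)
    )
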