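"""Pluggable per-image feature extraction ("embedding backends").

The study extracted frame features from the fully connected layer of many
ImageNet-pretrained networks; here the backend is an interface — any pure,
deterministic ``image -> fixed-length vector`` map qualifies — and the
default backend is a self-contained hand-crafted descriptor requiring no
downloads: grid intensity statistics, depth-decay profile shape, oriented
gradient histograms, and natural-scene-statistics (AGGD) parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import sobel

from .exceptions import RegistrationError
from .quality import compute_mscn, fit_aggd


@dataclass(frozen=True)
class EmbeddingBackend:
    """Named, fixed-dimension, deterministic image-to-vector transform."""

    name: str
    dim: int
    transform: Callable[[np.ndarray], np.ndarray]
    #: Per-coordinate flag: True where the feature is invariant to adding a
    #: small constant to all intensities (contrast/offset features are not).
    shift_invariant_mask: tuple[bool, ...] = field(default=(), compare=False)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        out = np.asarray(self.transform(np.asarray(image, dtype=float)), dtype=float)
        if out.shape != (self.dim,):
            raise RegistrationError(
                f"backend {self.name!r} returned shape {out.shape}, expected ({self.dim},)"
            )
        return out


_GRID = 4
_N_ORI_BINS = 8
_LOG_FLOOR = 1.0e-4


def _default_transform(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    feats: list[float] = []

    # (a) 4x4 grid of patch mean/sd
    for i in range(_GRID):
        for j in range(_GRID):
            patch = image[
                i * h // _GRID : (i + 1) * h // _GRID,
                j * w // _GRID : (j + 1) * w // _GRID,
            ]
            feats.append(float(patch.mean()))
            feats.append(float(patch.std()))

    # (b) depth-decay profile shape: quadratic fit of the column-mean
    # log-intensity below its brightest row
    profile = np.log10(np.maximum(image, _LOG_FLOOR)).mean(axis=1)
    r0 = int(np.argmax(profile))
    seg = profile[r0 : min(r0 + 60, h)]
    if seg.size >= 8:
        x = np.arange(seg.size, dtype=float)
        coef = np.polyfit(x, seg, 2)
        resid = seg - np.polyval(coef, x)
        feats.extend([float(coef[1]), float(coef[0]), float(resid.std())])
    else:
        feats.extend([0.0, 0.0, 0.0])

    # (c) oriented gradient-magnitude histograms, 8 bins x 4 quadrants
    gr = sobel(image, axis=0, mode="reflect")
    gc = sobel(image, axis=1, mode="reflect")
    mag = np.hypot(gr, gc)
    ang = np.mod(np.arctan2(gr, gc), np.pi)
    bins = np.minimum((ang / np.pi * _N_ORI_BINS).astype(int), _N_ORI_BINS - 1)
    for qi in range(2):
        for qj in range(2):
            sl = np.s_[qi * h // 2 : (qi + 1) * h // 2, qj * w // 2 : (qj + 1) * w // 2]
            hist = np.bincount(bins[sl].ravel(), weights=mag[sl].ravel(), minlength=_N_ORI_BINS)
            total = hist.sum()
            feats.extend((hist / total if total > 0 else hist).tolist())

    # (d) AGGD parameters of the MSCN field
    p = fit_aggd(compute_mscn(image))
    feats.extend([p.alpha, p.eta, p.beta_l, p.beta_r])
    return np.array(feats)


def _default_mask() -> tuple[bool, ...]:
    mask: list[bool] = []
    for _ in range(_GRID * _GRID):
        mask.extend([False, True])  # patch mean shifts, patch sd does not
    mask.extend([False, False, False])  # log-profile shape depends on offset
    mask.extend([True] * (_N_ORI_BINS * 4))  # gradients kill constants
    mask.extend([True] * 4)  # MSCN is mean-subtracted
    return tuple(mask)


DEFAULT_DIM = 2 * _GRID * _GRID + 3 + _N_ORI_BINS * 4 + 4

_REGISTRY: dict[str, EmbeddingBackend] = {}


def default_backend() -> EmbeddingBackend:
    """The self-contained hand-crafted descriptor (dim = 71)."""
    return _REGISTRY["default"]


def register_backend(
    name: str,
    dim: int,
    transform: Callable[[np.ndarray], np.ndarray],
    shift_invariant_mask: tuple[bool, ...] = (),
    probe_image: np.ndarray | None = None,
) -> EmbeddingBackend:
    """Register a backend after verifying its contract.

    The transform is called twice on a probe image; a wrong output length or
    non-deterministic output raises :class:`RegistrationError`. Re-registering
    an identical backend is idempotent.
    """
    backend = EmbeddingBackend(name, dim, transform, shift_invariant_mask)
    if probe_image is None:
        rng = np.random.default_rng(12345)
        probe_image = rng.random((96, 96))
    v1 = backend(probe_image)
    v2 = backend(probe_image)
    if not np.array_equal(v1, v2):
        raise RegistrationError(f"backend {name!r} is not deterministic")
    existing = _REGISTRY.get(name)
    if existing is not None and (existing.dim != dim or existing.transform is not transform):
        raise RegistrationError(f"backend name {name!r} already registered differently")
    _REGISTRY[name] = backend
    return backend


def get_backend(name: str) -> EmbeddingBackend:
    if name not in _REGISTRY:
        raise RegistrationError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


register_backend("default", DEFAULT_DIM, _default_transform, _default_mask())


def extract_features(
    records: list[tuple[dict, np.ndarray]],
    backend: EmbeddingBackend | str = "default",
) -> pd.DataFrame:
    """One feature row per (metadata, image) record.

    ``records`` typically holds split upper scans and, when the mirror-copy
    convention is on, the un-mirrored lower scans as separate rows (the
    metadata's ``half`` key distinguishes them). Unreadable/failing rows are
    recorded with an ``error`` column and the run continues.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    rows = []
    for meta, image in records:
        row = dict(meta)
        row["backend"] = backend.name
        try:
            vec = backend(image)
        except Exception as exc:  # noqa: BLE001 - per-row error policy
            row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            continue
        row["error"] = ""
        for k, v in enumerate(vec):
            row[f"f{k:03d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Extract the numeric feature block (f### columns) of a feature table."""
    cols = sorted(c for c in table.columns if c.startswith("f") and c[1:].isdigit())
    return table[cols].to_numpy(dtype=float)
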