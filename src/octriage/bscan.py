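"""Core image containers: single B-scans and composite device frames.

Coordinate convention: row 0 is the shallowest depth (tissue surface at the
top of the image), columns index lateral position, all indices are 0-based and
depth windows are half-open ``[a, b)``. Intensities are reals in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import DomainError

#: Axial (depth) pixel pitch of the handheld spectral-domain device, microns.
AXIAL_PITCH_UM = 7.0
#: Lateral pixel pitch, microns.
LATERAL_PITCH_UM = 15.0


@dataclass
class BScan:
    """A single depth-vs-lateral OCT cross-section.

    Parameters
    ----------
    intensity
        2-D float array, rows = depth, columns = lateral position, values in
        ``[0, 1]``.
    axial_pitch_um, lateral_pitch_um
        Physical pixel pitch. Defaults match the point-of-care device
        (7.0 um axial, 15.0 um lateral).
    meta
        Free-form acquisition metadata (subject_id, site_id, anatomic_site,
        frame_index, diagnosis, roi offsets, ...).
    """

    intensity: np.ndarray
    axial_pitch_um: float = AXIAL_PITCH_UM
    lateral_pitch_um: float = LATERAL_PITCH_UM
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise DomainError(f"B-scan intensity must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DomainError("B-scan must hold at least one pixel")
        if not np.all(np.isfinite(arr)):
            raise DomainError("B-scan intensity contains non-finite values")
        self.intensity = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    def with_intensity(self, intensity: np.ndarray, **meta_updates: Any) -> "BScan":
        """Copy carrying new pixel data and (optionally) updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return BScan(
            intensity=intensity,
            axial_pitch_um=self.axial_pitch_um,
            lateral_pitch_um=self.lateral_pitch_um,
            meta=meta,
        )


@dataclass
class DeviceFrame:
    """Raw composite frame as emitted by the device software.

    Vertical concatenation of the upper B-scan, a constant separator band and
    a vertically mirrored copy of the upper scan, so
    ``height == 2 * H + separator_rows``.
    """

    intensity: np.ndarray
    separator_rows: int = 3
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise DomainError("device frame must be a 2-D grid")
        if self.separator_rows < 1:
            raise DomainError("separator_rows must be >= 1")
        if (arr.shape[0] - self.separator_rows) % 2 != 0:
            raise DomainError(
                "frame height minus separator must be even "
                f"(height={arr.shape[0]}, separator_rows={self.separator_rows})"
            )
        self.intensity = arr

    @property
    def half_height(self) -> int:
        return (self.intensity.shape[0] - self.separator_rows) // 2

    @property
    def upper(self) -> np.ndarray:
        return self.intensity[: self.half_height]

    @property
    def lower_mirrored(self) -> np.ndarray:
        return self.intensity[self.half_height + self.separator_rows :]

    @property
    def lower_unmirrored(self) -> np.ndarray:
        return self.lower_mirrored[::-1]
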