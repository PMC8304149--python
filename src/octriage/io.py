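"""Cohort manifests and grayscale image I/O.

Manifests are plain CSV (comma-separated, UTF-8, header required, "." decimal)
with one row per acquired frame. Images are single-channel 8- or 16-bit
PNG/TIFF; intensities are mapped to reals in ``[0, 1]`` at read time by
dividing by the bit-depth maximum, so all downstream math is bit-depth
agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError, IntegrityError, SchemaError

ANATOMIC_SITES = (
    "buccal",
    "labial",
    "tongue_dorsal",
    "tongue_ventral",
    "floor_of_mouth",
    "palate",
    "gingiva",
    "other",
)

DIAGNOSES = (
    "normal",
    "benign",
    "mild_dysplasia",
    "moderate_dysplasia",
    "severe_dysplasia",
    "oscc",
)

SPLITS = ("train", "cv", "test", "none")

REQUIRED_COLUMNS = (
    "subject_id",
    "site_id",
    "anatomic_site",
    "frame_index",
    "image_path",
    "diagnosis",
    "split",
)


@dataclass
class CohortManifest:
    """Validated table mapping frames to subject, site, order and diagnosis."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _validate_manifest_df(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortManifest):
            return NotImplemented
        a = self.df[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        b = other.df[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        return a.equals(b)

    @property
    def site_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["site_id"]))

    def frames_of(self, site_id: str) -> pd.DataFrame:
        return self.df[self.df["site_id"] == site_id]

    def validate_paths(self, root: str | Path | None = None) -> None:
        """Check that every ``image_path`` resolves on disk."""
        base = Path(root) if root is not None else Path(".")
        missing = [
            p
            for p in self.df["image_path"]
            if not (base / p).exists() and not Path(p).exists()
        ]
        if missing:
            raise IntegrityError(
                f"{len(missing)} image path(s) do not resolve, e.g. {missing[0]!r}"
            )


def _validate_manifest_df(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    df = df.copy()
    df["frame_index"] = df["frame_index"].astype(int)
    if (df["frame_index"] < 0).any():
        raise IntegrityError("frame_index must be non-negative")
    for col in ("subject_id", "site_id", "image_path"):
        df[col] = df[col].astype(str)

    bad_site = set(df["anatomic_site"]) - set(ANATOMIC_SITES)
    if bad_site:
        raise SchemaError(f"unknown anatomic_site value(s): {sorted(bad_site)}")
    bad_dx = set(df["diagnosis"]) - set(DIAGNOSES) - {"unknown"}
    if bad_dx:
        raise SchemaError(f"unknown diagnosis value(s): {sorted(bad_dx)}")
    bad_split = set(df["split"]) - set(SPLITS)
    if bad_split:
        raise SchemaError(f"unknown split value(s): {sorted(bad_split)}")

    dup = df.duplicated(subset=["site_id", "frame_index"])
    if dup.any():
        first = df.loc[dup, ["site_id", "frame_index"]].iloc[0]
        raise IntegrityError(
            "duplicate (site_id, frame_index): "
            f"({first['site_id']!r}, {int(first['frame_index'])})"
        )

    unknown_ok = df["split"].isin(["none", "test"])
    bad_unknown = (df["diagnosis"] == "unknown") & ~unknown_ok
    if bad_unknown.any():
        raise IntegrityError(
            "diagnosis 'unknown' is only permitted for rows with split none/test"
        )
    return df


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Unknown columns are preserved in the underlying frame but ignored by the
    pipeline.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "site_id": str})
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, index=False)


_UINT_MAX = {np.uint8: 255, np.uint16: 65535}


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8- or 16-bit image as floats in ``[0, 1]``."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"{path!s}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    raise FormatError(f"{path!s}: unsupported dtype {arr.dtype}; need uint8 or uint16")


def write_image(image: np.ndarray, path: str | Path, depth: int = 16) -> None:
    """Write a ``[0, 1]`` float image as 8- or 16-bit PNG/TIFF.

    Values are quantized by rounding, so a write/read round trip differs from
    the source by at most ``1 / (2**depth - 1)`` per pixel.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FormatError("only single-channel 2-D images can be written")
    if depth == 8:
        q = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    elif depth == 16:
        q = np.clip(np.rint(image * 65535.0), 0, 65535).astype(np.uint16)
    else:
        raise FormatError(f"unsupported bit depth {depth}; need 8 or 16")
    iio.imwrite(Path(path), q)


def quantization_bound(depth: int) -> float:
    """Maximum absolute round-trip error for the given bit depth."""
    if depth not in (8, 16):
        raise DomainError("depth must be 8 or 16")
    return 1.0 / (2**depth - 1)
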