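"""Shared raster/table data model and the file formats the pipeline touches.

Images are single-plane grayscale TIFFs (8/16-bit or float), tables are CSV
with a header row, ground truth is JSON and configuration is YAML.
Coordinates are 0-based ``(row, column)`` throughout; masks are dense label
rasters sharing geometry with their source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelImage",
    "LabeledMask",
    "UnsupportedImageError",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "validate_measurement_table",
]


class UnsupportedImageError(ValueError):
    """Raised for multi-plane, RGB or otherwise unsupported image input."""


@dataclass
class ChannelImage:
    """A single-channel 2D intensity raster.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities. Intensity is treated
        as unitless counts; no background calibration is applied.
    channel
        Channel name, e.g. ``"dapi"``, ``"laminB1"``, ``"cgas"``.
    pixel_size
        Physical units per pixel, or ``None`` when unknown. The pipeline
        itself works in pixel units.
    """

    pixels: np.ndarray
    channel: str = ""
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise UnsupportedImageError(
                f"expected a non-empty 2D raster, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabeledMask:
    """Integer-labeled object raster; 0 is background.

    Labels need not be consecutive (object filters preserve original
    labels), but must be non-negative integers and every present label
    must have a non-empty pixel set by construction.
    """

    labels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError(f"expected a non-empty 2D label raster, got {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def present_labels(self) -> np.ndarray:
        lab = np.unique(self.labels)
        return lab[lab > 0]

    @property
    def n_objects(self) -> int:
        return int(self.present_labels.size)

    def require_same_shape(self, img: "ChannelImage | LabeledMask | np.ndarray") -> None:
        other = img.shape if hasattr(img, "shape") else np.asarray(img).shape
        if tuple(other) != tuple(self.shape):
            raise ValueError(f"shape mismatch: mask {self.shape} vs image {other}")


def read_image(path: str | Path, channel: str = "", pixel_size: float | None = None) -> ChannelImage:
    """Load a single-plane grayscale TIFF losslessly.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedImageError
        For multi-plane or RGB input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path}: expected single-plane grayscale, got shape {arr.shape}"
        )
    return ChannelImage(pixels=arr, channel=channel, pixel_size=pixel_size)


def write_image(img: ChannelImage | np.ndarray, path: str | Path) -> Path:
    """Write a 2D raster as a grayscale TIFF, preserving dtype."""
    arr = img.pixels if isinstance(img, ChannelImage) else np.asarray(img)
    if arr.ndim != 2:
        raise UnsupportedImageError(f"expected 2D raster, got shape {arr.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr)
    return path


def write_table(table: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> Path:
    """Write a measurement table as CSV with a header row.

    Numeric columns round-trip to better than 1e-12 relative (full float
    repr is used). When ``config_hash`` is given it is recorded as a
    leading ``#`` comment line so provenance travels with the file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        table.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV measurement table (leading ``#`` comment lines skipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        return pd.read_csv(path, comment="#", encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc


def validate_measurement_table(table: pd.DataFrame, key: tuple[str, ...] = ("image_id", "label")) -> None:
    """Check that the (image id, object label) key is unique."""
    cols = [c for c in key if c in table.columns]
    if len(cols) == len(key) and table.duplicated(subset=cols).any():
        dup = table[table.duplicated(subset=cols)]
        raise ValueError(f"duplicate table keys: {dup[cols].values[:5].tolist()}")
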