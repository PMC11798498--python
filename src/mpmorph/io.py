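"""Image and table input/output, and the pixel-to-micrometre calibration.

Every downstream measurement is expressed in micrometres through a single
user-supplied ``scale_um_per_px`` attached to the image at load time. The
acquisition scale of a light micrograph cannot be recovered from the pixel
data, so there is deliberately no default: callers must state it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "Micrograph",
    "read_micrograph",
    "write_png",
    "load_measurement_table",
    "MEASUREMENT_COLUMNS",
    "BUILTIN_TABLES",
]

MEASUREMENT_COLUMNS = ["source_id", "particle_id", "area_um2", "major_um", "minor_um"]

#: Builtin reference tables: mean particle dimensions measured from light
#: micrographs of residual saliva collected after cyclic compression of three
#: commercial clear aligners. One row per micrograph panel; a missing axis
#: entry means the fragments in that panel were not individually resolvable.
BUILTIN_TABLES = ("essix_ace", "ghost", "invisalign")


@dataclass
class Micrograph:
    """A calibrated RGB light-microscopy image.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3)
        Colour intensities normalised to [0, 1].
    scale_um_per_px : float
        Physical side length of one pixel in micrometres. Must be positive.
    magnification_tag : str
        Free-text objective tag, e.g. ``"10x"``.
    source_id : str
        Free-text provenance label.
    """

    pixels: np.ndarray
    scale_um_per_px: float
    magnification_tag: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 3 or w < 3:
            raise ValueError(f"image must be at least 3 x 3 (got {h} x {w})")
        if not (np.isfinite(self.pixels).all() and self.pixels.min() >= 0.0 and self.pixels.max() <= 1.0):
            raise ValueError("pixel intensities must be finite and lie in [0, 1]")
        if not (np.isfinite(self.scale_um_per_px) and self.scale_um_per_px > 0):
            raise ValueError(f"scale_um_per_px must be positive, got {self.scale_um_per_px}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def read_micrograph(
    path: str | Path,
    scale_um_per_px: float,
    magnification_tag: str = "",
) -> Micrograph:
    """Read a PNG or TIFF file into a calibrated :class:`Micrograph`.

    Integer images are rescaled by the container maximum of their bit depth
    (255 for 8-bit, 65535 for 16-bit), so full-scale pixels map to exactly
    1.0 — the normalisation on which the global 0.5 threshold of the
    binarisation step is defined. Grayscale files are broadcast to three
    identical channels; an alpha channel, if present, is dropped.
    """
    if not (np.isfinite(scale_um_per_px) and scale_um_per_px > 0):
        raise ValueError(f"scale_um_per_px must be positive, got {scale_um_per_px}")
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # backends raise a zoo of types for bad files
        raise OSError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(raw)
    if np.issubdtype(arr.dtype, np.integer):
        maxval = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(float) / maxval
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported image layout with shape {raw.shape}")
    arr = np.clip(arr, 0.0, 1.0)
    return Micrograph(arr, scale_um_per_px, magnification_tag=magnification_tag, source_id=str(path))


def write_png(m: Micrograph, path: str | Path, bit_depth: int = 8) -> None:
    """Write a micrograph to PNG at the requested bit depth (8 or 16)."""
    if bit_depth == 8:
        out = np.round(m.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(m.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(Path(path), out, extension=".png")


def _builtin_path(name: str):
    return resources.files("mpmorph.data").joinpath(f"{name}.csv")


def load_measurement_table(path_or_builtin: str | Path) -> pd.DataFrame:
    """Load a particle measurement table.

    Parameters
    ----------
    path_or_builtin : str or Path
        Either a CSV path with the columns ``source_id, particle_id,
        area_um2, major_um, minor_um``, or one of the builtin table names
        ``"essix_ace"``, ``"ghost"``, ``"invisalign"``.

    Returns
    -------
    DataFrame
        One row per particle; missing axis lengths are NaN.
    """
    name = str(path_or_builtin)
    if name in BUILTIN_TABLES:
        src = _builtin_path(name)
        with resources.as_file(src) as p:
            df = _read_table_csv(p)
    else:
        df = _read_table_csv(Path(path_or_builtin))
    return df


def _read_table_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError) as exc:
        raise ValueError(f"could not parse measurement table {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} lacks required columns {missing}")
    df = df[MEASUREMENT_COLUMNS].copy()
    for col in ("area_um2", "major_um", "minor_um"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad = df.index[~(df["area_um2"] > 0)]
    if len(bad):
        raise ValueError(f"non-positive area_um2 at row index {bad[0]} of {path}")
    both = df["major_um"].notna() & df["minor_um"].notna()
    violated = df.index[both & ~(df.loc[both, "major_um"] >= df.loc[both, "minor_um"])]
    if len(violated):
        raise ValueError(f"major_um < minor_um at row index {violated[0]} of {path}")
    return df


def write_measurement_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV (missing cells left empty)."""
    df.to_csv(Path(path), index=False)
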