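"""Brightfield cell-pixel quantification.

Wells of an extracellular-flux assay plate are imaged in brightfield before
the run; cells appear as dark objects on a bright, slowly varying background.
The pipeline estimates that background with a wide Gaussian blur, subtracts
the original from it (equivalently: subtract then invert) to obtain a
white-objects-on-black-background image, crops a margin to remove the plate's
molded stops, and counts every pixel whose intensity exceeds a threshold.
The resulting "cell-pixel" count is a proxy for the amount of cell material
in the well and is later calibrated to an absolute cell number.

All images are handled as 2-D float64 arrays on a canonical 0-255 intensity
scale (a ``GrayImage``); multi-channel or differently scaled inputs are
converted on entry by :func:`to_grayscale`.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MIN_IMAGE_SIZE",
    "ImagingParams",
    "CellPixelCount",
    "to_grayscale",
    "estimate_background",
    "correct_and_invert",
    "crop_margins",
    "count_cell_pixels",
    "quantify_well",
    "read_image",
    "well_id_from_filename",
    "quantify_directory",
    "write_pixel_table",
    "read_pixel_table",
]

#: Images smaller than this per side are rejected as degenerate.
MIN_IMAGE_SIZE = 16

_WELL_RE = re.compile(r"(?P<well>[A-H](?:0?[1-9]|1[0-2]))$")


class ImageError(ValueError):
    """Raised for invalid image inputs or parameters."""


@dataclass(frozen=True)
class ImagingParams:
    """Parameters of the cell-pixel pipeline.

    Attributes
    ----------
    background_sigma:
        Standard deviation of the Gaussian background filter, in pixels.
        ``None`` means "choose per image" as ``min(height, width) / 10``,
        wide enough that individual cells vanish from the background
        estimate while illumination gradients survive.
    crop_fraction:
        Margin fraction removed from *each* side after background
        correction (default 0.05, i.e. the central 90% of each dimension
        is retained).
    threshold:
        Intensity cutoff on the corrected, inverted image; pixels strictly
        above it count as cell-pixels. Default 1 on the 0-255 scale.
    """

    background_sigma: Optional[float] = None
    crop_fraction: float = 0.05
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.background_sigma is not None and not self.background_sigma > 0:
            raise ImageError("background_sigma must be positive")
        if not (0.0 <= self.crop_fraction < 0.5):
            raise ImageError("crop_fraction must lie in [0, 0.5)")
        if self.threshold < 0:
            raise ImageError("threshold must be non-negative")

    def sigma_for(self, shape: tuple[int, int]) -> float:
        if self.background_sigma is not None:
            return float(self.background_sigma)
        return min(shape[0], shape[1]) / 10.0

    def params_hash(self) -> str:
        """Short stable identifier of the parameter set, for provenance."""
        key = (
            f"sigma={'auto' if self.background_sigma is None else repr(float(self.background_sigma))};"
            f"crop={float(self.crop_fraction)!r};thr={float(self.threshold)!r}"
        )
        return hashlib.sha256(key.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class CellPixelCount:
    """Cell-pixel count for one well, tagged with the parameters used."""

    well_id: str
    count: int
    params_hash: str

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ImageError("cell-pixel count cannot be negative")


def _validate_gray(pixels: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_IMAGE_SIZE or arr.shape[1] < MIN_IMAGE_SIZE:
        raise ImageError(
            f"{name} must be at least {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ImageError(f"{name} contains non-finite pixels")
    return arr


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image array to a single-channel float image on 0-255.

    Accepts 2-D arrays (single channel) or ``(H, W, 3)`` arrays, which are
    collapsed by the unweighted channel mean. Integer inputs are rescaled
    by their dtype range (uint16 full scale maps to 255); float inputs on
    a unit scale (max <= 1) are multiplied by 255, other float inputs are
    assumed to already be on 0-255 and are clipped to it.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] == 3:
            arr = arr.astype(np.float64).mean(axis=2)
        else:
            raise ImageError(f"unsupported channel count: {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ImageError(f"expected 2-D or 3-channel image, got shape {arr.shape}")

    if np.issubdtype(np.asarray(image).dtype, np.integer):
        info = np.iinfo(np.asarray(image).dtype)
        scale = 255.0 / info.max if info.max != 255 else 1.0
        out = arr.astype(np.float64) * scale
    else:
        out = np.asarray(arr, dtype=np.float64)
        if not np.all(np.isfinite(out)):
            raise ImageError("image contains non-finite pixels")
        if out.size and out.max() <= 1.0 and out.min() >= 0.0:
            out = out * 255.0
        else:
            out = np.clip(out, 0.0, 255.0)
    return _validate_gray(out)


def estimate_background(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-blur background estimate with edge replication.

    The kernel is normalized, so constant images map to themselves; edges
    are handled by replicating the border pixel so that gradients behave
    predictably near the frame.
    """
    arr = _validate_gray(image)
    if not sigma > 0:
        raise ImageError("sigma must be positive")
    return ndimage.gaussian_filter(arr, sigma=float(sigma), mode="nearest")


def correct_and_invert(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Background-subtract and invert in one algebraic step.

    Subtracting the background and inverting the result is equivalent to
    ``clip(background - image, 0, 255)``: dark cells become bright objects
    on a black background, and pixels brighter than their local background
    map to zero.
    """
    img = _validate_gray(image)
    bg = _validate_gray(background, "background")
    if img.shape != bg.shape:
        raise ImageError(f"dimension mismatch: image {img.shape} vs background {bg.shape}")
    return np.clip(bg - img, 0.0, 255.0)


def crop_margins(image: np.ndarray, fraction: float) -> np.ndarray:
    """Remove ``floor(fraction * size)`` pixels from every side.

    ``fraction`` is per side: 0.05 retains the central 90% of each
    dimension. This trims artifacts from the plate's molded stops, which
    sit at the rim of every well image.
    """
    arr = _validate_gray(image)
    if not (0.0 <= fraction < 0.5):
        raise ImageError("crop fraction must lie in [0, 0.5)")
    dr = int(np.floor(fraction * arr.shape[0]))
    dc = int(np.floor(fraction * arr.shape[1]))
    out = arr[dr : arr.shape[0] - dr, dc : arr.shape[1] - dc]
    if out.size == 0:
        raise ImageError("crop removed the entire image")
    return out


def count_cell_pixels(image: np.ndarray, threshold: float) -> int:
    """Number of pixels with intensity strictly greater than ``threshold``."""
    arr = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ImageError("image contains non-finite pixels")
    return int(np.count_nonzero(arr > threshold))


def quantify_well(
    image: np.ndarray,
    params: ImagingParams = ImagingParams(),
    well_id: str = "",
) -> CellPixelCount:
    """Run the full cell-pixel pipeline on one raw well image.

    Equivalent, step for step, to grayscale conversion, Gaussian
    background estimation, background subtraction with inversion, margin
    cropping, and thresholded counting. Deterministic for fixed inputs.
    """
    gray = to_grayscale(image)
    background = estimate_background(gray, params.sigma_for(gray.shape))
    corrected = correct_and_invert(gray, background)
    cropped = crop_margins(corrected, params.crop_fraction)
    count = count_cell_pixels(cropped, params.threshold)
    return CellPixelCount(well_id=well_id, count=count, params_hash=params.params_hash())


# ---------------------------------------------------------------------------
# File IO


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG well image as a raw array (channels preserved)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im)


def well_id_from_filename(path: str | Path) -> str:
    """Extract a 96-well coordinate from a filename stem.

    The stem must end in a well coordinate like ``B07`` or ``B7``
    (optionally after a prefix such as ``plate1_``). The coordinate is
    normalized to a two-digit column.
    """
    stem = Path(path).stem
    m = _WELL_RE.search(stem)
    if m is None:
        raise ImageError(f"cannot parse well id from filename {path!r}")
    well = m.group("well")
    return f"{well[0]}{int(well[1:]):02d}"


def quantify_directory(
    image_dir: str | Path,
    params: ImagingParams = ImagingParams(),
    manifest: Optional[pd.DataFrame] = None,
) -> tuple[list[CellPixelCount], list[tuple[str, str]]]:
    """Quantify every image in a directory (or listed in a manifest).

    ``manifest``, if given, is a DataFrame with columns ``filename,well``
    and overrides filename-based well identification. Returns the counts
    plus a list of ``(filename, error message)`` for unreadable images;
    the run continues past individual failures.
    """
    image_dir = Path(image_dir)
    if manifest is not None:
        entries = [(image_dir / fn, str(w)) for fn, w in zip(manifest["filename"], manifest["well"])]
    else:
        paths = sorted(
            p for p in image_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        entries = []
        for p in paths:
            try:
                entries.append((p, well_id_from_filename(p)))
            except ImageError as exc:
                entries.append((p, ""))
    counts: list[CellPixelCount] = []
    errors: list[tuple[str, str]] = []
    for path, well in entries:
        try:
            if not well:
                raise ImageError(f"cannot parse well id from filename {path.name!r}")
            counts.append(quantify_well(read_image(path), params, well_id=well))
        except Exception as exc:  # record and continue: one bad image must not kill a plate
            errors.append((path.name, str(exc)))
    return counts, errors


def write_pixel_table(
    counts: Iterable[CellPixelCount], path: str | Path, plate_id: str = "plate1"
) -> pd.DataFrame:
    """Write the per-plate cell-pixel table CSV (plate_id,well,cell_pixels,params_hash)."""
    df = pd.DataFrame(
        [
            {
                "plate_id": plate_id,
                "well": c.well_id,
                "cell_pixels": c.count,
                "params_hash": c.params_hash,
            }
            for c in counts
        ],
        columns=["plate_id", "well", "cell_pixels", "params_hash"],
    )
    df.to_csv(path, index=False)
    return df


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    required = {"plate_id", "well", "cell_pixels"}
    missing = required - set(df.columns)
    if missing:
        raise ImageError(f"pixel table missing columns: {sorted(missing)}")
    return df
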