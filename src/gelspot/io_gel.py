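"""Reading and writing gel images.

All processing operates on a canonical representation: a 2-D float
array of intensities normalized to [0, 1], regardless of the source
file's bit depth or channel count.  Disk radii, h-parameters and
thresholds are therefore bit-depth independent.

Supported input formats are the common raster containers gel scanners
emit (TIFF, PNG, JPEG, BMP).  Output images are written as 16-bit
grayscale TIFF, which round-trips the float representation to within
one 16-bit quantization step per pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: ITU-R BT.709 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class GelImage:
    """A single gel image: 2-D grayscale raster in [0, 1] plus provenance.

    Parameters
    ----------
    pixels
        2-D float array, values in [0, 1].
    source_path
        Where the image came from ("" for in-memory images).
    bit_depth_original
        Bit depth of the source file (8, 16, or 0 for float sources).
    """

    pixels: np.ndarray
    source_path: str = ""
    bit_depth_original: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"GelImage requires a 2-D raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("GelImage must be at least 1x1 pixel")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"GelImage intensities must lie in [0, 1]; found range [{lo}, {hi}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def name(self) -> str:
        """File stem of the source, used as the gel identifier."""
        return Path(self.source_path).stem if self.source_path else ""


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel raster to one channel via BT.709 luma."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ LUMA_WEIGHTS
    raise ValidationError(f"Unsupported image shape {arr.shape}")


def load_gel_image(path: str | Path) -> GelImage:
    """Load a raster image and normalize it into the canonical [0, 1] domain.

    Integer pixel types are divided by their type maximum (255 for
    8-bit, 65535 for 16-bit); float inputs are expected to already lie
    in [0, 1].  Multi-channel images are converted to grayscale by the
    fixed BT.709 luma weighting.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"Cannot read gel image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValidationError(f"Zero-sized image: {path}")

    if raw.dtype == np.uint8:
        bit_depth, divisor = 8, 255.0
    elif raw.dtype == np.uint16:
        bit_depth, divisor = 16, 65535.0
    elif raw.dtype == bool:
        bit_depth, divisor = 1, 1.0
    elif np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        bit_depth, divisor = info.bits, float(info.max)
    elif np.issubdtype(raw.dtype, np.floating):
        bit_depth, divisor = 0, 1.0
    else:
        raise ValidationError(f"Unsupported pixel dtype {raw.dtype} in {path}")

    gray = _to_grayscale(raw.astype(np.float64)) / divisor
    gray = np.clip(gray, 0.0, 1.0)
    return GelImage(gray, source_path=str(path), bit_depth_original=bit_depth)


def save_gel_image(image: GelImage, path: str | Path) -> None:
    """Write a gel image as 16-bit grayscale TIFF, creating parent dirs.

    Values are rounded to the nearest of 65536 levels, so a load after
    save reproduces every pixel to within 1/65535.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    quantized = np.round(image.pixels * 65535.0).astype(np.uint16)
    try:
        tifffile.imwrite(path, quantized)
    except OSError as exc:
        raise OSError(f"Cannot write gel image {path}: {exc}") from exc


def list_gel_directory(directory: str | Path, standard_name: str | None = None) -> list[Path]:
    """Return lexicographically sorted paths of decodable images in a directory.

    Non-image files are skipped with a logged warning.  If
    ``standard_name`` is given, it must be among the returned images.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"Not a directory: {directory}")
    paths: list[Path] = []
    for p in sorted(directory.iterdir(), key=lambda q: q.name):
        if not p.is_file():
            continue
        if p.suffix.lower() not in IMAGE_SUFFIXES:
            logger.warning("Skipping non-image file %s", p.name)
            continue
        try:
            iio.imread(p)
        except (OSError, ValueError):
            logger.warning("Skipping undecodable file %s", p.name)
            continue
        paths.append(p)
    if not paths:
        raise ValidationError(f"No decodable gel images found in {directory}")
    if standard_name is not None and standard_name not in {p.name for p in paths}:
        raise ValidationError(
            f"Standard gel {standard_name!r} not found among images in {directory}"
        )
    return paths
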