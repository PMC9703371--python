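"""Protein-spot segmentation of the mean gel image.

The detection chain treats the image as a topographic surface: spots
must be peaks, so dark-spot gels (Coomassie-type: dark protein on a
light background) are complemented first.  A white top-hat with a disk
structuring element then removes any background structure wider than
the disk, leaving the spots on a flat zero baseline; the disk radius is
the main tuning knob — it bounds the size of the features kept.
Markers for the watershed come from the regional maxima of the
h-maxima-suppressed top-hat image: maxima with prominence <= h_suppress
are merged away, which is the standard lever against oversegmentation.
Marker-controlled watershed flooding of the inverted top-hat image,
restricted to a thresholded foreground inside the ROI, partitions the
foreground into one region per surviving marker.

All connectivity decisions (maxima, markers, regions) use the single
configured value (4 or 8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import ValidationError
from .io_gel import GelImage
from .registration import CropRect

logger = logging.getLogger(__name__)

DARK_SPOTS = "dark_spots"
BRIGHT_SPOTS = "bright_spots"


@dataclass
class SegmentationParams:
    """Tunable parameters of the spot-detection chain.

    disk_radius
        Radius (px) of the disk structuring element of the top-hat;
        should exceed the radius of the largest spot to keep.
    roi
        Rectangle of the mean image within which spots are detected;
        None means the full image.  Shrinking the ROI around faint
        spots improves their detection (the Otsu threshold adapts to
        the ROI statistics).
    h_suppress
        Prominence threshold of the h-maxima marker suppression; larger
        values merge shallow maxima and reduce oversegmentation.
    foreground_threshold
        Absolute intensity threshold on the top-hat image, or "otsu" to
        compute it from the ROI pixels.
    min_area, max_area
        Area filter (px^2) applied to the final regions.
    polarity
        "dark_spots" (complement before filtering; the usual stained
        gel) or "bright_spots".
    connectivity
        4 or 8; used for maxima, markers and regions alike.
    """

    disk_radius: int = 15
    roi: CropRect | None = None
    h_suppress: float = 0.02
    foreground_threshold: float | str = "otsu"
    min_area: int = 9
    max_area: int | None = None
    polarity: str = DARK_SPOTS
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.disk_radius < 1:
            raise ValidationError(f"disk_radius must be >= 1, got {self.disk_radius}")
        if self.min_area < 1:
            raise ValidationError(f"min_area must be >= 1, got {self.min_area}")
        if self.max_area is not None and self.max_area <= self.min_area:
            raise ValidationError("max_area must exceed min_area when set")
        if self.polarity not in (DARK_SPOTS, BRIGHT_SPOTS):
            raise ValidationError(f"Unknown polarity {self.polarity!r}")
        if self.connectivity not in (4, 8):
            raise ValidationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if not 0.0 <= self.h_suppress:
            raise ValidationError("h_suppress must be >= 0")


@dataclass
class LabelMap:
    """Integer raster partitioning the ROI into spot regions.

    0 is background/outside-ROI; 1..n_spots are spot regions, numbered
    in raster-scan order of each region's first pixel.
    """

    labels: np.ndarray
    n_spots: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("LabelMap must be a 2-D raster")


def _skimage_connectivity(connectivity: int) -> int:
    # skimage counts connectivity in orthogonal steps: 1 -> 4-neighbour, 2 -> 8.
    return 1 if connectivity == 4 else 2


def _footprint(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, _skimage_connectivity(connectivity))


def orient_spots_bright(image: GelImage, polarity: str = DARK_SPOTS) -> GelImage:
    """Return the image with spots as intensity peaks.

    Dark-spot gels are complemented (1 - pixels); bright-spot images
    pass through unchanged.
    """
    if polarity == DARK_SPOTS:
        return GelImage(1.0 - image.pixels, image.source_path, image.bit_depth_original)
    if polarity == BRIGHT_SPOTS:
        return image
    raise ValidationError(f"Unknown polarity {polarity!r}")


def tophat_filter(image: GelImage, disk_radius: int) -> GelImage:
    """White top-hat: image minus its grayscale opening by a disk.

    Removes background structure wider than the disk (radius in px,
    disk = pixels whose centre distance <= radius); the result is
    non-negative and zero wherever the image equals its opening.
    Expects a spots-bright input.
    """
    if disk_radius < 1:
        raise ValidationError(f"disk_radius must be >= 1, got {disk_radius}")
    footprint = morphology.disk(disk_radius)
    filtered = morphology.white_tophat(image.pixels, footprint=footprint)
    return GelImage(
        np.clip(filtered, 0.0, 1.0), image.source_path, image.bit_depth_original
    )


def suppress_shallow_maxima(image: GelImage, h: float, connectivity: int = 8) -> GelImage:
    """h-maxima transform: remove regional maxima of prominence <= h.

    Morphological reconstruction by dilation of (image - h) under the
    image; the surviving regional maxima correspond to input maxima of
    prominence > h under the given pixel connectivity.
    """
    if h < 0:
        raise ValidationError(f"h must be >= 0, got {h}")
    if h == 0:
        return GelImage(image.pixels.copy(), image.source_path, image.bit_depth_original)
    seed = image.pixels - h
    rec = morphology.reconstruction(
        seed, image.pixels, method="dilation", footprint=_footprint(connectivity)
    )
    return GelImage(np.clip(rec, 0.0, 1.0), image.source_path, image.bit_depth_original)


def _roi_mask(shape: tuple[int, int], roi: CropRect | None) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if roi is None:
        mask[:] = True
        return mask
    if roi.x0 + roi.width > shape[1] or roi.y0 + roi.height > shape[0]:
        raise ValidationError(
            f"ROI (x0={roi.x0}, y0={roi.y0}, w={roi.width}, h={roi.height}) "
            f"exceeds image bounds {shape[1]}x{shape[0]}"
        )
    mask[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width] = True
    return mask


def _relabel_raster_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..K by raster-scan order of each region's first pixel."""
    flat = labels.ravel()
    order = []
    seen = set()
    for v in flat:
        if v != 0 and v not in seen:
            seen.add(v)
            order.append(v)
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return lut[labels], len(order)


def watershed_segment(filtered: GelImage, params: SegmentationParams) -> LabelMap:
    """Marker-controlled watershed of the top-hat image within the ROI.

    Foreground = ROI pixels above the threshold (Otsu on ROI pixels by
    default).  Markers = connected components of the regional maxima of
    the h-suppressed image, computed with everything outside the
    foreground held below the minimum so each foreground component owns
    at least one marker.  Flooding the inverted image from the markers,
    restricted to the foreground, yields a ridge-free partition: every
    foreground pixel carries exactly one label.
    """
    img = filtered.pixels
    roi = _roi_mask(img.shape, params.roi)
    roi_vals = img[roi]

    if params.foreground_threshold == "otsu":
        if roi_vals.size == 0 or np.all(roi_vals == roi_vals.flat[0]):
            thr = np.inf  # constant ROI: nothing to segment
        else:
            thr = threshold_otsu(roi_vals)
    else:
        thr = float(params.foreground_threshold)

    fg = roi & (img > thr)
    if not fg.any():
        logger.warning("Empty foreground: no pixels above threshold inside the ROI")
        return LabelMap(np.zeros(img.shape, dtype=np.int32), 0)

    conn = _skimage_connectivity(params.connectivity)
    suppressed = suppress_shallow_maxima(
        filtered, params.h_suppress, params.connectivity
    ).pixels
    masked = np.where(fg, suppressed, suppressed.min() - 1.0)
    maxima = morphology.local_maxima(masked, connectivity=conn) & fg
    markers = cc_label(maxima, connectivity=conn)

    labels = watershed(-img, markers=markers, mask=fg, connectivity=conn)
    labels, k = _relabel_raster_order(labels.astype(np.int32))
    return LabelMap(labels, k)


def filter_regions(
    labels: LabelMap, min_area: int, max_area: int | None = None
) -> LabelMap:
    """Drop regions outside [min_area, max_area]; relabel survivors 1..K'
    preserving raster order."""
    arr = labels.labels
    if labels.n_spots == 0:
        return LabelMap(arr.copy(), 0)
    areas = np.bincount(arr.ravel(), minlength=labels.n_spots + 1)
    keep = areas >= min_area
    if max_area is not None:
        keep &= areas <= max_area
    keep[0] = False
    out = np.where(keep[arr], arr, 0)
    relabeled, k = _relabel_raster_order(out)
    return LabelMap(relabeled, k)


def make_overlay(filtered: GelImage, labels: LabelMap) -> np.ndarray:
    """RGB uint8 image: region boundaries drawn in red over the filtered gel."""
    from skimage.segmentation import find_boundaries

    base = np.clip(filtered.pixels, 0.0, 1.0)
    rgb = np.stack([base, base, base], axis=-1)
    edges = find_boundaries(labels.labels, mode="outer")
    rgb[edges] = [1.0, 0.0, 0.0]
    return (rgb * 255).astype(np.uint8)


def segment_mean_image(mean: GelImage, params: SegmentationParams) -> tuple[GelImage, LabelMap]:
    """Full detection chain on a mean gel image.

    Orients spots bright, top-hat filters, runs the marker-controlled
    watershed and applies the area filter.  Returns the filtered image
    (for overlay/quantification on the top-hat scale) and the label map.
    """
    bright = orient_spots_bright(mean, params.polarity)
    filtered = tophat_filter(bright, params.disk_radius)
    raw_labels = watershed_segment(filtered, params)
    labels = filter_regions(raw_labels, params.min_area, params.max_area)
    return filtered, labels
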