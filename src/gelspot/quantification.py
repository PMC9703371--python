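"""Superimposition quantification.

The label map segmented once on the mean gel is applied, unchanged, to
every aligned-and-cropped gel: corresponding spots therefore share an
identical pixel footprint on all gels (same area by construction), and
a spot's per-gel mean intensity is directly comparable across gels.
Intensities are reported on the spots-bright oriented scale, so a
darker (more protein) spot on a stained gel yields a larger value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_gel import GelImage
from .meanimage import GelStack
from .registration import CropRect
from .segmentation import DARK_SPOTS, LabelMap, orient_spots_bright

QUANT_COLUMNS = [
    "spot_id",
    "gel",
    "area_px",
    "mean_intensity",
    "integrated_intensity",
    "centroid_x",
    "centroid_y",
]


@dataclass
class SpotRecord:
    """Geometry and intensity of one labeled spot region on one image."""

    spot_id: int
    area: int
    mean_intensity: float
    centroid_x: float
    centroid_y: float
    bbox: CropRect


def extract_region_stats(labels: LabelMap, image: GelImage) -> list[SpotRecord]:
    """Per-label area, mean intensity, centroid and bounding box.

    The image must already be oriented spots-bright; the mean is the
    plain arithmetic mean over the region's pixels.
    """
    arr = labels.labels
    if arr.shape != image.pixels.shape:
        raise ValidationError(
            f"Label map shape {arr.shape} != image shape {image.pixels.shape}"
        )
    k = labels.n_spots
    if k == 0:
        return []
    flat = arr.ravel()
    counts = np.bincount(flat, minlength=k + 1)
    sums = np.bincount(flat, weights=image.pixels.ravel(), minlength=k + 1)
    yy, xx = np.nonzero(arr)
    vals = arr[yy, xx]
    cx_sum = np.bincount(vals, weights=xx, minlength=k + 1)
    cy_sum = np.bincount(vals, weights=yy, minlength=k + 1)
    records = []
    for spot in range(1, k + 1):
        area = int(counts[spot])
        if area == 0:
            raise ValidationError(f"Label {spot} has no pixels")
        sel = vals == spot
        x_min, x_max = int(xx[sel].min()), int(xx[sel].max())
        y_min, y_max = int(yy[sel].min()), int(yy[sel].max())
        records.append(
            SpotRecord(
                spot_id=spot,
                area=area,
                mean_intensity=float(sums[spot] / area),
                centroid_x=float(cx_sum[spot] / area),
                centroid_y=float(cy_sum[spot] / area),
                bbox=CropRect(x_min, y_min, x_max - x_min + 1, y_max - y_min + 1),
            )
        )
    return records


def quantify_stack(
    labels: LabelMap, stack: GelStack, polarity: str = DARK_SPOTS
) -> pd.DataFrame:
    """Apply the mean-image label map to every gel and tabulate the stats.

    Returns the tidy long table with one row per (spot, gel), ordered by
    (spot_id, gel order).  Per-spot area is identical across gels since
    the footprint is shared.
    """
    rows = []
    for name, gel in zip(stack.names, stack.images):
        if gel.pixels.shape != labels.labels.shape:
            raise ValidationError(
                f"Gel {name} shape {gel.pixels.shape} != label map shape "
                f"{labels.labels.shape}"
            )
        oriented = orient_spots_bright(gel, polarity)
        for rec in extract_region_stats(labels, oriented):
            rows.append(
                {
                    "spot_id": rec.spot_id,
                    "gel": name,
                    "area_px": rec.area,
                    "mean_intensity": rec.mean_intensity,
                    "integrated_intensity": rec.mean_intensity * rec.area,
                    "centroid_x": rec.centroid_x,
                    "centroid_y": rec.centroid_y,
                }
            )
    table = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    if len(table):
        gel_order = {n: i for i, n in enumerate(stack.names)}
        table = (
            table.assign(_g=table["gel"].map(gel_order))
            .sort_values(["spot_id", "_g"], kind="stable")
            .drop(columns="_g")
            .reset_index(drop=True)
        )
    return table


def local_background_table(
    labels: LabelMap,
    stack: GelStack,
    polarity: str = DARK_SPOTS,
    ring_radius: int = 8,
    guard_radius: int = 2,
) -> pd.DataFrame:
    """Per-(spot, gel) local background estimate for downstream correction.

    For each spot the background is the median oriented intensity over a
    ring of pixels within ``ring_radius`` of the spot region, excluding
    every labeled region dilated by ``guard_radius`` (so neighbouring
    spot tails do not contaminate the estimate).  Returns columns
    (spot_id, gel, background).
    """
    from skimage.morphology import dilation, disk

    arr = labels.labels
    any_region = dilation(arr > 0, footprint=disk(guard_radius))
    rings = {}
    for spot in range(1, labels.n_spots + 1):
        ring = dilation(arr == spot, footprint=disk(ring_radius)) & ~any_region
        rings[spot] = ring
    rows = []
    for name, gelimg in zip(stack.names, stack.images):
        oriented = orient_spots_bright(gelimg, polarity).pixels
        for spot, ring in rings.items():
            bgval = float(np.median(oriented[ring])) if ring.any() else np.nan
            rows.append({"spot_id": spot, "gel": name, "background": bgval})
    return pd.DataFrame(rows, columns=["spot_id", "gel", "background"])


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to spots x gels of mean intensity."""
    if len(table) == 0:
        return pd.DataFrame(columns=["spot_id"]).set_index("spot_id")
    gel_order = list(dict.fromkeys(table["gel"]))
    wide = table.pivot(index="spot_id", columns="gel", values="mean_intensity")
    return wide[gel_order]


def write_quant_table(table: pd.DataFrame, long_path: str | Path, wide_path: str | Path | None = None) -> None:
    """Write the long CSV and (optionally) the wide spots-x-gels CSV.

    Values are serialized with 9 significant digits so reruns are
    byte-identical.
    """
    long_path = Path(long_path)
    long_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(long_path, index=False, float_format="%.9g")
    if wide_path is not None:
        wide = to_wide(table)
        Path(wide_path).parent.mkdir(parents=True, exist_ok=True)
        wide.to_csv(wide_path, float_format="%.9g")


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read back a long-format quantification CSV."""
    return pd.read_csv(path)
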