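"""Orchestration of the full workflow from a PipelineConfig.

Stage 1 (align-crop): register every gel in the input directory to the
standard gel via its two control points, warp, crop all to the common
rectangle, and write both the aligned and the aligned-and-cropped
stacks plus a JSON manifest of the estimated transforms.

Stage 2 (segment + quantify): build the mean gel image from the
aligned-and-cropped stack, detect spots on it (top-hat + marker-
controlled watershed), superimpose the label map on every gel and
write the quantification tables.

Both stages are deterministic: the same config and inputs produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig
from .errors import ValidationError
from .io_gel import GelImage, list_gel_directory, load_gel_image, save_gel_image
from .meanimage import GelStack, compute_mean_image
from .quantification import quantify_stack, write_quant_table
from .registration import align_and_crop_batch, read_control_points
from .segmentation import (
    make_overlay,
    orient_spots_bright,
    segment_mean_image,
    tophat_filter,
)

logger = logging.getLogger(__name__)


def _setup_run_log(out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gelspot")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    logger.info("config hash %s", config.digest())


def run_align_crop(config: PipelineConfig) -> dict:
    """Stage 1: align every gel to the standard and crop to the common
    rectangle; returns the transform manifest (gel name -> parameters)."""
    config.validate_paths()
    out_dir = Path(config.output_dir)
    _setup_run_log(out_dir, config)
    t0 = time.perf_counter()

    gel_paths = list_gel_directory(config.gel_dir, config.standard_image)
    control = read_control_points(config.control_points_file)
    standard_path = Path(config.gel_dir) / config.standard_image
    result = align_and_crop_batch(
        gel_paths,
        standard_path,
        control,
        config.crop,
        out_aligned=out_dir / "aligned",
        out_cropped=out_dir / "aligned_cropped",
    )
    manifest = {
        name: {"scale": tf.scale, "rotation": tf.rotation, "tx": tf.tx, "ty": tf.ty}
        for name, tf in result.transforms.items()
    }
    with open(out_dir / "transforms.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info(
        "align-crop: %d gels in %.2f s", len(gel_paths), time.perf_counter() - t0
    )
    return manifest


def load_cropped_stack(cropped_dir: str | Path) -> GelStack:
    """Load the aligned-and-cropped images written by stage 1."""
    paths = list_gel_directory(cropped_dir)
    images = [load_gel_image(p) for p in paths]
    return GelStack(images, [p.stem for p in paths])


def run_segment_quantify(config: PipelineConfig) -> pd.DataFrame:
    """Stage 2: mean image, segmentation, superimposed quantification.

    Writes mean_gel.tif, mean_gel_tophat.tif, labels.tif, overlay.png,
    quant_long.csv and quant_wide.csv into the output directory and
    returns the long table.
    """
    out_dir = Path(config.output_dir)
    cropped_dir = out_dir / "aligned_cropped"
    if not cropped_dir.is_dir():
        raise ValidationError(
            f"{cropped_dir} not found: run the align-crop stage first"
        )
    _setup_run_log(out_dir, config)
    t0 = time.perf_counter()

    stack = load_cropped_stack(cropped_dir)
    mean = compute_mean_image(stack)
    save_gel_image(mean, out_dir / "mean_gel.tif")

    filtered, labels = segment_mean_image(mean, config.segmentation)
    save_gel_image(filtered, out_dir / "mean_gel_tophat.tif")
    tifffile.imwrite(out_dir / "labels.tif", labels.labels.astype(np.uint16))
    iio.imwrite(out_dir / "overlay.png", make_overlay(filtered, labels))
    if labels.n_spots == 0:
        logger.warning("No spots detected; quantification tables will be empty")
    logger.info("segmentation: %d spots in %.2f s", labels.n_spots, time.perf_counter() - t0)

    if config.quantify_on == "tophat":
        quant_images = [
            tophat_filter(
                orient_spots_bright(im, config.segmentation.polarity),
                config.segmentation.disk_radius,
            )
            for im in stack.images
        ]
        quant_stack = GelStack(quant_images, stack.names)
        # images are already spots-bright; skip re-orientation
        table = quantify_stack(labels, quant_stack, polarity="bright_spots")
    else:
        table = quantify_stack(labels, stack, polarity=config.segmentation.polarity)

    write_quant_table(table, out_dir / "quant_long.csv", out_dir / "quant_wide.csv")
    logger.info("quantification: %d rows in %.2f s", len(table), time.perf_counter() - t0)
    return table


def run_full(config: PipelineConfig) -> pd.DataFrame:
    """Both stages back to back."""
    run_align_crop(config)
    return run_segment_quantify(config)
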