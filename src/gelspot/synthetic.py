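"""Synthetic 2D-PAGE gel generator with known ground truth.

Emulates Coomassie-style stained gels: dark elliptical-Gaussian spots
subtracted from a light, smoothly varying background (constant plus a
linear gradient), replicated across gels under small similarity
transforms with a per-gel intensity scale factor and additive Gaussian
pixel noise.  Every random draw is determined by the seed, so the same
truth renders bit-identical images on every run.

Conventions: each gel's similarity transform maps standard-frame
coordinates to that gel's frame, so a spot planted at (cx, cy) on the
standard appears at T_i(cx, cy) on gel i; rendering evaluates the
standard-frame spot field at T_i^{-1}(pixel).  The first gel is the
standard and always carries the identity transform.  Aligning gel i
back to the standard therefore requires the map T_i^{-1}, which is what
two control points mapped through T_i let the registration recover.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_gel import GelImage, save_gel_image
from .meanimage import GelStack
from .registration import ControlPointPair, SimilarityTransform, write_control_points

logger = logging.getLogger(__name__)


@dataclass
class PlantedSpot:
    """One elliptical-Gaussian spot in standard-frame coordinates."""

    cx: float
    cy: float
    sigma_x: float
    sigma_y: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValidationError("Spot sigmas must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValidationError("Spot amplitude must be in (0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Complete description of a replicate gel set.

    background is (level, grad_x, grad_y): pixel background =
    level + grad_x * x / width + grad_y * y / height.
    """

    spots: list[PlantedSpot]
    transforms: list[SimilarityTransform]
    intensity_scales: list[float]
    background: tuple[float, float, float] = (0.85, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.transforms) != len(self.intensity_scales):
            raise ValidationError("One transform and one intensity scale per gel")
        if any(c <= 0 for c in self.intensity_scales):
            raise ValidationError("Intensity scales must be positive")

    @property
    def n_gels(self) -> int:
        return len(self.transforms)


def spot_field(truth: SyntheticGroundTruth, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sum of all planted Gaussians evaluated at standard-frame (x, y)."""
    total = np.zeros_like(np.asarray(x, dtype=np.float64))
    for s in truth.spots:
        total += s.amplitude * np.exp(
            -((x - s.cx) ** 2 / (2 * s.sigma_x**2) + (y - s.cy) ** 2 / (2 * s.sigma_y**2))
        )
    return total


def render_gel(
    truth: SyntheticGroundTruth, gel_index: int, size: tuple[int, int]
) -> GelImage:
    """Render one gel of the replicate set.

    pixel = background(x, y) - c_i * spot_field(T_i^{-1}(x, y)) + noise,
    clamped to [0, 1].  Deterministic given (seed, gel_index).
    """
    if not 0 <= gel_index < truth.n_gels:
        raise ValidationError(f"gel_index {gel_index} out of range 0..{truth.n_gels - 1}")
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    level, gx, gy = truth.background
    bg = level + gx * xx / w + gy * yy / h

    inv = truth.transforms[gel_index].inverse()
    src = inv.apply(np.column_stack([xx.ravel(), yy.ravel()]))
    signal = spot_field(truth, src[:, 0], src[:, 1]).reshape(h, w)
    img = bg - truth.intensity_scales[gel_index] * signal
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, gel_index]))
        img = img + rng.normal(0.0, truth.noise_sigma, size=img.shape)
    if img.min() < -0.5:
        logger.warning(
            "Gel %d saturates: background minus spots reaches %.3f pre-clamp",
            gel_index,
            img.min(),
        )
    return GelImage(np.clip(img, 0.0, 1.0), source_path=f"synthetic_gel_{gel_index:02d}")


def render_replicate_set(
    truth: SyntheticGroundTruth,
    size: tuple[int, int],
    click_noise_sigma: float = 0.0,
) -> tuple[GelStack, dict[str, ControlPointPair]]:
    """Render all gels plus their control-point coordinates.

    The first gel is the standard.  Control points are the first two
    planted spot centres mapped through each gel's transform (exact
    landmark positions); ``click_noise_sigma`` adds Gaussian jitter
    emulating imprecise manual point picking.
    """
    if len(truth.spots) < 2:
        raise ValidationError("At least two spots are needed for control points")
    centers = np.array([[truth.spots[0].cx, truth.spots[0].cy],
                        [truth.spots[1].cx, truth.spots[1].cy]])
    images, names = [], []
    control: dict[str, ControlPointPair] = {}
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 10_007]))
    for i in range(truth.n_gels):
        name = f"gel_{i:02d}"
        img = render_gel(truth, i, size)
        img.source_path = f"{name}.tif"
        images.append(img)
        names.append(name)
        pts = truth.transforms[i].apply(centers)
        if click_noise_sigma > 0:
            pts = pts + rng.normal(0.0, click_noise_sigma, size=pts.shape)
        control[f"{name}.tif"] = ControlPointPair(f"{name}.tif", pts)
    return GelStack(images, names), control


def default_ground_truth(
    n_gels: int = 5,
    n_spots: int = 12,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise_sigma: float = 0.005,
    intensity_scales: list[float] | None = None,
    max_rotation_deg: float = 3.0,
    max_translation: float = 10.0,
    scale_range: tuple[float, float] = (0.98, 1.02),
    sigma_px: float = 4.0,
    amplitude_range: tuple[float, float] = (0.12, 0.28),
    min_separation_sigmas: float = 6.0,
    background: tuple[float, float, float] = (0.85, 0.05, 0.04),
) -> SyntheticGroundTruth:
    """Sample a realistic replicate-set ground truth.

    Defaults model a small 2D-PAGE experiment: five replicate gels with
    per-gel loading/staining scale factors spanning 0.5x-2x, spots of
    ~4 px Gaussian radius separated by more than 6 sigma, mild scanner
    misplacement (|rotation| <= 3 deg, |translation| <= 10 px, scale
    within 2%), a light background with a gentle gradient, and additive
    noise of sigma 0.005 on the [0, 1] intensity scale.  The default
    amplitude range keeps even the heaviest-loaded gel (2x scale) clear
    of the 0-intensity floor, so rendering stays linear in the per-gel
    scale factor (the saturation regime is outside the model).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 42_001]))
    h, w = size
    if intensity_scales is None:
        intensity_scales = [0.5, 0.8, 1.0, 1.5, 2.0][:n_gels]
        while len(intensity_scales) < n_gels:
            intensity_scales.append(float(rng.uniform(0.5, 2.0)))

    # Rejection-sample spot centres with the pairwise separation floor.
    margin = 4 * sigma_px * 1.5 + max_translation
    min_dist = min_separation_sigmas * sigma_px
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_spots:
        attempts += 1
        if attempts > 100_000:
            raise ValidationError(
                f"Cannot place {n_spots} spots {min_dist:.0f} px apart in {w}x{h}"
            )
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all(np.hypot(cx - a, cy - b) > min_dist for a, b in centers):
            centers.append((cx, cy))
    spots = [
        PlantedSpot(
            cx=cx,
            cy=cy,
            sigma_x=float(rng.uniform(0.8, 1.2) * sigma_px),
            sigma_y=float(rng.uniform(0.8, 1.2) * sigma_px),
            amplitude=float(rng.uniform(*amplitude_range)),
        )
        for cx, cy in centers
    ]

    transforms = [SimilarityTransform.identity()]
    max_rot = np.deg2rad(max_rotation_deg)
    cx0, cy0 = w / 2.0, h / 2.0
    for _ in range(1, n_gels):
        s = float(rng.uniform(*scale_range))
        th = float(rng.uniform(-max_rot, max_rot))
        # rotate/scale about the image centre, then translate
        dx, dy = rng.uniform(-max_translation, max_translation, size=2)
        c, sn = s * np.cos(th), s * np.sin(th)
        tx = cx0 - (c * cx0 - sn * cy0) + dx
        ty = cy0 - (sn * cx0 + c * cy0) + dy
        transforms.append(SimilarityTransform(scale=s, rotation=th, tx=tx, ty=ty))

    return SyntheticGroundTruth(
        spots=spots,
        transforms=transforms,
        intensity_scales=list(intensity_scales),
        background=background,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def truth_to_dict(truth: SyntheticGroundTruth) -> dict:
    return {
        "seed": truth.seed,
        "noise_sigma": truth.noise_sigma,
        "background": list(truth.background),
        "intensity_scales": [float(c) for c in truth.intensity_scales],
        "spots": [
            {"cx": s.cx, "cy": s.cy, "sigma_x": s.sigma_x, "sigma_y": s.sigma_y,
             "amplitude": s.amplitude}
            for s in truth.spots
        ],
        "transforms": [
            {"scale": t.scale, "rotation": t.rotation, "tx": t.tx, "ty": t.ty}
            for t in truth.transforms
        ],
    }


def write_simulation(
    truth: SyntheticGroundTruth,
    size: tuple[int, int],
    out_dir: str | Path,
    click_noise_sigma: float = 0.0,
) -> tuple[GelStack, dict[str, ControlPointPair]]:
    """Render the set and write gel TIFFs, the control-points TSV and
    truth.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, control = render_replicate_set(truth, size, click_noise_sigma)
    for name, img in zip(stack.names, stack.images):
        save_gel_image(img, out_dir / f"{name}.tif")
    write_control_points(control, out_dir / "control_points.tsv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=2)
    return stack, control
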