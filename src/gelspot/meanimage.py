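"""Mean gel image construction.

Segmenting the pixel-wise mean of the aligned-and-cropped stack — once,
instead of segmenting every gel separately — is what guarantees that
corresponding spots occupy identical pixel footprints on every gel, so
intensities extracted later are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_gel import GelImage


@dataclass
class GelStack:
    """An ordered set of same-shape gel images with unique names."""

    images: list[GelImage]
    names: list[str]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValidationError("GelStack requires at least one image")
        if len(self.names) != len(self.images):
            raise ValidationError("GelStack names and images must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError(f"GelStack names must be unique: {self.names}")
        shape0 = self.images[0].pixels.shape
        bad = [n for n, im in zip(self.names, self.images) if im.pixels.shape != shape0]
        if bad:
            raise ValidationError(f"Gels with mismatched shape: {bad}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].pixels.shape


def compute_mean_image(stack: GelStack) -> GelImage:
    """Pixel-wise arithmetic mean of all gels in the stack."""
    mean = np.mean([im.pixels for im in stack.images], axis=0)
    return GelImage(np.clip(mean, 0.0, 1.0), source_path="", bit_depth_original=0)
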