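"""Declarative pipeline configuration.

One YAML file drives a whole run, replacing interactive prompts with
reviewable, reproducible settings.  The config round-trips through its
serialized form losslessly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .registration import CropRect
from .segmentation import SegmentationParams

QUANTIFY_MODES = ("raw", "tophat")


def _rect_to_dict(rect: CropRect | None) -> dict | None:
    if rect is None:
        return None
    return {"x0": rect.x0, "y0": rect.y0, "width": rect.width, "height": rect.height}


def _rect_from_dict(d: dict | None) -> CropRect | None:
    if d is None:
        return None
    return CropRect(int(d["x0"]), int(d["y0"]), int(d["width"]), int(d["height"]))


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    quantify_on selects the intensity source for the final table:
    "raw" reads the aligned-and-cropped gels directly (the default),
    "tophat" reads each gel after per-gel disk top-hat background
    removal.
    """

    gel_dir: str
    standard_image: str
    control_points_file: str
    crop: CropRect
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    quantify_on: str = "raw"
    output_dir: str = "gelspot_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.quantify_on not in QUANTIFY_MODES:
            raise ValidationError(
                f"quantify_on must be one of {QUANTIFY_MODES}, got {self.quantify_on!r}"
            )

    def validate_paths(self) -> None:
        if not Path(self.gel_dir).is_dir():
            raise ValidationError(f"gel_dir does not exist: {self.gel_dir}")
        if not (Path(self.gel_dir) / self.standard_image).is_file():
            raise ValidationError(
                f"standard_image {self.standard_image!r} not found in {self.gel_dir}"
            )
        if not Path(self.control_points_file).is_file():
            raise ValidationError(
                f"control_points_file does not exist: {self.control_points_file}"
            )

    def to_dict(self) -> dict:
        seg = self.segmentation
        return {
            "gel_dir": self.gel_dir,
            "standard_image": self.standard_image,
            "control_points_file": self.control_points_file,
            "crop": _rect_to_dict(self.crop),
            "segmentation": {
                "disk_radius": seg.disk_radius,
                "roi": _rect_to_dict(seg.roi),
                "h_suppress": seg.h_suppress,
                "foreground_threshold": seg.foreground_threshold,
                "min_area": seg.min_area,
                "max_area": seg.max_area,
                "polarity": seg.polarity,
                "connectivity": seg.connectivity,
            },
            "quantify_on": self.quantify_on,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        seg_d = dict(d.get("segmentation") or {})
        if "roi" in seg_d:
            seg_d["roi"] = _rect_from_dict(seg_d["roi"])
        crop = _rect_from_dict(d.get("crop"))
        if crop is None:
            raise ValidationError("Config requires a crop rectangle")
        return cls(
            gel_dir=d["gel_dir"],
            standard_image=d["standard_image"],
            control_points_file=d["control_points_file"],
            crop=crop,
            segmentation=SegmentationParams(**seg_d),
            quantify_on=d.get("quantify_on", "raw"),
            output_dir=d.get("output_dir", "gelspot_out"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValidationError(f"Config file {path} is not a YAML mapping")
        return cls.from_dict(d)

    def digest(self) -> str:
        """Short content hash of the config, logged for provenance."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
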