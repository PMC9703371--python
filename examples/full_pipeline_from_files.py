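"""The complete file-level workflow, as the CLI runs it.

Simulates a gel directory, writes a config, runs align-crop plus
segment-quantify, and prints the wide spots-by-gels intensity table.
Equivalent shell session:

    gelspot simulate -o gels --n-gels 3 --n-spots 6 --size 160 --seed 21
    gelspot init -o config.yaml   # then edit paths
    gelspot run -c config.yaml
"""

from pathlib import Path

import pandas as pd

from gelspot import CropRect, PipelineConfig, SegmentationParams, run_full
from gelspot.synthetic import default_ground_truth, write_simulation

base = Path("scratch_example_run")
gel_dir = base / "gels"
truth = default_ground_truth(n_gels=3, n_spots=6, size=(160, 160), seed=21)
write_simulation(truth, (160, 160), gel_dir)

config = PipelineConfig(
    gel_dir=str(gel_dir),
    standard_image="gel_00.tif",
    control_points_file=str(gel_dir / "control_points.tsv"),
    crop=CropRect(12, 12, 136, 136),
    segmentation=SegmentationParams(disk_radius=15),
    output_dir=str(base / "out"),
)
config.to_yaml(base / "config.yaml")
run_full(config)

wide = pd.read_csv(base / "out" / "quant_wide.csv", index_col=0)
print(f"planted spots: {len(truth.spots)}, quantified: {len(wide)}")
print(wide.round(4).to_string())
print("planted per-gel intensity scales:", truth.intensity_scales)
# Each row is one protein spot; columns are gels. Row-wise ratios track
# the planted per-gel scale factors once the shared background offset
# (~0.1 here) is subtracted.
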