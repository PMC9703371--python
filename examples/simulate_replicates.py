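"""Generate a synthetic 5-gel replicate set with known ground truth.

Renders Coomassie-style gels (dark Gaussian spots on a light gradient
background) under small per-gel similarity transforms and intensity
scale factors, and writes the images, the control-point TSV and the
planted parameters to disk.
"""

from pathlib import Path

from gelspot import default_ground_truth, write_simulation

out = Path("scratch_example_gels")
truth = default_ground_truth(n_gels=5, n_spots=12, size=(256, 256), seed=7)
write_simulation(truth, (256, 256), out)

print(f"wrote {truth.n_gels} gels to {out}/")
print(f"planted spots: {len(truth.spots)}")
print("per-gel intensity scales:", truth.intensity_scales)
for i, tf in enumerate(truth.transforms):
    print(
        f"  gel_{i:02d}: scale={tf.scale:.4f} rotation={tf.rotation:+.4f} rad "
        f"t=({tf.tx:+.2f}, {tf.ty:+.2f}) px"
    )
# The scales emulate different protein loads/staining; the transforms
# emulate scanner misplacement that the registration stage must undo.
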