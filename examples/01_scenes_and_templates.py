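"""Build the study's templates and scenes and look at their geometry."""
import numpy as np

from saim import make_template, reference_templates, reference_scenes

# the two stored objects, as the excitatory reference configuration draws them
templates = reference_templates("em")
for label, bitmap, weights in zip(templates.labels, templates.templates,
                                  templates.weights):
    print(f"{label}: {int(bitmap.sum())} active pixels, "
          f"weight scale {weights.max():.3f}")
    print("\n".join("".join("#" if v else "." for v in row) for row in bitmap))

# the three scenes: single cross, single two, and both objects side by side
scenes = reference_scenes(templates)
for name, scene in scenes.items():
    print(f"\nscene {name!r}: placements {scene.placements}, "
          f"expected winner {scene.expected_winner!r}, "
          f"ink {int(scene.image.sum())} px")

# a glyph is a deterministic construction rule: the thin cross has 2M-1 px
print("\nthin cross at M=5:\n", make_template("plus", 5).astype(int))
# The printed counts show the cross out-weighs the two (33 vs 25 px) in the
# excitatory setup, which is what biases competition toward the cross.
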