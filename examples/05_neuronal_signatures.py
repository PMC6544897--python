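"""Summed activation time courses: the two architectures' opposite signatures."""
import numpy as np

from saim import (neuronal_response, reference_params, reference_scenes,
                  reference_templates, run_model)

for model in ("em", "pe"):
    templates = reference_templates(model)
    scene = reference_scenes(templates)["plus_two"]
    params = reference_params(model)
    result = run_model(model, scene, templates, params, seed=3,
                       record_trajectories=True)
    series = neuronal_response(result, model, scene, templates, params)
    for net in ("sn", "kn"):
        s = series[net][: result.rt]
        print(f"{model} {net.upper()}: start {s[1]:9.2f}  "
              f"quarter {s[len(s) // 4]:9.2f}  end {s[-1]:9.2f}")
# The series sum each layer's output rates plus the magnitude of its
# between-network drive (leak and normalisation terms excluded) — a proxy for
# what an EEG/fMRI measurement would integrate.  Under this calibration the
# excitatory drives grow as the resonance forms, while the prediction-error
# variant opens with a large unmatched-prediction transient that then decays.
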