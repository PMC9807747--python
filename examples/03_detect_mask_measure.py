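"""Small end-to-end run: simulate, train both networks, detect, mask, measure.

This is a scaled-down version of the full pipeline (fewer scenes, shorter
training) so it finishes in a few minutes on a laptop CPU.  It prints the
detection tally against ground truth and the recovered axis distribution.
For the study-scale configuration see scripts/acceptance.py.
"""

import numpy as np

import toromorph as tm

config = {
    "simulate": {"n_scenes": 3, "n_particles": 15},
    "detector": {"n_pos": 30, "n_neg": 40, "epochs": 3, "holdout": 300},
    "masker": {"n_sources": 16, "per_image_samples": 100, "epochs": 6,
               "holdout": 400},
}

report = tm.run_pipeline(config, seed=11, verbose=True)

sim = report["stages"]["simulate"]
d = report["stages"]["detect"]
m = report["stages"]["measure"]
print(f"\nsimulated {sim['n_particles']} particles in {sim['n_scenes']} scenes")
print(f"detector holdout accuracy: {report['stages']['detector']['final_holdout_accuracy']:.3f}")
print(f"masker holdout accuracy:   {report['stages']['masker']['final_holdout_accuracy']:.3f}")
print(f"detected {d['n_detected']}, matched {d['n_matched']} "
      f"(recall {d['recall']:.2f}, {d['n_false_positive']} false positives)")
print(f"mean centre error: {d['mean_center_error_px']:.1f} px")
if m["n_measured"]:
    print(f"measured {m['n_measured']} particles: "
          f"major {m['major_mean_nm']:.0f} +/- {m['major_sd_nm']:.0f} nm, "
          f"minor {m['minor_mean_nm']:.0f} +/- {m['minor_sd_nm']:.0f} nm")
    print("(compare with the generator's defaults: major ~590 +/- 23 nm)")
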