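"""From factor images to labelled tissue masks and averaged curves.

Simulates the four-tissue phantom, fits the factor model, names each
component by the arrival order of its bolus dip (artery first), segments
each factor image with Otsu's threshold, and prints mask sizes and the
frame at which each tissue's averaged signal curve bottoms out.
"""

import numpy as np

import perfifa as pf

spec = pf.PhantomSpec(target_snr=240.0, seed=2)
result = pf.run_recovery_experiment(spec)

names = ("artery", "gray-matter", "white-matter", "other")
seg = pf.segment_factor_images(
    result.factor_images, result.model, result.series, names
)

print(f"{'tissue':<14} {'pixels':>7} {'dip frame':>10}")
for k, label in enumerate(seg.labels):
    dip = int(np.argmin(seg.averaged_curves[:, k]))
    print(f"{label:<14} {int(seg.masks[k].sum()):>7} {dip:>10}")
print()
print("True region sizes were 603 (artery), 1683 (GM), 1514 (WM), 924 (other).")
print("The artery is the component whose averaged curve dips earliest and")
print("deepest; later tissues dip progressively later and shallower.")
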