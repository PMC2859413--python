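"""rCBV / rCBF / MTT maps from a forward-modelled perfusion series.

Constructs a tiny series of 30 pixels from the indicator-dilution forward
model -- 10 arterial pixels carrying the input function, 10 gray-matter
pixels (flow 1.56, fast transit) and 10 white-matter pixels (flow 0.6,
slow transit), GM:WM flow ratio 2.6 -- converts concentration to MR signal,
then runs the map pipeline: signal -> concentration, first-pass detection,
area-ratio rCBV, truncated-SVD deconvolution for rCBF, and MTT = rCBV/rCBF.
"""

import numpy as np

import perfifa as pf

te, s0 = 0.06, 1000.0
t = np.arange(50, dtype=float)
ca = (t / 3.0) ** 2 * np.exp(-t / 3.0)                 # gamma-variate AIF
conv = pf.build_aif_convolution_matrix(ca, 1.0)
ct_gm = conv @ (2.6 * 0.6 * np.exp(-t / 4.0))          # fast, high flow
ct_wm = conv @ (0.6 * np.exp(-t / 5.07))               # slow, low flow

conc = np.column_stack([ca] * 10 + [ct_gm] * 10 + [ct_wm] * 10)
signal = s0 * np.exp(-te * conc)                       # susceptibility model
series = pf.DynamicSeries(signal, grid_shape=(1, 30), te=te)
arterial = np.zeros(30, dtype=bool)
arterial[:10] = True

maps = pf.parametric_maps(series, arterial, pf.MapConfig(baseline_frames=1))

gm, wm = slice(10, 20), slice(20, 30)
print(f"first-pass window (frames): {maps.first_pass}")
for name in ("rcbv", "rcbf", "mtt"):
    vals = getattr(maps, name)
    print(f"{name:>5}:  GM {np.median(vals[gm]):7.3f}   WM {np.median(vals[wm]):7.3f}"
          f"   GM/WM {np.median(vals[gm]) / np.median(vals[wm]):6.3f}")
print()
print("The GM/WM rCBF ratio recovers the constructed 2.6; the MTT ratio is")
print("below 1 because gray matter transits the bolus faster than white.")
print("rCBV and rCBF are relative (arbitrary units); MTT is in seconds.")
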