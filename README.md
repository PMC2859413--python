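# perfifa

Blind separation of dynamic susceptibility-contrast (DSC) perfusion MR
series into tissue factors, with hemodynamic parameter mapping.

After a gadolinium bolus, a T2\*-weighted dynamic scan shows transient
signal drops whose timing and depth differ by tissue: the bolus reaches
the artery first, then gray matter, white matter, veins and sinus, and
the choroid plexus.  Because of partial-volume mixing, each pixel's
time course is a linear blend of these pure-tissue patterns.  `perfifa`
models one slice as

```
y = H x + u,      u ~ N(0, Λ)   (Λ diagonal)
```

with `y` the T×P series (T frames, P pixels), the columns of `H` the
tissue signal-time curves, the rows of `x` the tissue factor images, and
mutually independent sources each following a mixture-of-Gaussians
density.  This independent-factor-analysis (IFA) model is fitted by exact
EM over the enumerated joint mixture states; factor images are recovered
by the least-mean-square (posterior-mean) estimator.  The package then

- names each factor by bolus **arrival order** (earliest, deepest dip =
  artery) and segments its pixels with **Otsu's threshold** into a
  composite tissue map with per-tissue averaged curves;
- converts signal to concentration (`C = -(k/TE)·ln(S/S0)`, k = 1) and
  computes **rCBV** (first-pass area ratio against the arterial input
  function), **rCBF** (peak of the residue curve from truncated-SVD
  deconvolution of `C_t = rCBF·C_a ⊗ R`) and **MTT = rCBV/rCBF** maps;
- provides a seeded **phantom**: disjoint tissue regions with exact pixel
  counts, a five-frame bolus mixing matrix, and Gaussian noise at a
  controlled SNR, for end-to-end recovery experiments.

Intended users: researchers working on perfusion post-processing who want
an operator-independent way to extract the arterial input function and
tissue compartments from a single dynamic slice, and a reproducible
simulation bench for separation quality.

## Worked example

```
python examples/phantom_recovery.py
```

simulates the default four-tissue phantom at SNR 240 and refits it
blindly.  Output from one run:

```
realized SNR:            240.0
EM iterations:           260 (converged: True)
image correlations:      1.000000 .. 1.000000
mixing correlations:     0.999999 .. 1.000000
max |J - I| entry:       0.0097
```

Each estimated factor image and signal-time curve is matched to its
ground-truth counterpart by maximal absolute Pearson correlation;
values of ~1 mean the blind separation recovered the true tissue images
and curves up to order and sign.  `J = (ĤᵀĤ)⁻¹ĤᵀH` is the cross-talk
matrix of the aligned mixing estimate — the identity when separation is
perfect.  At SNR 40 the mixing correlations stay above 0.9998 and the
image correlations above 0.989.

`examples/tissue_segmentation.py` shows arrival-order labelling and Otsu
segmentation on the phantom; `examples/perfusion_maps.py` builds a tiny
forward-modelled series (GM:WM flow ratio 2.6) and recovers the regional
rCBV/rCBF/MTT ratios from the maps.

There is also a thin CLI:

```
perfifa simulate --snr 240 --seed 1 --out sim/
perfifa all sim/observations.npy --te 0.06 --seed 1 --out run/
```

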