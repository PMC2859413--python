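"""Tissue identification and segmentation from fitted factors.

Tissue labelling uses the physiology of bolus transit: the contrast agent
reaches the artery first, then gray matter, white matter, venous
structures, and the choroid plexus.  Components are therefore ordered by
the arrival time of their signal dip.  Pixels belonging to each tissue are
extracted from the corresponding factor image by Otsu's threshold, and a
composite label map plus per-tissue averaged signal-time curves summarise
the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .ifa import FactorImages, IFAModel
from .series import DynamicSeries

#: Arrival-ordered tissue names for a five-factor decomposition.
DEFAULT_TISSUE_NAMES = (
    "artery",
    "gray-matter",
    "white-matter",
    "vein-sinus",
    "choroid-plexus",
)


@dataclass
class TissueSegmentation:
    """Per-tissue masks, composite label map and averaged curves.

    ``composite`` assigns each pixel the 1-based index of the component it
    belongs to (0 = background); ``labels[k]`` is the tissue name of
    component ``k``; ``averaged_curves[:, k]`` is the mean observed signal
    within that component's mask.
    """

    masks: np.ndarray                   # (N, P) bool
    labels: list[str]
    composite: np.ndarray               # (P,) int, 0 = background
    averaged_curves: np.ndarray         # (T, N)
    grid_shape: tuple[int, int]

    def mask_image(self, k: int) -> np.ndarray:
        return self.masks[k].reshape(self.grid_shape)

    def composite_image(self) -> np.ndarray:
        return self.composite.reshape(self.grid_shape)

    def mask_for(self, label: str) -> np.ndarray:
        """Binary P-vector of the tissue with the given name."""
        return self.masks[self.labels.index(label)]


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram cut maximising between-class variance.

    Deterministic for a given input and bin count; raises on (near-)
    constant input, for which no two-class split exists.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    return float(threshold_otsu(values, nbins=n_bins))


def normalize_curve(column: np.ndarray) -> np.ndarray:
    """Scale a signal-time curve so its baseline (first frame) equals 1.

    Mixing columns are defined up to scale and sign; dividing by the
    first-frame value puts every curve on the common display convention of
    a unit pre-bolus baseline with the bolus dip going below 1.
    """
    column = np.asarray(column, dtype=float)
    base = column[0]
    if base == 0:
        base = np.max(np.abs(column))
        if base == 0:
            raise ValueError("cannot normalize an all-zero curve")
    return column / base


def arrival_order(mixing: np.ndarray) -> np.ndarray:
    """Order components by bolus arrival.

    Each baseline-normalised mixing column is ranked by the frame index of
    its minimum (earlier dip = earlier arrival); components dipping at the
    same frame are ranked deeper-dip first.  Returns component indices from
    earliest (artery) to latest.
    """
    n = mixing.shape[1]
    keys = []
    for j in range(n):
        curve = normalize_curve(mixing[:, j])
        t_min = int(np.argmin(curve))
        depth = float(curve[t_min])
        keys.append((t_min, depth, j))
    keys.sort()                                  # earlier frame, then deeper minimum
    return np.array([k[2] for k in keys], dtype=int)


def identify_tissues(
    model: IFAModel,
    tissue_names: tuple[str, ...] | list[str] = DEFAULT_TISSUE_NAMES,
) -> list[str]:
    """Name each component by the arrival order of its signal-time curve.

    The component whose curve dips earliest (and, on ties, deepest) is the
    artery; later components take the subsequent names.  Returns the tissue
    name of each component, indexed like the model's mixing columns.
    """
    n = model.n_sources
    if len(tissue_names) < n:
        raise ValueError(
            f"{n} components but only {len(tissue_names)} tissue names configured"
        )
    order = arrival_order(model.mixing)
    labels = [""] * n
    for rank, j in enumerate(order):
        labels[j] = tissue_names[rank]
    return labels


def segment_factor_images(
    fimgs: FactorImages,
    model: IFAModel,
    series: DynamicSeries,
    tissue_names: tuple[str, ...] | list[str] = DEFAULT_TISSUE_NAMES,
    n_bins: int = 256,
) -> TissueSegmentation:
    """Threshold each factor image and assemble the composite tissue map.

    Each factor image is binarised at its Otsu threshold (after flipping
    components whose foreground came out negative, a residual sign
    ambiguity of the separation).  Pixels above threshold in several
    components go to the one with the highest factor value.  Averaged
    signal-time curves are means of the *observed* series over each final
    mask.
    """
    labels = identify_tissues(model, tissue_names)
    n, p = fimgs.images.shape
    oriented = np.empty_like(fimgs.images)
    for k in range(n):
        img = fimgs.images[k]
        med = np.median(img)
        # foreground is the long positive tail; flip if it points down
        oriented[k] = img if (img.max() - med) >= (med - img.min()) else -img

    raw_masks = np.zeros((n, p), dtype=bool)
    for k in range(n):
        try:
            thr = otsu_threshold(oriented[k], n_bins=n_bins)
        except ValueError:
            warnings.warn(f"component {k} ({labels[k]}) is constant; empty mask", RuntimeWarning)
            continue
        raw_masks[k] = oriented[k] > thr

    # overlap resolution: the highest (oriented) factor value wins
    strength = np.where(raw_masks, oriented, -np.inf)
    winner = np.argmax(strength, axis=0)
    any_fg = raw_masks.any(axis=0)
    composite = np.where(any_fg, winner + 1, 0)
    masks = np.zeros_like(raw_masks)
    for k in range(n):
        masks[k] = composite == k + 1
        if raw_masks[k].any() and not masks[k].any():
            warnings.warn(
                f"component {k} ({labels[k]}) lost all pixels to overlaps", RuntimeWarning
            )

    t = series.n_frames
    curves = np.zeros((t, n))
    for k in range(n):
        if masks[k].any():
            curves[:, k] = series.data[:, masks[k]].mean(axis=1)
        else:
            warnings.warn(f"tissue {labels[k]} has an empty mask", RuntimeWarning)
    return TissueSegmentation(
        masks=masks,
        labels=labels,
        composite=composite,
        averaged_curves=curves,
        grid_shape=fimgs.grid_shape,
    )
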