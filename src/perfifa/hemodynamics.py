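"""Perfusion quantification: rCBV, rCBF and MTT from concentration curves.

Signal is converted to contrast-agent concentration through the
susceptibility relation  C(t) = -(k/TE) ln(S(t)/S0)  with the unknown
proportionality constant k set to 1 (only relative quantities are
reported).  With a concentration-time curve per pixel, Ct, and the arterial
input function, Ca, indicator-dilution theory gives

    rCBV = int_first-pass Ct dt / int_first-pass Ca dt,
    Ct(t) = rCBF * (Ca (x) R)(t)        (deconvolved by truncated SVD),
    MTT  = rCBV / rCBF,

where R is the pixel's residue function and (x) denotes convolution.  The
rCBF of a pixel is the peak of the deconvolved rCBF*R(t) curve.

Discretisation: the convolution is the lower-triangular Toeplitz operator
A[i, j] = dt * Ca[i - j], i.e. the left-endpoint rectangle rule.  Integrals
default to the same rectangle rule so that rCBV, rCBF and MTT are mutually
consistent (an impulse-input boxcar-residue pixel then has MTT exactly
equal to the boxcar width); the trapezoidal rule is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .series import DynamicSeries

#: Default fraction of the largest singular value below which the
#: deconvolution truncates (the convention of SVD bolus-tracking work).
DEFAULT_SVD_THRESHOLD = 0.2
DEFAULT_BASELINE_FRAMES = 5


@dataclass
class ConcentrationCurves:
    """Per-pixel and arterial concentration-time curves."""

    ct: np.ndarray                          # (T, P)
    ca: np.ndarray                          # (T,)
    valid: np.ndarray                       # (P,) bool, False where S or S0 <= 0
    baseline_frames: int
    first_pass: tuple[int, int]             # inclusive frame window
    frame_times: np.ndarray


@dataclass
class HemodynamicMaps:
    """Pixelwise perfusion parameters on the image grid.

    ``valid`` marks pixels where all three quantities are defined; invalid
    pixels hold 0, never NaN.  MTT is in seconds; rCBV and rCBF are in
    arbitrary (relative) units.
    """

    rcbv: np.ndarray                        # (P,)
    rcbf: np.ndarray                        # (P,)
    mtt: np.ndarray                         # (P,)
    valid: np.ndarray                       # (P,) bool
    aif: np.ndarray                         # (T,)
    first_pass: tuple[int, int]
    grid_shape: tuple[int, int]
    svd_threshold_fraction: float = DEFAULT_SVD_THRESHOLD

    def map_image(self, name: str) -> np.ndarray:
        return getattr(self, name).reshape(self.grid_shape)


def _integrate(values: np.ndarray, dt: float, rule: str, axis: int = 0) -> np.ndarray:
    if rule == "sum":
        return values.sum(axis=axis) * dt
    if rule == "trapezoid":
        return np.trapezoid(values, dx=dt, axis=axis)
    raise ValueError(f"unknown integration rule {rule!r}")


def concentration_from_signal(
    signal: np.ndarray,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
    te: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert signal-time curves to concentration-time curves.

    ``signal`` is (T,) or (T, P).  The baseline S0 is the mean of the first
    ``baseline_frames`` frames.  Returns ``(ct, valid)`` where ``valid``
    flags curves whose signal stays positive (the log is undefined
    otherwise); invalid curves are zero-filled.
    """
    signal = np.asarray(signal, dtype=float)
    squeeze = signal.ndim == 1
    sig = signal[:, None] if squeeze else signal
    t = sig.shape[0]
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    if baseline_frames >= t:
        raise ValueError("baseline_frames must be smaller than the number of frames")
    if te <= 0:
        raise ValueError("te must be positive")
    s0 = sig[:baseline_frames].mean(axis=0)
    valid = (s0 > 0) & np.all(sig > 0, axis=0)
    ct = np.zeros_like(sig)
    if valid.any():
        ct[:, valid] = -(1.0 / te) * np.log(sig[:, valid] / s0[valid])
    if squeeze:
        return ct[:, 0], valid[0]
    return ct, valid


def detect_first_pass(
    ca: np.ndarray,
    arrival_fraction: float = 0.1,
    recirculation_fraction: float = 0.5,
) -> tuple[int, int]:
    """Locate the first-pass window on the arterial concentration curve.

    Start: first frame where Ca reaches ``arrival_fraction`` of its peak.
    End: after the peak, the curve falls below ``recirculation_fraction`` of
    the peak; the window closes on the last frame before it rises above
    that level again (recirculation).  If it never re-rises the window runs
    to the final frame.
    """
    ca = np.asarray(ca, dtype=float)
    peak = float(ca.max())
    if peak <= 0:
        raise ValueError("arterial curve has no positive peak")
    i_peak = int(np.argmax(ca))
    above = np.flatnonzero(ca >= arrival_fraction * peak)
    start = int(above[0])
    end = ca.size - 1
    fell = False
    for i in range(i_peak + 1, ca.size):
        if ca[i] < recirculation_fraction * peak:
            fell = True
        elif fell:
            end = i - 1
            break
    return start, end


def compute_rcbv(
    ct: np.ndarray,
    ca: np.ndarray,
    first_pass: tuple[int, int],
    dt: float,
    rule: str = "sum",
) -> tuple[np.ndarray, np.ndarray]:
    """Relative cerebral blood volume: first-pass area ratio of Ct to Ca.

    ``ct`` is (T,) or (T, P).  Returns ``(rcbv, valid)``; a pixel is invalid
    if the arterial first-pass area is not positive (then all pixels are
    invalid) -- negative tissue areas from noise are kept as-is.
    """
    ct = np.asarray(ct, dtype=float)
    ca = np.asarray(ca, dtype=float)
    lo, hi = first_pass
    if not (0 <= lo <= hi < ca.size):
        raise ValueError(f"first-pass window {first_pass} outside [0, {ca.size})")
    sl = slice(lo, hi + 1)
    area_a = float(_integrate(ca[sl], dt, rule))
    squeeze = ct.ndim == 1
    ctm = ct[:, None] if squeeze else ct
    area_t = _integrate(ctm[sl], dt, rule, axis=0)
    if area_a <= 0:
        rcbv = np.zeros(ctm.shape[1])
        valid = np.zeros(ctm.shape[1], dtype=bool)
    else:
        rcbv = area_t / area_a
        valid = np.ones(ctm.shape[1], dtype=bool)
    if squeeze:
        return rcbv[0], valid[0]
    return rcbv, valid


def build_aif_convolution_matrix(ca: np.ndarray, dt: float) -> np.ndarray:
    """Lower-triangular Toeplitz discretisation of convolution with Ca.

    ``A[i, j] = dt * ca[i - j]`` for ``j <= i``, so ``A @ (rcbf * R)``
    approximates ``rcbf * (Ca (x) R)`` sampled at the frame times.
    """
    ca = np.asarray(ca, dtype=float)
    if ca.ndim != 1:
        raise ValueError("ca must be a 1-D curve")
    return toeplitz(dt * ca, np.zeros_like(ca))


def svd_deconvolve(
    ct: np.ndarray,
    aif_matrix: np.ndarray,
    threshold_fraction: float = DEFAULT_SVD_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover the flow-scaled residue curve(s) by truncated-SVD inversion.

    Singular values below ``threshold_fraction`` times the largest are
    zeroed in the pseudo-inverse, suppressing the noise amplification of
    the ill-conditioned convolution operator.  ``ct`` is (T,) or (T, P).

    Returns
    -------
    residue : ndarray
        The recovered ``rcbf * R(t)`` curve(s), same shape as ``ct``.
    rcbf : float or ndarray
        Peak of each recovered curve.
    valid : bool or ndarray
        False where the system was entirely truncated away.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    ct = np.asarray(ct, dtype=float)
    u, s, vt = np.linalg.svd(np.asarray(aif_matrix, float))
    keep = s >= threshold_fraction * s[0]
    if not keep.any():
        squeeze = ct.ndim == 1
        shape = ct.shape
        zeros = np.zeros(shape)
        return zeros, (0.0 if squeeze else np.zeros(shape[1])), (
            False if squeeze else np.zeros(shape[1], dtype=bool)
        )
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    pinv = (vt.T * s_inv) @ u.T
    residue = pinv @ ct
    rcbf = residue.max(axis=0)
    if ct.ndim == 1:
        return residue, float(rcbf), True
    return residue, rcbf, np.ones(ct.shape[1], dtype=bool)


def compute_mtt(rcbv: np.ndarray, rcbf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean transit time MTT = rCBV / rCBF (seconds), defined where rCBF > 0."""
    rcbv = np.asarray(rcbv, dtype=float)
    rcbf = np.asarray(rcbf, dtype=float)
    valid = rcbf > 0
    mtt = np.zeros_like(rcbv)
    mtt[valid] = rcbv[valid] / rcbf[valid]
    if mtt.ndim == 0:
        return float(mtt), bool(valid)
    return mtt, valid


@dataclass
class MapConfig:
    """Knobs of the hemodynamic-map pipeline."""

    baseline_frames: int = DEFAULT_BASELINE_FRAMES
    svd_threshold_fraction: float = DEFAULT_SVD_THRESHOLD
    first_pass: tuple[int, int] | None = None       # None = detect on the AIF
    integration_rule: str = "sum"
    clip_negative_concentration: bool = False


def parametric_maps(
    series: DynamicSeries,
    arterial_mask: np.ndarray,
    config: MapConfig | None = None,
) -> HemodynamicMaps:
    """Compute rCBV, rCBF and MTT maps from a series and an arterial mask.

    The AIF is the concentration of the mask-averaged arterial signal.
    Pixels whose signal is non-positive anywhere (no valid concentration)
    or whose deconvolved peak is not positive are flagged invalid.
    """
    cfg = config or MapConfig()
    arterial_mask = np.asarray(arterial_mask, dtype=bool).ravel()
    if arterial_mask.size != series.n_pixels:
        raise ValueError("arterial mask size does not match the series")
    if not arterial_mask.any():
        raise ValueError("arterial mask is empty")
    if series.te is None:
        raise ValueError("series.te (echo time) is required for concentration maps")

    dt = series.frame_interval
    arterial_signal = series.data[:, arterial_mask].mean(axis=1)
    ca, ca_valid = concentration_from_signal(arterial_signal, cfg.baseline_frames, series.te)
    if not ca_valid:
        raise ValueError("arterial signal is non-positive; cannot form the AIF")
    ct, valid = concentration_from_signal(series.data, cfg.baseline_frames, series.te)
    if cfg.clip_negative_concentration:
        ct = np.clip(ct, 0.0, None)
        ca = np.clip(ca, 0.0, None)

    if cfg.first_pass is not None:
        first_pass = (int(cfg.first_pass[0]), int(cfg.first_pass[1]))
    else:
        first_pass = detect_first_pass(ca)

    rcbv, v_cbv = compute_rcbv(ct, ca, first_pass, dt, cfg.integration_rule)
    a = build_aif_convolution_matrix(ca, dt)
    _, rcbf, v_cbf = svd_deconvolve(ct, a, cfg.svd_threshold_fraction)
    mtt, v_mtt = compute_mtt(rcbv, rcbf)

    ok = valid & v_cbv & v_cbf & v_mtt
    rcbv = np.where(ok, rcbv, 0.0)
    rcbf = np.where(ok, rcbf, 0.0)
    mtt = np.where(ok, mtt, 0.0)
    return HemodynamicMaps(
        rcbv=rcbv,
        rcbf=rcbf,
        mtt=mtt,
        valid=ok,
        aif=ca,
        first_pass=first_pass,
        grid_shape=series.grid_shape,
        svd_threshold_fraction=cfg.svd_threshold_fraction,
    )
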