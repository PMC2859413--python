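"""Independent factor analysis (IFA) by exact EM.

The generative model for each pixel's time course ``y`` (a T-vector) is

    y = H x + u,        u ~ N(0, Lambda),   Lambda diagonal,

where the N hidden sources ``x_j`` are mutually independent, each with a
1-D mixture-of-Gaussians density.  Columns of the mixing matrix ``H`` are
the signal-time curves of the underlying tissue factors; rows of ``x`` are
their spatial images.  The P pixels of the slice are treated as i.i.d.
realisations of the model, so all expectations in the EM updates are
empirical means over pixels.

Exact EM enumerates every joint MoG state ``q = (q_1, ..., q_N)``.  Given a
state, the model is a linear-Gaussian factor model, so both the state
responsibilities and the conditional source moments are available in closed
form:

* responsibility  p(q|y) ~ w_q N(y; H mu_q, H V_q H^T + Lambda)
* posterior       p(x|q, y) = N(m_q, S_q) with
      S_q = (H^T Lambda^-1 H + V_q^-1)^-1,
      m_q = S_q (H^T Lambda^-1 y + V_q^-1 mu_q).

The cost tracked across iterations is the negative mean log-likelihood per
pixel, which the EM updates never increase.  After each M-step the scale
indeterminacy between H columns and source amplitudes is removed by
normalising every source's marginal MoG variance to one, a reparametrisation
that leaves the data likelihood unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .mog import DEFAULT_STATE_CAP, MoGSourceParams, QStateTable, build_q_states
from .series import DynamicSeries

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-9


@dataclass
class IFAModel:
    """Fitted IFA parameters.

    Attributes
    ----------
    mixing:
        T x N matrix; column ``j`` is the signal-time curve of factor ``j``.
    noise_diag:
        Length-T diagonal of the sensor-noise covariance ``Lambda``.
    mog:
        Per-source mixture-of-Gaussians parameters.
    loss_trace:
        Negative mean log-likelihood per pixel at the start of each EM
        iteration (plus a final value for the returned parameters).
    converged:
        Whether the relative loss change dropped below tolerance before
        ``max_iter``.
    seed:
        Seed of the restart that produced this model.
    """

    mixing: np.ndarray
    noise_diag: np.ndarray
    mog: MoGSourceParams
    loss_trace: list[float] = field(default_factory=list)
    converged: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.noise_diag = np.asarray(self.noise_diag, dtype=float)
        if self.mixing.ndim != 2:
            raise ValueError("mixing must be T x N")
        if self.noise_diag.shape != (self.mixing.shape[0],):
            raise ValueError("noise_diag must have one entry per frame")
        if np.any(self.noise_diag <= 0):
            raise ValueError("noise covariance diagonal must be positive")
        if self.mog.n_sources != self.mixing.shape[1]:
            raise ValueError("mog and mixing disagree on the number of sources")

    @property
    def n_frames(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_sources(self) -> int:
        return self.mixing.shape[1]

    def noise_cov(self) -> np.ndarray:
        """The full (diagonal) T x T noise covariance matrix."""
        return np.diag(self.noise_diag)

    def copy(self) -> "IFAModel":
        return IFAModel(
            mixing=self.mixing.copy(),
            noise_diag=self.noise_diag.copy(),
            mog=self.mog.copy(),
            loss_trace=list(self.loss_trace),
            converged=self.converged,
            seed=self.seed,
        )


@dataclass
class FactorImages:
    """Reconstructed source images, one row per factor."""

    images: np.ndarray                      # (N, P)
    grid_shape: tuple[int, int]
    component_order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 2:
            raise ValueError("images must be N x P")
        rows, cols = self.grid_shape
        if rows * cols != self.images.shape[1]:
            raise ValueError("grid_shape incompatible with image length")
        if np.any(~np.isfinite(self.images)):
            raise ValueError("factor images contain NaN/Inf")

    @property
    def n_components(self) -> int:
        return self.images.shape[0]

    def image(self, j: int) -> np.ndarray:
        return self.images[j].reshape(self.grid_shape)


# ---------------------------------------------------------------------------
# E-step machinery
# ---------------------------------------------------------------------------

@dataclass
class EStepStats:
    """Sufficient statistics of one E-step (pixel means where noted)."""

    nll: float                      # negative mean log-likelihood per pixel
    post_mean: np.ndarray           # (N, P)  E[x | y] per pixel
    rxx: np.ndarray                 # (N, N)  mean_p E[x x^T | y]
    ryx: np.ndarray                 # (T, N)  mean_p y E[x^T | y]
    syy_diag: np.ndarray            # (T,)    mean_p y_t^2
    # MoG sufficient statistics, indexed [source][component]:
    gamma: list[np.ndarray]         # mean_p p(q_j | y)
    s1: list[np.ndarray]            # mean_p p(q_j | y) E[x_j | q_j, y]
    s2: list[np.ndarray]            # mean_p p(q_j | y) E[x_j^2 | q_j, y]
    # Per-pixel state detail, populated when keep_states=True:
    log_resp: np.ndarray | None = None      # (Q, P) log p(q | y)
    state_means: np.ndarray | None = None   # (Q, N, P) posterior means m_q
    state_covs: np.ndarray | None = None    # (Q, N, N) posterior covariances S_q
    q_table: QStateTable | None = None


def _estep(
    y: np.ndarray,
    mixing: np.ndarray,
    noise_diag: np.ndarray,
    qt: QStateTable,
    keep_states: bool = False,
) -> EStepStats:
    """One exact E-step over all pixels, vectorised per joint state."""
    t, p = y.shape
    n = mixing.shape[1]
    q = qt.n_states

    lam_inv = 1.0 / noise_diag
    b = mixing.T * lam_inv                    # (N, T) = H^T Lambda^-1
    bh = b @ mixing                           # (N, N) = H^T Lambda^-1 H
    g = b @ y                                 # (N, P)

    log_r = np.empty((q, p))
    state_means = np.empty((q, n, p))
    state_covs = np.empty((q, n, n))

    log_w = np.log(np.maximum(qt.weights, 1e-300))
    for s in range(q):
        v = qt.variances[s]
        mu = qt.means[s]
        # marginal covariance of y under state s
        cy = (mixing * v) @ mixing.T
        cy[np.diag_indices(t)] += noise_diag
        try:
            cf = cho_factor(cy, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular marginal covariance for joint state {tuple(qt.states[s])}"
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        z = y - (mixing @ mu)[:, None]
        maha = np.sum(z * cho_solve(cf, z), axis=0)
        log_r[s] = log_w[s] - 0.5 * (t * _LOG_2PI + logdet + maha)
        # posterior over x given state s
        prec = bh + np.diag(1.0 / v)
        cov = np.linalg.inv(prec)
        state_covs[s] = cov
        state_means[s] = cov @ (g + (mu / v)[:, None])

    log_py = logsumexp(log_r, axis=0)         # (P,)
    if np.any(~np.isfinite(log_py)):
        raise ValueError("non-finite likelihood; check input for NaN")
    resp = np.exp(log_r - log_py)             # (Q, P)

    post_mean = np.einsum("qp,qnp->np", resp, state_means)
    rbar = resp.mean(axis=1)                  # (Q,)
    rxx = np.einsum("q,qnm->nm", rbar, state_covs)
    rxx += np.einsum("qnp,qp,qmp->nm", state_means, resp, state_means) / p
    ryx = (y @ post_mean.T) / p
    syy_diag = np.mean(y * y, axis=1)

    gamma: list[np.ndarray] = []
    s1: list[np.ndarray] = []
    s2: list[np.ndarray] = []
    for j in range(n):
        n_j = int(qt.states[:, j].max()) + 1
        gj = np.zeros(n_j)
        s1j = np.zeros(n_j)
        s2j = np.zeros(n_j)
        for s in range(q):
            a = qt.states[s, j]
            rs = resp[s]
            m = state_means[s, j]
            gj[a] += rbar[s]
            s1j[a] += np.mean(rs * m)
            s2j[a] += np.mean(rs * (state_covs[s, j, j] + m * m))
        gamma.append(gj)
        s1.append(s1j)
        s2.append(s2j)

    return EStepStats(
        nll=float(-np.mean(log_py)),
        post_mean=post_mean,
        rxx=rxx,
        ryx=ryx,
        syy_diag=syy_diag,
        gamma=gamma,
        s1=s1,
        s2=s2,
        log_resp=(log_r - log_py) if keep_states else None,
        state_means=state_means if keep_states else None,
        state_covs=state_covs if keep_states else None,
        q_table=qt if keep_states else None,
    )


def negative_log_likelihood(
    series: DynamicSeries | np.ndarray,
    model: IFAModel,
    state_cap: int = DEFAULT_STATE_CAP,
) -> float:
    """Negative mean log-likelihood per pixel of the data under the model.

    This is the model-dependent part of the Kullback-Leibler fit criterion
    that EM minimises; the (constant) data entropy is dropped.
    """
    y = series.data if isinstance(series, DynamicSeries) else np.asarray(series, float)
    _check_dims(y, model)
    qt = build_q_states(model.mog, state_cap)
    return _estep(y, model.mixing, model.noise_diag, qt).nll


@dataclass
class PosteriorMoments:
    """Per-pixel posterior moments returned by :func:`e_step`."""

    post_mean: np.ndarray               # (N, P)  E[x | y]
    post_second: np.ndarray             # (N, N, P)  E[x x^T | y]
    comp_resp: list[np.ndarray]         # per source: (n_j, P)  p(q_j | y)
    comp_mean: list[np.ndarray]         # per source: (n_j, P)  E[x_j | q_j, y]
    comp_second: list[np.ndarray]       # per source: (n_j, P)  E[x_j^2 | q_j, y]
    state_resp: np.ndarray              # (Q, P)  p(q | y)
    nll: float


def e_step(
    series: DynamicSeries | np.ndarray,
    model: IFAModel,
    state_cap: int = DEFAULT_STATE_CAP,
) -> PosteriorMoments:
    """Exact posterior moments of the hidden sources for every pixel.

    Intended for inspection and testing; :func:`fit_ifa` uses an internal
    streaming variant that accumulates only the sufficient statistics.
    """
    y = series.data if isinstance(series, DynamicSeries) else np.asarray(series, float)
    _check_dims(y, model)
    qt = build_q_states(model.mog, state_cap)
    st = _estep(y, model.mixing, model.noise_diag, qt, keep_states=True)
    resp = np.exp(st.log_resp)
    n, p = st.post_mean.shape

    post_second = np.einsum("qp,qnm->nmp", resp, st.state_covs)
    post_second += np.einsum("qnp,qp,qmp->nmp", st.state_means, resp, st.state_means)

    comp_resp: list[np.ndarray] = []
    comp_mean: list[np.ndarray] = []
    comp_second: list[np.ndarray] = []
    for j in range(n):
        n_j = int(qt.states[:, j].max()) + 1
        rj = np.zeros((n_j, p))
        mj = np.zeros((n_j, p))
        vj = np.zeros((n_j, p))
        for s in range(qt.n_states):
            a = qt.states[s, j]
            rj[a] += resp[s]
            mj[a] += resp[s] * st.state_means[s, j]
            vj[a] += resp[s] * (st.state_covs[s, j, j] + st.state_means[s, j] ** 2)
        nz = rj > 1e-300
        mj[nz] /= rj[nz]
        vj[nz] /= rj[nz]
        comp_resp.append(rj)
        comp_mean.append(mj)
        comp_second.append(vj)

    return PosteriorMoments(
        post_mean=st.post_mean,
        post_second=post_second,
        comp_resp=comp_resp,
        comp_mean=comp_mean,
        comp_second=comp_second,
        state_resp=resp,
        nll=st.nll,
    )


# ---------------------------------------------------------------------------
# M-step, rescaling
# ---------------------------------------------------------------------------

def m_step(stats: EStepStats, n_components: list[int]) -> tuple[np.ndarray, np.ndarray, MoGSourceParams]:
    """Closed-form parameter updates from E-step sufficient statistics.

    Returns the updated mixing matrix, noise-covariance diagonal and MoG
    parameters.  A near-singular second-moment matrix is ridge-regularised;
    variance updates are floored to keep the model proper.
    """
    rxx = stats.rxx
    cond = np.linalg.cond(rxx)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("ill-conditioned E[xx^T]; applying ridge", RuntimeWarning)
        rxx = rxx + 1e-9 * np.trace(rxx) * np.eye(rxx.shape[0])
    mixing = np.linalg.solve(rxx.T, stats.ryx.T).T          # Ryx Rxx^-1
    noise_diag = stats.syy_diag - np.einsum("tn,tn->t", stats.ryx, mixing)
    noise_diag = np.maximum(noise_diag, _VAR_FLOOR)

    weights: list[np.ndarray] = []
    means: list[np.ndarray] = []
    variances: list[np.ndarray] = []
    for j, n_j in enumerate(n_components):
        gj = np.maximum(stats.gamma[j], 1e-300)
        mu = stats.s1[j] / gj
        nu = stats.s2[j] / gj - mu**2
        nu = np.maximum(nu, _VAR_FLOOR)
        w = stats.gamma[j] / stats.gamma[j].sum()
        weights.append(w)
        means.append(mu)
        variances.append(nu)
    return mixing, noise_diag, MoGSourceParams(weights, means, variances)


def rescale(model: IFAModel) -> IFAModel:
    """Remove the source-scale indeterminacy.

    Each source's marginal MoG standard deviation ``sigma_j`` is absorbed
    into the corresponding mixing column: means and variances are divided by
    ``sigma_j`` (``sigma_j^2``), the column multiplied by ``sigma_j``.  The
    distribution of the data is unchanged.
    """
    out = model.copy()
    for j in range(out.n_sources):
        var = out.mog.marginal_variance(j)
        if var <= 0:
            raise ValueError(f"degenerate source {j}: marginal variance {var} <= 0")
        sigma = np.sqrt(var)
        out.mog.means[j] /= sigma
        out.mog.variances[j] /= var
        out.mixing[:, j] *= sigma
    return out


def orient_bolus_signs(model: IFAModel) -> IFAModel:
    """Resolve the sign ambiguity using perfusion physics.

    During bolus passage the susceptibility effect *lowers* the signal, so
    every mixing column should dip below its first-frame value.  Each
    component whose largest excursion from the first frame is upward is
    flipped (column and source means negated), which leaves the likelihood
    unchanged.
    """
    out = model.copy()
    for j in range(out.n_sources):
        col = out.mixing[:, j]
        up = col.max() - col[0]
        down = col[0] - col.min()
        if up > down:
            out.mixing[:, j] = -col
            out.mog.means[j] = -out.mog.means[j]
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_dims(y: np.ndarray, model: IFAModel) -> None:
    if y.ndim != 2 or y.shape[0] != model.n_frames:
        raise ValueError(
            f"data with {y.shape[0] if y.ndim == 2 else '?'} frames does not match "
            f"model with {model.n_frames} frames"
        )


def _init_model(
    y: np.ndarray,
    n_sources: int,
    n_gauss: int,
    rng: np.random.Generator,
    seed: int,
    method: str = "kmeans",
) -> IFAModel:
    """Seeded data-driven starting point for EM.

    ``"kmeans"`` clusters the pixel time courses into N+1 groups (one for
    background) and uses the non-background centroid curves as initial
    mixing columns -- on bolus data the pixel cloud is strongly clustered
    by tissue, so this starts EM near the separating basin.  ``"pca"``
    uses the first N principal directions scaled by their singular values.
    Both add seeded jitter so restarts explore different basins, and both
    derive the initial MoG and noise parameters from the implied source
    estimates.
    """
    if method == "kmeans":
        try:
            return _init_kmeans(y, n_sources, n_gauss, rng, seed)
        except Exception:  # degenerate clustering: fall back to PCA
            logger.info("k-means initialization failed; falling back to PCA")
    return _init_pca(y, n_sources, n_gauss, rng, seed)


def _mog_from_sources(x0: np.ndarray, n_gauss: int, rng: np.random.Generator) -> MoGSourceParams:
    """Initial per-source MoGs from rough source estimates (midpoint split)."""
    n = x0.shape[0]
    weights, means, variances = [], [], []
    for j in range(n):
        xs = x0[j]
        lo, hi = float(xs.min()), float(xs.max())
        if hi <= lo:
            mog = MoGSourceParams.default_init(1, n_gauss)
            weights.append(mog.weights[0])
            means.append(mog.means[0] + 0.01 * rng.standard_normal(n_gauss))
            variances.append(mog.variances[0])
            continue
        if n_gauss == 1:
            weights.append(np.array([1.0]))
            means.append(np.array([float(xs.mean())]))
            variances.append(np.array([max(float(xs.var()), 1e-6)]))
            continue
        thr = 0.5 * (lo + hi)
        high = xs > thr
        f = float(np.clip(high.mean(), 0.02, 0.98))
        m_lo = float(xs[~high].mean()) if (~high).any() else lo
        m_hi = float(xs[high].mean()) if high.any() else hi
        v_lo = max(float(xs[~high].var()), 1e-4) if (~high).any() else 1.0
        v_hi = max(float(xs[high].var()), 1e-4) if high.any() else 1.0
        # two anchor components; extra ones interpolate between the modes
        w = np.full(n_gauss, f / max(n_gauss - 1, 1))
        w[0] = 1.0 - f
        w /= w.sum()
        mu = np.linspace(m_lo, m_hi, n_gauss)
        nu = np.linspace(v_lo, v_hi, n_gauss)
        weights.append(w)
        means.append(mu)
        variances.append(np.maximum(nu, 1e-6))
    return MoGSourceParams(weights, means, variances)


def _init_kmeans(
    y: np.ndarray,
    n_sources: int,
    n_gauss: int,
    rng: np.random.Generator,
    seed: int,
) -> IFAModel:
    from scipy.cluster.vq import kmeans2
    from skimage.filters import threshold_otsu

    t, p = y.shape
    if p < 2 * (n_sources + 1):
        raise ValueError("too few pixels to cluster")
    # split off low-energy background pixels so they cannot absorb centroids
    energy = np.sum(y * y, axis=0)
    try:
        fg = energy > threshold_otsu(energy, nbins=256)
    except ValueError:
        fg = np.ones(p, dtype=bool)
    if fg.sum() < n_sources:
        fg = np.ones(p, dtype=bool)
    else:
        # drop straggler pixels barely above the cut so they cannot grab a
        # centroid of their own (tissue energies sit far above this level)
        refined = fg & (energy >= 0.1 * np.median(energy[fg]))
        if refined.sum() >= n_sources:
            fg = refined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-cluster warnings handled below
        centroids, _ = kmeans2(y[:, fg].T, n_sources, minit="++", seed=rng, iter=25)
    if np.unique(centroids, axis=0).shape[0] < n_sources:
        raise ValueError("degenerate clustering")
    mixing = centroids.T.copy()                                # (T, N)
    col_norm = np.linalg.norm(mixing, axis=0)
    if np.any(col_norm == 0):
        raise ValueError("zero centroid column")
    mixing = mixing + 0.01 * col_norm * rng.standard_normal((t, n_sources))

    x0, *_ = np.linalg.lstsq(mixing, y, rcond=None)
    resid = y - mixing @ x0
    floor = max(1e-6 * float(np.mean(y * y)), _VAR_FLOOR)
    noise_diag = np.maximum(np.mean(resid * resid, axis=1), floor)
    mog = _mog_from_sources(x0, n_gauss, rng)
    model = IFAModel(mixing=mixing, noise_diag=noise_diag, mog=mog, seed=seed)
    return rescale(model)


def _init_pca(
    y: np.ndarray,
    n_sources: int,
    n_gauss: int,
    rng: np.random.Generator,
    seed: int,
) -> IFAModel:
    t, p = y.shape
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    k = min(n_sources, s.size)
    mixing = np.zeros((t, n_sources))
    mixing[:, :k] = u[:, :k] * (s[:k] / np.sqrt(p))
    col_scale = np.linalg.norm(mixing, axis=0)
    col_scale[col_scale == 0] = np.max(col_scale) if np.max(col_scale) > 0 else 1.0
    mixing += 0.01 * col_scale * rng.standard_normal((t, n_sources))

    resid = y - u[:, :k] @ (s[:k, None] * vt[:k])
    noise_diag = np.mean(resid * resid, axis=1)
    floor = max(1e-6 * float(np.mean(y * y)), _VAR_FLOOR)
    noise_diag = np.maximum(noise_diag, floor)

    mog = MoGSourceParams.default_init(n_sources, n_gauss)
    for j in range(n_sources):
        mog.means[j] = mog.means[j] + 0.01 * rng.standard_normal(n_gauss)
    return IFAModel(mixing=mixing, noise_diag=noise_diag, mog=mog, seed=seed)


def fit_ifa(
    series: DynamicSeries | np.ndarray,
    n_sources: int,
    n_gauss: int = 2,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
    state_cap: int = DEFAULT_STATE_CAP,
    orient_signs: bool = True,
    init: str = "kmeans",
) -> IFAModel:
    """Fit the IFA model by exact EM with restarts.

    Parameters
    ----------
    series:
        The observed T x P series (or a bare matrix).
    n_sources:
        Number of independent factors N to extract.
    n_gauss:
        Gaussians per source MoG (two suffice for bright-cluster-on-
        background factor images).
    tol:
        Relative change of the loss below which EM is declared converged.
    max_iter:
        Iteration cap per restart; exceeding it sets ``converged=False``
        on the returned model rather than raising.
    n_restarts:
        Independent seeded restarts; the model with the best final loss
        wins, ties broken by the lowest restart index.
    seed:
        Base seed; restart ``r`` uses the independent stream ``(seed, r)``.
    orient_signs:
        Flip components so every mixing column dips below its first-frame
        value (the bolus-passage convention).
    init:
        Starting-point strategy, ``"kmeans"`` (default) or ``"pca"``; see
        the module docstring.

    Returns
    -------
    IFAModel
        The best model across restarts, with its ``loss_trace``.
    """
    y = series.data if isinstance(series, DynamicSeries) else np.asarray(series, float)
    if y.ndim != 2:
        raise ValueError("data must be T x P")
    t, p = y.shape
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if t < n_sources:
        warnings.warn(
            f"fewer frames ({t}) than sources ({n_sources}); the mixing matrix "
            "is underdetermined",
            RuntimeWarning,
        )

    best: IFAModel | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        model = _init_model(y, n_sources, n_gauss, rng, seed, method=init)
        model = _em_loop(y, model, tol=tol, max_iter=max_iter, state_cap=state_cap)
        if best is None or model.loss_trace[-1] < best.loss_trace[-1] - 1e-12:
            best = model
    assert best is not None
    if orient_signs:
        trace, conv = best.loss_trace, best.converged
        best = orient_bolus_signs(best)
        best.loss_trace, best.converged = trace, conv
    return best


def _em_loop(
    y: np.ndarray,
    model: IFAModel,
    tol: float,
    max_iter: int,
    state_cap: int,
) -> IFAModel:
    n_components = model.mog.n_components
    trace: list[float] = []
    converged = False
    prev = np.inf
    for it in range(max_iter):
        qt = build_q_states(model.mog, state_cap)
        stats = _estep(y, model.mixing, model.noise_diag, qt)
        trace.append(stats.nll)
        logger.info("EM iteration %d: loss %.8f", it, stats.nll)
        if np.isfinite(prev) and abs(prev - stats.nll) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = stats.nll
        mixing, noise_diag, mog = m_step(stats, n_components)
        model = IFAModel(mixing=mixing, noise_diag=noise_diag, mog=mog, seed=model.seed)
        model = rescale(model)
    if not converged:
        qt = build_q_states(model.mog, state_cap)
        trace.append(_estep(y, model.mixing, model.noise_diag, qt).nll)
        warnings.warn(
            f"EM did not converge within {max_iter} iterations", RuntimeWarning
        )
    model.loss_trace = trace
    model.converged = converged
    return model


# ---------------------------------------------------------------------------
# Source reconstruction and component matching
# ---------------------------------------------------------------------------

def reconstruct_sources_lms(
    series: DynamicSeries | np.ndarray,
    model: IFAModel,
    grid_shape: tuple[int, int] | None = None,
    state_cap: int = DEFAULT_STATE_CAP,
) -> FactorImages:
    """Least-mean-square source reconstruction.

    The LMS estimate is the posterior mean: a responsibility-weighted sum of
    the per-state linear estimators

        x_hat = sum_q p(q|y) (A_q y + b_q),
        A_q = S_q H^T Lambda^-1,   b_q = S_q V_q^-1 mu_q,

    with ``S_q`` the per-state posterior covariance.
    """
    if isinstance(series, DynamicSeries):
        y = series.data
        gshape = series.grid_shape
    else:
        y = np.asarray(series, float)
        gshape = grid_shape if grid_shape is not None else (1, y.shape[1])
    _check_dims(y, model)
    qt = build_q_states(model.mog, state_cap)
    st = _estep(y, model.mixing, model.noise_diag, qt)
    return FactorImages(images=st.post_mean, grid_shape=gshape)


@dataclass
class MatchResult:
    """Alignment of estimated components to a reference set."""

    permutation: np.ndarray     # est index matched to each reference component
    signs: np.ndarray           # +-1 sign making the matched correlation positive
    correlations: np.ndarray    # |Pearson r| of each matched pair


def _component_correlations(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between rows of est and rows of ref."""
    def center(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ac = a - a.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(ac, axis=1)
        return ac, norm

    ec, en = center(est)
    rc, rn = center(ref)
    corr = np.zeros((est.shape[0], ref.shape[0]))
    ok_e = en > 0
    ok_r = rn > 0
    if not (ok_e.all() and ok_r.all()):
        warnings.warn("zero-variance component; its correlations reported as 0", RuntimeWarning)
    denom = np.outer(np.where(ok_e, en, 1.0), np.where(ok_r, rn, 1.0))
    corr = (ec @ rc.T) / denom
    corr[~ok_e, :] = 0.0
    corr[:, ~ok_r] = 0.0
    return corr


def match_components(estimated: np.ndarray, reference: np.ndarray) -> MatchResult:
    """Optimally pair estimated components with reference components.

    Components are rows (pass ``H.T`` to match mixing columns).  The
    assignment maximises the total absolute Pearson correlation (Hungarian
    algorithm); each pair's sign is chosen to make its correlation positive.

    Returns
    -------
    MatchResult
        ``permutation[k]`` is the estimated row matched to reference row
        ``k``; ``correlations[k]`` the absolute correlation of that pair.
    """
    estimated = np.atleast_2d(np.asarray(estimated, float))
    reference = np.atleast_2d(np.asarray(reference, float))
    if estimated.shape[0] != reference.shape[0]:
        raise ValueError("component counts differ")
    corr = _component_correlations(estimated, reference)
    row, col = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(reference.shape[0], dtype=int)
    perm[col] = row
    matched = corr[perm, np.arange(reference.shape[0])]
    signs = np.where(matched >= 0, 1.0, -1.0)
    return MatchResult(permutation=perm, signs=signs, correlations=np.abs(matched))


def mixing_crosstalk(
    estimated_mixing: np.ndarray,
    reference_mixing: np.ndarray,
    match: MatchResult | None = None,
) -> np.ndarray:
    """Cross-talk matrix ``J = (Hhat^T Hhat)^-1 Hhat^T H``.

    ``J`` is the matrix of regression coefficients of the true mixing
    columns on the estimated ones; a correct separation gives the identity.
    The estimated matrix is first aligned (permutation and sign) to the
    reference, and both are column-normalised to unit Euclidean norm so
    that the comparison is scale-free.
    """
    h_ref = np.asarray(reference_mixing, float)
    h_est = np.asarray(estimated_mixing, float)
    if match is None:
        match = match_components(h_est.T, h_ref.T)
    h_al = h_est[:, match.permutation] * match.signs
    h_al = h_al / np.linalg.norm(h_al, axis=0)
    h_rn = h_ref / np.linalg.norm(h_ref, axis=0)
    j, *_ = np.linalg.lstsq(h_al, h_rn, rcond=None)
    return j
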