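"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import perfifa as pf
from perfifa.mog import MoGSourceParams


# ---------------------------------------------------------------------------
# Independent dense-grid oracle for the IFA posterior (T small, N <= 2).
# Marginalises over the sources by brute-force quadrature; shares no code
# with the package's Gaussian-conditioning E-step.
# ---------------------------------------------------------------------------

def _mog_pdf(x: np.ndarray, w, m, v) -> np.ndarray:
    out = np.zeros_like(x)
    for wi, mi, vi in zip(w, m, v):
        out += wi * np.exp(-0.5 * (x - mi) ** 2 / vi) / np.sqrt(2 * np.pi * vi)
    return out


def grid_oracle(y: np.ndarray, model: pf.IFAModel, lo=-10.0, hi=12.0, n=1101):
    """Return (nll, E[x|y] per pixel) by dense-grid numerical marginalization."""
    mog = model.mog
    h = model.mixing
    lam = model.noise_diag
    t = h.shape[0]
    n_src = h.shape[1]
    assert n_src in (1, 2), "oracle supports N <= 2"
    gs = np.linspace(lo, hi, n)
    dx = gs[1] - gs[0]
    if n_src == 1:
        grids = [gs]
        px = _mog_pdf(gs, mog.weights[0], mog.means[0], mog.variances[0])
        coords = gs[None, :]
    else:
        x1, x2 = np.meshgrid(gs, gs, indexing="ij")
        grids = [x1, x2]
        px = _mog_pdf(x1, mog.weights[0], mog.means[0], mog.variances[0]) * _mog_pdf(
            x2, mog.weights[1], mog.means[1], mog.variances[1]
        )
        coords = np.stack([x1, x2])
    nlls = []
    e_x = []
    for p in range(y.shape[1]):
        yp = y[:, p]
        mean_y = sum(h[:, j].reshape((t,) + (1,) * grids[0].ndim) * grids[j] for j in range(n_src))
        lik = np.ones_like(grids[0])
        for ti in range(t):
            lik = lik * np.exp(-0.5 * (yp[ti] - mean_y[ti]) ** 2 / lam[ti]) / np.sqrt(
                2 * np.pi * lam[ti]
            )
        joint = px * lik
        z = joint.sum() * dx**n_src
        nlls.append(-np.log(z))
        e_x.append([(coords[j] * joint).sum() * dx**n_src / z for j in range(n_src)])
    return float(np.mean(nlls)), np.array(e_x).T


def random_small_model(rng: np.random.Generator, t=3, n=2, n_gauss=2) -> pf.IFAModel:
    """A random well-conditioned small IFA model."""
    mog = MoGSourceParams(
        weights=[_rand_simplex(rng, n_gauss) for _ in range(n)],
        means=[rng.normal(0, 1.5, n_gauss) for _ in range(n)],
        variances=[rng.uniform(0.3, 1.5, n_gauss) for _ in range(n)],
    )
    return pf.IFAModel(
        mixing=rng.normal(size=(t, n)),
        noise_diag=rng.uniform(0.2, 1.0, t),
        mog=mog,
    )


def _rand_simplex(rng, k):
    w = rng.uniform(0.2, 1.0, k)
    return w / w.sum()


def sample_from_model(model: pf.IFAModel, p: int, rng: np.random.Generator) -> np.ndarray:
    """Draw P pixels from the IFA generative model."""
    n = model.n_sources
    x = np.empty((n, p))
    for j in range(n):
        comp = rng.choice(model.mog.weights[j].size, size=p, p=model.mog.weights[j])
        x[j] = rng.normal(
            model.mog.means[j][comp], np.sqrt(model.mog.variances[j][comp])
        )
    noise = rng.normal(0, np.sqrt(model.noise_diag)[:, None], size=(model.n_frames, p))
    return model.mixing @ x + noise


# ---------------------------------------------------------------------------
# Phantom recovery runs, shared across the acceptance and module tests.
# Each entry is one full simulate -> fit -> reconstruct -> match experiment.
# ---------------------------------------------------------------------------

PHANTOM_SEEDS = (1, 2, 3)


def _run_phantom(snr: float, seed: int) -> pf.PhantomResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pf.run_recovery_experiment(pf.PhantomSpec(target_snr=snr, seed=seed))


@pytest.fixture(scope="session")
def phantom_runs_high():
    """Recovery runs at the clean-acquisition SNR (240), one per seed."""
    return {seed: _run_phantom(240.0, seed) for seed in PHANTOM_SEEDS}


@pytest.fixture(scope="session")
def phantom_runs_low():
    """Recovery runs at the degraded SNR (40), one per seed."""
    return {seed: _run_phantom(40.0, seed) for seed in PHANTOM_SEEDS}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
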