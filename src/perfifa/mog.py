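"""Mixture-of-Gaussians source densities and their joint-state enumeration.

Each hidden source ``x_j`` is modelled as a 1-D mixture of Gaussians (MoG)
with weights ``w[j][q]``, means ``mu[j][q]`` and variances ``nu[j][q]``.
Because the sources are independent, the joint density of the source vector
is itself an MoG whose states are all combinations ``q = (q_1, ..., q_N)``;
the joint state table below materialises that enumeration for exact EM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

#: Maximum number of joint MoG states the exact EM will enumerate.
DEFAULT_STATE_CAP = 4096


@dataclass
class MoGSourceParams:
    """Per-source MoG parameters: one (weights, means, variances) triple per source."""

    weights: list[np.ndarray]
    means: list[np.ndarray]
    variances: list[np.ndarray]

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.means = [np.asarray(m, dtype=float) for m in self.means]
        self.variances = [np.asarray(v, dtype=float) for v in self.variances]
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValueError("weights, means, variances must have one entry per source")
        for j, (w, m, v) in enumerate(zip(self.weights, self.means, self.variances)):
            if not (w.shape == m.shape == v.shape) or w.ndim != 1 or w.size < 1:
                raise ValueError(f"source {j}: malformed MoG component arrays")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"source {j}: MoG weights sum to {w.sum()}, not 1")
            if np.any(w < 0):
                raise ValueError(f"source {j}: negative MoG weight")
            if np.any(v <= 0):
                raise ValueError(f"source {j}: non-positive MoG variance")

    @property
    def n_sources(self) -> int:
        return len(self.weights)

    @property
    def n_components(self) -> list[int]:
        """Number of Gaussians per source."""
        return [w.size for w in self.weights]

    def marginal_variance(self, j: int) -> float:
        """Total variance of source ``j`` under its MoG: E[x^2] - E[x]^2."""
        w, m, v = self.weights[j], self.means[j], self.variances[j]
        return float(np.sum(w * (v + m**2)) - np.sum(w * m) ** 2)

    def copy(self) -> "MoGSourceParams":
        return MoGSourceParams(
            [w.copy() for w in self.weights],
            [m.copy() for m in self.means],
            [v.copy() for v in self.variances],
        )

    @classmethod
    def default_init(cls, n_sources: int, n_gauss: int = 2) -> "MoGSourceParams":
        """Symmetric starting point: uniform weights, means spread in [-1, 1], unit variances."""
        if n_gauss == 1:
            means = np.zeros(1)
        else:
            means = np.linspace(-1.0, 1.0, n_gauss)
        return cls(
            weights=[np.full(n_gauss, 1.0 / n_gauss) for _ in range(n_sources)],
            means=[means.copy() for _ in range(n_sources)],
            variances=[np.ones(n_gauss) for _ in range(n_sources)],
        )


@dataclass
class QStateTable:
    """All joint MoG states of the N independent sources.

    ``states[s]`` holds the per-source component index of joint state ``s``;
    the joint prior is the product of the per-source weights, the joint mean
    the concatenation of the per-source means, and the joint covariance the
    diagonal of the per-source variances.
    """

    states: np.ndarray      # (Q, N) int component indices
    weights: np.ndarray     # (Q,) joint priors, sums to 1
    means: np.ndarray       # (Q, N)
    variances: np.ndarray   # (Q, N) diagonals of V_q

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_sources(self) -> int:
        return self.states.shape[1]


def build_q_states(mog: MoGSourceParams, state_cap: int = DEFAULT_STATE_CAP) -> QStateTable:
    """Enumerate the joint MoG states of independent sources.

    Raises
    ------
    ValueError
        If the number of joint states ``prod(n_j)`` exceeds ``state_cap`` --
        exact EM over the joint enumeration would be intractable.
    """
    n_j = mog.n_components
    n_states = int(np.prod(n_j))
    if n_states > state_cap:
        raise ValueError(
            f"joint enumeration of {n_states} states exceeds the cap of {state_cap}"
        )
    states = np.array(list(itertools.product(*(range(n) for n in n_j))), dtype=int)
    n = mog.n_sources
    weights = np.ones(n_states)
    means = np.empty((n_states, n))
    variances = np.empty((n_states, n))
    for j in range(n):
        idx = states[:, j]
        weights *= mog.weights[j][idx]
        means[:, j] = mog.means[j][idx]
        variances[:, j] = mog.variances[j][idx]
    return QStateTable(states=states, weights=weights, means=means, variances=variances)
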