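"""Reference (vectorized numpy) likelihoods for the two DFE models.

These functions define the model exactly and serve as the ground truth the
fast incremental samplers are checked against.  The likelihood for a
dataset (y, M, F, plate, line) and state comprises

* the category/side assignment probabilities Sum_j log q[label_j] plus the
  multinomial (or binomial) probability of the category counts — both terms
  are retained by default, with ``include_assignment_term=False`` exposing
  the count-only variant for sensitivity analysis;
* for the gamma model, the gamma density of each mutation's active-side
  magnitude;
* Normal(0, V_p) plate-effect terms;
* per-observation Normal residual terms with one mean per MA line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datasets import RLDataset

__all__ = [
    "SharedState",
    "MulticategoryState",
    "GammaState",
    "genotypic_values_multicat",
    "loglik_multicat",
    "genotypic_values_gamma",
    "loglik_gamma",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SharedState:
    """Nuisance state common to both DFE models."""

    f: np.ndarray  # fixed-effect values, (n_f,)
    p: np.ndarray  # plate effects, (n_p,)
    V_p: float
    ybar: np.ndarray  # overall mean per MA line, (n_lines,)
    V_e: float

    def __post_init__(self) -> None:
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.ybar = np.atleast_1d(np.asarray(self.ybar, dtype=float))
        if self.V_e <= 0 or (self.p.size and self.V_p <= 0):
            raise ValueError("variances must be positive")


@dataclass
class MulticategoryState:
    """Point-mass mixture state: category per mutation, effect and frequency
    per category (category 0 has effect fixed at zero)."""

    m: np.ndarray  # category index per mutation
    e: np.ndarray  # effect per category, e[0] == 0
    q: np.ndarray  # frequency per category, sums to 1

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        self.e = np.asarray(self.e, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.e[0] != 0.0:
            raise ValueError("e[0] must be 0 (zero-effect category)")
        if not np.isclose(self.q.sum(), 1.0):
            raise ValueError("q must sum to 1")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.m, minlength=len(self.e))


@dataclass
class GammaState:
    """Two-sided gamma state: side indicator and magnitude per mutation,
    side frequencies, and per-side gamma (rate, shape).

    ``rate`` is the gamma rate (mean = shape / rate); ``delta`` gives the
    sign, -1 for side 0 (deleterious) and +1 for side 1 (beneficial).
    """

    mu: np.ndarray  # side per mutation, 0 negative / 1 positive
    E: np.ndarray  # (2, n_m) positive magnitudes
    q: np.ndarray  # (q_neg, q_pos), sums to 1
    rate: np.ndarray  # (2,)
    shape: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.int64)
        self.E = np.asarray(self.E, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        if self.E.shape != (2, len(self.mu)):
            raise ValueError("E must be 2 x n_m")
        if not np.isclose(self.q.sum(), 1.0) or not (0 < self.q[0] < 1):
            raise ValueError("side frequencies must be in (0,1) and sum to 1")
        if (self.rate <= 0).any() or (self.shape <= 0).any():
            raise ValueError("rate and shape must be positive")

    @property
    def delta(self) -> np.ndarray:
        return np.where(self.mu == 0, -1.0, 1.0)

    @property
    def active_magnitudes(self) -> np.ndarray:
        return self.E[self.mu, np.arange(len(self.mu))]

    @property
    def signed_effects(self) -> np.ndarray:
        return self.delta * self.active_magnitudes


def genotypic_values_multicat(M: np.ndarray, m: np.ndarray, e: np.ndarray) -> np.ndarray:
    """g_i = sum over carried mutations of the effect of their category.

    Non-carried mutations contribute e[0] = 0 (indexing by M_ij * m_j).
    """
    M = np.asarray(M)
    return M @ np.asarray(e, dtype=float)[np.asarray(m, dtype=np.int64)]


def _residual_terms(
    data: RLDataset, g: np.ndarray, shared: SharedState
) -> float:
    resid = data.y - g
    if data.n_f:
        resid = resid - data.F @ shared.f
    if data.n_p:
        resid = resid - shared.p[data.plate]
    mu = shared.ybar[data.line] if data.n_b else shared.ybar[:0]
    obs = -0.5 * data.n_b * (LOG2PI + np.log(shared.V_e)) - float(
        ((resid - mu) ** 2).sum()
    ) / (2.0 * shared.V_e)
    plate = 0.0
    if data.n_p:
        plate = -0.5 * data.n_p * (LOG2PI + np.log(shared.V_p)) - float(
            (shared.p**2).sum()
        ) / (2.0 * shared.V_p)
    return obs + plate


def loglik_multicat(
    data: RLDataset,
    state: MulticategoryState,
    shared: SharedState,
    include_assignment_term: bool = True,
) -> float:
    """Log likelihood of the data under the point-mass mixture model.

    Terms: per-mutation assignment probabilities (optional), the multinomial
    probability of the category counts, plate-effect densities and the
    per-observation residual densities.  Any occupied category with q = 0
    yields -inf.
    """
    v = state.counts
    with np.errstate(divide="ignore"):
        logq = np.log(state.q)
    if np.any((v > 0) & ~np.isfinite(logq)):
        return -np.inf
    terms = 0.0
    if include_assignment_term:
        terms += float((v * logq).sum())
    # multinomial probability of the counts
    terms += float(
        gammaln(len(state.m) + 1) - gammaln(v + 1).sum() + (v * logq).sum()
    )
    g = genotypic_values_multicat(data.M, state.m, state.e)
    return terms + _residual_terms(data, g, shared)


def genotypic_values_gamma(M: np.ndarray, mu: np.ndarray, E: np.ndarray) -> np.ndarray:
    """g_i = sum over carried mutations of delta_j * E[mu_j, j]."""
    mu = np.asarray(mu, dtype=np.int64)
    signed = np.where(mu == 0, -1.0, 1.0) * np.asarray(E)[mu, np.arange(len(mu))]
    return np.asarray(M) @ signed


def _gamma_logpdf(x: np.ndarray, rate: float, shape: float) -> np.ndarray:
    return (
        shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    )


def loglik_gamma(
    data: RLDataset,
    state: GammaState,
    shared: SharedState,
    include_assignment_term: bool = True,
) -> float:
    """Log likelihood under the two-sided gamma model.

    Terms: gamma density of each active magnitude, per-mutation side
    probabilities (optional), the binomial probability of the side counts,
    plate densities and residual densities.  Nonpositive magnitudes give
    -inf.
    """
    n_m = len(state.mu)
    act = state.active_magnitudes
    if n_m and (act <= 0).any():
        return -np.inf
    terms = 0.0
    if n_m:
        terms += float(
            _gamma_logpdf(act, state.rate[state.mu], state.shape[state.mu]).sum()
        )
    v0 = int((state.mu == 0).sum())
    logq = np.log(state.q)
    if include_assignment_term:
        terms += float(v0 * logq[0] + (n_m - v0) * logq[1])
    terms += float(
        gammaln(n_m + 1)
        - gammaln(v0 + 1)
        - gammaln(n_m - v0 + 1)
        + v0 * logq[0]
        + (n_m - v0) * logq[1]
    )
    g = genotypic_values_gamma(data.M, state.mu, state.E)
    return terms + _residual_terms(data, g, shared)
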