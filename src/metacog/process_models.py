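"""Process-model measures of metacognition.

Two generative models extend the equal-variance SDT observer with an
explicit account of how confidence is corrupted:

* **Lognormal meta-noise model** — on each trial a single multiplier
  m ~ Lognormal(0, sigma_meta) rescales all confidence-criterion distances
  tau_j away from the decision criterion, so the effective criteria are
  c +/- m*tau_j.  A shared multiplicative jitter keeps criterion ordering
  intact and can never push a confidence criterion across the decision
  criterion.  sigma_meta (the log-scale of the jitter) is the measure
  *meta-noise*; larger values mean noisier confidence.

* **CASANDRE-style second-order uncertainty** — the observer does not know
  its own sensory noise exactly: it judges confidence from the scaled
  evidence strength v = |x - c| / sigma_hat where sigma_hat ~
  Lognormal(-u^2/2, u) is a unit-mean noisy estimate of the (unit) sensory
  noise, compared against fixed thresholds t_j.  The log-scale u is the
  measure *meta-uncertainty*.

Both likelihoods marginalize the lognormal variable by Gauss-Hermite
quadrature; the Gaussian evidence dimension is handled with exact segment
masses, so per-stimulus cell probabilities sum to 1 by construction.  At
zero noise both models reduce exactly to the fixed-criteria SDT observer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .sdt import EstimationError, RatingCounts, fit_type1
from .trials import TrialTable, ValidationError

__all__ = [
    "LognormalNoiseParams",
    "CasandreParams",
    "ModelFit",
    "LognormalNoiseModel",
    "CasandreModel",
    "simulate_lognoise",
    "simulate_casandre",
    "lognoise_likelihood",
    "casandre_likelihood",
    "fit_meta_noise",
    "fit_meta_uncertainty",
]


@dataclass(frozen=True)
class LognormalNoiseParams:
    """Parameters of the lognormal meta-noise observer."""

    d_prime: float
    c: float
    tau: tuple            # k-1 median criterion distances, strictly increasing
    sigma_meta: float     # lognormal log-scale of the shared criterion jitter

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or (tau <= 0).any() or (np.diff(tau) <= 0).any():
            raise ValidationError("tau must be strictly positive and increasing")
        if self.sigma_meta < 0:
            raise ValidationError("sigma_meta must be >= 0")
        object.__setattr__(self, "tau", tuple(float(t) for t in tau))

    @property
    def k(self) -> int:
        return len(self.tau) + 1

    @property
    def log_mean(self) -> float:  # multiplier has median 1
        return 0.0


@dataclass(frozen=True)
class CasandreParams:
    """Parameters of the second-order-uncertainty (CASANDRE-style) observer."""

    d_prime: float
    c: float
    conf_criteria: tuple  # k-1 thresholds on v = |x-c|/sigma_hat
    meta_uncertainty: float

    def __post_init__(self) -> None:
        t = np.asarray(self.conf_criteria, dtype=float)
        if t.ndim != 1 or (t <= 0).any() or (np.diff(t) <= 0).any():
            raise ValidationError("conf_criteria must be strictly positive "
                                  "and increasing")
        if self.meta_uncertainty < 0:
            raise ValidationError("meta_uncertainty must be >= 0")
        object.__setattr__(self, "conf_criteria", tuple(float(x) for x in t))

    @property
    def k(self) -> int:
        return len(self.conf_criteria) + 1

    @property
    def tau(self) -> tuple:
        return self.conf_criteria

    @property
    def sigma_meta(self) -> float:
        return self.meta_uncertainty

    @property
    def log_mean(self) -> float:  # sigma_hat has mean 1
        return -self.meta_uncertainty ** 2 / 2.0


@dataclass(frozen=True)
class ModelFit:
    """Result of a process-model maximum-likelihood fit."""

    params: LognormalNoiseParams | CasandreParams
    log_likelihood: float
    converged: bool
    n_restarts: int
    quadrature_nodes: int

    @property
    def measure_value(self) -> float:
        return self.params.sigma_meta

    def summary(self) -> str:
        p = self.params
        name = ("lognormal meta-noise" if isinstance(p, LognormalNoiseParams)
                else "CASANDRE second-order uncertainty")
        lines = [
            f"{name} model fit",
            "=" * 42,
            f"d':                  {p.d_prime: .4f}",
            f"c:                   {p.c: .4f}",
            f"criterion distances: {np.round(p.tau, 4)}",
            f"noise log-scale:     {p.sigma_meta: .4f}",
            f"log-likelihood:      {self.log_likelihood: .4f}",
            f"converged:           {self.converged}",
            f"restarts:            {self.n_restarts}",
            f"quadrature nodes:    {self.quadrature_nodes}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        rows = [("d_prime", p.d_prime), ("c", p.c)]
        rows += [(f"tau_{j + 1}", t) for j, t in enumerate(p.tau)]
        rows += [("noise_log_scale", p.sigma_meta),
                 ("log_likelihood", self.log_likelihood),
                 ("converged", float(self.converged)),
                 ("restarts", self.n_restarts)]
        return pd.DataFrame(rows, columns=["parameter", "estimate"])


# ---------------------------------------------------------------------------
# shared likelihood core

@lru_cache(maxsize=8)
def _hermite_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    return nodes, weights / np.sqrt(np.pi)


def _cell_probs(d_prime: float, c: float, tau: np.ndarray, sigma: float,
                log_mean: float, n_nodes: int) -> np.ndarray:
    """2 x 2k cell probabilities, cells ordered -k..-1, +1..+k.

    Marginalizes the lognormal multiplier by Gauss-Hermite quadrature; for
    each node the evidence axis is partitioned exactly, so rows sum to 1 up
    to quadrature weight normalization (exact).
    """
    tau = np.asarray(tau, dtype=float)
    k = tau.size + 1
    if sigma == 0.0:
        m = np.array([np.exp(log_mean)])
        w = np.array([1.0])
    else:
        nodes, w = _hermite_nodes(n_nodes)
        m = np.exp(log_mean + np.sqrt(2.0) * sigma * nodes)
    # edges per node: c - m*tau[::-1], c, c + m*tau  (length 2k-1)
    dist = np.concatenate([-tau[::-1], [0.0], tau])       # (2k-1,)
    edges = c + m[:, None] * dist[None, :]                # (q, 2k-1)
    p = np.empty((2, 2 * k))
    for s, mu in enumerate((-d_prime / 2.0, d_prime / 2.0)):
        cdf = norm.cdf(edges - mu)                        # (q, 2k-1)
        inner = np.diff(cdf, axis=1)                      # (q, 2k-2)
        cells = np.concatenate([cdf[:, :1], inner, 1.0 - cdf[:, -1:]], axis=1)
        # cells are ordered -k..-1,+1..+k along the evidence axis already:
        # below c - m*tau_{k-1} is response 1 / confidence k, etc.
        p[s] = w @ cells
    return p


def _loglike_from_probs(p: np.ndarray, counts: RatingCounts) -> float:
    return float((counts.counts * np.log(np.clip(p, 1e-300, None))).sum())


def lognoise_likelihood(params: LognormalNoiseParams, counts: RatingCounts,
                        n_nodes: int = 61) -> float:
    """Log-likelihood of a count table under the lognormal meta-noise model."""
    p = _cell_probs(params.d_prime, params.c, np.asarray(params.tau),
                    params.sigma_meta, params.log_mean, n_nodes)
    return _loglike_from_probs(p, counts)


def casandre_likelihood(params: CasandreParams, counts: RatingCounts,
                        n_nodes: int = 61) -> float:
    """Log-likelihood of a count table under the CASANDRE-style model."""
    p = _cell_probs(params.d_prime, params.c, np.asarray(params.conf_criteria),
                    params.meta_uncertainty, params.log_mean, n_nodes)
    return _loglike_from_probs(p, counts)


def predicted_cell_probs(params: LognormalNoiseParams | CasandreParams,
                         n_nodes: int = 61) -> np.ndarray:
    """Model-implied 2 x 2k cell probabilities (for checks and simulation)."""
    return _cell_probs(params.d_prime, params.c, np.asarray(params.tau),
                       params.sigma_meta, params.log_mean, n_nodes)


def check_quadrature(params, counts: RatingCounts, n_nodes: int = 61,
                     tol: float = 1e-6) -> float:
    """Node-doubling check: return |LL(n) - LL(2n)|; raise if above tol."""
    like = (lognoise_likelihood if isinstance(params, LognormalNoiseParams)
            else casandre_likelihood)
    delta = abs(like(params, counts, n_nodes) - like(params, counts, 2 * n_nodes))
    if delta > tol:
        raise EstimationError(
            f"quadrature under-resolved: node doubling moves the "
            f"log-likelihood by {delta:.2e} (> {tol:.0e})")
    return delta


# ---------------------------------------------------------------------------
# simulation

def _simulate(d_prime: float, c: float, tau: np.ndarray, sigma: float,
              log_mean: float, n: int, seed: int,
              p_category2: float = 0.5) -> TrialTable:
    rng = np.random.default_rng(seed)
    tau = np.asarray(tau, dtype=float)
    k = tau.size + 1
    stim = (rng.random(n) < p_category2).astype(int) + 1
    mu = np.where(stim == 2, d_prime / 2.0, -d_prime / 2.0)
    x = rng.normal(mu, 1.0)
    m = np.exp(rng.normal(log_mean, sigma, n)) if sigma > 0 else np.full(n, np.exp(log_mean))
    resp = np.where(x > c, 2, 1)
    conf = 1 + (np.abs(x - c)[:, None] >= m[:, None] * tau[None, :]).sum(axis=1)
    df = pd.DataFrame({"participant": 1, "stimulus": stim, "response": resp,
                       "confidence": conf.astype(int)})
    return TrialTable(df, k)


def simulate_lognoise(params: LognormalNoiseParams, n: int, seed: int,
                      p_category2: float = 0.5) -> TrialTable:
    """Simulate trials from the lognormal meta-noise observer.

    The decision is untouched by metacognitive noise: response follows the
    evidence sample against the fixed criterion c, while the shared trial
    multiplier only rescales the confidence-criterion distances.
    """
    return _simulate(params.d_prime, params.c, np.asarray(params.tau),
                     params.sigma_meta, params.log_mean, n, seed, p_category2)


def simulate_casandre(params: CasandreParams, n: int, seed: int,
                      p_category2: float = 0.5) -> TrialTable:
    """Simulate trials from the second-order-uncertainty observer."""
    return _simulate(params.d_prime, params.c, np.asarray(params.conf_criteria),
                     params.meta_uncertainty, params.log_mean, n, seed,
                     p_category2)


# ---------------------------------------------------------------------------
# fitting

class _ProcessModelBase:
    """Joint MLE over (d', c, criterion distances, noise log-scale)."""

    #: subclasses set the lognormal log-mean as a function of sigma
    @staticmethod
    def _log_mean(sigma: float) -> float:
        raise NotImplementedError

    def __init__(self, counts: RatingCounts, n_nodes: int = 61):
        if counts.k < 2:
            raise ValidationError("need a confidence scale with k >= 2")
        self.counts = counts
        self.k = counts.k
        self.n_nodes = n_nodes

    # theta = [d, c, log tau_1, log dtau_2.., log sigma]
    def _unpack(self, theta: np.ndarray):
        k = self.k
        d, c = theta[0], theta[1]
        inc = np.exp(theta[2:1 + k])
        tau = np.cumsum(inc)
        sigma = float(np.exp(theta[1 + k]))
        return d, c, tau, sigma

    def loglike(self, theta: np.ndarray) -> float:
        d, c, tau, sigma = self._unpack(theta)
        p = _cell_probs(d, c, tau, sigma, self._log_mean(sigma), self.n_nodes)
        return _loglike_from_probs(p, self.counts)

    def _initial_theta(self) -> np.ndarray:
        t1 = fit_type1(self.counts)
        k = self.k
        pos = t1.criteria[k:] - t1.c
        neg = t1.c - t1.criteria[:k - 1][::-1]
        tau0 = np.clip((pos + neg) / 2.0, 0.05, None)
        tau0 = np.maximum.accumulate(tau0 + 1e-3 * np.arange(k - 1))
        inc0 = np.diff(np.concatenate([[0.0], tau0]))
        return np.concatenate([[max(t1.d_prime, 0.1), t1.c],
                               np.log(np.clip(inc0, 1e-3, None)), [np.log(0.3)]])

    def fit(self, n_restarts: int = 5, seed: int = 0,
            tol: float = 1e-6) -> ModelFit:
        """Multi-start Nelder-Mead MLE; best likelihood wins, ties broken
        by the smaller noise estimate."""
        theta0 = self._initial_theta()
        rng = np.random.default_rng(seed)
        best = None
        converged = False
        for r in range(max(1, n_restarts)):
            start = theta0 if r == 0 else theta0 + rng.normal(0, 0.25, theta0.size)
            res = minimize(lambda th: -self.loglike(th), start,
                           method="Nelder-Mead",
                           options={"xatol": 1e-5, "fatol": tol,
                                    "maxiter": 300 * theta0.size,
                                    "maxfev": 300 * theta0.size})
            d, c, tau, sigma = self._unpack(res.x)
            cand = (-res.fun, -sigma, (d, c, tau, sigma), bool(res.success))
            if best is None or cand[:2] > best[:2]:
                best = cand
            converged = converged or bool(res.success)
        ll, _, (d, c, tau, sigma), _ = best
        if not converged:
            warnings.warn("process-model fit did not converge in any restart",
                          stacklevel=2)
        params = self._make_params(d, c, tau, sigma)
        return ModelFit(params=params, log_likelihood=float(ll),
                        converged=converged, n_restarts=max(1, n_restarts),
                        quadrature_nodes=self.n_nodes)


class LognormalNoiseModel(_ProcessModelBase):
    """MLE of the lognormal meta-noise observer; the measure is sigma_meta."""

    @staticmethod
    def _log_mean(sigma: float) -> float:
        return 0.0

    def _make_params(self, d, c, tau, sigma) -> LognormalNoiseParams:
        return LognormalNoiseParams(d_prime=float(d), c=float(c),
                                    tau=tuple(tau), sigma_meta=float(sigma))


class CasandreModel(_ProcessModelBase):
    """MLE of the CASANDRE-style observer; the measure is meta_uncertainty."""

    @staticmethod
    def _log_mean(sigma: float) -> float:
        return -sigma ** 2 / 2.0

    def _make_params(self, d, c, tau, sigma) -> CasandreParams:
        return CasandreParams(d_prime=float(d), c=float(c),
                              conf_criteria=tuple(tau),
                              meta_uncertainty=float(sigma))


def fit_meta_noise(counts: RatingCounts, n_restarts: int = 5,
                   n_nodes: int = 61, seed: int = 0) -> ModelFit:
    """Fit the lognormal meta-noise model; ``params.sigma_meta`` is the measure."""
    if counts.k < 3:
        warnings.warn("k < 3 gives little information to constrain "
                      "meta-noise", stacklevel=2)
    return LognormalNoiseModel(counts, n_nodes=n_nodes).fit(
        n_restarts=n_restarts, seed=seed)


def fit_meta_uncertainty(counts: RatingCounts, n_restarts: int = 5,
                         n_nodes: int = 61, seed: int = 0) -> ModelFit:
    """Fit the CASANDRE-style model; ``params.meta_uncertainty`` is the measure."""
    if counts.k < 3:
        warnings.warn("k < 3 gives little information to constrain "
                      "meta-uncertainty", stacklevel=2)
    if counts.n_trials < 200:
        warnings.warn("meta-uncertainty is unreliable below ~200 trials",
                      stacklevel=2)
    return CasandreModel(counts, n_nodes=n_nodes).fit(
        n_restarts=n_restarts, seed=seed)
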