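"""Maximum-likelihood estimation of meta-d'.

meta-d' is the sensitivity an ideal equal-variance SDT observer would need
in order to produce the observed type-2 (confidence) data.  The type-1
decision criterion is anchored at the same *relative* position as in the
data (meta-c = meta-d' * c/d'), while meta-d' and 2(k-1) response-
conditional type-2 criteria are free parameters maximizing the multinomial
likelihood of confidence ratings given each (stimulus, response) cell.
Because meta-d' is in d' units, M-Ratio = meta-d'/d' and M-Diff =
meta-d' - d' normalize it by observed task performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .sdt import EstimationError, RatingCounts, fit_type1

__all__ = ["MetaDPrimeModel", "MetaDPrimeResults"]

_MIN_INCREMENT = 1e-4  # smallest spacing between adjacent type-2 criteria


@dataclass(frozen=True)
class MetaDPrimeResults:
    """Fitted meta-d' parameters and diagnostics."""

    meta_d: float
    meta_c: float
    d_prime: float
    c: float
    k: int
    t2_criteria_r1: np.ndarray   # k-1 criteria below meta-c, ascending
    t2_criteria_r2: np.ndarray   # k-1 criteria above meta-c, ascending
    log_likelihood: float
    converged: bool
    n_iterations: int

    @property
    def m_ratio(self) -> float:
        return self.meta_d / self.d_prime if self.d_prime != 0 else np.nan

    @property
    def m_diff(self) -> float:
        return self.meta_d - self.d_prime

    def summary(self) -> str:
        lines = [
            "meta-d' type-2 maximum-likelihood fit",
            "=" * 38,
            f"scale points (k):     {self.k}",
            f"d' (type 1):          {self.d_prime: .4f}",
            f"c  (type 1):          {self.c: .4f}",
            f"meta-d':              {self.meta_d: .4f}",
            f"meta-c:               {self.meta_c: .4f}",
            f"M-Ratio:              {self.m_ratio: .4f}",
            f"M-Diff:               {self.m_diff: .4f}",
            f"log-likelihood:       {self.log_likelihood: .4f}",
            f"converged:            {self.converged}",
        ]
        return "\n".join(lines)


class MetaDPrimeModel:
    """Type-2 SDT model for a signed-confidence count table.

    Parameters
    ----------
    counts : RatingCounts
        2 x 2k stimulus-by-signed-confidence table.

    Examples
    --------
    >>> res = MetaDPrimeModel(counts).fit()
    >>> res.meta_d, res.m_ratio
    """

    def __init__(self, counts: RatingCounts):
        if (counts.counts.sum(axis=1) == 0).any():
            raise EstimationError("both stimulus rows must contain trials")
        self.counts = counts
        self.k = counts.k
        self.type1 = fit_type1(counts)
        if abs(self.type1.d_prime) < 1e-8:
            warnings.warn("d' is ~0; meta-c anchored at c ratio 0", stacklevel=2)
            self._c_ratio = 0.0
        else:
            self._c_ratio = self.type1.c / self.type1.d_prime

    # -- parameter packing: theta = [meta_d, log incr below, log incr above]
    def _unpack(self, theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        k = self.k
        meta_d = theta[0]
        meta_c = meta_d * self._c_ratio
        inc_lo = np.exp(theta[1:k]) + _MIN_INCREMENT
        inc_hi = np.exp(theta[k:2 * k - 1]) + _MIN_INCREMENT
        crit_r1 = meta_c - np.cumsum(inc_lo)[::-1]   # ascending, below meta-c
        crit_r2 = meta_c + np.cumsum(inc_hi)         # ascending, above meta-c
        return meta_d, crit_r1, crit_r2

    def _cell_log_probs(self, meta_d: float, crit_r1: np.ndarray,
                        crit_r2: np.ndarray) -> np.ndarray:
        """log P(signed-confidence cell | stimulus, response), 2 x 2k."""
        meta_c = meta_d * self._c_ratio
        edges = np.concatenate([[-np.inf], crit_r1, [meta_c], crit_r2, [np.inf]])
        out = np.empty((2, 2 * self.k))
        for s, mu in enumerate((-meta_d / 2.0, meta_d / 2.0)):
            cdf = norm.cdf(edges - mu)
            cell = np.diff(cdf)
            p_r1 = cdf[self.k]            # P(x < meta_c | stimulus)
            p_r2 = 1.0 - p_r1
            cond = np.concatenate([cell[:self.k] / max(p_r1, 1e-300),
                                   cell[self.k:] / max(p_r2, 1e-300)])
            out[s] = np.log(np.clip(cond, 1e-300, None))
        return out

    def loglike(self, theta: np.ndarray) -> float:
        meta_d, crit_r1, crit_r2 = self._unpack(theta)
        return float((self.counts.counts * self._cell_log_probs(
            meta_d, crit_r1, crit_r2)).sum())

    def _initial_theta(self) -> np.ndarray:
        k, t1 = self.k, self.type1
        # observed criteria relative to c, reused as type-2 spacings
        crit = t1.criteria
        inc_hi = np.diff(np.concatenate([[t1.c], crit[k:]]))
        inc_lo = np.diff(np.concatenate([crit[:k - 1], [t1.c]]))[::-1]
        inc_hi = np.clip(inc_hi, 0.05, None)
        inc_lo = np.clip(inc_lo, 0.05, None)
        return np.concatenate([[t1.d_prime], np.log(inc_lo), np.log(inc_hi)])

    def fit(self, tol: float = 1e-6, maxiter: int | None = None) -> MetaDPrimeResults:
        """Maximize the type-2 likelihood (derivative-free simplex).

        Criterion ordering is enforced by construction through a
        log-increment reparameterization.
        """
        t1 = self.type1
        theta0 = self._initial_theta()
        res = minimize(lambda th: -self.loglike(th), theta0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": tol,
                                "maxiter": maxiter or 400 * theta0.size,
                                "maxfev": maxiter or 400 * theta0.size})
        if not res.success:
            warnings.warn(f"meta-d' optimizer did not fully converge: "
                          f"{res.message}", stacklevel=2)
        meta_d, crit_r1, crit_r2 = self._unpack(res.x)
        return MetaDPrimeResults(
            meta_d=float(meta_d), meta_c=float(meta_d * self._c_ratio),
            d_prime=t1.d_prime, c=t1.c, k=self.k,
            t2_criteria_r1=crit_r1, t2_criteria_r2=crit_r2,
            log_likelihood=-float(res.fun), converged=bool(res.success),
            n_iterations=int(res.nit))
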