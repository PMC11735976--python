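"""Equal-variance signal detection theory on confidence-rating data.

Trials are summarized as a 2 x 2k table of *signed confidence* counts per
stimulus: a response for category 1 with confidence j occupies cell -j, a
response for category 2 with confidence j occupies cell +j, so the cell
order -k, ..., -1, +1, ..., +k simultaneously encodes the decision and the
rating.  Sensitivity is d' = z(HR) - z(FAR) and every decision/confidence
criterion is located at c_i = -(z(HR_i) + z(FAR_i))/2, where HR_i and FAR_i
are the probabilities that signed confidence falls above the i-th cell
boundary given stimulus 2 and stimulus 1 respectively (i = -(k-1), ...,
k-1; i = 0 is the decision criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .trials import TrialTable, ValidationError

__all__ = [
    "RatingCounts",
    "Type1Fit",
    "PredictedJoint",
    "EstimationError",
    "tabulate_ratings",
    "fit_type1",
    "predict_joint",
    "cumulative_rates",
]


class EstimationError(RuntimeError):
    """A fit could not be computed from the given table."""


@dataclass(frozen=True)
class RatingCounts:
    """2 x 2k signed-confidence count table (the sufficient statistic).

    ``counts[s, j]`` is the number of trials with stimulus s+1 falling in
    signed-confidence cell j, cells ordered -k, ..., -1, +1, ..., +k.
    """

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (2, 2 * self.k):
            raise ValidationError(f"counts must be 2 x {2 * self.k}, got {c.shape}")
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    @property
    def cell_values(self) -> np.ndarray:
        """Signed-confidence value of each column."""
        k = self.k
        return np.concatenate([np.arange(-k, 0), np.arange(1, k + 1)])

    def accuracy_by_confidence(self) -> np.ndarray:
        """Collapse to a 2 x k (error/correct x confidence level) table."""
        k = self.k
        neg = self.counts[:, :k][:, ::-1]  # columns now confidence 1..k, response 1
        pos = self.counts[:, k:]           # confidence 1..k, response 2
        correct = neg[0] + pos[1]          # response == stimulus
        error = pos[0] + neg[1]
        return np.vstack([error, correct])

    def mirrored(self) -> "RatingCounts":
        """Swap stimulus labels and mirror cells (response-label swap)."""
        return RatingCounts(self.k, self.counts[::-1, ::-1].copy())


@dataclass(frozen=True)
class Type1Fit:
    """Type-1 SDT parameters estimated from cumulative rating rates."""

    k: int
    d_prime: float
    c: float
    criteria: np.ndarray      # length 2k-1, strictly increasing; index k-1 is c
    hr_i: np.ndarray          # cumulative hit rates, i = -(k-1)..(k-1)
    far_i: np.ndarray
    correction_applied: bool


@dataclass(frozen=True)
class PredictedJoint:
    """Model-implied 2 x 2k cell probabilities under the fitted observer."""

    k: int
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (2, 2 * self.k):
            raise ValidationError(f"p must be 2 x {2 * self.k}")
        if (p < -1e-15).any():
            raise ValidationError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("stimulus rows must sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def counts(self) -> np.ndarray:  # duck-type with RatingCounts where useful
        return self.p

    @property
    def cell_values(self) -> np.ndarray:
        k = self.k
        return np.concatenate([np.arange(-k, 0), np.arange(1, k + 1)])

    def accuracy_by_confidence(self) -> np.ndarray:
        k = self.k
        neg = self.p[:, :k][:, ::-1]
        pos = self.p[:, k:]
        correct = neg[0] + pos[1]
        error = pos[0] + neg[1]
        return np.vstack([error, correct])


def dump_table_csv(table: RatingCounts | PredictedJoint, path) -> None:
    """Write a 2 x 2k table as a labeled CSV matrix (debugging/fixtures)."""
    import pandas as pd

    raw = table.counts if isinstance(table, RatingCounts) else table.p
    cols = [f"{'+' if v > 0 else ''}{v}" for v in table.cell_values]
    frame = pd.DataFrame(raw, index=["stimulus_1", "stimulus_2"], columns=cols)
    frame.to_csv(path, index_label="row")


def tabulate_ratings(trials: TrialTable) -> RatingCounts:
    """Cross-tabulate trials into the 2 x 2k signed-confidence table."""
    k = trials.scale_points
    stim = trials.df["stimulus"].to_numpy()
    resp = trials.df["response"].to_numpy()
    conf = trials.df["confidence"].to_numpy()
    signed = np.where(resp == 2, conf, -conf)
    # column index: -k..-1 -> 0..k-1 ; +1..+k -> k..2k-1
    col = np.where(signed > 0, signed + k - 1, signed + k)
    counts = np.zeros((2, 2 * k))
    np.add.at(counts, (stim - 1, col), 1.0)
    return RatingCounts(k, counts)


def _pad_if_needed(counts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Cell padding that keeps all cumulative rates strictly inside (0, 1).

    When any cumulative rate is exactly 0 or 1, 1/(2 * 2k) is added to every
    cell of both stimulus rows (the standard padding of the meta-d' toolbox).
    """
    n_cells = counts.shape[1]
    cum = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1]
    upper = cum[:, 1:]          # mass strictly above each interior boundary
    totals = counts.sum(axis=1, keepdims=True)
    if (upper == 0).any() or (upper == totals).any():
        return counts + 1.0 / (2 * n_cells), True
    return counts, False


def _rates_from_array(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    totals = raw.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise EstimationError("a stimulus row has zero trials")
    cum_above = np.cumsum(raw[:, ::-1], axis=1)[:, ::-1][:, 1:] / totals
    return cum_above[1], cum_above[0]  # hr_i, far_i


def cumulative_rates(table: RatingCounts | PredictedJoint) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative rates HR_i, FAR_i above each of the 2k-1 cell boundaries.

    ``hr_i[j]`` is the proportion of stimulus-2 trials whose signed
    confidence lies above boundary j (between ordered cells j and j+1);
    boundary index j = 0..2k-2 corresponds to i = -(k-1)..(k-1).
    """
    raw = table.counts if isinstance(table, RatingCounts) else table.p
    return _rates_from_array(raw)


def fit_type1(counts: RatingCounts) -> Type1Fit:
    """Estimate d', the decision criterion c, and all confidence criteria.

    Rates of exactly 0 or 1 are padded first so every probit transform is
    finite; criteria left non-monotone by empirical ties are separated by a
    minimal epsilon with a warning.
    """
    if (counts.counts.sum(axis=1) == 0).any():
        raise EstimationError("both stimulus rows must contain trials")
    padded, applied = _pad_if_needed(counts.counts)
    hr_i, far_i = _rates_from_array(padded)
    z_hr, z_far = norm.ppf(hr_i), norm.ppf(far_i)
    criteria = -(z_hr + z_far) / 2.0
    k = counts.k
    d_prime = float(z_hr[k - 1] - z_far[k - 1])
    c = float(criteria[k - 1])
    if not (np.diff(criteria) > 0).all():
        warnings.warn("non-monotone empirical criteria; enforcing strict "
                      "ordering with epsilon 1e-6", stacklevel=2)
        criteria = np.maximum.accumulate(criteria)
        criteria = criteria + np.arange(criteria.size) * 1e-6
    return Type1Fit(k=k, d_prime=d_prime, c=c, criteria=criteria,
                    hr_i=hr_i, far_i=far_i, correction_applied=applied)


def predict_joint(fit: Type1Fit) -> PredictedJoint:
    """Cell probabilities for the fitted equal-variance Gaussian observer.

    Stimulus means are placed symmetrically at -d'/2 (stimulus 1) and +d'/2
    (stimulus 2) with unit variance; each cell's probability is the normal
    mass between adjacent criteria, outer cells unbounded.
    """
    if not (np.diff(fit.criteria) > 0).all():
        raise EstimationError("criteria must be strictly increasing")
    edges = np.concatenate([[-np.inf], fit.criteria, [np.inf]])
    p = np.empty((2, 2 * fit.k))
    for s, mu in enumerate((-fit.d_prime / 2.0, fit.d_prime / 2.0)):
        cdf = norm.cdf(edges - mu)
        p[s] = np.diff(cdf)
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return PredictedJoint(fit.k, p)
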