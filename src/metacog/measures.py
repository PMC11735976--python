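"""The 17 measures of metacognitive ability.

Four traditional measures quantify how well confidence discriminates
correct from incorrect decisions:

* ``AUC2`` — area under the type-2 ROC (type-2 hit rate P(conf >= j |
  correct) against type-2 false-alarm rate P(conf >= j | error)).
* ``Gamma`` — Goodman-Kruskal rank correlation between confidence and
  accuracy, (C - D)/(C + D) over concordant/discordant trial pairs.
* ``Phi`` — Pearson correlation between binary accuracy and confidence.
* ``DeltaConf`` — mean confidence on correct minus mean confidence on
  error trials.

All four are known to rise with task performance, so each is also computed
a second time from the joint response-confidence distribution an ideal
equal-variance SDT observer with the same d' and criteria would produce
("expected" value), yielding ratio (observed/expected) and difference
(observed - expected) variants.  The meta-d' family (meta-d', M-Ratio,
M-Diff) applies the same normalization idea via a type-2 maximum-likelihood
fit, and two process-model measures (meta-noise, meta-uncertainty) are
delegated to :mod:`metacog.process_models`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sdt import (PredictedJoint, RatingCounts, Type1Fit, fit_type1,
                  predict_joint, tabulate_ratings)
from .trials import TrialTable

__all__ = [
    "MEASURES",
    "BASIC_MEASURES",
    "MeasureValue",
    "MeasureOptions",
    "basic_measure",
    "expected_measure",
    "normalized_measure",
    "fit_meta_d",
    "compute_all",
]

BASIC_MEASURES = ("AUC2", "Gamma", "Phi", "DeltaConf")

#: the 17 measure labels, in canonical order
MEASURES = (
    "meta-d'", "AUC2", "Gamma", "Phi", "DeltaConf",
    "M-Ratio", "AUC2-Ratio", "Gamma-Ratio", "Phi-Ratio", "DeltaConf-Ratio",
    "M-Diff", "AUC2-Diff", "Gamma-Diff", "Phi-Diff", "DeltaConf-Diff",
    "meta-noise", "meta-uncertainty",
)

#: denominator threshold below which a ratio measure is flagged unstable
RATIO_EPS = 1e-3

#: +1 where larger values mean better metacognition; -1 for the two noise
#: parameters (larger noise = worse metacognition).  Validity/precision
#: analyses orient measures by this sign so a corruption-induced loss of
#: metacognitive information registers as a decrease for every measure.
MEASURE_DIRECTION = {name: 1 for name in MEASURES}
MEASURE_DIRECTION["meta-noise"] = -1
MEASURE_DIRECTION["meta-uncertainty"] = -1


@dataclass(frozen=True)
class MeasureValue:
    """A named metacognitive score with its components and validity flags."""

    name: str
    value: float
    observed: float | None = None
    expected: float | None = None
    unstable: bool = False
    notes: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


@dataclass(frozen=True)
class MeasureOptions:
    """Fitting options shared by :func:`compute_all`."""

    include_process_models: bool = True
    n_restarts: int = 5
    quadrature_nodes: int = 61


# ---------------------------------------------------------------------------
# traditional measures on an accuracy x confidence distribution

def _acc_conf_table(data: RatingCounts | PredictedJoint) -> np.ndarray:
    return data.accuracy_by_confidence()


def _auc2(w: np.ndarray) -> float:
    err, cor = w[0], w[1]
    if err.sum() <= 0 or cor.sum() <= 0:
        return np.nan
    # type-2 rates above each confidence threshold j = 2..k, plus (0,0), (1,1)
    h2 = np.cumsum(cor[::-1])[::-1][1:] / cor.sum()
    f2 = np.cumsum(err[::-1])[::-1][1:] / err.sum()
    x = np.concatenate([[0.0], f2[::-1], [1.0]])
    y = np.concatenate([[0.0], h2[::-1], [1.0]])
    return float(np.trapezoid(y, x))


def _gamma(w: np.ndarray) -> float:
    err, cor = w[0], w[1]
    below_err = np.concatenate([[0.0], np.cumsum(err)[:-1]])
    above_err = err.sum() - np.cumsum(err)
    concordant = float((cor * below_err).sum())   # correct has higher conf
    discordant = float((cor * above_err).sum())
    if concordant + discordant == 0:
        return np.nan
    return (concordant - discordant) / (concordant + discordant)


def _phi(w: np.ndarray) -> float:
    total = w.sum()
    if w[0].sum() <= 0 or w[1].sum() <= 0:
        return np.nan
    p = w / total
    conf = np.arange(1, w.shape[1] + 1, dtype=float)
    p_acc = p.sum(axis=1)           # P(error), P(correct)
    p_conf = p.sum(axis=0)
    mean_a = p_acc[1]
    mean_c = float(conf @ p_conf)
    var_a = mean_a * (1 - mean_a)
    var_c = float((conf - mean_c) ** 2 @ p_conf)
    if var_a <= 0 or var_c <= 0:
        return np.nan
    cov = float(conf @ p[1]) - mean_a * mean_c
    return cov / np.sqrt(var_a * var_c)


def _delta_conf(w: np.ndarray) -> float:
    err, cor = w[0], w[1]
    if err.sum() <= 0 or cor.sum() <= 0:
        return np.nan
    conf = np.arange(1, w.shape[1] + 1, dtype=float)
    return float(conf @ cor / cor.sum() - conf @ err / err.sum())


_BASIC_FUNCS = {"AUC2": _auc2, "Gamma": _gamma, "Phi": _phi,
                "DeltaConf": _delta_conf}


def basic_measure(name: str, data: RatingCounts | PredictedJoint) -> MeasureValue:
    """Compute AUC2, Gamma, Phi or DeltaConf from a rating table.

    On count tables this is the empirical statistic; on probability tables
    it is the exact expectation of the same statistic under that
    distribution.  Measures that require both correct and error mass return
    a flagged NaN when one class is empty.
    """
    if name not in _BASIC_FUNCS:
        raise ValueError(f"unknown basic measure {name!r}")
    value = _BASIC_FUNCS[name](_acc_conf_table(data))
    notes = "" if np.isfinite(value) else "undefined on this table"
    return MeasureValue(name=name, value=float(value), observed=float(value),
                        notes=notes)


def expected_measure(name: str, fit: Type1Fit) -> MeasureValue:
    """The value of a traditional measure implied by the fitted SDT observer."""
    mv = basic_measure(name, predict_joint(fit))
    return MeasureValue(name=f"{name}-expected", value=mv.value,
                        expected=mv.value, notes=mv.notes)


def normalized_measure(name: str, trials: TrialTable) -> MeasureValue:
    """Ratio or difference variant of a traditional measure.

    ``<M>-Ratio`` is observed/expected and ``<M>-Diff`` observed - expected,
    both taken on the raw statistics.  Ratios whose expected value is within
    ``RATIO_EPS`` of zero are flagged unstable.
    """
    base, kind = name.rsplit("-", 1)
    if base not in BASIC_MEASURES or kind not in ("Ratio", "Diff"):
        raise ValueError(f"unknown normalized measure {name!r}")
    counts = tabulate_ratings(trials)
    observed = basic_measure(base, counts).value
    fit = fit_type1(counts)
    expected = basic_measure(base, predict_joint(fit)).value
    unstable = False
    notes = ""
    if not (np.isfinite(observed) and np.isfinite(expected)):
        value = np.nan
        notes = "undefined component"
    elif kind == "Diff":
        value = observed - expected
    else:
        if abs(expected) < RATIO_EPS:
            unstable = True
            notes = f"expected value {expected:.2g} below stability threshold"
            warnings.warn(f"{name}: {notes}", stacklevel=2)
        value = observed / expected if expected != 0 else np.nan
    return MeasureValue(name=name, value=float(value), observed=observed,
                        expected=expected, unstable=unstable, notes=notes)


def fit_meta_d(counts: RatingCounts, **kwargs) -> tuple[float, float, float]:
    """Convenience wrapper: (meta-d', M-Ratio, M-Diff) for a count table."""
    from .metad import MetaDPrimeModel

    res = MetaDPrimeModel(counts).fit(**kwargs)
    return res.meta_d, res.m_ratio, res.m_diff


def compute_measure(name: str, trials: TrialTable,
                    options: MeasureOptions | None = None) -> MeasureValue:
    """Compute a single named measure (cheaper than :func:`compute_all`
    when only one is needed, e.g. inside per-bin assessment loops)."""
    from .metad import MetaDPrimeModel
    from .process_models import fit_meta_noise, fit_meta_uncertainty

    options = options or MeasureOptions()
    if name in BASIC_MEASURES:
        return basic_measure(name, tabulate_ratings(trials))
    if name in {f"{b}-{k}" for b in BASIC_MEASURES for k in ("Ratio", "Diff")}:
        return normalized_measure(name, trials)
    if name in ("meta-d'", "M-Ratio", "M-Diff"):
        res = MetaDPrimeModel(tabulate_ratings(trials)).fit()
        value = {"meta-d'": res.meta_d, "M-Ratio": res.m_ratio,
                 "M-Diff": res.m_diff}[name]
        return MeasureValue(name, value, observed=res.meta_d,
                            expected=res.d_prime,
                            unstable=(name == "M-Ratio"
                                      and res.d_prime <= RATIO_EPS))
    if name == "meta-noise":
        fit = fit_meta_noise(tabulate_ratings(trials),
                             n_restarts=options.n_restarts,
                             n_nodes=options.quadrature_nodes)
        return MeasureValue(name, fit.params.sigma_meta)
    if name == "meta-uncertainty":
        fit = fit_meta_uncertainty(tabulate_ratings(trials),
                                   n_restarts=options.n_restarts,
                                   n_nodes=options.quadrature_nodes)
        return MeasureValue(name, fit.params.meta_uncertainty)
    raise ValueError(f"unknown measure {name!r}")


def compute_all(trials: TrialTable,
                options: MeasureOptions | None = None) -> dict[str, MeasureValue]:
    """All 17 measures for one set of trials.

    Per-measure failures are reported as flagged NaN entries; the batch
    never aborts.
    """
    from .metad import MetaDPrimeModel
    from .process_models import fit_meta_noise, fit_meta_uncertainty

    options = options or MeasureOptions()
    out: dict[str, MeasureValue] = {}
    counts = tabulate_ratings(trials)

    def _guard(name, fn):
        try:
            out[name] = fn()
        except Exception as exc:  # flagged, not fatal
            out[name] = MeasureValue(name=name, value=np.nan,
                                     notes=f"failed: {exc}")

    for base in BASIC_MEASURES:
        _guard(base, lambda b=base: basic_measure(b, counts))
        for kind in ("Ratio", "Diff"):
            _guard(f"{base}-{kind}",
                   lambda b=base, k=kind: normalized_measure(f"{b}-{k}", trials))

    def _meta_d_family():
        res = MetaDPrimeModel(counts).fit()
        out["meta-d'"] = MeasureValue("meta-d'", res.meta_d, observed=res.meta_d)
        out["M-Ratio"] = MeasureValue("M-Ratio", res.m_ratio,
                                      observed=res.meta_d, expected=res.d_prime,
                                      unstable=res.d_prime <= RATIO_EPS)
        out["M-Diff"] = MeasureValue("M-Diff", res.m_diff,
                                     observed=res.meta_d, expected=res.d_prime)
        return None

    try:
        _meta_d_family()
    except Exception as exc:
        for name in ("meta-d'", "M-Ratio", "M-Diff"):
            out[name] = MeasureValue(name=name, value=np.nan,
                                     notes=f"failed: {exc}")

    if options.include_process_models:
        _guard("meta-noise", lambda: MeasureValue(
            "meta-noise",
            fit_meta_noise(counts, n_restarts=options.n_restarts,
                           n_nodes=options.quadrature_nodes).params.sigma_meta))
        _guard("meta-uncertainty", lambda: MeasureValue(
            "meta-uncertainty",
            fit_meta_uncertainty(counts, n_restarts=options.n_restarts,
                                 n_nodes=options.quadrature_nodes).params.meta_uncertainty))
    else:
        for name in ("meta-noise", "meta-uncertainty"):
            out[name] = MeasureValue(name=name, value=np.nan,
                                     notes="process models disabled")
    return {name: out[name] for name in MEASURES}
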