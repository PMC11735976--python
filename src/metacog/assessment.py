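"""Psychometric assessment battery for measures of metacognition.

Four families of checks, each applicable to any per-trial measure:

* **Validity / precision** — a deterministic corruption that nudges
  confidence away from accuracy (correct trials down one point, error
  trials up one point, walking trials in order until a preset proportion
  is reached).  A valid measure must drop; the drop in units of the
  measure's own across-bin standard deviation is its precision.
* **Nuisance dependence** — effect sizes (Cohen's d, repeated-measures
  ANOVA partial eta^2, correlation with |c|) for task performance,
  metacognitive bias (via confidence recoding), and response bias.
* **Split-half reliability** — across-participant Pearson correlation of
  the measure computed on odd vs even trials, Fisher-z averaged over bins.
* **Test-retest reliability** — two-way absolute-agreement intraclass
  correlation ICC(A,1) (and Pearson r) across pairs of days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trials import TrialTable, ValidationError, make_bins

__all__ = [
    "PrecisionResult",
    "DependenceResult",
    "ReliabilityResult",
    "corrupt_confidence",
    "precision_score",
    "normalize_precision",
    "recode_bias",
    "split_half",
    "icc_a1",
    "test_retest",
    "dependence_report",
    "difficulty_median_split",
    "fisher_average",
]

#: a measure function maps a TrialTable to a scalar (NaN when undefined)
MeasureFn = Callable[[TrialTable], float]


@dataclass(frozen=True)
class PrecisionResult:
    """Corruption-based precision of one measure at one bin size."""

    measure: str
    bin_size: int
    corruption_level: float
    precision: float
    sd_orig: float
    n_bins: int
    per_bin_orig: np.ndarray
    per_bin_corrupted: np.ndarray
    n_dropped: int = 0


@dataclass(frozen=True)
class DependenceResult:
    """Effect of one nuisance factor on one measure."""

    measure: str
    factor: str
    cohens_d: float = np.nan
    t_stat: float = np.nan
    dof: float = np.nan
    p_value: float = np.nan
    direction: int = 0
    f_stat: float = np.nan
    partial_eta_sq: float = np.nan
    mean_abs_c_correlation: float = np.nan


@dataclass(frozen=True)
class ReliabilityResult:
    """Reliability coefficient for one measure at one bin size."""

    measure: str
    bin_size: int
    kind: str                 # split_half | test_retest_icc | test_retest_pearson
    coefficient: float
    n_pairs: int


# ---------------------------------------------------------------------------
# corruption and recoding

def corrupt_confidence(trials: TrialTable,
                       proportion: float) -> tuple[TrialTable, int]:
    """Deterministically corrupt a proportion of trials.

    Walking trials from the first in stored order: a correct trial with
    confidence above 1 is decreased by one point; an incorrect trial with
    confidence below k is increased by one point; other trials are skipped.
    The walk stops once round(proportion * n) corruptions have been made.
    Returns the corrupted table and the actual corruption count (smaller
    than the target, with a warning, when corruptible trials run out).
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValidationError("proportion must be in [0, 1]")
    n = trials.n_trials
    target = int(round(proportion * n))
    if target == 0:
        return trials, 0
    k = trials.scale_points
    conf = trials.df["confidence"].to_numpy().copy()
    acc = trials.accuracy
    corruptible = np.where(acc, conf > 1, conf < k)
    idx = np.flatnonzero(corruptible)[:target]
    conf[idx] = np.where(acc[idx], conf[idx] - 1, conf[idx] + 1)
    if idx.size < target:
        warnings.warn(f"only {idx.size} of {target} requested corruptions "
                      "were possible", stacklevel=2)
    df = trials.df.copy()
    df["confidence"] = conf
    return trials.with_df(df), int(idx.size)


def recode_bias(trials: TrialTable, direction: str) -> TrialTable:
    """Recode a k-point scale to k-1 points, inducing a confidence bias.

    ``low`` decreases every rating above 1 by one point (bias toward low
    confidence); ``high`` only folds the top rating k into k-1 (bias toward
    high confidence).  Trial count and accuracy are untouched; only the
    confidence marginal changes.
    """
    k = trials.scale_points
    if direction not in ("low", "high"):
        raise ValidationError("direction must be 'low' or 'high'")
    if k == 2 and direction == "low":
        warnings.warn("recoding a 2-point scale to a single level is "
                      "degenerate", stacklevel=2)
    df = trials.df.copy()
    conf = df["confidence"].to_numpy()
    if direction == "low":
        df["confidence"] = np.maximum(conf - 1, 1)
    else:
        df["confidence"] = np.minimum(conf, k - 1)
    return trials.with_df(df, max(k - 1, 1))


# ---------------------------------------------------------------------------
# precision

def precision_score(measure: str, bins: Sequence[TrialTable],
                    proportion: float, measure_fn: MeasureFn,
                    ) -> PrecisionResult:
    """Corruption-drop precision of a measure over a set of trial bins.

    precision = mean_i (orig_i - corrupted_i) / SD, where SD is the sample
    standard deviation of the uncorrupted per-bin values.  Positive values
    certify validity; larger values mean higher precision.  Bins on which
    the measure is undefined in either version are dropped with a log.
    """
    if len(bins) < 2:
        raise ValidationError("need at least 2 bins to estimate the SD")
    orig, corr = [], []
    for b in bins:
        corrupted, _ = corrupt_confidence(b, proportion)
        orig.append(measure_fn(b))
        corr.append(measure_fn(corrupted))
    orig, corr = np.asarray(orig, float), np.asarray(corr, float)
    ok = np.isfinite(orig) & np.isfinite(corr)
    n_dropped = int((~ok).sum())
    if ok.sum() == 0:
        raise ValidationError("measure undefined on every bin")
    if n_dropped:
        warnings.warn(f"{measure}: dropped {n_dropped} undefined bins",
                      stacklevel=2)
    orig, corr = orig[ok], corr[ok]
    sd = float(np.std(orig, ddof=1))
    precision = float(np.mean(orig - corr) / sd) if sd > 0 else np.nan
    bin_size = bins[0].n_trials
    return PrecisionResult(measure=measure, bin_size=bin_size,
                           corruption_level=proportion, precision=precision,
                           sd_orig=sd, n_bins=int(ok.sum()),
                           per_bin_orig=orig, per_bin_corrupted=corr,
                           n_dropped=n_dropped)


def normalize_precision(per_measure: dict[str, float],
                        reference_excludes: tuple = ("meta-uncertainty",),
                        ) -> dict[str, float]:
    """Rescale precision scores so the reference measures average to 1.

    The reference set excludes meta-uncertainty (the one measure whose
    precision stands apart), so its normalized score reads directly as a
    fraction of the consensus precision level.
    """
    if len(per_measure) < 2:
        raise ValidationError("need at least 2 measures")
    ref = [v for k, v in per_measure.items() if k not in reference_excludes]
    denom = float(np.mean(ref))
    if denom == 0:
        raise ValidationError("reference precision mean is zero")
    return {k: v / denom for k, v in per_measure.items()}


# ---------------------------------------------------------------------------
# reliability

def fisher_average(r_values: Sequence[float]) -> float:
    """Back-transformed mean Fisher z of correlation coefficients."""
    r = np.asarray([v for v in r_values if np.isfinite(v)], dtype=float)
    if r.size == 0:
        return np.nan
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    out = float(np.tanh(np.mean(np.arctanh(r))))
    return round(out, 15)  # snap 1 - O(1e-16) artifacts back to exact r


def icc_a1(scores: np.ndarray) -> float:
    """Two-way absolute-agreement single-measure ICC, ICC(A,1).

    ``scores`` is an n x m table of participants by occasions (m = 2 for a
    day pair).  Unlike Pearson r, ICC(A,1) penalizes occasion-to-occasion
    mean shifts through the column mean square.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValidationError("scores must be n x m with n >= 3")
    if np.isnan(x).any():
        raise ValidationError("scores must have no missing cells")
    n, m = x.shape
    grand = x.mean()
    ss_rows = m * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (m - 1)
    ms_err = ss_err / ((n - 1) * (m - 1))
    denom = ms_rows + (m - 1) * ms_err + (m / n) * (ms_cols - ms_err)
    if denom == 0:
        warnings.warn("zero between-row variance; ICC undefined", stacklevel=2)
        return np.nan
    return float((ms_rows - ms_err) / denom)


def split_half(measure: str, trials: TrialTable, bin_size: int,
               measure_fn: MeasureFn) -> ReliabilityResult:
    """Odd/even split-half reliability across participants.

    Each participant's trials are cut into non-overlapping bins of
    2*bin_size; within each bin, odd-position trials form half A and
    even-position trials half B, each half of size bin_size.  The measure
    is computed per half; for each bin index a Pearson r is taken across
    participants, and the r values are Fisher-z averaged.
    """
    pids = trials.participants
    if len(pids) < 3:
        raise ValidationError("need at least 3 participants")
    values: dict[int, dict] = {}
    for pid in pids:
        sub = trials.for_participant(pid)
        bins = make_bins(sub, 2 * bin_size)
        for b_idx, b in enumerate(bins):
            half_a = b.with_df(b.df.iloc[0::2])
            half_b = b.with_df(b.df.iloc[1::2])
            va, vb = measure_fn(half_a), measure_fn(half_b)
            if np.isfinite(va) and np.isfinite(vb):
                values.setdefault(b_idx, {})[pid] = (va, vb)
    r_values, n_pairs = [], 0
    for b_idx, d in sorted(values.items()):
        if len(d) < 3:
            continue
        arr = np.array(list(d.values()))
        if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
            continue
        r_values.append(float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]))
        n_pairs += len(d)
    return ReliabilityResult(measure=measure, bin_size=bin_size,
                             kind="split_half",
                             coefficient=fisher_average(r_values),
                             n_pairs=n_pairs)


def test_retest(measure: str, trials: TrialTable, bin_size: int,
                measure_fn: MeasureFn) -> tuple[ReliabilityResult, ReliabilityResult]:
    """Test-retest reliability across days: ICC(A,1) and Pearson variants.

    For every pair of days and every bin index available on both days, the
    measure is computed per participant per day on that day's bin of
    ``bin_size`` trials; coefficients across participants are Fisher-z
    averaged over bin indices and day pairs.
    """
    if "day" not in trials.df.columns:
        raise ValidationError("test-retest requires day labels")
    days = sorted(pd.unique(trials.df["day"]))
    if len(days) < 2:
        raise ValidationError("need at least 2 days")
    pids = trials.participants
    # value[day][bin_idx][pid]
    values: dict = {d: {} for d in days}
    for pid in pids:
        sub = trials.for_participant(pid)
        for d in days:
            day_trials = sub.select(sub.df["day"] == d)
            if day_trials.n_trials < bin_size:
                continue
            for b_idx, b in enumerate(make_bins(day_trials, bin_size)):
                v = measure_fn(b)
                if np.isfinite(v):
                    values[d].setdefault(b_idx, {})[pid] = v
    icc_vals, r_vals, n_pairs = [], [], 0
    for d1, d2 in combinations(days, 2):
        shared_bins = set(values[d1]) & set(values[d2])
        for b_idx in sorted(shared_bins):
            common = sorted(set(values[d1][b_idx]) & set(values[d2][b_idx]),
                            key=str)
            if len(common) < 3:
                continue
            a = np.array([values[d1][b_idx][p] for p in common])
            b = np.array([values[d2][b_idx][p] for p in common])
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            icc_vals.append(icc_a1(np.column_stack([a, b])))
            r_vals.append(float(np.corrcoef(a, b)[0, 1]))
            n_pairs += len(common)
    return (ReliabilityResult(measure, bin_size, "test_retest_icc",
                              fisher_average(icc_vals), n_pairs),
            ReliabilityResult(measure, bin_size, "test_retest_pearson",
                              fisher_average(r_vals), n_pairs))


# ---------------------------------------------------------------------------
# nuisance dependence

def _drop_3sd_outliers(df: pd.DataFrame) -> pd.DataFrame:
    keep = pd.Series(True, index=df.index)
    for _, grp in df.groupby("level", sort=False):
        v = grp["value"]
        sd = v.std(ddof=1)
        if np.isfinite(sd) and sd > 0:
            keep.loc[grp.index] = (v - v.mean()).abs() <= 3 * sd
    return df[keep]


def dependence_report(values: pd.DataFrame, measure: str, factor: str,
                      design: str) -> DependenceResult:
    """Nuisance-dependence effect sizes for one measure.

    ``values`` is tidy: columns ``participant``, ``level``, ``value`` (and
    ``c`` for the ``abs_c_correlation`` design).  Designs:

    * ``two_level_ttest`` — paired t-test between the lowest and highest
      level, after removing per-level 3-SD outliers; Cohen's d from the
      pooled SD of the two level distributions.
    * ``rm_anova`` — repeated-measures ANOVA over all levels; partial
      eta^2 = SS_effect / (SS_effect + SS_error).
    * ``abs_c_correlation`` — per-participant Pearson r between the
      measure and |c| over levels, Fisher-z averaged.
    """
    required = {"participant", "level", "value"}
    if not required <= set(values.columns):
        raise ValidationError(f"values needs columns {sorted(required)}")
    if design == "two_level_ttest":
        levels = sorted(pd.unique(values["level"]))
        lo, hi = levels[0], levels[-1]
        df = values[values["level"].isin([lo, hi])].copy()
        df = _drop_3sd_outliers(df)
        wide = df.pivot_table(index="participant", columns="level",
                              values="value").dropna()
        if len(wide) < 3:
            raise ValidationError("fewer than 3 retained participants")
        a, b = wide[lo].to_numpy(), wide[hi].to_numpy()
        t, p = stats.ttest_rel(a, b)
        s_pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        d = float((a.mean() - b.mean()) / s_pooled) if s_pooled > 0 else np.nan
        return DependenceResult(measure=measure, factor=factor,
                                cohens_d=d, t_stat=float(t),
                                dof=float(len(wide) - 1), p_value=float(p),
                                direction=int(np.sign(d)) if np.isfinite(d) else 0)
    if design == "rm_anova":
        import pingouin as pg

        wide = values.pivot_table(index="participant", columns="level",
                                  values="value").dropna()
        if len(wide) < 3:
            raise ValidationError("fewer than 3 retained participants")
        long = wide.reset_index().melt(id_vars="participant",
                                       var_name="level", value_name="value")
        aov = pg.rm_anova(data=long, dv="value", within="level",
                          subject="participant", detailed=True,
                          effsize="np2")
        row = aov.iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        return DependenceResult(measure=measure, factor=factor,
                                f_stat=float(row["F"]),
                                dof=float(row["DF"]),
                                p_value=float(row[p_col]),
                                partial_eta_sq=float(row["np2"]))
    if design == "abs_c_correlation":
        if "c" not in values.columns:
            raise ValidationError("abs_c_correlation needs a 'c' column")
        rs = []
        for _, grp in values.groupby("participant", sort=False):
            if len(grp) < 3:
                continue
            v, ac = grp["value"].to_numpy(), np.abs(grp["c"].to_numpy())
            if np.std(v) == 0 or np.std(ac) == 0:
                continue
            rs.append(float(np.corrcoef(v, ac)[0, 1]))
        if len(rs) < 3:
            raise ValidationError("fewer than 3 retained participants")
        return DependenceResult(measure=measure, factor=factor,
                                mean_abs_c_correlation=fisher_average(rs))
    raise ValidationError(f"unknown design {design!r}")


def difficulty_median_split(trials: TrialTable) -> TrialTable:
    """Median-split numeric difficulty labels into difficult vs easy.

    Trials at or below the per-participant median difficulty are labeled
    ``difficult`` and the rest ``easy`` (the convention for stimulus
    manipulations where a larger difference value means an easier trial).
    Rank-based, hence invariant to affine relabeling of difficulty.
    """
    if "difficulty" not in trials.df.columns:
        raise ValidationError("no difficulty labels present")
    df = trials.df.copy()
    diff = pd.to_numeric(df["difficulty"])
    labels = pd.Series(index=df.index, dtype=object)
    for pid, grp in df.groupby("participant", sort=False):
        d = diff.loc[grp.index]
        if d.nunique() < 2:
            raise ValidationError(
                f"participant {pid!r} has constant difficulty")
        med = d.median()
        labels.loc[grp.index] = np.where(d <= med, "difficult", "easy")
    df["difficulty"] = labels
    return trials.with_df(df)
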