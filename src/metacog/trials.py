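"""Trial-level confidence data: containers, readers, filters, and binning.

The universal input to every estimator in this package is a table of
2-choice trials, one row per trial, with a stimulus category, a response
category, and a confidence rating on a k-point scale.  The on-disk format
follows the Confidence Database CSV convention (columns ``Subj_idx``,
``Stimulus``, ``Response``, ``Confidence`` plus optional ``Day``,
``Condition``, ``Difficulty``, ``Training``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialTable",
    "DatasetRecipe",
    "ExclusionReport",
    "FormatError",
    "ValidationError",
    "read_confidence_db_csv",
    "write_trials_csv",
    "merge_rating_levels",
    "bin_continuous_confidence",
    "apply_exclusions",
    "make_bins",
    "load_recipes",
    "builtin_recipes",
]

#: canonical in-memory column names
COLUMNS = ["participant", "stimulus", "response", "confidence"]
OPTIONAL_COLUMNS = ["day", "condition", "difficulty"]

#: Confidence Database header -> canonical name
_CDB_MAP = {
    "Subj_idx": "participant",
    "Stimulus": "stimulus",
    "Response": "response",
    "Confidence": "confidence",
    "Day": "day",
    "Condition": "condition",
    "Difficulty": "difficulty",
}


class FormatError(ValueError):
    """Input file does not follow the expected CSV dialect."""


class ValidationError(ValueError):
    """Trial data violate an invariant (codes, scale range, monotonicity)."""


@dataclass(frozen=True)
class TrialTable:
    """Normalized 2-choice trial data.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per trial with columns ``participant``, ``stimulus``,
        ``response`` (both coded 1/2), ``confidence`` (integer 1..k), and
        optionally ``day``, ``condition``, ``difficulty``.  Row order is
        trial order and is significant (corruption and binning walk it).
    scale_points : int
        Number of points k on the confidence scale.
    """

    df: pd.DataFrame
    scale_points: int

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        if self.scale_points < 2:
            raise ValidationError("scale_points must be >= 2")
        for col in ("stimulus", "response"):
            vals = set(pd.unique(self.df[col]))
            if not vals <= {1, 2}:
                raise ValidationError(
                    f"{col} must be coded 1/2, found {sorted(vals - {1, 2})}"
                )
        conf = self.df["confidence"].to_numpy()
        if len(conf) and (
            (conf < 1).any() or (conf > self.scale_points).any()
            or not np.array_equal(conf, conf.astype(int))
        ):
            raise ValidationError(
                f"confidence ratings must be integers in 1..{self.scale_points}"
            )

    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def participants(self) -> list:
        return list(pd.unique(self.df["participant"]))

    @property
    def accuracy(self) -> np.ndarray:
        """Boolean per-trial accuracy, derived (never stored)."""
        return (self.df["response"] == self.df["stimulus"]).to_numpy()

    def with_df(self, df: pd.DataFrame, scale_points: int | None = None) -> "TrialTable":
        return TrialTable(df.reset_index(drop=True),
                          self.scale_points if scale_points is None else scale_points)

    def select(self, mask) -> "TrialTable":
        return self.with_df(self.df[mask])

    def for_participant(self, pid) -> "TrialTable":
        return self.select(self.df["participant"] == pid)


@dataclass(frozen=True)
class DatasetRecipe:
    """Per-dataset preprocessing declaration.

    ``stimulus_coding`` maps the source file's category codes onto the
    canonical 1/2 coding (files in the wild use 0/1 or 1/2); the same map
    is applied to responses.  ``confidence_transform`` is one of ``none``,
    ``merge_levels`` (with ``mapping``) or ``bin_continuous`` (with
    ``n_levels``, ``lower``, ``upper``).
    """

    name: str
    scale_points: int | None = None
    drop_days: tuple = ()
    drop_training: bool = True
    stimulus_coding: Mapping = field(default_factory=lambda: {1: 1, 2: 2})
    confidence_transform: str = "none"
    mapping: Mapping | None = None
    n_levels: int | None = None
    lower: float | None = None
    upper: float | None = None
    conditions_to_analyze: tuple | None = None


def read_confidence_db_csv(path, recipe: DatasetRecipe) -> TrialTable:
    """Read a Confidence Database CSV and normalize it per ``recipe``.

    Staircase/practice/training trials (``Training`` column truthy) and
    dropped days are removed; stimulus/response codes are normalized to
    1/2; the confidence transform named by the recipe is applied.  Row
    order within each participant is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path)
    for col in ("Subj_idx", "Stimulus", "Response", "Confidence"):
        if col not in raw.columns:
            raise FormatError(f"missing required column: {col}")
    df = pd.DataFrame({"participant": raw["Subj_idx"]})
    coding = {int(k): int(v) for k, v in recipe.stimulus_coding.items()}
    for src, dst in (("Stimulus", "stimulus"), ("Response", "response")):
        col = pd.to_numeric(raw[src])
        unknown = set(col.unique()) - set(coding)
        if unknown:
            raise ValidationError(
                f"{src} contains codes {sorted(unknown)} not covered by "
                f"recipe {recipe.name!r} stimulus_coding"
            )
        df[dst] = col.map(coding).astype(int)
    try:
        df["confidence"] = pd.to_numeric(raw["Confidence"])
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"confidence not parseable as numeric: {exc}")
    for src, dst in (("Day", "day"), ("Condition", "condition"),
                     ("Difficulty", "difficulty")):
        if src in raw.columns:
            df[dst] = raw[src]
    keep = pd.Series(True, index=df.index)
    if recipe.drop_training and "Training" in raw.columns:
        keep &= ~raw["Training"].fillna(0).astype(bool)
    if recipe.drop_days and "day" in df.columns:
        keep &= ~df["day"].isin(list(recipe.drop_days))
    if recipe.conditions_to_analyze is not None and "condition" in df.columns:
        keep &= df["condition"].isin(list(recipe.conditions_to_analyze))
    df = df[keep].reset_index(drop=True)

    if recipe.confidence_transform == "bin_continuous":
        k = int(recipe.n_levels)
        df["confidence"] = _bin_values(df["confidence"].to_numpy(float),
                                       k, recipe.lower, recipe.upper)
        return TrialTable(df, k)
    df["confidence"] = df["confidence"].astype(int)
    if recipe.confidence_transform == "merge_levels":
        table = TrialTable(df, _infer_k(df, recipe, pre_merge=True))
        return merge_rating_levels(table, recipe.mapping)
    return TrialTable(df, _infer_k(df, recipe))


def _infer_k(df: pd.DataFrame, recipe: DatasetRecipe, pre_merge: bool = False) -> int:
    if pre_merge and recipe.mapping is not None:
        return int(max(int(x) for x in recipe.mapping))
    if recipe.scale_points is not None:
        return int(recipe.scale_points)
    return int(df["confidence"].max())


def write_trials_csv(trials: TrialTable, path) -> None:
    """Write a TrialTable with canonical column names (round-trips exactly)."""
    trials.df.to_csv(path, index=False)


def read_trials_csv(path, scale_points: int) -> TrialTable:
    """Read a canonical-column trial CSV written by :func:`write_trials_csv`."""
    return TrialTable(pd.read_csv(path), scale_points)


def merge_rating_levels(trials: TrialTable, mapping: Mapping) -> TrialTable:
    """Recode confidence levels with an order-preserving total mapping.

    Used e.g. to collapse an 11-point scale whose bottom levels are rarely
    used into a 6-point scale.
    """
    mapping = {int(k): int(v) for k, v in mapping.items()}
    observed = set(int(x) for x in pd.unique(trials.df["confidence"]))
    uncovered = observed - set(mapping)
    if uncovered:
        raise ValidationError(f"mapping does not cover levels {sorted(uncovered)}")
    keys = sorted(mapping)
    vals = [mapping[k] for k in keys]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValidationError("mapping must be monotone non-decreasing")
    new_k = max(vals)
    if sorted(set(vals)) != list(range(1, new_k + 1)):
        raise ValidationError("mapped levels must cover 1..k without gaps")
    df = trials.df.copy()
    df["confidence"] = df["confidence"].map(mapping).astype(int)
    return trials.with_df(df, new_k)


def _bin_values(values: np.ndarray, n_levels: int, lower: float, upper: float) -> np.ndarray:
    if np.any(values < lower) or np.any(values > upper):
        bad = values[(values < lower) | (values > upper)]
        raise ValidationError(
            f"confidence values outside [{lower}, {upper}]: e.g. {bad[:3]}"
        )
    width = (upper - lower) / n_levels
    levels = np.floor((values - lower) / width).astype(int) + 1
    return np.clip(levels, 1, n_levels)  # upper edge inclusive in top bin


def bin_continuous_confidence(trials: TrialTable, n_levels: int,
                              lower: float, upper: float) -> TrialTable:
    """Discretize continuous confidence into equal-width bins on [lower, upper]."""
    df = trials.df.copy()
    df["confidence"] = _bin_values(df["confidence"].to_numpy(float),
                                   n_levels, lower, upper)
    return trials.with_df(df, n_levels)


@dataclass(frozen=True)
class ExclusionReport:
    """Per-participant exclusion statistics and firing reasons."""

    table: pd.DataFrame  # participant, accuracy, max_response_share, max_confidence_share, excluded, reason

    @property
    def excluded(self) -> list:
        return list(self.table.loc[self.table["excluded"], "participant"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def apply_exclusions(trials: TrialTable, acc_low: float = 0.60,
                     acc_high: float = 0.95, share_max: float = 0.85,
                     ) -> tuple[TrialTable, ExclusionReport]:
    """Drop participants with out-of-range accuracy or stereotyped responding.

    A participant is excluded when accuracy is strictly below ``acc_low`` or
    strictly above ``acc_high``, or when the modal response category or the
    modal confidence level accounts for strictly more than ``share_max`` of
    their trials.  Such participants tend to have unstable metacognitive
    scores.
    """
    if trials.n_trials == 0:
        raise ValidationError("empty trial table")
    rows = []
    acc = pd.Series(trials.accuracy, index=trials.df.index)
    for pid, grp in trials.df.groupby("participant", sort=False):
        p_acc = float(acc.loc[grp.index].mean())
        resp_share = float(grp["response"].value_counts(normalize=True).max())
        conf_share = float(grp["confidence"].value_counts(normalize=True).max())
        reasons = []
        if p_acc < acc_low:
            reasons.append("accuracy_low")
        if p_acc > acc_high:
            reasons.append("accuracy_high")
        if resp_share > share_max:
            reasons.append("response_share")
        if conf_share > share_max:
            reasons.append("confidence_share")
        rows.append({
            "participant": pid,
            "accuracy": p_acc,
            "max_response_share": resp_share,
            "max_confidence_share": conf_share,
            "excluded": bool(reasons),
            "reason": "+".join(reasons) if reasons else "",
        })
    report = ExclusionReport(pd.DataFrame(rows))
    kept = set(report.table.loc[~report.table["excluded"], "participant"])
    out = trials.select(trials.df["participant"].isin(kept))
    return out, report


def make_bins(trials: TrialTable, bin_size: int,
              within: Sequence[str] = ("participant", "day"),
              ) -> list[TrialTable]:
    """Split trials into consecutive non-overlapping bins of ``bin_size``.

    Binning respects trial order within each group defined by ``within``
    (participant, and day when present); trailing trials that do not fill a
    whole bin are discarded.  Groups smaller than ``bin_size`` contribute no
    bins and trigger a warning.
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    within = [c for c in within if c in trials.df.columns]
    groups = (trials.df.groupby(within, sort=False)
              if within else [((), trials.df)])
    bins: list[TrialTable] = []
    for _, grp in groups:
        n_full = len(grp) // bin_size
        if n_full == 0:
            warnings.warn(
                f"group of {len(grp)} trials smaller than bin_size={bin_size}; "
                "no bins produced", stacklevel=2)
            continue
        for b in range(n_full):
            bins.append(trials.with_df(grp.iloc[b * bin_size:(b + 1) * bin_size]))
    return bins


# ---------------------------------------------------------------------------
# recipes

def builtin_recipes() -> dict[str, DatasetRecipe]:
    """Recipes for the six public Confidence Database datasets analyzed here.

    Haddara_2022_Expt2: day 1 is shorter (350 trials) than days 2-7 (500
    each) and is dropped.  Rouault_2018_Expt1: the rarely-used bottom six
    levels of the 11-point scale are merged, giving a 6-point scale.
    Shekhar_2021: the continuous 50-100 scale is binned into six equal-width
    levels.
    """
    rouault_map = {i: 1 for i in range(1, 7)}
    rouault_map.update({7: 2, 8: 3, 9: 4, 10: 5, 11: 6})
    return {
        "haddara": DatasetRecipe("haddara", scale_points=4, drop_days=(1,)),
        "locke": DatasetRecipe("locke", scale_points=2),
        "maniscalco": DatasetRecipe("maniscalco", scale_points=4),
        "rouault1": DatasetRecipe("rouault1", confidence_transform="merge_levels",
                                  mapping=rouault_map),
        "rouault2": DatasetRecipe("rouault2", scale_points=6),
        "shekhar": DatasetRecipe("shekhar", confidence_transform="bin_continuous",
                                 n_levels=6, lower=50, upper=100),
    }


def load_recipes(path) -> dict[str, DatasetRecipe]:
    """Load recipes from a YAML/JSON config file (one mapping per dataset)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    out = {}
    for name, kwargs in spec.items():
        kwargs = dict(kwargs or {})
        kwargs.setdefault("name", name)
        if "drop_days" in kwargs:
            kwargs["drop_days"] = tuple(kwargs["drop_days"])
        if "conditions_to_analyze" in kwargs and kwargs["conditions_to_analyze"] is not None:
            kwargs["conditions_to_analyze"] = tuple(kwargs["conditions_to_analyze"])
        out[name] = DatasetRecipe(**kwargs)
    return out
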