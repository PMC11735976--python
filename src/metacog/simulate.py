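"""Synthetic confidence datasets with known ground truth.

The generator is an equal-variance SDT observer with configurable
sensitivity d', decision criterion c, confidence-criterion distances, and
lognormal criterion jitter (sigma_meta = 0 gives the ideal SDT observer).
Output follows the Confidence Database column convention so it can stand
in for real archive downloads in tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .process_models import LognormalNoiseParams, simulate_lognoise
from .trials import TrialTable, ValidationError

__all__ = [
    "SimObserverConfig",
    "simulate_observer",
    "simulate_cohort",
    "make_fixture",
    "write_confidence_db_csv",
    "PRESETS",
]


@dataclass(frozen=True)
class SimObserverConfig:
    """Configuration of one simulated observer.

    ``conf_criteria`` are the k-1 positive criterion distances per response
    side (so the scale has k points); ``sigma_meta`` is the log-scale of
    the shared lognormal criterion jitter, 0 for an ideal SDT observer.
    """

    d_prime: float = 1.5
    c: float = 0.0
    conf_criteria: tuple = (0.5, 1.0, 1.5)
    sigma_meta: float = 0.0
    p_category2: float = 0.5
    n_trials: int = 1000
    n_days: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_category2 < 1.0:
            raise ValidationError("p_category2 must be in (0, 1)")
        crit = np.asarray(self.conf_criteria, dtype=float)
        if (crit <= 0).any() or (np.diff(crit) <= 0).any():
            raise ValidationError("conf_criteria must be positive and "
                                  "strictly increasing")

    @property
    def k(self) -> int:
        return len(self.conf_criteria) + 1

    def params(self) -> LognormalNoiseParams:
        return LognormalNoiseParams(d_prime=self.d_prime, c=self.c,
                                    tau=tuple(self.conf_criteria),
                                    sigma_meta=self.sigma_meta)


def simulate_observer(config: SimObserverConfig,
                      participant=1) -> TrialTable:
    """Simulate one observer's trials, deterministic given the seed.

    Trials are split into ``n_days`` consecutive equal blocks with day
    labels 1..n_days (mirroring multi-session archive datasets).
    """
    trials = simulate_lognoise(config.params(), config.n_trials, config.seed,
                               p_category2=config.p_category2)
    df = trials.df.copy()
    df["participant"] = participant
    if config.n_days > 1:
        per_day = config.n_trials // config.n_days
        day = np.minimum(np.arange(config.n_trials) // per_day,
                         config.n_days - 1) + 1
        df["day"] = day
    return trials.with_df(df)


def simulate_cohort(base: SimObserverConfig, n_observers: int,
                    spreads: dict[str, float] | None = None,
                    seed: int = 0) -> tuple[TrialTable, pd.DataFrame]:
    """Simulate a cohort with between-subject trait variation.

    Per-observer parameters are drawn around the base configuration with
    the given normal spreads (keys: ``d_prime``, ``c``, ``sigma_meta``,
    ``conf_scale`` — a multiplicative jitter on all criterion distances).
    Returns the concatenated trials and a ground-truth parameter table, so
    downstream checks never re-derive truth from the data.
    """
    if n_observers < 3:
        raise ValidationError("need at least 3 observers")
    spreads = spreads or {}
    rng = np.random.default_rng(seed)
    tables, truth = [], []
    for i in range(1, n_observers + 1):
        d = base.d_prime + rng.normal(0, spreads.get("d_prime", 0.0))
        c = base.c + rng.normal(0, spreads.get("c", 0.0))
        sig = base.sigma_meta + rng.normal(0, spreads.get("sigma_meta", 0.0))
        scale = np.exp(rng.normal(0, spreads.get("conf_scale", 0.0)))
        cfg = replace(base, d_prime=max(d, 0.05), c=c,
                      sigma_meta=max(sig, 0.0),
                      conf_criteria=tuple(scale * np.asarray(base.conf_criteria)),
                      seed=int(rng.integers(2 ** 31)))
        tables.append(simulate_observer(cfg, participant=i).df)
        truth.append({"observer": i, "d_prime": cfg.d_prime, "c": cfg.c,
                      "sigma_meta": cfg.sigma_meta,
                      "conf_scale": float(scale), "seed": cfg.seed})
    df = pd.concat(tables, ignore_index=True)
    return TrialTable(df, base.k), pd.DataFrame(truth)


#: fixture presets: small, interpretable study conditions
PRESETS: dict[str, dict] = {
    # ideal SDT observer at comfortable performance
    "ideal_observer": dict(
        base=SimObserverConfig(d_prime=1.5, c=0.0, conf_criteria=(0.5, 1.0, 1.5),
                               sigma_meta=0.0, n_trials=2000, seed=11),
        n_observers=8, spreads={"d_prime": 0.2}),
    # substantial criterion jitter degrades confidence informativeness
    "noisy_metacognition": dict(
        base=SimObserverConfig(d_prime=1.5, c=0.0, conf_criteria=(0.5, 1.0, 1.5),
                               sigma_meta=0.6, n_trials=2000, seed=12),
        n_observers=8, spreads={"d_prime": 0.2, "sigma_meta": 0.1}),
    # confidence bias induced by shifting criterion distances, not relabeling
    "biased_confidence": dict(
        base=SimObserverConfig(d_prime=1.5, c=0.3, conf_criteria=(0.2, 0.5, 0.9),
                               sigma_meta=0.2, n_trials=2000, seed=13),
        n_observers=8, spreads={"d_prime": 0.2, "conf_scale": 0.3}),
    # six equal days per participant, mirroring multi-session designs
    "multi_day": dict(
        base=SimObserverConfig(d_prime=1.5, c=0.0, conf_criteria=(0.5, 1.0, 1.5),
                               sigma_meta=0.3, n_trials=3000, n_days=6, seed=14),
        n_observers=10, spreads={"d_prime": 0.25, "sigma_meta": 0.15}),
}


def write_confidence_db_csv(trials: TrialTable, path) -> None:
    """Write trials in the Confidence Database CSV dialect."""
    rename = {"participant": "Subj_idx", "stimulus": "Stimulus",
              "response": "Response", "confidence": "Confidence",
              "day": "Day", "condition": "Condition",
              "difficulty": "Difficulty"}
    out = trials.df.rename(columns=rename)
    out.to_csv(path, index=False)


def make_fixture(preset: str, out_dir) -> dict[str, Path]:
    """Write a preset cohort as CSV plus a ground-truth sidecar.

    Regenerates bit-identically from the preset's fixed seeds.
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; "
                              f"choose from {sorted(PRESETS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = PRESETS[preset]
    trials, truth = simulate_cohort(spec["base"], spec["n_observers"],
                                    spec["spreads"],
                                    seed=spec["base"].seed)
    data_path = out_dir / f"{preset}.csv"
    truth_path = out_dir / f"{preset}_truth.csv"
    write_confidence_db_csv(trials, data_path)
    truth.to_csv(truth_path, index=False)
    return {"data": data_path, "truth": truth_path}
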