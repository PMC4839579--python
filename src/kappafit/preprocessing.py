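"""Response-bias estimation/correction and descriptive Kappa statistics.

The reproduction task has an overall response bias — subjects overproduce
short intervals even with zero flash separation — which is estimated from
the zero-separation baseline (mean production minus the sample interval)
and subtracted per subject and condition before model fitting.  The
descriptive statistics are:

* ``BIAS_r`` — response bias at the baseline,
* ``BIAS_k`` — the Kappa bias: per-separation mean production minus the
  baseline mean (0 at zero separation by construction),
* ``VAR``   — mean across separations of the per-treatment sample variance
  of production time.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "MissingBaselineError",
    "estimate_response_bias",
    "response_bias_table",
    "correct_bias",
    "compute_bias_k",
    "compute_var",
    "location_bias_table",
]


class MissingBaselineError(ValueError):
    """No zero-separation trials available to anchor the bias estimate."""


def _one_condition(trials: pd.DataFrame, sample_interval: float) -> pd.DataFrame:
    sel = trials[trials["sample_interval_s"] == sample_interval]
    if sel.empty:
        raise MissingBaselineError(f"no trials for sample interval {sample_interval}")
    return sel


def estimate_response_bias(trials: pd.DataFrame, sample_interval: float) -> float:
    """Response bias for one condition: mean baseline production − t_s.

    The baseline is the zero-separation treatment.  Pass trials of a single
    subject for a per-subject bias, or of all subjects for the group value.
    """
    sel = _one_condition(trials, sample_interval)
    base = sel[sel["distance_deg"] == 0.0]
    if base.empty:
        raise MissingBaselineError(
            f"no zero-separation baseline trials for sample interval {sample_interval}"
        )
    return float(base["production_time_s"].mean() - sample_interval)


def response_bias_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, condition) response bias, long format."""
    rows = []
    for (subj, t_s), grp in trials.groupby(["subject_id", "sample_interval_s"], sort=True):
        rows.append(
            {
                "subject_id": subj,
                "sample_interval_s": float(t_s),
                "bias_r_s": estimate_response_bias(grp, float(t_s)),
            }
        )
    return pd.DataFrame(rows)


def correct_bias(trials: pd.DataFrame, bias: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-(subject, condition) response bias from every trial.

    After correction each subject's baseline mean equals the sample interval
    exactly (an arithmetic identity), so re-estimating the bias yields zero
    and the operation is idempotent.
    """
    merged = trials.merge(bias, on=["subject_id", "sample_interval_s"], how="left", validate="many_to_one")
    missing = merged["bias_r_s"].isna()
    if missing.any():
        bad = merged.loc[missing, ["subject_id", "sample_interval_s"]].drop_duplicates()
        raise KeyError(f"no bias estimate for: {bad.to_records(index=False).tolist()}")
    out = trials.copy()
    out["production_time_s"] = merged["production_time_s"] - merged["bias_r_s"]
    return out


def compute_bias_k(trials: pd.DataFrame, sample_interval: float) -> pd.Series:
    """Kappa bias per separation: mean production minus the baseline mean.

    Returns a Series indexed by distance (degrees); the zero-separation entry
    is exactly 0.
    """
    sel = _one_condition(trials, sample_interval)
    means = sel.groupby("distance_deg")["production_time_s"].mean()
    if 0.0 not in means.index:
        raise MissingBaselineError(
            f"no zero-separation baseline trials for sample interval {sample_interval}"
        )
    out = means - means.loc[0.0]
    out.name = "bias_k_s"
    return out


def compute_var(trials: pd.DataFrame, sample_interval: float) -> float:
    """Mean across treatments of the per-treatment sample variance (n−1) of
    production time, in s²."""
    sel = _one_condition(trials, sample_interval)
    counts = sel.groupby("distance_deg")["production_time_s"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"treatments with fewer than 2 trials at distances {bad}")
    return float(sel.groupby("distance_deg")["production_time_s"].var(ddof=1).mean())


def location_bias_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Group response bias by condition and flash location (control study).

    Each subject contributes one bias per (condition, location): mean
    production minus the sample interval.  Rows carry the across-subject
    mean and standard error.
    """
    per_subject = (
        trials.groupby(["subject_id", "sample_interval_s", "location_deg"])["production_time_s"]
        .mean()
        .reset_index()
    )
    per_subject["bias_s"] = per_subject["production_time_s"] - per_subject["sample_interval_s"]
    agg = (
        per_subject.groupby(["sample_interval_s", "location_deg"])["bias_s"]
        .agg(mean_bias_s="mean", se_s=lambda x: x.std(ddof=1) / len(x) ** 0.5 if len(x) > 1 else 0.0, n="count")
        .reset_index()
        .rename(columns={"sample_interval_s": "condition"})
    )
    return agg
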