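"""Trial-table I/O, prediction curves and table export.

The native interchange format is a plain CSV with one row per trial and
columns ``subject_id, experiment, sample_interval_s, distance_deg,
location_deg, trial_index, production_time_s`` (angles in degrees, times in
seconds throughout).  Output files may carry ``#``-prefixed header comment
lines recording the seed and generator provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ClassicalParams, SlownessParams
from .synth import TRIAL_COLUMNS

__all__ = ["TrialValidationError", "read_trials", "write_trials", "validate_trials", "PredictionCurve", "predict_curve"]

_NUMERIC = ["sample_interval_s", "distance_deg", "location_deg", "trial_index", "production_time_s"]


class TrialValidationError(ValueError):
    """A trial table violates the schema; the message names the rows."""


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise TrialValidationError(f"non-numeric or missing {col} in rows {rows}")
        df[col] = coerced
    checks = {
        "production_time_s must be > 0": df["production_time_s"] <= 0,
        "sample_interval_s must be > 0": df["sample_interval_s"] <= 0,
        "distance_deg must be >= 0": df["distance_deg"] < 0,
    }
    for msg, bad in checks.items():
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise TrialValidationError(f"{msg} (rows {rows})")
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV (``#`` lines are header comments)."""
    df = pd.read_csv(path, comment="#")
    return validate_trials(df)


def write_trials(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a trial CSV, optionally prefixed with provenance comments."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# prediction / extrapolation
# ---------------------------------------------------------------------------


@dataclass
class PredictionCurve:
    """Model-predicted mean production over a separation grid (bias-free)."""

    model: str
    condition: float
    distances: np.ndarray
    mean_production: np.ndarray
    se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"distance_deg": self.distances, "mean_production_s": self.mean_production}
        )
        if self.se is not None:
            out["se_s"] = self.se
        return out


def predict_curve(
    params_list,
    condition: float,
    distances=None,
    model: str | None = None,
) -> PredictionCurve:
    """Predicted mean production vs separation for one condition.

    ``params_list`` is one parameter set or a sequence (per subject); with
    several, curves are averaged and an across-subject SE attached.  The
    mean production equals the model's time estimate (response bias is
    excluded, matching fits on bias-corrected data).  The classical curve
    is exactly linear in separation with slope (1 − ω)/v0; the slowness
    curve decelerates because spatial noise grows with eccentricity.
    """
    if distances is None:
        distances = np.linspace(1.4, 150.0, 100)
    distances = np.asarray(distances, float)
    if np.any(np.diff(distances) <= 0):
        raise ValueError("distance grid must be strictly increasing")
    if isinstance(params_list, (ClassicalParams, SlownessParams)):
        params_list = [params_list]
    curves = np.array([np.atleast_1d(p.estimate(condition, distances)) for p in params_list])
    if np.any(curves <= 0):
        raise ValueError("non-positive predicted production on the grid")
    mean = curves.mean(axis=0)
    se = curves.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else None
    name = model or ("classical" if isinstance(params_list[0], ClassicalParams) else "slowness")
    return PredictionCurve(name, condition, distances, mean, se)
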