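"""Synthetic two-flash time-reproduction data.

Emulates the structure of the two experiments the analysis pipeline
expects:

* Experiment 1 — 9 subjects × 2 sample intervals (0.8 s, 1.2 s) ×
  17 flash separations (1.414°·i, i = 0..16) × 40 trials, i.e. 1360 trials
  per subject.  The internal time estimate per trial comes from one of the
  two observer models; production adds scalar-variability Gaussian noise
  (SD = w_p·t_e) plus a per-subject, per-condition response bias.
* Experiment 2 — the same-location control: 2 intervals × 3 horizontal
  locations (−12°, 0°, +12°) × 40 trials (240 per subject), no spatial
  separation, so the estimate is the sample interval itself and only the
  response bias and production noise remain.

Distances are presented in randomised blocks (each block one pass through
all separations, shuffled) so cell counts are exact while presentation
order is random.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    DEFAULT_VERTICAL_OFFSET,
    ClassicalParams,
    SlownessParams,
)
from . import published

__all__ = ["DesignSpec", "GeneratorSpec", "generate_exp1", "generate_exp2", "population_spec_from_tables"]

TRIAL_COLUMNS = [
    "subject_id",
    "experiment",
    "sample_interval_s",
    "distance_deg",
    "location_deg",
    "trial_index",
    "production_time_s",
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of a simulated session."""

    n_subjects: int = 9
    sample_intervals: Sequence[float] = (0.8, 1.2)
    distances: Sequence[float] = tuple(1.414 * i for i in range(17))
    locations: Sequence[float] = (-12.0, 0.0, 12.0)
    trials_per_cell: int = 40
    vertical_offset: float = DEFAULT_VERTICAL_OFFSET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_cell < 1:
            raise ValueError("counts must be >= 1")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class GeneratorSpec:
    """Observer model and noise settings driving one simulated subject.

    ``params`` is either a single parameter set shared by all subjects or a
    per-subject list.  ``measurement_noise_mode='on'`` additionally samples a
    noisy measurement t_m ~ N(t_s, σ_m) and feeds it through the estimator
    (model-mismatch experiments only); the default ``'off'`` uses the
    deterministic estimate, matching the fitted likelihood.
    """

    model: str  # 'classical' | 'slowness'
    params: "ClassicalParams | SlownessParams | Sequence" = None
    bias_by_condition: dict = field(default_factory=dict)
    measurement_noise_mode: str = "off"
    sigma_m: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("classical", "slowness"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.measurement_noise_mode not in ("off", "on"):
            raise ValueError("measurement_noise_mode must be 'off' or 'on'")

    def params_for(self, subject_index: int):
        if isinstance(self.params, (ClassicalParams, SlownessParams)):
            return self.params
        return self.params[subject_index % len(self.params)]


def _sample_production(rng, t_e, bias, wp):
    """Gaussian production draws, resampling any non-positive values.

    At realistic parameters the truncated mass is negligible (< 1e-6), so
    downstream likelihoods may ignore truncation.
    """
    t_e = np.asarray(t_e, dtype=float)
    t_p = rng.normal(t_e + bias, wp * t_e)
    bad = t_p <= 0
    for _ in range(100):
        if not bad.any():
            break
        t_p[bad] = rng.normal(t_e[bad] + bias, wp * t_e[bad])
        bad = t_p <= 0
    if bad.any():
        raise RuntimeError("could not draw positive production times; parameters pathological")
    return t_p


def _blocked_order(rng, levels: np.ndarray, trials_per_cell: int) -> np.ndarray:
    """Randomised block order: each block is one shuffled pass through all
    levels, guaranteeing exact per-level counts."""
    blocks = [rng.permutation(levels) for _ in range(trials_per_cell)]
    return np.concatenate(blocks)


def _estimate_for(gen: GeneratorSpec, params, t_s: float, l: np.ndarray, rng, vertical_offset: float) -> np.ndarray:
    if gen.measurement_noise_mode == "on":
        if gen.sigma_m <= 0:
            raise ValueError("sigma_m must be positive when measurement noise is on")
        t_in = rng.normal(t_s, gen.sigma_m, size=l.shape)
    else:
        t_in = None
    if gen.model == "classical":
        omega = params.omega_by_condition[t_s]
        base = t_in if t_in is not None else t_s
        return omega * np.asarray(base, float) + (1.0 - omega) * l / params.v0
    # slowness: deterministic in t_s; estimates depend on l only, so solve
    # once per unique separation and broadcast.
    uniq, inv = np.unique(l, return_inverse=True)
    if t_in is None:
        te_u = np.array([params.estimate(t_s, d, vertical_offset=vertical_offset) for d in uniq])
        return te_u[inv]
    return np.array(
        [params.estimate(float(max(t, 1e-3)), d, vertical_offset=vertical_offset) for t, d in zip(t_in, l)]
    )


def _generate(design: DesignSpec, gen: GeneratorSpec, experiment: str) -> pd.DataFrame:
    root = np.random.SeedSequence(design.seed)
    subject_seeds = root.spawn(design.n_subjects)
    frames = []
    for si in range(design.n_subjects):
        rng = np.random.default_rng(subject_seeds[si])
        subject = f"S{si + 1}"
        params = gen.params_for(si)
        for t_s in design.sample_intervals:
            bias = float(gen.bias_by_condition.get(t_s, 0.0))
            if experiment == "exp1":
                levels = np.asarray(design.distances, float)
                order = _blocked_order(rng, levels, design.trials_per_cell)
                l = order
                loc = np.zeros_like(order)
            else:
                levels = np.asarray(design.locations, float)
                order = _blocked_order(rng, levels, design.trials_per_cell)
                l = np.zeros_like(order)
                loc = order
            if experiment == "exp1":
                t_e = _estimate_for(gen, params, t_s, l, rng, design.vertical_offset)
            else:
                # same-location flashes: no Kappa term, the estimate is t_s
                t_e = np.full(l.shape, float(t_s))
            t_p = _sample_production(rng, t_e, bias, params.wp)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject,
                        "experiment": experiment,
                        "sample_interval_s": t_s,
                        "distance_deg": l,
                        "location_deg": loc,
                        "trial_index": np.arange(1, len(order) + 1),
                        "production_time_s": t_p,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_exp1(design: DesignSpec, gen: GeneratorSpec) -> pd.DataFrame:
    """Simulate the separation-manipulation experiment (Kappa effect)."""
    return _generate(design, gen, "exp1")


def generate_exp2(design: DesignSpec, gen: GeneratorSpec) -> pd.DataFrame:
    """Simulate the same-location control experiment (response bias only)."""
    return _generate(design, gen, "exp2")


def population_spec_from_tables(model: str = "classical", acuity: str = "vernier") -> GeneratorSpec:
    """Generator preloaded with the nine published per-subject parameter sets,
    for simulation faithful to the reported population."""
    if model == "classical":
        params = [published.classical_params(s) for s in published.SUBJECTS]
    else:
        params = [published.slowness_params(s, acuity=acuity) for s in published.SUBJECTS]
    return GeneratorSpec(model=model, params=params)
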