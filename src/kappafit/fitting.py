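"""Maximum-likelihood fitting and AIC comparison of the observer models.

Each subject's trials (both sample-interval conditions jointly) are fit by
maximising the trialwise log-likelihood

    log p(t_p1..t_pN | params) = Σ_i log N(t_pi ; t_e(t_si, l_i), w_p·t_e)

where t_e is the deterministic model estimate for the trial's condition and
separation (measurement noise is integrated out; its expectation enters
through the model parameters).  Optimisation is derivative-free simplex
search on transformed parameters (logit for ω, log for v0, σ's and w_p in
the standard fits), with moment-based initial guesses and jittered
multi-starts.  Six-parameter variants additionally estimate a response bias
per condition from uncorrected data and deliberately leave ω (classical) or
the σ's (slowness) unconstrained so degenerate solutions (ω ≥ 1,
non-positive σ) can be observed and flagged rather than hidden.

Model comparison uses AIC = 2k − 2 log L per condition (k the number of
free parameters) and the AIC difference Δ = AIC_i − AIC_min with the
conventional support bands, plus exact sign tests and t statistics across
subjects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats, special

from .models import (
    DEFAULT_VERTICAL_OFFSET,
    AcuityModel,
    ClassicalParams,
    SlownessParams,
    VERNIER,
    flash_eccentricity,
    get_acuity,
    slowness_estimate_many,
    spatial_sigma,
)

__all__ = [
    "FitResult",
    "neg_log_likelihood",
    "fit_classical",
    "fit_slowness",
    "fit_with_bias",
    "aic",
    "delta_aic",
    "support_label",
    "comparison_table",
    "sign_test",
    "one_sample_t",
    "paired_t",
    "fit_all_subjects",
]

logger = logging.getLogger(__name__)

PENALTY = 1e10  # returned when parameters imply a non-positive estimate


@dataclass
class FitResult:
    """Outcome of one subject-level fit."""

    model: str  # 'classical' | 'slowness_vernier' | 'slowness_grating'
    params: "ClassicalParams | SlownessParams"
    loglik: float
    loglik_by_condition: dict
    aic_by_condition: dict
    n_params: int
    converged: bool
    n_restarts_used: int
    degenerate: bool = False
    subject_id: str | None = None

    @property
    def aic_total(self) -> float:
        return aic(self.loglik, self.n_params)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class _ConditionData:
    """Per-condition trial arrays with separations factored to unique values,
    so the slowness roots are solved once per separation per evaluation."""

    def __init__(self, t_s: float, l: np.ndarray, t_p: np.ndarray, vertical_offset: float):
        self.t_s = t_s
        self.t_p = t_p
        self.l_unique, self.inverse = np.unique(l, return_inverse=True)
        self.ecc = flash_eccentricity(self.l_unique, vertical_offset)
        self._sigma_s_cache: dict = {}

    def sigma_s(self, acuity: AcuityModel) -> np.ndarray:
        out = self._sigma_s_cache.get(acuity.name)
        if out is None:
            out = self._sigma_s_cache[acuity.name] = spatial_sigma(self.ecc, acuity)
        return out


def _split_conditions(trials: pd.DataFrame, vertical_offset: float) -> dict:
    out = {}
    for t_s, grp in trials.groupby("sample_interval_s", sort=True):
        out[float(t_s)] = _ConditionData(
            float(t_s),
            grp["distance_deg"].to_numpy(float),
            grp["production_time_s"].to_numpy(float),
            vertical_offset,
        )
    return out


def _condition_loglik(cond: _ConditionData, params, bias: float, sigma_s_cache=None) -> float:
    """Log-likelihood of one condition; invalid parameter regions raise
    ValueError, converted to the penalty by the caller."""
    if isinstance(params, ClassicalParams):
        omega = params.omega_by_condition[cond.t_s]
        te_u = omega * cond.t_s + (1.0 - omega) * cond.l_unique / params.v0
    else:
        sigma_t = params.sigma_t_by_condition[cond.t_s]
        sigma_s = sigma_s_cache if sigma_s_cache is not None else cond.sigma_s(params.acuity)
        # Eq for t_e is even in sigma_t and sigma_v: use magnitudes so the
        # unconstrained 6-parameter variant stays solvable.
        te_u = slowness_estimate_many(cond.t_s, cond.l_unique, abs(sigma_t), sigma_s, abs(params.sigma_v))
    if not np.all(np.isfinite(te_u)) or np.any(te_u <= 0):
        raise ValueError("non-positive estimate")
    t_e = te_u[cond.inverse]
    # scalar-variability SD rides on t_e, not on the bias-shifted mean
    sd = params.wp * t_e
    z = (cond.t_p - (t_e + bias)) / sd
    return float(np.sum(-0.5 * z**2 - np.log(sd)) - 0.5 * len(cond.t_p) * math.log(2 * math.pi))


def _nll_conds(conds: dict, params) -> float:
    if params.wp <= 0:
        return PENALTY
    total = 0.0
    for t_s, cond in conds.items():
        bias = 0.0 if params.bias_by_condition is None else float(params.bias_by_condition.get(t_s, 0.0))
        try:
            total += _condition_loglik(cond, params, bias)
        except ValueError:
            logger.debug("penalised invalid parameters at t_s=%s", t_s)
            return PENALTY
    return -total


def neg_log_likelihood(
    trials: pd.DataFrame,
    params: "ClassicalParams | SlownessParams",
    vertical_offset: float = DEFAULT_VERTICAL_OFFSET,
) -> float:
    """Negative trialwise log-likelihood of a parameter set on a trial table.

    Returns the large penalty value (1e10) instead of raising when the
    parameters imply a non-positive time estimate, so simplex search can
    recover from excursions into invalid regions.
    """
    return _nll_conds(_split_conditions(trials, vertical_offset), params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _pooled_cv(trials: pd.DataFrame) -> float:
    cells = trials.groupby(["sample_interval_s", "distance_deg"])["production_time_s"]
    means, sds = cells.mean(), cells.std(ddof=1)
    cv = float((sds / means).mean())
    return cv if np.isfinite(cv) and cv > 0 else 0.15


def _classical_moments(trials: pd.DataFrame) -> tuple[dict, float, float]:
    """Moment-based starting values: ω from the per-condition intercept of
    t_p on l, v0 from the slope, w_p from the pooled CV."""
    omegas, v0s = {}, []
    for t_s, grp in trials.groupby("sample_interval_s"):
        l = grp["distance_deg"].to_numpy(float)
        tp = grp["production_time_s"].to_numpy(float)
        if np.ptp(l) > 0:
            slope, intercept = np.polyfit(l, tp, 1)
        else:
            slope, intercept = 0.0, tp.mean()
        omega = float(np.clip(intercept / t_s, 0.5, 0.9995))
        omegas[float(t_s)] = omega
        if slope > 1e-6:
            v0s.append((1.0 - omega) / slope)
    v0 = float(np.clip(np.mean(v0s), 1e-3, 100.0)) if v0s else 0.2
    return omegas, v0, _pooled_cv(trials)


def _simplex(fun, x0: np.ndarray) -> optimize.OptimizeResult:
    return optimize.minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-10, maxiter=5000, maxfev=10000),
    )


def _multi_start(objective, starts) -> tuple[np.ndarray, float, bool, int]:
    best_x, best_f, converged, used = None, np.inf, False, 0
    for x0 in starts:
        used += 1
        res = _simplex(objective, np.asarray(x0, float))
        if res.fun < best_f:
            best_x, best_f, converged = res.x, float(res.fun), bool(res.success)
    return best_x, best_f, converged, used


def _per_condition_results(trials, params, n_params, vertical_offset):
    conds = _split_conditions(trials, vertical_offset)
    ll, aics = {}, {}
    for t_s, cond in conds.items():
        bias = 0.0 if params.bias_by_condition is None else float(params.bias_by_condition.get(t_s, 0.0))
        ll[t_s] = _condition_loglik(cond, params, bias)
        aics[t_s] = aic(ll[t_s], n_params)
    return ll, aics


def fit_classical(
    trials: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    vertical_offset: float = DEFAULT_VERTICAL_OFFSET,
) -> FitResult:
    """Fit the constant-speed model (ω per condition, shared v0 and w_p) to
    one subject's bias-corrected trials by multi-start simplex MLE.

    Transformed search space: logit(ω), log(v0), log(w_p).
    """
    conditions = sorted(trials["sample_interval_s"].unique())
    omegas0, v0_0, wp0 = _classical_moments(trials)
    rng = np.random.default_rng(seed)
    conds = _split_conditions(trials, vertical_offset)

    def unpack(x):
        om = {c: float(special.expit(x[i])) for i, c in enumerate(conditions)}
        return ClassicalParams(om, v0=math.exp(x[len(conditions)]), wp=math.exp(x[len(conditions) + 1]))

    def objective(x):
        return _nll_conds(conds, unpack(x))

    base = np.array(
        [special.logit(omegas0.get(c, 0.99)) for c in conditions] + [math.log(v0_0), math.log(wp0)]
    )
    starts = [base] + [base + rng.normal(0, 0.5, size=base.size) for _ in range(max(0, n_restarts - 1))]
    x, f, converged, used = _multi_start(objective, starts)
    params = unpack(x)
    ll, aics = _per_condition_results(trials, params, 4, vertical_offset)
    return FitResult(
        model="classical",
        params=params,
        loglik=-f,
        loglik_by_condition=ll,
        aic_by_condition=aics,
        n_params=4,
        converged=converged,
        n_restarts_used=used,
        subject_id=_single_subject(trials),
    )


def fit_slowness(
    trials: pd.DataFrame,
    acuity: "str | AcuityModel" = VERNIER,
    n_restarts: int = 10,
    seed: int = 0,
    vertical_offset: float = DEFAULT_VERTICAL_OFFSET,
) -> FitResult:
    """Fit the slowness model (σ_t per condition, shared σ_v and w_p) to one
    subject's bias-corrected trials.  All parameters are log-transformed;
    σ_s is fixed per separation by the acuity law and flash eccentricity.
    """
    acuity = get_acuity(acuity)
    conditions = sorted(trials["sample_interval_s"].unique())
    wp0 = _pooled_cv(trials)
    rng = np.random.default_rng(seed)
    conds = _split_conditions(trials, vertical_offset)

    def unpack(x):
        st = {c: math.exp(x[i]) for i, c in enumerate(conditions)}
        return SlownessParams(st, sigma_v=math.exp(x[len(conditions)]), wp=math.exp(x[len(conditions) + 1]), acuity=acuity)

    def objective(x):
        return _nll_conds(conds, unpack(x))

    base = np.array([math.log(0.01)] * len(conditions) + [math.log(0.5), math.log(wp0)])
    starts = [base]
    for _ in range(max(0, n_restarts - 1)):
        x0 = base.copy()
        x0[: len(conditions)] += rng.normal(0, 1.0, len(conditions))
        x0[len(conditions)] = math.log(rng.uniform(0.05, 3.0))  # σ_v spans the bimodal range
        x0[len(conditions) + 1] += rng.normal(0, 0.3)
        starts.append(x0)
    x, f, converged, used = _multi_start(objective, starts)
    params = unpack(x)
    ll, aics = _per_condition_results(trials, params, 4, vertical_offset)
    return FitResult(
        model=f"slowness_{acuity.name}",
        params=params,
        loglik=-f,
        loglik_by_condition=ll,
        aic_by_condition=aics,
        n_params=4,
        converged=converged,
        n_restarts_used=used,
        subject_id=_single_subject(trials),
    )


def fit_with_bias(
    trials: pd.DataFrame,
    model: str = "classical",
    acuity: "str | AcuityModel" = VERNIER,
    n_restarts: int = 10,
    seed: int = 0,
    vertical_offset: float = DEFAULT_VERTICAL_OFFSET,
) -> FitResult:
    """Six-parameter variant fitted to *uncorrected* trials: the response
    bias per condition becomes a free parameter (production centred at
    t_e + BIAS_r) and ω resp. σ_t/σ_v are left unconstrained so degenerate
    optima (ω ≥ 1, non-positive σ) surface and are flagged.
    """
    acuity = get_acuity(acuity)
    conditions = sorted(trials["sample_interval_s"].unique())
    nc = len(conditions)
    rng = np.random.default_rng(seed)

    if model == "classical":
        omegas0, v0_0, wp0 = _classical_moments(trials)

        def unpack(x):
            om = {c: float(x[i]) for i, c in enumerate(conditions)}
            bias = {c: float(x[nc + 2 + i]) for i, c in enumerate(conditions)}
            return ClassicalParams(om, v0=math.exp(x[nc]), wp=math.exp(x[nc + 1]), bias_by_condition=bias)

        base = np.array([omegas0.get(c, 0.99) for c in conditions] + [math.log(v0_0), math.log(wp0)] + [0.0] * nc)
        jitter_scale = np.array([0.005] * nc + [0.5, 0.3] + [0.05] * nc)
    elif model == "slowness":

        def unpack(x):
            st = {c: float(x[i]) for i, c in enumerate(conditions)}
            bias = {c: float(x[nc + 2 + i]) for i, c in enumerate(conditions)}
            return SlownessParams(st, sigma_v=float(x[nc]), wp=math.exp(x[nc + 1]), acuity=acuity, bias_by_condition=bias)

        base = np.array([0.01] * nc + [0.5, math.log(_pooled_cv(trials))] + [0.0] * nc)
        jitter_scale = np.array([0.01] * nc + [0.8, 0.3] + [0.05] * nc)
    else:
        raise ValueError(f"unknown model {model!r}")

    conds = _split_conditions(trials, vertical_offset)

    def objective(x):
        return _nll_conds(conds, unpack(x))

    starts = [base] + [base + rng.normal(0, 1, base.size) * jitter_scale for _ in range(max(0, n_restarts - 1))]
    x, f, converged, used = _multi_start(objective, starts)
    params = unpack(x)
    if model == "classical":
        degenerate = any(w >= 1.0 or w <= 0.0 for w in params.omega_by_condition.values())
        name = "classical"
    else:
        degenerate = params.sigma_v <= 0 or any(s <= 0 for s in params.sigma_t_by_condition.values())
        name = f"slowness_{acuity.name}"
    if degenerate:
        logger.warning("degenerate 6-parameter %s fit (boundary/sign pathology) — flagged", name)
    ll, aics = _per_condition_results(trials, params, 2 + 2 * nc, vertical_offset)
    return FitResult(
        model=name,
        params=params,
        loglik=-f,
        loglik_by_condition=ll,
        aic_by_condition=aics,
        n_params=2 + 2 * nc,
        converged=converged,
        n_restarts_used=used,
        degenerate=degenerate,
        subject_id=_single_subject(trials),
    )


def _single_subject(trials: pd.DataFrame) -> str | None:
    subj = trials["subject_id"].unique()
    return str(subj[0]) if len(subj) == 1 else None


# ---------------------------------------------------------------------------
# AIC bookkeeping and comparison statistics
# ---------------------------------------------------------------------------


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k − 2 log L."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def support_label(delta: float) -> str:
    """Conventional evidence bands for the AIC difference Δ."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta <= 2:
        return "substantial"
    if 4 <= delta <= 7:
        return "considerably less"
    if delta > 10:
        return "essentially none"
    return "intermediate"


def delta_aic(aics: dict) -> dict:
    """Δ_i = AIC_i − min AIC across the competing models."""
    if len(aics) < 2:
        raise ValueError("need at least two models to compare")
    best = min(aics.values())
    return {m: a - best for m, a in aics.items()}


def comparison_table(fits_by_subject: dict) -> pd.DataFrame:
    """Per-(subject, condition) AIC and Δ across models.

    ``fits_by_subject`` maps subject id → list of FitResult (one per model).
    """
    rows = []
    for subject, fits in fits_by_subject.items():
        conditions = sorted({c for f in fits for c in f.aic_by_condition})
        for cond in conditions:
            aics = {f.model: f.aic_by_condition[cond] for f in fits}
            deltas = delta_aic(aics)
            for model in aics:
                rows.append(
                    {
                        "subject_id": subject,
                        "condition": cond,
                        "model": model,
                        "aic": aics[model],
                        "delta": deltas[model],
                        "support": support_label(deltas[model]),
                    }
                )
    return pd.DataFrame(rows)


def sign_test(x, y=None) -> dict:
    """Exact two-sided binomial sign test on paired differences (ties dropped)."""
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n < 1:
        raise ValueError("no non-tied pairs")
    k = int(np.sum(d > 0))
    res = stats.binomtest(k, n, 0.5, alternative="two-sided")
    return {"n": n, "n_positive": k, "p": float(res.pvalue)}


def one_sample_t(x, popmean: float = 0.0) -> dict:
    """One-sample t test with Cohen's d = mean / SD."""
    x = np.asarray(x, float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    t, p = stats.ttest_1samp(x, popmean)
    d = float((x.mean() - popmean) / x.std(ddof=1))
    return {"t": float(t), "p": float(p), "df": len(x) - 1, "cohen_d": d, "mean": float(x.mean()), "se": float(stats.sem(x))}


def paired_t(x, y) -> dict:
    """Paired t test with Cohen's d = mean difference / SD of differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    out = one_sample_t(d, 0.0)
    out["mean_diff"] = out.pop("mean")
    return out


def fit_all_subjects(
    trials: pd.DataFrame,
    models: tuple = ("classical", "slowness_vernier", "slowness_grating"),
    n_restarts: int = 10,
    seed: int = 0,
) -> dict:
    """Fit every requested model to every subject; returns
    subject id → list of FitResult (seed is split deterministically)."""
    out = {}
    for i, (subject, grp) in enumerate(sorted(trials.groupby("subject_id"))):
        fits = []
        for j, model in enumerate(models):
            sub_seed = (seed + 1000003 * i + 7919 * j) % (2**31)
            if model == "classical":
                fits.append(fit_classical(grp, n_restarts=n_restarts, seed=sub_seed))
            elif model.startswith("slowness"):
                acuity = model.split("_", 1)[1] if "_" in model else "vernier"
                fits.append(fit_slowness(grp, acuity=acuity, n_restarts=n_restarts, seed=sub_seed))
            else:
                raise ValueError(f"unknown model {model!r}")
        out[subject] = fits
    return out
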