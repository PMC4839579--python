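"""Perceptual estimators for the visual Kappa effect.

Two Bayesian observer models map a sample interval ``t_s`` and the spatial
separation ``l`` of two flashed stimuli onto an internal time estimate
``t_e``:

* the **constant-speed model**, whose estimate is a weighted average of the
  sample interval and the travel time ``l / v0`` expected under a prior
  belief in a fixed speed ``v0``:  ``t_e = ω·t_s + (1 − ω)·l/v0``;
* the **slowness model**, in which a zero-centred Gaussian prior over speed
  (SD ``σ_v``) interacts with noisy temporal (SD ``σ_t``) and spatial
  (SD ``σ_s``) measurements.  Its estimate is defined implicitly by

  .. math::

     t_s = t_e \\left(1 - 2\\left[\\frac{l\\,(σ_t/σ_s)(σ_v/σ_s)}
            {((σ_v/σ_s)\\,t_e)^2 + 2}\\right]^2\\right)

  and is obtained by numerical root finding with ``t_e ≥ t_s``.

Both models share a scalar-variability production stage: the produced
interval ``t_p`` is Gaussian with mean ``t_e`` and SD ``w_p·t_e`` (Weber
fraction ``w_p``).

Spatial noise for the slowness model comes from visual-acuity power laws:
the acuity threshold (a JND, in arcmin) grows with retinal eccentricity ε
as ``0.93·ε^0.69`` (Vernier) or ``1.34·ε^0.71`` (grating); converting
arcmin to degrees and JND to a Gaussian SD via ``σ = JND/0.6475`` gives
``σ_s = 0.0239·ε^0.69`` resp. ``0.0345·ε^0.71`` degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "JND_TO_SD",
    "VERNIER",
    "GRATING",
    "AcuityModel",
    "ClassicalParams",
    "SlownessParams",
    "DerivationParams",
    "acuity_coeff_deg",
    "spatial_sigma",
    "flash_eccentricity",
    "classical_estimate",
    "posterior_mean",
    "slowness_estimate",
    "slowness_estimate_many",
    "production_density",
    "production_log_density",
    "SlownessRootError",
]

#: Conversion from a just-noticeable difference (25%–75% points of a
#: psychometric function) to the SD of the underlying Gaussian.
JND_TO_SD = 0.6475

#: Vertical offset of the flashes above fixation, degrees of visual angle.
DEFAULT_VERTICAL_OFFSET = 2.865


def acuity_coeff_deg(coeff_arcmin: float, jnd_to_sd: float = JND_TO_SD) -> float:
    """Convert an acuity power-law coefficient from arcmin (JND scale) to a
    Gaussian-SD coefficient in degrees: ``coeff_arcmin / 60 / jnd_to_sd``."""
    if coeff_arcmin <= 0 or jnd_to_sd <= 0:
        raise ValueError("acuity coefficient and JND conversion must be positive")
    return coeff_arcmin / 60.0 / jnd_to_sd


@dataclass(frozen=True)
class AcuityModel:
    """Power-law map from retinal eccentricity to spatial-noise SD.

    ``σ_s(ε) = coeff_deg · ε**exponent`` with ε in degrees.  ``coeff_deg`` is
    derived from the published arcmin-scale acuity threshold coefficient.
    """

    name: str
    coeff_arcmin: float
    exponent: float
    jnd_to_sd: float = JND_TO_SD
    coeff_deg: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeff_deg", acuity_coeff_deg(self.coeff_arcmin, self.jnd_to_sd))
        if self.exponent <= 0:
            raise ValueError("acuity exponent must be positive")

    def sigma_s(self, eccentricity):
        return spatial_sigma(eccentricity, self)


VERNIER = AcuityModel("vernier", coeff_arcmin=0.93, exponent=0.69)
GRATING = AcuityModel("grating", coeff_arcmin=1.34, exponent=0.71)

_ACUITY_BY_NAME = {"vernier": VERNIER, "grating": GRATING}


def get_acuity(name_or_model: "str | AcuityModel") -> AcuityModel:
    """Resolve ``'vernier'``/``'grating'`` (or pass through an AcuityModel)."""
    if isinstance(name_or_model, AcuityModel):
        return name_or_model
    try:
        return _ACUITY_BY_NAME[str(name_or_model).lower()]
    except KeyError:
        raise ValueError(f"unknown acuity model {name_or_model!r}; expected 'vernier' or 'grating'") from None


def spatial_sigma(eccentricity, acuity: AcuityModel):
    """Spatial-noise SD (degrees) at a given retinal eccentricity (degrees)."""
    ecc = np.asarray(eccentricity, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be non-negative")
    out = acuity.coeff_deg * ecc**acuity.exponent
    return float(out) if np.isscalar(eccentricity) or ecc.ndim == 0 else out


def flash_eccentricity(l, vertical_offset: float = DEFAULT_VERTICAL_OFFSET, mode: str = "radial"):
    """Retinal eccentricity of either flash for a horizontal separation ``l``.

    The two flashes sit symmetrically about fixation at horizontal offsets
    ±l/2 and a fixed vertical offset, so both share the radial eccentricity
    ``sqrt((l/2)² + vertical_offset²)``.  ``mode='horizontal'`` ignores the
    vertical offset (ε = l/2), provided as a sensitivity switch.
    """
    larr = np.asarray(l, dtype=float)
    if np.any(larr < 0):
        raise ValueError("separation l must be non-negative")
    if mode == "radial":
        out = np.hypot(larr / 2.0, vertical_offset)
    elif mode == "horizontal":
        out = larr / 2.0
    else:
        raise ValueError(f"unknown eccentricity mode {mode!r}")
    return float(out) if np.isscalar(l) or larr.ndim == 0 else out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ClassicalParams:
    """Free parameters of the constant-speed observer for one subject.

    ``omega_by_condition`` maps each sample interval (s) to its weight ω;
    ``v0`` is the prior constant speed (deg/s); ``wp`` the production Weber
    fraction.  Under the standard (bias-corrected) fit 0 < ω < 1; the
    unconstrained 6-parameter variant may yield ω ≥ 1 and is only flagged.
    """

    omega_by_condition: Mapping[float, float]
    v0: float
    wp: float
    bias_by_condition: Mapping[float, float] | None = None

    def validate(self, strict: bool = True) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")
        if self.wp <= 0:
            raise ValueError("wp must be positive")
        if strict and any(not (0.0 < w < 1.0) for w in self.omega_by_condition.values()):
            raise ValueError("omega must lie in (0, 1) under the standard fit")

    def estimate(self, t_s: float, l):
        return classical_estimate(float(t_s), l, self.omega_by_condition[float(t_s)], self.v0)


@dataclass
class SlownessParams:
    """Free parameters of the slowness observer for one subject.

    ``sigma_t_by_condition`` maps each sample interval (s) to its temporal
    noise SD σ_t (s); ``sigma_v`` is the SD of the zero-centred speed prior
    (deg/s); ``wp`` the production Weber fraction.  ``acuity`` fixes the
    spatial-noise law (not a free parameter).
    """

    sigma_t_by_condition: Mapping[float, float]
    sigma_v: float
    wp: float
    acuity: AcuityModel = VERNIER
    bias_by_condition: Mapping[float, float] | None = None

    def validate(self, strict: bool = True) -> None:
        if self.wp <= 0:
            raise ValueError("wp must be positive")
        if strict and (self.sigma_v <= 0 or any(s <= 0 for s in self.sigma_t_by_condition.values())):
            raise ValueError("sigma_t and sigma_v must be positive under the standard fit")

    def estimate(self, t_s: float, l, vertical_offset: float = DEFAULT_VERTICAL_OFFSET, ecc_mode: str = "radial"):
        sigma_t = self.sigma_t_by_condition[float(t_s)]
        ecc = flash_eccentricity(l, vertical_offset, mode=ecc_mode)
        sigma_s = spatial_sigma(ecc, self.acuity)
        if np.isscalar(l) or np.asarray(l).ndim == 0:
            return slowness_estimate(float(t_s), float(l), sigma_t, float(sigma_s), self.sigma_v)
        return slowness_estimate_many(float(t_s), np.asarray(l, float), sigma_t, np.asarray(sigma_s, float), self.sigma_v)


@dataclass(frozen=True)
class DerivationParams:
    """Noise parameters of the generative constant-speed derivation.

    σ_m is the SD of the noisy measurement of the sample interval; σ_tau the
    SD of the constant-speed prior over elapsed time.  They enter the fitted
    model only through ω = σ_tau²/(σ_tau² + σ_m²) and are not separately
    identifiable from reproduction data.
    """

    sigma_m: float
    sigma_tau: float
    vertical_offset: float = DEFAULT_VERTICAL_OFFSET

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_tau <= 0:
            raise ValueError("noise SDs must be positive")

    @property
    def omega(self) -> float:
        return self.sigma_tau**2 / (self.sigma_tau**2 + self.sigma_m**2)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def classical_estimate(t_s, l, omega, v0):
    """Constant-speed estimate ``t_e = ω·t_s + (1 − ω)·l/v0``.

    Strictly increasing in ``l`` when ω < 1; reduces to ``ω·t_s`` at l = 0.
    """
    t_s = np.asarray(t_s, dtype=float)
    if np.any(t_s <= 0):
        raise ValueError("sample interval must be positive")
    if v0 <= 0:
        raise ValueError("prior speed v0 must be positive")
    out = omega * t_s + (1.0 - omega) * np.asarray(l, dtype=float) / v0
    return float(out) if out.ndim == 0 else out


def posterior_mean(t_m, l, deriv: DerivationParams, v0: float):
    """Posterior-mean time estimate of the generative constant-speed model.

    The prior over the elapsed interval is Gaussian with mean ``l/v0`` and SD
    σ_tau; the likelihood of the measured interval ``t_m`` is Gaussian with
    SD σ_m.  The Gaussian-product posterior mean is the precision-weighted
    average, identical to :func:`classical_estimate` with
    ω = σ_tau²/(σ_tau² + σ_m²).
    """
    return classical_estimate(t_m, l, deriv.omega, v0)


def production_density(t_p, t_e, wp):
    """Scalar-variability production density: Gaussian in ``t_p`` with mean
    ``t_e`` and SD ``wp·t_e``."""
    return np.exp(production_log_density(t_p, t_e, wp))


def production_log_density(t_p, t_e, wp):
    t_e = np.asarray(t_e, dtype=float)
    if np.any(t_e <= 0):
        raise ValueError("estimated time must be positive")
    if wp <= 0:
        raise ValueError("Weber fraction must be positive")
    sd = wp * t_e
    z = (np.asarray(t_p, dtype=float) - t_e) / sd
    out = -0.5 * z**2 - np.log(sd) - 0.5 * math.log(2.0 * math.pi)
    return float(out) if out.ndim == 0 else out


class SlownessRootError(RuntimeError):
    """Raised when no bracketing interval for the slowness root is found."""

    def __init__(self, t_s, l, sigma_t, sigma_s, sigma_v):
        super().__init__(
            f"no root with t_e >= t_s for slowness estimate "
            f"(t_s={t_s}, l={l}, sigma_t={sigma_t}, sigma_s={sigma_s}, sigma_v={sigma_v})"
        )
        self.inputs = dict(t_s=t_s, l=l, sigma_t=sigma_t, sigma_s=sigma_s, sigma_v=sigma_v)


def _slowness_rhs(t_e, l, sigma_t, sigma_s, sigma_v):
    """Right-hand side of the implicit slowness equation: the sample interval
    implied by an estimate ``t_e``.  Even in σ_t and σ_v."""
    rv = sigma_v / sigma_s
    bracket = l * (sigma_t / sigma_s) * rv / ((rv * t_e) ** 2 + 2.0)
    return t_e * (1.0 - 2.0 * bracket**2)


def slowness_estimate(t_s: float, l: float, sigma_t: float, sigma_s: float, sigma_v: float) -> float:
    """Solve the implicit slowness equation for the time estimate ``t_e``.

    Returns the smallest root ``t_e ≥ t_s`` of ``t_s = rhs(t_e)`` with
    back-substitution residual below 1e−9 s.  ``l = 0`` short-circuits to
    ``t_s`` exactly (no separation, no illusion); this also avoids the
    0·∞ indeterminacy when σ_s(0) = 0 under horizontal-only eccentricity.
    """
    if t_s <= 0:
        raise ValueError("sample interval must be positive")
    if l < 0:
        raise ValueError("separation l must be non-negative")
    if l == 0.0:
        return float(t_s)
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive when l > 0")
    if sigma_t == 0 or sigma_v == 0:
        return float(t_s)
    out = slowness_estimate_many(t_s, np.array([l]), sigma_t, np.array([sigma_s]), sigma_v)
    return float(out[0])


def slowness_estimate_many(t_s: float, l: np.ndarray, sigma_t: float, sigma_s: np.ndarray, sigma_v: float) -> np.ndarray:
    """Vectorised slowness estimates over arrays of separations.

    Root finding uses a geometrically expanded bracket [t_s, upper] followed
    by bisection to machine-level precision; every root is verified by
    back-substitution (residual < 1e−9 s).
    """
    if t_s <= 0:
        raise ValueError("sample interval must be positive")
    l = np.asarray(l, dtype=float)
    sigma_s = np.broadcast_to(np.asarray(sigma_s, dtype=float), l.shape).copy()
    if np.any(l < 0):
        raise ValueError("separation l must be non-negative")
    active = l > 0
    if np.any(sigma_s[active] <= 0):
        raise ValueError("sigma_s must be positive when l > 0")
    out = np.full(l.shape, float(t_s))
    if not np.any(active) or sigma_t == 0 or sigma_v == 0:
        return out

    la, sa = l[active], sigma_s[active]

    def f(te):
        return _slowness_rhs(te, la, sigma_t, sa, sigma_v) - t_s

    # rhs(t_e) <= t_e so f(t_s) <= 0; expand the upper bracket until f > 0.
    lo = np.full(la.shape, float(t_s))
    hi = np.full(la.shape, 10.0 * t_s)
    fhi = f(hi)
    for _ in range(60):
        need = fhi <= 0
        if not np.any(need):
            break
        hi[need] *= 2.0
        fhi = f(hi)
    if np.any(fhi <= 0):
        i = int(np.argmax(fhi <= 0))
        raise SlownessRootError(t_s, float(la[i]), sigma_t, float(sa[i]), sigma_v)

    # Bisection against the first sign change above t_s; 64 halvings put
    # the bracket width far below 1e-12 s at these magnitudes.
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    root = 0.5 * (lo + hi)
    resid = np.abs(_slowness_rhs(root, la, sigma_t, sa, sigma_v) - t_s)
    if np.any(resid > 1e-9):
        i = int(np.argmax(resid))
        raise SlownessRootError(t_s, float(la[i]), sigma_t, float(sa[i]), sigma_v)
    out[active] = root
    return out
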