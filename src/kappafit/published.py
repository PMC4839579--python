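"""Published per-subject parameter estimates and model-comparison values.

These are the reported best-fitting parameters of the two observer models
for the nine subjects of the original two-interval Kappa experiment, plus
the reported per-subject AIC table.  They serve two purposes: seeding the
synthetic-data generator with realistic, empirically grounded parameter
values, and providing the inputs for the AIC-difference bookkeeping checks.
"""

from __future__ import annotations

import pandas as pd

from .models import GRATING, VERNIER, ClassicalParams, SlownessParams

SUBJECTS = [f"S{i}" for i in range(1, 10)]

# columns: omega_0.8, omega_1.2, v0 (deg/s), wp
CLASSICAL_TABLE = {
    "S1": (0.9983, 0.9986, 0.2290, 0.1501),
    "S2": (0.9989, 0.9993, 0.1851, 0.1652),
    "S3": (0.9995, 0.9986, 0.2107, 0.1400),
    "S4": (0.9979, 0.9999, 0.2161, 0.1266),
    "S5": (0.9990, 0.9979, 0.2139, 0.1295),
    "S6": (0.9996, 0.9994, 0.1752, 0.1246),
    "S7": (0.9984, 0.9995, 0.2065, 0.2581),
    "S8": (0.9999, 0.9987, 0.2638, 0.2657),
    "S9": (0.9990, 0.9994, 0.2764, 0.2594),
    "Mean": (0.9989, 0.9990, 0.2196, 0.1799),
}

# columns: sigma_t_0.8 (s), sigma_t_1.2 (s), sigma_v (deg/s), wp
SLOWNESS_TABLE_VERNIER = {
    "S1": (0.0068, 0.0076, 0.2531, 0.1499),
    "S2": (0.0060, 0.0056, 0.2210, 0.1650),
    "S3": (0.0043, 0.0077, 0.1616, 0.1394),
    "S4": (0.0081, 0.0022, 0.1701, 0.1248),
    "S5": (0.0181, 0.0510, 1.8804, 0.1299),
    "S6": (0.0170, 0.0355, 2.5765, 0.1248),
    "S7": (0.0079, 0.0048, 0.1343, 0.2556),
    "S8": (0.0052, 0.0380, 2.1775, 0.2659),
    "S9": (0.0098, 0.0065, 0.0580, 0.2566),
    "Mean": (0.0092, 0.0177, 0.8481, 0.1791),
}

SLOWNESS_TABLE_GRATING = {
    "S1": (0.0107, 0.0121, 0.4085, 0.1499),
    "S2": (0.0094, 0.0089, 0.3595, 0.1650),
    "S3": (0.0066, 0.0121, 0.2626, 0.1394),
    "S4": (0.0127, 0.0034, 0.2779, 0.1249),
    "S5": (0.0235, 0.0657, 2.4121, 0.1299),
    "S6": (0.0180, 0.0372, 2.6780, 0.1248),
    "S7": (0.0122, 0.0075, 0.2220, 0.2556),
    "S8": (0.0046, 0.0327, 1.8416, 0.2659),
    "S9": (0.0137, 0.0093, 0.1043, 0.2567),
    "Mean": (0.0124, 0.0210, 0.9518, 0.1791),
}

# Reported per-subject AIC (and the published AIC differences Δ) for the
# classical model (CM) and the slowness model with Vernier (SMV) / grating
# (SMG) acuity, per sample-interval condition.
AIC_TABLE = pd.DataFrame(
    [
        # subject, cond, CM_aic, CM_delta, SMV_aic, SMV_delta, SMG_aic, SMG_delta
        ("S1", 0.8, -707, 1, -708, 0, -708, 0),
        ("S2", 0.8, -555, 1, -556, 0, -556, 0),
        ("S3", 0.8, -905, 4, -909, 0, -908, 1),
        ("S4", 0.8, -650, 16, -666, 0, -666, 0),
        ("S5", 0.8, -755, 4, -759, 0, -759, 0),
        ("S6", 0.8, -908, 6, -915, 0, -914, 1),
        ("S7", 0.8, -119, 7, -126, 0, -126, 0),
        ("S8", 0.8, -205, 1, -206, 0, -205, 1),
        ("S9", 0.8, -64, 7, -71, 0, -71, 0),
        ("S1", 1.2, -334, 2, -336, 0, -336, 0),
        ("S2", 1.2, -306, 0, -306, 0, -305, 1),
        ("S3", 1.2, -392, 1, -393, 0, -393, 0),
        ("S4", 1.2, -863, 8, -871, 0, -871, 0),
        ("S5", 1.2, -680, 1, -681, 0, -681, 0),
        ("S6", 1.2, -728, 0, -727, 1, -727, 1),
        ("S7", 1.2, 406, 0, 406, 0, 406, 0),
        ("S8", 1.2, 469, 2, 467, 0, 467, 0),
        ("S9", 1.2, 293, 1, 292, 0, 292, 0),
    ],
    columns=["subject_id", "condition", "CM_aic", "CM_delta", "SMV_aic", "SMV_delta", "SMG_aic", "SMG_delta"],
)

# Reported group response biases: mean and SE (s) by condition and visual
# field (same-location control experiment).
LOCATION_BIAS_TABLE = pd.DataFrame(
    {
        "condition": [0.8, 0.8, 0.8, 1.2, 1.2, 1.2],
        "location_deg": [-12.0, 0.0, 12.0, -12.0, 0.0, 12.0],
        "mean_bias_s": [0.134, 0.133, 0.146, 0.047, 0.054, 0.057],
        "se_s": [0.056, 0.038, 0.059, 0.042, 0.028, 0.042],
    }
)


def classical_params(subject: str = "Mean") -> ClassicalParams:
    """Published constant-speed parameters for one subject (or the mean row)."""
    w08, w12, v0, wp = CLASSICAL_TABLE[subject]
    return ClassicalParams(omega_by_condition={0.8: w08, 1.2: w12}, v0=v0, wp=wp)


def slowness_params(subject: str = "Mean", acuity: str = "vernier") -> SlownessParams:
    """Published slowness parameters for one subject under one acuity law."""
    table = SLOWNESS_TABLE_VERNIER if acuity == "vernier" else SLOWNESS_TABLE_GRATING
    s08, s12, sv, wp = table[subject]
    return SlownessParams(
        sigma_t_by_condition={0.8: s08, 1.2: s12},
        sigma_v=sv,
        wp=wp,
        acuity=VERNIER if acuity == "vernier" else GRATING,
    )
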