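"""Published vital-rate coefficient estimates for eastern Canadian boreal caribou.

These are the fixed-effect estimates (logit scale) reported for the
six-population, ten-year monitoring program that motivates this package:
adult-female survival and calf/female recruitment modelled against the
proportion of total landscape disturbance (D) and the proportion of
potentially productive forest stands (P; squared for recruitment).

They serve two roles here: as defaults for the synthetic-data generator
(the generating "truth"), and as ready-made models for threshold and
prediction examples when no raw monitoring data are at hand.
"""

from __future__ import annotations

import numpy as np

# survival: logit S = b0 + bD * D + bP * P
SURVIVAL_BETA = np.array([1.67, -0.77, 1.22])
SURVIVAL_SE = np.array([0.29, 0.29, 0.54])
SURVIVAL_NAMES = ("intercept", "disturbance", "productivity")

# recruitment (calf/female ratio): logit R = b0 + bD * D_lagged + bP2 * P**2
RECRUITMENT_BETA = np.array([-0.15, -5.05, 2.41])
RECRUITMENT_SE = np.array([0.59, 0.14, 1.22])
RECRUITMENT_NAMES = ("intercept", "disturbance", "productivity_sq")

# Observed covariate ranges across the monitored ranges.
D_RANGE = (0.22, 0.78)
P_RANGE = (0.04, 0.85)

# Aggregate sexed classification counts from the aerial surveys, used to
# justify the 65% female assumption for heavily-unclassified surveys.
SEXED_SURVEY_MALES = 246
SEXED_SURVEY_FEMALES = 453
ASSUMED_FEMALE_FRACTION = 0.65

# Monitoring filters.
MIN_COLLARED_PER_YEAR = 6
MIN_SURVEY_INDIVIDUALS = 50


def published_survival_model():
    """Survival model assembled from the published point estimates.

    The covariance is diagonal (only standard errors were published), which
    is adequate for the worked examples and threshold illustrations; fits to
    actual data carry a full covariance.
    """
    from .vital_rate_models import VitalRateModel

    return VitalRateModel(
        rate="survival",
        beta=SURVIVAL_BETA.copy(),
        names=SURVIVAL_NAMES,
        vcov=np.diag(SURVIVAL_SE**2),
        sigma_pop=0.0,
        n_obs=0,
    )


def published_recruitment_model():
    """Recruitment model assembled from the published point estimates."""
    from .vital_rate_models import VitalRateModel

    return VitalRateModel(
        rate="recruitment",
        beta=RECRUITMENT_BETA.copy(),
        names=RECRUITMENT_NAMES,
        vcov=np.diag(RECRUITMENT_SE**2),
        sigma_pop=0.0,
        n_obs=0,
    )
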