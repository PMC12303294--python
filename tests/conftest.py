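"""Shared fixtures: reference coefficient rows used across the suite.

The coefficient sets below are the fitted parameter rows for cancers
best described by each model family (linear: bladder, brain; convex:
nasopharynx, other pharynx; concave: Hodgkin lymphoma, leukemia), used
here as generating truths for synthetic series.
"""

import pytest
from hypothesis import settings

from multistage import CurvedParams, LinearParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BLADDER_MALE = LinearParams.from_slope_intercept(2.644, -1.236)
BLADDER_FEMALE = LinearParams.from_slope_intercept(2.114, -1.713)
BRAIN_MALE = LinearParams.from_slope_intercept(1.216, 0.029)
BRAIN_FEMALE = LinearParams.from_slope_intercept(1.167, -0.155)

# internally consistent curved rows (coefficient cells match k_p = exp(a0),
# k_q = a2 * k_p); keyed by "<cancer>_<gender>"
CURVED_ROWS = {
    "nasopharynx_male": CurvedParams(-0.54, 2.797, 0.73, 0.14, "convex"),
    "nasopharynx_female": CurvedParams(-1.36, 2.797, 0.73, 0.14, "convex"),
    "nasopharynx_both": CurvedParams(-0.845, 2.797, 0.73, 0.14, "convex"),
    "pharynx_male": CurvedParams(-0.485, 2.844, 0.47, 0.33, "convex"),
    "pharynx_female": CurvedParams(-0.642, 2.5295, 0.77, 0.11, "convex"),
    "pharynx_both": CurvedParams(-0.277, 2.814, 0.69, 0.16, "convex"),
    "hodgkin_male": CurvedParams(-0.036, 0.1405, 0.007, 2.1, "concave"),
    "hodgkin_female": CurvedParams(0.7843, -1.6493, 0.039, 2.9, "concave"),
    "hodgkin_both": CurvedParams(0.1634, -0.3739, 0.025, 2.1, "concave"),
    "leukemia_male": CurvedParams(1.15, -0.8291, 0.09, 2.75, "concave"),
    "leukemia_female": CurvedParams(0.8742, -0.8291, 0.11, 2.75, "concave"),
}


@pytest.fixture
def bladder_male():
    return BLADDER_MALE
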