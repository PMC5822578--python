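import copy

import numpy as np
import pytest

from hippolcs import (
    LatentChangeScoreModel,
    apply_attrition,
    build_model_spec,
    default_calibration,
    generate_cohort,
    residualize_table,
)

SMALL_MAP = {
    "logical_memory": "verbal_memory",
    "verbal_pairs": "verbal_memory",
    "spatial_span": "working_memory",
    "digit_backward": "working_memory",
    "letter_number": "working_memory",
}

# sub-model without any 2-indicator factor: with only two indicators a
# factor's variance is weakly identified under a null (zero cross-correlation)
# calibration, which distorts delta-method SEs in ways the full model does
# not show; coverage checks use this roster instead
WMSP_MAP = {
    "spatial_span": "working_memory",
    "digit_backward": "working_memory",
    "letter_number": "working_memory",
    "digit_symbol": "speed",
    "symbol_search": "speed",
    "choice_rt": "speed",
    "inspection_time": "speed",
}


def small_spec(biomarker="md"):
    """Two-domain sub-model (12 observed variables) for fast property tests."""
    return build_model_spec(biomarker, SMALL_MAP)


def null_config():
    """Calibration with every biomarker-cognition and cognitive-cognitive
    structural correlation set to zero (change means kept)."""
    cfg = default_calibration()
    cfg = copy.deepcopy(cfg)
    for bio in cfg.biomarkers.values():
        for kind in bio.paths:
            bio.paths[kind] = {d: 0.0 for d in bio.paths[kind]}
    for d1 in cfg.domain_level_corr:
        for d2 in cfg.domain_level_corr[d1]:
            cfg.domain_level_corr[d1][d2] = 0.0
    cfg.domain_level_change_corr = {d: 0.0 for d in cfg.domain_level_change_corr}
    cfg.cross_domain_change_corr = 0.0
    cfg.cross_domain_level_change_corr = 0.0
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def config():
    return default_calibration()


@pytest.fixture(scope="session")
def cohort(config):
    """Complete (pre-attrition) cohort at the study's wave-2 size."""
    return generate_cohort(config, seed=42)


@pytest.fixture(scope="session")
def attrited(config, cohort):
    return apply_attrition(cohort, config, seed=43)


@pytest.fixture(scope="session")
def residualized(attrited):
    return residualize_table(attrited)


@pytest.fixture(scope="session")
def md_model(residualized):
    """One fully fitted MD model (with SEs and fit indices), reused widely."""
    return LatentChangeScoreModel(biomarker="md").fit(residualized)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
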