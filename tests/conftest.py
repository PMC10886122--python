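"""Shared fixtures: small synthetic cohorts with reduced IDP blocks.

Reduced block sizes keep model fits fast while preserving the three-block
multimodal structure every stage expects.
"""

import pytest

from aba_subtypes import GeneratorConfig, generate_cohort

SMALL_BLOCKS = {"sMRI": 6, "dMRI": 5, "rsfMRI": 6}


@pytest.fixture(scope="session")
def small_cohort():
    """120 subjects, 17 IDPs, 3 planted subtypes."""
    cfg = GeneratorConfig(n_subjects=120, block_sizes=SMALL_BLOCKS, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """800 subjects, 70 IDPs — enough for stable model fits."""
    cfg = GeneratorConfig(
        n_subjects=800,
        block_sizes={"sMRI": 30, "dMRI": 20, "rsfMRI": 20},
        seed=7,
    )
    return generate_cohort(cfg)
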