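import numpy as np
import pytest

from hemegxe import (
    SimulationConfig,
    generate_platform_annotation,
    load_pathway,
    simulate_cohort,
)
from hemegxe.pathway import HEME_PATHWAY_FILE


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic, exposure or interaction effects."""
    cfg = SimulationConfig(n_cases=150, n_controls=250, n_snps=30, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort whose first SNP carries marginal and interaction effects."""
    cfg = SimulationConfig(
        n_cases=400,
        n_controls=600,
        n_snps=5,
        or_snp=1.5,
        or_interaction=1.8,
        maf_range=(0.3, 0.5),
        seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def heme_template():
    return load_pathway(HEME_PATHWAY_FILE)


@pytest.fixture(scope="session")
def platform(heme_template):
    """Annotation large enough to match the heme template many times over."""
    annotation, panel = generate_platform_annotation(
        600, heme_template.snp_counts, seed=3
    )
    return annotation, panel
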