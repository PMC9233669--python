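import numpy as np
import pytest

from kseqland.synthetic_data import (
    ExperimentDesign,
    FamilySpec,
    build_landscape,
    noiseless_design,
    simulate_kseq,
)

ALPHA = 0.479
T_MIN = 90.0
CONCENTRATIONS = (1250.0, 250.0, 50.0, 10.0, 2.0)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_center():
    return "ACGTACGTACGTACGTACGTA"


@pytest.fixture(scope="session")
def small_family_spec(small_center):
    return FamilySpec(
        name="toy",
        center=small_center,
        inactive_fraction=0.5,
        cross_substrate_correlation=0.8,
        specificity_coupling=0.5,
    )


@pytest.fixture(scope="session")
def tiny_dataset(small_family_spec):
    """Small noiseless end-to-end dataset: one family, exact fractions."""
    design = noiseless_design(ExperimentDesign())
    landscape = build_landscape([small_family_spec], design, seed=11)
    return simulate_kseq(landscape, design, seed=12)
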