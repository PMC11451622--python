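import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tmepredict import (
    PlantedCCI,
    SyntheticSpec,
    generate_deconvolved_fixture,
    generate_sc_cohort,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def signal_spec(seed: int = 1, n_patients: int = 80, effect: float = 1.5) -> SyntheticSpec:
    """Cohort with ten response-predictive genes planted in myeloid cells."""
    genes = [f"G{i:04d}" for i in range(1, 11)]
    return SyntheticSpec(
        n_patients=n_patients,
        n_genes=200,
        cell_types=("B-cells", "myeloid", "T-cells"),
        signal_genes={"myeloid": (genes, effect)},
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """80-patient deconvolved cohort with a planted myeloid signal."""
    return generate_deconvolved_fixture(signal_spec(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small unplanted cohort for fast structural tests."""
    spec = SyntheticSpec(
        n_patients=24,
        n_genes=60,
        cell_types=("B-cells", "myeloid"),
        cells_per_patient_per_type=10,
        seed=3,
    )
    return generate_deconvolved_fixture(spec)


@pytest.fixture(scope="session")
def small_sc():
    """Small single-cell cohort (3 cell types, 12 patients)."""
    spec = SyntheticSpec(
        n_patients=12,
        n_genes=50,
        cell_types=("B-cells", "myeloid", "T-cells"),
        cells_per_patient_per_type=(5, 20),
        seed=5,
    )
    return generate_sc_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
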