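import numpy as np
import pytest

from thermofoot.cohort import CohortRecord, LabeledCohort
from thermofoot.core import Group, Side, Thermogram
from thermofoot.synthetic import PhantomConfig, generate_cohort, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_thermogram():
    """Uniform 26 degC matrix, trivially partitionable."""
    return Thermogram(np.full((20, 10), 26.0), subject_id="flat", side=Side.RIGHT)


@pytest.fixture
def phantom_grade3():
    cfg = PhantomConfig(target_grade=3, target_tci=3.5, seed=11)
    return generate_phantom(cfg)


@pytest.fixture
def noise_free_cohort():
    """Small noise-free cohort, 3 per class."""
    return generate_cohort({g: 3 for g in range(6)}, seed=101, noise_sd=0.0)


def make_labeled_cohort(class_sizes: dict[int, int], shape=(20, 10)) -> LabeledCohort:
    """Cheap hand-built cohort for balancing tests (no phantom machinery)."""
    records = []
    i = 0
    for cls, n in sorted(class_sizes.items()):
        for _ in range(n):
            temps = np.full(shape, 24.0 + cls)
            group = Group.CONTROL if cls == 0 else Group.DIABETIC
            t = Thermogram(temps, subject_id=f"T{i:03d}", side=Side.RIGHT, group=group)
            records.append(CohortRecord(thermogram=t, label=cls))
            i += 1
    return LabeledCohort(records=records)
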