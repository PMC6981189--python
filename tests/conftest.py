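import numpy as np
import pytest

from technome.tables import Cohort, CohortLabels, RadiomeMatrix, SurrogateMatrix
from technome.synthetic import (
    copd_like,
    generate_perturbation_series,
    generate_phantom_series,
    make_cohort,
)


@pytest.fixture
def tiny_cohort():
    """Handmade 6-row cohort with one exact linear surrogate relation."""
    rng = np.random.default_rng(42)
    n = 6
    s0 = np.arange(n, dtype=float)
    s1 = rng.normal(size=n)
    r0 = 2.0 * s0 + 5.0
    r1 = rng.normal(size=n)
    ids = [f"p{i}" for i in range(n)]
    radiome = RadiomeMatrix(np.column_stack([r0, r1]), ids, ["fa", "fb"])
    surrogates = SurrogateMatrix(
        np.column_stack([s0, s1]), ids, ["air_mean", "liver_sd"],
        {"air_mean": "air", "liver_sd": "liver"},
    )
    labels = CohortLabels(np.array([0, 1, 0, 1, 0, 1]), ids)
    return Cohort(radiome, surrogates, labels)


@pytest.fixture(scope="session")
def preset_cohort():
    """One headline preset cohort with perturbation and phantom series."""
    cohort, truth = make_cohort(copd_like(11, n_patients=300))
    pert = generate_perturbation_series(cohort.radiome, cohort.surrogates, truth, seed=12)
    phan = generate_phantom_series(truth, seed=13)
    return cohort, truth, {"perturbation": pert, "phantom": phan}
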