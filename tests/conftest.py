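import warnings

import numpy as np
import pandas as pd
import pytest

from cistrat.synthetic import (
    CohortSpec,
    default_proportions,
    default_signature,
    gen_bulk,
    gen_cohort,
    gen_droplets,
    gen_ihc_counts,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=pd.errors.PerformanceWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared across tests (fixed seed)."""
    spec = CohortSpec(n_controls=12, n_ipd=40, seed=123)
    subjects, truth = gen_cohort(spec)
    records = gen_ihc_counts(subjects, truth, seed=124, regions=["PFC", "SNpc"])
    return spec, subjects, truth, records


@pytest.fixture(scope="session")
def bulk_mixture():
    """Synthetic bulk mixture with planted GABAergic decrease in CI-PD."""
    rng = np.random.default_rng(7)
    n = 60
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "sex": rng.choice(["M", "F"], n),
            "bulk_group": ["control"] * (n // 2) + ["CI-PD"] * (n // 2),
            "age": rng.normal(80, 6, n),
            "pmi": rng.lognormal(3, 0.5, n),
            "cohort": rng.choice(["NOR", "ESP"], n),
        }
    )
    signature, markers = default_signature(seed=7)
    proportions = default_proportions(subjects, seed=7)
    counts, meta = gen_bulk(subjects, signature, proportions, seed=7)
    return counts, meta, markers, proportions


@pytest.fixture(scope="session")
def droplet_data():
    """Default-sized droplet simulation with truth labels (fixed seed)."""
    adata, truth = gen_droplets(seed=42)
    return adata, truth
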