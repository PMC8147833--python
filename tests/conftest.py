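import numpy as np
import pandas as pd
import pytest

from mirdmi.pipeline import PipelineConfig, clean_records
from mirdmi.synthetic import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def small_cohort():
    """Default-conditions cohort shared across tests: 40 cows per country."""
    records, truth = generate_population(
        GeneratorConfig(seed=7, n_cows_per_country=40))
    return records, truth


@pytest.fixture(scope="session")
def cleaned_small(small_cohort):
    """The same cohort after range/GH filtering and window selection."""
    records, _ = small_cohort
    clean, report, counts = clean_records(records, PipelineConfig())
    return clean, report, counts


@pytest.fixture()
def tiny_records():
    """Hand-built minimal record table (no spectra) for fold/metric tests."""
    rng = np.random.default_rng(0)
    rows = []
    for country, n_cows, weeks in (("A", 6, 4), ("B", 5, 6)):
        for i in range(n_cows):
            for w in range(1, weeks + 1):
                rows.append({
                    "cow_id": f"{country}{i}", "country": country,
                    "parity": int(rng.integers(1, 4)), "wol": w,
                    "my": 25.0 + rng.normal(), "dmi": 20.0 + rng.normal(),
                    "pbw": 600.0, "pfat": 4.2, "pprot": 3.4, "plact": 4.8,
                })
    return pd.DataFrame(rows)
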