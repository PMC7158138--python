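import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import autoreg as ar

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """One full default-config protocol simulation shared across tests."""
    cfg = ar.SimConfig(seed=0)
    ds, truth = ar.simulate_experiment(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def default_windows(default_sim):
    _, ds, _ = default_sim
    return ar.extract_dose_windows(ds)


@pytest.fixture(scope="session")
def default_indices(default_windows):
    return ar.compute_indices(default_windows)


def make_recording(
    n_animals=1,
    n_samples=60,
    doses=(0.0,),
    condition="baseline",
    drug="phenylephrine",
    lumbar_missing=(),
    seed=0,
) -> pd.DataFrame:
    """Small hand-rolled recording frame in the canonical column layout."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        animal = f"A{a + 1:02d}"
        for dose in doses:
            for i in range(n_samples):
                rows.append(
                    {
                        "animal_id": animal,
                        "condition": condition,
                        "drug": drug,
                        "dose_ug_kg_min": dose,
                        "t_s": 10.0 * i,
                        "map_mmHg": 60.0 + rng.normal(0, 3),
                        "toi_cerebral_pct": 65.0 + rng.normal(0, 1),
                        "toi_thoracic_pct": 48.0 + rng.normal(0, 1),
                        "toi_lumbar_pct": (
                            np.nan if animal in lumbar_missing else 53.0 + rng.normal(0, 1)
                        ),
                    }
                )
    return pd.DataFrame(rows)
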