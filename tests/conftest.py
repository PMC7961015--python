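import numpy as np
import pandas as pd
import pytest

import dcisprofiler as dp


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with default artifact rates for QC tests."""
    cfg = dp.SimulationConfig(n_patients=12, bce_fraction=4 / 12,
                              cells_per_patient_mean=400,
                              cells_per_patient_dispersion=None, seed=11)
    return dp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Artifact-free single-slide cohort: the preprocessing chain inverts
    the generator exactly on this data."""
    cfg = dp.SimulationConfig(
        n_patients=8, bce_fraction=0.25, cells_per_patient_mean=400,
        cells_per_patient_dispersion=None,
        artifact_rates=dp.ArtifactRates(0.0, 0.0, 0.0, 0.0),
        stromal_fraction=0.0, n_slides=1, slide_offsets=(0.0,), seed=5)
    return dp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def archetype_cells():
    """10k cells drawn straight from the six default archetypes (z-space)."""
    rng = np.random.default_rng(73)
    arch = dp.default_archetypes()
    means = np.array([a.mean_z for a in arch])
    sds = np.array([a.sd_z for a in arch])
    labels = rng.integers(0, 6, size=10000)
    X = means[labels] + sds[labels] * rng.standard_normal((10000, 4))
    return X, labels + 1


def profiles_frame(profiles: np.ndarray, prefix: str = "P") -> pd.DataFrame:
    """Wrap a (n, 6) proportion array as a canonical profile table."""
    return pd.DataFrame(profiles,
                        columns=[f"cluster_{c}" for c in range(1, 7)],
                        index=pd.Index([f"{prefix}{i:04d}"
                                        for i in range(len(profiles))],
                                       name="patient_id"))
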