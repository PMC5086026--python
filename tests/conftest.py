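import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from panelweight import ArchetypeSpec, PipelineConfig, generate_population
from panelweight.features import VECTOR_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_pop():
    """Default-archetype population, small enough for fast end-to-end runs."""
    return generate_population(n_patients=1200, seed=7)


def recovery_archetypes() -> list[ArchetypeSpec]:
    """Five planted archetypes with cleanly separated rate profiles.

    The two low-PCP archetypes differ 8x in telephone rate (so round-1
    k-means merges them and the round-2 split separates them), the two
    medium archetypes differ ~7x in specialty rate, and the heavy archetype
    is 3x the medium PCP rate.  Every differentiating rate pair is >= 3x.
    """
    def mk(name, pcp, tel, spec):
        return ArchetypeSpec(
            name=name,
            rates=dict(pcp_visit=pcp, telephone=tel, specialty_visit=spec),
            med_count_mean=0.0,
            mixture_weight=0.2,
        )

    return [
        mk("b1", 3, 1, 1),
        mk("b2", 3, 8, 1),
        mk("m1", 12, 5, 3),
        mk("m2", 12, 5, 20),
        mk("h", 36, 14, 7),
    ]


def zero_vectors(patient_ids) -> pd.DataFrame:
    return pd.DataFrame(
        0.0, index=pd.Index(patient_ids, name="patient_id"),
        columns=VECTOR_COLUMNS,
    )


def random_vectors(n: int, seed: int = 0, scale: float = 3.0) -> pd.DataFrame:
    """Poisson visit-vector table for property tests."""
    rng = np.random.default_rng(seed)
    df = zero_vectors([f"p{i}" for i in range(n)])
    for col in VECTOR_COLUMNS:
        df[col] = rng.poisson(scale, size=n).astype(float)
    df["raw_pcp"] = rng.poisson(scale, size=n).astype(float)
    df["effective_pcp"] = df["raw_pcp"] * rng.choice([1.0, 1.5, 1.75], size=n)
    return df
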