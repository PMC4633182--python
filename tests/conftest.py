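import numpy as np
import pytest

from numobat import (
    GeneratorConfig,
    SpeciesProfile,
    TraitVector,
    generate_dataset,
    nylanderi_group_profiles,
    scale_separation,
)
from numobat.core import TRAIT_NAMES

# A plausible mid-sized worker used as a template in unit tests (μm).
BASE_TRAITS = {
    "CL": 640, "CWb": 540, "EL": 150, "FRS": 210, "ML": 715, "MW": 365,
    "NOdL": 160, "NOH": 105, "NOL": 150, "PEH": 225, "PEW": 155, "PL": 240,
    "PoOC": 245, "PPH": 175, "PPL": 135, "PPW": 205, "SL": 465, "SPL": 105,
    "SPBA": 160, "SPST": 170, "SPTI": 180, "SPWI": 195,
}


def make_traits(**overrides) -> TraitVector:
    values = dict(BASE_TRAITS)
    values.update(overrides)
    return TraitVector(values, check_window=False)


@pytest.fixture(scope="session")
def profiles():
    return nylanderi_group_profiles()


@pytest.fixture(scope="session")
def separated_profiles(profiles):
    """The 18 bundled profiles with sds shrunk to ≥6 pooled-sd separation."""
    return scale_separation(profiles, min_separation=6.0)


@pytest.fixture(scope="session")
def small_dataset(separated_profiles):
    """Compact 3-species dataset with clear separation (6 nests × 3 workers)."""
    config = GeneratorConfig(
        profiles=[
            p for p in separated_profiles
            if p.name in ("lichtensteini", "subtilis", "nylanderi")
        ],
        nests_per_species=6,
        workers_per_nest=3,
        seed=42,
    )
    return generate_dataset(config)


def two_gaussian_records(
    n_per_class=40, delta=10.0, sd=1.0, seed=0, trait="SPST", base=170.0
):
    """Two classes differing only in one trait; all other traits fixed.

    Returns (records, labels).  Used wherever a 1-D LDA oracle applies.
    """
    rng = np.random.default_rng(seed)
    from numobat.core import SpecimenRecord

    records, labels = [], []
    for ci, (name, mu) in enumerate((("A", base), ("B", base + delta))):
        for i in range(n_per_class):
            t = make_traits(**{trait: mu + rng.normal(0, sd)})
            records.append(
                SpecimenRecord(
                    specimen_id=f"{name}{i}",
                    nest_id=f"SYN:{name}-{i // 2 + 1}N-20200101-{i // 2 + 1}",
                    traits=t,
                    species=name,
                )
            )
            labels.append(name)
    return records, labels
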