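import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methscreen.pedigree import Pedigree
from methscreen.simulate import SimulationConfig, generate_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_pedigree(rows):
    """Build a Pedigree from (pedigree, individual, father, mother, sex, birth_order) tuples."""
    table = pd.DataFrame(
        rows,
        columns=["pedigree_id", "individual_id", "father_id", "mother_id", "sex", "birth_order"],
    )
    table["birth_order"] = table["birth_order"].astype("Int64")
    return Pedigree(table)


@pytest.fixture
def nuclear_ped():
    """Two founders with three children (birth orders 1..3)."""
    return make_pedigree(
        [
            ("F1", "dad", None, None, "male", None),
            ("F1", "mom", None, None, "female", None),
            ("F1", "kid1", "dad", "mom", "male", 1),
            ("F1", "kid2", "dad", "mom", "female", 2),
            ("F1", "kid3", "dad", "mom", "male", 3),
        ]
    )


@pytest.fixture
def three_gen_ped():
    """Three generations, 10 members: grandparents, two child couples, four grandchildren."""
    return make_pedigree(
        [
            ("G", "gpa", None, None, "male", None),
            ("G", "gma", None, None, "female", None),
            ("G", "son", "gpa", "gma", "male", 1),
            ("G", "dau", "gpa", "gma", "female", 2),
            ("G", "son_wife", None, None, "female", None),
            ("G", "dau_husb", None, None, "male", None),
            ("G", "gc1", "son", "son_wife", "male", 1),
            ("G", "gc2", "son", "son_wife", "female", 2),
            ("G", "gc3", "dau_husb", "dau", "male", 1),
            ("G", "gc4", "dau_husb", "dau", "female", 2),
        ]
    )


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study shared by read-only tests."""
    cfg = SimulationConfig(
        n_pedigrees=80,
        sibship_size_probs={2: 0.5, 3: 0.5},
        n_sites=400,
        site_class_fractions={"null": 0.975, "constitutive_meqtl": 0.0125, "responsive": 0.0125},
        seed=42,
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
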