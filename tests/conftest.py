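import numpy as np
import pandas as pd
import pytest

from ssnpatterns.core import TaxonomyPath, UNKNOWN
from ssnpatterns.pipeline import run_pipeline
from ssnpatterns.simulate import SyntheticSpec, synthesize


def make_tax(**labels) -> TaxonomyPath:
    """Syndiniales-flavoured taxonomy path with overridable ranks."""
    base = {
        "kingdom": "Eukaryota",
        "supergroup": "Alveolata",
        "division": "Dinoflagellata",
        "class": "Syndiniales",
        "order": "Dino-Group-II",
        "family": UNKNOWN,
        "genus": UNKNOWN,
        "species": UNKNOWN,
    }
    base.update(labels)
    return TaxonomyPath.from_mapping(base)


@pytest.fixture(scope="session")
def corpus():
    """One seeded synthetic corpus shared across read-only tests."""
    return synthesize(SyntheticSpec(seed=20))


@pytest.fixture(scope="session")
def pipeline_result(corpus):
    """The corpus pushed through harmonization, SSN and CC labelling."""
    return run_pipeline(corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def small_table():
    return pd.DataFrame(
        {"s1": [10.0, 30.0, 60.0], "s2": [5.0, 0.0, 0.0]},
        index=["m1", "m2", "m3"],
    )
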