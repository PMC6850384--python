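import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from traitflux import CommunityTimeSeries, TraitBlock, TraitMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_trait_matrix(rows, blocks):
    """Build a TraitMatrix from {taxon: flat affinity list} and block specs."""
    columns = pd.MultiIndex.from_tuples(
        [(b.name, c) for b in blocks for c in b.categories],
        names=["trait", "category"],
    )
    affinity = pd.DataFrame.from_dict(rows, orient="index")
    affinity.columns = columns
    return TraitMatrix(affinity=affinity, blocks=tuple(blocks))


@pytest.fixture
def two_taxon_contrast():
    """Two taxa, one 2-category fuzzy trait, fully opposed affinities."""
    block = TraitBlock("diet", ("a", "b"), "fuzzy")
    return make_trait_matrix({"t1": [1.0, 0.0], "t2": [0.0, 1.0]}, [block])


@pytest.fixture
def small_community():
    years = np.arange(2000, 2010)
    dens = pd.DataFrame(
        {
            "t1": np.linspace(1.0, 10.0, 10),
            "t2": np.full(10, 4.0),
            "t3": np.linspace(8.0, 2.0, 10),
        },
        index=pd.Index(years, name="year"),
    )
    return CommunityTimeSeries(density=dens, area="A", group="fish")
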