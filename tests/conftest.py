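import numpy as np
import pytest

from gcdiss.delineation import TaxonomyRecord, TaxonomyTable
from gcdiss.dissimilarity import DistanceMatrix
from gcdiss.profiles import OrthologProfile
from gcdiss.synth import CohortDesign, make_cohort


@pytest.fixture
def table1_pair():
    """The two-strain worked example: 9 vs 11 genes over OG1..OG5."""
    strain_i = OrthologProfile("I", {"OG1": 1, "OG2": 2, "OG3": 4, "OG5": 2})
    strain_j = OrthologProfile("J", {"OG1": 1, "OG2": 4, "OG3": 2, "OG4": 2, "OG5": 2})
    return strain_i, strain_j


@pytest.fixture(scope="session")
def default_cohort():
    """Separable synthetic cohort at the default study conditions."""
    return make_cohort(CohortDesign(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort used where pair-level hand counting is wanted."""
    return make_cohort(
        CohortDesign(
            n_orders=2,
            families_per_order=1,
            genera_per_family=2,
            species_per_genus=2,
            strains_per_species=2,
            genes_per_strain=300,
            seed=7,
        )
    )


@pytest.fixture
def two_species_taxonomy():
    return TaxonomyTable(
        {
            "s1": TaxonomyRecord("spA", "gen1", "fam1", "ord1"),
            "s2": TaxonomyRecord("spA", "gen1", "fam1", "ord1"),
            "s3": TaxonomyRecord("spB", "gen1", "fam1", "ord1"),
            "s4": TaxonomyRecord("spB", "gen1", "fam1", "ord1"),
        }
    )


def euclidean_dm(points, labels=None, scale=True):
    """DistanceMatrix of pairwise Euclidean distances, scaled into [0, 1]."""
    points = np.asarray(points, float)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    if scale and d.max() > 1:
        d = d / d.max()
    labels = labels or [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(labels, d)
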