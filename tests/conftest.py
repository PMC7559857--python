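import numpy as np
import pytest

from virofit.config import PipelineConfig
from virofit.simulate import SimulationDesign, simulate_pools
from virofit.taxonomy import TaxonomyNode, TaxonomyTree


@pytest.fixture(scope="session")
def seven_node_tree() -> TaxonomyTree:
    """Three-level fixture: root -> 2 families -> 4 species."""
    return TaxonomyTree(
        [
            TaxonomyNode(1, 1, "root", "root"),
            TaxonomyNode(10, 1, "family", "fam_a"),
            TaxonomyNode(20, 1, "family", "fam_b"),
            TaxonomyNode(11, 10, "species", "a1"),
            TaxonomyNode(12, 10, "species", "a2"),
            TaxonomyNode(21, 20, "species", "b1"),
            TaxonomyNode(22, 20, "species", "b2"),
        ]
    )


def random_tree(rng: np.random.Generator, n_nodes: int = 50) -> TaxonomyTree:
    """A random rooted tree with arbitrary topology (ranks unconstrained)."""
    nodes = [TaxonomyNode(1, 1, "root", "root")]
    ids = [1]
    for i in range(2, n_nodes + 1):
        parent = int(rng.choice(ids))
        nodes.append(TaxonomyNode(i, parent, "no_rank", f"n{i}"))
        ids.append(i)
    return TaxonomyTree(nodes)


@pytest.fixture(scope="session")
def small_design() -> SimulationDesign:
    """Compact study: two pools sharing two taxa; fast to search."""
    return SimulationDesign(
        n_pools=2,
        pool_names=("P0", "P1"),
        taxa_per_pool=6,
        shared_pairs={(0, 1): 2},
        n_circular=1,
        contaminant_subjects=1,
        n_broad_taxa=1,
        n_short_decoys=1,
        n_decoy_taxa=2,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_virome(small_design):
    return simulate_pools(small_design)


@pytest.fixture(scope="session")
def small_virome_dir(small_virome, tmp_path_factory):
    d = tmp_path_factory.mktemp("virome")
    small_virome.write(d)
    return d


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()
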