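import numpy as np
import pandas as pd
import pytest

import phyloturn as pt
from phyloturn.synthetic import ScenarioConfig

FOUR_TIP = "((A:1,B:1):2,(C:1,D:1):2);"


@pytest.fixture
def four_tip_tree() -> pt.Phylogeny:
    return pt.Phylogeny.from_newick(FOUR_TIP)


def small_bundle(tree: pt.Phylogeny, counts: dict, stages: dict,
                 env: pd.DataFrame | None = None) -> pt.AnalysisBundle:
    """Hand-built bundle from a counts dict {plot: {species: count}}."""
    community = (
        pd.DataFrame(counts).T.reindex(columns=list(tree.taxa)).fillna(0).astype(int)
    )
    stage = pd.Series(
        pd.Categorical([str(stages[p]) for p in community.index], ordered=True),
        index=community.index,
    )
    return pt.align_and_prune(tree, community, stage, env=env)


@pytest.fixture
def four_tip_bundle(four_tip_tree) -> pt.AnalysisBundle:
    return small_bundle(
        four_tip_tree,
        {"p1": {"A": 1, "B": 1}, "p2": {"C": 1, "D": 1}},
        {"p1": 1, "p2": 1},
    )


@pytest.fixture(scope="session")
def pool410() -> pt.Phylogeny:
    """One regional-pool phylogeny shared across tests (randomization tests
    are conditional on the tree)."""
    pool = pt.simulate_tree(410, seed=20240101)
    pool.cophenetic()
    return pool


@pytest.fixture(scope="session")
def pool64() -> pt.Phylogeny:
    pool = pt.simulate_tree(64, seed=20240202)
    pool.cophenetic()
    return pool


@pytest.fixture(scope="session")
def neutral_bundle(pool410) -> pt.AnalysisBundle:
    return pt.generate_bundle(ScenarioConfig(seed=77), pool=pool410)


@pytest.fixture(scope="session")
def deep_bundle(pool410) -> pt.AnalysisBundle:
    return pt.generate_bundle(
        ScenarioConfig(scenario="deep_filtering_late", seed=88), pool=pool410
    )


def random_instance(rng, n_species=None, n_plots=None):
    """Small random tree + community for oracle-equivalence checks."""
    n_species = n_species or int(rng.integers(4, 9))
    n_plots = n_plots or int(rng.integers(2, 5))
    tree = pt.simulate_tree(n_species, seed=int(rng.integers(2**31)))
    counts = rng.integers(0, 6, size=(n_plots, n_species))
    for k in range(n_plots):  # at least 2 species present per plot
        if (counts[k] > 0).sum() < 2:
            counts[k, rng.choice(n_species, 2, replace=False)] = 1
    return tree, counts
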