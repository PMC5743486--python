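"""Reading, validating, and aligning the five input artifacts.

Inputs are a dated Newick phylogeny of the regional species pool, a
plot x species abundance table (individual counts), a plot -> successional
stage map, a plot-level environmental table with x/y coordinates, and a
species x trait table.  Tables are delimited text (TSV or CSV, auto-detected)
with a header row and the identifier in the first column.

Name matching is exact after whitespace trimming and underscore/space
normalization; no fuzzy matching is attempted, because a silent mis-join is
worse than an error.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import Phylogeny, normalize_label

__all__ = [
    "AnalysisBundle",
    "read_newick",
    "read_community",
    "read_stage_map",
    "read_env",
    "read_traits",
    "read_tables",
    "apply_pool_filters",
    "align_and_prune",
    "cophenetic",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- phylogeny
def read_newick(
    path: str | Path,
    require_ultrametric: bool = True,
    ultrametric_rtol: float = 1e-6,
) -> Phylogeny:
    """Read a dated phylogeny from a Newick file (branch lengths required)."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(
        text,
        require_ultrametric=require_ultrametric,
        ultrametric_rtol=ultrametric_rtol,
    )


def write_newick(phylo: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylo.write_newick())


# -------------------------------------------------------------------- tables
def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Delimited table with header row, identifiers in the first column."""
    path = Path(path)
    sample = path.read_text()[:4096]
    try:
        delim = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        delim = "\t"
    df = pd.read_csv(path, sep=delim, index_col=0)
    df.index = [normalize_label(x) for x in df.index]
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate identifiers in {path}: {dupes}")
    return df


def read_community(path: str | Path) -> pd.DataFrame:
    """Plot x species counts; integer, nonnegative, every plot non-empty."""
    df = _read_delimited(path)
    df.columns = [normalize_label(c) for c in df.columns]
    vals = df.to_numpy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("community table contains missing values")
    if np.any(vals < 0):
        raise ValueError("community table contains negative counts")
    if np.any(vals != np.round(vals)):
        raise ValueError("community counts must be integers")
    df = df.astype(np.int64)
    empty = df.sum(axis=1) == 0
    if empty.any():
        raise ValueError(f"plots with zero individuals: {list(df.index[empty])}")
    return df


def read_stage_map(path: str | Path) -> pd.Series:
    """Plot -> successional stage, as an ordered categorical Series."""
    df = _read_delimited(path)
    if df.shape[1] < 1:
        raise ValueError("stage file needs a stage column")
    stages = df.iloc[:, 0].astype(str)
    order = sorted(stages.unique())
    return pd.Series(
        pd.Categorical(stages, categories=order, ordered=True),
        index=df.index,
        name="stage",
    )


def read_env(path: str | Path) -> pd.DataFrame:
    """Plot-level environmental variables including x, y coordinates."""
    df = _read_delimited(path)
    for coord in ("x", "y"):
        if coord not in df.columns:
            raise ValueError(f"environment table lacks coordinate column {coord!r}")
    if df[["x", "y"]].isna().any().any():
        raise ValueError("missing plot coordinates")
    return df.astype(float)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Species x trait table of real values (NaN = missing)."""
    df = _read_delimited(path)
    return df.astype(float)


_READERS = {
    "community": read_community,
    "stage": read_stage_map,
    "env": read_env,
    "trait": read_traits,
}


def read_tables(path: str | Path, kind: str):
    """Dispatching reader: ``kind`` in {community, stage, env, trait}."""
    try:
        reader = _READERS[kind]
    except KeyError:
        raise ValueError(f"unknown table kind {kind!r}") from None
    return reader(path)


# ------------------------------------------------------------- pool filtering
def apply_pool_filters(
    pool: Phylogeny, exclude: dict[str, list[str]]
) -> tuple[Phylogeny, dict[str, list[str]]]:
    """Prune the regional pool by named exclusion rules.

    ``exclude`` maps a rule label (e.g. ``"nonangiosperm"``, ``"bamboo"``,
    ``"cultivated"``) to a list of tip names to drop.  Names absent from the
    tree produce a warning, not an error.  Returns the pruned pool and a
    per-rule report of the tips actually removed.
    """
    report: dict[str, list[str]] = {}
    removed: set[str] = set()
    for rule, names in exclude.items():
        hits = []
        for name in names:
            key = normalize_label(name)
            if key in pool:
                if key not in removed:
                    hits.append(key)
                    removed.add(key)
            else:
                logger.warning("exclusion %r (%s): not in pool tree", name, rule)
        report[rule] = hits
    if not removed:
        return pool, report
    keep = [t for t in pool.taxa if t not in removed]
    if len(keep) < 2:
        raise ValueError("pool filtering would leave fewer than 2 tips")
    return pool.prune_to(keep), report


# ----------------------------------------------------------------- alignment
@dataclass
class AnalysisBundle:
    """All inputs aligned to a common species/plot universe.

    ``community`` columns are ordered exactly as ``tree.taxa``;
    ``pool_index[i]`` is the index of community species ``i`` in
    ``pool.taxa``, so a pool tip permutation ``perm`` maps the community's
    distance submatrix to ``D_pool[perm[pool_index]][:, perm[pool_index]]``.
    """

    pool: Phylogeny
    tree: Phylogeny
    community: pd.DataFrame
    stages: pd.Series
    env: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    pool_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.pool_index is None:
            self.pool_index = self.pool.index_of(self.community.columns)

    @property
    def plots(self) -> list[str]:
        return list(self.community.index)

    @property
    def species(self) -> list[str]:
        return list(self.community.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.community.to_numpy(dtype=float)

    @property
    def D_pool(self) -> np.ndarray:
        return self.pool.cophenetic()

    @property
    def D(self) -> np.ndarray:
        """Cophenetic distances among community species (tree taxa order)."""
        return self.tree.cophenetic()

    def stage_of(self, plot: str) -> str:
        return str(self.stages.loc[plot])

    def community_distances(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Community-species distance submatrix of the pool, optionally under
        a pool tip permutation (the randomization workhorse)."""
        idx = self.pool_index if perm is None else perm[self.pool_index]
        return self.D_pool[np.ix_(idx, idx)]


def align_and_prune(
    pool: Phylogeny,
    community: pd.DataFrame,
    stages: pd.Series,
    env: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
) -> AnalysisBundle:
    """Validate cross-references and build the aligned analysis bundle.

    Community species must be a subset of pool tips; every plot needs a
    stage; env plots must cover community plots.  All-zero species columns
    (possible after external pruning) are dropped with a logged notice.
    """
    community = community.copy()
    community.columns = [normalize_label(c) for c in community.columns]
    missing_sp = sorted(set(community.columns) - set(pool.taxa))
    if missing_sp:
        raise KeyError(f"community species absent from pool phylogeny: {missing_sp}")

    zero = community.sum(axis=0) == 0
    if zero.any():
        logger.info(
            "dropping %d all-zero species columns: %s",
            int(zero.sum()),
            list(community.columns[zero]),
        )
        community = community.loc[:, ~zero]

    empty_plots = community.sum(axis=1) == 0
    if empty_plots.any():
        raise ValueError(
            f"plots with zero individuals: {list(community.index[empty_plots])}"
        )

    missing_stage = sorted(set(community.index) - set(stages.index))
    if missing_stage:
        raise ValueError(f"plots without stage assignment: {missing_stage}")
    stages = stages.loc[community.index]

    if env is not None:
        missing_env = sorted(set(community.index) - set(env.index))
        if missing_env:
            raise ValueError(f"plots without environmental data: {missing_env}")
        env = env.loc[community.index]

    if traits is not None:
        traits = traits.copy()
        traits.index = [normalize_label(i) for i in traits.index]
        extra = sorted(set(traits.index) - set(pool.taxa))
        if extra:
            raise KeyError(f"trait species absent from pool phylogeny: {extra}")

    tree = pool.prune_to(list(community.columns))
    # reorder columns to the pruned tree's taxa order
    community = community.loc[:, list(tree.taxa)]
    return AnalysisBundle(
        pool=pool,
        tree=tree,
        community=community,
        stages=stages,
        env=env,
        traits=traits,
    )


def cophenetic(phylo: Phylogeny) -> np.ndarray:
    """Cophenetic (patristic) distance matrix of a phylogeny, in Myr."""
    return phylo.cophenetic()
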