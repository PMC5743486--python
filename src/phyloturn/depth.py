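"""Phylogenetic-depth decomposition of turnover.

Turnover is recomputed using only species pairs whose most recent common
ancestor (MRCA) is younger than a divergence-time threshold ``T`` (on an
ultrametric tree: ``d_ij < 2 T``), and tested against *partial*
randomizations that shuffle tip names only within maximal clades younger
than ``T``.  Sweeping ``T`` over a grid of ages yields an SES-versus-depth
profile per successional stage: a clustering signal that appears only at
large ``T`` indicates sorting among anciently diverged clades.

By default "younger than T" is strict (MRCA age < T); ties at exactly T are
excluded.  Pass ``inclusive=True`` for the <= convention.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnalysisBundle
from .nullmodels import null_distribution, significance, stage_statistic_fn
from .tree import Phylogeny
from .turnover import pair_deltas, pairwise_statistic

__all__ = [
    "threshold_grid",
    "pair_mask",
    "restricted_turnover",
    "young_clade_blocks",
    "partial_shuffle",
    "depth_profile",
]


def threshold_grid(
    min_age: float = 30.0, max_age: float = 128.0, step: float = 10.0
) -> np.ndarray:
    """Arithmetic grid of age thresholds (Myr), with the maximum appended.

    The default (30, 128, 10) yields the eleven thresholds
    30, 40, ..., 120, 128.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    grid = list(np.arange(min_age, max_age + 1e-9, step))
    if not grid or grid[-1] < max_age - 1e-9:
        grid.append(max_age)
    elif abs(grid[-1] - max_age) > 1e-9:
        grid.append(max_age)
    out = np.array(grid, dtype=float)
    if out.size == 0:
        raise ValueError("empty threshold grid")
    return out


def pair_mask(D: np.ndarray, T: float, inclusive: bool = False) -> np.ndarray:
    """Boolean species-pair filter: MRCA age < T (ultrametric: d < 2T)."""
    M = (D <= 2.0 * T) if inclusive else (D < 2.0 * T)
    M = M.copy()
    np.fill_diagonal(M, False)
    return M


def restricted_turnover(
    bundle: AnalysisBundle,
    mode: str,
    T: float,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Pairwise turnover using only species pairs with MRCA age below T.

    Plot pairs with no retained species pair are flagged undefined.
    """
    from .turnover import pairwise_turnover

    if T <= 0:
        raise ValueError("threshold must be positive")
    D = bundle.D
    return pairwise_turnover(bundle, mode, D=D, pair_mask=pair_mask(D, T, inclusive))


# -------------------------------------------------------------- partial null
def young_clade_blocks(
    phylo: Phylogeny, T: float, inclusive: bool = False
) -> list[np.ndarray]:
    """Tip-index blocks of the maximal clades younger than T.

    A depth-first walk from the root stops at the first node whose age is
    below T (<= T when ``inclusive``); its tip set becomes one shuffle block.
    Tips hanging directly below an older node form singleton blocks (returned
    only when larger than one tip, since singletons never move).
    """
    blocks: list[np.ndarray] = []

    def qualifies(age: float) -> bool:
        return age <= T if inclusive else age < T

    # map dendropy internal nodes to the cached node table (postorder order)
    internal_post = [n for n in phylo.tree.postorder_node_iter() if not n.is_leaf()]
    table_by_node = {id(n): phylo.nodes[i] for i, n in enumerate(internal_post)}

    stack = [phylo.tree.seed_node]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue  # singleton block; nothing to shuffle
        rec = table_by_node[id(node)]
        if qualifies(rec["age"]):
            if rec["tips"].size > 1:
                blocks.append(rec["tips"])
        else:
            stack.extend(node.child_nodes())
    return blocks


def partial_shuffle(
    blocks: Sequence[np.ndarray], n_tips: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation shuffling tip names independently within each block."""
    perm = np.arange(n_tips)
    for b in blocks:
        perm[b] = b[rng.permutation(b.size)]
    return perm


def make_partial_shuffler(
    phylo: Phylogeny, T: float | None, inclusive: bool = False
):
    """Shuffler closure for :func:`phyloturn.nullmodels.null_distribution`.

    ``T=None`` (or any T above the root age) reduces to the full 1p shuffle.
    """
    n = phylo.n_tips
    if T is None or T > phylo.root_age:
        return lambda rng: rng.permutation(n)
    blocks = young_clade_blocks(phylo, T, inclusive)
    return lambda rng: partial_shuffle(blocks, n, rng)


# ------------------------------------------------------------------- profile
def depth_profile(
    bundle: AnalysisBundle,
    mode: str = "presence",
    grid: np.ndarray | None = None,
    R: int = 999,
    rng: np.random.Generator | None = None,
    stages: Sequence[str] | None = None,
    alpha: float = 0.05,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Stage x threshold table of depth-restricted turnover and its SES.

    For every stage and threshold ``T``, the restricted within-stage
    turnover (mean over the stage's plot pairs) is compared against ``R``
    partial randomizations restricted to clades younger than ``T``;
    the standardized effect size is (obs - null mean) / null sd.
    """
    rng = np.random.default_rng() if rng is None else rng
    if grid is None:
        root = min(bundle.pool.root_age, 128.0)
        grid = threshold_grid(max_age=root)
    all_stages = sorted({str(s) for s in bundle.stages})
    if stages is None:
        stages = all_stages
    rows = []
    for T in np.asarray(grid, dtype=float):
        shuffler = make_partial_shuffler(bundle.pool, T, inclusive)
        mask_fn = lambda D, _T=T: pair_mask(D, _T, inclusive)  # noqa: E731
        for stage in stages:
            fn = stage_statistic_fn(
                bundle, mode, scope="within", stage=stage, pair_mask_fn=mask_fn
            )
            obs = fn(bundle.community_distances())
            # retained-pair diagnostics on the observed tree
            M = mask_fn(bundle.D)
            n_retained = int(M.sum() // 2)
            if not np.isfinite(obs):
                rows.append(
                    dict(stage=stage, threshold=T, statistic=np.nan, ses=np.nan,
                         p_two_sided=np.nan, significant=False,
                         n_pairs_retained=n_retained, defined=False)
                )
                continue
            null = null_distribution(
                fn, bundle, R=R, rng=rng, shuffler=shuffler,
                label=f"stage{stage}_T{T:g}",
            )
            res = significance(obs, null)
            rows.append(
                dict(
                    stage=stage,
                    threshold=T,
                    statistic=obs,
                    ses=res.ses,
                    p_two_sided=res.p_two_sided,
                    significant=bool(
                        np.isfinite(res.p_two_sided) and res.p_two_sided <= alpha
                    ),
                    n_pairs_retained=n_retained,
                    defined=True,
                )
            )
    return pd.DataFrame(rows)
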