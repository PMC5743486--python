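"""Ultrametric dated phylogenies and derived quantities.

The analyses in this package operate on a dated (ultrametric) phylogeny of a
regional species pool, with branch lengths in Myr.  This module wraps a
:class:`dendropy.Tree` and exposes the derived arrays everything else consumes:
the cophenetic (patristic) distance matrix ``d_ij``, node ages measured
backwards from the tip plane (tips at age 0), and per-clade tip-index sets
used by clade-restricted randomizations and node enrichment tests.
"""

from __future__ import annotations

import io as _io
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "normalize_label"]


def normalize_label(label: str) -> str:
    """Canonical species label: stripped, spaces folded to underscores."""
    return "_".join(str(label).strip().split())


class Phylogeny:
    """A rooted, dated phylogeny with cached derived matrices.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree`` with branch lengths (Myr).
    require_ultrametric:
        If True (default), reject trees whose root-to-tip path lengths differ
        by more than ``ultrametric_rtol`` relative to tree height.
    ultrametric_rtol:
        Relative tolerance of the ultrametricity check.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        require_ultrametric: bool = True,
        ultrametric_rtol: float = 1e-6,
    ):
        if len(tree.leaf_nodes()) < 2:
            raise ValueError("phylogeny must have at least 2 tips")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("all branches must have lengths")
            if edge.length < 0:
                raise ValueError(f"negative branch length: {edge.length}")
        labels = [normalize_label(lf.taxon.label) for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")

        self._tree = tree
        self.ultrametric_rtol = float(ultrametric_rtol)
        # Fix a stable tip order (input leaf order) and index map.
        self.taxa: tuple[str, ...] = tuple(labels)
        self._index = {name: i for i, name in enumerate(self.taxa)}

        self._depths = self._compute_depths()
        tip_depths = np.array(
            [self._depths[id(lf)] for lf in tree.leaf_node_iter()]
        )
        self._height = float(tip_depths.max())
        spread = float(tip_depths.max() - tip_depths.min())
        self._is_ultrametric = spread <= self.ultrametric_rtol * max(self._height, 1e-300)
        if require_ultrametric and not self._is_ultrametric:
            raise ValueError(
                f"tree is not ultrametric: root-to-tip depths span {spread:.6g} "
                f"(height {self._height:.6g}); pass require_ultrametric=False "
                "to accept it"
            )
        if not self._is_ultrametric:
            warnings.warn(
                "non-ultrametric tree accepted; node ages measured from the "
                "deepest tip plane",
                stacklevel=2,
            )
        self._cophenetic: np.ndarray | None = None
        self._nodes: list[dict] | None = None

    # ------------------------------------------------------------------ basic
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def is_ultrametric(self) -> bool:
        return self._is_ultrametric

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length (Myr) == root age for dated trees."""
        return self._height

    root_age = height

    def index_of(self, names: Iterable[str]) -> np.ndarray:
        """Tip indices for a sequence of (normalized) species names."""
        out = []
        for name in names:
            key = normalize_label(name)
            if key not in self._index:
                raise KeyError(f"tip not in phylogeny: {name!r}")
            out.append(self._index[key])
        return np.asarray(out, dtype=np.intp)

    def __contains__(self, name: str) -> bool:
        return normalize_label(name) in self._index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height:.4g} Myr)"

    # ------------------------------------------------------------ construction
    @classmethod
    def from_newick(
        cls,
        source: str,
        require_ultrametric: bool = True,
        ultrametric_rtol: float = 1e-6,
    ) -> "Phylogeny":
        """Parse a Newick string (not a path; see :func:`phyloturn.io.read_newick`)."""
        try:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"failed to parse Newick: {exc}") from exc
        return cls(tree, require_ultrametric, ultrametric_rtol)

    def write_newick(self) -> str:
        return self._tree.as_string(schema="newick", unquoted_underscores=True)

    def prune_to(self, names: Sequence[str]) -> "Phylogeny":
        """Subtree containing only ``names``; path lengths are preserved."""
        keep = {normalize_label(n) for n in names}
        missing = sorted(keep - set(self.taxa))
        if missing:
            raise KeyError(f"tips not in phylogeny: {missing}")
        labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()
                  if normalize_label(lf.taxon.label) in keep]
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        return Phylogeny(
            sub,
            require_ultrametric=False,
            ultrametric_rtol=self.ultrametric_rtol,
        )

    # -------------------------------------------------------------- internals
    def _compute_depths(self) -> dict[int, float]:
        depths: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[id(node)] = 0.0
            else:
                depths[id(node)] = depths[id(node.parent_node)] + float(
                    node.edge.length or 0.0
                )
        return depths

    def _build_nodes(self) -> list[dict]:
        """Internal-node table: age, tip indices, children tip-index blocks."""
        nodes = []
        tipsets: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[id(node)] = np.array(
                    [self._index[normalize_label(node.taxon.label)]], dtype=np.intp
                )
                continue
            child_sets = [tipsets[id(ch)] for ch in node.child_nodes()]
            tips = np.concatenate(child_sets)
            tipsets[id(node)] = tips
            nodes.append(
                {
                    "node_id": len(nodes),
                    "age": self._height - self._depths[id(node)],
                    "depth": self._depths[id(node)],
                    "tips": tips,
                    "child_tip_sets": child_sets,
                    "n_children": len(child_sets),
                    "is_root": node.parent_node is None,
                }
            )
        return nodes

    @property
    def nodes(self) -> list[dict]:
        """Internal nodes in postorder; each with age (Myr) and tip indices."""
        if self._nodes is None:
            self._nodes = self._build_nodes()
        return self._nodes

    def cophenetic(self) -> np.ndarray:
        """Pairwise patristic distances, ordered as ``self.taxa``.

        ``d_ij`` is the sum of branch lengths on the path i -> j; on an
        ultrametric tree ``d_ij = 2 * age(MRCA(i, j))``.  Computed by a single
        postorder sweep: for tips in different child subtrees of a node ``v``,
        ``d_ij = depth_i + depth_j - 2 * depth_v``.
        """
        if self._cophenetic is not None:
            return self._cophenetic
        n = self.n_tips
        tip_depth = np.empty(n)
        for lf in self._tree.leaf_node_iter():
            tip_depth[self._index[normalize_label(lf.taxon.label)]] = self._depths[
                id(lf)
            ]
        D = np.zeros((n, n))
        for node in self.nodes:
            sets = node["child_tip_sets"]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    ia = sets[a][:, None]
                    jb = sets[b][None, :]
                    d = tip_depth[ia] + tip_depth[jb] - 2.0 * node["depth"]
                    D[ia, jb] = d
                    D[jb.T, ia.T] = d.T
        self._cophenetic = D
        return D

    def mrca_ages(self) -> np.ndarray:
        """Pairwise MRCA ages (Myr); diagonal is 0 (a tip with itself)."""
        n = self.n_tips
        tip_depth = np.full(n, self._height)  # exact for ultrametric trees
        if not self._is_ultrametric:
            for lf in self._tree.leaf_node_iter():
                tip_depth[self._index[normalize_label(lf.taxon.label)]] = (
                    self._depths[id(lf)]
                )
        D = self.cophenetic()
        # depth(MRCA) = (depth_i + depth_j - d_ij) / 2 ; age = height - depth
        depth_mrca = (tip_depth[:, None] + tip_depth[None, :] - D) / 2.0
        A = self._height - depth_mrca
        np.fill_diagonal(A, 0.0)
        return A

    def bm_covariance(self) -> np.ndarray:
        """Brownian-motion covariance: shared path length from the root."""
        n = self.n_tips
        tip_depth = np.full(n, self._height)
        if not self._is_ultrametric:
            for lf in self._tree.leaf_node_iter():
                tip_depth[self._index[normalize_label(lf.taxon.label)]] = (
                    self._depths[id(lf)]
                )
        D = self.cophenetic()
        C = (tip_depth[:, None] + tip_depth[None, :] - D) / 2.0
        np.fill_diagonal(C, tip_depth)
        return C

    def rescale(self, target_height: float) -> "Phylogeny":
        """Multiply all branch lengths so the tree height equals ``target_height``."""
        if target_height <= 0:
            raise ValueError("target height must be positive")
        factor = target_height / self._height
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return Phylogeny(
            clone,
            require_ultrametric=False,
            ultrametric_rtol=self.ultrametric_rtol,
        )
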