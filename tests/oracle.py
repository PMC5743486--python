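"""Independent brute-force reference implementations for the test suite.

Everything here is deliberately written as explicit loops over species and
plots (O(S^2 P^2)), sharing no code with the package's vectorized engine,
so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_alpha(counts_row, D, mode, max_mrca_age=None):
    """Mean within-plot distance by pair enumeration; NaN when undefined."""
    idx = [i for i, c in enumerate(counts_row) if c > 0]
    total = sum(counts_row[i] for i in idx)
    num = den = 0.0
    for a in range(len(idx)):
        for b in range(len(idx)):
            i, j = idx[a], idx[b]
            if i == j:
                continue
            if max_mrca_age is not None and D[i][j] / 2.0 >= max_mrca_age:
                continue
            w = 1.0 if mode == "presence" else (
                counts_row[i] / total * counts_row[j] / total
            )
            num += w * D[i][j]
            den += w
    return num / den if den > 0 else float("nan")


def brute_beta(row_k, row_l, D, mode, max_mrca_age=None):
    """Mean cross-plot distance between distinct species, by enumeration."""
    tk = sum(row_k)
    tl = sum(row_l)
    num = den = 0.0
    for i in range(len(row_k)):
        for j in range(len(row_l)):
            if i == j or row_k[i] == 0 or row_l[j] == 0:
                continue
            if max_mrca_age is not None and D[i][j] / 2.0 >= max_mrca_age:
                continue
            w = 1.0 if mode == "presence" else (row_k[i] / tk * row_l[j] / tl)
            num += w * D[i][j]
            den += w
    return num / den if den > 0 else float("nan")


def brute_pair_statistic(row_k, row_l, D, mode, max_mrca_age=None):
    """1 - mean(dw_k, dw_l)/da for one plot pair; NaN when undefined."""
    dwk = brute_alpha(row_k, D, mode, max_mrca_age)
    dwl = brute_alpha(row_l, D, mode, max_mrca_age)
    da = brute_beta(row_k, row_l, D, mode, max_mrca_age)
    if not (np.isfinite(dwk) and np.isfinite(dwl) and np.isfinite(da)) or da == 0:
        return float("nan")
    return 1.0 - 0.5 * (dwk + dwl) / da


def dendropy_cophenetic(phylo):
    """Cophenetic matrix via dendropy's own distance machinery (independent
    of the package's traversal)."""
    pdm = phylo.tree.phylogenetic_distance_matrix()
    label_to_taxon = {}
    for taxon in phylo.tree.taxon_namespace:
        label_to_taxon["_".join(str(taxon.label).strip().split())] = taxon
    n = phylo.n_tips
    D = np.zeros((n, n))
    for i, a in enumerate(phylo.taxa):
        for j, b in enumerate(phylo.taxa):
            if i < j:
                d = pdm.patristic_distance(label_to_taxon[a], label_to_taxon[b])
                D[i, j] = D[j, i] = d
    return D


def dendropy_mrca_ages(phylo):
    """Pairwise MRCA ages via dendropy MRCA lookup (independent traversal)."""
    tree = phylo.tree
    label_to_taxon = {
        "_".join(str(t.label).strip().split()): t for t in tree.taxon_namespace
    }
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[id(node)] = 0.0 if parent is None else (
            depths[id(parent)] + float(node.edge.length or 0.0)
        )
    height = max(depths[id(lf)] for lf in tree.leaf_node_iter())
    n = phylo.n_tips
    A = np.zeros((n, n))
    for i, a in enumerate(phylo.taxa):
        for j, b in enumerate(phylo.taxa):
            if i < j:
                mrca = tree.mrca(taxa=[label_to_taxon[a], label_to_taxon[b]])
                A[i, j] = A[j, i] = height - depths[id(mrca)]
    return A


def brute_node_counts(phylo, species_names):
    """Per-internal-node descendant counts via dendropy leaf iteration."""
    wanted = {"_".join(str(s).strip().split()) for s in species_names}
    counts = []
    for node in phylo.tree.postorder_node_iter():
        if node.is_leaf():
            continue
        labels = {
            "_".join(str(lf.taxon.label).strip().split())
            for lf in node.leaf_iter()
        }
        counts.append(len(labels & wanted))
    return np.array(counts)


def brute_abouheif_proximity(phylo):
    """Abouheif proximity by explicit path walking on the dendropy tree."""
    tree = phylo.tree
    leaves = {
        "_".join(str(lf.taxon.label).strip().split()): lf
        for lf in tree.leaf_node_iter()
    }
    ancestors = {}
    for name, lf in leaves.items():
        path = []
        node = lf.parent_node
        while node is not None:
            path.append(node)
            node = node.parent_node
        ancestors[name] = path
    n = phylo.n_tips
    A = np.zeros((n, n))
    for i, a in enumerate(phylo.taxa):
        for j, b in enumerate(phylo.taxa):
            if i >= j:
                continue
            anc_a = ancestors[a]
            anc_b_set = {id(x) for x in ancestors[b]}
            mrca = next(x for x in anc_a if id(x) in anc_b_set)
            prod = 1.0
            for node in anc_a:
                prod /= len(node.child_nodes())
                if node is mrca:
                    break
            for node in ancestors[b]:
                if node is mrca:
                    break
                prod /= len(node.child_nodes())
            A[i, j] = A[j, i] = prod
    return A
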