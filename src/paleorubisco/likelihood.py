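"""Phylogenetic likelihood by the pruning algorithm.

Computes per-column likelihoods of a protein alignment on a fixed rooted
tree under a reversible substitution model with discrete-gamma rate
categories.  Partial likelihoods are propagated leaf-to-root
(Felsenstein's pruning), vectorized across alignment columns; per-node
rescaling with log bookkeeping prevents underflow on large trees.
Multifurcations are handled directly by the pruning product.

Missing symbols at tips ('-' and 'X') contribute a partial-likelihood
vector of ones, the standard treatment of missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .seqtree_io import Alignment, PhyloTree
from .subst_models import SubstModel, transition_matrix

logger = logging.getLogger(__name__)

#: Rescale a node's partials when their per-site maximum drops below this.
RESCALE_THRESHOLD = 1e-280

MAX_BRANCH_LENGTH = 50.0


@dataclass
class TreeIndex:
    """Flat, array-friendly view of a rooted tree.

    Nodes are numbered in postorder (root last).  ``children[i]`` lists the
    child indices of node i and ``lengths[i]`` is the branch length above
    node i (NaN for the root).
    """

    n_nodes: int
    children: list[list[int]]
    parent: np.ndarray
    lengths: np.ndarray
    leaf_index: dict[str, int]
    node_of: dict[int, object]  # index -> dendropy node
    index_of: dict[int, int]  # id(dendropy node) -> index

    @classmethod
    def from_tree(cls, tree: PhyloTree) -> "TreeIndex":
        nodes = tree.postorder()
        index_of = {id(n): i for i, n in enumerate(nodes)}
        children: list[list[int]] = []
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.full(len(nodes), np.nan)
        leaf_index: dict[str, int] = {}
        for i, node in enumerate(nodes):
            children.append([index_of[id(c)] for c in node.child_nodes()])
            if node.parent_node is not None:
                parent[i] = index_of[id(node.parent_node)]
                lengths[i] = node.edge.length if node.edge.length is not None else 0.0
            if node.is_leaf():
                leaf_index[node.taxon.label] = i
        return cls(
            n_nodes=len(nodes),
            children=children,
            parent=parent,
            lengths=lengths,
            leaf_index=leaf_index,
            node_of=dict(enumerate(nodes)),
            index_of=index_of,
        )

    @property
    def root(self) -> int:
        return self.n_nodes - 1


def encode_alignment(aln: Alignment, model: SubstModel) -> np.ndarray:
    """Map alignment symbols to model state indices; -1 marks missing.

    '-' and 'X' are missing for residue models.  For models whose alphabet
    contains the symbol (e.g. the two-state gap model over {a, g}) every
    symbol must be a real state.
    """
    lookup = {s: i for i, s in enumerate(model.alphabet)}
    out = np.empty((aln.n_taxa, aln.n_columns), dtype=np.int64)
    for r, row in enumerate(aln.rows):
        for c, sym in enumerate(row):
            if sym in lookup:
                out[r, c] = lookup[sym]
            elif sym in ("-", "X"):
                out[r, c] = -1
            else:
                raise ValueError(
                    f"symbol {sym!r} (taxon {aln.taxa[r]!r}, column {c + 1}) "
                    f"not representable in model alphabet {model.alphabet!r}"
                )
    return out


def edge_transition_matrices(
    idx: TreeIndex, model: SubstModel, rate: float
) -> list[np.ndarray | None]:
    """P(t * rate) for the branch above every node (None at the root)."""
    mats: list[np.ndarray | None] = [None] * idx.n_nodes
    for i in range(idx.n_nodes):
        if i != idx.root:
            mats[i] = transition_matrix(model, idx.lengths[i] * rate).P
    return mats


def inside_partials(
    idx: TreeIndex,
    states: np.ndarray,
    taxon_order: list[str],
    model: SubstModel,
    rate: float,
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray | None]]:
    """Postorder (inside/clade) partial likelihoods for one rate category.

    Returns per-node scaled partial arrays of shape (nsites, k), the
    per-site cumulative log scaling factor at the root, and the edge
    transition matrices used.
    """
    nsites = states.shape[1]
    k = model.k
    P_edge = edge_transition_matrices(idx, model, rate)
    partials: list[np.ndarray] = [None] * idx.n_nodes  # type: ignore[list-item]
    scalelog = [np.zeros(nsites) for _ in range(idx.n_nodes)]
    row_of = {t: r for r, t in enumerate(taxon_order)}
    label_of = {j: l for l, j in idx.leaf_index.items()}
    for i in range(idx.n_nodes):
        if not idx.children[i]:
            s = states[row_of[label_of[i]]]
            L = np.zeros((nsites, k))
            observed = s >= 0
            L[observed, s[observed]] = 1.0
            L[~observed, :] = 1.0
            partials[i] = L
        else:
            L = np.ones((nsites, k))
            acc = np.zeros(nsites)
            for c in idx.children[i]:
                L = L * (partials[c] @ P_edge[c].T)
                acc += scalelog[c]
            mx = L.max(axis=1)
            small = mx < RESCALE_THRESHOLD
            if small.any():
                safe = np.where(mx > 0, mx, 1.0)
                L = np.where(small[:, None], L / safe[:, None], L)
                acc = acc + np.where(small & (mx > 0), np.log(safe), 0.0)
            partials[i] = L
            scalelog[i] = acc
    return partials, scalelog[idx.root], P_edge


@dataclass
class SiteLikelihoods:
    """Per-column log-likelihoods and their total.

    ``category_logliks`` has shape (nsites, ncat): the log site likelihood
    conditional on each gamma category (before mixing).
    """

    site_logliks: np.ndarray
    category_logliks: np.ndarray

    @property
    def total(self) -> float:
        return float(self.site_logliks.sum())


def site_loglik(tree: PhyloTree, aln: Alignment, model: SubstModel) -> SiteLikelihoods:
    """Gamma-mixture log-likelihood of every alignment column on the tree."""
    tree.check_taxa(aln)
    idx = TreeIndex.from_tree(tree)
    states = encode_alignment(aln, model)
    rates = model.category_rates
    ncat = len(rates)
    nsites = aln.n_columns
    cat_loglik = np.empty((nsites, ncat))
    pi = model.frequencies
    for c, rate in enumerate(rates):
        partials, rootscale, _ = inside_partials(idx, states, aln.taxa, model, rate)
        lik = partials[idx.root] @ pi
        if np.any(lik <= 0):
            bad = int(np.argmax(lik <= 0))
            raise FloatingPointError(
                f"zero site likelihood at column {bad + 1} (category {c})"
            )
        cat_loglik[:, c] = np.log(lik) + rootscale
    site = logsumexp(cat_loglik, axis=1) - np.log(ncat)
    return SiteLikelihoods(site_logliks=site, category_logliks=cat_loglik)


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstModel,
    tol: float = 1e-4,
    max_cycles: int = 20,
) -> PhyloTree:
    """Coordinate-wise ML refinement of branch lengths on a fixed topology.

    Cycles over branches, maximizing the total log-likelihood in each
    length by bounded univariate optimization, until a full cycle improves
    the log-likelihood by less than `tol`.  The input tree is not modified.
    The log-likelihood never decreases across accepted updates.
    """
    import copy

    work = PhyloTree(copy.deepcopy(tree.tree), tree.default_branch_length)
    edges = [n for n in work.postorder() if n.parent_node is not None]
    best = site_loglik(work, aln, model).total

    def loglik_with(node, value: float) -> float:
        old = node.edge.length
        node.edge.length = value
        try:
            return site_loglik(work, aln, model).total
        finally:
            node.edge.length = old

    converged = False
    for _ in range(max_cycles):
        start = best
        snapshot = [n.edge.length for n in edges]
        for node in edges:
            res = minimize_scalar(
                lambda x, n=node: -loglik_with(n, x),
                bounds=(0.0, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > best:
                node.edge.length = float(res.x)
                best = -res.fun
        if best - start < tol:
            # sub-tolerance cycle: keep the pre-cycle lengths, so a tol
            # larger than any achievable gain returns the input unchanged
            for node, length in zip(edges, snapshot):
                node.edge.length = length
            best = start
            converged = True
            break
    if not converged:
        logger.warning(
            "branch-length optimization did not converge in %d cycles; "
            "returning best-so-far lengths",
            max_cycles,
        )
    return work
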