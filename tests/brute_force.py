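"""Independent enumeration oracle for likelihoods and marginal posteriors.

Computes site likelihoods and ancestral-state posteriors by summing the
joint probability over *all* internal-node state assignments (vectorized
over assignments), instead of the pruning recursion.  Feasible only for
tiny trees; used to cross-check the pruning implementation.
"""

from __future__ import annotations

import numpy as np

from paleorubisco.likelihood import TreeIndex, encode_alignment
from paleorubisco.subst_models import transition_matrix


def enumerate_likelihoods(tree, aln, model, target_node=None):
    """Return (site_likelihoods, posterior_at_target_or_None).

    Site likelihoods are gamma-mixture likelihoods (not logs).  The
    posterior is columns x states, normalized, for `target_node` (must be
    internal).
    """
    idx = TreeIndex.from_tree(tree)
    states = encode_alignment(aln, model)
    row_of = {t: r for r, t in enumerate(aln.taxa)}
    label_of = {j: l for l, j in idx.leaf_index.items()}
    internal = [i for i in range(idx.n_nodes) if idx.children[i]]
    leaves = [i for i in range(idx.n_nodes) if not idx.children[i]]
    pos = {n: j for j, n in enumerate(internal)}
    k = model.k
    nsites = aln.n_columns
    rates = model.category_rates
    ncat = len(rates)
    n_assign = k ** len(internal)
    grids = np.meshgrid(*([np.arange(k)] * len(internal)), indexing="ij")
    A = np.stack(grids, axis=-1).reshape(n_assign, len(internal))

    target_col = None
    if target_node is not None:
        ti = idx.index_of[id(target_node)]
        if ti not in pos:
            raise ValueError("target node must be internal")
        target_col = pos[ti]

    site_lik = np.zeros((nsites, ncat))
    post_acc = np.zeros((ncat, nsites, k))
    for ci, rate in enumerate(rates):
        P = [None] * idx.n_nodes
        for i in range(idx.n_nodes):
            if i != idx.root:
                P[i] = transition_matrix(model, float(idx.lengths[i]) * rate).P
        base = model.frequencies[A[:, pos[idx.root]]].copy()
        for i in internal:
            if i != idx.root:
                base *= P[i][A[:, pos[int(idx.parent[i])]], A[:, pos[i]]]
        for s in range(nsites):
            w = base.copy()
            for li in leaves:
                st = states[row_of[label_of[li]], s]
                if st >= 0:
                    w *= P[li][A[:, pos[int(idx.parent[li])]], st]
                # missing tip: sum over states of a stochastic row = 1
            site_lik[s, ci] = w.sum()
            if target_col is not None:
                post_acc[ci, s] = np.bincount(
                    A[:, target_col], weights=w, minlength=k
                )
    site = site_lik.mean(axis=1)  # equal category prior
    posterior = None
    if target_col is not None:
        posterior = post_acc.mean(axis=0) / site[:, None]
    return site, posterior
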