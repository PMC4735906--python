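"""Marginal (empirical-Bayes) ancestral sequence reconstruction.

For a requested internal node, the posterior distribution over states at
every alignment column is computed by combining the inside (clade) partial
likelihoods with an outside pass over the rest of the tree, under the same
reversible model used for the data likelihood.  With discrete-gamma rates,
per-category posteriors are averaged with weights proportional to the
per-category site likelihood (empirical Bayes over rate categories).

Ancestral indels are inferred Hall-style: the alignment is recoded over
{a, g} (residue/gap), marginal posteriors are computed at the node under
the symmetric two-state model, and columns whose most probable state is
'g' are masked out of the final ancestral sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

import dendropy

from .likelihood import TreeIndex, encode_alignment, inside_partials
from .seqtree_io import Alignment, PhyloTree
from .subst_models import SubstModel, build_model

logger = logging.getLogger(__name__)


def _outside_partials(
    idx: TreeIndex,
    inside: list[np.ndarray],
    P_edge: list[np.ndarray | None],
    pi: np.ndarray,
) -> list[np.ndarray]:
    """Preorder (outside) partials for every node, scaled per site.

    outside[v](s) is proportional to the likelihood of all data outside the
    clade of v, given state s at v, times the root prior.  Scaling factors
    are per-site constants; they cancel when posteriors are normalized.
    """
    nsites, k = inside[idx.root].shape
    outside: list[np.ndarray] = [None] * idx.n_nodes  # type: ignore[list-item]
    outside[idx.root] = np.tile(pi, (nsites, 1))
    # messages from child clades as a function of the parent state
    msg = [None] * idx.n_nodes
    for i in range(idx.n_nodes):
        if i != idx.root:
            msg[i] = inside[i] @ P_edge[i].T
    for v in range(idx.n_nodes - 1, -1, -1):  # preorder = reversed postorder
        for c in idx.children[v]:
            prod = outside[v].copy()
            for sib in idx.children[v]:
                if sib != c:
                    prod *= msg[sib]
            O = prod @ P_edge[c]
            mx = O.max(axis=1, keepdims=True)
            np.divide(O, np.where(mx > 0, mx, 1.0), out=O)
            outside[c] = O
    return outside


@dataclass
class AncestralReconstruction:
    """Per-site posteriors and the MAP sequence at one ancestral node.

    ``posteriors`` is columns x states (model alphabet order); ``gap_mask``
    marks columns inferred to be ancestral gaps; ``sequence`` is the MAP
    residue string with gap-masked columns omitted; ``site_map`` gives, for
    each position of ``sequence``, the 1-based alignment column it came from.
    """

    node_label: str
    alphabet: str
    posteriors: np.ndarray
    map_residues: str
    map_posterior: np.ndarray
    tie_flags: np.ndarray
    gap_mask: np.ndarray | None = None
    gap_posterior: np.ndarray | None = None
    sequence: str | None = None
    site_map: list[int] | None = None


def marginal_posteriors(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstModel,
    node: dendropy.Node,
) -> np.ndarray:
    """Columns x states posterior matrix at `node` (rows sum to 1).

    A leaf node yields point masses on its observed states (uniform over
    the alphabet where the observation is missing, by Bayes with the
    outside evidence).
    """
    tree.check_taxa(aln)
    idx = TreeIndex.from_tree(tree)
    if id(node) not in idx.index_of:
        raise ValueError(f"node {node!r} is not part of the given tree")
    target = idx.index_of[id(node)]
    states = encode_alignment(aln, model)
    rates = model.category_rates
    ncat = len(rates)
    nsites = aln.n_columns
    pi = model.frequencies
    cat_loglik = np.empty((nsites, ncat))
    cat_post = np.empty((ncat, nsites, model.k))
    for c, rate in enumerate(rates):
        inside, rootscale, P_edge = inside_partials(idx, states, aln.taxa, model, rate)
        lik = inside[idx.root] @ pi
        cat_loglik[:, c] = np.log(lik) + rootscale
        outside = _outside_partials(idx, inside, P_edge, pi)
        unnorm = inside[target] * outside[target]
        total = unnorm.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise FloatingPointError("zero posterior mass at some column")
        cat_post[c] = unnorm / total
    weights = softmax(cat_loglik, axis=1)  # equal prior over categories
    post = np.einsum("sc,csk->sk", weights, cat_post)
    post /= post.sum(axis=1, keepdims=True)
    return post


def map_sequence(
    posteriors: np.ndarray, alphabet: str
) -> tuple[str, np.ndarray, np.ndarray]:
    """MAP residue per column, its posterior, and a per-column tie flag.

    Exact ties are broken by alphabet order (lowest index wins) and
    flagged; ties are also logged so they are visible in pipeline runs.
    """
    post = np.asarray(posteriors)
    if post.ndim != 2 or post.shape[1] != len(alphabet):
        raise ValueError("posterior matrix shape does not match alphabet")
    best = post.argmax(axis=1)
    best_p = post[np.arange(post.shape[0]), best]
    ties = (np.isclose(post, best_p[:, None], rtol=0.0, atol=1e-12).sum(axis=1)) > 1
    if ties.any():
        logger.info(
            "MAP ties at %d column(s): %s (alphabet order used)",
            int(ties.sum()),
            ", ".join(str(i + 1) for i in np.flatnonzero(ties)[:20]),
        )
    seq = "".join(alphabet[i] for i in best)
    return seq, best_p, ties


def code_gaps(aln: Alignment) -> Alignment:
    """Recode an alignment over {a, g}: gaps to 'g', everything else to 'a'.

    Residues and the ambiguity symbol 'X' both count as present ('a'); only
    '-' becomes 'g'.
    """
    return Alignment.raw(
        aln.taxa,
        ["".join("g" if ch == "-" else "a" for ch in row) for row in aln.rows],
    )


def reconstruct_gaps(
    tree: PhyloTree,
    coded_aln: Alignment,
    node: dendropy.Node,
) -> tuple[np.ndarray, np.ndarray]:
    """Hall-style ancestral gap inference at `node`.

    Runs marginal reconstruction on the {a, g} coding under the symmetric
    two-state model (branch lengths reused from the residue tree) and masks
    a column iff the posterior of 'g' exceeds 0.5.  A posterior of exactly
    0.5 is not masked but is logged.  Returns (gap_mask, gap_posterior).
    """
    bad = {ch for row in coded_aln.rows for ch in row} - {"a", "g"}
    if bad:
        raise ValueError(f"coded alignment contains non-{{a,g}} symbols: {bad}")
    model = build_model("binary_gap")
    post = marginal_posteriors(tree, coded_aln, model, node)
    p_gap = post[:, model.state_index("g")]
    on_boundary = np.isclose(p_gap, 0.5, rtol=0.0, atol=1e-12)
    if on_boundary.any():
        logger.info(
            "gap posterior exactly 0.5 at column(s) %s; left unmasked",
            ", ".join(str(i + 1) for i in np.flatnonzero(on_boundary)),
        )
    mask = p_gap > 0.5
    mask[on_boundary] = False
    return mask, p_gap


def assemble_ancestor(
    map_seq: str, gap_mask: np.ndarray
) -> tuple[str, list[int]]:
    """Drop gap-masked columns from the MAP sequence.

    Returns the final ancestral sequence and a site map: for each output
    position (0-based list index), the 1-based alignment column it
    corresponds to.
    """
    mask = np.asarray(gap_mask, dtype=bool)
    if len(map_seq) != mask.shape[0]:
        raise ValueError(
            f"sequence length {len(map_seq)} != mask length {mask.shape[0]}"
        )
    seq = "".join(ch for ch, m in zip(map_seq, mask) if not m)
    site_map = [i + 1 for i, m in enumerate(mask) if not m]
    if not seq and len(map_seq):
        logger.warning("all columns gap-masked; ancestral sequence is empty")
    return seq, site_map


def reconstruct_ancestor(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstModel,
    node: dendropy.Node,
    node_label: str = "ancestor",
    infer_gaps: bool = True,
) -> AncestralReconstruction:
    """Full per-node reconstruction: posteriors, MAP, gaps, final sequence."""
    post = marginal_posteriors(tree, aln, model, node)
    seq, best_p, ties = map_sequence(post, model.alphabet)
    rec = AncestralReconstruction(
        node_label=node_label,
        alphabet=model.alphabet,
        posteriors=post,
        map_residues=seq,
        map_posterior=best_p,
        tie_flags=ties,
    )
    if infer_gaps:
        mask, p_gap = reconstruct_gaps(tree, code_gaps(aln), node)
    else:
        mask = np.zeros(aln.n_columns, dtype=bool)
        p_gap = np.zeros(aln.n_columns)
    rec.gap_mask = mask
    rec.gap_posterior = p_gap
    rec.sequence, rec.site_map = assemble_ancestor(seq, mask)
    return rec
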