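"""Synthetic alignments and kinetic assays with known ground truth.

Everything the pipeline consumes can be generated here: protein
alignments evolved down a tree under a reversible model with
discrete-gamma rate variation and lineage-persistent single-column
indels, and noisy RuBisCO assay tables drawn from Michaelis–Menten
kinetics with competitive O2 inhibition.  Each generator records the
truth (ancestral states, gap states, kinetic constants) so recovery can
be scored, and is deterministic given its seed.

Emulated study conditions: six CO2(aq) levels between 5 and 550 uM at
each of four O2 equilibrations (N2, air, 60% O2, 100% O2; dissolved 0,
260, ~743, ~1238 uM at 25 C), with multiplicative lognormal noise on
rates.  The default truth constants are those of an ancestral Form 1B
cyanobacterial RuBisCO (Vc=4.72 1/s, Kc=120 uM, Ko=641 uM, tau=49.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .kinetics import AssayTable, kc_at_o2
from .likelihood import TreeIndex
from .seqtree_io import Alignment, PhyloTree
from .subst_models import SubstModel, build_model, transition_matrix

#: CO2(aq) assay grid, uM.
DEFAULT_SUBSTRATE_UM = (5.0, 25.0, 60.0, 150.0, 300.0, 550.0)
#: Dissolved O2 at the four gas equilibrations (uM, 25 C).
DEFAULT_O2_UM = (0.0, 260.0, 742.9, 1238.1)

#: Probability that a column is present (not deleted) at the root.
ROOT_PRESENT_PROB = 0.9


@dataclass
class SimulationTruth:
    """Ground truth of one simulated alignment."""

    tree: PhyloTree
    model_name: str
    alpha: float | None
    ncat: int
    seed: int
    #: node label -> full-length residue string (gap columns included as '-')
    ancestral_sequences: dict[str, str]
    #: node label -> boolean gap mask over columns (True = column absent)
    gap_states: dict[str, np.ndarray]
    #: per-column gamma category index
    site_categories: np.ndarray
    #: label of the root node in ``ancestral_sequences``
    root_label: str = ""


def _label_nodes(tree: PhyloTree) -> dict[int, str]:
    """Stable labels for every node: leaf taxon labels, 'N<i>' internally."""
    labels: dict[int, str] = {}
    i = 0
    for node in tree.postorder():
        if node.is_leaf():
            labels[id(node)] = node.taxon.label
        else:
            labels[id(node)] = node.label or f"N{i}"
            i += 1
    return labels


def _sample_markov(
    rng: np.random.Generator, parent_states: np.ndarray, P: np.ndarray
) -> np.ndarray:
    """Draw child states given parent states under row-stochastic P."""
    probs = P[parent_states]
    u = rng.random(parent_states.shape[0])
    return (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstModel,
    nsites: int,
    indel_rate: float = 0.0,
    seed: int = 0,
    root_present_prob: float = ROOT_PRESENT_PROB,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve a protein alignment down `tree` under `model`.

    The root sequence is drawn from the stationary frequencies; each column
    keeps one gamma rate category along the whole tree; states evolve
    edge-wise through P(t * rate).  Indels are single-column
    presence/absence characters evolved under the symmetric two-state
    model scaled by `indel_rate` (0 disables them) and overlaid as '-'
    where a column is absent in a lineage.
    """
    if nsites < 1:
        raise ValueError("nsites must be >= 1")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    idx = TreeIndex.from_tree(tree)
    labels = _label_nodes(tree)
    k = model.k
    rates = model.category_rates
    cat = rng.integers(0, len(rates), size=nsites)

    states: dict[int, np.ndarray] = {}
    root = idx.root
    states[root] = rng.choice(k, size=nsites, p=model.frequencies)
    gap_model = build_model("binary_gap")
    gaps: dict[int, np.ndarray] = {}
    if indel_rate > 0:
        gaps[root] = rng.random(nsites) >= root_present_prob  # True = absent
    else:
        gaps[root] = np.zeros(nsites, dtype=bool)

    for i in range(idx.n_nodes - 2, -1, -1):  # preorder below the root
        p = int(idx.parent[i])
        t = float(idx.lengths[i])
        child = np.empty(nsites, dtype=np.int64)
        for c, rate in enumerate(rates):
            sel = cat == c
            if not sel.any():
                continue
            P = transition_matrix(model, t * rate).P
            child[sel] = _sample_markov(rng, states[p][sel], P)
        states[i] = child
        if indel_rate > 0:
            Pg = transition_matrix(gap_model, t * indel_rate).P
            parent_g = gaps[p].astype(np.int64)  # 0='a' present, 1='g' absent
            gaps[i] = _sample_markov(rng, parent_g, Pg).astype(bool)
        else:
            gaps[i] = np.zeros(nsites, dtype=bool)

    def to_string(node_i: int) -> str:
        chars = [model.alphabet[s] for s in states[node_i]]
        return "".join(
            "-" if gaps[node_i][j] else chars[j] for j in range(nsites)
        )

    taxa, rows = [], []
    node_objs = tree.postorder()
    for i, node in enumerate(node_objs):
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(to_string(i))
    from .seqtree_io import ALPHABET

    if set(model.alphabet) <= ALPHABET:
        aln = Alignment(taxa, rows)
    else:  # non-residue coding (binary gap, JC_k): skip residue validation
        aln = Alignment.raw(taxa, rows)

    anc_seqs = {
        labels[id(node_objs[i])]: to_string(i)
        for i, node in enumerate(node_objs)
        if not node.is_leaf()
    }
    gap_states = {
        labels[id(node_objs[i])]: gaps[i].copy()
        for i, node in enumerate(node_objs)
        if not node.is_leaf()
    }
    truth = SimulationTruth(
        tree=tree,
        model_name=model.name,
        alpha=model.alpha,
        ncat=model.ncat,
        seed=seed,
        ancestral_sequences=anc_seqs,
        gap_states=gap_states,
        site_categories=cat,
        root_label=labels[id(tree.root)],
    )
    return aln, truth


def random_tree(
    n_leaves: int,
    seed: int = 0,
    depth: float = 1.0,
) -> PhyloTree:
    """Random rooted bifurcating tree with the given root-to-tip depth.

    Built by recursive splitting with exponential relative node depths,
    then rescaled so every root-to-leaf path length equals `depth`
    (ultrametric), which makes "total tree depth in expected substitutions
    per site" well defined for recovery experiments.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i + 1}" for i in range(n_leaves)]

    def build(leaves: list[str], top: float) -> str:
        # returns a subtree string whose root-to-leaf paths all sum to `top`
        if len(leaves) == 1:
            return f"{leaves[0]}:{top:.10f}"
        split = int(rng.integers(1, len(leaves)))
        h = top * float(rng.uniform(0.3, 0.9))
        return f"({build(leaves[:split], h)},{build(leaves[split:], h)}):{top - h:.10f}"

    split = int(rng.integers(1, n_leaves))
    newick = f"({build(taxa[:split], depth)},{build(taxa[split:], depth)});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return PhyloTree(tree)


def radiation_tree(
    n_taxa: int,
    seed: int = 0,
    total_depth: float = 1.0,
    pool_size: int = 120,
) -> PhyloTree:
    """Ultrametric tree emulating a sparsely sampled radiation.

    A pure-birth (Yule) tree with `pool_size` extant tips is simulated and
    `n_taxa` tips are retained at random, mirroring an alignment that
    samples a small fraction of a large clade; incomplete sampling shifts
    the retained divergences toward the root, the shape typical of broad
    protein-family alignments.  Branch lengths are rescaled so the maximal
    tip-to-tip path ("total depth") equals `total_depth` expected
    substitutions per site, i.e. root-to-tip height total_depth / 2.
    """
    import random as _random

    from dendropy.model import birthdeath

    if not 2 <= n_taxa <= pool_size:
        raise ValueError("need 2 <= n_taxa <= pool_size")
    rng = _random.Random(seed)
    t = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=pool_size, rng=rng
    )
    keep = rng.sample([lf.taxon for lf in t.leaf_node_iter()], n_taxa)
    t.retain_taxa(keep)
    t.is_rooted = True
    height = max(leaf.distance_from_root() for leaf in t.leaf_node_iter())
    scale = (total_depth / 2.0) / height
    for edge in t.preorder_edge_iter():
        if edge.length:
            edge.length *= scale
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    return PhyloTree(t)


def asr_recovery_rate(
    total_depth: float,
    seed: int,
    n_taxa: int = 24,
    nsites: int = 300,
    alpha: float = 1.0,
    ncat: int = 4,
) -> float:
    """One closed-loop experiment: simulate, reconstruct the root, score.

    Returns the fraction of root residues whose MAP reconstruction equals
    the generating state.
    """
    from .asr import map_sequence, marginal_posteriors

    tree = radiation_tree(n_taxa, seed=seed, total_depth=total_depth)
    model = build_model("LG", alpha=alpha, ncat=ncat)
    aln, truth = simulate_alignment(tree, model, nsites, seed=seed)
    post = marginal_posteriors(tree, aln, model, tree.root)
    seq, _, _ = map_sequence(post, model.alphabet)
    true_seq = truth.ancestral_sequences[truth.root_label]
    return float(np.mean([a == b for a, b in zip(seq, true_seq)]))


@dataclass
class AssayTruth:
    """Generating constants for a synthetic RuBisCO assay."""

    Vc: float = 4.72
    Kc: float = 120.0
    Ko: float = 641.0
    tau: float = 49.6
    o2_levels: tuple[float, ...] = DEFAULT_O2_UM
    substrate_levels: tuple[float, ...] = DEFAULT_SUBSTRATE_UM
    sigma: float = 0.05
    replicates: int = 1
    seed: int = 0
    enzyme: str = "synthetic"


def simulate_assay(truth: AssayTruth) -> AssayTable:
    """Draw a noisy assay table from the MM surface with O2 competition.

    rate = Vc * S / (Kc * (1 + O2/Ko) + S) * eps, with eps lognormal with
    median 1 and log-scale `sigma`.  sigma=0 returns rates exactly on the
    surface.
    """
    if truth.sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for o2 in truth.o2_levels:
        km_app = kc_at_o2(truth.Kc, truth.Ko, o2) if o2 > 0 else truth.Kc
        for s in truth.substrate_levels:
            for _ in range(truth.replicates):
                rate = truth.Vc * s / (km_app + s)
                if truth.sigma > 0:
                    rate *= float(np.exp(rng.normal(0.0, truth.sigma)))
                rows.append({"o2": o2, "co2": s, "rate": rate})
    return AssayTable(truth.enzyme, pd.DataFrame(rows))


def recover_kinetics(table: AssayTable) -> dict[str, float]:
    """Closed-loop analysis of an assay table: MM fits per O2, then Ko.

    Returns Vc (mean of per-O2 Vmax), Kc in N2 and Ko (from the OLS of
    apparent Kc on O2), and the regression R^2.
    """
    from .kinetics import fit_mm, infer_ko

    series = []
    vmaxes = []
    for o2, grp in table.data.groupby("o2"):
        vmax, km, _ = fit_mm(grp["co2"].to_numpy(), grp["rate"].to_numpy())
        vmaxes.append(vmax)
        series.append((float(o2), km))
    kc_n2, ko, r2 = infer_ko(series)
    return {"Vc": float(np.mean(vmaxes)), "Kc": kc_n2, "Ko": ko, "r2": r2}
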