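"""Alignment and tree I/O.

Alignments are aligned protein matrices over the 20 amino acids plus the
gap character ``-`` and the ambiguity character ``X``.  Trees are rooted
phylogenies with branch lengths in expected substitutions per site.
Parsing is delegated to Biopython (FASTA / relaxed PHYLIP) and DendroPy
(Newick); this module adds the invariant checks the downstream
reconstruction machinery relies on (equal row lengths, unique labels,
alphabet membership, leaf/taxon agreement).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
AMBIGUOUS = "X"
ALPHABET = set(AMINO_ACIDS) | {GAP, AMBIGUOUS}

#: Branch length substituted for edges missing one in the input Newick.
DEFAULT_BRANCH_LENGTH = 0.1


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, bad symbols, dup labels)."""


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


@dataclass
class Alignment:
    """An aligned residue matrix: ordered taxa x columns.

    Rows are stored as uppercase strings over the amino-acid alphabet plus
    ``-`` (gap) and ``X`` (unknown residue).  Column indices are reported
    1-based everywhere user-facing.
    """

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            dups = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {', '.join(dups)}")
        self.rows = [r.upper() for r in self.rows]
        if self.rows:
            ncol = len(self.rows[0])
            for taxon, row in zip(self.taxa, self.rows):
                if len(row) != ncol:
                    raise AlignmentError(
                        f"ragged alignment: taxon {taxon!r} has {len(row)} "
                        f"columns, expected {ncol}"
                    )
                bad = set(row) - ALPHABET
                if bad:
                    raise AlignmentError(
                        f"taxon {taxon!r} contains symbols outside the "
                        f"alphabet: {', '.join(sorted(bad))}"
                    )

    @classmethod
    def raw(cls, taxa: Sequence[str], rows: Sequence[str]) -> "Alignment":
        """Construct without validation or uppercasing.

        For non-residue codings (e.g. the {a, g} gap recoding) whose
        symbols must not be forced into the amino-acid alphabet.
        """
        obj = cls.__new__(cls)
        obj.taxa = list(taxa)
        obj.rows = list(rows)
        return obj

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def column(self, col: int) -> str:
        """Column by 1-based index."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return "".join(r[col - 1] for r in self.rows)


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP protein alignment.

    Symbols are uppercased; ``-`` and ``X`` are preserved.  Ragged rows and
    duplicate labels raise :class:`AlignmentError`.
    """
    fmt = fmt.lower()
    if fmt not in ("fasta", "phylip"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    bio_fmt = "fasta" if fmt == "fasta" else "phylip-relaxed"
    try:
        records = list(SeqIO.parse(str(path), bio_fmt))
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    fmt = fmt.lower()
    bio_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, str(path), bio_fmt)


@dataclass
class PhyloTree:
    """A rooted tree with non-negative branch lengths, wrapping dendropy.

    Multifurcations are allowed.  Leaf labels must be unique.  Missing
    branch lengths are replaced by a configurable default with a warning,
    so toy trees run while the substitution stays visible in the log.
    """

    tree: dendropy.Tree
    default_branch_length: float = DEFAULT_BRANCH_LENGTH

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {', '.join(dups)}")
        n_defaulted = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                edge.length = None  # root has no branch
                continue
            if edge.length is None:
                edge.length = self.default_branch_length
                n_defaulted += 1
            elif edge.length < 0:
                raise TreeError(
                    f"negative branch length {edge.length} above node "
                    f"{_node_label(edge.head_node)!r}"
                )
        if n_defaulted:
            logger.warning(
                "%d branch length(s) missing; defaulted to %g",
                n_defaulted,
                self.default_branch_length,
            )

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def n_branches(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter() if n is not self.root)

    def postorder(self) -> list[dendropy.Node]:
        return list(self.tree.postorder_node_iter())

    def check_taxa(self, aln: Alignment) -> None:
        """Require leaf-label set == alignment taxa; report the difference."""
        leaves, taxa = set(self.leaf_labels()), set(aln.taxa)
        if leaves != taxa:
            only_tree = sorted(leaves - taxa)
            only_aln = sorted(taxa - leaves)
            raise TreeError(
                "tree leaves and alignment taxa differ; "
                f"tree-only: {only_tree or '[]'}, alignment-only: {only_aln or '[]'}"
            )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal>"


def read_tree(
    path_or_newick: str | Path,
    default_branch_length: float = DEFAULT_BRANCH_LENGTH,
    outgroup: Sequence[str] | None = None,
) -> PhyloTree:
    """Read a rooted Newick tree.

    An explicitly rooted Newick (``[&R]`` or a bifurcating base) is used
    as-is.  A basal trifurcation is treated as unrooted: it is accepted only
    when `outgroup` names a leaf set, in which case the tree is rooted on
    the midpoint of the edge above the outgroup's MRCA.  Rooting is a user
    decision here, never automatic.
    """
    text = None
    p = Path(str(path_or_newick))
    if p.exists():
        text = p.read_text()
    else:
        s = str(path_or_newick).strip()
        if s.endswith(";") and "(" in s:
            text = s
        else:
            raise TreeError(f"tree file not found: {path_or_newick}")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick: {exc}") from exc
    tree.is_rooted = True
    basal_children = len(tree.seed_node.child_nodes())
    if basal_children > 2 and outgroup:
        _root_by_outgroup(tree, outgroup)
    elif basal_children > 2 and outgroup is None:
        logger.warning(
            "input tree has a basal %s-furcation and no outgroup was given; "
            "treating the basal node as the root",
            basal_children,
        )
    return PhyloTree(tree, default_branch_length=default_branch_length)


def _root_by_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> None:
    taxa = set(outgroup)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(taxa - leaves)
    if missing:
        raise TreeError(f"outgroup labels not in tree: {', '.join(missing)}")
    mrca = tree.mrca(taxon_labels=list(taxa))
    if mrca is tree.seed_node:
        raise TreeError("outgroup spans the whole tree; cannot root on it")
    edge = mrca.edge
    length = edge.length if edge.length is not None else DEFAULT_BRANCH_LENGTH
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)


def find_mrca(tree: PhyloTree, taxa: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of a non-empty leaf-label set.

    A single taxon returns the leaf itself.
    """
    labels = list(taxa)
    if not labels:
        raise ValueError("taxon set must be non-empty")
    leaves = set(tree.leaf_labels())
    missing = sorted(set(labels) - leaves)
    if missing:
        raise TreeError(f"unknown taxa: {', '.join(missing)}")
    if len(set(labels)) == 1:
        for lf in tree.tree.leaf_node_iter():
            if lf.taxon.label == labels[0]:
                return lf
    node = tree.tree.mrca(taxon_labels=list(set(labels)))
    if node is None:  # pragma: no cover - dendropy returns root at worst
        raise TreeError("MRCA computation failed")
    return node
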