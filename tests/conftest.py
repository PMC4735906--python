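from pathlib import Path

import numpy as np
import pytest

import paleorubisco as pr

FIXTURE_DIR = Path(__file__).parent / "data" / "synthetic_8taxa"


def make_binary_alignment(taxa, rows):
    """Alignment over the {a, g} coding, bypassing the residue alphabet."""
    return pr.Alignment.raw(taxa, rows)


def random_alignment(tree, model, nsites, seed):
    aln, _ = pr.simulate_alignment(tree, model, nsites, indel_rate=0.0, seed=seed)
    return aln


@pytest.fixture
def four_taxon_tree():
    return pr.read_tree("((A:0.12,B:0.3):0.2,(C:0.08,D:0.5):0.15);")


@pytest.fixture
def lg_g4():
    return pr.build_model("LG", alpha=0.7, ncat=4)


@pytest.fixture
def binary_model():
    return pr.build_model("binary_gap")


@pytest.fixture
def fixture_bundle():
    import yaml

    truth = yaml.safe_load((FIXTURE_DIR / "truth.yaml").read_text())
    aln = pr.read_alignment(FIXTURE_DIR / "alignment.fasta")
    tree = pr.read_tree(FIXTURE_DIR / "tree.nwk")
    return aln, tree, truth
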