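import numpy as np
import pytest

from selfavoid.core import Element, ModelParams, TubuleTree


@pytest.fixture
def params():
    """Default model parameters (the calibrated reference set)."""
    return ModelParams()


@pytest.fixture
def quiet_params():
    """Noise-free parameters on a small domain, for deterministic checks."""
    return ModelParams(noise_sd=0.0, domain_width=64, domain_height=64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_tree(chains, tree_id=0):
    """Build a TubuleTree from a root cell plus daughter chains.

    ``chains`` is (root_chain, [(parent_index, [cells...]), ...]);
    the root chain becomes elements 0..n-1 in order.
    """
    root_chain, branches = chains
    tree = TubuleTree(tree_id=tree_id)
    for i, cell in enumerate(root_chain):
        tree.elements.append(
            Element(cell, "stalk", None if i == 0 else i - 1, 0, 0)
        )
    for parent_idx, cells in branches:
        idx = parent_idx
        gen = tree.elements[parent_idx].generation + 1
        for cell in cells:
            tree.elements.append(Element(cell, "stalk", idx, gen, 0))
            idx = len(tree.elements) - 1
    return tree


@pytest.fixture
def vee_tree():
    """Trunk up from (10, 0) with daughters along (1,1) and (-1,1): 90 deg."""
    trunk = [(10, y) for y in range(5)]
    right = [(10 + i, 4 + i) for i in range(1, 8)]
    left = [(10 - i, 4 + i) for i in range(1, 8)]
    return build_tree((trunk, [(4, right), (4, left)]))
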