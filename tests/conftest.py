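"""Shared fixtures and tree-generation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from clcfam.synthetic_data import TrueGeneLabel


def random_binary_newick(
    rng: np.random.Generator,
    leaf_labels: list[str],
    with_lengths: bool = True,
    length_range: tuple[float, float] = (0.5, 3.0),
) -> str:
    """Random binary topology by successive pair joining."""
    nodes = list(leaf_labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if with_lengths:
            la, lb = rng.uniform(*length_range, size=2)
            nodes.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
        else:
            nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


#: the headline design: 4 antiporters (one NO3-selective) + 3 channels
SEVEN_LABELS = [
    TrueGeneLabel("P", gating=True, proton=True),    # antiporter, NO3-
    TrueGeneLabel("S", gating=True, proton=True),    # antiporter, Cl-
    TrueGeneLabel("S", gating=True, proton=True),    # antiporter, Cl-
    TrueGeneLabel("S", gating=True, proton=True),    # antiporter, Cl-
    TrueGeneLabel("A", gating=False, proton=True),   # channel
    TrueGeneLabel("A", gating=True, proton=False),   # channel
    TrueGeneLabel("S", gating=False, proton=True),   # channel, Cl-
]


@pytest.fixture
def seven_labels():
    return list(SEVEN_LABELS)
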