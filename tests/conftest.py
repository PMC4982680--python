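"""Shared fixtures: textbook cations and graph-permutation helpers.

All fixture molecules are built from SMILES at test time; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from cationet.molgraph import CationGraph, parse_smiles

SMILES_FIXTURES = {
    "ethyl": "[CH2+]C",
    "propyl": "[CH2+]CC",
    "isobutyl": "[CH2+]C(C)C",
    "tert_butyl": "C[C+](C)C",
    "sec_butyl": "C[CH+]CC",
    "neopentyl": "CC(C)(C)[CH2+]",
    "allyl": "[CH2+]C=C",
    "homoallyl": "C=CC[CH2+]",
    "cyclopropylcarbinyl": "[CH2+]C1CC1",
    "cyclobutyl": "[CH+]1CCC1",
    "pentenyl": "[CH2+]CCC=C",
    "geranyl": "[CH2+]C=C(C)CCC=C(C)C",
    "linalyl": "C=C[C+](C)CCC=C(C)C",
    "alpha_terpinyl": "CC1=CCC([C+](C)C)CC1",
}


@pytest.fixture(scope="session")
def mol():
    """Name -> freshly parsed CationGraph factory."""

    def factory(name: str) -> CationGraph:
        return parse_smiles(SMILES_FIXTURES[name])

    return factory


def permute_graph(g: CationGraph, perm: list[int]) -> CationGraph:
    """Relabel atoms of *g* by ``new_index = perm[old_index]``."""
    inv = [0] * len(perm)
    for old, new in enumerate(perm):
        inv[new] = old
    elements = [g.elements[inv[i]] for i in range(g.n_atoms)]
    bonds = [
        (perm[i], perm[j], o)
        for i in range(g.n_atoms)
        for j, o in g.adj[i].items()
        if i < j
    ]
    charge = None if g.charge_site is None else perm[g.charge_site]
    return CationGraph(elements, bonds, charge_site=charge)


def random_permutation(n: int, seed: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return list(rng.permutation(n))
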