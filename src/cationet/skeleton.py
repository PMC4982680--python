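"""Skeleton extraction and ring-topology classification.

A *skeleton* abstracts a carbocation down to its product-defining carbon
framework: the cation is neutralized by a hydride quench at the charge site
(which leaves the alkene pattern untouched), hydrogens are dropped, and
saturated terminal carbons are pruned to fixpoint.  What remains — rings
plus double-bond placement — is what distinguishes one monoterpene product
family from another.

Cyclic skeletons fall into five topology groups: one ring (with its double
bond), and the four kinds of two-ring system (bridged, fused, spiro,
separated).  For a C10H17+ network the degree of unsaturation is pinned at
2, so more than two rings cannot occur.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import networkx as nx
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from .molgraph import CationGraph

if TYPE_CHECKING:  # pragma: no cover
    from .enumerate import ReactionNetwork

__all__ = [
    "Topology",
    "Skeleton",
    "neutralize",
    "extract_skeleton",
    "framework_graph",
    "classify_topology",
    "cluster_network",
    "EC_REFERENCE_FRAMEWORKS",
    "ec_reference_keys",
]


class Topology(enum.Enum):
    ACYCLIC = "acyclic"
    MONOCYCLIC = "monocyclic"
    BRIDGED = "bridged"
    FUSED = "fused"
    SPIRO = "spiro"
    SEPARATED = "separated"


@dataclass
class Skeleton:
    """One row of the skeleton table."""

    key: str                  # canonical SMILES of the pruned framework
    topology: Topology
    n_carbocation: int        # member cations in the network
    min_step: Optional[int]   # shortest-route step count over members
    is_ec_reference: bool = False


#: Reference frameworks of the monoterpene skeletons associated with EC
#: numbers: the menthane-type cyclohexene and the pinane, bornane, thujane
#: and carane ring frames.  This is configuration, not chemistry code — the
#: recovery checks accept any replacement list of canonical framework keys.
_EC_REFERENCE_SMILES = {
    "menthane": "C1=CCCCC1",        # cyclohexene frame
    "pinane": "C1CC2CC(C2)C1",      # bicyclo[3.1.1]heptane
    "bornane": "C1CC2CCC1C2",       # bicyclo[2.2.1]heptane
    "thujane": "C1CC2CC2C1",        # bicyclo[3.1.0]hexane
    "carane": "C1CCC2CC2C1",        # bicyclo[4.1.0]heptane
}

EC_REFERENCE_FRAMEWORKS: dict[str, str] = {
    name: Chem.CanonSmiles(smi) for name, smi in _EC_REFERENCE_SMILES.items()
}


def ec_reference_keys() -> frozenset:
    return frozenset(EC_REFERENCE_FRAMEWORKS.values())


def neutralize(g: CationGraph) -> CationGraph:
    """Hydride-quench the cation: add one H at the charge site and clear the
    charge.  No double bond is created or destroyed, so the substrate's
    alkene pattern survives unchanged (a deprotonation quench would not
    have this property)."""
    if g.charge_site is None:
        raise ValueError("neutralize requires a charged species")
    out = g.add_hydrogen(g.charge_site)
    out.validate()
    return out


def _pruned_carbon_mol(g: CationGraph) -> Chem.Mol:
    """Carbon framework of (neutralized) *g* after pruning saturated
    degree-1 carbons to fixpoint; hydrogens become implicit."""
    if g.charge_site is not None:
        g = neutralize(g)
    carbons = {i for i, el in enumerate(g.elements) if el == "C"}
    adj = {
        i: {j: o for j, o in g.adj[i].items() if g.elements[j] == "C"}
        for i in carbons
    }
    changed = True
    while changed:
        changed = False
        for i in list(carbons):
            nbrs = [j for j in adj[i] if j in carbons]
            if len(nbrs) == 1 and adj[i][nbrs[0]] == 1:
                carbons.discard(i)
                changed = True
            elif len(nbrs) == 0 and len(carbons) > 1:
                carbons.discard(i)
                changed = True
    index = {a: k for k, a in enumerate(sorted(carbons))}
    rw = RWMol()
    for _ in index:
        rw.AddAtom(Chem.Atom(6))
    for a in index:
        for b, order in adj[a].items():
            if b in index and a < b:
                rw.AddBond(index[a], index[b],
                           Chem.BondType.DOUBLE if order == 2
                           else Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def extract_skeleton(g: CationGraph) -> str:
    """Canonical framework key of *g*: neutralize, drop hydrogens, then
    iteratively delete degree-1 carbons that are not in a double bond.

    Idempotent: pruning a pruned framework is the identity.  An exocyclic
    alkene carbon is retained (it is in a double bond, hence not prunable).
    """
    return Chem.MolToSmiles(_pruned_carbon_mol(g))


def framework_graph(framework_key: str) -> nx.Graph:
    """The pruned framework as a NetworkX graph with ``order`` edge data."""
    mol = Chem.MolFromSmiles(framework_key)
    if mol is None:
        raise ValueError(f"invalid framework SMILES {framework_key!r}")
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                   order=int(b.GetBondTypeAsDouble()))
    return g


def classify_topology(skeleton) -> Topology:
    """Topology class of a skeleton (a :class:`Skeleton`, framework SMILES,
    or framework graph).

    Ring count is the cyclomatic number; for two-ring systems the class is
    read off the subgraph of ring bonds (bonds on some cycle):

    - two ring-bond components        -> SEPARATED (rings share no atom),
    - one branch atom of ring-degree 4 -> SPIRO (rings share one atom),
    - two adjacent branch atoms        -> FUSED (rings share one bond),
    - two non-adjacent branch atoms    -> BRIDGED (rings share >= 2
      non-adjacent atoms, i.e. at least one bridge path).

    Raises ``ValueError`` for more than two rings, which cannot occur at
    degree of unsaturation 2.
    """
    if isinstance(skeleton, Skeleton):
        skeleton = skeleton.key
    g = framework_graph(skeleton) if isinstance(skeleton, str) else skeleton
    n_rings = g.number_of_edges() - g.number_of_nodes() + \
        nx.number_connected_components(g)
    if n_rings == 0:
        return Topology.ACYCLIC
    if n_rings == 1:
        return Topology.MONOCYCLIC
    if n_rings > 2:
        raise ValueError(f"{n_rings}-ring system exceeds the two-ring bound")
    ring_edges = set(g.edges) - set(nx.bridges(g))
    ring_graph = g.edge_subgraph(ring_edges)
    if nx.number_connected_components(ring_graph) == 2:
        return Topology.SEPARATED
    degrees = dict(ring_graph.degree)
    if any(d == 4 for d in degrees.values()):
        return Topology.SPIRO
    branch = [v for v, d in degrees.items() if d == 3]
    assert len(branch) == 2, "two-ring system must have two branch atoms"
    return Topology.FUSED if ring_graph.has_edge(*branch) else Topology.BRIDGED


def cluster_network(net: "ReactionNetwork",
                    ec_keys: Optional[frozenset] = None,
                    min_steps: Optional[dict[str, int]] = None
                    ) -> pd.DataFrame:
    """Cluster a reaction network by skeleton.

    Returns one row per distinct framework with columns ``framework_key``,
    ``topology``, ``n_carbocation``, ``log10_n``, ``min_step`` and
    ``is_ec_reference``.  ``min_step`` is filled from *min_steps* (node key
    -> paper-style step count, see :mod:`cationet.routes`); when omitted it
    is computed here via the shortest-route machinery.

    Rows are sorted by descending member count, then key.
    """
    if not net.nodes:
        raise ValueError("cannot cluster an empty network")
    if ec_keys is None:
        ec_keys = ec_reference_keys()
    if min_steps is None:
        from .routes import all_shortest_steps
        min_steps = all_shortest_steps(net)
    members: dict[str, list[str]] = {}
    for key, rec in net.nodes.items():
        members.setdefault(extract_skeleton(rec.graph), []).append(key)
    rows = []
    for fkey, node_keys in members.items():
        n = len(node_keys)
        rows.append({
            "framework_key": fkey,
            "topology": classify_topology(fkey).value,
            "n_carbocation": n,
            "log10_n": math.log10(n),
            "min_step": min(min_steps[k] for k in node_keys),
            "is_ec_reference": fkey in ec_keys,
        })
    df = pd.DataFrame(rows).sort_values(
        ["n_carbocation", "framework_key"], ascending=[False, True],
        ignore_index=True)
    return df
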