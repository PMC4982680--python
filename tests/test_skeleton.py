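"""Skeleton extraction, pruning, topology classification, clustering."""


import networkx as nx
import pytest
from rdkit import Chem

from cationet.enumerate import EnumConfig, run_enumeration
from cationet.molgraph import formula, parse_smiles
from cationet.reactions import ReactionType, apply_alkylation, reactive_atoms
from cationet.skeleton import (EC_REFERENCE_FRAMEWORKS, Topology,
                               classify_topology, cluster_network,
                               extract_skeleton, neutralize)
from cationet.stability import StabilityConfig


class TestNeutralize:
    def test_tert_butyl_to_isobutane(self, mol):
        n = neutralize(mol("tert_butyl"))
        assert formula(n) == (4, 10, 0)
        assert n.key() == Chem.CanonSmiles("CC(C)C")

    def test_geranyl_keeps_diene(self, mol):
        n = neutralize(mol("geranyl"))
        assert formula(n) == (10, 18, 0)
        assert len(n.double_bonds()) == 2

    def test_alpha_terpinyl_keeps_ring_alkene(self, mol):
        n = neutralize(mol("alpha_terpinyl"))
        assert n.key() == Chem.CanonSmiles("CC1=CCC(C(C)C)CC1")

    def test_neutral_input_rejected(self):
        with pytest.raises(ValueError):
            neutralize(parse_smiles("CC"))


class TestExtractSkeleton:
    def test_alpha_terpinyl_prunes_to_cyclohexene(self, mol):
        assert extract_skeleton(mol("alpha_terpinyl")) == \
            EC_REFERENCE_FRAMEWORKS["menthane"]

    def test_pinyl_type_prunes_to_bicycloheptane(self, mol):
        # build the bicyclics by cyclizing the alpha-terpinyl cation and
        # check the known frames appear
        g = mol("alpha_terpinyl")
        frames = set()
        for a in reactive_atoms(g):
            if g.elements[a] == "C" and g.in_double_bond(a):
                for p, _ in apply_alkylation(g, a):
                    frames.add(extract_skeleton(p))
        assert EC_REFERENCE_FRAMEWORKS["pinane"] in frames
        assert EC_REFERENCE_FRAMEWORKS["bornane"] in frames

    def test_exocyclic_alkene_carbon_retained(self):
        skel = extract_skeleton(parse_smiles("C=C1CCC([CH+]C)CC1"))
        assert skel == Chem.CanonSmiles("C=C1CCCCC1")

    def test_acyclic_chain_prunes_to_diene_core(self, mol):
        skel = extract_skeleton(mol("geranyl"))
        m = Chem.MolFromSmiles(skel)
        assert m.GetRingInfo().NumRings() == 0
        assert sum(b.GetBondType() == Chem.BondType.DOUBLE
                   for b in m.GetBonds()) == 2

    def test_idempotent(self, mol):
        for name in ("alpha_terpinyl", "geranyl", "cyclopropylcarbinyl"):
            k1 = extract_skeleton(mol(name))
            g1 = parse_smiles(k1)
            assert extract_skeleton(g1) == k1


def _bridged_frame(a, b, c):
    """Bicyclo[a.b.c] graph: two bridgeheads joined by three paths."""
    g = nx.Graph()
    heads = [0, 1]
    nxt = 2
    for length in (a, b, c):
        prev = heads[0]
        for _ in range(length):
            g.add_edge(prev, nxt)
            prev = nxt
            nxt += 1
        g.add_edge(prev, heads[1])
    return g


def _spiro_frame(a, b):
    g = nx.Graph()
    nxt = 1
    for length in (a, b):
        prev = 0
        for _ in range(length):
            g.add_edge(prev, nxt)
            prev = nxt
            nxt += 1
        g.add_edge(prev, 0)
    return g


def _separated_frame(p, q, link):
    g = nx.Graph()
    ring1 = list(range(p))
    for i in range(p):
        g.add_edge(ring1[i], ring1[(i + 1) % p])
    ring2 = list(range(p, p + q))
    for i in range(q):
        g.add_edge(ring2[i], ring2[(i + 1) % q])
    prev = 0
    nxt = p + q
    for _ in range(link - 1):
        g.add_edge(prev, nxt)
        prev = nxt
        nxt += 1
    g.add_edge(prev, p)
    return g


def _sssr_shared_atom_oracle(g: nx.Graph) -> Topology:
    """Independent classifier from a minimum cycle basis: shared-atom and
    adjacency counting per the textbook definitions."""
    cycles = nx.minimum_cycle_basis(g)
    if len(cycles) == 0:
        return Topology.ACYCLIC
    if len(cycles) == 1:
        return Topology.MONOCYCLIC
    assert len(cycles) == 2
    shared = set(cycles[0]) & set(cycles[1])
    if len(shared) == 0:
        return Topology.SEPARATED
    if len(shared) == 1:
        return Topology.SPIRO
    if len(shared) == 2 and g.has_edge(*shared):
        return Topology.FUSED
    return Topology.BRIDGED


class TestTopology:
    @pytest.mark.parametrize("smiles, expected", [
        ("C1CC2CCC1C2", Topology.BRIDGED),    # bornane frame
        ("C1CC2CC2C1", Topology.FUSED),       # thujane frame
        ("C1CCC2(CC1)CCCC2", Topology.SPIRO), # spiro[4.5]decane
        ("C1CCC(CC1)C1CC1", Topology.SEPARATED),
        ("C1=CCCCC1", Topology.MONOCYCLIC),
        ("C=CCC=C", Topology.ACYCLIC),
    ])
    def test_named_frames(self, smiles, expected):
        assert classify_topology(Chem.CanonSmiles(smiles)) is expected

    def test_three_ring_systems_rejected(self):
        with pytest.raises(ValueError):
            classify_topology("C1CC2CC3CC1C1CC(C2)C31")  # adamantane-like

    def test_agrees_with_cycle_basis_oracle_on_all_two_ring_frames(self):
        frames = []
        # bridged bicyclo[a.b.c], c >= 1, up to 10 carbons
        for a in range(1, 7):
            for b in range(1, a + 1):
                for c in range(1, b + 1):
                    if a + b + c + 2 <= 10:
                        frames.append(_bridged_frame(a, b, c))
        # fused (c = 0)
        for a in range(2, 8):
            for b in range(2, a + 1):
                if a + b + 2 <= 10:
                    frames.append(_bridged_frame(a, b, 0))
        # spiro and separated
        for a in range(2, 8):
            for b in range(2, a + 1):
                if a + b + 1 <= 10:
                    frames.append(_spiro_frame(a, b))
        for p in range(3, 8):
            for q in range(3, p + 1):
                for link in (1, 2):
                    if p + q + link - 1 <= 10:
                        frames.append(_separated_frame(p, q, link))
        assert len(frames) > 40
        for frame in frames:
            assert classify_topology(frame) is _sssr_shared_atom_oracle(frame)


class TestClusterNetwork:
    def test_single_monocyclic_row(self, mol):
        cfg = EnumConfig(max_rounds=1,
                         enabled_types={ReactionType.HYDRIDE_SHIFT},
                         stability=StabilityConfig(mode="permissive"))
        net = run_enumeration([mol("alpha_terpinyl")], cfg)
        table = cluster_network(net)
        cyclohexene = EC_REFERENCE_FRAMEWORKS["menthane"]
        row = table[table.framework_key == cyclohexene]
        assert len(row) == 1
        assert row.iloc[0].topology == "monocyclic"
        assert row.iloc[0].is_ec_reference
        # hydride shifts cannot alter the framework
        assert row.iloc[0].n_carbocation == len(net.nodes)

    def test_same_frame_members_pool(self, mol):
        cfg = EnumConfig(max_rounds=1, enabled_types=set(),
                         stability=StabilityConfig(mode="permissive"))
        terpinen_4_yl = parse_smiles("CC1=CC[C+](C(C)C)CC1")
        net = run_enumeration([mol("alpha_terpinyl"), terpinen_4_yl], cfg)
        table = cluster_network(net)
        assert len(table) == 1
        assert table.iloc[0].n_carbocation == 2

    def test_empty_network_rejected(self):
        from cationet.enumerate import ReactionNetwork
        with pytest.raises(ValueError):
            cluster_network(ReactionNetwork(EnumConfig()))
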