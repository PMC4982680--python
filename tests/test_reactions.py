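"""Reaction operators: preconditions, hand-derived products, conservation
and reversibility."""

import pytest

from cationet.enumerate import EnumConfig, run_enumeration
from cationet.molgraph import (degree_of_unsaturation, formula, parse_smiles)
from cationet.reactions import (ReactionType, apply_alkyl_shift,
                                apply_alkylation, apply_hydride_shift,
                                apply_methyl_shift, apply_proton_transfer,
                                enumerate_products, reactive_atoms)
from cationet.stability import StabilityConfig

from conftest import permute_graph, random_permutation

ALL = EnumConfig(shift_range_bonds=None)


def keys(products):
    return {ev.product_key for _, ev in products}


class TestReactiveAtoms:
    def test_tert_butyl_only_hydrogens(self, mol):
        g = mol("tert_butyl")
        atoms = reactive_atoms(g)
        assert len(atoms) == 9
        assert all(g.elements[a] == "H" for a in atoms)

    def test_allyl_excludes_cation_frame(self, mol):
        g = mol("allyl")
        assert len(reactive_atoms(g)) == 4  # far CH2, its 2 H, central H

    def test_ethyl_beta_hydrogens(self, mol):
        g = mol("ethyl")
        atoms = reactive_atoms(g)
        assert len(atoms) == 3
        assert all(g.elements[a] == "H" for a in atoms)

    def test_neutral_rejected(self):
        with pytest.raises(ValueError):
            reactive_atoms(parse_smiles("CC"))


class TestAlkylation:
    def test_homoallyl_near_and_far_attack(self, mol):
        g = mol("homoallyl")
        got = set()
        for a in reactive_atoms(g):
            if g.elements[a] == "C" and g.in_double_bond(a):
                got |= keys(apply_alkylation(g, a))
        assert got == {mol("cyclopropylcarbinyl").key(),
                       mol("cyclobutyl").key()}

    def test_allyl_yields_nothing(self, mol):
        g = mol("allyl")
        prods = []
        for a in reactive_atoms(g):
            if g.elements[a] == "C" and g.in_double_bond(a):
                prods += apply_alkylation(g, a)
        assert prods == []

    def test_neryl_16_and_17_closures(self, mol):
        g = mol("geranyl")  # cis/trans collapse constitutionally
        got = set()
        for a in reactive_atoms(g):
            if g.elements[a] == "C" and g.in_double_bond(a):
                got |= keys(apply_alkylation(g, a))
        assert mol("alpha_terpinyl").key() in got           # 1,6-closure
        assert parse_smiles("CC1=CCC(C)(C)[CH+]CC1").key() in got  # 1,7
        assert len(got) == 2

    def test_adjacent_target_rejected(self, mol):
        g = mol("allyl")
        near = next(a for a in g.carbon_neighbors(g.charge_site)
                    if g.in_double_bond(a))
        with pytest.raises(ValueError):
            apply_alkylation(g, near)


class TestHydrideShift:
    def test_degenerate_shift_returns_same_key(self, mol):
        g = mol("sec_butyl")
        c3_h = [a for a in reactive_atoms(g)
                if g.elements[a] == "H"
                and len(g.carbon_neighbors(next(iter(g.adj[a])))) == 2]
        prods = [apply_hydride_shift(g, a) for a in c3_h]
        assert any(ev.product_key == g.key() for p in prods for _, ev in p)

    def test_isobutyl_to_tert_butyl(self, mol):
        g = mol("isobutyl")
        got = set()
        for a in reactive_atoms(g):
            if g.elements[a] == "H":
                got |= keys(apply_hydride_shift(g, a))
        assert mol("tert_butyl").key() in got

    def test_sec_butyl_to_primary(self, mol):
        g = mol("sec_butyl")
        got = set()
        for a in reactive_atoms(g):
            if g.elements[a] == "H":
                got |= keys(apply_hydride_shift(g, a))
        assert parse_smiles("[CH2+]CCC").key() in got

    def test_range_gate_blocks_long_shift(self, mol):
        g = parse_smiles("[CH2+]CCCCCC")  # heptyl: terminal H is 6 bonds out
        terminal_h = [a for a in reactive_atoms(g) if g.elements[a] == "H"
                      and g.bond_path_length(next(iter(g.adj[a])),
                                             g.charge_site) == 6]
        assert terminal_h
        assert apply_hydride_shift(g, terminal_h[0], max_range=4) == []
        assert apply_hydride_shift(g, terminal_h[0], max_range=None)


class TestCarbonShifts:
    def test_ring_expansion_and_contraction(self, mol):
        g = mol("cyclopropylcarbinyl")
        got = set()
        for a in reactive_atoms(g):
            if g.elements[a] == "C" and not g.is_methyl(a):
                got |= keys(apply_alkyl_shift(g, a))
        assert mol("cyclobutyl").key() in got
        back = set()
        cb = mol("cyclobutyl")
        for a in reactive_atoms(cb):
            if cb.elements[a] == "C" and not cb.is_methyl(a):
                back |= keys(apply_alkyl_shift(cb, a))
        assert g.key() in back

    def test_neopentyl_has_no_alkyl_shift(self, mol):
        g = mol("neopentyl")
        prods = []
        for a in reactive_atoms(g):
            if g.elements[a] == "C" and not g.is_methyl(a):
                prods += apply_alkyl_shift(g, a)
        assert prods == []

    def test_neopentyl_methyl_shift(self, mol):
        g = mol("neopentyl")
        got = set()
        for a in reactive_atoms(g):
            if g.is_methyl(a):
                got |= keys(apply_methyl_shift(g, a))
        assert got == {parse_smiles("CC[C+](C)C").key()}  # tert-amyl

    def test_tert_butyl_methyls_excluded(self, mol):
        g = mol("tert_butyl")
        assert not any(g.is_methyl(a) for a in reactive_atoms(g))

    def test_pinacol_type_shift(self):
        g = parse_smiles("CC(C)(C)[CH+]C")  # 3,3-dimethyl-2-butyl
        got = set()
        for a in reactive_atoms(g):
            if g.is_methyl(a):
                got |= keys(apply_methyl_shift(g, a))
        assert parse_smiles("CC(C)[C+](C)C").key() in got

    def test_wrong_migrating_kind_raises(self, mol):
        g = mol("neopentyl")
        methyl = next(a for a in reactive_atoms(g) if g.is_methyl(a))
        with pytest.raises(ValueError):
            apply_alkyl_shift(g, methyl)


class TestProtonTransfer:
    def test_pentenyl_transfer(self, mol):
        g = mol("pentenyl")  # [CH2+]CCC=C
        got = set()
        for a in reactive_atoms(g):
            if g.elements[a] != "H":
                continue
            (dc,) = g.adj[a]
            if g.charge_site in g.adj[dc] and not g.in_double_bond(dc):
                for i, j in g.double_bonds():
                    got |= keys(apply_proton_transfer(g, a, i))
                    got |= keys(apply_proton_transfer(g, a, j))
        assert parse_smiles("C=CC[CH+]C").key() in got
        for k in got:
            assert formula(parse_smiles(k)) == formula(g)

    def test_no_alkene_no_products(self, mol):
        g = mol("sec_butyl")
        prods = enumerate_products(
            g, EnumConfig(enabled_types={ReactionType.PROTON_TRANSFER},
                          shift_range_bonds=None))
        assert prods == []

    def test_conserves_rings_plus_double_bonds(self, mol):
        g = mol("alpha_terpinyl")
        prods = enumerate_products(
            g, EnumConfig(enabled_types={ReactionType.PROTON_TRANSFER},
                          shift_range_bonds=None))
        assert prods
        for p, _ in prods:
            assert degree_of_unsaturation(p) == 2


EXPECTED_DELTA = {  # (delta rings, delta double bonds) per operator
    ReactionType.ALKYLATION: (1, -1),
    ReactionType.ALKYL_SHIFT: (0, 0),
    ReactionType.HYDRIDE_SHIFT: (0, 0),
    ReactionType.METHYL_SHIFT: (0, 0),
    ReactionType.PROTON_TRANSFER: (0, 0),
    ReactionType.RESONANCE: (0, 0),
}


class TestEnumerateProducts:
    def test_tert_butyl_closed_set(self, mol):
        g = mol("tert_butyl")
        assert keys(enumerate_products(g, ALL)) == {mol("isobutyl").key()}

    def test_allyl_only_self(self, mol):
        assert enumerate_products(mol("allyl"), ALL) == []

    @pytest.mark.parametrize("name", ["geranyl", "alpha_terpinyl",
                                      "pentenyl", "neopentyl",
                                      "cyclopropylcarbinyl"])
    def test_conservation_and_unsaturation_accounting(self, name, mol):
        g = mol(name)
        rings_r = sum(len(a) for a in g.adj) // 2 - g.n_atoms + 1
        db_r = len(g.double_bonds())
        for p, ev in enumerate_products(g, ALL):
            assert formula(p) == formula(g)
            rings_p = sum(len(a) for a in p.adj) // 2 - p.n_atoms + 1
            d_rings, d_db = EXPECTED_DELTA[ev.rtype]
            assert rings_p - rings_r == d_rings
            assert len(p.double_bonds()) - db_r == d_db

    def test_output_independent_of_atom_ordering(self, mol):
        for name in ("geranyl", "alpha_terpinyl", "cyclopropylcarbinyl"):
            g = mol(name)
            ref = keys(enumerate_products(g, ALL))
            for seed in range(3):
                h = permute_graph(g, random_permutation(g.n_atoms, seed))
                assert keys(enumerate_products(h, ALL)) == ref

    def test_shifts_and_transfers_reversible_on_c5_closures(self, mol):
        # exhaustive reversibility over the saturated and unsaturated C5
        # cation spaces: for each emitted g -> p some operator on p emits g.
        # Cyclization is excluded: alkylation changes (rings, double bonds)
        # by (+1, -1) and no operator in the set carries the inverse delta,
        # so ring closure is one-way by conservation accounting.
        cfg = EnumConfig(max_rounds=None,
                         stability=StabilityConfig(mode="permissive"),
                         shift_range_bonds=None)
        for seed in ("[CH2+]CCCC", "[CH2+]CCC=C"):
            net = run_enumeration([parse_smiles(seed)], cfg)
            for rec in net.nodes.values():
                for p, ev in enumerate_products(rec.graph, ALL):
                    if ev.product_key == rec.key:
                        continue
                    if ev.rtype is ReactionType.ALKYLATION:
                        continue
                    back = keys(enumerate_products(p, ALL))
                    assert rec.key in back, (
                        f"{ev.rtype} {rec.key} -> {ev.product_key} "
                        "has no reverse")
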