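"""The five carbocation rearrangement operators and the reactive-atom rule.

Each operator is a pure graph edit: it takes a reactant :class:`CationGraph`
plus the participating atom(s) and returns product graphs paired with typed
:class:`ReactionEvent` records.  Operators never mutate their input and never
deduplicate — degenerate products equal to the reactant are emitted and
removed downstream, which keeps every operator locally testable.

The reactive-atom rule: every atom of the reactant is eligible except the
cationic carbon and its three directly bonded atoms (those three are the
resonance/ionization frame, not rearrangement sites).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from .molgraph import CationGraph, resonance_forms

if TYPE_CHECKING:  # pragma: no cover
    from .enumerate import EnumConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionType",
    "ReactionEvent",
    "reactive_atoms",
    "apply_alkylation",
    "apply_hydride_shift",
    "apply_alkyl_shift",
    "apply_methyl_shift",
    "apply_proton_transfer",
    "enumerate_products",
    "CHEMICAL_TYPES",
]


class ReactionType(enum.Enum):
    """Closed enumeration of edge types in the reaction network.

    ``RESONANCE`` marks the zero-step allylic-delocalization edges; the other
    five are the chemical rearrangement steps.
    """

    ALKYLATION = "alkylation"            # intramolecular alkylation of a C=C
    ALKYL_SHIFT = "alkyl_shift"          # 1,2-alkyl shift (non-methyl)
    HYDRIDE_SHIFT = "hydride_shift"      # hydride shift
    METHYL_SHIFT = "methyl_shift"        # 1,2-methyl shift
    PROTON_TRANSFER = "proton_transfer"  # concerted deprotonation/reprotonation
    RESONANCE = "resonance"


CHEMICAL_TYPES = frozenset(
    t for t in ReactionType if t is not ReactionType.RESONANCE
)


@dataclass(frozen=True)
class ReactionEvent:
    """One directed edge of the network.

    ``atoms`` are the participating atom indices in the *reactant* frame;
    their meaning depends on ``rtype`` (documented in each operator).
    """

    reactant_key: str
    product_key: str
    rtype: ReactionType
    atoms: tuple[int, ...]

    def identity(self) -> tuple:
        return (self.reactant_key, self.product_key, self.rtype, self.atoms)


def reactive_atoms(g: CationGraph) -> list[int]:
    """Atom indices eligible for rearrangement: everything except the
    cationic carbon and its three bonded atoms."""
    c = g.charge_site
    if c is None:
        raise ValueError("reactive_atoms requires a charged species")
    excluded = {c, *g.adj[c]}
    return [i for i in range(g.n_atoms) if i not in excluded]


def _finish(g: CationGraph, product: CationGraph, rtype: ReactionType,
            atoms: tuple[int, ...]) -> Optional[tuple[CationGraph, ReactionEvent]]:
    """Validate a freshly edited product and wrap it in an event, or drop it."""
    try:
        product.validate()
    except ValueError as exc:
        logger.debug("dropping invalid %s product of %s: %s",
                     rtype.value, g.key(), exc)
        return None
    return product, ReactionEvent(g.key(), product.key(), rtype, atoms)


def apply_alkylation(
    g: CationGraph, alkene_carbon: int
) -> list[tuple[CationGraph, ReactionEvent]]:
    """Intramolecular alkylation: the cationic carbon attacks *alkene_carbon*
    of an internal C=C, forming a ring of size >= 3; the charge moves to the
    other alkene carbon.

    Alkenes conjugated with the charge site (either alkene carbon adjacent to
    it) are not alkylation targets — that interaction is the allylic
    resonance handled separately — so an allyl cation yields no products.

    Event atoms: ``(charge_site, alkene_carbon, partner)``.
    """
    c = g.charge_site
    if c is None:
        raise ValueError("alkylation requires a charged species")
    if g.elements[alkene_carbon] != "C" or not g.in_double_bond(alkene_carbon):
        raise ValueError("alkylation target must be a carbon of a C=C")
    if alkene_carbon in g.adj[c] or alkene_carbon == c:
        raise ValueError("alkylation target adjacent to the charge site")
    partner = g.double_bond_partner(alkene_carbon)
    if partner == c or partner in g.adj[c]:
        return []  # conjugated alkene: resonance, not cyclization
    product = g.with_edits(
        add_bonds=[(c, alkene_carbon, 1)],
        set_orders=[(alkene_carbon, partner, 1)],
        charge_site=partner,
    )
    out = _finish(g, product, ReactionType.ALKYLATION, (c, alkene_carbon, partner))
    return [out] if out else []


def apply_hydride_shift(
    g: CationGraph, h_atom: int, max_range: Optional[int] = None
) -> list[tuple[CationGraph, ReactionEvent]]:
    """Hydride shift: *h_atom* migrates to the cationic carbon and the charge
    moves to the hydrogen's origin carbon.

    ``max_range`` bounds the through-bond separation between the origin
    carbon and the charge site (``None`` = unlimited); a 1,2-shift has
    separation 1.

    Event atoms: ``(h_atom, origin_carbon, charge_site)``.
    """
    c = g.charge_site
    if c is None:
        raise ValueError("hydride shift requires a charged species")
    if g.elements[h_atom] != "H":
        raise ValueError("hydride shift requires a hydrogen atom")
    (origin,) = g.adj[h_atom]
    if origin == c:
        raise ValueError("hydride already on the charge site")
    if max_range is not None and g.bond_path_length(origin, c, max_range) is None:
        return []
    product = g.with_edits(
        remove_bonds=[(h_atom, origin)],
        add_bonds=[(h_atom, c, 1)],
        charge_site=origin,
    )
    out = _finish(g, product, ReactionType.HYDRIDE_SHIFT, (h_atom, origin, c))
    return [out] if out else []


def _shift_carbon(
    g: CationGraph, migrating: int, want_methyl: bool, rtype: ReactionType
) -> list[tuple[CationGraph, ReactionEvent]]:
    c = g.charge_site
    if c is None:
        raise ValueError("carbon shifts require a charged species")
    if g.elements[migrating] != "C":
        raise ValueError("migrating atom must be a carbon")
    if g.is_methyl(migrating) != want_methyl:
        kind = "a methyl" if want_methyl else "a non-methyl carbon"
        raise ValueError(f"migrating atom must be {kind}")
    out = []
    # every anchor bonded to both the migrating carbon and the charge site
    for anchor in g.carbon_neighbors(migrating):
        if anchor == c or c not in g.adj[anchor]:
            continue
        if g.bond_order(migrating, anchor) != 1:
            continue  # only sigma bonds migrate
        if g.in_double_bond(anchor):
            continue  # charge would land on an sp2 carbon
        if migrating in g.adj[c]:
            continue  # would form a two-membered ring
        product = g.with_edits(
            remove_bonds=[(migrating, anchor)],
            add_bonds=[(migrating, c, 1)],
            charge_site=anchor,
        )
        res = _finish(g, product, rtype, (migrating, anchor, c))
        if res:
            out.append(res)
    return out


def apply_alkyl_shift(
    g: CationGraph, migrating_carbon: int
) -> list[tuple[CationGraph, ReactionEvent]]:
    """1,2-alkyl shift: a non-methyl carbon bonded to an anchor carbon
    adjacent to the charge site migrates onto the cationic carbon; the charge
    moves to the anchor.  When the migrating bond lies in a ring this is a
    ring expansion or contraction (ring opening of a bond adjacent to the
    charge site is the retro-alkylation pathway).

    One product is emitted per valid anchor (a migrating ring carbon can have
    two).  Event atoms: ``(migrating_carbon, anchor, charge_site)``.
    """
    return _shift_carbon(g, migrating_carbon, want_methyl=False,
                         rtype=ReactionType.ALKYL_SHIFT)


def apply_methyl_shift(
    g: CationGraph, methyl_carbon: int
) -> list[tuple[CationGraph, ReactionEvent]]:
    """1,2-methyl shift: as :func:`apply_alkyl_shift` but the migrating
    carbon must be a methyl group (CH3 with one carbon neighbor)."""
    return _shift_carbon(g, methyl_carbon, want_methyl=True,
                         rtype=ReactionType.METHYL_SHIFT)


def apply_proton_transfer(
    g: CationGraph, donor_h: int, acceptor_carbon: int,
    max_range: Optional[int] = None,
) -> list[tuple[CationGraph, ReactionEvent]]:
    """Intramolecular proton transfer: a hydrogen beta to the charge site is
    removed (its carbon forms a new C=C with the old cationic carbon) and
    concertedly protonates *acceptor_carbon* of a remote alkene, putting the
    charge on the other carbon of the accepting alkene.

    ``max_range`` bounds the through-bond separation between the donor H and
    the acceptor carbon (the topological analog of a geometric H...C gate).

    Event atoms: ``(donor_h, donor_carbon, acceptor_carbon, new_charge)``.
    """
    c = g.charge_site
    if c is None:
        raise ValueError("proton transfer requires a charged species")
    if g.elements[donor_h] != "H":
        raise ValueError("donor must be a hydrogen atom")
    (donor_c,) = g.adj[donor_h]
    if donor_c == c or c not in g.adj[donor_c]:
        raise ValueError("donor hydrogen must sit beta to the charge site")
    if g.in_double_bond(donor_c):
        return []  # deprotonation would create a cumulated diene
    if g.elements[acceptor_carbon] != "C" or not g.in_double_bond(acceptor_carbon):
        raise ValueError("acceptor must be a carbon of an existing C=C")
    new_charge = g.double_bond_partner(acceptor_carbon)
    if {acceptor_carbon, new_charge} & {donor_c, c}:
        return []  # acceptor alkene is the one being formed
    if max_range is not None and \
            g.bond_path_length(donor_h, acceptor_carbon, max_range) is None:
        return []
    product = g.with_edits(
        remove_bonds=[(donor_h, donor_c)],
        set_orders=[(donor_c, c, 2), (acceptor_carbon, new_charge, 1)],
        add_bonds=[(donor_h, acceptor_carbon, 1)],
        charge_site=new_charge,
    )
    out = _finish(g, product, ReactionType.PROTON_TRANSFER,
                  (donor_h, donor_c, acceptor_carbon, new_charge))
    return [out] if out else []


def enumerate_products(
    g: CationGraph, config: "EnumConfig"
) -> list[tuple[CationGraph, ReactionEvent]]:
    """All products of every enabled operator over the reactive-atom list.

    Two nested iterations drive generation: the outer loop walks the
    reactive atoms, the inner loop tries each enabled reaction type whose
    structural precondition the atom satisfies.  Allylic resonance partners
    are appended last (when enabled).  Invalid products are dropped silently
    with a debug log entry; degenerate products equal to the reactant are
    kept (deduplication is the network's job).
    """
    enabled = config.enabled_types
    rng = config.shift_range_bonds
    c = g.charge_site
    out: list[tuple[CationGraph, ReactionEvent]] = []
    for a in reactive_atoms(g):
        if g.elements[a] == "H":
            if ReactionType.HYDRIDE_SHIFT in enabled:
                out.extend(apply_hydride_shift(g, a, max_range=rng))
            if ReactionType.PROTON_TRANSFER in enabled:
                (donor_c,) = g.adj[a]
                if c in g.adj[donor_c] and not g.in_double_bond(donor_c):
                    for i, j in g.double_bonds():
                        for acceptor in (i, j):
                            out.extend(apply_proton_transfer(
                                g, a, acceptor, max_range=rng))
        else:
            if ReactionType.ALKYLATION in enabled and g.in_double_bond(a):
                out.extend(apply_alkylation(g, a))
            if (ReactionType.ALKYL_SHIFT in enabled
                    or ReactionType.METHYL_SHIFT in enabled):
                is_me = g.is_methyl(a)
                if is_me and ReactionType.METHYL_SHIFT in enabled:
                    out.extend(apply_methyl_shift(g, a))
                elif not is_me and ReactionType.ALKYL_SHIFT in enabled:
                    out.extend(apply_alkyl_shift(g, a))
    if ReactionType.RESONANCE in enabled:
        gkey = g.key()
        for form in resonance_forms(g):
            if form.key() != gkey:
                out.append((form, ReactionEvent(gkey, form.key(),
                                                ReactionType.RESONANCE, ())))
    return out
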