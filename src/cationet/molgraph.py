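"""Explicit-hydrogen molecular graphs for classical carbocations.

The central type is :class:`CationGraph`, a small immutable graph of C and H
atoms with integer bond orders (1 or 2) and an optional designated cationic
carbon (the *charge site*).  Hydrogens are first-class graph atoms so that
hydride shifts and proton transfers can be expressed as edits on real atoms.

Canonical identity is delegated to RDKit canonical SMILES: two graphs denote
the same constitutional isomer iff their canonical keys are equal.  By
default stereochemistry is erased before canonicalization (constitutional
mode); skeleton- and route-level analyses are stereo-independent.
"""

from __future__ import annotations

import enum
from collections import deque
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

__all__ = [
    "CationGraph",
    "CationClass",
    "parse_smiles",
    "render_smiles",
    "canonical_key",
    "formula",
    "classify_cation",
    "resonance_forms",
]


class CationClass(enum.Enum):
    """Substitution class of the cationic carbon.

    ``allylic_*`` means a C=C is adjacent to the charge site, so the charge
    is delocalized over an allyl system.
    """

    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"
    ALLYLIC_PRIMARY = "allylic_primary"
    ALLYLIC_SECONDARY = "allylic_secondary"
    ALLYLIC_TERTIARY = "allylic_tertiary"

    @property
    def is_allylic(self) -> bool:
        return self.value.startswith("allylic")

    @property
    def base(self) -> "CationClass":
        """The class with any allylic qualifier removed."""
        return CationClass(self.value.replace("allylic_", ""))


class CationGraph:
    """Connected C/H molecular graph with at most one trivalent cationic C.

    Parameters
    ----------
    elements
        Per-atom element symbols, each ``"C"`` or ``"H"``.
    bonds
        ``(i, j, order)`` triples with ``order`` 1 or 2.
    charge_site
        Index of the cationic carbon, or ``None`` for a neutral species.
    coords
        Optional ``(n_atoms, 3)`` Cartesian coordinates in Angstrom
        (geometric mode only).
    stereo_tags
        Optional per-atom parity labels (stereo mode only).

    Instances are immutable by convention; all reaction operators return new
    graphs via :meth:`with_edits`.
    """

    __slots__ = ("elements", "adj", "charge_site", "coords", "stereo_tags",
                 "_key", "_key_stereo")

    def __init__(
        self,
        elements: Sequence[str],
        bonds: Iterable[tuple[int, int, int]],
        charge_site: Optional[int] = None,
        coords: Optional[np.ndarray] = None,
        stereo_tags: Optional[dict[int, int]] = None,
        validate: bool = True,
    ) -> None:
        self.elements: tuple[str, ...] = tuple(elements)
        adj: list[dict[int, int]] = [dict() for _ in self.elements]
        for i, j, order in bonds:
            adj[i][j] = order
            adj[j][i] = order
        self.adj: tuple[dict[int, int], ...] = tuple(adj)
        self.charge_site = charge_site
        self.coords = coords
        self.stereo_tags = stereo_tags
        self._key: Optional[str] = None
        self._key_stereo: Optional[str] = None
        if validate:
            self.validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> Iterator[int]:
        return iter(self.adj[i])

    def bond_order(self, i: int, j: int) -> int:
        """Bond order between *i* and *j*, or 0 if not bonded."""
        return self.adj[i].get(j, 0)

    def total_order(self, i: int) -> int:
        return sum(self.adj[i].values())

    def carbon_neighbors(self, i: int) -> list[int]:
        return [j for j in self.adj[i] if self.elements[j] == "C"]

    def hydrogen_neighbors(self, i: int) -> list[int]:
        return [j for j in self.adj[i] if self.elements[j] == "H"]

    def h_count(self, i: int) -> int:
        return len(self.hydrogen_neighbors(i))

    def in_double_bond(self, i: int) -> bool:
        return any(order == 2 for order in self.adj[i].values())

    def double_bond_partner(self, i: int) -> Optional[int]:
        for j, order in self.adj[i].items():
            if order == 2:
                return j
        return None

    def double_bonds(self) -> list[tuple[int, int]]:
        """All C=C bonds as ``(i, j)`` with ``i < j``."""
        return [
            (i, j)
            for i in range(self.n_atoms)
            for j, order in self.adj[i].items()
            if order == 2 and i < j
        ]

    def is_methyl(self, i: int) -> bool:
        """True iff atom *i* is a CH3 carbon bonded to exactly one carbon."""
        return (
            self.elements[i] == "C"
            and self.h_count(i) == 3
            and len(self.carbon_neighbors(i)) == 1
        )

    def bond_path_length(self, i: int, j: int,
                         cutoff: Optional[int] = None) -> Optional[int]:
        """Through-bond separation (number of bonds) between atoms *i*, *j*.

        Returns ``None`` if no path within *cutoff* bonds exists.
        """
        if i == j:
            return 0
        seen = {i}
        frontier = [i]
        dist = 0
        while frontier:
            dist += 1
            if cutoff is not None and dist > cutoff:
                return None
            nxt = []
            for a in frontier:
                for b in self.adj[a]:
                    if b == j:
                        return dist
                    if b not in seen:
                        seen.add(b)
                        nxt.append(b)
            frontier = nxt
        return None

    def atom_path(self, i: int, j: int) -> list[int]:
        """One shortest atom path from *i* to *j* (inclusive), BFS order."""
        if i == j:
            return [i]
        prev = {i: -1}
        q = deque([i])
        while q:
            a = q.popleft()
            for b in sorted(self.adj[a]):
                if b not in prev:
                    prev[b] = a
                    if b == j:
                        path = [b]
                        while path[-1] != i:
                            path.append(prev[path[-1]])
                        return path[::-1]
                    q.append(b)
        raise ValueError(f"no path between atoms {i} and {j}")

    # -- validity ----------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        n = self.n_atoms
        if n == 0:
            raise ValueError("empty graph")
        for el in self.elements:
            if el not in ("C", "H"):
                raise ValueError(f"unsupported element {el!r}")
        # connectivity
        if n > 1:
            seen = {0}
            stack = [0]
            while stack:
                a = stack.pop()
                for b in self.adj[a]:
                    if b not in seen:
                        seen.add(b)
                        stack.append(b)
            if len(seen) != n:
                raise ValueError("graph is disconnected")
        for i in range(n):
            tot = self.total_order(i)
            if self.elements[i] == "H":
                if len(self.adj[i]) != 1 or tot != 1:
                    raise ValueError(f"H atom {i} must have exactly one single bond")
            elif i == self.charge_site:
                if tot != 3 or len(self.adj[i]) != 3:
                    raise ValueError("charge site must carry exactly 3 single bonds")
                if self.in_double_bond(i):
                    raise ValueError("charge site cannot be in a double bond")
            else:
                if tot != 4:
                    raise ValueError(f"carbon {i} has total bond order {tot} != 4")
        for i, j in self.double_bonds():
            if self.elements[i] != "C" or self.elements[j] != "C":
                raise ValueError("double bonds must join two carbons")
        if self.charge_site is not None and self.elements[self.charge_site] != "C":
            raise ValueError("charge site must be a carbon")

    def is_valid(self) -> bool:
        try:
            self.validate()
        except ValueError:
            return False
        return True

    # -- editing -----------------------------------------------------------

    def with_edits(
        self,
        remove_bonds: Iterable[tuple[int, int]] = (),
        add_bonds: Iterable[tuple[int, int, int]] = (),
        set_orders: Iterable[tuple[int, int, int]] = (),
        charge_site: Optional[int] = None,
        validate: bool = False,
    ) -> "CationGraph":
        """Return a copy with the given bond edits and new charge site.

        ``charge_site`` is the charge site of the *result* (``None`` clears
        the charge).  Validation is off by default: operators validate the
        finished product once.
        """
        bonds: dict[tuple[int, int], int] = {}
        for i in range(self.n_atoms):
            for j, order in self.adj[i].items():
                if i < j:
                    bonds[(i, j)] = order
        for i, j in remove_bonds:
            bonds.pop((min(i, j), max(i, j)), None)
        for i, j, order in set_orders:
            bonds[(min(i, j), max(i, j))] = order
        for i, j, order in add_bonds:
            bonds[(min(i, j), max(i, j))] = order
        return CationGraph(
            self.elements,
            [(i, j, o) for (i, j), o in bonds.items()],
            charge_site=charge_site,
            coords=self.coords,
            stereo_tags=self.stereo_tags,
            validate=validate,
        )

    def add_hydrogen(self, carbon: int) -> "CationGraph":
        """Return a neutral copy with one new H bonded to *carbon*."""
        elements = self.elements + ("H",)
        h = len(elements) - 1
        bonds = [
            (i, j, o)
            for i in range(self.n_atoms)
            for j, o in self.adj[i].items()
            if i < j
        ]
        bonds.append((carbon, h, 1))
        coords = None
        if self.coords is not None:
            # place the new H on top of its carbon; geometric users re-minimize
            coords = np.vstack([self.coords, self.coords[carbon]])
        return CationGraph(elements, bonds, charge_site=None, coords=coords,
                           validate=False)

    # -- RDKit bridge ------------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        """Heavy-atom RDKit molecule (hydrogens folded into H counts)."""
        carbons = [i for i, el in enumerate(self.elements) if el == "C"]
        index = {a: k for k, a in enumerate(carbons)}
        rw = RWMol()
        for a in carbons:
            atom = Chem.Atom(6)
            atom.SetNumExplicitHs(self.h_count(a))
            atom.SetNoImplicit(True)
            if a == self.charge_site:
                atom.SetFormalCharge(1)
            rw.AddAtom(atom)
        for a in carbons:
            for b, order in self.adj[a].items():
                if self.elements[b] == "C" and a < b:
                    rw.AddBond(index[a], index[b],
                               Chem.BondType.DOUBLE if order == 2
                               else Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def key(self, use_stereo: bool = False) -> str:
        """Memoized canonical key; see :func:`canonical_key`."""
        if use_stereo:
            if self._key_stereo is None:
                self._key_stereo = canonical_key(self, use_stereo=True)
            return self._key_stereo
        if self._key is None:
            self._key = canonical_key(self)
        return self._key

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        nc, nh, q = formula(self)
        return f"CationGraph(C{nc}H{nh}{'+' if q else ''} {self.key()})"


# -- module-level operations ----------------------------------------------


def parse_smiles(text: str) -> CationGraph:
    """Parse a C/H SMILES string into an explicit-hydrogen ``CationGraph``.

    The input may carry at most one ``+1`` formal charge; all other atoms
    must be neutral carbons or hydrogens.  Stereochemical annotations are
    accepted and ignored (constitutional mode).

    Raises
    ------
    ValueError
        On malformed SMILES, elements other than C/H, charges other than
        0/+1, or more than one charged atom.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"malformed SMILES: {text!r}")
    charged = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ("C", "H"):
            raise ValueError(f"unsupported element {atom.GetSymbol()!r} in {text!r}")
        if atom.GetFormalCharge() == 1:
            charged.append(atom.GetIdx())
        elif atom.GetFormalCharge() != 0:
            raise ValueError(f"only +1/neutral atoms allowed: {text!r}")
        if atom.GetNumRadicalElectrons():
            raise ValueError(f"radical species not supported: {text!r}")
    if len(charged) > 1:
        raise ValueError(f"more than one charged atom in {text!r}")
    mol = Chem.AddHs(mol)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = []
    for b in mol.GetBonds():
        if b.GetBondType() == Chem.BondType.SINGLE:
            order = 1
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            order = 2
        else:
            raise ValueError(f"unsupported bond order in {text!r}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    charge_site = charged[0] if charged else None
    return CationGraph(elements, bonds, charge_site=charge_site)


def canonical_key(g: CationGraph, use_stereo: bool = False) -> str:
    """Permutation-invariant canonical SMILES key of *g*.

    With ``use_stereo`` off (the default) stereo descriptors are erased, so
    configurational isomers collapse onto one constitutional key.
    """
    return Chem.MolToSmiles(g.to_rdkit(), isomericSmiles=use_stereo)


def render_smiles(g: CationGraph) -> str:
    """Canonical SMILES of *g* (alias of :func:`canonical_key`)."""
    return g.key()


def formula(g: CationGraph) -> tuple[int, int, int]:
    """``(nC, nH, charge)`` of the species."""
    nc = sum(1 for el in g.elements if el == "C")
    nh = len(g.elements) - nc
    return nc, nh, (1 if g.charge_site is not None else 0)


def degree_of_unsaturation(g: CationGraph) -> int:
    """Rings plus double bonds, from cyclomatic number + pi-bond count."""
    n_bonds = sum(len(a) for a in g.adj) // 2
    rings = n_bonds - g.n_atoms + 1
    return rings + len(g.double_bonds())


def classify_cation(g: CationGraph) -> CationClass:
    """Substitution class of the charge site (primary/secondary/tertiary,
    with an ``allylic_`` qualifier when a C=C is adjacent).

    Raises ``ValueError`` for neutral species.
    """
    c = g.charge_site
    if c is None:
        raise ValueError("classify_cation requires a charged species")
    carbons = g.carbon_neighbors(c)
    base = {0: "primary", 1: "primary", 2: "secondary", 3: "tertiary"}[len(carbons)]
    allylic = any(g.in_double_bond(j) for j in carbons)
    return CationClass(("allylic_" if allylic else "") + base)


def _allylic_shift(g: CationGraph, near: int, far: int) -> CationGraph:
    """Move the charge across one adjacent C=C: ``C+ -near=far`` becomes
    ``C=near-far+``."""
    c = g.charge_site
    assert c is not None
    return g.with_edits(
        set_orders=[(c, near, 2), (near, far, 1)],
        charge_site=far,
    )


def resonance_forms(g: CationGraph) -> list[CationGraph]:
    """All allylic resonance forms of *g*, including *g* itself.

    The allylic shift is applied to closure (a conjugated polyene cation can
    delocalize over more than three carbons), and the result deduplicated by
    canonical key.  Output order: the input first, then newly reached forms
    sorted by key for determinism.
    """
    if g.charge_site is None:
        raise ValueError("resonance_forms requires a charged species")
    seen = {g.key(): g}
    frontier = [g]
    while frontier:
        cur = frontier.pop()
        c = cur.charge_site
        for near in cur.carbon_neighbors(c):
            far = cur.double_bond_partner(near)
            if far is None or far == c:
                continue
            shifted = _allylic_shift(cur, near, far)
            k = shifted.key()
            if k not in seen:
                shifted.validate()
                seen[k] = shifted
                frontier.append(shifted)
    first = g.key()
    rest = sorted(k for k in seen if k != first)
    return [seen[first]] + [seen[k] for k in rest]
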