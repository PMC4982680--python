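"""Optional geometric mode: conformers, stereo duplication, distance gates.

The default enumeration is purely topological; everything in this module is
opt-in machinery for runs that carry 3D coordinates.  Force-field and
conformer engines are *contracts*: any callable satisfying the documented
interface can be plugged in, and small deterministic implementations are
bundled (an RDKit ETKDG embedder, a UFF minimizer with a harmonic fallback,
and a torsion-scan conformer generator).

Three numeric rules live here:

- the stereochemistry trigger: when the diagnostic dihedral of a reacting
  frame lies within +/-45 degrees (inclusive) of zero, both faces of the
  sp2 cation plane are viable and two placements are generated;
- the donor-acceptor distance gate: hydride shifts and proton transfers
  are unrestricted through round 5, and gated at 5.0 Angstrom (inclusive)
  afterwards;
- bond-length sanity: any returned geometry must keep bonded pairs within
  0.9-1.8 Angstrom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .molgraph import CationGraph

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryConfig",
    "stereo_placements",
    "distance_gate",
    "minimize_contract",
    "conformer_contract",
    "embed_coords",
    "uff_minimizer",
    "harmonic_relaxer",
    "torsion_scan_conformers",
    "bond_lengths_sane",
]

BOND_SANITY = (0.9, 1.8)  # Angstrom window for any bonded pair
_TARGET_LENGTH = {(1, "C", "C"): 1.54, (2, "C", "C"): 1.34,
                  (1, "C", "H"): 1.09}


@dataclass
class GeometryConfig:
    """Numeric knobs of geometric mode (lengths in Angstrom, angles in
    degrees, rounds counted from 1)."""

    dihedral_window_deg: float = 45.0
    default_bond_length: float = 1.54
    distance_cutoff_A: float = 5.0
    gate_after_round: int = 5
    conformer_rounds: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.dihedral_window_deg <= 90:
            raise ValueError("dihedral window must lie in (0, 90] degrees")
        if self.default_bond_length <= 0 or self.distance_cutoff_A <= 0:
            raise ValueError("lengths must be positive")


def _require_coords(g: CationGraph) -> np.ndarray:
    if g.coords is None:
        raise ValueError("this operation requires 3D coordinates")
    return np.asarray(g.coords, dtype=float)


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = n1 @ n2, m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def bond_lengths_sane(g: CationGraph,
                      coords: Optional[np.ndarray] = None) -> bool:
    """Whether every bonded pair lies within the 0.9-1.8 A sanity window."""
    xyz = coords if coords is not None else _require_coords(g)
    for i in range(g.n_atoms):
        for j in g.adj[i]:
            if i < j:
                d = float(np.linalg.norm(xyz[i] - xyz[j]))
                if not BOND_SANITY[0] <= d <= BOND_SANITY[1]:
                    return False
    return True


def _diagnostic_frame(g: CationGraph, reactive_atom: int) -> list[int]:
    """Four atoms defining the diagnostic dihedral of a reacting frame:
    the reactive atom followed by the first three atoms on its shortest
    path toward the cationic carbon (padded with a charge-site neighbor
    when the path is shorter than four atoms)."""
    if g.charge_site is None:
        raise ValueError("stereo placement requires a charged species")
    path = g.atom_path(reactive_atom, g.charge_site)
    frame = path[:4]
    while len(frame) < 4:
        extra = [j for j in sorted(g.adj[g.charge_site]) if j not in frame]
        if not extra:
            raise ValueError("cannot build a 4-atom dihedral frame")
        frame.append(extra[0])
    return frame


def stereo_placements(
    g: CationGraph, reactive_atom: int,
    cfg: Optional[GeometryConfig] = None,
) -> list[np.ndarray]:
    """Candidate coordinate sets for moving *reactive_atom* onto the cation.

    When the diagnostic dihedral is within the trigger window (inclusive),
    neither face of the sp2 cation plane is preferred and both placements
    are returned; otherwise only the near-face one.  Each placement puts
    the reactive atom at (plane normal x default bond length) from the
    cationic carbon, translating the atom — and, for a carbon, its bonded
    substituents rigidly — by the same vector.
    """
    cfg = cfg or GeometryConfig()
    xyz = _require_coords(g)
    c = g.charge_site
    frame = _diagnostic_frame(g, reactive_atom)
    dihedral = _dihedral(*(xyz[a] for a in frame))

    nbrs = sorted(g.adj[c])
    v1 = xyz[nbrs[1]] - xyz[nbrs[0]]
    v2 = xyz[nbrs[2]] - xyz[nbrs[0]]
    normal = np.cross(v1, v2)
    norm = np.linalg.norm(normal)
    if norm < 1e-8:
        raise ValueError("cation plane undefined (collinear neighbors)")
    normal /= norm

    moved = [reactive_atom]
    if g.elements[reactive_atom] == "C":
        moved += [j for j in g.adj[reactive_atom]]

    placements = []
    signs = (1.0, -1.0) if abs(dihedral) <= cfg.dihedral_window_deg else (1.0,)
    for s in signs:
        final = xyz[c] + s * normal * cfg.default_bond_length
        shift = final - xyz[reactive_atom]
        new = xyz.copy()
        new[moved] += shift
        placements.append(new)
    return placements


def distance_gate(
    g: CationGraph, donor_atom: int, acceptor_atom: int,
    round_idx: int, cfg: Optional[GeometryConfig] = None,
) -> bool:
    """Geometric gate on long-range hydride shifts and proton transfers:
    unrestricted through ``gate_after_round``, then allowed iff the
    donor-acceptor Euclidean distance is within the cutoff (inclusive)."""
    cfg = cfg or GeometryConfig()
    if round_idx <= cfg.gate_after_round:
        return True
    xyz = _require_coords(g)
    d = float(np.linalg.norm(xyz[donor_atom] - xyz[acceptor_atom]))
    return d <= cfg.distance_cutoff_A


# -- pluggable engines -----------------------------------------------------

MinimizerPlugin = Callable[[CationGraph], np.ndarray]


def _to_rdkit_with_h(g: CationGraph, coords: Optional[np.ndarray] = None):
    """Explicit-hydrogen RDKit molecule mirroring *g* atom-for-atom."""
    rw = Chem.RWMol()
    for i, el in enumerate(g.elements):
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        if i == g.charge_site:
            atom.SetFormalCharge(1)
        rw.AddAtom(atom)
    for i in range(g.n_atoms):
        for j, order in g.adj[i].items():
            if i < j:
                rw.AddBond(i, j, Chem.BondType.DOUBLE if order == 2
                           else Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    if coords is not None:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(coords):
            conf.SetAtomPosition(i, tuple(float(x) for x in p))
        mol.AddConformer(conf)
    return mol


def embed_coords(g: CationGraph, seed: int = 0) -> np.ndarray:
    """Deterministic distance-geometry (ETKDG) embedding of *g*."""
    mol = _to_rdkit_with_h(g)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (1 << 31)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError("embedding failed")
    return np.array(mol.GetConformer().GetPositions(), dtype=float)


def uff_minimizer(g: CationGraph) -> np.ndarray:
    """UFF minimization of the current coordinates (RDKit)."""
    xyz = _require_coords(g)
    mol = _to_rdkit_with_h(g, xyz)
    AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    return np.array(mol.GetConformer().GetPositions(), dtype=float)


def harmonic_relaxer(g: CationGraph, steps: int = 500,
                     rate: float = 0.1) -> np.ndarray:
    """Minimal bonded-terms-only relaxer: gradient steps pulling every
    bonded pair toward its ideal length.  Deterministic; used where a full
    force field is unnecessary (e.g. repairing a stretched bond)."""
    xyz = _require_coords(g).copy()
    pairs = [(i, j, g.adj[i][j]) for i in range(g.n_atoms)
             for j in g.adj[i] if i < j]
    for _ in range(steps):
        grad = np.zeros_like(xyz)
        worst = 0.0
        for i, j, order in pairs:
            key = (order, *sorted((g.elements[i], g.elements[j])))
            target = _TARGET_LENGTH.get(key, 1.54)
            delta = xyz[j] - xyz[i]
            d = float(np.linalg.norm(delta))
            if d < 1e-9:
                continue
            err = d - target
            worst = max(worst, abs(err))
            f = err * delta / d
            grad[i] += f
            grad[j] -= f
        if worst < 1e-3:
            break
        xyz += rate * grad
    return xyz


def minimize_contract(
    g: CationGraph, plugin: Optional[MinimizerPlugin] = None,
) -> CationGraph:
    """Run a minimizer plugin and return *g* with updated coordinates.

    The returned geometry must pass bond-length sanity; a failing or
    crashing plugin surfaces as ``None`` -> the caller skips the species
    (logged), mirroring how un-minimizable products are dropped.
    """
    _require_coords(g)
    plugin = plugin or (lambda graph: _require_coords(graph))
    try:
        new_xyz = np.asarray(plugin(g), dtype=float)
    except Exception as exc:  # plugin failure is a skip, not a crash
        logger.warning("minimizer plugin failed on %s: %s", g.key(), exc)
        raise ValueError("minimizer plugin failed") from exc
    if new_xyz.shape != (g.n_atoms, 3):
        raise ValueError("minimizer returned wrong-shaped coordinates")
    if not bond_lengths_sane(g, new_xyz):
        raise ValueError("minimized geometry violates bond-length sanity")
    return CationGraph(
        g.elements,
        [(i, j, o) for i in range(g.n_atoms)
         for j, o in g.adj[i].items() if i < j],
        charge_site=g.charge_site, coords=new_xyz, validate=False)


ConformerGenerator = Callable[[CationGraph, int], list[np.ndarray]]


def _rotatable_bonds(g: CationGraph) -> list[tuple[int, int]]:
    """Acyclic single C-C bonds with at least one heavy substituent on each
    side (torsions worth scanning)."""
    out = []
    for i in range(g.n_atoms):
        for j, order in g.adj[i].items():
            if i < j and order == 1 and g.elements[i] == g.elements[j] == "C":
                if len(g.carbon_neighbors(i)) < 2 or len(g.carbon_neighbors(j)) < 2:
                    continue
                if _alt_path(g, i, j):
                    continue  # in-ring bond: not a free torsion
                out.append((i, j))
    return out


def _alt_path(g: CationGraph, i: int, j: int) -> bool:
    """Whether i-j lies in a ring (another i->j path avoiding the bond)."""
    seen = {i}
    stack = [n for n in g.adj[i] if n != j]
    while stack:
        a = stack.pop()
        if a == j:
            return True
        if a in seen:
            continue
        seen.add(a)
        stack.extend(n for n in g.adj[a] if n not in seen)
    return False


def _side_atoms(g: CationGraph, i: int, j: int) -> list[int]:
    """Atoms on the j-side of the (acyclic) i-j bond, j excluded."""
    seen = {i, j}
    stack = [n for n in g.adj[j] if n != i]
    out = []
    while stack:
        a = stack.pop()
        if a in seen:
            continue
        seen.add(a)
        out.append(a)
        stack.extend(g.adj[a])
    return out


def torsion_scan_conformers(g: CationGraph, seed: int = 0,
                            angles=(120.0, 240.0),
                            max_conformers: int = 32) -> list[np.ndarray]:
    """Bundled conformer generator: rigid rotations about each rotatable
    C-C bond by the given angles, input conformer first, deduplicated by
    rounded coordinates.  ``seed`` fixes the (already deterministic) output
    order, honoring the seeded-generator contract."""
    xyz = _require_coords(g)
    conformers = [xyz.copy()]
    seen = {np.round(xyz, 2).tobytes()}
    for i, j in _rotatable_bonds(g):
        side = _side_atoms(g, i, j)
        if not side:
            continue
        axis = xyz[j] - xyz[i]
        axis = axis / np.linalg.norm(axis)
        for angle in angles:
            theta = np.radians(angle)
            k = axis
            kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]],
                           [-k[1], k[0], 0]])
            rot = (np.eye(3) + np.sin(theta) * kx
                   + (1 - np.cos(theta)) * (kx @ kx))
            new = xyz.copy()
            new[side] = (new[side] - xyz[j]) @ rot.T + xyz[j]
            fp = np.round(new, 2).tobytes()
            if fp not in seen and bond_lengths_sane(g, new):
                seen.add(fp)
                conformers.append(new)
            if len(conformers) >= max_conformers:
                return conformers
    return conformers


def conformer_contract(
    g: CationGraph, generator: Optional[ConformerGenerator] = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Run a conformer generator plugin, falling back to the single input
    conformer when the generator fails.  Every returned conformer must pass
    bond-length sanity; at least one conformer is always returned."""
    xyz = _require_coords(g)
    generator = generator or torsion_scan_conformers
    try:
        conformers = [np.asarray(c, dtype=float) for c in generator(g, seed)]
    except Exception as exc:
        logger.warning("conformer generator failed on %s: %s", g.key(), exc)
        conformers = []
    conformers = [c for c in conformers if bond_lengths_sane(g, c)]
    return conformers or [xyz.copy()]
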