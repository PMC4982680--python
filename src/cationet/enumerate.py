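"""Breadth-first closure engine for carbocation reaction networks.

Starting from one or more seed cations, rounds of product generation are
interleaved with canonical-SMILES deduplication and stability filtering
until a fixpoint (no new species) or a round limit is reached.  Allylic
resonance partners of every accepted node are folded in at the node's own
discovery round, so round indices count chemical transformations only.

The module also houses the validation harness: enumeration over linear
alkane cations with the three shift operators must reproduce, species for
species, an independent brute-force oracle that builds every constitutional
alkyl-cation isomer from scratch (all carbon trees crossed with all
H-bearing charge placements).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional, Sequence

import networkx as nx

from .molgraph import (CationClass, CationGraph, classify_cation, formula,
                       parse_smiles, resonance_forms)
from .reactions import (CHEMICAL_TYPES, ReactionEvent, ReactionType,
                        enumerate_products)
from .stability import EnergyPlugin, StabilityConfig, passes_filter

logger = logging.getLogger(__name__)

__all__ = [
    "EnumConfig",
    "CationRecord",
    "ReactionNetwork",
    "run_enumeration",
    "validate_alkanes",
    "alkane_cation_oracle",
    "linear_alkane_cation",
    "monoterpene_seed",
    "LINEAR_MONOTERPENE_SMILES",
]

#: Constitutional SMILES of the linear C10H17+ allylic substrate cation
#: (the cis/trans distinction collapses in constitutional mode).
LINEAR_MONOTERPENE_SMILES = "[CH2+]C=C(C)CCC=C(C)C"

ALL_TYPES = frozenset(ReactionType)


@dataclass
class EnumConfig:
    """Run parameters of the closure engine.

    ``shift_range_bonds`` is the through-bond cap on hydride shifts and
    proton transfers (``None`` = unlimited), the topological stand-in for a
    geometric donor-acceptor distance gate.  ``max_rounds`` of ``None``
    runs to fixpoint.
    """

    enabled_types: frozenset = ALL_TYPES
    max_rounds: Optional[int] = 10
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    stereo_enabled: bool = False
    geometry_enabled: bool = False
    shift_range_bonds: Optional[int] = 4
    geometric_gate: Optional[object] = None  # GeometryConfig, geometric mode

    def __post_init__(self) -> None:
        self.enabled_types = frozenset(self.enabled_types)
        if self.max_rounds is not None and self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1 when bounded")


@dataclass
class CationRecord:
    """One deduplicated node of the network."""

    key: str
    graph: CationGraph
    round_found: int
    cation_class: CationClass
    energy_kcal: Optional[float] = None


class ReactionNetwork:
    """Deduplicated node set plus typed, directed, deduplicated edge set."""

    def __init__(self, config: EnumConfig,
                 seeds: Sequence[str] = ()) -> None:
        self.config = config
        self.nodes: dict[str, CationRecord] = {}
        self.edges: list[ReactionEvent] = []
        self.seeds: list[str] = list(seeds)
        self._edge_ids: set[tuple] = set()
        self.rounds_run: int = 0

    def __len__(self) -> int:
        return len(self.nodes)

    def dedup_insert(self, candidate: CationRecord,
                     event: Optional[ReactionEvent] = None) -> bool:
        """Insert *candidate* unless its key is already present; record the
        generating *event* unless it is a duplicate or a degenerate
        self-edge.  Returns True iff a new node was inserted."""
        inserted = False
        if candidate.key not in self.nodes:
            self.nodes[candidate.key] = candidate
            inserted = True
        if event is not None and event.reactant_key != event.product_key:
            ident = event.identity()
            if ident not in self._edge_ids:
                self._edge_ids.add(ident)
                self.edges.append(event)
        return inserted

    def per_round_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for rec in self.nodes.values():
            counts[rec.round_found] = counts.get(rec.round_found, 0) + 1
        return dict(sorted(counts.items()))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for key, rec in self.nodes.items():
            g.add_node(key, round_found=rec.round_found,
                       cation_class=rec.cation_class.value,
                       energy_kcal=("" if rec.energy_kcal is None
                                    else rec.energy_kcal))
        for ev in self.edges:
            g.add_edge(ev.reactant_key, ev.product_key,
                       rtype=ev.rtype.value,
                       atoms=",".join(map(str, ev.atoms)))
        g.graph["seeds"] = ";".join(self.seeds)
        return g


def _insert_with_resonance(net: ReactionNetwork, g: CationGraph,
                           round_idx: int,
                           event: Optional[ReactionEvent]) -> list[str]:
    """Insert *g* plus (if enabled) its allylic resonance partners, all at
    *round_idx*.  Returns the keys of newly inserted nodes."""
    new_keys: list[str] = []
    rec = CationRecord(g.key(), g, round_idx, classify_cation(g))
    if net.dedup_insert(rec, event):
        new_keys.append(rec.key)
    if ReactionType.RESONANCE in net.config.enabled_types:
        for form in resonance_forms(g):
            if form.key() == g.key():
                continue
            ev = ReactionEvent(g.key(), form.key(), ReactionType.RESONANCE, ())
            partner = CationRecord(form.key(), form, round_idx,
                                   classify_cation(form))
            if net.dedup_insert(partner, ev):
                new_keys.append(partner.key)
    return new_keys


def run_enumeration(
    seeds: Sequence[CationGraph],
    config: Optional[EnumConfig] = None,
    plugin: Optional[EnergyPlugin] = None,
) -> ReactionNetwork:
    """Run the breadth-first closure from *seeds* under *config*.

    Every enabled operator is applied to every node; products that fail the
    stability filter are discarded (and remembered, so they are evaluated
    once), all others are recorded as nodes and edges.  Rounds proceed
    breadth-first; the run stops at fixpoint or after ``max_rounds``.
    """
    if not seeds:
        raise ValueError("at least one seed cation is required")
    config = config or EnumConfig()
    formulas = {formula(s) for s in seeds}
    if len(formulas) > 1:
        raise ValueError(f"seeds have inconsistent formulas: {formulas}")

    net = ReactionNetwork(config)
    chem_config = replace(
        config, enabled_types=config.enabled_types & CHEMICAL_TYPES)
    rejected: set[str] = set()

    frontier: list[str] = []
    for s in seeds:
        s.validate()
        if s.key() not in net.seeds:
            net.seeds.append(s.key())
        frontier.extend(_insert_with_resonance(net, s, 0, None))

    round_idx = 0
    while frontier and (config.max_rounds is None
                        or round_idx < config.max_rounds):
        round_idx += 1
        new_edges_before = len(net.edges)
        next_frontier: list[str] = []
        for key in frontier:
            reactant = net.nodes[key].graph
            for product, event in enumerate_products(reactant, chem_config):
                pkey = event.product_key
                if pkey == key:
                    continue  # degenerate rearrangement
                if pkey in rejected:
                    continue
                if pkey not in net.nodes:
                    if not passes_filter(product, config.stability, plugin):
                        rejected.add(pkey)
                        continue
                    next_frontier.extend(
                        _insert_with_resonance(net, product, round_idx, event))
                else:
                    net.dedup_insert(net.nodes[pkey], event)
        net.rounds_run = round_idx
        logger.info(
            "round %d: +%d nodes, +%d edges (cumulative %d nodes, %d edges)",
            round_idx, len(next_frontier), len(net.edges) - new_edges_before,
            len(net.nodes), len(net.edges))
        frontier = next_frontier
    return net


def monoterpene_seed() -> CationGraph:
    """The linear allylic C10H17+ substrate cation (constitutional form)."""
    return parse_smiles(LINEAR_MONOTERPENE_SMILES)


def linear_alkane_cation(n_carbons: int) -> CationGraph:
    """The 1-alkyl cation of the linear CnH(2n+1)+ series."""
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    return parse_smiles("[CH2+]" + "C" * (n_carbons - 1)
                        if n_carbons > 1 else "[CH3+]")


def alkane_cation_oracle(n_carbons: int) -> set[str]:
    """Brute-force generation of every constitutional CnH(2n+1)+ isomer.

    All carbon trees on *n* vertices (maximum degree 4) are crossed with all
    charge placements on carbons that bear at least one hydrogen in the
    neutral alkane (degree <= 3); the results are deduplicated by canonical
    key.  Independent of the reaction operators by construction.
    """
    if not 2 <= n_carbons <= 10:
        raise ValueError("alkane oracle supports 2..10 carbons")
    keys: set[str] = set()
    if n_carbons == 2:
        trees = [nx.path_graph(2)]
    else:
        trees = list(nx.nonisomorphic_trees(n_carbons))
    for tree in trees:
        if any(d > 4 for _, d in tree.degree()):
            continue
        index = {v: i for i, v in enumerate(tree.nodes)}
        cbonds = [(index[u], index[v]) for u, v in tree.edges]
        degree = [0] * n_carbons
        for u, v in cbonds:
            degree[u] += 1
            degree[v] += 1
        for site in range(n_carbons):
            if degree[site] > 3:
                continue  # no hydrogen to ionize away
            elements = ["C"] * n_carbons
            bonds = [(u, v, 1) for u, v in cbonds]
            h = n_carbons
            for atom in range(n_carbons):
                want = 3 - degree[atom] if atom == site else 4 - degree[atom]
                for _ in range(want):
                    elements.append("H")
                    bonds.append((atom, h, 1))
                    h += 1
            keys.add(CationGraph(elements, bonds, charge_site=site).key())
    return keys


class AlkaneValidation(NamedTuple):
    found: int
    oracle: int
    match: bool


def validate_alkanes(n_carbons: int) -> AlkaneValidation:
    """Compare shift-only enumeration against the brute-force isomer oracle.

    Enumeration starts from the linear 1-alkyl cation with the alkyl-,
    hydride- and methyl-shift operators, unlimited shift range, permissive
    filter, and runs to fixpoint.  ``match`` is set equality of canonical
    keys (not just equal counts).
    """
    if not 2 <= n_carbons <= 10:
        raise ValueError("validate_alkanes supports 2..10 carbons")
    config = EnumConfig(
        enabled_types=frozenset({ReactionType.ALKYL_SHIFT,
                                 ReactionType.HYDRIDE_SHIFT,
                                 ReactionType.METHYL_SHIFT}),
        max_rounds=None,
        stability=StabilityConfig(mode="permissive"),
        shift_range_bonds=None,
    )
    net = run_enumeration([linear_alkane_cation(n_carbons)], config)
    found = set(net.nodes)
    oracle = alkane_cation_oracle(n_carbons)
    return AlkaneValidation(len(found), len(oracle), found == oracle)


def is_closed(net: ReactionNetwork,
              plugin: Optional[EnergyPlugin] = None) -> bool:
    """Closure check: every enabled-operator product of every node either
    fails the stability filter or is already a node (with its edge
    recorded).  Only meaningful for fixpoint (unbounded) runs."""
    chem_config = replace(
        net.config, enabled_types=net.config.enabled_types & CHEMICAL_TYPES)
    for key, rec in net.nodes.items():
        for product, event in enumerate_products(rec.graph, chem_config):
            if event.product_key == key:
                continue
            if event.product_key in net.nodes:
                continue
            if passes_filter(product, net.config.stability, plugin):
                return False
    return True
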