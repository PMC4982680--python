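"""Stability filtering of candidate carbocations.

Three modes are supported:

``permissive``
    accept everything (used for exhaustive constitutional enumeration and
    for the alkane validation runs, where energies play no role);
``heuristic``
    reject cations whose substitution class is in a configurable reject set
    (default: primary), with allylic cations always exempt — the linear
    allylic substrate cation itself is formally primary and must survive;
``energy_plugin``
    accept iff the plugged-in energy of the species relative to a reference
    cation is at or below a cutoff (boundary inclusive, so the reference
    passes at cutoff 0.0).

The energy engine itself is a contract, not an implementation: any object
with a deterministic ``evaluate(graph) -> kcal/mol`` method qualifies.  A
table-lookup stub and a JSON-over-subprocess adapter are bundled.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol, runtime_checkable

from .molgraph import CationClass, CationGraph, classify_cation

__all__ = [
    "StabilityConfig",
    "EnergyPlugin",
    "TableEnergyPlugin",
    "ExecutableEnergyPlugin",
    "passes_filter",
    "secondary_fraction",
]


@runtime_checkable
class EnergyPlugin(Protocol):
    """Contract for pluggable energy engines.

    ``evaluate`` must be deterministic for a fixed input and return an
    energy in kcal/mol.  Geometry-based engines should require ``coords``
    on the graph and raise otherwise.
    """

    def evaluate(self, g: CationGraph) -> float:  # pragma: no cover - protocol
        ...


class TableEnergyPlugin:
    """Deterministic stub engine: energies looked up by canonical key.

    Intended for tests and worked examples; unknown species fall back to
    ``default`` (kcal/mol).
    """

    def __init__(self, table: dict[str, float], default: float = 0.0) -> None:
        self.table = dict(table)
        self.default = default

    def evaluate(self, g: CationGraph) -> float:
        return self.table.get(g.key(), self.default)


class ExecutableEnergyPlugin:
    """Adapter that shells out to an external energy engine.

    The executable receives one JSON object on stdin — ``{"smiles": ...,
    "coords": [[x, y, z], ...] | null}`` — and must print one JSON object
    ``{"energy_kcal": <float>}``.
    """

    def __init__(self, executable: str) -> None:
        self.executable = executable

    def evaluate(self, g: CationGraph) -> float:
        payload = {
            "smiles": g.key(),
            "coords": None if g.coords is None else g.coords.tolist(),
        }
        proc = subprocess.run(
            [self.executable], input=json.dumps(payload),
            capture_output=True, text=True, check=True,
        )
        return float(json.loads(proc.stdout)["energy_kcal"])


@dataclass
class StabilityConfig:
    """Parameters of the stability filter.

    ``cutoff_kcal`` is only meaningful in ``energy_plugin`` mode and is the
    allowed energy excess over ``reference`` (the linear substrate cation by
    convention).  ``reject_classes`` drives ``heuristic`` mode and may never
    contain ``TERTIARY``.
    """

    mode: str = "permissive"  # permissive | heuristic | energy_plugin
    cutoff_kcal: float = 0.0
    reference: Optional[CationGraph] = None
    reject_classes: frozenset = field(
        default_factory=lambda: frozenset({CationClass.PRIMARY}))

    def __post_init__(self) -> None:
        if self.mode not in ("permissive", "heuristic", "energy_plugin"):
            raise ValueError(f"unknown stability mode {self.mode!r}")
        if CationClass.TERTIARY in self.reject_classes:
            raise ValueError("tertiary cations may not be rejected")


def passes_filter(
    g: CationGraph,
    cfg: StabilityConfig,
    plugin: Optional[EnergyPlugin] = None,
) -> bool:
    """Whether candidate *g* survives the configured stability filter."""
    if cfg.mode == "permissive":
        return True
    if cfg.mode == "heuristic":
        cls = classify_cation(g)
        if cls.is_allylic:
            return True
        return cls not in cfg.reject_classes
    # energy_plugin
    if plugin is None:
        raise ValueError("energy_plugin mode requires an energy plugin")
    if cfg.reference is None:
        raise ValueError("energy_plugin mode requires a reference cation")
    return plugin.evaluate(g) - plugin.evaluate(cfg.reference) <= cfg.cutoff_kcal


def secondary_fraction(nodes: Iterable[CationGraph]) -> float:
    """Fraction of cations whose charge site is secondary (allylic or not)."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("secondary_fraction of an empty node set")
    secondary = sum(
        1 for g in nodes
        if classify_cation(g).base is CationClass.SECONDARY
    )
    return secondary / len(nodes)
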