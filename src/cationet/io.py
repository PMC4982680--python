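"""Serialization: node/edge TSV tables, GraphML export, run manifests,
and programmatic SMILES fixture generation.

Tables are tab-separated UTF-8 with a header row; the network graph goes to
GraphML via NetworkX; manifests and configs are JSON.  All fixtures are
generated, never shipped.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import time
from pathlib import Path
from typing import Optional

import networkx as nx

from . import __version__
from .enumerate import (CationRecord, EnumConfig, ReactionNetwork,
                        LINEAR_MONOTERPENE_SMILES)
from .molgraph import CationGraph, classify_cation, formula, parse_smiles
from .reactions import ReactionEvent, ReactionType

__all__ = [
    "write_nodes_tsv", "read_nodes_tsv", "write_edges_tsv", "read_edges_tsv",
    "write_graphml", "read_graphml", "write_manifest", "write_network",
    "read_network", "fixture_generator", "FIXTURE_KINDS",
]

NODE_COLUMNS = ["key", "formula", "class", "round_found", "energy"]
EDGE_COLUMNS = ["reactant_key", "product_key", "rtype", "atoms"]


def _formula_str(g: CationGraph) -> str:
    nc, nh, q = formula(g)
    return f"C{nc}H{nh}{'+' if q else ''}"


def write_nodes_tsv(net: ReactionNetwork, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(NODE_COLUMNS)
        for rec in net.nodes.values():
            w.writerow([rec.key, _formula_str(rec.graph),
                        rec.cation_class.value, rec.round_found,
                        "" if rec.energy_kcal is None else rec.energy_kcal])


def read_nodes_tsv(path) -> list[CationRecord]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            g = parse_smiles(row["key"])
            out.append(CationRecord(
                key=row["key"], graph=g, round_found=int(row["round_found"]),
                cation_class=classify_cation(g),
                energy_kcal=float(row["energy"]) if row["energy"] else None))
    return out


def write_edges_tsv(net: ReactionNetwork, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(EDGE_COLUMNS)
        for ev in net.edges:
            w.writerow([ev.reactant_key, ev.product_key, ev.rtype.value,
                        ",".join(map(str, ev.atoms))])


def read_edges_tsv(path) -> list[ReactionEvent]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            atoms = tuple(int(x) for x in row["atoms"].split(",")) \
                if row["atoms"] else ()
            out.append(ReactionEvent(row["reactant_key"], row["product_key"],
                                     ReactionType(row["rtype"]), atoms))
    return out


def write_graphml(net: ReactionNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)


def read_graphml(path) -> nx.MultiDiGraph:
    return nx.read_graphml(path, force_multigraph=True)


def _config_dict(config: EnumConfig) -> dict:
    d = dataclasses.asdict(config)
    d["enabled_types"] = sorted(t.value for t in config.enabled_types)
    d["stability"] = {
        "mode": config.stability.mode,
        "cutoff_kcal": config.stability.cutoff_kcal,
        "reference": (None if config.stability.reference is None
                      else config.stability.reference.key()),
        "reject_classes": sorted(c.value
                                 for c in config.stability.reject_classes),
    }
    d.pop("geometric_gate", None)
    return d


def write_manifest(net: ReactionNetwork, path,
                   wall_clock_s: Optional[float] = None,
                   extra: Optional[dict] = None) -> dict:
    """Write ``manifest.json``: config echo, seeds, per-round counters and
    totals.  Totals are recomputed from the in-memory network, so they match
    the serialized files exactly."""
    manifest = {
        "software": "cationet",
        "version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _config_dict(net.config),
        "seeds": list(net.seeds),
        "rounds_run": net.rounds_run,
        "per_round_new_nodes": net.per_round_counts(),
        "totals": {"nodes": len(net.nodes), "edges": len(net.edges)},
    }
    if wall_clock_s is not None:
        manifest["wall_clock_s"] = round(wall_clock_s, 2)
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest


def write_network(net: ReactionNetwork, outdir,
                  wall_clock_s: Optional[float] = None) -> Path:
    """Write nodes.tsv, edges.tsv, network.graphml and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_nodes_tsv(net, outdir / "nodes.tsv")
    write_edges_tsv(net, outdir / "edges.tsv")
    write_graphml(net, outdir / "network.graphml")
    write_manifest(net, outdir / "manifest.json", wall_clock_s=wall_clock_s)
    return outdir


def read_network(outdir, config: Optional[EnumConfig] = None
                 ) -> ReactionNetwork:
    """Rebuild a ReactionNetwork from a serialized output directory."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    net = ReactionNetwork(config or EnumConfig(), seeds=manifest["seeds"])
    for rec in read_nodes_tsv(outdir / "nodes.tsv"):
        net.dedup_insert(rec)
    for ev in read_edges_tsv(outdir / "edges.tsv"):
        net.dedup_insert(net.nodes[ev.reactant_key], ev)
    net.rounds_run = manifest["rounds_run"]
    return net


FIXTURE_KINDS = ("alkanes", "textbook_cations", "monoterpene_seeds")

_TEXTBOOK = {
    "allyl": "[CH2+]C=C",
    "homoallyl": "C=CC[CH2+]",
    "tert_butyl": "C[C+](C)C",
    "neopentyl": "CC(C)(C)[CH2+]",
    "cyclopropylcarbinyl": "[CH2+]C1CC1",
    "cyclobutyl": "[CH+]1CCC1",
    "2_butyl": "C[CH+]CC",
}

_MONOTERPENE = {
    "linear_allylic": LINEAR_MONOTERPENE_SMILES,   # geranyl/neryl type
    "linalyl_type": "C=C[C+](C)CCC=C(C)C",
    "alpha_terpinyl_type": "CC1=CCC([C+](C)C)CC1",
}


def fixture_generator(kind: str, outdir) -> Path:
    """Write one SMILES fixture file (one species per line, tab-separated
    name column) and return its path.  Kinds: linear alkane cations C4-C10,
    classic textbook rearrangement substrates, or monoterpene seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "alkanes":
        lines = [("[CH2+]" + "C" * (n - 1), f"linear_C{n}_cation")
                 for n in range(4, 11)]
    elif kind == "textbook_cations":
        lines = [(smi, name) for name, smi in _TEXTBOOK.items()]
    elif kind == "monoterpene_seeds":
        lines = [(smi, name) for name, smi in _MONOTERPENE.items()]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    path = outdir / f"{kind}.smi"
    with open(path, "w", encoding="utf-8") as fh:
        for smi, name in lines:
            fh.write(f"{smi}\t{name}\n")
    return path
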