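"""Pattern-transition networks aggregated over a patient group.

Nodes are treatment patterns, weighted by the number of distinct patients
ever observed in the pattern; directed edges are pattern-to-pattern
switches, weighted by the number of distinct patients who ever make the
switch (a patient making the same switch twice counts once). Edges are
displayed only when they represent at least a configurable fraction
(default 2%) of the group; nodes are never thresholded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .regimen_patterns import RegimenPattern


@dataclass
class TransitionNetwork:
    group: str
    n_group: int
    nodes: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    threshold: float = 0.0  # edge fraction already applied

    def edge_fraction(self, edge: tuple[str, str]) -> float:
        return self.edges[edge] / self.n_group if self.n_group else 0.0


def aggregate_network(
    pattern_sequences: Mapping[str, Sequence[RegimenPattern]] | Iterable[Sequence[RegimenPattern]],
    group: str = "all",
    *,
    count_events: bool = False,
) -> TransitionNetwork:
    """Build the unfiltered network from per-patient pattern sequences.

    ``pattern_sequences`` maps patient id to that patient's ordered
    patterns (or is simply an iterable of sequences). ``count_events``
    switches edge weights from distinct patients to transition events.
    """
    if isinstance(pattern_sequences, Mapping):
        sequences = list(pattern_sequences.values())
    else:
        sequences = [list(s) for s in pattern_sequences]

    nodes: dict[str, int] = {}
    edges: dict[tuple[str, str], int] = {}
    for seq in sequences:
        names = [p.name for p in seq]
        for name in set(names):
            nodes[name] = nodes.get(name, 0) + 1
        steps = [(a, b) for a, b in zip(names, names[1:]) if a != b]
        if not count_events:
            steps = list(dict.fromkeys(steps))  # distinct per patient, stable order
        for step in steps:
            edges[step] = edges.get(step, 0) + 1
    return TransitionNetwork(group=group, n_group=len(sequences), nodes=nodes, edges=edges)


def filter_edges(network: TransitionNetwork, edge_fraction_threshold: float) -> TransitionNetwork:
    """Keep edges representing at least the threshold fraction of the group.

    The comparison is inclusive (>=). Nodes are retained even when every
    incident edge is removed. Threshold 0 is the identity.
    """
    if network.n_group <= 0:
        raise ValueError("cannot threshold edges of an empty group")
    kept = {
        edge: count
        for edge, count in network.edges.items()
        if count / network.n_group >= edge_fraction_threshold
    }
    return replace(network, edges=kept, threshold=edge_fraction_threshold)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def to_networkx(network: TransitionNetwork) -> nx.DiGraph:
    g = nx.DiGraph(group=network.group, n_group=network.n_group, threshold=network.threshold)
    for name, count in network.nodes.items():
        g.add_node(name, n_patients=count)
    for (src, dst), count in network.edges.items():
        g.add_edge(src, dst, n_patients=count)
    return g


def to_json_dict(network: TransitionNetwork) -> dict:
    """Documented JSON schema: group metadata, node list, edge list."""
    return {
        "group": network.group,
        "n_group": network.n_group,
        "threshold": network.threshold,
        "nodes": [
            {"pattern": name, "n_patients": count}
            for name, count in sorted(network.nodes.items())
        ],
        "edges": [
            {"from": src, "to": dst, "n_patients": count}
            for (src, dst), count in sorted(network.edges.items())
        ],
    }


def network_from_json(payload: dict | str) -> TransitionNetwork:
    data = json.loads(payload) if isinstance(payload, str) else payload
    return TransitionNetwork(
        group=data["group"],
        n_group=int(data["n_group"]),
        nodes={n["pattern"]: int(n["n_patients"]) for n in data["nodes"]},
        edges={(e["from"], e["to"]): int(e["n_patients"]) for e in data["edges"]},
        threshold=float(data.get("threshold", 0.0)),
    )


def _to_dot(network: TransitionNetwork) -> str:
    def q(s: str) -> str:
        return '"' + s.replace('"', r"\"") + '"'

    lines = [f"digraph {q(network.group)} {{"]
    for name, count in sorted(network.nodes.items()):
        lines.append(f"  {q(name)} [n_patients={count}];")
    for (src, dst), count in sorted(network.edges.items()):
        lines.append(f"  {q(src)} -> {q(dst)} [n_patients={count}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(network: TransitionNetwork, path: str | Path, format: Optional[str] = None) -> Path:
    """Write the network as ``graphml``, ``dot`` or ``json`` (format inferred
    from the file suffix when not given)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        nx.write_graphml(to_networkx(network), path)
    elif fmt == "dot":
        path.write_text(_to_dot(network))
    elif fmt == "json":
        path.write_text(json.dumps(to_json_dict(network), indent=2))
    else:
        raise ValueError(f"unknown network export format {fmt!r}")
    return path
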