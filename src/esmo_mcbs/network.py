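"""Relative-benefit comparator network.

Graded trials in one treatment setting form a directed graph: an edge runs
from the (normalized) comparator arm to the experimental arm and carries
the final MCBS grade as its weight — a larger grade meaning more relative
benefit of the intervention over that particular comparator.  The graph
makes explicit that grades earned against different comparators are not
directly exchangeable; no indirect-comparison estimation is performed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx

from .records import Form, GradedResult, Setting, TrialRecord

_SYNONYMS_RESOURCE = "arm_synonyms.json"


def _load_synonyms() -> dict[str, str]:
    with resources.files("esmo_mcbs.data").joinpath(_SYNONYMS_RESOURCE).open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


_SYNONYMS: Optional[dict[str, str]] = None


def normalize_label(label: str, synonyms: Optional[Mapping[str, str]] = None) -> str:
    """Canonicalize an arm label so spelling variants merge to one node.

    Case-folds, collapses whitespace, rewrites ``plus``/``+`` and ``with``
    to ``/``, then applies the curated synonym table (shipped as data).
    """
    global _SYNONYMS
    if synonyms is None:
        if _SYNONYMS is None:
            _SYNONYMS = _load_synonyms()
        synonyms = _SYNONYMS
    s = label.strip().casefold()
    s = re.sub(r"\s*(?:\bplus\b|\+|\bwith\b)\s*", "/", s)
    s = re.sub(r"\s+", " ", s)
    s = re.sub(r"\s*/\s*", "/", s)
    return synonyms.get(s, s)


@dataclass(frozen=True)
class BenefitEdge:
    """One graded comparison: comparator arm -> experimental arm."""

    source: str
    target: str
    grade: int
    trial_id: str
    setting: Setting


@dataclass
class BenefitNetwork:
    """Directed comparator network for one treatment setting."""

    setting: Setting
    nodes: set[str] = field(default_factory=set)
    edges: list[BenefitEdge] = field(default_factory=list)

    def to_networkx(self) -> "nx.MultiDiGraph":
        g = nx.MultiDiGraph(setting=self.setting.value)
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.source, e.target, key=e.trial_id, grade=e.grade, trial_id=e.trial_id)
        return g


def build_network(
    records: Sequence[TrialRecord],
    results: Union[Mapping[str, GradedResult], Sequence[GradedResult]],
    setting: Setting,
) -> BenefitNetwork:
    """One edge per *graded* trial of ``setting``; nodes deduplicated by label.

    Every record in the setting must have a result; a missing one raises
    KeyError naming the trial.  NOT_GRADED results contribute no edge.
    """
    if not isinstance(results, Mapping):
        results = {r.trial_id: r for r in results}
    net = BenefitNetwork(setting=Setting(setting))
    for record in records:
        if record.setting is not net.setting:
            continue
        if record.trial_id not in results:
            raise KeyError(f"no graded result for trial {record.trial_id!r}")
        result = results[record.trial_id]
        if result.final is None:
            continue
        source = normalize_label(record.comparator_label)
        target = normalize_label(record.experimental_label)
        if source == target:
            raise ValueError(
                f"{record.trial_id}: experimental and comparator arms normalize "
                f"to the same label {source!r}"
            )
        triple = (source, target, record.trial_id)
        if any((e.source, e.target, e.trial_id) == triple for e in net.edges):
            raise ValueError(f"duplicate edge {triple}")
        net.nodes.update((source, target))
        net.edges.append(
            BenefitEdge(
                source=source,
                target=target,
                grade=result.final,
                trial_id=record.trial_id,
                setting=net.setting,
            )
        )
    return net


def _quote(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def export_network(network: BenefitNetwork, path: Union[str, Path], format: str = "json") -> None:
    """Write the network as DOT, GraphML or JSON (grades kept as attributes)."""
    path = Path(path)
    if format == "dot":
        lines = ["digraph benefit {"]
        lines += [f"  {_quote(n)};" for n in sorted(network.nodes)]
        lines += [
            f"  {_quote(e.source)} -> {_quote(e.target)} "
            f'[label="{e.grade}", grade={e.grade}, trial_id={_quote(e.trial_id)}];'
            for e in network.edges
        ]
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif format == "json":
        payload = {
            "setting": network.setting.value,
            "nodes": sorted(network.nodes),
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "grade": e.grade,
                    "trial_id": e.trial_id,
                }
                for e in network.edges
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}; admissible: dot, graphml, json")


def read_network_json(path: Union[str, Path]) -> BenefitNetwork:
    """Inverse of the JSON export."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    setting = Setting(data["setting"])
    return BenefitNetwork(
        setting=setting,
        nodes=set(data["nodes"]),
        edges=[
            BenefitEdge(
                source=e["source"],
                target=e["target"],
                grade=e["grade"],
                trial_id=e["trial_id"],
                setting=setting,
            )
            for e in data["edges"]
        ],
    )
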