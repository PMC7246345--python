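"""Thresholded similarity networks, annotation mapping, concordance.

Nodes are entities (structures, reactions or substrates); an edge is drawn
between two nodes iff their pairwise similarity score is greater than or
equal to the chosen threshold (inclusive, per the "at least" convention).
Ingested scores are used on their native scale (e.g. TM-score in (0,1]) with
no renormalization.  Clusters are connected components at the threshold --
the deterministic proxy for visually tight groups.  The concordance layer
quantifies agreement between an evolutionary labeling and a chemistry-side
clustering: adjusted Rand index, per-label edge homophily, and per-cluster
purity.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd
from sklearn.metrics import adjusted_rand_score


@dataclass
class SimilarityMatrix:
    """Sparse symmetric pairwise scores over an ordered entity list."""

    entity_ids: list[str]
    scores: dict[frozenset, float] = field(default_factory=dict)
    metric_name: str = ""

    def get(self, id1: str, id2: str) -> Optional[float]:
        return self.scores.get(frozenset((id1, id2)))

    def set(self, id1: str, id2: str, score: float) -> None:
        if id1 == id2:
            return  # the diagonal is ignored
        key = frozenset((id1, id2))
        existing = self.scores.get(key)
        if existing is not None and existing != score:
            raise ValueError(
                f"conflicting duplicate scores for pair ({id1}, {id2}): "
                f"{existing} vs {score}"
            )
        self.scores[key] = float(score)
        for i in (id1, id2):
            if i not in self._seen:
                self._seen.add(i)
                self.entity_ids.append(i)

    def __post_init__(self) -> None:
        self._seen = set(self.entity_ids)

    def pairs(self) -> list[tuple[str, str, float]]:
        out = []
        for key, s in self.scores.items():
            a, b = sorted(key)
            out.append((a, b, s))
        return sorted(out)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pairs(), columns=["id1", "id2", "score"]).to_csv(
            path, sep="\t", index=False
        )


def load_score_table(source, metric_name: str = "") -> SimilarityMatrix:
    """Load a three-column (id1, id2, score) TSV into a similarity matrix.

    Duplicate unordered pairs with conflicting scores are an error; the
    score column must be numeric.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError("score table needs three columns: id1, id2, score")
    df = df.rename(columns=dict(zip(df.columns[:3], ["id1", "id2", "score"])))
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = df.loc[scores.isna()].head(3).to_dict("records")
        raise ValueError(f"non-numeric scores in rows: {bad}")
    matrix = SimilarityMatrix(entity_ids=[], metric_name=metric_name)
    for id1, id2, score in zip(df["id1"], df["id2"], scores):
        if not str(id1) or not str(id2):
            raise ValueError("empty entity id in score table")
        matrix.set(str(id1), str(id2), float(score))
    return matrix


class SimilarityNetwork:
    """An undirected thresholded network over a similarity matrix.

    Wraps a :class:`networkx.Graph`; nodes with no passing edge are kept as
    isolated nodes (they correspond to entities drawn disconnected).
    """

    def __init__(self, graph: nx.Graph, threshold: float, metric_name: str = ""):
        self.graph = graph
        self.threshold = threshold
        self.metric_name = metric_name

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def __repr__(self) -> str:
        return (
            f"<SimilarityNetwork {self.metric_name or 'scores'} "
            f"t={self.threshold} |V|={self.graph.number_of_nodes()} "
            f"|E|={self.graph.number_of_edges()}>"
        )


def build_network(
    matrix: SimilarityMatrix, threshold: float, node_shape: str = ""
) -> SimilarityNetwork:
    """Draw an edge for every pair scoring >= threshold (inclusive)."""
    g = nx.Graph()
    for eid in matrix.entity_ids:
        g.add_node(eid)
    for a, b, score in matrix.pairs():
        if score >= threshold:
            g.add_edge(a, b, score=score)
    if node_shape:
        nx.set_node_attributes(g, node_shape, "shape")
    return SimilarityNetwork(g, threshold=threshold, metric_name=matrix.metric_name)


def connected_components(network: SimilarityNetwork) -> list[list[str]]:
    """Components as sorted member lists, ordered by smallest member id."""
    comps = [sorted(c) for c in nx.connected_components(network.graph)]
    return sorted(comps, key=lambda c: c[0])


def components_as_labels(network: SimilarityNetwork) -> dict[str, int]:
    return {
        node: i
        for i, comp in enumerate(connected_components(network))
        for node in comp
    }


def annotate_network(
    network: SimilarityNetwork, labels: Union[pd.DataFrame, Mapping[str, Mapping]]
) -> list[str]:
    """Attach label attributes to nodes; returns warning messages.

    ``labels`` is either an annotation DataFrame with an ``entity_id``
    column (remaining columns become attributes) or a mapping node ->
    attribute dict.  A node covered by several rows (a reaction shared
    between subgroups) accumulates label lists; uncovered nodes are flagged
    ``unlabeled``; label rows for unknown nodes are reported back.
    """
    if isinstance(labels, pd.DataFrame):
        records = labels.to_dict("records")
        items = [(str(r.pop("entity_id")), r) for r in records]
    else:
        items = [(str(k), dict(v)) for k, v in labels.items()]
    messages: list[str] = []
    unknown = sorted({nid for nid, _ in items if nid not in network.graph})
    if unknown:
        messages.append(f"label table covers unknown node ids: {unknown}")
    for nid, attrs in items:
        if nid not in network.graph:
            continue
        node = network.graph.nodes[nid]
        for key, value in attrs.items():
            if key in node and node[key] != value:
                current = node[key]
                if not isinstance(current, list):
                    current = [current]
                if value not in current:
                    current.append(value)
                node[key] = current
            else:
                node[key] = value
    for nid, data in network.graph.nodes(data=True):
        data["unlabeled"] = not any(k not in ("shape", "unlabeled") for k in data)
    n_flagged = sum(1 for _, d in network.graph.nodes(data=True) if d["unlabeled"])
    if n_flagged:
        messages.append(f"{n_flagged} nodes have no labels")
    for m in messages:
        warnings.warn(m, stacklevel=2)
    return messages


# --------------------------------------------------------------------------
# Concordance between two classifications
# --------------------------------------------------------------------------


def _as_label_map(labeling) -> dict[str, object]:
    if isinstance(labeling, SimilarityNetwork):
        return components_as_labels(labeling)
    if isinstance(labeling, Mapping):
        return dict(labeling)
    # a partition: iterable of member lists
    return {m: i for i, part in enumerate(labeling) for m in part}


def edge_homophily(
    network: SimilarityNetwork, labels: Mapping[str, object]
) -> dict[object, Optional[float]]:
    """Per-label fraction of touching edges whose endpoints share the label.

    For label L: |edges with both endpoints labeled L| / |edges with at
    least one endpoint labeled L|.  A label with no touching edges has no
    within-set pairs to measure and maps to None (undefined-flagged).
    Multi-label nodes (label lists) count for each of their labels.
    """
    node_labels = {
        n: set(v) if isinstance(v := labels.get(n), (list, set, tuple)) else {v}
        for n in network.graph.nodes
        if labels.get(n) is not None
    }
    touching: dict[object, int] = {}
    within: dict[object, int] = {}
    for u, v in network.graph.edges:
        lu = node_labels.get(u, set())
        lv = node_labels.get(v, set())
        for lab in lu | lv:
            touching[lab] = touching.get(lab, 0) + 1
            if lab in lu and lab in lv:
                within[lab] = within.get(lab, 0) + 1
    all_labels = {l for labs in node_labels.values() for l in labs}
    return {
        lab: (within.get(lab, 0) / touching[lab]) if touching.get(lab) else None
        for lab in sorted(all_labels, key=str)
    }


def cluster_purity(
    clusters: Mapping[str, object],
    labels: Mapping[str, object],
    fractional_multilabel: bool = False,
) -> float:
    """Fraction of entities whose label matches their cluster's majority label.

    Multi-label entities count as correct if any of their labels matches the
    cluster majority (default) or contribute fractionally when
    ``fractional_multilabel`` is set.
    """
    common = sorted(set(clusters) & set(labels))
    if not common:
        raise ValueError("clusterings share no entities")
    by_cluster: dict[object, list[str]] = {}
    for e in common:
        by_cluster.setdefault(clusters[e], []).append(e)
    total = 0.0
    for members in by_cluster.values():
        votes: dict[object, float] = {}
        for e in members:
            labs = labels[e]
            labs = list(labs) if isinstance(labs, (list, set, tuple)) else [labs]
            for l in labs:
                votes[l] = votes.get(l, 0) + 1 / len(labs)
        majority = max(sorted(votes, key=str), key=lambda l: votes[l])
        for e in members:
            labs = labels[e]
            labs = list(labs) if isinstance(labs, (list, set, tuple)) else [labs]
            if fractional_multilabel:
                total += (majority in labs) / len(labs)
            else:
                total += majority in labs
    return total / len(common)


def _flatten_for_ari(label_map: Mapping[str, object], entities: Sequence[str]):
    out = []
    for e in entities:
        v = label_map[e]
        if isinstance(v, (list, set, tuple)):
            v = sorted(map(str, v))[0]  # ARI needs a hard partition
        out.append(str(v))
    return out


@dataclass
class ConcordanceReport:
    n_common: int
    adjusted_rand_index: float
    purity_1_vs_2: float
    purity_2_vs_1: float
    homophily_1: Optional[dict] = None
    homophily_2: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "adjusted_rand_index": self.adjusted_rand_index,
            "purity_1_vs_2": self.purity_1_vs_2,
            "purity_2_vs_1": self.purity_2_vs_1,
            "homophily_1": self.homophily_1,
            "homophily_2": self.homophily_2,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        lines = [
            f"entities compared : {self.n_common}",
            f"adjusted Rand idx : {self.adjusted_rand_index:.4f}",
            f"purity (1 under 2): {self.purity_1_vs_2:.4f}",
            f"purity (2 under 1): {self.purity_2_vs_1:.4f}",
        ]
        for name, hom in (("net1", self.homophily_1), ("net2", self.homophily_2)):
            if hom is not None:
                shown = ", ".join(
                    f"{k}={v:.3f}" if v is not None else f"{k}=undef"
                    for k, v in hom.items()
                )
                lines.append(f"edge homophily {name}: {shown}")
        return "\n".join(lines)


def concordance(
    labeling1,
    labeling2,
    network1: Optional[SimilarityNetwork] = None,
    network2: Optional[SimilarityNetwork] = None,
) -> ConcordanceReport:
    """Quantify agreement between two classifications of one entity set.

    ``labeling1``/``labeling2`` may each be a node->label mapping, a
    partition (iterable of member lists) or a network (its connected
    components are used).  The intersection of the two entity sets is
    compared; an empty intersection is an error.  When networks are
    supplied, per-label edge homophily of the *other* labeling on each
    network is included, which is how a subgroup's cohesion can be compared
    between a structure network and a reaction network.
    """
    map1 = _as_label_map(labeling1)
    map2 = _as_label_map(labeling2)
    common = sorted(set(map1) & set(map2))
    if not common:
        raise ValueError("the two labelings share no entities")
    ari = adjusted_rand_score(
        _flatten_for_ari(map1, common), _flatten_for_ari(map2, common)
    )
    report = ConcordanceReport(
        n_common=len(common),
        adjusted_rand_index=float(ari),
        purity_1_vs_2=cluster_purity(map2, map1),
        purity_2_vs_1=cluster_purity(map1, map2),
        homophily_1=edge_homophily(network1, map2) if network1 else None,
        homophily_2=edge_homophily(network2, map1) if network2 else None,
    )
    return report


# --------------------------------------------------------------------------
# Export / import
# --------------------------------------------------------------------------

_FORMATS = ("edge_tsv", "node_tsv", "sif", "xgmml_minimal")


def export_network(network: SimilarityNetwork, format: str, path) -> Path:
    """Write the network in one of: edge_tsv, node_tsv, sif, xgmml_minimal.

    edge_tsv columns: id1, id2, score.  node_tsv: node followed by every
    node attribute (lists joined with ``;``).  SIF lines: ``idA relation
    idB`` with the metric name as the relation; isolated nodes appear as
    bare ids.  XGMML is the minimal graph/node/edge subset Cytoscape reads.
    """
    path = Path(path)
    if format == "edge_tsv":
        rows = [
            {"id1": u, "id2": v, "score": d.get("score", "")}
            for u, v, d in sorted(network.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["id1", "id2", "score"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "node_tsv":
        keys = sorted({k for _, d in network.graph.nodes(data=True) for k in d})
        rows = []
        for n, d in sorted(network.graph.nodes(data=True)):
            row = {"node": n}
            for k in keys:
                v = d.get(k, "")
                row[k] = ";".join(map(str, v)) if isinstance(v, list) else v
            rows.append(row)
        pd.DataFrame(rows, columns=["node"] + keys).to_csv(path, sep="\t", index=False)
    elif format == "sif":
        relation = network.metric_name or "sim"
        lines = []
        grouped: dict[str, list[str]] = {}
        for u, v in sorted(network.graph.edges):
            grouped.setdefault(u, []).append(v)
        isolated = [n for n in sorted(network.graph.nodes) if network.graph.degree(n) == 0]
        for u, targets in sorted(grouped.items()):
            lines.append("\t".join([u, relation] + targets))
        lines.extend(isolated)
        path.write_text("\n".join(lines) + "\n")
    elif format == "xgmml_minimal":
        root = ET.Element(
            "graph",
            label=network.metric_name or "similarity network",
            directed="0",
        )
        ids = {n: str(i) for i, n in enumerate(sorted(network.graph.nodes))}
        for n in sorted(network.graph.nodes):
            node = ET.SubElement(root, "node", id=ids[n], label=str(n))
            for k, v in network.graph.nodes[n].items():
                vv = ";".join(map(str, v)) if isinstance(v, list) else str(v)
                ET.SubElement(node, "att", name=str(k), value=vv, type="string")
        for u, v, d in sorted(network.graph.edges(data=True)):
            edge = ET.SubElement(root, "edge", source=ids[u], target=ids[v])
            if "score" in d:
                ET.SubElement(
                    edge, "att", name="score", value=str(d["score"]), type="real"
                )
        ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    else:
        raise ValueError(f"unknown export format {format!r}; choose from {_FORMATS}")
    return path


def import_edge_tsv(path, threshold: float = 0.0, metric_name: str = "") -> SimilarityNetwork:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    g = nx.Graph()
    for _, row in df.iterrows():
        attrs = {"score": float(row["score"])} if row.get("score", "") != "" else {}
        g.add_edge(str(row["id1"]), str(row["id2"]), **attrs)
    return SimilarityNetwork(g, threshold=threshold, metric_name=metric_name)


def import_sif(path, threshold: float = 0.0) -> SimilarityNetwork:
    g = nx.Graph()
    metric = ""
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t") if "\t" in line else line.split()
        if not parts:
            continue
        if len(parts) == 1:
            g.add_node(parts[0])
        else:
            source, relation, *targets = parts
            metric = metric or relation
            for t in targets:
                g.add_edge(source, t)
    return SimilarityNetwork(g, threshold=threshold, metric_name=metric)


def import_xgmml(path, threshold: float = 0.0) -> SimilarityNetwork:
    tree = ET.parse(path)
    root = tree.getroot()
    g = nx.Graph()
    by_id: dict[str, str] = {}
    for node in root.findall("node"):
        label = node.get("label")
        by_id[node.get("id")] = label
        attrs = {}
        for att in node.findall("att"):
            value = att.get("value", "")
            attrs[att.get("name")] = value.split(";") if ";" in value else value
        g.add_node(label, **attrs)
    for edge in root.findall("edge"):
        attrs = {}
        for att in edge.findall("att"):
            if att.get("name") == "score":
                attrs["score"] = float(att.get("value"))
        g.add_edge(by_id[edge.get("source")], by_id[edge.get("target")], **attrs)
    return SimilarityNetwork(
        g, threshold=threshold, metric_name=root.get("label", "")
    )
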