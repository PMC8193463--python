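"""Network comparison as binary classification over edges and graphlets.

Two networks are compared item-by-item — single directed edges, or
weakly connected 3-node graphlet instances — and summarized with
precision P = TP/(TP+FP), recall R = TP/(TP+FN) and their harmonic mean
F1 = 2PR/(P+R). Computed globally they measure overall network
similarity; restricted to the graphlet instances a single gene
participates in, they measure variation in that gene's local topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from .network import GRN
from .triads import CANONICAL_CODE, IS_CONNECTED, class_name, code_of

F1_BINS: Tuple[Tuple[float, float, str], ...] = (
    (0.0, 0.5, "[0.0,0.5)"),
    (0.5, 0.7, "[0.5,0.7)"),
    (0.7, 0.9, "[0.7,0.9)"),
    (0.9, 1.0, "[0.9,1.0]"),  # closed: F1 = 1 belongs here
)

BIN_GENE_TYPES = ("TF", "coding", "noncoding")  # miRNA genes count as noncoding


@dataclass(frozen=True)
class ClassificationCounts:
    """TP/FP/FN (optional TN) over a shared item universe."""

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None

    def __post_init__(self) -> None:
        counts = [self.tp, self.fp, self.fn] + ([] if self.tn is None else [self.tn])
        if any(c < 0 for c in counts):
            raise ValueError("classification counts must be non-negative")

    def swapped(self) -> "ClassificationCounts":
        """Counts with the roles of the two networks exchanged (FP <-> FN)."""
        return ClassificationCounts(self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class Metrics:
    """Precision, recall and F1 in [0, 1].

    A degenerate denominator (e.g. no predicted items at all) yields the
    value 0 with the corresponding ``*_defined`` flag cleared, rather than
    NaN, so reports stay numeric.
    """

    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True

    def rounded(self, ndigits: int = 3) -> Tuple[float, float, float]:
        """(P, R, F1) at report precision (round-half-even)."""
        return (round(self.precision, ndigits), round(self.recall, ndigits), round(self.f1, ndigits))


def metrics_from_counts(counts: ClassificationCounts) -> Metrics:
    """P, R and F1 from a contingency table."""
    p_den = counts.tp + counts.fp
    r_den = counts.tp + counts.fn
    precision = counts.tp / p_den if p_den else 0.0
    recall = counts.tp / r_den if r_den else 0.0
    f1_den = precision + recall
    f1 = 2 * precision * recall / f1_den if f1_den else 0.0
    return Metrics(
        precision,
        recall,
        f1,
        precision_defined=p_den > 0,
        recall_defined=r_den > 0,
        f1_defined=f1_den > 0,
    )


def _classify_sets(
    predicted: Set, gold: Set, universe: Optional[Set] = None
) -> ClassificationCounts:
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = None
    if universe is not None:
        tn = len(universe - predicted - gold)
    return ClassificationCounts(tp, fp, fn, tn)


def compare_edges(
    predicted: GRN, gold: GRN, universe: Optional[GRN] = None
) -> Tuple[ClassificationCounts, Metrics]:
    """Edge-presence comparison keyed by (regulator, target, kind).

    TP: edge in both; FP: in ``predicted`` only; FN: in ``gold`` only. TN is
    reported only when an explicit ``universe`` network (e.g. the reference)
    supplies the full candidate edge set.
    """
    counts = _classify_sets(
        predicted.edge_keys(),
        gold.edge_keys(),
        universe.edge_keys() if universe is not None else None,
    )
    return counts, metrics_from_counts(counts)


# ---------------------------------------------------------------------------
# graphlets


@dataclass(frozen=True)
class GraphletInstance:
    """A weakly connected node triple together with its triad class."""

    nodes: Tuple[str, str, str]  # sorted
    class_code: int

    @property
    def key(self) -> Tuple[str, str, str, int]:
        return (*self.nodes, self.class_code)

    @property
    def name(self) -> str:
        return class_name(self.class_code)


def _simple_arcs(grn: GRN) -> Set[Tuple[str, str]]:
    """Directed arcs of the simple-digraph view: kinds collapsed, no self-loops."""
    return {
        (e.regulator_id, e.target_id)
        for e in grn.iter_edges()
        if e.regulator_id != e.target_id
    }


def _instance(nodes: Iterable[str], arcs: Set[Tuple[str, str]]) -> Optional[GraphletInstance]:
    triple = tuple(sorted(nodes))
    idx = {n: i for i, n in enumerate(triple)}
    code = code_of(
        frozenset(
            (idx[u], idx[v])
            for u in triple
            for v in triple
            if u != v and (u, v) in arcs
        )
    )
    if not IS_CONNECTED[code]:
        return None
    return GraphletInstance(triple, CANONICAL_CODE[code])


def enumerate_graphlets(grn: GRN) -> Set[GraphletInstance]:
    """All weakly connected 3-node induced subgraphs, with their triad class.

    Edge-anchored enumeration: every connected triple contains an arc (u, v)
    plus a third node adjacent to u or v, so only such triples are visited —
    never all n^3 combinations. Self-loops are ignored for both
    connectivity and classing.
    """
    arcs = _simple_arcs(grn)
    adj: Dict[str, Set[str]] = {}
    for u, v in arcs:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    triples: Set[frozenset] = set()
    for u, v in arcs:
        for w in (adj[u] | adj[v]) - {u, v}:
            triples.add(frozenset((u, v, w)))
    instances = set()
    for triple in triples:
        inst = _instance(triple, arcs)
        if inst is not None:  # by construction always connected, kept as a guard
            instances.add(inst)
    return instances


def compare_graphlets(
    net_a: GRN, net_b: GRN
) -> Tuple[ClassificationCounts, Metrics]:
    """Graphlet-presence comparison: ``net_a`` vs the truth/earlier ``net_b``.

    Instances are keyed by (sorted triple, class): a triple whose induced
    subgraph changes class is a different instance in each network and
    counts as one FP plus one FN. TP: instance in both; FP: in ``net_a``
    only; FN: in ``net_b`` only — for time series, ``net_a`` is the later
    network and ``net_b`` the earlier one.
    """
    keys_a = {g.key for g in enumerate_graphlets(net_a)}
    keys_b = {g.key for g in enumerate_graphlets(net_b)}
    counts = _classify_sets(keys_a, keys_b)
    return counts, metrics_from_counts(counts)


# ---------------------------------------------------------------------------
# per-node local topology


@dataclass
class NodeTopology:
    node: str
    gene_type: Optional[str]
    counts: ClassificationCounts
    metrics: Optional[Metrics]  # None when the node joins no instance anywhere

    @property
    def f1(self) -> Optional[float]:
        return self.metrics.f1 if self.metrics is not None else None


@dataclass
class NodeTopologyReport:
    per_node: Dict[str, NodeTopology] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for nt in self.per_node.values():
            m = nt.metrics
            rows.append(
                {
                    "node": nt.node,
                    "gene_type": nt.gene_type,
                    "TP": nt.counts.tp,
                    "FP": nt.counts.fp,
                    "FN": nt.counts.fn,
                    "P": m.precision if m else float("nan"),
                    "R": m.recall if m else float("nan"),
                    "F1": m.f1 if m else float("nan"),
                }
            )
        return pd.DataFrame(rows).set_index("node") if rows else pd.DataFrame()


def node_local_f1(net_a: GRN, net_b: GRN) -> NodeTopologyReport:
    """Per-gene P/R/F1 over the graphlet instances that gene participates in.

    Each instance contributes to exactly its three member nodes. Nodes of
    either network that participate in no instance on either side get
    ``metrics=None`` (undefined, not 0).
    """
    keys_a = {g.key for g in enumerate_graphlets(net_a)}
    keys_b = {g.key for g in enumerate_graphlets(net_b)}
    per_node_sets: Dict[str, List[Set]] = {}
    for keys, slot in ((keys_a, 0), (keys_b, 1)):
        for key in keys:
            for node in key[:3]:
                per_node_sets.setdefault(node, [set(), set()])[slot].add(key)

    types: Dict[str, str] = {}
    for net in (net_b, net_a):  # net_a wins on conflict
        types.update(net.gene_types())

    report = NodeTopologyReport()
    for node in set(types) | set(per_node_sets):
        sets = per_node_sets.get(node)
        if sets is None:
            counts = ClassificationCounts(0, 0, 0)
            metrics = None
        else:
            counts = _classify_sets(sets[0], sets[1])
            metrics = metrics_from_counts(counts)
        report.per_node[node] = NodeTopology(node, types.get(node), counts, metrics)
    return report


def bin_nodes_by_f1(report: NodeTopologyReport) -> pd.DataFrame:
    """Count genes per (gene type, F1 interval).

    Intervals are [0, 0.5), [0.5, 0.7), [0.7, 0.9) and the closed-top
    [0.9, 1.0]. Types follow the TF / non-TF coding / non-coding partition
    (miRNA genes are non-coding); the "all" row sums the three. Nodes with
    undefined F1 are excluded.
    """
    labels = [label for _, _, label in F1_BINS]
    table = {t: {label: 0 for label in labels} for t in ("all", *BIN_GENE_TYPES)}
    for nt in report.per_node.values():
        if nt.metrics is None:
            continue
        f1 = nt.metrics.f1
        label = None
        for lo, hi, lab in F1_BINS:
            if lo <= f1 < hi or (lab == labels[-1] and f1 <= 1.0 and f1 >= lo):
                label = lab
                break
        gtype = nt.gene_type or "coding"
        if gtype == "miRNA":
            gtype = "noncoding"
        table[gtype][label] += 1
        table["all"][label] += 1
    return pd.DataFrame.from_dict(table, orient="index")[labels]
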