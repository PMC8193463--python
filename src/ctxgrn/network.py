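"""Reference gene regulatory network construction.

A reference GRN holds every candidate regulation regardless of context:
TF->gene edges derived from binding-site-to-TSS distance, plus
experimentally determined miRNA->target edges. Context-specific networks
are produced later by filtering this reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .intervals import EvidenceTrack, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

TF_GENE = "tf_gene"
MIRNA_GENE = "mirna_gene"

EdgeKey = Tuple[str, str, str]  # (regulator_id, target_id, edge_kind)


@dataclass(frozen=True)
class TFBSAssignment:
    """One TFBS assigned to the regulation of one gene.

    ``distance`` is the gap in nucleotides between the TFBS edge nearest the
    TSS and the TSS itself (0 when the TFBS touches or straddles the TSS).
    """

    tf_id: str
    tfbs: GenomicInterval
    target_id: str
    distance: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("TFBS-to-TSS distance cannot be negative")


@dataclass(frozen=True)
class RegulatoryEdge:
    """Directed regulator->target relation with its TFBS evidence and weight.

    Reference edges carry weight 0; the filter cascade raises the weight by
    one per filter passed. miRNA edges have no TFBS evidence.
    """

    regulator_id: str
    target_id: str
    edge_kind: str = TF_GENE
    evidence: Tuple[TFBSAssignment, ...] = ()
    weight: int = 0
    passed_filters: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.edge_kind not in (TF_GENE, MIRNA_GENE):
            raise ValueError(f"unknown edge kind {self.edge_kind!r}")
        if self.edge_kind == MIRNA_GENE and self.evidence:
            raise ValueError("miRNA edges carry no TFBS evidence")
        if self.weight < 0:
            raise ValueError("edge weight must be >= 0")

    @property
    def key(self) -> EdgeKey:
        return (self.regulator_id, self.target_id, self.edge_kind)


class GRN:
    """A directed regulatory network: GeneModel nodes, RegulatoryEdge edges.

    Edges are keyed by (regulator, target, kind); duplicates are rejected.
    Isolated nodes are retained — a gene without surviving regulations is
    still part of the annotation universe.
    """

    def __init__(
        self,
        nodes: Iterable[GeneModel] = (),
        edges: Iterable[RegulatoryEdge] = (),
        d: Optional[int] = None,
        provenance: Tuple[str, ...] = (),
    ):
        self._nodes: Dict[str, GeneModel] = {}
        for g in nodes:
            if g.gene_id in self._nodes:
                raise ValueError(f"duplicate node {g.gene_id!r}")
            self._nodes[g.gene_id] = g
        self._edges: Dict[EdgeKey, RegulatoryEdge] = {}
        self.d = d
        self.provenance = tuple(provenance)
        for e in edges:
            self.add_edge(e)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, key: EdgeKey) -> bool:
        return key in self._edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRN):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def nodes(self) -> List[GeneModel]:
        return list(self._nodes.values())

    def node(self, gene_id: str) -> GeneModel:
        return self._nodes[gene_id]

    def has_node(self, gene_id: str) -> bool:
        return gene_id in self._nodes

    def edges(self) -> List[RegulatoryEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def edge(self, key: EdgeKey) -> RegulatoryEdge:
        return self._edges[key]

    def edge_keys(self) -> set:
        return set(self._edges)

    def iter_edges(self) -> Iterator[RegulatoryEdge]:
        return iter(self.edges())

    # -- construction -------------------------------------------------------
    def add_node(self, gene: GeneModel) -> None:
        existing = self._nodes.get(gene.gene_id)
        if existing is not None and existing != gene:
            raise ValueError(f"conflicting definitions for node {gene.gene_id!r}")
        self._nodes[gene.gene_id] = gene

    def add_edge(self, edge: RegulatoryEdge) -> None:
        if edge.key in self._edges:
            raise ValueError(f"duplicate edge {edge.key}")
        for endpoint in (edge.regulator_id, edge.target_id):
            if endpoint not in self._nodes:
                raise ValueError(f"edge endpoint {endpoint!r} is not a node")
        self._edges[edge.key] = edge

    def replace_edges(self, edges: Iterable[RegulatoryEdge]) -> "GRN":
        """New GRN with the same nodes/metadata and the given edges."""
        return GRN(self.nodes(), edges, d=self.d, provenance=self.provenance)

    def subset(self, keys: Iterable[EdgeKey]) -> "GRN":
        return self.replace_edges(self._edges[k] for k in keys)

    # -- views --------------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        """Simple digraph view (parallel tf/miRNA edges collapse to one arc)."""
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for e in self._edges.values():
            g.add_edge(e.regulator_id, e.target_id, weight=e.weight, kind=e.edge_kind)
        return g

    def gene_types(self) -> Dict[str, str]:
        return {gid: g.gene_type for gid, g in self._nodes.items()}


# ---------------------------------------------------------------------------
# TFBS -> gene assignment


def assign_tfbs_to_genes(
    tfbs_by_tf: Mapping[str, EvidenceTrack],
    genes: Sequence[GeneModel],
    d: int,
    fully_contained: bool = False,
    deduplicate: bool = True,
) -> List[TFBSAssignment]:
    """Assign each TFBS to every gene whose upstream window it intersects.

    The window is the strand-aware upstream span of width ``d`` ending
    (half-open) at the TSS; downstream sites are never assigned. By default a
    1 bp overlap with the window suffices (``fully_contained=True`` demands
    the whole TFBS inside the window), and exact-coordinate duplicate TFBSs
    within one TF's track are collapsed first.
    """
    if d <= 0:
        raise ValueError(f"distance threshold d must be positive, got {d}")
    known = {g.gene_id for g in genes}
    missing = sorted(set(tfbs_by_tf) - known)
    if missing:
        raise ValueError(
            "TF ids absent from the annotation: " + ", ".join(missing)
        )

    # index TFBSs once per TF; query per gene window
    assignments: List[TFBSAssignment] = []
    for tf_id in sorted(tfbs_by_tf):
        track = tfbs_by_tf[tf_id]
        if deduplicate:
            track = track.deduplicated()
        for gene in genes:
            chrom, w_start, w_end = gene.upstream_window(d)
            for tfbs in track.overlapping(chrom, w_start, w_end):
                if fully_contained and not (w_start <= tfbs.start and tfbs.end <= w_end):
                    continue
                if gene.strand == "+":
                    distance = max(0, gene.tss - tfbs.end)
                else:
                    distance = max(0, tfbs.start - gene.tss - 1)
                assignments.append(TFBSAssignment(tf_id, tfbs, gene.gene_id, distance))
    return assignments


def build_reference_network(
    assignments: Iterable[TFBSAssignment],
    genes: Sequence[GeneModel],
    d: Optional[int] = None,
) -> GRN:
    """Aggregate assignments into one TF->gene edge per regulator/target pair.

    Every annotated gene becomes a node (isolated nodes retained); all edges
    start with weight 0. Evidence is kept sorted by coordinate so identical
    inputs yield identical networks regardless of input order.
    """
    known = {g.gene_id for g in genes}
    by_pair: Dict[Tuple[str, str], List[TFBSAssignment]] = {}
    for a in assignments:
        if a.tf_id not in known or a.target_id not in known:
            raise ValueError(f"assignment references unknown gene: {a.tf_id}->{a.target_id}")
        by_pair.setdefault((a.tf_id, a.target_id), []).append(a)
    edges = []
    for (tf_id, target_id), ev in sorted(by_pair.items()):
        ev = tuple(sorted(ev, key=lambda a: (a.tfbs.chrom, a.tfbs.start, a.tfbs.end)))
        edges.append(RegulatoryEdge(tf_id, target_id, TF_GENE, ev))
    return GRN(sorted(genes, key=lambda g: g.gene_id), edges, d=d)


def add_mirna_edges(grn: GRN, mirna_targets: Iterable[Tuple[str, str]]) -> GRN:
    """Merge experimentally determined miRNA->target pairs into the network.

    Duplicate pairs collapse to one edge; pairs with unknown targets are
    skipped with a logged count; miRNA regulators missing from the
    annotation are auto-added as miRNA nodes with a warning.
    """
    out = GRN(grn.nodes(), grn.edges(), d=grn.d, provenance=grn.provenance)
    skipped = 0
    added_nodes = []
    for mirna_id, target_id in dict.fromkeys(mirna_targets):  # dedup, order kept
        if not out.has_node(target_id):
            skipped += 1
            continue
        if not out.has_node(mirna_id):
            target = out.node(target_id)
            out.add_node(GeneModel(mirna_id, target.chrom, "+", 0, "miRNA"))
            added_nodes.append(mirna_id)
        key = (mirna_id, target_id, MIRNA_GENE)
        if key not in out:
            out.add_edge(RegulatoryEdge(mirna_id, target_id, MIRNA_GENE))
    if added_nodes:
        warnings.warn(
            f"{len(added_nodes)} miRNA regulator(s) absent from the annotation "
            "were added as miRNA nodes",
            stacklevel=2,
        )
    if skipped:
        logger.warning("skipped %d miRNA pair(s) with unknown target genes", skipped)
    return out


def network_summary(grn: GRN) -> Dict[str, int]:
    """Node/edge/regulator counts (Table-2-style description of a network)."""
    edges = grn.edges()
    tf_regs = {e.regulator_id for e in edges if e.edge_kind == TF_GENE}
    mirna_regs = {e.regulator_id for e in edges if e.edge_kind == MIRNA_GENE}
    connected = {e.regulator_id for e in edges} | {e.target_id for e in edges}
    return {
        "genes": grn.n_nodes,
        "edges": len(edges),
        "tf_gene_edges": sum(e.edge_kind == TF_GENE for e in edges),
        "mirna_gene_edges": sum(e.edge_kind == MIRNA_GENE for e in edges),
        "tf_regulators": len(tf_regs),
        "mirna_regulators": len(mirna_regs),
        "connected_genes": len(connected),
    }


# ---------------------------------------------------------------------------
# network serialization (weighted edge list TSV and SIF)

_EDGE_HEADER = ["regulator", "target", "kind", "weight", "n_tfbs", "tfbs", "passed_filters"]


def write_edge_list(grn: GRN, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write a GRN as a weighted edge-list TSV.

    TFBS evidence is serialized as semicolon-joined ``chrom:start-end/distance``
    tokens so the network can be re-filtered after a round trip; passed
    filters are semicolon-joined identifiers.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for e in grn.edges():
            ev = ";".join(f"{a.tfbs}/{a.distance}" for a in e.evidence)
            passed = ";".join(e.passed_filters)
            fh.write(
                f"{e.regulator_id}\t{e.target_id}\t{e.edge_kind}\t{e.weight}\t"
                f"{len(e.evidence)}\t{ev or '.'}\t{passed or '.'}\n"
            )


def read_edge_list(path: str, genes: Sequence[GeneModel], d: Optional[int] = None) -> GRN:
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    edges: List[RegulatoryEdge] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("regulator\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated columns")
            reg, tgt, kind, weight, _n, ev_field, passed_field = fields[:7]
            evidence: List[TFBSAssignment] = []
            if ev_field != ".":
                for token in ev_field.split(";"):
                    span, dist = token.rsplit("/", 1)
                    chrom, coords = span.rsplit(":", 1)
                    start, end = coords.split("-")
                    evidence.append(
                        TFBSAssignment(
                            reg, GenomicInterval(chrom, int(start), int(end)), tgt, int(dist)
                        )
                    )
            passed = tuple(passed_field.split(";")) if passed_field != "." else ()
            edges.append(
                RegulatoryEdge(reg, tgt, kind, tuple(evidence), int(weight), passed)
            )
    return GRN(sorted(genes, key=lambda g: g.gene_id), edges, d=d)


def write_sif(grn: GRN, path: str) -> None:
    """SIF export for Cytoscape: one ``regulator<TAB>kind<TAB>target`` line."""
    with open(path, "w") as fh:
        for e in grn.edges():
            fh.write(f"{e.regulator_id}\t{e.edge_kind}\t{e.target_id}\n")
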