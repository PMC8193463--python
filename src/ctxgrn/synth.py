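"""Deterministic synthetic genomes with planted, fully known ground truth.

The generator lays genes along a toy chromosome with non-overlapping
upstream windows, plants TFBSs inside (and decoys outside) those windows,
and then constructs every evidence track — methylation, accessibility,
histone marks, expression, miRNA abundance, ChIP occupancy — so that the
fate of every edge under the filter cascade is decided at planting time.
That makes the expected reference network, the expected surviving edges
with their exact weights, the per-filter removal counts and the expected
gold standard all computable by construction, independently of the
pipeline they are used to test.

Scenarios select which removal causes are planted:

- ``all_pass``: full supporting evidence, no removals; uniform weights.
- ``methylated_out``: every other TF edge has all its TFBSs methylated.
- ``closed_out``: every third target promoter lacks accessibility signal.
- ``repressed_out``: every third TF edge sees only a repressive mark.
- ``silent_regulators``: the first TF is unexpressed and the first miRNA
  undetected.
- ``mixed``: all of the above causes at once, on disjoint-by-construction
  granularities (per edge, per target, per regulator).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import io as gio
from .intervals import AbundanceTable, EvidenceTrack, GeneModel, GenomicInterval
from .network import (
    GRN,
    MIRNA_GENE,
    TF_GENE,
    EdgeKey,
    RegulatoryEdge,
    TFBSAssignment,
)

SCENARIOS = (
    "all_pass",
    "methylated_out",
    "closed_out",
    "repressed_out",
    "silent_regulators",
    "mixed",
)

ACTIVE_MARKS = ("H3K36me3", "H3K4me3", "H3K9ac")
REPRESSIVE_MARK = "H3K27me3"

_TFBS_LEN = 10
_SLOT_STEP = 40


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic study: genome, network and evidence sizes."""

    n_genes: int = 12
    n_tfs: int = 3
    n_mirnas: int = 2
    d: int = 1500
    seed: int = 0
    scenario: str = "all_pass"
    chrom: str = "chr2L"
    chrom_length: Optional[int] = None
    edge_density: float = 0.6

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_tfs + self.n_mirnas > self.n_genes:
            raise ValueError("n_tfs + n_mirnas must not exceed n_genes")
        if self.n_tfs < 1 or self.n_genes < 3:
            raise ValueError("need at least one TF and three genes")
        if self.d < 300:
            raise ValueError("d below 300 leaves no room for planted evidence")
        spacing = self.gene_spacing
        needed = (self.n_genes + 1) * spacing + self.d + 1
        if self.chrom_length is not None and self.chrom_length < needed:
            raise ValueError(
                f"chrom_length {self.chrom_length} cannot fit {self.n_genes} genes "
                f"(needs >= {needed})"
            )

    @property
    def gene_spacing(self) -> int:
        # windows reach d on either side of a TSS; 2d + 2000 keeps every
        # window and its planted peaks clear of the neighbours'
        return 2 * self.d + 2000

    @property
    def effective_chrom_length(self) -> int:
        return self.chrom_length or (self.n_genes + 2) * self.gene_spacing


@dataclass
class GroundTruth:
    """What the pipeline must recover, decided entirely at planting time."""

    reference_edges: Set[EdgeKey] = field(default_factory=set)
    surviving: Dict[EdgeKey, int] = field(default_factory=dict)  # key -> weight
    removed_by_filter: Dict[str, int] = field(default_factory=dict)
    gold_edges: Set[EdgeKey] = field(default_factory=set)
    chip_tfs: Tuple[str, ...] = ()


@dataclass
class Fixture:
    """In-memory synthetic dataset plus its ground truth."""

    spec: FixtureSpec
    genes: List[GeneModel]
    tfbs_by_tf: Dict[str, EvidenceTrack]
    methylation: EvidenceTrack
    accessibility: EvidenceTrack
    histone_marks: Dict[str, EvidenceTrack]
    expression: AbundanceTable
    mirna_expression: AbundanceTable
    mirna_targets: List[Tuple[str, str]]
    chip_peaks_by_tf: Dict[str, EvidenceTrack]
    truth: GroundTruth

    def write(self, outdir: str) -> Dict[str, str]:
        """Write every input in the formats the readers consume; returns paths."""
        paths: Dict[str, str] = {}
        os.makedirs(outdir, exist_ok=True)
        for sub in ("tfbs", "histone", "chip"):
            os.makedirs(os.path.join(outdir, sub), exist_ok=True)

        paths["annotation"] = os.path.join(outdir, "genes.tsv")
        gio.write_gene_annotation_tsv(self.genes, paths["annotation"])
        for tf, track in self.tfbs_by_tf.items():
            p = os.path.join(outdir, "tfbs", f"{tf}.bed")
            gio.write_bed(track, p)
            paths[f"tfbs:{tf}"] = p
        paths["methylation"] = os.path.join(outdir, "methylation.bed")
        gio.write_bed(self.methylation, paths["methylation"])
        paths["accessibility"] = os.path.join(outdir, "accessibility.bed")
        gio.write_bed(self.accessibility, paths["accessibility"])
        for mark, track in self.histone_marks.items():
            p = os.path.join(outdir, "histone", f"{mark}.bed")
            gio.write_bed(track, p)
            paths[f"histone:{mark}"] = p
        paths["expression"] = os.path.join(outdir, "expression.tsv")
        gio.write_abundance_table(self.expression, paths["expression"])
        paths["mirna_expression"] = os.path.join(outdir, "mirna_expression.tsv")
        gio.write_abundance_table(self.mirna_expression, paths["mirna_expression"])
        paths["mirna_targets"] = os.path.join(outdir, "mirna_targets.tsv")
        gio.write_pair_list(self.mirna_targets, paths["mirna_targets"])
        for tf, track in self.chip_peaks_by_tf.items():
            p = os.path.join(outdir, "chip", f"{tf}.bed")
            gio.write_bed(track, p)
            paths[f"chip:{tf}"] = p

        paths["truth_surviving"] = os.path.join(outdir, "truth_surviving.tsv")
        with open(paths["truth_surviving"], "w") as fh:
            for key in sorted(self.truth.surviving):
                fh.write("\t".join(key) + f"\t{self.truth.surviving[key]}\n")
        paths["truth_removals"] = os.path.join(outdir, "truth_removals.tsv")
        with open(paths["truth_removals"], "w") as fh:
            for name in sorted(self.truth.removed_by_filter):
                fh.write(f"{name}\t{self.truth.removed_by_filter[name]}\n")
        return paths


def _gene_models(spec: FixtureSpec) -> List[GeneModel]:
    genes = []
    for i in range(spec.n_genes):
        tss = (i + 1) * spec.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        if i < spec.n_tfs:
            gid, gtype = f"tf{i}", "TF"
        elif i < spec.n_tfs + spec.n_mirnas:
            gid, gtype = f"mir{i - spec.n_tfs}", "miRNA"
        else:
            j = i - spec.n_tfs - spec.n_mirnas
            gid = f"g{j}"
            gtype = "noncoding" if j % 4 == 3 else "coding"
        genes.append(GeneModel(gid, spec.chrom, strand, tss, gtype))
    return genes


def _bucket_depths(d: int) -> Tuple[int, int, int]:
    """TSS distances of the three planting depths (proximal, mid, distal).

    Spread so that sub-threshold reassignment at smaller d picks up planted
    sites bucket by bucket, and spaced widely enough that slot shifts never
    let buckets collide.
    """
    proximal = max(320, d // 4)
    mid = proximal + max(220, int(0.13 * d))
    distal = int(0.85 * d)
    return (proximal, mid, distal)


def _tfbs_interval(gene: GeneModel, d: int, slot: int, bucket: int) -> GenomicInterval:
    """The ``slot``-th planted TFBS at depth ``bucket`` in ``gene``'s window."""
    depth = _bucket_depths(d)[bucket] + slot * _SLOT_STEP
    # stay inside the window and clear of the TSS-proximal accessibility peak
    if depth + _TFBS_LEN > d or depth - _TFBS_LEN < 300:
        raise ValueError("too many TFBSs planted in one window for this d")
    if gene.strand == "+":
        start = gene.tss - depth
    else:
        start = gene.tss + 1 + depth - _TFBS_LEN
    return GenomicInterval(gene.chrom, start, start + _TFBS_LEN)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the synthetic dataset for ``spec`` (deterministic in (spec, seed))."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_models(spec)
    by_id = {g.gene_id: g for g in genes}
    tfs = [g for g in genes if g.gene_type == "TF"]
    mirnas = [g for g in genes if g.gene_type == "miRNA"]

    # --- plant the TF -> target plan -----------------------------------
    pairs: List[Tuple[str, str]] = []
    for tf in tfs:
        chosen = [
            g.gene_id
            for g in genes
            if g.gene_id != tf.gene_id and rng.random() < spec.edge_density
        ]
        if not chosen:
            fallback = genes[-1] if genes[-1].gene_id != tf.gene_id else genes[-2]
            chosen = [fallback.gene_id]
        pairs.extend((tf.gene_id, t) for t in chosen)
    pairs.sort()

    slot_counter: Dict[Tuple[str, int], int] = {}
    tfbs_of_edge: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    for idx, (tf_id, target_id) in enumerate(pairs):
        n_sites = 2 if idx % 3 == 0 else 1
        bucket = idx % 3
        sites = []
        for _ in range(n_sites):
            slot = slot_counter.get((target_id, bucket), 0)
            slot_counter[(target_id, bucket)] = slot + 1
            sites.append(_tfbs_interval(by_id[target_id], spec.d, slot, bucket))
        tfbs_of_edge[(tf_id, target_id)] = sites

    # decoy TFBSs in the intergenic gap downstream of the first window:
    # they must never produce an edge
    gap_start = genes[0].tss + spec.d + 200
    tfbs_by_tf: Dict[str, EvidenceTrack] = {}
    for k, tf in enumerate(tfs):
        sites = [
            iv
            for (tf_id, _t), ivs in sorted(tfbs_of_edge.items())
            if tf_id == tf.gene_id
            for iv in ivs
        ]
        decoy_start = gap_start + k * 30
        sites.append(GenomicInterval(spec.chrom, decoy_start, decoy_start + _TFBS_LEN))
        tfbs_by_tf[tf.gene_id] = EvidenceTrack(tf.gene_id, "tfbs", sites)

    # --- scenario: removal causes on their natural granularity ----------
    methylated_edges: Set[Tuple[str, str]] = set()
    closed_targets: Set[str] = set()
    repressed_edges: Set[Tuple[str, str]] = set()
    silent_tfs: Set[str] = set()
    silent_mirnas: Set[str] = set()

    targets_in_order = sorted({t for _, t in pairs})
    sc = spec.scenario
    if sc == "methylated_out":
        methylated_edges = {p for i, p in enumerate(pairs) if i % 2 == 0}
    elif sc == "closed_out":
        closed_targets = {t for i, t in enumerate(targets_in_order) if i % 3 == 0}
    elif sc == "repressed_out":
        repressed_edges = {p for i, p in enumerate(pairs) if i % 3 == 0}
    elif sc == "silent_regulators":
        silent_tfs = {tfs[0].gene_id}
        if mirnas:
            silent_mirnas = {mirnas[0].gene_id}
    elif sc == "mixed":
        methylated_edges = {p for i, p in enumerate(pairs) if i % 5 == 0}
        closed_targets = {targets_in_order[-1]}
        repressed_edges = {p for i, p in enumerate(pairs) if i % 5 == 1}
        silent_tfs = {tfs[-1].gene_id}
        if mirnas:
            silent_mirnas = {mirnas[0].gene_id}

    # --- evidence tracks from the plan ----------------------------------
    meth_sites: List[GenomicInterval] = []
    for pair in sorted(methylated_edges):
        meth_sites.extend(tfbs_of_edge[pair])  # cover every TFBS of the edge
    # harmless intergenic decoy so the track is never empty
    meth_sites.append(GenomicInterval(spec.chrom, gap_start + 1600, gap_start + 1650))
    methylation = EvidenceTrack("methylation", "methylation", meth_sites)

    dnase_sites: List[GenomicInterval] = []
    for t in targets_in_order:
        if t in closed_targets:
            continue
        g = by_id[t]
        if g.strand == "+":
            dnase_sites.append(GenomicInterval(g.chrom, g.tss - 260, g.tss - 210))
        else:
            dnase_sites.append(GenomicInterval(g.chrom, g.tss + 210, g.tss + 260))
    accessibility = EvidenceTrack("accessibility", "accessibility", dnase_sites)

    n_active_of_edge: Dict[Tuple[str, str], int] = {}
    mark_sites: Dict[str, List[GenomicInterval]] = {m: [] for m in ACTIVE_MARKS}
    mark_sites[REPRESSIVE_MARK] = []
    for idx, pair in enumerate(pairs):
        first_site = tfbs_of_edge[pair][0]
        if pair in repressed_edges:
            n_active_of_edge[pair] = 0
            mark_sites[REPRESSIVE_MARK].append(first_site)
            continue
        n_active = len(ACTIVE_MARKS) if sc == "all_pass" else 1 + idx % len(ACTIVE_MARKS)
        n_active_of_edge[pair] = n_active
        for mark in ACTIVE_MARKS[:n_active]:
            mark_sites[mark].append(first_site)
    histone_marks = {
        mark: EvidenceTrack(mark, "histone_mark", sites)
        for mark, sites in mark_sites.items()
        if sites
    }

    expr_values: Dict[str, float] = {}
    for i, g in enumerate(genes):
        if g.gene_type == "TF":
            expr_values[g.gene_id] = 0.0 if g.gene_id in silent_tfs else 5.0 + i
        elif g.gene_type != "miRNA":
            expr_values[g.gene_id] = 1.0
    expression = AbundanceTable(expr_values, label="expression")
    mirna_expression = AbundanceTable(
        {m.gene_id: 3.0 for m in mirnas if m.gene_id not in silent_mirnas},
        label="mirna_expression",
    )

    coding = [g for g in genes if g.gene_type == "coding"]
    mirna_targets: List[Tuple[str, str]] = []
    for j, m in enumerate(mirnas):
        for k in range(2):
            mirna_targets.append((m.gene_id, coding[(2 * j + k) % len(coding)].gene_id))
    mirna_targets = list(dict.fromkeys(mirna_targets))

    chip_tf_ids = tuple(t.gene_id for t in tfs[:-1]) if len(tfs) > 1 else (tfs[0].gene_id,)
    occupied: Set[Tuple[str, str]] = set()
    chip_sites: Dict[str, List[GenomicInterval]] = {t: [] for t in chip_tf_ids}
    for idx, pair in enumerate(pairs):
        tf_id = pair[0]
        if tf_id in chip_sites and idx % 3 != 2:
            occupied.add(pair)
            s = tfbs_of_edge[pair][0]
            chip_sites[tf_id].append(GenomicInterval(s.chrom, max(0, s.start - 5), s.end + 5))
    chip_peaks_by_tf = {
        tf: EvidenceTrack(tf, "chip_peak", sites) for tf, sites in chip_sites.items()
    }

    # --- ground truth by construction ------------------------------------
    truth = GroundTruth(chip_tfs=chip_tf_ids)
    truth.removed_by_filter = {f: 0 for f in ("methylation", "accessibility", "histone", "expression", "mirna")}
    for pair in pairs:
        key = (pair[0], pair[1], TF_GENE)
        truth.reference_edges.add(key)
        causes = []
        if pair in methylated_edges:
            causes.append("methylation")
        if pair[1] in closed_targets:
            causes.append("accessibility")
        if pair in repressed_edges:
            causes.append("histone")
        if pair[0] in silent_tfs:
            causes.append("expression")
        if causes:
            truth.removed_by_filter[causes[0]] += 1  # cascade order attribution
        else:
            # methylation + accessibility + distinct active marks + expression
            truth.surviving[key] = 3 + n_active_of_edge[pair]
        if pair in occupied:
            truth.gold_edges.add(key)
    for m_id, t_id in mirna_targets:
        key = (m_id, t_id, MIRNA_GENE)
        truth.reference_edges.add(key)
        if m_id in silent_mirnas:
            truth.removed_by_filter["mirna"] += 1
        else:
            truth.surviving[key] = 1

    return Fixture(
        spec=spec,
        genes=genes,
        tfbs_by_tf=tfbs_by_tf,
        methylation=methylation,
        accessibility=accessibility,
        histone_marks=histone_marks,
        expression=expression,
        mirna_expression=mirna_expression,
        mirna_targets=mirna_targets,
        chip_peaks_by_tf=chip_peaks_by_tf,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# time series


def _grn_from_keys(keys: Set[EdgeKey], genes: Sequence[GeneModel]) -> GRN:
    edges = [RegulatoryEdge(r, t, k) for r, t, k in sorted(keys)]
    return GRN(sorted(genes, key=lambda g: g.gene_id), edges)


def generate_timeseries_fixture(
    spec: FixtureSpec, n_timepoints: int = 4, churn_rate: float = 0.2
):
    """Consecutive network snapshots differing by a known rewiring fraction.

    Starting from the fixture's reference edge set, each step removes
    ``churn_rate`` of the current edges and adds the same number of fresh
    TF->gene edges (fewer if the candidate pool runs out). Returns the
    snapshots together with the exact expected edge-level TP/FP/FN between
    each consecutive pair (later network vs earlier), straight from the
    rewiring log.
    """
    from .compare import ClassificationCounts  # local import avoids a cycle

    if not 0.0 <= churn_rate <= 1.0:
        raise ValueError("churn_rate must be in [0, 1]")
    if n_timepoints < 2:
        raise ValueError("need at least two timepoints")

    fixture = generate_fixture(spec)
    genes = fixture.genes
    tf_ids = [g.gene_id for g in genes if g.gene_type == "TF"]
    all_pairs = {
        (tf, g.gene_id, TF_GENE) for tf in tf_ids for g in genes if g.gene_id != tf
    }
    rng = np.random.default_rng(spec.seed + 1)

    current = set(fixture.truth.reference_edges)
    networks = [_grn_from_keys(current, genes)]
    expected: List[ClassificationCounts] = []
    for _ in range(n_timepoints - 1):
        n_churn = int(round(churn_rate * len(current)))
        ordered = sorted(current)
        drop_idx = rng.choice(len(ordered), size=min(n_churn, len(ordered)), replace=False)
        dropped = {ordered[i] for i in drop_idx}
        pool = sorted(all_pairs - current)
        add_idx = rng.choice(len(pool), size=min(n_churn, len(pool)), replace=False) if pool else []
        added = {pool[i] for i in add_idx}
        nxt = (current - dropped) | added
        expected.append(
            ClassificationCounts(tp=len(current & nxt), fp=len(added), fn=len(dropped))
        )
        networks.append(_grn_from_keys(nxt, genes))
        current = nxt
    return networks, expected
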