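"""Gold-standard network construction from per-TF ChIP-seq occupancy.

A gold standard is the reference network restricted to the benchmarked
TFs and, within those, to the edges whose binding sites the ChIP-seq data
show actually occupied by their TF in the profiled condition.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping

from .intervals import EvidenceTrack
from .network import GRN, TF_GENE


def restrict_to_regulators(grn: GRN, regulator_ids: Iterable[str]) -> GRN:
    """Keep only edges emitted by the listed regulators; node set preserved.

    Applied to predicted networks before benchmarking so that false
    positives reflect occupancy disagreement rather than regulator coverage.
    """
    allowed = set(regulator_ids)
    return grn.replace_edges(e for e in grn.edges() if e.regulator_id in allowed)


def build_gold_standard(reference: GRN, peaks_by_tf: Mapping[str, EvidenceTrack]) -> GRN:
    """Occupancy-backed subnetwork of ``reference`` for the profiled TFs.

    An edge survives iff its regulator has a ChIP track AND at least one of
    its TFBSs overlaps (>=1 bp) a peak of that same TF. Weights are reset
    to 0: gold standards are unweighted truth sets.
    """
    unknown = sorted(
        tf for tf in peaks_by_tf
        if not reference.has_node(tf) or reference.node(tf).gene_type != "TF"
    )
    if unknown:
        raise ValueError("ChIP tracks for ids that are not TF nodes: " + ", ".join(unknown))

    kept = []
    for e in restrict_to_regulators(reference, peaks_by_tf).edges():
        if e.edge_kind != TF_GENE:
            continue
        peaks = peaks_by_tf[e.regulator_id]
        if any(peaks.any_overlap(a.tfbs.chrom, a.tfbs.start, a.tfbs.end) for a in e.evidence):
            kept.append(replace(e, weight=0, passed_filters=()))
    return reference.replace_edges(kept)
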