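import numpy as np
import pytest

from ctxgrn import (
    GRN,
    EvidenceTrack,
    GeneModel,
    GenomicInterval,
    RegulatoryEdge,
    TFBSAssignment,
)


def make_track(spans, label="track", kind="chip_peak", chrom="chr2L"):
    """Evidence track from (start, end) pairs on one chromosome."""
    return EvidenceTrack(
        label, kind, [GenomicInterval(chrom, s, e) for s, e in spans]
    )


def random_digraph_grn(rng, n_nodes, n_arcs):
    """A random simple digraph wrapped as a GRN (for graphlet tests)."""
    nodes = [GeneModel(f"n{i}", "chr1", "+", i * 10_000, "coding") for i in range(n_nodes)]
    keys = set()
    while len(keys) < n_arcs:
        u, v = rng.choice(n_nodes, 2, replace=False)
        keys.add((f"n{u}", f"n{v}"))
    edges = [RegulatoryEdge(u, v, "tf_gene") for u, v in sorted(keys)]
    return GRN(nodes, edges)


@pytest.fixture
def genes():
    """Toy annotation: two TFs, two targets, a noncoding gene, a miRNA."""
    return [
        GeneModel("tfA", "chr2L", "+", 100_000, "TF"),
        GeneModel("tfB", "chr2L", "-", 200_000, "TF"),
        GeneModel("g1", "chr2L", "+", 10_000, "coding"),
        GeneModel("g2", "chr2L", "-", 50_000, "coding"),
        GeneModel("nc1", "chr2L", "+", 300_000, "noncoding"),
        GeneModel("mir1", "chr2L", "+", 400_000, "miRNA"),
    ]


def _assignment(tf, target, start, end, distance):
    return TFBSAssignment(tf, GenomicInterval("chr2L", start, end), target, distance)


@pytest.fixture
def small_grn(genes):
    """Hand-built reference GRN at d=1500.

    tfA->g1 has one TFBS at [9000, 9010) (990 nt upstream of g1's TSS);
    tfA->g2 one TFBS in the minus-strand window; tfB->g1 two TFBSs;
    mir1->g1 is a miRNA edge.
    """
    edges = [
        RegulatoryEdge("tfA", "g1", "tf_gene", (_assignment("tfA", "g1", 9000, 9010, 990),)),
        RegulatoryEdge("tfA", "g2", "tf_gene", (_assignment("tfA", "g2", 50_200, 50_210, 199),)),
        RegulatoryEdge(
            "tfB",
            "g1",
            "tf_gene",
            (
                _assignment("tfB", "g1", 8600, 8610, 1390),
                _assignment("tfB", "g1", 9500, 9510, 490),
            ),
        ),
        RegulatoryEdge("mir1", "g1", "mirna_gene"),
    ]
    return GRN(genes, edges, d=1500)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)
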