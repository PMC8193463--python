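# Methods

## Model and assumptions

`ctxgrn` models transcriptional regulation at the resolution of directed
regulator→target edges. The reference network is deliberately permissive: a
TF is linked to every gene whose upstream promoter window one of its
binding sites touches, on the assumption that proximal upstream binding
implies candidate regulation. The window is strand-aware and half-open at
the TSS — `[TSS − d, TSS)` for + strand genes, `(TSS, TSS + d]` for −
strand — so a site exactly at the TSS position is *not* upstream, and
downstream sites never create edges. Distal regulation through enhancers is
out of model: known edges driven by sites beyond d, or downstream of the
TSS, are invisible to the reference builder by construction.

Contextualization assumes each evidence type maps to a simple rule about
TF binding: methylated DNA blocks binding; a TF can only act where
chromatin is accessible; active histone marks (H3K4me1/2/3, H3K36me2/3,
H3K79me2, H3K9ac, H3S10ph, H4K16ac) permit binding while repressive marks
(H3K27me3, H3K9me2/3, H4K20me3) indicate inactive sites; a regulator must
be expressed to act. These are heuristics, not a learned model: where marks
genuinely conflict, a rule system cannot resolve them, and the benchmark
behaviour at high weights (precision does not rise monotonically with
weight) reflects exactly that.

## Filter semantics and edge weights

Every filter is an independent, conjunctive veto evaluated against an
edge's **full** binding-site evidence:

| filter        | scope               | veto condition                                   | credit |
|---------------|---------------------|--------------------------------------------------|--------|
| methylation   | per TFBS            | all TFBSs of the edge overlap methylation peaks  | +1     |
| accessibility | per target window   | no accessibility peak in the target's d-window   | +1     |
| histone       | per TFBS, per mark  | no active mark type over any TFBS (policy below) | +1 per distinct active mark type |
| expression    | per regulator       | regulator abundance ≤ threshold or absent        | +1     |
| miRNA         | per miRNA regulator | same rule against the miRNA table                | +1     |

An edge survives a TFBS-scoped filter if at least one of its sites
survives. Histone credits count distinct mark *types* once per edge — ten
active mark data sets plus expression bound the weight at 11 — and a mark
type's effect must be configured (`MarkEffectConfig`), with the defaults
above overridable from a two-column table. Two repressive-mark policies are
exposed because the mixed-signal case is genuinely open:
`veto_if_no_active` (default) removes an edge only when no active mark
supports it; `always_veto` additionally removes any edge touched by a
repressive mark. miRNA edges are untouched by the three chromatin filters
(they have no TFBS) and are uncredited by them.

Because every filter is evaluated independently, the surviving edge set
and the credits are invariant to filter order; the fixed cascade order
(methylation → accessibility → histone → expression → miRNA) matters only
for attributing each removal to one filter in the report. Filters whose
data are not supplied are skipped entirely — no veto, no credit — with
regulator expression as the mandatory minimum input. A supplied-but-empty
track passes and credits everything (logged), since "no peaks anywhere" is
evidence of absence under the peak-calling conventions assumed here.

## Key parameters

| parameter              | units       | default            | why |
|------------------------|-------------|--------------------|-----|
| d (assignment window)  | nucleotides | 1500 (also 2000, 5000) | proximal-promoter scale; the three canonical choices give nested reference networks |
| expression_threshold   | abundance units of the input table | 0, strict `>` | "any nonzero signal" is the minimal reading of *expressed*; RPKM/FPKM users should set an explicit floor |
| repressive_policy      | —           | veto_if_no_active  | removals observed in benchmarking involved sites with *only* repressive marks; mixed signals keep the edge |
| min_weight             | filters passed | 0               | weight ≥ 2 (expression + one mark) is the empirically best operating point in the published benchmark |

Overlap anywhere ≥ 1 bp counts, for assignment, occupancy and every
filter: the inputs are already peak calls, and no score thresholding is
applied on top of them (`fully_contained` and TFBS-scoped accessibility
are available as stricter variants). Exact-coordinate duplicate TFBSs
within one TF's track are collapsed before assignment. Chromosome names
match by exact string comparison; a warning lists evidence chromosomes
absent from the annotation rather than silently aliasing them.

## Gold standards and comparison

A gold standard is the reference restricted to ChIP-profiled TFs, keeping
only edges with at least one TFBS overlapping a peak of *the same* TF;
weights are reset because occupancy is binary truth, not graded evidence.
Predicted networks should be restricted to the same regulator set before
scoring (`restrict_to_regulators`), so false positives measure occupancy
disagreement; edges of unprofiled TFs are excluded from the universe and
true negatives are only reported when an explicit universe is supplied.

Graphlets are weakly connected 3-node induced subgraphs of the
simple-digraph view (parallel TF/miRNA arcs collapse; self-loops are
ignored, as the triad taxonomy is defined on simple digraphs). Each
instance is keyed by its node triple *and* its triad class, so a triple
whose wiring changes between networks counts as one false positive plus
one false negative. Enumeration is edge-anchored — every connected triple
contains an arc plus a node adjacent to an endpoint — and is verified
against exhaustive all-triples enumeration in the tests. Classing uses the
canonical 6-bit edge code minimized over node permutations, frozen against
the standard 13-class census labels and cross-checked against an
independent library implementation in the tests.

Degenerate metric denominators yield 0 with an explicit `*_defined` flag
rather than NaN, keeping tabular reports numeric. Internally metrics are
full precision; `Metrics.rounded()` gives the 3-decimal report form
(round-half-even). Per-gene F1 bins are half-open except the last,
[0.9, 1.0], which includes perfect agreement; miRNA genes are tallied with
the non-coding class in the three-way TF / coding / non-coding partition.

## Synthetic data

The generator builds a toy chromosome with genes spaced `2d + 2000` nt
apart, so promoter windows never overlap and every planted evidence
interval affects exactly one edge; strands alternate to exercise both
window orientations. TFBSs are planted at three depths relative to the TSS
(~d/4, ~d/4 + max(220, 0.13 d), 0.85 d), which makes reassignment at
smaller thresholds pick up sites bucket by bucket; decoy TFBSs in
intergenic space must never produce edges. Each scenario plants removal
causes on their natural granularity — per edge (methylation, repressive
marks), per target promoter (closed chromatin), per regulator (silent TF,
undetected miRNA) — so the expected surviving edges, their exact weights
and the per-filter removal counts are computed at planting time, not by
running the pipeline. Default sizes (12 genes, 3 TFs, 2 miRNAs, ~26
edges) keep every test sub-second while covering all code paths;
determinism is byte-level for fixed (spec, seed).

What the fixtures do **not** emulate: realistic peak shapes or widths,
overlapping promoters (available as future scenario work; windows here are
disjoint by design), expression-level distributions, genome-scale edge
counts, or noise in any track. Passing tests therefore demonstrate that
the implementation applies the stated rules exactly, not that the rules
recover biology; the published full-genome benchmark numbers enter only
through their printed contingency tables, whose metric layer the
acceptance script recomputes.

The time-series generator rewires a fixed fraction of edges per step and
logs the rewiring, giving exact expected edge-level TP/FP/FN between
consecutive snapshots; graphlet-level expectations come from the
enumeration itself, which is independently verified by brute force.

## Numerical and design choices

- All internal coordinates are 0-based half-open; GTF/GFF3 (1-based
  inclusive) are converted on read, and TSS = feature start (+) or feature
  end − 1 (−).
- TFBS-to-TSS distance is the gap from the site edge nearest the TSS, 0
  for sites touching or straddling the TSS.
- Edges are keyed (regulator, target, kind); a gene pair can carry one TF
  edge and one miRNA edge simultaneously.
- Determinism: edge evidence is sorted by coordinate, edge listings by
  key, so identical inputs give identical outputs regardless of input
  order; CLI outputs carry no timestamps and embed input digests, making
  reruns byte-identical.
- Isolated genes remain nodes: the annotation defines the node universe,
  and weight-thresholded views drop edges, not gene records.
- The metric layer reports exactly what the counts imply; where published
  tables contain last-digit inconsistencies between printed counts and
  printed metrics, the recomputed value from the counts is taken as
  authoritative.

## Known limitations

- Regulation is promoter-proximal only; enhancer-mediated and downstream
  TFBS-driven edges are out of scope of the assignment rule.
- The filters are binary rules on called peaks; signal strength, peak
  scores and probabilistic footprinting are ignored.
- Expression of the regulator's gene proxies regulator activity; maternally
  deposited or post-transcriptionally controlled regulators are missed.
- The graphlet census is fixed at size 3; larger graphlets and orbit
  signatures are not implemented.
- Gold standards inherit the reference's TFBS set: an occupancy peak with
  no annotated TFBS under it cannot create an edge.
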