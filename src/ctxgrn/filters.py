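"""The ordered evidence-filter cascade that contextualizes a reference GRN.

Five conjunctive filters — DNA methylation, chromatin accessibility,
histone marks, regulator expression, miRNA abundance — each veto edges
that their evidence says are unlikely in the profiled condition, and each
credits +1 to the weight of every edge it passes (each distinct active
histone-mark type counts as its own filter). A filter runs only when its
data are supplied; regulator expression is the mandatory minimum input.

Because every filter is an independent veto evaluated against an edge's
full TFBS evidence, the surviving edge set and the credits are invariant
to the order in which filters run; the fixed methylation -> accessibility
-> histone -> expression -> miRNA order only determines which filter a
removal is attributed to in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .intervals import AbundanceTable, EvidenceTrack
from .network import GRN, MIRNA_GENE, TF_GENE, EdgeKey, RegulatoryEdge

logger = logging.getLogger(__name__)

#: Default histone-mark effects on TF binding: "active" marks permit
#: binding at the site, "repressive" marks indicate inactive chromatin.
DEFAULT_MARK_EFFECTS: Dict[str, str] = {
    "H3K27me3": "repressive",
    "H3K36me2": "active",
    "H3K36me3": "active",
    "H3K4me1": "active",
    "H3K4me2": "active",
    "H3K4me3": "active",
    "H3K79me2": "active",
    "H3K9ac": "active",
    "H3K9me2": "repressive",
    "H3K9me3": "repressive",
    "H3S10ph": "active",
    "H4K16ac": "active",
    "H4K20me3": "repressive",
}

VETO_IF_NO_ACTIVE = "veto_if_no_active"
ALWAYS_VETO = "always_veto"

FILTER_ORDER = ("methylation", "accessibility", "histone", "expression", "mirna")


@dataclass(frozen=True)
class MarkEffectConfig:
    """Maps each histone-mark name to its effect on TF binding."""

    effects: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MARK_EFFECTS))

    def __post_init__(self) -> None:
        bad = {m: e for m, e in self.effects.items() if e not in ("active", "repressive")}
        if bad:
            raise ValueError(f"mark effects must be 'active' or 'repressive': {bad}")

    def effect(self, mark: str) -> str:
        try:
            return self.effects[mark]
        except KeyError:
            raise ValueError(
                f"histone mark {mark!r} has no configured effect; known marks: "
                + ", ".join(sorted(self.effects))
            ) from None

    @classmethod
    def from_tsv(cls, path: str) -> "MarkEffectConfig":
        """Two-column TSV: mark name, effect (active/repressive or +/-)."""
        effects = dict(DEFAULT_MARK_EFFECTS)
        symbol = {"+": "active", "-": "repressive", "−": "repressive"}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                effects[fields[0]] = symbol.get(fields[1], fields[1])
        return cls(effects)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable knobs of the cascade.

    ``expression_threshold`` / ``mirna_threshold``: a regulator counts as
    expressed when its abundance is strictly greater than the threshold
    (default 0, i.e. any nonzero signal). ``repressive_policy`` controls
    mixed histone signals: under ``veto_if_no_active`` an edge survives the
    histone filter whenever at least one active mark supports it, even if
    repressive marks are also present; ``always_veto`` additionally removes
    any edge touched by a repressive mark. ``accessibility_on_tfbs`` tests
    accessibility overlap against the TFBS itself instead of the whole
    upstream window.
    """

    d: Optional[int] = None
    expression_threshold: float = 0.0
    mirna_threshold: float = 0.0
    mark_effects: MarkEffectConfig = field(default_factory=MarkEffectConfig)
    repressive_policy: str = VETO_IF_NO_ACTIVE
    accessibility_on_tfbs: bool = False
    enabled: Optional[frozenset] = None  # None = every filter with data

    def __post_init__(self) -> None:
        if self.repressive_policy not in (VETO_IF_NO_ACTIVE, ALWAYS_VETO):
            raise ValueError(f"unknown repressive policy {self.repressive_policy!r}")
        if self.enabled is not None:
            unknown = set(self.enabled) - set(FILTER_ORDER)
            if unknown:
                raise ValueError(f"unknown filter name(s): {sorted(unknown)}")
            if "expression" not in self.enabled:
                raise ValueError("the expression filter cannot be disabled (minimum input)")

    def filter_enabled(self, name: str) -> bool:
        return self.enabled is None or name in self.enabled


@dataclass
class FilterOutcome:
    """Per-edge record of credited filters and (optionally) the removing one."""

    key: EdgeKey
    passed: Tuple[str, ...] = ()
    removed_by: Optional[str] = None

    @property
    def weight(self) -> int:
        return len(self.passed)


@dataclass
class CascadeData:
    """The evidence bundle for one condition. Absent tracks disable filters."""

    expression: AbundanceTable
    methylation: Optional[EvidenceTrack] = None
    accessibility: Optional[EvidenceTrack] = None
    histone_marks: Mapping[str, EvidenceTrack] = field(default_factory=dict)
    mirna_expression: Optional[AbundanceTable] = None


@dataclass
class CascadeReport:
    applied_filters: List[str]
    removed_by_filter: Dict[str, int]
    outcomes: Dict[EdgeKey, FilterOutcome]
    weight_histogram: Dict[int, int]

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by_filter.values())


Outcomes = Dict[EdgeKey, FilterOutcome]


def _split(grn: GRN, outcomes: Outcomes, keep: Dict[EdgeKey, Tuple[str, ...]], veto_name: str) -> GRN:
    """Record outcomes and return the GRN restricted to kept edges."""
    kept_edges = []
    for e in grn.edges():
        if e.key in keep:
            outcomes[e.key] = FilterOutcome(e.key, keep[e.key])
            kept_edges.append(e)
        else:
            outcomes[e.key] = FilterOutcome(e.key, (), removed_by=veto_name)
    return grn.replace_edges(kept_edges)


def filter_methylation(grn: GRN, meth: EvidenceTrack) -> Tuple[GRN, Outcomes]:
    """Remove edges whose every TFBS shows a methylation signal.

    A methylated TFBS is assumed unbindable; an edge survives if at least
    one of its TFBSs is unmethylated, and surviving TF->gene edges are
    credited +1. miRNA edges pass untouched and uncredited.
    """
    if len(meth) == 0:
        logger.info("methylation track is empty: all edges pass and are credited")
    outcomes: Outcomes = {}
    keep: Dict[EdgeKey, Tuple[str, ...]] = {}
    for e in grn.edges():
        if e.edge_kind == MIRNA_GENE:
            keep[e.key] = ()
            continue
        unmethylated = [
            a for a in e.evidence
            if not meth.any_overlap(a.tfbs.chrom, a.tfbs.start, a.tfbs.end)
        ]
        if unmethylated:
            keep[e.key] = ("methylation",)
    return _split(grn, outcomes, keep, "methylation"), outcomes


def filter_accessibility(
    grn: GRN, dnase: EvidenceTrack, d: int, on_tfbs: bool = False
) -> Tuple[GRN, Outcomes]:
    """Keep edges whose target promoter region shows open chromatin.

    Default semantics: the target gene's strand-aware upstream window of
    width ``d`` (the reference network's assignment window) must overlap at
    least one accessibility interval. With ``on_tfbs`` the overlap is tested
    against the edge's own TFBSs instead. miRNA edges pass untouched.
    """
    if grn.d is not None and d != grn.d:
        raise ValueError(
            f"accessibility window d={d} does not match the network's construction d={grn.d}"
        )
    outcomes: Outcomes = {}
    keep: Dict[EdgeKey, Tuple[str, ...]] = {}
    open_target: Dict[str, bool] = {}
    for e in grn.edges():
        if e.edge_kind == MIRNA_GENE:
            keep[e.key] = ()
            continue
        if on_tfbs:
            ok = any(
                dnase.any_overlap(a.tfbs.chrom, a.tfbs.start, a.tfbs.end) for a in e.evidence
            )
        else:
            if e.target_id not in open_target:
                chrom, w_start, w_end = grn.node(e.target_id).upstream_window(d)
                open_target[e.target_id] = dnase.any_overlap(chrom, w_start, w_end)
            ok = open_target[e.target_id]
        if ok:
            keep[e.key] = ("accessibility",)
    return _split(grn, outcomes, keep, "accessibility"), outcomes


def filter_histone(
    grn: GRN,
    marks: Mapping[str, EvidenceTrack],
    effects: Optional[MarkEffectConfig] = None,
    policy: str = VETO_IF_NO_ACTIVE,
) -> Tuple[GRN, Outcomes]:
    """Keep edges whose binding sites carry active-chromatin histone marks.

    Each distinct mark *type* overlapping >=1 of an edge's TFBSs counts once:
    active marks credit +1 each, repressive marks never credit. Under
    ``veto_if_no_active`` an edge needs at least one active mark to survive;
    ``always_veto`` additionally removes edges touched by any repressive
    mark. miRNA edges pass untouched.
    """
    effects = effects or MarkEffectConfig()
    if policy not in (VETO_IF_NO_ACTIVE, ALWAYS_VETO):
        raise ValueError(f"unknown repressive policy {policy!r}")
    resolved = {name: effects.effect(name) for name in marks}  # raises before filtering
    outcomes: Outcomes = {}
    keep: Dict[EdgeKey, Tuple[str, ...]] = {}
    for e in grn.edges():
        if e.edge_kind == MIRNA_GENE:
            keep[e.key] = ()
            continue
        active: List[str] = []
        repressive: List[str] = []
        for name in sorted(marks):
            track = marks[name]
            if any(track.any_overlap(a.tfbs.chrom, a.tfbs.start, a.tfbs.end) for a in e.evidence):
                (active if resolved[name] == "active" else repressive).append(name)
        ok = bool(active) and (policy == VETO_IF_NO_ACTIVE or not repressive)
        if ok:
            keep[e.key] = tuple(active)
    return _split(grn, outcomes, keep, "histone"), outcomes


def filter_expression(
    grn: GRN, expr: AbundanceTable, threshold: float = 0.0
) -> Tuple[GRN, Outcomes]:
    """Keep TF->gene edges whose regulator gene is expressed.

    Expressed means abundance strictly greater than ``threshold``; a
    regulator absent from the table is not expressed. miRNA edges are the
    miRNA filter's business and pass untouched here.
    """
    outcomes: Outcomes = {}
    keep: Dict[EdgeKey, Tuple[str, ...]] = {}
    for e in grn.edges():
        if e.edge_kind == MIRNA_GENE:
            keep[e.key] = ()
        elif expr.is_expressed(e.regulator_id, threshold):
            keep[e.key] = ("expression",)
    return _split(grn, outcomes, keep, "expression"), outcomes


def filter_mirna(
    grn: GRN, mirna_expr: AbundanceTable, threshold: float = 0.0
) -> Tuple[GRN, Outcomes]:
    """Expression filter for miRNA->target edges (same contract, miRNA table)."""
    outcomes: Outcomes = {}
    keep: Dict[EdgeKey, Tuple[str, ...]] = {}
    for e in grn.edges():
        if e.edge_kind == TF_GENE:
            keep[e.key] = ()
        elif mirna_expr.is_expressed(e.regulator_id, threshold):
            keep[e.key] = ("mirna_expression",)
    return _split(grn, outcomes, keep, "mirna"), outcomes


def apply_cascade(
    grn: GRN, data: CascadeData, config: Optional[FilterConfig] = None
) -> Tuple[GRN, CascadeReport]:
    """Run the filters in cascade order and weight the surviving edges.

    Filters run in the fixed order methylation -> accessibility -> histone
    -> expression -> miRNA, each only when its data are supplied (and, if
    ``config.enabled`` is set, listed there). Every surviving edge's weight
    is the total number of credited filter identifiers; the report carries
    per-filter removal counts, per-edge outcomes and the weight histogram.
    """
    config = config or FilterConfig()
    if config.d is not None and grn.d is not None and config.d != grn.d:
        raise ValueError(f"config d={config.d} does not match network d={grn.d}")
    d = config.d if config.d is not None else grn.d
    if data.expression is None:
        raise ValueError("regulator expression is the minimum required input")

    steps = []
    if data.methylation is not None and config.filter_enabled("methylation"):
        steps.append(("methylation", lambda g: filter_methylation(g, data.methylation)))
    if data.accessibility is not None and config.filter_enabled("accessibility"):
        if d is None:
            raise ValueError("accessibility filtering needs the distance threshold d")
        steps.append(
            (
                "accessibility",
                lambda g: filter_accessibility(
                    g, data.accessibility, d, on_tfbs=config.accessibility_on_tfbs
                ),
            )
        )
    if data.histone_marks and config.filter_enabled("histone"):
        steps.append(
            (
                "histone",
                lambda g: filter_histone(
                    g, data.histone_marks, config.mark_effects, config.repressive_policy
                ),
            )
        )
    steps.append(
        ("expression", lambda g: filter_expression(g, data.expression, config.expression_threshold))
    )
    if data.mirna_expression is not None and config.filter_enabled("mirna"):
        steps.append(
            ("mirna", lambda g: filter_mirna(g, data.mirna_expression, config.mirna_threshold))
        )

    credits: Dict[EdgeKey, List[str]] = {e.key: [] for e in grn.edges()}
    final: Dict[EdgeKey, FilterOutcome] = {}
    removed_by_filter: Dict[str, int] = {}
    current = grn
    for name, step in steps:
        current, outcomes = step(current)
        n_removed = 0
        for key, oc in outcomes.items():
            if oc.removed_by is not None:
                final[key] = FilterOutcome(key, tuple(credits[key]), removed_by=name)
                n_removed += 1
            else:
                credits[key].extend(oc.passed)
        removed_by_filter[name] = n_removed
        logger.info("filter %-13s removed %d edge(s), %d remain", name, n_removed, len(current))

    weighted = []
    histogram: Dict[int, int] = {}
    for e in current.edges():
        passed = tuple(credits[e.key])
        final[e.key] = FilterOutcome(e.key, passed)
        weighted.append(replace(e, weight=len(passed), passed_filters=passed))
        histogram[len(passed)] = histogram.get(len(passed), 0) + 1
    report = CascadeReport(
        applied_filters=[name for name, _ in steps],
        removed_by_filter=removed_by_filter,
        outcomes=final,
        weight_histogram=dict(sorted(histogram.items())),
    )
    return current.replace_edges(weighted), report


def threshold_by_weight(grn: GRN, min_weight: int) -> GRN:
    """Sub-network of edges with weight >= ``min_weight`` (nodes retained)."""
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    return grn.replace_edges(e for e in grn.edges() if e.weight >= min_weight)
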