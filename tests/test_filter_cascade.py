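"""Semantics of the evidence filters and the cascade's weight accounting."""

import itertools

import pytest

from ctxgrn import (
    CascadeData,
    FilterConfig,
    MarkEffectConfig,
    apply_cascade,
    assign_tfbs_to_genes,
    add_mirna_edges,
    build_reference_network,
    filter_accessibility,
    filter_expression,
    filter_histone,
    filter_methylation,
    filter_mirna,
    generate_fixture,
    threshold_by_weight,
    AbundanceTable,
)
from ctxgrn.filters import ALWAYS_VETO, VETO_IF_NO_ACTIVE
from ctxgrn.synth import FixtureSpec
from conftest import make_track


def _keys(grn):
    return grn.edge_keys()


class TestMethylation:
    def test_fully_methylated_edge_removed(self, small_grn):
        meth = make_track([(9005, 9100)], kind="methylation")
        out, outcomes = filter_methylation(small_grn, meth)
        assert ("tfA", "g1", "tf_gene") not in _keys(out)
        assert outcomes[("tfA", "g1", "tf_gene")].removed_by == "methylation"

    def test_edge_with_one_unmethylated_tfbs_survives_credited(self, small_grn):
        meth = make_track([(8600, 8610)], kind="methylation")  # covers 1 of tfB's 2 sites
        out, outcomes = filter_methylation(small_grn, meth)
        key = ("tfB", "g1", "tf_gene")
        assert key in _keys(out)
        assert outcomes[key].passed == ("methylation",)

    def test_mirna_edges_untouched_and_uncredited(self, small_grn):
        meth = make_track([(0, 500_000)], kind="methylation")  # blankets everything
        out, outcomes = filter_methylation(small_grn, meth)
        assert _keys(out) == {("mir1", "g1", "mirna_gene")}
        assert outcomes[("mir1", "g1", "mirna_gene")].passed == ()

    def test_empty_track_passes_and_credits_all(self, small_grn):
        out, outcomes = filter_methylation(small_grn, make_track([], kind="methylation"))
        assert _keys(out) == _keys(small_grn)
        assert outcomes[("tfA", "g1", "tf_gene")].passed == ("methylation",)


class TestAccessibility:
    def test_open_promoter_keeps_and_credits_all_incoming(self, small_grn):
        dnase = make_track([(9500, 9550)], kind="accessibility")  # 500 nt upstream of g1
        out, outcomes = filter_accessibility(small_grn, dnase, d=1500)
        assert ("tfA", "g1", "tf_gene") in _keys(out)
        assert ("tfB", "g1", "tf_gene") in _keys(out)
        assert outcomes[("tfA", "g1", "tf_gene")].passed == ("accessibility",)
        assert ("tfA", "g2", "tf_gene") not in _keys(out)  # g2 promoter closed

    def test_peak_beyond_window_removes(self, small_grn):
        dnase = make_track([(7000, 7050)], kind="accessibility")  # 3000 nt upstream
        out, _ = filter_accessibility(small_grn, dnase, d=1500)
        assert ("tfA", "g1", "tf_gene") not in _keys(out)

    def test_larger_window_recovers_distal_peak(self, genes):
        # same promoter, d=5000 construction: the 3000-nt-upstream peak now counts
        tracks = {"tfA": make_track([(9000, 9010)], kind="tfbs")}
        grn = build_reference_network(assign_tfbs_to_genes(tracks, genes, 5000), genes, d=5000)
        dnase = make_track([(7000, 7050)], kind="accessibility")
        out, _ = filter_accessibility(grn, dnase, d=5000)
        assert ("tfA", "g1", "tf_gene") in _keys(out)

    def test_mismatched_d_rejected(self, small_grn):
        with pytest.raises(ValueError, match="does not match"):
            filter_accessibility(small_grn, make_track([], kind="accessibility"), d=2000)

    def test_tfbs_scoped_variant(self, small_grn):
        dnase = make_track([(9005, 9008)], kind="accessibility")  # inside tfA->g1's TFBS
        out, _ = filter_accessibility(small_grn, dnase, d=1500, on_tfbs=True)
        assert _keys(out) == {("tfA", "g1", "tf_gene"), ("mir1", "g1", "mirna_gene")}


class TestHistone:
    def test_two_active_marks_credit_two(self, small_grn):
        marks = {
            "H3K4me3": make_track([(9000, 9010)], kind="histone_mark"),
            "H3K9ac": make_track([(9002, 9012)], kind="histone_mark"),
        }
        out, outcomes = filter_histone(small_grn, marks)
        key = ("tfA", "g1", "tf_gene")
        assert key in _keys(out)
        assert outcomes[key].passed == ("H3K4me3", "H3K9ac")

    @pytest.mark.parametrize("policy", [VETO_IF_NO_ACTIVE, ALWAYS_VETO])
    def test_repressive_only_edge_removed_under_both_policies(self, small_grn, policy):
        marks = {"H3K27me3": make_track([(9000, 9010)], kind="histone_mark")}
        out, outcomes = filter_histone(small_grn, marks, policy=policy)
        assert ("tfA", "g1", "tf_gene") not in _keys(out)
        assert outcomes[("tfA", "g1", "tf_gene")].removed_by == "histone"

    def test_mark_type_counts_once_despite_many_peaks(self, small_grn):
        marks = {
            "H3K4me3": make_track(
                [(9000, 9004), (9004, 9007), (9007, 9010)], kind="histone_mark"
            )
        }
        _, outcomes = filter_histone(small_grn, marks)
        assert outcomes[("tfA", "g1", "tf_gene")].passed == ("H3K4me3",)

    def test_mixed_signal_depends_on_policy(self, small_grn):
        marks = {
            "H3K4me3": make_track([(9000, 9010)], kind="histone_mark"),
            "H3K27me3": make_track([(9000, 9010)], kind="histone_mark"),
        }
        kept, outcomes = filter_histone(small_grn, marks, policy=VETO_IF_NO_ACTIVE)
        assert ("tfA", "g1", "tf_gene") in _keys(kept)
        # repressive mark never credits
        assert outcomes[("tfA", "g1", "tf_gene")].passed == ("H3K4me3",)
        vetoed, _ = filter_histone(small_grn, marks, policy=ALWAYS_VETO)
        assert ("tfA", "g1", "tf_gene") not in _keys(vetoed)

    def test_unknown_mark_rejected_before_filtering(self, small_grn):
        with pytest.raises(ValueError, match="H9Z99me9"):
            filter_histone(small_grn, {"H9Z99me9": make_track([], kind="histone_mark")})


class TestExpressionFilters:
    def test_expressed_regulator_keeps_and_credits(self, small_grn):
        expr = AbundanceTable({"tfA": 5.0, "tfB": 1.0})
        out, outcomes = filter_expression(small_grn, expr)
        assert ("tfA", "g1", "tf_gene") in _keys(out)
        assert outcomes[("tfA", "g1", "tf_gene")].passed == ("expression",)

    def test_absent_regulator_is_not_expressed(self, small_grn):
        expr = AbundanceTable({"tfA": 5.0})  # tfB missing
        out, _ = filter_expression(small_grn, expr)
        assert ("tfB", "g1", "tf_gene") not in _keys(out)

    def test_threshold_boundary_is_strict(self, small_grn):
        expr = AbundanceTable({"tfA": 2.0, "tfB": 5.0})
        out, _ = filter_expression(small_grn, expr, threshold=2.0)
        assert ("tfA", "g1", "tf_gene") not in _keys(out)
        assert ("tfB", "g1", "tf_gene") in _keys(out)

    def test_mirna_filter_only_touches_mirna_edges(self, small_grn):
        out, outcomes = filter_mirna(small_grn, AbundanceTable({}))
        assert ("mir1", "g1", "mirna_gene") not in _keys(out)
        assert all(k in _keys(out) for k in _keys(small_grn) if k[2] == "tf_gene")
        detected, outcomes = filter_mirna(small_grn, AbundanceTable({"mir1": 3.0}))
        assert outcomes[("mir1", "g1", "mirna_gene")].passed == ("mirna_expression",)


class TestCascade:
    def test_expression_only_gives_weight_one(self, small_grn):
        data = CascadeData(expression=AbundanceTable({"tfA": 5.0, "tfB": 1.0}))
        out, report = apply_cascade(small_grn, data)
        tf_weights = {e.weight for e in out.edges() if e.edge_kind == "tf_gene"}
        assert tf_weights == {1}
        assert report.applied_filters == ["expression"]

    def test_expression_plus_one_mark_gives_weight_two(self, small_grn):
        data = CascadeData(
            expression=AbundanceTable({"tfA": 5.0}),
            histone_marks={"H3K4me3": make_track([(9000, 9010)], kind="histone_mark")},
        )
        out, _ = apply_cascade(small_grn, data)
        assert out.edge(("tfA", "g1", "tf_gene")).weight == 2
        assert out.edge(("tfA", "g1", "tf_gene")).passed_filters == ("H3K4me3", "expression")

    def test_ten_mark_types_plus_expression_reach_weight_eleven(self, small_grn):
        mark_names = [f"MARK{i}" for i in range(10)]
        effects = MarkEffectConfig({m: "active" for m in mark_names})
        data = CascadeData(
            expression=AbundanceTable({"tfA": 5.0}),
            histone_marks={
                m: make_track([(9000, 9010)], label=m, kind="histone_mark") for m in mark_names
            },
        )
        out, _ = apply_cascade(small_grn, data, FilterConfig(mark_effects=effects))
        assert out.edge(("tfA", "g1", "tf_gene")).weight == 11

    def test_missing_expression_table_rejected(self, small_grn):
        with pytest.raises(ValueError, match="minimum required input"):
            apply_cascade(small_grn, CascadeData(expression=None))

    def test_report_histogram_accounts_for_every_survivor(self, small_grn):
        data = CascadeData(
            expression=AbundanceTable({"tfA": 5.0, "tfB": 1.0}),
            mirna_expression=AbundanceTable({"mir1": 2.0}),
        )
        out, report = apply_cascade(small_grn, data)
        assert sum(report.weight_histogram.values()) == len(out)
        assert report.n_removed == len(small_grn) - len(out)


def _fixture_pipeline(scenario, seed=3):
    fx = generate_fixture(FixtureSpec(scenario=scenario, seed=seed))
    grn = add_mirna_edges(
        build_reference_network(
            assign_tfbs_to_genes(fx.tfbs_by_tf, fx.genes, fx.spec.d), fx.genes, d=fx.spec.d
        ),
        fx.mirna_targets,
    )
    return fx, grn


class TestCascadeInvariants:
    def test_output_edges_subset_of_input_after_every_filter(self):
        fx, grn = _fixture_pipeline("mixed")
        current = grn
        for step in (
            lambda g: filter_methylation(g, fx.methylation)[0],
            lambda g: filter_accessibility(g, fx.accessibility, fx.spec.d)[0],
            lambda g: filter_histone(g, fx.histone_marks)[0],
            lambda g: filter_expression(g, fx.expression)[0],
            lambda g: filter_mirna(g, fx.mirna_expression)[0],
        ):
            nxt = step(current)
            assert _keys(nxt) <= _keys(current)
            current = nxt

    def test_weight_equals_credited_filters_and_is_bounded(self):
        fx, grn = _fixture_pipeline("mixed")
        data = CascadeData(
            expression=fx.expression,
            methylation=fx.methylation,
            accessibility=fx.accessibility,
            histone_marks=fx.histone_marks,
            mirna_expression=fx.mirna_expression,
        )
        out, report = apply_cascade(grn, data, FilterConfig(d=fx.spec.d))
        n_active = sum(
            1 for m in fx.histone_marks if m != "H3K27me3"
        )
        for e in out.edges():
            assert e.weight == len(e.passed_filters)
            assert e.weight == report.outcomes[e.key].weight
            if e.edge_kind == "tf_gene":
                assert e.weight <= 2 + n_active + 1

    def test_surviving_edge_set_invariant_under_filter_order(self):
        fx, grn = _fixture_pipeline("mixed")
        steps = {
            "methylation": lambda g: filter_methylation(g, fx.methylation),
            "accessibility": lambda g: filter_accessibility(g, fx.accessibility, fx.spec.d),
            "histone": lambda g: filter_histone(g, fx.histone_marks),
            "expression": lambda g: filter_expression(g, fx.expression),
            "mirna": lambda g: filter_mirna(g, fx.mirna_expression),
        }
        reference_result = None
        for order in itertools.permutations(steps):
            current, credits = grn, {}
            for name in order:
                current, outcomes = steps[name](current)
                for key, oc in outcomes.items():
                    if oc.removed_by is None:
                        credits.setdefault(key, set()).update(oc.passed)
            result = (_keys(current), {k: frozenset(v) for k, v in credits.items() if k in _keys(current)})
            if reference_result is None:
                reference_result = result
            assert result == reference_result

    def test_active_mark_peak_never_hurts_methylation_never_helps(self):
        fx, grn = _fixture_pipeline("repressed_out")
        base_data = CascadeData(
            expression=fx.expression,
            methylation=fx.methylation,
            accessibility=fx.accessibility,
            histone_marks=fx.histone_marks,
            mirna_expression=fx.mirna_expression,
        )
        base_out, _ = apply_cascade(grn, base_data, FilterConfig(d=fx.spec.d))

        blanket = make_track([(0, 10_000_000)], label="H3K4me1", kind="histone_mark")
        more_active = dict(fx.histone_marks, H3K4me1=blanket)
        rescued, _ = apply_cascade(
            grn,
            CascadeData(
                expression=fx.expression,
                methylation=fx.methylation,
                accessibility=fx.accessibility,
                histone_marks=more_active,
                mirna_expression=fx.mirna_expression,
            ),
            FilterConfig(d=fx.spec.d),
        )
        assert _keys(base_out) <= _keys(rescued)
        for e in base_out.edges():
            assert rescued.edge(e.key).weight >= e.weight

        meth_blanket = make_track([(0, 10_000_000)], kind="methylation")
        smothered, _ = apply_cascade(
            grn,
            CascadeData(
                expression=fx.expression,
                methylation=meth_blanket,
                accessibility=fx.accessibility,
                histone_marks=fx.histone_marks,
                mirna_expression=fx.mirna_expression,
            ),
            FilterConfig(d=fx.spec.d),
        )
        assert _keys(smothered) <= _keys(base_out)
        for e in smothered.edges():
            assert e.weight <= base_out.edge(e.key).weight

    def test_histone_enabled_survivors_have_weight_at_least_two(self):
        fx, grn = _fixture_pipeline("all_pass")
        data = CascadeData(expression=fx.expression, histone_marks=fx.histone_marks)
        out, _ = apply_cascade(grn, data)
        tf_weights = [e.weight for e in out.edges() if e.edge_kind == "tf_gene"]
        k = len(fx.histone_marks)
        assert tf_weights and min(tf_weights) >= 2
        assert max(tf_weights) <= 1 + k


class TestThresholdByWeight:
    def test_zero_threshold_is_identity(self, small_grn):
        assert threshold_by_weight(small_grn, 0) == small_grn

    def test_selects_exactly_heavy_edges(self):
        fx, grn = _fixture_pipeline("mixed")
        data = CascadeData(
            expression=fx.expression,
            methylation=fx.methylation,
            accessibility=fx.accessibility,
            histone_marks=fx.histone_marks,
            mirna_expression=fx.mirna_expression,
        )
        out, _ = apply_cascade(grn, data, FilterConfig(d=fx.spec.d))
        cut = threshold_by_weight(out, 5)
        assert _keys(cut) == {e.key for e in out.edges() if e.weight >= 5}

    def test_edge_count_non_increasing_in_threshold(self):
        fx, grn = _fixture_pipeline("all_pass")
        data = CascadeData(
            expression=fx.expression,
            methylation=fx.methylation,
            accessibility=fx.accessibility,
            histone_marks=fx.histone_marks,
            mirna_expression=fx.mirna_expression,
        )
        out, _ = apply_cascade(grn, data, FilterConfig(d=fx.spec.d))
        sizes = [len(threshold_by_weight(out, k)) for k in range(0, 9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_threshold_rejected(self, small_grn):
        with pytest.raises(ValueError):
            threshold_by_weight(small_grn, -1)
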