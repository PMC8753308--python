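import pytest
from hypothesis import given, settings, strategies as st

from gmfpm import (
    PanelRegistry,
    PanelResponseGrid,
    ValueSet,
    Variable,
    aggregate_values_ex1,
    build_exercise_grid,
    build_model_from_panel,
    check_conformance,
    decide_inclusion_ex2,
)


class TestAggregateEx1:
    def agg(self, sets):
        return aggregate_values_ex1("v", {1: sets})

    def test_unanimity_is_consensus(self):
        a = self.agg([{"Independent"}] * 4)
        assert a.per_class_values[1] == {"Independent"}
        assert a.aggregation_path[1] == "consensus"

    def test_majority_is_consensus(self):
        a = self.agg([{"A"}, {"A"}, {"A"}, {"B"}])
        assert a.per_class_values[1] == {"A"}
        assert a.aggregation_path[1] == "consensus"

    def test_two_two_tie_keeps_both(self):
        a = self.agg([{"A"}, {"A"}, {"B"}, {"B"}])
        assert a.per_class_values[1] == {"A", "B"}
        assert a.aggregation_path[1] == "tie_or_multiple"

    def test_shared_multi_value_assignments_keep_both(self):
        a = self.agg([{"A", "B"}] * 4)
        assert a.per_class_values[1] == {"A", "B"}
        assert a.aggregation_path[1] == "tie_or_multiple"

    def test_four_way_scatter_unions_all(self):
        a = self.agg([{"A"}, {"B"}, {"C"}, {"D"}])
        assert a.per_class_values[1] == {"A", "B", "C", "D"}
        assert a.aggregation_path[1] == "union_fallback"

    def test_empty_cell_flagged_unresolved(self):
        a = self.agg([set(), set(), set(), set()])
        assert a.unresolved_classes == {1}
        assert 1 not in a.per_class_values

    @given(st.lists(st.sets(st.sampled_from("ABCDE"), min_size=1, max_size=3), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_result_contained_in_union_and_union_fallback_contains_all(self, sets):
        a = aggregate_values_ex1("v", {1: sets})
        union = set().union(*sets)
        assert a.per_class_values[1] <= union
        if a.aggregation_path[1] == "union_fallback":
            assert a.per_class_values[1] == union

    @given(st.permutations(
        [{"A"}, {"A", "B"}, {"B"}, {"C"}]
    ))
    @settings(max_examples=24, deadline=None, derandomize=True)
    def test_permutation_invariant_over_panelists(self, sets):
        a = aggregate_values_ex1("v", {1: list(sets)})
        b = aggregate_values_ex1("v", {1: [{"A"}, {"A", "B"}, {"B"}, {"C"}]})
        assert a.per_class_values == b.per_class_values
        assert a.aggregation_path == b.aggregation_path


class TestDecideEx2:
    @pytest.mark.parametrize(
        "ratings, decision, basis",
        [
            ([4, 4, 3, 5], "include", "consensus_ge3"),
            ([2, 2, 3, 4], "include_split", "split_across_boundary"),
            ([2, 2, "declined", 3], "exclude", "consensus_le2"),
            ([2, 1, 2, 2], "exclude", "consensus_le2"),
            ([3, 3, 2, "declined"], "include", "consensus_ge3"),
            (["declined"] * 4, "exclude", "no_ratings"),
        ],
    )
    def test_decisions(self, ratings, decision, basis):
        d = decide_inclusion_ex2("v", ratings)
        assert (d.decision, d.basis) == (decision, basis)

    def test_rating_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decide_inclusion_ex2("v", [6, 3, 3])


class TestConformance:
    def agg(self, c1, c2, c3):
        from gmfpm import AggregatedValueSet

        return AggregatedValueSet(
            variable="v", per_class_values={1: c1, 2: c2, 3: c3},
            aggregation_path={1: "consensus", 2: "consensus", 3: "consensus"},
        )

    def test_identical_values_despite_inclusion_dropped(self):
        r = check_conformance(self.agg({"Yes"}, {"Yes"}, {"Yes"}),
                              decide_inclusion_ex2("v", [3, 3, 4, 3]))
        assert not r.values_deviate_across_classes
        assert r.rated_ge3 and not r.conformant
        assert r.final_status == "dropped"

    def test_rating_exclusion_with_override_retained(self):
        r = check_conformance(self.agg({"0"}, {"2"}, {"4"}),
                              decide_inclusion_ex2("v", [2, 2, None, 3]),
                              overrides={"v"})
        assert r.final_status == "retained_by_override"

    def test_deviating_and_included_is_conformant(self):
        r = check_conformance(self.agg({"0"}, {"2"}, {"4"}),
                              decide_inclusion_ex2("v", [4, 4, 3, 5]))
        assert r.conformant and r.final_status == "retained"

    def test_variable_mismatch_rejected(self):
        with pytest.raises(ValueError):
            check_conformance(self.agg({"A"}, {"B"}, {"C"}),
                              decide_inclusion_ex2("other", [3, 3, 3]))


class TestPackagedFixture:
    def test_registry_shape(self, panel_fixture):
        reg = panel_fixture["registry"]
        assert len(reg.variables) == 31
        assert reg.n_unique == 14 and reg.n_derived == 17

    def test_each_panelist_completed_93_cells(self, panel_fixture):
        assert [g.n_cells for g in panel_fixture["grids"]] == [93] * 4

    def test_blank_exercise_has_93_rows(self, panel_fixture):
        assert len(build_exercise_grid(panel_fixture["registry"])) == 93

    def test_pipeline_reproduces_reported_outcomes(self, panel_fixture):
        res = build_model_from_panel(
            panel_fixture["grids"], panel_fixture["registry"],
            merges=panel_fixture["merges"], overrides=panel_fixture["overrides"],
        )
        assert res.model.n_variables == 20
        audit = {r["variable"]: r for r in res.audit}
        # One conformance drop: rated >=3 but identical values in every class.
        conf_drops = [
            v for v, r in audit.items()
            if r["status"] == "dropped" and r["decision"] in ("include", "include_split")
            and not r["values_deviate_across_classes"]
        ]
        assert conf_drops == ["General Lower Extremity Muscle Tone"]
        # One rating-based exclusion retained only by discretionary override.
        assert audit["Elbow Tone"]["decision"] == "exclude"
        assert audit["Elbow Tone"]["status"] == "retained_by_override"

    def test_without_override_elbow_tone_is_dropped(self, panel_fixture):
        res = build_model_from_panel(
            panel_fixture["grids"], panel_fixture["registry"],
            merges=panel_fixture["merges"], overrides=[],
        )
        audit = {r["variable"]: r for r in res.audit}
        assert audit["Elbow Tone"]["status"] == "dropped"
        assert res.model.n_variables == 19

    def test_audit_covers_every_registry_variable_exactly_once(self, panel_fixture):
        res = build_model_from_panel(
            panel_fixture["grids"], panel_fixture["registry"],
            merges=panel_fixture["merges"], overrides=panel_fixture["overrides"],
        )
        assert [r["variable"] for r in res.audit] == [
            v.name for v in panel_fixture["registry"].variables
        ]
        statuses = {r["status"].split(":")[0] for r in res.audit}
        assert statuses <= {"retained", "retained_by_override", "dropped", "merged_into"}

    def test_grid_order_invariance(self, panel_fixture):
        kw = dict(merges=panel_fixture["merges"], overrides=panel_fixture["overrides"])
        a = build_model_from_panel(panel_fixture["grids"], panel_fixture["registry"], **kw)
        b = build_model_from_panel(
            list(reversed(panel_fixture["grids"])), panel_fixture["registry"], **kw
        )
        assert a.model == b.model

    def test_built_model_passes_validation(self, panel_fixture):
        res = build_model_from_panel(
            panel_fixture["grids"], panel_fixture["registry"],
            merges=panel_fixture["merges"], overrides=panel_fixture["overrides"],
        )
        assert res.model.validate_invariants().ok


class TestMinimalPipeline:
    def registry(self):
        return PanelRegistry(
            variables=[Variable(name="Tone", kind="unique", domain="Motor Performance",
                                value_set="mas", elements=[{"name": "Tone"}])],
            value_sets=[ValueSet(name="mas", kind="ordinal",
                                 values=["0", "1", "1.5", "2", "3", "4"])],
            domains=["Motor Performance"],
        )

    def test_single_panelist_single_variable(self):
        grid = PanelResponseGrid(
            panelist_id="EXP1",
            ex1={"Tone": {1: {"0"}, 2: {"2"}, 3: {"4"}}},
            ex2={"Tone": 5},
        )
        res = build_model_from_panel([grid], self.registry())
        assert res.model.n_variables == 1
        assert len(res.model.statements) == 3

    def test_merge_directive_with_unknown_variable_rejected(self):
        grid = PanelResponseGrid(
            panelist_id="EXP1", ex1={"Tone": {1: {"0"}, 2: {"2"}, 3: {"4"}}}, ex2={"Tone": 5}
        )
        with pytest.raises(ValueError, match="unknown variable"):
            build_model_from_panel([grid], self.registry(), merges={"Ghost": "Tone"})

    def test_grid_not_covering_registry_rejected(self):
        grid = PanelResponseGrid(panelist_id="EXP1", ex1={}, ex2={})
        with pytest.raises(ValueError, match="does not cover"):
            build_model_from_panel([grid], self.registry())
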