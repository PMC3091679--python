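"""Fold/t-test classification, Venn partitioning and stage categorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import naive_venn, pooled_t_pvalue
from prxarray import (
    DifferentialConfig,
    classify,
    differential_calls,
    normalize,
    organ_enrichment,
    simulate_experiment,
    stage_category,
    ttest_gene,
    venn_partition,
)
from prxarray.simulate import SampleSpec, SimulationDesign


class TestClassify:
    @pytest.mark.parametrize(
        "fold, p, expected",
        [
            (1.3, 0.01, "up"),       # threshold inclusive on the up side
            (0.7, 0.01, "down"),     # and on the down side
            (1.299, 0.01, "stable"),
            (0.701, 0.01, "stable"),
            (5.0, 0.20, "stable"),   # fails significance
            (0.1, 0.05, "stable"),   # p = alpha is not significant
            (1.0, 0.001, "stable"),
        ],
    )
    def test_rule(self, fold, p, expected):
        assert classify(fold, p) == expected

    def test_custom_thresholds(self):
        cfg = DifferentialConfig(up_threshold=2.0, down_threshold=0.5, alpha=0.01)
        assert classify(1.5, 0.001, cfg) == "stable"
        assert classify(2.0, 0.001, cfg) == "up"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify(-1.0, 0.01)
        with pytest.raises(ValueError):
            classify(2.0, 1.5)

    def test_monotonicity_in_fold(self):
        """With p fixed below alpha, increasing the fold never demotes a call."""
        rank = {"down": -1, "stable": 0, "up": 1}
        folds = np.linspace(0.1, 3.0, 60)
        calls = [rank[classify(f, 0.01)] for f in folds]
        assert all(b >= a for a, b in zip(calls, calls[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DifferentialConfig(up_threshold=0.9)
        with pytest.raises(ValueError):
            DifferentialConfig(alpha=1.5)
        with pytest.raises(ValueError):
            DifferentialConfig(organ_enrichment_fold=0.5)


class TestTTest:
    def test_identical_constant_groups_return_one(self):
        assert ttest_gene([1, 1, 1], [1, 1, 1]) == 1.0

    def test_constant_unequal_groups_maximally_significant(self):
        p = ttest_gene([2, 2, 2], [1, 1, 1])
        assert 0 < p < 1e-300

    def test_strong_separation(self):
        assert ttest_gene([10, 11, 9], [1, 1.1, 0.9]) < 0.001

    @settings(max_examples=40, deadline=None)
    @given(
        a=st.lists(st.floats(0.1, 100), min_size=2, max_size=6),
        b=st.lists(st.floats(0.1, 100), min_size=2, max_size=6),
    )
    def test_matches_textbook_pooled_formula(self, a, b):
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return  # degenerate branch tested separately
        assert ttest_gene(a, b) == pytest.approx(pooled_t_pvalue(a, b), rel=1e-9)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="not_evaluable"):
            ttest_gene([1.0], [1.0, 2.0])


class TestVenn:
    def _calls_frame(self, mapping):
        return pd.DataFrame(
            [
                {"gene_id": g, "comparison": c, "fold": 1.0, "p_value": 1.0, "call": v}
                for (g, c), v in mapping.items()
            ]
        )

    def test_matches_bruteforce_on_hand_instance(self):
        mapping = {
            ("g1", "c1"): "up", ("g1", "c2"): "up",
            ("g2", "c1"): "down", ("g2", "c2"): "stable",
            ("g3", "c1"): "not_evaluable", ("g3", "c2"): "down",
        }
        venn = venn_partition(self._calls_frame(mapping))
        expected = naive_venn(mapping, ["c1", "c2"])
        assert {sig: set(genes) for sig, genes in venn.cells.items()} == expected

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_matches_bruteforce_on_random_instances(self, data):
        n_genes = data.draw(st.integers(1, 10))
        n_comp = data.draw(st.integers(2, 3))
        genes = [f"g{i}" for i in range(n_genes)]
        comps = [f"c{j}" for j in range(n_comp)]
        mapping = {
            (g, c): data.draw(
                st.sampled_from(["up", "down", "stable", "not_evaluable"])
            )
            for g in genes
            for c in comps
        }
        venn = venn_partition(self._calls_frame(mapping))
        assert {sig: set(v) for sig, v in venn.cells.items()} == naive_venn(mapping, comps)
        # conservation: cells are disjoint and exhaust the universe
        sizes = sum(len(v) for v in venn.cells.values())
        assert sizes == n_genes

    def test_all_stable_single_cell(self):
        mapping = {(f"g{i}", c): "stable" for i in range(5) for c in ("c1", "c2")}
        venn = venn_partition(self._calls_frame(mapping))
        assert set(venn.cells) == {("neither", "neither")}
        assert len(venn.cells[("neither", "neither")]) == 5

    def test_duplicate_calls_rejected(self):
        frame = self._calls_frame({("g1", "c1"): "up", ("g1", "c2"): "up"})
        frame = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            venn_partition(frame)

    def test_missing_calls_rejected(self):
        frame = self._calls_frame(
            {("g1", "c1"): "up", ("g1", "c2"): "up", ("g2", "c1"): "down"}
        )
        with pytest.raises(ValueError, match="missing"):
            venn_partition(frame)


class TestStageCategory:
    def _expr(self, profiles, detected=True):
        """Build an ExpressionMatrix by simulating zero intensities manually."""
        import prxarray.expression as ex

        stages = ["F1", "F2", "F3", "S1", "S2"]
        values = pd.DataFrame(profiles, index=stages).T
        values.loc["ctrl"] = 1.0
        values.loc["neg"] = 0.01
        det = pd.DataFrame(detected, index=values.index, columns=values.columns)
        det.loc["neg"] = False
        rr = pd.DataFrame(
            [
                (g, s, r, values.at[g, s])
                for g in values.index
                for s in stages
                for r in (1, 2, 3)
            ],
            columns=["gene_id", "sample_id", "replicate", "ratio"],
        )
        return ex.ExpressionMatrix(values, rr, det, "ctrl", "neg")

    def test_single_dominant_stage(self):
        expr = self._expr({"g1": [10, 2, 2, 2, 2]})
        cats = stage_category(expr, ["F1", "F2", "F3", "S1", "S2"])
        assert cats["g1"] == "Highest in F1"

    def test_flat_profile_is_stable(self):
        expr = self._expr({"g1": [1, 1, 1, 1, 1]})
        cats = stage_category(expr, ["F1", "F2", "F3", "S1", "S2"])
        assert cats["g1"] == "Stable F1-S2"

    def test_contiguous_band_around_argmax(self):
        """Values within down_threshold × max of the peak extend the block."""
        expr = self._expr({"g1": [2, 9, 8.5, 9.2, 2]})
        cats = stage_category(expr, ["F1", "F2", "F3", "S1", "S2"])
        assert cats["g1"] == "Highest in F2-S1"

    def test_ties_break_toward_earlier_stage(self):
        expr = self._expr({"g1": [9, 1, 9, 1, 1]})
        cats = stage_category(expr, ["F1", "F2", "F3", "S1", "S2"])
        assert cats["g1"] == "Highest in F1"

    def test_all_undetected_not_evaluable(self):
        expr = self._expr({"g1": [0.01] * 5}, detected=False)
        cats = stage_category(expr, ["F1", "F2", "F3", "S1", "S2"])
        assert cats["g1"] == "not_evaluable"

    def test_missing_stage_rejected(self, flower_design):
        exp, _ = simulate_experiment(flower_design)
        expr = normalize(exp)
        with pytest.raises(ValueError, match="S9"):
            stage_category(expr, ["F1", "S9"])


class TestOrganEnrichment:
    def _design(self):
        return SimulationDesign(
            gene_ids=["gA", "gB", "gC"],
            samples=[
                SampleSpec("F1", "flower"), SampleSpec("F2", "flower"),
                SampleSpec("yL", "leaf"), SampleSpec("mL", "leaf"),
            ],
            noise_cv=0.0,
            baseline_range=(0.5, 2.0),
            seed=3,
        )

    def test_fourfold_cutoff(self):
        # gA: 8x higher in flowers; gB: just below the cutoff; gC: flat
        effects = {("gA", "yL"): 0.125, ("gA", "mL"): 0.125,
                   ("gB", "yL"): 1 / 3.9, ("gB", "mL"): 1 / 3.9}
        exp, _ = simulate_experiment(self._design(), effects)
        expr = normalize(exp)
        result = organ_enrichment(expr, ["F1", "F2"], ["yL", "mL"])
        assert result.at["gA", "label"] == "a-enriched"
        assert result.at["gB", "label"] == "neither"
        assert result.at["gC", "label"] == "neither"

    def test_group_swap_symmetry(self):
        effects = {("gA", "yL"): 0.125, ("gA", "mL"): 0.125}
        exp, _ = simulate_experiment(self._design(), effects)
        expr = normalize(exp)
        ab = organ_enrichment(expr, ["F1", "F2"], ["yL", "mL"])
        ba = organ_enrichment(expr, ["yL", "mL"], ["F1", "F2"])
        swap = {"a-enriched": "b-enriched", "b-enriched": "a-enriched",
                "neither": "neither"}
        assert [swap[x] for x in ab["label"]] == list(ba["label"])

    def test_overlapping_groups_rejected(self, flower_design):
        exp, _ = simulate_experiment(flower_design)
        expr = normalize(exp)
        with pytest.raises(ValueError, match="overlap"):
            organ_enrichment(expr, ["F1", "F2"], ["F2", "S1"])


class TestDifferentialCalls:
    def test_conservation_per_comparison(self, flower_design):
        """Every gene receives exactly one call per comparison."""
        exp, _ = simulate_experiment(flower_design)
        calls = differential_calls(normalize(exp), "F1")
        counts = calls.groupby("comparison")["call"].count()
        assert (counts == 73).all()
        assert set(calls["call"]) <= {"up", "down", "stable", "not_evaluable"}

    def test_zero_noise_calls_match_truth(self, noiseless_design):
        effects = {("AtPrx05", "F2"): 3.0, ("AtPrx06", "F2"): 0.33}
        exp, truth = simulate_experiment(noiseless_design, effects)
        calls = differential_calls(normalize(exp), "F1", samples=["F2"])
        by_gene = calls.set_index("gene_id")["call"]
        assert by_gene["AtPrx05"] == "up"
        assert by_gene["AtPrx06"] == "down"
        stable = [g for g in noiseless_design.gene_ids
                  if g not in ("AtPrx05", "AtPrx06")]
        assert (by_gene[stable] == "stable").all()
        assert truth.true_class[("AtPrx05", "F2_vs_F1")] == "up"
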