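"""Simulator correctness: expected signals, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

from cnevolve import simulate as sim
from cnevolve.simulate import CloneTree, ConflictError, EventSpec, SnvSpec


def two_clone_tree(purity=1.0, fraction=1.0):
    return CloneTree(
        parent={"trunk": None, "sub": "trunk"},
        fractions={"s": {"trunk": purity * (1 - fraction), "sub": purity * fraction}},
    )


GENOME = {"chr1": 10_000_000}
LOSS = lambda clone: EventSpec("chr1", 2_000_000, 6_000_000, "het_loss", clone)


class TestCloneTree:
    def test_fraction_sum_validation(self):
        with pytest.raises(ValueError, match="sum above 1"):
            CloneTree(parent={"a": None}, fractions={"s": {"a": 1.2}})

    def test_carrier_fraction_includes_descendants(self):
        tree = CloneTree(
            parent={"a": None, "b": "a", "c": "b"},
            fractions={"s": {"a": 0.2, "b": 0.3, "c": 0.4}},
        )
        assert tree.carrier_fraction("s", "a") == pytest.approx(0.9)
        assert tree.carrier_fraction("s", "b") == pytest.approx(0.7)
        assert tree.purity("s") == pytest.approx(0.9)

    def test_carrier_fraction_monotone_down_lineage(self, scenario):
        tree = scenario.tree
        for s in tree.samples:
            for c, p in tree.parent.items():
                if p is not None:
                    assert tree.carrier_fraction(s, c) <= tree.carrier_fraction(s, p) + 1e-12


class TestSimulateCounts:
    def test_no_events_pure_tumor_ratio_one(self):
        tree = two_clone_tree(1.0, 1.0)
        res = sim.simulate_counts(tree, [], depth=500, genome=GENOME, seed=0)
        assert np.allclose(res["s"].truth_copy, 2.0)

    def test_clonal_het_loss_ratio_half(self):
        """A clonal heterozygous loss at purity 1 halves the tumor/normal ratio."""
        tree = two_clone_tree(1.0, 1.0)
        res = sim.simulate_counts(tree, [LOSS("sub")], depth=500, genome=GENOME, seed=0)
        w = res["s"].windows
        inside = (w.start >= 2_000_000) & (w.end <= 6_000_000)
        assert np.allclose(res["s"].truth_copy[inside], 1.0)
        assert np.allclose(res["s"].truth_copy[~inside.to_numpy()], 2.0)

    def test_subclonal_loss_cell_counting(self):
        # f=0.4 of tumor cells, purity 0.75: expected copy 2 - 0.75*0.4 = 1.7
        tree = two_clone_tree(0.75, 0.4)
        res = sim.simulate_counts(tree, [LOSS("sub")], depth=500, genome=GENOME, seed=0)
        w = res["s"].windows
        inside = (w.start >= 2_000_000) & (w.end <= 6_000_000)
        assert np.allclose(res["s"].truth_copy[inside], 1.7)

    def test_counts_converge_to_truth_at_high_depth(self):
        tree = two_clone_tree(0.8, 0.6)
        res = sim.simulate_counts(tree, [LOSS("sub")], depth=10_000, genome=GENOME, seed=5)
        w = res["s"].windows
        ratio = w.n_tumor / w.n_normal
        assert np.abs(ratio - res["s"].truth_copy / 2).mean() < 0.01

    def test_conflicting_same_haplotype_events_rejected(self):
        tree = two_clone_tree()
        a = EventSpec("chr1", 1_000_000, 3_000_000, "het_loss", "trunk", allele=0)
        b = EventSpec("chr1", 2_000_000, 4_000_000, "het_loss", "sub", allele=0)
        with pytest.raises(ConflictError, match="overlaps"):
            sim.simulate_counts(tree, [a, b], genome=GENOME, seed=0)
        # different haplotypes are fine
        c = EventSpec("chr1", 2_000_000, 4_000_000, "het_loss", "sub", allele=1)
        sim.simulate_counts(tree, [a, c], genome=GENOME, seed=0)

    def test_event_retention_in_descendants(self, scenario):
        """Every ancestral event is present wherever a descendant clone lives."""
        tree = scenario.tree
        for e in scenario.events:
            for s in tree.samples:
                if any(
                    tree.fractions[s].get(d, 0) > 0 for d in tree.descendants(e.clone)
                ):
                    assert scenario.event_carrier(s, e) > 0

    def test_determinism(self):
        tree = two_clone_tree(0.8, 0.5)
        a = sim.simulate_counts(tree, [LOSS("sub")], genome=GENOME, seed=42)
        b = sim.simulate_counts(tree, [LOSS("sub")], genome=GENOME, seed=42)
        pd.testing.assert_frame_equal(a["s"].windows, b["s"].windows)


class TestSimulateSnps:
    def test_expected_baf_outside_events_is_half(self):
        tree = two_clone_tree(1.0, 1.0)
        snps = sim.simulate_snp_counts(tree, [LOSS("sub")], n_sites=300, depth=100,
                                       genome=GENOME, seed=1, frac_hom=0, frac_unknown=0)
        df = snps["s"]
        outside = (df.pos < 2_000_000) | (df.pos >= 6_000_000)
        assert np.allclose(df.truth_baf[outside], 0.5)

    def test_clonal_loss_splits_baf_to_zero_or_one(self):
        tree = two_clone_tree(1.0, 1.0)
        snps = sim.simulate_snp_counts(tree, [LOSS("sub")], n_sites=300, depth=100,
                                       genome=GENOME, seed=1, frac_hom=0, frac_unknown=0)
        df = snps["s"]
        inside = (df.pos >= 2_000_000) & (df.pos < 6_000_000)
        assert set(np.round(df.truth_baf[inside], 6)) <= {0.0, 1.0}

    def test_half_population_loss_minor_baf_one_third(self):
        # p*f = 0.5 -> minor expected BAF (1-0.5)/(2-0.5) = 1/3
        tree = two_clone_tree(1.0, 0.5)
        snps = sim.simulate_snp_counts(tree, [LOSS("sub")], n_sites=400, depth=100,
                                       genome=GENOME, seed=1, frac_hom=0, frac_unknown=0)
        df = snps["s"]
        inside = (df.pos >= 2_000_000) & (df.pos < 6_000_000)
        vals = set(np.round(df.truth_baf[inside], 6))
        assert vals <= {round(1 / 3, 6), round(2 / 3, 6)}

    def test_observed_baf_bimodal_at_clonal_loss(self):
        tree = two_clone_tree(1.0, 1.0)
        snps = sim.simulate_snp_counts(tree, [LOSS("sub")], n_sites=2000, depth=100,
                                       genome=GENOME, seed=7, frac_hom=0, frac_unknown=0)
        df = snps["s"]
        inside = (df.pos >= 2_000_000) & (df.pos < 6_000_000)
        baf = df.b_depth_t[inside] / (df.a_depth_t[inside] + df.b_depth_t[inside])
        lo, hi = baf[df.truth_baf[inside] < 0.5], baf[df.truth_baf[inside] > 0.5]
        assert lo.mean() < 0.05 and hi.mean() > 0.95

    def test_rejects_nonpositive_sites(self):
        with pytest.raises(ValueError):
            sim.simulate_snp_counts(two_clone_tree(), [], n_sites=0, genome=GENOME, seed=0)


class TestSimulateSnvs:
    def test_absent_clone_has_zero_vaf(self):
        tree = CloneTree(parent={"a": None, "b": "a"},
                         fractions={"s1": {"a": 0.8}, "s2": {"a": 0.4, "b": 0.4}})
        snvs = [SnvSpec("chr1", 500_000, "A", "T", "b")]
        df = sim.simulate_snvs(tree, snvs, depth=200, seed=0)
        assert df.loc[0, "truth_vaf_s1"] == 0
        assert df.loc[0, "alt_s1"] == 0

    def test_clonal_vaf_is_half_purity(self):
        # p=0.8, f=1 -> expected VAF 0.40
        tree = two_clone_tree(0.8, 1.0)
        df = sim.simulate_snvs(tree, [SnvSpec("chr1", 1000, "C", "T", "sub")],
                               depth=5000, seed=3)
        assert df.loc[0, "truth_vaf_s"] == pytest.approx(0.40)
        assert df.loc[0, "alt_s"] / df.loc[0, "depth_s"] == pytest.approx(0.40, abs=0.03)


class TestScenarioIO:
    def test_yaml_round_trip(self, scenario, tmp_path):
        path = tmp_path / "scenario.yaml"
        sim.scenario_to_yaml(scenario, path)
        back = sim.scenario_from_yaml(path)
        assert back.tree.parent == scenario.tree.parent
        assert back.tree.fractions == scenario.tree.fractions
        assert len(back.events) == len(scenario.events)
        assert back.events[0] == scenario.events[0]
        assert back.genome == scenario.genome
        assert back.stage_order == scenario.stage_order

    def test_four_stage_scenario_structure(self, scenario):
        assert scenario.stage_order == ["dcis1", "dcis2", "primary", "metastasis"]
        # 17 shallow subclonal losses + 1 homozygous loss in the burst clone
        f_events = [e for e in scenario.events if e.clone == "F"]
        assert sum(e.kind == "het_loss" for e in f_events) == 17
        assert sum(e.kind == "hom_loss" for e in f_events) == 1
        # purification: metastasis founder subclonal in primary, clonal in met
        t = scenario.tree
        assert 0.1 < t.carrier_fraction("primary", "D") / t.purity("primary") < 0.5
        assert t.carrier_fraction("metastasis", "D") == pytest.approx(t.purity("metastasis"))
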