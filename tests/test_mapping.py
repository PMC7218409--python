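import numpy as np
import pytest
from scipy.stats import kendalltau

from fretmap.mapping import (AnchorConstraint, MapConfig, PairResult,
                             TerminusNode, apply_ruler_evidence, assign_layers,
                             brute_force_embedding, build_graph, find_networks,
                             infer_orientation, planted_geometry_instance)


def node(p, t="N", v="full"):
    return TerminusNode(p, t, v)


def pos(a, b, mean=5.0, values=None):
    return PairResult(a, b, mean_E_pct=mean, ci95_halfwidth_pct=0.5,
                      verdict="positive", values_pct=values)


def neg(a, b, values=None):
    return PairResult(a, b, mean_E_pct=0.0, ci95_halfwidth_pct=0.5,
                      verdict="negative", values_pct=values)


class TestGraph:
    def test_edges_only_for_positive_verdicts(self):
        rows = [pos(node("A"), node("B")), neg(node("B"), node("C")),
                pos(node("C"), node("D"))]
        g = build_graph(rows)
        assert g.number_of_edges() == 2
        assert g.number_of_nodes() == 4
        assert g[node("A")][node("B")]["weight"] == 5.0

    def test_classification_from_mean_and_ci(self):
        row = PairResult(node("A"), node("B"), mean_E_pct=2.5,
                         ci95_halfwidth_pct=0.6)
        assert row.verdict == "positive"
        row2 = PairResult(node("A"), node("B"), mean_E_pct=0.1,
                          ci95_halfwidth_pct=0.7)
        assert row2.verdict == "negative"

    def test_conflicting_duplicate_verdicts_raise(self):
        rows = [pos(node("A"), node("B")), neg(node("A"), node("B"))]
        with pytest.raises(ValueError, match="conflicting"):
            build_graph(rows)

    def test_terminus_nodes_hash_on_identity_not_role(self):
        a = TerminusNode("Sla2", "N", role="membrane_anchor")
        b = TerminusNode("Sla2", "N")
        assert a == b and hash(a) == hash(b)
        assert TerminusNode("Sla2", "N") != TerminusNode("Sla2", "C")
        assert TerminusNode("Pan1", "C") != TerminusNode("Pan1", "C", "1-1050")


class TestNetworks:
    def test_two_triangles_and_one_disjoint_edge(self):
        t1 = [pos(node("A"), node("B")), pos(node("B"), node("C")),
              pos(node("A"), node("C"))]
        t2 = [pos(node("D"), node("E")), pos(node("E"), node("F")),
              pos(node("D"), node("F"))]
        iso = [pos(node("X"), node("Y"))]
        dec = find_networks(build_graph(t1 + t2 + iso))
        assert len(dec.networks) == 2
        assert len(dec.isolated_pairs) == 1
        assert dec.singletons == []

    def test_singletons_are_tested_but_unconnected(self):
        dec = find_networks(build_graph([neg(node("A"), node("B"))]))
        assert dec.networks == [] and dec.isolated_pairs == []
        assert len(dec.singletons) == 2

    def test_membership_invariant_to_row_order(self, rng):
        rows = [pos(node(f"P{i}"), node(f"P{(i + 1) % 5}")) for i in range(5)]
        rows += [pos(node("Q1"), node("Q2"))]
        base = find_networks(build_graph(rows))
        for _ in range(3):
            perm = [rows[i] for i in rng.permutation(len(rows))]
            dec = find_networks(build_graph(perm))
            assert dec.networks == base.networks
            assert dec.isolated_pairs == base.isolated_pairs


class TestOrientation:
    @staticmethod
    def graph_with_termini(vals_n, vals_c):
        ref = node("Ref", "C")
        rows = [pos(node("P", "N"), ref, float(np.mean(vals_n)), list(vals_n)),
                pos(node("P", "C"), ref, float(np.mean(vals_c)), list(vals_c))]
        return build_graph(rows), ref

    def test_equal_means_unresolved(self):
        g, ref = self.graph_with_termini([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        call = infer_orientation(g, "P", ref)
        assert call.closer == "unresolved"

    def test_swapping_termini_swaps_the_call(self, rng):
        a = list(rng.normal(6.7, 2.0, size=20))
        b = list(rng.normal(2.8, 2.0, size=20))
        g1, ref = self.graph_with_termini(a, b)
        g2, _ = self.graph_with_termini(b, a)
        c1 = infer_orientation(g1, "P", ref)
        c2 = infer_orientation(g2, "P", ref)
        assert c1.closer == "N" and c2.closer == "C"
        assert c1.p == pytest.approx(c2.p)

    def test_gts1_like_separation_called_with_significance(self, rng):
        """Means 6.7 vs 2.8 with CIs +-1.6/+-1.5 at n = 20: the closer
        terminus is called at p < 0.05 in >= 90% of replicates."""
        sd_n = 1.6 * np.sqrt(20) / 2.093
        sd_c = 1.5 * np.sqrt(20) / 2.093
        wins = 0
        for _ in range(50):
            g, ref = self.graph_with_termini(rng.normal(6.7, sd_n, 20),
                                             rng.normal(2.8, sd_c, 20))
            call = infer_orientation(g, "P", ref)
            wins += call.closer == "N" and call.p < 0.05
        assert wins >= 45

    def test_means_only_flagged_low_confidence(self):
        ref = node("Ref", "C")
        rows = [pos(node("P", "N"), ref, 6.0), pos(node("P", "C"), ref, 2.0)]
        call = infer_orientation(build_graph(rows), "P", ref)
        assert call.closer == "N"
        assert call.low_confidence

    def test_missing_terminus_raises(self):
        ref = node("Ref", "C")
        g = build_graph([pos(node("P", "N"), ref, 5.0)])
        with pytest.raises(ValueError):
            infer_orientation(g, "P", ref)


class TestRulers:
    def test_full_negative_truncated_positive_emits_bounds(self):
        clc = node("Clc1", "C")
        rows = [neg(node("Pan1", "C"), clc),
                pos(node("Pan1", "C", "1-1050"), clc)]
        bounds, conflicts = apply_ruler_evidence(rows, d_max_nm=10.0)
        assert conflicts == []
        kinds = {(str(b.terminus), b.kind) for b in bounds}
        assert ("Pan1-C", "min") in kinds
        assert ("Pan1(1-1050)-C", "max") in kinds
        assert all(b.distance_nm == 10.0 for b in bounds)

    def test_no_truncation_pairs_no_bounds(self):
        rows = [neg(node("A", "C"), node("M", "C")),
                pos(node("B", "C"), node("M", "C"))]
        bounds, _ = apply_ruler_evidence(rows)
        assert bounds == []

    def test_truncation_series_bounds_follow_length(self):
        m = node("M", "C")
        rows = [neg(node("P", "C"), m),                 # full length: no FRET
                pos(node("P", "C", "1-900"), m),        # shortened: FRET
                pos(node("P", "C", "1-600"), m)]        # shorter still: FRET
        bounds, conflicts = apply_ruler_evidence(rows)
        assert conflicts == []
        by_variant = {b.terminus.variant: b.kind for b in bounds}
        assert by_variant == {"full": "min", "1-900": "max", "1-600": "max"}

    def test_contradictory_series_reported(self):
        m = node("M", "C")
        rows = [pos(node("P", "C"), m),                 # longer positive...
                neg(node("P", "C", "1-600"), m)]        # ...shorter negative
        bounds, conflicts = apply_ruler_evidence(rows)
        assert len(conflicts) == 1
        assert "longer construct" in conflicts[0]


class TestEmbedding:
    def test_chain_midpoint_forced_by_two_constraints(self):
        a, b, c = node("A"), node("B"), node("C")
        g = build_graph([pos(a, b, mean=None), pos(b, c, mean=None)])
        anchors = [AnchorConstraint(a, position_nm=0.0),
                   AnchorConstraint(c, position_nm=20.0)]
        asg = assign_layers(g, anchors, MapConfig(x_max_nm=30.0))
        assert asg.coordinates_nm[b] == pytest.approx(10.0, abs=0.5)

    def test_optimizer_matches_grid_oracle_on_small_instances(self):
        for k in range(3):
            rows, anchors, _ = planted_geometry_instance(5, k, x_span=35.0)
            g = build_graph(rows)
            cfg = MapConfig(seed=k, x_max_nm=40.0)
            asg = assign_layers(g, anchors, cfg)
            _, brute_val = brute_force_embedding(g, anchors, cfg)
            assert asg.objective <= brute_val * 1.01 + 1e-9

    def test_planted_ordering_recovered(self):
        rows, anchors, truth = planted_geometry_instance(12, 3)
        asg = assign_layers(build_graph(rows), anchors, MapConfig(seed=3))
        nodes = list(truth)
        tau = kendalltau([truth[n] for n in nodes],
                         [asg.coordinates_nm[n] for n in nodes]).statistic
        assert tau >= 0.9

    def test_unconstrained_node_reported_unplaced(self):
        a, b = node("A"), node("B")
        lone = node("Z")
        g = build_graph([pos(a, b, mean=None)])
        g.add_node(lone)
        asg = assign_layers(g, [AnchorConstraint(a, position_nm=0.0),
                                AnchorConstraint(b, position_nm=5.0)],
                            MapConfig())
        assert asg.unplaced == [lone]
        assert lone not in asg.coordinates_nm

    def test_layer_labels_follow_intervals(self):
        a, b = node("A"), node("B")
        g = build_graph([pos(a, b, mean=None)])
        asg = assign_layers(g, [AnchorConstraint(a, position_nm=1.0),
                                AnchorConstraint(b, position_nm=30.0)],
                            MapConfig())
        assert asg.layer_labels[a] == "membrane_binding"
        assert asg.layer_labels[b] == "actin_regulatory"

    def test_determinism_same_seed_same_coordinates(self):
        rows, anchors, _ = planted_geometry_instance(8, 5)
        g1 = assign_layers(build_graph(rows), anchors, MapConfig(seed=11))
        g2 = assign_layers(build_graph(rows), anchors, MapConfig(seed=11))
        assert g1.coordinates_nm == g2.coordinates_nm

    def test_two_anchors_required(self):
        g = build_graph([pos(node("A"), node("B"), mean=None)])
        with pytest.raises(ValueError):
            assign_layers(g, [AnchorConstraint(node("A"), position_nm=0.0)],
                          MapConfig())


class TestConfigValidation:
    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError):
            MapConfig(layers=(("a", 0, 10), ("b", 5, 20)))

    def test_anchor_needs_exactly_one_position_spec(self):
        with pytest.raises(ValueError):
            AnchorConstraint(node("A"))
        with pytest.raises(ValueError):
            AnchorConstraint(node("A"), position_nm=1.0, interval_nm=(0, 2))
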