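"""Correlation matrices, differential networks, Tanimoto grouping, overlays."""

import numpy as np
import pandas as pd
import pytest

from metanmr import datasets, network, stats, synth
from metanmr.containers import QuantMatrix
from .conftest import brute_force_pearson, make_two_group_config


def _quant(values_by_group, features=None):
    rows, groups, sids = [], [], []
    for g, vals in values_by_group.items():
        vals = np.atleast_2d(vals)
        rows.append(vals)
        groups += [g] * vals.shape[0]
        sids += [f"{g}{i}" for i in range(vals.shape[0])]
    vals = np.vstack(rows)
    features = features or [f"f{j}" for j in range(vals.shape[1])]
    return QuantMatrix(sids, groups, features, vals)


def _corr_pair(r, n, seed):
    """Two vectors with population correlation r (Cholesky construction)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]
    return x, y


class TestGroupCorrelations:
    def test_unit_diagonal_and_symmetry(self, study_cohort):
        r, p = network.group_correlations(study_cohort, "model")
        assert np.allclose(np.diag(r.to_numpy()), 1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()

    def test_exact_linear_relation_gives_unit_r(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = _quant({"g": np.column_stack([x, 2 * x + 1])})
        r, p = network.group_correlations(m, "g")
        assert r.iat[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert p.iat[0, 1] < 1e-10

    def test_matches_textbook_formula_on_hand_sized_data(self):
        rng = np.random.default_rng(7)
        vals = rng.random((5, 3))
        m = _quant({"g": vals})
        r, _ = network.group_correlations(m, "g")
        for i in range(3):
            for j in range(3):
                assert r.iat[i, j] == pytest.approx(
                    brute_force_pearson(vals[:, i], vals[:, j]), abs=1e-12
                )

    def test_brute_force_equivalence_on_random_instances(self):
        """All entries match a two-pass Pearson implementation to 1e-12."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            vals = rng.random((rng.integers(5, 15), 4))
            m = _quant({"g": vals})
            r, _ = network.group_correlations(m, "g")
            i, j = rng.integers(0, 4, 2)
            assert r.iat[i, j] == pytest.approx(
                brute_force_pearson(vals[:, i], vals[:, j]), abs=1e-12
            )

    def test_zero_variance_metabolite_flagged_na(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        m = _quant({"g": vals})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = network.group_correlations(m, "g")
        assert np.isnan(r.iat[0, 1]) and np.isnan(p.iat[0, 1])

    def test_too_few_samples_rejected(self):
        m = _quant({"g": np.random.default_rng(0).random((3, 2))})
        with pytest.raises(ValueError, match="at least 4"):
            network.group_correlations(m, "g")


class TestDifferentialNetwork:
    def test_equal_correlations_give_no_delta_edge(self):
        x, y = _corr_pair(0.9, 30, 1)
        vals = np.column_stack([x, y]) + 10.0
        m = _quant({"A": vals, "B": vals})
        net = network.differential_network(m, ("A", "B"), mode="delta_r")
        assert net.edge_pairs("diff_corr") == set()

    def test_opposite_correlations_linked_with_positive_sign(self):
        """r_A ~ +0.9, r_B ~ -0.9 at n=50: delta ~ 1.8 > 0.65 with a
        significant Fisher-z test (oracle: direct Pearson + Fisher-z)."""
        from scipy.stats import norm

        xa, ya = _corr_pair(0.9, 50, 2)
        xb, yb = _corr_pair(-0.9, 50, 3)
        m = _quant({"A": np.column_stack([xa, ya]) + 10,
                    "B": np.column_stack([xb, yb]) + 10})
        net = network.differential_network(m, ("A", "B"), mode="delta_r")
        assert ("f0", "f1") in net.edge_pairs("diff_corr")
        edge = net.edges.iloc[0]
        ra = brute_force_pearson(xa, ya)
        rb = brute_force_pearson(xb, yb)
        assert edge.delta_r == pytest.approx(ra - rb, abs=1e-12)
        assert edge.sign == 1 and edge.width == pytest.approx(abs(ra - rb))
        z = abs(np.arctanh(ra) - np.arctanh(rb)) / np.sqrt(2 / 47)
        assert edge.p == pytest.approx(2 * norm.sf(z), rel=1e-9)

    def test_delta_below_threshold_is_not_linked(self):
        """|delta_r| = 0.60 stays unlinked at the 0.65 threshold."""
        n = 2000  # large n: sample r pinned near population r
        xa, ya = _corr_pair(0.60, n, 4)
        xb, yb = _corr_pair(0.0, n, 5)
        m = _quant({"A": np.column_stack([xa, ya]) + 10,
                    "B": np.column_stack([xb, yb]) + 10})
        net = network.differential_network(m, ("A", "B"), mode="delta_r")
        assert abs(net.meta["n_a"] - n) == 0
        assert ("f0", "f1") not in net.edge_pairs("diff_corr")

    def test_per_pair_mode_uses_group_a_correlation(self):
        xa, ya = _corr_pair(0.9, 40, 6)
        xb, yb = _corr_pair(0.9, 40, 7)
        m = _quant({"A": np.column_stack([xa, ya]) + 10,
                    "B": np.column_stack([xb, yb]) + 10})
        assert network.differential_network(m, ("A", "B"), mode="delta_r").edges.empty
        per = network.differential_network(m, ("A", "B"), mode="per_pair_r")
        assert ("f0", "f1") in per.edge_pairs("diff_corr")

    def test_antisymmetry_of_reversed_comparison(self):
        cfg = make_two_group_config(
            n_per_group=20, p=8, corr_blocks=[("A", ["m00", "m01"], 0.9)], seed=9
        )
        q = synth.simulate_concentrations(cfg)
        ab = network.differential_network(q, ("A", "B"))
        ba = network.differential_network(q, ("B", "A"))
        assert ab.edge_pairs() == ba.edge_pairs()
        merged = ab.edges.merge(ba.edges, on=["source", "target"])
        assert np.allclose(merged["delta_r_x"], -merged["delta_r_y"])

    def test_threshold_monotonicity(self):
        cfg = make_two_group_config(
            n_per_group=15, p=10,
            corr_blocks=[("A", ["m00", "m01", "m02"], 0.85)], seed=10,
        )
        q = synth.simulate_concentrations(cfg)
        edges = [
            network.differential_network(q, ("A", "B"), threshold=t).edge_pairs()
            for t in (0.5, 0.65, 0.9)
        ]
        assert edges[2] <= edges[1] <= edges[0]

    def test_delta_mode_recovers_group_specific_block_at_n50(self):
        """The delta rule recovers an r=0.9-vs-independent block reliably
        once n is large enough that sampling noise of r cannot eat the 0.65
        margin (at n=20 the rule itself only reaches ~0.86 sensitivity)."""
        hits = 0
        reps = 25
        for rep in range(reps):
            cfg = make_two_group_config(
                n_per_group=50, p=6, corr_blocks=[("A", ["m00", "m01"], 0.9)],
                seed=3000 + rep,
            )
            q = synth.simulate_concentrations(cfg)
            net = network.differential_network(q, ("A", "B"), mode="delta_r")
            hits += ("m00", "m01") in net.edge_pairs("diff_corr")
        assert hits / reps >= 0.8

    def test_node_colors_follow_stats_table(self):
        cfg = make_two_group_config(
            n_per_group=15, p=6, effects={"m00": 1.5, "m01": -1.5}, noise_cv=0.05,
            seed=11,
        )
        q = synth.simulate_concentrations(cfg)
        st = stats.stats_table(q, [("B", "A")])
        net = network.differential_network(q, ("B", "A"), stats=st)
        directions = net.nodes.set_index("metabolite")["direction"]
        assert directions["m00"] == "increased"
        assert directions["m01"] == "decreased"
        assert directions["m03"] == "ns"

    def test_bad_arguments_rejected(self, study_cohort):
        with pytest.raises(ValueError, match="mode"):
            network.differential_network(study_cohort, ("model", "sham"),
                                         mode="nope")
        with pytest.raises(ValueError, match="threshold"):
            network.differential_network(study_cohort, ("model", "sham"),
                                         threshold=2.5)


class TestTanimoto:
    def test_identical_fingerprints(self):
        assert network.tanimoto([1, 0, 1, 1], [1, 0, 1, 1]) == 1.0

    def test_worked_example_one_third(self):
        assert network.tanimoto([1, 1, 0, 0], [0, 1, 1, 0]) == pytest.approx(1 / 3)

    def test_disjoint_fingerprints(self):
        assert network.tanimoto([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            network.tanimoto([1, 0], [1, 0, 1])
        with pytest.raises(ValueError, match="all-zero"):
            network.tanimoto([0, 0], [0, 0])


class TestStructuralGroups:
    def _fps(self, rows):
        return pd.DataFrame(rows)

    def test_all_dissimilar_gives_singletons(self):
        fps = self._fps({"a": [1, 0, 0, 0], "b": [0, 1, 0, 0], "c": [0, 0, 1, 1]}).T
        gid, pairs = network.structural_groups(fps, cutoff=0.7)
        assert pairs == []
        assert sorted(gid) == [0, 1, 2]
        assert gid.nunique() == 3

    def test_single_linkage_transitivity(self):
        """A~B and B~C above cutoff pull A, B, C into one group even though
        A~C is low (oracle: explicit component search)."""
        fps = self._fps(
            {
                "A": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
                "B": [1, 1, 1, 1, 1, 1, 0, 0, 0, 0],  # A~B = 4/6
                "C": [0, 0, 1, 1, 1, 1, 1, 1, 0, 0],  # hand-checked overlaps
            }
        ).T
        tab = network.tanimoto
        assert tab(fps.loc["A"], fps.loc["B"]) > 0.6
        gid, _ = network.structural_groups(fps, cutoff=0.4)
        assert gid["A"] == gid["B"] == gid["C"]

    def test_similarity_exactly_at_cutoff_not_linked(self):
        """'over 0.7' is strict: a pair at exactly 0.7 stays unlinked."""
        a = [1] * 7 + [0] * 3
        b = [1] * 7 + [0] * 3
        b[0], b[7], b[8], b[9] = 0, 1, 1, 1  # |and|=6... construct 7/10
        a2 = [1] * 7 + [0, 0, 0]
        b2 = [1] * 7 + [1, 1, 1]  # and=7, or=10 -> exactly 0.7
        fps = self._fps({"x": a2, "y": b2}).T
        assert network.tanimoto(a2, b2) == pytest.approx(0.7)
        gid, pairs = network.structural_groups(fps, cutoff=0.7)
        assert pairs == [] and gid["x"] != gid["y"]

    def test_packaged_fingerprints_group_purine_nucleotides(self):
        fps = datasets.load_fingerprints()
        gid, pairs = network.structural_groups(fps, cutoff=0.7)
        assert gid["AMP"] == gid["ADP"] == gid["ATP"]
        assert gid["Lactate"] != gid["ATP"]


class TestReactionOverlay:
    def _net(self, quant):
        st = stats.stats_table(quant, [("model", "sham")])
        return network.differential_network(quant, ("model", "sham"), stats=st)

    def test_empty_reaction_list_changes_nothing(self, study_cohort):
        net = self._net(study_cohort)
        out = network.reaction_overlay(net, [])
        assert out.edges.equals(net.edges)

    def test_purine_chain_adds_two_edges(self, study_cohort):
        net = self._net(study_cohort)
        out = network.reaction_overlay(net, [("AMP", "ADP"), ("ADP", "ATP")])
        assert out.edge_pairs("reaction") == {("AMP", "ADP"), ("ADP", "ATP")}

    def test_duplicates_deduplicated_and_unknowns_skipped(self, study_cohort):
        net = self._net(study_cohort)
        with pytest.warns(UserWarning, match="unknown metabolite"):
            out = network.reaction_overlay(
                net, [("AMP", "ADP"), ("AMP", "ADP"), ("AMP", "unobtainium")]
            )
        assert len(out.edges[out.edges["type"] == "reaction"]) == 1

    def test_diff_edges_untouched_and_groups_annotated(self, study_cohort):
        net = self._net(study_cohort)
        out = network.reaction_overlay(
            net, datasets.load_reactions(), fingerprints=datasets.load_fingerprints()
        )
        pd.testing.assert_frame_equal(
            out.edges[out.edges["type"] == "diff_corr"].reset_index(drop=True),
            net.edges[net.edges["type"] == "diff_corr"].reset_index(drop=True),
        )
        assert (out.nodes["structural_group"] >= 0).all()


class TestPairScatter:
    def test_matches_correlation_matrix_entry(self, study_cohort):
        out = network.pair_scatter(
            study_cohort, ("Lactate", "ATP"), ["model", "sham"]
        )
        r, _ = network.group_correlations(study_cohort, "model")
        assert out["model"]["r"] == r.loc["Lactate", "ATP"]

    def test_degenerate_metabolite_flagged(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        m = _quant({"g": vals})
        out = network.pair_scatter(m, ("f0", "f1"), ["g"])
        assert out["g"]["degenerate"] and out["g"]["r"] is None

    def test_recovers_injected_block_correlation(self):
        cfg = make_two_group_config(
            n_per_group=200, p=4, corr_blocks=[("A", ["m00", "m01"], 0.8)], seed=13
        )
        q = synth.simulate_concentrations(cfg)
        out = network.pair_scatter(q, ("m00", "m01"), ["A", "B"])
        assert out["A"]["r"] == pytest.approx(0.8, abs=0.1)
        assert abs(out["B"]["r"]) < 0.2


def test_graphml_roundtrip(tmp_path, study_cohort):
    import networkx as nx

    st = stats.stats_table(study_cohort, [("model", "sham")])
    net = network.differential_network(study_cohort, ("model", "sham"), stats=st)
    net = network.reaction_overlay(
        net, datasets.load_reactions(), fingerprints=datasets.load_fingerprints()
    )
    path = tmp_path / "net.graphml"
    net.write_graphml(path)
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 38
    assert g.number_of_edges() == len(net.edges)
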