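"""Separation/flux identities, landscape capacity, lineage classification."""

import numpy as np
import pytest

from celldiff3d.dynamics import find_attractors
from celldiff3d.noise_kernel import TransitionKernel
from celldiff3d.mfpt import MfptMatrix, mfpt_attractors
from celldiff3d.metrics import (
    LineageTree,
    build_metrics,
    classify_transition,
    edge_direction,
    flux,
    landscape_capacity,
    metrics_frame,
    metrics_tsv,
    separation,
    TRANSITION_KINDS,
)
from celldiff3d.fixtures import RandomNetSpec, random_network


def asym_matrix():
    values = np.array([[0.0, 20.0], [30.0, 0.0]])
    return MfptMatrix(values, 0.01, "exact", ("a", "b"))


class TestPairMetrics:
    def test_separation_is_min_of_directions(self):
        assert separation(asym_matrix(), 0, 1) == 20.0
        assert separation(asym_matrix(), 1, 0) == 20.0

    def test_flux_is_signed_difference(self):
        assert flux(asym_matrix(), 0, 1) == -10.0
        assert flux(asym_matrix(), 1, 0) == 10.0

    def test_direction_favors_smaller_mfpt(self):
        assert edge_direction(asym_matrix(), 0, 1) == (0, 1)
        assert edge_direction(asym_matrix(), 1, 0) == (0, 1)

    def test_exact_tie_has_no_direction(self, nets):
        aset = find_attractors(nets["identity-1"])
        M = mfpt_attractors(TransitionKernel(nets["identity-1"], 0.01), aset)
        assert edge_direction(M, 0, 1) is None
        assert flux(M, 0, 1) == pytest.approx(0.0, abs=1e-9)
        assert separation(M, 0, 1) == pytest.approx(100.0, rel=1e-9)

    @pytest.mark.parametrize("fn", [separation, flux, edge_direction])
    def test_diagonal_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(asym_matrix(), 1, 1)

    def test_mfpts_reconstructable_from_metrics(self):
        M = asym_matrix()
        sep = separation(M, 0, 1)
        fl = flux(M, 0, 1)
        d = edge_direction(M, 0, 1)
        forward = sep if d == (0, 1) else sep + abs(fl)
        reverse = sep + abs(fl) if d == (0, 1) else sep
        assert (forward, reverse) == (20.0, 30.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_identities_on_computed_tables(self, seed):
        net = random_network(RandomNetSpec(n=5, k=2, bias=0.5, seed=200 + seed))
        aset = find_attractors(net)
        table = build_metrics(mfpt_attractors(TransitionKernel(net, 0.05), aset))
        assert np.allclose(table.separation, table.separation.T)
        assert np.allclose(table.flux, -table.flux.T)
        assert np.all(np.diag(table.flux) == 0)
        off = ~np.eye(aset.m, dtype=bool)
        assert np.allclose(
            table.separation[off],
            np.minimum(table.mfpt, table.mfpt.T)[off],
        )
        for i in range(aset.m):
            for j in range(i + 1, aset.m):
                d = table.direction(i, j)
                if d == (i, j):
                    assert table.mfpt[i, j] < table.mfpt[j, i]
                elif d == (j, i):
                    assert table.mfpt[j, i] < table.mfpt[i, j]
                else:
                    assert table.mfpt[i, j] == pytest.approx(
                        table.mfpt[j, i], rel=1e-9
                    )


class TestLandscapeCapacity:
    @pytest.mark.parametrize("m,expected", [(1, 0), (3, 3), (7, 10), (15, 25)])
    def test_perfect_tree_sizes(self, m, expected):
        assert landscape_capacity(m) == expected

    def test_general_m_floors_log_term(self):
        assert landscape_capacity(4) == 2 * 4 - 2 - 1

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            landscape_capacity(0)


class TestLineageTree:
    def test_newick_parse(self, lineage_tree):
        t = lineage_tree
        assert t.root == "CMP"
        assert t.depth("CMP") == 0
        assert t.depth("MEP") == t.depth("GMP") == 1
        assert {n for n in t.nodes if t.is_leaf(n)} == {"ERY", "MEG", "MON", "GRA"}
        assert t.ancestors("ERY") == ["MEP", "CMP"]

    def test_parent_tsv_equivalent(self, lineage_tree):
        tsv = "\n".join(
            f"{c}\t{p or ''}" for c, p in lineage_tree.parent.items()
        )
        t2 = LineageTree.from_parent_tsv(tsv)
        assert t2.parent == dict(lineage_tree.parent)

    def test_newick_round_trip(self, lineage_tree):
        back = LineageTree.from_newick(lineage_tree.to_newick())
        assert back.parent == dict(lineage_tree.parent)

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="exactly one root"):
            LineageTree({"a": None, "b": None})

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle|parent"):
            LineageTree({"a": "b", "b": "a", "r": None})


class TestClassification:
    @pytest.mark.parametrize(
        "source,sink,kind",
        [
            ("CMP", "MEP", "spontaneous-differentiation"),
            ("MON", "GMP", "spontaneous-dedifferentiation"),
            ("GMP", "ERY", "off-differentiation"),
            ("MEG", "GMP", "off-dedifferentiation"),
            ("GRA", "ERY", "transdifferentiation"),
            ("MEP", "GMP", "off-differentiation"),  # equal-depth, off-path
            ("ERY", "CMP", "spontaneous-dedifferentiation"),
            ("CMP", "GRA", "spontaneous-differentiation"),
            ("MEP", "MON", "off-differentiation"),
        ],
    )
    def test_myeloid_examples(self, lineage_tree, source, sink, kind):
        assert classify_transition(lineage_tree, source, sink) == kind

    def test_total_over_all_ordered_pairs(self, lineage_tree):
        nodes = lineage_tree.nodes
        kinds = [
            classify_transition(lineage_tree, s, t)
            for s in nodes
            for t in nodes
            if s != t
        ]
        assert len(kinds) == 7 * 6
        assert set(kinds) <= set(TRANSITION_KINDS)
        assert set(kinds) == set(TRANSITION_KINDS)  # all five occur

    def test_errors(self, lineage_tree):
        with pytest.raises(KeyError):
            classify_transition(lineage_tree, "CMP", "HSC")
        with pytest.raises(ValueError):
            classify_transition(lineage_tree, "CMP", "CMP")


class TestMetricsTable:
    def test_frame_has_all_ordered_pairs(self, demo_kernel, demo_attractors,
                                          lineage_tree):
        table = build_metrics(mfpt_attractors(demo_kernel, demo_attractors))
        frame = metrics_frame(table, lineage_tree)
        assert len(frame) == 7 * 6
        assert np.allclose(
            frame["flux"],
            [table.mfpt[i, j] - table.mfpt[j, i]
             for i in range(7) for j in range(7) if i != j],
        )
        assert set(frame["classification"]) <= set(TRANSITION_KINDS)

    def test_unlabeled_attractors_reported_unclassified(self, nets):
        net = nets["swap-2"]
        table = build_metrics(
            mfpt_attractors(TransitionKernel(net, 0.1), find_attractors(net))
        )
        frame = metrics_frame(table, None)
        assert (frame["classification"] == "unclassified").all()

    def test_tsv_header_records_noise_level(self, nets):
        net = nets["identity-2"]
        table = build_metrics(
            mfpt_attractors(TransitionKernel(net, 0.1), find_attractors(net))
        )
        text = metrics_tsv(table)
        assert text.startswith("# p=0.1\n")
        assert len(text.strip().splitlines()) == 2 + 4 * 3
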