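"""Numeric kernels: TPM, alpha diversity, Bray-Curtis, UPGMA, network stats."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from viromine.stats import (alpha_diversity, bray_curtis, network_stats, tpm,
                            upgma)


class TestTPM:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"a": [7], "b": [7]}, index=["s1"])
        out = tpm(counts, {"a": 500, "b": 500})
        assert out.loc["s1", "a"] == pytest.approx(500_000)

    def test_hand_computed_length_normalisation(self):
        counts = pd.DataFrame({"a": [10], "b": [10]}, index=["s1"])
        out = tpm(counts, {"a": 1000, "b": 2000})
        assert out.loc["s1", "a"] == pytest.approx(666_666.6667, rel=1e-6)
        assert out.loc["s1", "b"] == pytest.approx(333_333.3333, rel=1e-6)

    def test_rows_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (10, 30)) + 1)
        lengths = {c: int(l) for c, l in
                   zip(counts.columns, rng.integers(200, 5000, 30))}
        out = tpm(counts, lengths)
        assert np.allclose(out.sum(axis=1), 1e6, rtol=1e-6)

    def test_all_zero_sample_warns_and_zeroes(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [0, 5]}, index=["z", "s"])
        with pytest.warns(UserWarning):
            out = tpm(counts, {"a": 100, "b": 100})
        assert (out.loc["z"] == 0).all()

    def test_negative_count_rejected(self):
        counts = pd.DataFrame({"a": [-1]}, index=["s"])
        with pytest.raises(ValueError):
            tpm(counts, {"a": 100})


def oracle_alpha(v):
    """Hand-coded formula oracle for every index."""
    v = np.asarray([x for x in v if x > 0], dtype=float)
    n = v.sum()
    p = v / n
    s = len(v)
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    chao1 = s + f1 * (f1 - 1) / (2 * (f2 + 1))
    rare = v[v <= 10]
    if rare.size == 0:
        ace = float(s)
    else:
        n_rare = rare.sum()
        f1r = int((rare == 1).sum())
        if n_rare == f1r:
            ace = chao1
        else:
            c = 1 - f1r / n_rare
            top = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, 11))
            g2 = max(0.0, (rare.size / c) * top / (n_rare * (n_rare - 1)) - 1)
            ace = (s - rare.size) + rare.size / c + f1r / c * g2
    h = float(-(p * np.log(p)).sum())
    return {
        "richness": s, "chao1": chao1, "ace": ace, "shannon": h,
        "simpson": float(1 - (p ** 2).sum()),
        "pielou": h / math.log(s) if s > 1 else np.nan,
    }


class TestAlpha:
    def test_uniform_four_taxa_closed_forms(self):
        out = alpha_diversity(pd.DataFrame([[5, 5, 5, 5]], index=["s"]))
        assert out.loc["s", "shannon"] == pytest.approx(math.log(4))
        assert out.loc["s", "pielou"] == pytest.approx(1.0)
        assert out.loc["s", "simpson"] == pytest.approx(0.75)

    def test_chao1_worked_example(self):
        # counts (5,1,1,2): F1=2, F2=1 -> 4 + 2*1/(2*2) = 4.5
        out = alpha_diversity(pd.DataFrame([[5, 1, 1, 2]], index=["s"]))
        assert out.loc["s", "chao1"] == pytest.approx(4.5)

    def test_matches_formula_oracle_on_random_counts(self, rng):
        mats = rng.integers(0, 30, size=(200, 12))
        mats[rng.random(mats.shape) < 0.3] = 0
        mats[:, 0] += 1  # no all-zero samples
        out = alpha_diversity(pd.DataFrame(mats))
        for i in range(len(mats)):
            exp = oracle_alpha(mats[i])
            for key, val in exp.items():
                assert out.iloc[i][key] == pytest.approx(val, abs=1e-10), key

    def test_estimators_bound_richness(self, rng):
        mats = rng.integers(0, 8, size=(100, 20))
        mats[:, 0] += 1
        out = alpha_diversity(pd.DataFrame(mats))
        assert (out["chao1"] >= out["richness"] - 1e-12).all()
        assert (out["ace"] >= out["richness"] - 1e-9).all()
        assert out["simpson"].between(0, 1).all()
        assert out["pielou"].dropna().between(0, 1 + 1e-12).all()

    def test_pooling_samples_never_decreases_richness(self, rng):
        a = rng.integers(0, 5, 30)
        b = rng.integers(0, 5, 30)
        df = pd.DataFrame([a, b, a + b], index=["a", "b", "pool"])
        out = alpha_diversity(df)
        assert out.loc["pool", "richness"] >= out.loc["a", "richness"]
        assert out.loc["pool", "richness"] >= out.loc["b", "richness"]

    def test_all_zero_sample_warns_nan(self):
        with pytest.warns(UserWarning):
            out = alpha_diversity(pd.DataFrame([[0, 0]], index=["z"]))
        assert out.loc["z"].isna().all()

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(pd.DataFrame([[1.5, 2.0]]))


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        m = pd.DataFrame([[3, 1, 4], [3, 1, 4]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 0

    def test_disjoint_supports_distance_one(self):
        m = pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(1.0)

    def test_matches_brute_force_formula(self, rng):
        m = pd.DataFrame(rng.integers(0, 20, (6, 15)))
        out = bray_curtis(m)
        for i in range(6):
            for j in range(6):
                x, y = m.iloc[i].to_numpy(), m.iloc[j].to_numpy()
                exp = np.abs(x - y).sum() / (x + y).sum()
                assert out.iloc[i, j] == pytest.approx(exp)
        assert np.allclose(out, out.T)

    def test_two_zero_samples_defined_zero_with_warning(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            out = bray_curtis(m)
        assert out.loc["a", "b"] == 0


class TestUPGMA:
    def test_hand_worked_three_points(self):
        d = pd.DataFrame([[0, .2, .8], [.2, 0, .8], [.8, .8, 0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = TreeNode.read([upgma(d)])
        # ((A,B),C): A and B merge at height 0.1, the root sits at 0.4
        assert tree.find("A").length == pytest.approx(0.1)
        assert tree.find("C").length == pytest.approx(0.4)
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}

    def test_two_samples_cherry_at_half_distance(self):
        d = pd.DataFrame([[0, .6], [.6, 0]], index=["a", "b"],
                         columns=["a", "b"])
        tree = TreeNode.read([upgma(d)])
        assert tree.find("a").length == pytest.approx(0.3)

    def test_topology_matches_scipy_average_linkage(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"s{i}" for i in range(n)]
            df = pd.DataFrame(d, index=labels, columns=labels)
            tree = TreeNode.read([upgma(df)])
            link = hierarchy.linkage(squareform(d), method="average")

            # compare the sets of clades rather than newick strings
            def clades_from_linkage(link, labels):
                clusters = {i: frozenset([labels[i]]) for i in range(n)}
                clades = set()
                for k, row in enumerate(link):
                    merged = clusters[int(row[0])] | clusters[int(row[1])]
                    clusters[n + k] = merged
                    clades.add(merged)
                return clades
            got = {frozenset(t.name for t in node.tips())
                   for node in tree.non_tips(include_self=True)}
            assert got == clades_from_linkage(link, labels)

    def test_merge_heights_match_scipy(self, rng):
        n = 6
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(n)]
        tree = TreeNode.read([upgma(pd.DataFrame(d, index=labels, columns=labels))])
        link = hierarchy.linkage(squareform(d), method="average")
        # depth from any tip to root equals half the final merge distance
        depth = tree.find("s0").accumulate_to_ancestor(tree)
        assert depth == pytest.approx(link[-1, 2] / 2)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            upgma(d)


class TestNetworkStats:
    def test_triangle(self):
        s = network_stats([("a", "b"), ("b", "c"), ("a", "c")])
        assert s.density == pytest.approx(1.0)
        assert s.avg_clustering_coefficient == pytest.approx(1.0)
        assert s.avg_neighbors == pytest.approx(2.0)

    def test_star_k13(self):
        s = network_stats([("hub", f"leaf{i}") for i in range(3)])
        assert s.density == pytest.approx(0.5)
        assert s.avg_clustering_coefficient == pytest.approx(0.0)
        assert s.avg_neighbors == pytest.approx(1.5)

    def test_self_loops_and_duplicates_dropped(self):
        s = network_stats([("a", "a"), ("a", "b"), ("b", "a")])
        assert s.n_edges == 1 and s.n_dropped == 2

    def test_single_node_density_undefined(self):
        s = network_stats([], nodes=["a"])
        assert s.density is None

    def test_erdos_renyi_matches_brute_force(self, rng):
        import itertools
        n = 25
        nodes = [f"n{i}" for i in range(n)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.2]
        s = network_stats(edges, nodes=nodes)
        e = len(edges)
        assert s.density == pytest.approx(2 * e / (n * (n - 1)))
        assert s.avg_neighbors == pytest.approx(2 * e / n)
        # brute-force clustering coefficient
        adj = {u: set() for u in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        cs = []
        for u in nodes:
            k = len(adj[u])
            if k < 2:
                cs.append(0.0)
                continue
            t = sum(1 for a, b in itertools.combinations(adj[u], 2)
                    if b in adj[a])
            cs.append(2 * t / (k * (k - 1)))
        assert s.avg_clustering_coefficient == pytest.approx(np.mean(cs))
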