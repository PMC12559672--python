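"""Bipartite network construction and structural metrics.

Every non-trivial metric is checked against an independently coded
brute-force oracle from conftest: explicit pair loops for NODF,
exhaustive set-partition search for Barber modularity, exhaustive
partner-set enumeration for the cnodf null, and pair counting for the
Mann-Whitney U.
"""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from metapatch import (AbundanceMatrix, UndefinedMetricError, ValidationError,
                       build_network, cnodf, connectance, modularity, nodf,
                       node_metric_series, rank_sum_compare)
from metapatch.network import _cv, _nodf_matrix

from conftest import (make_network, oracle_barber_q_max, oracle_mannwhitney_u,
                      oracle_nodf, random_network)


def matrix(rows, period="T"):
    rows = np.asarray(rows)
    return AbundanceMatrix(period,
                           [f"sp{i + 1}" for i in range(rows.shape[0])],
                           [f"p{j + 1}" for j in range(rows.shape[1])],
                           rows)


class TestBuildNetwork:
    def test_threshold_one(self):
        net = build_network(matrix([[5, 0], [0, 2]]), 1)
        assert net.links == {("sp1", "p1"), ("sp2", "p2")}

    def test_higher_threshold_drops_nodes(self):
        net = build_network(matrix([[5, 0], [0, 2]]), 3)
        assert net.links == {("sp1", "p1")}
        assert net.species_nodes == {"sp1"} and net.patch_nodes == {"p1"}

    def test_all_zero_matrix_gives_empty_network(self):
        net = build_network(matrix([[0, 0], [0, 0]]), 1)
        assert not net.links and not net.species_nodes

    def test_keep_isolated_retains_surveyed_nodes(self):
        net = build_network(matrix([[5, 0], [0, 0]]), 1, keep_isolated=True)
        assert net.patch_nodes == {"p1", "p2"}

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValidationError):
            build_network(matrix([[1]]), 0)


class TestConnectance:
    def test_complete_network(self):
        net = make_network({(s, p) for s in "ab" for p in "xy"})
        assert connectance(net) == 1.0

    def test_half_filled(self):
        assert connectance(make_network({("a", "x"), ("b", "y")})) == 0.5

    def test_hand_count(self):
        net = make_network({("a", "x"), ("a", "y"), ("b", "y"), ("c", "z")})
        assert connectance(net) == pytest.approx(4 / 9)

    def test_empty_class_rejected(self):
        net = make_network(set(), species={"a"}, patches=set())
        with pytest.raises(UndefinedMetricError):
            connectance(net)

    def test_adding_a_link_strictly_increases(self, rng):
        net = random_network(rng, 5, 5, 0.4)
        missing = [(s, p) for s in net.species_nodes for p in net.patch_nodes
                   if (s, p) not in net.links]
        if not missing:
            return
        bigger = make_network(set(net.links) | {missing[0]},
                              species=net.species_nodes,
                              patches=net.patch_nodes)
        assert connectance(bigger) > connectance(net)


class TestNodf:
    def test_perfect_staircase(self):
        net = make_network({("a", "p1"), ("a", "p2"), ("a", "p3"),
                            ("b", "p1"), ("b", "p2"), ("c", "p1")})
        assert nodf(net) == pytest.approx(100.0)

    def test_degree_tied_checkerboard(self):
        net = make_network({("a", "x"), ("b", "y")})
        assert nodf(net) == 0.0

    def test_brute_force_example(self):
        # rows {p1,p2},{p2,p3},{p3}: only (r2,r3) and one column pair nest
        net = make_network({("a", "p1"), ("a", "p2"), ("b", "p2"),
                            ("b", "p3"), ("c", "p3")})
        assert nodf(net) == pytest.approx(200 / 6)
        assert nodf(net) == pytest.approx(oracle_nodf(net))

    def test_too_small_rejected(self):
        with pytest.raises(UndefinedMetricError):
            nodf(make_network({("a", "x"), ("a", "y")}))

    def test_matches_oracle_on_random_networks(self, rng):
        for _ in range(40):
            net = random_network(rng, int(rng.integers(2, 8)),
                                 int(rng.integers(2, 8)),
                                 float(rng.uniform(0.2, 0.8)))
            assert nodf(net) == pytest.approx(oracle_nodf(net), abs=1e-9)

    def test_transpose_symmetry(self, rng):
        for _ in range(20):
            net = random_network(rng, 5, 7, 0.4)
            flipped = make_network({(p, s) for s, p in net.links},
                                   species=net.patch_nodes,
                                   patches=net.species_nodes)
            assert nodf(net) == pytest.approx(nodf(flipped), abs=1e-9)

    def test_matches_vegan_reference(self, tmp_path):
        """Cross-check against the R vegan implementation on one matrix."""
        import subprocess
        rng = np.random.default_rng(11)
        a = (rng.random((6, 5)) < 0.5).astype(int)
        while a.sum(0).min() == 0 or a.sum(1).min() == 0:
            a = (rng.random((6, 5)) < 0.5).astype(int)
        np.savetxt(tmp_path / "m.csv", a, fmt="%d", delimiter=",")
        script = tmp_path / "nodf.R"
        script.write_text(
            'm <- as.matrix(read.csv("%s", header=FALSE))\n'
            "res <- vegan::nestednodf(m, order=TRUE)\n"
            'cat(res$statistic["NODF"])\n' % (tmp_path / "m.csv"))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        expected = float(out.stdout.strip())
        assert _nodf_matrix(a) == pytest.approx(expected, abs=1e-6)


class TestModularity:
    def test_two_disjoint_blocks(self):
        links = {(f"s{i}", f"p{j}") for i in (1, 2) for j in (1, 2)}
        links |= {(f"s{i}", f"p{j}") for i in (3, 4) for j in (3, 4)}
        net = make_network(links)
        q, partition = modularity(net, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(partition.values())) == 2
        assert q == pytest.approx(oracle_barber_q_max(net), abs=1e-9)

    def test_complete_bipartite_gives_zero(self):
        net = make_network({(s, p) for s in "abc" for p in "xyz"})
        q, partition = modularity(net, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_single_link(self):
        q, _ = modularity(make_network({("a", "x")}), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_no_links_rejected(self):
        net = make_network(set(), species={"a"}, patches={"x"})
        with pytest.raises(UndefinedMetricError):
            modularity(net)

    def test_seed_determinism(self, rng):
        net = random_network(rng, 6, 6, 0.35)
        assert modularity(net, seed=5) == modularity(net, seed=5)

    def test_matches_exhaustive_optimum_on_small_networks(self, rng):
        for _ in range(10):
            net = random_network(rng, int(rng.integers(2, 5)),
                                 int(rng.integers(2, 5)),
                                 float(rng.uniform(0.3, 0.7)))
            q, _ = modularity(net, seed=1, restarts=20)
            assert q >= -1e-12  # never worse than the single-module baseline
            assert q == pytest.approx(oracle_barber_q_max(net), abs=1e-9)


class TestCnodf:
    def test_complete_network_degenerate_sd(self):
        net = make_network({(s, p) for s in "abc" for p in "xyz"})
        assert cnodf(net, "a", n_random=10, seed=0) == 0.0

    def test_seed_determinism(self, rng):
        net = random_network(rng, 5, 5, 0.5)
        node = sorted(net.species_nodes)[0]
        assert cnodf(net, node, n_random=50, seed=3) == \
            cnodf(net, node, n_random=50, seed=3)

    def test_absent_node_rejected(self, rng):
        with pytest.raises(KeyError):
            cnodf(random_network(rng, 3, 3, 0.6), "ghost")

    def test_converges_to_exhaustive_null(self):
        """Sampling estimate approaches the exact all-partner-sets null for
        a focal row with few possible partner sets."""
        links = {("a", "p1"), ("a", "p2"), ("a", "p3"),
                 ("b", "p1"), ("b", "p2"), ("c", "p1")}
        net = make_network(links)
        a, species, patches = net.incidence()
        focal = species.index("b")  # degree 2 of 3 partners: 3 subsets
        nulls = []
        for partners in combinations(range(len(patches)), 2):
            work = a.copy()
            work[focal] = 0
            work[focal, list(partners)] = 1
            nulls.append(oracle_nodf_matrix(work))
        exact = (oracle_nodf_matrix(a) - np.mean(nulls)) / np.std(nulls,
                                                                  ddof=1)
        sampled = cnodf(net, "b", n_random=4000, seed=0)
        assert sampled == pytest.approx(exact, abs=0.15)


def oracle_nodf_matrix(a):
    """Brute-force NODF on a raw 0/1 matrix via the conftest oracle."""
    links = {(f"s{i}", f"p{j}") for i, j in zip(*np.nonzero(a))}
    species = {f"s{i}" for i in range(a.shape[0])}
    patches = {f"p{j}" for j in range(a.shape[1])}
    return oracle_nodf(make_network(links, species=species, patches=patches))


class TestNodeMetricSeries:
    def nets(self):
        base = {("a", "x"), ("a", "y"), ("b", "x"), ("c", "y"), ("c", "x")}
        other = {("a", "x"), ("b", "y"), ("b", "x"), ("c", "y")}
        return [make_network(base, period="T1"),
                make_network(other, period="T2")]

    def test_constant_series_has_zero_cv(self):
        assert _cv([2, 2, 2, 2]) == 0.0

    def test_cv_hand_value(self):
        assert _cv([2, 4, 6, 8]) == pytest.approx(2.581989 / 5, abs=1e-6)

    def test_single_period_cv_undefined(self):
        assert _cv([3]) is None

    def test_zero_mean_cv_undefined(self):
        assert _cv([0, 0]) is None

    def test_series_collects_degrees_per_period(self):
        series = node_metric_series(self.nets(), n_random=10, seed=0)
        by_key = {(s.node_class, s.node_id): s for s in series}
        a = by_key[("species", "a")]
        assert a.degree_by_period == {"T1": 2, "T2": 1}
        assert a.cv_degree == pytest.approx(
            np.std([2, 1], ddof=1) / 1.5)

    def test_requires_two_networks(self):
        with pytest.raises(ValidationError):
            node_metric_series(self.nets()[:1])


class TestRankSumCompare:
    def test_identical_groups(self):
        u, z, p = rank_sum_compare([1, 2, 3], [1, 2, 3])
        assert z == 0.0 and p == 1.0

    def test_complete_separation(self):
        u, z, p = rank_sum_compare([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p < 0.1

    def test_degenerate_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            rank_sum_compare([5, 5], [5, 5, 5])

    def test_u_matches_pair_counting_and_scipy(self, rng):
        for _ in range(30):
            a = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            b = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            u, z, p = rank_sum_compare(a, b)
            assert u == pytest.approx(oracle_mannwhitney_u(a, b))
            ref = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
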