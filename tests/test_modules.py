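"""Topological overlap, Q maximization, macromodules, specular detection."""

import itertools

import numpy as np
import pytest

from anna import (
    SkullNetwork,
    detect_specular,
    hierarchical_modules,
    label_modules,
    macromodules,
    modularity_strength,
    newman_q,
    topological_overlap,
)
from anna.modules import PartitionResult
from anna.synthetic_data import generate_planted_network
from conftest import make_net, random_connected_net


def q_literal_double_sum(net, assignment):
    """Literal (1/2K) sum over all ordered pairs of [A_ij - k_i k_j / 2K]."""
    a = net.adjacency.astype(float)
    k = a.sum(axis=1)
    two_k = a.sum()
    labels = [assignment[b] for b in net.bones]
    total = 0.0
    n = net.n_bones
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                total += a[i, j] - k[i] * k[j] / two_k
    return total / two_k


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestTopologicalOverlap:
    def test_identical_neighborhoods_score_one(self):
        # u and v both adjacent to exactly {x, y}, not to each other
        net = make_net("c4", ["u", "x", "v", "y"],
                       [("u", "x"), ("u", "y"), ("v", "x"), ("v", "y")])
        for conv in ("open_neighborhood", "raw_degree"):
            to = topological_overlap(net, conv)
            iu, iv = to.labels.index("u"), to.labels.index("v")
            assert to.values[iu, iv] == pytest.approx(1.0)

    def test_disjoint_neighborhoods_score_zero(self):
        net = make_net("p5", list("abcde"),
                       [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        to = topological_overlap(net)
        ia, ie = to.labels.index("a"), to.labels.index("e")
        assert to.values[ia, ie] == 0.0

    @pytest.mark.parametrize(
        "convention, expected",
        [("open_neighborhood", 1.0), ("raw_degree", 0.5), ("gtom1", 1.0)],
    )
    def test_triangle_conventions(self, triangle, convention, expected):
        # pair-excluded: J={c}, sizes 1,1 -> 1; raw degrees: 1/2;
        # gtom1: (1+1)/(2+1-1) = 1
        to = topological_overlap(triangle, convention)
        assert to.values[0, 1] == pytest.approx(expected)

    @pytest.mark.parametrize("convention", ["open_neighborhood", "raw_degree", "gtom1"])
    def test_matrix_invariants(self, convention):
        for seed in range(10):
            net = random_connected_net(10, 0.35, seed)
            to = topological_overlap(net, convention)
            assert np.allclose(to.values, to.values.T)
            assert np.all(to.values >= 0) and np.all(to.values <= 1)
            assert np.allclose(np.diag(to.values), 1.0)

    def test_permutation_equivariance(self):
        net = random_connected_net(9, 0.4, 17)
        to = topological_overlap(net)
        rng = np.random.default_rng(0)
        perm = rng.permutation(net.n_bones)
        bones = tuple(net.bones[i] for i in perm)
        shuffled = SkullNetwork(
            net.taxon_name, bones, net.adjacency[np.ix_(perm, perm)]
        )
        to_shuffled = topological_overlap(shuffled)
        assert np.allclose(to_shuffled.values, to.values[np.ix_(perm, perm)])


class TestNewmanQ:
    def test_single_module_is_zero(self, barbell):
        assert newman_q(barbell, {b: 0 for b in barbell.bones}) == pytest.approx(0.0)

    def test_barbell_two_triangles(self, barbell):
        assignment = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert newman_q(barbell, assignment) == pytest.approx(5 / 14, abs=1e-12)
        assert newman_q(barbell, assignment) == pytest.approx(
            q_literal_double_sum(barbell, assignment), abs=1e-12
        )

    def test_agrees_with_double_sum_on_all_partitions(self):
        """Q = sum_c (e_c - a_c^2) equals the literal ordered-pair double sum."""
        for seed, n in [(1, 5), (2, 6)]:
            net = random_connected_net(n, 0.5, seed)
            for part in set_partitions(list(net.bones)):
                assignment = {
                    b: idx for idx, group in enumerate(part) for b in group
                }
                assert newman_q(net, assignment) == pytest.approx(
                    q_literal_double_sum(net, assignment), abs=1e-12
                )

    def test_random_assignment_mean_matches_closed_form(self):
        """Q over uniform random assignments is centred near 0: its exact
        expectation is -(1 - 1/g) * sum_i (k_i / 2K)^2 (Monte-Carlo, 3 SE)."""
        net = random_connected_net(10, 0.4, 5)
        g = 3
        w = net.degrees() / net.adjacency.sum()
        expected = -(1 - 1 / g) * float(w @ w)
        rng = np.random.default_rng(42)
        qs = np.array([
            newman_q(net, dict(zip(net.bones, rng.integers(0, g, 10))))
            for _ in range(10_000)
        ])
        se = qs.std(ddof=1) / np.sqrt(len(qs))
        assert abs(qs.mean() - expected) < 3 * se
        assert abs(expected) < 0.15  # "approximately zero" on this scale

    def test_incomplete_assignment_rejected(self, barbell):
        with pytest.raises(ValueError, match="misses"):
            newman_q(barbell, {"a": 0})


class TestHierarchicalModules:
    def test_two_cliques_recovered_and_globally_optimal(self, two_cliques):
        part = hierarchical_modules(two_cliques)
        mods = {frozenset(m) for m in part.modules().values()}
        assert mods == {
            frozenset({"x0", "x1", "x2", "x3"}),
            frozenset({"y0", "y1", "y2", "y3"}),
        }
        # exhaustive maximum over every partition of the 8 nodes
        best = max(
            newman_q(two_cliques,
                     {b: i for i, grp in enumerate(p) for b in grp})
            for p in set_partitions(list(two_cliques.bones))
        )
        assert part.q == pytest.approx(best, abs=1e-12)
        assert modularity_strength(part) == pytest.approx(2 * part.q)

    def test_complete_graph_stays_single_module(self):
        bones = list("abcde")
        k5 = make_net("k5", bones, list(itertools.combinations(bones, 2)))
        part = hierarchical_modules(k5)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0)
        assert part.m == pytest.approx(0.0)

    def test_selected_q_dominates_every_cut(self):
        for seed in range(5):
            net = random_connected_net(12, 0.3, 300 + seed)
            part = hierarchical_modules(net)
            assert part.q == pytest.approx(max(part.q_by_cluster_count), abs=1e-12)

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        net, blocks = generate_planted_network(seed=9)
        part = hierarchical_modules(net)
        truth = [blocks[b] for b in net.bones]
        pred = [part.assignment[b] for b in net.bones]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_deterministic(self, two_cliques):
        p1 = hierarchical_modules(two_cliques)
        p2 = hierarchical_modules(two_cliques)
        assert p1.assignment == p2.assignment and p1.q == p2.q


class TestMacromodules:
    def test_planted_blocks_are_the_first_split(self, two_cliques):
        res = macromodules(hierarchical_modules(two_cliques))
        assert set(res.macromodules) == {
            frozenset({"x0", "x1", "x2", "x3"}),
            frozenset({"y0", "y1", "y2", "y3"}),
        }
        assert res.is_refinement

    def test_star_first_split_deterministic(self, star4):
        r1 = macromodules(hierarchical_modules(star4))
        r2 = macromodules(hierarchical_modules(star4))
        assert r1.macromodules == r2.macromodules

    def test_nested_hierarchy_macromodules_are_superblocks(self):
        # 2 super-blocks of 2 dense sub-blocks each: the optimal partition is
        # the 4 sub-blocks, the first split the 2 super-blocks
        blocks = [[f"s{b}{i}" for i in range(4)] for b in range(4)]
        edges = []
        for block in blocks:
            edges += list(itertools.combinations(block, 2))
        edges += [("s00", "s10"), ("s01", "s11")]     # within super-block A
        edges += [("s20", "s30"), ("s21", "s31")]     # within super-block B
        edges += [("s03", "s23")]                      # single bridge A-B
        net = make_net("nested", [b for blk in blocks for b in blk], edges)
        part = hierarchical_modules(net)
        assert {frozenset(m) for m in part.modules().values()} == {
            frozenset(blk) for blk in blocks
        }
        res = macromodules(part)
        assert set(res.macromodules) == {
            frozenset(blocks[0] + blocks[1]),
            frozenset(blocks[2] + blocks[3]),
        }
        assert res.is_refinement


def _partition_from_groups(groups):
    bones = tuple(b for grp in groups for b in grp)
    assignment = {b: i for i, grp in enumerate(groups) for b in grp}
    return PartitionResult(bones, assignment, len(groups), 0.0)


class TestSpecularAndLabels:
    def test_exact_mirror_pair(self):
        part = _partition_from_groups([["nas_l", "lac_l"], ["nas_r", "lac_r"]])
        net = make_net(
            "m", ["nas_l", "lac_l", "nas_r", "lac_r"],
            [("nas_l", "lac_l"), ("nas_r", "lac_r"), ("nas_l", "nas_r")],
        )
        pairs = detect_specular(part, net)
        assert len(pairs) == 1
        assert pairs[0].arbitrary_bones == ()

    def test_unpaired_bone_flagged_arbitrary(self):
        part = _partition_from_groups(
            [["nas_l", "lac_l", "vom"], ["nas_r", "lac_r"]]
        )
        net = make_net(
            "m", ["nas_l", "lac_l", "vom", "nas_r", "lac_r"],
            [("nas_l", "lac_l"), ("nas_r", "lac_r"), ("vom", "nas_l"),
             ("vom", "nas_r")],
        )
        pairs = detect_specular(part, net)
        assert len(pairs) == 1
        assert pairs[0].arbitrary_bones == ("vom",)

    def test_non_mirror_modules_do_not_pair(self):
        part = _partition_from_groups([["nas_l"], ["lac_r"]])
        net = make_net("m", ["nas_l", "lac_r"], [("nas_l", "lac_r")])
        assert detect_specular(part, net) == []

    def test_no_suffixes_yields_empty(self, barbell):
        part = hierarchical_modules(barbell)
        assert detect_specular(part, barbell) == []

    @pytest.mark.parametrize(
        "bones, expected",
        [
            (["occ", "par_l", "par_r", "tem_l", "tem_r", "sph"], "neurocranial"),
            (["pal_l", "pal_r", "vom"], "palatal"),
            (["zyg_l"], "unlabeled"),
            (["eth", "lac_l", "lac_r"], "midfacial"),
            (["pmx_l", "pmx_r", "nas_l", "nas_r"], "premaxillary"),
            (["nas_l", "lac_l"], "unlabeled_l"),
        ],
    )
    def test_anchor_labels(self, bones, expected):
        part = _partition_from_groups([bones])
        assert label_modules(part)[0] == expected

    def test_anchor_priority_on_conflict(self):
        part = _partition_from_groups([["occ", "eth", "pal_l", "pal_r", "pmx"]])
        assert label_modules(part)[0] == "neurocranial"

    def test_one_palatine_is_not_a_palatal_anchor(self):
        part = _partition_from_groups([["pal_l", "vom"]])
        assert label_modules(part)[0] == "unlabeled"
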