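"""Age estimation: p-distances, NJ cherries, burst detection."""

import itertools

import numpy as np
import pytest
from skbio.tree import TreeNode

from mobilome.ages import (AgeHistogram, DistanceMatrix, build_tree,
                           burst_histogram, copy_consensus_divergence,
                           detect_bursts, family_ages, p_distance,
                           pairwise_distances, terminal_fork_pairs)
from mobilome.alignment import MasterSlaveMSA


def _msa(rows, consensus=None):
    consensus = consensus or next(iter(rows.values())).replace("-", "A")
    return MasterSlaveMSA("cons", consensus, rows=dict(rows))


def _dm(ids, matrix, sites=1000, min_sites=1):
    n = len(ids)
    return DistanceMatrix(list(ids), np.asarray(matrix, dtype=float),
                          np.full((n, n), sites), min_sites)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        msa = _msa({"a": "ACGT", "b": "ACGT"})
        assert p_distance(msa, "a", "b", min_sites=1) == (0.0, 4)

    def test_one_mismatch_in_four(self):
        msa = _msa({"a": "ACGT", "b": "ACGA"})
        assert p_distance(msa, "a", "b", min_sites=1) == (0.25, 4)

    def test_gap_and_n_columns_excluded(self):
        # hand-worked: column 2 gapped in a, column 0 N in b -> 2 usable
        msa = _msa({"a": "AC-T", "b": "NCGT"})
        d, sites = p_distance(msa, "a", "b", min_sites=1)
        assert (d, sites) == (0.0, 2)

    def test_min_sites_marks_pair_uncomparable(self):
        msa = _msa({"a": "AC-T", "b": "ACGT"})
        d, sites = p_distance(msa, "a", "b", min_sites=50)
        assert np.isnan(d) and sites == 3

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        rows = {f"r{i}": "".join(rng.choice(list("ACGT-"), 60)) for i in range(4)}
        msa = _msa(rows, consensus="A" * 60)
        for a, b in itertools.combinations(rows, 2):
            assert p_distance(msa, a, b, 1) == p_distance(msa, b, a, 1)

    def test_hky_correction_exceeds_p_distance(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        s1 = bases[rng.integers(0, 4, 500)]
        s2 = s1.copy()
        flip = rng.random(500) < 0.3
        s2[flip] = bases[rng.integers(0, 4, int(flip.sum()))]
        msa = _msa({"a": "".join(s1), "b": "".join(s2)})
        raw = pairwise_distances(msa, 50, "none").values[0, 1]
        corr = pairwise_distances(msa, 50, "hky").values[0, 1]
        assert corr > raw > 0


def _quartet_oracle(ids, dm):
    """Least-squares fit of all three quartet topologies; returns the best
    split as a frozenset pair."""
    best = None
    for (a, b), (c, d) in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        # path-length design matrix for the 5 branches of topology ab|cd
        pairs = list(itertools.combinations(range(4), 2))
        A = np.zeros((6, 5))
        leaf_edge = {a: 0, b: 1, c: 2, d: 3}
        for r, (i, j) in enumerate(pairs):
            A[r, leaf_edge[i]] = 1
            A[r, leaf_edge[j]] = 1
            if {i, j} not in ({a, b}, {c, d}):
                A[r, 4] = 1
        y = np.array([dm[i, j] for i, j in pairs])
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(((A @ np.maximum(x, 0) - y) ** 2).sum())
        split = frozenset([frozenset({ids[a], ids[b]}),
                           frozenset({ids[c], ids[d]})])
        if best is None or rss < best[0]:
            best = (rss, split)
    return best[1]


class TestBuildTree:
    def test_two_copy_family_single_edge(self):
        tree = build_tree(_dm(["x", "y"], [[0, 0.1], [0.1, 0]]))
        tips = list(tree.tips())
        assert len(tips) == 2
        assert sum(t.length for t in tips) == pytest.approx(0.1)

    def test_nj_recovers_additive_quartet(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        ids = ["a", "b", "c", "d"]
        D = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        dm = _dm(ids, D)
        assert _quartet_oracle(ids, np.asarray(D, float)) == \
            frozenset([frozenset({"a", "b"}), frozenset({"c", "d"})])
        assert terminal_fork_pairs(build_tree(dm)) == [("a", "b"), ("c", "d")]

    def test_random_additive_quartets_match_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            # generate additive distances from random positive branch lengths
            e = rng.uniform(0.5, 3.0, 5)
            D = np.zeros((4, 4))
            leaf_edges = [e[0], e[1], e[2], e[3]]
            for i, j in itertools.combinations(range(4), 2):
                D[i, j] = D[j, i] = leaf_edges[i] + leaf_edges[j] + \
                    (e[4] if {i, j} not in ({0, 1}, {2, 3}) else 0)
            ids = ["a", "b", "c", "d"]
            oracle = _quartet_oracle(ids, D)
            cherries = terminal_fork_pairs(build_tree(_dm(ids, D)))
            got = frozenset(frozenset(p) for p in cherries)
            assert got == oracle

    def test_topology_invariant_under_input_permutation(self):
        ids = ["a", "b", "c", "d", "e"]
        rng = np.random.default_rng(3)
        # caterpillar-ish additive matrix with distinct entries
        base = np.array([0.0, 0.11, 0.35, 0.52, 0.71])
        D = np.abs(base[:, None] - base[None, :]) + \
            0.2 * (np.ones((5, 5)) - np.eye(5))
        ref = None
        for perm in itertools.islice(itertools.permutations(range(5)), 8):
            pids = [ids[i] for i in perm]
            PD = D[np.ix_(perm, perm)]
            cherries = set(terminal_fork_pairs(build_tree(_dm(pids, PD))))
            if ref is None:
                ref = cherries
            assert cherries == ref

    def test_single_copy_family_is_skipped(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_tree(_dm(["only"], [[0.0]]))

    def test_uncomparable_rows_dropped_before_inference(self):
        values = np.array([[0, 0.1, np.nan], [0.1, 0, np.nan],
                           [np.nan, np.nan, 0]])
        dm = DistanceMatrix(["a", "b", "c"], values,
                            np.full((3, 3), 100), 50)
        tree = build_tree(dm)
        assert sorted(t.name for t in tree.tips()) == ["a", "b"]


class TestTerminalForks:
    def test_two_leaf_tree(self):
        t = TreeNode.read(["(a:0.05,b:0.05);"])
        assert terminal_fork_pairs(t) == [("a", "b")]

    def test_balanced_four_leaf(self):
        t = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        assert terminal_fork_pairs(t) == [("a", "b"), ("c", "d")]

    def test_rooted_caterpillar_has_single_cherry(self):
        t = TreeNode.read(["(((a:1,b:1):1,c:2):1,d:3);"])
        assert terminal_fork_pairs(t) == [("a", "b")]

    def test_three_leaf_star_returns_closest_pair_only(self):
        t = TreeNode.read(["(a:0.05,b:0.06,c:0.4);"])
        assert terminal_fork_pairs(t) == [("a", "b")]

    def test_cherry_count_never_exceeds_half_the_leaves(self):
        rng = np.random.default_rng(9)
        for n in (2, 3, 4, 5, 8, 13):
            pts = np.sort(rng.uniform(0, 1, n))
            D = np.abs(pts[:, None] - pts[None, :]) + \
                0.05 * (np.ones((n, n)) - np.eye(n))
            ids = [f"t{i}" for i in range(n)]
            pairs = terminal_fork_pairs(build_tree(_dm(ids, D)))
            assert 1 <= len(pairs) <= n // 2


class TestFamilyAges:
    def test_two_identical_copies_age_zero(self):
        msa = _msa({"a": "ACGT" * 30, "b": "ACGT" * 30})
        dm = pairwise_distances(msa, 50)
        ages, dropped = family_ages(msa, dm, build_tree(dm), "fam")
        assert len(ages) == 1 and ages[0].age == 0.0 and not dropped

    def test_cherry_ages_bounded_for_planted_family(self):
        # 10 copies planted at d=0.02 from a 1 kb consensus: every cherry
        # age is below 2d + 3 binomial sd of the pairwise difference
        from mobilome.simulate import BurstSpec, FamilySpec, evolve_copy, make_consensus

        cons = make_consensus(FamilySpec("f", "RLX", 1000), 5)
        rows = {}
        for i in range(10):
            seq, _ = evolve_copy(cons, BurstSpec("f", 1, 0.02), rng_seed=50 + i)
            rows[f"c{i}"] = seq
        msa = MasterSlaveMSA("f", cons, rows=rows)
        dm = pairwise_distances(msa, 50)
        ages, _ = family_ages(msa, dm, build_tree(dm), "f")
        assert 1 <= len(ages) <= 5
        bound = 2 * 0.02 + 3 * np.sqrt(0.04 * 0.96 / 1000)
        assert all(a.age <= bound for a in ages)

    def test_age_equals_distance_matrix_entry_exactly(self):
        rng = np.random.default_rng(4)
        rows = {f"c{i}": "".join(rng.choice(list("ACGT"), 200))
                for i in range(6)}
        msa = _msa(rows, consensus="A" * 200)
        dm = pairwise_distances(msa, 50)
        ages, _ = family_ages(msa, dm, build_tree(dm), "f")
        for ca in ages:
            assert ca.age == dm[ca.copy_a, ca.copy_b]

    def test_branch_sum_variant_runs(self):
        msa = _msa({"a": "ACGT" * 30, "b": "ACGA" * 30, "c": "TCGT" * 30})
        dm = pairwise_distances(msa, 50)
        ages, _ = family_ages(msa, dm, build_tree(dm), "f", method="branch_sum")
        assert all(a.age >= 0 for a in ages)


class TestConsensusDivergence:
    def test_copy_equal_to_consensus(self):
        msa = _msa({"a": "ACGT" * 30}, consensus="ACGT" * 30)
        (d, sites), = copy_consensus_divergence(msa).values()
        assert d == 0.0 and sites == 120

    def test_all_gap_row_uncomparable(self):
        msa = _msa({"a": "-" * 120}, consensus="ACGT" * 30)
        (d, sites), = copy_consensus_divergence(msa).values()
        assert np.isnan(d) and sites == 0

    def test_planted_divergence_within_binomial_interval(self):
        from scipy import stats

        from mobilome.simulate import BurstSpec, FamilySpec, evolve_copy, make_consensus

        cons = make_consensus(FamilySpec("f", "RLX", 1000), 6)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.20) / 1000
        for seed in range(5):
            seq, _ = evolve_copy(cons, BurstSpec("f", 1, 0.20), rng_seed=seed)
            msa = MasterSlaveMSA("f", cons, rows={"c": seq})
            d, _ = copy_consensus_divergence(msa)["c"]
            assert lo <= d <= hi


class TestBurstDetection:
    def test_single_value_fills_one_bin(self):
        hist = burst_histogram([0.015] * 7)
        assert hist.counts.sum() == 7
        assert np.argmax(hist.counts) == 1  # bin [0.01, 0.02)
        assert detect_bursts(hist) == [0.015]

    def test_empty_ages_detect_nothing(self):
        hist = burst_histogram([])
        assert detect_bursts(hist) == []

    def test_flat_histogram_never_yields_two_peaks(self):
        hist = AgeHistogram(0.01, np.full(30, 4.0))
        assert len(detect_bursts(hist)) <= 1

    def test_bimodal_ages_separate_into_two_regions(self):
        rng = np.random.default_rng(12)
        ages = np.concatenate([
            rng.binomial(1000, 0.02, 100) / 1000,
            rng.binomial(1000, 0.20, 100) / 1000,
        ])
        hist = burst_histogram(ages)
        nz = np.nonzero(hist.counts)[0]
        gap = np.diff(nz).max()
        assert gap >= 5  # two regions separated by >= 5 empty bins
        peaks = detect_bursts(hist)
        assert len(peaks) == 2
        assert abs(peaks[0] - 0.02) <= 0.015
        assert abs(peaks[1] - 0.20) <= 0.015

    def test_stratified_counts_sum_to_total(self):
        ages = [0.01, 0.02, 0.21, 0.22, 0.05]
        labels = ["x", "y", "x", "x", "y"]
        hist = burst_histogram(ages, labels=labels)
        total = sum(hist.strata.values())
        assert np.array_equal(total, hist.counts)

    def test_out_of_range_ages_rejected(self):
        with pytest.raises(ValueError):
            burst_histogram([1.5])
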