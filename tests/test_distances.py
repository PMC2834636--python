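"""Alignment, TN93/JC distances, Ki summaries and the rank-sum test."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from salicoid import distances as dist
from salicoid.simulate import (evolve_indices, indices_to_seq,
                               tn93_rate_matrix)

from conftest import rng

BASES = "ACGT"


def gotoh_score(a, b, match=1, mismatch=-2, gap_open=-7, gap_extend=-2):
    """Independent affine-gap global alignment score (full DP)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def score_aligned_pair(sa, sb, match=1, mismatch=-2, gap_open=-7,
                       gap_extend=-2):
    """Score a gapped pair, dropping dual-gap columns."""
    score = 0.0
    in_gap = False
    for ca, cb in zip(sa, sb):
        if ca == "-" and cb == "-":
            continue
        if ca == "-" or cb == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += match if ca == cb else mismatch
            in_gap = False
    return score


def random_seq(n, g):
    return "".join(g.choice(list(BASES), size=n))


class TestAlignment:
    def test_pairwise_score_matches_full_dp_oracle(self):
        g = rng(0)
        for _ in range(30):
            a = random_seq(int(g.integers(3, 11)), g)
            b = random_seq(int(g.integers(3, 11)), g)
            _, _, score = dist.align_pair(a, b)
            assert score == pytest.approx(gotoh_score(a, b))

    def test_identical_triplet_aligns_without_gaps(self):
        seq = random_seq(50, rng(1))
        triplet = dist.align_triplet(seq, seq, seq)
        assert triplet.focal == triplet.paralog1 == triplet.paralog2 == seq

    def test_planted_deletion_recovered(self):
        g = rng(2)
        focal = random_seq(80, g)
        deleted = focal[:30] + focal[33:]
        triplet = dist.align_triplet(focal, deleted, focal)
        assert triplet.focal == focal
        assert triplet.paralog2 == focal
        assert triplet.paralog1.count("-") == 3
        gap_start = triplet.paralog1.index("-")
        assert triplet.paralog1[gap_start:gap_start + 3] == "---"
        # alignment content is the original sequence around the gap
        assert triplet.paralog1.replace("-", "") == deleted

    def test_merged_pairwise_scores_near_optimal(self):
        """Pairwise scores inside the merged triplet stay within the
        gap-merge penalty bound of the optimal pairwise scores."""
        g = rng(3)
        for _ in range(10):
            focal = random_seq(40, g)
            p1 = focal[:18] + focal[20:]          # deletion
            p2 = focal[:30] + "ACG" + focal[30:]  # insertion
            triplet = dist.align_triplet(focal, p1, p2)
            for a, b in (("focal", "paralog1"), ("focal", "paralog2"),
                         ("paralog1", "paralog2")):
                sa, sb = triplet.pair(a, b)
                opt = gotoh_score(sa.replace("-", ""), sb.replace("-", ""))
                got = score_aligned_pair(sa, sb)
                n_gap_runs = len([1 for x, y in zip(sa, sb)
                                  if (x == "-") != (y == "-")])
                assert got <= opt + 1e-9
                assert got >= opt - 7 * max(n_gap_runs, 1)


def balanced_pair(p=0.10, n=600):
    """Uniform composition with all substitution classes balanced."""
    a = "ACGT" * (n // 4)
    b = list(a)
    pos = {c: [i for i, x in enumerate(a) if x == c] for c in BASES}
    k = int(p * n / 6)
    # transitions: k of each class; transversions: 4k total (= 2/3 of
    # changes), placed composition-neutrally
    for i in pos["A"][:k]:
        b[i] = "G"
    for i in pos["C"][:k]:
        b[i] = "T"
    for i in pos["A"][k:2 * k]:
        b[i] = "C"
    for i in pos["C"][k:2 * k]:
        b[i] = "A"
    for i in pos["G"][:k]:
        b[i] = "T"
    for i in pos["T"][:k]:
        b[i] = "G"
    return a, "".join(b)


def ape_fixture():
    """The deterministic unequal-frequency pair scored with ape::dist.dna.

    Generated once with the generator below and handed to R's ape package
    (models TN93 and JC69); the returned distances are frozen in the tests.
    """
    g = np.random.default_rng(42)
    pi = np.array([0.3, 0.2, 0.2, 0.3])
    Q = tn93_rate_matrix(pi, 2.0, 4.0)
    anc = g.choice(4, size=800, p=pi)
    tip = evolve_indices(anc, expm(Q * 0.35), g)
    return indices_to_seq(anc), indices_to_seq(tip)


class TestKiPairwise:
    def test_identical_sequences_have_zero_distance(self):
        seq = random_seq(200, rng(4))
        est = dist.ki_pairwise(seq, seq)
        assert est.distance == 0.0
        assert est.sites_used == 200
        assert not est.saturated

    def test_reduces_to_equal_rate_closed_form(self):
        a, b = balanced_pair(0.10)
        expected = -0.75 * math.log(1 - 4 * 0.10 / 3)
        assert dist.ki_pairwise(a, b).distance == pytest.approx(expected,
                                                                abs=1e-4)
        assert dist.ki_pairwise(a, b, model="jc").distance == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1073, abs=5e-5)

    def test_matches_independent_tn93_implementation(self):
        a, b = ape_fixture()
        assert dist.ki_pairwise(a, b).distance == \
            pytest.approx(0.3482546943, abs=1e-9)
        assert dist.ki_pairwise(a, b, model="jc").distance == \
            pytest.approx(0.3386317850, abs=1e-9)

    def test_symmetric_in_arguments(self):
        a, b = ape_fixture()
        assert dist.ki_pairwise(a, b).distance == \
            pytest.approx(dist.ki_pairwise(b, a).distance)

    def test_pairwise_gap_deletion(self):
        est = dist.ki_pairwise("AC-GTACGTACGTACG", "ACCG-ACGTACGTACG")
        assert est.sites_used == 14

    def test_monotone_in_simulated_divergence(self):
        """Mean estimate increases over the 0.05-0.8 divergence grid."""
        Q = tn93_rate_matrix([0.25] * 4)
        g = np.random.default_rng(5)
        means = []
        for d in (0.05, 0.1, 0.2, 0.4, 0.6, 0.8):
            P = expm(Q * d)
            ests = []
            for _ in range(150):
                anc = g.choice(4, size=500)
                tip = evolve_indices(anc, P, g)
                ests.append(dist.ki_pairwise(indices_to_seq(anc),
                                             indices_to_seq(tip)).distance)
            means.append(np.mean(ests))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_saturation_flagged(self):
        a = "ACGT" * 50
        b = "CATG" * 50  # every site differs
        est = dist.ki_pairwise(a, b)
        assert est.saturated
        assert np.isfinite(est.distance)

    def test_zero_usable_sites_is_an_error(self):
        with pytest.raises(dist.EstimationError):
            dist.ki_pairwise("---", "AAA")


class TestSummaries:
    def test_singleton_summary(self):
        s = dist.summarize_ki([dist.KiEstimate("p", None, 100, 0.2)])
        assert (s.mean, s.median, s.sem) == (0.2, 0.2, 0.0)
        assert s.counts[-1] == 1
        assert s.bin_edges[-2] == pytest.approx(0.2)

    def test_mean_and_median_arithmetic(self):
        ests = [dist.KiEstimate("p", None, 100, d) for d in (0.1, 0.1, 0.4)]
        s = dist.summarize_ki(ests)
        assert s.mean == pytest.approx(0.2)
        assert s.median == pytest.approx(0.1)
        assert s.sem == pytest.approx(np.std([0.1, 0.1, 0.4], ddof=1)
                                      / math.sqrt(3))

    def test_histogram_counts_sum_to_n(self):
        g = rng(6)
        ests = [dist.KiEstimate("p", None, 100, float(d))
                for d in g.uniform(0, 1.4, size=57)]
        s = dist.summarize_ki(ests)
        assert sum(s.counts) == 57
        assert s.bin_edges[0] == 0.0
        assert s.bin_width == 0.1

    def test_saturated_kept_by_default_and_filterable(self):
        ests = [dist.KiEstimate("a", None, 100, 0.2),
                dist.KiEstimate("b", None, 100, 2.5, saturated=True)]
        assert dist.summarize_ki(ests).n == 2
        filtered = dist.summarize_ki(ests, keep_saturated=False)
        assert filtered.n == 1
        assert filtered.mean == pytest.approx(0.2)

    def test_empty_list_is_an_error(self):
        with pytest.raises(dist.EstimationError):
            dist.summarize_ki([])


def brute_force_ranksum_p(a, b):
    """Full enumeration over index partitions, independent implementation."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1 = len(a)
    mu = n1 * len(b) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_singletons_fully_overlap(self):
        res = dist.rank_sum_test([1.0], [1.0])
        assert res.U == 0.5
        assert res.p == 1.0

    def test_fully_separated_small_groups(self):
        res = dist.rank_sum_test([1, 2, 3, 4], [5, 6, 7])
        assert res.W == 10.0
        assert res.U == 0.0
        assert res.p == pytest.approx(2 / 35)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        g = rng(seed + 10)
        n1, n2 = int(g.integers(2, 8)), int(g.integers(2, 8))
        a = g.integers(0, 6, size=n1).astype(float)  # ties likely
        b = g.integers(0, 6, size=n2).astype(float)
        res = dist.rank_sum_test(a, b)
        assert res.method == "exact"
        assert res.p == pytest.approx(brute_force_ranksum_p(a, b))

    def test_normal_approximation_close_to_exact_at_crossover(self):
        g = rng(17)
        rel_errs = []
        for _ in range(10):
            a = g.normal(size=8)
            b = g.normal(loc=1.0, size=8)
            exact = dist.rank_sum_test(a, b, exact_below=9)
            approx = dist.rank_sum_test(a, b, exact_below=8)
            assert exact.method == "exact" and approx.method == "normal"
            if exact.p > 1e-3:
                rel_errs.append(abs(approx.p - exact.p) / exact.p)
        assert rel_errs and np.median(rel_errs) < 0.10

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha = 0.05 is nominal under the null."""
        g = rng(18)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            a = g.normal(size=115)
            b = g.normal(size=115)
            if dist.rank_sum_test(a, b).p < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 4 * math.sqrt(0.05 * 0.95 / n_sims)
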