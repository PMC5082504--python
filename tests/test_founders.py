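"""Founder-allele partitioning: ranked-cut search vs brute force, LD tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpqtl.founders import (
    FounderPartition,
    PartitionError,
    _anova_F,
    best_two_class_partition,
    founder_assignments,
    founder_means,
    ld_fisher,
    partition_at,
    resistant_probability,
)


def _toy_instance(rng, n_founders=5, n_per=12, spread=3.0):
    """RILs hard-assigned to founders with founder-specific means."""
    mu = rng.normal(0, spread, n_founders)
    assign = np.repeat(np.arange(n_founders), n_per)
    y = mu[assign] + rng.normal(0, 1.0, len(assign))
    P = np.zeros((len(assign), 8))
    P[np.arange(len(assign)), assign] = 1.0
    return pd.Series(y), P


def brute_force_best_cut(y, assign, means_by_founder, higher_is_resistant=True):
    """Exhaustive maximisation over ranked cuts (independent oracle)."""
    present = sorted(set(assign[assign >= 0]))
    order = sorted(present, key=lambda f: means_by_founder[f])
    best = (-np.inf, None)
    for cut in range(1, len(order)):
        low = set(order[:cut])
        groups = np.isin(assign, list(low)).astype(int)
        F = _anova_F(np.asarray(y), groups[assign >= 0] if (assign >= 0).all() else groups)
        if F > best[0]:
            best = (F, frozenset(order[cut:]) if higher_is_resistant else frozenset(low))
    return best


def brute_force_all_bipartitions(y, assign):
    """Max F over every bipartition of the represented founders."""
    present = sorted(set(assign[assign >= 0]))
    best = -np.inf
    for r in range(1, len(present)):
        for combo in itertools.combinations(present, r):
            groups = np.isin(assign, combo).astype(int)
            F = _anova_F(np.asarray(y), groups)
            best = max(best, F)
    return best


class TestFounderMeans:
    def test_means_and_counts_on_clean_toy(self):
        y = pd.Series([0.0] * 10 + [10.0] * 10)
        P = np.zeros((20, 8))
        P[:10, 0] = 1.0
        P[10:, 1] = 1.0
        means, counts, assign = founder_means(y, P)
        assert means[0] == pytest.approx(0.0)
        assert means[1] == pytest.approx(10.0)
        assert list(counts[:2]) == [10, 10]
        assert np.isnan(means[2:]).all()

    def test_single_founder_is_an_error(self):
        y = pd.Series(np.random.default_rng(0).normal(size=15))
        P = np.zeros((15, 8))
        P[:, 2] = 1.0
        with pytest.raises(PartitionError):
            founder_means(y, P)

    def test_ambiguous_rils_excluded(self):
        P = np.full((10, 8), 1 / 8)
        P[:5, 0] = 1.0
        P[:5, 1:] = 0.0
        P[5:, 1] = 0.9  # below the 0.95 threshold
        P[5:, 0] = 0.1 - 7e-9
        y = pd.Series(np.arange(10.0))
        assign = founder_assignments(P)
        assert (assign[:5] == 0).all()
        assert (assign[5:] == -1).all()


class TestBestPartition:
    def test_clean_four_vs_four_split(self):
        means = np.array([0, 0, 0, 0, 10, 10, 10, 10], dtype=float)
        assign = np.repeat(np.arange(8), 10)
        y = pd.Series(means[assign])
        part = best_two_class_partition(means, y, assign)
        assert part.resistant_founders == frozenset({5, 6, 7, 8})
        assert math.isinf(part.best_F)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(60):
            k = int(rng.integers(2, 7))
            y, P = _toy_instance(rng, n_founders=k, n_per=int(rng.integers(5, 15)))
            means, counts, assign = founder_means(y, P)
            part = best_two_class_partition(means, y, assign)
            F_oracle, res_oracle = brute_force_best_cut(
                y, assign, {f: means[f] for f in range(k)})
            assert part.best_F == pytest.approx(F_oracle, rel=1e-10)
            assert frozenset(f - 1 for f in part.resistant_founders) == res_oracle
            # ranked-cut optimum is bounded by the all-bipartition optimum
            assert part.best_F <= brute_force_all_bipartitions(y, assign) + 1e-9

    def test_partition_invariant_to_founder_relabelling(self, rng):
        y, P = _toy_instance(rng, n_founders=4)
        means, _, assign = founder_means(y, P)
        part = best_two_class_partition(means, y, assign)
        # relabel founders by a permutation
        perm = rng.permutation(8)
        P2 = P[:, np.argsort(perm)]
        means2, _, assign2 = founder_means(y, P2)
        part2 = best_two_class_partition(means2, y, assign2)
        relabelled = frozenset(int(perm[f - 1]) + 1 for f in part.resistant_founders)
        assert part2.resistant_founders == relabelled
        assert part2.best_F == pytest.approx(part.best_F, rel=1e-12)

    def test_tie_breaks_toward_smaller_resistant_class(self):
        # two founders, equal counts, symmetric means: single cut, fine;
        # force a tie with four founders in two identical pairs
        means = np.array([0, 0, 5, 5, np.nan, np.nan, np.nan, np.nan])
        assign = np.repeat([0, 1, 2, 3], 8)
        y = pd.Series(means[assign])
        part = best_two_class_partition(means, y, assign)
        # cuts between the pairs give F=inf once; within-pair cuts are worse;
        # the 2v2 split is the unique max here
        assert part.resistant_founders == frozenset({3, 4})


class TestResistantProbability:
    def test_unit_vector_and_uniform_rows(self):
        part = FounderPartition(None, np.zeros(8), np.zeros(8, dtype=int),
                                {f: ("resistant" if f <= 3 else "susceptible")
                                 for f in range(1, 9)}, 1.0, 0)
        P = np.vstack([np.eye(8)[0], np.full(8, 1 / 8)])
        pr = resistant_probability(part, P, ["a", "b"])
        assert pr["a"] == pytest.approx(1.0)
        assert pr["b"] == pytest.approx(3 / 8)

    def test_resistant_plus_susceptible_is_one(self, rng):
        raw = rng.dirichlet(np.ones(8), size=30)
        part = FounderPartition(None, np.zeros(8), np.zeros(8, dtype=int),
                                {f: ("resistant" if f in (2, 5, 7) else "susceptible")
                                 for f in range(1, 9)}, 1.0, 0)
        flipped = FounderPartition(None, np.zeros(8), np.zeros(8, dtype=int),
                                   {f: ("susceptible" if f in (2, 5, 7) else "resistant")
                                    for f in range(1, 9)}, 1.0, 0)
        ids = [str(i) for i in range(30)]
        total = resistant_probability(part, raw, ids) + resistant_probability(flipped, raw, ids)
        assert np.allclose(total, 1.0)


class TestLdFisher:
    def _perfect_partition(self, resistant):
        return FounderPartition(None, np.zeros(8), np.zeros(8, dtype=int),
                                {f: ("resistant" if f in resistant else "susceptible")
                                 for f in range(1, 9)}, 1.0, 0)

    def test_perfectly_associated_loci(self):
        """Table [[10,0],[0,10]] has exact two-sided p = 2 / C(20,10)."""
        pa = self._perfect_partition({1})
        pb = self._perfect_partition({2})
        A = np.zeros((20, 8))
        B = np.zeros((20, 8))
        A[:10, 0] = 1.0; A[10:, 3] = 1.0     # locus A: resistant then susceptible
        B[:10, 1] = 1.0; B[10:, 4] = 1.0     # locus B mirrors locus A
        odds, p, table, flags = ld_fisher(A, pa, B, pb, [str(i) for i in range(20)])
        assert table.tolist() == [[10, 0], [0, 10]]
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_degenerate_margin_flagged_p_one(self):
        pa = self._perfect_partition({1})
        pb = self._perfect_partition({2})
        A = np.zeros((12, 8)); A[:, 0] = 1.0          # everyone resistant at A
        B = np.zeros((12, 8)); B[:6, 1] = 1.0; B[6:, 4] = 1.0
        odds, p, table, flags = ld_fisher(A, pa, B, pb, [str(i) for i in range(12)])
        assert p == 1.0
        assert "degenerate_table" in flags

    def test_independent_loci_p_uniform(self, rng):
        """Null calibration: p approximately Uniform(0,1) across replicates."""
        pa = self._perfect_partition({1})
        pb = self._perfect_partition({2})
        ps = []
        for _ in range(200):
            n = 300
            a = rng.random(n) < 0.4
            b = rng.random(n) < 0.5
            A = np.zeros((n, 8)); A[a, 0] = 1.0; A[~a, 3] = 1.0
            B = np.zeros((n, 8)); B[b, 1] = 1.0; B[~b, 4] = 1.0
            _, p, _, _ = ld_fisher(A, pa, B, pb, [str(i) for i in range(n)])
            ps.append(p)
        # Fisher exact p-values are discrete and conservative; KS against
        # Uniform(0,1) must not reject at alpha = 0.01 in the enriched sense
        assert stats.kstest(ps, "uniform").pvalue > 0.01 or np.mean(np.array(ps) < 0.05) <= 0.07


def test_partition_at_recovers_planted_split(qtl_panel):
    from mpqtl.pheno import fit_baseline, ril_blups
    cfg, panel, vials = qtl_panel
    bl = ril_blups(fit_baseline(vials))
    part = partition_at(bl, panel.at("2L", 1500), "q1")
    assert part.resistant_founders == frozenset({1, 2, 3})
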