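"""Genome scan: least-squares oracle equivalence, permutation machinery."""

import numpy as np
import pandas as pd
import pytest

from mpqtl.scan import (
    PermutationNull,
    genome_scan,
    genomewide_pvalue,
    genomewide_threshold,
    permutation_null,
    position_lod,
    refine_interval,
    support_intervals,
)


def oracle_lod_F(y, P, cov=None):
    """Independent normal-equations least-squares oracle."""
    n = len(y)
    cols = [np.ones((n, 1))]
    if cov is not None:
        cols.append(np.atleast_2d(cov.T).T)
    X0 = np.hstack(cols)
    X1 = np.hstack(cols + [P])
    b0, _, rank0, _ = np.linalg.lstsq(X0, y, rcond=None)
    b1, _, rank1, _ = np.linalg.lstsq(X1, y, rcond=None)
    r0 = y - X0 @ b0
    r1 = y - X1 @ b1
    rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
    lod = 0.5 * n * np.log10(rss0 / rss1)
    dfn = rank1 - rank0
    dfd = n - rank1
    F = ((rss0 - rss1) / dfn) / (rss1 / dfd)
    return lod, F, dfn, dfd


def _random_instance(rng):
    n = int(rng.integers(12, 31))
    k = int(rng.integers(2, 5))
    # soft probability rows over k founders (rest zero), rows sum to 1
    raw = rng.dirichlet(np.ones(k), size=n)
    P = np.zeros((n, 8))
    P[:, :k] = raw
    y = rng.normal(size=n)
    return y, P


def test_position_lod_matches_bruteforce_oracle(rng):
    for _ in range(150):
        y, P = _random_instance(rng)
        sp = position_lod(y, P)
        lod, F, dfn, dfd = oracle_lod_F(y, P)
        assert sp.lod == pytest.approx(lod, abs=1e-9)
        assert sp.F == pytest.approx(F, rel=1e-8)
        assert (sp.df_num, sp.df_den) == (dfn, dfd)


def test_position_lod_with_covariate_matches_oracle(rng):
    for _ in range(50):
        y, P = _random_instance(rng)
        cov = rng.normal(size=len(y))
        sp = position_lod(y, P, covariate=cov)
        lod, _, _, _ = oracle_lod_F(y, P, cov=cov)
        assert sp.lod == pytest.approx(lod, abs=1e-9)


def test_constant_phenotype_gives_zero_lod_everywhere(null_panel):
    _, _, panel = null_panel
    y = pd.Series(2.0, index=panel.ril_ids)
    sp = position_lod(y, panel.at("2L", 1000))
    assert sp.F == 0.0 and sp.lod == 0.0
    scan = genome_scan(y, panel)
    assert (scan["lod"] == 0).all()


def test_lod_invariant_to_affine_blup_transform(null_panel, rng):
    _, _, panel = null_panel
    y = pd.Series(rng.normal(size=panel.n_ril), index=panel.ril_ids)
    s1 = genome_scan(y, panel)
    s2 = genome_scan(3.7 * y - 11.0, panel)
    assert np.abs(s1["lod"] - s2["lod"]).max() < 1e-8


def test_scan_invariant_to_ril_order(null_panel, rng):
    _, _, panel = null_panel
    y = pd.Series(rng.normal(size=panel.n_ril), index=panel.ril_ids)
    order = rng.permutation(panel.n_ril)
    s1 = genome_scan(y, panel)
    s2 = genome_scan(y, panel.reorder(list(order)))
    assert np.abs(s1["lod"] - s2["lod"]).max() < 1e-8


def test_planted_signal_recovered_within_two_grid_steps(null_panel, rng):
    """Phenotype built from founder-1 probability at a chosen position."""
    _, _, panel = null_panel
    target = ("2R", 1500)
    signal = panel.at(*target)[:, 0]
    for _ in range(5):
        y = pd.Series(signal + 0.01 * rng.normal(size=panel.n_ril), index=panel.ril_ids)
        scan = genome_scan(y, panel)
        pk = scan.loc[scan["lod"].idxmax()]
        assert pk["arm"] == "2R"
        near = abs(pk["pos_kb"] - 1500) <= 2 * panel.grid.step_kb
        # positions whose founder-1 column matches the target's are exactly
        # equivalent designs for this phenotype: mapping resolution is set
        # by informative recombination, not grid spacing
        equivalent = np.array_equal(panel.at("2R", pk["pos_kb"])[:, 0], signal)
        assert near or equivalent


def test_rank_deficiency_reduces_df(rng):
    """A founder absent at a position lowers df_num without crashing."""
    n = 40
    f = rng.integers(0, 3, n)  # founders 4..8 absent
    P = np.zeros((n, 8))
    P[np.arange(n), f] = 1.0
    y = rng.normal(size=n)
    sp = position_lod(y, P)
    assert sp.df_num == 2
    assert sp.rank_deficient


class TestPermutation:
    def test_deterministic_given_seed(self, null_panel, rng):
        _, _, panel = null_panel
        y = pd.Series(rng.normal(size=panel.n_ril), index=panel.ril_ids)
        n1 = permutation_null(y, panel, 25, seed=7)
        n2 = permutation_null(y, panel, 25, seed=7)
        assert np.array_equal(n1.max_lods, n2.max_lods)

    def test_null_max_lod_grows_with_scanned_positions(self, null_panel, rng):
        """More tested positions -> stochastically larger genomewide max."""
        from mpqtl import GenomeGrid, SimConfig, simulate_panel
        _, _, big = null_panel  # 600 positions
        small_cfg = SimConfig(n_ril=150, grid=GenomeGrid.toy(arm_kb=500), seed=101)
        _, small = simulate_panel(small_cfg)  # 50 positions
        y = pd.Series(rng.normal(size=150), index=big.ril_ids)
        ys = pd.Series(y.to_numpy(), index=small.ril_ids)
        nb = permutation_null(y, big, 150, seed=3)
        ns = permutation_null(ys, small, 150, seed=3)
        assert nb.max_lods.mean() > ns.max_lods.mean()

    def test_threshold_is_order_statistic(self):
        null = PermutationNull(np.arange(1.0, 101.0), 100, 0)
        assert genomewide_threshold(null, 0.05) == 96.0
        assert genomewide_threshold(null, 1.0) == 1.0
        with pytest.raises(ValueError):
            genomewide_threshold(null, 0.001)  # resolution insufficient

    def test_threshold_monotone_in_alpha(self, rng):
        null = PermutationNull(rng.exponential(size=500), 500, 0)
        alphas = [0.01, 0.05, 0.1, 0.5, 1.0]
        thr = [genomewide_threshold(null, a) for a in alphas]
        assert all(a >= b for a, b in zip(thr, thr[1:]))

    def test_pvalue_add_one_convention(self, rng):
        null = PermutationNull(np.linspace(0, 5, 2000), 2000, 0)
        assert genomewide_pvalue(null, 10.0) == pytest.approx(1 / 2001)
        assert genomewide_pvalue(null, -1.0) == 1.0
        # non-increasing in the observed statistic
        obs = np.sort(rng.uniform(0, 6, 50))
        ps = [genomewide_pvalue(null, o) for o in obs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestIntervals:
    def test_delta_profile_gives_single_step_intervals(self):
        pos = np.arange(100, 1100, 10)
        lod = np.zeros(len(pos))
        lod[42] = 10.0
        ipk, bayes, drop = support_intervals(pos, lod)
        assert ipk == 42
        assert bayes == (pos[42], pos[42])
        assert drop == (pos[42], pos[42])

    def test_quadratic_profile_matches_closed_form_drop(self):
        """LOD(x) = L - c (x - x0)^2 has 2-LOD support at x0 +/- sqrt(2/c)."""
        pos = np.arange(0, 2000, 10.0)
        x0, c, L = 1000.0, 1e-4, 8.0
        lod = np.maximum(L - c * (pos - x0) ** 2, 0.0)
        ipk, bayes, drop = support_intervals(pos, lod, lod_drop=2.0)
        half = np.sqrt(2.0 / c)
        assert abs(drop[0] - (x0 - half)) <= 10
        assert abs(drop[1] - (x0 + half)) <= 10
        assert drop[0] <= pos[ipk] <= drop[1]
        assert bayes[0] <= pos[ipk] <= bayes[1]

    def test_refine_interval_brackets_planted_peak(self, qtl_panel):
        from mpqtl.pheno import fit_baseline, ril_blups
        cfg, panel, vials = qtl_panel
        bl = ril_blups(fit_baseline(vials))
        iv = refine_interval(bl, panel, "2L", (1000, 2000))
        assert iv.bayes_ci[0] <= 1500 <= iv.bayes_ci[1]
        assert iv.lod_drop_ci[0] <= iv.peak_pos_kb <= iv.lod_drop_ci[1]

    def test_edge_peak_warns(self, qtl_panel):
        """A window that excludes the true peak leaves the local maximum on
        the window edge and triggers a warning."""
        from mpqtl.pheno import fit_baseline, ril_blups
        cfg, panel, vials = qtl_panel
        bl = ril_blups(fit_baseline(vials))
        with pytest.warns(UserWarning, match="edge"):
            refine_interval(bl, panel, "2L", (1510, 2500))
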