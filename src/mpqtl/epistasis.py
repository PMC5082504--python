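"""Epistasis: pairwise QTL interaction tests and modifier genome scans.

Two complementary detectors.  ``pairwise_epistasis`` tests an interaction
between two mapped QTL in the vial-level mixed model

    y = beta + QTL_g + QTL_h + QTL_g:QTL_h + date + RIL + eps

fitted by maximum likelihood, with a 1-df likelihood-ratio test; the test
is only reported when all four joint genotype classes hold at least
``min_class_n`` RILs (rare-class pairs, such as a QTL with very few
resistant lines, are skipped with the reason recorded).

``modifier_scan`` hunts loci that alter a known QTL's effect even without
a main effect of their own: at every grid position an OLS model on the
per-RIL BLUPs

    y = beta + QTL_g + Locus_h + QTL_g:Locus_h + eps

is compared with the same model lacking the interaction; the interaction
LOD is the log10 likelihood ratio.  The known QTL enters as the continuous
resistant probability (configurable to a two-level class), and founder
columns with less than ``min_mass`` expected carriers at a position are
pooled before forming interaction products.  Genomewide significance uses
the same phenotype-permutation machinery as the main scans.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import fit_crossed
from .panel import Panel
from .scan import PermutationNull, _lod_from_rss, _null_basis, _orth, genomewide_threshold

logger = logging.getLogger(__name__)

_CHUNK = 256


@dataclass
class EpistasisTest:
    """Pairwise interaction test between two mapped QTL."""

    qtl_pair: tuple
    main_effects: tuple
    interaction: float
    lrt: float
    p: float
    class_counts: np.ndarray     # 2x2 RIL counts (susceptible/resistant at each locus)
    skipped: bool = False
    skip_reason: Optional[str] = None


def pairwise_epistasis(vials: pd.DataFrame, class_a: pd.Series, class_b: pd.Series,
                       min_class_n: int = 10,
                       pair_ids: tuple = ("qtl_a", "qtl_b")) -> EpistasisTest:
    """ML likelihood-ratio test for epistasis between two QTL.

    ``class_a``/``class_b`` give each RIL's hard allele class (0 =
    susceptible, 1 = resistant) at the two loci; RILs missing a class are
    excluded.  Random date and RIL terms are retained in both models.
    """
    cls = pd.DataFrame({"a": class_a, "b": class_b}).dropna()
    counts = np.zeros((2, 2), dtype=np.int64)
    a = cls["a"].astype(int).to_numpy()
    b = cls["b"].astype(int).to_numpy()
    if not set(np.unique(a)) <= {0, 1} or not set(np.unique(b)) <= {0, 1}:
        raise ValueError("allele classes must be 0/1")
    np.add.at(counts, (a, b), 1)
    if counts.min() < min_class_n:
        reason = (f"sparse genotype class: min joint class count {int(counts.min())} "
                  f"< {min_class_n}")
        logger.info("pairwise_epistasis %s skipped: %s", pair_ids, reason)
        return EpistasisTest(pair_ids, (math.nan, math.nan), math.nan, math.nan,
                             math.nan, counts, skipped=True, skip_reason=reason)

    v = vials[vials["ril_id"].isin(cls.index)].copy()
    av = cls["a"].astype(float).reindex(v["ril_id"]).to_numpy()
    bv = cls["b"].astype(float).reindex(v["ril_id"]).to_numpy()
    y = v["value"].to_numpy(float)
    ones = np.ones(len(v))
    X_full = np.column_stack([ones, av, bv, av * bv])
    X_red = np.column_stack([ones, av, bv])
    names = ["intercept", pair_ids[0], pair_ids[1], f"{pair_ids[0]}:{pair_ids[1]}"]
    full = fit_crossed(y, X_full, v["date"].to_numpy(), v["ril_id"].to_numpy(),
                       method="ml", fixed_names=names)
    red = fit_crossed(y, X_red, v["date"].to_numpy(), v["ril_id"].to_numpy(),
                      method="ml", fixed_names=names[:3])
    lrt = max(2.0 * (full.loglik - red.loglik), 0.0)
    p = float(stats.chi2.sf(lrt, 1))
    mains = (float(full.beta[full.fixed_names.index(pair_ids[0])]),
             float(full.beta[full.fixed_names.index(pair_ids[1])]))
    inter = float(full.beta[full.fixed_names.index(names[3])])
    return EpistasisTest(pair_ids, mains, inter, float(lrt), p, counts)


# ---------------------------------------------------------------------------
# modifier interaction genome scan
# ---------------------------------------------------------------------------

def _qtl_vector(qtl_resistant_prob, panel: Panel) -> np.ndarray:
    q = qtl_resistant_prob
    if isinstance(q, pd.Series):
        q = q.reindex(panel.ril_ids)
        if q.isna().any():
            raise ValueError("qtl resistant probability missing for some RILs")
        q = q.to_numpy(dtype=float)
    else:
        q = np.asarray(q, dtype=float)
        if len(q) != panel.n_ril:
            raise ValueError("qtl vector length must match panel")
    return q


def _pooled_founder_block(block: np.ndarray, min_mass: float) -> np.ndarray:
    """Pool founder columns whose probability mass is below ``min_mass``.

    ``block`` is (P, n, 8).  At each position, columns with total expected
    carrier count < min_mass are summed into the first such column and the
    others zeroed; the numerical rank machinery then adjusts the df.
    """
    mass = block.sum(axis=1)  # (P, 8)
    low = mass < min_mass
    if not low.any():
        return block
    out = block.copy()
    for pidx in np.nonzero(low.any(axis=1))[0]:
        cols = np.nonzero(low[pidx])[0]
        if len(cols) > 1:
            pooled = out[pidx, :, cols].sum(axis=0)
            out[pidx, :, cols] = 0.0
            out[pidx, :, cols[0]] = pooled
    return out


def _interaction_lod_block(block: np.ndarray, q: np.ndarray, Q0: np.ndarray,
                           Yr: np.ndarray, min_mass: float):
    """Interaction LOD for a block of positions, vectorised over phenotype
    columns.

    Returns (lods, dfs): lods is (P, B) for the B columns of Yr (already
    residualised against the null basis), dfs is (P,).
    """
    n = block.shape[1]
    blk = _pooled_founder_block(block, min_mass)
    # main-effect founder basis beyond [1, q]
    Xm = blk - np.matmul(Q0, np.matmul(Q0.T, blk))
    Um, sm, _ = np.linalg.svd(Xm, full_matrices=False)
    keep = sm > np.maximum(sm[:, :1] * n * np.finfo(float).eps * 8, 1e-12)
    Um = Um * keep[:, None, :]
    # interaction columns residualised against null + mains
    Xi = blk * q[None, :, None]
    Xi = Xi - np.matmul(Q0, np.matmul(Q0.T, Xi))
    Xi = Xi - np.matmul(Um, np.matmul(Um.transpose(0, 2, 1), Xi))
    Ui, si, _ = np.linalg.svd(Xi, full_matrices=False)
    keepi = si > np.maximum(si[:, :1] * n * np.finfo(float).eps * 8, 1e-10)
    Ui = Ui * keepi[:, None, :]
    dfs = keepi.sum(axis=1)

    rss0 = (Yr ** 2).sum(axis=0)                        # (B,)
    Tm = np.einsum("pnk,nb->pkb", Um, Yr, optimize=True)
    rss_red = rss0[None, :] - (Tm ** 2).sum(axis=1)
    Ti = np.einsum("pnk,nb->pkb", Ui, Yr, optimize=True)
    rss_full = rss_red - (Ti ** 2).sum(axis=1)
    lods = _lod_from_rss(n, rss_red, rss_full)
    lods[dfs == 0] = 0.0
    return lods, dfs


def modifier_scan(blups_corrected: pd.Series, panel: Panel, qtl_resistant_prob,
                  min_mass: float = 5.0) -> pd.DataFrame:
    """Genomewide scan for loci that interact with a known QTL.

    Returns one row per grid position: arm, pos_kb, int_lod, df.
    """
    y = blups_corrected.reindex(panel.ril_ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("blups missing for some panel RILs")
    q = _qtl_vector(qtl_resistant_prob, panel)
    Q0 = _null_basis(panel.n_ril, q[:, None])
    yr = (y - Q0 @ (Q0.T @ y))[:, None]

    frames = []
    for a in panel.grid.arms:
        block = np.ascontiguousarray(panel.arm_block(a.name).transpose(1, 0, 2))
        pos = panel.grid.positions(a.name)
        lods = np.empty(len(pos))
        dfs = np.empty(len(pos), dtype=int)
        for s in range(0, len(pos), _CHUNK):
            l, d = _interaction_lod_block(block[s:s + _CHUNK], q, Q0, yr, min_mass)
            lods[s:s + _CHUNK] = l[:, 0]
            dfs[s:s + _CHUNK] = d
        frames.append(pd.DataFrame({"arm": a.name, "pos_kb": pos,
                                    "int_lod": np.maximum(lods, 0.0), "df": dfs}))
    return pd.concat(frames, ignore_index=True)


def modifier_null(blups_corrected: pd.Series, panel: Panel, qtl_resistant_prob,
                  n_perm: int = 1000, seed: int = 0,
                  min_mass: float = 5.0) -> PermutationNull:
    """Permutation null of the genomewide maximum interaction LOD.

    BLUPs are permuted across RILs; the QTL covariate stays attached to the
    genotypes, and both the full and main-effects-only models are refitted
    for every permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = blups_corrected.reindex(panel.ril_ids).to_numpy(dtype=float)
    q = _qtl_vector(qtl_resistant_prob, panel)
    n = panel.n_ril
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y[rng.permutation(n)]
    Q0 = _null_basis(n, q[:, None])
    Yr = perms - Q0 @ (Q0.T @ perms)

    max_lod = np.zeros(n_perm)
    for a in panel.grid.arms:
        block = np.ascontiguousarray(panel.arm_block(a.name).transpose(1, 0, 2))
        for s in range(0, block.shape[0], _CHUNK):
            lods, _ = _interaction_lod_block(block[s:s + _CHUNK], q, Q0, Yr, min_mass)
            np.maximum(max_lod, lods.max(axis=0), out=max_lod)
    return PermutationNull(max_lods=max_lod, n_perm=n_perm, seed=seed)


def modifier_threshold(blups_corrected: pd.Series, panel: Panel, qtl_resistant_prob,
                       n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
                       min_mass: float = 5.0) -> float:
    """alpha-level genomewide threshold for the interaction LOD."""
    null = modifier_null(blups_corrected, panel, qtl_resistant_prob,
                         n_perm=n_perm, seed=seed, min_mass=min_mass)
    return genomewide_threshold(null, alpha)
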