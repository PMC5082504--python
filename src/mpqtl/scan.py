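"""Founder-haplotype genome scans with permutation significance.

At every grid position the RIL phenotype (usually a date-corrected BLUP) is
regressed on the eight founder genotype probabilities; the model-comparison
F statistic is converted to a LOD score

    LOD = (n / 2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares of the null model (intercept, plus
any covariate) and RSS1 that of the model with the founder probabilities
added.  Because the founder probabilities at a position sum to one, the full
design has at most seven independent founder columns beyond the intercept;
rank is determined numerically per position so absent founders simply reduce
the degrees of freedom.

Genomewide significance comes from permuting phenotypes across RILs while
genotypes (and genotype-linked covariates) stay attached to the genomes,
recording the maximum LOD per permutation.  Internally each position is
reduced once to an orthonormal basis of its founder columns (residualised
against the null design), making thresholds exact least-squares while
vectorising over permutations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import Panel

logger = logging.getLogger(__name__)

_CHUNK = 512  # positions per block in vectorised passes


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ScanPoint:
    """Association summary at one genome position."""

    arm: Optional[str]
    pos_kb: Optional[float]
    F: float
    df_num: int
    df_den: int
    lod: float
    rank_deficient: bool = False


@dataclass
class PermutationNull:
    """Null distribution of the genomewide maximum LOD."""

    max_lods: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        self.max_lods = np.asarray(self.max_lods, dtype=float)
        if len(self.max_lods) != self.n_perm:
            raise ValueError("max_lods length must equal n_perm")


@dataclass
class QtlInterval:
    """Refined QTL peak with Bayesian and LOD-drop support intervals."""

    arm: str
    peak_pos_kb: float
    peak_lod: float
    bayes_ci: tuple
    lod_drop_ci: tuple
    genomewide_p: Optional[float] = None


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _as_matrix(covariate, ril_ids: Sequence[str]) -> Optional[np.ndarray]:
    """Align a per-RIL covariate (Series/DataFrame/array) with panel order."""
    if covariate is None:
        return None
    if isinstance(covariate, pd.Series):
        covariate = covariate.to_frame()
    if isinstance(covariate, pd.DataFrame):
        missing = [r for r in ril_ids if r not in covariate.index]
        if missing:
            raise ValueError(f"covariate missing {len(missing)} RIL(s), e.g. {missing[0]!r}")
        M = covariate.loc[list(ril_ids)].to_numpy(dtype=float)
    else:
        M = np.asarray(covariate, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        if M.shape[0] != len(ril_ids):
            raise ValueError("covariate rows must match panel RILs")
    return M


def _orth(M: np.ndarray, tol_scale: float = 1.0) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, numerical rank)."""
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0:
        return U[:, :0]
    keep = s > s[0] * max(M.shape) * np.finfo(float).eps * tol_scale
    return U[:, keep]


def _null_basis(n: int, covariate: Optional[np.ndarray]) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariate is not None:
        cols.append(covariate)
    return _orth(np.hstack(cols))


def _position_bases(block: np.ndarray, Q0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position orthonormal bases of founder columns beyond the null.

    ``block`` has shape (P, n, 8).  Returns (U, ranks): U is (P, n, 8) with
    columns beyond each position's rank zeroed; ranks is (P,).
    """
    Xr = block - Q0 @ (Q0.T @ block)
    U, s, _ = np.linalg.svd(Xr, full_matrices=False)
    smax = s[:, :1]
    tol = smax * block.shape[1] * np.finfo(float).eps * 8
    keep = s > np.maximum(tol, 1e-12)
    U = U * keep[:, None, :]
    return U, keep.sum(axis=1)


def _lod_from_rss(n: int, rss0, rss1) -> np.ndarray:
    """LOD = (n/2) log10(RSS0/RSS1), guarded against degenerate fits.

    A perfect fit (RSS1 numerically zero) is capped relative to RSS0 so the
    LOD stays finite; a null model that already fits perfectly (RSS0 ~ 0,
    e.g. a constant phenotype) yields LOD 0.
    """
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.maximum(np.asarray(rss1, dtype=float), rss0 * 1e-280)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(rss0 / rss1)
    return np.where(rss0 > 0, lod, 0.0)


# ---------------------------------------------------------------------------
# single-position test
# ---------------------------------------------------------------------------

def _degenerate_null(y: np.ndarray, rss0: float) -> bool:
    """True when the null residual is numerically zero (constant phenotype)."""
    scale = float(y @ y) + 1.0
    return rss0 <= scale * (len(y) * np.finfo(float).eps) ** 2


def position_lod(blups: Union[pd.Series, np.ndarray], prob_rows: np.ndarray,
                 covariate=None, arm: Optional[str] = None,
                 pos_kb: Optional[float] = None) -> ScanPoint:
    """Regression of RIL phenotypes on founder probabilities at one position.

    Parameters
    ----------
    blups : Series or array
        One phenotype (BLUP) per RIL.
    prob_rows : array (n, 8)
        Founder genotype probabilities per RIL at the position.
    covariate : optional
        Extra fixed columns included in both the null and full models, so
        the LOD measures the position's increment.
    """
    y = np.asarray(blups.to_numpy() if isinstance(blups, pd.Series) else blups, dtype=float)
    P = np.asarray(prob_rows, dtype=float)
    n = len(y)
    if P.shape != (n, 8):
        raise ValueError("prob_rows must have shape (n_ril, 8)")
    if n <= 9:
        raise ValueError("need more than 9 RILs")
    cov = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    Q0 = _null_basis(n, cov)
    y_r = y - Q0 @ (Q0.T @ y)
    rss0 = float(y_r @ y_r)
    U, ranks = _position_bases(P[None], Q0)
    rank = int(ranks[0])
    proj = U[0].T @ y_r
    rss1 = rss0 - float(proj @ proj)
    q0 = Q0.shape[1]
    df_den = n - q0 - rank
    if rank == 0 or df_den <= 0 or _degenerate_null(y, rss0):
        return ScanPoint(arm, pos_kb, 0.0, rank, max(df_den, 0), 0.0, rank_deficient=rank < 7)
    F = ((rss0 - rss1) / rank) / (rss1 / df_den) if rss1 > 0 else math.inf
    lod = float(_lod_from_rss(n, rss0, rss1))
    return ScanPoint(arm, pos_kb, float(F), rank, df_den, max(lod, 0.0),
                     rank_deficient=rank < 7)


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def genome_scan(blups: pd.Series, panel: Panel, covariate=None) -> pd.DataFrame:
    """LOD profile over the whole grid.

    ``blups`` is aligned to the panel by RIL id.  Returns a frame with one
    row per position: arm, pos_kb, F, df_num, df_den, lod.
    """
    y = blups.reindex(panel.ril_ids).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("blups missing for some panel RILs")
    n = panel.n_ril
    cov = _as_matrix(covariate, panel.ril_ids)
    Q0 = _null_basis(n, cov)
    q0 = Q0.shape[1]
    y_r = y - Q0 @ (Q0.T @ y)
    rss0 = float(y_r @ y_r)
    degenerate = _degenerate_null(y, rss0)

    frames = []
    for a in panel.grid.arms:
        block = np.ascontiguousarray(panel.arm_block(a.name).transpose(1, 0, 2))
        pos = panel.grid.positions(a.name)
        lods = np.empty(len(pos))
        Fs = np.empty(len(pos))
        dfn = np.empty(len(pos), dtype=int)
        for s in range(0, len(pos), _CHUNK):
            sub = block[s:s + _CHUNK]
            U, ranks = _position_bases(sub, Q0)
            proj = np.einsum("pnk,n->pk", U, y_r)
            rss1 = rss0 - (proj ** 2).sum(axis=1)
            lods[s:s + _CHUNK] = _lod_from_rss(n, rss0, rss1)
            r = np.maximum(ranks, 1)
            df_den = n - q0 - ranks
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                F = ((rss0 - rss1) / r) / (np.maximum(rss1, rss0 * 1e-280) / np.maximum(df_den, 1))
            F = np.where((ranks == 0) | (df_den <= 0) | degenerate, 0.0, F)
            if degenerate:
                lods[s:s + _CHUNK] = 0.0
            Fs[s:s + _CHUNK] = F
            dfn[s:s + _CHUNK] = ranks
        frames.append(pd.DataFrame({
            "arm": a.name, "pos_kb": pos, "F": Fs, "df_num": dfn,
            "df_den": n - q0 - dfn, "lod": np.maximum(lods, 0.0),
        }))
    return pd.concat(frames, ignore_index=True)


def permutation_null(blups: pd.Series, panel: Panel, n_perm: int, seed: int,
                     covariate=None) -> PermutationNull:
    """Null distribution of the genomewide maximum LOD.

    Phenotypes are permuted across RIL labels; genotypes and any
    genotype-linked covariate stay with the genomes, preserving LD
    structure under the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = blups.reindex(panel.ril_ids).to_numpy(dtype=float)
    n = panel.n_ril
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = y[rng.permutation(n)]

    cov = _as_matrix(covariate, panel.ril_ids)
    Q0 = _null_basis(n, cov)
    Yr = perms - Q0 @ (Q0.T @ perms)
    rss0 = (Yr ** 2).sum(axis=0)

    max_lod = np.zeros(n_perm)
    for a in panel.grid.arms:
        block = np.ascontiguousarray(panel.arm_block(a.name).transpose(1, 0, 2))
        for s in range(0, block.shape[0], _CHUNK):
            sub = block[s:s + _CHUNK]
            U, _ = _position_bases(sub, Q0)
            T = np.einsum("pnk,nb->pkb", U, Yr, optimize=True)
            rss1 = rss0[None, :] - (T ** 2).sum(axis=1)
            lods = _lod_from_rss(n, rss0[None, :], rss1)
            np.maximum(max_lod, lods.max(axis=0), out=max_lod)
    return PermutationNull(max_lods=max_lod, n_perm=n_perm, seed=seed)


def genomewide_threshold(null: PermutationNull, alpha: float) -> float:
    """alpha-level genomewide LOD threshold (order statistic of the null).

    The threshold is the ceil(alpha * n_perm)-th largest null maximum.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha * null.n_perm < 1:
        raise ValueError("alpha * n_perm < 1: permutation resolution insufficient")
    k = math.ceil(alpha * null.n_perm)
    return float(np.sort(null.max_lods)[::-1][k - 1])


def genomewide_pvalue(null: PermutationNull, observed_max_lod: float) -> float:
    """Add-one permutation p-value: (r + 1) / (n_perm + 1)."""
    r = int((null.max_lods >= observed_max_lod).sum())
    return (r + 1) / (null.n_perm + 1)


# ---------------------------------------------------------------------------
# local interval refinement
# ---------------------------------------------------------------------------

def support_intervals(pos: np.ndarray, lod: np.ndarray, cover: float = 0.95,
                      lod_drop: float = 2.0) -> tuple[int, tuple, tuple]:
    """Peak index plus Bayesian and LOD-drop intervals of a LOD profile.

    The Bayesian credible interval is the smallest contiguous set of grid
    steps, grown outward from the peak, holding at least ``cover`` of the
    normalised 10^LOD mass; the LOD-drop interval spans the outermost
    positions with LOD >= peak - lod_drop.  Ties for the peak go to the
    lowest position.
    """
    pos = np.asarray(pos, dtype=float)
    lod = np.asarray(lod, dtype=float)
    ipk = int(np.argmax(lod))  # ties: first (lowest position) wins

    above = lod >= lod[ipk] - lod_drop
    n_modes = int(np.sum(np.diff(np.concatenate(([0], above.astype(np.int8), [0]))) == 1))
    if n_modes > 1:
        logger.info("support_intervals: %d local modes above peak-%.3g", n_modes, lod_drop)

    w = np.power(10.0, lod - lod.max())
    w = w / w.sum()
    i0 = i1 = ipk
    mass = w[ipk]
    while mass < cover and (i0 > 0 or i1 < len(pos) - 1):
        left = w[i0 - 1] if i0 > 0 else -1.0
        right = w[i1 + 1] if i1 < len(pos) - 1 else -1.0
        if left >= right:
            i0 -= 1
            mass += left
        else:
            i1 += 1
            mass += right
    bayes_ci = (float(pos[i0]), float(pos[i1]))

    idx = np.nonzero(above)[0]
    lod_ci = (float(pos[idx.min()]), float(pos[idx.max()]))
    return ipk, bayes_ci, lod_ci


def refine_interval(blups: pd.Series, panel: Panel, arm: str,
                    window: tuple, cover: float = 0.95, lod_drop: float = 2.0,
                    covariate=None, genomewide_p: Optional[float] = None) -> QtlInterval:
    """Local interval mapping around a mapped peak.

    Recomputes the LOD profile on the grid inside ``window = (lo_kb,
    hi_kb)`` and summarises it with :func:`support_intervals`.
    """
    lo, hi = window
    scan = genome_scan(blups, panel, covariate=covariate)
    local = scan[(scan["arm"] == arm) & (scan["pos_kb"] >= lo) & (scan["pos_kb"] <= hi)]
    if local.empty:
        raise ValueError("window contains no grid positions")
    pos = local["pos_kb"].to_numpy()
    lod = local["lod"].to_numpy()
    ipk, bayes_ci, lod_ci = support_intervals(pos, lod, cover=cover, lod_drop=lod_drop)
    if ipk in (0, len(pos) - 1):
        warnings.warn("peak on window edge; consider widening the window")
    return QtlInterval(arm=arm, peak_pos_kb=float(pos[ipk]), peak_lod=float(lod[ipk]),
                       bayes_ci=bayes_ci, lod_drop_ci=lod_ci, genomewide_p=genomewide_p)
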