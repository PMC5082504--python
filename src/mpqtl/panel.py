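"""Founder genotype-probability panel.

A :class:`Panel` holds, for every RIL, the probability that its haplotype at
each grid position descends from each of the eight founders.  It is the
in-memory form of the genotype-probability tables distributed for
multiparent panels and the object every scan consumes.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import GenomeGrid

N_FOUNDERS = 8
PROB_COLS = [f"p_F{i}" for i in range(1, N_FOUNDERS + 1)]


class Panel:
    """Founder genotype probabilities for a RIL panel on a genome grid.

    Parameters
    ----------
    ril_ids
        One identifier per RIL, in row order.
    grid
        The genome grid the probabilities are defined on.
    probs
        Array of shape ``(n_ril, n_positions, 8)``; every row must sum to 1
        within 1e-9 and entries must lie in [0, 1].
    """

    def __init__(self, ril_ids: Sequence[str], grid: GenomeGrid, probs: np.ndarray,
                 validate: bool = True):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 3 or probs.shape[2] != N_FOUNDERS:
            raise ValueError("probs must have shape (n_ril, n_positions, 8)")
        if probs.shape[0] != len(ril_ids):
            raise ValueError("ril_ids length does not match probs")
        if probs.shape[1] != grid.n_positions:
            raise ValueError("probs positions do not match grid")
        if validate:
            if probs.min() < -1e-12 or probs.max() > 1 + 1e-9:
                raise ValueError("probabilities outside [0, 1]")
            sums = probs.sum(axis=2)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("probability rows must sum to 1 within 1e-9")
        self.ril_ids = list(ril_ids)
        self.grid = grid
        self.probs = probs

    # ------------------------------------------------------------------
    @property
    def n_ril(self) -> int:
        return len(self.ril_ids)

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def positions(self) -> pd.DataFrame:
        return self.grid.position_frame()

    def at(self, arm: str, pos_kb: float) -> np.ndarray:
        """Probability rows (n_ril, 8) at one grid position."""
        return self.probs[:, self.grid.locate(arm, pos_kb), :]

    def arm_block(self, arm: str) -> np.ndarray:
        """View of shape (n_ril, n_arm_positions, 8)."""
        return self.probs[:, self.grid.arm_slice(arm), :]

    def subset(self, ril_ids: Iterable[str]) -> "Panel":
        idx = [self.ril_ids.index(r) for r in ril_ids]
        return Panel([self.ril_ids[i] for i in idx], self.grid,
                     self.probs[idx], validate=False)

    def reorder(self, order: Sequence[int]) -> "Panel":
        return Panel([self.ril_ids[i] for i in order], self.grid,
                     self.probs[list(order)], validate=False)

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long table: ril_id, arm, pos_kb, p_F1..p_F8 (one row per RIL and
        position, in grid order)."""
        pos = self.grid.position_frame()
        n, p = self.n_ril, self.n_positions
        out = pd.DataFrame({
            "ril_id": np.repeat(self.ril_ids, p),
            "arm": np.tile(pos["arm"].to_numpy(), n),
            "pos_kb": np.tile(pos["pos_kb"].to_numpy(), n),
        })
        flat = self.probs.reshape(n * p, N_FOUNDERS)
        for j, c in enumerate(PROB_COLS):
            out[c] = flat[:, j]
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid: Optional[GenomeGrid] = None) -> "Panel":
        """Build a panel from a long genotype-probability table.

        When ``grid`` is omitted it is inferred from the positions present
        (arm length = largest position; genetic lengths unknown).
        """
        from .grid import ArmSpec, VALID_ARMS

        required = ["ril_id", "arm", "pos_kb", *PROB_COLS]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"genotype table missing columns: {missing}")
        bad = sorted(set(df["arm"]) - set(VALID_ARMS))
        if bad:
            raise ValueError(f"unknown arm(s) in genotype table: {bad}")

        if grid is None:
            arm_order = [a for a in VALID_ARMS if a in set(df["arm"])]
            pos_by_arm = {a: np.sort(df.loc[df["arm"] == a, "pos_kb"].unique()) for a in arm_order}
            steps = {a: int(np.diff(p).min()) if len(p) > 1 else int(p[0]) for a, p in pos_by_arm.items()}
            step = min(steps.values())
            grid = GenomeGrid(
                arms=tuple(ArmSpec(a, float(pos_by_arm[a].max())) for a in arm_order),
                step_kb=step,
            )

        pos = grid.position_frame()
        key = pos["arm"].astype(str) + ":" + pos["pos_kb"].astype(str)
        order = pd.Series(np.arange(len(key)), index=key)

        ril_ids = list(pd.unique(df["ril_id"]))
        n, p = len(ril_ids), len(pos)
        probs = np.full((n, p, N_FOUNDERS), np.nan)
        ril_index = pd.Series(np.arange(n), index=ril_ids)
        rows = ril_index[df["ril_id"]].to_numpy()
        dfkey = df["arm"].astype(str) + ":" + df["pos_kb"].astype(str)
        unknown = ~dfkey.isin(order.index)
        if unknown.any():
            bad_row = df.index[unknown][0]
            raise ValueError(f"row {bad_row}: position not on the grid")
        cols = order[dfkey].to_numpy()
        probs[rows, cols, :] = df[PROB_COLS].to_numpy(dtype=np.float64)
        if np.isnan(probs).any():
            raise ValueError("genotype table does not cover every (RIL, position)")
        return cls(ril_ids, grid, probs)

    # ------------------------------------------------------------------
    def founder_shares(self) -> np.ndarray:
        """Mean genomewide probability mass per founder, averaged over RILs
        and positions; sums to 1."""
        return self.probs.mean(axis=(0, 1))
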