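"""Genome grid for multiparent RIL panels.

Positions are 1-based kilobase coordinates on a fixed grid (default spacing
10 kb), covering each chromosome arm exactly once.  Arm naming follows the
Drosophila melanogaster convention (X, 2L, 2R, 3L, 3R); coordinates refer to
reference genome version 5 and no liftover is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

VALID_ARMS = ("X", "2L", "2R", "3L", "3R")


@dataclass(frozen=True)
class ArmSpec:
    """One chromosome arm: physical length in kb and genetic length in cM.

    ``length_cm`` may be None for panels read from genotype files, where only
    physical coordinates are known; it is required for simulation.
    """

    name: str
    length_kb: float
    length_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in VALID_ARMS:
            raise ValueError(f"unknown arm {self.name!r}; expected one of {VALID_ARMS}")
        if not self.length_kb > 0:
            raise ValueError(f"arm {self.name}: length_kb must be > 0")
        if self.length_cm is not None and not self.length_cm > 0:
            raise ValueError(f"arm {self.name}: length_cm must be > 0")


@dataclass(frozen=True)
class GenomeGrid:
    """Ordered chromosome arms plus an evenly spaced scan grid.

    Grid positions on an arm of physical length L are ``step_kb, 2*step_kb,
    ..., floor(L/step_kb)*step_kb`` (1-based kb, multiples of the spacing).
    """

    arms: tuple[ArmSpec, ...]
    step_kb: int = 10

    def __post_init__(self) -> None:
        if len(self.arms) == 0:
            raise ValueError("grid needs at least one arm")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate arm names")
        if self.step_kb <= 0:
            raise ValueError("step_kb must be positive")
        object.__setattr__(self, "arms", tuple(self.arms))

    # -- lookups ---------------------------------------------------------
    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    def arm(self, name: str) -> ArmSpec:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"arm {name!r} not in grid")

    def positions(self, arm: str) -> np.ndarray:
        """Grid positions (kb) on one arm."""
        spec = self.arm(arm)
        n = int(spec.length_kb // self.step_kb)
        return np.arange(1, n + 1, dtype=np.int64) * self.step_kb

    @property
    def n_positions(self) -> int:
        return sum(int(a.length_kb // self.step_kb) for a in self.arms)

    def position_frame(self) -> pd.DataFrame:
        """All grid positions as a (arm, pos_kb) frame in scan order."""
        frames = [
            pd.DataFrame({"arm": a.name, "pos_kb": self.positions(a.name)})
            for a in self.arms
        ]
        return pd.concat(frames, ignore_index=True)

    def arm_slice(self, arm: str) -> slice:
        """Index range of an arm's positions within the flat scan order."""
        start = 0
        for a in self.arms:
            n = int(a.length_kb // self.step_kb)
            if a.name == arm:
                return slice(start, start + n)
            start += n
        raise KeyError(f"arm {arm!r} not in grid")

    def locate(self, arm: str, pos_kb: float) -> int:
        """Flat index of a grid position; raises if off-grid."""
        pos = self.positions(arm)
        i = np.searchsorted(pos, pos_kb)
        if i >= len(pos) or pos[i] != pos_kb:
            raise ValueError(f"position {arm}:{pos_kb} is not on the {self.step_kb}-kb grid")
        return self.arm_slice(arm).start + int(i)

    # -- constructors ----------------------------------------------------
    @classmethod
    def dspr_like(cls, step_kb: int = 10) -> "GenomeGrid":
        """Five-arm D. melanogaster genome with release-5 scale arm lengths
        and standard genetic map lengths (~2.87 M total)."""
        return cls(
            arms=(
                ArmSpec("X", 22_400, 66.0),
                ArmSpec("2L", 23_000, 55.0),
                ArmSpec("2R", 21_100, 52.0),
                ArmSpec("3L", 24_500, 47.0),
                ArmSpec("3R", 27_900, 59.0),
            ),
            step_kb=step_kb,
        )

    @classmethod
    def toy(cls, arm_kb: float = 2_000, cm_per_mb: float = 2.2,
            arms: tuple[str, ...] = ("2L",), step_kb: int = 10) -> "GenomeGrid":
        """Small grid for tests and scaled-down experiments.

        Genetic length defaults to a fly-like 2.2 cM/Mb.
        """
        return cls(
            arms=tuple(ArmSpec(a, arm_kb, cm_per_mb * arm_kb / 1000.0) for a in arms),
            step_kb=step_kb,
        )
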