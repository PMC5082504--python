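"""File formats for panels, phenotypes and results.

All formats are plain text: tab-separated genotype probabilities and scan
results, comma-separated phenotypes, JSON for configuration, intervals,
partitions and simulation truth.  Readers validate aggressively and name
the offending line on failure; writers produce files the readers accept
(round-trip identity is a tested property).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .founders import FounderPartition
from .grid import GenomeGrid, VALID_ARMS
from .panel import N_FOUNDERS, PROB_COLS, Panel
from .scan import QtlInterval


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genotype probabilities (TSV)
# ---------------------------------------------------------------------------

def write_genotype_probs(panel: Panel, path) -> None:
    """Write the long genotype-probability TSV: ril_id, arm, pos_kb, p_F1..p_F8."""
    panel.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_genotype_probs(path, grid: Optional[GenomeGrid] = None) -> Panel:
    """Read a genotype-probability TSV into a panel.

    Rows whose probabilities sum to 1 within 1e-6 are renormalised; larger
    deviations raise a :class:`FormatError` naming the line.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["ril_id", "arm", "pos_kb", *PROB_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_arm = ~df["arm"].isin(VALID_ARMS)
    if bad_arm.any():
        line = int(df.index[bad_arm][0]) + 2  # header is line 1
        raise FormatError(f"{path}:{line}: unknown arm {df.loc[df.index[bad_arm][0], 'arm']!r}")
    P = df[PROB_COLS].to_numpy(dtype=float)
    sums = P.sum(axis=1)
    off = np.abs(sums - 1.0) > 1e-6
    if off.any():
        line = int(df.index[off][0]) + 2
        raise FormatError(f"{path}:{line}: probability row sums to {sums[off][0]:.6g}, not 1")
    df = df.copy()
    df[PROB_COLS] = P / sums[:, None]
    return Panel.from_dataframe(df, grid=grid)


# ---------------------------------------------------------------------------
# phenotypes (CSV)
# ---------------------------------------------------------------------------

VIAL_HEADER = ["ril_id", "vial_id", "date", "assay", "n_flies", "value"]
FLY_HEADER_DCV = ["ril_id", "vial_id", "fly_id", "date", "assay", "day", "censored"]
FLY_HEADER_SIGMA = ["ril_id", "vial_id", "fly_id", "date", "assay", "infected"]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_phenotypes(path, assay: Optional[str] = None) -> pd.DataFrame:
    """Read a phenotype CSV (vial-level or fly-level, auto-detected).

    Dates are opaque labels; no calendar arithmetic is performed.  Returns
    the validated frame with a ``level`` attribute of 'vial' or 'fly' in
    ``df.attrs``.
    """
    df = pd.read_csv(path, dtype={"date": str, "ril_id": str, "vial_id": str})
    cols = set(df.columns)
    if {"value", "n_flies"} <= cols:
        level = "vial"
    elif {"day"} <= cols or {"infected"} <= cols:
        level = "fly"
    else:
        raise FormatError(f"{path}: header matches neither the vial nor the fly dialect")

    if "assay" not in cols:
        if assay is None:
            raise FormatError(f"{path}: no assay column and no assay given")
        df["assay"] = assay
    assays = set(df["assay"].unique())
    if len(assays) != 1:
        raise FormatError(f"{path}: mixed assays {sorted(assays)}")
    found = assays.pop()
    if assay is not None and found != assay:
        raise FormatError(f"{path}: expected assay {assay!r}, found {found!r}")

    if level == "vial":
        if found == "sigma":
            bad = (df["value"] < 0) | (df["value"] > 1)
            if bad.any():
                line = int(df.index[bad][0]) + 2
                raise FormatError(f"{path}:{line}: sigma proportion outside [0, 1]")
        if (df["n_flies"] < 1).any():
            raise FormatError(f"{path}: n_flies must be >= 1")
    else:
        if "fly_id" in cols:
            dup = df.duplicated(subset=["vial_id", "fly_id"])
            if dup.any():
                line = int(df.index[dup][0]) + 2
                raise FormatError(f"{path}:{line}: duplicate (vial, fly) key")
        if found == "dcv":
            censored = df["censored"].astype(bool) if "censored" in cols else False
            alive = df["day"].where(~censored) if "censored" in cols else df["day"]
            bad = alive.notna() & (alive < 1)
            if bad.any():
                line = int(df.index[bad][0]) + 2
                raise FormatError(f"{path}:{line}: death day < 1 "
                                  f"(observation window starts at day 1)")
        else:
            if not df["infected"].isin([0, 1]).all():
                raise FormatError(f"{path}: sigma 'infected' must be 0/1")
    df.attrs["level"] = level
    return df


# ---------------------------------------------------------------------------
# results (TSV/JSON)
# ---------------------------------------------------------------------------

def write_scan(scan: pd.DataFrame, path) -> None:
    scan.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_null(null, path) -> None:
    pd.DataFrame({"max_lod": null.max_lods}).to_csv(path, sep="\t", index=False,
                                                    float_format="%.10g")


def interval_to_dict(iv: QtlInterval) -> dict:
    return {
        "arm": iv.arm,
        "peak_pos_kb": iv.peak_pos_kb,
        "peak_lod": iv.peak_lod,
        "bayes_ci_kb": list(iv.bayes_ci),
        "lod_drop_ci_kb": list(iv.lod_drop_ci),
        "genomewide_p": iv.genomewide_p,
    }


def partition_to_dict(part: FounderPartition) -> dict:
    return {
        "qtl_id": part.qtl_id,
        "founder_means": [None if np.isnan(m) else float(m) for m in part.founder_means],
        "counts": [int(c) for c in part.counts],
        "class_of": {str(f): c for f, c in sorted(part.class_of.items())},
        "best_F": part.best_F,
        "n_rils_used": part.n_rils_used,
        "higher_is_resistant": part.higher_is_resistant,
    }


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    In real mode ``genotype_path``/``phenotype_path`` point at user-supplied
    tables; in synthetic mode (the default for tests) a simulation config is
    embedded instead.  ``seed`` drives every stochastic step.
    """

    out_dir: Union[str, Path]
    seed: int
    assay: str = "dcv"
    genotype_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    sim: Optional[dict] = None              # SimConfig fields for synthetic mode
    n_perm: int = 2000
    alpha_grid: tuple = (0.05, 0.01, 0.001)
    assign_threshold: float = 0.95
    min_class_n: int = 10
    min_mass: float = 5.0
    n_perm_interaction: int = 1000
    interval_window_kb: float = 1000.0
    mcmc: dict = field(default_factory=dict)
    run_epistasis: bool = True

    def __post_init__(self) -> None:
        real = self.genotype_path is not None or self.phenotype_path is not None
        if real and (self.genotype_path is None or self.phenotype_path is None):
            raise ValueError("real mode needs both genotype_path and phenotype_path")
        if real:
            for p in (self.genotype_path, self.phenotype_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        elif self.sim is None:
            raise ValueError("either real-mode paths or a sim config is required")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "alpha_grid" in data:
            data["alpha_grid"] = tuple(data["alpha_grid"])
        return cls(**data)
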