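"""Founder-allele classes at a QTL.

At a mapped QTL the eight founder alleles are partitioned into a
'resistant' and a 'susceptible' class: RILs are hard-assigned to the
founder whose genotype probability exceeds a threshold (default 0.95;
ambiguous lines are excluded, the computable analogue of genotyping
ambiguous lines by PCR), founders are ranked by their mean phenotype, and
the ranked list is cut at each of the k-1 possible points; the cut with
the highest one-way ANOVA F is the best two-class partition.  Each RIL's
probability of carrying the resistant allele is then the summed genotype
probability over resistant-class founders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import N_FOUNDERS


class PartitionError(ValueError):
    """Raised when fewer than two founders are represented at the locus."""


def founder_assignments(prob_rows: np.ndarray, assign_threshold: float = 0.95) -> np.ndarray:
    """Hard founder assignment per RIL: founder index 0..7 or -1 (ambiguous)."""
    P = np.asarray(prob_rows, dtype=float)
    best = P.argmax(axis=1)
    conf = P[np.arange(len(P)), best] >= assign_threshold
    out = np.where(conf, best, -1)
    return out.astype(np.int64)


def founder_means(blups: pd.Series, prob_rows: np.ndarray,
                  assign_threshold: float = 0.95):
    """Per-founder mean phenotype and counts at a QTL peak.

    Returns ``(means, counts, assignments)``: means is length 8 with NaN
    for unrepresented founders; assignments is the hard per-RIL founder
    index (-1 when no founder reaches the threshold).
    """
    y = np.asarray(blups.to_numpy() if isinstance(blups, pd.Series) else blups, dtype=float)
    assign = founder_assignments(prob_rows, assign_threshold)
    means = np.full(N_FOUNDERS, np.nan)
    counts = np.zeros(N_FOUNDERS, dtype=int)
    for f in range(N_FOUNDERS):
        mask = assign == f
        counts[f] = mask.sum()
        if counts[f]:
            means[f] = y[mask].mean()
    if (counts > 0).sum() < 2:
        raise PartitionError("fewer than two founders represented; partition impossible")
    return means, counts, assign


@dataclass
class FounderPartition:
    """Best two-class (resistant/susceptible) split of the founder alleles."""

    qtl_id: Optional[str]
    founder_means: np.ndarray          # length 8, NaN where absent
    counts: np.ndarray                 # RILs hard-assigned per founder
    class_of: dict                     # founder (1-based) -> 'resistant' | 'susceptible'
    best_F: float
    n_rils_used: int
    higher_is_resistant: bool = True

    @property
    def resistant_founders(self) -> frozenset:
        return frozenset(f for f, c in self.class_of.items() if c == "resistant")

    @property
    def susceptible_founders(self) -> frozenset:
        return frozenset(f for f, c in self.class_of.items() if c == "susceptible")


def _anova_F(y: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F between two groups (0/1 labels)."""
    n = len(y)
    n1 = int(groups.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0 or n < 3:
        return 0.0
    gm = y.mean()
    m0 = y[groups == 0].mean()
    m1 = y[groups == 1].mean()
    ssb = n0 * (m0 - gm) ** 2 + n1 * (m1 - gm) ** 2
    ssw = ((y[groups == 0] - m0) ** 2).sum() + ((y[groups == 1] - m1) ** 2).sum()
    if ssw <= 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / 1.0) / (ssw / (n - 2))


def best_two_class_partition(means: np.ndarray, blups: pd.Series,
                             assignments: np.ndarray, qtl_id: Optional[str] = None,
                             higher_is_resistant: bool = True) -> FounderPartition:
    """Maximal-F ranked-cut split of the represented founders.

    Founders are ranked by mean phenotype and each of the k-1 ranked
    cut-points is scored by the between/within ANOVA F over hard-assigned
    RILs; ties in F go to the split with the smaller resistant class.
    ``higher_is_resistant`` states which end of the trait scale means
    resistance (True for survival time, False for infection proportion).
    """
    y = np.asarray(blups.to_numpy() if isinstance(blups, pd.Series) else blups, dtype=float)
    means = np.asarray(means, dtype=float)
    present = np.nonzero(~np.isnan(means))[0]
    if len(present) < 2:
        raise PartitionError("fewer than two founders represented")
    used = assignments >= 0
    y_used = y[used]
    a_used = assignments[used]

    order = present[np.argsort(means[present], kind="stable")]  # ascending phenotype
    best = None
    counts_all = np.zeros(N_FOUNDERS, dtype=int)
    for f in present:
        counts_all[f] = int((a_used == f).sum())
    for cut in range(1, len(order)):
        low = set(order[:cut])  # founders with the smaller phenotype
        groups = np.isin(a_used, list(low)).astype(np.int64)
        F = _anova_F(y_used, groups)
        resistant = set(order[cut:]) if higher_is_resistant else low
        n_res = sum(counts_all[f] for f in resistant)
        size_res = len(resistant)
        cand = (F, -size_res, -cut)  # higher F wins; ties -> smaller resistant class
        if best is None or cand[:2] > best[0][:2]:
            best = (cand, resistant)
    (F_best, _, _), resistant = best
    class_of = {}
    for f in present:
        class_of[int(f) + 1] = "resistant" if f in resistant else "susceptible"
    return FounderPartition(
        qtl_id=qtl_id, founder_means=means, counts=counts_all, class_of=class_of,
        best_F=float(F_best), n_rils_used=int(used.sum()),
        higher_is_resistant=higher_is_resistant)


def partition_at(blups: pd.Series, prob_rows: np.ndarray, qtl_id: Optional[str] = None,
                 assign_threshold: float = 0.95,
                 higher_is_resistant: bool = True) -> FounderPartition:
    """Convenience: founder means + best ranked-cut partition in one call."""
    means, counts, assign = founder_means(blups, prob_rows, assign_threshold)
    return best_two_class_partition(means, blups, assign, qtl_id=qtl_id,
                                    higher_is_resistant=higher_is_resistant)


def resistant_probability(partition: FounderPartition, prob_rows: np.ndarray,
                          ril_ids: Sequence[str]) -> pd.Series:
    """Per-RIL probability of carrying the resistant allele.

    The sum of founder genotype probabilities over resistant-class
    founders; linear in the probability rows and bounded in [0, 1].
    """
    P = np.asarray(prob_rows, dtype=float)
    idx = [f - 1 for f in sorted(partition.resistant_founders)]
    return pd.Series(P[:, idx].sum(axis=1), index=list(ril_ids), name="p_resistant")


def ld_fisher(prob_rows_a: np.ndarray, partition_a: FounderPartition,
              prob_rows_b: np.ndarray, partition_b: FounderPartition,
              ril_ids: Sequence[str], assign_threshold: float = 0.95):
    """Fisher's exact test of linkage disequilibrium between two QTL.

    RILs are hard-classified resistant/susceptible at each locus (a RIL
    counts only when its resistant probability is >= threshold or <=
    1 - threshold at both loci) and cross-tabulated.  Returns
    ``(odds_ratio, p_two_sided, table, flags)``; a table with an empty
    margin is degenerate and reported with p = 1.
    """
    pa = resistant_probability(partition_a, prob_rows_a, ril_ids).to_numpy()
    pb = resistant_probability(partition_b, prob_rows_b, ril_ids).to_numpy()

    def classify(p):
        out = np.full(len(p), -1, dtype=np.int64)
        out[p >= assign_threshold] = 1
        out[p <= 1 - assign_threshold] = 0
        return out

    ca, cb = classify(pa), classify(pb)
    ok = (ca >= 0) & (cb >= 0)
    table = np.zeros((2, 2), dtype=np.int64)
    np.add.at(table, (ca[ok], cb[ok]), 1)
    flags = []
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        flags.append("degenerate_table")
        return math.nan, 1.0, table, flags
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), table, flags
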