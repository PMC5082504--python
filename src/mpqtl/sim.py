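"""Synthetic multiparent RIL panel and phenotype simulator.

Emulates the construction of an eight-founder advanced-intercross panel:
founders are intercrossed for ``n_generations`` in a finite pedigree with
equalised family sizes, individuals are then inbred until their genomes are
effectively homozygous, and one haplotype per line is retained as the RIL
genome — a fine-scale mosaic of founder segments.  Phenotypes are generated
under the vial-level model

    y[i,j,k] = beta + date[i] + RIL[j] + eps[i,j,k]

with planted QTL contributing founder-class effects (and optional epistatic
interactions) to the RIL term.

Recombination model: crossovers per arm per meiosis are Poisson with mean
equal to the arm's genetic length in Morgans, positions uniform on the
genetic map, and the genetic-to-physical map is linear within an arm (so
crossover positions are uniform in physical coordinates too).  Family sizes
are equalised (random pairing, two offspring per pair) so that founder
frequencies do not drift coherently: each founder's expected genomewide
share stays at 1/8 with only Mendelian-segregation noise, matching how
laboratory advanced-intercross populations are maintained with controlled
census.  The X is treated like an autosome for mosaic purposes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import GenomeGrid
from .panel import N_FOUNDERS, Panel

# A haplotype on one arm: (segment end positions kb ascending, ending at the
# arm length; founder index 0..7 per segment).  Immutable by convention so
# recombination-free gametes can share storage with their parent.
Haplotype = Tuple[np.ndarray, np.ndarray]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedQtl:
    """A simulated causal locus with a two-class founder partition.

    ``resistant_founders`` lists founders (1-based) whose allele raises the
    trait (survival days for dcv; infection-probability points, usually
    negative effect, for sigma).  ``interaction`` optionally names a partner
    QTL and an interaction coefficient added when a RIL carries the
    resistant allele at both loci.
    """

    qtl_id: str
    arm: str
    pos_kb: float
    resistant_founders: frozenset
    effect: float
    interaction: Optional[Tuple[str, float]] = None

    def __post_init__(self) -> None:
        rf = frozenset(int(f) for f in self.resistant_founders)
        object.__setattr__(self, "resistant_founders", rf)
        if not rf or any(f < 1 or f > N_FOUNDERS for f in rf):
            raise InvalidConfigError("resistant_founders must be a non-empty subset of 1..8")

    @property
    def founder_class(self) -> List[str]:
        """8-vector of labels in founder order 1..8."""
        return ["resistant" if f in self.resistant_founders else "susceptible"
                for f in range(1, N_FOUNDERS + 1)]


@dataclass
class SimConfig:
    """Study-design parameters for a simulated panel and assay.

    Defaults mirror the design of the resistance screens the package
    targets: an 8-founder panel intercrossed for 50 generations, vials of 20
    injected flies, roughly 50 vials infected per day, and (for the dcv
    assay) variance components giving a single-day repeatability near 0.77.
    """

    n_ril: int
    grid: GenomeGrid = field(default_factory=GenomeGrid.dspr_like)
    n_generations: int = 50
    n_founders: int = N_FOUNDERS
    qtl_list: List[PlantedQtl] = field(default_factory=list)
    beta: float = 10.0
    sigma2_ril: float = 3.0
    sigma2_date: float = 0.5
    sigma2_resid: float = 0.9
    n_vials_per_ril: int = 1
    flies_per_vial: int = 20
    assay: str = "dcv"
    vials_per_day: int = 50
    census_pairs: Optional[int] = None  # default 2 * n_ril mating pairs
    het_threshold: float = 0.01
    max_inbreed_generations: int = 60
    blur: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders != N_FOUNDERS:
            raise InvalidConfigError("the panel model is fixed at 8 founders")
        if self.n_ril < 1:
            raise InvalidConfigError("n_ril must be >= 1")
        if self.n_generations < 0:
            raise InvalidConfigError("n_generations must be >= 0")
        for v in (self.sigma2_ril, self.sigma2_date, self.sigma2_resid):
            if v < 0:
                raise InvalidConfigError("variances must be >= 0")
        if self.flies_per_vial < 1:
            raise InvalidConfigError("flies_per_vial must be >= 1")
        if self.assay not in ("dcv", "sigma"):
            raise InvalidConfigError("assay must be 'dcv' or 'sigma'")
        if not 0 <= self.blur < 1:
            raise InvalidConfigError("blur must be in [0, 1)")
        for q in self.qtl_list:
            self.grid.locate(q.arm, q.pos_kb)  # raises if off-grid

    @property
    def census(self) -> int:
        pairs = self.census_pairs if self.census_pairs is not None else 2 * self.n_ril
        n = 2 * pairs
        # need at least n_ril individuals to found lines from, and >= 8 to
        # represent every founder
        return max(n, self.n_ril, N_FOUNDERS, 2)


@dataclass
class FounderMosaic:
    """True founder-of-origin segments of one RIL genome.

    ``segments[arm]`` is a list of ``(start_kb, end_kb, founder)`` tuples
    (founder 1-based) tiling the arm without gaps or overlaps.
    """

    ril_id: str
    segments: Dict[str, List[Tuple[float, float, int]]]

    def founder_at(self, grid: GenomeGrid, arm: str, pos_kb: float) -> int:
        segs = self.segments[arm]
        for s, e, f in segs:
            if s < pos_kb <= e:
                return f
        raise ValueError(f"position {arm}:{pos_kb} outside mosaic")


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gamete(hap_a: Haplotype, hap_b: Haplotype, length_kb: float,
            n_xo: int, phase: int, rng: np.random.Generator,
            xs: Optional[np.ndarray] = None) -> Haplotype:
    """One recombinant gamete from a parental haplotype pair.

    ``xs`` may supply pre-drawn crossover positions (sorted); otherwise
    ``n_xo`` positions are drawn uniformly on the arm.
    """
    if xs is None:
        if n_xo == 0:
            return hap_a if phase == 0 else hap_b
        xs = np.sort(rng.uniform(0.0, length_kb, n_xo))
    elif len(xs) == 0:
        return hap_a if phase == 0 else hap_b
    haps = (hap_a, hap_b)
    cur = phase
    out_e: List[float] = []
    out_f: List[int] = []
    prev = 0.0
    for x in list(xs) + [length_kb]:
        if x > prev:
            ends, fnd = haps[cur]
            i = int(np.searchsorted(ends, prev, side="right"))
            while prev < x:
                e = min(float(ends[i]), x)
                f = int(fnd[i])
                if out_f and out_f[-1] == f:
                    out_e[-1] = e
                else:
                    out_e.append(e)
                    out_f.append(f)
                prev = e
                i += 1
        cur ^= 1
        prev = x
    return np.asarray(out_e), np.asarray(out_f, dtype=np.int8)


def _heterozygosity(hap_a: Haplotype, hap_b: Haplotype, length_kb: float) -> float:
    """Fraction of the arm where the two haplotypes carry different founders."""
    ends = np.union1d(hap_a[0], hap_b[0])
    mids = (np.concatenate(([0.0], ends[:-1])) + ends) / 2.0
    fa = hap_a[1][np.searchsorted(hap_a[0], mids, side="left")]
    fb = hap_b[1][np.searchsorted(hap_b[0], mids, side="left")]
    widths = np.diff(np.concatenate(([0.0], ends)))
    return float(widths[fa != fb].sum() / length_kb)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def simulate_mosaics(config: SimConfig, rng: Optional[np.random.Generator] = None
                     ) -> List[FounderMosaic]:
    """Simulate the panel pedigree and return one founder mosaic per RIL.

    Deterministic given ``config.seed`` (or an explicitly supplied
    generator).  See the module docstring for the recombination and
    inbreeding model.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arms = config.grid.arms
    arm_L = [a.length_kb for a in arms]
    arm_M = []
    for a in arms:
        if a.length_cm is None:
            raise InvalidConfigError(f"arm {a.name}: genetic length required for simulation")
        arm_M.append(a.length_cm / 100.0)

    n = config.census
    if n % 2:
        n += 1

    # generation 0: homozygous founder individuals, balanced founder counts
    founder_of = np.tile(np.arange(N_FOUNDERS, dtype=np.int8), n // N_FOUNDERS + 1)[:n]
    pop: List[List[Tuple[Haplotype, Haplotype]]] = []
    base_haps = []
    for k, a in enumerate(arms):
        base_haps.append([
            (np.asarray([arm_L[k]]), np.asarray([f], dtype=np.int8))
            for f in range(N_FOUNDERS)
        ])
    for ind in range(n):
        f = founder_of[ind]
        pop.append([(base_haps[k][f], base_haps[k][f]) for k in range(len(arms))])

    # intercross generations: random pairing, exactly two offspring per
    # pair, and balanced transmission — each parent passes complementary
    # gametes (same crossover realisation, opposite phase) to its two
    # offspring, so every allele copy at every locus is transmitted exactly
    # once and founder frequencies are conserved generation to generation
    # (no coherent drift; only mosaic structure is randomised)
    for _ in range(config.n_generations):
        perm = rng.permutation(n)
        new_pop: List[List[Tuple[Haplotype, Haplotype]]] = [
            [None] * len(arms) for _ in range(n)  # type: ignore
        ]
        n_pairs = n // 2
        for k, (L, M) in enumerate(zip(arm_L, arm_M)):
            counts = rng.poisson(M, size=(n_pairs, 2))
            phases = rng.integers(0, 2, size=(n_pairs, 2))
            for pi in range(n_pairs):
                p1 = pop[perm[2 * pi]][k]
                p2 = pop[perm[2 * pi + 1]][k]
                xs1 = np.sort(rng.uniform(0.0, L, int(counts[pi, 0])))
                xs2 = np.sort(rng.uniform(0.0, L, int(counts[pi, 1])))
                ph1, ph2 = int(phases[pi, 0]), int(phases[pi, 1])
                g1a = _gamete(p1[0], p1[1], L, 0, ph1, rng, xs=xs1)
                g1b = _gamete(p1[0], p1[1], L, 0, ph1 ^ 1, rng, xs=xs1)
                g2a = _gamete(p2[0], p2[1], L, 0, ph2, rng, xs=xs2)
                g2b = _gamete(p2[0], p2[1], L, 0, ph2 ^ 1, rng, xs=xs2)
                new_pop[2 * pi][k] = (g1a, g2a)
                new_pop[2 * pi + 1][k] = (g1b, g2b)
        pop = new_pop

    # found each RIL from one sampled individual; inbreed by gamete-pair
    # resampling until genomewide heterozygosity < het_threshold, then keep
    # one haplotype
    chosen = rng.choice(n, size=config.n_ril, replace=False)
    mosaics: List[FounderMosaic] = []
    w = np.asarray(arm_L)
    w = w / w.sum()
    for r, ind_idx in enumerate(chosen):
        ind = list(pop[ind_idx])
        for _ in range(config.max_inbreed_generations):
            het = sum(w[k] * _heterozygosity(ind[k][0], ind[k][1], arm_L[k])
                      for k in range(len(arms)))
            if het < config.het_threshold:
                break
            nxt = []
            for k, (L, M) in enumerate(zip(arm_L, arm_M)):
                g1 = _gamete(ind[k][0], ind[k][1], L, int(rng.poisson(M)),
                             int(rng.integers(0, 2)), rng)
                g2 = _gamete(ind[k][0], ind[k][1], L, int(rng.poisson(M)),
                             int(rng.integers(0, 2)), rng)
                nxt.append((g1, g2))
            ind = nxt
        segments: Dict[str, List[Tuple[float, float, int]]] = {}
        for k, a in enumerate(arms):
            ends, fnd = ind[k][0]
            starts = np.concatenate(([0.0], ends[:-1]))
            segments[a.name] = [(float(s), float(e), int(f) + 1)
                                for s, e, f in zip(starts, ends, fnd)]
        mosaics.append(FounderMosaic(ril_id=f"RIL{r + 1:04d}", segments=segments))
    return mosaics


def mosaics_to_panel(mosaics: Sequence[FounderMosaic], grid: GenomeGrid,
                     blur: float = 0.0) -> Panel:
    """Emit genotype probabilities from true mosaics.

    With ``blur == 0`` every probability row is the unit vector on the true
    founder; otherwise the row is mixed with the uniform distribution,
    emulating residual haplotype-inference uncertainty.
    """
    n, p = len(mosaics), grid.n_positions
    probs = np.zeros((n, p, N_FOUNDERS))
    for i, m in enumerate(mosaics):
        col = 0
        for a in grid.arms:
            pos = grid.positions(a.name)
            segs = m.segments[a.name]
            ends = np.asarray([e for _, e, _ in segs])
            fnd = np.asarray([f - 1 for _, _, f in segs], dtype=np.int64)
            idx = np.searchsorted(ends, pos, side="left")
            idx = np.minimum(idx, len(ends) - 1)
            probs[i, col + np.arange(len(pos)), fnd[idx]] = 1.0
            col += len(pos)
    if blur > 0:
        probs = (1.0 - blur) * probs + blur / N_FOUNDERS
    return Panel([m.ril_id for m in mosaics], grid, probs)


def simulate_panel(config: SimConfig) -> Tuple[List[FounderMosaic], Panel]:
    """Simulate mosaics and the matching genotype-probability panel."""
    rng = np.random.default_rng(config.seed)
    mosaics = simulate_mosaics(config, rng)
    return mosaics, mosaics_to_panel(mosaics, config.grid, config.blur)


def founder_shares(mosaics: Sequence[FounderMosaic]) -> np.ndarray:
    """Length-weighted genomewide share of each founder, averaged over RILs."""
    totals = np.zeros(N_FOUNDERS)
    length = 0.0
    for m in mosaics:
        for segs in m.segments.values():
            for s, e, f in segs:
                totals[f - 1] += e - s
    length = totals.sum()
    return totals / length


def breakpoint_counts(mosaics: Sequence[FounderMosaic]) -> pd.DataFrame:
    """Number of founder switches per arm per RIL (junction density)."""
    rows = []
    for m in mosaics:
        for arm, segs in m.segments.items():
            rows.append({"ril_id": m.ril_id, "arm": arm, "n_breakpoints": len(segs) - 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted genetic values and vial phenotypes
# ---------------------------------------------------------------------------

def plant_genetic_values(mosaics: Sequence[FounderMosaic], qtl_list: Sequence[PlantedQtl],
                         grid: GenomeGrid) -> pd.Series:
    """Per-RIL genetic value from planted QTL, using the TRUE mosaics.

    value = sum over QTL of effect * 1[true founder in resistant class]
    plus, for QTL with an interaction partner, coefficient * 1[resistant at
    both loci].
    """
    by_id = {q.qtl_id: q for q in qtl_list}
    for q in qtl_list:
        grid.locate(q.arm, q.pos_kb)
        if q.interaction is not None and q.interaction[0] not in by_id:
            raise InvalidConfigError(f"interaction partner {q.interaction[0]!r} not in qtl_list")
    values = {}
    for m in mosaics:
        carrier = {
            q.qtl_id: m.founder_at(grid, q.arm, q.pos_kb) in q.resistant_founders
            for q in qtl_list
        }
        g = 0.0
        for q in qtl_list:
            if carrier[q.qtl_id]:
                g += q.effect
            if q.interaction is not None:
                partner, coeff = q.interaction
                if carrier[q.qtl_id] and carrier[partner]:
                    g += coeff
        values[m.ril_id] = g
    return pd.Series(values, name="genetic_value", dtype=float)


def simulate_vials(genetic_values: pd.Series, config: SimConfig,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate vial-level phenotypes under the date/RIL/residual model.

    Vials are assigned to injection days in batches of ``vials_per_day``,
    with replicate vials of the same RIL always on different days.  For the
    dcv assay the vial value is the latent mean survival time in days; for
    the sigma assay a latent infection probability is clipped to [0, 1] and
    the value is a binomial proportion of infected flies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rils = list(genetic_values.index)
    n = len(rils)
    if n == 0:
        raise InvalidConfigError("no genetic values supplied")

    ril_dev = rng.normal(0.0, math.sqrt(config.sigma2_ril), size=n)
    rows = []
    day = 0
    date_effects: Dict[int, float] = {}
    for rep in range(config.n_vials_per_ril):
        order = rng.permutation(n)
        for start in range(0, n, config.vials_per_day):
            day += 1
            date_effects[day] = rng.normal(0.0, math.sqrt(config.sigma2_date))
            for i in order[start:start + config.vials_per_day]:
                rows.append((rils[i], f"{rils[i]}_v{rep + 1}", f"day{day:03d}", i, day))
    df = pd.DataFrame(rows, columns=["ril_id", "vial_id", "date", "_i", "_day"])
    latent = (config.beta
              + genetic_values.to_numpy()[df["_i"].to_numpy()]
              + ril_dev[df["_i"].to_numpy()]
              + np.asarray([date_effects[d] for d in df["_day"]])
              + rng.normal(0.0, math.sqrt(config.sigma2_resid), size=len(df)))
    if config.assay == "dcv":
        value = latent
    else:
        p = np.clip(latent, 0.0, 1.0)
        value = rng.binomial(config.flies_per_vial, p) / config.flies_per_vial
    out = df.drop(columns=["_i", "_day"]).copy()
    out["assay"] = config.assay
    out["n_flies"] = config.flies_per_vial
    out["value"] = value
    return out


# ---------------------------------------------------------------------------
# truth bundle
# ---------------------------------------------------------------------------

def truth_dict(config: SimConfig) -> dict:
    """JSON-serialisable record of the planted simulation truth."""
    return {
        "seed": config.seed,
        "n_ril": config.n_ril,
        "n_generations": config.n_generations,
        "assay": config.assay,
        "beta": config.beta,
        "sigma2_ril": config.sigma2_ril,
        "sigma2_date": config.sigma2_date,
        "sigma2_resid": config.sigma2_resid,
        "qtl": [
            {
                "qtl_id": q.qtl_id,
                "arm": q.arm,
                "pos_kb": q.pos_kb,
                "resistant_founders": sorted(q.resistant_founders),
                "effect": q.effect,
                "interaction": list(q.interaction) if q.interaction else None,
            }
            for q in config.qtl_list
        ],
    }


def write_truth(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict(config), fh, indent=2)
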