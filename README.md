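# mpqtl

QTL mapping in multiparent recombinant inbred panels — founder-haplotype
genome scans with permutation genomewide significance, interval
estimation, founder-allele partitioning, mixed-model variance
decomposition and effect sizes, and epistasis/modifier scans.  A built-in
panel simulator generates DSPR-like synthetic data with planted QTL so
every stage of the pipeline is verifiable by parameter recovery, without
any downloads.

## Who this is for

Quantitative geneticists analysing eight-founder advanced-intercross
panels (DSPR-style *Drosophila* RILs, and panels with the same data
shape): each recombinant inbred line's genome is a homozygous fine-scale
mosaic of the founders, summarised as founder genotype probabilities on an
evenly spaced 10-kb grid, and phenotypes are replicate-vial assays (e.g.
post-infection survival days, or the proportion of infected flies).

## The model

Vial phenotypes follow the crossed random-effects model

    y_ijk = beta + date_i + RIL_j + eps_ijk

with repeatability `R = s2_RIL / (s2_RIL + s2_resid)`.  Date-corrected
RIL BLUPs are regressed on the eight founder genotype probabilities at
every grid position; the model-comparison F becomes
`LOD = (n/2) log10(RSS0/RSS1)`, and genomewide significance comes from
permuting phenotypes across lines (2,000 permutations by default) and
recording the maximum LOD.  Mapped peaks get 95% Bayesian credible and
2-LOD drop intervals; founder alleles at a peak are split into resistant
and susceptible classes by maximal one-way ANOVA F over ranked cuts;
per-QTL variance explained is a Bayesian (Gibbs) contrast of the
between-RIL variance with and without the QTL as a fixed effect; joint
effect sizes are REML coefficients on the 0→1 resistant-probability
scale; and epistasis is tested pairwise (ML likelihood ratio) and by
genomewide interaction scans against mapped QTL.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

Simulate a 600-RIL panel with one planted major QTL (founders 1–3
resistant, +5.2 days) and run the core analysis:

```python
from mpqtl import (GenomeGrid, PlantedQtl, SimConfig, simulate_panel,
                   plant_genetic_values, simulate_vials)
from mpqtl.pheno import (fit_baseline, repeatability, ril_blups,
                         effect_sizes_joint, variance_explained)
from mpqtl.founders import partition_at, resistant_probability
from mpqtl.scan import (genome_scan, permutation_null, genomewide_threshold,
                        genomewide_pvalue, refine_interval)
from mpqtl.mixed import McmcSettings

grid = GenomeGrid.toy(arm_kb=5000, arms=("2L", "2R"))
qtl = PlantedQtl("pst_like", "2L", 2500, frozenset({1, 2, 3}), 5.2)
cfg = SimConfig(n_ril=600, grid=grid, qtl_list=[qtl], n_vials_per_ril=2,
                sigma2_ril=1.8, sigma2_date=0.5, sigma2_resid=0.9, seed=42)
mosaics, panel = simulate_panel(cfg)
vials = simulate_vials(plant_genetic_values(mosaics, cfg.qtl_list, grid), cfg)

fit = fit_baseline(vials)
decomp = repeatability(fit)
blups = ril_blups(fit)
scan = genome_scan(blups, panel)
peak = scan.loc[scan["lod"].idxmax()]
null = permutation_null(blups, panel, n_perm=1000, seed=1)
iv = refine_interval(blups, panel, peak["arm"],
                     (peak["pos_kb"] - 500, peak["pos_kb"] + 500))
part = partition_at(blups, panel.at(peak["arm"], iv.peak_pos_kb), "pst_like")
prob = resistant_probability(part, panel.at(peak["arm"], iv.peak_pos_kb),
                             panel.ril_ids)
est = effect_sizes_joint(vials, prob.to_frame("pst_like"))[0]
ve = variance_explained(vials, prob.rename("pst_like"),
                        McmcSettings(n_iter=5000, burn_in=1500, thin=5), seed=2)
```

Output (formatted):

```
repeatability R = 0.896 (95% CI 0.879-0.911)
peak 2L:2500 kb, LOD 174.7 (0.05 threshold 5.78, genomewide p = 0.000999)
95% Bayesian CI 2500-2500 kb, 2-LOD drop 2500-2500 kb
resistant founders: [1, 2, 3] (F = 1677)
effect 5.14 days (95% CI 4.89-5.39); explains 77.9% of between-RIL variance
```

Reading it: the assay is highly repeatable (R ≈ 0.9 — most between-vial
variance is genetic), the scan peak lands exactly on the planted position
with overwhelming support (LOD 175 against a genomewide 0.05 threshold of
5.8; none of 1,000 permutations came close, so p is the add-one floor
1/1001), both support intervals collapse to the single causal grid step,
the maximal-F split recovers the planted 3-resistant/5-susceptible
founder classes, and the joint model estimates the allele swap at
5.14 days (planted: 5.2) explaining ~78% of the between-RIL variance.

The same pipeline runs from the shell (`mpqtl simulate`, `mpqtl scan`,
`mpqtl partition`, `mpqtl variance`, `mpqtl epistasis`, or `mpqtl run`
for the end-to-end report bundle); every stochastic subcommand requires
`--seed`.  Real panels are supplied as a genotype-probability TSV
(`ril_id, arm, pos_kb, p_F1..p_F8`) and a phenotype CSV (vial-level or
fly-level; see `mpqtl.io`).

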