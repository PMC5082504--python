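"""End-to-end orchestration: simulate/load -> models -> scans -> report.

Mirrors the analysis sequence of a multiparent-RIL resistance study:
baseline mixed model and repeatability, date-corrected BLUPs, primary
founder-haplotype scan with permutation thresholds, local interval
refinement, founder-allele partitioning, a covariate-controlled secondary
scan, Bayesian variance decomposition and joint effect sizes, then
pairwise-epistasis tests and a modifier-interaction scan.

Every stochastic step draws its seed from the run seed; two runs with the
same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .founders import partition_at, resistant_probability, ld_fisher
from .grid import GenomeGrid
from .mixed import McmcSettings
from .panel import Panel
from .pheno import (
    build_vial_phenotypes,
    blups_corrected,
    effect_sizes_joint,
    fit_baseline,
    repeatability,
    ril_blups,
    variance_explained,
)
from .epistasis import modifier_scan, modifier_null, pairwise_epistasis
from .scan import (
    genome_scan,
    genomewide_pvalue,
    genomewide_threshold,
    permutation_null,
    refine_interval,
)
from .sim import SimConfig, PlantedQtl, plant_genetic_values, simulate_panel, simulate_vials, truth_dict

logger = logging.getLogger(__name__)


def _sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "grid" in d and isinstance(d["grid"], dict):
        g = d["grid"]
        from .grid import ArmSpec
        d["grid"] = GenomeGrid(
            arms=tuple(ArmSpec(*a) for a in g["arms"]), step_kb=g.get("step_kb", 10))
    if "qtl_list" in d:
        d["qtl_list"] = [
            PlantedQtl(q["qtl_id"], q["arm"], q["pos_kb"],
                       frozenset(q["resistant_founders"]), q["effect"],
                       tuple(q["interaction"]) if q.get("interaction") else None)
            for q in d["qtl_list"]
        ]
    return SimConfig(**d)


def _load_inputs(config: mio.RunConfig, seeds) -> tuple[Panel, pd.DataFrame, Optional[dict]]:
    if config.genotype_path is not None:
        logger.info("reading genotypes from %s", config.genotype_path)
        panel = mio.read_genotype_probs(config.genotype_path)
        pheno = mio.read_phenotypes(config.phenotype_path, assay=config.assay)
        if pheno.attrs.get("level") == "fly":
            vials = build_vial_phenotypes(pheno)
        else:
            vials = pheno
        return panel, vials, None
    sim = dict(config.sim)
    sim.setdefault("assay", config.assay)
    sim["seed"] = int(seeds["sim"])
    sc = _sim_config_from_dict(sim)
    logger.info("simulating panel: %d RILs, %d generations", sc.n_ril, sc.n_generations)
    mosaics, panel = simulate_panel(sc)
    genetic = plant_genetic_values(mosaics, sc.qtl_list, sc.grid)
    vials = simulate_vials(genetic, sc, np.random.default_rng(int(seeds["vials"])))
    return panel, vials, truth_dict(sc)


def run_pipeline(config: mio.RunConfig) -> dict:
    """Run the full analysis; writes the report bundle and returns a summary."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    names = ["sim", "vials", "perm", "perm_cov", "mcmc", "perm_int"]
    seeds = {k: int(s.generate_state(1)[0] % (2**31 - 1)) for k, s in zip(names, ss.spawn(len(names)))}
    log = {"seed": config.seed, "stage_seeds": seeds, "n_perm": config.n_perm,
           "alpha_grid": list(config.alpha_grid), "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        log["stages"].append({"name": name, "t": round(time.time() - t_start, 3)})

    stage("inputs")
    panel, vials, truth = _load_inputs(config, seeds)
    if truth is not None:
        mio.write_json(truth, out / "truth.json")
    higher_is_resistant = config.assay == "dcv"

    stage("baseline model")
    fit = fit_baseline(vials)
    decomp = repeatability(fit)
    blups = ril_blups(fit)
    mio.write_json({
        "beta": fit.intercept,
        "sigma2_date": fit.sigma2_date,
        "sigma2_ril": fit.sigma2_ril,
        "sigma2_resid": fit.sigma2_resid,
        "repeatability": decomp.R,
        "repeatability_ci_95": list(decomp.R_ci_95),
        "method": fit.method,
    }, out / "model_fit.json")
    blups.rename("blup").to_frame().reset_index(names="ril_id").to_csv(
        out / "blups.tsv", sep="\t", index=False, float_format="%.10g")

    stage("primary scan")
    scan = genome_scan(blups, panel)
    mio.write_scan(scan, out / "scan.tsv")
    null = permutation_null(blups, panel, config.n_perm, seeds["perm"])
    mio.write_null(null, out / "null.tsv")
    usable_alphas = [a for a in config.alpha_grid if a * config.n_perm >= 1]
    skipped = sorted(set(config.alpha_grid) - set(usable_alphas))
    if skipped:
        logger.info("alpha level(s) %s below permutation resolution; skipped", skipped)
    thresholds = {a: genomewide_threshold(null, a) for a in usable_alphas}

    peak = scan.loc[scan["lod"].idxmax()]
    peak_p = genomewide_pvalue(null, float(peak["lod"]))
    intervals = []
    partitions = []
    qtl_probs = {}
    mapped = []

    def map_qtl(qtl_id: str, scan_df: pd.DataFrame, y: pd.Series, p_gw: float, covariate=None):
        pk = scan_df.loc[scan_df["lod"].idxmax()]
        arm, pos = str(pk["arm"]), float(pk["pos_kb"])
        w = config.interval_window_kb
        arm_len = panel.grid.arm(arm).length_kb
        iv = refine_interval(y, panel, arm, (max(pos - w, 0), min(pos + w, arm_len)),
                             covariate=covariate, genomewide_p=p_gw)
        part = partition_at(y, panel.at(arm, iv.peak_pos_kb), qtl_id,
                            assign_threshold=config.assign_threshold,
                            higher_is_resistant=higher_is_resistant)
        prob = resistant_probability(part, panel.at(arm, iv.peak_pos_kb), panel.ril_ids)
        intervals.append((qtl_id, iv))
        partitions.append(part)
        qtl_probs[qtl_id] = prob
        mapped.append({"qtl_id": qtl_id, "arm": arm, "pos_kb": iv.peak_pos_kb,
                       "lod": iv.peak_lod, "genomewide_p": p_gw})
        return iv, part, prob

    alpha0 = max(usable_alphas)
    significant = float(peak["lod"]) >= thresholds[alpha0]
    if significant:
        stage("primary QTL")
        qtl1 = f"Q1_{peak['arm']}{int(peak['pos_kb'])//1000}"
        iv1, part1, prob1 = map_qtl(qtl1, scan, blups, peak_p)

        stage("covariate rescan")
        cov = pd.DataFrame(panel.at(iv1.arm, iv1.peak_pos_kb)[:, :7],
                           index=panel.ril_ids,
                           columns=[f"{qtl1}_p{j}" for j in range(1, 8)])
        scan_cov = genome_scan(blups, panel, covariate=cov)
        mio.write_scan(scan_cov, out / "scan_covariate.tsv")
        null_cov = permutation_null(blups, panel, config.n_perm, seeds["perm_cov"],
                                    covariate=cov)
        thr_cov = genomewide_threshold(null_cov, alpha0)
        pk2 = scan_cov.loc[scan_cov["lod"].idxmax()]
        if float(pk2["lod"]) >= thr_cov and str(pk2["arm"]) != iv1.arm:
            p2 = genomewide_pvalue(null_cov, float(pk2["lod"]))
            qtl2 = f"Q2_{pk2['arm']}{int(pk2['pos_kb'])//1000}"
            # secondary mapping on BLUPs corrected for the primary QTL
            bl_cov = blups_corrected(vials, prob1.rename(qtl1))
            map_qtl(qtl2, scan_cov, bl_cov, p2)
    else:
        logger.info("no genomewide-significant QTL at alpha=%s", alpha0)

    mio.write_json({"thresholds": {str(a): t for a, t in thresholds.items()},
                    "max_lod": float(peak["lod"]),
                    "max_lod_genomewide_p": peak_p,
                    "qtl": [dict(m, **mio.interval_to_dict(iv))
                            for m, (qid, iv) in zip(mapped, intervals)]},
                   out / "intervals.json")
    mio.write_json([mio.partition_to_dict(p) for p in partitions], out / "partitions.json")

    effects_rows = []
    if mapped:
        stage("variance decomposition and effect sizes")
        mcmc = McmcSettings(**config.mcmc) if config.mcmc else McmcSettings()
        probs_df = pd.DataFrame(qtl_probs)
        estimates = effect_sizes_joint(vials, probs_df,
                                       units="days" if config.assay == "dcv" else "proportion")
        for est in estimates:
            ve = variance_explained(vials, probs_df[est.qtl_id].rename(est.qtl_id),
                                    settings=mcmc, seed=seeds["mcmc"])
            effects_rows.append({
                "qtl_id": est.qtl_id, "effect": est.effect,
                "ci_lo": est.ci_95[0], "ci_hi": est.ci_95[1], "p": est.p,
                "units": est.units, "type2_F": est.type2_F,
                "prop_var_explained": ve.proportion,
                "flags": ";".join(est.flags + ve.flags),
            })
        pd.DataFrame(effects_rows).to_csv(out / "effects.tsv", sep="\t", index=False,
                                          float_format="%.10g")

    epistasis_rows = []
    ld_rows = []
    modifier_summary = None
    if config.run_epistasis and len(mapped) >= 1:
        stage("epistasis")
        ids = [m["qtl_id"] for m in mapped]
        classes = {}
        for qid in ids:
            pr = qtl_probs[qid]
            cls = pd.Series(np.nan, index=pr.index)
            cls[pr >= config.assign_threshold] = 1.0
            cls[pr <= 1 - config.assign_threshold] = 0.0
            classes[qid] = cls
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                et = pairwise_epistasis(vials, classes[ids[i]], classes[ids[j]],
                                        min_class_n=config.min_class_n,
                                        pair_ids=(ids[i], ids[j]))
                epistasis_rows.append({
                    "qtl_a": ids[i], "qtl_b": ids[j],
                    "main_a": et.main_effects[0], "main_b": et.main_effects[1],
                    "interaction": et.interaction, "lrt": et.lrt, "p": et.p,
                    "skipped": et.skipped, "skip_reason": et.skip_reason or "",
                })
                orat, pld, table, fl = ld_fisher(
                    panel.at(intervals[i][1].arm, intervals[i][1].peak_pos_kb), partitions[i],
                    panel.at(intervals[j][1].arm, intervals[j][1].peak_pos_kb), partitions[j],
                    panel.ril_ids, assign_threshold=config.assign_threshold)
                ld_rows.append({"qtl_a": ids[i], "qtl_b": ids[j], "odds_ratio": orat,
                                "p": pld, "table": json.dumps(table.tolist()),
                                "flags": ";".join(fl)})
        if epistasis_rows:
            pd.DataFrame(epistasis_rows).to_csv(out / "epistasis.tsv", sep="\t",
                                                index=False, float_format="%.10g")
            pd.DataFrame(ld_rows).to_csv(out / "ld_fisher.tsv", sep="\t", index=False,
                                         float_format="%.10g")

        stage("modifier scan")
        qid = mapped[0]["qtl_id"]
        ms = modifier_scan(blups, panel, qtl_probs[qid], min_mass=config.min_mass)
        mio.write_scan(ms, out / "modifier_scan.tsv")
        mnull = modifier_null(blups, panel, qtl_probs[qid],
                              n_perm=config.n_perm_interaction, seed=seeds["perm_int"],
                              min_mass=config.min_mass)
        mthr = genomewide_threshold(mnull, alpha0)
        mp = ms.loc[ms["int_lod"].idxmax()]
        modifier_summary = {
            "against_qtl": qid, "arm": str(mp["arm"]), "pos_kb": float(mp["pos_kb"]),
            "int_lod": float(mp["int_lod"]), "threshold_0.05": mthr,
            "genomewide_p": genomewide_pvalue(mnull, float(mp["int_lod"])),
            "significant": bool(mp["int_lod"] >= mthr),
        }
        mio.write_json(modifier_summary, out / "modifier.json")

    stage("done")
    log["runtime_s"] = round(time.time() - t_start, 3)
    mio.write_json(log, out / "run_log.json")
    return {
        "repeatability": decomp.R,
        "repeatability_ci_95": decomp.R_ci_95,
        "thresholds": thresholds,
        "qtl": mapped,
        "intervals": {qid: mio.interval_to_dict(iv) for qid, iv in intervals},
        "partitions": [mio.partition_to_dict(p) for p in partitions],
        "effects": effects_rows,
        "epistasis": epistasis_rows,
        "modifier": modifier_summary,
        "out_dir": str(out),
    }
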