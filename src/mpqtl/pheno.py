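"""Phenotype models: vial aggregation, repeatability, BLUPs, effect sizes.

Implements the analysis layer that sits between raw assay records and the
genome scans: aggregation of fly-level outcomes into vial means, REML fits
of the date/RIL mixed model, repeatability with profile-likelihood CIs,
per-RIL BLUPs (raw and QTL-corrected), the Bayesian variance-decomposition
contrast, and joint effect sizes on the resistant-probability scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .mixed import (
    McmcSettings,
    MixedFit,
    fit_crossed,
    gibbs_crossed,
    profile_repeatability_ci,
)

logger = logging.getLogger(__name__)

VIAL_COLUMNS = ["ril_id", "vial_id", "date", "assay", "n_flies", "value"]


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# vial aggregation
# ---------------------------------------------------------------------------

def build_vial_phenotypes(records: pd.DataFrame, *, early_death_day: int = 1,
                          observation_days: int = 15,
                          survivors_at: Optional[float] = None) -> pd.DataFrame:
    """Aggregate fly-level records into vial-level phenotypes.

    For the dcv assay, flies dying within ``early_death_day`` days are
    excluded (assumed injection deaths) and survivors at the end of the
    observation window enter at ``survivors_at`` (default: the window
    length, 15 days); the vial value is the mean death day of the remaining
    flies.  For the sigma assay the value is the proportion of infected
    flies.  Vials with no remaining flies are dropped with a warning.

    Parameters
    ----------
    records : DataFrame
        Columns ``ril_id, vial_id, date, assay`` plus, for dcv, ``day``
        (death day, int) and ``censored`` (bool: alive at end of window);
        for sigma, ``infected`` (0/1).
    """
    if "assay" not in records.columns:
        raise InputError("records need an 'assay' column")
    assays = set(records["assay"].unique())
    if len(assays) != 1:
        raise InputError(f"records mix assays: {sorted(assays)}")
    assay = assays.pop()
    if survivors_at is None:
        survivors_at = float(observation_days)

    rows = []
    group_cols = ["ril_id", "vial_id", "date"]
    if assay == "dcv":
        if "day" not in records.columns:
            raise InputError("dcv records need a 'day' column")
        censored = records["censored"] if "censored" in records.columns else pd.Series(False, index=records.index)
        day = records["day"].astype(float).where(~censored, survivors_at)
        if (records.loc[~censored, "day"] < 1).any():
            raise InputError("death day must be >= 1 (observation window starts at day 1)")
        keep = censored | (records["day"] > early_death_day)
        for (ril, vial, date), grp in records.assign(_day=day, _keep=keep).groupby(group_cols, sort=False):
            vals = grp.loc[grp["_keep"], "_day"]
            if len(vals) == 0:
                warnings.warn(f"vial {vial!r}: all flies died within {early_death_day} day(s); vial dropped")
                continue
            rows.append((ril, vial, date, assay, len(vals), float(vals.mean())))
    elif assay == "sigma":
        if "infected" not in records.columns:
            raise InputError("sigma records need an 'infected' column")
        if not records["infected"].isin([0, 1]).all():
            raise InputError("sigma 'infected' must be 0/1")
        for (ril, vial, date), grp in records.groupby(group_cols, sort=False):
            rows.append((ril, vial, date, assay, len(grp), float(grp["infected"].mean())))
    else:
        raise InputError(f"unknown assay {assay!r}")
    return pd.DataFrame(rows, columns=VIAL_COLUMNS)


def _check_vials(vials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("ril_id", "date", "value") if c not in vials.columns]
    if missing:
        raise InputError(f"vial table missing columns: {missing}")
    if not np.all(np.isfinite(vials["value"].to_numpy(dtype=float))):
        raise InputError("non-finite vial values")
    return vials


# ---------------------------------------------------------------------------
# baseline model, repeatability, BLUPs
# ---------------------------------------------------------------------------

def fit_baseline(vials: pd.DataFrame, method: str = "reml") -> MixedFit:
    """REML fit of value = beta + date + RIL + eps (all random but beta)."""
    vials = _check_vials(vials)
    y = vials["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    return fit_crossed(y, X, vials["date"].to_numpy(), vials["ril_id"].to_numpy(),
                       method=method, fixed_names=["intercept"])


@dataclass
class VarianceDecomposition:
    """Repeatability and (optionally) per-QTL variance proportions."""

    R: float
    R_ci_95: tuple
    sigma2_ril: float
    sigma2_resid: float
    sigma2_date: float
    proportion_explained: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def repeatability(fit: MixedFit, ci: bool = True, seed: int = 0) -> VarianceDecomposition:
    """Repeatability R = s2_RIL / (s2_RIL + s2_resid) with 95% profile CI.

    The between-date variance is deliberately excluded: R is repeatability
    of the assay on a single day.
    """
    tot = fit.sigma2_ril + fit.sigma2_resid
    if tot <= 0:
        raise InputError("repeatability undefined: both variance components are zero")
    R = fit.sigma2_ril / tot
    ci_pair = profile_repeatability_ci(fit, seed=seed) if ci else (math.nan, math.nan)
    return VarianceDecomposition(
        R=R, R_ci_95=ci_pair, sigma2_ril=fit.sigma2_ril,
        sigma2_resid=fit.sigma2_resid, sigma2_date=fit.sigma2_date)


def ril_blups(fit: MixedFit) -> pd.Series:
    """Empirical BLUPs of the RIL deviations (shrunken, date-corrected)."""
    s = fit.ril_effects.copy()
    s.name = "blup"
    return s


def _covariate_design(vials: pd.DataFrame, covariate) -> tuple[np.ndarray, list, pd.DataFrame]:
    """Expand a per-RIL covariate into fixed-effect columns per vial.

    Accepts a Series (two-level class or a single continuous column, e.g. a
    resistant probability) or a DataFrame (e.g. the eight founder
    probabilities at a QTL; one linearly dependent column is dropped by the
    rank reduction downstream).  RILs without covariate values are dropped
    with a warning.
    """
    if isinstance(covariate, pd.Series):
        cov = covariate.to_frame(covariate.name or "qtl")
    elif isinstance(covariate, pd.DataFrame):
        cov = covariate
    else:
        raise InputError("covariate must be a pandas Series or DataFrame indexed by ril_id")
    have = vials["ril_id"].isin(cov.index)
    if not have.all():
        dropped = sorted(set(vials.loc[~have, "ril_id"]))
        warnings.warn(f"{len(dropped)} RIL(s) lack covariate values and were dropped")
        vials = vials.loc[have]
    M = cov.loc[vials["ril_id"]]
    cols = []
    names = []
    for c in M.columns:
        col = M[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(str(c))
    X = np.column_stack([np.ones(len(vials))] + cols) if cols else np.ones((len(vials), 1))
    return X, ["intercept"] + names, vials


def fit_with_qtl(vials: pd.DataFrame, covariate, method: str = "reml") -> MixedFit:
    """REML/ML fit of value = beta + QTL + date + RIL + eps.

    The QTL enters as fixed-effect column(s): a two-level allele class or
    the founder genotype probabilities at the peak.
    """
    vials = _check_vials(vials)
    X, names, vials = _covariate_design(vials, covariate)
    return fit_crossed(vials["value"].to_numpy(float), X,
                       vials["date"].to_numpy(), vials["ril_id"].to_numpy(),
                       method=method, fixed_names=names)


def blups_corrected(vials: pd.DataFrame, qtl_covariate) -> pd.Series:
    """Per-RIL BLUPs net of a fixed QTL term (and injection date)."""
    return ril_blups(fit_with_qtl(vials, qtl_covariate))


# ---------------------------------------------------------------------------
# Bayesian variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceExplained:
    proportion: float
    posterior_samples: np.ndarray
    s2_ril_base_median: float
    s2_ril_qtl_median: float
    flags: list = field(default_factory=list)


def variance_explained(vials: pd.DataFrame, qtl_covariate,
                       settings: McmcSettings = McmcSettings(),
                       seed: int = 0) -> VarianceExplained:
    """Proportion of between-RIL variance absorbed by a QTL.

    Both the baseline model and the model with the QTL as a fixed effect
    are fitted by Gibbs sampling; the proportion is the relative drop in
    the posterior median of the between-RIL variance.  Negative values
    (sampling noise around zero) are reported as-is with a flag.
    """
    vials = _check_vials(vials)
    ss = np.random.SeedSequence(seed)
    s_base, s_qtl = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]

    y = vials["value"].to_numpy(float)
    X0 = np.ones((len(y), 1))
    ch0 = gibbs_crossed(y, X0, vials["date"].to_numpy(), vials["ril_id"].to_numpy(),
                        settings, seed=s_base)
    X1, names, v1 = _covariate_design(vials, qtl_covariate)
    ch1 = gibbs_crossed(v1["value"].to_numpy(float), X1, v1["date"].to_numpy(),
                        v1["ril_id"].to_numpy(), settings, seed=s_qtl)

    m0 = float(np.median(ch0["sigma2_ril"]))
    m1 = float(np.median(ch1["sigma2_ril"]))
    prop = (m0 - m1) / m0
    flags = []
    if prop < 0:
        flags.append("negative_proportion")
    for tag, ch in (("base", ch0), ("qtl", ch1)):
        if ch["ess_sigma2_ril"] < settings.min_ess:
            flags.append(f"low_ess_{tag}")
    # paired posterior contrast (draws are independent across the chains)
    m = min(len(ch0["sigma2_ril"]), len(ch1["sigma2_ril"]))
    samples = (ch0["sigma2_ril"][:m] - ch1["sigma2_ril"][:m]) / ch0["sigma2_ril"][:m]
    return VarianceExplained(proportion=prop, posterior_samples=samples,
                             s2_ril_base_median=m0, s2_ril_qtl_median=m1, flags=flags)


# ---------------------------------------------------------------------------
# joint effect sizes
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    qtl_id: str
    effect: float
    ci_95: tuple
    p: float
    units: str
    type2_F: float
    flags: list = field(default_factory=list)


def effect_sizes_joint(vials: pd.DataFrame, resistant_probs: pd.DataFrame,
                       units: str = "days") -> list[EffectEstimate]:
    """Joint effect sizes of all mapped QTL on the 0->1 resistant scale.

    Fits value = beta + sum_h QTL_h + date + RIL + eps by REML with every
    QTL's per-RIL resistant probability as a simultaneous fixed effect.
    Effects are the coefficients (trait change from the susceptible to the
    resistant allele), with Wald 95% intervals and two-sided p; the Wald
    chi-square of each coefficient given all others serves as the type II
    test.  Covariate pairs with |r| > 0.99 are flagged as collinear.
    """
    vials = _check_vials(vials)
    if not isinstance(resistant_probs, pd.DataFrame):
        raise InputError("resistant_probs must be a DataFrame (rils x qtls)")
    flags_global = []
    corr = resistant_probs.corr().to_numpy()
    qtl_names = list(resistant_probs.columns)
    for i in range(len(qtl_names)):
        for j in range(i + 1, len(qtl_names)):
            if abs(corr[i, j]) > 0.99:
                flags_global.append(f"collinear:{qtl_names[i]}~{qtl_names[j]}")

    fit = fit_with_qtl(vials, resistant_probs)
    out = []
    se_all = np.sqrt(np.diag(fit.cov_beta))
    for q in qtl_names:
        if q not in fit.fixed_names:
            out.append(EffectEstimate(q, math.nan, (math.nan, math.nan), math.nan,
                                      units, math.nan, flags=["dropped_collinear"] + flags_global))
            continue
        i = fit.fixed_names.index(q)
        eff = float(fit.beta[i])
        se = float(se_all[i])
        z = eff / se if se > 0 else math.inf
        p = 2 * stats.norm.sf(abs(z))
        out.append(EffectEstimate(q, eff, (eff - 1.959963984540054 * se, eff + 1.959963984540054 * se),
                                  float(p), units, float(z * z), flags=list(flags_global)))
    return out
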