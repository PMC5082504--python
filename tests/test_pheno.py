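"""Vial aggregation, repeatability, BLUP correction and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpqtl.mixed import McmcSettings
from mpqtl.pheno import (
    InputError,
    VarianceDecomposition,
    blups_corrected,
    build_vial_phenotypes,
    effect_sizes_joint,
    fit_baseline,
    fit_with_qtl,
    repeatability,
    ril_blups,
    variance_explained,
)


def _fly_frame(days, censored=None, assay="dcv"):
    n = len(days)
    return pd.DataFrame({
        "ril_id": ["r1"] * n, "vial_id": ["v1"] * n, "date": ["d1"] * n,
        "assay": [assay] * n, "day": days,
        "censored": censored if censored is not None else [False] * n,
    })


class TestBuildVialPhenotypes:
    def test_early_deaths_excluded_then_mean(self):
        vials = build_vial_phenotypes(_fly_frame([1, 1, 5, 7]))
        assert len(vials) == 1
        assert vials.loc[0, "value"] == 6.0
        assert vials.loc[0, "n_flies"] == 2

    def test_sigma_proportion(self):
        rec = pd.DataFrame({
            "ril_id": ["r1"] * 20, "vial_id": ["v1"] * 20, "date": ["d1"] * 20,
            "assay": ["sigma"] * 20, "infected": [1] * 14 + [0] * 6,
        })
        vials = build_vial_phenotypes(rec)
        assert vials.loc[0, "value"] == pytest.approx(0.7)

    def test_vial_of_only_early_deaths_dropped_with_warning(self):
        rec = pd.concat([_fly_frame([1, 1]), _fly_frame([3, 4]).assign(vial_id="v2")])
        with pytest.warns(UserWarning, match="dropped"):
            vials = build_vial_phenotypes(rec)
        assert list(vials["vial_id"]) == ["v2"]

    def test_survivors_enter_at_window_end(self):
        vials = build_vial_phenotypes(_fly_frame([5, 5], censored=[False, True]))
        assert vials.loc[0, "value"] == pytest.approx((5 + 15) / 2)

    def test_mixed_assays_rejected(self):
        rec = pd.concat([_fly_frame([3]), _fly_frame([4]).assign(assay="sigma")])
        with pytest.raises(InputError):
            build_vial_phenotypes(rec)


@given(a=st.floats(0, 1e6), b=st.floats(1e-9, 1e6))
@settings(max_examples=200, deadline=None)
def test_repeatability_arithmetic_exact(a, b):
    """R = a / (a + b) for every non-negative variance pair."""
    fit = _fake_fit(a, b)
    out = repeatability(fit, ci=False)
    assert out.R == pytest.approx(a / (a + b))


def _fake_fit(s2r, s2e):
    from mpqtl.mixed import MixedFit
    return MixedFit(beta=np.array([0.0]), fixed_names=["intercept"],
                    cov_beta=np.zeros((1, 1)), sigma2_date=0.0, sigma2_ril=s2r,
                    sigma2_resid=s2e, date_effects=pd.Series(dtype=float),
                    ril_effects=pd.Series(dtype=float), loglik=0.0, method="reml",
                    n=10, converged=True)


def test_repeatability_edge_cases():
    assert repeatability(_fake_fit(1.0, 1.0), ci=False).R == pytest.approx(0.5)
    assert repeatability(_fake_fit(2.0, 0.0), ci=False).R == pytest.approx(1.0)
    with pytest.raises(InputError):
        repeatability(_fake_fit(0.0, 0.0), ci=False)


def _sim_vials(rng, n_ril=60, n_vial=2, effect=None, s2r=1.0, s2e=0.5, s2d=0.3):
    """Hand-rolled vial table with a known per-RIL covariate."""
    rils = [f"r{i:03d}" for i in range(n_ril)]
    cov = pd.Series(rng.uniform(0, 1, n_ril), index=rils, name="q")
    rr = rng.normal(0, np.sqrt(s2r), n_ril)
    rows = []
    day = 0
    for v in range(n_vial):
        de = rng.normal(0, np.sqrt(s2d))
        day += 1
        for i, r in enumerate(rils):
            y = 5 + rr[i] + de + rng.normal(0, np.sqrt(s2e))
            if effect is not None:
                y += effect * cov[r]
            rows.append((r, f"{r}v{v}", f"d{day}", "dcv", 20, y))
    return pd.DataFrame(rows, columns=["ril_id", "vial_id", "date", "assay",
                                       "n_flies", "value"]), cov


def test_blups_sum_to_zero_and_follow_phenotype(rng):
    vials, _ = _sim_vials(rng)
    fit = fit_baseline(vials)
    bl = ril_blups(fit)
    assert abs(bl.sum()) < 1e-6
    means = vials.groupby("ril_id")["value"].mean()
    assert np.corrcoef(bl[means.index], means)[0, 1] > 0.9


def test_constant_covariate_reproduces_baseline_blups(rng):
    vials, cov = _sim_vials(rng)
    const = pd.Series(1.0, index=cov.index, name="q")
    base = ril_blups(fit_baseline(vials))
    corr = blups_corrected(vials, const)
    assert np.abs((base - corr).to_numpy()).max() < 1e-6


def test_orthogonal_covariate_leaves_blups_nearly_unchanged(rng):
    vials, cov = _sim_vials(rng, n_ril=100)
    # covariate independent of phenotype
    other = pd.Series(rng.normal(size=100), index=cov.index, name="z")
    base = ril_blups(fit_baseline(vials))
    corr = blups_corrected(vials, other)
    assert np.corrcoef(base, corr[base.index])[0, 1] > 0.98


def test_covariate_missing_rils_dropped_with_warning(rng):
    vials, cov = _sim_vials(rng, n_ril=20)
    with pytest.warns(UserWarning, match="lack covariate"):
        fit = fit_with_qtl(vials, cov.iloc[:-3])
    assert len(fit.ril_effects) == 17


def test_variance_explained_orthogonal_covariate_near_zero(rng):
    vials, cov = _sim_vials(rng, n_ril=80)
    other = pd.Series(rng.normal(size=80), index=cov.index, name="z")
    ve = variance_explained(vials, other,
                            McmcSettings(n_iter=3000, burn_in=1000, thin=5), seed=5)
    assert abs(ve.proportion) < 0.05


def test_variance_explained_invariant_to_relabelling(rng):
    """Rank-preserving relabels reproduce the chain exactly; arbitrary
    relabels agree up to Monte Carlo noise."""
    vials, cov = _sim_vials(rng, n_ril=40, effect=3.0)
    settings = McmcSettings(n_iter=2000, burn_in=500, thin=5)
    v1 = variance_explained(vials, cov, settings, seed=9)
    relab = vials.copy()
    relab["ril_id"] = "X" + relab["ril_id"]
    relab["date"] = relab["date"].map({"d1": "a1", "d2": "a2"})
    cov2 = cov.copy()
    cov2.index = "X" + cov2.index
    v2 = variance_explained(relab, cov2, settings, seed=9)
    assert v1.proportion == pytest.approx(v2.proportion, abs=1e-12)
    swapped = vials.copy()
    swapped["date"] = swapped["date"].map({"d1": "zz", "d2": "aa"})
    v3 = variance_explained(swapped, cov, settings, seed=9)
    assert v1.proportion == pytest.approx(v3.proportion, abs=0.05)


def test_joint_single_qtl_reduces_to_marginal(rng):
    vials, cov = _sim_vials(rng, effect=4.0)
    joint = effect_sizes_joint(vials, cov.to_frame())
    marginal = fit_with_qtl(vials, cov)
    i = marginal.fixed_names.index("q")
    assert joint[0].effect == pytest.approx(float(marginal.beta[i]), abs=1e-8)


def test_zero_effect_covariate_interval_covers_zero(rng):
    vials, cov = _sim_vials(rng, n_ril=100, effect=4.0)
    zero = pd.Series(rng.uniform(0, 1, 100), index=cov.index, name="null_qtl")
    ests = effect_sizes_joint(vials, pd.DataFrame({"q": cov, "null_qtl": zero}))
    by_id = {e.qtl_id: e for e in ests}
    lo, hi = by_id["null_qtl"].ci_95
    assert lo < 0 < hi
    assert by_id["q"].p < 1e-6


def test_collinear_covariates_flagged(rng):
    vials, cov = _sim_vials(rng, effect=2.0)
    dup = pd.DataFrame({"q": cov, "q2": cov * 0.999 + 1e-4})
    ests = effect_sizes_joint(vials, dup)
    assert any("collinear" in f for e in ests for f in e.flags)
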