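"""Mixed-model solver checks: OLS oracle, Wald identities, LRT df counting,
an independent lme4 cross-check, and small-scale parameter recovery."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionbench import (ModelSpec, RandomTerm, fit_lmm, hypothesis_a,
                         hypothesis_b, hypothesis_c, likelihood_ratio_test,
                         simulate_lmm_dataset, zscore_columns)

SPEC_B = ModelSpec(outcome="pvd", fixed_terms=["hemi_role"],
                   random_terms=[RandomTerm("pair_id"), RandomTerm("lesion_id"),
                                 RandomTerm("control_id")])


# --- z-scoring --------------------------------------------------------------

def test_zscore_basic():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    out = zscore_columns(df, ["x"])
    assert out.x.tolist() == pytest.approx([-1.0, 0.0, 1.0])


def test_zscore_idempotent(rng):
    df = pd.DataFrame({"x": rng.normal(5, 2, 50)})
    once = zscore_columns(df, ["x"])
    twice = zscore_columns(once, ["x"])
    assert np.allclose(once.x, twice.x, atol=1e-8)


def test_zscore_constant_column_named():
    with pytest.raises(ValueError, match="x"):
        zscore_columns(pd.DataFrame({"x": [2.0, 2.0]}), ["x"])


# --- fixed effects against the OLS oracle -----------------------------------

def _ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


@pytest.mark.parametrize("estimation", ["REML", "ML"])
def test_zero_variance_data_matches_ols(estimation):
    df = simulate_lmm_dataset(
        "b", {"sd_pair": 0.0, "sd_lesion": 0.0, "sd_control": 0.0},
        n_lesions=8, n_controls=5, seed=2)
    fit = fit_lmm(df, ModelSpec(**{**SPEC_B.__dict__, "estimation": estimation}))
    X = np.column_stack([np.ones(len(df)),
                         (df.hemi_role == "lesioned").to_numpy(float)])
    beta = _ols(X, df.pvd.to_numpy())
    got = [fit.coefficients["(Intercept)"].B,
           fit.coefficients["hemi_role[lesioned]"].B]
    assert got == pytest.approx(list(beta), rel=1e-4)


def test_wald_identities_hold():
    df = simulate_lmm_dataset("b", n_lesions=6, n_controls=4, seed=3)
    fit = fit_lmm(df, SPEC_B)
    for c in fit.coefficients.values():
        assert c.t == pytest.approx(c.B / c.SE, abs=1e-10)
        assert c.p == pytest.approx(2 * stats.norm.sf(abs(c.t)), abs=1e-12)
        assert c.SE > 0
        assert 0 < c.p <= 1


# --- likelihood-ratio tests -------------------------------------------------

def test_lrt_identical_models_is_zero():
    df = simulate_lmm_dataset("b", n_lesions=5, n_controls=4, seed=4)
    spec = ModelSpec(**{**SPEC_B.__dict__, "estimation": "ML"})
    fit = fit_lmm(df, spec)
    lrt = likelihood_ratio_test(fit, fit)
    assert lrt.chi_square == 0.0


def test_lrt_requires_ml():
    df = simulate_lmm_dataset("b", n_lesions=5, n_controls=4, seed=4)
    reml = fit_lmm(df, SPEC_B)
    with pytest.raises(ValueError, match="ML"):
        likelihood_ratio_test(reml, reml)


def test_lrt_statistic_nonnegative_across_seeds():
    spec = ModelSpec(**{**SPEC_B.__dict__, "estimation": "ML"})
    null = ModelSpec(outcome="pvd", fixed_terms=["hemi_role"], estimation="ML")
    for seed in range(5):
        df = simulate_lmm_dataset("b", n_lesions=5, n_controls=4, seed=seed)
        lrt = likelihood_ratio_test(fit_lmm(df, spec), fit_lmm(df, null))
        assert lrt.chi_square >= 0.0


def test_hypothesis_b_lrt_has_three_df():
    """Three crossed random intercepts against the fixed-only model."""
    df = simulate_lmm_dataset("b", n_lesions=6, n_controls=4, seed=6)
    res = hypothesis_b(df)
    assert res.lrt.df == 3


def test_hypothesis_a_lrt_has_five_df():
    """Correlated case slope within pair (3 params) + 2 crossed intercepts."""
    df = simulate_lmm_dataset("a", n_lesions=5, n_controls=4, seed=6)
    res = hypothesis_a(df.assign(measure="cortex"), "cortex")
    if res.fit.correlation_dropped:
        assert res.lrt.df == 4
    else:
        assert res.lrt.df == 5


def test_hypothesis_a_subset_uses_intercept_only():
    df = simulate_lmm_dataset("a", n_lesions=5, n_controls=4, seed=6)
    res = hypothesis_a(df.assign(measure="cwm"), "cwm", "lesioned")
    assert all(rt.slope is None for rt in res.fit.spec.random_terms)


def test_hypothesis_c_has_no_lesion_grouping():
    df = simulate_lmm_dataset("c", n_lesions=6, n_controls=4, seed=7)
    df = df.assign(hemi_role="lesioned")
    res = hypothesis_c(df, None, None, "lesioned")
    groups = {rt.group for rt in res.fit.spec.random_terms}
    assert groups == {"control_id"}


def test_null_case_effect_recovered_as_zero():
    """simulated == ground truth exactly -> B(case) = 0."""
    rows = []
    rng = np.random.default_rng(8)
    for l in range(4):
        for c in range(3):
            v = {h: rng.normal(100.0, 5.0)
                 for h in ("lesioned", "contralesional")}
            for case in ("simulated", "ground_truth"):
                for hemi in ("lesioned", "contralesional"):
                    rows.append({"pair_id": f"L{l}_x_C{c}",
                                 "lesion_id": f"L{l}", "control_id": f"C{c}",
                                 "case": case, "hemi_role": hemi,
                                 "measure": "cortex", "volume_mm3": v[hemi]})
    res = hypothesis_a(pd.DataFrame(rows), "cortex")
    assert abs(res.fit.coefficients["case[simulated]"].B) < 1e-8


# --- independent oracle: lme4 via Rscript ------------------------------------

R_SCRIPT = """\
suppressMessages(library(lme4))
d <- read.csv('{csv}')
m  <- lmer(pvd ~ hemi_role + (1|pair_id) + (1|lesion_id) + (1|control_id),
           data=d, REML=TRUE)
mML <- lmer(pvd ~ hemi_role + (1|pair_id) + (1|lesion_id) + (1|control_id),
            data=d, REML=FALSE)
co <- summary(m)$coefficients
cat(co[1,1], co[1,2], co[2,1], co[2,2],
    as.numeric(logLik(m)), as.numeric(logLik(mML)), sep='\\n')
"""


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
def test_crossed_fit_matches_lme4(tmp_path):
    df = simulate_lmm_dataset("b", n_lesions=6, n_controls=4, seed=7)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(R_SCRIPT.format(csv=csv))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    b0, se0, b1, se1, ll_reml, ll_ml = map(float, out.stdout.split())

    reml = fit_lmm(df, SPEC_B)
    ml = fit_lmm(df, ModelSpec(**{**SPEC_B.__dict__, "estimation": "ML"}))
    assert reml.coefficients["(Intercept)"].B == pytest.approx(b0, rel=1e-4)
    assert reml.coefficients["(Intercept)"].SE == pytest.approx(se0, rel=1e-3)
    assert reml.coefficients["hemi_role[lesioned]"].B == pytest.approx(b1, rel=1e-4)
    assert reml.coefficients["hemi_role[lesioned]"].SE == pytest.approx(se1, rel=1e-3)
    assert reml.log_likelihood == pytest.approx(ll_reml, abs=1e-3)
    assert ml.log_likelihood == pytest.approx(ll_ml, abs=1e-3)


# --- small-scale parameter recovery -----------------------------------------

def test_hemisphere_effect_recovery_small():
    """Mean estimate across replicates within 3 Monte-Carlo SEs of truth."""
    truth = 0.14
    estimates = []
    for rep in range(40):
        df = simulate_lmm_dataset("b", {"hemisphere": truth},
                                  n_lesions=8, n_controls=5, seed=1000 + rep)
        fit = fit_lmm(df, SPEC_B)
        estimates.append(fit.coefficients["hemi_role[lesioned]"].B)
    est = np.asarray(estimates)
    mc_se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - truth) < 3 * mc_se


def test_rank_deficient_design_rejected():
    df = simulate_lmm_dataset("b", n_lesions=4, n_controls=3, seed=1)
    df["dup"] = (df.hemi_role == "lesioned").astype(float)
    spec = ModelSpec(outcome="pvd", fixed_terms=["hemi_role", "dup"],
                     random_terms=[RandomTerm("pair_id")])
    with pytest.raises(ValueError, match="rank deficient"):
        fit_lmm(df, spec)
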