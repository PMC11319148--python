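"""REML machinery: single-trial fits, FA-LMM vs dense oracle, model search."""

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_rcbd
from germeval import pedigree as pm
from germeval.famm import (
    METDataset,
    connectivity,
    detect_outliers,
    fit_famm,
    fit_single_trial,
    model_search,
    reliability,
    reml_loglik_direct,
)
from germeval.synth import SimConfig, gen_met, gen_pedigree

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# single-trial analyses
# ---------------------------------------------------------------------------

def test_single_trial_recovery(rng):
    """Balanced RCBD with sigma_g = sigma_e = 1: estimates within 3 s.e."""
    tr = balanced_rcbd(rng, m=100, r=2)
    fit = fit_single_trial(tr, terms=("block",))
    # rough large-sample s.e.: ~0.16 for sigma2_g, ~0.14 for sigma2_e at m=100
    assert abs(fit.sigma2_g - 1.0) < 0.5
    assert abs(fit.sigma2_e - 1.0) < 0.45


def test_single_trial_zero_signal_boundary():
    """With no genotype variance, the REML estimate collapses toward zero.

    The unconstrained estimator is negative in about half of the samples, so
    the boundary is hit at close to that rate and the non-boundary estimates
    stay small relative to the residual variance.
    """
    at_boundary = 0
    small = 0
    n_seeds = 30
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        tr = balanced_rcbd(rng, m=40, r=2, sigma_g=0.0, sigma_e=1.0)
        fit = fit_single_trial(tr, terms=("block",))
        if fit.boundary["genotype"]:
            at_boundary += 1
        if fit.sigma2_g < 0.4 * fit.sigma2_e:
            small += 1
    assert at_boundary >= 0.2 * n_seeds
    assert small >= 0.9 * n_seeds


def test_single_trial_validation_contracts(rng):
    tr = balanced_rcbd(rng, m=10, r=2)
    fit_single_trial(tr)  # duplicate-free p-rep input accepted
    bad = tr.df.copy()
    bad.loc[1, ["row", "col"]] = bad.loc[0, ["row", "col"]]
    with pytest.raises(ValueError, match="duplicate"):
        fit_single_trial(METDataset(bad))
    const = tr.df.assign(**{"yield": 1.0})
    with pytest.raises(ValueError, match="degenerate"):
        fit_single_trial(METDataset(const))


def test_reliability_closed_form(rng):
    """Balanced design: reliability ~ sigma2_g / (sigma2_g + sigma2_e / r)."""
    tr = balanced_rcbd(rng, m=150, r=2, sigma_g=1.0, sigma_e=0.8)
    fit = fit_single_trial(tr, terms=("block",))
    closed = fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e / 2)
    assert abs(reliability(fit) - closed) < 0.02


def test_reliability_limits(rng):
    tr = balanced_rcbd(rng, m=60, r=2, sigma_g=1.0, sigma_e=0.01)
    fit = fit_single_trial(tr, terms=("block",))
    assert reliability(fit) > 0.98
    fit0 = fit_single_trial(balanced_rcbd(np.random.default_rng(1002), m=40, r=2,
                                          sigma_g=0.0), terms=("block",))
    if fit0.boundary["genotype"]:
        assert reliability(fit0) == 0.0


def test_outlier_detection(rng):
    tr = balanced_rcbd(rng, m=120, r=2)
    fit = fit_single_trial(tr, terms=("block",))
    assert detect_outliers(fit, threshold=3.0).mean() <= 0.01
    assert not detect_outliers(fit, threshold=np.inf).any()
    spiked = tr.df.copy()
    spiked.loc[11, "yield"] += 10.0
    fs = fit_single_trial(METDataset(spiked), terms=("block",))
    assert bool(detect_outliers(fs, threshold=3.0).loc[11])


# ---------------------------------------------------------------------------
# dense REML oracle properties
# ---------------------------------------------------------------------------

def _small_met(seed=5, p=3, m=12, ka=1, ke=0):
    cfg = SimConfig(n_founders=8, n_crosses=20, n_environments=p, n_genotypes=m,
                    ka=ka, ke=ke, replication_fraction=0.5, seed=seed)
    ped = gen_pedigree(cfg)
    met, truth = gen_met(cfg, ped)
    return met, pm.nrm(ped), truth


def test_direct_loglik_translation_invariance():
    met, A, truth = _small_met()
    Lam = truth.Lambda_a
    args = (Lam, truth.psi_a, None, None, truth.residual_variances, 0.01)
    ll1 = reml_loglik_direct(met, A, *args)
    shifted = METDataset(met.df.assign(**{"yield": met.df["yield"] + 7.5}))
    ll2 = reml_loglik_direct(shifted, A, *args)
    assert abs(ll1 - ll2) < 1e-8


def test_direct_loglik_oneway_closed_form(rng):
    """Balanced one-way layout matches the scalar textbook REML formula."""
    m, r, s2g, s2e = 25, 3, 0.7, 0.4
    g = rng.normal(0, np.sqrt(s2g), m)
    rows = [{"env": "E1", "genotype": f"g{i:02d}", "row": i + 1, "col": rep + 1,
             "yield": 2.0 + g[i] + rng.normal(0, np.sqrt(s2e))}
            for rep in range(r) for i in range(m)]
    met = METDataset(pd.DataFrame(rows))
    ll = reml_loglik_direct(met, None, None, np.array([s2g]), None, None, np.array([s2e]))
    y = met.df["yield"].to_numpy()
    ybar_map = met.df.groupby("genotype")["yield"].mean()
    ssw = float(((met.df["yield"] - met.df["genotype"].map(ybar_map)) ** 2).sum())
    ybar = y.mean()
    ssb = r * float(np.sum((ybar_map.to_numpy() - ybar) ** 2))
    w = s2e + r * s2g
    N = m * r
    neg2 = (N - m) * np.log(s2e) + m * np.log(w) + np.log(N / w) \
        + ssw / s2e + ssb / w + (N - 1) * _LOG2PI
    assert abs(-2.0 * ll - neg2) < 1e-8


def test_direct_loglik_penalizes_inflated_variance():
    met, A, truth = _small_met()
    base = (truth.Lambda_a, truth.psi_a, None, None)
    ll = reml_loglik_direct(met, A, *base, truth.residual_variances, 0.01)
    ll_inflated = reml_loglik_direct(met, A, *base, truth.residual_variances * 400.0, 0.01)
    assert ll_inflated < ll


# ---------------------------------------------------------------------------
# fit_famm
# ---------------------------------------------------------------------------

def test_fit_matches_dense_oracle_small():
    met, A, _ = _small_met(seed=21, p=3, m=14)
    fit = fit_famm(met, A, ka=1, ke=None)
    ll = reml_loglik_direct(met, A, fit.Lambda_a, fit.psi_a, None, None,
                            fit.sigma2, fit.sigma2_block)
    assert abs(fit.loglik - ll) < 1e-6


def test_fit_psd_and_nonnegative_variances():
    met, A, _ = _small_met(seed=22, p=4, m=15, ka=1, ke=1)
    fit = fit_famm(met, A, ka=1, ke=1)
    assert np.linalg.eigvalsh(fit.Ga()).min() > -1e-10
    assert np.linalg.eigvalsh(fit.Gi()).min() > -1e-10
    assert (fit.sigma2 > 0).all()
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_vparams)


def test_single_environment_collapse(rng):
    """p=1, FA(1), A=I: the loading squared is the genotype variance."""
    tr = balanced_rcbd(rng, m=80, r=2, sigma_g=0.8, sigma_e=0.5)
    single = fit_single_trial(tr, terms=("block",))
    fit = fit_famm(tr, None, ka=1, ke=None)
    lam2 = float(fit.Lambda_a[0, 0] ** 2)
    assert lam2 == pytest.approx(single.sigma2_g, rel=1e-3, abs=1e-6)
    assert fit.sigma2.iloc[0] == pytest.approx(single.sigma2_e, rel=1e-3, abs=1e-6)


def test_identity_A_with_no_nonadditive_is_single_component():
    met, _, _ = _small_met(seed=23, p=3, m=12)
    f1 = fit_famm(met, None, ka=1, ke=None)
    ident = pd.DataFrame(np.eye(len(met.genotypes)), index=met.genotypes,
                         columns=met.genotypes)
    f2 = fit_famm(met, ident, ka=1, ke=None)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


def test_loglik_monotone_over_accepted_iterations():
    """L-BFGS-B line search: the objective never increases between iterates."""
    from germeval.famm import _FammObjective, _Structure, _two_stage_start
    from scipy import optimize

    met, A, _ = _small_met(seed=25, p=3, m=12)
    st = _Structure(met, A, 1, None)
    obj = _FammObjective(st)
    theta0 = _two_stage_start(st, obj)
    vals = []
    optimize.minimize(obj, theta0, jac=True, method="L-BFGS-B",
                      callback=lambda xk: vals.append(obj(xk)[0]),
                      options={"maxiter": 60})
    assert all(b <= a + 1e-8 for a, b in zip(vals, vals[1:]))


def test_identifiability_and_input_errors():
    met, A, _ = _small_met(seed=26, p=2, m=10)
    with pytest.raises(ValueError):
        fit_famm(met, A, ka=3, ke=None)  # ka > p
    with pytest.raises(ValueError):
        fit_famm(met, A, ka=None, ke=None)
    bad = A.copy()
    g0, g1 = met.genotypes[:2]
    bad.loc[g0, g1] = bad.loc[g1, g0] = 1.9  # breaks PSD within the fitted block
    with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
        fit_famm(met, bad, ka=1, ke=None)


def test_fa1_recovery_quick():
    corrs = []
    for seed in (31, 32, 33):
        cfg = SimConfig(n_founders=20, n_crosses=80, n_environments=6, n_genotypes=60,
                        ka=1, ke=0, replication_fraction=0.5, seed=seed)
        ped = gen_pedigree(cfg)
        met, truth = gen_met(cfg, ped)
        fit = fit_famm(met, pm.nrm(ped), ka=1, ke=None)
        corrs.append(abs(np.corrcoef(truth.Lambda_a[:, 0], fit.Lambda_a[:, 0])[0, 1]))
    assert np.median(corrs) > 0.8


def test_model_search_base_case():
    met, A, _ = _small_met(seed=27, p=3, m=12)
    best, table = model_search(met, A, max_ka=0, max_ke=0)
    assert best.ka is None and best.ke == 0
    assert table.iloc[0]["model"] == "independent"
    assert best.aic == pytest.approx(-2 * best.loglik + 2 * best.n_vparams)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def test_connectivity_counts(rng):
    rows = []
    sets = {"E1": {"a", "b", "c"}, "E2": {"b", "c", "d"}, "E3": {"x", "y"}}
    for env, gs in sets.items():
        for i, g in enumerate(sorted(gs)):
            rows.append({"env": env, "genotype": g, "row": i + 1, "col": 1, "yield": 1.0 + i})
    met = METDataset(pd.DataFrame(rows))
    C = connectivity(met)
    assert C.loc["E1", "E1"] == 3
    assert C.loc["E1", "E2"] == 2
    assert C.loc["E1", "E3"] == 0
    # brute-force oracle on random sets
    for _ in range(5):
        labels = rng.choice(["E1", "E2", "E3"], size=len(met.df))
        df = met.df.assign(env=labels, row=np.arange(len(met.df)))
        C = connectivity(METDataset(df))
        for a in C.index:
            for b in C.columns:
                sa = set(df[df["env"] == a]["genotype"])
                sb = set(df[df["env"] == b]["genotype"])
                assert C.loc[a, b] == len(sa & sb)
    # grouping by year pools environments
    C = connectivity(met, grouping={"E1": 2019, "E2": 2019, "E3": 2020})
    assert C.loc[2019, 2019] == 4
    assert C.loc[2019, 2020] == 0
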