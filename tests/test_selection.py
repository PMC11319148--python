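"""FAST selection tools: rotation, %vaf, OP, RMSD, responsiveness, top fraction."""

import numpy as np
import pandas as pd
import pytest

from germeval.famm import FAModelFit
from germeval.selection import (
    overall_performance,
    responsiveness,
    rmsd_stability,
    rotate,
    selection_summary,
    top_fraction,
    vaf,
)


def make_fit(Lam_a, psi_a, scores_a, Lam_i=None, psi_i=None, scores_i=None,
             source=None):
    """Assemble an FAModelFit directly from component matrices (test fixture)."""
    p = Lam_a.shape[0] if Lam_a is not None else len(psi_a)
    m = scores_a.shape[0] if scores_a is not None else 0
    envs = [f"E{j}" for j in range(p)]
    genotypes = [f"g{i:03d}" for i in range(m)]
    ka = Lam_a.shape[1] if Lam_a is not None else 0
    ke = None if Lam_i is None and psi_i is None else (
        Lam_i.shape[1] if Lam_i is not None else 0)
    return FAModelFit(
        envs=envs, genotypes=genotypes,
        tau=pd.Series(0.0, index=envs), ka=ka, ke=ke,
        Lambda_a=Lam_a, psi_a=psi_a, Lambda_i=Lam_i, psi_i=psi_i,
        scores_a=scores_a, scores_i=scores_i,
        delta_a=None, delta_i=None, effects_a=None, effects_i=None,
        sigma2=pd.Series(0.1, index=envs), sigma2_block=None,
        loglik=0.0, n_vparams=0, converged=True, boundary=False,
        source=source,
    )


def random_fit(rng, p=5, k=2, m=30):
    Lam = rng.normal(0, 0.4, (p, k))
    psi = rng.uniform(0.01, 0.2, p)
    scores = rng.normal(0, 1, (m, k))
    return make_fit(Lam, psi, scores)


def test_rotate_sign_convention_k1():
    Lam = np.array([[-0.5], [-0.3], [-0.4]])
    scores = np.array([[1.0], [-2.0]])
    rot = rotate(make_fit(Lam, np.zeros(3), scores))
    assert (rot.loadings[:, 0] > 0).all()
    assert np.allclose(rot.scores, -scores)


def test_rotate_preserves_reconstruction(rng):
    fit = random_fit(rng)
    rot = rotate(fit)
    assert np.allclose(rot.loadings @ rot.loadings.T,
                       fit.Lambda_a @ fit.Lambda_a.T, atol=1e-10)
    # fitted common-factor effects unchanged by the counter-rotation
    assert np.allclose(rot.scores @ rot.loadings.T,
                       fit.scores_a @ fit.Lambda_a.T, atol=1e-10)


def test_rotate_orders_factors_by_variance(rng):
    fit = random_fit(rng, p=6, k=3)
    rot = rotate(fit)
    # columns orthogonal, sum of squares matches the SVD spectrum in order
    G = rot.loadings.T @ rot.loadings
    assert np.allclose(G, np.diag(np.diag(G)), atol=1e-10)
    s2 = np.diag(G)
    assert np.all(np.diff(s2) <= 1e-12)
    sv = np.linalg.svd(fit.Lambda_a, compute_uv=False)
    assert np.allclose(np.sort(s2)[::-1], sv**2, atol=1e-10)


def test_vaf_simple_cases():
    fit = make_fit(np.array([[1.0], [1.0]]), np.array([1.0, 1.0]), np.zeros((3, 1)))
    per_env, per_factor, overall = vaf(fit)
    assert np.allclose(per_env["additive_f1"], 50.0)
    assert overall == pytest.approx(50.0)
    fit = make_fit(np.array([[1.0], [2.0]]), np.zeros(2), np.zeros((3, 1)))
    per_env, _, overall = vaf(fit)
    assert np.allclose(per_env["additive_f1"], 100.0)
    assert overall == pytest.approx(100.0)


def test_vaf_matches_trace_ratio_oracle(rng):
    for _ in range(5):
        fit = random_fit(rng, p=6, k=2)
        _, _, overall = vaf(fit)
        G = fit.Lambda_a @ fit.Lambda_a.T
        oracle = 100.0 * np.trace(G) / (np.trace(G) + fit.psi_a.sum())
        assert abs(overall - oracle) < 1e-12


def test_vaf_per_env_sums_below_100(rng):
    fit = random_fit(rng, p=5, k=3)
    per_env, _, _ = vaf(fit)
    sums = per_env.filter(like="additive").sum(axis=1)
    assert (sums <= 100.0 + 1e-9).all()


def test_overall_performance_values(rng):
    fit = random_fit(rng, p=4, k=2, m=20)
    rot = rotate(fit)
    op = overall_performance(rot)
    zero_idx = rot.genotypes[0]
    rot.scores[0, 0] = 0.0
    assert overall_performance(rot)[zero_idx] == 0.0
    # ranking by OP equals ranking by mean factor-1 fitted effect
    fitted1 = np.outer(rot.scores[:, 0], rot.loadings[:, 0]).mean(axis=1)
    assert (pd.Series(fitted1, index=rot.genotypes).rank() == op.rank()).all()


def test_rmsd_zero_for_single_factor(rng):
    fit = random_fit(rng, p=4, k=1)
    rot = rotate(fit)
    assert (rmsd_stability(rot) == 0.0).all()


def test_rmsd_linearity_and_bruteforce(rng):
    fit = random_fit(rng, p=5, k=3, m=15)
    rot = rotate(fit)
    rmsd = rmsd_stability(rot)
    assert (rmsd >= 0).all()
    # brute force: deviation of the full common-factor fit from factor-1 only
    full = rot.scores @ rot.loadings.T
    f1 = np.outer(rot.scores[:, 0], rot.loadings[:, 0])
    brute = np.sqrt(np.mean((full - f1) ** 2, axis=1))
    assert np.allclose(rmsd.to_numpy(), brute, atol=1e-12)
    # doubling the higher-factor scores of one genotype doubles its RMSD
    rot.scores[3, 1:] *= 2.0
    assert rmsd_stability(rot).iloc[3] == pytest.approx(2 * rmsd.iloc[3])


def test_responsiveness_rules(rng):
    fit = random_fit(rng, p=5, k=3, m=10)
    rot = rotate(fit)
    with pytest.raises(ValueError):
        responsiveness(rot, 1)
    with pytest.raises(ValueError):
        responsiveness(rot, 4)
    r2 = responsiveness(rot, 2)
    rot.scores[2, 1] = rot.scores[5, 1]
    r2b = responsiveness(rot, 2)
    assert r2b.iloc[2] == r2b.iloc[5]
    # flipping the raw loading sign convention leaves the measure unchanged
    fit2 = make_fit(-fit.Lambda_a, fit.psi_a, -fit.scores_a)
    assert np.allclose(responsiveness(rotate(fit2), 2).to_numpy(), r2.to_numpy(),
                       atol=1e-12)


def test_selection_summary_and_total_op(rng):
    Lam_a = rng.normal(0, 0.4, (4, 2))
    Lam_i = rng.normal(0, 0.2, (4, 1))
    fit = make_fit(Lam_a, rng.uniform(0.01, 0.1, 4), rng.normal(0, 1, (12, 2)),
                   Lam_i=Lam_i, psi_i=rng.uniform(0.01, 0.1, 4),
                   scores_i=rng.normal(0, 1, (12, 1)),
                   source=pd.Series({f"g{i:03d}": "CIMMYT" for i in range(12)}))
    summ = selection_summary(fit)
    add = overall_performance(rotate(fit, "additive"))
    non = overall_performance(rotate(fit, "non-additive"))
    assert np.allclose(summ["OP_total"], add + non, atol=1e-12)
    assert set(summ.columns) >= {"OP_additive", "OP_total", "RMSD", "resp_2", "source"}


def test_top_fraction_counts_and_ties():
    df = pd.DataFrame({
        "OP_additive": np.arange(20, dtype=float),
        "source": ["A"] * 10 + ["B"] * 10,
    }, index=[f"g{i}" for i in range(20)])
    counts, members = top_fraction(df, "OP_additive", 0.10)
    assert counts.sum() == 2 and counts.get("B", 0) == 2
    # ties at the cutoff are all included
    df.loc[:, "OP_additive"] = [0.0] * 17 + [5.0, 5.0, 5.0]
    counts, members = top_fraction(df, "OP_additive", 0.10)
    assert counts.sum() == 3
    # single source takes all slots
    df["source"] = "A"
    counts, _ = top_fraction(df, "OP_additive", 0.10)
    assert set(counts.index) == {"A"}
    with pytest.raises(ValueError):
        top_fraction(df.iloc[:0], "OP_additive", 0.10)
    with pytest.raises(ValueError):
        top_fraction(df, "OP_additive", 1.5)
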