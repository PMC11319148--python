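"""Factor-analytic selection tools (FAST).

Summarises a fitted factor-analytic MET model per genotype, on the trait
scale (t/ha for yield): overall performance (OP) from the first factor,
stability as the root mean square deviation (RMSD) of the higher-factor
contributions, and signed responsiveness per higher factor.  All are computed
after a principal-axis rotation of the loadings, so factor 1 accounts for the
most genetic variance and the measures are invariant to the rotational
indeterminacy of the raw fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .famm import FAModelFit

__all__ = [
    "RotatedFit",
    "rotate",
    "vaf",
    "overall_performance",
    "rmsd_stability",
    "responsiveness",
    "selection_summary",
    "top_fraction",
]


@dataclass
class RotatedFit:
    """Principal-axis rotated loadings and counter-rotated scores for one component."""

    envs: list
    genotypes: list
    loadings: np.ndarray          # p x k, columns orthogonal, variance-ordered
    scores: np.ndarray            # m x k
    rotation: np.ndarray          # k x k orthogonal matrix applied to the raw fit
    psi: np.ndarray | None

    @property
    def k(self) -> int:
        return 0 if self.loadings is None else self.loadings.shape[1]

    @property
    def mean_loadings(self) -> np.ndarray:
        return self.loadings.mean(axis=0)

    def fitted_effects(self) -> np.ndarray:
        """Common-factor fitted GE effects, m x p."""
        return self.scores @ self.loadings.T


def _component(fit: FAModelFit, component: str):
    if component == "additive":
        return fit.Lambda_a, fit.scores_a, fit.psi_a, fit.ka
    if component in ("non-additive", "nonadditive"):
        return fit.Lambda_i, fit.scores_i, fit.psi_i, fit.ke
    raise ValueError(f"unknown component {component!r}")


def rotate(fit: FAModelFit, component: str = "additive") -> RotatedFit:
    """Principal-axis rotation of one component's loadings.

    The SVD of Lambda gives the orthogonal rotation that orders factors by
    variance accounted for; scores are counter-rotated so the fitted effects
    ``scores @ loadings'`` are unchanged.  Sign convention: each factor is
    flipped so its mean loading is >= 0.
    """
    Lam, scores, psi, k = _component(fit, component)
    if k is None or k == 0 or Lam is None:
        return RotatedFit(fit.envs, fit.genotypes, np.zeros((len(fit.envs), 0)),
                          np.zeros((len(fit.genotypes), 0)), np.zeros((0, 0)), psi)
    U, s, Vt = np.linalg.svd(Lam, full_matrices=False)
    R = Vt.T                       # Lam @ R = U * s, columns ordered by s
    Lam_rot = Lam @ R
    scores_rot = scores @ R
    flip = np.where(Lam_rot.mean(axis=0) < 0, -1.0, 1.0)
    Lam_rot = Lam_rot * flip
    scores_rot = scores_rot * flip
    return RotatedFit(fit.envs, fit.genotypes, Lam_rot, scores_rot, R * flip, psi)


def vaf(fit: FAModelFit) -> tuple[pd.DataFrame, pd.Series, float]:
    """Percentage genetic variance accounted for by the common factors.

    Returns ``(per_env, per_factor_mean, overall)``.  ``per_env`` rows are
    environments; columns ``<component>_f<k>`` give
    ``100 lambda*_jk^2 / (sum_k lambda*_jk^2 + psi_j)`` within each component.
    The overall figure pools both components:
    ``100 * sum_j (LL')_jj / sum_j (LL' + Psi)_jj`` summed over components.
    """
    per_env = pd.DataFrame(index=fit.envs)
    num_tot = den_tot = 0.0
    means = {}
    for comp in ("additive", "non-additive"):
        Lam, _, psi, k = _component(fit, comp)
        if k is None:
            continue
        common_diag = np.sum(Lam**2, axis=1) if Lam is not None and k >= 1 else np.zeros(len(fit.envs))
        spec = psi if psi is not None else np.zeros(len(fit.envs))
        den = common_diag + spec
        num_tot += float(common_diag.sum())
        den_tot += float(den.sum())
        if Lam is not None and k >= 1:
            rot = rotate(fit, comp)
            with np.errstate(invalid="ignore", divide="ignore"):
                for f in range(rot.k):
                    col = 100.0 * rot.loadings[:, f] ** 2 / den
                    name = f"{comp}_f{f + 1}"
                    per_env[name] = col
                    means[name] = float(np.nanmean(col))
    if den_tot <= 0:
        return per_env, pd.Series(means, dtype=float), float("nan")
    overall = 100.0 * num_tot / den_tot
    return per_env, pd.Series(means, dtype=float), overall


def overall_performance(rot: RotatedFit) -> pd.Series:
    """OP_i = mean first-factor loading x first-factor score, per genotype (t/ha)."""
    if rot.k < 1:
        raise ValueError("overall performance needs at least one factor")
    op = rot.mean_loadings[0] * rot.scores[:, 0]
    return pd.Series(op, index=rot.genotypes)


def rmsd_stability(rot: RotatedFit) -> pd.Series:
    """RMSD_i = sqrt(mean_j (sum_{k>=2} lambda*_jk f*_ik)^2): 0 means fully stable."""
    if rot.k < 1:
        raise ValueError("stability needs at least one factor")
    if rot.k == 1:
        return pd.Series(0.0, index=rot.genotypes)
    dev = rot.scores[:, 1:] @ rot.loadings[:, 1:].T  # m x p higher-factor effects
    rmsd = np.sqrt(np.mean(dev**2, axis=1))
    return pd.Series(rmsd, index=rot.genotypes)


def responsiveness(rot: RotatedFit, factor: int) -> pd.Series:
    """Signed factor-k contribution, lambda-bar*_k x f*_ik (t/ha), for k >= 2."""
    if factor == 1:
        raise ValueError("factor 1 is reserved for overall performance")
    if factor < 2 or factor > rot.k:
        raise ValueError(f"factor must be in [2, {rot.k}]")
    resp = rot.mean_loadings[factor - 1] * rot.scores[:, factor - 1]
    return pd.Series(resp, index=rot.genotypes)


def selection_summary(fit: FAModelFit) -> pd.DataFrame:
    """Per-genotype FAST summary: OP (additive and total), RMSD, responsiveness.

    Total OP adds the non-additive component's OP to the additive one (each
    from its own rotation); RMSD and responsiveness are reported for the
    additive component, the basis for parental selection.
    """
    rot_a = rotate(fit, "additive")
    if rot_a.k < 1:
        raise ValueError("selection summary needs an additive FA component of order >= 1")
    out = pd.DataFrame(index=pd.Index(fit.genotypes, name="genotype"))
    out["OP_additive"] = overall_performance(rot_a)
    op_total = out["OP_additive"].copy()
    if fit.ke is not None and fit.ke >= 1:
        rot_i = rotate(fit, "non-additive")
        op_total = op_total + overall_performance(rot_i)
    out["OP_total"] = op_total
    out["RMSD"] = rmsd_stability(rot_a)
    for f in range(2, rot_a.k + 1):
        out[f"resp_{f}"] = responsiveness(rot_a, f)
    out["source"] = fit.source if fit.source is not None else ""
    return out


def top_fraction(
    summary: pd.DataFrame,
    measure: str = "OP_additive",
    fraction: float = 0.10,
) -> tuple[pd.Series, pd.Index]:
    """Counts by source tag in the top ``fraction`` of genotypes by ``measure``.

    The cutoff admits ``ceil(fraction * m)`` genotypes; ties at the cutoff are
    all included, so the count can exceed the nominal size.  Returns
    ``(counts_by_source, selected_index)``.
    """
    if summary.empty:
        raise ValueError("empty selection summary")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    vals = summary[measure]
    # round before ceiling so fraction*m sitting a float-ulp above an integer
    # does not admit an extra genotype
    n_sel = int(np.ceil(np.round(fraction * len(vals), 9)))
    cutoff = vals.sort_values(ascending=False).iloc[n_sel - 1]
    selected = summary[vals >= cutoff]
    counts = selected.groupby("source").size()
    return counts, selected.index
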