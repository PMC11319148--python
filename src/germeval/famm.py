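"""Factor-analytic linear mixed models for multi-environment trials (METs).

The MET model partitions genotype-by-environment (GE) effects into an
additive component, correlated between genotypes by the pedigree numerator
relationship matrix A, and a non-additive component, independent between
genotypes.  Each component's between-environment covariance is a factor
analytic (FA) structure ``G = Lambda Lambda' + diag(psi)`` of low order k:

    yield = env mean + block(env) + u_a + u_i + e
    var(u_a) = Ga (x) A,   var(u_i) = Gi (x) I,   var(e) = diag(sigma2_env)

Estimation is REML.  The log-likelihood is evaluated through the mixed-model
equations after whitening the additive effects by a matrix square root of A,
and maximized by L-BFGS over an unconstrained parameterization (free loadings
with an upper-triangle-zero constraint, log variances) with analytic
gradients derived from the inverse of the augmented coefficient matrix.  A
dense brute-force evaluation of the same likelihood
(:func:`reml_loglik_direct`) serves as an independent oracle in the tests.

Component order conventions: ``k >= 1`` fits FA(k); ``k == 0`` fits a
diagonal covariance (specific variances only); ``None`` omits the component.
When ``k >= p`` the specific variances are fixed at zero (an FA(p) loading
matrix already spans the full covariance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

__all__ = [
    "METDataset",
    "SingleTrialFit",
    "FAModelFit",
    "fit_single_trial",
    "reliability",
    "detect_outliers",
    "fit_famm",
    "reml_loglik_direct",
    "model_search",
    "connectivity",
]

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class METDataset:
    """Plot-level MET observations: env, genotype, block, row, col, yield (t/ha)."""

    df: pd.DataFrame

    REQUIRED = ("env", "genotype", "row", "col", "yield")

    def validate(self, A: pd.DataFrame | None = None) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"MET table missing columns {missing}")
        if not np.all(np.isfinite(self.df["yield"].to_numpy(dtype=float))):
            raise ValueError("non-finite yields in MET table")
        dup = self.df.duplicated(subset=["env", "row", "col"])
        if dup.any():
            first = self.df.loc[dup, ["env", "row", "col"]].iloc[0]
            raise ValueError(
                f"duplicate plot coordinate (env={first['env']}, row={first['row']}, "
                f"col={first['col']})"
            )
        if A is not None:
            absent = set(self.df["genotype"]) - set(A.index)
            if absent:
                raise ValueError(f"genotypes missing from relationship matrix: {sorted(absent)[:5]}")

    @property
    def envs(self) -> list:
        return sorted(self.df["env"].unique())

    @property
    def genotypes(self) -> list:
        return sorted(self.df["genotype"].unique())

    def environment(self, env) -> "METDataset":
        return METDataset(self.df[self.df["env"] == env].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "METDataset":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# generic dense REML (single-trial scale)
# ---------------------------------------------------------------------------

def _dense_reml_neg2ll(y, X, Zs, variances, resid_var):
    """-2 REML log-likelihood with V built explicitly; used at single-trial scale."""
    n = len(y)
    V = resid_var * np.eye(n)
    for Z, v in zip(Zs, variances):
        if v > 0:
            V += v * (Z @ Z.T)
    cf = sla.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = sla.cho_solve(cf, X)
    Vi_y = sla.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    yPy = float(r @ sla.cho_solve(cf, r))
    nv = n - X.shape[1]
    return logdetV + logdetX + yPy + nv * _LOG2PI, beta


@dataclass
class SingleTrialFit:
    """REML fit of one trial: yield = mean + genotype + block + row + col + error."""

    mean: float
    sigma2_g: float
    sigma2_e: float
    component_variances: dict[str, float]
    genotypes: list
    blups: pd.Series
    pev: pd.Series
    residuals: pd.Series  # conditional residuals, plot-indexed
    loglik: float
    boundary: dict[str, bool]
    n_plots: int


def fit_single_trial(
    trial: METDataset,
    terms: tuple[str, ...] = ("block", "row", "col"),
) -> SingleTrialFit:
    """Preliminary single-trial REML analysis.

    Fits random genotype plus the requested random design terms over a fixed
    intercept, with an iid residual.  Variances are floored near zero
    (boundary estimates allowed and flagged).
    """
    df = trial.df
    if df["env"].nunique() > 1:
        raise ValueError("fit_single_trial expects a one-environment dataset")
    trial.validate()
    y = df["yield"].to_numpy(dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("degenerate trial: all yields identical")
    genotypes = sorted(df["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need at least 2 genotypes")
    X = np.ones((n, 1))

    def indicator(labels):
        levels = sorted(pd.unique(labels))
        Z = np.zeros((n, len(levels)))
        lut = {l: i for i, l in enumerate(levels)}
        Z[np.arange(n), [lut[l] for l in labels]] = 1.0
        return Z

    Zg = indicator(df["genotype"])
    Zs = [Zg]
    names = ["genotype"]
    for t in terms:
        if t in df.columns and df[t].nunique() > 1:
            Zs.append(indicator(df[t]))
            names.append(t)

    vary = float(np.var(y))
    floor = max(_VAR_FLOOR, 1e-8 * vary)
    lb = np.log(floor)

    def neg2ll(theta):
        vs = np.exp(theta)
        val, _ = _dense_reml_neg2ll(y, X, Zs, vs[:-1], vs[-1])
        return val

    x0 = np.log(np.full(len(Zs) + 1, 0.4 * vary + floor))
    res = optimize.minimize(
        neg2ll, x0, method="L-BFGS-B",
        bounds=[(lb, np.log(vary * 1e4 + 1.0))] * len(x0),
        options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
    )
    vs = np.exp(res.x)
    variances = dict(zip(names, vs[:-1]))
    sigma2_e = float(vs[-1])
    # a component is "at the boundary" when its variance is negligible on the
    # scale of the data (the optimizer flattens out before the hard floor)
    bnd = max(floor * 10, 1e-4 * vary)
    boundary = {nm: v <= bnd for nm, v in zip(names + ["residual"], vs)}

    # BLUPs and PEV from the augmented mixed-model equations at the estimates
    T = np.hstack([X] + Zs)
    ginv = np.concatenate([np.zeros(1)] + [np.full(Z.shape[1], 1.0 / max(v, floor))
                                           for Z, v in zip(Zs, vs[:-1])])
    C = (T.T @ T) / sigma2_e + np.diag(ginv)
    Cinv = np.linalg.inv(C)
    sol = Cinv @ (T.T @ y) / sigma2_e
    mean = float(sol[0])
    ug = sol[1 : 1 + Zg.shape[1]]
    pev = np.diag(Cinv)[1 : 1 + Zg.shape[1]]
    fitted = T @ sol
    resid = y - fitted
    return SingleTrialFit(
        mean=mean,
        sigma2_g=float(variances["genotype"]),
        sigma2_e=sigma2_e,
        component_variances={**variances, "residual": sigma2_e},
        genotypes=genotypes,
        blups=pd.Series(ug, index=genotypes),
        pev=pd.Series(pev, index=genotypes),
        residuals=pd.Series(resid, index=df.index),
        loglik=-0.5 * float(res.fun),
        boundary=boundary,
        n_plots=n,
    )


def reliability(fit: SingleTrialFit) -> float:
    """Trial reliability: 1 - mean(PEV)/sigma2_g, clamped to [0, 1].

    Equals the line-mean broad-sense heritability for a balanced design; 0 when
    the genotype variance is at the boundary.
    """
    if fit.sigma2_g <= 0 or fit.boundary.get("genotype", False):
        return 0.0
    r = 1.0 - float(fit.pev.mean()) / fit.sigma2_g
    return float(min(max(r, 0.0), 1.0))


def detect_outliers(fit: SingleTrialFit, threshold: float = 3.0) -> pd.Series:
    """Flag plots whose standardized conditional residual exceeds ``threshold``."""
    if not np.isfinite(threshold):
        return pd.Series(False, index=fit.residuals.index)
    z = fit.residuals / np.sqrt(fit.sigma2_e)
    return z.abs() > threshold


# ---------------------------------------------------------------------------
# FA-LMM
# ---------------------------------------------------------------------------

def _component_params(k: int | None, p: int):
    """(n_loadings_free, psi_free) for one FA component of order ``k``."""
    if k is None:
        return 0, False
    if k == 0:
        return 0, True
    free = p * k - k * (k - 1) // 2
    return free, k < p


def _unpack_loadings(flat: np.ndarray, p: int, k: int) -> np.ndarray:
    Lam = np.zeros((p, k))
    pos = 0
    for c in range(k):
        nrows = p - c
        Lam[c:, c] = flat[pos : pos + nrows]
        pos += nrows
    return Lam


def _pack_loadings(Lam: np.ndarray) -> np.ndarray:
    p, k = Lam.shape
    return np.concatenate([Lam[c:, c] for c in range(k)])


def _chol_psd(A: np.ndarray) -> np.ndarray:
    """Matrix square root L with L L' = A, tolerating a PSD (singular) A."""
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(A)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise np.linalg.LinAlgError(
                f"relationship matrix not PSD: smallest eigenvalue {w.min():.3e}"
            )
        return U * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class FAModelFit:
    """REML estimates of the FA-LMM."""

    envs: list
    genotypes: list
    tau: pd.Series                    # environment means, t/ha
    ka: int | None
    ke: int | None
    Lambda_a: np.ndarray | None       # p x ka additive loadings
    psi_a: np.ndarray | None          # additive specific variances
    Lambda_i: np.ndarray | None
    psi_i: np.ndarray | None
    scores_a: np.ndarray | None       # m x ka additive factor scores (BLUPs)
    scores_i: np.ndarray | None
    delta_a: np.ndarray | None        # m x p additive specific-effect BLUPs
    delta_i: np.ndarray | None
    effects_a: np.ndarray | None      # m x p additive GE-effect BLUPs
    effects_i: np.ndarray | None
    sigma2: pd.Series                 # per-environment residual variances
    sigma2_block: float | None
    loglik: float
    n_vparams: int
    converged: bool
    boundary: bool
    source: pd.Series | None = None   # optional genotype source tags

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_vparams

    def Ga(self) -> np.ndarray | None:
        return _fa_cov(self.Lambda_a, self.psi_a, len(self.envs), self.ka)

    def Gi(self) -> np.ndarray | None:
        return _fa_cov(self.Lambda_i, self.psi_i, len(self.envs), self.ke)


def _fa_cov(Lam, psi, p, k):
    if k is None:
        return None
    G = np.zeros((p, p))
    if Lam is not None and k >= 1:
        G += Lam @ Lam.T
    if psi is not None:
        G += np.diag(psi)
    return G


class _Structure:
    """Precomputed design cross-products for the whitened MME assembly."""

    def __init__(self, data: METDataset, A: pd.DataFrame | None, ka, ke):
        df = data.df.reset_index(drop=True)
        self.envs = sorted(df["env"].unique())
        self.genotypes = sorted(df["genotype"].unique())
        self.p = len(self.envs)
        self.m = len(self.genotypes)
        self.ka, self.ke = ka, ke
        self.n = len(df)
        env_lut = {e: j for j, e in enumerate(self.envs)}
        g_lut = {g: i for i, g in enumerate(self.genotypes)}
        self.env_idx = df["env"].map(env_lut).to_numpy()
        self.g_idx = df["genotype"].map(g_lut).to_numpy()
        self.y = df["yield"].to_numpy(dtype=float)

        if A is None:
            self.L = np.eye(self.m)
        else:
            Amat = A.loc[self.genotypes, self.genotypes].to_numpy(dtype=float)
            self.L = _chol_psd(Amat)

        self.has_blocks = "block" in df.columns and df["block"].notna().all() \
            and df.groupby("env")["block"].nunique().min() > 1
        if self.has_blocks:
            blk_pairs = sorted(set(zip(df["env"], df["block"])))
            self.blk_lut = {bp: i for i, bp in enumerate(blk_pairs)}
            self.n_blk = len(blk_pairs)
            self.blk_idx = np.array([self.blk_lut[(e, b)] for e, b in zip(df["env"], df["block"])])
            self.blk_env = np.array([env_lut[e] for e, _ in blk_pairs])
        else:
            self.n_blk = 0
            self.blk_idx = None

        m, p = self.m, self.p
        self.mask = [self.env_idx == j for j in range(p)]
        self.n_j = np.array([msk.sum() for msk in self.mask])
        self.d = np.zeros((p, m))      # plot counts per genotype per env
        self.s = np.zeros((p, m))      # yield sums per genotype per env
        self.ysum = np.zeros(p)
        self.yy = np.zeros(p)
        self.S = np.zeros((p, m, m))   # L' D_j L
        self.LtD = np.zeros((p, m, m))
        self.Ltd = np.zeros((p, m))
        for j in range(p):
            msk = self.mask[j]
            np.add.at(self.d[j], self.g_idx[msk], 1.0)
            np.add.at(self.s[j], self.g_idx[msk], self.y[msk])
            self.ysum[j] = self.y[msk].sum()
            self.yy[j] = float(self.y[msk] @ self.y[msk])
            self.LtD[j] = self.L.T * self.d[j]
            self.S[j] = self.LtD[j] @ self.L
            self.Ltd[j] = self.L.T @ self.d[j]
        if self.has_blocks:
            self.blk_count = np.bincount(self.blk_idx, minlength=self.n_blk).astype(float)
            self.blk_ysum = np.bincount(self.blk_idx, weights=self.y, minlength=self.n_blk)
            self.n_gb = np.zeros((self.n_blk, m))
            for b in range(self.n_blk):
                np.add.at(self.n_gb[b], self.g_idx[self.blk_idx == b], 1.0)
            self.Lt_ngb = self.n_gb @ self.L  # row b: (L' n_gb)'

        # column offsets in the augmented system [beta | v_a | v_i | blocks]
        off = p
        self.add_present = ka is not None
        self.non_present = ke is not None
        self.a_off = off if self.add_present else None
        off += p * m if self.add_present else 0
        self.i_off = off if self.non_present else None
        off += p * m if self.non_present else 0
        self.b_off = off if self.has_blocks else None
        off += self.n_blk
        self.q = off
        self._diag = np.arange(m)

    # -- likelihood + gradient ------------------------------------------------

    def assemble(self, sigma2, Ga_inv, Gi_inv, s2b):
        p, m, q = self.p, self.m, self.q
        C = np.zeros((q, q))
        rhs = np.zeros(q)
        w = 1.0 / sigma2
        for j in range(p):
            C[j, j] = self.n_j[j] * w[j]
            rhs[j] = self.ysum[j] * w[j]
        if self.add_present:
            ao = self.a_off
            for j in range(p):
                sl = slice(ao + j * m, ao + (j + 1) * m)
                C[sl, sl] += self.S[j] * w[j]
                C[j, sl] = self.Ltd[j] * w[j]
                C[sl.start : sl.stop, j] = C[j, sl]
                rhs[sl] = (self.L.T @ self.s[j]) * w[j]
            for j in range(p):
                for l in range(p):
                    C[ao + j * m + self._diag, ao + l * m + self._diag] += Ga_inv[j, l]
        if self.non_present:
            io = self.i_off
            for j in range(p):
                sl = slice(io + j * m, io + (j + 1) * m)
                C[io + j * m + self._diag, io + j * m + self._diag] += self.d[j] * w[j]
                C[j, sl] = self.d[j] * w[j]
                C[sl, j] = C[j, sl]
                rhs[sl] = self.s[j] * w[j]
            for j in range(p):
                for l in range(p):
                    C[io + j * m + self._diag, io + l * m + self._diag] += Gi_inv[j, l]
            if self.add_present:
                ao = self.a_off
                for j in range(p):
                    sa = slice(ao + j * m, ao + (j + 1) * m)
                    si = slice(io + j * m, io + (j + 1) * m)
                    C[sa, si] += self.LtD[j] * w[j]
                    C[si, sa] += self.LtD[j].T * w[j]
        if self.has_blocks:
            bo = self.b_off
            for b in range(self.n_blk):
                j = self.blk_env[b]
                cb = bo + b
                C[cb, cb] = self.blk_count[b] * w[j] + 1.0 / s2b
                C[j, cb] = self.blk_count[b] * w[j]
                C[cb, j] = C[j, cb]
                rhs[cb] = self.blk_ysum[b] * w[j]
                if self.add_present:
                    sl = slice(self.a_off + j * m, self.a_off + (j + 1) * m)
                    C[sl, cb] = self.Lt_ngb[b] * w[j]
                    C[cb, sl] = C[sl, cb]
                if self.non_present:
                    sl = slice(self.i_off + j * m, self.i_off + (j + 1) * m)
                    C[sl, cb] = self.n_gb[b] * w[j]
                    C[cb, sl] = C[sl, cb]
        return C, rhs

    def residuals(self, sol, sigma2):
        """Plot residuals y - fitted and the Py vector (residual / sigma2_env)."""
        p, m = self.p, self.m
        fitted = sol[self.env_idx]
        if self.add_present:
            Va = sol[self.a_off : self.a_off + p * m].reshape(p, m).T  # m x p
            Ua = self.L @ Va
            fitted = fitted + Ua[self.g_idx, self.env_idx]
        else:
            Ua = None
        if self.non_present:
            Vi = sol[self.i_off : self.i_off + p * m].reshape(p, m).T
            fitted = fitted + Vi[self.g_idx, self.env_idx]
        else:
            Vi = None
        if self.has_blocks:
            fitted = fitted + sol[self.b_off + self.blk_idx]
        resid = self.y - fitted
        return resid, resid / sigma2[self.env_idx], Ua, Vi


def _inv_logdet(G: np.ndarray):
    cf = sla.cho_factor(G, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return sla.cho_solve(cf, np.eye(G.shape[0])), logdet


class _FammObjective:
    """-2 REML log-likelihood and analytic gradient over the packed parameters."""

    def __init__(self, st: _Structure):
        self.st = st
        p = st.p
        self.na_free, self.pa_free = _component_params(st.ka, p)
        self.ni_free, self.pi_free = _component_params(st.ke, p)
        self.n_theta = (
            self.na_free + (p if self.pa_free else 0)
            + self.ni_free + (p if self.pi_free else 0)
            + p + (1 if st.has_blocks else 0)
        )

    def unpack(self, theta):
        st, p = self.st, self.st.p
        pos = 0
        Lam_a = psi_a = Lam_i = psi_i = None
        if st.ka is not None and st.ka >= 1:
            Lam_a = _unpack_loadings(theta[pos : pos + self.na_free], p, st.ka)
            pos += self.na_free
        if self.pa_free:
            psi_a = np.exp(theta[pos : pos + p]); pos += p
        elif st.ka is not None:
            psi_a = np.zeros(p)
        if st.ke is not None and st.ke >= 1:
            Lam_i = _unpack_loadings(theta[pos : pos + self.ni_free], p, st.ke)
            pos += self.ni_free
        if self.pi_free:
            psi_i = np.exp(theta[pos : pos + p]); pos += p
        elif st.ke is not None:
            psi_i = np.zeros(p)
        sigma2 = np.exp(theta[pos : pos + p]); pos += p
        s2b = float(np.exp(theta[pos])) if st.has_blocks else None
        return Lam_a, psi_a, Lam_i, psi_i, sigma2, s2b

    def __call__(self, theta):
        st = self.st
        p, m, q = st.p, st.m, st.q
        Lam_a, psi_a, Lam_i, psi_i, sigma2, s2b = self.unpack(theta)
        jitter = 1e-12
        Ga = _fa_cov(Lam_a, psi_a, p, st.ka)
        Gi = _fa_cov(Lam_i, psi_i, p, st.ke)
        logG = 0.0
        Ga_inv = Gi_inv = None
        if Ga is not None:
            Ga_inv, ld = _inv_logdet(Ga + jitter * np.eye(p))
            logG += m * ld
        if Gi is not None:
            Gi_inv, ld = _inv_logdet(Gi + jitter * np.eye(p))
            logG += m * ld
        if st.has_blocks:
            logG += st.n_blk * np.log(s2b)
        C, rhs = st.assemble(sigma2, Ga_inv, Gi_inv, s2b)
        cS, low = sla.cho_factor(C, lower=True)
        logdetC = 2.0 * np.sum(np.log(np.diag(cS)))
        sol = sla.cho_solve((cS, low), rhs)
        yRy = float(np.sum(st.yy / sigma2))
        yPy = yRy - float(rhs @ sol)
        logR = float(np.sum(st.n_j * np.log(sigma2)))
        neg2 = logR + logG + logdetC + yPy + (st.n - p) * _LOG2PI

        # ---- gradient ------------------------------------------------------
        # inverse of C from its Cholesky factor (dpotri fills one triangle)
        Cinv, info = sla.lapack.dpotri(cS, lower=True)
        if info != 0:  # pragma: no cover - numerical guard
            Cinv = sla.cho_solve((cS, low), np.eye(q))
        else:
            Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        resid, Py, Ua_w, Vi_w = st.residuals(sol, sigma2)

        grad = np.zeros_like(theta)
        pos = 0

        def block_traces(off):
            H = np.empty((p, p))
            for j in range(p):
                for l in range(j, p):
                    H[j, l] = H[l, j] = np.trace(
                        Cinv[off + j * m : off + (j + 1) * m, off + l * m : off + (l + 1) * m]
                    )
            return H

        if st.ka is not None:
            Va = sol[st.a_off : st.a_off + p * m].reshape(p, m).T
            H = block_traces(st.a_off)
            Q = Va.T @ Va
            Gmat = m * Ga_inv - Ga_inv @ (H + Q) @ Ga_inv
            if st.ka >= 1:
                gL = 2.0 * Gmat @ Lam_a
                grad[pos : pos + self.na_free] = _pack_loadings(gL)
                pos += self.na_free
            if self.pa_free:
                grad[pos : pos + p] = np.diag(Gmat) * psi_a
                pos += p
        if st.ke is not None:
            Vi = sol[st.i_off : st.i_off + p * m].reshape(p, m).T
            H = block_traces(st.i_off)
            Q = Vi.T @ Vi
            Gmat = m * Gi_inv - Gi_inv @ (H + Q) @ Gi_inv
            if st.ke >= 1:
                gL = 2.0 * Gmat @ Lam_i
                grad[pos : pos + self.ni_free] = _pack_loadings(gL)
                pos += self.ni_free
            if self.pi_free:
                grad[pos : pos + p] = np.diag(Gmat) * psi_i
                pos += p

        # residual variances: tr(P E_j) - (Py)' E_j (Py) per environment
        for j in range(p):
            w = 1.0 / sigma2[j]
            tr_K = st.n_j[j] * Cinv[j, j]
            if st.ka is not None:
                sl = slice(st.a_off + j * m, st.a_off + (j + 1) * m)
                tr_K += float(np.sum(Cinv[sl, sl] * st.S[j]))
                tr_K += 2.0 * float(Cinv[j, sl] @ st.Ltd[j])
            if st.ke is not None:
                sl = slice(st.i_off + j * m, st.i_off + (j + 1) * m)
                tr_K += float(np.einsum("ii,i->", Cinv[sl, sl], st.d[j]))
                tr_K += 2.0 * float(Cinv[j, sl] @ st.d[j])
                if st.ka is not None:
                    sa = slice(st.a_off + j * m, st.a_off + (j + 1) * m)
                    tr_K += 2.0 * float(np.sum(Cinv[sa, sl] * st.LtD[j]))
            if st.has_blocks:
                for b in np.flatnonzero(st.blk_env == j):
                    cb = st.b_off + b
                    tr_K += st.blk_count[b] * Cinv[cb, cb]
                    tr_K += 2.0 * st.blk_count[b] * Cinv[j, cb]
                    if st.ka is not None:
                        sl = slice(st.a_off + j * m, st.a_off + (j + 1) * m)
                        tr_K += 2.0 * float(Cinv[sl, cb] @ st.Lt_ngb[b])
                    if st.ke is not None:
                        sl = slice(st.i_off + j * m, st.i_off + (j + 1) * m)
                        tr_K += 2.0 * float(Cinv[sl, cb] @ st.n_gb[b])
            msk = st.mask[j]
            trP = st.n_j[j] * w - tr_K * w * w
            quad = float(Py[msk] @ Py[msk])
            grad[pos] = (trP - quad) * sigma2[j]
            pos += 1
        if st.has_blocks:
            bo = st.b_off
            ub = sol[bo : bo + st.n_blk]
            trC = float(np.einsum("ii->", Cinv[bo : bo + st.n_blk, bo : bo + st.n_blk]))
            g = st.n_blk / s2b - trC / s2b**2 - float(ub @ ub) / s2b**2
            grad[pos] = g * s2b
            pos += 1
        return neg2, grad


def _two_stage_start(st: _Structure, obj: _FammObjective) -> np.ndarray:
    """Two-stage starting values: env-wise genotype means -> covariance -> PCA."""
    p, m = st.p, st.m
    with np.errstate(invalid="ignore", divide="ignore"):
        Ybar = np.where(st.d > 0, st.s / np.where(st.d > 0, st.d, 1.0), np.nan)  # p x m
    Ybar = Ybar - np.nanmean(Ybar, axis=1, keepdims=True)
    Yc = np.nan_to_num(Ybar)
    Sg = (Yc @ Yc.T) / max(m - 1, 1)
    # residual start: half the mean squared within-genotype replicate difference
    # where an environment has duplicated plots, else a share of the total variance
    vary = np.array([np.var(st.y[st.mask[j]]) for j in range(p)])
    sig0 = np.empty(p)
    for j in range(p):
        dup = st.d[j] >= 2
        if dup.sum() >= 5:
            resid_ss = st.yy[j] - float(np.sum(np.where(st.d[j] > 0,
                                                        st.s[j] ** 2 / np.where(st.d[j] > 0, st.d[j], 1.0),
                                                        0.0)))
            dof = st.n_j[j] - int((st.d[j] > 0).sum())
            sig0[j] = resid_ss / dof if dof > 0 else 0.4 * vary[j]
        else:
            sig0[j] = 0.4 * vary[j]
    sig0 = np.clip(sig0, 1e-4, None)
    # remove the replicate-noise inflation from the genotype-mean covariance
    nbar = np.array([np.mean(st.d[j][st.d[j] > 0]) for j in range(p)])
    np.fill_diagonal(Sg, np.clip(np.diag(Sg) - sig0 / nbar, 1e-4, None))
    w, U = np.linalg.eigh(Sg)
    w = np.clip(w[::-1], 1e-6, None)
    U = U[:, ::-1]
    theta = []
    total_k = max([k for k in (st.ka, st.ke) if k], default=0)

    def fa_start(k, scale):
        Lam = U[:, :k] * np.sqrt(w[:k]) * scale
        # rotate to the upper-triangle-zero identification frame
        if k > 1:
            qr_R = np.linalg.qr(Lam[:k, :].T)[0]
            Lam = Lam @ qr_R
        for c in range(k):
            Lam[:c, c] = 0.0
            if Lam[c, c] < 0:
                Lam[:, c] = -Lam[:, c]
        return Lam

    if st.ka is not None and st.ka >= 1:
        theta.append(_pack_loadings(fa_start(st.ka, 0.8)))
    if obj.pa_free:
        theta.append(np.log(np.clip(0.3 * np.diag(Sg) + 1e-4, 1e-6, None)))
    if st.ke is not None and st.ke >= 1:
        theta.append(_pack_loadings(fa_start(st.ke, 0.4)))
    if obj.pi_free:
        theta.append(np.log(np.clip(0.2 * np.diag(Sg) + 1e-4, 1e-6, None)))
    theta.append(np.log(sig0))
    if st.has_blocks:
        theta.append(np.array([np.log(0.1 * float(np.mean(sig0)) + 1e-6)]))
    return np.concatenate(theta)


def fit_famm(
    data: METDataset,
    A: pd.DataFrame | None,
    ka: int | None,
    ke: int | None,
    max_iter: int = 400,
    start: np.ndarray | None = None,
    source: pd.Series | None = None,
    ftol: float = 1e-9,
    gtol: float = 1e-5,
) -> FAModelFit:
    """Fit the factor-analytic mixed model to a MET by REML.

    ``ka``/``ke`` give the FA orders of the additive and non-additive GE
    components (0 = diagonal covariance, None = component omitted).  ``A`` is
    the pedigree numerator relationship matrix (None means identity).
    """
    data.validate(A)
    st = _Structure(data, A, ka, ke)
    p = st.p
    for k, nm in ((ka, "ka"), (ke, "ke")):
        if k is not None and k > p:
            raise ValueError(f"{nm}={k} exceeds the number of environments {p}")
    if ka is None and ke is None:
        raise ValueError("at least one genetic component must be present")
    obj = _FammObjective(st)
    theta0 = start if start is not None else _two_stage_start(st, obj)
    if len(theta0) != obj.n_theta:
        raise ValueError(f"start vector length {len(theta0)} != {obj.n_theta}")

    lb = np.full(obj.n_theta, -np.inf)
    ub = np.full(obj.n_theta, np.inf)
    pos = 0
    if ka is not None and ka >= 1:
        pos += obj.na_free
    if obj.pa_free:
        lb[pos : pos + p] = np.log(_VAR_FLOOR); pos += p
    if ke is not None and ke >= 1:
        pos += obj.ni_free
    if obj.pi_free:
        lb[pos : pos + p] = np.log(_VAR_FLOOR); pos += p
    lb[pos : pos + p] = np.log(1e-8); pos += p
    if st.has_blocks:
        lb[pos] = np.log(_VAR_FLOOR)

    opts = {"ftol": ftol, "gtol": gtol, "maxiter": max_iter, "maxfun": 4 * max_iter,
            "maxcor": 25}
    res = optimize.minimize(obj, theta0, jac=True, method="L-BFGS-B",
                            bounds=list(zip(lb, ub)), options=opts)
    # a stalled line search (ABNORMAL) often clears after restarting with a
    # fresh quasi-Newton memory; retry from the stall point a few times
    for _ in range(3):
        if res.success or "ABNORMAL" not in str(res.message):
            break
        res2 = optimize.minimize(obj, res.x, jac=True, method="L-BFGS-B",
                                 bounds=list(zip(lb, ub)), options=opts)
        if res2.fun >= res.fun - 1e-12:
            res = res2 if res2.fun < res.fun else res
            break
        res = res2
    if not res.success and "ABNORMAL" in str(res.message):
        warnings.warn(f"FA-LMM optimizer did not converge cleanly: {res.message}")

    Lam_a, psi_a, Lam_i, psi_i, sigma2, s2b = obj.unpack(res.x)
    # final solve for BLUPs at the optimum
    jitter = 1e-12
    Ga = _fa_cov(Lam_a, psi_a, p, ka)
    Gi = _fa_cov(Lam_i, psi_i, p, ke)
    Ga_inv = _inv_logdet(Ga + jitter * np.eye(p))[0] if Ga is not None else None
    Gi_inv = _inv_logdet(Gi + jitter * np.eye(p))[0] if Gi is not None else None
    C, rhs = st.assemble(sigma2, Ga_inv, Gi_inv, s2b)
    sol = sla.cho_solve(sla.cho_factor(C, lower=True), rhs)
    _, _, Ua, Vi = st.residuals(sol, sigma2)

    scores_a = delta_a = scores_i = delta_i = None
    if ka is not None and ka >= 1:
        scores_a = Ua @ Ga_inv @ Lam_a
        delta_a = Ua @ Ga_inv * psi_a if psi_a is not None else np.zeros_like(Ua)
    if ke is not None and ke >= 1:
        scores_i = Vi @ Gi_inv @ Lam_i
        delta_i = Vi @ Gi_inv * psi_i if psi_i is not None else np.zeros_like(Vi)

    boundary = bool(
        (psi_a is not None and obj.pa_free and np.any(psi_a <= 10 * _VAR_FLOOR))
        or (psi_i is not None and obj.pi_free and np.any(psi_i <= 10 * _VAR_FLOOR))
        or (st.has_blocks and s2b <= 10 * _VAR_FLOOR)
    )
    src = None
    if source is not None:
        src = pd.Series({g: source.get(g, "") for g in st.genotypes})
    return FAModelFit(
        envs=st.envs,
        genotypes=st.genotypes,
        tau=pd.Series(sol[:p], index=st.envs),
        ka=ka, ke=ke,
        Lambda_a=Lam_a, psi_a=psi_a, Lambda_i=Lam_i, psi_i=psi_i,
        scores_a=scores_a, scores_i=scores_i,
        delta_a=delta_a, delta_i=delta_i,
        effects_a=Ua, effects_i=Vi,
        sigma2=pd.Series(sigma2, index=st.envs),
        sigma2_block=s2b,
        loglik=-0.5 * float(res.fun),
        n_vparams=obj.n_theta,
        converged=bool(res.success),
        boundary=boundary,
        source=src,
    )


def reml_loglik_direct(
    data: METDataset,
    A: pd.DataFrame | None,
    Lambda_a: np.ndarray | None,
    psi_a: np.ndarray | None,
    Lambda_i: np.ndarray | None,
    psi_i: np.ndarray | None,
    sigma2,
    sigma2_block: float | None = None,
) -> float:
    """Brute-force REML log-likelihood with the marginal covariance built densely.

    Independent of the MME path in :func:`fit_famm`; intended for small
    problems (a few thousand plots at most).  ``sigma2`` maps environment ->
    residual variance (dict, Series, or array in sorted-env order).
    """
    df = data.df.reset_index(drop=True)
    envs = sorted(df["env"].unique())
    genotypes = sorted(df["genotype"].unique())
    p, m, n = len(envs), len(genotypes), len(df)
    if n > 4000:
        raise ValueError("dense REML oracle limited to small problems")
    env_lut = {e: j for j, e in enumerate(envs)}
    g_lut = {g: i for i, g in enumerate(genotypes)}
    e_idx = df["env"].map(env_lut).to_numpy()
    gi = df["genotype"].map(g_lut).to_numpy()
    y = df["yield"].to_numpy(dtype=float)
    if isinstance(sigma2, dict):
        s2 = np.array([sigma2[e] for e in envs], dtype=float)
    elif isinstance(sigma2, pd.Series):
        s2 = sigma2.loc[envs].to_numpy(dtype=float)
    else:
        s2 = np.asarray(sigma2, dtype=float)

    Amat = np.eye(m) if A is None else A.loc[genotypes, genotypes].to_numpy(dtype=float)
    ka = None if Lambda_a is None and psi_a is None else (Lambda_a.shape[1] if Lambda_a is not None else 0)
    ke = None if Lambda_i is None and psi_i is None else (Lambda_i.shape[1] if Lambda_i is not None else 0)
    Ga = _fa_cov(Lambda_a, psi_a, p, ka)
    Gi = _fa_cov(Lambda_i, psi_i, p, ke)

    V = np.diag(s2[e_idx])
    if Ga is not None:
        V += Ga[np.ix_(e_idx, e_idx)] * Amat[np.ix_(gi, gi)]
    if Gi is not None:
        V += Gi[np.ix_(e_idx, e_idx)] * (gi[:, None] == gi[None, :])
    if sigma2_block is not None and "block" in df.columns:
        blk = pd.factorize(pd.Series(zip(df["env"], df["block"])))[0]
        V += sigma2_block * (blk[:, None] == blk[None, :])

    X = np.zeros((n, p))
    X[np.arange(n), e_idx] = 1.0
    cf = sla.cho_factor(V, lower=True)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ViX = sla.cho_solve(cf, X)
    Viy = sla.cho_solve(cf, y)
    XtViX = X.T @ ViX
    _, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    r = y - X @ beta
    yPy = float(r @ sla.cho_solve(cf, r))
    return -0.5 * (logdetV + logdetX + yPy + (n - p) * _LOG2PI)


def model_search(
    data: METDataset,
    A: pd.DataFrame | None,
    max_ka: int,
    max_ke: int,
    alpha: float = 0.05,
    **fit_kwargs,
):
    """Forward search over FA orders: increment ka, then ke, while the LRT accepts.

    The base model is the independent genetic-variance model (additive
    component omitted, diagonal non-additive covariance).  Nested increments
    are accepted when the likelihood-ratio test has p < ``alpha``; the chi2
    p-value is halved because the null pins parameters at a boundary.
    Returns ``(best_fit, table)`` where ``table`` lists every candidate with
    its log-likelihood, AIC, overall %vaf, and LRT p-value.
    """
    rows = []
    best = None

    def try_fit(ka, ke):
        try:
            return fit_famm(data, A, ka, ke, **fit_kwargs), None
        except Exception as exc:  # noqa: BLE001 - search records and continues
            return None, str(exc)

    def overall_vaf(fit):
        num = den = 0.0
        for Lam, psi, k in ((fit.Lambda_a, fit.psi_a, fit.ka), (fit.Lambda_i, fit.psi_i, fit.ke)):
            if k is None:
                continue
            common = np.sum(Lam**2) if Lam is not None else 0.0
            spec = np.sum(psi) if psi is not None else 0.0
            num += common
            den += common + spec
        return 100.0 * num / den if den > 0 else np.nan

    def record(label, ka, ke, fit, err, pval, accepted):
        rows.append({
            "model": label, "ka": ka, "ke": ke,
            "n_vparams": fit.n_vparams if fit else np.nan,
            "loglik": fit.loglik if fit else np.nan,
            "aic": fit.aic if fit else np.nan,
            "overall_vaf": overall_vaf(fit) if fit else np.nan,
            "lrt_p": pval, "accepted": accepted, "error": err,
        })

    current, err = try_fit(None, 0)
    if current is None:
        raise RuntimeError(f"base independent-variance model failed: {err}")
    record("independent", None, 0, current, None, np.nan, True)
    best = current

    def lrt(new, old):
        stat = max(0.0, 2.0 * (new.loglik - old.loglik))
        df_ = new.n_vparams - old.n_vparams
        if df_ <= 0:
            return 1.0
        return 0.5 * float(stats.chi2.sf(stat, df_))

    ka = None
    for cand_ka in range(1, max_ka + 1):
        fit, err = try_fit(cand_ka, 0)
        if fit is None:
            record(f"fa{cand_ka}-add", cand_ka, 0, None, err, np.nan, False)
            break
        pval = lrt(fit, best)
        accept = pval < alpha
        record(f"fa{cand_ka}-add", cand_ka, 0, fit, None, pval, accept)
        if not accept:
            break
        best, ka = fit, cand_ka
    ke = 0
    for cand_ke in range(1, max_ke + 1):
        fit, err = try_fit(ka, cand_ke)
        if fit is None:
            record(f"fa{cand_ke}-nonadd", ka, cand_ke, None, err, np.nan, False)
            break
        pval = lrt(fit, best)
        accept = pval < alpha
        record(f"fa{cand_ke}-nonadd", ka, cand_ke, fit, None, pval, accept)
        if not accept:
            break
        best, ke = fit, cand_ke
    return best, pd.DataFrame(rows)


def connectivity(data: METDataset, grouping: dict | pd.Series | None = None) -> pd.DataFrame:
    """Pairwise counts of shared genotypes between environments (or groups).

    ``grouping`` maps environment -> label (e.g. year); environments sharing a
    label are pooled.  The diagonal holds each group's own genotype count.
    """
    df = data.df
    if grouping is not None:
        g = pd.Series(grouping)
        labels = df["env"].map(g)
    else:
        labels = df["env"]
    sets = {lab: set(sub["genotype"]) for lab, sub in df.groupby(labels)}
    keys = sorted(sets)
    out = pd.DataFrame(0, index=keys, columns=keys, dtype=int)
    for a in keys:
        for b in keys:
            out.loc[a, b] = len(sets[a] & sets[b])
    return out
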