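"""Linear mixed-effects models with crossed random effects.

The three hypothesis families of the simulated-lesion analysis share one
Gaussian mixed model

    y = Xβ + Zb + ε,   b ~ N(0, σ²ΛΛᵀ),   ε ~ N(0, σ²I),

where the random-effects design Z stacks blocks for *crossed* grouping
factors (the lesion×control pair, the lesion used, the control image used)
and Λ(θ) is the block-diagonal relative covariance factor: one non-negative
scale per random intercept, and a 2×2 lower-triangular factor per level for
a correlated random slope.  β and σ² are profiled out, and the profiled
ML or REML deviance is minimized over θ with a quasi-Newton method from a
deterministic start (no random initialization).  Boundary estimates (zero
variances) are legitimate results, not failures.

Wald p-values use the normal approximation, p = 2·Φ(−|t|) with t = B/SE.
Model comparison against the fixed-effects-only linear model uses a
likelihood-ratio test on ML fits; df counts every fixed, variance and
covariance parameter that differs (residual variance is common and not
counted).

If a maximal model with a correlated random slope fails to converge, the
slope–intercept correlation is removed and the model refit; the fallback is
flagged on the returned fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "Coefficient",
    "LmmFit",
    "LrtResult",
    "HypothesisResult",
    "zscore_columns",
    "fit_lmm",
    "likelihood_ratio_test",
    "hypothesis_a",
    "hypothesis_b",
    "hypothesis_c",
]


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects block: a random intercept for ``group``, optionally
    with a random slope of ``slope`` (correlated with the intercept unless
    ``correlated=False``)."""

    group: str
    slope: str | None = None
    correlated: bool = True

    @property
    def k(self) -> int:
        return 2 if self.slope is not None else 1

    @property
    def n_theta(self) -> int:
        if self.slope is None:
            return 1
        return 3 if self.correlated else 2

    def label(self) -> str:
        if self.slope is None:
            return f"(1 | {self.group})"
        sep = " + " if self.correlated else " || "
        return f"(1{sep}{self.slope} | {self.group})"


@dataclass
class ModelSpec:
    """Declarative model: outcome ~ 1 + fixed_terms + random terms."""

    outcome: str
    fixed_terms: list[str] = field(default_factory=list)
    random_terms: list[RandomTerm] = field(default_factory=list)
    estimation: str = "REML"  # 'REML' | 'ML'
    subset: dict | None = None  # {column: value} row filter

    def validate(self, data: pd.DataFrame) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValueError(f"estimation must be REML or ML, got {self.estimation!r}")
        needed = [self.outcome, *self.fixed_terms]
        for rt in self.random_terms:
            needed.append(rt.group)
            if rt.slope is not None:
                needed.append(rt.slope)
        if self.subset:
            needed.extend(self.subset)
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValueError(f"columns not in data: {missing}")

    def apply_subset(self, data: pd.DataFrame) -> pd.DataFrame:
        if not self.subset:
            return data
        sel = np.ones(len(data), dtype=bool)
        for col, val in self.subset.items():
            sel &= (data[col] == val).to_numpy()
        return data.loc[sel]


@dataclass
class Coefficient:
    term: str
    B: float
    SE: float
    t: float
    p: float


@dataclass
class LrtResult:
    chi_square: float
    df: int
    p: float


@dataclass
class LmmFit:
    """One converged (or flagged) mixed-model fit."""

    spec: ModelSpec
    coefficients: dict[str, Coefficient]
    variance_components: dict[str, float]
    log_likelihood: float
    n_parameters: int  # fixed + variance/covariance + residual
    n_obs: int
    sigma2: float
    converged: bool
    estimation: str
    correlation_dropped: bool = False  # fallback applied?
    theta: np.ndarray | None = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"term": c.term, "B": c.B, "SE": c.SE, "t": c.t, "p": c.p}
             for c in self.coefficients.values()])


@dataclass
class HypothesisResult:
    """REML fit for reporting plus the ML-vs-OLS likelihood-ratio test."""

    fit: LmmFit        # REML, for the reported coefficients
    ml_fit: LmmFit     # ML, full model
    null_fit: LmmFit   # ML, fixed effects only
    lrt: LrtResult


# ---------------------------------------------------------------------------
# design construction

def _encode_fixed(data: pd.DataFrame, terms: list[str]
                  ) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["(Intercept)"]
    for t in terms:
        s = data[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) \
                or s.dtype == bool:
            levels = sorted(pd.unique(s.astype(str)))
            if len(levels) < 2:
                raise ValueError(f"fixed term {t!r} has a single level")
            for lv in levels[1:]:  # treatment coding, first level = reference
                cols.append((s.astype(str) == lv).to_numpy(float))
                names.append(f"{t}[{lv}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(t)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"fixed-effects design is rank deficient (terms {terms})")
    return X, names


def _slope_column(data: pd.DataFrame, term: str) -> np.ndarray:
    s = data[term]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
        levels = sorted(pd.unique(s.astype(str)))
        if len(levels) != 2:
            raise ValueError(
                f"random slope over categorical {term!r} needs exactly 2 levels")
        return (s.astype(str) == levels[1]).to_numpy(float)
    return s.to_numpy(dtype=float)


@dataclass
class _Block:
    term: RandomTerm
    levels: list
    Z: np.ndarray  # n × (m·k), per-level columns contiguous

    @property
    def m(self) -> int:
        return len(self.levels)

    def lambda_factor(self, theta_block: np.ndarray) -> np.ndarray:
        k = self.term.k
        T = np.zeros((k, k))
        if k == 1:
            T[0, 0] = theta_block[0]
        elif self.term.correlated:
            T[0, 0], T[1, 0], T[1, 1] = theta_block
        else:
            T[0, 0], T[1, 1] = theta_block
        return np.kron(np.eye(self.m), T)


def _build_blocks(data: pd.DataFrame, terms: list[RandomTerm]) -> list[_Block]:
    n = len(data)
    blocks = []
    for rt in terms:
        g = data[rt.group].astype(str)
        levels = sorted(pd.unique(g))
        if len(levels) < 2:
            raise ValueError(f"grouping {rt.group!r} has fewer than 2 levels")
        code = g.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        k = rt.k
        Z = np.zeros((n, len(levels) * k))
        rows = np.arange(n)
        Z[rows, code * k] = 1.0
        if rt.slope is not None:
            Z[rows, code * k + 1] = _slope_column(data, rt.slope)
        blocks.append(_Block(term=rt, levels=levels, Z=Z))
    return blocks


# ---------------------------------------------------------------------------
# profiled deviance

class _Problem:
    def __init__(self, y: np.ndarray, X: np.ndarray, blocks: list[_Block],
                 reml: bool):
        self.y, self.X, self.blocks, self.reml = y, X, blocks, reml
        self.n, self.p = X.shape
        Z = (np.hstack([b.Z for b in blocks])
             if blocks else np.zeros((self.n, 0)))
        self.q = Z.shape[1]
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.theta_sizes = [b.term.n_theta for b in blocks]

    def split_theta(self, theta: np.ndarray) -> list[np.ndarray]:
        out, i = [], 0
        for s in self.theta_sizes:
            out.append(theta[i:i + s])
            i += s
        return out

    def _factors(self, theta: np.ndarray) -> list[np.ndarray]:
        """Per-block k×k relative Cholesky factors T (shared across levels)."""
        out = []
        for b, tb in zip(self.blocks, self.split_theta(theta)):
            k = b.term.k
            T = np.zeros((k, k))
            if k == 1:
                T[0, 0] = tb[0]
            elif b.term.correlated:
                T[0, 0], T[1, 0], T[1, 1] = tb
            else:
                T[0, 0], T[1, 1] = tb
            out.append(T)
        return out

    def _apply_LT(self, M: np.ndarray, Ts: list[np.ndarray]) -> np.ndarray:
        """Λᵀ M for a q×p matrix, blockwise (Λ = blockdiag kron(I_m, T))."""
        out = np.empty_like(M, dtype=float)
        i = 0
        for b, T in zip(self.blocks, Ts):
            k, m = b.term.k, b.m
            j = i + m * k
            Mb = M[i:j].reshape(m, k, -1)
            out[i:j] = np.einsum("ik,aij->akj", T, Mb).reshape(m * k, -1)
            i = j
        return out

    def _solve(self, theta: np.ndarray):
        """Core linear algebra at one θ.  Returns everything the deviance and
        the post-fit statistics need."""
        if self.q:
            Ts = self._factors(theta)
            LtS = self._apply_LT(self.ZtZ, Ts)          # Λᵀ ZᵀZ
            A = self._apply_LT(np.ascontiguousarray(LtS.T), Ts).T  # Λᵀ ZᵀZ Λ
            A = A + np.eye(self.q)
            L = np.linalg.cholesky(A)
            UtX = self._apply_LT(self.ZtX, Ts)          # q × p
            Uty = self._apply_LT(self.Zty[:, None], Ts)[:, 0]
            CX = solve_triangular(L, UtX, lower=True)
            cu = solve_triangular(L, Uty, lower=True)
            logdetA = 2.0 * float(np.sum(np.log(np.diag(L))))
        else:
            CX = np.zeros((0, self.p))
            cu = np.zeros(0)
            logdetA = 0.0
        XtMX = self.XtX - CX.T @ CX  # X' M^{-1} X,  M = I + ZΛΛ'Z'
        XtMy = self.Xty - CX.T @ cu
        RX = np.linalg.cholesky(XtMX)
        beta = solve_triangular(
            RX.T, solve_triangular(RX, XtMy, lower=True), lower=False)
        r2 = self.yty - float(cu @ cu) - float(beta @ XtMy)
        r2 = max(r2, 1e-300)
        logdetRX = 2.0 * float(np.sum(np.log(np.diag(RX))))
        return beta, r2, logdetA, logdetRX, XtMX

    def deviance(self, theta: np.ndarray) -> float:
        try:
            _, r2, logdetA, logdetRX, _ = self._solve(theta)
        except np.linalg.LinAlgError:
            return 1e30  # finite: keeps numeric gradients usable
        n, p = self.n, self.p
        if self.reml:
            nu = n - p
            return logdetA + logdetRX + nu * (1.0 + np.log(2 * np.pi * r2 / nu))
        return logdetA + n * (1.0 + np.log(2 * np.pi * r2 / n))

    def bounds(self) -> list[tuple]:
        bnds = []
        for b in self.blocks:
            rt = b.term
            if rt.k == 1:
                bnds.append((0.0, None))
            elif rt.correlated:
                bnds.extend([(0.0, None), (None, None), (0.0, None)])
            else:
                bnds.extend([(0.0, None), (0.0, None)])
        return bnds

    # -- optimization coordinates ------------------------------------------
    # Scale parameters (diagonal θ entries) live on a log scale during
    # optimization — variance components can differ by orders of magnitude
    # and the profiled deviance is far better conditioned in log-coordinates.
    # Off-diagonal (correlation) entries stay linear.  θ = 0 boundaries are
    # reached in the limit ζ → −∞ and reported as (numerically) zero
    # variances, which is a legitimate boundary estimate.

    _ZETA_MIN, _ZETA_MAX = -20.0, 20.0

    def _is_diag(self) -> np.ndarray:
        flags = []
        for b in self.blocks:
            rt = b.term
            if rt.k == 1:
                flags.append(True)
            elif rt.correlated:
                flags.extend([True, False, True])
            else:
                flags.extend([True, True])
        return np.array(flags, dtype=bool)

    def to_opt(self, theta: np.ndarray) -> np.ndarray:
        x = np.array(theta, dtype=float)
        d = self._is_diag()
        x[d] = np.log(np.clip(x[d], np.exp(self._ZETA_MIN), np.exp(self._ZETA_MAX)))
        return x

    def from_opt(self, x: np.ndarray) -> np.ndarray:
        theta = np.array(x, dtype=float)
        d = self._is_diag()
        theta[d] = np.exp(np.clip(theta[d], self._ZETA_MIN, self._ZETA_MAX))
        return theta

    def deviance_opt(self, x: np.ndarray) -> float:
        return self.deviance(self.from_opt(x))

    def start(self) -> np.ndarray:
        """Deterministic start: variance-partition heuristic.

        θ entries are relative SDs (sd_b/σ); each block starts at the SD of
        OLS-residual group means divided by the OLS residual SD, floored to
        keep the start off the boundary.  Slope scales start equal to the
        intercept scale, correlations at 0.
        """
        if not self.blocks:
            return np.zeros(0)
        beta_ols, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta_ols
        dof = max(self.n - self.p, 1)
        sigma2_ols = float(resid @ resid / dof)
        inds = [b.Z[:, ::b.term.k] for b in self.blocks]  # level indicators
        raw = []
        for ind in inds:
            counts = ind.sum(axis=0)
            means = (ind.T @ resid) / np.maximum(counts, 1)
            raw.append(float(means.var(ddof=1)) if means.size > 1 else 0.0)
        # a finer grouping's level means absorb the variance of every coarser
        # grouping that is constant within its levels (e.g. the lesion and
        # control of a lesion×control pair); subtract those estimates
        adj = list(raw)
        for i, ind_i in enumerate(inds):
            for j, ind_j in enumerate(inds):
                if i == j:
                    continue
                cross = ind_i.T @ ind_j  # m_i × m_j co-occurrence counts
                if np.all((cross > 0).sum(axis=1) == 1):  # j constant within i
                    adj[i] -= raw[j]
        adj = [max(v, 0.0) for v in adj]
        # residual scale from the within-group variance of the finest grouping
        finest = int(np.argmax([ind.shape[1] for ind in inds]))
        ind_f = inds[finest]
        counts_f = np.maximum(ind_f.sum(axis=0), 1)
        demeaned = resid - ind_f @ ((ind_f.T @ resid) / counts_f)
        dof_w = max(self.n - ind_f.shape[1], 1)
        sigma2_res = float(demeaned @ demeaned / dof_w)
        sigma2_res = max(sigma2_res, 1e-6 * sigma2_ols, 1e-12)
        parts = []
        for b, v in zip(self.blocks, adj):
            t0 = min(max(np.sqrt(v / sigma2_res), 0.1), 100.0)
            if b.term.k == 1:
                parts.append([t0])
            elif b.term.correlated:
                parts.append([t0, 0.0, t0])
            else:
                parts.append([t0, t0])
        return np.concatenate(parts)


def _variance_components(blocks: list[_Block], theta_split: list[np.ndarray],
                         sigma2: float) -> dict[str, float]:
    out: dict[str, float] = {}
    for b, tb in zip(blocks, theta_split):
        rt = b.term
        if rt.k == 1:
            out[f"{rt.group}:(Intercept)"] = sigma2 * float(tb[0] ** 2)
        else:
            T = np.zeros((2, 2))
            if rt.correlated:
                T[0, 0], T[1, 0], T[1, 1] = tb
            else:
                T[0, 0], T[1, 1] = tb
            G = sigma2 * (T @ T.T)
            out[f"{rt.group}:(Intercept)"] = float(G[0, 0])
            out[f"{rt.group}:{rt.slope}"] = float(G[1, 1])
            if rt.correlated:
                out[f"{rt.group}:cov((Intercept),{rt.slope})"] = float(G[0, 1])
    out["Residual"] = sigma2
    return out


def zscore_columns(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Replace each named column by (x − mean)/sample SD over the given rows."""
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (x - x.mean()) / sd
    return out


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """Fit one mixed model (or, with no random terms, the Gaussian linear
    model) by profiled ML/REML.

    On non-convergence of a model containing a correlated random slope, the
    slope–intercept correlation is removed and the model refit; the returned
    fit is flagged ``correlation_dropped``.  Non-convergence after the
    fallback raises.
    """
    spec.validate(data)
    df = spec.apply_subset(data)
    y = df[spec.outcome].to_numpy(dtype=float)
    X, names = _encode_fixed(df, spec.fixed_terms)
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than fixed parameters ({X.shape[1]})")
    blocks = _build_blocks(df, spec.random_terms)
    prob = _Problem(y, X, blocks, reml=(spec.estimation == "REML"))

    converged = True
    theta = prob.start()
    if prob.q:
        x0 = prob.to_opt(theta)
        # Powell's direction-set method on the log-scaled coordinates: the
        # profiled deviance mixes parameter scales spanning orders of
        # magnitude and has flat boundary regions where quasi-Newton numeric
        # gradients stall; derivative-free conjugate directions handle both
        res = optimize.minimize(
            prob.deviance_opt, x0, method="Powell",
            options={"xtol": 1e-5, "ftol": 1e-10, "maxfev": 4000})
        best = res
        if not res.success:
            polish = optimize.minimize(
                prob.deviance_opt, res.x, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9,
                         "maxfev": 400 * (len(res.x) + 1)})
            best = polish if polish.fun <= res.fun else res
            converged = bool(polish.success)
        else:
            converged = True
        theta = prob.from_opt(best.x)
        if not converged and any(rt.slope and rt.correlated
                                 for rt in spec.random_terms):
            fallback_spec = replace(
                spec, random_terms=[
                    replace(rt, correlated=False) if rt.slope else rt
                    for rt in spec.random_terms])
            fit = fit_lmm(data, fallback_spec)
            fit.correlation_dropped = True
            return fit
        if not converged:
            raise RuntimeError(
                f"mixed model failed to converge: {res.message} "
                f"(outcome {spec.outcome!r})")

    beta, r2, logdetA, logdetRX, XtMX = prob._solve(theta)
    n, p = prob.n, prob.p
    nu = n - p if spec.estimation == "REML" else n
    sigma2 = r2 / nu
    if spec.estimation == "REML":
        loglik = -0.5 * (logdetA + logdetRX + nu * (1.0 + np.log(2 * np.pi * sigma2)))
    else:
        loglik = -0.5 * (logdetA + n * (1.0 + np.log(2 * np.pi * sigma2)))

    cov_beta = sigma2 * np.linalg.inv(XtMX)
    se = np.sqrt(np.diag(cov_beta))
    coefs = {}
    for i, name in enumerate(names):
        b_i = float(beta[i])
        se_i = float(se[i])
        t_i = b_i / se_i
        p_i = max(float(2.0 * stats.norm.sf(abs(t_i))), 1e-300)  # keep p > 0
        coefs[name] = Coefficient(term=name, B=b_i, SE=se_i, t=t_i, p=p_i)

    vc = _variance_components(blocks, prob.split_theta(theta), sigma2)
    n_theta = sum(prob.theta_sizes)
    return LmmFit(
        spec=spec, coefficients=coefs, variance_components=vc,
        log_likelihood=float(loglik), n_parameters=p + n_theta + 1,
        n_obs=n, sigma2=float(sigma2), converged=converged,
        estimation=spec.estimation, theta=theta,
    )


def likelihood_ratio_test(full: LmmFit, reduced: LmmFit) -> LrtResult:
    """χ² = 2(llₓ − llᵣ) with df = parameter-count difference.

    Both fits must be ML (REML log-likelihoods of models with different
    fixed/random structure are not comparable) and on the same rows.
    """
    if full.estimation != "ML" or reduced.estimation != "ML":
        raise ValueError("likelihood-ratio tests require ML fits, not REML")
    if full.n_obs != reduced.n_obs:
        raise ValueError(
            f"fits use different data: {full.n_obs} vs {reduced.n_obs} rows")
    df = full.n_parameters - reduced.n_parameters
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    chi = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if chi < -1e-8:
        warnings.warn(
            f"LRT statistic negative beyond numerical slack ({chi:.3g}); "
            "models may not be nested")
    chi = max(chi, 0.0)
    df = max(df, 1)
    return LrtResult(chi_square=float(chi), df=int(df),
                     p=float(stats.chi2.sf(chi, df)))


# ---------------------------------------------------------------------------
# the three hypothesis families

def _fit_family(data: pd.DataFrame, spec: ModelSpec) -> HypothesisResult:
    reml_fit = fit_lmm(data, replace(spec, estimation="REML"))
    # carry any fallback (dropped correlation) into the ML comparison
    ml_spec = replace(reml_fit.spec, estimation="ML")
    ml_fit = fit_lmm(data, ml_spec)
    null_fit = fit_lmm(data, replace(ml_spec, random_terms=[]))
    lrt = likelihood_ratio_test(ml_fit, null_fit)
    return HypothesisResult(fit=reml_fit, ml_fit=ml_fit, null_fit=null_fit,
                            lrt=lrt)


def hypothesis_a(long_table: pd.DataFrame, measure: str,
                 hemisphere: str | None = None) -> HypothesisResult:
    """Does the presence of a simulated lesion change measured volume?

    Outcome: volume (mm³); fixed effect: case (simulated vs. ground truth).
    Across both hemispheres the maximal model has a correlated random slope
    of case within pair plus crossed random intercepts for the lesion and
    control used; in a single-hemisphere subset there is only one
    observation per pair × case, so the pair term reduces to an intercept.
    """
    subset: dict = {"measure": measure}
    if hemisphere is None:
        pair_term = RandomTerm("pair_id", slope="case", correlated=True)
    else:
        subset["hemi_role"] = hemisphere
        pair_term = RandomTerm("pair_id")
    spec = ModelSpec(
        outcome="volume_mm3",
        fixed_terms=["case"],
        random_terms=[pair_term, RandomTerm("lesion_id"),
                      RandomTerm("control_id")],
        subset=subset,
    )
    return _fit_family(long_table, spec)


def hypothesis_b(pvds: pd.DataFrame, measure: str | None = None
                 ) -> HypothesisResult:
    """Is the *magnitude* of error (PVD) different between hemispheres?

    Outcome: PVD; fixed effect: hemisphere role; random intercepts for pair,
    lesion and control (no random slope — one observation per pair and
    hemisphere).
    """
    subset = {"measure": measure} if measure is not None else None
    spec = ModelSpec(
        outcome="pvd",
        fixed_terms=["hemi_role"],
        random_terms=[RandomTerm("pair_id"), RandomTerm("lesion_id"),
                      RandomTerm("control_id")],
        subset=subset,
    )
    return _fit_family(pvds, spec)


def hypothesis_c(pvds: pd.DataFrame, characteristics: pd.DataFrame | None,
                 measure: str | None, hemisphere: str) -> HypothesisResult:
    """Which lesion characteristics explain PVD, within one hemisphere role?

    Fixed effects: z-scored lesion volume, mean lesion intensity and SD of
    lesion intensity; random intercept for the control image only (lesion
    variance should be absorbed by the lesion covariates; no repeated
    measures per pair remain in a single-hemisphere subset).
    """
    df = pvds
    covars = ["volume_transplanted_mm3", "mean_intensity_ui", "sd_intensity_ui"]
    if characteristics is not None:
        df = df.merge(
            characteristics[["lesion_id", *covars]], on="lesion_id",
            how="left", validate="many_to_one")
        if df[covars].isna().any().any():
            missing = sorted(df.loc[df[covars].isna().any(axis=1), "lesion_id"].unique())
            raise ValueError(f"characteristics missing for lesions: {missing}")
    if "hemi_role" in df:
        df = df[df.hemi_role == hemisphere]
    if measure is not None:
        df = df[df.measure == measure]
    if len(df) == 0:
        raise ValueError("empty subset for hypothesis (c)")
    df = zscore_columns(df.reset_index(drop=True), covars)
    spec = ModelSpec(
        outcome="pvd",
        fixed_terms=covars,
        random_terms=[RandomTerm("control_id")],
    )
    return _fit_family(df, spec)
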