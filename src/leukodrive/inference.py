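"""Correlation, standardized regression and path analysis.

This stage works entirely on second moments, so it can run either on a
simulated cohort table or directly on the published correlation matrix
and standard deviations of the reference cohort (n = 101).  Three tools:

* :func:`standardized_regression` — standardized coefficients
  ``beta = Rxx^{-1} rxy`` straight from a correlation matrix, with R²,
  adjusted R² and the overall F test;
* :func:`fit_path_model` — maximum-likelihood fit of a recursive path
  model (observed variables only) to a covariance matrix, minimizing
  the normal-theory discrepancy
  ``F_ML = log|Sigma| + tr(S Sigma^{-1}) - log|S| - p``;
* :func:`fit_indices` — chi-squared, GFI, AGFI, RMSEA and AIC.

For recursive models with uncorrelated residuals the ML path
coefficients coincide with per-equation least squares; those closed
forms initialize the optimizer and serve as an independent check in the
test suite.  The chi-squared statistic uses (n-1) * F_ML by default
(Wishart convention, matching the n-1 in the RMSEA denominator); n *
F_ML is available since published software conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import tables

DSP_OUTCOMES = ["dsp_p1", "dsp_p2", "dsp_p3", "dsp_p4", "dsp_p5", "dsp_p6"]
LA_PREDICTORS = ["la_frontal", "la_temporal", "la_parietal", "la_occipital",
                 "la_periventricular"]
#: Predictors of the six DSP regressions: age, both DVC tasks, atrophy, LA.
DSP_MODEL_PREDICTORS = ["age", "dvc_tracking", "dvc_sudden", "brain_atrophy",
                        *LA_PREDICTORS]
#: Predictors of the two DVC regressions: age, atrophy, LA.
DVC_MODEL_PREDICTORS = ["age", "brain_atrophy", *LA_PREDICTORS]


# ---------------------------------------------------------------------------
# correlation containers


@dataclass
class CorrelationMatrix:
    """A named Pearson correlation matrix with its sample size."""

    r: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        a = self.r.to_numpy(dtype=float)
        if list(self.r.index) != list(self.r.columns):
            raise ValueError("correlation matrix index and columns must match")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.abs(a).max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def variables(self) -> list[str]:
        return list(self.r.index)


def pearson_matrix(cohort: pd.DataFrame, n: int | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations over complete rows of a cohort table."""
    data = cohort.select_dtypes("number").dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    sds = data.std()
    dead = list(sds.index[sds == 0])
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    r = data.corr()
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(r=r, n=n if n is not None else len(data))


def corr_to_cov(
    corr: CorrelationMatrix | pd.DataFrame, sds: pd.Series | Mapping[str, float]
) -> pd.DataFrame:
    """cov_ij = r_ij * sd_i * sd_j, aligning SDs to the matrix's variables."""
    r = corr.r if isinstance(corr, CorrelationMatrix) else corr
    sds = pd.Series(sds).reindex(r.index)
    if sds.isna().any():
        raise ValueError(f"missing SDs for: {list(sds.index[sds.isna()])}")
    if (sds <= 0).any():
        raise ValueError(f"non-positive SDs for: {list(sds.index[sds <= 0])}")
    s = sds.to_numpy(dtype=float)
    return pd.DataFrame(r.to_numpy() * np.outer(s, s), index=r.index,
                        columns=r.columns)


# ---------------------------------------------------------------------------
# standardized regression from a correlation matrix


@dataclass
class RegressionResult:
    outcome: str
    predictors: list[str]
    beta: pd.Series
    r2: float
    adj_r2: float
    f: float
    df1: int
    df2: int
    p: float
    condition_number: float


def standardized_regression(
    corr: CorrelationMatrix, predictors: Sequence[str], outcome: str
) -> RegressionResult:
    """Standardized multiple regression computed from second moments only.

    beta = Rxx^{-1} rxy;  R² = rxy' beta;
    adjusted R² and F use the matrix's n with df = (k, n-k-1).
    """
    predictors = list(predictors)
    missing = [v for v in (*predictors, outcome) if v not in corr.variables]
    if missing:
        raise ValueError(f"variables not in correlation matrix: {missing}")
    rxx = corr.r.loc[predictors, predictors].to_numpy()
    rxy = corr.r.loc[predictors, outcome].to_numpy()
    w = np.linalg.eigvalsh(rxx)
    if w.min() <= 1e-12:
        _, v = np.linalg.eigh(rxx)
        culprit = pd.Series(v[:, 0], index=predictors)
        raise ValueError(
            "predictor correlation matrix is singular; offending "
            f"eigenvector:\n{culprit.round(3)}"
        )
    cond = float(w.max() / w.min())
    beta = np.linalg.solve(rxx, rxy)
    r2 = float(rxy @ beta)
    n, k = corr.n, len(predictors)
    df2 = n - k - 1
    adj_r2 = 1 - (1 - r2) * (n - 1) / df2
    f = (r2 / k) / ((1 - r2) / df2)
    return RegressionResult(
        outcome=outcome,
        predictors=predictors,
        beta=pd.Series(beta, index=predictors),
        r2=r2,
        adj_r2=float(adj_r2),
        f=float(f),
        df1=k,
        df2=df2,
        p=float(stats.f.sf(f, k, df2)),
        condition_number=cond,
    )


# ---------------------------------------------------------------------------
# path analysis


@dataclass
class PathModelSpec:
    """A recursive system of regressions among observed variables.

    ``regressions`` lists (endogenous variable, its predictors).
    Exogenous variables covary freely; residuals of the endogenous
    variables are mutually uncorrelated — the conventions under which
    the default model has df = 3.
    """

    regressions: list[tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        self.regressions = [(y, tuple(xs)) for y, xs in self.regressions]
        endo = [y for y, _ in self.regressions]
        if len(set(endo)) != len(endo):
            raise ValueError("each endogenous variable may appear once")
        # recursiveness: an endogenous variable may only depend on
        # variables that precede it in the listed order
        seen_endo: set[str] = set()
        later = set(endo)
        for y, xs in self.regressions:
            later.discard(y)
            if set(xs) & later:
                raise ValueError(
                    f"model is not recursive: {y} depends on {set(xs) & later}"
                )
            seen_endo.add(y)

    @property
    def endogenous(self) -> list[str]:
        return [y for y, _ in self.regressions]

    @property
    def variables(self) -> list[str]:
        names: list[str] = []
        for y, xs in self.regressions:
            for v in (*xs, y):
                if v not in names:
                    names.append(v)
        return names

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.endogenous)
        return [v for v in self.variables if v not in endo]

    @property
    def n_free(self) -> int:
        q = len(self.exogenous)
        return (
            q * (q + 1) // 2
            + sum(len(xs) for _, xs in self.regressions)
            + len(self.regressions)
        )

    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free


def default_path_model() -> PathModelSpec:
    """Age, brain atrophy and occipital LA drive the DVC sudden-motion
    score, which in turn drives the right-turn (P2) DSP score."""
    return PathModelSpec(
        regressions=[
            ("dvc_sudden", ("age", "brain_atrophy", "la_occipital")),
            ("dsp_p2", ("dvc_sudden",)),
        ]
    )


@dataclass
class FitIndices:
    """Goodness-of-fit summary of a covariance-structure model."""

    chi2: float
    df: int
    p: float
    gfi: float
    agfi: float | None
    rmsea: float
    aic: float
    n: int
    p_vars: int
    f_ml: float

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p": self.p, "GFI": self.gfi,
            "AGFI": self.agfi, "RMSEA": self.rmsea, "AIC": self.aic,
            "n": self.n, "p_vars": self.p_vars, "F_ML": self.f_ml,
        }


def fit_indices(
    S: np.ndarray,
    Sigma: np.ndarray,
    n: int,
    df: int,
    n_free: int,
    chi2_convention: str = "wishart",
) -> FitIndices:
    """Chi-squared, GFI, AGFI, RMSEA and AIC for implied vs sample covariance.

    GFI   = 1 - tr[(Sigma^{-1}S - I)^2] / tr[(Sigma^{-1}S)^2]
    AGFI  = 1 - [p(p+1) / (2 df)] (1 - GFI)          (absent when df = 0)
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)))     (0 when df = 0)
    AIC   = -2 logL + 2 n_free, with the multivariate-normal logL of S.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("covariance matrices must be positive definite")
    W = np.linalg.solve(Sigma, S)
    f_ml = float(logdet_m + np.trace(W) - logdet_s - p)
    f_ml = max(f_ml, 0.0)
    if chi2_convention == "wishart":
        chi2 = (n - 1) * f_ml
    elif chi2_convention == "ml":
        chi2 = n * f_ml
    else:
        raise ValueError("chi2_convention must be 'wishart' or 'ml'")
    WI = W - np.eye(p)
    gfi = float(1.0 - np.trace(WI @ WI) / np.trace(W @ W))
    agfi = (
        float(1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)) if df > 0 else None
    )
    rmsea = (
        float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
    )
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet_m + np.trace(W))
    aic = float(-2 * loglik + 2 * n_free)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return FitIndices(
        chi2=float(chi2), df=int(df), p=pval, gfi=gfi, agfi=agfi, rmsea=rmsea,
        aic=aic, n=int(n), p_vars=int(p), f_ml=f_ml,
    )


@dataclass
class PathFit:
    spec: PathModelSpec
    estimates: pd.DataFrame          # path, est (raw), std (standardized)
    exog_cov: pd.DataFrame
    residual_variances: pd.Series
    implied: pd.DataFrame
    fit: FitIndices
    converged: bool
    grad_norm: float


class _PathParametrization:
    """Packs (exogenous covariance block, path coefficients, residual
    variances) into a flat vector and builds the implied covariance
    Sigma = (I - B)^{-1} Psi (I - B)^{-T}."""

    def __init__(self, spec: PathModelSpec, names: list[str]):
        self.spec = spec
        self.names = names
        self.idx = {v: i for i, v in enumerate(names)}
        self.p = len(names)
        self.exog = [v for v in names if v in set(spec.exogenous)]
        self.exog_i = [self.idx[v] for v in self.exog]
        self.tril = np.tril_indices(len(self.exog))
        self.paths = [
            (self.idx[y], self.idx[x])
            for y, xs in spec.regressions
            for x in xs
        ]
        self.endo_i = [self.idx[y] for y in spec.endogenous]
        self.n_free = len(self.tril[0]) + len(self.paths) + len(self.endo_i)

    def pack(self, phi: np.ndarray, b: np.ndarray, psi: np.ndarray) -> np.ndarray:
        return np.concatenate([phi[self.tril], b, psi])

    def unpack(self, theta: np.ndarray):
        q = len(self.tril[0])
        phi = np.zeros((len(self.exog), len(self.exog)))
        phi[self.tril] = theta[:q]
        phi = phi + np.tril(phi, -1).T
        b = theta[q : q + len(self.paths)]
        psi = theta[q + len(self.paths) :]
        return phi, b, psi

    def matrices(self, theta: np.ndarray):
        phi, b, psi = self.unpack(theta)
        B = np.zeros((self.p, self.p))
        for coef, (yi, xi) in zip(b, self.paths):
            B[yi, xi] = coef
        Psi = np.zeros((self.p, self.p))
        Psi[np.ix_(self.exog_i, self.exog_i)] = phi
        Psi[self.endo_i, self.endo_i] = psi
        A = np.linalg.inv(np.eye(self.p) - B)
        return A, Psi

    def implied(self, theta: np.ndarray) -> np.ndarray:
        A, Psi = self.matrices(theta)
        return A @ Psi @ A.T

    def gradient(self, theta: np.ndarray, S: np.ndarray) -> np.ndarray:
        """Analytic gradient of F_ML: dF = tr[(Sigma^{-1} -
        Sigma^{-1} S Sigma^{-1}) dSigma]."""
        A, Psi = self.matrices(theta)
        Sigma = A @ Psi @ A.T
        Sinv = np.linalg.inv(Sigma)
        G = Sinv - Sinv @ S @ Sinv
        M = A.T @ G @ A                 # for Psi parameters
        SGA = Sigma @ G @ A             # for B parameters
        g = np.empty(self.n_free)
        k = 0
        for r, c in zip(*self.tril):
            i, j = self.exog_i[r], self.exog_i[c]
            g[k] = M[i, j] if i == j else 2.0 * M[i, j]
            k += 1
        for yi, xi in self.paths:
            g[k] = 2.0 * SGA[xi, yi]
            k += 1
        for yi in self.endo_i:
            g[k] = M[yi, yi]
            k += 1
        return g


def fit_path_model(
    cov: pd.DataFrame,
    n: int,
    spec: PathModelSpec | None = None,
    chi2_convention: str = "wishart",
    gtol: float = 1e-8,
) -> PathFit:
    """Maximum-likelihood fit of a recursive path model to a covariance.

    The optimizer starts at the per-equation least-squares solution
    (exact ML for recursive models with uncorrelated residuals) and
    polishes with BFGS on F_ML until the gradient norm is below
    ``gtol``; failure to reach it raises.
    """
    spec = spec or default_path_model()
    if spec.df() < 0:
        raise ValueError("model has negative degrees of freedom")
    names = [v for v in cov.index if v in set(spec.variables)]
    missing = set(spec.variables) - set(names)
    if missing:
        raise ValueError(f"covariance matrix lacks variables: {sorted(missing)}")
    S_raw = cov.loc[names, names].to_numpy(dtype=float)
    w = np.linalg.eigvalsh(S_raw)
    if w.min() <= 0:
        raise ValueError("sample covariance matrix must be positive definite")
    par = _PathParametrization(spec, names)
    p = par.p

    # F_ML and the fit indices are invariant to per-variable rescaling
    # for this model class, so optimize on the correlation scale where
    # the problem is well conditioned, then map estimates back.
    d = np.sqrt(np.diag(S_raw))
    S = S_raw / np.outer(d, d)

    # closed-form start: per-equation OLS on S
    phi0 = S[np.ix_(par.exog_i, par.exog_i)]
    b0, psi0 = [], []
    for y, xs in spec.regressions:
        yi = par.idx[y]
        xi = [par.idx[x] for x in xs]
        coef = np.linalg.solve(S[np.ix_(xi, xi)], S[xi, yi])
        b0.extend(coef)
        psi0.append(S[yi, yi] - S[xi, yi] @ coef)
    theta0 = par.pack(phi0, np.array(b0), np.array(psi0))

    sign_s, logdet_s = np.linalg.slogdet(S)

    def f_ml(theta: np.ndarray) -> float:
        Sigma = par.implied(theta)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e12
        return logdet + np.trace(np.linalg.solve(Sigma, S)) - logdet_s - p

    def grad(theta: np.ndarray) -> np.ndarray:
        return par.gradient(theta, S)

    res = optimize.minimize(f_ml, theta0, jac=grad, method="BFGS",
                            options={"gtol": gtol, "maxiter": 5000})
    theta = res.x if res.fun <= f_ml(theta0) else theta0
    grad_norm = float(np.abs(grad(theta)).max())
    if grad_norm > gtol:
        raise RuntimeError(
            f"path-model fit did not converge (max |grad| = {grad_norm:.2e})"
        )

    # back to the original units
    phi, b, psi = par.unpack(theta)
    d_exog = d[par.exog_i]
    phi_raw = phi * np.outer(d_exog, d_exog)
    b_raw = np.array(
        [coef * d[yi] / d[xi] for coef, (yi, xi) in zip(b, par.paths)]
    )
    psi_raw = psi * d[par.endo_i] ** 2
    theta_raw = par.pack(phi_raw, b_raw, psi_raw)
    Sigma = par.implied(theta_raw)
    fit = fit_indices(S_raw, Sigma, n, spec.df(), par.n_free, chi2_convention)
    sds = np.sqrt(np.diag(Sigma))
    rows = []
    for coef, (yi, xi) in zip(b_raw, par.paths):
        rows.append({
            "outcome": names[yi],
            "predictor": names[xi],
            "est": float(coef),
            "std": float(coef * sds[xi] / sds[yi]),
        })
    return PathFit(
        spec=spec,
        estimates=pd.DataFrame(rows),
        exog_cov=pd.DataFrame(phi_raw, index=par.exog, columns=par.exog),
        residual_variances=pd.Series(psi_raw, index=spec.endogenous),
        implied=pd.DataFrame(Sigma, index=names, columns=names),
        fit=fit,
        converged=bool(grad_norm <= max(gtol, 1e-6)),
        grad_norm=grad_norm,
    )


# ---------------------------------------------------------------------------
# significance stars and the full report


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the t distribution."""
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def stars(p: float) -> str:
    """Two-sided significance stars at 0.05 / 0.01 / 0.001."""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class StudyReport:
    """Everything the statistical stage produces in one object."""

    correlations: CorrelationMatrix
    correlation_stars: pd.DataFrame
    dsp_regressions: dict[str, RegressionResult]
    dvc_regressions: dict[str, RegressionResult]
    path_fit: PathFit
    source: str

    def to_dict(self) -> dict:
        def _reg(r: RegressionResult) -> dict:
            return {
                "outcome": r.outcome,
                "beta": {k: float(v) for k, v in r.beta.items()},
                "R2": r.r2, "adj_R2": r.adj_r2,
                "F": r.f, "df1": r.df1, "df2": r.df2, "p": r.p,
            }

        return {
            "source": self.source,
            "n": self.correlations.n,
            "correlations": self.correlations.r.round(6).to_dict(),
            "dsp_regressions": {k: _reg(v) for k, v in self.dsp_regressions.items()},
            "dvc_regressions": {k: _reg(v) for k, v in self.dvc_regressions.items()},
            "path_model": {
                "paths": self.path_fit.estimates.to_dict(orient="records"),
                "fit": self.path_fit.fit.as_dict(),
            },
        }

    def render_text(self) -> str:
        out = [f"Statistical report (source: {self.source}, "
               f"n = {self.correlations.n})", ""]
        out.append("Path model fit:")
        f = self.path_fit.fit
        agfi = "n/a" if f.agfi is None else f"{f.agfi:.3f}"
        out.append(
            f"  chi2(df={f.df}) = {f.chi2:.3g}, p = {f.p:.3f}, "
            f"GFI = {f.gfi:.3f}, AGFI = {agfi}, RMSEA = {f.rmsea:.3f}, "
            f"AIC = {f.aic:.6g}"
        )
        for row in self.path_fit.estimates.itertuples():
            out.append(
                f"  {row.outcome} <- {row.predictor}: "
                f"b = {row.est:.6g} (std {row.std:.3f})"
            )
        out.append("")
        for title, group in (
            ("DSP regressions", self.dsp_regressions),
            ("DVC regressions", self.dvc_regressions),
        ):
            out.append(f"{title} (standardized coefficients):")
            for name, reg in group.items():
                out.append(
                    f"  {name}: R2 = {reg.r2:.3f}, adj R2 = {reg.adj_r2:.3f}, "
                    f"F({reg.df1},{reg.df2}) = {reg.f:.3g}"
                    f"{stars(reg.p)}"
                )
                for pred, b in reg.beta.items():
                    out.append(f"    {pred:22s} {b:+.3f}")
            out.append("")
        return "\n".join(out)


def run_analyses(
    cohort: pd.DataFrame | None = None,
    path_spec: PathModelSpec | None = None,
    n: int | None = None,
    chi2_convention: str = "wishart",
) -> StudyReport:
    """Full statistical stage: correlations, regressions, path model.

    With ``cohort=None`` the published reference correlation matrix and
    SDs are used at n = 101; otherwise both are computed from the given
    cohort table.  The regression batteries are the six DSP-outcome
    models (nine predictors each) and the two DVC-outcome models (seven
    predictors each); the path model defaults to the df = 3 structure.
    """
    if cohort is None:
        corr = CorrelationMatrix(tables.cohort_correlations(), tables.COHORT_N)
        sds = tables.cohort_sds()
        source = "reference-tables"
    else:
        if len(cohort) == 0:
            raise ValueError("cohort table is empty")
        corr = pearson_matrix(cohort, n=n)
        sds = cohort.select_dtypes("number").std()
        source = "cohort"

    star_df = corr.r.map(lambda r: stars(correlation_p(r, corr.n)))
    np.fill_diagonal(star_df.values, "")

    def _battery(outcomes, predictors):
        out = {}
        for y in outcomes:
            if y in corr.variables and all(p in corr.variables for p in predictors):
                out[y] = standardized_regression(corr, predictors, y)
        return out

    dsp = _battery(DSP_OUTCOMES, DSP_MODEL_PREDICTORS)
    dvc = _battery(["dvc_tracking", "dvc_sudden"], DVC_MODEL_PREDICTORS)

    spec = path_spec or default_path_model()
    cov = corr_to_cov(corr, sds.reindex(corr.variables))
    pfit = fit_path_model(cov, corr.n, spec, chi2_convention=chi2_convention)

    return StudyReport(
        correlations=corr,
        correlation_stars=star_df,
        dsp_regressions=dsp,
        dvc_regressions=dvc,
        path_fit=pfit,
        source=source,
    )
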