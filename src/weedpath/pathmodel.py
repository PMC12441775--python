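"""Multi-group path analysis of weed diversity and herbicide intensity.

The model is a recursive two-equation linear system per treatment
group g, over field-level observations:

    TFI    = alpha1_g + a_g * D_aut + b_g * logN_aut            + eps1,
    D_sum  = alpha2_g + c_g * TFI   + d_g * D_aut + e_g * logN_aut + eps2,

with Gaussian errors and a saturated bivariate-normal exogenous block
for (D_aut, logN_aut) whose covariance is the correlation path f.
D_aut and D_sum are a weed-diversity metric (species richness or
Shannon index), logN_aut the log of total autumn weed density, and
TFI the treatment frequency index mediating between them.

Estimation is normal-theory maximum likelihood with the ML (1/n)
variance convention; any of the path families a..f (and the residual
variances) can be constrained equal across groups.  Because the
system is recursive with independent errors, the likelihood separates
into the two regression equations and the exogenous block, each of
which is maximised on its own.  Nested constraint sets are compared
by likelihood-ratio tests, and a greedy stepwise search constrains
one family at a time as long as the LRT does not reject.

Standard errors of regression coefficients use degrees-of-freedom
corrected residual variances (a small-sample correction on top of the
ML point estimates); the exogenous covariance uses its asymptotic
normal-theory variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

PATHS = ("a", "b", "c", "d", "e", "f")
#: families that may be constrained equal across groups
CONSTRAINABLE = PATHS + ("psi1", "psi2")

_LOG2PI = math.log(2.0 * math.pi)


class SingularDesignError(ValueError):
    """A predictor has zero variance within a group."""


@dataclass(frozen=True)
class PathModelSpec:
    """Structure of the multi-group path model.

    ``shared`` lists the parameter families constrained equal across
    groups; everything else is group-specific.
    """

    groups: tuple[str, ...]
    shared: frozenset = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.shared) - set(CONSTRAINABLE)
        if unknown:
            raise ValueError(f"unknown constraint families {sorted(unknown)}")

    def constrain(self, family: str) -> "PathModelSpec":
        return replace(self, shared=self.shared | {family})

    def n_free_parameters(self) -> int:
        g = len(self.groups)

        def width(fam: str) -> int:
            return 1 if fam in self.shared else g

        # eq1: intercepts + a + b + psi1 ; eq2: intercepts + c + d + e + psi2
        # exog: 2 means + 2 variances per group + covariance f
        return (g + width("a") + width("b") + width("psi1")
                + g + width("c") + width("d") + width("e") + width("psi2")
                + 4 * g + width("f"))


@dataclass
class GroupData:
    """Arrays of the four model variables for one treatment group."""

    name: str
    d_aut: np.ndarray
    logn_aut: np.ndarray
    tfi: np.ndarray
    d_sum: np.ndarray

    @property
    def n(self) -> int:
        return self.d_aut.size


@dataclass
class PathModelFit:
    """Maximum-likelihood fit of a :class:`PathModelSpec`.

    Coefficient tables are DataFrames indexed by path (a..f), columns
    are groups; shared parameters repeat identical values.
    """

    spec: PathModelSpec
    coef: pd.DataFrame
    se: pd.DataFrame
    intercepts: pd.DataFrame      # rows alpha1, alpha2
    resid_var: pd.DataFrame       # rows psi1, psi2 (ML convention)
    exog_mean: pd.DataFrame       # rows d_aut, logn_aut
    exog_var: pd.DataFrame        # rows d_aut, logn_aut (ML convention)
    loglik: float
    n_params: int
    n_per_group: dict[str, int]
    converged: bool = True

    @property
    def zscores(self) -> pd.DataFrame:
        return self.coef / self.se

    @property
    def pvalues(self) -> pd.DataFrame:
        return pd.DataFrame(2.0 * stats.norm.sf(np.abs(self.zscores.to_numpy())),
                            index=self.coef.index, columns=self.coef.columns)


@dataclass(frozen=True)
class StepRecord:
    """One stepwise decision: the family tested and its LRT."""

    family: str
    chi2: float
    df: int
    p: float
    accepted: bool


# ---------------------------------------------------------------------------
# data handling

REQUIRED_COLUMNS = ("group", "d_aut", "logn_aut", "tfi", "d_sum")


def group_data(data: pd.DataFrame, groups: Sequence[str] | None = None) -> list[GroupData]:
    """Split an observations table into per-group arrays, with checks."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"observations table lacks columns {missing}")
    if data[list(REQUIRED_COLUMNS)].isna().any(axis=None):
        raise ValueError("observations contain missing values")
    if groups is None:
        groups = list(dict.fromkeys(data["group"]))
    out = []
    for g in groups:
        sub = data[data["group"] == g]
        if sub.empty:
            raise ValueError(f"no observations for group {g!r}")
        gd = GroupData(str(g),
                       sub["d_aut"].to_numpy(float), sub["logn_aut"].to_numpy(float),
                       sub["tfi"].to_numpy(float), sub["d_sum"].to_numpy(float))
        for var in ("d_aut", "logn_aut", "tfi"):
            x = getattr(gd, var)
            if np.std(x) <= 1e-12 * max(1.0, float(np.abs(x).max())):
                raise SingularDesignError(
                    f"predictor {var!r} has zero variance in group {g!r}")
        out.append(gd)
    return out


# ---------------------------------------------------------------------------
# equation-block ML (weighted-least-squares fixed point)

def _fit_equation(Xs: list[np.ndarray], ys: list[np.ndarray],
                  shared_cols: set[int], shared_var: bool,
                  tol: float = 1e-12, max_iter: int = 500):
    """ML fit of y_g = X_g beta_g + eps_g with optional equality constraints.

    ``shared_cols`` are column indices of X whose coefficient is equal
    across groups.  Returns per-group coefficient vectors, ML residual
    variances, the block log-likelihood, and per-group coefficient SEs
    (df-corrected).  The ML stationary point is reached by iterating
    variance-weighted least squares; with no constraints a single OLS
    pass is already exact.
    """
    G = len(Xs)
    p = Xs[0].shape[1]
    ns = np.array([X.shape[0] for X in Xs])
    # column layout of the stacked design: shared columns once, free per group
    col_of: list[dict[int, int]] = [dict() for _ in range(G)]
    ncols = 0
    for j in range(p):
        if j in shared_cols:
            for g in range(G):
                col_of[g][j] = ncols
            ncols += 1
        else:
            for g in range(G):
                col_of[g][j] = ncols + g
            ncols += G
    rows = int(ns.sum())
    Xbig = np.zeros((rows, ncols))
    ybig = np.concatenate(ys)
    starts = np.concatenate([[0], np.cumsum(ns)])
    for g in range(G):
        sl = slice(starts[g], starts[g + 1])
        for j in range(p):
            Xbig[sl, col_of[g][j]] = Xs[g][:, j]

    sigma2 = np.ones(G)
    loglik_old = -np.inf
    converged = False
    for _ in range(max_iter):
        w = np.repeat(1.0 / sigma2, ns)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xbig * sw[:, None], ybig * sw, rcond=None)
        resid = ybig - Xbig @ beta
        rss = np.array([np.sum(resid[starts[g]:starts[g + 1]] ** 2) for g in range(G)])
        if shared_var:
            sigma2 = np.full(G, rss.sum() / ns.sum())
        else:
            sigma2 = rss / ns
        if (sigma2 <= 0).any():
            raise np.linalg.LinAlgError("zero residual variance; likelihood unbounded")
        loglik = float(np.sum(-0.5 * ns * (_LOG2PI + np.log(sigma2)) - rss / (2 * sigma2)))
        if abs(loglik - loglik_old) < tol:
            converged = True
            break
        loglik_old = loglik

    # SEs: information for beta given sigma, with a df correction on sigma
    n_coef_per_group = p  # coefficients counted per group (shared ones repeat)
    if shared_var:
        df_total = ns.sum() - ncols
        sigma2_dfc = np.full(G, rss.sum() / max(df_total, 1))
    else:
        dfs = np.maximum(ns - n_coef_per_group, 1)
        sigma2_dfc = rss / dfs
    w_dfc = np.repeat(1.0 / sigma2_dfc, ns)
    info = (Xbig * w_dfc[:, None]).T @ Xbig
    cov = np.linalg.pinv(info)
    beta_se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    betas = [np.array([beta[col_of[g][j]] for j in range(p)]) for g in range(G)]
    ses = [np.array([beta_se[col_of[g][j]] for j in range(p)]) for g in range(G)]
    return betas, sigma2, loglik, ses, converged


# ---------------------------------------------------------------------------
# exogenous block ML

def _exog_loglik(ns, S_list, v1, v2, f) -> float:
    ll = 0.0
    for n, S, a, b in zip(ns, S_list, v1, v2):
        det = a * b - f * f
        if det <= 0 or a <= 0 or b <= 0:
            return -np.inf
        inv_tr = (b * S[0, 0] - 2 * f * S[0, 1] + a * S[1, 1]) / det
        ll += -0.5 * n * (2 * _LOG2PI + math.log(det) + inv_tr)
    return ll


def _fit_exog(groups: list[GroupData], share_f: bool):
    """ML of the bivariate exogenous block (means saturated).

    Returns per-group means, per-group covariance matrices, per-group
    f estimates with SEs, the block log-likelihood, and convergence.
    """
    ns = [g.n for g in groups]
    mus, S_list = [], []
    for g in groups:
        X = np.column_stack([g.d_aut, g.logn_aut])
        mus.append(X.mean(axis=0))
        Xc = X - X.mean(axis=0)
        S_list.append(Xc.T @ Xc / g.n)
    if not share_f:
        covs = [S.copy() for S in S_list]
        # saturated: each group's own ML covariance maximises its block
        ll = float(sum(-0.5 * n * (2 * _LOG2PI + math.log(np.linalg.det(S)) + 2.0)
                       for n, S in zip(ns, S_list)))
        # report the df-corrected (unbiased) covariance as the f estimate,
        # with its normal-theory variance; the likelihood itself stays ML
        fs, ses = [], []
        for n, S in zip(ns, S_list):
            Q = S * n / max(n - 1, 1)
            fs.append(Q[0, 1])
            ses.append(math.sqrt((Q[0, 0] * Q[1, 1] + Q[0, 1] ** 2) / max(n - 1, 1)))
        return mus, covs, fs, ses, ll, True

    G = len(groups)

    def unpack(theta):
        v1 = np.exp(theta[:G])
        v2 = np.exp(theta[G:2 * G])
        f = theta[2 * G]
        return v1, v2, f

    def nll(theta):
        v1, v2, f = unpack(theta)
        return -_exog_loglik(ns, S_list, v1, v2, f)

    f0 = float(np.mean([S[0, 1] for S in S_list]))
    theta0 = np.concatenate([np.log([S[0, 0] for S in S_list]),
                             np.log([S[1, 1] for S in S_list]), [f0]])
    res = optimize.minimize(nll, theta0, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    # BFGS reports "precision loss" when the warm start is already the
    # optimum (identical group moments); a vanishing gradient is converged
    grad_ok = np.linalg.norm(res.jac) < 1e-4 * max(1.0, abs(float(res.fun)))
    converged = bool(res.success or grad_ok)
    v1, v2, f = unpack(res.x)
    covs = [np.array([[a, f], [f, b]]) for a, b in zip(v1, v2)]
    # observed information for f from a central-difference Hessian
    hess = _numerical_hessian(nll, res.x)
    try:
        cov_theta = np.linalg.pinv(hess)
        se_f = math.sqrt(max(cov_theta[2 * G, 2 * G], 0.0))
    except np.linalg.LinAlgError:
        se_f = float("nan")
    ll = -float(res.fun)
    # same df correction on the reported shared estimate (N/(N-G) equals
    # the per-group n/(n-1) factor for balanced groups)
    N = int(sum(ns))
    f_rep = f * N / max(N - G, 1)
    return mus, covs, [f_rep] * G, [se_f] * G, ll, converged


def _numerical_hessian(fun, x, eps: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * eps * eps)
    return H


# ---------------------------------------------------------------------------
# public API

def fit_multigroup(data: pd.DataFrame, spec: PathModelSpec) -> PathModelFit:
    """Fit the multi-group path model by maximum likelihood.

    With an empty constraint set the estimates coincide with per-group
    ordinary least squares of the two equations plus sample moments of
    the exogenous block.
    """
    gds = group_data(data, spec.groups)
    if len(gds) != len(spec.groups):
        raise ValueError("group mismatch between data and spec")
    names = [g.name for g in gds]

    # eq1: TFI ~ 1 + d_aut + logn_aut   (columns 0=const, 1=a, 2=b)
    X1 = [np.column_stack([np.ones(g.n), g.d_aut, g.logn_aut]) for g in gds]
    y1 = [g.tfi for g in gds]
    shared1 = set()
    if "a" in spec.shared:
        shared1.add(1)
    if "b" in spec.shared:
        shared1.add(2)
    b1, s1, ll1, se1, c1 = _fit_equation(X1, y1, shared1, "psi1" in spec.shared)

    # eq2: D_sum ~ 1 + tfi + d_aut + logn_aut (1=c, 2=d, 3=e)
    X2 = [np.column_stack([np.ones(g.n), g.tfi, g.d_aut, g.logn_aut]) for g in gds]
    y2 = [g.d_sum for g in gds]
    shared2 = set()
    if "c" in spec.shared:
        shared2.add(1)
    if "d" in spec.shared:
        shared2.add(2)
    if "e" in spec.shared:
        shared2.add(3)
    b2, s2, ll2, se2, c2 = _fit_equation(X2, y2, shared2, "psi2" in spec.shared)

    mus, covs, fs, f_ses, ll3, c3 = _fit_exog(gds, "f" in spec.shared)

    coef = pd.DataFrame(
        {name: [b1[g][1], b1[g][2], b2[g][1], b2[g][2], b2[g][3], fs[g]]
         for g, name in enumerate(names)}, index=list(PATHS))
    se = pd.DataFrame(
        {name: [se1[g][1], se1[g][2], se2[g][1], se2[g][2], se2[g][3], f_ses[g]]
         for g, name in enumerate(names)}, index=list(PATHS))
    intercepts = pd.DataFrame(
        {name: [b1[g][0], b2[g][0]] for g, name in enumerate(names)},
        index=["alpha1", "alpha2"])
    resid_var = pd.DataFrame(
        {name: [s1[g], s2[g]] for g, name in enumerate(names)}, index=["psi1", "psi2"])
    exog_mean = pd.DataFrame(
        {name: mus[g] for g, name in enumerate(names)}, index=["d_aut", "logn_aut"])
    exog_var = pd.DataFrame(
        {name: [covs[g][0, 0], covs[g][1, 1]] for g, name in enumerate(names)},
        index=["d_aut", "logn_aut"])

    return PathModelFit(
        spec=spec, coef=coef, se=se, intercepts=intercepts, resid_var=resid_var,
        exog_mean=exog_mean, exog_var=exog_var,
        loglik=float(ll1 + ll2 + ll3), n_params=spec.n_free_parameters(),
        n_per_group={g.name: g.n for g in gds}, converged=bool(c1 and c2 and c3))


def lrt(full: PathModelFit, reduced: PathModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a constrained (reduced) model vs a fuller one.

    Returns (chi2, df, p).  chi2 is clipped at zero; df is the
    difference in free-parameter counts.
    """
    if not full.spec.shared <= reduced.spec.shared:
        raise ValueError("models are not nested: reduced must add constraints to full")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more free parameters than full")
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def stepwise_constrain(data: pd.DataFrame, spec: PathModelSpec | None = None,
                       alpha_keep: float = 0.05,
                       families: Sequence[str] = PATHS,
                       ) -> tuple[PathModelSpec, PathModelFit, list[StepRecord]]:
    """Greedy cross-group equality-constraint selection.

    Starting from the fully group-specific model, repeatedly constrain
    the still-free family whose LRT against the current model has the
    largest p-value, as long as that p-value exceeds ``alpha_keep``.
    Ties are broken by the order of ``families``.  Returns the final
    spec, its fit and the decision trail.
    """
    if spec is None:
        groups = tuple(dict.fromkeys(data["group"].astype(str)))
        spec = PathModelSpec(groups=groups)
    current = fit_multigroup(data, spec)
    trail: list[StepRecord] = []
    if len(spec.groups) < 2:
        return spec, current, trail
    while True:
        candidates = [f for f in families if f not in current.spec.shared]
        if not candidates:
            break
        best = None
        for fam in candidates:
            cand_fit = fit_multigroup(data, current.spec.constrain(fam))
            chi2, df, p = lrt(current, cand_fit)
            if best is None or p > best[3]:
                best = (fam, cand_fit, chi2, p, df)
        fam, cand_fit, chi2, p, df = best[0], best[1], best[2], best[3], best[4]
        if p > alpha_keep:
            trail.append(StepRecord(fam, chi2, df, p, True))
            current = cand_fit
        else:
            trail.append(StepRecord(fam, chi2, df, p, False))
            break
    return current.spec, current, trail


def _group_sds(data: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """ML (1/n) standard deviations of the four variables per group."""
    out = {}
    for g in groups:
        sub = data[data["group"] == g]
        out[g] = [float(np.std(sub[c].to_numpy(float))) for c in
                  ("d_aut", "logn_aut", "tfi", "d_sum")]
    return pd.DataFrame(out, index=["d_aut", "logn_aut", "tfi", "d_sum"])


#: predictor/response variable of each path, for standardization
_PATH_VARS = {
    "a": ("d_aut", "tfi"),
    "b": ("logn_aut", "tfi"),
    "c": ("tfi", "d_sum"),
    "d": ("d_aut", "d_sum"),
    "e": ("logn_aut", "d_sum"),
}


def standardize(fit: PathModelFit, data: pd.DataFrame) -> pd.DataFrame:
    """Standardized coefficients: coef x sd(predictor)/sd(response).

    The correlation path f is standardized to the Pearson correlation
    implied by the fitted covariance and the sample variances.
    """
    sds = _group_sds(data, fit.spec.groups)
    if (sds.to_numpy() == 0).any():
        zero = sds.stack()[sds.stack() == 0].index.tolist()
        raise ValueError(f"zero variance prevents standardization: {zero}")
    out = fit.coef.copy()
    for path, (pred, resp) in _PATH_VARS.items():
        for g in fit.spec.groups:
            out.loc[path, g] = fit.coef.loc[path, g] * sds.loc[pred, g] / sds.loc[resp, g]
    for g in fit.spec.groups:
        # the Pearson correlation; invariant to the 1/n vs 1/(n-1) convention
        sub = data[data["group"] == g]
        out.loc["f", g] = float(np.corrcoef(sub["d_aut"], sub["logn_aut"])[0, 1])
    return out


@dataclass(frozen=True)
class MediationEffects:
    """Direct, indirect (through TFI) and total effect of log density
    on summer diversity."""

    group: str
    direct: float
    indirect: float
    total: float


def effects(fit: PathModelFit, group: str) -> MediationEffects:
    """Effect decomposition of autumn log density on summer diversity.

    direct = e; indirect = b*c (mediated by herbicide intensity);
    total = e + b*c.  Coefficients are on the unstandardized scale.
    """
    if group not in fit.coef.columns:
        raise KeyError(f"group {group!r} not in fit")
    b = float(fit.coef.loc["b", group])
    c = float(fit.coef.loc["c", group])
    e = float(fit.coef.loc["e", group])
    return MediationEffects(group, direct=e, indirect=b * c, total=e + b * c)


def total_effect(direct: float, indirect: float) -> float:
    """Total effect from a direct and a mediated (indirect) component."""
    return direct + indirect


def r_squared(fit: PathModelFit, data: pd.DataFrame) -> pd.DataFrame:
    """R² per endogenous variable (TFI, D_sum) per group.

    1 - ML residual variance / ML sample variance of the response,
    clipped to [0, 1].
    """
    out = {}
    for g in fit.spec.groups:
        sub = data[data["group"] == g]
        var_t = float(np.var(sub["tfi"].to_numpy(float)))
        var_s = float(np.var(sub["d_sum"].to_numpy(float)))
        r2_t = 1.0 - fit.resid_var.loc["psi1", g] / var_t
        r2_s = 1.0 - fit.resid_var.loc["psi2", g] / var_s
        out[g] = [float(np.clip(r2_t, 0.0, 1.0)), float(np.clip(r2_s, 0.0, 1.0))]
    return pd.DataFrame(out, index=["tfi", "d_sum"])


def coefficient_table(fit: PathModelFit, data: pd.DataFrame) -> pd.DataFrame:
    """Long-format report: group, path, estimate, se, z, p, standardized."""
    std = standardize(fit, data)
    z = fit.zscores
    p = fit.pvalues
    rows = []
    for g in fit.spec.groups:
        for path in PATHS:
            rows.append({
                "group": g, "path": path,
                "unstandardized": float(fit.coef.loc[path, g]),
                "se": float(fit.se.loc[path, g]),
                "z": float(z.loc[path, g]),
                "p": float(p.loc[path, g]),
                "standardized": float(std.loc[path, g]),
                "shared": path in fit.spec.shared,
            })
    return pd.DataFrame(rows)
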