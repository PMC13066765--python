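"""Inference layer: correlation screening, PCA, beta and Gaussian regression,
all-subsets AIC selection, and spatial/collinearity diagnostics.

Beta regression uses the mean-precision parameterisation with a logit link
(mu = logistic(X beta), density parameters mu*phi and (1-mu)*phi), fitted by
maximum likelihood with an analytic gradient; standard errors come from the
observed information (finite differences of the gradient).  AIC counts every
estimated parameter: the coefficients plus phi (beta family) or sigma^2
(Gaussian family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from scipy.spatial.distance import cdist

from .errors import DomainError, NumericalError, ScreeningError

log = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"


# ---------------------------------------------------------------------------
# screening / standardisation / PCA
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    correlations: pd.DataFrame
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, partner, r)


def pearson_screen(
    table: pd.DataFrame,
    threshold: float = 0.70,
    drop_priority: tuple[str, ...] = ("mean_patch_size",),
) -> ScreenReport:
    """Iteratively drop one member of every predictor pair with |r| > threshold.

    The member appearing earlier in ``drop_priority`` is dropped; if neither
    is listed, the later column (table order) goes.  The retained set has all
    pairwise |r| <= threshold.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ScreeningError("need >= 2 columns and >= 3 rows to screen")
    for col in table.columns:
        if table[col].std(ddof=1) == 0 or table[col].isna().all():
            raise ScreeningError(f"column {col!r} is constant; r is undefined")
    cols = list(table.columns)
    dropped: list[tuple[str, str, float]] = []
    full_corr = table.corr()
    while True:
        corr = table[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = cols[i], cols[j]
        r = float(table[a].corr(table[b]))

        def rank(name: str) -> int:
            return drop_priority.index(name) if name in drop_priority else len(drop_priority)

        if rank(a) < rank(b):
            out, partner = a, b
        elif rank(b) < rank(a):
            out, partner = b, a
        else:  # neither prioritised: drop the later column
            out, partner = (b, a) if cols.index(b) > cols.index(a) else (a, b)
        cols.remove(out)
        dropped.append((out, partner, r))
    return ScreenReport(correlations=full_corr, retained=cols, dropped=dropped)


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise zero mean, unit sample standard deviation (ddof=1)."""
    sd = table.std(ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise ScreeningError(f"constant columns cannot be standardized: {bad}")
    return (table - table.mean()) / sd


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x axes
    variance_explained: np.ndarray  # percent per axis, sums to 100


def pca(table: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the correlation structure of a standardized table."""
    Z = standardize(table).to_numpy()
    n = Z.shape[0]
    cov = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    var_pct = 100.0 * eigval / eigval.sum()
    axes = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=table.columns, columns=axes),
        variance_explained=var_pct,
    )


# ---------------------------------------------------------------------------
# regression fits
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    family: str
    terms: list[str]
    coefficients: pd.Series
    se: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    r2: float
    phi: float | None
    residuals: np.ndarray
    converged: bool
    n_params: int = 0


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    names = [INTERCEPT] + list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return mat, names


def fit_gaussian(y, X: pd.DataFrame) -> FitResult:
    """Ordinary least squares with t-based p-values, adjusted R-squared, and
    AIC counting sigma^2 as an estimated parameter."""
    y = np.asarray(y, dtype=float)
    mat, names = _design(X)
    n, p = mat.shape
    if n <= p:
        raise DomainError("need more observations than parameters")
    if np.linalg.matrix_rank(mat) < p:
        raise NumericalError(f"design is rank deficient for terms {names}")
    beta, *_ = np.linalg.lstsq(mat, y, rcond=None)
    resid = y - mat @ beta
    rss = float(resid @ resid)
    sigma2_mle = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_mle) + 1.0)
    k = p + 1  # coefficients + sigma^2
    aic = 2 * k - 2 * loglik
    sigma2_ols = rss / (n - p)
    cov = sigma2_ols * np.linalg.inv(mat.T @ mat)
    se = np.sqrt(np.diag(cov))
    tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * sps.t.sf(np.abs(tvals), df=n - p)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    return FitResult(
        family="gaussian",
        terms=list(X.columns),
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=loglik,
        aic=aic,
        r2=adj_r2,
        phi=None,
        residuals=resid,
        converged=True,
        n_params=k,
    )


def _beta_nll_grad(theta: np.ndarray, mat: np.ndarray, y: np.ndarray):
    p = mat.shape[1]
    beta, logphi = theta[:p], theta[p]
    phi = np.exp(logphi)
    eta = mat @ beta
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(a) - special.digamma(b)
    dmu = mu * (1.0 - mu)
    g_beta = mat.T @ (phi * dmu * (ystar - mustar))
    g_phi = np.sum(
        mu * (ystar - mustar)
        + np.log1p(-y)
        - special.digamma(b)
        + special.digamma(phi)
    )
    grad = np.concatenate([g_beta, [g_phi * phi]])  # chain rule for log-phi
    return -ll, -grad


def _fd_hessian(theta: np.ndarray, mat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Observed information via central differences of the analytic gradient."""
    m = theta.size
    hess = np.zeros((m, m))
    eps = 1e-5
    for j in range(m):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        gp = _beta_nll_grad(tp, mat, y)[1]
        gm = _beta_nll_grad(tm, mat, y)[1]
        hess[:, j] = (gp - gm) / (2 * eps)
    return 0.5 * (hess + hess.T)


def fit_beta_regression(y, X: pd.DataFrame, maxiter: int = 500) -> FitResult:
    """ML beta regression (logit link, mean-precision parameterisation).

    Pseudo-R^2 is the squared Pearson correlation between the linear predictor
    and logit(y).  Wald z p-values from the observed information.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise DomainError("beta regression requires y strictly inside (0, 1)")
    mat, names = _design(X)
    n, p = mat.shape
    if np.linalg.matrix_rank(mat) < p:
        raise NumericalError(f"design is rank deficient for terms {names}")
    # starting values: OLS on logit(y); method-of-moments phi
    ylogit = np.log(y) - np.log1p(-y)
    b0, *_ = np.linalg.lstsq(mat, ylogit, rcond=None)
    e = ylogit - mat @ b0
    sigma2 = max(float(e @ e) / max(n - p, 1), 1e-6)
    mu0 = np.clip(special.expit(mat @ b0), 1e-6, 1 - 1e-6)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / sigma2), 1.1)
    theta0 = np.concatenate([b0, [np.log(phi0)]])
    res = optimize.minimize(
        _beta_nll_grad,
        theta0,
        args=(mat, y),
        jac=True,
        method="BFGS",
        options={"maxiter": maxiter, "gtol": 1e-8},
    )
    theta = res.x
    nll, grad = _beta_nll_grad(theta, mat, y)
    # Newton polish: BFGS can stop on line-search precision loss near the
    # optimum; a few damped Newton steps push the gradient to stationarity
    hess = _fd_hessian(theta, mat, y)
    converged = np.max(np.abs(grad)) < 1e-6
    for _ in range(50):
        if converged:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(30):
            cand = theta - scale * step
            c_nll, c_grad = _beta_nll_grad(cand, mat, y)
            if np.isfinite(c_nll) and c_nll <= nll + 1e-12:
                theta, nll, grad = cand, c_nll, c_grad
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
        hess = _fd_hessian(theta, mat, y)
        converged = np.max(np.abs(grad)) < 1e-6
    beta, phi = theta[:p], float(np.exp(theta[p]))
    loglik = -float(nll)
    k = p + 1
    aic = 2 * k - 2 * loglik
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(p + 1, np.nan)
    se = se_all[:p]
    zvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * sps.norm.sf(np.abs(zvals))
    eta = mat @ beta
    if np.std(eta) > 0 and np.std(ylogit) > 0:
        r2 = float(np.corrcoef(eta, ylogit)[0, 1] ** 2)
    else:
        r2 = 0.0
    mu = special.expit(eta)
    return FitResult(
        family="beta_logit",
        terms=list(X.columns),
        coefficients=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=loglik,
        aic=aic,
        r2=r2,
        phi=phi,
        residuals=y - mu,
        converged=bool(converged or res.success),
        n_params=k,
    )


def squeeze_unit_interval(y, n: int | None = None) -> np.ndarray:
    """Smithson-Verkuilen transform y' = (y*(n-1) + 0.5)/n onto (0, 1)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise DomainError("y must lie in [0, 1]")
    if n is None:
        n = y.size
    return (y * (n - 1) + 0.5) / n


# ---------------------------------------------------------------------------
# all-subsets selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTable:
    rows: pd.DataFrame  # one row per model: rank, terms, aic, delta_aic, r2, ...
    fits: list[FitResult]
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    @property
    def best(self) -> pd.DataFrame:
        return self.rows[self.rows["delta_aic"] <= 2.0]


def _interaction_column(X: pd.DataFrame, a: str, b: str) -> pd.Series:
    return (X[a] * X[b]).rename(f"{a}:{b}")


def all_subsets(
    y,
    predictors: pd.DataFrame,
    family: str = "gaussian",
    interaction: tuple[str, str] | None = None,
) -> SelectionTable:
    """Fit every predictor subset (intercept always included) and rank by AIC.

    The optional interaction term obeys marginality: it only enters models
    containing both main effects.  AIC ties break by fewer parameters, then
    lexicographic term order.
    """
    terms = list(predictors.columns)
    if len(terms) + (1 if interaction else 0) > 12:
        raise DomainError("more than 12 candidate terms; exhaustive search refused")
    if interaction is not None:
        a, b = interaction
        if a not in terms or b not in terms:
            raise DomainError("interaction members must be candidate predictors")
    fitter = {"gaussian": fit_gaussian, "beta_logit": fit_beta_regression}[family]
    candidates: list[tuple[str, ...]] = []
    for r in range(len(terms) + 1):
        for combo in combinations(terms, r):
            candidates.append(combo)
            if interaction is not None and interaction[0] in combo and interaction[1] in combo:
                candidates.append(combo + (f"{interaction[0]}:{interaction[1]}",))
    fits: list[FitResult] = []
    kept: list[tuple[str, ...]] = []
    failures: list[tuple[tuple[str, ...], str]] = []
    for combo in candidates:
        X = pd.DataFrame(index=predictors.index)
        for t in combo:
            if ":" in t:
                a, b = t.split(":")
                X[t] = _interaction_column(predictors, a, b)
            else:
                X[t] = predictors[t]
        try:
            fit = fitter(y, X)
        except (DomainError, NumericalError) as exc:
            failures.append((combo, str(exc)))
            continue
        if not fit.converged:
            failures.append((combo, "non-convergence"))
            continue
        fits.append(fit)
        kept.append(combo)
    if not fits:
        raise NumericalError("no candidate model could be fitted")
    order = sorted(
        range(len(fits)), key=lambda i: (fits[i].aic, fits[i].n_params, kept[i])
    )
    fits = [fits[i] for i in order]
    kept = [kept[i] for i in order]
    best_aic = fits[0].aic
    rows = pd.DataFrame(
        {
            "rank": np.arange(1, len(fits) + 1),
            "terms": ["+".join(c) if c else "(intercept only)" for c in kept],
            "n_terms": [len(c) for c in kept],
            "aic": [f.aic for f in fits],
            "delta_aic": [f.aic - best_aic for f in fits],
            "r2": [f.r2 for f in fits],
            "loglik": [f.loglik for f in fits],
        }
    )
    return SelectionTable(rows=rows, fits=fits, failures=failures)


def selection_report(table: SelectionTable) -> pd.DataFrame:
    """Long-format report of the best (delta AIC <= 2) models: one row per
    model term with its standardized effect and p-value."""
    out = []
    for _, row in table.best.iterrows():
        fit = table.fits[int(row["rank"]) - 1]
        for term in fit.terms:
            out.append(
                {
                    "rank": int(row["rank"]),
                    "aic": row["aic"],
                    "delta_aic": row["delta_aic"],
                    "r2": row["r2"],
                    "term": term,
                    "effect": fit.coefficients[term],
                    "p": fit.pvalues[term],
                }
            )
    return pd.DataFrame(out, columns=["rank", "aic", "delta_aic", "r2", "term", "effect", "p"])


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) per predictor; inf when perfectly
    collinear."""
    if predictors.shape[1] < 2:
        raise DomainError("VIF needs at least 2 predictors")
    out = {}
    for col in predictors.columns:
        others = predictors.drop(columns=[col])
        mat = np.column_stack([np.ones(len(others)), others.to_numpy(dtype=float)])
        yj = predictors[col].to_numpy(dtype=float)
        bj, *_ = np.linalg.lstsq(mat, yj, rcond=None)
        resid = yj - mat @ bj
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class MoransI:
    statistic: float
    expectation: float
    variance: float
    pvalue: float


#: distance floor (km) substituted for coincident coordinates
DUPLICATE_EPS = 1e-6


def morans_i(residuals, coords, weights: str = "inverse_distance", k: int = 4) -> MoransI:
    """Moran's I of residuals with inverse-distance (default) or binary
    k-nearest-neighbour weights; normal-approximation two-sided p-value."""
    e = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = e.size
    if n < 5:
        raise DomainError("Moran's I needs n >= 5")
    if np.allclose(e, e[0]):
        raise DomainError("zero residual variance; Moran's I undefined")
    D = cdist(xy, xy)
    off = ~np.eye(n, dtype=bool)
    D[off & (D == 0)] = DUPLICATE_EPS  # coincident points: documented epsilon
    if weights == "inverse_distance":
        W = np.zeros_like(D)
        W[off] = 1.0 / D[off]
    elif weights == "knn":
        W = np.zeros_like(D)
        for i in range(n):
            idx = np.argsort(D[i])[1 : k + 1]
            W[i, idx] = 1.0
    else:
        raise DomainError(f"unknown weight scheme {weights!r}")
    ec = e - e.mean()
    S0 = W.sum()
    I = (n / S0) * float(ec @ W @ ec) / float(ec @ ec)
    E = -1.0 / (n - 1)
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    var = (n * n * S1 - n * S2 + 3 * S0 * S0) / ((n * n - 1) * S0 * S0) - E * E
    z = (I - E) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return MoransI(statistic=float(I), expectation=E, variance=float(var), pvalue=float(p))
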