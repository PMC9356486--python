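"""Statistical machinery: 2x2 odds ratios with Wald intervals, GEE logistic
regression with cluster-robust (sandwich) variance, and the classical tests
and agreement statistics used around them.

The GEE solver is implemented directly from the estimating equations
(iteratively reweighted fitting; exchangeable working correlation estimated
by the standard moment estimator from Pearson residuals) because the
population-averaged logistic fit with intra-individual clustering of the
two hips is the analysis this package exists for.  `statsmodels` serves as
an independent cross-check in the test suite, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "ORResult",
    "GEEFit",
    "ZeroCellError",
    "SeparationError",
    "crude_or",
    "gee_logistic",
    "build_design",
    "cohens_kappa",
    "lins_ccc",
    "pearson_r",
    "chi_squared",
    "two_sample_t",
    "one_way_anova",
    "standardize",
]

_Z = {0.95: sps.norm.ppf(0.975)}


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; Wald quantities are undefined without correction."""


class SeparationError(RuntimeError):
    """Coefficients diverged: the outcome is (quasi-)separated."""


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-outcome counts: a,b = exposed +/-, c,d = unexposed +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class ORResult:
    or_: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    p: float
    conf_level: float = 0.95
    method: str = "wald"


@dataclass(frozen=True)
class GEEFit:
    """Population-averaged logistic fit with cluster-robust inference."""

    terms: list[str]
    coefficients: np.ndarray
    robust_se: np.ndarray
    cov_robust: np.ndarray
    or_table: pd.DataFrame
    working: str
    alpha_hat: float
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.robust_se[self.terms.index(term)])


def _zcrit(conf_level: float) -> float:
    return float(sps.norm.ppf(0.5 + conf_level / 2.0))


def crude_or(
    t: TwoByTwo, conf_level: float = 0.95, haldane: bool = False
) -> ORResult:
    """Unadjusted odds ratio with Wald confidence interval and p-value.

    ``or_ = ad/bc``; ``se(log OR) = sqrt(1/a + 1/b + 1/c + 1/d)``.  Zero
    cells raise :class:`ZeroCellError` unless the Haldane-Anscombe +0.5
    correction is explicitly requested — silent corrections would corrupt
    oracle comparisons elsewhere in the package.
    """
    cells = {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
    if not haldane:
        for name, v in cells.items():
            if v == 0:
                raise ZeroCellError(
                    f"cell {name} is zero; pass haldane=True for the +0.5 correction"
                )
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
        method = "wald"
    else:
        a, b, c, d = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
        method = "wald-haldane"
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _zcrit(conf_level)
    p = float(2.0 * sps.norm.sf(abs(log_or / se)))
    return ORResult(
        or_=float(np.exp(log_or)),
        log_or=float(log_or),
        se_log_or=float(se),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p=p,
        conf_level=conf_level,
        method=method,
    )


# ---------------------------------------------------------------------------
# GEE logistic
# ---------------------------------------------------------------------------

def build_design(
    df: pd.DataFrame,
    covariates: list[str],
    reference: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categoricals dummy-coded against a
    stated reference level (default: first category / first sorted value)."""
    reference = reference or {}
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for cov in covariates:
        s = df[cov]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            levels = (
                list(s.cat.categories)
                if isinstance(s.dtype, pd.CategoricalDtype)
                else sorted(pd.unique(s.dropna()))
            )
            ref = reference.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference {ref!r} not a level of {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    return X, names


def _cluster_slices(cluster_ids: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(cluster_ids, kind="stable")
    sorted_ids = cluster_ids[order]
    breaks = np.nonzero(sorted_ids[1:] != sorted_ids[:-1])[0] + 1
    return np.split(order, breaks)


def gee_logistic(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    cluster: str,
    working: str = "exchangeable",
    conf_level: float = 0.95,
    reference: dict[str, str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GEEFit:
    """Population-averaged logistic regression with clustered observations.

    Solves the GEE score equations by Fisher scoring; under ``exchangeable``
    working correlation the common intra-cluster correlation is re-estimated
    each iteration by the moment estimator from Pearson residuals.  Variances
    are the robust (sandwich) estimator over clusters, so inference is valid
    whichever working structure is chosen.  Convergence failure is reported
    via ``converged=False``, never silently.
    """
    if working not in ("independence", "exchangeable"):
        raise ValueError("working must be 'independence' or 'exchangeable'")
    y = data[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    X, names = build_design(data, covariates, reference)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("singular design matrix")
    groups = _cluster_slices(data[cluster].to_numpy())
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")

    beta = np.zeros(p)
    alpha = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        var = mu * (1.0 - mu)
        var = np.maximum(var, 1e-12)
        if working == "exchangeable":
            alpha = _exchangeable_alpha(y, mu, var, groups, p)
        lhs = np.zeros((p, p))
        rhs = np.zeros(p)
        for g in groups:
            Dg = X[g] * var[g][:, None]            # dmu/deta * X
            Vg = _working_cov(var[g], alpha, working)
            Vi = np.linalg.inv(Vg)
            DtVi = Dg.T @ Vi
            lhs += DtVi @ Dg
            rhs += DtVi @ (y[g] - mu[g])
        step = np.linalg.solve(lhs, rhs)
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "coefficients diverged (|coef| > 30); outcome is separated"
            )
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    # robust sandwich covariance over clusters
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    var = np.maximum(mu * (1.0 - mu), 1e-12)
    bread = np.zeros((p, p))
    meat = np.zeros((p, p))
    for g in groups:
        Dg = X[g] * var[g][:, None]
        Vi = np.linalg.inv(_working_cov(var[g], alpha, working))
        DtVi = Dg.T @ Vi
        bread += DtVi @ Dg
        sg = DtVi @ (y[g] - mu[g])
        meat += np.outer(sg, sg)
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    se = np.sqrt(np.diag(cov))

    z = _zcrit(conf_level)
    pvals = 2.0 * sps.norm.sf(np.abs(beta / se))
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "p": pvals,
        }
    )
    return GEEFit(
        terms=names,
        coefficients=beta,
        robust_se=se,
        cov_robust=cov,
        or_table=table,
        working=working,
        alpha_hat=float(alpha),
        n_obs=n,
        n_clusters=len(groups),
        converged=converged,
        n_iter=n_iter,
    )


def _working_cov(var_g: np.ndarray, alpha: float, working: str) -> np.ndarray:
    sd = np.sqrt(var_g)
    if working == "independence" or len(var_g) == 1:
        return np.diag(var_g)
    R = np.full((len(var_g), len(var_g)), alpha)
    np.fill_diagonal(R, 1.0)
    return np.outer(sd, sd) * R


def _exchangeable_alpha(
    y: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    groups: list[np.ndarray],
    p: int,
) -> float:
    """Moment estimator of the common intra-cluster correlation."""
    resid = (y - mu) / np.sqrt(var)
    phi_num = float(resid @ resid)
    n = len(y)
    phi = phi_num / max(n - p, 1)
    num = 0.0
    n_pairs = 0
    for g in groups:
        r = resid[g]
        k = len(r)
        if k < 2:
            continue
        s = r.sum()
        num += (s * s - float(r @ r)) / 2.0
        n_pairs += k * (k - 1) // 2
    denom = max(n_pairs - p, 1) * phi
    if denom <= 0:
        return 0.0
    return float(np.clip(num / denom, -0.99, 0.99))


# ---------------------------------------------------------------------------
# agreement statistics and classical tests
# ---------------------------------------------------------------------------

def cohens_kappa(r1, r2) -> float:
    """Chance-corrected agreement for two binary ratings of the same items."""
    r1 = np.asarray(r1).astype(int)
    r2 = np.asarray(r2).astype(int)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) < 2:
        raise ValueError("ratings must be equal-length vectors with n >= 2")
    if not (np.isin(r1, (0, 1)).all() and np.isin(r2, (0, 1)).all()):
        raise ValueError("ratings must be binary")
    n = len(r1)
    p_o = float(np.mean(r1 == r2))
    p1, p2 = r1.mean(), r2.mean()
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: both raters are constant")
    return float((p_o - p_e) / (1.0 - p_e))


def lins_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length vectors with n >= 3")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("CCC undefined: both inputs are constant")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length vectors with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("Pearson r undefined: zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def chi_squared(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction, df=1."""
    obs = t.as_array()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-squared undefined: zero margin")
    expected = np.outer(rows, cols) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(sps.chi2.sf(stat, df=1))


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Unpaired two-tailed t-test (pooled Student by default, Welch by flag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            raise ValueError("zero variance in both groups")
        stat = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        stat = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    return float(stat), float(2.0 * sps.t.sf(abs(stat), df))


def one_way_anova(groups: list) -> tuple[float, float]:
    """One-way ANOVA F statistic and upper-tail p across >=2 groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(g) < 2 for g in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    df_b = len(arrs) - 1
    df_w = len(all_vals) - len(arrs)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("ANOVA undefined: no variance at all")
    ms_w = ss_within / df_w
    if ms_w == 0:
        return float("inf"), 0.0
    F = float((ss_between / df_b) / ms_w)
    return F, float(sps.f.sf(F, df_b, df_w))


def standardize(values) -> np.ndarray:
    """Centre and scale to sample (n-1) SD; used for per-SD odds ratios."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize: zero standard deviation")
    return (v - v.mean()) / sd
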