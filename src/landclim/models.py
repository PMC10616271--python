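"""Five-formulation logistic model suite with AIC selection and AMEs.

Persistence (1) vs extirpation (0) of a species across its occupied squares
is modelled by logistic regression on land conversion ``L``, temperature
trend ``dT``, and their interaction, always controlling for recorder effort,
microclimatic variability and two spatial eigenvector (PCNM) axes.  The
five formulations span a complexity gradient:

    1  controls only
    2  + L
    3  + dT
    4  + L + dT            (additive)
    5  + L + dT + L:dT     (interactive)

Per species the best formulation is the AIC minimum; per taxon the same
formulations are fitted with a species-level random intercept (maximum
likelihood via Gauss-Hermite quadrature).  Effect sizes are reported as
average marginal effects (AMEs) per interpretable unit: 0.1 degC/decade of
warming, 10 percentage points of land conversion.  Covariates are z-scored
internally for numerical conditioning and coefficients mapped back to the
raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from scipy.special import expit, logsumexp
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

__all__ = [
    "ModelSpec", "ModelFit", "AMEResult",
    "FORMULATIONS", "CONTROLS", "ENV_L", "ENV_T", "INTERACTION",
    "pcnm_axes", "fit_logistic", "fit_mixed_logistic", "fit_formulations",
    "select_best", "average_marginal_effect", "bootstrap_ci", "r2_mixed",
    "collinearity_report",
]

ENV_L = "land_conversion"
ENV_T = "temperature_trend"
INTERACTION = f"{ENV_L}:{ENV_T}"
CONTROLS = ("effort", "microclimate", "pcnm1", "pcnm2")

#: formulation id -> environmental-change terms added to the controls
FORMULATIONS: dict[int, tuple[str, ...]] = {
    1: (),
    2: (ENV_L,),
    3: (ENV_T,),
    4: (ENV_L, ENV_T),
    5: (ENV_L, ENV_T, INTERACTION),
}


@dataclass(frozen=True)
class ModelSpec:
    formulation_id: int
    controls: tuple[str, ...] = CONTROLS
    random_intercept: bool = False

    def __post_init__(self) -> None:
        if self.formulation_id not in FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation_id}")

    @property
    def env_terms(self) -> tuple[str, ...]:
        return FORMULATIONS[self.formulation_id]

    @property
    def terms(self) -> tuple[str, ...]:
        return self.env_terms + self.controls


@dataclass
class ModelFit:
    """A fitted (possibly mixed) logistic model on the raw covariate scale."""

    spec: ModelSpec
    params: pd.Series            # includes "const"; raw covariate scale
    llf: float
    k: int                       # parameter count incl. variance components
    converged: bool
    sigma2_u: float | None = None        # species random-intercept variance
    n: int = 0
    design: pd.DataFrame | None = None   # raw-scale design incl. const
    y: np.ndarray | None = None
    groups: np.ndarray | None = None     # species labels, mixed case

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    def linear_predictor(self, design: pd.DataFrame | None = None) -> np.ndarray:
        X = self.design if design is None else design
        return X[self.params.index].to_numpy(float) @ self.params.to_numpy()

    def predict(self, design: pd.DataFrame | None = None) -> np.ndarray:
        return expit(self.linear_predictor(design))


@dataclass
class AMEResult:
    variable: str
    unit: float
    ame: float
    ci: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Spatial eigenvector (PCNM) axes
# ---------------------------------------------------------------------------

def pcnm_axes(centroids: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Leading PCNM spatial eigenvectors of the square centroids.

    Builds the Euclidean distance matrix, truncates it at ``t`` = the longest
    edge of the minimum spanning tree (distances above ``t`` replaced by
    ``4t``), double-centres the squared distances and eigen-decomposes.
    Returns the eigenvectors of the ``n_axes`` largest positive eigenvalues,
    unit-normalised, sign fixed so each vector's first nonzero loading is
    positive.
    """
    xy = centroids[["x", "y"]].to_numpy(float)
    if len(xy) < 3:
        raise ValueError("need at least 3 centroids")
    D = squareform(pdist(xy))
    mst = minimum_spanning_tree(D).toarray()
    t = mst.max()
    Dt = np.where(D > t, 4.0 * t, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt ** 2
    J = np.eye(len(xy)) - np.ones((len(xy), len(xy))) / len(xy)
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(1.0, abs(vals[0]))
    if pos.sum() < n_axes:
        raise ValueError(f"only {int(pos.sum())} positive eigenvalues; "
                         f"{n_axes} axes requested")
    out = {}
    for a in range(n_axes):
        v = vecs[:, a] / np.linalg.norm(vecs[:, a])
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if len(nz) and v[nz[0]] < 0:
            v = -v
        out[f"pcnm{a + 1}"] = v
    return pd.DataFrame(out, index=centroids.index)


# ---------------------------------------------------------------------------
# Design construction and plain logistic fits
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Raw-scale design matrix (const first) for a formulation."""
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for term in spec.terms:
        if term == INTERACTION:
            X[term] = data[ENV_L] * data[ENV_T]
        else:
            X[term] = data[term].astype(float)
    return X


def _standardize(X: pd.DataFrame):
    """Z-score non-constant columns; return (Xs, means, sds)."""
    Xs = X.copy()
    means = pd.Series(0.0, index=X.columns)
    sds = pd.Series(1.0, index=X.columns)
    for c in X.columns:
        if c == "const":
            continue
        m, s = X[c].mean(), X[c].std(ddof=0)
        if s <= 0:
            raise ValueError(f"constant covariate {c!r}")
        Xs[c] = (X[c] - m) / s
        means[c], sds[c] = m, s
    return Xs, means, sds


def _destandardize(beta_std: pd.Series, means: pd.Series,
                   sds: pd.Series) -> pd.Series:
    beta = beta_std / sds
    beta["const"] = beta_std["const"] - float(
        (beta_std.drop("const") * means.drop("const") / sds.drop("const")).sum())
    return beta


def fit_logistic(data: pd.DataFrame, y: np.ndarray | pd.Series,
                 spec: ModelSpec | None = None,
                 design: pd.DataFrame | None = None) -> ModelFit:
    """Maximum-likelihood logistic regression for one species.

    Newton/IRLS via statsmodels on z-scored covariates; converged means the
    raw-scale score norm is below 1e-8 per observation scale.
    """
    import statsmodels.api as sm

    spec = spec or ModelSpec(5)
    X = build_design(data, spec) if design is None else design
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    Xs, means, sds = _standardize(X)
    # near-separated designs overflow harmlessly mid-iteration; the explicit
    # gradient check below decides convergence
    with warnings.catch_warnings(), np.errstate(over="ignore",
                                                divide="ignore"):
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.Logit(y, Xs).fit(method="newton", maxiter=100, tol=1e-10,
                                  disp=0, warn_convergence=False)
    beta = _destandardize(pd.Series(res.params, index=X.columns), means, sds)
    # gradient check on the standardized problem
    p = expit(Xs.to_numpy() @ res.params)
    grad = Xs.to_numpy().T @ (y - p)
    converged = bool(res.mle_retvals.get("converged", True)
                     and np.linalg.norm(grad) < 1e-6)
    return ModelFit(spec=spec, params=beta, llf=float(res.llf), k=X.shape[1],
                    converged=converged, n=len(y), design=X, y=y)


# ---------------------------------------------------------------------------
# Mixed logistic (species random intercept) by Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _gh_loglik(beta: np.ndarray, log_sigma: float, X: np.ndarray,
               y: np.ndarray, starts: np.ndarray, nodes: np.ndarray,
               wts: np.ndarray) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, scalar random intercept.

    Each cluster's integrand ``exp(h(u))`` with
    ``h(u) = sum_i ll(y_i, eta_i + u) + log N(u; 0, sigma^2)`` is integrated
    with nodes centred at the cluster's posterior mode and scaled by the
    curvature there (plain GH is badly biased once clusters hold hundreds of
    observations, because the integrand is far narrower than the prior).
    """
    sigma = np.exp(log_sigma)
    eta = X @ beta
    n_clusters = len(starts)
    counts = np.diff(np.r_[starts, len(y)])
    clusters = np.repeat(np.arange(n_clusters), counts)

    # posterior mode per cluster by Newton on h'(u) = sum(y - p) - u/sigma^2
    u = np.zeros(n_clusters)
    for _ in range(50):
        p = expit(eta + u[clusters])
        grad = np.add.reduceat(y - p, starts) - u / sigma ** 2
        hess = -np.add.reduceat(p * (1 - p), starts) - 1.0 / sigma ** 2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta + u[clusters])
    hess = -np.add.reduceat(p * (1 - p), starts) - 1.0 / sigma ** 2
    tau = 1.0 / np.sqrt(-hess)                     # Laplace sd per cluster

    # adaptive nodes u_ck = u_c + sqrt(2) tau_c x_k
    z = eta[:, None] + (u[clusters, None]
                        + np.sqrt(2.0) * tau[clusters, None] * nodes[None, :])
    ll = y[:, None] * z - np.logaddexp(0.0, z)
    csum = np.add.reduceat(ll, starts, axis=0)      # (n_clusters, n_nodes)
    u_nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    log_prior = (-0.5 * (u_nodes / sigma) ** 2
                 - 0.5 * np.log(2 * np.pi) - np.log(sigma))
    lw = (csum + log_prior + np.log(wts)[None, :] + nodes[None, :] ** 2
          + 0.5 * np.log(2.0) + np.log(tau)[:, None])
    return float(np.sum(logsumexp(lw, axis=1)))


def fit_mixed_logistic(data: pd.DataFrame, y: np.ndarray | pd.Series,
                       groups: np.ndarray | pd.Series,
                       spec: ModelSpec | None = None,
                       n_quad: int = 25,
                       fix_sigma: float | None = None) -> ModelFit:
    """ML random-intercept logistic model for one taxon.

    The species-level intercept ``u_s ~ N(0, sigma2_u)`` is integrated out by
    Gauss-Hermite quadrature (``n_quad`` nodes) and ``(beta, log sigma)``
    maximised jointly.  With ``fix_sigma=0`` the fit reduces exactly to the
    pooled fixed-effects model.
    """
    spec = spec or ModelSpec(5, random_intercept=True)
    X = build_design(data, spec)
    Xs, means, sds = _standardize(X)
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2 and fix_sigma is None:
        raise ValueError("need >=2 species for a random intercept")
    order = np.argsort(g, kind="stable")
    Xo, yo, go = Xs.to_numpy()[order], y[order], g[order]
    starts = np.r_[0, np.nonzero(go[1:] != go[:-1])[0] + 1]
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)

    pooled = fit_logistic(data, y, spec, design=X)
    beta0 = _standardize_params(pooled.params, means, sds)

    if fix_sigma is not None and fix_sigma == 0:
        return ModelFit(spec=spec, params=pooled.params, llf=pooled.llf,
                        k=pooled.k, converged=pooled.converged, sigma2_u=0.0,
                        n=len(y), design=X, y=y, groups=g)

    def nll(theta: np.ndarray) -> float:
        return -_gh_loglik(theta[:-1], theta[-1], Xo, yo, starts, nodes, wts)

    x0 = np.r_[beta0.to_numpy(), np.log(0.5)]
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-7,
                            "eps": 1e-6})
    beta_std = pd.Series(res.x[:-1], index=X.columns)
    sigma = float(np.exp(res.x[-1]))
    beta = _destandardize(beta_std, means, sds)
    k = X.shape[1] + 1
    return ModelFit(spec=spec, params=beta, llf=float(-res.fun), k=k,
                    converged=bool(res.success), sigma2_u=sigma ** 2,
                    n=len(y), design=X, y=y, groups=g)


def _standardize_params(beta_raw: pd.Series, means: pd.Series,
                        sds: pd.Series) -> pd.Series:
    beta = beta_raw * sds
    beta["const"] = beta_raw["const"] + float(
        (beta_raw.drop("const") * means.drop("const")).sum())
    return beta


# ---------------------------------------------------------------------------
# Selection and effect summaries
# ---------------------------------------------------------------------------

def fit_formulations(data: pd.DataFrame, y, groups=None,
                     formulations=(1, 2, 3, 4, 5)) -> dict[int, ModelFit]:
    """Fit every formulation for one unit (species, or taxon when grouped)."""
    fits: dict[int, ModelFit] = {}
    for fid in formulations:
        try:
            if groups is None:
                fit = fit_logistic(data, y, ModelSpec(fid))
            else:
                fit = fit_mixed_logistic(data, y, groups,
                                         ModelSpec(fid, random_intercept=True))
        except (ValueError, np.linalg.LinAlgError, PerfectSeparationError):
            continue
        if fit.converged and np.isfinite(fit.aic):
            fits[fid] = fit
    return fits


def select_best(fits: dict[int, ModelFit]) -> ModelFit:
    """AIC minimum; ties broken toward fewer parameters."""
    if not fits:
        raise ValueError("no converged fits to select from")
    return min(fits.values(), key=lambda f: (round(f.aic, 10), f.k))


def average_marginal_effect(fit: ModelFit, variable: str, unit: float,
                            data: pd.DataFrame | None = None) -> AMEResult:
    """AME of ``variable`` per ``unit`` on the probability scale.

    ``AME = unit * mean_i (beta_v + beta_int * w_i) * p_i (1 - p_i)`` where
    ``w`` is the interaction partner when the fit includes the product term.
    Requesting a variable absent from the fit is an error, never zero.
    """
    if variable not in fit.params.index:
        raise KeyError(f"variable {variable!r} not in fitted model")
    X = fit.design if data is None else build_design(data, fit.spec)
    p = fit.predict(X)
    slope = fit.params[variable]
    deriv = np.full(len(X), slope)
    if INTERACTION in fit.params.index and variable in (ENV_L, ENV_T):
        partner = ENV_T if variable == ENV_L else ENV_L
        deriv = slope + fit.params[INTERACTION] * X[partner].to_numpy(float)
    ame = float(unit * np.mean(deriv * p * (1 - p)))
    return AMEResult(variable=variable, unit=unit, ame=ame)


def bootstrap_ci(fit: ModelFit, n_sim: int = 100, level: float = 0.95,
                 rng: np.random.Generator | int | None = None,
                 ame_variables: dict[str, float] | None = None):
    """Parametric bootstrap percentile intervals for coefficients (and AMEs).

    Simulates outcomes from the fitted probabilities, refits the same
    formulation, and takes percentile intervals; refit failures are dropped
    and counted.  Returns ``(param_ci, ame_ci, n_failed)`` where the CI
    frames have columns ``lo``/``hi``.
    """
    rng = np.random.default_rng(rng)
    p = fit.predict()
    draws, ame_draws, failed = [], {v: [] for v in (ame_variables or {})}, 0
    for _ in range(n_sim):
        ysim = rng.binomial(1, p).astype(float)
        try:
            refit = fit_logistic(fit.design.drop(columns="const"), ysim,
                                 fit.spec, design=fit.design)
        except (ValueError, np.linalg.LinAlgError, PerfectSeparationError):
            failed += 1
            continue
        if not refit.converged:
            failed += 1
            continue
        draws.append(refit.params)
        for v, unit in (ame_variables or {}).items():
            ame_draws[v].append(average_marginal_effect(refit, v, unit).ame)
    if not draws:
        raise RuntimeError("every bootstrap refit failed")
    alpha = (1 - level) / 2
    boot = pd.DataFrame(draws)
    param_ci = pd.DataFrame({
        "lo": boot.quantile(alpha), "hi": boot.quantile(1 - alpha)})
    ame_ci = pd.DataFrame({
        v: {"lo": float(np.quantile(a, alpha)),
            "hi": float(np.quantile(a, 1 - alpha))}
        for v, a in ame_draws.items()}).T if ame_variables else None
    return param_ci, ame_ci, failed


def r2_mixed(fit: ModelFit) -> tuple[float, float]:
    """Latent-scale marginal and conditional R2 for a mixed logistic fit.

    ``R2m = s2_f / (s2_f + s2_u + pi^2/3)`` and
    ``R2c = (s2_f + s2_u) / (s2_f + s2_u + pi^2/3)`` with ``s2_f`` the
    variance of the fixed-effect linear predictor.
    """
    if fit.sigma2_u is None:
        raise ValueError("r2_mixed requires a mixed fit")
    s2f = float(np.var(fit.linear_predictor()))
    denom = s2f + fit.sigma2_u + np.pi ** 2 / 3
    return s2f / denom, (s2f + fit.sigma2_u) / denom


def collinearity_report(table: pd.DataFrame,
                        columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation tests between explanatory variables.

    Reports r, d.f. = n - 2 and the two-sided p-value from
    ``t = r sqrt(df) / sqrt(1 - r^2)`` for every pair of columns; pairs with
    a constant member are flagged with NaN.
    """
    cols = columns or [c for c in table.columns
                       if np.issubdtype(table[c].dtype, np.number)]
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = table[[a, b]].dropna()
            n = len(sub)
            if n < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                rows.append((a, b, np.nan, max(n - 2, 0), np.nan))
                continue
            r, p = stats.pearsonr(sub[a], sub[b])
            rows.append((a, b, float(r), n - 2, float(p)))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "df", "p"])
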