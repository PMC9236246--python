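"""Conditional (cluster-conditioned) quasi-Poisson estimation.

The estimation core of the case-crossover analysis. Daily counts y_i within
a time-stratified cluster C are modelled as Poisson with log-rate
alpha_C + beta' x_i; conditioning on the cluster total N_C = sum_{i in C} y_i
eliminates the cluster intercepts alpha_C and leaves a multinomial
likelihood with cell probabilities

    pi_i = exp(beta' x_i) / sum_{j in C} exp(beta' x_j).

The conditional log-likelihood (dropping the beta-free multinomial
coefficient) is

    l(beta) = sum_i y_i eta_i - sum_C N_C log sum_{j in C} exp(eta_j),
    eta_i = beta' x_i,

which is concave in beta; it is maximized by Newton iteration with
log-sum-exp stabilization and step-halving, started at beta = 0.
Overdispersion is absorbed quasi-Poisson style: a Pearson dispersion
estimate scales the model-based variances, so standard errors are
sqrt(dispersion x diag(inverse observed information)).

The conditional estimate coincides exactly with the unconditional Poisson
fit that includes one fixed-effect indicator per cluster — a property the
test suite exercises against an independent fixed-effects fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class NonIdentifiableError(ValueError):
    """Raised when the exposure shows no within-cluster variation anywhere."""


@dataclass
class DesignMatrix:
    """Model-ready arrays for one conditional Poisson fit.

    Column 0 of ``X`` is the exposure term by convention; the remaining
    columns are the spline covariates. ``cluster`` holds integer cluster
    ids (0..K-1) aligned with the rows.
    """

    X: np.ndarray
    y: np.ndarray
    cluster: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster)
        if self.X.ndim != 2 or len(self.y) != len(self.X) or len(self.cluster) != len(self.X):
            raise ValueError("X, y and cluster must have matching row counts")
        if not np.isfinite(self.X).all() or not np.isfinite(self.y).all():
            raise ValueError("design matrix contains non-finite entries")
        if (self.y < 0).any():
            raise ValueError("counts must be non-negative")
        # re-encode clusters densely
        _, self.cluster = np.unique(self.cluster, return_inverse=True)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1 if len(self.cluster) else 0

    def cluster_totals(self) -> np.ndarray:
        return np.bincount(self.cluster, weights=self.y, minlength=self.n_clusters)


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit for one model.

    ``beta`` is on the log-rate scale per native exposure unit (column 0)
    and per spline-basis unit otherwise. ``se`` is dispersion-scaled;
    ``cov_unscaled`` is the inverse observed information without the
    dispersion factor.
    """

    beta: np.ndarray
    se: np.ndarray
    cov_unscaled: np.ndarray
    dispersion: float
    loglik: float
    converged: bool
    n_days: int
    n_clusters: int
    n_iter: int
    names: tuple[str, ...]

    def coef(self, name: str = None) -> float:
        i = 0 if name is None else self.names.index(name)
        return float(self.beta[i])

    def stderr(self, name: str = None) -> float:
        i = 0 if name is None else self.names.index(name)
        return float(self.se[i])


def _cluster_logsumexp(eta: np.ndarray, cluster: np.ndarray, n_clusters: int) -> np.ndarray:
    m = np.full(n_clusters, -np.inf)
    np.maximum.at(m, cluster, eta)
    s = np.bincount(cluster, weights=np.exp(eta - m[cluster]), minlength=n_clusters)
    return m + np.log(s)


def conditional_loglik(beta, design: DesignMatrix):
    """Conditional log-likelihood with analytic gradient and Hessian.

    Returns ``(loglik, gradient, hessian)``. The additive multinomial
    coefficient (beta-free) is dropped, so at beta = 0 the value is
    ``-sum_C N_C log |C|``. Computation is log-sum-exp stable.
    """
    beta = np.asarray(beta, dtype=float)
    X, y, cl = design.X, design.y, design.cluster
    K = design.n_clusters
    eta = X @ beta
    if not np.isfinite(eta).all():
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise ValueError(f"non-finite linear predictor at row {bad}")
    N = design.cluster_totals()
    lse = _cluster_logsumexp(eta, cl, K)
    ll = float(y @ eta - N @ lse)

    # pi_i: within-cluster softmax; mu_i = N_C pi_i are the conditional means
    pi = np.exp(eta - lse[cl])
    mu = N[cl] * pi
    grad = X.T @ (y - mu)

    # Hessian = -(X' diag(mu) X - sum_C N_C m_C m_C'), m_C = sum_{i in C} pi_i x_i
    M = np.zeros((K, X.shape[1]))
    np.add.at(M, cl, pi[:, None] * X)
    H = -(X.T @ (mu[:, None] * X) - (M * N[:, None]).T @ M)
    return ll, grad, H


def conditional_means(beta, design: DesignMatrix) -> np.ndarray:
    """Fitted means mu_i = N_C pi_i(beta) implied by the conditional model."""
    eta = design.X @ np.asarray(beta, dtype=float)
    N = design.cluster_totals()
    lse = _cluster_logsumexp(eta, design.cluster, design.n_clusters)
    return N[design.cluster] * np.exp(eta - lse[design.cluster])


def fit(
    design: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Maximize the conditional log-likelihood by damped Newton iteration.

    Starts at beta = 0 (benign for a concave objective); declares
    convergence when the gradient max-norm falls below ``tol``. The
    quasi-Poisson dispersion is the Pearson statistic over rows in clusters
    with a positive total, divided by n_rows - n_clusters - p, mirroring
    the residual df of the equivalent fixed-effects fit; when that df is
    not positive the dispersion (and the scaled standard errors) are NaN.

    Raises
    ------
    NonIdentifiableError
        If the exposure column is constant within every cluster — the
        conditioning then removes all information about it.
    """
    X, y, cl = design.X, design.y, design.cluster
    K = design.n_clusters
    # exposure must vary within at least one cluster
    x0 = X[:, 0]
    cluster_mean = np.bincount(cl, weights=x0, minlength=K) / np.bincount(cl, minlength=K)
    if np.allclose(x0, cluster_mean[cl]):
        raise NonIdentifiableError(
            "exposure is constant within every cluster; the conditional "
            "likelihood carries no information about its coefficient"
        )

    # standardize column scales (spline columns are cubic-scale); the
    # gradient tolerance then applies to a well-conditioned problem
    col_scale = np.max(np.abs(X), axis=0)
    col_scale[col_scale == 0] = 1.0
    scaled = DesignMatrix(
        X=X / col_scale, y=y, cluster=cl, names=design.names
    )

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, H = conditional_loglik(beta, scaled)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, grad, rcond=None)[0]
        # step-halving keeps the ascent monotone on hard cases
        improved = False
        halving = 1.0
        for _ in range(40):
            cand = beta + halving * step
            try:
                ll_new, grad_new, H_new = conditional_loglik(cand, scaled)
            except (ValueError, FloatingPointError):
                ll_new = -np.inf
            if ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                improved = True
                break
            halving *= 0.5
        if not improved:
            break
        beta, ll, grad, H = cand, ll_new, grad_new, H_new
    converged = converged or bool(np.max(np.abs(grad)) < tol)

    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    # undo the column scaling
    beta = beta / col_scale
    cov = cov / np.outer(col_scale, col_scale)

    # Pearson dispersion over informative rows (clusters with events)
    N = design.cluster_totals()
    informative = N[cl] > 0
    mu = conditional_means(beta, design)
    n_used = int(informative.sum())
    k_used = int((N > 0).sum())
    ddf = n_used - k_used - p
    if ddf > 0 and n_used:
        pearson = np.sum((y[informative] - mu[informative]) ** 2 / mu[informative])
        dispersion = float(pearson / ddf)
    else:
        dispersion = float("nan")
    se = np.sqrt(np.clip(np.diag(cov), 0, None) * dispersion)

    return FitResult(
        beta=beta,
        se=se,
        cov_unscaled=cov,
        dispersion=dispersion,
        loglik=ll,
        converged=converged,
        n_days=len(y),
        n_clusters=K,
        n_iter=it,
        names=design.names,
    )


@dataclass
class RelativeRisk:
    rr: float
    lower: float
    upper: float
    delta: float
    level: float

    @property
    def significant_positive(self) -> bool:
        return self.lower > 1.0


def rr_from_fit(result: FitResult, delta: float, level: float = 0.95, name: str = None) -> RelativeRisk:
    """Relative risk per ``delta`` exposure units, with a Wald CI.

    RR = exp(beta * delta); CI endpoints exp((beta +/- z * SE) * delta)
    with the dispersion-scaled standard error. ``delta`` is typically the
    exposure's interquartile range. Rejects non-converged fits.
    """
    if not result.converged:
        raise ValueError("relative risk requested from a non-converged fit")
    if not delta > 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    b, s = result.coef(name), result.stderr(name)
    z = stats.norm.ppf(0.5 + level / 2)
    return RelativeRisk(
        rr=float(np.exp(b * delta)),
        lower=float(np.exp((b - z * s) * delta)),
        upper=float(np.exp((b + z * s) * delta)),
        delta=delta,
        level=level,
    )
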