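"""Gamma/beta marginals, the Gaussian copula density and its semi-parametric fit.

A class-conditional density over the descriptor space is built by Sklar's
construction: parametric univariate marginals (gamma for the strictly
positive cell count, beta for each proportion) glued together by a
Gaussian copula with correlation matrix R,

    f(x) = c_R(F_1(x_1), ..., F_D(x_D)) * prod_d f_d(x_d),
    ln c_R(u) = -1/2 ln|R| - 1/2 q^T (R^{-1} - I) q,   q_d = Phi^{-1}(u_d).

This has exactly as many free parameters as a full-covariance Gaussian:
D(D-1)/2 correlations plus two parameters per marginal, i.e. D(D+3)/2.

The copula correlation is estimated semi-parametrically: rank-based
pseudo-observations are mapped to normal scores and their (weighted)
Pearson correlation — the closed-form maximizer of the Gaussian-copula
pseudo-likelihood — is projected to the nearest positive-definite
correlation matrix.  Density *evaluation* always uses the parametric
marginal CDFs so the mixture likelihood is a proper density.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import special, stats
from statsmodels.stats.correlation_tools import corr_nearest

__all__ = [
    "MarginalParams",
    "CopulaClassParams",
    "marginal_logpdf",
    "marginal_cdf",
    "marginal_ppf",
    "gaussian_copula_logdensity",
    "copula_class_logdensity",
    "fit_marginal_weighted",
    "pseudo_observations",
    "estimate_copula_correlation",
    "project_to_correlation",
    "validate_correlation",
]

CDF_EPS = 1e-12
MIN_EIGENVALUE = 1e-6


@dataclasses.dataclass(frozen=True)
class MarginalParams:
    """One univariate marginal: gamma(shape, rate) or beta(a, b)."""

    family: str  # "gamma" | "beta"
    param1: float  # gamma shape / beta a
    param2: float  # gamma rate / beta b

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta"):
            raise ValueError(f"unknown marginal family {self.family!r}")
        if not (np.isfinite(self.param1) and np.isfinite(self.param2)):
            raise ValueError("marginal parameters must be finite")
        if self.param1 <= 0 or self.param2 <= 0:
            raise ValueError("marginal parameters must be strictly positive")

    @property
    def mean(self) -> float:
        if self.family == "gamma":
            return self.param1 / self.param2
        return self.param1 / (self.param1 + self.param2)

def _check_support(x: np.ndarray, family: str) -> None:
    if family == "gamma":
        if np.any(x <= 0):
            raise ValueError("gamma support is x > 0")
    else:
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError("beta support is 0 < x < 1")


# direct special-function formulas: building scipy frozen distributions per
# call costs orders of magnitude more than the density evaluation itself

def marginal_logpdf(x, params: MarginalParams):
    """Natural-log marginal density; scalar in, scalar out (arrays accepted)."""
    arr = np.asarray(x, dtype=float)
    _check_support(arr, params.family)
    a, b = params.param1, params.param2
    if params.family == "gamma":
        out = a * np.log(b) + (a - 1.0) * np.log(arr) - b * arr - special.gammaln(a)
    else:
        out = (a - 1.0) * np.log(arr) + (b - 1.0) * np.log1p(-arr) - special.betaln(a, b)
    return float(out) if np.isscalar(x) else out


def marginal_cdf(x, params: MarginalParams):
    """Marginal CDF, clipped to [1e-12, 1 - 1e-12] for stable normal scores."""
    arr = np.asarray(x, dtype=float)
    _check_support(arr, params.family)
    a, b = params.param1, params.param2
    if params.family == "gamma":
        out = special.gammainc(a, b * arr)
    else:
        out = special.betainc(a, b, arr)
    out = np.clip(out, CDF_EPS, 1 - CDF_EPS)
    return float(out) if np.isscalar(x) else out


def marginal_ppf(u, params: MarginalParams):
    """Marginal quantile function (used by the generative sampler)."""
    uu = np.clip(np.asarray(u, dtype=float), CDF_EPS, 1 - CDF_EPS)
    a, b = params.param1, params.param2
    if params.family == "gamma":
        out = special.gammaincinv(a, uu) / b
    else:
        out = special.betaincinv(a, b, uu)
    return float(out) if np.isscalar(u) else out


def validate_correlation(R: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.abs(R) > 1 + 1e-10):
        raise ValueError("correlation entries must lie in [-1, 1]")
    if np.linalg.eigvalsh(R)[0] <= min_eig:
        raise ValueError(
            "correlation matrix is not positive definite; repair with project_to_correlation"
        )
    return R


@dataclasses.dataclass
class CopulaClassParams:
    """One population-phenotype class: copula correlation + D parametric marginals."""

    R: np.ndarray
    marginals: tuple[MarginalParams, ...]

    def __post_init__(self) -> None:
        self.R = validate_correlation(self.R)
        self.marginals = tuple(self.marginals)
        if len(self.marginals) != self.R.shape[0]:
            raise ValueError("need one marginal per descriptor")

    @property
    def D(self) -> int:
        return len(self.marginals)

    @property
    def n_free_params(self) -> int:
        """D(D-1)/2 correlations + 2 parameters per marginal = D(D+3)/2."""
        D = self.D
        return D * (D - 1) // 2 + 2 * D

    def to_json(self) -> dict:
        return {
            "family_pattern": [m.family for m in self.marginals],
            "marginals": [[m.param1, m.param2] for m in self.marginals],
            "R": self.R.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CopulaClassParams":
        marg = tuple(
            MarginalParams(f, p1, p2)
            for f, (p1, p2) in zip(obj["family_pattern"], obj["marginals"])
        )
        return cls(np.asarray(obj["R"], dtype=float), marg)


def gaussian_copula_logdensity(u: np.ndarray, R: np.ndarray) -> float | np.ndarray:
    """Log of the Gaussian copula density c_R at u (rows of u if 2-D).

    Equals ln phi_D(q; R) - sum_d ln phi(q_d) with q the normal scores of
    u; exactly 0 for the identity matrix (independence copula).
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    U = np.atleast_2d(u)
    if np.any((U <= 0) | (U >= 1)):
        raise ValueError("copula arguments must lie strictly inside the unit cube")
    R = np.asarray(R, dtype=float)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is not positive definite; repair with project_to_correlation"
        ) from exc
    q = special.ndtri(U)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    z = np.linalg.solve(L, q.T)  # R^{-1} = L^{-T} L^{-1}
    quad = np.sum(z * z, axis=0) - np.sum(q * q, axis=1)
    out = -0.5 * logdet - 0.5 * quad
    return float(out[0]) if single else out


def copula_class_logdensity(x: np.ndarray, params: CopulaClassParams) -> float | np.ndarray:
    """Log density of the copula-with-parametric-marginals construction at x.

    Accepts a single descriptor vector or an m x D matrix of them.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.D:
        raise ValueError(f"expected {params.D} descriptors, got {X.shape[1]}")
    U = np.empty_like(X)
    marg_sum = np.zeros(X.shape[0])
    for d, m in enumerate(params.marginals):
        U[:, d] = marginal_cdf(X[:, d], m)
        marg_sum += marginal_logpdf(X[:, d], m)
    out = gaussian_copula_logdensity(U, params.R) + marg_sum
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# estimation


def _weighted_moments(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    m = float(np.dot(weights, values) / wsum)
    v = float(np.dot(weights, (values - m) ** 2) / wsum)
    return m, v


def _gamma_moments(m: float, v: float) -> tuple[float, float]:
    v = max(v, 1e-8)
    return m * m / v, m / v


def _beta_moments(m: float, v: float) -> tuple[float, float]:
    m = min(max(m, 1e-6), 1 - 1e-6)
    v = min(max(v, 1e-8), m * (1 - m) * 0.999)
    common = m * (1 - m) / v - 1.0
    return m * common, (1 - m) * common


def _gamma_mle(values, weights, init, max_steps=50):
    # Newton on the profile equation ln(a) - psi(a) = ln(mean) - mean(ln x).
    wsum = weights.sum()
    m = float(np.dot(weights, values) / wsum)
    s = np.log(m) - float(np.dot(weights, np.log(values)) / wsum)
    if s <= 0:  # numerically degenerate (near-constant sample)
        return init
    a = init[0]
    for _ in range(max_steps):
        g = np.log(a) - special.digamma(a) - s
        h = 1.0 / a - special.polygamma(1, a)
        step = g / h
        a_new = a - step
        if a_new <= 0 or not np.isfinite(a_new):
            a_new = a / 2
        if abs(a_new - a) < 1e-10 * a:
            a = a_new
            break
        a = a_new
    if not np.isfinite(a) or a <= 0:
        return init
    return a, a / m


def _beta_mle(values, weights, init, max_steps=50):
    # Newton on the sufficient-statistic equations
    # psi(a) - psi(a+b) = E_w[ln x],  psi(b) - psi(a+b) = E_w[ln(1-x)].
    wsum = weights.sum()
    s1 = float(np.dot(weights, np.log(values)) / wsum)
    s2 = float(np.dot(weights, np.log1p(-values)) / wsum)
    ab = np.array(init, dtype=float)
    for _ in range(max_steps):
        a, b = ab
        psi_ab = special.digamma(a + b)
        g = np.array([special.digamma(a) - psi_ab - s1, special.digamma(b) - psi_ab - s2])
        tri_ab = special.polygamma(1, a + b)
        H = np.array(
            [
                [special.polygamma(1, a) - tri_ab, -tri_ab],
                [-tri_ab, special.polygamma(1, b) - tri_ab],
            ]
        )
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return init
        new = ab - step
        if np.any(new <= 0) or not np.all(np.isfinite(new)):
            new = np.maximum(ab / 2, 1e-3)
        if np.max(np.abs(new - ab) / np.maximum(ab, 1e-8)) < 1e-10:
            ab = new
            break
        ab = new
    if not np.all(np.isfinite(ab)) or np.any(ab <= 0):
        return init
    return float(ab[0]), float(ab[1])


def fit_marginal_weighted(
    values: np.ndarray,
    weights: np.ndarray | None,
    family: str,
    refine: bool = True,
) -> MarginalParams:
    """Weighted fit of a gamma or beta marginal.

    Weighted method-of-moments initializer, refined (when ``refine``) by
    Newton iterations on the weighted log-likelihood sufficient-statistic
    equations; falls back to moments on non-convergence.  Uniform weights
    reproduce the unweighted estimate.
    """
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.ones_like(values)
    else:
        weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    _check_support(values, family)

    m, v = _weighted_moments(values, weights)
    if v < 1e-8:
        warnings.warn(
            f"near-zero weighted variance for {family} fit; using variance floor",
            RuntimeWarning,
        )
        v = 1e-8
        refine = False
    init = _gamma_moments(m, v) if family == "gamma" else _beta_moments(m, v)
    if refine:
        fit = _gamma_mle(values, weights, init) if family == "gamma" else _beta_mle(values, weights, init)
    else:
        fit = init
    return MarginalParams(family, float(fit[0]), float(fit[1]))


def pseudo_observations(values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Rank-based surrogates for marginal CDF values, strictly inside (0, 1).

    Unweighted: rank_i / (n+1) with average ranks for ties.  Weighted: a
    mid-point weighted empirical CDF, u_i = S_i / (sum_j w_j + wbar) with
    S_i counting half of the tied weight at x_i and wbar the weighted mean
    weight (sum w^2 / sum w); reduces to (rank - 1/2)/(n + 1) under any
    uniform weighting, and one-hot weights reproduce the subset estimate.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for pseudo-observations")
    if weights is None:
        ranks = stats.rankdata(values, method="average")
        return ranks / (n + 1.0)
    w = np.asarray(weights, dtype=float)
    if w.shape != values.shape:
        raise ValueError("weights must match values in shape")
    order = np.argsort(values, kind="stable")
    xs, ws = values[order], w[order]
    cum = np.cumsum(ws)
    # S_i = sum_{x_j < x_i} w_j + 0.5 * sum_{x_j == x_i} w_j via tie blocks
    starts = np.flatnonzero(np.r_[True, xs[1:] != xs[:-1]])
    ends = np.r_[starts[1:], n] - 1
    below = np.where(starts > 0, cum[np.maximum(starts - 1, 0)], 0.0)
    mid = below + 0.5 * (cum[ends] - below)
    s_sorted = np.repeat(mid, ends - starts + 1)
    s = np.empty(n)
    s[order] = s_sorted
    wsum = w.sum()
    wbar = float(w @ w) / wsum  # weighted mean weight: scale-invariant "+1"
    return np.clip(s / (wsum + wbar), CDF_EPS, 1 - CDF_EPS)


def estimate_copula_correlation(
    pseudo_u: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian-copula correlation from pseudo-observations.

    The weighted Pearson correlation of the normal scores Phi^{-1}(u)
    is the closed-form maximizer of the Gaussian-copula pseudo-likelihood;
    the result is clipped and projected to a valid correlation matrix.
    """
    U = np.asarray(pseudo_u, dtype=float)
    if U.ndim != 2:
        raise ValueError("pseudo_u must be an n x D matrix")
    n, D = U.shape
    if n <= D:
        raise ValueError(f"need more observations ({n}) than dimensions ({D})")
    if np.any((U <= 0) | (U >= 1)):
        raise ValueError("pseudo-observations must lie strictly inside (0, 1)")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    q = special.ndtri(U)
    wsum = w.sum()
    mu = (w @ q) / wsum
    qc = q - mu
    cov = (qc.T * w) @ qc / wsum
    sd = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    R = cov / np.outer(sd, sd)
    return project_to_correlation(R)


def project_to_correlation(M: np.ndarray, min_eig: float = MIN_EIGENVALUE) -> np.ndarray:
    """Nearest (Frobenius) valid correlation matrix; idempotent on valid input."""
    M = np.asarray(M, dtype=float)
    R = 0.5 * (M + M.T)
    np.fill_diagonal(R, 1.0)
    off = ~np.eye(R.shape[0], dtype=bool)
    R[off] = np.clip(R[off], -(1 - 1e-6), 1 - 1e-6)
    if np.linalg.eigvalsh(R)[0] >= min_eig:
        return R
    R = corr_nearest(R, threshold=min_eig, n_fact=200)
    R = 0.5 * (np.asarray(R) + np.asarray(R).T)
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R)[0] < min_eig / 10:
        # corr_nearest guarantees threshold up to numerical slack; nudge if needed
        eigval, eigvec = np.linalg.eigh(R)
        eigval = np.clip(eigval, min_eig, None)
        R = eigvec @ np.diag(eigval) @ eigvec.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R
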