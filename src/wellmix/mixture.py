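"""Hierarchical mixture model over wells with EM-type learning.

Each well carries one latent population-phenotype class Z_i drawn from a
multinomial pi; given the class, the well's K fields are independent
draws from the class-conditional density.  The well density is

    p(W_i) = sum_c pi_c prod_k f(x_ik | theta_c)                    (well)
    ln p(X) = sum_i ln p(W_i)                                        (dataset)

Three parametrizations are supported:

``copula``
    Gaussian copula with gamma/beta marginals per class (hierarchical).
``gaussian_full``
    Full-covariance multivariate normal per class (hierarchical).
``baseline_diag``
    Diagonal-covariance Gaussian mixture over *fields*, ignoring well
    grouping — the baseline that drops both the dependence structure and
    the within-population hierarchy.  Its per-well score is the sum of
    its fields' mixture log-densities.

EM is exact for the Gaussian parametrizations (non-decreasing likelihood
trajectory).  The copula M-step is a generalized-EM approximation
(semi-parametric correlation + weighted marginal ML), so monotonicity is
not guaranteed; the best-seen iterate is returned.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .copula import (
    CopulaClassParams,
    copula_class_logdensity,
    estimate_copula_correlation,
    fit_marginal_weighted,
    pseudo_observations,
)
from .data import Dataset, WellData

__all__ = [
    "GaussianClassParams",
    "MixtureModel",
    "FitResult",
    "PARAMETRIZATIONS",
    "well_log_density",
    "dataset_log_likelihood",
    "e_step",
    "m_step",
    "initialize",
    "fit_em",
    "default_families",
]

logger = logging.getLogger(__name__)

PARAMETRIZATIONS = ("copula", "gaussian_full", "baseline_diag")

#: Responsibility mass below this fraction of n marks a class as degenerate.
EMPTY_CLASS_FRACTION = 1e-3


@dataclasses.dataclass
class GaussianClassParams:
    """Multivariate-normal class-conditional: mean + (full or diagonal) covariance."""

    mean: np.ndarray
    covariance: np.ndarray
    diagonal: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape must match mean")
        if self.diagonal:
            off = self.covariance[~np.eye(self.mean.size, dtype=bool)]
            if np.any(off != 0):
                raise ValueError("diagonal class must have exactly-zero off-diagonals")
        if np.linalg.eigvalsh(0.5 * (self.covariance + self.covariance.T))[0] < 1e-8:
            raise ValueError("covariance must be positive definite (eigenvalues >= 1e-8)")

    @property
    def D(self) -> int:
        return self.mean.size

    @property
    def n_free_params(self) -> int:
        D = self.D
        return D + (D if self.diagonal else D * (D + 1) // 2)

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X - self.mean
        L = np.linalg.cholesky(self.covariance)
        z = np.linalg.solve(L, diff.T)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return -0.5 * (self.D * np.log(2 * np.pi) + logdet + np.sum(z * z, axis=0))

    def to_json(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "diagonal": self.diagonal,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GaussianClassParams":
        return cls(np.asarray(obj["mean"]), np.asarray(obj["covariance"]), obj["diagonal"])


@dataclasses.dataclass
class MixtureModel:
    """Class proportions pi + C class-conditional densities + hierarchy flag."""

    pi: np.ndarray
    classes: list
    parametrization: str
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.parametrization not in PARAMETRIZATIONS:
            raise ValueError(f"unknown parametrization {self.parametrization!r}")
        if abs(self.pi.sum() - 1.0) > 1e-10 or np.any(self.pi < 0):
            raise ValueError("pi must be nonnegative and sum to 1")
        if len(self.classes) != self.pi.size:
            raise ValueError("pi length must equal number of classes")
        kinds = {type(c) for c in self.classes}
        if len(kinds) > 1:
            raise ValueError("all classes must share one parametrization")
        self.descriptor_names = tuple(self.descriptor_names)

    @property
    def C(self) -> int:
        return self.pi.size

    @property
    def D(self) -> int:
        return len(self.descriptor_names)

    @property
    def hierarchical(self) -> bool:
        """Wells share a latent class; False only for the flat field-level baseline."""
        return self.parametrization != "baseline_diag"

    def class_log_densities(self, X: np.ndarray) -> np.ndarray:
        """m x C matrix of per-field class-conditional log densities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], self.C))
        for c, params in enumerate(self.classes):
            if isinstance(params, CopulaClassParams):
                out[:, c] = copula_class_logdensity(X, params)
            else:
                out[:, c] = params.logpdf(X)
        return out

    def to_json(self) -> dict:
        return {
            "parametrization": self.parametrization,
            "hierarchical": self.hierarchical,
            "pi": self.pi.tolist(),
            "classes": [c.to_json() for c in self.classes],
            "descriptor_names": list(self.descriptor_names),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MixtureModel":
        if obj["parametrization"] == "copula":
            classes = [CopulaClassParams.from_json(c) for c in obj["classes"]]
        else:
            classes = [GaussianClassParams.from_json(c) for c in obj["classes"]]
        return cls(
            np.asarray(obj["pi"]), classes, obj["parametrization"], tuple(obj["descriptor_names"])
        )


@dataclasses.dataclass
class FitResult:
    model: MixtureModel
    loglik_trajectory: list[float]
    converged: bool
    n_iter: int
    seed: int

    @property
    def loglik(self) -> float:
        return self.loglik_trajectory[-1]

    def to_json(self) -> dict:
        """Fitted-model export: model parameters plus fit provenance."""
        obj = self.model.to_json()
        obj["seed"] = self.seed
        obj["loglik"] = self.loglik
        return obj


def default_families(descriptor_names) -> tuple[str, ...]:
    """gamma for the count descriptor (first), beta for each proportion."""
    return ("gamma",) + ("beta",) * (len(descriptor_names) - 1)


# ---------------------------------------------------------------------------
# likelihood


def _log_mix_terms(model: MixtureModel, X: np.ndarray) -> np.ndarray:
    """m x C matrix of ln pi_c + per-field class log density (pi_c=0 -> -inf)."""
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    return model.class_log_densities(X) + log_pi


def _well_log_terms(model: MixtureModel, dataset: Dataset) -> np.ndarray:
    """n_wells x C matrix of ln pi_c + sum_k class log density over each well."""
    logdens = model.class_log_densities(dataset.field_matrix())
    out = np.zeros((dataset.n_wells, model.C))
    np.add.at(out, dataset.field_well_index(), logdens)
    with np.errstate(divide="ignore"):
        return out + np.log(model.pi)


def well_log_density(well: WellData, model: MixtureModel) -> float:
    """Log well density: logsumexp_c [ln pi_c + sum_k ln f(x_k | theta_c)].

    For the flat baseline, fields are independent observations and the
    well's score is the sum of its fields' mixture log-densities.
    """
    X = well.field_matrix()
    if X.shape[1] != model.D:
        raise ValueError("descriptor mismatch between well and model")
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    logdens = model.class_log_densities(X)
    if model.hierarchical:
        # fsum makes the per-class sums independent of field order, so
        # permuting fields within a well is exactly free
        sums = np.array([math.fsum(logdens[:, c]) for c in range(model.C)])
        return float(logsumexp(log_pi + sums))
    return float(logsumexp(logdens + log_pi, axis=1).sum())


def dataset_log_likelihood(dataset: Dataset, model: MixtureModel) -> float:
    """Total log-likelihood: wells are i.i.d., fields conditionally independent."""
    if dataset.n_wells == 0:
        raise ValueError("empty dataset")
    if model.hierarchical:
        return float(logsumexp(_well_log_terms(model, dataset), axis=1).sum())
    terms = _log_mix_terms(model, dataset.field_matrix())
    return float(logsumexp(terms, axis=1).sum())


# ---------------------------------------------------------------------------
# EM


def e_step(dataset: Dataset, model: MixtureModel) -> np.ndarray:
    """Posterior class responsibilities; one row per well (per field if flat)."""
    if model.hierarchical:
        terms = _well_log_terms(model, dataset)
    else:
        terms = _log_mix_terms(model, dataset.field_matrix())
    norm = logsumexp(terms, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    resp = np.exp(terms - np.where(np.isfinite(norm), norm, 0.0))
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} rows had numerically zero density under every class; "
            "assigning uniform responsibilities",
            RuntimeWarning,
        )
        resp[bad] = 1.0 / model.C
    return resp


def _field_weights(dataset: Dataset, resp: np.ndarray, hierarchical: bool) -> np.ndarray:
    """n_fields x C weights: fields inherit their well's responsibility row."""
    if hierarchical:
        return resp[dataset.field_well_index()]
    return resp


def m_step(
    dataset: Dataset,
    resp: np.ndarray,
    parametrization: str,
    families: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, list]:
    """Weighted maximum-likelihood update of (pi, classes) given responsibilities."""
    if parametrization not in PARAMETRIZATIONS:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    hierarchical = parametrization != "baseline_diag"
    n_rows = dataset.n_wells if hierarchical else dataset.n_fields
    if resp.shape[0] != n_rows:
        raise ValueError("responsibility rows do not match the dataset")
    if not np.allclose(resp.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("responsibilities must be row-stochastic")

    pi = resp.sum(axis=0) / resp.shape[0]
    pi = pi / pi.sum()

    X = dataset.field_matrix()
    W = _field_weights(dataset, resp, hierarchical)
    classes: list = []
    for c in range(resp.shape[1]):
        w = W[:, c]
        if parametrization == "copula":
            classes.append(_fit_copula_class(X, w, families or default_families(dataset.descriptor_names)))
        else:
            classes.append(_fit_gaussian_class(X, w, diagonal=parametrization == "baseline_diag"))
    return pi, classes


def _fit_gaussian_class(X: np.ndarray, w: np.ndarray, diagonal: bool) -> GaussianClassParams:
    wsum = w.sum()
    if wsum <= 0:
        w = np.ones(X.shape[0])
        wsum = w.sum()
    mean = (w @ X) / wsum
    diff = X - mean
    cov = (diff.T * w) @ diff / wsum
    if diagonal:
        cov = np.diag(np.clip(np.diag(cov), 1e-8, None))
    else:
        eigmin = np.linalg.eigvalsh(0.5 * (cov + cov.T))[0]
        if eigmin < 1e-8:
            cov = cov + (1e-8 - eigmin + 1e-10) * np.eye(X.shape[1])
    return GaussianClassParams(mean, 0.5 * (cov + cov.T) if not diagonal else cov, diagonal)


def _fit_copula_class(X: np.ndarray, w: np.ndarray, families) -> CopulaClassParams:
    if w.sum() <= 0:
        w = np.ones(X.shape[0])
    marginals = tuple(
        fit_marginal_weighted(X[:, d], w, fam) for d, fam in enumerate(families)
    )
    U = np.column_stack([pseudo_observations(X[:, d], w) for d in range(X.shape[1])])
    R = estimate_copula_correlation(U, w)
    return CopulaClassParams(R, marginals)


def _initialize_labels(dataset: Dataset, C: int, seed: int) -> np.ndarray:
    means = np.vstack([w.field_matrix().mean(axis=0) for w in dataset.wells])
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    sd[sd < 1e-12] = 1.0
    Z = (means - mu) / sd
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        km_seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=C, n_init=4, random_state=km_seed)
        labels = km.fit_predict(Z)
        if len(np.unique(labels)) == C:
            return labels
    raise RuntimeError(f"k-means produced a degenerate clustering in 5 attempts (C={C})")


def _init_params(
    dataset: Dataset, C: int, seed: int, parametrization: str, families
) -> tuple[np.ndarray, list]:
    if C == 1:
        labels = np.zeros(dataset.n_wells, dtype=int)
    else:
        labels = _initialize_labels(dataset, C, seed)
    hierarchical = parametrization != "baseline_diag"
    if hierarchical:
        resp = np.eye(C)[labels]
    else:
        resp = np.eye(C)[labels[dataset.field_well_index()]]
    pi, classes = m_step(dataset, resp, parametrization, families)
    pi = 0.9 * pi + 0.1 / C
    pi = pi / pi.sum()
    return pi, classes


def initialize(dataset: Dataset, C: int, seed: int, parametrization: str = "gaussian_full"):
    """Seeded initialization: k-means on per-well mean vectors -> one M-step.

    Wells are summarized by their scaled mean field vector and clustered
    with k-means; the hard assignment is pushed through one M-step and
    pi is uniform-smoothed (90% empirical + 10% uniform).  Different
    seeds may give different initializations; a given seed is fully
    deterministic.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if C > dataset.n_wells:
        raise ValueError(f"C={C} exceeds the number of wells ({dataset.n_wells})")
    families = default_families(dataset.descriptor_names)
    return _init_params(dataset, C, seed, parametrization, families)


def fit_em(
    dataset: Dataset,
    C: int,
    parametrization: str,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Fit the mixture by EM from a seeded k-means initialization.

    Convergence: relative change in total log-likelihood < ``tol``.  For
    the Gaussian parametrizations the trajectory is non-decreasing (exact
    EM); the copula M-step is approximate, so the best-seen parameters
    are returned and the final trajectory entry is their likelihood.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if C >= dataset.n_wells:
        raise ValueError(f"need more wells ({dataset.n_wells}) than classes ({C})")
    families = default_families(dataset.descriptor_names)
    pi, classes = _init_params(dataset, C, seed, parametrization, families)
    model = MixtureModel(pi, classes, parametrization, dataset.descriptor_names)

    traj: list[float] = []
    best_ll = -np.inf
    best_model = model
    reseeded: dict[int, int] = {}
    converged = False
    prev = None
    for _ in range(max_iter):
        resp = e_step(dataset, model)

        # empty-class rule: reseed once from the worst-fit well, then drop
        col = resp.sum(axis=0)
        small = np.flatnonzero(col < EMPTY_CLASS_FRACTION * resp.shape[0])
        drop: list[int] = []
        if small.size:
            if model.hierarchical:
                well_ll = logsumexp(_well_log_terms(model, dataset), axis=1)
            else:
                well_ll = logsumexp(_log_mix_terms(model, dataset.field_matrix()), axis=1)
            worst = int(np.argmin(well_ll))
            for c in small:
                reseeded[c] = reseeded.get(c, 0) + 1
                if reseeded[c] > 1:
                    drop.append(int(c))
                    logger.info("dropping twice-degenerate class %d", c)
                else:
                    logger.info("reseeding degenerate class %d from worst-fit row %d", c, worst)
                    resp[worst] = 0.0
                    resp[worst, c] = 1.0
        if drop:
            keep = [c for c in range(model.C) if c not in drop]
            resp = resp[:, keep]
            resp = resp / resp.sum(axis=1, keepdims=True)
            reseeded = {keep.index(c): k for c, k in reseeded.items() if c in keep}

        pi, classes = m_step(dataset, resp, parametrization, families)
        model = MixtureModel(pi, classes, parametrization, dataset.descriptor_names)
        ll = dataset_log_likelihood(dataset, model)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite log-likelihood at iteration {len(traj) + 1} "
                f"(parametrization={parametrization}, C={model.C}, seed={seed})"
            )
        traj.append(ll)
        if ll > best_ll:
            best_ll = ll
            best_model = model
        if prev is not None and abs(ll - prev) <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = ll

    if parametrization == "copula" and best_ll > traj[-1] + 1e-12:
        model = best_model
        traj.append(best_ll)
    return FitResult(model, traj, converged, len(traj), seed)
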