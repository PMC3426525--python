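"""Downstream analyses: novelty scoring, class inspection, dispersion, association.

A model fitted to negative controls is a density over well descriptor
space; scoring new wells by their log-likelihood under it ranks them by
how atypical their cell populations are (novelty detection).  The raw
data analyses here — within-well vs. random-group dispersion and
Spearman association between cell count and phase proportions — are the
checks that motivate the hierarchical, dependence-aware model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, derive_g0g1
from .mixture import MixtureModel, e_step, well_log_density

__all__ = [
    "WellScore",
    "score_wells",
    "scores_frame",
    "flag_small_classes",
    "dispersion",
    "within_vs_random_dispersion",
    "spearman_association",
]


@dataclasses.dataclass
class WellScore:
    """One well's log-likelihood and posterior class membership under a model."""

    well_id: str
    condition: str
    loglik: float
    map_class: int
    class_posterior: np.ndarray


def score_wells(model: MixtureModel, dataset: Dataset) -> list[WellScore]:
    """Score each well by its log density and posterior class distribution.

    For the flat baseline the well posterior is the average of its
    fields' responsibilities (its loglik is still the sum over fields).
    """
    if tuple(dataset.descriptor_names) != tuple(model.descriptor_names):
        raise ValueError(
            f"descriptor mismatch: model has {model.descriptor_names}, "
            f"data has {dataset.descriptor_names}"
        )
    resp = e_step(dataset, model)
    if not model.hierarchical:
        idx = dataset.field_well_index()
        agg = np.zeros((dataset.n_wells, model.C))
        np.add.at(agg, idx, resp)
        resp = agg / agg.sum(axis=1, keepdims=True)
    out = []
    for i, w in enumerate(dataset.wells):
        post = resp[i]
        out.append(
            WellScore(
                well_id=w.well_id,
                condition=w.condition,
                loglik=well_log_density(w, model),
                map_class=int(np.argmax(post)),  # argmax takes smallest index on ties
                class_posterior=post,
            )
        )
    return out


def scores_frame(scores: list[WellScore]) -> pd.DataFrame:
    """Tidy CSV-ready table, sorted ascending by loglik (most novel first)."""
    frame = pd.DataFrame(
        {
            "well_id": [s.well_id for s in scores],
            "condition": [s.condition for s in scores],
            "loglik": [s.loglik for s in scores],
            "map_class": [s.map_class for s in scores],
        }
    )
    return frame.sort_values("loglik", kind="stable").reset_index(drop=True)


def flag_small_classes(
    scores: list[WellScore], min_fraction: float = 0.05
) -> dict[int, list[str]]:
    """Classes whose MAP-member count falls below min_fraction of all wells.

    Small classes tend to collect recurrent atypical behaviour; their
    member wells are returned for inspection as candidate experimental
    outliers.  ``min_fraction=0`` flags nothing (strict inequality).
    """
    n = len(scores)
    members: dict[int, list[str]] = {}
    for s in scores:
        members.setdefault(s.map_class, []).append(s.well_id)
    return {c: wells for c, wells in members.items() if len(wells) < min_fraction * n}


def dispersion(points: np.ndarray) -> float:
    """Multivariate dispersion of a point set: (1/m) sum_{i<j} ||p_i - p_j||^2.

    Identically equal to the sum of squared distances from the centroid,
    which is how it is computed here.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need an m x D matrix with m >= 2 points")
    centered = P - P.mean(axis=0)
    return float(np.sum(centered * centered))


def within_vs_random_dispersion(
    dataset: Dataset, n_random_groups: int = 500, seed: int = 0
) -> dict:
    """Compare dispersion of each well's own fields against random field groups.

    Sample A holds one dispersion value per well (K >= 2 fields); sample
    B holds ``n_random_groups`` dispersions of groups of the modal K
    fields drawn without replacement from the whole dataset.  Fields of
    one well share an experiment, so median(A) < median(B) whenever the
    data carry within-population coherence.  Expects scaled descriptors.
    """
    rng = np.random.default_rng(seed)
    X = dataset.field_matrix()
    ks = [w.K for w in dataset.wells if w.K >= 2]
    if not ks:
        raise ValueError("no wells with at least 2 fields")
    modal_k = int(stats.mode(np.asarray(ks), keepdims=False).mode)
    within = np.array([dispersion(w.field_matrix()) for w in dataset.wells if w.K >= 2])
    random_groups = np.array(
        [
            dispersion(X[rng.choice(X.shape[0], size=modal_k, replace=False)])
            for _ in range(n_random_groups)
        ]
    )
    return {
        "within_well": within,
        "random_groups": random_groups,
        "median_within": float(np.median(within)),
        "median_random": float(np.median(random_groups)),
        "group_size": modal_k,
    }


def _spearman_t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return float(np.finfo(float).tiny)  # below any printable floor
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_association(
    dataset: Dataset, reference: str = "cell_count", include_g0g1: bool = True
) -> pd.DataFrame:
    """Field-level Spearman association of one descriptor against the others.

    Rho uses average ranks; the two-sided p-value uses the asymptotic t
    approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom.  The derived G0/G1 proportion (1 - S - G2 - M) is included
    as an extra reporting row by default.  A constant descriptor yields
    a missing rho with the reason recorded.
    """
    names = list(dataset.descriptor_names)
    if reference not in names:
        raise ValueError(f"unknown reference descriptor {reference!r}")
    X = dataset.field_matrix()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 fields")
    ref = X[:, names.index(reference)]
    columns: list[tuple[str, np.ndarray]] = [
        (d, X[:, j]) for j, d in enumerate(names) if d != reference
    ]
    if include_g0g1:
        g0g1 = np.array([derive_g0g1(f) for w in dataset.wells for f in w.fields])
        columns.append(("prop_G0G1", g0g1))

    rows = []
    ref_ranks = stats.rankdata(ref)
    for name, col in columns:
        if np.ptp(col) == 0 or np.ptp(ref) == 0:
            rows.append({"descriptor": name, "rho": np.nan, "p_value": np.nan, "n": n,
                         "note": "constant descriptor: rho undefined"})
            continue
        rho = float(np.corrcoef(ref_ranks, stats.rankdata(col))[0, 1])
        rows.append(
            {"descriptor": name, "rho": rho, "p_value": _spearman_t_pvalue(rho, n), "n": n,
             "note": ""}
        )
    return pd.DataFrame(rows)
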