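"""Class-number selection by k-fold cross-validation over wells.

Wells (never fields) are partitioned into folds; for each candidate
number of classes the model is trained on the training folds with
several random restarts, the restart with the highest *training*
likelihood is kept (choosing by test likelihood would leak), and its
held-out log-likelihood is recorded.  The whole experiment is repeated
over independent well splits.  The selected C maximizes the mean over
repeats of the summed test log-likelihood.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset
from .mixture import FitResult, dataset_log_likelihood, fit_em

__all__ = ["CVResult", "cross_validate", "select_num_classes", "refit_selected", "derive_seed"]


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from (seed, repeat, fold, restart, ...); < 2**31."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class CVResult:
    """Tidy per-(parametrization, C, repeat, fold) cross-validation records."""

    records: pd.DataFrame
    C_range: tuple[int, ...]
    n_folds: int
    n_restarts: int
    n_repeats: int
    seed: int

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _fold_assignment(n_wells: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n_wells)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


def cross_validate(
    dataset: Dataset,
    parametrizations: Sequence[str],
    C_range: Iterable[int],
    n_folds: int = 5,
    n_restarts: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> CVResult:
    """Grid of held-out log-likelihoods over parametrizations and class counts.

    Deterministic given ``seed``: the well permutation of repeat r uses
    a child seed of (seed, r) and restart s of fold f uses a child seed
    of (seed, r, f, s).  A grid cell whose training fold cannot support
    C classes (or whose fit fails) is marked invalid rather than fatal.
    """
    C_range = tuple(sorted(set(int(c) for c in C_range)))
    if dataset.n_wells < 2 * n_folds:
        raise ValueError("need at least 2 wells per fold")
    rows = []
    for repeat in range(n_repeats):
        rng = np.random.default_rng(derive_seed(seed, repeat))
        folds = _fold_assignment(dataset.n_wells, n_folds, rng)
        for fold_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(dataset.n_wells), test_idx)
            train, test = dataset.subset(train_idx), dataset.subset(test_idx)
            for parametrization in parametrizations:
                for C in C_range:
                    row = {
                        "parametrization": parametrization,
                        "C": C,
                        "repeat": repeat,
                        "fold": fold_idx,
                        "test_loglik": np.nan,
                        "train_loglik": np.nan,
                        "best_restart_seed": -1,
                        "valid": False,
                    }
                    if train.n_wells > C:
                        best: FitResult | None = None
                        for restart in range(n_restarts):
                            rs = derive_seed(seed, repeat, fold_idx, restart)
                            try:
                                fit = fit_em(train, C, parametrization, seed=rs, tol=tol, max_iter=max_iter)
                            except (RuntimeError, FloatingPointError, np.linalg.LinAlgError):
                                continue
                            if best is None or fit.loglik > best.loglik:
                                best = fit
                        if best is not None:
                            row.update(
                                test_loglik=dataset_log_likelihood(test, best.model),
                                train_loglik=best.loglik,
                                best_restart_seed=best.seed,
                                valid=True,
                            )
                    rows.append(row)
    return CVResult(pd.DataFrame(rows), C_range, n_folds, n_restarts, n_repeats, seed)


def select_num_classes(cv: CVResult, parametrization: str) -> int:
    """C maximizing the mean over repeats of summed test log-likelihood.

    Repeats with any invalid fold at a given C are excluded for that C;
    exact ties go to the smallest C.
    """
    rec = cv.records
    rec = rec[(rec["parametrization"] == parametrization) & rec["valid"]]
    if rec.empty:
        raise ValueError(f"no valid cross-validation records for {parametrization!r}")
    # only keep (C, repeat) cells with a full set of folds
    counts = rec.groupby(["C", "repeat"])["fold"].count()
    complete = counts[counts == cv.n_folds].reset_index()[["C", "repeat"]]
    rec = rec.merge(complete, on=["C", "repeat"])
    if rec.empty:
        raise ValueError(f"no complete repeats for {parametrization!r}")
    summed = rec.groupby(["C", "repeat"])["test_loglik"].sum()
    score = summed.groupby("C").mean()
    best = score.max()
    return int(min(c for c, s in score.items() if s == best))


def refit_selected(
    dataset: Dataset,
    cv: CVResult,
    parametrization: str,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FitResult:
    """Refit the selected C on all wells, keeping the best of n_restarts fits."""
    C = select_num_classes(cv, parametrization)
    best: FitResult | None = None
    for restart in range(n_restarts):
        rs = derive_seed(seed, C, restart)
        fit = fit_em(dataset, C, parametrization, seed=rs, tol=tol, max_iter=max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best
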