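"""Generative sampler and scenario presets for synthetic screening data.

The model is generative: to create a well, first draw its population
phenotype Z ~ Multinomial(pi), then draw its K fields independently
from the class-conditional density.  Copula classes are sampled through
the Gaussian latent representation (z ~ N(0, R), u = Phi(z),
x_d = F_d^{-1}(u_d)); Gaussian classes are sampled directly and clipped
into the descriptor supports.

Presets emulate the plate layout the model was designed for: two
conditions (GL2 negative / KIF11 positive control), 336 wells per
condition, 4 fields per well, with a correlated three-class negative
control mixture and a cell-death positive contrast.  Their parameters
are frozen in ``presets/presets.yaml``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources

import numpy as np
import yaml
from scipy import special

from .copula import CopulaClassParams, MarginalParams, marginal_ppf, project_to_correlation
from .data import DEFAULT_DESCRIPTORS, Dataset, FieldRecord, WellData, write_field_table
from .mixture import GaussianClassParams, MixtureModel

__all__ = ["Scenario", "sample_model", "make_scenario", "write_scenario", "PRESET_NAMES"]

PRESET_NAMES = ("paper_layout", "negative_like", "positive_contrast", "with_outliers")

PROP_CLIP = 1e-6


def _load_presets() -> dict:
    ref = importlib.resources.files("wellmix") / "presets" / "presets.yaml"
    return yaml.safe_load(ref.read_text())


@dataclasses.dataclass
class Scenario:
    """A named synthetic study: true models per condition + plate layout."""

    name: str
    true_models: dict[str, MixtureModel]
    n_wells: int
    K: int
    conditions: tuple[str, ...]
    outlier_fraction: float = 0.0
    outlier_class: CopulaClassParams | None = None

    def to_yaml(self) -> str:
        obj = {
            "name": self.name,
            "n_wells": self.n_wells,
            "K": self.K,
            "conditions": list(self.conditions),
            "outlier_fraction": self.outlier_fraction,
            "true_models": {c: m.to_json() for c, m in self.true_models.items()},
        }
        return yaml.safe_dump(obj, sort_keys=False)


def _sample_class_fields(params, K: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(params, CopulaClassParams):
        L = np.linalg.cholesky(params.R)
        z = rng.standard_normal((K, params.D)) @ L.T
        u = special.ndtr(z)
        X = np.column_stack([marginal_ppf(u[:, d], m) for d, m in enumerate(params.marginals)])
        X[:, 0] = np.maximum(X[:, 0], 1e-6)
        X[:, 1:] = np.clip(X[:, 1:], PROP_CLIP, 1 - PROP_CLIP)
        return X
    if isinstance(params, GaussianClassParams):
        L = np.linalg.cholesky(params.covariance)
        X = params.mean + rng.standard_normal((K, params.D)) @ L.T
        # keep samples inside the descriptor supports
        X[:, 0] = np.maximum(X[:, 0], 0.5)
        X[:, 1:] = np.clip(X[:, 1:], PROP_CLIP, 1 - PROP_CLIP)
        return X
    raise ValueError(f"cannot sample from class of type {type(params).__name__}")


def sample_model(
    model: MixtureModel,
    n_wells: int,
    K: int,
    seed: int,
    condition: str = "sim",
    well_prefix: str = "w",
) -> tuple[Dataset, np.ndarray]:
    """Draw a dataset from the two-step generative process.

    Returns the dataset together with the true per-well class labels for
    recovery tests.  Fully reproducible given ``seed``.
    """
    if n_wells < 1 or K < 1:
        raise ValueError("n_wells and K must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(model.C, size=n_wells, p=model.pi)
    wells = []
    width = len(str(n_wells))
    for i, z in enumerate(labels):
        X = _sample_class_fields(model.classes[z], K, rng)
        well_id = f"{well_prefix}{i:0{width}d}"
        fields = [
            FieldRecord(
                condition=condition,
                well_id=well_id,
                field_index=k,
                cell_count=float(X[k, 0]),
                proportions=X[k, 1:],
                proportion_names=tuple(model.descriptor_names[1:]),
            )
            for k in range(K)
        ]
        wells.append(WellData(well_id, condition, fields))
    return Dataset(wells, model.descriptor_names), labels


def _class_from_config(cfg: dict) -> tuple[MarginalParams, ...]:
    return tuple(
        MarginalParams(cfg[name][0], float(cfg[name][1]), float(cfg[name][2]))
        for name in DEFAULT_DESCRIPTORS
    )


def negative_control_model() -> MixtureModel:
    """The frozen three-class copula mixture emulating negative controls."""
    cfg = _load_presets()
    neg = cfg["negative_like"]
    R = project_to_correlation(np.asarray(neg["correlation"], dtype=float))
    classes = [CopulaClassParams(R, _class_from_config(c)) for c in neg["classes"]]
    return MixtureModel(np.asarray(neg["pi"], dtype=float), classes, "copula", DEFAULT_DESCRIPTORS)


def positive_control_model() -> MixtureModel:
    """Cell-death contrast: count mean / 5 and apoptotic mean x 5 per class."""
    cfg = _load_presets()
    pos = cfg["positive_contrast"]
    base = negative_control_model()
    rate_f = float(pos["count_rate_factor"])
    apo_f = float(pos["apoptosis_mean_factor"])
    apo_idx = DEFAULT_DESCRIPTORS.index("prop_apoptotic")
    classes = []
    for cls in base.classes:
        marg = list(cls.marginals)
        count = marg[0]
        marg[0] = MarginalParams("gamma", count.param1, count.param2 * rate_f)
        apo = marg[apo_idx]
        new_mean = min(apo_f * apo.mean, 0.8)
        # keep b, rescale a to hit the shifted mean
        marg[apo_idx] = MarginalParams("beta", apo.param2 * new_mean / (1 - new_mean), apo.param2)
        classes.append(CopulaClassParams(cls.R, tuple(marg)))
    return MixtureModel(base.pi, classes, "copula", DEFAULT_DESCRIPTORS)


def make_scenario(
    name: str, seed: int, n_wells: int | None = None, K: int | None = None
) -> tuple[Dataset, Scenario, np.ndarray]:
    """Build a preset synthetic study: (dataset, scenario, true labels).

    Presets: ``negative_like`` (three-class negative-control mixture),
    ``positive_contrast`` (cell-death shift of every class),
    ``paper_layout`` (both conditions at the full plate layout:
    2 x 336 wells x 4 fields = 2688 fields) and ``with_outliers``
    (negative-like with 5% of wells drawn from a shifted outlier class).
    Labels for ``with_outliers`` mark outlier wells with class index C.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
    cfg = _load_presets()
    layout = cfg["layout"]
    n_wells = int(n_wells if n_wells is not None else layout["n_wells_per_condition"])
    K = int(K if K is not None else layout["fields_per_well"])
    neg_cond = layout["negative_condition"]
    pos_cond = layout["positive_condition"]
    neg_model = negative_control_model()

    if name == "negative_like":
        data, labels = sample_model(neg_model, n_wells, K, seed, condition=neg_cond, well_prefix="GL2_")
        scen = Scenario(name, {neg_cond: neg_model}, n_wells, K, (neg_cond,))
        return data, scen, labels

    if name == "positive_contrast":
        pos_model = positive_control_model()
        data, labels = sample_model(pos_model, n_wells, K, seed, condition=pos_cond, well_prefix="KIF11_")
        scen = Scenario(name, {pos_cond: pos_model}, n_wells, K, (pos_cond,))
        return data, scen, labels

    if name == "paper_layout":
        pos_model = positive_control_model()
        neg_data, neg_labels = sample_model(
            neg_model, n_wells, K, seed, condition=neg_cond, well_prefix="GL2_"
        )
        pos_data, pos_labels = sample_model(
            pos_model, n_wells, K, seed + 1, condition=pos_cond, well_prefix="KIF11_"
        )
        data = Dataset(neg_data.wells + pos_data.wells, DEFAULT_DESCRIPTORS)
        scen = Scenario(
            name, {neg_cond: neg_model, pos_cond: pos_model}, n_wells, K, (neg_cond, pos_cond)
        )
        return data, scen, np.concatenate([neg_labels, pos_labels])

    # with_outliers
    out_cfg = cfg["with_outliers"]
    fraction = float(out_cfg["fraction"])
    outlier = CopulaClassParams(
        neg_model.classes[0].R, _class_from_config(out_cfg["outlier_class"])
    )
    data, labels = sample_model(neg_model, n_wells, K, seed, condition=neg_cond, well_prefix="GL2_")
    rng = np.random.default_rng(seed + 10_000)
    # floor, not round: an injected count at or above the small-class flag
    # cutoff (strict <) would make the outlier class unflaggable by design
    n_out = max(1, int(fraction * n_wells))
    out_idx = rng.choice(n_wells, size=n_out, replace=False)
    labels = labels.copy()
    for i in out_idx:
        X = _sample_class_fields(outlier, K, rng)
        old = data.wells[i]
        fields = [
            FieldRecord(
                condition=old.condition,
                well_id=old.well_id,
                field_index=k,
                cell_count=float(X[k, 0]),
                proportions=X[k, 1:],
                proportion_names=tuple(DEFAULT_DESCRIPTORS[1:]),
            )
            for k in range(K)
        ]
        data.wells[i] = WellData(old.well_id, old.condition, fields)
        labels[i] = neg_model.C
    scen = Scenario(
        name,
        {neg_cond: neg_model},
        n_wells,
        K,
        (neg_cond,),
        outlier_fraction=fraction,
        outlier_class=outlier,
    )
    return data, scen, labels


def write_scenario(directory, dataset: Dataset, scenario: Scenario, labels: np.ndarray) -> None:
    """Emit the standard field-table CSV, scenario YAML and truth-label sidecar."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_field_table(dataset, directory / "fields.csv")
    (directory / "scenario.yaml").write_text(scenario.to_yaml())
    import pandas as pd

    pd.DataFrame(
        {"well_id": [w.well_id for w in dataset.wells], "true_class": labels}
    ).to_csv(directory / "labels.csv", index=False)
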