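"""Neural-network blood-pressure-stage classification and ablation importance.

A fully connected classifier predicts the blood-pressure stage from clinical
risk factors (age, weight, BMI, eGFR) with or without metabolite features.
Feature importance is measured by leave-one-feature-out ablation: the model
is retrained without each feature on the same train/test split and seed
schedule, and the importance of the feature is the drop in held-out accuracy
(a drop means positive importance; an accuracy INCREASE after removal is a
legitimate outcome and means negative importance).

Because small networks on tabular data are noise-dominated, deltas are
averaged over several seeds and reported with their across-seed SD. The
network itself is scikit-learn's multilayer perceptron; with a fixed seed
and single-threaded training the whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import OneHotEncoder, StandardScaler

__all__ = ["NetSpec", "ImportanceReport", "preprocess", "train_classifier",
           "ablation_importance", "accuracy_curve"]


@dataclass
class NetSpec:
    """Architecture and training protocol of the stage classifier."""

    features: tuple[str, ...]
    outcome: str = "bp_code4"
    hidden_layers: tuple[int, ...] = (32, 16)
    activation: str = "relu"
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    split_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if len(self.features) < 1:
            raise ValueError("need at least one input feature")


@dataclass
class ImportanceReport:
    """Baseline accuracy and per-feature ablation deltas (mean ± SD over seeds)."""

    baseline_accuracy: float
    baseline_sd: float
    deltas: pd.DataFrame  # columns: feature, delta_mean, delta_sd
    seeds: tuple[int, ...] = field(default_factory=tuple)


def preprocess(
    data: pd.DataFrame,
    spec: NetSpec,
    train_index: pd.Index | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardize inputs and one-hot encode the staged outcome.

    Standardization statistics come from ``train_index`` rows only (all rows
    if None), so applying them to held-out samples leaks nothing.
    Zero-variance features (on the training rows) are dropped with a warning.
    Returns (X standardized, Y one-hot, kept feature names).
    """
    import warnings

    missing = [f for f in spec.features if f not in data.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if spec.outcome not in data.columns:
        raise ValueError(f"missing outcome column {spec.outcome!r}")
    train = data if train_index is None else data.loc[train_index]
    kept = []
    for f in spec.features:
        if np.isclose(train[f].std(), 0):
            warnings.warn(f"dropping zero-variance feature {f!r}")
        else:
            kept.append(f)
    if not kept:
        raise ValueError("all features have zero variance on the training rows")
    scaler = StandardScaler().fit(train[kept])
    X = scaler.transform(data[kept])
    encoder = OneHotEncoder(sparse_output=False).fit(train[[spec.outcome]])
    Y = encoder.transform(data[[spec.outcome]])
    return X, Y, kept


def _fit_once(data: pd.DataFrame, spec: NetSpec, seed: int) -> float:
    """One stratified split + fit; returns held-out accuracy."""
    y = data[spec.outcome].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples for a stratified split")
    idx_train, idx_test = train_test_split(
        data.index,
        test_size=spec.split_fraction,
        random_state=seed,
        stratify=y,
    )
    X, _, _ = preprocess(data, spec, train_index=idx_train)
    loc = data.index.get_indexer
    X_train, X_test = X[loc(idx_train)], X[loc(idx_test)]
    y_train, y_test = data.loc[idx_train, spec.outcome], data.loc[idx_test, spec.outcome]
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layers,
        activation=spec.activation,
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=spec.batch_size,
        max_iter=spec.epochs,
        random_state=seed,
        tol=1e-5,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # non-convergence within the epoch budget is reported as-is
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_train, y_train)
    return float((clf.predict(X_test) == y_test.to_numpy()).mean())


def train_classifier(data: pd.DataFrame, spec: NetSpec) -> float:
    """Train once with the spec's seed; returns held-out accuracy."""
    return _fit_once(data, spec, spec.seed)


def _seed_schedule(spec: NetSpec, n_seeds: int) -> tuple[int, ...]:
    return tuple(int(s) for s in np.random.SeedSequence(spec.seed).generate_state(n_seeds) % (2**31))


def ablation_importance(
    data: pd.DataFrame,
    spec: NetSpec,
    features_to_test: Sequence[str] | None = None,
    n_seeds: int = 10,
) -> ImportanceReport:
    """Leave-one-feature-out importance over a schedule of seeds.

    For each feature, the network is retrained without it on the same
    split/seed schedule as the baseline; delta = baseline accuracy − ablated
    accuracy. Raises if ablation would leave no input feature.
    """
    if len(spec.features) < 2:
        raise ValueError("ablation needs at least 2 input features")
    features_to_test = list(features_to_test or spec.features)
    unknown = [f for f in features_to_test if f not in spec.features]
    if unknown:
        raise ValueError(f"not inputs of the model: {unknown}")
    seeds = _seed_schedule(spec, n_seeds)
    baseline = np.array([_fit_once(data, spec, s) for s in seeds])
    rows = []
    for f in features_to_test:
        ablated_spec = replace(spec, features=tuple(x for x in spec.features if x != f))
        ablated = np.array([_fit_once(data, ablated_spec, s) for s in seeds])
        delta = baseline - ablated
        sd = float(delta.std(ddof=1)) if delta.size > 1 else float("nan")
        rows.append({"feature": f, "delta_mean": delta.mean(), "delta_sd": sd})
    return ImportanceReport(
        baseline_accuracy=float(baseline.mean()),
        baseline_sd=float(baseline.std(ddof=1)) if baseline.size > 1 else float("nan"),
        deltas=pd.DataFrame(rows),
        seeds=seeds,
    )


def accuracy_curve(
    data: pd.DataFrame,
    spec: NetSpec,
    ranked_metabolites: Sequence[str],
    n_seeds: int = 10,
) -> pd.DataFrame:
    """Held-out accuracy of nested models: covariates only, then adding
    metabolites one at a time in association-rank order.

    ``spec.features`` are the baseline covariates. Returns a table with one
    row per nested model (n_metabolites, accuracy_mean, accuracy_sd).
    """
    seeds = _seed_schedule(spec, n_seeds)
    rows = []
    for k in range(len(ranked_metabolites) + 1):
        feats = tuple(spec.features) + tuple(ranked_metabolites[:k])
        spec_k = replace(spec, features=feats)
        acc = np.array([_fit_once(data, spec_k, s) for s in seeds])
        rows.append(
            {"n_metabolites": k, "accuracy_mean": acc.mean(),
             "accuracy_sd": float(acc.std(ddof=1)) if acc.size > 1 else float("nan")}
        )
    return pd.DataFrame(rows)
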