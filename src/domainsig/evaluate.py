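"""Stratified cross-validated classification of samples from signatures.

Four general-purpose classifiers (k-nearest neighbors, RBF support vector
machine, a single-hidden-layer neural network, random forest) are trained
on the log-CPM of a signature's genes under repeated stratified k-fold
cross-validation; the reported score is the percentage of misclassified
samples pooled over the folds of one repeat. Feature standardization is
fitted on training folds only, so no test-fold information leaks into the
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .coexpression import log_cpm
from .datasets import CountDataset
from .errors import InputError, InsufficientDataError
from .signatures import Signature

CLASSIFIER_KINDS = ("knn", "svm", "neural_net", "random_forest")

#: hyperparameter defaults, all overridable through ClassifierSpec
DEFAULT_HYPERPARAMETERS = {
    "knn": {"n_neighbors": 3},
    "svm": {"C": 1.0, "kernel": "rbf", "gamma": "auto"},  # gamma = 1 / n_features
    "neural_net": {"hidden_layer_sizes": (8,), "max_iter": 500},
    "random_forest": {"n_estimators": 500, "max_features": "sqrt"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration: kind, hyperparameter overrides, seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise InputError(f"unknown classifier kind {self.kind!r}")
        unknown = set(self.hyperparameters) - set(DEFAULT_HYPERPARAMETERS[self.kind])
        if unknown:
            raise InputError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")

    def make_estimator(self):
        params = {**DEFAULT_HYPERPARAMETERS[self.kind], **self.hyperparameters}
        if self.kind == "knn":
            return KNeighborsClassifier(**params)
        if self.kind == "svm":
            return SVC(**params, random_state=self.seed)
        if self.kind == "neural_net":
            return MLPClassifier(**params, random_state=self.seed)
        return RandomForestClassifier(**params, random_state=self.seed)


@dataclass
class EvaluationResult:
    """Long-format misclassification table plus a per-cell summary."""

    rows: pd.DataFrame  # classifier, origin, repeat, percent_misclassified, fold_seed

    @property
    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of the misclassification percentage
        per (classifier, signature origin) cell."""
        if self.rows.empty:
            return pd.DataFrame(columns=["classifier", "origin", "mean_pct", "sd_pct", "n_repeats"])
        g = self.rows.groupby(["classifier", "origin"])["percent_misclassified"]
        out = g.agg(mean_pct="mean", sd_pct="std", n_repeats="count").reset_index()
        return out.sort_values(["classifier", "origin"], kind="mergesort").reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path) -> "EvaluationResult":
        return cls(pd.read_csv(path, sep="\t"))


def _feature_matrix(counts: CountDataset, signature: Signature) -> np.ndarray:
    missing = [g for g in signature.gene_ids if g not in counts.counts.index]
    if missing:
        raise InputError(f"signature genes absent from counts: {missing[:5]}")
    logm = log_cpm(counts)
    return logm.loc[signature.gene_ids].to_numpy().T  # samples x genes


def cross_validate(
    counts: CountDataset,
    signature: Signature,
    spec: ClassifierSpec,
    k: int = 5,
    n_repeats: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Repeated stratified k-fold CV of one classifier on one signature.

    Each repeat draws a fresh fold assignment from ``rng``; within a fold,
    features are standardized with training-fold statistics and the
    misclassified test samples are pooled across the k folds into one
    percentage. Returns the long-format rows (one per repeat).
    """
    if signature.is_empty:
        raise InsufficientDataError("cannot cross-validate an empty signature")
    rng = np.random.default_rng() if rng is None else rng
    y = counts.classes.to_numpy()
    class_counts = pd.Series(y).value_counts()
    if class_counts.min() < k:
        raise InputError(
            f"smallest class has {class_counts.min()} samples < k={k}; use a smaller k"
        )
    X = _feature_matrix(counts, signature)
    n = len(y)
    records = []
    for rep in range(n_repeats):
        fold_seed = int(rng.integers(2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        errors = 0
        for train_idx, test_idx in skf.split(X, y):
            scaler = StandardScaler().fit(X[train_idx])
            clf = spec.make_estimator()
            clf.fit(scaler.transform(X[train_idx]), y[train_idx])
            pred = clf.predict(scaler.transform(X[test_idx]))
            errors += int((pred != y[test_idx]).sum())
        records.append(
            {
                "classifier": spec.kind,
                "origin": signature.origin,
                "repeat": rep,
                "percent_misclassified": 100.0 * errors / n,
                "fold_seed": fold_seed,
            }
        )
    return pd.DataFrame.from_records(records)


def evaluate_all(
    counts: CountDataset,
    signatures: Sequence[Signature],
    specs: Sequence[ClassifierSpec],
    k: int = 5,
    n_repeats: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> EvaluationResult:
    """Full factorial classifier x signature x repeat evaluation."""
    rng = np.random.default_rng() if rng is None else rng
    frames = []
    for sig in signatures:
        for spec in specs:
            frames.append(cross_validate(counts, sig, spec, k=k, n_repeats=n_repeats, rng=rng))
    if not frames:
        return EvaluationResult(
            pd.DataFrame(
                columns=["classifier", "origin", "repeat", "percent_misclassified", "fold_seed"]
            )
        )
    return EvaluationResult(pd.concat(frames, ignore_index=True))
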