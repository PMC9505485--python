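"""Workload classification: model families, tuning protocol, and fusion.

Protocol: a stratified 80/20 train/test split per seed; classical families
(k-NN with k in [1, 30], naive Bayes over its event models, random forest
with 1-50 trees, SVM over linear/polynomial/RBF/sigmoid kernels) are tuned
by stratified 5-fold cross-validation on the training set, re-fit on all
training data, and scored on the held-out test set. The fully connected
network is tuned on a fixed stratified validation split of the training set
(no cross-validation) over a learning-rate x batch-size grid with the Adam
optimizer. Each benchmark cell is repeated over several seeds (split and
initialization both follow the seed) and reported as mean -/+ SD accuracy
in percent.

Feature standardization is always fit on training data only (inside each CV
fold during tuning), so no test-set statistics leak into model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import (BernoulliNB, CategoricalNB, ComplementNB,
                                 GaussianNB, MultinomialNB)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import KBinsDiscretizer, MinMaxScaler, StandardScaler
from sklearn.svm import SVC

from .core import FeatureTable

TASKS = ("0-1", "0-2", "1-2")

# network widths per modality: (T2, T3, T4) hidden layers; the input layer
# width is set by the feature vector itself
MLP_HIDDEN = {
    "eeg": (1024, 512, 64),
    "pcps": (256, 128, 128),
    "default": (32, 16, 16),
}
MLP_LR_GRID = (1e-5, 5e-5, 1e-4, 5e-4)
MLP_BATCH_GRID = (32, 64, 128, 256)
MLP_EPOCHS = 300

#: plug-in point for external time-series classifiers (e.g. convolutional or
#: recurrent architectures operating on the raw traces). Register a factory
#: ``name -> callable(seed) -> estimator`` with fit(X, y)/score(X, y); the
#: benchmark will treat it as an additional model family.
TIMESERIES_MODELS: dict = {}


def register_timeseries_model(name: str, factory) -> None:
    TIMESERIES_MODELS[name] = factory


@dataclass
class ModelSpec:
    """A model family plus its hyper-parameter grid."""

    family: str  # knn | nb | rf | svm | mlp
    grid: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class ModelResult:
    task: str
    modality: str
    family: str
    chosen: list
    accuracies_pct: list  # per-seed test accuracy, %

    @property
    def mean_pct(self) -> float:
        return float(np.mean(self.accuracies_pct))

    @property
    def sd_pct(self) -> float:
        if len(self.accuracies_pct) < 2:
            return 0.0
        return float(np.std(self.accuracies_pct, ddof=1))


def split_dataset(table: FeatureTable, seed: int, test_fraction: float = 0.2
                  ) -> tuple[FeatureTable, FeatureTable]:
    """Stratified 80/20 split, deterministic per seed."""
    if len(np.unique(table.labels)) < 2:
        raise ValueError("cannot stratify a single-class table")
    idx = np.arange(len(table))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=table.labels)
    return table.select(np.sort(tr)), table.select(np.sort(te))


# ---------------------------------------------------------------------------
# Candidate construction


def _default_grid(family: str) -> dict:
    if family == "knn":
        return {"k": list(range(1, 31))}
    if family == "nb":
        return {"variant": ["gaussian", "bernoulli", "multinomial",
                            "complement", "categorical"]}
    if family == "rf":
        return {"n_trees": list(range(1, 51))}
    if family == "svm":
        return {"kernel": ["linear", "poly", "rbf", "sigmoid"]}
    if family == "mlp":
        return {"lr": list(MLP_LR_GRID), "batch": list(MLP_BATCH_GRID)}
    raise ValueError(f"unknown model family {family!r}")


def _candidates(spec: ModelSpec) -> list[tuple[tuple, Pipeline]]:
    """Ordered (simplest first) list of (params, pipeline) candidates."""
    grid = {**_default_grid(spec.family), **spec.grid}
    fam = spec.family
    out: list[tuple[tuple, Pipeline]] = []
    if fam == "knn":
        for k in grid["k"]:
            out.append(((("k", k),), Pipeline([
                ("scale", StandardScaler()),
                ("clf", KNeighborsClassifier(n_neighbors=k))])))
    elif fam == "nb":
        builders = {
            "gaussian": lambda: Pipeline([("scale", StandardScaler()),
                                          ("clf", GaussianNB())]),
            "bernoulli": lambda: Pipeline([("scale", StandardScaler()),
                                           ("clf", BernoulliNB())]),
            "multinomial": lambda: Pipeline([("scale", MinMaxScaler()),
                                             ("clf", MultinomialNB())]),
            "complement": lambda: Pipeline([("scale", MinMaxScaler()),
                                            ("clf", ComplementNB())]),
            "categorical": lambda: Pipeline([
                ("scale", KBinsDiscretizer(n_bins=8, encode="ordinal",
                                           strategy="uniform")),
                ("clf", CategoricalNB(min_categories=8))]),
        }
        for variant in grid["variant"]:
            out.append(((("variant", variant),), builders[variant]()))
    elif fam == "rf":
        for n in grid["n_trees"]:
            out.append(((("n_trees", n),), Pipeline([
                ("scale", StandardScaler()),
                ("clf", RandomForestClassifier(n_estimators=n,
                                               random_state=spec.seed))])))
    elif fam == "svm":
        for kernel in grid["kernel"]:
            out.append(((("kernel", kernel),), Pipeline([
                ("scale", StandardScaler()),
                ("clf", SVC(kernel=kernel, random_state=spec.seed))])))
    elif fam == "mlp":
        hidden = grid.get("hidden", MLP_HIDDEN["default"])
        epochs = grid.get("epochs", MLP_EPOCHS)
        for lr in grid["lr"]:
            for batch in grid["batch"]:
                out.append(((("lr", lr), ("batch", batch)), Pipeline([
                    ("scale", StandardScaler()),
                    ("clf", _make_mlp(hidden, lr, batch, epochs, spec.seed))])))
    return out


def _make_mlp(hidden: Sequence[int], lr: float, batch: int, epochs: int,
              seed: int) -> MLPClassifier:
    return MLPClassifier(hidden_layer_sizes=tuple(hidden), activation="relu",
                         solver="adam", learning_rate_init=lr,
                         batch_size=batch, max_iter=epochs, alpha=1e-4,
                         random_state=seed, early_stopping=False,
                         n_iter_no_change=epochs)


# ---------------------------------------------------------------------------
# Tuning


def tune_classical(spec: ModelSpec, train: FeatureTable, n_folds: int = 5
                   ) -> tuple[list, Pipeline]:
    """Grid search with stratified 5-fold CV on the training set.

    Candidates are scored by mean validation accuracy across folds; ties go
    to the earlier (simpler) candidate. The winner is re-fit on all training
    data. Standardization is fit inside each fold, never on validation data.
    """
    X, y = train.X(), train.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows; cannot stratify "
            f"{n_folds}-fold CV — reduce folds or supply more data")
    candidates = _candidates(spec)
    if len(candidates) == 1:
        params, pipe = candidates[0]
        pipe.fit(X, y)
        return list(params), pipe

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))
    best_score, best_idx = -1.0, None
    for idx, (params, pipe) in enumerate(candidates):
        scores = []
        try:
            for tr_idx, va_idx in folds:
                model = clone(pipe)
                model.fit(X[tr_idx], y[tr_idx])
                scores.append(model.score(X[va_idx], y[va_idx]))
        except ValueError:
            continue  # infeasible candidate (e.g. k exceeds fold size)
        mean_score = float(np.mean(scores))
        if mean_score > best_score + 1e-12:
            best_score, best_idx = mean_score, idx
    if best_idx is None:
        raise ValueError("no feasible hyper-parameter candidate for this dataset")
    params, pipe = candidates[best_idx]
    final = clone(pipe)
    final.fit(X, y)
    return list(params), final


def train_mlp(train: FeatureTable, modality: str = "default", seed: int = 0,
              val_fraction: float = 0.2, lr_grid: Sequence[float] = MLP_LR_GRID,
              batch_grid: Sequence[int] = MLP_BATCH_GRID,
              epochs: int = MLP_EPOCHS,
              hidden: Sequence[int] | None = None) -> tuple[list, Pipeline]:
    """Tune and fit the fully connected network for one modality.

    The (learning rate, batch size) grid is scored on a fixed stratified
    validation split of the training data — no cross-validation — and the
    winner is re-fit on the full training set. Adam optimization throughout;
    the seed fixes the split and the weight initialization.
    """
    if hidden is None:
        hidden = MLP_HIDDEN.get(modality, MLP_HIDDEN["default"])
    spec = ModelSpec("mlp", grid={"lr": list(lr_grid), "batch": list(batch_grid),
                                  "hidden": tuple(hidden), "epochs": epochs},
                     seed=seed)
    X, y = train.X(), train.labels
    idx = np.arange(len(y))
    fit_idx, val_idx = train_test_split(idx, test_size=val_fraction,
                                        random_state=seed, stratify=y)
    candidates = _candidates(spec)
    best_score, best_idx = -1.0, 0
    for i, (params, pipe) in enumerate(candidates):
        model = clone(pipe)
        model.fit(X[fit_idx], y[fit_idx])
        score = model.score(X[val_idx], y[val_idx])
        if score > best_score + 1e-12:
            best_score, best_idx = score, i
    params, pipe = candidates[best_idx]
    final = clone(pipe)
    final.fit(X, y)
    return list(params), final


# ---------------------------------------------------------------------------
# Fusion


def fuse_feature_level(pupil: FeatureTable, eeg: FeatureTable) -> FeatureTable:
    """Row-aligned concatenation of handcrafted features from two modalities.

    With the 2-d pupil (mean, variance) features and the 32-d EEG band-power
    vector this yields the 34-column fused table.

    Raises
    ------
    ValueError
        On mismatched row counts or label disagreement.
    """
    if len(pupil) != len(eeg):
        raise ValueError(f"row counts differ: {len(pupil)} vs {len(eeg)}")
    if not np.array_equal(pupil.labels, eeg.labels):
        raise ValueError("label sequences differ between modalities")
    left, right = pupil.data.copy(), eeg.data.copy()
    clash = set(left.columns) & set(right.columns)
    if clash:
        left = left.rename(columns={c: f"pupil_{c}" for c in clash})
        right = right.rename(columns={c: f"eeg_{c}" for c in clash})
    data = pd.concat([left.reset_index(drop=True), right.reset_index(drop=True)],
                     axis=1)
    return FeatureTable(data, pupil.labels.copy(),
                        {"fusion": "feature-level",
                         "modalities": ["pupil", "eeg"]})


class DataLevelFusion:
    """Two per-modality networks feeding a third fusion network.

    Each modality's network is trained on its own representation; its last
    hidden layer's activations are then frozen as a learned embedding, the
    two embeddings concatenated, and a small head network (32, 16, 16)
    trained on the concatenation. Training is stage-wise (per-modality
    networks first, head second), all stages seeded.

    The per-modality networks are fit on one stratified part of the training
    data and the head on the embeddings of the remaining part: a network can
    memorize its own training rows, so embeddings of those rows would
    overstate an uninformative modality and mislead the head. The held-out
    part gives the head an honest view of what each embedding carries, in
    the same coordinate basis used at prediction time.
    """

    def __init__(self, pupil_hidden: Sequence[int] = MLP_HIDDEN["pcps"],
                 eeg_hidden: Sequence[int] = MLP_HIDDEN["eeg"],
                 head_hidden: Sequence[int] = MLP_HIDDEN["default"],
                 lr: float = 5e-4, batch: int = 64, epochs: int = MLP_EPOCHS,
                 head_fraction: float = 0.4, head_alpha: float = 1.0,
                 seed: int = 0):
        self.pupil_hidden = tuple(pupil_hidden)
        self.eeg_hidden = tuple(eeg_hidden)
        self.head_hidden = tuple(head_hidden)
        self.lr, self.batch, self.epochs, self.seed = lr, batch, epochs, seed
        self.head_fraction = head_fraction
        # the head sees high-dimensional learned embeddings from few rows;
        # a stiff weight penalty keeps it from chasing uninformative ones
        self.head_alpha = head_alpha

    def fit(self, X_pupil: np.ndarray, X_eeg: np.ndarray, y: np.ndarray
            ) -> "DataLevelFusion":
        idx = np.arange(len(y))
        net_idx, head_idx = train_test_split(idx, test_size=self.head_fraction,
                                             random_state=self.seed, stratify=y)
        self.scale_p_ = StandardScaler().fit(X_pupil[net_idx])
        self.scale_e_ = StandardScaler().fit(X_eeg[net_idx])
        self.net_p_ = _make_mlp(self.pupil_hidden, self.lr, self.batch,
                                self.epochs, self.seed)
        self.net_e_ = _make_mlp(self.eeg_hidden, self.lr, self.batch,
                                self.epochs, self.seed + 1)
        self.net_p_.fit(self.scale_p_.transform(X_pupil[net_idx]), y[net_idx])
        self.net_e_.fit(self.scale_e_.transform(X_eeg[net_idx]), y[net_idx])
        Z = self._embed(X_pupil[head_idx], X_eeg[head_idx])
        self.scale_z_ = StandardScaler().fit(Z)
        self.head_ = _make_mlp(self.head_hidden, self.lr, self.batch,
                               self.epochs, self.seed + 2)
        self.head_.set_params(alpha=self.head_alpha)
        self.head_.fit(self.scale_z_.transform(Z), y[head_idx])
        return self

    def _embed(self, X_pupil: np.ndarray, X_eeg: np.ndarray) -> np.ndarray:
        zp = _hidden_activations(self.net_p_, self.scale_p_.transform(X_pupil))
        ze = _hidden_activations(self.net_e_, self.scale_e_.transform(X_eeg))
        return np.hstack([zp, ze])

    def predict(self, X_pupil: np.ndarray, X_eeg: np.ndarray) -> np.ndarray:
        Z = self._embed(X_pupil, X_eeg)
        return self.head_.predict(self.scale_z_.transform(Z))

    def score(self, X_pupil: np.ndarray, X_eeg: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X_pupil, X_eeg) == y))


def _hidden_activations(net: MLPClassifier, X: np.ndarray) -> np.ndarray:
    """Forward pass up to (and including) the last hidden ReLU layer."""
    a = X
    for W, b in zip(net.coefs_[:-1], net.intercepts_[:-1]):
        a = np.maximum(a @ W + b, 0.0)
    return a


# ---------------------------------------------------------------------------
# Benchmark


def run_benchmark(tables: dict[str, FeatureTable],
                  tasks: Sequence[str] = TASKS,
                  modalities: Sequence[str] | None = None,
                  families: Sequence[str] = ("knn", "nb", "rf", "svm", "mlp"),
                  n_seeds: int = 5, master_seed: int = 0,
                  grids: dict | None = None,
                  mlp_kwargs: dict | None = None) -> pd.DataFrame:
    """Full task x modality x model cross, repeated over seeds.

    ``tables`` maps a modality tag (pcps, eeg, fix, hrv, bpv, pcps+eeg, ...)
    to its three-level feature table. Each cell reports mean and SD test
    accuracy (%) over ``n_seeds`` repeats; the per-repeat seed governs the
    80/20 split, CV folds, and model initialization.
    """
    if modalities is None:
        modalities = list(tables)
    grids = grids or {}
    mlp_kwargs = mlp_kwargs or {}
    rows = []
    for task in tasks:
        lvl_a, lvl_b = (int(s) for s in task.split("-"))
        for modality in modalities:
            table = tables[modality].subset_levels([lvl_a, lvl_b])
            for family in families:
                accs, chosen_last = [], None
                for rep in range(n_seeds):
                    seed = master_seed * 1000 + rep
                    train, test = split_dataset(table, seed=seed)
                    if family == "mlp":
                        chosen, model = train_mlp(train, modality=modality,
                                                  seed=seed, **mlp_kwargs)
                    elif family in TIMESERIES_MODELS:
                        model = TIMESERIES_MODELS[family](seed)
                        model.fit(train.X(), train.labels)
                        chosen = [("plugin", family)]
                    else:
                        spec = ModelSpec(family, grid=grids.get(family, {}),
                                         seed=seed)
                        chosen, model = tune_classical(spec, train)
                    acc = model.score(test.X(), test.labels) * 100.0
                    accs.append(acc)
                    chosen_last = chosen
                res = ModelResult(task, modality, family, chosen_last, accs)
                rows.append({
                    "task": task, "modality": modality, "model": family,
                    "mean_acc_pct": res.mean_pct, "sd_acc_pct": res.sd_pct,
                    "accs_pct": ";".join(f"{a:.4f}" for a in accs),
                    "chosen": ";".join(f"{k}={v}" for k, v in chosen_last),
                })
    return pd.DataFrame(rows)
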