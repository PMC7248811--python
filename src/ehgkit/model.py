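"""Imminent-labor classifier: SMOTE balancing, standardized PCA at 98%
retained variance, and a tanh multilayer perceptron with a grid-searched
hidden layer, evaluated over repeated stratified three-way holdout.

The study design mirrors the clinical analysis being emulated: the
imbalanced dataset is first balanced with SMOTE, the balanced data are
split 1/3-1/3-1/3 into train/validation/test with class proportions
preserved, the scaler and PCA projection are fitted on training rows
only, hidden-layer sizes 2-10 are trained with early stopping on the
validation loss, and the topology with the best validation AUC is
selected without ever consulting the test rows. Thirty random partitions
give the mean +/- SD of every metric. A ``smote_after_split`` flag
provides the leakage-safe variant (balance the training set only) for
sensitivity analyses; the default keeps the balance-then-split order of
the emulated study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .evaluate import PartitionResult, confusion, metric_set, roc_auc

logger = logging.getLogger(__name__)

INPUT_SETS = ("ehg", "obstetric", "both")


@dataclass
class ModelConfig:
    """Classifier pipeline settings (defaults = emulated study design)."""

    smote_k: int = 5
    pca_variance: float = 0.98
    hidden_grid: tuple[int, ...] = tuple(range(2, 11))
    activation: str = "tanh"
    max_epochs: int = 500
    patience: int = 20
    learning_rate: float = 0.5
    n_partitions: int = 30
    smote_after_split: bool = False
    threshold: float = 0.5
    min_valid_partitions: int = 25

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise ValueError("smote_k must be at least 1")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")
        if not self.hidden_grid:
            raise ValueError("hidden_grid must not be empty")
        if self.activation != "tanh":
            raise ValueError("only the tanh hidden activation is supported")


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity by SMOTE interpolation.

    Each synthetic row is x_i + u (x_nn - x_i) with u ~ U(0, 1) and x_nn
    one of the k nearest minority neighbors of a randomly chosen
    minority row x_i. Original rows are returned unchanged, synthetic
    rows appended; deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    if n_min < k + 1:
        raise ValueError(
            f"minority class has {n_min} rows; needs at least k+1 = {k + 1} for SMOTE"
        )
    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
    base_idx = rng.integers(0, n_min, size=n_new)
    nn_choice = rng.integers(1, k + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    x_base = X_min[base_idx]
    x_nn = X_min[neigh[base_idx, nn_choice]]
    X_new = x_base + u[:, None] * (x_nn - x_base)
    Xb = np.vstack([X, X_new])
    yb = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return Xb, yb


# ---------------------------------------------------------------------------
# standardization + PCA


@dataclass
class Projection:
    """Train-fitted standardizer + PCA applied identically to all splits."""

    scaler: StandardScaler
    pca: PCA
    kept_columns: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)


def fit_reduce(train_X: np.ndarray, variance: float = 0.98) -> Projection:
    """Standardize (train statistics) and fit PCA keeping ``variance``.

    Keeps the smallest number of components whose cumulative explained
    variance reaches the target. Zero-variance features are dropped with
    a warning before projection.
    """
    X = np.asarray(train_X, dtype=float)
    variances = X.var(axis=0)
    # relative threshold: constant columns can carry ~1e-31 float residue
    kept = np.flatnonzero(variances > 1e-15 * max(variances.max(), 1e-30))
    if kept.size < X.shape[1]:
        logger.warning(
            "dropping %d zero-variance feature(s) before PCA", X.shape[1] - kept.size
        )
    if kept.size == 0:
        raise ValueError("all features have zero variance")
    scaler = StandardScaler().fit(X[:, kept])
    Z = scaler.transform(X[:, kept])
    n_comp = variance if variance < 1 else min(Z.shape)
    pca = PCA(n_components=n_comp, svd_solver="full").fit(Z)
    return Projection(scaler=scaler, pca=pca, kept_columns=kept)


def apply_reduce(projection: Projection, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Z = projection.scaler.transform(X[:, projection.kept_columns])
    return projection.pca.transform(Z)


# ---------------------------------------------------------------------------
# MLP


class MLP:
    """Single-hidden-layer perceptron: tanh hidden units, sigmoid output.

    Trained by full-batch gradient backpropagation on the cross-entropy
    loss with a fixed learning rate; early stopping restores the weights
    with the best validation loss once no improvement is seen for
    ``patience`` epochs. Weight init and training are deterministic for
    a fixed seed.
    """

    def __init__(
        self,
        n_hidden: int,
        learning_rate: float = 0.5,
        max_epochs: int = 500,
        patience: int = 20,
        seed: int = 0,
    ) -> None:
        if n_hidden < 1:
            raise ValueError("n_hidden must be positive")
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.W1: np.ndarray | None = None
        self.n_epochs_: int = 0

    def _init_weights(self, n_in: int) -> None:
        rng = np.random.default_rng(self.seed)
        lim1 = np.sqrt(6.0 / (n_in + self.n_hidden))
        lim2 = np.sqrt(6.0 / (self.n_hidden + 1))
        self.W1 = rng.uniform(-lim1, lim1, size=(n_in, self.n_hidden))
        self.b1 = np.zeros(self.n_hidden)
        self.W2 = rng.uniform(-lim2, lim2, size=(self.n_hidden, 1))
        self.b2 = np.zeros(1)

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = np.tanh(X @ self.W1 + self.b1)
        logits = H @ self.W2 + self.b2
        return H, 1.0 / (1.0 + np.exp(-logits))

    @staticmethod
    def _loss(p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        p = np.clip(p.ravel(), eps, 1 - eps)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MLP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        self._init_weights(d)
        best = (np.inf, None)
        stall = 0
        for epoch in range(self.max_epochs):
            H, p = self._forward(X)
            delta_out = (p.ravel() - y)[:, None] / n  # dL/dlogits
            gW2 = H.T @ delta_out
            gb2 = delta_out.sum(axis=0)
            delta_h = (delta_out @ self.W2.T) * (1 - H**2)
            gW1 = X.T @ delta_h
            gb1 = delta_h.sum(axis=0)
            if not np.all(np.isfinite(gW1)) or not np.all(np.isfinite(gW2)):
                raise FloatingPointError("non-finite gradient during MLP training")
            lr = self.learning_rate
            self.W1 -= lr * gW1
            self.b1 -= lr * gb1
            self.W2 -= lr * gW2
            self.b2 -= lr * gb2
            self.n_epochs_ = epoch + 1
            if X_val is not None and len(X_val):
                val_loss = self._loss(self._forward(np.asarray(X_val, dtype=float))[1],
                                      np.asarray(y_val, dtype=float).ravel())
                if not np.isfinite(val_loss):
                    raise FloatingPointError("non-finite validation loss")
                if val_loss < best[0] - 1e-9:
                    best = (val_loss, self._snapshot())
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best[1] is not None:
            self._restore(best[1])
        return self

    def _snapshot(self) -> tuple[np.ndarray, ...]:
        return (self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())

    def _restore(self, snap: tuple[np.ndarray, ...]) -> None:
        self.W1, self.b1, self.W2, self.b2 = (a.copy() for a in snap)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid output in (0, 1); usable directly as a ROC score."""
        if self.W1 is None:
            raise RuntimeError("model is not fitted")
        return self._forward(np.asarray(X, dtype=float))[1].ravel()


def train_ann(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    hidden_n: int,
    cfg: ModelConfig,
    seed: int = 0,
) -> MLP:
    """Fit one MLP topology with early stopping on the validation loss."""
    model = MLP(
        n_hidden=hidden_n,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        seed=seed,
    )
    return model.fit(train[0], train[1], validation[0], validation[1])


def select_topology(validation_aucs: dict[int, float]) -> int:
    """Hidden-layer size with the best validation AUC; ties -> fewer units."""
    if not validation_aucs:
        raise ValueError("no topologies to select from")
    best_auc = max(validation_aucs.values())
    return min(h for h, auc in validation_aucs.items() if auc >= best_auc - 1e-12)


# ---------------------------------------------------------------------------
# holdout study


def stratified_three_way_split(
    y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 1/3-1/3-1/3 split preserving class proportions (to rounding)."""
    y = np.asarray(y).astype(int)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        a, b = n // 3, (2 * n) // 3
        train.append(idx[:a])
        val.append(idx[a:b])
        test.append(idx[b:])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def run_partition(
    Xb: np.ndarray,
    yb: np.ndarray,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: ModelConfig,
    seed: int,
    partition_id: int = 0,
) -> PartitionResult:
    """Train, select and score the classifier on one balanced partition.

    Test rows influence nothing upstream of the final scoring: the
    scaler/PCA are fitted on training rows, early stopping watches the
    validation loss, and the topology choice uses validation AUC only.
    """
    tr_idx, va_idx, te_idx = split
    proj = fit_reduce(Xb[tr_idx], cfg.pca_variance)
    Ztr, Zva, Zte = (apply_reduce(proj, Xb[i]) for i in (tr_idx, va_idx, te_idx))
    ytr, yva, yte = yb[tr_idx], yb[va_idx], yb[te_idx]

    models: dict[int, MLP] = {}
    val_aucs: dict[int, float] = {}
    for gi, h in enumerate(cfg.hidden_grid):
        model = train_ann((Ztr, ytr), (Zva, yva), h, cfg, seed=seed + 1000 * (gi + 1))
        _, _, auc = roc_auc(model.scores(Zva), yva)
        models[h] = model
        val_aucs[h] = auc
    h_star = select_topology(val_aucs)
    model = models[h_star]

    metrics = {
        "train": metric_set(model.scores(Ztr), ytr, cfg.threshold),
        "validation": metric_set(model.scores(Zva), yva, cfg.threshold),
        "test": metric_set(model.scores(Zte), yte, cfg.threshold),
    }
    te_scores = model.scores(Zte)
    return PartitionResult(
        partition_id=partition_id,
        hidden_n=h_star,
        n_components=proj.n_components,
        metrics=metrics,
        test_scores=te_scores,
        test_labels=yte.copy(),
        test_confusion=confusion(te_scores, yte, cfg.threshold),
    )


def run_study(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> list[PartitionResult]:
    """The full repeated-holdout study on one labeled feature matrix.

    Per partition: SMOTE on the whole dataset (or training set only when
    ``smote_after_split``), stratified 1/3-1/3-1/3 split, train-fitted
    standardization + PCA, hidden-layer grid search, final scoring of
    all three splits. A failed partition is logged and marked invalid;
    the study raises only when fewer than ``min_valid_partitions``
    succeed.
    """
    cfg = cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if len(np.unique(y)) != 2:
        raise ValueError("need both classes present")
    results: list[PartitionResult] = []
    for p in range(cfg.n_partitions):
        part_seed = seed + 7919 * p  # distinct, reproducible per partition
        try:
            rng = np.random.default_rng(part_seed)
            if cfg.smote_after_split:
                tr, va, te = stratified_three_way_split(y, rng)
                Xtr, ytr = smote_balance(X[tr], y[tr], cfg.smote_k, part_seed)
                Xb = np.vstack([Xtr, X[va], X[te]])
                yb = np.concatenate([ytr, y[va], y[te]])
                n_tr = len(ytr)
                split = (
                    np.arange(n_tr),
                    np.arange(n_tr, n_tr + len(va)),
                    np.arange(n_tr + len(va), len(yb)),
                )
            else:
                Xb, yb = smote_balance(X, y, cfg.smote_k, part_seed)
                split = stratified_three_way_split(yb, rng)
            results.append(run_partition(Xb, yb, split, cfg, part_seed, partition_id=p))
        except (FloatingPointError, ValueError) as exc:
            logger.warning("partition %d failed: %s", p, exc)
            results.append(
                PartitionResult(
                    partition_id=p,
                    hidden_n=-1,
                    n_components=-1,
                    metrics={},
                    test_scores=np.empty(0),
                    test_labels=np.empty(0, dtype=int),
                    test_confusion=(0, 0, 0, 0),
                    valid=False,
                    failure=str(exc),
                )
            )
    n_valid = sum(r.valid for r in results)
    if n_valid < min(cfg.min_valid_partitions, cfg.n_partitions):
        raise RuntimeError(
            f"only {n_valid} of {cfg.n_partitions} partitions succeeded"
        )
    return results
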