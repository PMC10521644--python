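"""Two-stage augmentation search and network match.

Stage 1 searches the execution probability ``P`` of the augmentation space by
grouped 5-fold cross-validation: for every candidate probability and every
candidate backbone, five models are trained on the augmented folds and the
screening criterion is the mean over folds of the best validation balanced
accuracy (BACC) seen across epoch checkpoints.  The winning probability is
the one preferred by the majority of backbones (ties broken by the higher
mean criterion).

Stage 2 retrains every backbone on the full training set with the selected
strategy, scores each on the held-out test set with multi-crop averaged
predictions, and recommends the backbone with the best test BACC.

Training protocol per epoch: every training image passes through the
stochastic augmentation executor and is then randomly cropped to the
configured input size; the loss is inverse-class-frequency weighted
cross-entropy (weights computed on the training split only); the optimizer
is Adam with a step learning-rate schedule (1e-3, divided by 10 after 20
epochs and again every 10 epochs).

All randomness derives from a single integer seed fanned out into named
substreams (folds, per-fold init, augmentation), so a fixed seed reproduces
the full SearchReport byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import zlib

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from .augment import AugmentationStrategy, SearchSpace, apply_strategy, build_default_space, enumerate_candidates
from .backbone import SmallCNNClassifier
from .evaluation import make_crop_grid, multicrop_predict
from .losses import class_weights
from .metrics import bacc, confusion_counts

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "CandidateResult",
    "SearchReport",
    "substream",
    "make_grouped_folds",
    "lr_schedule",
    "train_backbone",
    "stage1_augmentation_search",
    "stage2_network_match",
    "LCASearchCV",
]


@dataclasses.dataclass
class TrainConfig:
    """Training-protocol knobs; the defaults reproduce the reference schedule
    (lr 1e-3, /10 after epoch 20 then every 10, 70 epochs, Adam, 224 crops,
    4x4 evaluation crops)."""

    initial_lr: float = 1e-3
    lr_decay: float = 0.1
    first_decay_epoch: int = 20
    decay_every: int = 10
    max_epochs: int = 70
    optimizer: str = "adam"
    batch_size: int = 32
    crop_size: int = 224
    eval_crops_per_axis: int = 4
    checkpoint_interval: int = 1
    checkpoint_start: int = 0  # epochs before this are trained but not scored
    use_class_weights: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    """One grouped CV fold; no group id ever appears on both sides."""

    fold_index: int
    train_ids: np.ndarray
    val_ids: np.ndarray
    group_ids: np.ndarray


@dataclasses.dataclass
class CandidateResult:
    probability: float
    backbone: str
    fold_baccs: list
    criterion: float  # mean of the per-fold best validation BACCs


@dataclasses.dataclass
class SearchReport:
    stage1: list
    selected_probability: float | None
    stage2: list
    selected_backbone: str | None
    seed: int
    config: dict
    space_size: int | None = None

    def to_dict(self) -> dict:
        return {
            "stage1": [dataclasses.asdict(c) for c in self.stage1],
            "selected_probability": self.selected_probability,
            "stage2": self.stage2,
            "selected_backbone": self.selected_backbone,
            "seed": self.seed,
            "config": self.config,
            "space_size": self.space_size,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named RNG substream from one master seed."""
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode()))
        else:
            words.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Piecewise-constant step schedule: initial_lr until the first decay
    epoch, then multiplied by the decay factor every ``decay_every`` epochs
    (defaults: 1e-3 for epochs 0-19, 1e-4 for 20-29, 1e-5 for 30-39, ...)."""
    if epoch < config.first_decay_epoch:
        return config.initial_lr
    n_decays = 1 + (epoch - config.first_decay_epoch) // config.decay_every
    return config.initial_lr * config.lr_decay**n_decays


def make_grouped_folds(groups, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Partition samples into k folds by group id (seeded shuffle, greedy
    balancing), so all images of one lesion stay on one side of every split."""
    groups = np.asarray(groups)
    uniq, inverse = np.unique(groups, return_inverse=True)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds the number of groups ({len(uniq)})")
    rng = substream(seed, "folds")
    order = rng.permutation(len(uniq))
    sizes = np.bincount(inverse, minlength=len(uniq))
    fold_of_group = np.empty(len(uniq), dtype=int)
    fold_load = np.zeros(k, dtype=int)
    for g in order:
        f = int(np.argmin(fold_load))  # ties -> lowest fold index
        fold_of_group[g] = f
        fold_load[f] += sizes[g]
    fold_of_sample = fold_of_group[inverse]
    splits = []
    for f in range(k):
        val = np.flatnonzero(fold_of_sample == f)
        train = np.flatnonzero(fold_of_sample != f)
        splits.append(FoldSplit(fold_index=f + 1, train_ids=train, val_ids=val,
                                group_ids=groups))
    return splits


def _random_crop(img: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop {size}")
    y0 = int(rng.integers(h - size + 1))
    x0 = int(rng.integers(w - size + 1))
    return img[y0 : y0 + size, x0 : x0 + size]


def _eval_bacc(model, X, y, config: TrainConfig) -> float:
    grid = make_crop_grid(X.shape[1:3], (config.crop_size, config.crop_size),
                          config.eval_crops_per_axis)
    probs = np.stack([multicrop_predict(model, img, grid) for img in X])
    n_classes = probs.shape[1]
    return bacc(confusion_counts(y, probs.argmax(axis=1), n_classes), allow_missing=True)


def train_backbone(
    backbone,
    X,
    y,
    strategy: AugmentationStrategy,
    config: TrainConfig,
    rng: np.random.Generator,
    X_val=None,
    y_val=None,
    n_epochs: int | None = None,
):
    """Train one backbone under the augmented protocol.

    Returns ``(backbone, trace)`` where trace is a list of
    ``{"epoch", "lr", "loss", "val_bacc"}`` dicts — one entry per checkpoint
    (``val_bacc`` is None when no validation set is supplied).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n_classes = int(y.max()) + 1
    if not hasattr(backbone, "train_step"):
        raise TypeError("backbone must implement the train_step contract")
    if not hasattr(backbone, "params_"):
        backbone.init_params(n_classes, rng)
    wts = class_weights(np.bincount(y, minlength=n_classes)).weights if config.use_class_weights else None
    n_epochs = config.max_epochs if n_epochs is None else n_epochs
    n = len(X)
    trace = []
    for epoch in range(n_epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = np.stack(
                [
                    _random_crop(apply_strategy(X[i], strategy, rng), config.crop_size, rng)
                    for i in idx
                ]
            )
            losses.append(backbone.train_step(batch, y[idx], wts, lr))
        # the final epoch is always scored so the trace is never empty
        scored = (epoch == n_epochs - 1 and not trace) or (
            epoch >= config.checkpoint_start
            and ((epoch + 1) % config.checkpoint_interval == 0 or epoch == n_epochs - 1)
        )
        if scored:
            val = _eval_bacc(backbone, X_val, y_val, config) if X_val is not None else None
            trace.append(
                {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)), "val_bacc": val}
            )
    return backbone, trace


def _normalize_backbones(backbones) -> list[tuple[str, object]]:
    if backbones is None:
        backbones = [SmallCNNClassifier()]
    if isinstance(backbones, dict):
        return list(backbones.items())
    out = []
    for i, b in enumerate(backbones):
        if isinstance(b, tuple):
            out.append(b)
        else:
            out.append((f"{type(b).__name__}_{i}", b))
    return out


def stage1_augmentation_search(
    X,
    y,
    groups,
    space: SearchSpace,
    backbones=None,
    config: TrainConfig | None = None,
    seed: int = 0,
    k: int = 5,
    n_epochs: int | None = None,
    trainer=None,
):
    """Cross-validated search for the best execution probability.

    ``trainer`` (mainly for testing) overrides the per-fold training: a
    callable ``(backbone_name, probability, fold) -> list of per-epoch
    validation BACCs``.

    Returns ``(results, selected_probability, traces)``.
    """
    config = config or TrainConfig()
    backbones = _normalize_backbones(backbones)
    candidates = enumerate_candidates(space)
    folds = make_grouped_folds(groups, k=k, seed=seed)
    y = np.asarray(y)
    results: list[CandidateResult] = []
    traces: dict = {}
    for name, proto in backbones:
        for cand in candidates:
            fold_best = []
            for fold in folds:
                if trainer is not None:
                    val_trace = trainer(name, cand.probability, fold)
                else:
                    model = clone(proto)
                    rng = substream(seed, "stage1", name, f"P{cand.probability}", fold.fold_index)
                    model.init_params(int(y.max()) + 1, rng)
                    _, trace = train_backbone(
                        model,
                        X[fold.train_ids],
                        y[fold.train_ids],
                        cand,
                        config,
                        rng,
                        X_val=X[fold.val_ids],
                        y_val=y[fold.val_ids],
                        n_epochs=n_epochs,
                    )
                    val_trace = [t["val_bacc"] for t in trace]
                    traces[(name, cand.probability, fold.fold_index)] = trace
                fold_best.append(float(np.max(val_trace)))
            results.append(
                CandidateResult(
                    probability=cand.probability,
                    backbone=name,
                    fold_baccs=fold_best,
                    criterion=float(np.mean(fold_best)),
                )
            )
    selected = _select_probability(results)
    return results, selected, traces


def _select_probability(results: list[CandidateResult]) -> float:
    """Majority vote of per-backbone argmax probabilities; ties broken by the
    higher mean criterion across backbones."""
    by_backbone: dict[str, list[CandidateResult]] = {}
    for r in results:
        by_backbone.setdefault(r.backbone, []).append(r)
    votes: dict[float, int] = {}
    for cands in by_backbone.values():
        best = max(cands, key=lambda c: c.criterion)
        votes[best.probability] = votes.get(best.probability, 0) + 1
    top = max(votes.values())
    tied = [p for p, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    mean_criterion = {
        p: float(np.mean([r.criterion for r in results if r.probability == p])) for p in tied
    }
    return max(tied, key=lambda p: mean_criterion[p])


def stage2_network_match(
    X_train,
    y_train,
    X_test,
    y_test,
    strategy: AugmentationStrategy,
    backbones=None,
    config: TrainConfig | None = None,
    seed: int = 0,
    n_epochs: int | None = None,
    eval_interval: int | None = None,
):
    """Retrain every backbone on the full training set with the selected
    strategy and recommend the one with the best multi-crop test BACC.

    Returns ``(stage2_results, selected_backbone_name, fitted_models)``; each
    result records the per-checkpoint test BACCs and the best epoch.
    """
    if len(np.asarray(X_test)) == 0:
        raise ValueError("empty test set")
    config = config or TrainConfig()
    backbones = _normalize_backbones(backbones)
    X_train, y_train = np.asarray(X_train), np.asarray(y_train)
    X_test, y_test = np.asarray(X_test), np.asarray(y_test)
    interval = eval_interval or config.checkpoint_interval
    results, models = [], {}
    for name, proto in backbones:
        model = clone(proto)
        rng = substream(seed, "stage2", name)
        model.init_params(int(y_train.max()) + 1, rng)
        n_ep = config.max_epochs if n_epochs is None else n_epochs
        n_classes = int(y_train.max()) + 1
        wts = (
            class_weights(np.bincount(y_train, minlength=n_classes)).weights
            if config.use_class_weights
            else None
        )
        checkpoints = []
        for epoch in range(n_ep):
            lr = lr_schedule(epoch, config)
            order = rng.permutation(len(X_train))
            for start in range(0, len(X_train), config.batch_size):
                idx = order[start : start + config.batch_size]
                batch = np.stack(
                    [
                        _random_crop(
                            apply_strategy(X_train[i], strategy, rng), config.crop_size, rng
                        )
                        for i in idx
                    ]
                )
                model.train_step(batch, y_train[idx], wts, lr)
            if (epoch == n_ep - 1 and not checkpoints) or (
                epoch >= config.checkpoint_start
                and ((epoch + 1) % interval == 0 or epoch == n_ep - 1)
            ):
                checkpoints.append(
                    {"epoch": epoch, "test_bacc": _eval_bacc(model, X_test, y_test, config)}
                )
        best = max(checkpoints, key=lambda c: c["test_bacc"])
        results.append(
            {
                "backbone": name,
                "checkpoints": checkpoints,
                "best_epoch": best["epoch"],
                "test_bacc": best["test_bacc"],
            }
        )
        models[name] = model
    selected = max(results, key=lambda r: r["test_bacc"])["backbone"]
    return results, selected, models


class LCASearchCV(BaseEstimator, ClassifierMixin):
    """Two-stage augmentation-and-backbone search as a CV meta-estimator.

    ``fit(X, y, groups)`` splits off a grouped test set, runs the stage-1
    cross-validated probability search on the remainder, then the stage-2
    network match, and exposes ``best_probability_``, ``best_backbone_``,
    ``best_estimator_`` and the full ``report_``.

    Parameters
    ----------
    space : SearchSpace or None
        Augmentation space (default: the 12-subpolicy LCA space).
    backbones : list/dict of backbone estimators or None
        Candidates for the network match (default: one SmallCNNClassifier).
    config : TrainConfig or None
    k : int
        Stage-1 fold count.
    test_fraction : float
        Grouped held-out fraction used by stage 2.
    n_epochs : int or None
        Epoch budget per training run (None = config.max_epochs).
    random_state : int
    """

    def __init__(self, space=None, backbones=None, config=None, k=5,
                 test_fraction=0.2, n_epochs=None, random_state=0):
        self.space = space
        self.backbones = backbones
        self.config = config
        self.k = k
        self.test_fraction = test_fraction
        self.n_epochs = n_epochs
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if groups is None:
            groups = np.arange(len(y))
        groups = np.asarray(groups)
        space = self.space or build_default_space()
        config = self.config or TrainConfig()

        # grouped test split: reuse the fold machinery with k = 1/test_fraction
        n_chunks = max(int(round(1.0 / self.test_fraction)), 2)
        chunk = make_grouped_folds(groups, k=n_chunks, seed=self.random_state * 7919 + 1)[0]
        tr, te = chunk.train_ids, chunk.val_ids

        stage1, selected_p, traces = stage1_augmentation_search(
            X[tr], y[tr], groups[tr], space, self.backbones, config,
            seed=self.random_state, k=self.k, n_epochs=self.n_epochs,
        )
        strategy = AugmentationStrategy(space, selected_p)
        stage2, selected_b, models = stage2_network_match(
            X[tr], y[tr], X[te], y[te], strategy, self.backbones, config,
            seed=self.random_state, n_epochs=self.n_epochs,
        )
        self.best_probability_ = selected_p
        self.best_backbone_ = selected_b
        self.best_estimator_ = models[selected_b]
        self.classes_ = np.unique(y)
        self.strategy_ = strategy
        self.config_ = config
        self.report_ = SearchReport(
            stage1=stage1,
            selected_probability=selected_p,
            stage2=stage2,
            selected_backbone=selected_b,
            seed=self.random_state,
            config=config.to_dict(),
            space_size=space.combinatorial_size,
        )
        return self

    def predict_proba(self, X):
        config = self.config_
        grid = make_crop_grid(np.asarray(X).shape[1:3],
                              (config.crop_size, config.crop_size),
                              config.eval_crops_per_axis)
        return np.stack([multicrop_predict(self.best_estimator_, img, grid) for img in X])

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
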