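"""Scikit-learn estimator wrapping the residual attention classifiers.

``OtoscopyClassifier`` consumes *standardized* images — square float RGB
arrays in [0, 1] as produced by :func:`otoshuffle.preprocess.standardize` —
and handles patch augmentation, mini-batch optimisation and prediction.  It
follows the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``clone``-ability), so it composes
with pipelines and model selection.
"""

from __future__ import annotations

import zlib

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder

from . import nn
from .models import ModelSpec, ResNetClassifier, build_model
from .preprocess import apply_augment, draw_augment_params, eval_patch


def derive_seed(master_seed: int, component: str) -> int:
    """Fan a single run seed out to a named component (splitmix-style via
    SeedSequence over the master seed and a CRC of the component name)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(component.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _to_nchw(batch: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(batch.transpose(0, 3, 1, 2), dtype=np.float32)


class OtoscopyClassifier(ClassifierMixin, BaseEstimator):
    """Residual-network diagnosis classifier with optional attention.

    Parameters
    ----------
    backbone, attention:
        Architecture choice: ``resnet18``/``resnet50`` crossed with
        ``none``/``shuffle``/``cbam``.
    patch_size:
        Side of the square patch fed to the network.  Training randomly
        crops it from the standardized image; prediction centre-crops.
    augment:
        Apply the random mirror/rotation/crop transform during training.
    optimizer, lr, momentum, weight_decay, epochs, batch_size:
        Optimisation hyperparameters (cross-entropy objective).
    class_weight:
        ``None`` for unweighted sampling or ``"balanced"`` for
        inverse-frequency class weights in the loss.
    seed:
        Master seed; weight init, shuffling and augmentation draw
        independent streams from it.
    """

    def __init__(self, backbone: str = "resnet18", attention: str = "shuffle",
                 patch_size: int = 256, augment: bool = True,
                 optimizer: str = "adam", lr: float = 1e-3, momentum: float = 0.9,
                 weight_decay: float = 0.0, epochs: int = 8, batch_size: int = 32,
                 class_weight: str | None = None, cbam_reduction: int = 16,
                 seed: int = 0, verbose: int = 0):
        self.backbone = backbone
        self.attention = attention
        self.patch_size = patch_size
        self.augment = augment
        self.optimizer = optimizer
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.cbam_reduction = cbam_reduction
        self.seed = seed
        self.verbose = verbose

    # -- internals ------------------------------------------------------
    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"expected (n, size, size, 3) standardized images, got {X.shape}")
        if X.shape[1] < self.patch_size:
            raise ValueError("standardized size smaller than patch_size")
        return X

    def _batch_patches(self, X: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        size = X.shape[1]
        if train and self.augment and size > self.patch_size:
            patches = [apply_augment(img, draw_augment_params(rng, size, self.patch_size), self.patch_size)
                       for img in X]
        else:
            patches = [eval_patch(img, self.patch_size) for img in X]
        return _to_nchw(np.stack(patches))

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train on standardized images ``X`` with labels ``y``.

        ``validation_data=(Xv, yv)`` adds a per-epoch validation accuracy
        to ``history_``.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty dataset")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self._le_ = LabelEncoder().fit(y)
        self.classes_ = self._le_.classes_
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        yi = self._le_.transform(y)

        spec = ModelSpec(self.backbone, self.attention, num_classes=len(self.classes_),
                         cbam_reduction=self.cbam_reduction)
        self.model_: ResNetClassifier = build_model(spec, seed=derive_seed(self.seed, "init"))
        params = self.model_.parameters()
        if self.optimizer == "adam":
            opt = nn.Adam(params, lr=self.lr, weight_decay=self.weight_decay)
        elif self.optimizer == "sgd":
            opt = nn.SGD(params, lr=self.lr, momentum=self.momentum, weight_decay=self.weight_decay)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        cw = None
        if self.class_weight == "balanced":
            counts = np.bincount(yi, minlength=len(self.classes_)).astype(np.float32)
            cw = counts.sum() / (len(counts) * np.maximum(counts, 1))
        elif self.class_weight is not None:
            raise ValueError(f"unknown class_weight {self.class_weight!r}")

        shuffle_rng = np.random.default_rng(derive_seed(self.seed, "shuffle"))
        aug_rng = np.random.default_rng(derive_seed(self.seed, "augment"))
        n = len(X)
        self.history_: list[dict] = []
        for epoch in range(self.epochs):
            self.model_.train()
            order = shuffle_rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = self._batch_patches(X[idx], train=True, rng=aug_rng)
                logits = self.model_(nn.Tensor(xb))
                loss = nn.softmax_cross_entropy(logits, yi[idx], class_weights=cw)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                correct += int((logits.data.argmax(axis=1) == yi[idx]).sum())
            rec = {"epoch": epoch, "loss": float(np.mean(losses)), "train_acc": correct / n}
            if validation_data is not None:
                Xv, yv = validation_data
                rec["val_acc"] = float(np.mean(self.predict(Xv) == np.asarray(yv)))
            self.history_.append(rec)
            if self.verbose:
                print(f"epoch {epoch}: " + " ".join(f"{k}={v:.4f}" for k, v in rec.items() if k != "epoch"))
        return self

    def _forward_eval(self, X: np.ndarray) -> np.ndarray:
        self.model_.eval()
        out = []
        for start in range(0, len(X), self.batch_size):
            xb = self._batch_patches(X[start : start + self.batch_size], train=False, rng=None)
            out.append(self.model_(nn.Tensor(xb)).data)
        return np.concatenate(out)

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the classifier first")
        return self._forward_eval(self._validate_X(X))

    def predict_proba(self, X) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self._le_.inverse_transform(scores.argmax(axis=1))
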