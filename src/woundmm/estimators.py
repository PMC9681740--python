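"""scikit-learn style estimators over the WIC / WLC / WMC networks.

These are the primary user surface: ``fit(X, y)`` / ``predict`` /
``predict_proba`` / ``score`` classifiers that compose with sklearn model
selection. After fitting, the weights of the best-validation-accuracy
checkpoint are restored, so ``predict`` reflects the selected model, not
the final epoch. The second checkpoint (best combined train/val accuracy)
is kept on the fitted estimator for inspection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .architectures import (
    ModelHandle,
    WICConfig,
    WLCConfig,
    WMCConfig,
    build_ohv_direct,  # noqa: F401  (re-exported for convenience)
    build_wic,
    build_wlc,
    build_wmc,
)
from .training import TrainingConfig, train

__all__ = [
    "MultiModalWoundClassifier",
    "WoundImageClassifier",
    "WoundLocationClassifier",
]


class _NeuralClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for the three network families."""

    def __init__(
        self,
        epochs: int = 250,
        batch_size: int = 25,
        learning_rate: float = 0.001,
        validation_fraction: float = 0.2,
        combined_policy: str = "mean",
        seed: int = 0,
    ) -> None:
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.combined_policy = combined_policy
        self.seed = seed

    # subclasses build the network for the already-encoded problem
    def _build(self, X, n_classes: int) -> ModelHandle:
        raise NotImplementedError

    def _check_X(self, X):
        return np.asarray(X, dtype=np.float32)

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on (X, y); an explicit validation set overrides the internal
        stratified holdout of ``validation_fraction``."""
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit a classifier")
        if X_val is None:
            X, y_enc, X_val_enc, yv_enc = self._holdout(X, y_enc)
        else:
            X_val_enc = self._check_X(X_val)
            yv_enc = np.searchsorted(self.classes_, np.asarray(y_val))
        cfg = TrainingConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.seed,
            combined_policy=self.combined_policy,
        )
        self._fit_model(X, y_enc, X_val_enc, yv_enc, cfg)
        self.n_epochs_ = len(self.history_)
        return self

    def _fit_model(self, X, y_enc, X_val, yv_enc, cfg: TrainingConfig) -> None:
        self.model_ = self._build(X, len(self.classes_))
        result = train(self.model_, X, y_enc, X_val, yv_enc, cfg)
        self.history_ = result.history
        self.best_val_checkpoint_ = result.best_val
        self.best_combined_checkpoint_ = result.best_combined
        result.best_val.restore(self.model_)

    def _holdout(self, X, y_enc):
        """Per-class random validation holdout (at least one sample per class)."""
        rng = np.random.default_rng(self.seed)
        n = self._n_samples(X)
        val_mask = np.zeros(n, dtype=bool)
        for cls in np.unique(y_enc):
            idx = np.flatnonzero(y_enc == cls)
            k = max(1, int(round(self.validation_fraction * len(idx))))
            k = min(k, len(idx) - 1) if len(idx) > 1 else 0
            val_mask[rng.choice(idx, size=k, replace=False)] = True
        if not val_mask.any():
            raise ValueError("validation holdout is empty; provide X_val explicitly")
        tr = ~val_mask
        return (
            self._subset(X, tr),
            y_enc[tr],
            self._subset(X, val_mask),
            y_enc[val_mask],
        )

    @staticmethod
    def _n_samples(X) -> int:
        return len(X[0]) if isinstance(X, tuple) else len(X)

    @staticmethod
    def _subset(X, idx):
        if isinstance(X, tuple):
            return tuple(xi[idx] for xi in X)
        return X[idx]

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._check_X(X))

    def predict(self, X):
        check_is_fitted(self, "model_")
        idx = self.model_.predict(self._check_X(X))
        return self.classes_[idx]

    def describe(self):
        """Layer table of the fitted (or freshly built) network."""
        check_is_fitted(self, "model_")
        return self.model_.describe()


class WoundImageClassifier(_NeuralClassifierBase):
    """Image-branch (WIC) classifier: backbone + Dense(512)x3 head.

    Parameters mirror the image-network family: ``backbone`` is one of
    vgg16 / vgg19 / resnet50 / inceptionv3 / alexnet / tinytest; the four
    transfer backbones are frozen by default, alexnet and tinytest train
    end to end. ``X`` is (n, H, W, 3) float in [0, 1].
    """

    def __init__(
        self,
        backbone: str = "tinytest",
        input_size: int | None = None,
        freeze_backbone: bool | None = None,
        dropout_rate: float = 0.5,
        epochs: int = 250,
        batch_size: int = 25,
        learning_rate: float = 0.001,
        validation_fraction: float = 0.2,
        combined_policy: str = "mean",
        seed: int = 0,
    ) -> None:
        super().__init__(epochs, batch_size, learning_rate, validation_fraction, combined_policy, seed)
        self.backbone = backbone
        self.input_size = input_size
        self.freeze_backbone = freeze_backbone
        self.dropout_rate = dropout_rate

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"image input must be (n, H, W, 3): got {X.shape}")
        return X

    def _build(self, X, n_classes: int) -> ModelHandle:
        cfg = WICConfig(
            n_classes=n_classes,
            backbone=self.backbone,
            input_size=self.input_size if self.input_size is not None else X.shape[1],
            freeze_backbone=self.freeze_backbone,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )
        return build_wic(cfg)


class WoundLocationClassifier(_NeuralClassifierBase):
    """Location-branch (WLC) classifier over one-hot body-map vectors.

    ``kind='mlp'`` is the 9-layer ReLU MLP (128x3, 256x3, 512x3);
    ``kind='lstm'`` is the 4-layer LSTM stack (32, 32, 64, 64) + Dense(512).
    ``X`` is (n, L+1) one-hot.
    """

    def __init__(
        self,
        kind: str = "mlp",
        sequence_shaping: str = "timesteps_of_1",
        epochs: int = 250,
        batch_size: int = 25,
        learning_rate: float = 0.001,
        validation_fraction: float = 0.2,
        combined_policy: str = "mean",
        seed: int = 0,
    ) -> None:
        super().__init__(epochs, batch_size, learning_rate, validation_fraction, combined_policy, seed)
        self.kind = kind
        self.sequence_shaping = sequence_shaping

    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError(f"location input must be (n, L+1) one-hot: got {X.shape}")
        return X

    def _build(self, X, n_classes: int) -> ModelHandle:
        cfg = WLCConfig(
            input_dim=X.shape[1],
            n_classes=n_classes,
            kind=self.kind,
            sequence_shaping=self.sequence_shaping,
            seed=self.seed,
        )
        return build_wlc(cfg)


class MultiModalWoundClassifier(_NeuralClassifierBase):
    """Late-fusion (WMC) classifier over paired image and location inputs.

    ``X`` is a 2-tuple ``(images, locations)`` whose rows are index-aligned:
    row i of both arrays must come from the same ROI. ``fusion='features'``
    concatenates the branches' terminal 512-wide representations;
    ``fusion='probabilities'`` concatenates their class outputs.

    With ``branch_pretraining`` (the default) the image and location
    branches are first trained as stand-alone classifiers on their own
    modality, their weights are frozen inside the fused network, and the
    post-fusion layers are then trained on the concatenated branch outputs.
    With ``branch_pretraining=False`` the whole fused network trains end to
    end from scratch.
    """

    def __init__(
        self,
        backbone: str = "tinytest",
        wlc_kind: str = "mlp",
        fusion: str = "features",
        input_size: int | None = None,
        freeze_backbone: bool | None = None,
        dropout_rate: float = 0.5,
        sequence_shaping: str = "timesteps_of_1",
        branch_pretraining: bool = True,
        epochs: int = 250,
        batch_size: int = 25,
        learning_rate: float = 0.001,
        validation_fraction: float = 0.2,
        combined_policy: str = "mean",
        seed: int = 0,
    ) -> None:
        super().__init__(epochs, batch_size, learning_rate, validation_fraction, combined_policy, seed)
        self.backbone = backbone
        self.wlc_kind = wlc_kind
        self.fusion = fusion
        self.input_size = input_size
        self.freeze_backbone = freeze_backbone
        self.dropout_rate = dropout_rate
        self.sequence_shaping = sequence_shaping
        self.branch_pretraining = branch_pretraining

    def _check_X(self, X):
        if not isinstance(X, (tuple, list)) or len(X) != 2:
            raise ValueError("multimodal input must be a (images, locations) pair")
        images = np.asarray(X[0], dtype=np.float32)
        locations = np.asarray(X[1], dtype=np.float32)
        if len(images) != len(locations):
            raise ValueError(
                f"modalities disagree on sample count: {len(images)} images vs "
                f"{len(locations)} locations"
            )
        if images.ndim != 4 or images.shape[-1] != 3:
            raise ValueError(f"image input must be (n, H, W, 3): got {images.shape}")
        if locations.ndim != 2:
            raise ValueError(f"location input must be (n, L+1): got {locations.shape}")
        return (images, locations)

    def _build(self, X, n_classes: int) -> ModelHandle:
        images, locations = X
        wic = WICConfig(
            n_classes=n_classes,
            backbone=self.backbone,
            input_size=self.input_size if self.input_size is not None else images.shape[1],
            freeze_backbone=self.freeze_backbone,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )
        wlc = WLCConfig(
            input_dim=locations.shape[1],
            n_classes=n_classes,
            kind=self.wlc_kind,
            sequence_shaping=self.sequence_shaping,
            seed=self.seed,
        )
        return build_wmc(WMCConfig(wic=wic, wlc=wlc, fusion_point=self.fusion))

    def _fit_model(self, X, y_enc, X_val, yv_enc, cfg: TrainingConfig) -> None:
        if not self.branch_pretraining:
            super()._fit_model(X, y_enc, X_val, yv_enc, cfg)
            return
        images, locations = X
        images_val, locations_val = X_val
        n_classes = len(self.classes_)

        wic_net = build_wic(
            WICConfig(
                n_classes=n_classes,
                backbone=self.backbone,
                input_size=self.input_size if self.input_size is not None else images.shape[1],
                freeze_backbone=self.freeze_backbone,
                dropout_rate=self.dropout_rate,
                seed=self.seed,
            )
        )
        wlc_net = build_wlc(
            WLCConfig(
                input_dim=locations.shape[1],
                n_classes=n_classes,
                kind=self.wlc_kind,
                sequence_shaping=self.sequence_shaping,
                seed=self.seed,
            )
        )
        wic_result = train(wic_net, images, y_enc, images_val, yv_enc, cfg)
        wic_result.best_val.restore(wic_net)
        wlc_result = train(wlc_net, locations, y_enc, locations_val, yv_enc, cfg)
        wlc_result.best_val.restore(wlc_net)
        self.branch_histories_ = {
            "image": wic_result.history,
            "location": wlc_result.history,
        }

        self.model_ = self._build(X, n_classes)
        img_branch, loc_branch = self.model_.net.branches
        n_strip = 0 if self.fusion == "probabilities" else 1
        self._adopt_weights(wic_net.net.layers[: len(wic_net.net.layers) - n_strip], img_branch)
        self._adopt_weights(wlc_net.net.layers[: len(wlc_net.net.layers) - n_strip], loc_branch)
        img_branch.trainable = False
        loc_branch.trainable = False

        # branches are frozen and deterministic at inference: train the
        # post-fusion head on precomputed concatenated branch outputs
        feats = _BranchFeatures(img_branch, loc_branch)
        head = ModelHandle(self.model_.net.head, None, n_classes, "features")
        result = train(head, feats(X), y_enc, feats(X_val), yv_enc, cfg)
        self.history_ = result.history
        self.best_val_checkpoint_ = result.best_val
        self.best_combined_checkpoint_ = result.best_combined
        result.best_val.restore(head)

    @staticmethod
    def _adopt_weights(src_layers, dst_branch) -> None:
        from .nn import Sequential

        src = Sequential(list(src_layers))
        src_params = list(src.iter_all())
        dst_params = list(dst_branch.iter_all())
        if len(src_params) != len(dst_params):
            raise RuntimeError("branch structure mismatch while adopting weights")
        for sl, dl in zip(src_params, dst_params):
            for name in sl.params:
                dl.params[name] = sl.params[name].copy()


class _BranchFeatures:
    """Concatenated eval-mode outputs of two frozen branches, batched."""

    def __init__(self, img_branch, loc_branch, batch_size: int = 64) -> None:
        self.img_branch = img_branch
        self.loc_branch = loc_branch
        self.batch_size = batch_size

    def __call__(self, X) -> np.ndarray:
        images, locations = X
        chunks = []
        for start in range(0, len(images), self.batch_size):
            sl = slice(start, start + self.batch_size)
            chunks.append(
                np.hstack(
                    [
                        self.img_branch.forward(images[sl], training=False),
                        self.loc_branch.forward(locations[sl], training=False),
                    ]
                )
            )
        return np.concatenate(chunks, axis=0)
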