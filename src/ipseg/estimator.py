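"""Scikit-learn-style estimator wrapping the multi-scale segmentation model.

``PANetSegmenter`` exposes the whole pipeline — inverted input pyramid,
per-scale position-attention networks, multi-scale fusion, SGD training —
behind ``fit`` / ``predict`` / ``score`` so it composes with scikit-learn
tooling (``clone``, ``get_params``/``set_params``, model selection).

Samples are 2D frames: ``X`` has shape (n, H, W) or (n, 1, H, W) with values
in [0, 1]; ``y`` holds binary masks of shape (n, H, W).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import engine
from .metrics import dice
from .pablock import PABlockConfig
from .panet import ASPPConfig, BackboneConfig, PANet, PANetConfig

__all__ = ["PANetSegmenter"]


def _as_image_stack(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None]
    if X.ndim != 4:
        raise ValueError(f"X must be (n, H, W) or (n, C, H, W), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _as_mask_stack(y, spatial) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 3 or y.shape[-2:] != spatial:
        raise ValueError(f"y must be (n, H, W) masks matching X, got {y.shape}")
    if not np.isin(np.unique(y), (0, 1)).all():
        raise ValueError("y must be binary {0,1} masks")
    return y.astype(np.uint8)


class PANetSegmenter(BaseEstimator):
    """Position-attention inverted-pyramid segmenter for 2D frames.

    Parameters mirror the architecture and optimizer: ``factors`` is the
    pyramid ladder (ascending, starting at 1), ``use_pablocks`` toggles the
    attention blocks, ``pablock_r``/``pablock_d``/``pe_base`` control spatial
    compression and the sinusoidal encoding, and ``lr``/``momentum``/
    ``epochs``/``batch_size`` configure SGD with step decay.

    Fitted attributes
    -----------------
    model_ : the trained PANet
    config_ : the resolved architecture config
    history_ : per-epoch DataFrame (lr, train loss, validation Dice)
    """

    def __init__(self, factors=(1.0, 2.0), backbone="tiny", output_stride=8,
                 feature_channels=32, aspp_rates=(2, 4, 6), branch_channels=32,
                 global_pooling_branch=True, n_pablocks=3, use_pablocks=True,
                 pablock_r=64, pablock_d=64, pe_base=1000.0,
                 share_scale_weights=False, lr=0.01, momentum=0.9, epochs=10,
                 batch_size=8, lr_step_interval=None, lr_step_factor=0.1,
                 aux_weight=0.4, augment_flip=False, validation_fraction=0.0,
                 random_state=0, verbose=0):
        self.factors = factors
        self.backbone = backbone
        self.output_stride = output_stride
        self.feature_channels = feature_channels
        self.aspp_rates = aspp_rates
        self.branch_channels = branch_channels
        self.global_pooling_branch = global_pooling_branch
        self.n_pablocks = n_pablocks
        self.use_pablocks = use_pablocks
        self.pablock_r = pablock_r
        self.pablock_d = pablock_d
        self.pe_base = pe_base
        self.share_scale_weights = share_scale_weights
        self.lr = lr
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_step_interval = lr_step_interval
        self.lr_step_factor = lr_step_factor
        self.aux_weight = aux_weight
        self.augment_flip = augment_flip
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------- plumbing
    def _model_config(self, in_channels: int) -> PANetConfig:
        return PANetConfig(
            factors=tuple(float(f) for f in self.factors),
            n_classes=2,
            in_channels=in_channels,
            backbone=BackboneConfig(name=self.backbone,
                                    output_stride=self.output_stride,
                                    feature_channels=self.feature_channels),
            aspp=ASPPConfig(dilation_rates=tuple(self.aspp_rates),
                            branch_channels=self.branch_channels,
                            global_pooling_branch=self.global_pooling_branch),
            pablock=PABlockConfig(r=self.pablock_r, d=self.pablock_d,
                                  base=self.pe_base),
            n_pablocks=self.n_pablocks,
            use_pablocks=self.use_pablocks,
            share_scale_weights=self.share_scale_weights,
        )

    def _train_config(self) -> engine.TrainConfig:
        return engine.TrainConfig(
            lr=self.lr, momentum=self.momentum, epochs=self.epochs,
            batch_size=self.batch_size, seed=int(self.random_state),
            lr_step_interval=self.lr_step_interval,
            lr_step_factor=self.lr_step_factor, aux_weight=self.aux_weight,
            augment_flip=self.augment_flip)

    # ------------------------------------------------------------------ API
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on image/mask stacks; optional held-out set drives model
        selection (otherwise ``validation_fraction`` or the final epoch)."""
        X = _as_image_stack(X)
        y = _as_mask_stack(y, X.shape[-2:])
        if len(X) != len(y):
            raise ValueError("X and y have different sample counts")
        if X_val is not None:
            X_val = _as_image_stack(X_val)
            y_val = _as_mask_stack(y_val, X_val.shape[-2:])
        elif self.validation_fraction > 0:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(X))
            X, X_val = X[order[n_val:]], X[order[:n_val]]
            y, y_val = y[order[n_val:]], y[order[:n_val]]

        self.config_ = self._model_config(in_channels=X.shape[1])
        model = PANet(self.config_, np.random.default_rng(self.random_state))
        result = engine.fit_model(model, X, y, self._train_config(),
                                  X_val, y_val, verbose=self.verbose)
        self.model_ = model
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.best_val_dice_ = result.best_val_dice
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this PANetSegmenter instance is not fitted yet")

    def predict_scores(self, X) -> np.ndarray:
        """Fused per-class score maps (n, 2, H, W)."""
        self._check_fitted()
        return engine.predict_scores(self.model_, _as_image_stack(X),
                                     batch_size=self.batch_size)

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, H, W) by argmax over the fused scores."""
        self._check_fitted()
        return engine.predict_masks(self.model_, _as_image_stack(X),
                                    batch_size=self.batch_size)

    def score(self, X, y) -> float:
        """Mean per-image Dice against ground-truth masks."""
        X = _as_image_stack(X)
        y = _as_mask_stack(y, X.shape[-2:])
        preds = self.predict(X)
        return float(np.mean([dice(p, g) for p, g in zip(preds, y)]))
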