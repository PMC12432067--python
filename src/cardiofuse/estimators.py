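"""Scikit-learn-style estimators wrapping the branch and fusion networks.

All three classifiers follow the sklearn contract: constructor arguments
are hyperparameters stored verbatim, ``fit`` validates input and creates
fitted attributes with trailing underscores (``net_``, ``history_``,
``classes_``), and ``predict_proba`` returns an ``(n, 2)`` column-stacked
probability matrix. ``transform`` returns the penultimate embedding so a
fitted branch can sit inside an sklearn pipeline as a feature extractor.

``LateFusionClassifier`` consumes ``X`` as a pair ``(X_ecg, X_pcg)`` of
per-modality signal matrices. When both branches are frozen (the default,
matching the best published configuration) it trains only the fusion MLP
on cached branch embeddings, which is orders of magnitude faster than
backpropagating through the branches.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn as nn
from .models import (AudioBackboneConfig, CNN1DConfig, FusionConfig, BranchNet,
                     build_branch, build_fusion, CANONICAL_ARCHS)
from .training import TrainConfig, fit_network


def _default_cnn1d_config() -> CNN1DConfig:
    fm, ks = CANONICAL_ARCHS[0]
    return CNN1DConfig.from_table(fm, ks, pooling_mode="both", dropout_p=0.2)


def _check_Xy(X, y):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D (n_samples, n_timesteps), got shape {X.shape}")
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError(f"labels must be binary 0/1, got classes {classes}")
    return X, y


def _split_val(X, y, fraction, rng):
    n_val = max(1, int(round(fraction * len(y))))
    order = rng.permutation(len(y))
    vi, ti = order[:n_val], order[n_val:]
    return X[ti], y[ti], X[vi], y[vi]


class _BranchClassifierBase(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Shared fit/predict machinery for the unimodal branch estimators."""

    def _build_net(self) -> BranchNet:  # pragma: no cover - abstract
        raise NotImplementedError

    def _train_cfg(self) -> TrainConfig:
        return TrainConfig(max_epochs=self.max_epochs, patience=self.patience,
                           batch_size=self.batch_size,
                           learning_rate=self.learning_rate,
                           weight_decay=self.weight_decay,
                           seed=self.random_state)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = _check_Xy(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0.0, 1.0])
        if X_val is None:
            rng = np.random.default_rng(self.random_state)
            X, y, X_val, y_val = _split_val(X, y, self.val_fraction, rng)
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=np.float64).ravel()
        self.net_ = self._build_net()
        self.history_ = fit_network(self.net_, X, y, X_val, y_val, self._train_cfg())
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        out = [self.net_.forward(X[i:i + 64]) for i in range(0, len(X), 64)]
        return np.concatenate(out) if out else np.empty(0)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        p = self.net_.predict_proba(np.asarray(X, dtype=np.float32))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)

    def transform(self, X):
        """Penultimate embedding (post global pooling), rows aligned to X."""
        check_is_fitted(self, "net_")
        return self.net_.embed(np.asarray(X, dtype=np.float32))


class CNN1DClassifier(_BranchClassifierBase):
    """1D-CNN branch for a fixed-length single-channel physiological signal.

    Parameters
    ----------
    config : CNN1DConfig or None
        Architecture; None selects the depth-5 canonical configuration
        (feature maps 16-256, kernels 7,5,5,3,3, mixed pooling, dropout 0.2).
    modality : str
        "ecg" or "pcg"; used by pipeline helpers to pick the matching signal.
    """

    def __init__(self, config: CNN1DConfig | None = None, modality: str = "ecg",
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 30, patience: int = 15,
                 val_fraction: float = 0.2, weight_decay: float = 0.0,
                 random_state: int = 0):
        self.config = config
        self.modality = modality
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _build_net(self):
        return build_branch(self.config or _default_cnn1d_config(),
                            seed=self.random_state)


class PCGBackboneClassifier(_BranchClassifierBase):
    """Audio-tagging-style 2D CNN over log-mel spectrograms of heart sounds.

    Supports transfer learning: ``freeze_k`` freezes the first k of the six
    convolutional blocks, ``pretrained_weights`` (``.npz``) initializes the
    backbone (never the replaced head); without weights the backbone is
    randomly initialized and a warning is logged. ``continue_fit`` resumes
    training on new data with a different freeze depth (stage 2 of the
    transfer schedule).
    """

    def __init__(self, config: AudioBackboneConfig | None = None, fs: float = 1000.0,
                 freeze_k: int = 0, pretrained_weights: str | None = None,
                 modality: str = "pcg", learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 30, patience: int = 15,
                 val_fraction: float = 0.2, weight_decay: float = 0.0,
                 random_state: int = 0):
        self.config = config
        self.fs = fs
        self.weight_decay = weight_decay
        self.freeze_k = freeze_k
        self.pretrained_weights = pretrained_weights
        self.modality = modality
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _build_net(self):
        import dataclasses
        cfg = self.config or AudioBackboneConfig()
        cfg = dataclasses.replace(cfg, freeze_k=self.freeze_k,
                                  pretrained_weights=self.pretrained_weights
                                  or cfg.pretrained_weights)
        if not cfg.pretrained_weights:
            import logging
            logging.getLogger(__name__).warning(
                "no pretrained backbone weights provided; using random "
                "initialization (freezing/head-replacement logic unchanged)")
        return build_branch(cfg, seed=self.random_state, fs=self.fs)

    def continue_fit(self, X, y, X_val=None, y_val=None, freeze_k: int | None = None):
        """Resume training of a fitted backbone on new data (transfer stage 2)."""
        check_is_fitted(self, "net_")
        X, y = _check_Xy(X, y)
        if X_val is None:
            rng = np.random.default_rng(self.random_state + 1)
            X, y, X_val, y_val = _split_val(X, y, self.val_fraction, rng)
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=np.float64).ravel()
        if freeze_k is not None:
            self.net_.set_frozen_blocks(freeze_k)
            self.freeze_k = freeze_k
        stage2 = fit_network(self.net_, X, y, X_val, y_val, self._train_cfg())
        self.history_ = {"stage1": self.history_, "stage2": stage2}
        return self


class LateFusionClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Bimodal classifier fusing ECG and PCG branch embeddings.

    ``X`` is a pair ``(X_ecg, X_pcg)``. The branches are taken from fitted
    unimodal estimators (their dense heads are discarded; only the
    embedding extractors are reused). With both branches frozen only the
    fusion MLP trains, on cached embeddings; unfreezing a branch
    backpropagates into it end to end.
    """

    def __init__(self, ecg_estimator=None, pcg_estimator=None,
                 freeze_ecg_branch: bool = True, freeze_pcg_branch: bool = True,
                 head_hidden: int = 128, dropout_p: float = 0.2,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 30, patience: int = 15,
                 val_fraction: float = 0.2, weight_decay: float = 1e-2,
                 random_state: int = 0):
        self.ecg_estimator = ecg_estimator
        self.pcg_estimator = pcg_estimator
        self.freeze_ecg_branch = freeze_ecg_branch
        self.freeze_pcg_branch = freeze_pcg_branch
        self.head_hidden = head_hidden
        self.dropout_p = dropout_p
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.weight_decay = weight_decay
        self.random_state = random_state

    modality = "bimodal"

    def _check_X(self, X):
        if not (isinstance(X, (tuple, list)) and len(X) == 2):
            raise ValueError("X must be a pair (X_ecg, X_pcg)")
        Xe = np.asarray(X[0], dtype=np.float32)
        Xp = np.asarray(X[1], dtype=np.float32)
        if len(Xe) != len(Xp):
            raise ValueError("modalities have different sample counts")
        return Xe, Xp

    def fit(self, X, y, X_val=None, y_val=None):
        Xe, Xp, = self._check_X(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        for name, est in (("ecg", self.ecg_estimator), ("pcg", self.pcg_estimator)):
            if est is None or not hasattr(est, "net_"):
                raise ValueError(f"{name}_estimator must be a fitted branch estimator")
        self.classes_ = np.array([0.0, 1.0])
        cfg = FusionConfig(freeze_ecg_branch=self.freeze_ecg_branch,
                           freeze_pcg_branch=self.freeze_pcg_branch,
                           head_hidden=self.head_hidden, dropout_p=self.dropout_p)
        self.net_ = build_fusion(self.ecg_estimator.net_, self.pcg_estimator.net_,
                                 cfg, seed=self.random_state)
        tc = TrainConfig(max_epochs=self.max_epochs, patience=self.patience,
                         batch_size=self.batch_size, learning_rate=self.learning_rate,
                         weight_decay=self.weight_decay, seed=self.random_state)
        if X_val is None:
            rng = np.random.default_rng(self.random_state)
            n_val = max(1, int(round(self.val_fraction * len(y))))
            order = rng.permutation(len(y))
            vi, ti = order[:n_val], order[n_val:]
        else:
            Xev, Xpv = self._check_X(X_val)
            y_val = np.asarray(y_val, dtype=np.float64).ravel()
            ti = np.arange(len(y))
            vi = None
        if vi is not None:
            Xev, Xpv, y_val = Xe[vi], Xp[vi], y[vi]
            Xe, Xp, y = Xe[ti], Xp[ti], y[ti]

        if self.freeze_ecg_branch and self.freeze_pcg_branch:
            # fast path: branches are fixed feature extractors
            Ze = np.concatenate([self.net_.ecg.embed(Xe), self.net_.pcg.embed(Xp)],
                                axis=1).astype(np.float32)
            Zv = np.concatenate([self.net_.ecg.embed(Xev), self.net_.pcg.embed(Xpv)],
                                axis=1).astype(np.float32)
            head = _HeadOnly(self.net_.head)
            self.history_ = fit_network(head, Ze, y, Zv, y_val, tc)
        else:
            self.history_ = fit_network(self.net_, (Xe, Xp), y, (Xev, Xpv), y_val, tc)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        Xe, Xp = self._check_X(X)
        out = [self.net_.forward((Xe[i:i + 64], Xp[i:i + 64]))
               for i in range(0, len(Xe), 64)]
        return np.concatenate(out) if out else np.empty(0)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        p = self.net_.predict_proba(self._check_X(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)

    def transform(self, X):
        """Concatenated bimodal embedding matrix (rows aligned to X)."""
        check_is_fitted(self, "net_")
        return self.net_.embed(self._check_X(X))


class _HeadOnly:
    """Adapter exposing a dense head as a trainable net over embeddings."""

    def __init__(self, head: nn.Sequential) -> None:
        self.head = head

    @property
    def all_layers(self):
        return self.head

    def forward(self, X, training=False):
        return self.head.forward(X, training=training).ravel()

    def backward(self, dz):
        self.head.backward(dz.reshape(-1, 1))

    def predict_proba(self, X, batch_size: int = 4096):
        return nn.sigmoid(self.head.forward(X, training=False).ravel())

    def state_dict(self):
        return self.head.state_dict()

    def load_state_dict(self, state):
        self.head.load_state_dict(state)
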