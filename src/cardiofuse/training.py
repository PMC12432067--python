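"""Training protocols: early-stopped optimization, the two-stage
transfer-learning schedule, and configuration grid search.

Training minimizes binary cross-entropy with Adam and monitors validation
accuracy; when the monitor has not improved for ``patience`` consecutive
epochs, training stops and the weights from the best epoch are restored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._nn import Adam, bce_with_logits
from .dataio import BimodalSample, samples_to_arrays

log = logging.getLogger(__name__)

CORPORA = ("physionet2016", "yaseen", "circor", "synthetic")


@dataclass
class TrainConfig:
    max_epochs: int = 30
    patience: int = 15
    monitor: str = "validation_accuracy"
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TransferPlan:
    """Two-stage fine-tuning schedule for the audio backbone: stage 1 on
    pooled unimodal heart-sound corpora with the first 0-3 blocks frozen,
    stage 2 on the downstream bimodal data with 4 or 5 blocks frozen."""

    stage1_corpora: tuple[str, ...] = ("physionet2016", "circor")
    stage1_freeze_k: int = 0
    stage2_freeze_k: int = 4

    def __post_init__(self):
        if not self.stage1_corpora:
            raise ValueError("stage 1 needs at least one corpus")
        unknown = set(self.stage1_corpora) - set(CORPORA)
        if unknown:
            raise ValueError(f"unknown corpora: {sorted(unknown)}")
        if not 0 <= self.stage1_freeze_k <= 3:
            raise ValueError("stage1_freeze_k must be in {0, 1, 2, 3}")
        if self.stage2_freeze_k not in (4, 5):
            raise ValueError("stage2_freeze_k must be 4 or 5")


def _batch(X, idx):
    if isinstance(X, tuple):
        return tuple(x[idx] for x in X)
    return X[idx]


def _n_samples(X):
    return len(X[0]) if isinstance(X, tuple) else len(X)


def fit_network(net, X, y, X_val, y_val, config: TrainConfig) -> dict:
    """Early-stopped Adam/BCE training loop on a BranchNet or FusionNet.

    Returns a history dict with per-epoch train loss and the monitored
    validation accuracy; the network is left holding the best-epoch weights.
    Raises on an empty training set or non-finite loss.
    """
    n = _n_samples(X)
    if n == 0:
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.all_layers, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    history = {"epoch": [], "train_loss": [], "val_accuracy": []}
    best_monitor, best_state, best_epoch = -np.inf, None, -1
    since_improve = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = net.forward(_batch(X, idx), training=True)
            loss, dz = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            net.backward(dz)
            opt.step()
            losses.append(loss)
        proba = net.predict_proba(X_val)
        val_acc = float(np.mean((proba >= 0.5) == (np.asarray(y_val) == 1)))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_monitor:
            best_monitor, best_epoch = val_acc, epoch
            best_state = net.state_dict()
            since_improve = 0
        else:
            if val_acc == best_monitor:
                # among tying epochs keep the latest weights: equal monitor,
                # more optimization (matters when accuracy saturates early)
                best_epoch = epoch
                best_state = net.state_dict()
            since_improve += 1
            if since_improve >= config.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_monitor"] = best_monitor
    history["stopped_epoch"] = history["epoch"][-1] if history["epoch"] else -1
    return history


def simulate_early_stopping(monitor_values, patience: int = 15,
                            max_epochs: int | None = None) -> tuple[int, int]:
    """Replay the early-stopping rule on a scripted monitor sequence.

    Returns (epochs_run, best_epoch), both 1-based counts of epochs actually
    executed. Stopping triggers after ``patience`` consecutive epochs without
    strict improvement.
    """
    best, best_epoch, since = -np.inf, 0, 0
    n = len(monitor_values) if max_epochs is None else min(len(monitor_values), max_epochs)
    for e in range(n):
        if monitor_values[e] > best:
            best, best_epoch, since = monitor_values[e], e + 1, 0
        else:
            since += 1
            if since >= patience:
                return e + 1, best_epoch
    return n, best_epoch


def train(estimator, train_samples: list[BimodalSample],
          validation_samples: list[BimodalSample], config: TrainConfig | None = None):
    """Fit an estimator on BimodalSample lists; returns (estimator, history).

    Train and validation patient sets must be disjoint. The estimator's
    ``modality`` attribute ("ecg", "pcg" or "bimodal") selects which signals
    it consumes.
    """
    if not train_samples:
        raise ValueError("empty training set")
    tp = {s.patient_id for s in train_samples}
    vp = {s.patient_id for s in validation_samples}
    if tp & vp:
        raise ValueError(f"patients appear in both train and validation: {sorted(tp & vp)[:5]}")
    Xe, Xp, y = samples_to_arrays(train_samples)
    Xev, Xpv, yv = samples_to_arrays(validation_samples)
    modality = getattr(estimator, "modality", "bimodal")
    pick = {"ecg": (Xe, Xev), "pcg": (Xp, Xpv),
            "bimodal": ((Xe, Xp), (Xev, Xpv))}[modality]
    if config is not None:
        estimator.set_params(**{k: getattr(config, k) for k in
                                ("max_epochs", "patience", "batch_size", "learning_rate")})
    estimator.fit(pick[0], y, X_val=pick[1], y_val=yv)
    return estimator, estimator.history_


def run_transfer(backbone_config, plan: TransferPlan, corpora: dict,
                 downstream_train: list[BimodalSample],
                 downstream_val: list[BimodalSample],
                 config: TrainConfig | None = None, fs: float = 1000.0):
    """Two-stage transfer learning for the PCG backbone.

    ``corpora`` maps corpus name -> (X waveform array, y labels); the
    stage-1 selection from ``plan`` is pooled and fitted with
    ``stage1_freeze_k`` blocks frozen, then training continues on the
    downstream PCG windows with ``stage2_freeze_k`` blocks frozen.
    """
    from .estimators import PCGBackboneClassifier

    config = config or TrainConfig()
    missing = [c for c in plan.stage1_corpora if c not in corpora]
    if missing:
        raise ValueError(f"stage-1 corpora not provided: {missing}")
    X1 = np.concatenate([np.asarray(corpora[c][0]) for c in plan.stage1_corpora])
    y1 = np.concatenate([np.asarray(corpora[c][1]) for c in plan.stage1_corpora])
    est = PCGBackboneClassifier(
        config=backbone_config, fs=fs, freeze_k=plan.stage1_freeze_k,
        max_epochs=config.max_epochs, patience=config.patience,
        batch_size=config.batch_size, learning_rate=config.learning_rate,
        random_state=config.seed)
    log.info("transfer stage 1: corpora=%s freeze_k=%d n=%d",
             plan.stage1_corpora, plan.stage1_freeze_k, len(X1))
    # stage 1 keeps a held-out slice of the pooled corpora as its monitor
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X1))
    n_val = max(1, len(X1) // 5)
    vi, ti = order[:n_val], order[n_val:]
    est.fit(X1[ti], y1[ti], X_val=X1[vi], y_val=y1[vi])
    log.info("transfer stage 2: freeze_k=%d n=%d",
             plan.stage2_freeze_k, len(downstream_train))
    _, Xp, y = samples_to_arrays(downstream_train)
    _, Xpv, yv = samples_to_arrays(downstream_val)
    est.continue_fit(Xp, y, X_val=Xpv, y_val=yv, freeze_k=plan.stage2_freeze_k)
    return est


def grid_search(estimators: list, train_samples, validation_samples, test_samples,
                selection_metric: str = "auroc",
                selection_split: str = "validation",
                config: TrainConfig | None = None,
                replicate_paper_selection: bool = False) -> list[dict]:
    """Train each candidate and rank by the selection metric.

    Default selection uses the validation split. Selecting on the test
    split — the protocol some studies report — leaks test information into
    model choice and is only honored when ``replicate_paper_selection`` is
    set, with a logged warning. Ties break on the other metric, then on
    fewer parameters.
    """
    from .evaluation import auroc
    from .dataio import samples_to_arrays

    if not estimators:
        raise ValueError("need at least one candidate estimator")
    if selection_split == "test" and not replicate_paper_selection:
        raise ValueError(
            "test-split selection requires replicate_paper_selection=True")
    if selection_split == "test":
        log.warning("selecting models on the TEST split replicates the "
                    "published protocol but leaks test information")
    split = validation_samples if selection_split == "validation" else test_samples
    Xe, Xp, y = samples_to_arrays(split)
    results = []
    for i, est in enumerate(estimators):
        est, history = train(est, train_samples, validation_samples, config)
        modality = getattr(est, "modality", "bimodal")
        X = {"ecg": Xe, "pcg": Xp, "bimodal": (Xe, Xp)}[modality]
        proba = est.predict_proba(X)[:, 1]
        res = {
            "rank": None, "index": i, "estimator": est,
            "auroc": auroc(y, proba),
            "accuracy": float(np.mean((proba >= 0.5) == (y == 1))),
            "n_params": est.net_.n_params if hasattr(est.net_, "n_params")
            else est.net_.all_layers.n_params,
            "history": history,
        }
        results.append(res)
    other = "accuracy" if selection_metric == "auroc" else "auroc"
    results.sort(key=lambda r: (-r[selection_metric], -r[other], r["n_params"]))
    for rank, r in enumerate(results, start=1):
        r["rank"] = rank
    return results
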