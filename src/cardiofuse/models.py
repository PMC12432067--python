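"""Model families: 1D-CNN branches, an audio-tagging-style PCG backbone,
and the late-fusion bimodal network.

Three declarative configs drive construction:

* :class:`CNN1DConfig` — a stack of conv blocks (conv -> batch norm -> ReLU
  -> pool) with decreasing kernel sizes, global average pooling and a small
  dense head. :func:`canonical_configs` enumerates the four canonical
  depth-5/6/7/8 variants crossed with three pooling modes and two dropout
  settings (24 configurations).
* :class:`AudioBackboneConfig` — a CNN14-style 2D backbone over log-mel
  spectrograms: six double-conv blocks with channel doubling, supporting
  freezing of the first ``freeze_k`` blocks for transfer learning and
  optional loading of pretrained weights (the classification head is always
  freshly initialized).
* :class:`FusionConfig` — the late-fusion head: branch embeddings are
  concatenated and classified by an MLP; either branch can be frozen.

Pooling halves the time axis (kernel = stride = 2), so the receptive field
of deeper blocks grows geometrically; :func:`receptive_field` computes the
exact input span of one output unit so configurations can be checked
against the design rule that a unit should see at least one full average
heartbeat (taken as 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn as nn

AVG, MAX = "avg", "max"
POOLING_MODES = ("all_avg", "all_max", "both")


# ---------------------------------------------------------------------------
# configs


@dataclass
class ConvBlockSpec:
    out_channels: int
    kernel: int
    pool_type: str = AVG
    pool_size: int = 2
    frozen: bool = False

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.pool_type not in (AVG, MAX):
            raise ValueError(f"pool_type must be 'avg' or 'max', got {self.pool_type}")


def pooling_schedule(n_layers: int, mode: str) -> list[str]:
    """Pool types per block: 'both' uses avg for the first floor(n/2)+1
    blocks and max for the rest."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if mode == "all_avg":
        return [AVG] * n_layers
    if mode == "all_max":
        return [MAX] * n_layers
    if mode == "both":
        n_avg = n_layers // 2 + 1
        return [AVG] * n_avg + [MAX] * (n_layers - n_avg)
    raise ValueError(f"unknown pooling mode {mode!r}")


@dataclass
class CNN1DConfig:
    blocks: list[ConvBlockSpec]
    pooling_mode: str = "both"
    dropout_p: float = 0.2
    head_hidden: int = 64
    n_outputs: int = 1

    def __post_init__(self):
        kernels = [b.kernel for b in self.blocks]
        if any(k2 > k1 for k1, k2 in zip(kernels, kernels[1:])):
            raise ValueError(f"kernel sizes must be non-increasing, got {kernels}")
        sched = pooling_schedule(len(self.blocks), self.pooling_mode)
        for b, p in zip(self.blocks, sched):
            b.pool_type = p

    @classmethod
    def from_table(cls, feature_maps: tuple[int, ...], kernels: tuple[int, ...],
                   pooling_mode: str = "both", dropout_p: float = 0.2,
                   **kw) -> "CNN1DConfig":
        blocks = [ConvBlockSpec(out_channels=c, kernel=k)
                  for c, k in zip(feature_maps, kernels)]
        return cls(blocks=blocks, pooling_mode=pooling_mode, dropout_p=dropout_p, **kw)

    @property
    def embedding_dim(self) -> int:
        return self.blocks[-1].out_channels


CANONICAL_ARCHS = (
    ((16, 32, 64, 128, 256), (7, 5, 5, 3, 3)),
    ((16, 32, 64, 128, 256, 256), (7, 7, 5, 5, 3, 3)),
    ((16, 32, 64, 64, 128, 256, 256), (7, 7, 5, 5, 3, 3, 3)),
    ((16, 32, 64, 64, 128, 128, 256, 256), (7, 7, 5, 5, 5, 3, 3, 3)),
)


def canonical_configs() -> list[CNN1DConfig]:
    """All 24 canonical unimodal 1D-CNN configurations: the four depth
    5/6/7/8 architectures crossed with {all_avg, all_max, both} pooling and
    dropout in {0, 0.2}."""
    out = []
    for fm, ks in CANONICAL_ARCHS:
        for mode in POOLING_MODES:
            for p in (0.0, 0.2):
                out.append(CNN1DConfig.from_table(fm, ks, pooling_mode=mode,
                                                  dropout_p=p))
    return out


@dataclass
class AudioBackboneConfig:
    n_blocks: int = 6
    base_channels: int = 64     # doubles per block; embedding = base * 2**(n_blocks-1)
    mel_bins: int = 64
    fft_size: int = 256
    hop: int = 80
    freeze_k: int = 0
    pretrained_weights: str | None = None
    head_hidden: int = 256
    dropout_p: float = 0.2

    def __post_init__(self):
        if not 0 <= self.freeze_k <= self.n_blocks:
            raise ValueError(f"freeze_k must be in [0, {self.n_blocks}]")

    @property
    def embedding_dim(self) -> int:
        return self.base_channels * 2 ** (self.n_blocks - 1)


@dataclass
class FusionConfig:
    freeze_ecg_branch: bool = True
    freeze_pcg_branch: bool = True
    head_hidden: int = 128
    dropout_p: float = 0.2


# ---------------------------------------------------------------------------
# receptive field


def receptive_field_layers(layers: list[tuple[int, int]]) -> int:
    """Receptive field of a chain of (kernel, stride) layers:
    RF = 1 + sum_i (k_i - 1) * J_i with J_i the product of the strides of
    all layers before layer i."""
    rf, jump = 1, 1
    for k, s in layers:
        rf += (k - 1) * jump
        jump *= s
    return rf


def receptive_field(config: CNN1DConfig) -> int:
    """Exact receptive field (input samples per output unit) of the conv
    stack; convs have stride 1, pools have kernel = stride = pool_size."""
    chain = []
    for b in config.blocks:
        chain.append((b.kernel, 1))
        chain.append((b.pool_size, b.pool_size))
    return receptive_field_layers(chain)


def check_receptive_field(config: CNN1DConfig, fs: float,
                          heartbeat_s: float = 1.0) -> bool:
    """Warn (not error) when the receptive field covers less than one
    average heartbeat at the given sampling rate."""
    ok = receptive_field(config) >= heartbeat_s * fs
    if not ok:
        import warnings
        warnings.warn(
            f"receptive field {receptive_field(config)} samples < one average "
            f"heartbeat ({heartbeat_s:.2f} s at {fs:.0f} Hz)", stacklevel=2)
    return ok


# ---------------------------------------------------------------------------
# networks


class BranchNet:
    """A unimodal branch: feature extractor -> embedding -> dense head.

    ``features`` maps a signal batch to a fixed-size embedding (global
    average pooling over time); ``head`` maps embeddings to a single logit.
    ``blocks`` keeps per-block sub-sequentials for freezing control.
    """

    def __init__(self, blocks: list[nn.Sequential], head: nn.Sequential,
                 embedding_dim: int, frontend=None) -> None:
        self.blocks = blocks
        self.features = nn.Sequential(blocks + [nn.GlobalAvgPool()])
        self.head = head
        self.embedding_dim = embedding_dim
        self.frontend = frontend  # optional fixed waveform->image transform

    # -- shape plumbing ---------------------------------------------------
    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if self.frontend is not None:
            return self.frontend(X)
        return X[:, :, None]  # (N, L) -> (N, L, 1)

    def forward(self, X, training=False, capture=False) -> np.ndarray:
        emb = self.features.forward(self._prep(X), training=training, capture=capture)
        return self.head.forward(emb, training=training).ravel()

    def backward(self, dlogit: np.ndarray, capture=False) -> None:
        demb = self.head.backward(dlogit.reshape(-1, 1))
        self.features.backward(demb, capture=capture)

    def embed(self, X, batch_size: int = 64) -> np.ndarray:
        X = np.asarray(X)
        out = [self.features.forward(self._prep(X[i:i + batch_size]),
                                     training=False)
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out).astype(np.float64) if out \
            else np.empty((0, self.embedding_dim))

    def predict_proba(self, X, batch_size: int = 64) -> np.ndarray:
        # modest batches keep per-layer forward caches small
        X = np.asarray(X)
        out = [nn.sigmoid(self.forward(X[i:i + batch_size]))
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out) if out else np.empty(0)

    # -- freezing & bookkeeping -------------------------------------------
    def set_frozen_blocks(self, k: int) -> None:
        for i, blk in enumerate(self.blocks):
            for layer in blk.iter_layers():
                layer.frozen = i < k

    def set_all_frozen(self, frozen: bool) -> None:
        for blk in self.blocks:
            for layer in blk.iter_layers():
                layer.frozen = frozen

    @property
    def all_layers(self) -> nn.Sequential:
        return nn.Sequential([self.features, self.head])

    def conv_layers(self) -> list:
        return [l for l in self.features.iter_layers()
                if isinstance(l, (nn.Conv1d, nn.Conv2d))]

    def trainable_param_count(self) -> int:
        return self.all_layers.trainable_param_count()

    @property
    def n_params(self) -> int:
        return self.all_layers.n_params

    def state_dict(self):
        return self.all_layers.state_dict()

    def load_state_dict(self, state):
        self.all_layers.load_state_dict(state)


def build_branch(config, seed: int = 0, fs: float | None = None,
                 dtype=np.float32) -> BranchNet:
    """Instantiate a branch network from a declarative config.

    ``CNN1DConfig`` builds the 1D conv stack; ``AudioBackboneConfig`` builds
    the log-mel 2D backbone (``fs`` required). Initialization is
    deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(config, CNN1DConfig):
        blocks, in_ch = [], 1
        for spec in config.blocks:
            pool = nn.AvgPool1d(spec.pool_size) if spec.pool_type == AVG \
                else nn.MaxPool1d(spec.pool_size)
            blocks.append(nn.Sequential([
                nn.Conv1d(in_ch, spec.out_channels, spec.kernel, rng, dtype=dtype),
                nn.BatchNorm(spec.out_channels, dtype=dtype),
                nn.ReLU(), pool]))
            in_ch = spec.out_channels
        head = nn.Sequential([
            nn.Dense(config.embedding_dim, config.head_hidden, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(config.dropout_p, rng),
            nn.Dense(config.head_hidden, config.n_outputs, rng, dtype=dtype)])
        return BranchNet(blocks, head, config.embedding_dim)

    if isinstance(config, AudioBackboneConfig):
        if fs is None:
            raise ValueError("fs is required to build the audio backbone")
        frontend = nn.LogMelFrontend(fs, n_fft=config.fft_size, hop=config.hop,
                                     n_mels=config.mel_bins)
        blocks, in_ch = [], 1
        for b in range(config.n_blocks):
            out_ch = config.base_channels * 2 ** b
            blocks.append(nn.Sequential([
                nn.Conv2d(in_ch, out_ch, 3, rng, dtype=dtype),
                nn.BatchNorm(out_ch, dtype=dtype), nn.ReLU(),
                nn.Conv2d(out_ch, out_ch, 3, rng, dtype=dtype),
                nn.BatchNorm(out_ch, dtype=dtype), nn.ReLU(),
                nn.AvgPool2d(2)]))
            in_ch = out_ch
        head = nn.Sequential([
            nn.Dense(config.embedding_dim, config.head_hidden, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(config.dropout_p, rng),
            nn.Dense(config.head_hidden, 1, rng, dtype=dtype)])
        net = BranchNet(blocks, head, config.embedding_dim, frontend=frontend)
        if config.pretrained_weights:
            report = load_pretrained(net, config.pretrained_weights)
            import logging
            logging.getLogger(__name__).info(
                "loaded pretrained backbone weights: %d matched, %d unmatched",
                len(report["matched"]), len(report["unmatched"]))
        net.set_frozen_blocks(config.freeze_k)
        return net

    raise TypeError(f"unsupported config type {type(config).__name__}")


def load_pretrained(net: BranchNet, path: str) -> dict:
    """Load backbone weights from an ``.npz`` checkpoint into all layers
    except the (freshly initialized) head; returns {matched, unmatched}.
    A shape mismatch outside the head raises with the offending tensors."""
    state = dict(np.load(path))
    own = net.features.state_dict()
    matched, unmatched, bad = [], [], []
    for name, v in state.items():
        if name.startswith("head"):
            continue  # the replaced classification head is never loaded
        if name in own:
            if own[name].shape != v.shape:
                bad.append(f"{name}: checkpoint {v.shape} vs model {own[name].shape}")
            else:
                matched.append(name)
        else:
            unmatched.append(name)
    if bad:
        raise ValueError("pretrained weight shape mismatch: " + "; ".join(bad))
    net.features.load_state_dict({k: state[k] for k in matched})
    return {"matched": matched, "unmatched": unmatched}


class FusionNet:
    """Late fusion: concat(ecg embedding, pcg embedding) -> MLP -> logit."""

    def __init__(self, ecg: BranchNet, pcg: BranchNet, config: FusionConfig,
                 seed: int = 0, dtype=np.float32) -> None:
        rng = np.random.default_rng(seed)
        self.ecg, self.pcg, self.config = ecg, pcg, config
        cat = ecg.embedding_dim + pcg.embedding_dim
        self.head = nn.Sequential([
            nn.Dense(cat, config.head_hidden, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(config.dropout_p, rng),
            nn.Dense(config.head_hidden, 1, rng, dtype=dtype)])
        self.ecg.set_all_frozen(config.freeze_ecg_branch)
        self.pcg.set_all_frozen(config.freeze_pcg_branch)
        self.embedding_dim = cat

    def forward(self, X, training=False, capture=False) -> np.ndarray:
        Xe, Xp = X
        ze = self.ecg.features.forward(self.ecg._prep(Xe), training=training,
                                       capture=capture)
        zp = self.pcg.features.forward(self.pcg._prep(Xp), training=training,
                                       capture=capture)
        self._dims = (ze.shape[1], zp.shape[1])
        return self.head.forward(np.concatenate([ze, zp], axis=1),
                                 training=training).ravel()

    def backward(self, dlogit: np.ndarray, capture=False) -> None:
        dcat = self.head.backward(dlogit.reshape(-1, 1))
        de, dp = dcat[:, :self._dims[0]], dcat[:, self._dims[0]:]
        self.ecg.features.backward(de, capture=capture)
        self.pcg.features.backward(dp, capture=capture)

    def embed(self, X) -> np.ndarray:
        Xe, Xp = X
        return np.concatenate([self.ecg.embed(Xe), self.pcg.embed(Xp)], axis=1)

    def predict_proba(self, X, batch_size: int = 64) -> np.ndarray:
        Xe, Xp = np.asarray(X[0]), np.asarray(X[1])
        out = [nn.sigmoid(self.forward((Xe[i:i + batch_size], Xp[i:i + batch_size])))
               for i in range(0, len(Xe), batch_size)]
        return np.concatenate(out) if out else np.empty(0)

    @property
    def all_layers(self) -> nn.Sequential:
        return nn.Sequential([self.ecg.all_layers, self.pcg.all_layers, self.head])

    def trainable_param_count(self) -> int:
        return self.all_layers.trainable_param_count()

    def state_dict(self):
        return self.all_layers.state_dict()

    def load_state_dict(self, state):
        self.all_layers.load_state_dict(state)


def build_fusion(ecg_branch: BranchNet, pcg_branch: BranchNet,
                 fusion_config: FusionConfig | None = None, seed: int = 0) -> FusionNet:
    return FusionNet(ecg_branch, pcg_branch, fusion_config or FusionConfig(), seed=seed)


def extract_embeddings(model, X) -> np.ndarray:
    """Embedding matrix (rows aligned to input order, eval mode, deterministic)."""
    emb = model.embed(X)
    if not np.all(np.isfinite(emb)):
        raise FloatingPointError("non-finite values in embeddings")
    return emb
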