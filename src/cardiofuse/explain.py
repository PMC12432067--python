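"""Attribution methods for 1D physiological signals and the global
modality-contribution metric.

Three complementary views of what a trained bimodal model looks at:

* **Grad-CAM** — channel-weighted activation map from the last conv layer
  of a branch, weights being the time-averaged gradients of the
  abnormal-class logit; ReLU'd and linearly upsampled to signal length.
* **Multi-Layer Grad-CAM** — the same map from each of the last three conv
  layers (with absolute time-averaged-gradient channel weights), fused by
  a convex combination whose weights are the absolute Pearson correlation
  of each upsampled map with the absolute value of the input signal
  (an envelope proxy); a constant map gets weight 0.
* **Time-series LIME** — the input pair is cut into equal segments, half
  of the segments are perturbed per draw by noise matched to each
  segment's local mean/SD, and a proximity-weighted ridge surrogate maps
  binary masks to model probabilities; coefficients score segments.

Because ECG and PCG windows are not beat-aligned across patients, per-time
attribution is not pooled; instead each modality's contribution is the mean
of its heatmap after joint normalization by the maximum over the sample's
ECG+PCG pair — the only scope that makes the two modality means comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .dataio import BimodalSample
from .evaluation import significance_stars, wilcoxon_signed_rank
from .models import BranchNet, FusionNet

METHODS = ("gradcam", "ml_gradcam", "lime")


@dataclass
class Heatmap:
    values: np.ndarray
    modality: str
    sample_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class LayerFusionWeights:
    weights: np.ndarray  # one |Pearson r|-derived weight per fused layer
    degenerate: bool = False


@dataclass
class LimeExplanation:
    segment_weights: np.ndarray
    n_segments: int           # per modality
    n_perturbations: int
    surrogate_r2: float
    intercept: float
    seed: int
    segment_bounds: dict      # modality -> list of (start, stop) sample indices


@dataclass
class ModalityContribution:
    ecg_mean: float
    pcg_mean: float
    class_label: str
    method: str
    degenerate: bool = False


def _upsample(map_coarse: np.ndarray, length: int) -> np.ndarray:
    if map_coarse.size == length:
        return map_coarse.astype(np.float64)
    if map_coarse.size == 1:
        return np.full(length, float(map_coarse[0]))
    x_old = np.linspace(0.0, 1.0, map_coarse.size)
    x_new = np.linspace(0.0, 1.0, length)
    return np.interp(x_new, x_old, map_coarse)


def _branch_of(model, branch: str) -> BranchNet:
    if isinstance(model, FusionNet):
        return model.ecg if branch == "ecg" else model.pcg
    return model


def _forward_backward(model, sample: BimodalSample, branch: str) -> None:
    """One captured forward/backward pass of the abnormal-class logit."""
    Xe = sample.ecg.samples[None, :].astype(np.float32)
    Xp = sample.pcg.samples[None, :].astype(np.float32)
    if isinstance(model, FusionNet):
        model.forward((Xe, Xp), training=False, capture=True)
        model.backward(np.ones(1), capture=True)
    else:
        X = Xe if branch == "ecg" else Xp
        model.forward(X, training=False, capture=True)
        model.backward(np.ones(1), capture=True)


def _conv_time_map(layer) -> tuple[np.ndarray, np.ndarray]:
    """Activation and gradient at a captured conv layer, collapsed to
    (time, channels). 2D spectrogram layers are averaged over frequency."""
    act = np.asarray(layer.cached_output, dtype=np.float64)[0]
    grad = np.asarray(layer.cached_output_grad, dtype=np.float64)[0]
    if act.ndim == 3:  # (mel, frames, C) -> (frames, C)
        act, grad = act.mean(axis=0), grad.mean(axis=0)
    return act, grad


def grad_cam(model, sample: BimodalSample, branch: str = "ecg",
             target_layer=None) -> Heatmap:
    """Gradient-weighted class activation map from a branch's final conv
    layer, upsampled to the input signal length. Values are >= 0."""
    net = _branch_of(model, branch)
    convs = net.conv_layers()
    if not convs:
        raise ValueError("branch has no convolutional layers")
    layer = convs[-1] if target_layer is None else target_layer
    _forward_backward(model, sample, branch)
    act, grad = _conv_time_map(layer)
    if act.shape[-1] == 0:
        raise RuntimeError("zero-length activations at the target layer")
    weights = grad.mean(axis=0)  # time-averaged gradient per channel
    cam = np.maximum(act @ weights, 0.0)
    length = (sample.ecg if branch == "ecg" else sample.pcg).samples.size
    return Heatmap(values=_upsample(cam, length), modality=branch.upper(),
                   sample_id=sample.sample_id)


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def fuse_layer_maps(maps: list[np.ndarray], reference: np.ndarray,
                    ) -> tuple[np.ndarray, LayerFusionWeights]:
    """Convex combination of layer maps with |Pearson r|-vs-reference
    weights, renormalized to sum 1. A constant map (undefined correlation)
    gets weight 0; if all correlations vanish the result is flagged
    degenerate and weights fall back to uniform."""
    weights = np.array([_abs_pearson(m, reference) for m in maps])
    total = weights.sum()
    degenerate = total == 0
    norm_w = (np.full(len(maps), 1.0 / len(maps)) if degenerate
              else weights / total)
    fused = np.einsum("l,lt->t", norm_w, np.asarray(maps))
    return fused, LayerFusionWeights(weights=norm_w, degenerate=degenerate)


def multilayer_grad_cam(model, sample: BimodalSample, branch: str = "ecg",
                        n_layers: int = 3) -> tuple[Heatmap, LayerFusionWeights]:
    """Fuse activation maps from the last ``n_layers`` conv layers.

    Each layer map uses absolute time-averaged-gradient channel weights;
    maps are upsampled to signal length and combined with weights
    proportional to |Pearson r| against the absolute input signal,
    renormalized to sum 1 (constant maps get weight 0)."""
    net = _branch_of(model, branch)
    convs = net.conv_layers()
    if len(convs) < n_layers:
        raise ValueError(f"branch has {len(convs)} conv layers; need >= {n_layers}")
    _forward_backward(model, sample, branch)
    signal = (sample.ecg if branch == "ecg" else sample.pcg).samples
    maps = []
    for layer in convs[-n_layers:]:
        act, grad = _conv_time_map(layer)
        w = np.abs(grad.mean(axis=0))
        maps.append(_upsample(np.maximum(act @ w, 0.0), signal.size))
    fused, lfw = fuse_layer_maps(maps, np.abs(signal))
    return (Heatmap(values=fused, modality=branch.upper(),
                    sample_id=sample.sample_id), lfw)


# ---------------------------------------------------------------------------
# LIME for paired time series


def _segment_bounds(length: int, n_segments: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, length, n_segments + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def lime_timeseries(model, sample: BimodalSample, n_segments: int = 16,
                    n_perturbations: int = 500, seed: int = 0,
                    kernel_width: float = 0.25, ridge_alpha: float = 1.0,
                    ) -> LimeExplanation:
    """Local surrogate explanation over jointly segmented ECG+PCG.

    Each modality is cut into ``n_segments`` equal-duration segments
    (2 * n_segments joint features). Every perturbation masks a uniformly
    random half of all segments, replacing masked samples by Gaussian noise
    with that segment's own mean and SD. A ridge surrogate is fitted from
    mask vectors to model probability with proximity weights
    exp(-d^2 / kernel_width^2), d being the cosine distance of the mask to
    the all-ones (unperturbed) mask. Deterministic given ``seed``.
    """
    total_seg = 2 * n_segments
    if n_perturbations < total_seg:
        raise ValueError(
            f"n_perturbations ({n_perturbations}) must be >= number of "
            f"segments ({total_seg}); the surrogate would be underdetermined")
    rng = np.random.default_rng(seed)
    sigs = {"ecg": sample.ecg.samples, "pcg": sample.pcg.samples}
    bounds = {m: _segment_bounds(s.size, n_segments) for m, s in sigs.items()}
    seg_stats = {m: [(sigs[m][a:b].mean(), sigs[m][a:b].std())
                     for a, b in bounds[m]] for m in sigs}

    masks = np.ones((n_perturbations, total_seg), dtype=np.float64)
    n_off = total_seg // 2
    for i in range(n_perturbations):
        off = rng.choice(total_seg, size=n_off, replace=False)
        masks[i, off] = 0.0

    Xe = np.repeat(sigs["ecg"][None, :], n_perturbations, axis=0)
    Xp = np.repeat(sigs["pcg"][None, :], n_perturbations, axis=0)
    for i in range(n_perturbations):
        for j in np.flatnonzero(masks[i] == 0.0):
            m, k = ("ecg", j) if j < n_segments else ("pcg", j - n_segments)
            a, b = bounds[m][k]
            mu, sd = seg_stats[m][k]
            noise = mu + sd * rng.standard_normal(b - a)
            (Xe if m == "ecg" else Xp)[i, a:b] = noise

    if isinstance(model, FusionNet):
        proba = model.predict_proba((Xe.astype(np.float32), Xp.astype(np.float32)))
        orig = model.predict_proba((sigs["ecg"][None, :].astype(np.float32),
                                    sigs["pcg"][None, :].astype(np.float32)))[0]
    else:
        X = Xe if model_modality(model) == "ecg" else Xp
        proba = model.predict_proba(X.astype(np.float32))
        xs = sigs[model_modality(model)][None, :].astype(np.float32)
        orig = model.predict_proba(xs)[0]

    ones = np.ones(total_seg)
    cos = masks @ ones / (np.linalg.norm(masks, axis=1) * np.linalg.norm(ones))
    d = 1.0 - cos
    w = np.exp(-(d ** 2) / kernel_width ** 2)
    ridge = Ridge(alpha=ridge_alpha)
    ridge.fit(masks, proba, sample_weight=w)
    r2 = float(ridge.score(masks, proba, sample_weight=w))
    return LimeExplanation(segment_weights=ridge.coef_.astype(np.float64),
                           n_segments=n_segments, n_perturbations=n_perturbations,
                           surrogate_r2=r2, intercept=float(ridge.intercept_ + 0.0),
                           seed=seed, segment_bounds=bounds)


def model_modality(model) -> str:
    if isinstance(model, FusionNet):
        return "bimodal"
    fe = getattr(model, "frontend", None)
    return "pcg" if fe is not None else "ecg"


def lime_heatmaps(explanation: LimeExplanation, sample: BimodalSample,
                  ) -> tuple[Heatmap, Heatmap]:
    """Expand |segment coefficient| to sample resolution per modality."""
    out = {}
    coefs = np.abs(explanation.segment_weights)
    n = explanation.n_segments
    for m, offset in (("ecg", 0), ("pcg", n)):
        sig = getattr(sample, m).samples
        values = np.zeros(sig.size)
        for k, (a, b) in enumerate(explanation.segment_bounds[m]):
            values[a:b] = coefs[offset + k]
        out[m] = Heatmap(values=values, modality=m.upper(),
                         sample_id=sample.sample_id)
    return out["ecg"], out["pcg"]


# ---------------------------------------------------------------------------
# modality contribution


def modality_contribution(ecg_heatmap: Heatmap, pcg_heatmap: Heatmap,
                          method: str, class_label: str) -> ModalityContribution:
    """Mean of each modality's heatmap after normalizing both by their joint
    maximum, so the two means are directly comparable within a sample."""
    ve, vp = ecg_heatmap.values, pcg_heatmap.values
    if (ve < 0).any() or (vp < 0).any():
        raise ValueError("heatmaps must be non-negative")
    joint_max = max(ve.max(initial=0.0), vp.max(initial=0.0))
    if joint_max == 0:
        return ModalityContribution(0.0, 0.0, class_label, method, degenerate=True)
    return ModalityContribution(ecg_mean=float(ve.mean() / joint_max),
                                pcg_mean=float(vp.mean() / joint_max),
                                class_label=class_label, method=method)


def sample_contributions(model, samples: list[BimodalSample],
                         methods=METHODS, lime_kwargs: dict | None = None,
                         ) -> list[ModalityContribution]:
    """Per-sample modality contributions for each requested method."""
    lime_kwargs = lime_kwargs or {}
    out = []
    for i, s in enumerate(samples):
        for method in methods:
            if method == "gradcam":
                he = grad_cam(model, s, "ecg")
                hp = grad_cam(model, s, "pcg")
            elif method == "ml_gradcam":
                he, _ = multilayer_grad_cam(model, s, "ecg")
                hp, _ = multilayer_grad_cam(model, s, "pcg")
            elif method == "lime":
                kw = dict(lime_kwargs)
                kw.setdefault("seed", 1000 + i)
                expl = lime_timeseries(model, s, **kw)
                he, hp = lime_heatmaps(expl, s)
            else:
                raise ValueError(f"unknown method {method!r}")
            out.append(modality_contribution(he, hp, method, s.label))
    return out


def export_heatmap_csv(heatmap: Heatmap, fs: float, path: str) -> None:
    """Write a heatmap as a two-column (time, value) CSV."""
    import pandas as pd

    t = np.arange(heatmap.values.size) / fs
    pd.DataFrame({"time": t, "value": heatmap.values}).to_csv(path, index=False)


def plot_heatmap_overlay(heatmap: Heatmap, signal: np.ndarray, fs: float,
                         path: str | None = None):
    """Signal trace with the attribution map shaded underneath."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(signal.size) / fs
    fig, ax = plt.subplots(figsize=(9, 2.5))
    ax.plot(t, signal, lw=0.6, color="k")
    m = heatmap.values.max()
    ax.imshow(heatmap.values[None, :], aspect="auto", cmap="Reds",
              alpha=0.5, extent=(0, t[-1], signal.min(), signal.max()),
              vmin=0, vmax=m if m > 0 else 1)
    ax.set_xlabel("time [s]")
    ax.set_title(f"{heatmap.modality} attribution ({heatmap.sample_id})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def contribution_boxplot(contributions: list[ModalityContribution],
                         method: str, path: str | None = None):
    """Per-class boxplots of ECG vs PCG contribution means for one method,
    annotated with the paired Wilcoxon significance stars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = [c for c in contributions if c.method == method]
    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels, positions = [], [], []
    pos = 1
    for cls in ("normal", "abnormal"):
        cc = [c for c in sub if c.class_label == cls]
        if not cc:
            continue
        ecg = [c.ecg_mean for c in cc]
        pcg = [c.pcg_mean for c in cc]
        data += [ecg, pcg]
        labels += [f"{cls}\nECG", f"{cls}\nPCG"]
        positions += [pos, pos + 1]
        if len(cc) >= 5:
            p = wilcoxon_signed_rank(ecg, pcg)
            top = max(max(ecg), max(pcg))
            ax.text(pos + 0.5, top * 1.05, significance_stars(p),
                    ha="center", fontsize=10)
        pos += 3
    ax.boxplot(data, positions=positions, widths=0.8)
    ax.set_xticks(positions, labels)
    ax.set_ylabel("mean normalized heatmap value")
    ax.set_title(method)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def compare_contributions(contributions: list[ModalityContribution]) -> list[dict]:
    """Per (method, class): paired Wilcoxon signed-rank on the ECG vs PCG
    contribution means across samples, with medians and significance stars.
    A class/method cell with < 5 samples is skipped with a warning."""
    import warnings

    rows = []
    for method in METHODS:
        for cls in ("normal", "abnormal"):
            sub = [c for c in contributions
                   if c.method == method and c.class_label == cls]
            if not sub:
                continue
            if len(sub) < 5:
                warnings.warn(f"skipping {method}/{cls}: only {len(sub)} samples",
                              stacklevel=2)
                continue
            ecg = np.array([c.ecg_mean for c in sub])
            pcg = np.array([c.pcg_mean for c in sub])
            p = wilcoxon_signed_rank(ecg, pcg)
            rows.append({
                "method": method, "class": cls, "n": len(sub),
                "median_ecg": float(np.median(ecg)),
                "median_pcg": float(np.median(pcg)),
                "p": p, "stars": significance_stars(p),
            })
    return rows
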