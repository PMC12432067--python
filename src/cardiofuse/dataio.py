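"""Recordings, bimodal samples, windowed augmentation and patient-level splits.

A :class:`Recording` is one single-channel physiological trace (ECG or PCG)
with its sampling rate; a :class:`BimodalSample` pairs an 8-second ECG window
with the simultaneous PCG window and carries the binary label and patient id
— the atomic training unit throughout the package.

The augmentation scheme cuts long recordings into fixed 8 s windows with a
label-dependent stride (8 s for abnormal recordings, 3 s for normal ones) so
that over-represented normal recordings yield more, overlapping, windows and
the window-level class distribution approaches balance. Splitting is always
by patient: no patient contributes windows to more than one partition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

NORMAL, ABNORMAL = "normal", "abnormal"
_LABELS = {NORMAL: 0, ABNORMAL: 1}


def label_to_int(label: str) -> int:
    try:
        return _LABELS[label]
    except KeyError:
        raise ValueError(f"unparseable label {label!r}; expected 'normal' or 'abnormal'")


@dataclass
class Recording:
    """One single-channel signal with provenance."""

    samples: np.ndarray
    fs: float
    modality: str  # "ECG" | "PCG"
    record_id: str
    patient_id: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def standardized(self) -> "Recording":
        """Per-recording z-score; a zero-variance signal maps to all-zeros."""
        sd = self.samples.std()
        if sd == 0:
            return replace(self, samples=np.zeros_like(self.samples))
        return replace(self, samples=(self.samples - self.samples.mean()) / sd)

    def resampled(self, fs_target: float) -> "Recording":
        if fs_target == self.fs:
            return self
        from fractions import Fraction
        frac = Fraction(fs_target / self.fs).limit_denominator(1000)
        out = resample_poly(self.samples, frac.numerator, frac.denominator)
        return replace(self, samples=out, fs=fs_target)


@dataclass
class BimodalSample:
    ecg: Recording
    pcg: Recording
    label: str
    patient_id: str
    window_index: int = 0
    subclass: str = ""
    sample_id: str = ""

    def __post_init__(self):
        if self.label not in _LABELS:
            raise ValueError(f"unparseable label {self.label!r}")
        if self.ecg.patient_id != self.pcg.patient_id:
            raise ValueError("ECG and PCG belong to different patients")
        tol = max(1.0 / self.ecg.fs, 1.0 / self.pcg.fs)
        if abs(self.ecg.duration - self.pcg.duration) > tol:
            raise ValueError(
                f"modality durations differ: ECG {self.ecg.duration:.4f}s vs "
                f"PCG {self.pcg.duration:.4f}s")
        if not self.sample_id:
            self.sample_id = f"{self.ecg.record_id}_w{self.window_index}"

    @property
    def y(self) -> int:
        return label_to_int(self.label)

    @property
    def duration(self) -> float:
        return self.ecg.duration


@dataclass
class SplitAssignment:
    """Partition of samples into train/validation/test, grouped by patient."""

    mapping: dict[str, str]
    seed: int
    patient_of: dict[str, str] = field(default_factory=dict)

    def partitions(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
        for sid, part in self.mapping.items():
            out[part].append(sid)
        return out

    def subset(self, samples: list[BimodalSample], partition: str) -> list[BimodalSample]:
        return [s for s in samples if self.mapping.get(s.sample_id) == partition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.mapping), "partition": list(self.mapping.values())})


# ---------------------------------------------------------------------------
# windowed augmentation


def window_count(duration: float, window: float, stride: float) -> int:
    """Closed form floor((D - W)/s) + 1 for D >= W, else 0."""
    if duration < window:
        return 0
    # guard float jitter at exact multiples (e.g. 14.0 with stride 3)
    return int(np.floor((duration - window) / stride + 1e-9)) + 1


def window_augment(ecg: Recording, pcg: Recording, label: str, window: float = 8.0,
                   stride_abnormal: float = 8.0, stride_normal: float = 3.0,
                   ) -> list[BimodalSample]:
    """Cut a paired recording into fixed windows with a label-dependent stride.

    Both modalities are cut at identical absolute time intervals
    [k*s, k*s + window); a recording shorter than one window yields an
    empty list.
    """
    if window <= 0 or stride_abnormal <= 0 or stride_normal <= 0:
        raise ValueError("window and strides must be positive")
    label_int = label_to_int(label)
    tol = max(1.0 / ecg.fs, 1.0 / pcg.fs)
    if abs(ecg.duration - pcg.duration) > tol:
        raise ValueError("ECG and PCG must cover the same time span")
    stride = stride_abnormal if label_int == 1 else stride_normal
    n = window_count(min(ecg.duration, pcg.duration), window, stride)
    out = []
    for k in range(n):
        t0 = k * stride
        cuts = {}
        for rec in (ecg, pcg):
            i0 = int(round(t0 * rec.fs))
            i1 = i0 + int(round(window * rec.fs))
            cuts[rec.modality] = replace(
                rec, samples=rec.samples[i0:i1],
                record_id=f"{rec.record_id}_w{k}")
        out.append(BimodalSample(ecg=cuts["ECG"], pcg=cuts["PCG"], label=label,
                                 patient_id=ecg.patient_id, window_index=k))
    return out


# ---------------------------------------------------------------------------
# patient-grouped stratified split


def _greedy_assign(patients: list[str], weights: dict[str, int],
                   labels: dict[str, int], fractions: tuple[float, ...],
                   rng: np.random.Generator) -> dict[str, int]:
    """Assign patients to len(fractions) bins, balancing sample counts and
    per-class proportions: process classes separately, largest patients first,
    placing each into the bin with the largest remaining quota."""
    assign: dict[str, int] = {}
    for cls in sorted(set(labels.values())):
        cls_pat = [p for p in patients if labels[p] == cls]
        order = rng.permutation(len(cls_pat))
        cls_pat = [cls_pat[i] for i in order]
        cls_pat.sort(key=lambda p: -weights[p])  # stable: keeps shuffled tie order
        total = sum(weights[p] for p in cls_pat)
        quota = [f * total for f in fractions]
        filled = [0.0] * len(fractions)
        for p in cls_pat:
            deficit = [q - f for q, f in zip(quota, filled)]
            b = int(np.argmax(deficit))
            assign[p] = b
            filled[b] += weights[p]
    return assign


def patient_grouped_split(samples: list[BimodalSample], seed: int,
                          test_fraction: float = 0.2, val_fraction: float = 0.2,
                          predefined_test: set[str] | None = None,
                          ) -> SplitAssignment:
    """Split samples into train/validation/test with no patient in two sets.

    First ``test_fraction`` of samples (by patient) is held out as test —
    or, when ``predefined_test`` patient ids are given, that partition is
    honored verbatim. The remainder is split again into train/validation
    with ``val_fraction``. Both splits stratify by class so each partition's
    class ratio tracks the global one.
    """
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients to split, got {len(patients)}")
    weights = {p: 0 for p in patients}
    labels: dict[str, int] = {}
    for s in samples:
        weights[s.patient_id] += 1
        # patient label: abnormal if any of its windows is abnormal
        labels[s.patient_id] = max(labels.get(s.patient_id, 0), s.y)
    rng = np.random.default_rng(seed)

    if predefined_test is not None:
        test_pat = set(predefined_test)
        rest = [p for p in patients if p not in test_pat]
    else:
        a = _greedy_assign(patients, weights, labels,
                           (1.0 - test_fraction, test_fraction), rng)
        test_pat = {p for p, b in a.items() if b == 1}
        rest = [p for p in patients if a[p] == 0]
    a2 = _greedy_assign(rest, weights, labels, (1.0 - val_fraction, val_fraction), rng)
    part_of = {}
    for p in patients:
        if p in test_pat:
            part_of[p] = "test"
        else:
            part_of[p] = "validation" if a2[p] == 1 else "train"
    mapping = {s.sample_id: part_of[s.patient_id] for s in samples}
    return SplitAssignment(mapping=mapping, seed=seed,
                           patient_of={s.sample_id: s.patient_id for s in samples})


# ---------------------------------------------------------------------------
# file I/O


def write_wav(path: str, rec: Recording) -> None:
    peak = np.abs(rec.samples).max()
    scale = 0.9 * 32767 / peak if peak > 0 else 1.0
    wavfile.write(path, int(rec.fs), (rec.samples * scale).astype(np.int16))


def read_wav(path: str, modality: str, record_id: str, patient_id: str) -> Recording:
    fs, data = wavfile.read(path)
    return Recording(samples=data.astype(np.float64) / 32767.0, fs=float(fs),
                     modality=modality, record_id=record_id, patient_id=patient_id)


def write_ecg_csv(path: str, rec: Recording) -> None:
    """One header line (fs, ids), then one sample value per row."""
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs},record_id={rec.record_id},patient_id={rec.patient_id}\n")
        np.savetxt(fh, rec.samples, fmt="%.6g")


def read_ecg_csv(path: str) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.split(","))
        samples = np.loadtxt(fh)
    return Recording(samples=np.atleast_1d(samples), fs=float(meta["fs"]), modality="ECG",
                     record_id=meta.get("record_id", os.path.basename(path)),
                     patient_id=meta.get("patient_id", ""))


MANIFEST_COLUMNS = ["sample_id", "patient_id", "label", "subclass",
                    "ecg_path", "pcg_path", "fs_ecg", "fs_pcg"]


def write_manifest(path: str, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_bimodal_dataset(manifest_path: str, fs_ecg: float | None = None,
                         fs_pcg: float | None = None,
                         standardize: bool = True) -> list[BimodalSample]:
    """Load a manifest of paired recordings into standardized BimodalSamples.

    Signals are optionally resampled to per-modality target rates and
    z-scored per recording (a constant signal maps to all-zeros).
    """
    df = pd.read_csv(manifest_path, dtype={"patient_id": str, "sample_id": str})
    base = os.path.dirname(os.path.abspath(manifest_path))
    samples = []
    for _, row in df.iterrows():
        for col in ("ecg_path", "pcg_path"):
            p = os.path.join(base, str(row[col]))
            if not os.path.exists(p):
                raise IOError(f"missing file for sample {row['sample_id']}: {p}")
        ecg = read_ecg_csv(os.path.join(base, str(row["ecg_path"])))
        ecg.patient_id = str(row["patient_id"])
        pcg = read_wav(os.path.join(base, str(row["pcg_path"])), "PCG",
                       record_id=str(row["sample_id"]) + "_pcg",
                       patient_id=str(row["patient_id"]))
        if fs_ecg:
            ecg = ecg.resampled(fs_ecg)
        if fs_pcg:
            pcg = pcg.resampled(fs_pcg)
        if standardize:
            ecg, pcg = ecg.standardized(), pcg.standardized()
        samples.append(BimodalSample(
            ecg=ecg, pcg=pcg, label=str(row["label"]), patient_id=str(row["patient_id"]),
            subclass=str(row.get("subclass", "") or ""), sample_id=str(row["sample_id"])))
    return samples


def samples_to_arrays(samples: list[BimodalSample]):
    """Stack a sample list into (X_ecg, X_pcg, y) model-ready arrays."""
    X_ecg = np.stack([s.ecg.samples for s in samples]).astype(np.float32)
    X_pcg = np.stack([s.pcg.samples for s in samples]).astype(np.float32)
    y = np.array([s.y for s in samples], dtype=np.float64)
    return X_ecg, X_pcg, y


# ---------------------------------------------------------------------------
# deposit structure validation (for the public augmented bimodal corpus)

EXPECTED_DEPOSIT = {"total": 1975, "normal": 1009, "abnormal": 966}


def validate_deposit_structure(manifest: pd.DataFrame,
                               expected: dict | None = None) -> dict:
    """Check a downloaded-corpus manifest against its published composition.

    Returns a report dict with observed counts and a boolean ``ok`` flag;
    ``expected`` defaults to the published totals of the 8-second augmented
    bimodal heart-sound corpus (1,975 windows: 1,009 normal, 966 abnormal,
    pre-split 80/20 into development and test subsets).
    """
    exp = dict(EXPECTED_DEPOSIT if expected is None else expected)
    counts = manifest["label"].value_counts().to_dict()
    report = {
        "total": int(len(manifest)),
        "normal": int(counts.get("normal", 0)),
        "abnormal": int(counts.get("abnormal", 0)),
    }
    if "subset" in manifest.columns:
        sub = manifest["subset"].value_counts().to_dict()
        report["test_fraction"] = float(sub.get("test", 0)) / max(len(manifest), 1)
    report["ok"] = all(report.get(k) == v for k, v in exp.items())
    return report
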