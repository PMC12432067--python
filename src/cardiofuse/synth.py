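"""Synthetic paired ECG/PCG cohorts with controllable class evidence.

The generator produces, per patient, simultaneous single-lead ECG and
heart-sound (PCG) recordings that share one cardiac rhythm: beat onset
times are drawn once per record and drive both the electrical waveform
(P-QRS-T complexes modelled as five Gaussian deflections) and the acoustic
one (S1/S2 bursts as decaying sinusoids, with an optional systolic murmur).

Abnormal patients carry a morphological pathology in the ECG (ST-segment
elevation, PR prolongation, flattened T wave), in the PCG (a band-limited
systolic murmur), or in both — chosen per patient from the cohort's
``modality_evidence`` distribution. This lets tests place the class signal
in exactly one modality and check that models and attribution methods find
it there.

The waveform model is deliberately parametric and desk-scale: it gives
convolutional models learnable, localized features but is not a
hemodynamic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dataio import (ABNORMAL, NORMAL, BimodalSample, Recording,
                     write_ecg_csv, write_manifest, write_wav)

EVIDENCE_CHANNELS = ("ecg_only", "pcg_only", "both")

# (wave, time offset within cycle [fraction of 1 s], width [s], amplitude)
_ECG_WAVES = (
    ("P", -0.20, 0.025, 0.12),
    ("Q", -0.035, 0.010, -0.14),
    ("R", 0.0, 0.014, 1.0),
    ("S", 0.035, 0.012, -0.22),
    ("T", 0.28, 0.060, 0.32),
)


@dataclass
class Pathology:
    """Morphology perturbations applied to abnormal signals.

    ECG knobs: ``st_offset`` raises the ST segment (units of R amplitude),
    ``pr_prolongation`` delays the QRS relative to P (seconds), ``t_scale``
    multiplies the T-wave amplitude. PCG knob: ``murmur_amplitude`` sets the
    systolic band-limited noise level. All are scaled by the cohort
    ``effect_size`` before use.
    """

    st_offset: float = 0.0
    pr_prolongation: float = 0.0
    t_scale: float = 1.0
    murmur_amplitude: float = 0.0

    @staticmethod
    def none() -> "Pathology":
        return Pathology()

    @staticmethod
    def ecg(effect_size: float = 1.0) -> "Pathology":
        return Pathology(st_offset=0.18 * effect_size,
                         pr_prolongation=0.04 * effect_size,
                         t_scale=max(1.0 - 0.5 * effect_size, 0.0))

    @staticmethod
    def pcg(effect_size: float = 1.0) -> "Pathology":
        return Pathology(murmur_amplitude=0.5 * effect_size)

    @staticmethod
    def both(effect_size: float = 1.0) -> "Pathology":
        p = Pathology.ecg(effect_size)
        p.murmur_amplitude = 0.5 * effect_size
        return p


@dataclass
class CohortSpec:
    n_patients: int = 100
    records_per_patient: int = 1
    abnormal_fraction: float = 0.5
    # distribution over evidence channels for abnormal patients
    modality_evidence: dict = field(
        default_factory=lambda: {"ecg_only": 0.0, "pcg_only": 0.0, "both": 1.0})
    heart_rate_range: tuple[float, float] = (55.0, 95.0)
    duration: float = 8.0
    fs_ecg: float = 500.0
    fs_pcg: float = 1000.0
    effect_size: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must lie in [0, 1]")
        if self.duration <= 0 or self.fs_ecg <= 0 or self.fs_pcg <= 0:
            raise ValueError("duration and sampling rates must be positive")
        tot = sum(self.modality_evidence.get(k, 0.0) for k in EVIDENCE_CHANNELS)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("modality_evidence probabilities must sum to 1")


@dataclass
class PatientGroundTruth:
    patient_id: str
    label: str
    evidence_channel: str  # ecg_only | pcg_only | both | none
    heart_rate: float
    subclass: str = ""

    def __post_init__(self):
        if (self.evidence_channel == "none") != (self.label == NORMAL):
            raise ValueError("evidence_channel is 'none' iff label is 'normal'")


def _beat_onsets(heart_rate: float, duration: float, rng: np.random.Generator,
                 jitter_sd: float = 0.02) -> np.ndarray:
    """Beat start times with 2% SD cycle-length jitter, covering [0, duration]."""
    mean_cycle = 60.0 / heart_rate
    onsets = [-mean_cycle]  # one extra beat before t=0 so early waves exist
    while onsets[-1] < duration + mean_cycle:
        cyc = mean_cycle * (1.0 + jitter_sd * rng.standard_normal())
        onsets.append(onsets[-1] + max(cyc, 0.2))
    return np.array(onsets)


def _check_args(heart_rate, duration, fs):
    if fs <= 0 or duration <= 0:
        raise ValueError("fs and duration must be positive")
    if not 30.0 <= heart_rate <= 220.0:
        raise ValueError(f"heart_rate {heart_rate} outside plausible range [30, 220] bpm")


def generate_ecg(heart_rate: float, duration: float, fs: float,
                 pathology: Pathology | None = None, seed: int = 0,
                 noise_sd: float = 0.05, record_id: str = "ecg",
                 patient_id: str = "p0",
                 beat_onsets: np.ndarray | None = None) -> Recording:
    """Simulate a single-lead ECG as per-beat sums of five Gaussian waves.

    Each cardiac cycle places P, Q, R, S and T deflections (offsets scale
    with cycle length); pathology shifts the ST segment, prolongs PR and
    flattens T. Additive Gaussian noise and low-frequency baseline wander
    are always present. Deterministic given ``seed``.
    """
    _check_args(heart_rate, duration, fs)
    p = pathology or Pathology.none()
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    onsets = _beat_onsets(heart_rate, duration, rng) if beat_onsets is None else beat_onsets
    sig = np.zeros(n)
    cycles = np.diff(onsets)
    for onset, cyc in zip(onsets[:-1], cycles):
        scale = cyc / 1.0  # wave offsets defined for a 1 s cycle
        for name, off, width, amp in _ECG_WAVES:
            center = onset + off * scale
            if name in ("Q", "R", "S"):
                center += p.pr_prolongation
            if name == "T":
                amp = amp * p.t_scale
            center += 0.002 * rng.standard_normal()  # small per-wave jitter
            sig += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        if p.st_offset:
            # raised plateau between S and T
            st0, st1 = onset + 0.06 * scale, onset + 0.22 * scale
            ramp = 0.02
            sig += p.st_offset * 0.5 * (np.tanh((t - st0) / ramp) - np.tanh((t - st1) / ramp))
    # baseline wander + measurement noise
    sig += 0.08 * np.sin(2 * np.pi * 0.3 * t + 2 * np.pi * rng.random())
    sig += noise_sd * rng.standard_normal(n)
    return Recording(samples=sig, fs=fs, modality="ECG",
                     record_id=record_id, patient_id=patient_id)


def _burst(t: np.ndarray, center: float, freq: float, dur: float, amp: float,
           phase: float) -> np.ndarray:
    """Decaying-sinusoid heart-sound burst centered near its onset."""
    rel = t - center
    env = np.exp(-0.5 * (rel / (dur / 2.5)) ** 2)
    return amp * env * np.sin(2 * np.pi * freq * rel + phase)


def generate_pcg(heart_rate: float, duration: float, fs: float,
                 murmur: Pathology | None = None, seed: int = 0,
                 noise_sd: float = 0.05, record_id: str = "pcg",
                 patient_id: str = "p0", s2_fraction: float = 0.35,
                 murmur_band: tuple[float, float] = (100.0, 400.0),
                 beat_onsets: np.ndarray | None = None) -> Recording:
    """Simulate a phonocardiogram with S1/S2 bursts and an optional murmur.

    Each cycle has an S1 burst at cycle start and an S2 burst at
    ``s2_fraction`` of the cycle; a murmur injects band-limited noise in the
    systolic interval between them. Deterministic given ``seed``.
    """
    _check_args(heart_rate, duration, fs)
    p = murmur or Pathology.none()
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    onsets = _beat_onsets(heart_rate, duration, rng) if beat_onsets is None else beat_onsets
    sig = np.zeros(n)
    murmur_mask = np.zeros(n)
    for onset, cyc in zip(onsets[:-1], np.diff(onsets)):
        f1 = rng.uniform(60.0, 120.0)   # S1 in the 50-150 Hz band
        f2 = rng.uniform(80.0, 150.0)
        sig += _burst(t, onset + 0.02, f1, 0.10, 1.0, rng.uniform(0, 2 * np.pi))
        sig += _burst(t, onset + s2_fraction * cyc, f2, 0.08, 0.75,
                      rng.uniform(0, 2 * np.pi))
        if p.murmur_amplitude > 0:
            sys0, sys1 = onset + 0.08, onset + s2_fraction * cyc - 0.03
            if sys1 > sys0:
                murmur_mask += 0.5 * (np.tanh((t - sys0) / 0.01) - np.tanh((t - sys1) / 0.01))
    if p.murmur_amplitude > 0:
        nyq = fs / 2.0
        hi = min(murmur_band[1], 0.45 * fs)
        sos = butter(4, [murmur_band[0] / nyq, hi / nyq], btype="band", output="sos")
        noise = sosfiltfilt(sos, rng.standard_normal(n))
        noise /= max(noise.std(), 1e-12)
        sig += p.murmur_amplitude * murmur_mask * noise
    sig += noise_sd * rng.standard_normal(n)
    return Recording(samples=sig, fs=fs, modality="PCG",
                     record_id=record_id, patient_id=patient_id)


def generate_cohort(spec: CohortSpec) -> tuple[list[BimodalSample], list[PatientGroundTruth]]:
    """Generate a paired cohort; ECG and PCG of each record share beat times."""
    rng = np.random.default_rng(spec.seed)
    ev_names = list(EVIDENCE_CHANNELS)
    ev_probs = np.array([spec.modality_evidence.get(k, 0.0) for k in ev_names])
    samples: list[BimodalSample] = []
    truths: list[PatientGroundTruth] = []
    for i in range(spec.n_patients):
        pid = f"pat{i:04d}"
        hr = rng.uniform(*spec.heart_rate_range)
        abnormal = rng.random() < spec.abnormal_fraction
        if abnormal:
            channel = ev_names[rng.choice(len(ev_names), p=ev_probs)]
            label = ABNORMAL
        else:
            channel, label = "none", NORMAL
        truths.append(PatientGroundTruth(patient_id=pid, label=label,
                                         evidence_channel=channel, heart_rate=hr,
                                         subclass=channel if abnormal else "Normal"))
        ecg_path = {"ecg_only": Pathology.ecg, "both": Pathology.both}
        for r in range(spec.records_per_patient):
            sub = rng.integers(0, 2**31 - 1)
            beat_rng = np.random.default_rng(sub)
            onsets = _beat_onsets(hr, spec.duration, beat_rng)
            ecg_p = (ecg_path[channel](spec.effect_size)
                     if channel in ecg_path else Pathology.none())
            pcg_p = (Pathology.pcg(spec.effect_size)
                     if channel in ("pcg_only", "both") else Pathology.none())
            rid = f"{pid}_r{r}"
            ecg = generate_ecg(hr, spec.duration, spec.fs_ecg, ecg_p,
                               seed=int(sub), noise_sd=spec.noise_sd,
                               record_id=rid + "_ecg", patient_id=pid,
                               beat_onsets=onsets)
            pcg = generate_pcg(hr, spec.duration, spec.fs_pcg, pcg_p,
                               seed=int(sub) + 1, noise_sd=spec.noise_sd,
                               record_id=rid + "_pcg", patient_id=pid,
                               beat_onsets=onsets)
            samples.append(BimodalSample(
                ecg=ecg.standardized(), pcg=pcg.standardized(), label=label,
                patient_id=pid, window_index=r,
                subclass=truths[-1].subclass, sample_id=rid))
    return samples, truths


def write_cohort(out_dir: str, samples: list[BimodalSample]) -> str:
    """Write signals (ECG CSV, PCG 16-bit WAV) plus a manifest; returns its path."""
    sig_dir = os.path.join(out_dir, "signals")
    os.makedirs(sig_dir, exist_ok=True)
    rows = []
    for s in samples:
        ecg_rel = os.path.join("signals", f"{s.sample_id}_ecg.csv")
        pcg_rel = os.path.join("signals", f"{s.sample_id}_pcg.wav")
        write_ecg_csv(os.path.join(out_dir, ecg_rel), s.ecg)
        write_wav(os.path.join(out_dir, pcg_rel), s.pcg)
        rows.append({"sample_id": s.sample_id, "patient_id": s.patient_id,
                     "label": s.label, "subclass": s.subclass,
                     "ecg_path": ecg_rel, "pcg_path": pcg_rel,
                     "fs_ecg": s.ecg.fs, "fs_pcg": s.pcg.fs})
    manifest = os.path.join(out_dir, "manifest.csv")
    write_manifest(manifest, rows)
    return manifest
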