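"""End-to-end reproduction protocols on synthetic cohorts.

These functions bundle the full pipeline — cohort generation,
patient-grouped splitting, branch and fusion training, evaluation and
explainability — into the three headline analyses the package supports:

* :func:`fusion_benefit` — does late fusion of ECG and PCG branches beat
  each unimodal branch when the class evidence is split between the
  modalities? (the central claim of bimodal cardiac screening)
* :func:`modality_shift` — when the pathology lives in one modality, do
  the attribution methods assign that modality the larger share of the
  model's decision?
* :func:`embedding_separation` — does training increase the class
  separation (silhouette) of the fused embedding space?

Problem sizes default to desk-scale cohorts that run on one CPU in
minutes; every random choice derives from the ``seed`` arguments.

The branch training protocol used throughout (Adam, learning rate 2e-3,
batch 64, 8 epochs) is deliberately short: the synthetic pathologies are
strong, so branches converge within a few epochs. The fusion head is
instead trained to a fixed budget with weight decay (validation accuracy
saturates immediately on separable cohorts, so early stopping alone would
return a barely-trained head, which distorts gradient-based attribution).
"""

from __future__ import annotations

import numpy as np

from .dataio import patient_grouped_split, samples_to_arrays
from .estimators import CNN1DClassifier, LateFusionClassifier
from .evaluation import auroc
from .explain import compare_contributions, sample_contributions
from .models import CNN1DConfig
from .synth import CohortSpec, generate_cohort

BRANCH_KW = dict(max_epochs=8, patience=8, batch_size=64, learning_rate=2e-3)
HEAD_KW = dict(max_epochs=300, patience=300, batch_size=64,
               learning_rate=5e-3, weight_decay=0.1)


def _train_split(spec: CohortSpec, split_seed: int):
    samples, truths = generate_cohort(spec)
    sp = patient_grouped_split(samples, seed=split_seed)
    return tuple(sp.subset(samples, p) for p in ("train", "validation", "test"))


def _fit_models(tr, va, seed: int, config: CNN1DConfig | None = None,
                head_kw: dict | None = None):
    Xe, Xp, y = samples_to_arrays(tr)
    Xev, Xpv, yv = samples_to_arrays(va)
    ecg = CNN1DClassifier(config=config, modality="ecg", random_state=seed,
                          **BRANCH_KW)
    ecg.fit(Xe, y, X_val=Xev, y_val=yv)
    pcg = CNN1DClassifier(config=config, modality="pcg", random_state=seed,
                          **BRANCH_KW)
    pcg.fit(Xp, y, X_val=Xpv, y_val=yv)
    fusion = LateFusionClassifier(ecg_estimator=ecg, pcg_estimator=pcg,
                                  random_state=seed, **(head_kw or HEAD_KW))
    fusion.fit((Xe, Xp), y, X_val=(Xev, Xpv), y_val=yv)
    return ecg, pcg, fusion


def fusion_benefit(n_patients: int = 300, seeds: tuple[int, ...] = (11, 12, 13),
                   effect_size: float = 1.0) -> dict:
    """Median test AUROC of ECG-only, PCG-only and fused models on cohorts
    whose abnormal patients carry evidence in exactly one modality (half
    ECG-only, half PCG-only). One cohort + model set per seed."""
    rows = []
    for seed in seeds:
        spec = CohortSpec(n_patients=n_patients, abnormal_fraction=0.5,
                          modality_evidence={"ecg_only": 0.5, "pcg_only": 0.5,
                                             "both": 0.0},
                          effect_size=effect_size, seed=seed)
        tr, va, te = _train_split(spec, split_seed=seed)
        ecg, pcg, fusion = _fit_models(tr, va, seed=seed)
        Xet, Xpt, yt = samples_to_arrays(te)
        rows.append({
            "seed": seed,
            "ecg_auroc": auroc(yt, ecg.predict_proba(Xet)[:, 1]),
            "pcg_auroc": auroc(yt, pcg.predict_proba(Xpt)[:, 1]),
            "fusion_auroc": auroc(yt, fusion.predict_proba((Xet, Xpt))[:, 1]),
        })
    med = {f"median_{k}": float(np.median([r[k] for r in rows]))
           for k in ("ecg_auroc", "pcg_auroc", "fusion_auroc")}
    return {"per_seed": rows, **med,
            "fusion_margin": med["median_fusion_auroc"]
            - max(med["median_ecg_auroc"], med["median_pcg_auroc"])}


def modality_shift(n_patients: int = 100, seed: int = 8,
                   evidence: str = "pcg_only",
                   lime_perturbations: int = 300) -> dict:
    """Train a fusion model on a cohort whose abnormal evidence is confined
    to one modality, then compare attribution-based modality contributions
    of the abnormal test samples across the three methods."""
    spec = CohortSpec(n_patients=n_patients, abnormal_fraction=0.5,
                      modality_evidence={"ecg_only": 0.0, "pcg_only": 0.0,
                                         "both": 0.0, evidence: 1.0},
                      seed=seed)
    tr, va, te = _train_split(spec, split_seed=0)
    _, _, fusion = _fit_models(tr, va, seed=0)
    Xet, Xpt, yt = samples_to_arrays(te)
    fusion_auroc = auroc(yt, fusion.predict_proba((Xet, Xpt))[:, 1])
    abnormal = [s for s in te if s.label == "abnormal"]
    contribs = sample_contributions(
        fusion.net_, abnormal, lime_kwargs={"n_perturbations": lime_perturbations})
    table = compare_contributions(contribs)
    n_shifted = sum(1 for row in table
                    if row["class"] == "abnormal"
                    and row["median_pcg"] > row["median_ecg"])
    return {"fusion_auroc": fusion_auroc, "table": table,
            "n_abnormal": len(abnormal),
            "n_methods_favoring_pcg": n_shifted}


def _tiny_config() -> CNN1DConfig:
    return CNN1DConfig.from_table((8, 16, 16), (7, 5, 3), pooling_mode="both",
                                  dropout_p=0.2)


def embedding_separation(n_patients: int = 60, seeds: tuple[int, ...] = (0, 1, 2),
                         ) -> dict:
    """Silhouette of fused test embeddings from trained vs untrained models
    (small branch architecture), per seed and as medians."""
    from .viz import separation_score

    rows = []
    for seed in seeds:
        spec = CohortSpec(n_patients=n_patients, abnormal_fraction=0.5, seed=seed)
        tr, va, te = _train_split(spec, split_seed=seed)
        Xet, Xpt, yt = samples_to_arrays(te)
        cfg = _tiny_config()
        ecg, pcg, fusion = _fit_models(tr, va, seed=seed, config=cfg)
        trained, _ = separation_score(fusion.transform((Xet, Xpt)), yt)
        # untrained reference: freshly initialized branches, untrained head
        Xe, Xp, y = samples_to_arrays(tr[:4])
        e0 = CNN1DClassifier(config=cfg, modality="ecg", max_epochs=0,
                             random_state=seed + 100)
        p0 = CNN1DClassifier(config=cfg, modality="pcg", max_epochs=0,
                             random_state=seed + 100)
        e0.fit(Xe, y, X_val=Xe, y_val=y)
        p0.fit(Xp, y, X_val=Xp, y_val=y)
        f0 = LateFusionClassifier(ecg_estimator=e0, pcg_estimator=p0,
                                  max_epochs=0, random_state=seed + 100)
        f0.fit((Xe, Xp), y, X_val=(Xe, Xp), y_val=y)
        untrained, _ = separation_score(f0.transform((Xet, Xpt)), yt)
        rows.append({"seed": seed, "trained": trained, "untrained": untrained})
    return {"per_seed": rows,
            "median_trained": float(np.median([r["trained"] for r in rows])),
            "median_untrained": float(np.median([r["untrained"] for r in rows]))}
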