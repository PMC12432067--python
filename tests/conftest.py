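import pytest

from cardiofuse import (CNN1DClassifier, CNN1DConfig, CohortSpec,
                        LateFusionClassifier, generate_cohort,
                        patient_grouped_split, samples_to_arrays)


def tiny_config() -> CNN1DConfig:
    """Three shallow blocks (8/16/16 channels): fast enough for unit tests
    while exercising conv, both pool types, batch norm and the dense head."""
    return CNN1DConfig.from_table((8, 16, 16), (7, 5, 3), pooling_mode="both",
                                  dropout_p=0.2)


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 patients, abnormal evidence in both modalities."""
    spec = CohortSpec(n_patients=24, abnormal_fraction=0.5, seed=7)
    samples, truths = generate_cohort(spec)
    return samples, truths


@pytest.fixture(scope="session")
def tiny_split(tiny_cohort):
    samples, _ = tiny_cohort
    sp = patient_grouped_split(samples, seed=3)
    return tuple(sp.subset(samples, p) for p in ("train", "validation", "test"))


@pytest.fixture(scope="session")
def trained_fusion(tiny_split):
    """A small fusion model trained on the tiny cohort; shared across tests
    that only need *some* trained bimodal network."""
    tr, va, te = tiny_split
    Xe, Xp, y = samples_to_arrays(tr)
    Xev, Xpv, yv = samples_to_arrays(va)
    kw = dict(config=tiny_config(), max_epochs=4, patience=4, batch_size=16,
              learning_rate=2e-3)
    ecg = CNN1DClassifier(modality="ecg", random_state=0, **kw)
    ecg.fit(Xe, y, X_val=Xev, y_val=yv)
    pcg = CNN1DClassifier(modality="pcg", random_state=1, **kw)
    pcg.fit(Xp, y, X_val=Xpv, y_val=yv)
    fusion = LateFusionClassifier(ecg_estimator=ecg, pcg_estimator=pcg,
                                  max_epochs=30, patience=30, random_state=0)
    fusion.fit((Xe, Xp), y, X_val=(Xev, Xpv), y_val=yv)
    return fusion


def make_labels_scores(rng, n, ties=False):
    y = rng.integers(0, 2, n)
    while y.sum() in (0, n):
        y = rng.integers(0, 2, n)
    if ties:
        s = rng.integers(0, 5, n) / 4.0
    else:
        s = rng.random(n)
    return y.astype(float), s
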