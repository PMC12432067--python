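"""Training protocols: early stopping, checkpoint restoration, freezing,
the two-stage transfer schedule, and grid search."""

import numpy as np
import pytest

from cardiofuse import (CNN1DClassifier,
                        AudioBackboneConfig, TrainConfig, TransferPlan,
                        grid_search, run_transfer, samples_to_arrays,
                        simulate_early_stopping, train)
from cardiofuse.training import fit_network

from conftest import tiny_config


class TestEarlyStoppingRule:
    def test_constant_monitor_stops_at_patience_plus_one(self):
        stopped, best = simulate_early_stopping([0.7] * 100, patience=15)
        assert stopped == 16

    def test_strictly_increasing_never_triggers(self):
        stopped, best = simulate_early_stopping(
            list(np.linspace(0.5, 0.9, 50)), patience=15, max_epochs=50)
        assert stopped == 50 and best == 50

    @pytest.mark.parametrize("patience", [1, 3, 7])
    def test_stops_exactly_patience_after_last_improvement(self, patience):
        seq = [0.5, 0.6, 0.7] + [0.65] * 50  # last improvement at epoch 3
        stopped, best = simulate_early_stopping(seq, patience=patience)
        assert stopped == 3 + patience and best == 3

    def test_plateau_at_best_still_counts_toward_patience(self):
        seq = [0.8] + [0.8] * 50
        stopped, _ = simulate_early_stopping(seq, patience=5)
        assert stopped == 6


class TestFitNetwork:
    def _data(self, tiny_split):
        tr, va, _ = tiny_split
        Xe, _, y = samples_to_arrays(tr)
        Xev, _, yv = samples_to_arrays(va)
        return Xe, y, Xev, yv

    def test_restored_weights_reproduce_best_monitor(self, tiny_split):
        Xe, y, Xev, yv = self._data(tiny_split)
        est = CNN1DClassifier(config=tiny_config(), max_epochs=5, patience=5,
                              batch_size=16, random_state=0)
        est.fit(Xe, y, X_val=Xev, y_val=yv)
        proba = est.predict_proba(Xev)[:, 1]
        acc = float(np.mean((proba >= 0.5) == (yv == 1)))
        assert acc == pytest.approx(est.history_["best_monitor"])

    def test_empty_training_set_rejected(self):
        from cardiofuse import build_branch
        net = build_branch(tiny_config(), seed=0)
        with pytest.raises(ValueError, match="empty"):
            fit_network(net, np.empty((0, 10), dtype=np.float32), np.empty(0),
                        None, None, TrainConfig())

    def test_nonfinite_loss_aborts_with_diagnostic(self, tiny_split):
        Xe, y, Xev, yv = self._data(tiny_split)
        Xbad = Xe.copy()
        Xbad[0, 0] = np.inf
        est = CNN1DClassifier(config=tiny_config(), max_epochs=2, batch_size=64,
                              random_state=0)
        with pytest.raises(FloatingPointError):
            est.fit(Xbad, y, X_val=Xev, y_val=yv)

    def test_frozen_branch_weights_unchanged_by_fusion_training(
            self, trained_fusion):
        # the conftest fusion model froze both branches; its branch nets are
        # the estimators' nets — compare against freshly stored copies
        net = trained_fusion.net_
        for blk in net.ecg.blocks + net.pcg.blocks:
            for layer in blk.iter_layers():
                assert layer.frozen
        before_e = trained_fusion.ecg_estimator.net_.features.state_dict()
        assert all(np.array_equal(v, net.ecg.features.state_dict()[k])
                   for k, v in before_e.items())

    def test_training_is_deterministic_given_seed(self, tiny_split):
        Xe, y, Xev, yv = self._data(tiny_split)
        nets = []
        for _ in range(2):
            est = CNN1DClassifier(config=tiny_config(), max_epochs=2,
                                  batch_size=16, random_state=5)
            est.fit(Xe, y, X_val=Xev, y_val=yv)
            nets.append(est.net_.state_dict())
        for k in nets[0]:
            np.testing.assert_array_equal(nets[0][k], nets[1][k])


class TestTrainWrapper:
    def test_overlapping_patients_rejected(self, tiny_split):
        tr, va, _ = tiny_split
        est = CNN1DClassifier(config=tiny_config(), max_epochs=1)
        with pytest.raises(ValueError, match="patients"):
            train(est, tr, tr[:4])

    def test_fits_and_reports_history(self, tiny_split):
        tr, va, _ = tiny_split
        est = CNN1DClassifier(config=tiny_config(), max_epochs=2,
                              batch_size=16, random_state=0)
        est, history = train(est, tr, va)
        assert len(history["epoch"]) <= 2
        assert np.isfinite(history["train_loss"]).all()


class TestTransfer:
    def test_plan_validation(self):
        with pytest.raises(ValueError):
            TransferPlan(stage1_corpora=())
        with pytest.raises(ValueError):
            TransferPlan(stage1_freeze_k=4)
        with pytest.raises(ValueError):
            TransferPlan(stage2_freeze_k=3)
        with pytest.raises(ValueError):
            TransferPlan(stage1_corpora=("unknown_corpus",))

    def test_two_stage_schedule_runs_and_freezes(self, tiny_split):
        tr, va, _ = tiny_split
        _, Xp, y = samples_to_arrays(tr + va)
        corpora = {"synthetic": (Xp, y)}
        cfg = AudioBackboneConfig(base_channels=2, mel_bins=16, fft_size=64,
                                  hop=200)
        plan = TransferPlan(stage1_corpora=("synthetic",), stage1_freeze_k=1,
                            stage2_freeze_k=5)
        tc = TrainConfig(max_epochs=1, batch_size=16, seed=0)
        est = run_transfer(cfg, plan, corpora, tr, va, config=tc)
        # stage 2 left only block 6 + head trainable
        blocks = est.net_.blocks
        n_block6 = sum(l.n_params for l in blocks[5].iter_layers())
        assert est.net_.trainable_param_count() == n_block6 + est.net_.head.n_params
        assert "stage1" in est.history_ and "stage2" in est.history_

    def test_missing_corpus_rejected(self, tiny_split):
        tr, va, _ = tiny_split
        plan = TransferPlan(stage1_corpora=("physionet2016",))
        with pytest.raises(ValueError, match="physionet2016"):
            run_transfer(AudioBackboneConfig(base_channels=2, mel_bins=16,
                                             fft_size=64, hop=200),
                         plan, {}, tr, va)

    def test_stage1_freeze_zero_leaves_all_trainable(self):
        cfg = AudioBackboneConfig(base_channels=2, mel_bins=16, fft_size=64,
                                  hop=200, freeze_k=0)
        from cardiofuse import build_branch
        net = build_branch(cfg, seed=0, fs=1000.0)
        assert net.trainable_param_count() == net.n_params


class TestGridSearch:
    def test_single_candidate_ranks_first(self, tiny_split):
        tr, va, te = tiny_split
        est = CNN1DClassifier(config=tiny_config(), max_epochs=1,
                              batch_size=16, random_state=0)
        results = grid_search([est], tr, va, te)
        assert results[0]["rank"] == 1 and len(results) == 1

    def test_ranking_prefers_higher_selection_metric(self, tiny_split):
        tr, va, te = tiny_split
        good = CNN1DClassifier(config=tiny_config(), max_epochs=4,
                               batch_size=16, random_state=0)
        barely = CNN1DClassifier(config=tiny_config(), max_epochs=4,
                                 batch_size=16, learning_rate=1e-7,
                                 random_state=0)
        results = grid_search([good, barely], tr, va, te)
        by_rank = sorted(results, key=lambda r: r["rank"])
        assert by_rank[0]["auroc"] >= by_rank[1]["auroc"]

    def test_test_split_selection_requires_explicit_flag(self, tiny_split):
        tr, va, te = tiny_split
        est = CNN1DClassifier(config=tiny_config(), max_epochs=1)
        with pytest.raises(ValueError):
            grid_search([est], tr, va, te, selection_split="test")

    def test_rerun_with_same_seed_is_identical(self, tiny_split):
        tr, va, te = tiny_split
        outs = []
        for _ in range(2):
            est = CNN1DClassifier(config=tiny_config(), max_epochs=2,
                                  batch_size=16, random_state=4)
            outs.append(grid_search([est], tr, va, te)[0])
        assert outs[0]["auroc"] == outs[1]["auroc"]
        assert outs[0]["accuracy"] == outs[1]["accuracy"]


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(patience=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)


def test_evidence_isolation_in_trained_models():
    """On a cohort whose abnormal evidence lives only in the ECG, an
    ECG-branch classifier learns the task while a PCG-branch classifier
    stays near chance — the class signal does not leak across modalities."""
    from cardiofuse import CohortSpec, generate_cohort, patient_grouped_split

    spec = CohortSpec(n_patients=200, abnormal_fraction=0.5, seed=17,
                      modality_evidence={"ecg_only": 1.0, "pcg_only": 0.0,
                                         "both": 0.0})
    samples, _ = generate_cohort(spec)
    sp = patient_grouped_split(samples, seed=0)
    tr, va, te = (sp.subset(samples, p) for p in ("train", "validation", "test"))
    Xe, Xp, y = samples_to_arrays(tr)
    Xev, Xpv, yv = samples_to_arrays(va)
    Xet, Xpt, yt = samples_to_arrays(te)
    from cardiofuse import auroc

    kw = dict(max_epochs=8, patience=8, batch_size=64, learning_rate=2e-3,
              random_state=0)
    ecg = CNN1DClassifier(modality="ecg", **kw).fit(Xe, y, X_val=Xev, y_val=yv)
    assert auroc(yt, ecg.predict_proba(Xet)[:, 1]) >= 0.85
    pcg = CNN1DClassifier(modality="pcg", **kw).fit(Xp, y, X_val=Xpv, y_val=yv)
    assert 0.35 <= auroc(yt, pcg.predict_proba(Xpt)[:, 1]) <= 0.65
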