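"""Fine-tuning harness: early stopping, determinism, selection, sweeps."""

import dataclasses
import hashlib
import json

import numpy as np
import pytest

import ageaug.transfer as transfer
from ageaug import (AGEAugmentation, ErasingPolicy, REPolicy, ThresholdSpec,
                    TrainConfig, select_head, sweep_probability,
                    train_classifier)
from ageaug.phantoms import fixture_attention_source
from ageaug.transfer import HeadSelectionReport, RunResult


@pytest.fixture
def fast_config():
    return TrainConfig(epochs=3, batch_size=4, learning_rate=1e-4,
                       weight_decay=1e-4, patience=2, n_repeats=1)


def result_digest(result: RunResult) -> str:
    payload = json.dumps({
        "train_losses": result.train_losses,
        "val_f1s": result.val_f1s,
        "best_val_f1": result.best_val_f1,
        "best_epoch": result.best_epoch,
        "test_f1": result.test_f1,
        "seed": result.seed,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


class TestEarlyStopping:
    def test_stops_after_patience_without_improvement(self, monkeypatch,
                                                      toy_backbone, tiny_dataset):
        scripted = iter([0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6])
        monkeypatch.setattr(transfer, "_evaluate",
                            lambda model, samples, bs: next(scripted))
        cfg = TrainConfig(epochs=50, batch_size=4, learning_rate=1e-5,
                          patience=3, n_repeats=1)
        result = train_classifier(toy_backbone, tiny_dataset, None, cfg, seed=0)
        # epochs 3, 4, 5 show no improvement over epoch 2 -> stop after epoch 5
        assert len(result.val_f1s) == 5
        assert result.best_epoch == 2
        assert result.best_val_f1 == 0.6

    def test_runs_all_epochs_when_improving(self, monkeypatch, toy_backbone,
                                            tiny_dataset):
        scripted = iter([0.1, 0.2, 0.3, 0.4])
        monkeypatch.setattr(transfer, "_evaluate",
                            lambda model, samples, bs: next(scripted))
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=1e-5,
                          patience=2, n_repeats=1)
        result = train_classifier(toy_backbone, tiny_dataset, None, cfg, seed=0)
        assert len(result.val_f1s) == 3 and result.best_epoch == 3


class TestDeterminismAndIsolation:
    def test_identical_seeds_identical_results(self, toy_backbone, tiny_dataset,
                                               fast_config):
        a = train_classifier(toy_backbone, tiny_dataset, None, fast_config, seed=7)
        b = train_classifier(toy_backbone, tiny_dataset, None, fast_config, seed=7)
        assert result_digest(a) == result_digest(b)

    def test_age_with_p_zero_equals_no_erasing(self, toy_backbone, tiny_dataset,
                                               fast_config):
        aug = AGEAugmentation(
            policy=ErasingPolicy(head_index=1, probability=0.0),
            attention_source=fixture_attention_source(1, 6, 0.9, seed=0))
        a = train_classifier(toy_backbone, tiny_dataset, None, fast_config, seed=3)
        b = train_classifier(toy_backbone, tiny_dataset, aug, fast_config, seed=3)
        assert result_digest(a) == result_digest(b)

    @pytest.mark.parametrize("arm", ["none", "re", "age"])
    def test_evaluation_images_untouched_by_training(self, arm, toy_backbone,
                                                     tiny_dataset, fast_config):
        def split_hash():
            h = hashlib.sha256()
            for name in ("val", "test"):
                for s in tiny_dataset.split(name):
                    h.update(s.image.tobytes())
            return h.hexdigest()

        before = split_hash()
        aug = {"none": None, "re": REPolicy(probability=0.8),
               "age": AGEAugmentation(
                   policy=ErasingPolicy(head_index=2, probability=0.8),
                   attention_source=fixture_attention_source(2, 6, 0.9, 0))}[arm]
        train_classifier(toy_backbone, tiny_dataset, aug, fast_config, seed=1)
        assert split_hash() == before

    def test_frozen_backbone_leaves_backbone_parameters_unchanged(
            self, toy_backbone, tiny_dataset):
        cfg = TrainConfig(epochs=3, batch_size=6, learning_rate=1e-2,
                          patience=3, n_repeats=1, freeze_backbone=True)
        before = {k: v.data.copy() for k, v in toy_backbone.params.items()}
        train_classifier(toy_backbone, tiny_dataset, None, cfg, seed=0)
        for k, v in toy_backbone.params.items():
            assert np.array_equal(v.data, before[k])


class _StubResult:
    def __init__(self, f1):
        self.best_val_f1 = f1


class TestSelectHead:
    def test_report_has_one_entry_per_head(self, monkeypatch, toy_backbone,
                                           tiny_dataset, fast_config):
        scripted = {1: 0.4, 2: 0.6, 3: 0.5, 4: 0.3, 5: 0.2, 6: 0.1}
        monkeypatch.setattr(
            transfer, "train_classifier",
            lambda bb, ds, aug, cfg, seed, max_epochs=None:
            _StubResult(scripted[aug.policy.head_index]))
        rep = select_head(toy_backbone, tiny_dataset, ThresholdSpec(), 0.6,
                          fast_config,
                          attention_source=fixture_attention_source(1, 6, 0.9, 0))
        assert len(rep.per_head_val_f1) == 6
        assert rep.selected_head == 2 and not rep.tie_broken

    def test_tie_breaks_to_lowest_head(self, monkeypatch, toy_backbone,
                                       tiny_dataset, fast_config):
        scripted = {1: 0.5, 2: 0.7, 3: 0.7, 4: 0.4, 5: 0.3, 6: 0.2}
        monkeypatch.setattr(
            transfer, "train_classifier",
            lambda bb, ds, aug, cfg, seed, max_epochs=None:
            _StubResult(scripted[aug.policy.head_index]))
        rep = select_head(toy_backbone, tiny_dataset, ThresholdSpec(), 0.6,
                          fast_config,
                          attention_source=fixture_attention_source(1, 6, 0.9, 0))
        assert rep.selected_head == 2 and rep.tie_broken

    def test_selection_report_invariant_asserted(self):
        with pytest.raises(AssertionError):
            HeadSelectionReport(per_head_val_f1=[0.1, 0.9], selected_head=1,
                                tie_broken=False)


class TestSweepProbability:
    def test_one_entry_per_probability(self, monkeypatch, toy_backbone,
                                       tiny_dataset, fast_config):
        monkeypatch.setattr(
            transfer, "train_classifier",
            lambda bb, ds, aug, cfg, seed, max_epochs=None: _StubResult(0.5))
        rep = sweep_probability(toy_backbone, tiny_dataset, "RE",
                                [0.2, 0.4, 0.6, 0.8], fast_config)
        assert len(rep.per_p_val_f1) == 4

    def test_tie_breaks_to_lowest_probability(self, monkeypatch, toy_backbone,
                                              tiny_dataset, fast_config):
        scripted = {0.2: 0.6, 0.4: 0.6, 0.6: 0.5, 0.8: 0.4}
        monkeypatch.setattr(
            transfer, "train_classifier",
            lambda bb, ds, aug, cfg, seed, max_epochs=None:
            _StubResult(scripted[round(aug.probability if hasattr(aug, "probability")
                                       else aug.policy.probability, 1)]))
        rep = sweep_probability(toy_backbone, tiny_dataset, "RE",
                                [0.2, 0.4, 0.6, 0.8], fast_config)
        assert rep.best_probability == 0.2 and rep.tie_broken

    def test_p_zero_sweep_equals_no_erasing_run(self, toy_backbone, tiny_dataset):
        cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-4,
                          patience=2, n_repeats=1, seed=5)
        rep = sweep_probability(toy_backbone, tiny_dataset, "AGE", [0.0], cfg,
                                attention_source=fixture_attention_source(1, 6, 0.9, 0))
        baseline = train_classifier(toy_backbone, tiny_dataset, None, cfg,
                                    seed=5, max_epochs=None)
        assert rep.best_probability == 0.0
        assert rep.per_p_val_f1[0] == baseline.best_val_f1

    def test_invalid_inputs_rejected(self, toy_backbone, tiny_dataset, fast_config):
        with pytest.raises(ValueError):
            sweep_probability(toy_backbone, tiny_dataset, "RE", [], fast_config)
        with pytest.raises(ValueError):
            sweep_probability(toy_backbone, tiny_dataset, "XX", [0.5], fast_config)
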