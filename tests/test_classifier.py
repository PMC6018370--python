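"""Autoencoder pretraining, fusion heads, two-stage diagnosis."""

import numpy as np
import pytest

from octdr import (
    AutoencoderSpec,
    FusionNetwork,
    classify,
    load_model,
    pretrain_autoencoders,
    save_model,
    train_stage,
)
from octdr.classifier import N_SLOTS, _slot_matrix
from octdr.features import FeatureCDF, SubjectDescriptor

G = 64


def _synthetic_descriptor(shift: float, subject_id: str, eye: str = "OD",
                          grade: str = "normal",
                          rng: np.random.Generator | None = None):
    """Descriptor whose 36 CDFs are sigmoid ramps centred at ``shift``."""
    grid01 = np.linspace(0, 1, G)
    cdfs = []
    for i in range(36):
        jitter = 0.0 if rng is None else rng.normal(0, 0.01)
        values = 1.0 / (1.0 + np.exp(-(grid01 - shift - jitter) * 30))
        values = np.maximum.accumulate(values)
        cdfs.append(FeatureCDF(grid=grid01, values=values))
    return SubjectDescriptor(cdfs=cdfs, subject_id=subject_id, eye=eye,
                             grade_label=grade)


def _separable_set(n_per_class=6, seed=0):
    rng = np.random.default_rng(seed)
    descs, labels = [], []
    for j in range(n_per_class):
        descs.append(_synthetic_descriptor(0.35, f"N{j}", grade="normal",
                                           rng=rng))
        labels.append("normal")
        descs.append(_synthetic_descriptor(0.65, f"D{j}", grade="mild_moderate",
                                           rng=rng))
        labels.append("mild_moderate")
    return descs, labels


class TestAutoencoderSpec:
    def test_hidden_dims_must_decrease(self):
        with pytest.raises(ValueError):
            AutoencoderSpec(input_dim=64, hidden_dims=(32, 40))
        with pytest.raises(ValueError):
            AutoencoderSpec(input_dim=16, hidden_dims=(32, 8))


class TestPretraining:
    def test_single_point_training_set_is_memorised(self):
        d = _synthetic_descriptor(0.5, "S1")
        spec = AutoencoderSpec(epochs=300, seed=0)
        stacks = pretrain_autoencoders([d, d, d], spec)
        X = _slot_matrix([d], spec.input_dim)
        for i in (0, 17, 35):
            recon = stacks[i].reconstruct(X[i])
            assert np.abs(recon - X[i]).max() <= 1e-3

    def test_fixed_seed_gives_identical_weights(self, small_cohort):
        _, _, descriptors = small_cohort
        spec = AutoencoderSpec(epochs=10, seed=42)
        s1 = pretrain_autoencoders(descriptors[:8], spec)
        s2 = pretrain_autoencoders(descriptors[:8], spec)
        for a, b in zip(s1, s2):
            for (Wa, ba), (Wb, bb) in zip(a.enc_layers, b.enc_layers):
                assert np.array_equal(Wa, Wb)
                assert np.array_equal(ba, bb)

    def test_high_nonnegativity_penalty_removes_negative_weights(
            self, small_cohort):
        _, _, descriptors = small_cohort
        spec = AutoencoderSpec(epochs=60, nonnegativity_weight=1.0, seed=0)
        stacks = pretrain_autoencoders(descriptors[:8], spec)
        neg = total = 0
        for s in stacks:
            for W, _ in s.enc_layers:
                neg += int((W < 0).sum())
                total += W.size
        assert neg / total < 0.01

    def test_reconstruction_loss_traces_are_monotone(self, small_cohort):
        _, _, descriptors = small_cohort
        spec = AutoencoderSpec(epochs=30, seed=1)
        stacks = pretrain_autoencoders(descriptors[:8], spec)
        for s in stacks[:6]:
            for trace in s.loss_traces:
                assert (np.diff(trace) <= 1e-12).all()

    def test_too_few_descriptors_rejected(self):
        with pytest.raises(ValueError):
            pretrain_autoencoders([_synthetic_descriptor(0.5, "S1")],
                                  AutoencoderSpec())


class TestTrainStage:
    def test_architecture_census_36_encoders(self, small_cohort):
        _, _, descriptors = small_cohort
        spec = AutoencoderSpec(epochs=5, head_epochs=20, seed=0)
        net = train_stage(descriptors, [d.grade_label for d in descriptors],
                          "screen", spec)
        assert len(net.encoders) == N_SLOTS
        assert net.head_W.shape == (N_SLOTS * spec.code_dim, 2)
        with pytest.raises(ValueError, match="36"):
            FusionNetwork(stage="screen", encoders=net.encoders[:-1],
                          head_W=net.head_W, head_b=net.head_b,
                          classes=net.classes, input_dim=G)

    def test_separable_descriptors_reach_perfect_training_accuracy(self):
        descs, labels = _separable_set()
        spec = AutoencoderSpec(epochs=30, head_epochs=150, seed=0)
        net = train_stage(descs, labels, "screen", spec)
        pred = net.predict_proba(descs)[:, 1] >= 0.5
        truth = np.array([lab != "normal" for lab in labels])
        assert (pred == truth).all()

    def test_flipping_label_encoding_mirrors_probabilities(self):
        descs, labels = _separable_set()
        spec = AutoencoderSpec(epochs=20, head_epochs=100, seed=0)
        enc = pretrain_autoencoders(descs, spec)
        net = train_stage(descs, labels, "screen", spec, encoders=enc)
        flipped = ["normal" if lab != "normal" else "mild_moderate"
                   for lab in labels]
        net_f = train_stage(descs, flipped, "screen", spec, encoders=enc)
        np.testing.assert_allclose(net.predict_proba(descs)[:, 1],
                                   net_f.predict_proba(descs)[:, 0],
                                   atol=1e-9)

    def test_grade_stage_rejects_normal_subjects(self, small_cohort):
        _, _, descriptors = small_cohort
        spec = AutoencoderSpec(epochs=5, head_epochs=10, seed=0)
        with pytest.raises(ValueError, match="DR subjects"):
            train_stage(descriptors, [d.grade_label for d in descriptors],
                        "grade", spec)

    def test_absent_class_rejected(self):
        descs, _ = _separable_set(n_per_class=3)
        spec = AutoencoderSpec(epochs=5, head_epochs=10, seed=0)
        with pytest.raises(ValueError, match="absent"):
            train_stage(descs, ["normal"] * len(descs), "screen", spec)

    def test_head_loss_trace_is_monotone(self):
        descs, labels = _separable_set()
        spec = AutoencoderSpec(epochs=10, head_epochs=80, seed=0)
        net = train_stage(descs, labels, "screen", spec)
        assert (np.diff(net.loss_trace) <= 1e-12).all()


@pytest.fixture(scope="module")
def nets():
    descs, labels = _separable_set()
    grade_labels = ["subclinical" if lab == "normal" else "mild_moderate"
                    for lab in labels]
    spec = AutoencoderSpec(epochs=20, head_epochs=100, seed=0)
    enc = pretrain_autoencoders(descs, spec)
    screen = train_stage(descs, labels, "screen", spec, encoders=enc)
    grade = train_stage(descs, grade_labels, "grade", spec, encoders=enc)
    return descs, labels, screen, grade


class TestClassify:

    def test_training_points_get_their_training_labels(self, nets):
        descs, labels, screen, grade = nets
        for d, lab in zip(descs, labels):
            diag = classify(d, screen, grade)
            assert diag.stage1 == ("normal" if lab == "normal" else "dr")

    def test_stage2_unset_for_normal_calls(self, nets):
        descs, labels, screen, grade = nets
        normal = descs[labels.index("normal")]
        diag = classify(normal, screen, grade)
        assert diag.stage1 == "normal"
        assert diag.stage2 is None
        assert diag.stage2_probability is None

    def test_threshold_extremes(self, nets):
        descs, _, screen, grade = nets
        assert all(classify(d, screen, grade, threshold=0.0).stage1 == "dr"
                   for d in descs)
        assert all(classify(d, screen, grade, threshold=1.0).stage1 == "normal"
                   for d in descs)

    def test_model_round_trip_preserves_predictions(self, nets, tmp_path):
        descs, _, screen, _ = nets
        save_model(screen, tmp_path / "screen.json")
        back = load_model(tmp_path / "screen.json")
        np.testing.assert_allclose(back.predict_proba(descs),
                                   screen.predict_proba(descs), atol=1e-12)
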