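"""The Siamese model: head, body, score, loss, training, checkpointing."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ncminer.chem_io import FingerprintSpec
from ncminer.errors import (
    CheckpointError,
    ConfigurationError,
    SpecMismatchError,
)
from ncminer.pair_sampler import PairExample, generate_pairs, split_dataset
from ncminer.snn_core import (
    HeadParams,
    SiameseModel,
    TrainConfig,
    bce_loss,
    cosine_distance,
    embed,
    fine_tune,
    load_model,
    save_model,
    sigmoid,
    train,
)
from ncminer.synth_data import SynthSpec, generate_dataset

from conftest import N_BITS_SMALL


def _rand_pairs(rng, n, n_bits=N_BITS_SMALL):
    return [
        PairExample(
            (rng.random(n_bits) < 0.3).astype(np.uint8),
            (rng.random(n_bits) < 0.3).astype(np.uint8),
            int(rng.integers(2)), f"a{i}", f"b{i}", "negative",
        )
        for i in range(n)
    ]


class TestEmbed:
    def test_zero_weights_give_zero_embedding(self):
        head = HeadParams.initialize(4, (3, 2), rng=np.random.default_rng(0))
        for w in head.weights:
            w[:] = 0.0
        assert np.allclose(embed(head, np.ones(4)), 0.0)

    def test_eval_mode_deterministic(self, small_model):
        fp = (np.random.default_rng(1).random(N_BITS_SMALL) < 0.3).astype(np.uint8)
        assert np.array_equal(small_model.embed(fp), small_model.embed(fp))

    def test_hand_arithmetic_through_relu(self):
        head = HeadParams.initialize(2, (2, 2), rng=np.random.default_rng(0))
        head.weights[0][:] = np.array([[1.0, -2.0], [0.5, 3.0]], dtype=np.float32)
        head.biases[0][:] = np.array([0.25, -0.5], dtype=np.float32)
        head.weights[1][:] = np.eye(2, dtype=np.float32)
        head.biases[1][:] = 0.0
        x = np.array([2.0, -4.0])
        # pre-activation: [2*1 - 4*0.5 + 0.25, 2*(-2) - 4*3 - 0.5] = [0.25, -16.5]
        # ReLU clips the negative unit; identity final layer passes it through
        assert np.allclose(embed(head, x), [0.25, 0.0])

    def test_dimension_mismatch(self, small_model):
        with pytest.raises(SpecMismatchError):
            small_model.embed(np.ones(N_BITS_SMALL + 1))

    def test_train_mode_needs_rng(self, small_model):
        with pytest.raises(ConfigurationError):
            embed(small_model.head, np.ones(N_BITS_SMALL), mode="train")


class TestCosineDistance:
    def test_self_similarity(self):
        z = np.array([0.3, -1.2, 2.0])
        assert cosine_distance(z, z) == pytest.approx(1.0)

    def test_orthogonal_and_closed_form(self):
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert cosine_distance(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(
            1 / math.sqrt(2)
        )

    def test_zero_vector_defined(self):
        with pytest.warns(UserWarning):
            assert cosine_distance(np.zeros(3), np.ones(3)) == 0.0

    @given(st.integers(0, 2**30 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.standard_normal(8), rng.standard_normal(8)
        num = sum(float(a) * float(b) for a, b in zip(z1, z2))
        den = math.sqrt(sum(float(a) ** 2 for a in z1)) * math.sqrt(
            sum(float(b) ** 2 for b in z2)
        )
        assert cosine_distance(z1, z2) == pytest.approx(num / den, abs=1e-9)
        assert -1.0 <= cosine_distance(z1, z2) <= 1.0


class TestSimilarityScore:
    def test_identical_inputs_sigma_one(self, small_model):
        fp = (np.random.default_rng(0).random(N_BITS_SMALL) < 0.3).astype(np.uint8)
        assert small_model.similarity_score(fp, fp) == pytest.approx(sigmoid(1.0))

    def test_symmetry_and_bounds(self, small_model):
        rng = np.random.default_rng(4)
        lo, hi = sigmoid(-1.0), sigmoid(1.0)
        for _ in range(100):
            a = (rng.random(N_BITS_SMALL) < 0.3).astype(np.uint8)
            b = (rng.random(N_BITS_SMALL) < 0.3).astype(np.uint8)
            s_ab = small_model.similarity_score(a, b)
            assert s_ab == small_model.similarity_score(b, a)
            assert lo <= s_ab <= hi

    def test_toy_model_manual_composition(self):
        model = SiameseModel.create(FingerprintSpec.synthetic(2), hidden_dims=(2,), seed=0)
        model.head.weights[0][:] = np.eye(2, dtype=np.float32)
        model.head.biases[0][:] = 0.0
        s = model.similarity_score(np.array([1, 0]), np.array([1, 1]))
        assert s == pytest.approx(sigmoid(1 / math.sqrt(2)))


class TestBCELoss:
    def test_symmetric_midpoint(self):
        assert bce_loss([0.5, 0.5], [1, 0]) == pytest.approx(math.log(2))

    def test_perfect_scores_near_zero(self):
        assert bce_loss([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-6)

    def test_hand_arithmetic(self):
        s1 = sigmoid(1.0)
        assert bce_loss([s1, 1 - s1], [1, 0]) == pytest.approx(-math.log(s1), abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(ConfigurationError):
            bce_loss([], [])

    @given(st.integers(0, 2**30 - 1))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.01, 0.99, size=10)
        y = rng.integers(0, 2, size=10)
        expected = -sum(
            yi * math.log(si) + (1 - yi) * math.log(1 - si) for si, yi in zip(s, y)
        ) / len(s)
        assert bce_loss(s, y) == pytest.approx(expected, abs=1e-9)


@pytest.fixture
def train_material():
    ds = generate_dataset(
        SynthSpec(n_proteins=2, actives_per_protein=40, inactives_per_protein=20,
                  fingerprint_length=N_BITS_SMALL, flip_rate=0.02, seed=11)
    )
    sp = split_dataset(ds, seed=11)
    tr = generate_pairs(sp.train, 100, 100, seed=11)
    val = generate_pairs(sp.validation, 30, 30, seed=12)
    return ds, tr, val


class TestTraining:
    def test_training_reduces_validation_bce(self, train_material):
        from ncminer.snn_core import evaluate_pairs_bce

        ds, tr, val = train_material
        model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(32, 16), seed=0)
        before = evaluate_pairs_bce(model, val)
        train(model, tr, val, TrainConfig(learning_rate=1e-3, max_epochs=20,
                                          patience=20, batch_size=32, seed=0))
        after = evaluate_pairs_bce(model, val)
        assert after < before
        log = model.training_log[-1]
        assert log["phase"] == "train" and log["epochs_run"] >= 1

    def test_shuffled_labels_stay_near_chance(self, train_material):
        from ncminer.snn_core import evaluate_pairs_bce

        ds, tr, val = train_material
        rng = np.random.default_rng(0)
        for p in tr + val:
            p.label = int(rng.integers(2))
        model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(32, 16), seed=0)
        train(model, tr, val, TrainConfig(learning_rate=1e-3, max_epochs=10,
                                          patience=10, batch_size=32, seed=0))
        assert evaluate_pairs_bce(model, val) == pytest.approx(math.log(2), abs=0.1)

    def test_zero_learning_rate_leaves_weights(self, train_material):
        ds, tr, val = train_material
        model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(16,), seed=0)
        before = [w.copy() for w in model.head.weights]
        train(model, tr, [], TrainConfig(learning_rate=0.0, max_epochs=2, seed=0))
        assert all(np.array_equal(a, b) for a, b in zip(before, model.head.weights))

    def test_seed_determinism(self, train_material):
        ds, tr, val = train_material
        outs = []
        for _ in range(2):
            model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(16,), seed=5)
            train(model, tr, val, TrainConfig(learning_rate=1e-3, max_epochs=3, seed=5))
            outs.append([w.copy() for w in model.head.weights])
        assert all(np.array_equal(a, b) for a, b in zip(*outs))

    def test_positive_pairs_score_above_negative_after_training(self, train_material):
        # margin > 0.05 across seeds on well-separated clusters
        ds, tr, val = train_material
        for seed in (0, 1, 2):
            model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(32, 16), seed=seed)
            train(model, tr, val, TrainConfig(learning_rate=1e-3, max_epochs=15,
                                              patience=15, batch_size=32, seed=seed))
            pos = [model.similarity_score(p.fp_a, p.fp_b) for p in val if p.label == 1]
            neg = [model.similarity_score(p.fp_a, p.fp_b) for p in val if p.label == 0]
            assert np.mean(pos) - np.mean(neg) > 0.05


class TestFineTune:
    def test_zero_epochs_is_identity(self, small_model, train_material):
        _, tr, _ = train_material
        before = [w.copy() for w in small_model.head.weights]
        fine_tune(small_model, tr, [], TrainConfig(max_epochs=0))
        assert all(np.array_equal(a, b) for a, b in zip(before, small_model.head.weights))
        assert small_model.training_log[-1]["phase"] == "transfer"

    def test_spec_mismatched_pairs_rejected(self, small_model):
        rng = np.random.default_rng(0)
        bad = _rand_pairs(rng, 4, n_bits=32)
        with pytest.raises(SpecMismatchError):
            fine_tune(small_model, bad, [], TrainConfig(max_epochs=1))

    def test_pretraining_helps_on_new_clusters(self):
        """Transfer from clusters A,B improves (or matches) support-set recall
        on new clusters C,D versus training on C,D alone with the same budget."""
        from ncminer.evaluation import evaluate_predictions
        from ncminer.inference import build_support_set, predict_targets, truth_matrix

        wins = 0
        for seed in range(5):
            pre = generate_dataset(SynthSpec(
                n_proteins=2, actives_per_protein=40, inactives_per_protein=20,
                fingerprint_length=N_BITS_SMALL, protein_prefix="AB", seed=100 + seed))
            new = generate_dataset(SynthSpec(
                n_proteins=2, actives_per_protein=20, inactives_per_protein=10,
                fingerprint_length=N_BITS_SMALL, protein_prefix="CD", seed=200 + seed))
            sp_new = split_dataset(new, seed=seed)
            budget = TrainConfig(learning_rate=1e-3, max_epochs=5, patience=5,
                                 batch_size=32, seed=seed)

            def _recall(model):
                support = build_support_set(sp_new.train, seed=seed)
                queries = [sp_new.test.compounds[c] for c in sp_new.test.compound_ids]
                pred = predict_targets(model, support, queries)
                truth = truth_matrix(sp_new.test, pred.query_ids, pred.protein_ids)
                return evaluate_predictions(pred, truth).weighted["recall"]

            new_pairs = generate_pairs(sp_new.train, 60, 60, seed=seed)
            pre_pairs = generate_pairs(split_dataset(pre, seed=seed).train, 100, 100, seed=seed)

            transferred = SiameseModel.create(new.fingerprint_spec, hidden_dims=(32, 16), seed=seed)
            train(transferred, pre_pairs, [], budget)
            fine_tune(transferred, new_pairs, [], budget)

            scratch = SiameseModel.create(new.fingerprint_spec, hidden_dims=(32, 16), seed=seed)
            train(scratch, new_pairs, [], budget)

            if _recall(transferred) >= _recall(scratch):
                wins += 1
        assert wins >= 3  # majority of paired seeds


class TestCheckpoint:
    def test_round_trip_identical_scores(self, tmp_path, small_model):
        rng = np.random.default_rng(0)
        probes = _rand_pairs(rng, 10)
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        loaded = load_model(path)
        assert loaded.fingerprint_spec == small_model.fingerprint_spec
        for p in probes:
            assert loaded.similarity_score(p.fp_a, p.fp_b) == small_model.similarity_score(
                p.fp_a, p.fp_b
            )

    def test_corrupt_file_raises(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a checkpoint")
        with pytest.raises(CheckpointError):
            load_model(bad)

    def test_log_appends_across_load_and_finetune(self, tmp_path, train_material):
        ds, tr, val = train_material
        model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(16,), seed=0)
        train(model, tr, val, TrainConfig(max_epochs=1, seed=0))
        path = tmp_path / "m.npz"
        save_model(model, path)
        loaded = load_model(path)
        fine_tune(loaded, tr, val, TrainConfig(max_epochs=1, seed=1))
        phases = [e["phase"] for e in loaded.training_log]
        assert phases == ["train", "transfer"]
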