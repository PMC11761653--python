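"""Specificity model: training, retrieval, ablations, serialization."""

import numpy as np
import pytest

from hybridforge.chem import FINGERPRINT_LENGTH
from hybridforge.errors import ConfigurationError
from hybridforge.model import (
    ClassifierHead,
    TrainConfig,
    attribute_substructures,
    build_db,
    load_model,
    predict_topk,
    save_model,
    train,
)
from hybridforge.nn import cosine_distance


def test_training_decreases_loss(small_model):
    losses = small_model.losses
    assert len(losses) == small_model.config.epochs
    assert losses[-1] < losses[0]


def test_head_double_update_counter(small_model):
    # protocol: two head cross-entropy updates per predictor step
    assert small_model.head_updates == 2 * small_model.predictor_steps
    assert small_model.predictor_steps > 0


def test_head_first_layer_identity_at_init():
    rng = np.random.default_rng(0)
    head = ClassifierHead(5, rng)
    W = head.lin1.W
    assert np.array_equal(W, np.eye(FINGERPRINT_LENGTH))
    assert np.array_equal(head.lin1.b, np.zeros(FINGERPRINT_LENGTH))


def test_latent_embedding_nonnegative_and_sized(small_model, small_dataset):
    for rec in small_dataset.library.records:
        emb = small_model.head.embed(rec.fingerprint)
        assert emb.shape == (FINGERPRINT_LENGTH,)
        assert np.all(emb >= 0.0)  # ReLU latent


def test_training_recovers_planted_signal(small_model, small_pairs):
    correct = sum(
        predict_topk(rec, small_model, k=1)[0][0] == sub.name
        for rec, sub in small_pairs
    )
    assert correct / len(small_pairs) >= 0.9


def test_predict_topk_matches_exhaustive_cosine_sort(small_model, small_pairs):
    rec = small_pairs[0][0]
    pred_fp = small_model.predictor.predict(rec.features)
    query = small_model.head.embed(pred_fp)
    oracle = sorted(
        (
            (cosine_distance(query, vec), name)
            for name, vec in small_model.db.entries.items()
        ),
    )
    got = predict_topk(rec, small_model, k=len(oracle))
    for (od, on), (gn, gd) in zip(oracle, got):
        assert on == gn
        assert gd == pytest.approx(od, abs=1e-9)


def test_topk_distances_ascending(small_model, small_pairs):
    out = predict_topk(small_pairs[3][0], small_model, k=6)
    dists = [d for _, d in out]
    assert dists == sorted(dists)
    with pytest.raises(ValueError):
        predict_topk(small_pairs[0][0], small_model, k=0)


def test_fingerprint_ablation_mode(small_pairs, small_dataset):
    cfg = TrainConfig(epochs=6, seed=7, mode="fingerprint")
    m = train(small_pairs, cfg, library=small_dataset.library)
    assert m.head is None
    # db stores raw fingerprints in this ablation
    for rec in small_dataset.library.records:
        assert np.array_equal(m.db.entries[rec.name], rec.fingerprint)
    out = predict_topk(small_pairs[0][0], m, k=3)
    assert len(out) == 3


def test_direct_classification_mode(small_pairs, small_dataset):
    cfg = TrainConfig(epochs=6, seed=7, mode="direct")
    m = train(small_pairs, cfg, library=small_dataset.library)
    assert m.head is None
    out = predict_topk(small_pairs[0][0], m, k=3)
    assert len(out) == 3
    # scores are 1 - softmax probability, so within [0, 1]
    assert all(0.0 <= d <= 1.0 for _, d in out)


def test_zero_shot_db_contains_unseen_substrate(small_pairs, small_dataset):
    # train without one substrate but keep it in the library: it must be
    # retrievable (present in the db) although never seen in training
    held = small_dataset.library.names[0]
    subset = [(r, s) for r, s in small_pairs if s.name != held]
    m = train(subset, TrainConfig(epochs=4, seed=1), library=small_dataset.library)
    assert held not in m.labels
    assert held in m.db.entries
    out = predict_topk(small_pairs[0][0], m, k=len(small_dataset.library))
    assert held in {n for n, _ in out}


def test_build_db_requires_records(small_model):
    from hybridforge.chem import SubstrateLibrary

    with pytest.raises(ConfigurationError):
        build_db(SubstrateLibrary(), small_model.head)


def test_mixed_feature_shapes_rejected(small_pairs):
    rec, sub = small_pairs[0]
    import dataclasses

    bad = dataclasses.replace(rec, features=np.zeros((10, 8)))
    with pytest.raises(ConfigurationError):
        train([small_pairs[1], (bad, sub)], TrainConfig(epochs=1, seed=0))


def test_save_load_roundtrip(tmp_path, small_model, small_pairs):
    path = tmp_path / "model.npz"
    save_model(small_model, path)
    back = load_model(path)
    assert back.labels == small_model.labels
    assert back.config == small_model.config
    assert back.predictor_steps == small_model.predictor_steps
    for rec, _ in small_pairs[:5]:
        assert predict_topk(rec, back, k=3) == predict_topk(rec, small_model, k=3)


def test_attribute_substructures(small_model, small_pairs):
    rec, sub = small_pairs[0]
    fp = small_model.predictor.predict(rec.features)
    entries = attribute_substructures(fp, sub, threshold=0.5)
    for idx, desc, present in entries:
        assert 0 <= idx < FINGERPRINT_LENGTH - 1  # charge entry excluded
        assert isinstance(desc, str) and desc
        assert present == bool(sub.fingerprint[idx] == 1.0)
    with pytest.raises(ValueError):
        attribute_substructures(fp, sub, threshold=1.5)


def test_training_determinism(small_pairs, small_dataset):
    cfg = TrainConfig(epochs=3, seed=9)
    m1 = train(small_pairs, cfg, library=small_dataset.library)
    m2 = train(small_pairs, cfg, library=small_dataset.library)
    assert m1.losses == m2.losses
    for p1, p2 in zip(m1.predictor.net.params, m2.predictor.net.params):
        assert np.array_equal(p1, p2)
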