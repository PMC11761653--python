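"""Two-network substrate-specificity model for adenylation domains.

The *fingerprint predictor* regresses a 296-entry substructure fingerprint
from binding-pocket residue features.  A *classifier head* is trained on top
(with the gradient stopped at the predictor boundary) to recover substrate
labels from both predicted and target fingerprints; its rectified hidden
layer defines a latent substrate space.  Prediction is nearest-neighbour
retrieval in that latent space against a precomputed embedding database,
which may contain substrates never seen in training (zero-shot).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from rdkit.Chem import MACCSkeys

from . import nn
from .adomain import AdomainRecord
from .chem import FINGERPRINT_LENGTH, MACCS_BITS, SubstrateLibrary, SubstrateRecord
from .errors import ConfigurationError

LATENT_DIM = FINGERPRINT_LENGTH  # 296

Mode = Literal["latent", "fingerprint", "direct"]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance 1 - cos(u, v), in [0, 2]; errors on zero vectors."""
    return nn.cosine_distance(np.asarray(u, float), np.asarray(v, float))


@dataclass
class TrainConfig:
    """Training hyper-parameters (defaults are the recommended schedule)."""

    epochs: int = 80
    batch_size: int = 128
    learning_rate: float = 1e-4
    lr_decay: float = 0.8
    lr_decay_every: int = 10
    weight_decay: float = 0.01
    hidden_per_residue: tuple[int, int] = (480, 240)
    trunk_hidden: tuple[int, int] = (240, 240)
    seed: int = 0
    mode: Mode = "latent"


class FingerprintPredictor:
    """MLP mapping a (P, D) residue-feature matrix to a 296-entry fingerprint.

    Per-residue affine layers (shared across the P positions) are followed by
    a flatten and a dense trunk; every non-final affine layer is followed by
    ELU and layer normalization.  ``n_out`` is 296 in regression mode and the
    number of labels in the direct-classification ablation.
    """

    def __init__(
        self,
        n_positions: int,
        n_features: int,
        config: TrainConfig,
        rng: np.random.Generator,
        n_out: int = FINGERPRINT_LENGTH,
    ) -> None:
        h1, h2 = config.hidden_per_residue
        t1, t2 = config.trunk_hidden
        self.n_positions = n_positions
        self.n_features = n_features
        self.n_out = n_out
        self.net = nn.Sequential(
            nn.Linear(n_features, h1, rng), nn.ELU(), nn.LayerNorm(h1),
            nn.Linear(h1, h2, rng), nn.ELU(), nn.LayerNorm(h2),
            nn.Flatten(),
            nn.Linear(n_positions * h2, t1, rng), nn.ELU(), nn.LayerNorm(t1),
            nn.Linear(t1, t2, rng), nn.ELU(), nn.LayerNorm(t2),
            nn.Linear(t2, n_out, rng),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, P, D) -> (B, n_out)."""
        return self.net.forward(x)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Single-record forward pass; features (P, D) -> (n_out,)."""
        return self.forward(features[None, :, :])[0]


class ClassifierHead:
    """296 -> 296 affine (identity-initialized) + ReLU latent + 296 -> L logits."""

    def __init__(self, n_labels: int, rng: np.random.Generator) -> None:
        self.n_labels = n_labels
        lin1 = nn.Linear(LATENT_DIM, LATENT_DIM, rng)
        lin1.W[...] = np.eye(LATENT_DIM)
        lin1.b[...] = 0.0
        self.lin1 = lin1
        self.relu = nn.ReLU()
        self.lin2 = nn.Linear(LATENT_DIM, n_labels, rng)
        self.net = nn.Sequential(self.lin1, self.relu, self.lin2)

    def embed(self, fingerprint: np.ndarray) -> np.ndarray:
        """Latent substrate embedding: rectified first-layer output (>= 0)."""
        fp = np.asarray(fingerprint, float)
        if fp.shape != (LATENT_DIM,):
            raise ValueError(f"expected length-{LATENT_DIM} fingerprint, got {fp.shape}")
        return np.maximum(fp @ self.lin1.W + self.lin1.b, 0.0)

    def logits(self, fingerprints: np.ndarray) -> np.ndarray:
        return self.net.forward(fingerprints)


def embed_substrate(fingerprint: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Latent embedding of a substrate fingerprint (works for unseen substrates)."""
    return head.embed(fingerprint)


class EmbeddingDatabase:
    """Substrate name -> length-296 nonnegative latent vector."""

    def __init__(self) -> None:
        self.entries: dict[str, np.ndarray] = {}

    def add(self, name: str, vector: np.ndarray) -> None:
        vec = np.asarray(vector, float)
        if vec.shape != (LATENT_DIM,):
            raise ValueError("embedding must have length 296")
        self.entries[name] = vec

    def __len__(self) -> int:
        return len(self.entries)

    def matrix(self) -> tuple[list[str], np.ndarray]:
        names = sorted(self.entries)
        return names, np.stack([self.entries[n] for n in names])


def build_db(
    library: SubstrateLibrary, head: ClassifierHead | None
) -> EmbeddingDatabase:
    """Embed every library substrate from its true fingerprint.

    With ``head=None`` (classifier-head ablation) raw fingerprints are stored
    so nearest-substrate search happens directly in fingerprint space.
    """
    if len(library) == 0:
        raise ConfigurationError("substrate library is empty")
    db = EmbeddingDatabase()
    for rec in library.records:
        vec = rec.fingerprint if head is None else head.embed(rec.fingerprint)
        db.add(rec.name, vec)
    return db


@dataclass
class TrainedMaspr:
    """Trained model artifact: predictor, head, database and provenance."""

    predictor: FingerprintPredictor
    head: ClassifierHead | None
    db: EmbeddingDatabase | None
    labels: list[str]
    config: TrainConfig
    seed: int
    predictor_steps: int = 0
    head_updates: int = 0
    library_hash: str = ""
    losses: list[float] = field(default_factory=list)

    @property
    def mode(self) -> Mode:
        return self.config.mode


def _stack_dataset(
    dataset: Sequence[tuple[AdomainRecord, SubstrateRecord]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    if not dataset:
        raise ConfigurationError("training dataset is empty")
    shapes = {rec.features.shape for rec, _ in dataset}
    if len(shapes) != 1:
        raise ConfigurationError(f"mixed feature shapes in dataset: {sorted(shapes)}")
    feats = np.stack([rec.features for rec, _ in dataset]).astype(float)
    fps = np.stack([sub.fingerprint for _, sub in dataset]).astype(float)
    labels = sorted({sub.name for _, sub in dataset})
    index = {n: i for i, n in enumerate(labels)}
    y = np.array([index[sub.name] for _, sub in dataset])
    return feats, fps, y, labels


def train(
    dataset: Sequence[tuple[AdomainRecord, SubstrateRecord]],
    config: TrainConfig | None = None,
    library: SubstrateLibrary | None = None,
) -> TrainedMaspr:
    """Train the fingerprint predictor and (mode-dependent) classifier head.

    Per batch, the predictor takes one AdamW step on the batch-mean cosine
    distance to target fingerprints; the head takes two cross-entropy steps,
    first on the predicted fingerprints (gradient stopped at the predictor
    boundary), then on the target fingerprints.  ``library`` defaults to the
    training substrates and populates the embedding database.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    feats, fps, y, labels = _stack_dataset(dataset)
    n, n_pos, n_dim = feats.shape
    n_labels = len(labels)

    direct = config.mode == "direct"
    n_out = n_labels if direct else FINGERPRINT_LENGTH
    predictor = FingerprintPredictor(n_pos, n_dim, config, rng, n_out=n_out)
    head = ClassifierHead(n_labels, rng) if config.mode == "latent" else None

    popt = nn.AdamW(
        predictor.net.params, predictor.net.grads,
        lr=config.learning_rate, weight_decay=config.weight_decay,
    )
    hopt = (
        nn.AdamW(
            head.net.params, head.net.grads,
            lr=config.learning_rate, weight_decay=config.weight_decay,
        )
        if head is not None
        else None
    )

    predictor_steps = 0
    head_updates = 0
    losses: list[float] = []
    for epoch in range(config.epochs):
        lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        popt.lr = lr
        if hopt is not None:
            hopt.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, fb, yb = feats[idx], fps[idx], y[idx]

            predictor.net.zero_grads()
            pred = predictor.forward(xb)
            if direct:
                loss, grad = nn.cross_entropy(pred, yb)
            else:
                loss, grad = nn.cosine_loss(pred, fb)
            predictor.net.backward(grad)
            popt.step()
            predictor_steps += 1
            epoch_loss += loss
            n_batches += 1

            if head is not None and hopt is not None:
                # update 1: predicted fingerprints (stop-gradient: `pred` is
                # consumed as a constant input, nothing flows to the predictor)
                for inputs in (pred, fb):
                    head.net.zero_grads()
                    logits = head.net.forward(inputs)
                    _, hgrad = nn.cross_entropy(logits, yb)
                    head.net.backward(hgrad)
                    hopt.step()
                    head_updates += 1
        losses.append(epoch_loss / max(n_batches, 1))

    if library is None:
        library = SubstrateLibrary()
        for _, sub in dataset:
            library.add(sub)
    db = None if direct else build_db(library, head)
    lib_hash = hashlib.sha256(
        "\n".join(f"{r.name}\t{r.smiles}" for r in library.records).encode()
    ).hexdigest()
    return TrainedMaspr(
        predictor=predictor,
        head=head,
        db=db,
        labels=labels,
        config=config,
        seed=config.seed,
        predictor_steps=predictor_steps,
        head_updates=head_updates,
        library_hash=lib_hash,
        losses=losses,
    )


def predict_topk(
    record: AdomainRecord, model: TrainedMaspr, k: int = 3
) -> list[tuple[str, float]]:
    """Top-k substrates with cosine distances, ascending; ties break by name.

    In latent mode the query is the head embedding of the predicted
    fingerprint; in fingerprint mode the predicted fingerprint itself; in the
    direct-classification ablation the ranking comes from softmax scores and
    the reported value is ``1 - probability``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pred = model.predictor.predict(record.features)
    if model.mode == "direct":
        shifted = pred - pred.max()
        probs = np.exp(shifted) / np.exp(shifted).sum()
        ranked = sorted(zip(model.labels, 1.0 - probs), key=lambda t: (t[1], t[0]))
        return ranked[:k]
    if model.db is None or len(model.db) == 0:
        raise ConfigurationError("embedding database is empty")
    query = pred if model.head is None else model.head.embed(pred)
    eps = 1e-12
    qn = np.linalg.norm(query) + eps
    out = []
    for name, vec in model.db.entries.items():
        cos = float(np.dot(query, vec) / (qn * (np.linalg.norm(vec) + eps)))
        out.append((name, 1.0 - cos))
    out.sort(key=lambda t: (t[1], t[0]))
    return out[: min(k, len(out))]


def attribute_substructures(
    predicted_fp: np.ndarray,
    substrate: SubstrateRecord,
    threshold: float = 0.5,
) -> list[tuple[int, str, bool]]:
    """Binary fingerprint positions predicted above threshold, annotated.

    Each entry is (feature index, human-readable substructure description,
    whether the substrate's own fingerprint sets that bit).  The trailing
    charge entry is not a binary feature and is excluded.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    fp = np.asarray(predicted_fp, float)
    if fp.shape != (FINGERPRINT_LENGTH,):
        raise ValueError("predicted fingerprint must have length 296")
    out = []
    for i in np.nonzero(fp[: FINGERPRINT_LENGTH - 1] >= threshold)[0]:
        i = int(i)
        if i < MACCS_BITS:
            smarts = MACCSkeys.smartsPatts.get(i, ("?", 0))[0]
            desc = f"MACCS key {i}: {smarts}"
        else:
            desc = f"Morgan bit {i - MACCS_BITS} (radius 2, 128 bits)"
        out.append((i, desc, bool(substrate.fingerprint[i] == 1.0)))
    return out


# ---------------------------------------------------------------------------
# serialization: a single .npz archive with a JSON manifest
# ---------------------------------------------------------------------------


def save_model(model: TrainedMaspr, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.predictor.net.params):
        arrays[f"pred_{i}"] = p
    if model.head is not None:
        for i, p in enumerate(model.head.net.params):
            arrays[f"head_{i}"] = p
    if model.db is not None:
        names, mat = model.db.matrix()
        arrays["db_matrix"] = mat
    else:
        names = []
    manifest = {
        "labels": model.labels,
        "db_names": names,
        "config": asdict(model.config),
        "seed": model.seed,
        "predictor_steps": model.predictor_steps,
        "head_updates": model.head_updates,
        "library_hash": model.library_hash,
        "n_positions": model.predictor.n_positions,
        "n_features": model.predictor.n_features,
        "n_out": model.predictor.n_out,
        "losses": model.losses,
    }
    arrays["manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8
    ).copy()
    np.savez_compressed(str(path), **arrays)


def load_model(path: str | Path) -> TrainedMaspr:
    data = np.load(str(path))
    manifest = json.loads(bytes(data["manifest"]).decode())
    cfg = manifest["config"]
    cfg["hidden_per_residue"] = tuple(cfg["hidden_per_residue"])
    cfg["trunk_hidden"] = tuple(cfg["trunk_hidden"])
    config = TrainConfig(**cfg)
    rng = np.random.default_rng(0)
    predictor = FingerprintPredictor(
        manifest["n_positions"], manifest["n_features"], config, rng,
        n_out=manifest["n_out"],
    )
    for i, p in enumerate(predictor.net.params):
        p[...] = data[f"pred_{i}"]
    head = None
    if config.mode == "latent":
        head = ClassifierHead(len(manifest["labels"]), rng)
        for i, p in enumerate(head.net.params):
            p[...] = data[f"head_{i}"]
    db = None
    if manifest["db_names"]:
        db = EmbeddingDatabase()
        for name, row in zip(manifest["db_names"], data["db_matrix"]):
            db.add(name, row)
    return TrainedMaspr(
        predictor=predictor,
        head=head,
        db=db,
        labels=manifest["labels"],
        config=config,
        seed=manifest["seed"],
        predictor_steps=manifest["predictor_steps"],
        head_updates=manifest["head_updates"],
        library_hash=manifest["library_hash"],
        losses=list(manifest["losses"]),
    )
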