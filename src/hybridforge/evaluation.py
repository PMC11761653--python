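"""Evaluation protocols for the specificity model.

Implements distance-stratified accuracy (Hamming buckets on the 34-residue
signature), top-k accuracy with multi-label ground truth, leave-one-substrate-
out zero-shot evaluation, a promiscuous-domain split, and a generic grouped
split (e.g. train on one taxon, test on another).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .adomain import hamming
from .chem import SubstrateLibrary
from .errors import ConfigurationError

#: a dataset pair: (record id, signature, substrate name); the record id ties
#: together multiple pairs of a promiscuous sequence.
Pair = tuple[str, str, str]


@dataclass(frozen=True)
class BucketSpec:
    """Hamming-distance thresholds defining nested buckets B{i}+."""

    thresholds: tuple[int, ...] = (0, 3, 6, 9, 12)

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(x < 0 for x in t) or list(t) != sorted(set(t)):
            raise ValueError("thresholds must be nonnegative, strictly increasing")


@dataclass
class EvalReport:
    """Accuracies per bucket and overall, with split provenance."""

    split: str
    seed: int
    overall: dict[int, float]  # k -> top-k accuracy
    per_bucket: dict[str, dict[int, float]] = field(default_factory=dict)
    bucket_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def stratify_buckets(
    test_signatures: Sequence[str],
    train_signatures: Sequence[str],
    spec: BucketSpec = BucketSpec(),
) -> dict[str, list[int]]:
    """Bucket membership: test record i is in B{t}+ iff its minimum Hamming
    distance to any training signature is >= t.  Buckets are nested."""
    if not train_signatures:
        raise ConfigurationError("empty training set")
    out: dict[str, list[int]] = {f"B{t}+": [] for t in spec.thresholds}
    for i, sig in enumerate(test_signatures):
        dmin = min(hamming(sig, tr) for tr in train_signatures)
        for t in spec.thresholds:
            if dmin >= t:
                out[f"B{t}+"].append(i)
    return out


def topk_accuracy(
    predictions: Sequence[Sequence[tuple[str, float]]],
    truths: Sequence[set[str] | str],
    k: int,
) -> float:
    """Fraction of records whose true substrate is in the first k predictions.

    For promiscuous records ``truths[i]`` may be a set; any observed substrate
    counts as a hit.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    hits = 0
    for preds, truth in zip(predictions, truths):
        if not truth:
            raise ConfigurationError("record without a truth label")
        labels = {truth} if isinstance(truth, str) else set(truth)
        top = {name for name, _ in preds[:k]}
        hits += bool(top & labels)
    return hits / len(predictions) if predictions else float("nan")


def loso_split(
    dataset: Sequence[Pair], held_out_substrate: str, library: SubstrateLibrary
) -> tuple[list[Pair], list[Pair], SubstrateLibrary]:
    """Leave-one-substrate-out: train without the label, test only on it.

    The returned library (for the embedding database) still contains the
    held-out substrate, which is the zero-shot retrieval target.
    """
    test = [p for p in dataset if p[2] == held_out_substrate]
    if not test:
        raise ConfigurationError(f"substrate {held_out_substrate!r} absent from dataset")
    train = [p for p in dataset if p[2] != held_out_substrate]
    if held_out_substrate not in library:
        raise ConfigurationError("held-out substrate missing from library")
    return train, test, library


def promiscuous_split(
    dataset: Sequence[Pair], seed: int = 0
) -> tuple[list[Pair], list[Pair]]:
    """Train on all non-promiscuous pairs plus one random pair per promiscuous
    sequence; the remaining n-1 pairs of each promiscuous sequence form the
    test set.  Promiscuity = same record id with >1 distinct substrate labels.
    """
    rng = np.random.default_rng(seed)
    by_id: dict[str, list[Pair]] = {}
    for p in dataset:
        by_id.setdefault(p[0], []).append(p)
    train: list[Pair] = []
    test: list[Pair] = []
    for rid in sorted(by_id):
        pairs = sorted(by_id[rid], key=lambda p: p[2])
        labels = {p[2] for p in pairs}
        if len(labels) <= 1:
            train.extend(pairs)
        else:
            keep = int(rng.integers(len(pairs)))
            for i, p in enumerate(pairs):
                (train if i == keep else test).append(p)
    return train, test


def grouped_split(
    dataset: Sequence[Pair], groups: Mapping[str, str], train_group: str, test_group: str
) -> tuple[list[Pair], list[Pair]]:
    """Generic metadata split: train on one group, test on another.

    ``groups`` maps record ids to group labels (e.g. 'bacterial'/'fungal').
    """
    train = [p for p in dataset if groups.get(p[0]) == train_group]
    test = [p for p in dataset if groups.get(p[0]) == test_group]
    return train, test


def random_splits(
    dataset: Sequence[Pair], n_splits: int = 12, test_fraction: float = 0.2, seed: int = 0
) -> list[tuple[list[Pair], list[Pair]]]:
    """Repeated seeded random train/test splits (default 12 at 80/20)."""
    rng = np.random.default_rng(seed)
    n = len(dataset)
    n_test = max(1, int(round(n * test_fraction)))
    out = []
    for _ in range(n_splits):
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
        train = [p for i, p in enumerate(dataset) if i not in test_idx]
        test = [p for i, p in enumerate(dataset) if i in test_idx]
        out.append((train, test))
    return out
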