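"""Shared fixtures: reference alignment, small planted dataset, trained model,
AT classifier and a toy genome bundle.  Session-scoped because training and
HMM construction dominate the suite's runtime."""

from __future__ import annotations

from pathlib import Path

import pytest

from hybridforge import synth
from hybridforge.adomain import ReferenceAlignment
from hybridforge.model import TrainConfig, save_model, train

SEED = 101


@pytest.fixture(scope="session")
def ref() -> ReferenceAlignment:
    return ReferenceAlignment.default()


@pytest.fixture(scope="session")
def small_dataset(ref):
    spec = synth.PlantedSpec(
        n_substrates=6, sequences_per_substrate=12, seed=SEED
    )
    return synth.make_adomain_dataset(spec, ref)


@pytest.fixture(scope="session")
def small_pairs(small_dataset, ref):
    return small_dataset.featurized(ref)


@pytest.fixture(scope="session")
def small_model(small_pairs, small_dataset):
    cfg = TrainConfig(epochs=25, seed=SEED)
    return train(small_pairs, cfg, library=small_dataset.library)


@pytest.fixture(scope="session")
def at_model():
    return synth.make_at_model(seed=SEED)


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory, small_dataset, at_model, ref):
    """Canonical 4-gene toy genome plus all files the pipeline needs."""
    out = tmp_path_factory.mktemp("toy")
    genome = synth.make_toy_genome(
        synth.acceptance_bgc_spec(seed=SEED),
        code_map=small_dataset.code_map,
        ref=ref,
        at_model=at_model,
    )
    genome.write_fasta(out / "genome.fasta")
    synth.write_hmms(
        synth.build_fixture_hmms(genome.classes, ref=ref, seed=SEED),
        out / "domains.hmm",
    )
    synth.write_fixture_modifications(out / "modifications.tsv")
    return {"dir": out, "genome": genome}


@pytest.fixture(scope="session")
def model_file(tmp_path_factory, small_model) -> Path:
    path = tmp_path_factory.mktemp("model") / "model.npz"
    save_model(small_model, path)
    return path
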