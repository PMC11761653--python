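"""Binding-pocket code extraction and featurization for adenylation domains.

An A-domain's substrate specificity is largely determined by ten
binding-pocket residues (the Stachelhaus code); a wider 34-residue
signature covers all residues within 8 Angstroms of the pocket.  Both are
recovered from a query sequence by global pairwise alignment to a single
reference A-domain whose code positions are known, and are then featurized
either as one-hot matrices or as per-residue protein-language-model
embeddings selected at the aligned code positions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Protocol

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .errors import BackendUnavailableError, EncodingError, UnalignableSequenceError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: one-hot alphabet: 20 amino acids plus a dedicated gap column
ONEHOT_ALPHABET = AA_ALPHABET + GAP

STACHELHAUS_LENGTH = 10
SIGNATURE_LENGTH = 34

#: minimum fraction of identical residues over aligned (non-gap) columns
DEFAULT_MIN_IDENTITY = 0.30
MIN_SEQUENCE_LENGTH = 100


@dataclass(frozen=True)
class ReferenceAlignment:
    """Reference A-domain and its configured code positions.

    The shipped default is a synthetic scaffold (see
    ``data/reference_adomain_synthetic.json``); a real reference such as the
    GrsA Phe-activating A-domain can be supplied in the same schema.  The 10
    Stachelhaus positions need not be a subset of the 34 signature positions,
    although the shipped file satisfies that containment.
    """

    reference_sequence: str
    stachelhaus_positions: tuple[int, ...]
    signature_positions: tuple[int, ...]
    min_identity: float = DEFAULT_MIN_IDENTITY

    def __post_init__(self) -> None:
        for name, positions, expected in (
            ("stachelhaus_positions", self.stachelhaus_positions, STACHELHAUS_LENGTH),
            ("signature_positions", self.signature_positions, SIGNATURE_LENGTH),
        ):
            if len(positions) != expected:
                raise ValueError(f"{name} must have {expected} entries")
            if list(positions) != sorted(set(positions)):
                raise ValueError(f"{name} must be strictly increasing")
            if positions[-1] >= len(self.reference_sequence):
                raise ValueError(f"{name} exceeds reference length")

    @classmethod
    def from_json(cls, path: str | Path, **kwargs) -> "ReferenceAlignment":
        obj = json.loads(Path(path).read_text())
        return cls(
            reference_sequence=obj["reference_sequence"],
            stachelhaus_positions=tuple(obj["stachelhaus_positions"]),
            signature_positions=tuple(obj["signature_positions"]),
            **kwargs,
        )

    @classmethod
    def default(cls, **kwargs) -> "ReferenceAlignment":
        with resources.as_file(
            resources.files("hybridforge.data") / "reference_adomain_synthetic.json"
        ) as path:
            return cls.from_json(path, **kwargs)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def _align_to_reference(sequence: str, ref: ReferenceAlignment) -> dict[int, int]:
    """Map each aligned reference position to the query position."""
    sequence = sequence.upper()
    if len(sequence) < MIN_SEQUENCE_LENGTH:
        raise UnalignableSequenceError(
            f"sequence length {len(sequence)} < {MIN_SEQUENCE_LENGTH}"
        )
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise EncodingError(f"unsupported residues in sequence: {sorted(bad)}")
    aligner = _make_aligner()
    aln = aligner.align(ref.reference_sequence, sequence)[0]
    ref_blocks, qry_blocks = aln.aligned
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (rs, re), (qs, _qe) in zip(ref_blocks, qry_blocks):
        for off in range(re - rs):
            rpos = rs + off
            qpos = qs + off
            mapping[rpos] = qpos
            aligned_cols += 1
            if sequence[qpos] == ref.reference_sequence[rpos]:
                matches += 1
    # identity over the full alignment length (gap columns included), so a
    # sparse, gappy alignment of an unrelated sequence cannot pass on the
    # strength of its few cherry-picked matched columns
    total_cols = len(ref.reference_sequence) + len(sequence) - aligned_cols
    identity = matches / total_cols if total_cols else 0.0
    if identity < ref.min_identity:
        raise UnalignableSequenceError(
            f"alignment identity {identity:.2f} below threshold {ref.min_identity:.2f}"
        )
    return mapping


def extract_codes(sequence: str, ref: ReferenceAlignment) -> tuple[str, str]:
    """Extract (10-residue Stachelhaus code, 34-residue 8A signature).

    Reference positions aligned to a gap in the query yield ``'-'``.
    """
    seq = sequence.upper()
    mapping = _align_to_reference(seq, ref)
    stach = "".join(
        seq[mapping[p]] if p in mapping else GAP for p in ref.stachelhaus_positions
    )
    sig = "".join(
        seq[mapping[p]] if p in mapping else GAP for p in ref.signature_positions
    )
    return stach, sig


def hamming(sig_a: str, sig_b: str) -> int:
    """Number of differing positions; the gap counts as an ordinary symbol."""
    if len(sig_a) != len(sig_b):
        raise ValueError(f"length mismatch: {len(sig_a)} vs {len(sig_b)}")
    return sum(a != b for a, b in zip(sig_a, sig_b))


def featurize_onehot(signature: str) -> np.ndarray:
    """One-hot encode a signature: one row per position, 21 columns (20 aa + gap)."""
    mat = np.zeros((len(signature), len(ONEHOT_ALPHABET)))
    for i, ch in enumerate(signature.upper()):
        j = ONEHOT_ALPHABET.find(ch)
        if j < 0:
            raise EncodingError(f"unknown character {ch!r} at position {i}")
        mat[i, j] = 1.0
    return mat


class EmbeddingBackend(Protocol):
    """Per-residue embedding provider for full protein sequences."""

    #: embedding width D
    dim: int
    #: stable identifier used for on-disk caching
    backend_id: str

    def embed(self, sequence: str) -> np.ndarray:  # (len(sequence), dim)
        ...


class EsmBackend:
    """Protein-language-model backend (650M-parameter default checkpoint).

    Requires the optional ``fair-esm``/``torch`` stack; when absent, raises
    a :class:`BackendUnavailableError` directing the caller to one-hot mode.
    """

    def __init__(self, checkpoint: str = "esm2_t33_650M_UR50D") -> None:
        self.checkpoint = checkpoint
        self.backend_id = f"plm:{checkpoint}"
        try:
            import esm  # type: ignore
            import torch  # type: ignore  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                f"PLM backend {checkpoint!r} needs the fair-esm/torch stack, "
                "which is not installed; use the one-hot backend instead "
                "(backend='onehot')."
            ) from exc
        model, alphabet = esm.pretrained.load_model_and_alphabet(checkpoint)
        self._model = model.eval()
        self._converter = alphabet.get_batch_converter()
        self.dim = model.embed_dim

    def embed(self, sequence: str) -> np.ndarray:
        import torch  # type: ignore

        _, _, tokens = self._converter([("query", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[self._model.num_layers])
        rep = out["representations"][self._model.num_layers][0, 1 : len(sequence) + 1]
        return rep.cpu().numpy().astype(np.float64)


class MockBackend:
    """Deterministic toy backend: residue-type + position-tagged constants.

    Used in tests and anywhere a cheap stand-in for a language model is
    needed; the embedding of residue ``r`` at position ``p`` depends only on
    ``(r, p)`` so selection logic can be verified by hand.
    """

    def __init__(self, dim: int = 8) -> None:
        self.dim = dim
        self.backend_id = f"mock:{dim}"

    def embed(self, sequence: str) -> np.ndarray:
        mat = np.zeros((len(sequence), self.dim))
        for p, ch in enumerate(sequence.upper()):
            mat[p, 0] = float(p)
            mat[p, 1] = float(ONEHOT_ALPHABET.find(ch))
        return mat


def featurize_plm(
    sequence: str,
    ref: ReferenceAlignment,
    backend: EmbeddingBackend,
    cache_dir: str | Path | None = None,
) -> np.ndarray:
    """10 x D matrix of backend embeddings at the aligned Stachelhaus positions.

    Embeddings are computed once over the full sequence; rows are then
    selected at the 10 aligned code positions in reference order, with zero
    rows for positions aligned to a gap.  Results may be cached on disk keyed
    by (sequence hash, backend id).
    """
    cache_path = None
    if cache_dir is not None:
        digest = hashlib.sha256(sequence.upper().encode()).hexdigest()[:24]
        safe_id = backend.backend_id.replace(":", "_").replace("/", "_")
        cache_path = Path(cache_dir) / f"{digest}.{safe_id}.npy"
        if cache_path.exists():
            return np.load(cache_path)

    sequence = sequence.upper()
    mapping = _align_to_reference(sequence, ref)
    full = backend.embed(sequence)
    rows = np.zeros((STACHELHAUS_LENGTH, backend.dim))
    for i, rpos in enumerate(ref.stachelhaus_positions):
        if rpos in mapping:
            rows[i] = full[mapping[rpos]]
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.save(cache_path, rows)
    return rows


@dataclass
class AdomainRecord:
    """A-domain sequence with extracted codes and a feature matrix."""

    id: str
    sequence: str
    stachelhaus: str
    signature8A: str
    features: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.stachelhaus) != STACHELHAUS_LENGTH:
            raise ValueError("Stachelhaus code must be 10 residues")
        if len(self.signature8A) != SIGNATURE_LENGTH:
            raise ValueError("8A signature must be 34 residues")


def featurize_record(
    rec_id: str,
    sequence: str,
    ref: ReferenceAlignment,
    backend: str | EmbeddingBackend = "onehot",
    cache_dir: str | Path | None = None,
) -> AdomainRecord:
    """Build an :class:`AdomainRecord` with the requested featurization.

    ``backend='onehot'`` one-hot encodes the 34-residue signature (34 x 21);
    any :class:`EmbeddingBackend` instance yields a 10 x D matrix at the
    Stachelhaus positions.
    """
    stach, sig = extract_codes(sequence, ref)
    if backend == "onehot":
        features = featurize_onehot(sig)
    elif backend == "plm":
        features = featurize_plm(sequence, ref, EsmBackend(), cache_dir=cache_dir)
    elif isinstance(backend, str):
        raise ValueError(f"unknown backend {backend!r}; use 'onehot' or 'plm'")
    else:
        features = featurize_plm(sequence, ref, backend, cache_dir=cache_dir)
    return AdomainRecord(
        id=rec_id, sequence=sequence.upper(), stachelhaus=stach,
        signature8A=sig, features=features,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a protein FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
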