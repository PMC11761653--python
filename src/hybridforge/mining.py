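"""Hybrid BGC detection and active-domain annotation.

Contigs are translated in six frames and scanned with profile HMMs of
biosynthetic domains (adenylation, condensation, carrier proteins,
acyltransferase, ketosynthase, release and tailoring domains).  Hits are
inflated by a flank and merged into candidate BGC regions; genes are
approximated as runs of same-frame, same-strand hits.  A-domains are
annotated with top-3 substrate predictions from a trained specificity model
and AT-domains with a random-forest classifier over a 24-residue active-site
signature extracted by profile alignment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pyhmmer
from Bio.Seq import Seq

from .adomain import ONEHOT_ALPHABET, ReferenceAlignment, featurize_record
from .errors import ConfigurationError, UnalignableSequenceError
from .model import TrainedMaspr, predict_topk

#: controlled vocabulary of domain classes
DOMAIN_CLASSES = {
    "A", "C", "PCP",            # NRPS core
    "AT", "KS", "ACP",          # PKS core
    "TE", "TR",                 # release (thioesterase / thioreductase)
    "NCOM", "CCOM",             # communication-mediating terminal domains
    "MT", "F", "CY", "OX", "RED",  # module tailoring (NRPS side)
    "KR", "DH", "ER",           # ketide reduction
    "P450", "OMT", "NMT", "HAL", "GT",  # standalone tailoring enzymes
}
ACTIVE_CLASSES = {"A", "AT"}
RELEASE_CLASSES = {"TE", "TR"}

DEFAULT_EVALUE = 1e-5
DEFAULT_FLANK = 10_000
#: maximum within-gene gap between consecutive same-frame hits (bp)
GENE_GAP = 2_000

AT_SIGNATURE_LENGTH = 24


@dataclass(frozen=True)
class DomainHit:
    """A profile-HMM hit mapped back to genomic coordinates (0-based, half-open)."""

    contig: str
    strand: int  # +1 / -1
    frame: int   # 0..2 within the strand
    domain_class: str
    prot_start: int
    prot_end: int
    start: int
    end: int
    score: float
    evalue: float
    sequence: str = ""  # protein envelope sequence (used for A/AT annotation)

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ConfigurationError(f"unknown domain class {self.domain_class!r}")


@dataclass
class Gene:
    """Approximate gene: a same-frame, same-strand run of domain hits."""

    id: str
    contig: str
    strand: int
    start: int
    end: int
    domains: list[DomainHit] = field(default_factory=list)

    @property
    def architecture(self) -> list[str]:
        return [d.domain_class for d in self.domains]

    @property
    def starts_with_ncom(self) -> bool:
        return bool(self.domains) and self.domains[0].domain_class == "NCOM"

    @property
    def ends_with_ccom(self) -> bool:
        return bool(self.domains) and self.domains[-1].domain_class == "CCOM"

    @property
    def contains_release(self) -> bool:
        return any(d.domain_class in RELEASE_CLASSES for d in self.domains)

    @property
    def active_domains(self) -> list[DomainHit]:
        return [d for d in self.domains if d.domain_class in ACTIVE_CLASSES]

    @property
    def is_singleton(self) -> bool:
        return len(self.active_domains) == 1


@dataclass
class BGCRegion:
    """Merged genomic segment containing at least one active domain."""

    contig: str
    start: int
    end: int
    genes: list[Gene] = field(default_factory=list)
    hits: list[DomainHit] = field(default_factory=list)


@dataclass
class Frame:
    """One of six reading frames with a protein<->genomic coordinate map."""

    contig: str
    contig_length: int
    strand: int
    frame: int
    protein: str

    def to_genomic(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Map a protein interval [p_start, p_end) to a genomic interval."""
        if self.strand == 1:
            return self.frame + 3 * p_start, self.frame + 3 * p_end
        L = self.contig_length
        return L - self.frame - 3 * p_end, L - self.frame - 3 * p_start


def six_frame_translate(contig_id: str, sequence: str) -> list[Frame]:
    """Translate a DNA contig in all six frames; stops rendered as '*'."""
    seq = sequence.upper()
    if not seq:
        raise ConfigurationError("empty contig")
    if set(seq) - set("ACGTN"):
        raise ConfigurationError("contig must be over the ACGTN alphabet")
    L = len(seq)
    frames = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in ((1, seq), (-1, rc)):
        for f in range(3):
            sub = s[f : f + 3 * ((L - f) // 3)]
            prot = str(Seq(sub).translate()) if sub else ""
            frames.append(
                Frame(contig=contig_id, contig_length=L, strand=strand, frame=f,
                      protein=prot)
            )
    return frames


def _orf_segments(protein: str) -> Iterable[tuple[int, str]]:
    """Yield (offset, segment) pieces of a frame translation split at stops."""
    start = 0
    for i, ch in enumerate(protein):
        if ch == "*":
            if i > start:
                yield start, protein[start:i]
            start = i + 1
    if len(protein) > start:
        yield start, protein[start:]


def load_hmms(path: str | Path) -> list[pyhmmer.plan7.HMM]:
    """Read profile HMMs from a HMMER3-format file."""
    try:
        with pyhmmer.plan7.HMMFile(str(path)) as hf:
            return list(hf)
    except ValueError as exc:
        raise ConfigurationError(f"malformed HMM file {path}: {exc}") from exc


def find_domains(
    frames: Sequence[Frame],
    hmms: Sequence[pyhmmer.plan7.HMM] | str | Path,
    evalue: float = DEFAULT_EVALUE,
) -> list[DomainHit]:
    """Search frame translations with profile HMMs and map hits to genomic space.

    HMM names are the domain-class labels.  The per-domain envelope
    coordinates are used; hits above the e-value threshold are dropped.
    """
    if isinstance(hmms, (str, Path)):
        hmms = load_hmms(hmms)
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = []
    index: list[tuple[Frame, int]] = []
    for fi, fr in enumerate(frames):
        for off, seg in _orf_segments(fr.protein):
            if len(seg) < 10:
                continue
            name = f"{fi}:{off}".encode()
            seqs.append(
                pyhmmer.easel.TextSequence(name=name, sequence=seg).digitize(alphabet)
            )
            index.append((fr, off))
    hits_out: list[DomainHit] = []
    if not seqs or not hmms or evalue <= 0:
        return hits_out
    for tophits in pyhmmer.hmmer.hmmsearch(hmms, seqs, E=evalue, cpus=1):
        qname = tophits.query.name
        cls = qname.decode() if isinstance(qname, bytes) else str(qname)
        if cls not in DOMAIN_CLASSES:
            warnings.warn(f"skipping HMM with unknown class name {cls!r}")
            continue
        for hit in tophits:
            if hit.evalue > evalue:
                continue
            hname = hit.name
            if isinstance(hname, bytes):
                hname = hname.decode()
            fi, off = map(int, hname.split(":"))
            fr = frames[fi]
            for dom in hit.domains:
                if dom.i_evalue > evalue:
                    continue
                p0 = off + dom.env_from - 1
                p1 = off + dom.env_to
                g0, g1 = fr.to_genomic(p0, p1)
                hits_out.append(
                    DomainHit(
                        contig=fr.contig, strand=fr.strand, frame=fr.frame,
                        domain_class=cls, prot_start=p0, prot_end=p1,
                        start=g0, end=g1, score=float(dom.score),
                        evalue=float(dom.i_evalue),
                        sequence=fr.protein[p0:p1],
                    )
                )
    hits_out.sort(key=lambda h: (h.contig, h.start, h.end, h.domain_class))
    return hits_out


def merge_regions(
    hits: Sequence[DomainHit],
    contig_lengths: dict[str, int],
    flank: int = DEFAULT_FLANK,
) -> list[BGCRegion]:
    """Inflate hits by ``flank`` on both sides, clip to the contig, merge
    overlapping/touching segments, and keep only segments containing an
    active (A or AT) domain hit."""
    if flank < 0:
        raise ConfigurationError("flank must be >= 0")
    by_contig: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    regions: list[BGCRegion] = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: (h.start, h.end))
        L = contig_lengths[contig]
        intervals = [
            (max(0, h.start - flank), min(L, h.end + flank)) for h in chits
        ]
        merged: list[list[int]] = []
        members: list[list[DomainHit]] = []
        for (s, e), h in zip(intervals, chits):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                members[-1].append(h)
            else:
                merged.append([s, e])
                members.append([h])
        for (s, e), mem in zip(merged, members):
            if not any(h.domain_class in ACTIVE_CLASSES for h in mem):
                continue
            region = BGCRegion(contig=contig, start=s, end=e, hits=mem)
            region.genes = call_genes(region)
            regions.append(region)
    return regions


def call_genes(region: BGCRegion, max_gap: int = GENE_GAP) -> list[Gene]:
    """Approximate genes as maximal runs of same-frame, same-strand hits
    separated by less than ``max_gap`` bp; domain order follows translation
    order (genomic order on +, reversed on -)."""
    groups: dict[tuple[int, int], list[DomainHit]] = {}
    for h in region.hits:
        groups.setdefault((h.strand, h.frame), []).append(h)
    genes: list[Gene] = []
    for (strand, frame) in sorted(groups):
        run: list[DomainHit] = []
        for h in sorted(groups[(strand, frame)], key=lambda h: h.start):
            if run and h.start - run[-1].end >= max_gap:
                genes.append(_make_gene(region.contig, strand, run))
                run = []
            run.append(h)
        if run:
            genes.append(_make_gene(region.contig, strand, run))
    genes.sort(key=lambda g: (g.start, g.end))
    for i, g in enumerate(genes):
        g.id = f"{region.contig}:g{i + 1}"
    return genes


def _make_gene(contig: str, strand: int, run: list[DomainHit]) -> Gene:
    ordered = sorted(run, key=lambda h: h.start, reverse=(strand == -1))
    return Gene(
        id="", contig=contig, strand=strand,
        start=min(h.start for h in run), end=max(h.end for h in run),
        domains=ordered,
    )


def annotate_adomains(
    region: BGCRegion,
    model: TrainedMaspr,
    ref: ReferenceAlignment,
    backend: str = "onehot",
    k: int = 3,
) -> dict[str, list[tuple[str, float]]]:
    """Top-k (substrate, score) per A-domain; score = 1 - cosine distance.

    Unalignable A-domains are annotated with an empty prediction list and a
    warning, and contribute no monomer constraint downstream.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for gene in region.genes:
        for j, hit in enumerate(gene.domains):
            if hit.domain_class != "A":
                continue
            key = f"{gene.id}:A{j}"
            try:
                rec = featurize_record(key, hit.sequence, ref, backend=backend)
            except UnalignableSequenceError as exc:
                warnings.warn(f"A-domain {key} unalignable: {exc}")
                out[key] = []
                continue
            preds = predict_topk(rec, model, k=k)
            out[key] = [(name, 1.0 - dist) for name, dist in preds]
    return out


# ---------------------------------------------------------------------------
# AT-domain specificity: 24-residue active-site signature + random forest
# ---------------------------------------------------------------------------


class AtSpecificityModel:
    """AT-domain substrate classifier.

    A single profile HMM built over reference AT-domains provides the
    alignment; the query residues at 24 configured match-state columns form
    the signature, which is one-hot encoded (24 x 21) and classified by a
    random forest over ketide monomers.
    """

    def __init__(
        self,
        hmm: pyhmmer.plan7.HMM,
        signature_columns: Sequence[int],
        seed: int = 0,
    ) -> None:
        if len(signature_columns) != AT_SIGNATURE_LENGTH:
            raise ValueError("exactly 24 signature columns are required")
        self.hmm = hmm
        self.signature_columns = tuple(signature_columns)
        self.seed = seed
        self._forest = None
        self.classes_: list[str] = []

    def signature(self, sequence: str) -> str:
        """Extract the 24-residue signature by alignment to the AT profile."""
        alphabet = pyhmmer.easel.Alphabet.amino()
        seq = pyhmmer.easel.TextSequence(name=b"q", sequence=sequence).digitize(alphabet)
        msa = pyhmmer.hmmer.hmmalign(self.hmm, [seq], trim=False)
        row = msa.alignment[0]
        # walk match states: uppercase residue or '-' consume one match column
        wanted = set(self.signature_columns)
        sig: dict[int, str] = {}
        mi = 0
        for ch in row:
            if ch == "-" or ch.isupper():
                if mi in wanted:
                    sig[mi] = "-" if ch == "-" else ch
                mi += 1
        if len(sig) != AT_SIGNATURE_LENGTH:
            raise UnalignableSequenceError(
                "AT profile alignment does not cover all signature columns"
            )
        out = "".join(sig[c] for c in self.signature_columns)
        # hmmalign aligns any input; call a signature unalignable when more
        # than half its columns are gaps
        if out.count("-") * 2 > AT_SIGNATURE_LENGTH:
            raise UnalignableSequenceError(
                "more than half of the AT signature columns are gaps"
            )
        return out

    @staticmethod
    def encode(signature: str) -> np.ndarray:
        """One-hot encode a 24-residue signature as a flat 24*21 vector."""
        mat = np.zeros((AT_SIGNATURE_LENGTH, len(ONEHOT_ALPHABET)))
        for i, ch in enumerate(signature.upper()):
            j = ONEHOT_ALPHABET.find(ch)
            if j < 0:
                raise ConfigurationError(f"bad signature character {ch!r}")
            mat[i, j] = 1.0
        return mat.ravel()

    def fit(self, signatures: Sequence[str], monomers: Sequence[str]) -> None:
        from sklearn.ensemble import RandomForestClassifier

        X = np.stack([self.encode(s) for s in signatures])
        self._forest = RandomForestClassifier(
            n_estimators=100, random_state=self.seed
        ).fit(X, list(monomers))
        self.classes_ = list(self._forest.classes_)

    def predict(self, sequence: str) -> tuple[str, float, bool]:
        """(ketide monomer, probability, fallback_flag) for an AT sequence.

        Unalignable sequences fall back to the malonyl-derived default unit
        with a flag set.
        """
        if self._forest is None:
            raise ConfigurationError("AT specificity forest is not trained")
        try:
            sig = self.signature(sequence)
        except UnalignableSequenceError:
            return "malonyl", 0.0, True
        probs = self._forest.predict_proba([self.encode(sig)])[0]
        best = int(np.argmax(probs))
        return str(self._forest.classes_[best]), float(probs[best]), False


def at_signature(sequence: str, at_model: AtSpecificityModel) -> str:
    return at_model.signature(sequence)


def at_specificity(sequence: str, at_model: AtSpecificityModel) -> tuple[str, float, bool]:
    return at_model.predict(sequence)


def annotate_atdomains(
    region: BGCRegion, at_model: AtSpecificityModel
) -> dict[str, list[tuple[str, float]]]:
    """Top-1 ketide prediction per AT-domain (single best monomer)."""
    out: dict[str, list[tuple[str, float]]] = {}
    for gene in region.genes:
        for j, hit in enumerate(gene.domains):
            if hit.domain_class != "AT":
                continue
            monomer, prob, _flag = at_model.predict(hit.sequence)
            out[f"{gene.id}:AT{j}"] = [(monomer, prob)]
    return out


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def regions_to_gff3(regions: Sequence[BGCRegion], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, r in enumerate(regions):
        rid = f"bgc{i + 1}"
        lines.append(
            "\t".join(
                [r.contig, "hybridforge", "biosynthetic_gene_cluster",
                 str(r.start + 1), str(r.end), ".", ".", ".", f"ID={rid}"]
            )
        )
        for g in r.genes:
            strand = "+" if g.strand == 1 else "-"
            lines.append(
                "\t".join(
                    [r.contig, "hybridforge", "gene", str(g.start + 1), str(g.end),
                     ".", strand, ".",
                     f"ID={g.id};Parent={rid};architecture={'-'.join(g.architecture)}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def regions_to_json(regions: Sequence[BGCRegion], path: str | Path) -> None:
    obj = []
    for r in regions:
        obj.append(
            {
                "contig": r.contig, "start": r.start, "end": r.end,
                "genes": [
                    {
                        "id": g.id, "strand": g.strand, "start": g.start,
                        "end": g.end, "architecture": g.architecture,
                    }
                    for g in r.genes
                ],
                "hits": [
                    {
                        "class": h.domain_class, "start": h.start, "end": h.end,
                        "strand": h.strand, "score": h.score, "evalue": h.evalue,
                    }
                    for h in r.hits
                ],
            }
        )
    Path(path).write_text(json.dumps(obj, indent=1))
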