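"""Synthetic data generators: planted A-domain datasets and toy BGC genomes.

These emulate the statistical structure the specificity model assumes —
binding-pocket residues determine substrate choice — and the layout of
hybrid NRPS/PKS gene clusters, so every pipeline stage is testable without
external databases.  Generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pyhmmer

from .adomain import AA_ALPHABET, ReferenceAlignment, featurize_record
from .assembly import Modification, STANDARD_MONOMERS
from .chem import SubstrateLibrary, SubstrateRecord
from .errors import ConfigurationError
from .mining import AT_SIGNATURE_LENGTH, AtSpecificityModel, DomainHit, Gene

# ---------------------------------------------------------------------------
# planted A-domain datasets
# ---------------------------------------------------------------------------

#: default substrates for planted datasets (names match the monomer library)
DEFAULT_SUBSTRATES = [
    "glycine", "alanine", "serine", "proline",
    "phenylalanine", "valine", "leucine", "threonine",
    "cysteine", "tyrosine", "aspartate", "methionine",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Specification of a planted code -> substrate dataset.

    Each substrate gets an injective random 10-residue binding-pocket code;
    sequences are the reference scaffold with that code planted at the
    Stachelhaus positions and point mutations elsewhere.  Promiscuous
    sequences carry additional substrate labels; label noise swaps labels.
    """

    n_substrates: int = 8
    sequences_per_substrate: int = 40
    promiscuity: float = 0.0
    label_noise: float = 0.0
    mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promiscuity", "label_noise", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class AdomainDataset:
    """Planted dataset: (record id, sequence, substrate) pairs plus truth."""

    pairs: list[tuple[str, str, str]]
    library: SubstrateLibrary
    code_map: dict[str, str]
    spec: PlantedSpec

    def to_tsv(self, path: str | Path) -> None:
        lines = ["id\tsequence\tsubstrate"]
        lines += [f"{r}\t{s}\t{sub}" for r, s, sub in self.pairs]
        Path(path).write_text("\n".join(lines) + "\n")

    def featurized(
        self, ref: ReferenceAlignment, backend: str = "onehot"
    ) -> list[tuple[object, SubstrateRecord]]:
        """(AdomainRecord, SubstrateRecord) training pairs; featurization is
        cached per unique sequence id."""
        cache: dict[str, object] = {}
        out = []
        for rid, seq, sub in self.pairs:
            if rid not in cache:
                cache[rid] = featurize_record(rid, seq, ref, backend=backend)
            out.append((cache[rid], self.library[sub]))
        return out

    def eval_pairs(self, ref: ReferenceAlignment) -> list[tuple[str, str, str]]:
        """(record id, 8A signature, substrate) tuples for the evaluation
        protocols."""
        feats = self.featurized(ref)
        sigs = {rec.id: rec.signature8A for rec, _ in feats}
        return [(rid, sigs[rid], sub) for rid, _seq, sub in self.pairs]


def _sample_codes(
    rng: np.random.Generator, n: int, length: int = 10
) -> list[str]:
    codes: set[str] = set()
    alphabet = list(AA_ALPHABET)
    while len(codes) < n:
        codes.add("".join(rng.choice(alphabet, size=length)))
    return sorted(codes)  # deterministic order given the generated set


def make_adomain_dataset(
    spec: PlantedSpec,
    ref: ReferenceAlignment | None = None,
    substrates: Sequence[str] | None = None,
) -> AdomainDataset:
    """Generate a planted sequence -> substrate dataset (reproducible by seed)."""
    ref = ref or ReferenceAlignment.default()
    names = list(substrates or DEFAULT_SUBSTRATES)
    if spec.n_substrates > len(names):
        raise ConfigurationError(
            f"at most {len(names)} substrates available, got {spec.n_substrates}"
        )
    names = names[: spec.n_substrates]
    max_codes = len(AA_ALPHABET) ** 10
    if spec.n_substrates > max_codes:  # pragma: no cover - astronomically large
        raise ConfigurationError("more substrates than available injective codes")
    rng = np.random.default_rng(spec.seed)
    codes = _sample_codes(rng, spec.n_substrates)
    code_map = dict(zip(names, codes))

    library = SubstrateLibrary()
    for name in names:
        library.add_smiles(name, STANDARD_MONOMERS[name].smiles)

    scaffold = list(ref.reference_sequence)
    code_positions = set(ref.stachelhaus_positions)
    alphabet = list(AA_ALPHABET)
    pairs: list[tuple[str, str, str]] = []
    counter = 0
    for name in names:
        code = code_map[name]
        for _ in range(spec.sequences_per_substrate):
            seq = scaffold.copy()
            for pos, ch in zip(ref.stachelhaus_positions, code):
                seq[pos] = ch
            for pos in range(len(seq)):
                if pos not in code_positions and rng.random() < spec.mutation_rate:
                    seq[pos] = alphabet[int(rng.integers(len(alphabet)))]
            rid = f"ad{counter:05d}"
            counter += 1
            label = name
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                others = [n for n in names if n != name]
                label = others[int(rng.integers(len(others)))]
            seq_str = "".join(seq)
            pairs.append((rid, seq_str, label))
            if spec.promiscuity > 0 and rng.random() < spec.promiscuity:
                others = [n for n in names if n != label]
                extra = others[int(rng.integers(len(others)))]
                pairs.append((rid, seq_str, extra))
    return AdomainDataset(pairs=pairs, library=library, code_map=code_map, spec=spec)


# ---------------------------------------------------------------------------
# domain consensus sequences and fixture profile HMMs
# ---------------------------------------------------------------------------

_CONSENSUS_SEED = 777_001
_CONSENSUS_LENGTH = 60

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

#: fixed match columns of the fixture AT profile carrying the specificity code
AT_SIGNATURE_COLUMNS = tuple(range(10, 10 + AT_SIGNATURE_LENGTH))


def domain_consensus(domain_class: str, ref: ReferenceAlignment | None = None) -> str:
    """Deterministic consensus protein per domain class.

    The A-domain consensus is the full reference scaffold (so extraction of
    binding-pocket codes works on mined hits); all other classes get a random
    60-residue sequence seeded by the class name.
    """
    if domain_class == "A":
        ref = ref or ReferenceAlignment.default()
        return ref.reference_sequence
    rng = np.random.default_rng(_CONSENSUS_SEED + sum(map(ord, domain_class)))
    return "".join(rng.choice(list(AA_ALPHABET), size=_CONSENSUS_LENGTH))


def _variants(
    consensus: str, n: int, rate: float, rng: np.random.Generator
) -> list[str]:
    alphabet = list(AA_ALPHABET)
    out = [consensus]
    for _ in range(n - 1):
        seq = list(consensus)
        for i in range(len(seq)):
            if rng.random() < rate:
                seq[i] = alphabet[int(rng.integers(len(alphabet)))]
        out.append("".join(seq))
    return out


def build_fixture_hmms(
    classes: Sequence[str],
    ref: ReferenceAlignment | None = None,
    n_variants: int = 10,
    mutation_rate: float = 0.04,
    seed: int = 0,
) -> list[pyhmmer.plan7.HMM]:
    """Profile HMMs built from synthetic variant alignments, one per class."""
    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    rng = np.random.default_rng(seed)
    hmms = []
    for cls in classes:
        consensus = domain_consensus(cls, ref)
        seqs = [
            pyhmmer.easel.TextSequence(name=f"{cls}_{i}".encode(), sequence=v)
            for i, v in enumerate(_variants(consensus, n_variants, mutation_rate, rng))
        ]
        msa = pyhmmer.easel.TextMSA(name=cls.encode(), sequences=seqs)
        hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
        hmms.append(hmm)
    return hmms


def write_hmms(hmms: Sequence[pyhmmer.plan7.HMM], path: str | Path) -> None:
    with open(path, "wb") as fh:
        for hmm in hmms:
            hmm.write(fh, binary=False)


def make_at_model(
    monomer_signatures: dict[str, str] | None = None, seed: int = 0
) -> AtSpecificityModel:
    """Fixture AT-specificity model: profile over the AT consensus plus a
    random forest on planted 24-residue signatures."""
    rng = np.random.default_rng(seed + 11)
    if monomer_signatures is None:
        monomer_signatures = {
            "malonyl": "".join(rng.choice(list(AA_ALPHABET), size=AT_SIGNATURE_LENGTH)),
            "methylmalonyl": "".join(
                rng.choice(list(AA_ALPHABET), size=AT_SIGNATURE_LENGTH)
            ),
        }
    hmm = build_fixture_hmms(["AT"], seed=seed)[0]
    model = AtSpecificityModel(hmm, AT_SIGNATURE_COLUMNS, seed=seed)
    sigs, labels = [], []
    for monomer, sig in sorted(monomer_signatures.items()):
        for variant in _variants(sig, 6, 0.05, rng):
            sigs.append(variant)
            labels.append(monomer)
    model.fit(sigs, labels)
    model.monomer_signatures = dict(monomer_signatures)  # type: ignore[attr-defined]
    return model


def at_sequence_for(monomer: str, at_model: AtSpecificityModel) -> str:
    """AT-domain protein carrying the planted signature of ``monomer``."""
    seq = list(domain_consensus("AT"))
    sig = at_model.monomer_signatures[monomer]  # type: ignore[attr-defined]
    for col, ch in zip(at_model.signature_columns, sig):
        seq[col] = ch
    return "".join(seq)


# ---------------------------------------------------------------------------
# toy BGC genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainSpec:
    """One domain in a gene blueprint; A/AT domains carry their monomer."""

    cls: str
    monomer: str | None = None


@dataclass(frozen=True)
class GeneBlueprint:
    domains: tuple[DomainSpec, ...]
    strand: int = 1


@dataclass(frozen=True)
class ToyBgcSpec:
    """Blueprint of a toy hybrid BGC genome."""

    genes: tuple[GeneBlueprint, ...]
    intergenic: int = 2500
    margin: int = 300
    contig_id: str = "toyctg"
    seed: int = 0

    def __post_init__(self) -> None:
        active = sum(
            1 for g in self.genes for d in g.domains if d.cls in ("A", "AT")
        )
        if active < 1:
            raise ValueError("blueprint needs at least one active domain")


def acceptance_bgc_spec(seed: int = 0) -> ToyBgcSpec:
    """Canonical 4-gene NRPS-PKS demo cluster: three single-module NRPS genes
    with COM-domain chaining and a terminal PKS gene with KR and TE."""
    return ToyBgcSpec(
        genes=(
            GeneBlueprint(domains=(
                DomainSpec("A", "valine"), DomainSpec("PCP"),
                DomainSpec("CCOM"),
            )),
            GeneBlueprint(domains=(
                DomainSpec("NCOM"), DomainSpec("C"),
                DomainSpec("A", "glycine"), DomainSpec("PCP"),
                DomainSpec("CCOM"),
            )),
            GeneBlueprint(domains=(
                DomainSpec("NCOM"), DomainSpec("C"),
                DomainSpec("A", "serine"), DomainSpec("PCP"),
                DomainSpec("CCOM"),
            )),
            GeneBlueprint(domains=(
                DomainSpec("NCOM"), DomainSpec("KS"),
                DomainSpec("AT", "malonyl"), DomainSpec("KR"),
                DomainSpec("ACP"), DomainSpec("TE"),
            )),
        ),
        seed=seed,
    )


@dataclass
class ToyGenome:
    """Generated genome with coordinate-level truth."""

    contig_id: str
    sequence: str
    genes: list[Gene]  # expected genes with architectures and coordinates
    a_substrates: dict[str, str]  # "<gene id>:A<j>" -> substrate name
    at_monomers: dict[str, str]
    classes: list[str]
    spec: ToyBgcSpec

    def write_fasta(self, path: str | Path) -> None:
        Path(path).write_text(f">{self.contig_id}\n{self.sequence}\n")


_LINKER = "GS" * 5


def make_toy_genome(
    spec: ToyBgcSpec,
    code_map: dict[str, str] | None = None,
    ref: ReferenceAlignment | None = None,
    at_model: AtSpecificityModel | None = None,
) -> ToyGenome:
    """Encode blueprint genes into a contig with known coordinates.

    A-domain sequences are the reference scaffold with the substrate's
    planted code (from ``code_map``); AT-domains carry the planted signature
    of their ketide monomer.  Intergenic spacers are random DNA.
    """
    ref = ref or ReferenceAlignment.default()
    rng = np.random.default_rng(spec.seed)
    a_substrates: dict[str, str] = {}
    at_monomers: dict[str, str] = {}
    classes = sorted({d.cls for g in spec.genes for d in g.domains})

    def random_dna(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    genome_parts: list[str] = [random_dna(spec.margin)]
    pos = spec.margin
    genes: list[Gene] = []
    for gi, gbp in enumerate(spec.genes):
        gene_id = f"{spec.contig_id}:g{gi + 1}"
        # protein with per-domain offsets
        protein_parts: list[str] = []
        domain_offsets: list[tuple[DomainSpec, int, int]] = []
        off = 0
        for di, dom in enumerate(gbp.domains):
            if di > 0:
                protein_parts.append(_LINKER)
                off += len(_LINKER)
            if dom.cls == "A":
                if code_map is None or dom.monomer not in code_map:
                    raise ConfigurationError(
                        f"A-domain in gene {gi + 1} needs a code_map entry for "
                        f"{dom.monomer!r}"
                    )
                seq = list(ref.reference_sequence)
                for p, ch in zip(ref.stachelhaus_positions, code_map[dom.monomer]):
                    seq[p] = ch
                dseq = "".join(seq)
            elif dom.cls == "AT":
                if at_model is None:
                    raise ConfigurationError("AT-domains need an at_model")
                dseq = at_sequence_for(dom.monomer or "malonyl", at_model)
            else:
                dseq = domain_consensus(dom.cls, ref)
            protein_parts.append(dseq)
            domain_offsets.append((dom, off, off + len(dseq)))
            off += len(dseq)
        protein = "".join(protein_parts)
        dna = "ATG" + "".join(_CODON[aa] for aa in protein) + "TAA"
        gene_start = pos
        gene_end = pos + len(dna)
        if gbp.strand == -1:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            dna = "".join(comp[c] for c in reversed(dna))
        genome_parts.append(dna)
        pos = gene_end
        genome_parts.append(random_dna(spec.intergenic))
        pos += spec.intergenic

        hits = []
        for j, (dom, p0, p1) in enumerate(domain_offsets):
            # +3 skips the start codon in genomic coordinates
            if gbp.strand == 1:
                g0 = gene_start + 3 + 3 * p0
                g1 = gene_start + 3 + 3 * p1
            else:
                g0 = gene_end - 3 - 3 * p1
                g1 = gene_end - 3 - 3 * p0
            seq_for_hit = protein[p0:p1]
            hits.append(
                DomainHit(
                    contig=spec.contig_id, strand=gbp.strand, frame=g0 % 3,
                    domain_class=dom.cls, prot_start=p0, prot_end=p1,
                    start=g0, end=g1, score=0.0, evalue=0.0,
                    sequence=seq_for_hit,
                )
            )
            if dom.cls == "A":
                a_substrates[f"{gene_id}:A{j}"] = dom.monomer or ""
            elif dom.cls == "AT":
                at_monomers[f"{gene_id}:AT{j}"] = dom.monomer or "malonyl"
        genes.append(
            Gene(
                id=gene_id, contig=spec.contig_id, strand=gbp.strand,
                start=min(h.start for h in hits), end=max(h.end for h in hits),
                domains=hits,  # already in translation (N- to C-terminal) order
            )
        )
    genome_parts.append(random_dna(spec.margin))
    return ToyGenome(
        contig_id=spec.contig_id,
        sequence="".join(genome_parts),
        genes=genes,
        a_substrates=a_substrates,
        at_monomers=at_monomers,
        classes=classes,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# fixture modification library
# ---------------------------------------------------------------------------

FIXTURE_MODIFICATIONS: list[Modification] = [
    Modification(
        name="aromatic-chlorination",
        motif="[cH1:1][cH1:2][c:3][OX2H1:4]",
        product="[c:1](Cl)[cH1:2][c:3][OX2H1:4]",
        enzymes=("HAL",),
    ),
    Modification(
        name="phenol-O-methylation",
        motif="[OX2H1:1][c:2]",
        product="[O:1](C)[c:2]",
        enzymes=("OMT",),
    ),
    Modification(
        name="amide-N-methylation",
        motif="[NX3;H1:1]([CX4:2])[CX3:3]=[OX1:4]",
        product="[N:1](C)([C:2])[C:3]=[O:4]",
        enzymes=("NMT",),
    ),
    Modification(
        name="beta-hydroxylation",
        motif="[CX4;H2:1][CX4;H1:2][CX3:3](=[OX1:4])[NX3:5]",
        product="[C:1](O)[C:2][C:3](=[O:4])[N:5]",
        enzymes=("P450",),
    ),
    Modification(
        name="side-chain-oxidation",
        motif="[CX4;H2:1][OX2H1:2]",
        product="[C:1]=[O:2]",
        enzymes=("P450", "OX"),
    ),
]


def write_fixture_modifications(path: str | Path) -> None:
    from .assembly import save_modifications

    save_modifications(FIXTURE_MODIFICATIONS, path)


def write_monomer_table(path: str | Path) -> None:
    """Write the built-in monomer library (standard + conditional) as TSV."""
    import pandas as pd

    from .assembly import CONDITIONAL_MONOMERS

    rows = []
    for m in list(STANDARD_MONOMERS.values()) + list(CONDITIONAL_MONOMERS.values()):
        rows.append(
            (m.name, m.smiles, m.kind,
             "" if m.head is None else m.head,
             "" if m.tail is None else m.tail,
             "+".join(m.required_enzymes))
        )
    pd.DataFrame(
        rows, columns=["name", "smiles", "kind", "head", "tail", "enzymes"]
    ).to_csv(path, sep="\t", index=False)
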