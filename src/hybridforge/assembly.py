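"""Core-molecule assembly and enzymatic modification of NRP-PK hybrids.

Monomer assignments for an assembly line are scored and enumerated by an
exact beam-merge dynamic program; the chosen monomers are condensed into a
core molecule (amide bonds for amino acids, ester bonds for hydroxy acids,
C-C bonds for ketide extender units, with the junction carbonyl becoming the
beta-keto group that ketoreductase/dehydratase/enoylreductase domains reduce
stepwise).  Post-assembly modifications are SMARTS-motif rewrites gated on
the presence of their enzymes in the BGC, matched by subgraph isomorphism
and applied combinatorially over all non-overlapping site subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import AssemblyError, ConfigurationError, InvalidMoleculeError

DEFAULT_TOP_S = 1000
DEFAULT_PRODUCT_CAP = 100_000

MonomerKind = str  # "amino" | "hydroxy" | "ketide"


@dataclass(frozen=True)
class Monomer:
    """A building block with defined attachment chemistry.

    ``head`` / ``tail`` are atom indices in the monomer SMILES: the head is
    the nucleophile that attacks the previous unit's carboxyl carbon (amine N,
    hydroxyl O, or ketide alpha-carbon) and the tail is the carboxyl carbon
    extended by the next unit.  When omitted they are detected by SMARTS.
    ``required_enzymes`` lists domain classes whose presence in the BGC gates
    this (pre-assembly modified) monomer; standard monomers have none.
    """

    name: str
    smiles: str
    kind: MonomerKind
    head: int | None = None
    tail: int | None = None
    required_enzymes: tuple[str, ...] = ()

    def attachment_atoms(self) -> tuple[int, int]:
        if self.head is not None and self.tail is not None:
            return self.head, self.tail
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise InvalidMoleculeError(f"bad monomer SMILES for {self.name!r}")
        patterns = {
            "amino": "[NX3;H2,H1][CX4][CX3](=O)[OX2H1]",
            "hydroxy": "[OX2H1][CX4][CX3](=O)[OX2H1]",
            "ketide": "[CX4][CX3](=O)[OX2H1]",
        }
        patt = Chem.MolFromSmarts(patterns[self.kind])
        matches = mol.GetSubstructMatches(patt)
        if not matches:
            raise AssemblyError(
                f"monomer {self.name!r} has no attachment atoms for kind {self.kind!r}"
            )
        m = matches[0]
        if self.kind == "ketide":
            return m[0], m[1]
        return m[0], m[2]


#: standard monomers always available to the assembler
STANDARD_MONOMERS: dict[str, Monomer] = {
    m.name: m
    for m in [
        Monomer("glycine", "NCC(O)=O", "amino"),
        Monomer("alanine", "NC(C)C(O)=O", "amino"),
        Monomer("serine", "NC(CO)C(O)=O", "amino"),
        Monomer("cysteine", "NC(CS)C(O)=O", "amino"),
        Monomer("threonine", "NC(C(C)O)C(O)=O", "amino"),
        Monomer("valine", "NC(C(C)C)C(O)=O", "amino"),
        Monomer("leucine", "NC(CC(C)C)C(O)=O", "amino"),
        Monomer("isoleucine", "NC(C(C)CC)C(O)=O", "amino"),
        Monomer("proline", "OC(=O)C1CCCN1", "amino"),
        Monomer("phenylalanine", "NC(Cc1ccccc1)C(O)=O", "amino"),
        Monomer("tyrosine", "NC(Cc1ccc(O)cc1)C(O)=O", "amino"),
        Monomer("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(O)=O", "amino"),
        Monomer("aspartate", "NC(CC(O)=O)C(O)=O", "amino"),
        Monomer("glutamate", "NC(CCC(O)=O)C(O)=O", "amino"),
        Monomer("asparagine", "NC(CC(N)=O)C(O)=O", "amino"),
        Monomer("glutamine", "NC(CCC(N)=O)C(O)=O", "amino"),
        Monomer("lysine", "NCCCCC(N)C(O)=O", "amino", head=6, tail=7),
        Monomer("histidine", "NC(Cc1c[nH]cn1)C(O)=O", "amino"),
        Monomer("methionine", "NC(CCSC)C(O)=O", "amino"),
        Monomer("lactate", "CC(O)C(O)=O", "hydroxy", head=2, tail=3),
        Monomer("glycolate", "OCC(O)=O", "hydroxy", head=0, tail=2),
        Monomer("malonyl", "CC(O)=O", "ketide", head=0, tail=1),
        Monomer("methylmalonyl", "CCC(O)=O", "ketide", head=1, tail=2),
    ]
}

#: example monomers requiring pre-assembly modification enzymes in the BGC
CONDITIONAL_MONOMERS: dict[str, Monomer] = {
    m.name: m
    for m in [
        Monomer(
            "beta-hydroxytyrosine", "NC(C(O)c1ccc(O)cc1)C(O)=O", "amino",
            required_enzymes=("P450",),
        ),
        Monomer(
            "n-methylglycine", "CNCC(O)=O", "amino", head=1, tail=3,
            required_enzymes=("MT",),
        ),
        Monomer(
            "chloro-tyrosine", "NC(Cc1cc(Cl)c(O)cc1)C(O)=O", "amino",
            required_enzymes=("HAL", "P450"),
        ),
    ]
}


def gate_preassembly(
    bgc_domain_classes: set[str],
    monomer_library: Iterable[Monomer] | None = None,
) -> list[Monomer]:
    """Monomers usable in this BGC: standard ones always, conditional ones
    only when every required enzyme class has a hit in the BGC."""
    if monomer_library is None:
        monomer_library = list(STANDARD_MONOMERS.values()) + list(
            CONDITIONAL_MONOMERS.values()
        )
    out = []
    for m in monomer_library:
        if all(enz in bgc_domain_classes for enz in m.required_enzymes):
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# monomer assignment dynamic program
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonomerAssignment:
    """One monomer per active domain, with the summed score."""

    monomers: tuple[str, ...]
    score: float


def top_assignments(
    predictions: Sequence[Sequence[tuple[str, float]]],
    s: int = DEFAULT_TOP_S,
) -> list[MonomerAssignment]:
    """Exact top-s monomer assignments by total score.

    ``predictions[d]`` is the ranked (monomer, score) list for active domain
    d.  A beam-merge dynamic program keeps the s best partial assignments per
    step, which is exact for the final top-s; ties break lexicographically by
    the monomer name tuple.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if any(len(p) == 0 for p in predictions):
        raise ConfigurationError("every active domain needs at least one prediction")
    partial: list[tuple[float, tuple[str, ...]]] = [(0.0, ())]
    for preds in predictions:
        nxt = [
            (score + ps, names + (name,))
            for ps, names in partial
            for name, score in preds
        ]
        nxt.sort(key=lambda t: (-t[0], t[1]))
        partial = nxt[:s]
    return [MonomerAssignment(monomers=n, score=sc) for sc, n in partial]


# ---------------------------------------------------------------------------
# core assembly
# ---------------------------------------------------------------------------

PROP_MONOMER = "monomer_idx"
PROP_HEAD = "head_of"
PROP_TAIL = "tail_of"
PROP_JUNCTION = "junction_before"


@dataclass
class CoreMolecule:
    """Assembled core with per-atom monomer provenance."""

    mol: Chem.Mol
    monomers: tuple[str, ...]
    cyclic: bool = False

    @property
    def smiles(self) -> str:
        m = Chem.Mol(self.mol)
        Chem.RemoveStereochemistry(m)
        return Chem.MolToSmiles(m)

    def provenance(self) -> dict[int, int]:
        return {
            a.GetIdx(): a.GetIntProp(PROP_MONOMER)
            for a in self.mol.GetAtoms()
            if a.HasProp(PROP_MONOMER)
        }

    def _atom_with(self, prop: str, value: int) -> int | None:
        for a in self.mol.GetAtoms():
            if a.HasProp(prop) and a.GetIntProp(prop) == value:
                return a.GetIdx()
        return None


def _combine(mols: Sequence[Chem.Mol]) -> Chem.RWMol:
    combined = Chem.RWMol()
    for mol in mols:
        amap = {}
        for atom in mol.GetAtoms():
            na = Chem.Atom(atom.GetAtomicNum())
            na.SetFormalCharge(atom.GetFormalCharge())
            idx = combined.AddAtom(na)
            for prop in (PROP_MONOMER, PROP_HEAD, PROP_TAIL, PROP_JUNCTION):
                if atom.HasProp(prop):
                    combined.GetAtomWithIdx(idx).SetIntProp(
                        prop, atom.GetIntProp(prop)
                    )
            amap[atom.GetIdx()] = idx
        for bond in mol.GetBonds():
            combined.AddBond(
                amap[bond.GetBeginAtomIdx()],
                amap[bond.GetEndAtomIdx()],
                bond.GetBondType(),
            )
    return combined


def _hydroxyl_oxygen(mol: Chem.Mol, carboxyl_c: int) -> int:
    atom = mol.GetAtomWithIdx(carboxyl_c)
    for nbr in atom.GetNeighbors():
        bond = mol.GetBondBetweenAtoms(carboxyl_c, nbr.GetIdx())
        # degree-1 singly-bonded oxygen = the free hydroxyl (the carbonyl O is
        # double-bonded); GetTotalNumHs is unavailable mid-edit
        if (
            nbr.GetAtomicNum() == 8
            and bond.GetBondType() == Chem.BondType.SINGLE
            and nbr.GetDegree() == 1
            and nbr.GetFormalCharge() == 0
        ):
            return nbr.GetIdx()
    raise AssemblyError("carboxyl carbon has no free hydroxyl to condense")


def assemble_core(
    monomers: Sequence[Monomer],
    cyclize: bool = False,
) -> CoreMolecule:
    """Condense monomers head-to-tail into a core molecule.

    Each junction removes the hydroxyl of the previous unit's carboxyl group
    and bonds the carboxyl carbon to the next unit's head atom (N, O or C
    depending on monomer kind); with ``cyclize`` the last carboxyl also bonds
    to the first unit's head, yielding the head-to-tail macrocycle.
    """
    if not monomers:
        raise AssemblyError("no monomers to assemble")
    frags: list[Chem.Mol] = []
    for mi, m in enumerate(monomers):
        mol = Chem.MolFromSmiles(m.smiles)
        if mol is None:
            raise AssemblyError(f"monomer {m.name!r} has invalid SMILES")
        Chem.RemoveStereochemistry(mol)
        head, tail = m.attachment_atoms()
        for atom in mol.GetAtoms():
            atom.SetIntProp(PROP_MONOMER, mi)
        mol.GetAtomWithIdx(head).SetIntProp(PROP_HEAD, mi)
        mol.GetAtomWithIdx(tail).SetIntProp(PROP_TAIL, mi)
        frags.append(mol)
    rw = _combine(frags)

    def find(prop: str, value: int) -> int:
        for a in rw.GetAtoms():
            if a.HasProp(prop) and a.GetIntProp(prop) == value:
                return a.GetIdx()
        raise AssemblyError(f"missing {prop}={value}")

    rw.BeginBatchEdit()
    n = len(monomers)
    pairs = [(i - 1, i) for i in range(1, n)]
    if cyclize:
        pairs.append((n - 1, 0))
    for prev_i, cur_i in pairs:
        tail_c = find(PROP_TAIL, prev_i)
        head_a = find(PROP_HEAD, cur_i)
        oh = _hydroxyl_oxygen(rw, tail_c)
        rw.RemoveAtom(oh)
        rw.AddBond(tail_c, head_a, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(tail_c).SetIntProp(PROP_JUNCTION, cur_i)
    rw.CommitBatchEdit()
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise AssemblyError(f"assembled core failed sanitization: {exc}") from exc
    return CoreMolecule(
        mol=mol, monomers=tuple(m.name for m in monomers), cyclic=cyclize
    )


# ---------------------------------------------------------------------------
# module tailoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleContext:
    """Tailoring domains attached to one module (one active domain)."""

    monomer_index: int
    domain_classes: tuple[str, ...] = ()
    n_terminal: bool = False


def _side_chain_heteroatom(mol: Chem.Mol, mi: int, head: int) -> int | None:
    """Side-chain O or S of monomer mi usable for heterocyclization (on the
    beta carbon next to the residue's alpha carbon)."""
    for alpha in mol.GetAtomWithIdx(head).GetNeighbors():
        if alpha.GetAtomicNum() != 6:
            continue
        if not (alpha.HasProp(PROP_MONOMER) and alpha.GetIntProp(PROP_MONOMER) == mi):
            continue
        for beta in alpha.GetNeighbors():
            if beta.GetIdx() == head or beta.HasProp(PROP_TAIL):
                continue
            for x in beta.GetNeighbors():
                if (
                    x.GetAtomicNum() in (8, 16)
                    and x.GetTotalNumHs() >= 1
                    and x.GetDegree() == 1
                ):
                    return x.GetIdx()
    return None


def apply_module_tailoring(
    core: CoreMolecule, contexts: Sequence[ModuleContext]
) -> CoreMolecule:
    """Apply domain-triggered edits at each module's monomer.

    F on the N-terminal module formylates the head amine; a methylation
    domain after an A-domain N-methylates the residue (after an AT-domain it
    C-methylates the ketide alpha-carbon); a heterocyclization domain on a
    Ser/Thr/Cys-loading module forms the oxazoline/thiazoline ring at the
    preceding junction; KR reduces the junction beta-keto group to a
    hydroxyl, KR+DH to an alkene, and KR+DH+ER to a methylene.  Edits without
    an applicable site are skipped with a warning.
    """
    rw = Chem.RWMol(core.mol)
    to_remove: list[int] = []  # atom deletions deferred so indices stay valid

    def atom_with(prop: str, value: int) -> int | None:
        for a in rw.GetAtoms():
            if a.HasProp(prop) and a.GetIntProp(prop) == value:
                return a.GetIdx()
        return None

    def add_methyl(idx: int) -> None:
        c = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(idx, c, Chem.BondType.SINGLE)

    def junction_keto(mi: int) -> tuple[int, int] | None:
        jc = atom_with(PROP_JUNCTION, mi)
        if jc is None:
            return None
        for nbr in rw.GetAtomWithIdx(jc).GetNeighbors():
            bond = rw.GetBondBetweenAtoms(jc, nbr.GetIdx())
            if nbr.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
                return jc, nbr.GetIdx()
        return None

    for ctx in contexts:
        mi = ctx.monomer_index
        classes = set(ctx.domain_classes)
        head = atom_with(PROP_HEAD, mi)
        if head is None:
            warnings.warn(f"module {mi}: monomer head not found; tailoring skipped")
            continue
        head_atom = rw.GetAtomWithIdx(head)
        if "F" in classes and ctx.n_terminal:
            if head_atom.GetAtomicNum() == 7 and head_atom.GetTotalNumHs() >= 1:
                c = rw.AddAtom(Chem.Atom(6))
                o = rw.AddAtom(Chem.Atom(8))
                rw.AddBond(head, c, Chem.BondType.SINGLE)
                rw.AddBond(c, o, Chem.BondType.DOUBLE)
            else:
                warnings.warn(f"module {mi}: no free amine to formylate")
        if "MT" in classes:
            if head_atom.GetAtomicNum() == 7 and head_atom.GetTotalNumHs() >= 1:
                add_methyl(head)  # N-methylation after an A-domain
            elif head_atom.GetAtomicNum() == 6:
                add_methyl(head)  # C-methylation of the ketide alpha-carbon
            else:
                warnings.warn(f"module {mi}: no methylation site")
        if "CY" in classes:
            x = _side_chain_heteroatom(rw, mi, head)
            keto = junction_keto(mi)
            if x is None or keto is None:
                warnings.warn(f"module {mi}: heterocyclization not applicable")
            else:
                jc, oxo = keto
                to_remove.append(oxo)
                rw.GetBondBetweenAtoms(jc, head).SetBondType(Chem.BondType.DOUBLE)
                rw.AddBond(jc, x, Chem.BondType.SINGLE)
                # further ring oxidation/reduction states collapse to the base
                # heterocycle here; see the methods note
        reductions = classes & {"KR", "DH", "ER"}
        if reductions:
            # only a ketide junction (C-C bond into the carbonyl, i.e. a
            # ketone) is reducible; amide/ester junction carbonyls are not
            keto = junction_keto(mi) if head_atom.GetAtomicNum() == 6 else None
            if keto is None:
                warnings.warn(f"module {mi}: no beta-keto group to reduce")
            else:
                jc, oxo = keto
                if reductions == {"KR"}:
                    rw.GetBondBetweenAtoms(jc, oxo).SetBondType(Chem.BondType.SINGLE)
                elif reductions == {"KR", "DH"}:
                    to_remove.append(oxo)
                    rw.GetBondBetweenAtoms(jc, head).SetBondType(Chem.BondType.DOUBLE)
                elif reductions == {"KR", "DH", "ER"}:
                    to_remove.append(oxo)
                else:
                    warnings.warn(
                        f"module {mi}: incomplete reduction set {sorted(reductions)}"
                    )
    for idx in sorted(set(to_remove), reverse=True):
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return CoreMolecule(mol=mol, monomers=core.monomers, cyclic=core.cyclic)


# ---------------------------------------------------------------------------
# post-assembly modifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Modification:
    """A tailoring reaction: SMARTS motif, product template and enzyme gate.

    The rewrite applied is ``motif >> product`` so the motif is by
    construction the left side of the transformation.  ``constitutive``
    modifications need no enzyme evidence.
    """

    name: str
    motif: str
    product: str
    enzymes: tuple[str, ...] = ()
    constitutive: bool = False

    def __post_init__(self) -> None:
        if Chem.MolFromSmarts(self.motif) is None:
            raise ConfigurationError(f"modification {self.name!r}: bad motif SMARTS")
        if not self.enzymes and not self.constitutive:
            raise ConfigurationError(
                f"modification {self.name!r}: enzyme list empty and not constitutive"
            )

    @property
    def reaction_smarts(self) -> str:
        return f"{self.motif}>>{self.product}"


def load_modifications(path: str | Path) -> list[Modification]:
    """TSV columns: name, motif, product, enzymes ('+'-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t").fillna("")
    mods = []
    for row in df.itertuples(index=False):
        enzymes = tuple(e for e in str(row.enzymes).split("+") if e)
        mods.append(
            Modification(
                name=str(row.name), motif=str(row.motif), product=str(row.product),
                enzymes=enzymes, constitutive=not enzymes,
            )
        )
    return mods


def save_modifications(mods: Sequence[Modification], path: str | Path) -> None:
    pd.DataFrame(
        [(m.name, m.motif, m.product, "+".join(m.enzymes)) for m in mods],
        columns=["name", "motif", "product", "enzymes"],
    ).to_csv(path, sep="\t", index=False)


def match_modification(
    core: CoreMolecule | Chem.Mol, mod: Modification
) -> list[tuple[int, ...]]:
    """All embeddings of the motif into the core, deduplicated by atom set."""
    mol = core.mol if isinstance(core, CoreMolecule) else core
    patt = Chem.MolFromSmarts(mod.motif)
    seen: set[frozenset[int]] = set()
    out: list[tuple[int, ...]] = []
    for match in mol.GetSubstructMatches(patt, uniquify=False, maxMatches=100_000):
        key = frozenset(match)
        if key not in seen:
            seen.add(key)
            out.append(match)
    return out


@dataclass(frozen=True)
class MatureProduct:
    """A core molecule after a set of non-overlapping modifications."""

    smiles: str
    core_smiles: str
    modifications: tuple[tuple[str, tuple[int, ...]], ...]
    line_id: str = ""
    assignment_id: str = ""


def _apply_at_site(
    mol: Chem.Mol,
    mod: Modification,
    site: frozenset[int],
    orig_map: list[int | None],
) -> tuple[Chem.Mol, list[int | None]] | None:
    """Apply one modification at the site given in original-core atom indices.

    ``orig_map[i]`` is the original-core index of current atom i (None for
    atoms introduced by earlier modifications).  Returns the product and its
    updated map, or None when the reaction fails or produces bad valences.
    """
    rxn = AllChem.ReactionFromSmarts(mod.reaction_smarts)
    template = rxn.GetReactantTemplate(0)
    matches = mol.GetSubstructMatches(template, uniquify=False, maxMatches=100_000)
    products = rxn.RunReactants((mol,), maxProducts=max(len(matches), 1) * 4)
    for match, prods in zip(matches, products):
        match_orig = frozenset(
            orig_map[a] for a in match if orig_map[a] is not None
        )
        if match_orig != site:
            continue
        prod = prods[0]
        new_map: list[int | None] = []
        for atom in prod.GetAtoms():
            if atom.HasProp("react_atom_idx"):
                new_map.append(orig_map[atom.GetIntProp("react_atom_idx")])
            else:
                new_map.append(None)
        try:
            Chem.SanitizeMol(prod)
        except Exception:
            warnings.warn(
                f"modification {mod.name!r} at site {sorted(site)} produced an "
                "invalid molecule; product dropped"
            )
            return None
        return prod, new_map
    return None


def apply_postassembly(
    core: CoreMolecule,
    mods: Sequence[Modification],
    bgc_domain_classes: set[str],
    cap: int = DEFAULT_PRODUCT_CAP,
    line_id: str = "",
    assignment_id: str = "",
) -> tuple[list[MatureProduct], bool]:
    """Combinatorially apply non-overlapping enzyme-gated modifications.

    Candidate (modification, site) pairs come from subgraph matching of each
    gated motif; every subset of pairwise non-overlapping pairs (sharing no
    atoms) yields one product, including the empty subset (the unmodified
    core).  Products are deduplicated by canonical SMILES; the result is
    truncated at ``cap`` with a flag.
    """
    gated = [
        m
        for m in mods
        if m.constitutive or all(e in bgc_domain_classes for e in m.enzymes)
    ]
    pairs: list[tuple[Modification, frozenset[int]]] = []
    for mod in sorted(gated, key=lambda m: m.name):
        for match in match_modification(core, mod):
            pairs.append((mod, frozenset(match)))

    core_smiles = core.smiles
    products: dict[str, MatureProduct] = {}
    truncated = False

    def record(smiles: str, applied: tuple[tuple[str, tuple[int, ...]], ...]) -> None:
        if smiles not in products:
            products[smiles] = MatureProduct(
                smiles=smiles, core_smiles=core_smiles, modifications=applied,
                line_id=line_id, assignment_id=assignment_id,
            )

    record(core_smiles, ())

    # enumerate subsets of pairwise non-overlapping pairs
    n = len(pairs)
    for size in range(1, n + 1):
        if truncated:
            break
        for combo in combinations(range(n), size):
            sites = [pairs[i][1] for i in combo]
            if any(
                sites[a] & sites[b]
                for a in range(len(sites))
                for b in range(a + 1, len(sites))
            ):
                continue
            mol = Chem.Mol(core.mol)
            orig_map: list[int | None] = list(range(mol.GetNumAtoms()))
            ok = True
            applied = []
            for i in combo:
                mod, site = pairs[i]
                result = _apply_at_site(mol, mod, site, orig_map)
                if result is None:
                    ok = False
                    break
                mol, orig_map = result
                applied.append((mod.name, tuple(sorted(site))))
            if not ok:
                continue
            m2 = Chem.Mol(mol)
            Chem.RemoveStereochemistry(m2)
            record(Chem.MolToSmiles(m2), tuple(applied))
            if len(products) >= cap:
                truncated = True
                break
    ordered = sorted(products.values(), key=lambda p: (len(p.modifications), p.smiles))
    return ordered, truncated


def products_to_tsv(products: Sequence[MatureProduct], path: str | Path) -> None:
    rows = [
        (
            f"p{i + 1}", p.smiles, p.line_id, p.assignment_id,
            ";".join(f"{name}@{','.join(map(str, site))}" for name, site in p.modifications),
        )
        for i, p in enumerate(products)
    ]
    pd.DataFrame(
        rows, columns=["product_id", "smiles", "line_id", "assignment_id", "modifications"]
    ).to_csv(path, sep="\t", index=False)


def products_to_sdf(products: Sequence[MatureProduct], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for i, p in enumerate(products):
            mol = Chem.MolFromSmiles(p.smiles)
            if mol is None:
                continue
            mol.SetProp("_Name", f"p{i + 1}")
            mol.SetProp("line_id", p.line_id)
            writer.write(mol)
    finally:
        writer.close()
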