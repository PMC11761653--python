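"""Monomer assignment, core assembly, tailoring and modifications."""

from itertools import product as iproduct

import networkx as nx
import pytest
from rdkit import Chem

from hybridforge.assembly import (
    CONDITIONAL_MONOMERS,
    STANDARD_MONOMERS,
    Modification,
    ModuleContext,
    apply_module_tailoring,
    apply_postassembly,
    assemble_core,
    gate_preassembly,
    load_modifications,
    match_modification,
    products_to_sdf,
    products_to_tsv,
    save_modifications,
    top_assignments,
)
from hybridforge.errors import AssemblyError, ConfigurationError


def canon(smiles: str) -> str:
    return Chem.CanonSmiles(smiles)


M = STANDARD_MONOMERS


# ---------------------------------------------------------------------------
# monomers and the assignment DP
# ---------------------------------------------------------------------------


def test_attachment_atom_detection():
    head, tail = M["glycine"].attachment_atoms()
    mol = Chem.MolFromSmiles(M["glycine"].smiles)
    assert mol.GetAtomWithIdx(head).GetSymbol() == "N"
    assert mol.GetAtomWithIdx(tail).GetSymbol() == "C"
    # the tail is the carboxyl carbon: double-bonded O neighbor
    assert any(
        n.GetSymbol() == "O"
        and mol.GetBondBetweenAtoms(tail, n.GetIdx()).GetBondTypeAsDouble() == 2
        for n in mol.GetAtomWithIdx(tail).GetNeighbors()
    )


def test_all_builtin_monomers_have_valid_attachments():
    for m in list(M.values()) + list(CONDITIONAL_MONOMERS.values()):
        head, tail = m.attachment_atoms()
        mol = Chem.MolFromSmiles(m.smiles)
        assert 0 <= head < mol.GetNumAtoms()
        assert 0 <= tail < mol.GetNumAtoms()
        expected_head = {"amino": "N", "hydroxy": "O", "ketide": "C"}[m.kind]
        assert mol.GetAtomWithIdx(head).GetSymbol() == expected_head


def test_gate_preassembly():
    names = {m.name for m in gate_preassembly(set())}
    assert set(M) <= names
    assert "beta-hydroxytyrosine" not in names
    names2 = {m.name for m in gate_preassembly({"P450"})}
    assert "beta-hydroxytyrosine" in names2
    assert "chloro-tyrosine" not in names2  # needs HAL too
    names3 = {m.name for m in gate_preassembly({"P450", "HAL"})}
    assert "chloro-tyrosine" in names3


def test_top_assignments_matches_exhaustive_enumeration():
    preds = [
        [("a", 0.9), ("b", 0.5), ("c", 0.1)],
        [("d", 0.8), ("e", 0.7), ("f", 0.2)],
        [("g", 0.6), ("h", 0.4), ("i", 0.3)],
        [("j", 1.0), ("k", 0.05), ("l", 0.01)],
    ]
    s = 20
    got = top_assignments(preds, s=s)
    exhaustive = sorted(
        (
            (sum(sc for _, sc in combo), tuple(n for n, _ in combo))
            for combo in iproduct(*preds)
        ),
        key=lambda t: (-t[0], t[1]),
    )[:s]
    assert [(a.score, a.monomers) for a in got] == pytest.approx(exhaustive)


def test_top_assignments_validation():
    with pytest.raises(ValueError):
        top_assignments([[("a", 1.0)]], s=0)
    with pytest.raises(ConfigurationError):
        top_assignments([[("a", 1.0)], []])


# ---------------------------------------------------------------------------
# core assembly (frozen SMILES oracles)
# ---------------------------------------------------------------------------


def test_dipeptide_amide_bond():
    core = assemble_core([M["glycine"], M["alanine"]])
    assert core.smiles == canon("NCC(=O)NC(C)C(=O)O")
    assert core.monomers == ("glycine", "alanine")
    assert not core.cyclic


def test_ester_bond_with_hydroxy_acid():
    core = assemble_core([M["alanine"], M["lactate"]])
    assert core.smiles == canon("CC(N)C(=O)OC(C)C(=O)O")


def test_ketide_extension_leaves_beta_keto():
    core = assemble_core([M["alanine"], M["malonyl"]])
    assert core.smiles == canon("CC(N)C(=O)CC(=O)O")
    core2 = assemble_core([M["alanine"], M["methylmalonyl"]])
    assert core2.smiles == canon("CC(N)C(=O)C(C)C(=O)O")


def test_proline_secondary_amine_junction():
    core = assemble_core([M["glycine"], M["proline"]])
    assert core.smiles == canon("NCC(=O)N1CCCC1C(=O)O")


def test_macrocyclization():
    core = assemble_core([M["glycine"], M["alanine"]], cyclize=True)
    assert core.smiles == canon("CC1NC(=O)CNC1=O")  # diketopiperazine
    assert core.cyclic


def test_provenance_covers_all_atoms():
    core = assemble_core([M["glycine"], M["alanine"], M["serine"]])
    prov = core.provenance()
    assert set(prov.keys()) == set(range(core.mol.GetNumAtoms()))
    assert set(prov.values()) == {0, 1, 2}


def test_assemble_core_requires_monomers():
    with pytest.raises(AssemblyError):
        assemble_core([])


# ---------------------------------------------------------------------------
# module tailoring
# ---------------------------------------------------------------------------


def _ctx(i, classes=(), first=False):
    return ModuleContext(monomer_index=i, domain_classes=tuple(classes), n_terminal=first)


def test_formylation_of_n_terminal_amine():
    core = assemble_core([M["glycine"], M["alanine"]])
    t = apply_module_tailoring(core, [_ctx(0, ["F"], True), _ctx(1)])
    assert t.smiles == canon("O=CNCC(=O)NC(C)C(=O)O")


def test_n_methylation_after_a_domain():
    core = assemble_core([M["glycine"], M["alanine"]])
    t = apply_module_tailoring(core, [_ctx(0), _ctx(1, ["MT"])])
    assert t.smiles == canon("NCC(=O)N(C)C(C)C(=O)O")


def test_c_methylation_of_ketide_alpha_carbon():
    core = assemble_core([M["alanine"], M["malonyl"]])
    t = apply_module_tailoring(core, [_ctx(0), _ctx(1, ["MT"])])
    assert t.smiles == canon("CC(N)C(=O)C(C)C(=O)O")


def test_heterocyclization_thiazoline_and_oxazoline():
    core = assemble_core([M["valine"], M["cysteine"]])
    t = apply_module_tailoring(core, [_ctx(0), _ctx(1, ["CY"])])
    assert t.smiles == canon("CC(C)C(N)C1=NC(C(=O)O)CS1")
    core2 = assemble_core([M["valine"], M["serine"]])
    t2 = apply_module_tailoring(core2, [_ctx(0), _ctx(1, ["CY"])])
    assert t2.smiles == canon("CC(C)C(N)C1=NC(C(=O)O)CO1")


def test_ketoreduction_series():
    units = [M["alanine"], M["malonyl"]]
    kr = apply_module_tailoring(assemble_core(units), [_ctx(0), _ctx(1, ["KR"])])
    assert kr.smiles == canon("CC(N)C(O)CC(=O)O")
    krdh = apply_module_tailoring(
        assemble_core(units), [_ctx(0), _ctx(1, ["KR", "DH"])]
    )
    assert krdh.smiles == canon("CC(N)C=CC(=O)O")
    full = apply_module_tailoring(
        assemble_core(units), [_ctx(0), _ctx(1, ["KR", "DH", "ER"])]
    )
    assert full.smiles == canon("CC(N)CCC(=O)O")


def test_amide_junction_is_never_reduced():
    core = assemble_core([M["glycine"], M["alanine"]])
    with pytest.warns(UserWarning, match="no beta-keto"):
        t = apply_module_tailoring(core, [_ctx(0), _ctx(1, ["KR"])])
    assert t.smiles == core.smiles


def test_tailoring_without_site_warns_and_skips():
    # formylation needs an amine head; lactate's head is a hydroxyl oxygen
    core = assemble_core([M["lactate"], M["alanine"]])
    with pytest.warns(UserWarning, match="no free amine"):
        t = apply_module_tailoring(core, [_ctx(0, ["F"], True), _ctx(1)])
    assert t.smiles == core.smiles
    # F on a non-terminal module is silently inapplicable
    core2 = assemble_core([M["glycine"], M["alanine"]])
    t2 = apply_module_tailoring(core2, [_ctx(0), _ctx(1, ["F"])])
    assert t2.smiles == core2.smiles


# ---------------------------------------------------------------------------
# post-assembly modifications
# ---------------------------------------------------------------------------

PHENOL_OME = Modification(
    name="phenol-O-methylation",
    motif="[OX2H1:1][c:2]",
    product="[O:1](C)[c:2]",
    enzymes=("OMT",),
)


def test_modification_validation():
    with pytest.raises(ConfigurationError):
        Modification(name="bad", motif="[[[", product="C", enzymes=("X",))
    with pytest.raises(ConfigurationError):
        Modification(name="nogate", motif="[OX2H1]", product="O")
    ok = Modification(name="const", motif="[OX2H1]", product="O", constitutive=True)
    assert ok.reaction_smarts == "[OX2H1]>>O"


def test_match_modification_counts_and_dedup():
    core = assemble_core([M["tyrosine"], M["tyrosine"]])
    sites = match_modification(core, PHENOL_OME)
    assert len(sites) == 2  # one phenol per tyrosine
    assert len({frozenset(s) for s in sites}) == 2


def test_match_modification_vs_networkx_monomorphism_oracle():
    # element-only motif with any-order bonds: amide N-C(=O) fragment
    mod = Modification(
        name="probe", motif="[#7]~[#6](~[#8])~[#6]", product="C",
        constitutive=True,
    )
    core = assemble_core([M["glycine"], M["alanine"], M["serine"]])
    mol = core.mol
    got = {frozenset(s) for s in match_modification(core, mod)}

    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), z=a.GetAtomicNum())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    patt = nx.Graph()
    for i, z in enumerate([7, 6, 8, 6]):
        patt.add_node(i, z=z)
    patt.add_edges_from([(0, 1), (1, 2), (1, 3)])
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g, patt, node_match=lambda a, b: a["z"] == b["z"]
    )
    expected = {
        frozenset(mapping) for mapping in gm.subgraph_monomorphisms_iter()
    }
    assert got == expected


def test_postassembly_combinatorics_two_independent_sites():
    core = assemble_core([M["tyrosine"], M["tyrosine"]])
    products, truncated = apply_postassembly(core, [PHENOL_OME], {"OMT"})
    # empty set + 2 singles + 1 pair = 4 products
    assert not truncated
    assert len(products) == 4
    n_mods = sorted(len(p.modifications) for p in products)
    assert n_mods == [0, 1, 1, 2]
    # each applied modification adds exactly one aryl methyl ether
    methoxy = Chem.MolFromSmarts("[CH3][OX2][c]")
    for p in products:
        assert p.core_smiles == core.smiles
        mol = Chem.MolFromSmiles(p.smiles)
        assert len(mol.GetSubstructMatches(methoxy)) == len(p.modifications)


def test_postassembly_enzyme_gating():
    core = assemble_core([M["tyrosine"], M["tyrosine"]])
    products, _ = apply_postassembly(core, [PHENOL_OME], set())
    assert len(products) == 1  # only the unmodified core
    const = Modification(
        name="c", motif="[OX2H1:1][c:2]", product="[O:1](C)[c:2]",
        constitutive=True,
    )
    products2, _ = apply_postassembly(core, [const], set())
    assert len(products2) == 4


def test_postassembly_cap_truncates():
    core = assemble_core([M["tyrosine"]] * 3)
    products, truncated = apply_postassembly(core, [PHENOL_OME], {"OMT"}, cap=3)
    assert truncated
    assert len(products) == 3


def test_postassembly_deduplicates_symmetric_products():
    # two identical sites on a symmetric substrate give identical single-site
    # products that must collapse
    mol = Chem.MolFromSmiles("Oc1ccc(O)cc1")  # hydroquinone, aromatic OH x2
    from hybridforge.assembly import CoreMolecule

    core = CoreMolecule(mol=mol, monomers=("x",))
    products, _ = apply_postassembly(core, [PHENOL_OME], {"OMT"})
    singles = [p for p in products if len(p.modifications) == 1]
    assert len(singles) == 1  # both sites give the same molecule


def test_modification_tsv_roundtrip(tmp_path):
    mods = [
        PHENOL_OME,
        Modification(name="c", motif="[OX2H1]", product="O", constitutive=True),
    ]
    path = tmp_path / "mods.tsv"
    save_modifications(mods, path)
    back = load_modifications(path)
    assert [(m.name, m.motif, m.product, m.enzymes, m.constitutive) for m in back] == [
        (m.name, m.motif, m.product, m.enzymes, m.constitutive) for m in mods
    ]


def test_product_exports(tmp_path):
    core = assemble_core([M["tyrosine"], M["alanine"]])
    products, _ = apply_postassembly(core, [PHENOL_OME], {"OMT"})
    tsv = tmp_path / "p.tsv"
    sdf = tmp_path / "p.sdf"
    products_to_tsv(products, tsv)
    products_to_sdf(products, sdf)
    import pandas as pd

    df = pd.read_csv(tsv, sep="\t")
    assert list(df.columns) == [
        "product_id", "smiles", "line_id", "assignment_id", "modifications"
    ]
    assert len(df) == len(products)
    assert sdf.stat().st_size > 0
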