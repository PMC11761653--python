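"""Substrate registry, substructure fingerprints and molecular similarity.

Substrates (amino acids, hydroxy acids, ketide units and non-standard
monomers) are represented by a 296-entry fingerprint: the 167 MACCS keys,
a 128-bit radius-2 Morgan (ECFP4-style) bit vector, and the mean Gasteiger
partial charge over all atoms.  The binary part is the regression target of
the specificity model; the full vector also drives substructure attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, MACCSkeys
from rdkit.Chem import rdFingerprintGenerator

from .errors import ChargeComputationError, InvalidMoleculeError

MACCS_BITS = 167
MORGAN_BITS = 128
MORGAN_RADIUS = 2
FINGERPRINT_LENGTH = MACCS_BITS + MORGAN_BITS + 1

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
)
_tanimoto_gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=1024)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical (stereo-stripped) SMILES used as the substrate identity key.

    Stereochemistry is erased because the fingerprint cannot distinguish
    stereoisomers, so enantiomeric inputs must collapse to one record.
    """
    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def mean_partial_charge(smiles: str) -> float:
    """Arithmetic mean of per-atom Gasteiger partial charges."""
    mol = _mol_from_smiles(smiles)
    AllChem.ComputeGasteigerCharges(mol)
    charges = [
        float(a.GetDoubleProp("_GasteigerCharge")) for a in mol.GetAtoms()
    ]
    if not charges or not all(np.isfinite(charges)):
        raise ChargeComputationError(
            f"partial charges did not converge for {smiles!r}"
        )
    return float(np.mean(charges))


def compute_fingerprint(smiles: str) -> np.ndarray:
    """296-entry fingerprint: MACCS(167) + Morgan 128/r2 + mean charge."""
    mol = _mol_from_smiles(smiles)
    maccs = np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64)
    morgan = np.array(_morgan_gen.GetFingerprint(mol), dtype=np.float64)
    charge = mean_partial_charge(smiles)
    return np.concatenate([maccs, morgan, [charge]])


def tanimoto(smiles_a: str, smiles_b: str) -> float:
    """Bit-set Jaccard similarity on 1024-bit radius-3 Morgan fingerprints."""
    fa = _tanimoto_gen.GetFingerprint(_mol_from_smiles(smiles_a))
    fb = _tanimoto_gen.GetFingerprint(_mol_from_smiles(smiles_b))
    a = set(fa.GetOnBits())
    b = set(fb.GetOnBits())
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class SubstrateRecord:
    """A named substrate with canonical SMILES and 296-entry fingerprint."""

    name: str
    smiles: str
    fingerprint: np.ndarray = field(repr=False)

    @classmethod
    def from_smiles(cls, name: str, smiles: str) -> "SubstrateRecord":
        canon = canonical_smiles(smiles)
        return cls(name=name, smiles=canon, fingerprint=compute_fingerprint(canon))

    def validate(self) -> None:
        fp = self.fingerprint
        if fp.shape != (FINGERPRINT_LENGTH,):
            raise ValueError(f"fingerprint length {fp.shape} != {FINGERPRINT_LENGTH}")
        binary = fp[: FINGERPRINT_LENGTH - 1]
        if not np.isin(binary, (0.0, 1.0)).all():
            raise ValueError("binary fingerprint entries must be 0/1")
        if not np.isfinite(fp[-1]):
            raise ValueError("charge entry must be finite")


class SubstrateLibrary:
    """Collection of substrates unique by canonical SMILES.

    Duplicate SMILES are merged keeping the first-seen name so repeated
    loads are deterministic.
    """

    def __init__(self, records: Iterable[SubstrateRecord] = ()) -> None:
        self._by_smiles: dict[str, SubstrateRecord] = {}
        self._by_name: dict[str, SubstrateRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SubstrateRecord) -> SubstrateRecord:
        record.validate()
        existing = self._by_smiles.get(record.smiles)
        if existing is not None:
            return existing
        self._by_smiles[record.smiles] = record
        self._by_name[record.name] = record
        return record

    def add_smiles(self, name: str, smiles: str) -> SubstrateRecord:
        return self.add(SubstrateRecord.from_smiles(name, smiles))

    @property
    def records(self) -> list[SubstrateRecord]:
        return list(self._by_smiles.values())

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __len__(self) -> int:
        return len(self._by_smiles)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> SubstrateRecord:
        return self._by_name[name]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstrateLibrary":
        """Load a `name<TAB>smiles` table, validating and canonicalizing."""
        df = pd.read_csv(path, sep="\t")
        missing = {"name", "smiles"} - set(df.columns)
        if missing:
            raise ValueError(f"substrate table missing columns: {sorted(missing)}")
        lib = cls()
        for row in df.itertuples(index=False):
            lib.add_smiles(str(row.name), str(row.smiles))
        return lib

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(r.name, r.smiles) for r in self.records], columns=["name", "smiles"]
        ).to_csv(path, sep="\t", index=False)

    def fingerprint_matrix(self) -> pd.DataFrame:
        """Named-row numeric matrix of all fingerprints (export as TSV)."""
        recs = self.records
        mat = np.stack([r.fingerprint for r in recs]) if recs else np.empty((0, FINGERPRINT_LENGTH))
        return pd.DataFrame(mat, index=[r.name for r in recs])
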