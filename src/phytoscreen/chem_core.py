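"""Structure-derived quantities: MACCS fingerprints, Tanimoto similarity,
molecular properties and Lipinski rule-of-five evaluation.

All similarity computations in the package run on the 166 public MACCS
substructure keys. RDKit emits a 167-bit vector whose bit 0 is unused; it is
dropped here so that a fingerprint is exactly the 166 keys. The Tanimoto
coefficient between two fingerprints is |A∩B| / |A∪B| over the set bits, with
the degenerate both-empty case defined as 0 (no shared substructure evidence
never counts as similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdMolDescriptors

from .errors import ContractViolation, StructureError

RDLogger.DisableLog("rdApp.*")

N_MACCS_BITS = 166


@dataclass(frozen=True)
class Fingerprint:
    """Binary substructure-key fingerprint (166 public MACCS keys)."""

    bits: np.ndarray  # shape (166,), dtype bool

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def __eq__(self, other) -> bool:  # ndarray equality needs care
        return isinstance(other, Fingerprint) and bool(
            np.array_equal(self.bits, other.bits)
        )


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return mol


def compute_fingerprint(smiles: str) -> Fingerprint:
    """MACCS-key fingerprint of a structure.

    Deterministic: two SMILES of the same molecule (any atom ordering) give
    identical bit vectors, because RDKit perceives the molecular graph before
    key generation.
    """
    mol = _mol_from_smiles(smiles)
    return fingerprint_from_mol(mol)


def fingerprint_from_mol(mol: Chem.Mol) -> Fingerprint:
    keys = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(167, dtype=bool)
    on = list(keys.GetOnBits())
    bits[on] = True
    return Fingerprint(bits=bits[1:])  # bit 0 is unused padding


def fingerprint_matrix(smiles_list) -> np.ndarray:
    """Stack fingerprints of parseable structures into an (n, 166) bool array.

    Raises StructureError on the first unparseable entry; callers that want
    skip-and-log behaviour filter beforehand (see io_chem / activity).
    """
    return np.vstack([compute_fingerprint(s).bits for s in smiles_list]) if smiles_list else np.zeros((0, N_MACCS_BITS), dtype=bool)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient Tc = C(i,j) / U(i,j) over fingerprint bits."""
    if a.bits.shape != b.bits.shape:
        raise ContractViolation(
            f"fingerprint length mismatch: {a.bits.shape[0]} vs {b.bits.shape[0]}"
        )
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a.bits, b.bits).sum()) / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of two (nA,166)/(nB,166) bool arrays."""
    if A.shape[1] != B.shape[1]:
        raise ContractViolation(
            f"fingerprint length mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    Ai = A.astype(np.int32)
    Bi = B.astype(np.int32)
    inter = Ai @ Bi.T
    union = Ai.sum(axis=1)[:, None] + Bi.sum(axis=1)[None, :] - inter
    out = np.zeros_like(inter, dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


@dataclass(frozen=True)
class LipinskiFlags:
    """Rule-of-five verdicts; all inequalities strict."""

    hbd_ok: bool  # H-bond donors < 5
    hba_ok: bool  # H-bond acceptors < 10
    mw_ok: bool  # molecular weight < 500 Da
    alogp_ok: bool  # ALogP < 5

    @property
    def passes(self) -> bool:
        return self.hbd_ok and self.hba_ok and self.mw_ok and self.alogp_ok


@dataclass(frozen=True)
class PropertyProfile:
    """Molecular properties used for drug-likeness characterization.

    alogp is a Crippen-type atom-contribution estimate of logP; ring counts
    come from the smallest set of smallest rings (SSSR); rotatable bonds
    exclude amide and ring bonds.
    """

    alogp: float
    mol_weight: float  # daltons
    hbd: int
    hba: int
    rotatable_bonds: int
    n_rings: int
    n_aromatic_rings: int

    def __post_init__(self):
        if self.n_aromatic_rings > self.n_rings:
            raise ContractViolation(
                f"aromatic rings ({self.n_aromatic_rings}) exceed total rings ({self.n_rings})"
            )


def compute_properties(smiles: str) -> PropertyProfile:
    mol = _mol_from_smiles(smiles)
    return PropertyProfile(
        alogp=float(Crippen.MolLogP(mol)),
        mol_weight=float(Descriptors.MolWt(mol)),
        hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
        hba=int(rdMolDescriptors.CalcNumHBA(mol)),
        rotatable_bonds=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        n_rings=int(rdMolDescriptors.CalcNumRings(mol)),
        n_aromatic_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
    )


def lipinski_flags(profile: PropertyProfile) -> LipinskiFlags:
    """Evaluate the four rule-of-five criteria (strict '<' on every bound)."""
    return LipinskiFlags(
        hbd_ok=profile.hbd < 5,
        hba_ok=profile.hba < 10,
        mw_ok=profile.mol_weight < 500.0,
        alogp_ok=profile.alogp < 5.0,
    )
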