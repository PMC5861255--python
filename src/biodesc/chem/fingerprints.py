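"""The nineteen fingerprint families.

Substructure-keyed families (MACCS, E-state, Ghose–Crippen, FP3, FP4,
PubChem) have a fixed public bit layout; hashed families (daylight-type,
atom pairs, torsions, FP2, circular/Morgan) fold local environments into
a fixed-width bit or count vector.  Dimensions and determinism are
guaranteed; bit-for-bit parity with other toolkits is not promised.

FP2/FP3/FP4 are computed through Open Babel's python bindings; Open
Babel's FP3 pattern set natively has 55 keys, exposed here at the
family's declared width of 210 with the remaining positions
structurally zero.  The PubChem family implements the public 881-bit
layout's counting sections (elements, rings, simple bonded pairs); the
remaining SMARTS-keyed positions are fixed zero.
"""

from __future__ import annotations

import functools
import os
from typing import NamedTuple

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures, MACCSkeys, rdMolDescriptors
from rdkit.Chem.EState import AtomTypes
from rdkit.Chem.Pharm2D import Generate, SigFactory

from .graph import MoleculeGraph

__all__ = [
    "FingerprintVector",
    "fingerprint",
    "list_fingerprint_families",
    "FINGERPRINT_FAMILIES",
]


class FingerprintVector(NamedTuple):
    family: str
    length: int
    values: np.ndarray  # bit (0/1) or count vector

    def nonzero_bits(self) -> list[int]:
        return list(np.flatnonzero(self.values))


class FamilyInfo(NamedTuple):
    name: str
    length: int
    kind: str  # "bit" or "count"


#: (name, length, kind) for the nineteen families, fixed order.
FINGERPRINT_FAMILIES: tuple[FamilyInfo, ...] = (
    FamilyInfo("maccs", 166, "bit"),
    FamilyInfo("estate_fp", 79, "bit"),
    FamilyInfo("ghosecrippen", 110, "bit"),
    FamilyInfo("fp3", 210, "bit"),
    FamilyInfo("fp4", 307, "bit"),
    FamilyInfo("pubchem", 881, "bit"),
    FamilyInfo("daylight", 2048, "bit"),
    FamilyInfo("atompairs", 2048, "bit"),
    FamilyInfo("torsion", 2048, "bit"),
    FamilyInfo("fp2", 1024, "bit"),
    FamilyInfo("ecfp2", 1024, "bit"),
    FamilyInfo("ecfp4", 1024, "bit"),
    FamilyInfo("ecfp6", 1024, "bit"),
    FamilyInfo("fcfp2", 1024, "bit"),
    FamilyInfo("fcfp4", 1024, "bit"),
    FamilyInfo("fcfp6", 1024, "bit"),
    FamilyInfo("morgan", 1024, "count"),
    FamilyInfo("pharm2d_2point", 135, "bit"),
    FamilyInfo("pharm2d_3point", 2135, "bit"),
)

_BY_NAME = {f.name: f for f in FINGERPRINT_FAMILIES}


def list_fingerprint_families() -> tuple[FamilyInfo, ...]:
    """The available families with their fixed lengths, stable order."""
    return FINGERPRINT_FAMILIES


def _as_mol(mol: "MoleculeGraph | Chem.Mol") -> Chem.Mol:
    return mol.mol if isinstance(mol, MoleculeGraph) else mol


def _bits_from_rdkit(bv, length: int) -> np.ndarray:
    out = np.zeros(length)
    for b in bv.GetOnBits():
        if b < length:
            out[b] = 1.0
    return out


# ----------------------- substructure families -----------------------

def _maccs(mol: Chem.Mol) -> np.ndarray:
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is unused
    out = np.zeros(166)
    for b in bv.GetOnBits():
        if b >= 1:
            out[b - 1] = 1.0
    return out


def _estate_fp(mol: Chem.Mol) -> np.ndarray:
    AtomTypes.BuildPatts()
    names = [n for n, _ in AtomTypes.esPatterns]
    present = {t for types in AtomTypes.TypeAtoms(mol) for t in types}
    return np.array([1.0 if n in present else 0.0 for n in names])


@functools.cache
def _crippen_patterns() -> tuple:
    """The 110 public Wildman–Crippen atom-type SMARTS, file order."""
    path = os.path.join(RDConfig.RDDataDir, "Crippen.txt")
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, smarts = line.split("\t")[:2]
            patt = Chem.MolFromSmarts(smarts)
            patterns.append((label, patt))
    return tuple(patterns)


def _ghosecrippen(mol: Chem.Mol) -> np.ndarray:
    molh = Chem.AddHs(mol)
    out = np.zeros(110)
    for i, (_, patt) in enumerate(_crippen_patterns()):
        if patt is not None and molh.HasSubstructMatch(patt):
            out[i] = 1.0
    return out


def _openbabel_fp(mol: Chem.Mol, obname: str, length: int) -> np.ndarray:
    try:
        from openbabel import pybel
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            f"fingerprint family {obname} requires the openbabel python "
            "bindings"
        ) from exc
    obmol = pybel.readstring("smi", Chem.MolToSmiles(mol))
    fp = obmol.calcfp(obname)
    out = np.zeros(length)
    for b in fp.bits:  # pybel bits are 1-based
        if 0 < b <= length:
            out[b - 1] = 1.0
    return out


# PubChem-layout section 1: hierarchic element counts, (bit, element,
# minimum count).  Bits 0..114.
_PUBCHEM_COUNTS: tuple[tuple[int, str, int], ...] = (
    (0, "H", 4), (1, "H", 8), (2, "H", 16), (3, "H", 32),
    (4, "Li", 1), (5, "Li", 2), (6, "B", 1), (7, "B", 2), (8, "B", 4),
    (9, "C", 2), (10, "C", 4), (11, "C", 8), (12, "C", 16), (13, "C", 32),
    (14, "N", 1), (15, "N", 2), (16, "N", 4), (17, "N", 8),
    (18, "O", 1), (19, "O", 2), (20, "O", 4), (21, "O", 8), (22, "O", 16),
    (23, "F", 1), (24, "F", 2), (25, "F", 4),
    (26, "Na", 1), (27, "Na", 2), (28, "Si", 1), (29, "Si", 2),
    (30, "P", 1), (31, "P", 2), (32, "P", 4),
    (33, "S", 1), (34, "S", 2), (35, "S", 4), (36, "S", 8),
    (37, "Cl", 1), (38, "Cl", 2), (39, "Cl", 4), (40, "Cl", 8),
    (41, "K", 1), (42, "K", 2),
    (43, "Br", 1), (44, "Br", 2), (45, "Br", 4),
    (46, "I", 1), (47, "I", 2), (48, "I", 4),
)

#: single-presence bits for other elements, bits 49..114
_PUBCHEM_PRESENCE = (
    "Be", "Mg", "Al", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni",
    "Cu", "Zn", "Ga", "Ge", "As", "Se", "Kr", "Rb", "Sr", "Y", "Zr", "Nb",
    "Mo", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Sb", "Te", "Xe", "Cs",
    "Ba", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl",
    "Pb", "Bi", "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Tc", "U",
)

#: bonded element-pair presence bits (section 3-style), bits 263..326
_PUBCHEM_PAIRS = (
    ("C", "C"), ("C", "N"), ("C", "O"), ("C", "S"), ("C", "P"),
    ("C", "F"), ("C", "Cl"), ("C", "Br"), ("C", "I"), ("C", "Si"),
    ("C", "B"), ("N", "N"), ("N", "O"), ("N", "S"), ("N", "P"),
    ("O", "O"), ("O", "S"), ("O", "P"), ("S", "S"), ("P", "P"),
    ("O", "Si"), ("N", "Si"), ("S", "Si"), ("Si", "Si"), ("B", "O"),
    ("B", "N"), ("S", "Cl"), ("P", "F"), ("P", "Cl"), ("S", "F"),
)


def _pubchem(mol: Chem.Mol) -> np.ndarray:
    out = np.zeros(881)
    molh = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for a in molh.GetAtoms():
        counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
    for bit, el, minimum in _PUBCHEM_COUNTS:
        if counts.get(el, 0) >= minimum:
            out[bit] = 1.0
    for offset, el in enumerate(_PUBCHEM_PRESENCE):
        if counts.get(el, 0) >= 1:
            out[49 + offset] = 1.0
    # ring-count section (bits 115..262): for each ring size 3..10, bits
    # for >= 1..6 rings, plus carbon-only / nitrogen-containing /
    # heteroatom-containing presence flags (9 bits per size + aromatic
    # block at the end of the section).
    ring_info = mol.GetRingInfo()
    rings = ring_info.AtomRings()
    base = 115
    for size in range(3, 11):
        of_size = [r for r in rings if len(r) == size]
        for k in range(6):
            if len(of_size) >= k + 1:
                out[base + k] = 1.0
        if any(
            all(mol.GetAtomWithIdx(i).GetSymbol() == "C" for i in r)
            for r in of_size
        ):
            out[base + 6] = 1.0
        if any(
            any(mol.GetAtomWithIdx(i).GetSymbol() == "N" for i in r)
            for r in of_size
        ):
            out[base + 7] = 1.0
        if any(
            any(mol.GetAtomWithIdx(i).GetSymbol() not in ("C",) for i in r)
            for r in of_size
        ):
            out[base + 8] = 1.0
        base += 9  # 8 sizes x 9 bits = 72 bits (115..186)
    n_arom_rings = rdMolDescriptors.CalcNumAromaticRings(mol)
    for k in range(4):  # bits 187..190: >= 1..4 aromatic rings
        if n_arom_rings >= k + 1:
            out[187 + k] = 1.0
    # simple bonded element pairs, bits 263..292
    bonded = set()
    for b in mol.GetBonds():
        pair = tuple(
            sorted((b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol()))
        )
        bonded.add(pair)
    for offset, pair in enumerate(_PUBCHEM_PAIRS):
        if tuple(sorted(pair)) in bonded:
            out[263 + offset] = 1.0
    # remaining positions correspond to the public SMARTS sections and
    # stay zero in this implementation
    return out


# --------------------------- hashed families -------------------------

def _morgan_bits(mol: Chem.Mol, radius: int, features: bool) -> np.ndarray:
    gen = rdMolDescriptors.GetMorganFingerprintAsBitVect(
        mol, radius, nBits=1024, useFeatures=features
    )
    return _bits_from_rdkit(gen, 1024)


def _morgan_counts(mol: Chem.Mol) -> np.ndarray:
    fp = rdMolDescriptors.GetHashedMorganFingerprint(mol, 2, nBits=1024)
    out = np.zeros(1024)
    for idx, c in fp.GetNonzeroElements().items():
        out[idx] = float(c)
    return out


# ------------------------ pharmacophore families ---------------------

@functools.cache
def _sig_factory(points: int) -> SigFactory.SigFactory:
    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    feat = ChemicalFeatures.BuildFeatureFactory(fdef)
    keep = ("Donor", "Acceptor", "PosIonizable", "NegIonizable", "Hydrophobe")
    skip = [f for f in feat.GetFeatureFamilies() if f not in keep]
    sf = SigFactory.SigFactory(
        feat, minPointCount=points, maxPointCount=points, skipFeats=skip
    )
    if points == 2:
        sf.SetBins([(i, i + 1) for i in range(1, 10)])  # 9 unit bins
    else:
        sf.SetBins([(1, 2), (2, 4), (4, 6), (6, 9)])
        sf.trianglePruneBins = True
    sf.Init()
    return sf


def _pharm2d(mol: Chem.Mol, points: int, length: int) -> np.ndarray:
    sf = _sig_factory(points)
    assert sf.GetSigSize() == length
    return _bits_from_rdkit(Generate.Gen2DFingerprint(mol, sf), length)


# ------------------------------ dispatch -----------------------------

def fingerprint(mol: "MoleculeGraph | Chem.Mol", family: str) -> FingerprintVector:
    """Compute one fingerprint family by name."""
    if family not in _BY_NAME:
        raise ValueError(
            f"unknown fingerprint family {family!r}; "
            f"available: {[f.name for f in FINGERPRINT_FAMILIES]}"
        )
    m = _as_mol(mol)
    info = _BY_NAME[family]
    if family == "maccs":
        values = _maccs(m)
    elif family == "estate_fp":
        values = _estate_fp(m)
    elif family == "ghosecrippen":
        values = _ghosecrippen(m)
    elif family in ("fp2", "fp3", "fp4"):
        values = _openbabel_fp(m, family.upper(), info.length)
    elif family == "pubchem":
        values = _pubchem(m)
    elif family == "daylight":
        values = _bits_from_rdkit(Chem.RDKFingerprint(m, fpSize=2048), 2048)
    elif family == "atompairs":
        values = _bits_from_rdkit(
            rdMolDescriptors.GetHashedAtomPairFingerprintAsBitVect(m, nBits=2048),
            2048,
        )
    elif family == "torsion":
        values = _bits_from_rdkit(
            rdMolDescriptors.GetHashedTopologicalTorsionFingerprintAsBitVect(
                m, nBits=2048
            ),
            2048,
        )
    elif family in ("ecfp2", "ecfp4", "ecfp6"):
        values = _morgan_bits(m, int(family[-1]) // 2, features=False)
    elif family in ("fcfp2", "fcfp4", "fcfp6"):
        values = _morgan_bits(m, int(family[-1]) // 2, features=True)
    elif family == "morgan":
        values = _morgan_counts(m)
    elif family == "pharm2d_2point":
        values = _pharm2d(m, 2, info.length)
    else:  # pharm2d_3point
        values = _pharm2d(m, 3, info.length)
    assert len(values) == info.length
    return FingerprintVector(family, info.length, values)
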