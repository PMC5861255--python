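"""Charge, molecular property, MOE-type and CATS pharmacophore groups."""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors, rdPartialCharges
from rdkit.Chem.EState import EState_VSA as _estate_vsa

from ..vector import FeatureVector
from .graphutils import distance_matrix

__all__ = ["charge", "molproperty", "moe", "cats"]


# ----------------------------- charge (25) ---------------------------

def _gasteiger(mol: Chem.Mol) -> tuple[Chem.Mol, np.ndarray]:
    molh = Chem.AddHs(mol)
    rdPartialCharges.ComputeGasteigerCharges(molh)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in molh.GetAtoms()]
    )
    q[~np.isfinite(q)] = 0.0
    return molh, q


def charge(mol: Chem.Mol) -> FeatureVector:
    """25 statistics of Gasteiger partial charges (hydrogens included).

    Extremes, sums of squares (overall and per C/N/O/H), total/mean
    positive, negative and absolute charge, relative extreme charges,
    the submolecular polarity parameter SPP = q_max − q_min and the
    local dipole index (mean |q_i − q_j| over bonds).
    """
    molh, q = _gasteiger(mol)
    sym = [a.GetSymbol() for a in molh.GetAtoms()]

    def stat(el: str, fn, default=0.0) -> float:
        vals = [qi for s, qi in zip(sym, q) if s == el]
        return float(fn(vals)) if vals else default

    qpos = q[q > 0]
    qneg = q[q < 0]
    tpc = float(qpos.sum())
    tnc = float(qneg.sum())
    bonds = molh.GetBonds()
    ldi = (
        float(
            np.mean(
                [abs(q[b.GetBeginAtomIdx()] - q[b.GetEndAtomIdx()]) for b in bonds]
            )
        )
        if bonds
        else 0.0
    )
    values = {
        "Qmax": float(q.max()) if len(q) else 0.0,
        "Qmin": float(q.min()) if len(q) else 0.0,
        "Qass": float((q**2).sum()),
        "QCmax": stat("C", max),
        "QCmin": stat("C", min),
        "QCss": stat("C", lambda v: sum(x**2 for x in v)),
        "QNmax": stat("N", max),
        "QNmin": stat("N", min),
        "QNss": stat("N", lambda v: sum(x**2 for x in v)),
        "QOmax": stat("O", max),
        "QOmin": stat("O", min),
        "QOss": stat("O", lambda v: sum(x**2 for x in v)),
        "QHmax": stat("H", max),
        "QHmin": stat("H", min),
        "QHss": stat("H", lambda v: sum(x**2 for x in v)),
        "Tpc": tpc,
        "Mpc": float(qpos.mean()) if len(qpos) else 0.0,
        "Tnc": tnc,
        "Mnc": float(qneg.mean()) if len(qneg) else 0.0,
        "Tac": float(np.abs(q).sum()),
        "Mac": float(np.abs(q).mean()) if len(q) else 0.0,
        "Rpc": float(q.max() / tpc) if tpc > 0 else 0.0,
        "Rnc": float(q.min() / tnc) if tnc < 0 else 0.0,
        "SPP": float(q.max() - q.min()) if len(q) else 0.0,
        "LDI": ldi,
    }
    return FeatureVector(
        [f"charge.{nm}" for nm in values], list(values.values())
    )


# ---------------------------- property (6) ---------------------------

def molproperty(mol: Chem.Mol) -> FeatureVector:
    """LogP, LogP², molar refractivity, TPSA, unsaturation and
    hydrophilicity indices."""
    logp = Crippen.MolLogP(mol)
    mr = Crippen.MolMR(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    n_unsat = sum(
        1
        for b in mol.GetBonds()
        if b.GetBondType()
        in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)
    )
    ui = math.log2(1 + n_unsat)
    # hydrophilic index: counts hydrogens on N/O/S vs carbons
    a_heavy = mol.GetNumAtoms()
    n_hy = sum(
        a.GetTotalNumHs()
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("N", "O", "S")
    )
    n_c = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    if a_heavy > 1:
        hy = (
            (1 + n_hy) * math.log2(1 + n_hy)
            + n_c * (1.0 / a_heavy) * math.log2(1.0 / a_heavy)
            + math.sqrt(n_hy / a_heavy**2)
        ) / math.log2(1 + a_heavy)
    else:
        hy = 0.0
    names = ["LogP", "LogP2", "MR", "TPSA", "UI", "Hy"]
    return FeatureVector(
        [f"property.{nm}" for nm in names],
        [logp, logp**2, mr, tpsa, ui, hy],
    )


# ----------------------------- MOE-type (60) -------------------------

def moe(mol: Chem.Mol) -> FeatureVector:
    """60 surface-area descriptors: LabuteASA, TPSA (without and with
    S/P contributions) and the SlogP/SMR/PEOE/EState VSA bin series."""
    names: list[str] = ["moe.LabuteASA", "moe.TPSA", "moe.MTPSA"]
    values: list[float] = [
        rdMolDescriptors.CalcLabuteASA(mol),
        rdMolDescriptors.CalcTPSA(mol),
        rdMolDescriptors.CalcTPSA(mol, includeSandP=True),
    ]
    series = (
        ("SlogP_VSA", rdMolDescriptors.SlogP_VSA_(mol)),
        ("SMR_VSA", rdMolDescriptors.SMR_VSA_(mol)),
        ("PEOE_VSA", rdMolDescriptors.PEOE_VSA_(mol)),
        ("EState_VSA", _estate_vsa.EState_VSA_(mol)),
        ("VSA_EState", _estate_vsa.VSA_EState_(mol)),
    )
    for prefix, vals in series:
        for i, v in enumerate(vals, start=1):
            names.append(f"moe.{prefix}{i}")
            values.append(float(v))
    return FeatureVector(names, values)


# ------------------------------ CATS (150) ---------------------------

#: Potential pharmacophore point definitions (SMARTS, applied per atom).
CATS_SMARTS: dict[str, tuple[str, ...]] = {
    # hydrogen-bond donor: O/S/N bearing at least one hydrogen
    "D": ("[#7;H1,H2,H3;+0,+1]", "[#8;H1]", "[#16;H1]"),
    # hydrogen-bond acceptor: O with lone pair, or neutral N that is not
    # a pyrrole-type NH
    "A": ("[#8;X1,X2;-0,-1]", "[#7;+0;!$([nX3;H1]);X1,X2,X3]"),
    # positively charged / protonatable
    "P": (
        "[+1,+2;!$([N+](=O)[O-])]",
        "[$([NH2]-[CX4])]",
        "[$(N=C(-N)-N)]",
    ),
    # negatively charged / deprotonatable
    "N": (
        "[-1,-2]",
        "[$([OH]-C=O)]",
        "[$([OH]-S(=O)=O)]",
        "[$([OH]-P=O)]",
    ),
    # lipophilic: halogens, thioether sulfur, carbon with no heteroatom
    # neighbours
    "L": (
        "[Cl,Br,I]",
        "[SX2;$(S(-[#6])-[#6])]",
        "[#6;!$([#6]~[#7,#8,#15,#16,F,Cl,Br,I])]",
    ),
}

CATS_TYPES = ("D", "A", "P", "N", "L")
CATS_MAX_DISTANCE = 9


def _assign_cats_types(mol: Chem.Mol) -> dict[int, set]:
    assignment: dict[int, set] = {i: set() for i in range(mol.GetNumAtoms())}
    for t, patterns in CATS_SMARTS.items():
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            for match in mol.GetSubstructMatches(patt):
                assignment[match[0]].add(t)
    return assignment


def cats(mol: Chem.Mol) -> FeatureVector:
    """150 CATS2D pharmacophore-pair counts.

    Atoms are typed as donor/acceptor/positive/negative/lipophilic (an
    atom may carry several types); for every unordered type pair the
    count of atom pairs at topological distance 0–9 is recorded (pairs
    farther than 9 bonds are not counted).
    """
    assignment = _assign_cats_types(mol)
    n = mol.GetNumAtoms()
    D = distance_matrix(mol) if n else np.zeros((0, 0))
    pair_labels = [
        (CATS_TYPES[i], CATS_TYPES[j])
        for i in range(len(CATS_TYPES))
        for j in range(i, len(CATS_TYPES))
    ]
    index = {p: k for k, p in enumerate(pair_labels)}
    counts = np.zeros((len(pair_labels), CATS_MAX_DISTANCE + 1))

    def pair_key(t1: str, t2: str):
        i1, i2 = CATS_TYPES.index(t1), CATS_TYPES.index(t2)
        return (t1, t2) if i1 <= i2 else (t2, t1)

    for i in range(n):
        types_i = assignment[i]
        # distance-0: distinct types on one atom
        tlist = sorted(types_i, key=CATS_TYPES.index)
        for a in range(len(tlist)):
            for b in range(a + 1, len(tlist)):
                counts[index[(tlist[a], tlist[b])], 0] += 1
        for j in range(i + 1, n):
            d = int(D[i, j])
            if d > CATS_MAX_DISTANCE:
                continue
            for t1 in types_i:
                for t2 in assignment[j]:
                    counts[index[pair_key(t1, t2)], d] += 1
    names = [
        f"cats.{t1}{t2}.d{d}"
        for (t1, t2) in pair_labels
        for d in range(CATS_MAX_DISTANCE + 1)
    ]
    return FeatureVector(names, counts.ravel())
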