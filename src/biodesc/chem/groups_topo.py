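"""Constitutional, topological, connectivity and kappa descriptor groups.

All indices are computed on the hydrogen-suppressed heavy-atom graph
unless a descriptor explicitly counts hydrogens.  Descriptors that are
undefined on degenerate graphs (single atom, no bonds, zero variance)
report 0.0 so that vectors stay finite.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors

from ..vector import FeatureVector
from .graphutils import (
    atom_paths,
    degrees,
    distance_matrix,
    subgraph_shapes,
    valence_deltas,
)

__all__ = ["constitution", "topology", "connectivity", "kappa"]


def _safe(x: float) -> float:
    return float(x) if math.isfinite(x) else 0.0


# ------------------------- constitution (30) -------------------------

def constitution(mol: Chem.Mol) -> FeatureVector:
    """30 constitutional counts: elements, bonds, rings, H-bonding, paths."""
    atoms = mol.GetAtoms()
    sym = [a.GetSymbol() for a in atoms]
    n_h = sum(a.GetTotalNumHs() for a in atoms)
    bond_types = [b.GetBondType() for b in mol.GetBonds()]
    names_values = [
        ("Weight", Descriptors.MolWt(mol)),
        ("AWeight", Descriptors.MolWt(mol) / max(1, mol.GetNumAtoms() + n_h)),
        ("nhyd", n_h),
        ("nhal", sum(s in ("F", "Cl", "Br", "I") for s in sym)),
        ("nhet", sum(s not in ("C", "H") for s in sym)),
        ("nhev", mol.GetNumAtoms()),
        ("ncof", sym.count("F")),
        ("ncocl", sym.count("Cl")),
        ("ncobr", sym.count("Br")),
        ("ncoi", sym.count("I")),
        ("ncarb", sym.count("C")),
        ("nphos", sym.count("P")),
        ("nsulph", sym.count("S")),
        ("noxy", sym.count("O")),
        ("nnitro", sym.count("N")),
        ("nring", rdMolDescriptors.CalcNumRings(mol)),
        ("nrot", Lipinski.NumRotatableBonds(mol)),
        ("ndonr", Lipinski.NumHDonors(mol)),
        ("naccr", Lipinski.NumHAcceptors(mol)),
        ("nsb", bond_types.count(Chem.BondType.SINGLE)),
        ("ndb", bond_types.count(Chem.BondType.DOUBLE)),
        ("ntb", bond_types.count(Chem.BondType.TRIPLE)),
        ("naro", bond_types.count(Chem.BondType.AROMATIC)),
        ("nta", mol.GetNumAtoms() + n_h),
    ]
    for n in range(1, 7):
        names_values.append(
            (f"PC{n}", len(Chem.FindAllPathsOfLengthN(mol, n, useBonds=True)))
        )
    return FeatureVector(
        [f"constitution.{n}" for n, _ in names_values],
        [_safe(v) for _, v in names_values],
    )


# --------------------------- topology (35) ---------------------------

def _entropy_bits(counts: list[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum(c / total * math.log2(c / total) for c in counts if c)


def topology(mol: Chem.Mol) -> FeatureVector:
    """35 distance- and degree-based topological indices."""
    n = mol.GetNumAtoms()
    deg = degrees(mol)
    m = mol.GetNumBonds()
    if n < 2:
        # every index below needs at least one bond; report the sentinel
        return FeatureVector([f"topology.{nm}" for nm in _TOPOLOGY_NAMES],
                             [0.0] * len(_TOPOLOGY_NAMES))
    D = distance_matrix(mol)
    iu = np.triu_indices(n, 1)
    dvals = D[iu]
    dd = D.sum(axis=1)  # distance degree per atom
    wiener = float(dvals.sum())
    n_pairs = len(dvals)
    ecc = D.max(axis=1)
    diam, rad = float(ecc.max()), float(ecc.min())
    zm1 = float((deg**2).sum())
    zm2 = float(
        sum(
            deg[b.GetBeginAtomIdx()] * deg[b.GetEndAtomIdx()]
            for b in mol.GetBonds()
        )
    )
    with np.errstate(divide="ignore"):
        harary = float((1.0 / dvals[dvals > 0]).sum())
    schultz = float((deg * (deg + dd)).sum())
    gutman = float(sum(deg[i] * deg[j] * D[i, j] for i, j in zip(*iu)))
    # Laplacian spectrum for the quasi-Wiener (Mohar) index
    A = np.asarray(Chem.GetAdjacencyMatrix(mol), dtype=float)
    lap_eig = np.linalg.eigvalsh(np.diag(deg) - A)
    pos = lap_eig[lap_eig > 1e-10]
    quasi_wiener = float(n * (1.0 / pos).sum()) if len(pos) else 0.0
    # information-theoretic indices
    dist_counts = [int((dvals == k).sum()) for k in range(1, int(diam) + 1)]
    ide = _entropy_bits(dist_counts)
    idet = (
        n_pairs * math.log2(n_pairs) - sum(c * math.log2(c) for c in dist_counts if c)
        if n_pairs
        else 0.0
    )
    idw = (
        wiener * math.log2(wiener)
        - sum(c * k * math.log2(k) for k, c in enumerate(dist_counts, 1) if k > 1)
        if wiener > 0
        else 0.0
    )
    deg_counts = [int((deg == d).sum()) for d in sorted(set(deg))]
    ivde = _entropy_bits(deg_counts)
    elem_counts = {}
    for a in mol.GetAtoms():
        elem_counts[a.GetSymbol()] = elem_counts.get(a.GetSymbol(), 0) + 1
    tiac = (
        n * math.log2(n) - sum(c * math.log2(c) for c in elem_counts.values() if c)
        if n
        else 0.0
    )
    pt = Chem.GetPeriodicTable()
    dz = sum(
        pt.GetNOuterElecs(a.GetAtomicNum()) / _principal_quantum(a.GetAtomicNum())
        for a in mol.GetAtoms()
    )
    # Narumi indices on degrees
    logprod = float(np.log(deg[deg > 0]).sum()) if (deg > 0).any() else 0.0
    sito = logprod
    hato = n / float((1.0 / deg[deg > 0]).sum()) if (deg > 0).all() else 0.0
    geto = math.exp(logprod / n) if (deg > 0).all() else 0.0
    arto = 2.0 * m / n
    sdd = float((deg * dd).sum())  # degree distance
    xu_num = float((deg * dd**2).sum())
    xu = (
        math.sqrt(n) * math.log(xu_num / sdd) if sdd > 0 and xu_num > 0 else 0.0
    )
    values = {
        "W": wiener,
        "AW": wiener / n_pairs if n_pairs else 0.0,
        "J": GraphDescriptors.BalabanJ(mol),
        "Harary": harary,
        "Schultz": schultz,
        "Gutman": gutman,
        "ZM1": zm1,
        "ZM2": zm2,
        "MZM1": float((1.0 / deg[deg > 0] ** 2).sum()),
        "MZM2": float(
            sum(
                1.0
                / (deg[b.GetBeginAtomIdx()] * deg[b.GetEndAtomIdx()])
                for b in mol.GetBonds()
            )
        ),
        "Qindex": 3 - 2 * n + zm1 / 2.0,
        "Platt": float(
            sum(
                deg[b.GetBeginAtomIdx()] + deg[b.GetEndAtomIdx()] - 2
                for b in mol.GetBonds()
            )
        ),
        "Pogliani": float(dz),
        "Ipc": GraphDescriptors.Ipc(mol, avg=True),
        "BertzCT": GraphDescriptors.BertzCT(mol),
        "diameter": diam,
        "radius": rad,
        "Petitjean": (diam - rad) / rad if rad > 0 else 0.0,
        "Xu": xu,
        "Pol": float((dvals == 3).sum()),
        "hyperW": float(0.5 * (dvals + dvals**2).sum()),
        "Sito": sito,
        "Hato": hato,
        "Geto": geto,
        "Arto": arto,
        "TIAC": tiac,
        "IDE": ide,
        "IDET": idet,
        "IDW": idw,
        "IVDE": ivde,
        "ECC": float((deg * ecc).sum()),
        "AEcc": float(ecc.mean()),
        "TEcc": float(ecc.sum()),
        "QW": quasi_wiener,
        "DD": sdd,
    }
    assert list(values) == _TOPOLOGY_NAMES
    return FeatureVector(
        [f"topology.{nm}" for nm in values], [_safe(v) for v in values.values()]
    )


_TOPOLOGY_NAMES = [
    "W", "AW", "J", "Harary", "Schultz", "Gutman", "ZM1", "ZM2", "MZM1",
    "MZM2", "Qindex", "Platt", "Pogliani", "Ipc", "BertzCT", "diameter",
    "radius", "Petitjean", "Xu", "Pol", "hyperW", "Sito", "Hato", "Geto",
    "Arto", "TIAC", "IDE", "IDET", "IDW", "IVDE", "ECC", "AEcc", "TEcc",
    "QW", "DD",
]


def _principal_quantum(z: int) -> int:
    for limit, period in ((2, 1), (10, 2), (18, 3), (36, 4), (54, 5), (86, 6)):
        if z <= limit:
            return period
    return 7


# ------------------------- connectivity (44) -------------------------

def _chi_from_atoms(delta: np.ndarray, atom_sets) -> float:
    total = 0.0
    for atoms in atom_sets:
        prod = 1.0
        ok = True
        for a in atoms:
            if delta[a] <= 0:
                ok = False
                break
            prod *= delta[a]
        if ok:
            total += 1.0 / math.sqrt(prod)
    return total


def connectivity(mol: Chem.Mol) -> FeatureVector:
    """44 Kier–Hall molecular connectivity (chi) indices.

    Simple and valence chi for path orders 0–10, 3/4-clusters,
    4-path/cluster and 3–6 chains, the mean Randić index, the cluster
    "knot" differences and the simple-vs-valence differences of orders
    0–4.
    """
    delta = degrees(mol)
    deltav = valence_deltas(mol)
    names: list[str] = []
    values: list[float] = []
    paths = {k: atom_paths(mol, k) for k in range(0, 11)}
    shapes = {k: subgraph_shapes(mol, k) for k in (3, 4, 5, 6)}

    chi: dict[str, float] = {}
    for d_name, d in (("", delta), ("v", deltav)):
        for order in range(0, 11):
            chi[f"chi{d_name}{order}"] = _chi_from_atoms(d, paths[order])
        chi[f"chi{d_name}3c"] = _chi_from_atoms(d, shapes[3]["cluster"])
        chi[f"chi{d_name}4c"] = _chi_from_atoms(d, shapes[4]["cluster"])
        chi[f"chi{d_name}4pc"] = _chi_from_atoms(d, shapes[4]["pathcluster"])
        for order in (3, 4, 5, 6):
            chi[f"chi{d_name}{order}ch"] = _chi_from_atoms(
                d, shapes[order]["chain"]
            )
    n_bonds = mol.GetNumBonds()
    mchi1 = chi["chi1"] / n_bonds if n_bonds else 0.0

    for order in range(0, 11):
        names.append(f"Chi{order}")
        values.append(chi[f"chi{order}"])
    names.append("mChi1")
    values.append(mchi1)
    for tag in ("3c", "4c", "4pc", "3ch", "4ch", "5ch", "6ch"):
        names.append(f"Chi{tag}")
        values.append(chi[f"chi{tag}"])
    names.append("knotp")
    values.append(chi["chi3c"] - chi["chi4pc"])
    for order in range(0, 11):
        names.append(f"Chiv{order}")
        values.append(chi[f"chiv{order}"])
    for tag in ("3c", "4c", "4pc", "3ch", "4ch", "5ch", "6ch"):
        names.append(f"Chiv{tag}")
        values.append(chi[f"chiv{tag}"])
    names.append("knotpv")
    values.append(chi["chiv3c"] - chi["chiv4pc"])
    for order in range(0, 5):
        names.append(f"dchi{order}")
        values.append(abs(chi[f"chi{order}"] - chi[f"chiv{order}"]))
    return FeatureVector(
        [f"connectivity.{nm}" for nm in names], [_safe(v) for v in values]
    )


# ----------------------------- kappa (7) -----------------------------

def kappa(mol: Chem.Mol) -> FeatureVector:
    """Kier shape indices κ1–κ3, the α-modified κα1–κα3 and flexibility Φ."""
    A = mol.GetNumAtoms()
    p1 = mol.GetNumBonds()
    p2 = len(Chem.FindAllPathsOfLengthN(mol, 2, useBonds=True))
    p3 = len(Chem.FindAllPathsOfLengthN(mol, 3, useBonds=True))
    alpha = rdMolDescriptors.CalcHallKierAlpha(mol)

    def k1(a: float, p: float) -> float:
        return a * (a - 1) ** 2 / p**2 if p > 0 else 0.0

    def k2(a: float, p: float) -> float:
        return (a - 1) * (a - 2) ** 2 / p**2 if p > 0 else 0.0

    def k3(a: float, p: float) -> float:
        if p <= 0:
            return 0.0
        if int(round(a)) % 2:
            return (a - 1) * (a - 3) ** 2 / p**2
        return (a - 3) * (a - 2) ** 2 / p**2

    kap1, kap2, kap3 = k1(A, p1), k2(A, p2), k3(A, p3)
    kpa1 = k1(A + alpha, p1 + alpha)
    kpa2 = k2(A + alpha, p2 + alpha)
    kpa3 = k3(A + alpha, p3 + alpha)
    phi = kpa1 * kpa2 / A if A > 0 else 0.0
    names = ["kappa1", "kappa2", "kappa3", "kappam1", "kappam2", "kappam3", "phi"]
    return FeatureVector(
        [f"kappa.{nm}" for nm in names],
        [_safe(v) for v in (kap1, kap2, kap3, kpa1, kpa2, kpa3, phi)],
    )
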