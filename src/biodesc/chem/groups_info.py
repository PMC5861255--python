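"""Basak information, E-state, Burden and autocorrelation groups."""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem
from rdkit.Chem.EState import EState, AtomTypes

from ..vector import FeatureVector
from .elements import WEIGHTING_SCHEMES, atom_weight
from .graphutils import distance_matrix

__all__ = ["basak", "estate", "burden", "autocorrelation_group"]


# ----------------------------- Basak (21) ----------------------------

def _neighborhood_classes(mol: Chem.Mol, radius: int) -> list[int]:
    """Atom equivalence classes by iterated neighborhood refinement.

    Radius-0 classes are (element, H-count) pairs on the H-included
    graph; each refinement round appends the sorted multiset of
    neighbour classes, Morgan-style.
    """
    molh = Chem.AddHs(mol)
    labels = [
        (a.GetAtomicNum(),) for a in molh.GetAtoms()
    ]
    codes = _relabel(labels)
    for _ in range(radius):
        new = []
        for a in molh.GetAtoms():
            neigh = sorted(codes[n.GetIdx()] for n in a.GetNeighbors())
            new.append((codes[a.GetIdx()], tuple(neigh)))
        codes = _relabel(new)
    return codes


def _relabel(keys: list) -> list[int]:
    mapping: dict = {}
    out = []
    for k in keys:
        if k not in mapping:
            mapping[k] = len(mapping)
        out.append(mapping[k])
    return out


def basak(mol: Chem.Mol) -> FeatureVector:
    """21 Basak indices: IC/SIC/CIC for neighborhood orders 0–6.

    IC_r is the Shannon entropy (bits/atom) of the radius-r atom
    equivalence classes on the hydrogen-included graph; SIC_r = IC_r /
    log2(n); CIC_r = log2(n) − IC_r.
    """
    n = Chem.AddHs(mol).GetNumAtoms()
    names: list[str] = []
    values: list[float] = []
    for r in range(0, 7):
        codes = _neighborhood_classes(mol, r)
        counts: dict[int, int] = {}
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
        ic = -sum(
            c / n * math.log2(c / n) for c in counts.values()
        ) if n else 0.0
        log_n = math.log2(n) if n > 1 else 0.0
        sic = ic / log_n if log_n else 0.0
        cic = log_n - ic
        names += [f"IC{r}", f"SIC{r}", f"CIC{r}"]
        values += [ic, sic, cic]
    return FeatureVector([f"basak.{nm}" for nm in names], values)


# ---------------------------- E-state (237) --------------------------

def _estate_types_and_indices(mol: Chem.Mol):
    types = AtomTypes.TypeAtoms(mol)  # tuple of type-name tuples per atom
    indices = EState.EStateIndices(mol)
    return types, indices


def estate_type_names() -> list[str]:
    AtomTypes.BuildPatts()
    return [name for name, _ in AtomTypes.esPatterns]


def estate(mol: Chem.Mol) -> FeatureVector:
    """237 electrotopological-state values: per-atom-type sum/max/min.

    Atoms are classified into the 79 standard E-state atom types; for
    each type the sum, maximum and minimum of the E-state indices of its
    atoms are reported (0 for types absent from the molecule).
    """
    type_names = estate_type_names()
    types, indices = _estate_types_and_indices(mol)
    by_type: dict[str, list[float]] = {t: [] for t in type_names}
    for atom_types, value in zip(types, indices):
        for t in atom_types:
            if t in by_type:
                by_type[t].append(float(value))
    names: list[str] = []
    values: list[float] = []
    for agg, fn in (("sum", sum), ("max", max), ("min", min)):
        for t in type_names:
            names.append(f"estate.{agg}.{t}")
            vals = by_type[t]
            values.append(float(fn(vals)) if vals else 0.0)
    return FeatureVector(names, values)


# ----------------------------- Burden (64) ---------------------------

def _burden_matrix(mol: Chem.Mol, scheme: str) -> np.ndarray:
    n = mol.GetNumAtoms()
    B = np.full((n, n), 0.001)
    deg = [a.GetDegree() for a in mol.GetAtoms()]
    for i, a in enumerate(mol.GetAtoms()):
        B[i, i] = atom_weight(a.GetAtomicNum(), scheme)
    order_value = {
        Chem.BondType.SINGLE: 0.1,
        Chem.BondType.DOUBLE: 0.2,
        Chem.BondType.TRIPLE: 0.3,
        Chem.BondType.AROMATIC: 0.15,
    }
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        v = order_value.get(b.GetBondType(), 0.1)
        if deg[i] == 1 or deg[j] == 1:
            v += 0.01
        B[i, j] = B[j, i] = v
    return B


def burden(mol: Chem.Mol) -> FeatureVector:
    """64 Burden eigenvalue descriptors.

    For each of the four atomic weightings the Burden matrix (weighted
    diagonal, bond-order off-diagonal, 0.001 elsewhere) is diagonalized
    and the 8 lowest and 8 highest eigenvalues reported; molecules with
    fewer than 8 heavy atoms pad with zeros.
    """
    names: list[str] = []
    values: list[float] = []
    n = mol.GetNumAtoms()
    for scheme in WEIGHTING_SCHEMES:
        if n == 0:
            eig = np.empty(0)
        else:
            eig = np.linalg.eigvalsh(_burden_matrix(mol, scheme))
        lowest = list(eig[:8]) + [0.0] * max(0, 8 - n)
        highest = list(eig[::-1][:8]) + [0.0] * max(0, 8 - n)
        for k in range(8):
            names.append(f"burden.low{k + 1}.{scheme}")
            values.append(float(lowest[k]))
        for k in range(8):
            names.append(f"burden.high{k + 1}.{scheme}")
            values.append(float(highest[k]))
    return FeatureVector(names, values)


# ------------------- autocorrelations (3 x 32) -----------------------

def autocorrelation_group(mol: Chem.Mol, kind: str) -> FeatureVector:
    """Topological autocorrelation over atom pairs at distance d = 1..8.

    Weights are carbon-relative atomic properties (mass, van der Waals
    volume, Sanderson electronegativity, polarizability).  For the pair
    set S_d = {(i, j): i < j, D_ij = d}:

    * ``moreau_broto``: ATS(d) = Σ_{S_d} w_i w_j
    * ``moran``:  I(d) = [mean_{S_d} (w_i − w̄)(w_j − w̄)] / [Σ(w_i − w̄)² / n]
    * ``geary``:  C(d) = [Σ_{S_d} (w_i − w_j)² / (2|S_d|)] / [Σ(w_i − w̄)² / (n−1)]

    Lags with no pairs, or zero weight variance, report 0.
    """
    if kind not in ("moreau_broto", "moran", "geary"):
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    n = mol.GetNumAtoms()
    D = distance_matrix(mol) if n else np.zeros((0, 0))
    names: list[str] = []
    values: list[float] = []
    for scheme in WEIGHTING_SCHEMES:
        w = np.array(
            [atom_weight(a.GetAtomicNum(), scheme) for a in mol.GetAtoms()]
        )
        wbar = w.mean() if n else 0.0
        dev = w - wbar
        ss = float(dev @ dev)
        for d in range(1, 9):
            pairs = (
                [(i, j) for i in range(n) for j in range(i + 1, n) if D[i, j] == d]
                if n
                else []
            )
            if not pairs:
                val = 0.0
            elif kind == "moreau_broto":
                val = sum(w[i] * w[j] for i, j in pairs)
            elif kind == "moran":
                if ss == 0:
                    val = 0.0
                else:
                    num = sum(dev[i] * dev[j] for i, j in pairs) / len(pairs)
                    val = num / (ss / n)
            else:
                if ss == 0:
                    val = 0.0
                else:
                    num = sum((w[i] - w[j]) ** 2 for i, j in pairs) / (
                        2 * len(pairs)
                    )
                    val = num / (ss / (n - 1)) if n > 1 else 0.0
            names.append(f"{kind}.{scheme}.d{d}")
            values.append(float(val))
    return FeatureVector(names, values)
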