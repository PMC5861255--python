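"""Shared graph machinery for the descriptor groups.

Everything here works on the hydrogen-suppressed heavy-atom graph:
topological distance matrices, degree vectors, Kier–Hall simple and
valence deltas, and connected-subgraph enumeration classified into the
path / cluster / path-cluster / chain shapes used by the connectivity
indices.
"""

from __future__ import annotations

import numpy as np
from rdkit import Chem

__all__ = [
    "distance_matrix",
    "degrees",
    "valence_deltas",
    "subgraph_shapes",
    "atom_paths",
]


def distance_matrix(mol: Chem.Mol) -> np.ndarray:
    """Topological (bond-count) distance matrix of the heavy-atom graph."""
    return np.asarray(Chem.GetDistanceMatrix(mol), dtype=float)


def degrees(mol: Chem.Mol) -> np.ndarray:
    """Heavy-atom connectivity degrees (Kier–Hall simple delta)."""
    return np.array([a.GetDegree() for a in mol.GetAtoms()], dtype=float)


def valence_deltas(mol: Chem.Mol) -> np.ndarray:
    """Kier–Hall valence delta: (Zv − h) / (Z − Zv − 1); Zv − h for C/H row."""
    pt = Chem.GetPeriodicTable()
    out = np.empty(mol.GetNumAtoms())
    for i, atom in enumerate(mol.GetAtoms()):
        z = atom.GetAtomicNum()
        zv = pt.GetNOuterElecs(z)
        h = atom.GetTotalNumHs()
        denom = z - zv - 1
        out[i] = (zv - h) / denom if denom > 0 else float(zv - h)
    return out


def atom_paths(mol: Chem.Mol, n_bonds: int) -> list[tuple[int, ...]]:
    """Simple paths with *n_bonds* bonds, as atom index tuples."""
    if n_bonds == 0:
        return [(i,) for i in range(mol.GetNumAtoms())]
    paths = []
    for bond_path in Chem.FindAllPathsOfLengthN(mol, n_bonds, useBonds=True):
        atoms = _bond_path_atoms(mol, bond_path)
        if atoms is not None:
            paths.append(atoms)
    return paths


def _bond_path_atoms(mol: Chem.Mol, bond_path) -> tuple[int, ...] | None:
    """Order the atoms of a bond path; None if the subgraph is not a path."""
    bonds = [mol.GetBondWithIdx(b) for b in bond_path]
    count: dict[int, int] = {}
    adj: dict[int, list[int]] = {}
    for b in bonds:
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        count[i] = count.get(i, 0) + 1
        count[j] = count.get(j, 0) + 1
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    ends = [a for a, c in count.items() if c == 1]
    if len(ends) != 2 or any(c > 2 for c in count.values()):
        return None
    # walk from one end
    walk = [ends[0]]
    prev = None
    while len(walk) < len(count):
        nxts = [x for x in adj[walk[-1]] if x != prev]
        if not nxts:
            return None
        prev = walk[-1]
        walk.append(nxts[0])
    return tuple(walk)


def subgraph_shapes(mol: Chem.Mol, n_bonds: int) -> dict[str, list[tuple[int, ...]]]:
    """Connected n-bond edge subgraphs classified by shape.

    Returns atom-index tuples keyed by ``path`` (two degree-1 ends, rest
    degree 2, acyclic), ``cluster`` (one centre, all others terminal),
    ``pathcluster`` (acyclic, max internal degree 3, both degree-1 and
    degree-2 atoms present) and ``chain`` (a pure cycle).  Subgraphs of
    other shapes are ignored, matching the usual chi-index bookkeeping.
    """
    shapes: dict[str, list[tuple[int, ...]]] = {
        "path": [], "cluster": [], "pathcluster": [], "chain": [],
    }
    for bond_ids in Chem.FindAllSubgraphsOfLengthN(mol, n_bonds):
        count: dict[int, int] = {}
        for b in bond_ids:
            bond = mol.GetBondWithIdx(b)
            for a in (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()):
                count[a] = count.get(a, 0) + 1
        atoms = tuple(count)
        degs = sorted(count.values())
        n_atoms = len(atoms)
        acyclic = n_atoms == n_bonds + 1
        if acyclic:
            if degs[-1] <= 2:
                shapes["path"].append(atoms)
            elif degs[-1] == n_bonds and all(d == 1 for d in degs[:-1]):
                shapes["cluster"].append(atoms)
            elif degs[-1] == 3:
                shapes["pathcluster"].append(atoms)
            # higher branching inside acyclic subgraphs: not a chi shape
        elif n_atoms == n_bonds and all(d == 2 for d in degs):
            shapes["chain"].append(atoms)
    return shapes
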