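"""Descriptor-group registry: names, dimensions and the 775-value vector.

The group membership is frozen here (the manifest); each entry records
the expected dimension so the 775 total stays auditable.  Groups are
computed on the sanitized heavy-atom graph; fourteen callable families
are exposed under twelve group labels (autocorrelation has three
flavours).
"""

from __future__ import annotations

from typing import Callable

from rdkit import Chem

from ..vector import FeatureVector
from .graph import MoleculeGraph
from .groups_info import autocorrelation_group, basak, burden, estate
from .groups_phys import cats, charge, moe, molproperty
from .groups_topo import connectivity, constitution, kappa, topology

__all__ = [
    "DESCRIPTOR_GROUPS",
    "descriptor_group",
    "all_descriptors",
    "descriptor_group_names",
]


def _as_mol(mol: "MoleculeGraph | Chem.Mol") -> Chem.Mol:
    return mol.mol if isinstance(mol, MoleculeGraph) else mol


#: family -> (function, expected dimension), in output order
DESCRIPTOR_GROUPS: dict[str, tuple[Callable, int]] = {
    "constitution": (constitution, 30),
    "topology": (topology, 35),
    "connectivity": (connectivity, 44),
    "estate": (estate, 237),
    "basak": (basak, 21),
    "burden": (burden, 64),
    "kappa": (kappa, 7),
    "autocorrelation_mb": (
        lambda m: autocorrelation_group(m, "moreau_broto"), 32,
    ),
    "autocorrelation_moran": (
        lambda m: autocorrelation_group(m, "moran"), 32,
    ),
    "autocorrelation_geary": (
        lambda m: autocorrelation_group(m, "geary"), 32,
    ),
    "charge": (charge, 25),
    "property": (molproperty, 6),
    "moe": (moe, 60),
    "cats": (cats, 150),
}

TOTAL_DESCRIPTORS = sum(dim for _, dim in DESCRIPTOR_GROUPS.values())  # 775


def descriptor_group_names() -> tuple[str, ...]:
    return tuple(DESCRIPTOR_GROUPS)


def descriptor_group(
    mol: "MoleculeGraph | Chem.Mol", group: str
) -> FeatureVector:
    """Compute one named descriptor group; dimension is checked."""
    if group not in DESCRIPTOR_GROUPS:
        raise ValueError(
            f"unknown descriptor group {group!r}; "
            f"available: {list(DESCRIPTOR_GROUPS)}"
        )
    fn, dim = DESCRIPTOR_GROUPS[group]
    vec = fn(_as_mol(mol))
    if len(vec) != dim:
        raise AssertionError(
            f"group {group} produced {len(vec)} values, manifest says {dim}"
        )
    return vec


def all_descriptors(mol: "MoleculeGraph | Chem.Mol") -> FeatureVector:
    """All 775 descriptors, groups concatenated in registry order."""
    return FeatureVector.concat(
        *(descriptor_group(mol, g) for g in DESCRIPTOR_GROUPS)
    )
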