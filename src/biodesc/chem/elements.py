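"""Atomic constants used as weights in graph descriptors.

Four atomic weighting schemes drive the autocorrelation and Burden
descriptors: atomic mass, van der Waals volume, Sanderson
electronegativity and atomic polarizability.  All weights are expressed
relative to carbon (w(C) = 1), the usual convention for topological
autocorrelations, so carbon-only molecules give clean reference values.
"""

from __future__ import annotations

import math

from rdkit import Chem

__all__ = ["atom_weight", "WEIGHTING_SCHEMES"]

_PT = Chem.GetPeriodicTable()

#: Sanderson electronegativities for common elements.
_SANDERSON = {
    1: 2.592, 3: 0.670, 4: 1.810, 5: 2.275, 6: 2.746, 7: 3.194, 8: 3.654,
    9: 4.000, 11: 0.560, 12: 1.318, 13: 1.714, 14: 2.138, 15: 2.515,
    16: 2.957, 17: 3.475, 19: 0.445, 20: 0.946, 26: 2.000, 29: 2.033,
    30: 2.223, 33: 2.816, 34: 3.014, 35: 3.219, 53: 2.778,
}

#: Static atomic polarizabilities (1e-24 cm^3) for common elements.
_POLARIZABILITY = {
    1: 0.666, 3: 24.3, 4: 5.60, 5: 3.03, 6: 1.76, 7: 1.10, 8: 0.802,
    9: 0.557, 11: 23.6, 12: 10.6, 13: 6.8, 14: 5.38, 15: 3.63, 16: 2.90,
    17: 2.18, 19: 43.4, 20: 22.8, 26: 8.4, 29: 6.1, 30: 7.1, 33: 4.31,
    34: 3.77, 35: 3.05, 53: 5.35,
}


def _vdw_volume(z: int) -> float:
    r = _PT.GetRvdw(z)
    return 4.0 / 3.0 * math.pi * r**3


def atom_weight(z: int, scheme: str) -> float:
    """Carbon-relative atomic weight of element *z* under a scheme."""
    if scheme == "mass":
        return _PT.GetAtomicWeight(z) / _PT.GetAtomicWeight(6)
    if scheme == "volume":
        return _vdw_volume(z) / _vdw_volume(6)
    if scheme == "electronegativity":
        return _SANDERSON.get(z, 2.2) / _SANDERSON[6]
    if scheme == "polarizability":
        return _POLARIZABILITY.get(z, 1.5) / _POLARIZABILITY[6]
    raise ValueError(f"unknown weighting scheme {scheme!r}")


WEIGHTING_SCHEMES = ("mass", "volume", "electronegativity", "polarizability")
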