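"""Physicochemical constant tables that drive the sequence descriptors.

All autocorrelation, covariance and pseudo-composition descriptors are
parameterised by per-residue (or per-oligonucleotide) property scales and
by residue-pair distance matrices.  This module defines the typed
containers for those constants, loads the versioned tables bundled under
``biodesc/data``, and standardizes them (z-score over the alphabet,
population SD) as the normalized descriptor definitions require.

Bundled residue scales: Kyte–Doolittle hydrophobicity, Hopp–Woods
hydrophilicity, side-chain mass, Bhaskaran–Ponnuswamy flexibility,
Charton polarizability, free energy of solution, Chothia accessible
surface area, Bigelow residue volume, Charton steric parameter and
Dayhoff relative mutability.

Distance matrices: Grantham's chemical distance, evaluated from his
composition/polarity/volume table with the original constants, and a
physicochemical distance built from the z-scored hydrophobicity,
hydrophilicity and side-chain-mass scales.  The latter is a synthetic
stand-in for the classic Schneider–Wrede scale (same role, same shape;
values are this package's own construction).

DNA tables: a 38-column dinucleotide and a 12-column trinucleotide
property collection (the conventional sizes for covariance descriptors).
Scales whose published values could not be sourced faithfully live in
``*_synthetic.csv`` files and carry ``synthetic`` in their names.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import json
import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, DNA_BASES

__all__ = [
    "PropertyTable",
    "DistanceMatrix",
    "AttributeGrouping",
    "OligoPropertyTable",
    "load_aa_property",
    "default_autocorrelation_properties",
    "default_pseaac_properties",
    "load_distance_matrix",
    "default_distance_matrices",
    "load_ctd_groupings",
    "load_oligo_properties",
    "read_user_property_table",
]

_STANDARD_TOL = 1e-9


def _data_path(name: str) -> Path:
    return Path(str(resources.files("biodesc").joinpath("data", name)))


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()  # population SD
    if sd == 0:
        raise ValueError("cannot standardize a constant property scale")
    return (values - values.mean()) / sd


@dataclasses.dataclass(frozen=True)
class PropertyTable:
    """A named per-residue property scale over the 20 canonical residues."""

    name: str
    values: Mapping[str, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.values)
            extra = set(self.values) - set(AMINO_ACIDS)
            raise ValueError(
                f"property table {self.name!r} must cover exactly the 20 "
                f"canonical residues (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        if self.standardized:
            arr = np.array([self.values[a] for a in AMINO_ACIDS])
            if abs(arr.mean()) > _STANDARD_TOL or abs(arr.std() - 1) > _STANDARD_TOL:
                raise ValueError(
                    f"table {self.name!r} marked standardized but is not"
                )

    def standardize(self) -> "PropertyTable":
        """Z-score over the 20 residues (population SD); idempotent."""
        if self.standardized:
            return self
        arr = np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)
        z = _zscore(arr)
        return PropertyTable(self.name, dict(zip(AMINO_ACIDS, z)), True)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """A 20x20 nonnegative residue-pair distance with zero diagonal."""

    name: str
    d: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        expect = {(a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS}
        if set(self.d) != expect:
            raise ValueError(
                f"distance matrix {self.name!r} must have 400 entries"
            )
        for (a, b), v in self.d.items():
            if v < 0:
                raise ValueError(f"negative distance {a}{b} in {self.name!r}")
        for a in AMINO_ACIDS:
            if self.d[(a, a)] != 0:
                raise ValueError(f"nonzero self-distance {a} in {self.name!r}")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.d[pair]


@dataclasses.dataclass(frozen=True)
class AttributeGrouping:
    """A partition of the 20 residues into 3 classes for one attribute."""

    attribute: str
    classes: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        union: set[str] = set()
        for cls in self.classes:
            if union & cls:
                raise ValueError(f"{self.attribute}: classes overlap")
            union |= cls
        if union != set(AMINO_ACIDS):
            raise ValueError(f"{self.attribute}: classes must cover all residues")

    def class_of(self, residue: str) -> int:
        """1-based class index of a residue."""
        for i, cls in enumerate(self.classes, start=1):
            if residue in cls:
                return i
        raise KeyError(residue)


@dataclasses.dataclass(frozen=True)
class OligoPropertyTable:
    """Per-oligonucleotide property scales (k = 2 or 3, 4**k oligos)."""

    k: int
    property_names: tuple[str, ...]
    values: Mapping[str, tuple[float, ...]]
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        expect = {"".join(p) for p in itertools.product(DNA_BASES, repeat=self.k)}
        if set(self.values) != expect:
            raise ValueError(f"expected exactly {4 ** self.k} oligo keys")
        lens = {len(v) for v in self.values.values()}
        if lens != {len(self.property_names)}:
            raise ValueError("per-oligo value vectors must match property names")
        if self.standardized:
            mat = self.matrix()
            if (np.abs(mat.mean(axis=0)) > _STANDARD_TOL).any() or (
                np.abs(mat.std(axis=0) - 1) > _STANDARD_TOL
            ).any():
                raise ValueError("table marked standardized but is not")

    @property
    def oligos(self) -> tuple[str, ...]:
        return tuple(
            "".join(p) for p in itertools.product(DNA_BASES, repeat=self.k)
        )

    def matrix(self) -> np.ndarray:
        """(4**k, n_properties) value matrix in lexicographic oligo order."""
        return np.array([self.values[o] for o in self.oligos], dtype=float)

    def standardize(self) -> "OligoPropertyTable":
        if self.standardized:
            return self
        mat = self.matrix()
        z = np.column_stack([_zscore(mat[:, j]) for j in range(mat.shape[1])])
        return OligoPropertyTable(
            self.k,
            self.property_names,
            {o: tuple(z[i]) for i, o in enumerate(self.oligos)},
            True,
        )

    def subset(self, names: Sequence[str]) -> "OligoPropertyTable":
        idx = [self.property_names.index(n) for n in names]
        return OligoPropertyTable(
            self.k,
            tuple(names),
            {o: tuple(v[i] for i in idx) for o, v in self.values.items()},
            self.standardized,
        )


# ----------------------------- loaders ------------------------------


@functools.cache
def _aa_frame() -> pd.DataFrame:
    return pd.read_csv(_data_path("aa_properties.csv"), index_col="residue")


def available_aa_properties() -> tuple[str, ...]:
    return tuple(_aa_frame().columns)


def load_aa_property(name: str, standardize: bool = True) -> PropertyTable:
    """Load one bundled residue scale, z-scored by default."""
    frame = _aa_frame()
    if name not in frame.columns:
        raise KeyError(
            f"unknown residue property {name!r}; available: {list(frame.columns)}"
        )
    table = PropertyTable(name, frame[name].to_dict())
    return table.standardize() if standardize else table


#: The classic octet driving the 8 x 30 = 240 protein autocorrelations.
AUTOCORRELATION_OCTET = (
    "hydrophobicity",
    "flexibility",
    "polarizability",
    "free_energy",
    "asa",
    "volume",
    "steric",
    "mutability",
)

#: Chou's triple for pseudo amino acid composition.
PSEAAC_TRIPLE = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


def default_autocorrelation_properties() -> list[PropertyTable]:
    return [load_aa_property(n) for n in AUTOCORRELATION_OCTET]


def default_pseaac_properties() -> list[PropertyTable]:
    return [load_aa_property(n) for n in PSEAAC_TRIPLE]


@functools.cache
def _grantham() -> DistanceMatrix:
    # Grantham's chemical distance: D(a,b) = r*sqrt(alpha dc^2 + beta dp^2
    # + gamma dv^2); constants chosen by Grantham so the mean distance is 100.
    frame = pd.read_csv(_data_path("grantham_cpv.csv"), index_col="residue")
    alpha, beta, gamma, rho = 1.833, 0.1018, 0.000399, 50.723
    d = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            dc = frame.loc[a, "composition"] - frame.loc[b, "composition"]
            dp = frame.loc[a, "polarity"] - frame.loc[b, "polarity"]
            dv = frame.loc[a, "volume"] - frame.loc[b, "volume"]
            d[(a, b)] = rho * math.sqrt(
                alpha * dc**2 + beta * dp**2 + gamma * dv**2
            )
    return DistanceMatrix("grantham", d)


@functools.cache
def _physchem_synthetic() -> DistanceMatrix:
    # Synthetic stand-in for the Schneider-Wrede scale: Euclidean distance
    # over the z-scored hydrophobicity / hydrophilicity / side-chain-mass
    # triple, normalized by the number of scales.
    props = [load_aa_property(n) for n in PSEAAC_TRIPLE]
    d = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            d[(a, b)] = math.sqrt(
                sum((p[a] - p[b]) ** 2 for p in props) / len(props)
            )
    return DistanceMatrix("physchem_synthetic", d)


def load_distance_matrix(name: str) -> DistanceMatrix:
    if name == "grantham":
        return _grantham()
    if name == "physchem_synthetic":
        return _physchem_synthetic()
    raise KeyError(
        f"unknown distance matrix {name!r}; "
        "available: ['physchem_synthetic', 'grantham']"
    )


def default_distance_matrices() -> list[DistanceMatrix]:
    """The two bundled matrices used by the sequence-order descriptors."""
    return [_physchem_synthetic(), _grantham()]


@functools.cache
def load_ctd_groupings() -> tuple[AttributeGrouping, ...]:
    """The 7 bundled 3-class physicochemical partitions, fixed order."""
    with open(_data_path("ctd_groupings.json")) as fh:
        raw = json.load(fh)
    return tuple(
        AttributeGrouping(attr, tuple(frozenset(g) for g in groups))
        for attr, groups in raw.items()
    )


@functools.cache
def load_oligo_properties(k: int, standardize: bool = True) -> OligoPropertyTable:
    """The bundled k=2 (38 scales) or k=3 (12 scales) property collection.

    Genuine scales come first; columns named ``synthetic_*`` are the
    package's seeded stand-ins (see module docstring).
    """
    if k == 2:
        names = ("dinucleotide_properties.csv", "dinucleotide_properties_synthetic.csv")
    elif k == 3:
        names = ("trinucleotide_properties.csv", "trinucleotide_properties_synthetic.csv")
    else:
        raise ValueError("k must be 2 or 3")
    frames = [pd.read_csv(_data_path(n), index_col="oligo") for n in names]
    frame = pd.concat(frames, axis=1)
    table = OligoPropertyTable(
        k,
        tuple(frame.columns),
        {o: tuple(frame.loc[o]) for o in frame.index},
    )
    return table.standardize() if standardize else table


def read_user_property_table(path: str | Path, standardize: bool = True) -> PropertyTable:
    """Read a two-column (residue, value) text table as a residue scale.

    Accepts comma or whitespace separation; requires exactly the 20
    canonical residues, once each.
    """
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'residue value'")
            res, val = parts[0].upper(), parts[1]
            if lineno == 1 and res not in AMINO_ACIDS:
                continue  # header row
            if res in values:
                raise ValueError(f"{path}:{lineno}: duplicate residue {res}")
            values[res] = float(val)
    table = PropertyTable(path.stem, values)
    return table.standardize() if standardize else table
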