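"""Molecule parsing and structure standardization.

Parsing, sanitization, aromaticity perception and SMARTS matching are
delegated to RDKit; :class:`MoleculeGraph` is a thin hydrogen-suppressed
view of the sanitized molecule that the descriptor code operates on.

Standardization applies up to ten steps, in a fixed order:

1. normalization of functional groups to consistent forms
2. recombination of separated charges (handled by the same transform set)
3. disconnection of bonds to metal atoms
4. competitive reionization (strongest acids ionize first)
5. tautomer canonicalization
6. neutralization of charges
7. removal of stereochemistry information
8. salt/solvent stripping (keep the fragment with most heavy atoms)
9. generation of the insensitive parent (fragment + isotope + charge +
   tautomer + stereo insensitive)
10. validation — flags unusual features without raising

The full preset is idempotent: standardizing twice gives the same graph.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Literal, NamedTuple

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

__all__ = [
    "MoleculeGraph",
    "ParseError",
    "StandardizationOptions",
    "parse_structure",
    "iter_structures",
    "standardize_structure",
]

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """Raised when a structure string cannot be parsed."""


class AtomView(NamedTuple):
    element: str
    formal_charge: int
    aromatic: bool
    n_hydrogens: int


class BondView(NamedTuple):
    begin: int
    end: int
    order: float  # 1, 2, 3 or 1.5 for aromatic


class MoleculeGraph:
    """Hydrogen-suppressed atom/bond view of a sanitized RDKit molecule."""

    def __init__(self, mol: Chem.Mol):
        if mol is None:
            raise ParseError("cannot build a MoleculeGraph from None")
        self._mol = mol
        self.validation_flags: tuple[str, ...] = ()

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def atoms(self) -> list[AtomView]:
        return [
            AtomView(
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetIsAromatic(),
                a.GetTotalNumHs(),
            )
            for a in self._mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[BondView]:
        order = {
            Chem.BondType.SINGLE: 1.0,
            Chem.BondType.DOUBLE: 2.0,
            Chem.BondType.TRIPLE: 3.0,
            Chem.BondType.AROMATIC: 1.5,
        }
        return [
            BondView(
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                order.get(b.GetBondType(), 1.0),
            )
            for b in self._mol.GetBonds()
        ]

    @property
    def num_heavy_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self._mol)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MoleculeGraph({self.to_smiles()!r})"


def _as_mol(mol: "MoleculeGraph | Chem.Mol") -> Chem.Mol:
    return mol.mol if isinstance(mol, MoleculeGraph) else mol


Format = Literal["smiles", "mol", "sdf", "inchi"]


def _parse_one(text: str, fmt: Format) -> Chem.Mol:
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif fmt in ("mol", "sdf"):
        mol = Chem.MolFromMolBlock(text)
    elif fmt == "inchi":
        mol = Chem.MolFromInchi(text)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if mol is None:
        raise ParseError(f"could not parse {fmt} input: {text[:80]!r}")
    return mol


def parse_structure(text: str, format: Format = "smiles") -> MoleculeGraph:
    """Parse one structure; for multi-record SDF text the first record."""
    if not text or not text.strip():
        raise ParseError("empty structure input")
    if format == "sdf" and "$$$$" in text:
        text = text.split("$$$$")[0]
    return MoleculeGraph(_parse_one(text, format))


def iter_structures(path: str, format: Format = "sdf") -> Iterator[MoleculeGraph]:
    """Iterate the structures of a file (SDF multi-record, or one per line
    for SMILES/InChI; optional tab-separated identifier is ignored)."""
    if format == "sdf":
        for mol in Chem.SDMolSupplier(str(path)):
            if mol is not None:
                yield MoleculeGraph(mol)
        return
    if format == "mol":
        with open(path) as fh:
            yield parse_structure(fh.read(), "mol")
        return
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield parse_structure(line.split("\t")[0].split()[0], format)


@dataclasses.dataclass(frozen=True)
class StandardizationOptions:
    """Independently toggleable flags for the ten pretreatment steps."""

    normalize: bool = True
    reconnect_charges: bool = True
    disconnect_metals: bool = True
    reionize: bool = True
    canonicalize_tautomer: bool = True
    neutralize: bool = True
    strip_stereo: bool = True
    largest_fragment: bool = True
    insensitive_parent: bool = True
    validate: bool = True

    @classmethod
    def none(cls) -> "StandardizationOptions":
        return cls(**{f.name: False for f in dataclasses.fields(cls)})


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumAtoms())


def _validate(mol: Chem.Mol) -> tuple[str, ...]:
    flags = []
    if mol.GetNumAtoms() == 0:
        flags.append("no_atoms")
    if len(Chem.GetMolFrags(mol)) > 1:
        flags.append("multiple_fragments")
    if any(a.GetIsotope() for a in mol.GetAtoms()):
        flags.append("isotopes_present")
    if any(a.GetFormalCharge() for a in mol.GetAtoms()):
        flags.append("net_or_local_charges")
    if any(a.GetAtomicNum() not in _ORGANIC_SUBSET for a in mol.GetAtoms()):
        flags.append("non_organic_elements")
    if mol.GetNumAtoms() > 0 and not any(
        a.GetAtomicNum() == 6 for a in mol.GetAtoms()
    ):
        flags.append("no_carbon")
    return tuple(flags)


_ORGANIC_SUBSET = frozenset({1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53})


def standardize_structure(
    mol: "MoleculeGraph | Chem.Mol",
    opts: StandardizationOptions | None = None,
) -> MoleculeGraph:
    """Apply the enabled pretreatment steps in their listed order."""
    opts = opts or StandardizationOptions()
    m = Chem.Mol(_as_mol(mol))
    try:
        if opts.normalize or opts.reconnect_charges:
            # the normalizer's transform set includes the charge
            # recombination patterns, so both flags route here
            m = rdMolStandardize.Normalize(m)
        if opts.disconnect_metals:
            m = rdMolStandardize.MetalDisconnector().Disconnect(m)
        if opts.reionize:
            m = rdMolStandardize.Reionize(m)
        if opts.largest_fragment:
            # strip salts/solvents before tautomer/charge work so the
            # parent fragment drives those steps
            m = _largest_fragment(m)
        if opts.canonicalize_tautomer:
            m = rdMolStandardize.TautomerEnumerator().Canonicalize(m)
        if opts.neutralize:
            m = rdMolStandardize.Uncharger().uncharge(m)
        if opts.strip_stereo:
            Chem.RemoveStereochemistry(m)
        if opts.insensitive_parent:
            for atom in m.GetAtoms():
                atom.SetIsotope(0)
            m = _largest_fragment(m)
        Chem.SanitizeMol(m)
    except ParseError:
        raise
    except Exception as exc:  # broken valence after an operation
        raise ValueError(f"standardization failed: {exc}") from exc
    out = MoleculeGraph(m)
    if opts.validate:
        out.validation_flags = _validate(m)
    return out
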