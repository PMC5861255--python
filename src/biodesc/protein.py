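"""Protein sequence descriptors.

Implements the five classic feature groups for a canonical amino-acid
sequence of length L (1-based positions R_1 … R_L):

* k-mer compositions (k = 1, 2, 3): counts of each of the 20**k words over
  the L−k+1 sliding windows, divided by the window count.
* Three lagged autocorrelations (normalized Moreau–Broto, Moran, Geary)
  of z-scored physicochemical scales, lags 1..maxlag.
* CTD — composition, transition, distribution over 3-class partitions of
  the alphabet for 7 physicochemical attributes.
* Conjoint-triad counts over a 7-class electrostatic/volume alphabet.
* Sequence-order descriptors: coupling numbers τ_d = Σ_i d(R_i, R_{i+d})²,
  the quasi-sequence-order vector, and Chou's pseudo amino acid
  composition in its standard and amphiphilic forms.

All functions accept a raw string (validated and cleaned on entry) and
return a :class:`~biodesc.vector.FeatureVector` with stable names, so the
concatenation :func:`protein_all` is well-defined and reproducible.
"""

from __future__ import annotations

import itertools
from typing import Literal, Sequence

import numpy as np

from .seqio import AMINO_ACIDS, clean_protein
from .tables import (
    AttributeGrouping,
    DistanceMatrix,
    PropertyTable,
    default_autocorrelation_properties,
    default_distance_matrices,
    default_pseaac_properties,
    load_aa_property,
    load_ctd_groupings,
)
from .vector import FeatureVector

__all__ = [
    "peptide_composition",
    "autocorrelation",
    "ctd",
    "conjoint_triad",
    "socn",
    "qso",
    "pseaac",
    "apseaac",
    "protein_all",
    "CONJOINT_TRIAD_CLASSES",
]

DEFAULT_MAXLAG = 30
DEFAULT_QSO_WEIGHT = 0.1
DEFAULT_PSEAAC_WEIGHT = 0.05
DEFAULT_PSEAAC_LAMBDA = 30
DEFAULT_APSEAAC_LAMBDA = 15

#: Conjoint-triad residue classes (dipole / side-chain volume clusters).
CONJOINT_TRIAD_CLASSES: tuple[frozenset, ...] = (
    frozenset("AGV"),
    frozenset("ILFP"),
    frozenset("YMTS"),
    frozenset("HNQW"),
    frozenset("RK"),
    frozenset("DE"),
    frozenset("C"),
)


def peptide_composition(seq: str, k: Literal[1, 2, 3] = 1) -> FeatureVector:
    """Normalized k-mer composition (k=1: 20, k=2: 400, k=3: 8000 values).

    Value for word w = count(w) / (L − k + 1); entries sum to 1.
    """
    seq = clean_protein(seq)
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    words = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=k)]
    index = {w: i for i, w in enumerate(words)}
    counts = np.zeros(len(words))
    for i in range(L - k + 1):
        counts[index[seq[i : i + k]]] += 1
    return FeatureVector(words, counts / (L - k + 1))


def _property_series(seq: str, prop: PropertyTable) -> np.ndarray:
    return np.array([prop[a] for a in seq], dtype=float)


def autocorrelation(
    seq: str,
    kind: Literal["moreau_broto", "moran", "geary"],
    properties: Sequence[PropertyTable] | None = None,
    maxlag: int = DEFAULT_MAXLAG,
) -> FeatureVector:
    """Lagged autocorrelation of physicochemical scales along the chain.

    With P the z-scored per-residue property, sequence mean P̄ and lag d:

    * ``moreau_broto``: ATS(d) = Σ_{i=1}^{L−d} P_i P_{i+d} / (L − d)
    * ``moran``:  I(d) = [Σ (P_i−P̄)(P_{i+d}−P̄)/(L−d)] / [Σ (P_i−P̄)²/L]
    * ``geary``:  C(d) = [Σ (P_i−P_{i+d})²/(2(L−d))] / [Σ (P_i−P̄)²/(L−1)]

    Moran/Geary are undefined on a zero-variance sequence (homopolymer);
    those entries are reported as 0.0 so vectors stay finite.
    Defaults (8 scales, maxlag 30) give 240 values.
    """
    seq = clean_protein(seq)
    if kind not in ("moreau_broto", "moran", "geary"):
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    if properties is None:
        properties = default_autocorrelation_properties()
    if maxlag < 1:
        raise ValueError("maxlag must be >= 1")
    L = len(seq)
    if maxlag >= L:
        raise ValueError(f"maxlag {maxlag} must be < sequence length {L}")
    names: list[str] = []
    values: list[float] = []
    for prop in properties:
        prop = prop.standardize()
        p = _property_series(seq, prop)
        pbar = p.mean()
        dev = p - pbar
        # a constant series has no variance; the mean subtraction can
        # leave rounding residue, so detect degeneracy from the range
        ss = 0.0 if np.ptp(p) == 0 else float(dev @ dev)
        for d in range(1, maxlag + 1):
            head, tail = p[: L - d], p[d:]
            if kind == "moreau_broto":
                val = float(head @ tail) / (L - d)
            elif kind == "moran":
                if ss == 0:
                    val = 0.0
                else:
                    num = float(dev[: L - d] @ dev[d:]) / (L - d)
                    val = num / (ss / L)
            else:  # geary
                if ss == 0:
                    val = 0.0
                else:
                    num = float(((head - tail) ** 2).sum()) / (2 * (L - d))
                    val = num / (ss / (L - 1))
            names.append(f"{kind}.{prop.name}.lag{d}")
            values.append(val)
    return FeatureVector(names, values)


def _distribution_positions(positions: list[int], L: int) -> list[float]:
    """CTD distribution block for one class: 5 position percentiles.

    ``positions`` are the 1-based occurrence positions of the class.  The
    reported values are the positions of the first occurrence and of the
    ⌈q·n⌉-th occurrence for q = 25/50/75/100 %, each divided by L and
    scaled to a percentage; an absent class reports five zeros.
    """
    if not positions:
        return [0.0] * 5
    n = len(positions)
    out = [positions[0] / L * 100.0]
    for q in (0.25, 0.5, 0.75, 1.0):
        idx = max(1, int(np.ceil(q * n)))
        out.append(positions[idx - 1] / L * 100.0)
    return out


def ctd(
    seq: str, groupings: Sequence[AttributeGrouping] | None = None
) -> FeatureVector:
    """Composition/Transition/Distribution features (21 + 21 + 105 = 147).

    Per attribute the sequence is recoded into 3 classes; composition is
    the class fraction, transition T(r,s) = (N_rs + N_sr)/(L−1) for the 3
    unordered class pairs, and distribution locates the 1st/25%/50%/75%/
    100% occurrence of each class as a percentage of L.
    """
    seq = clean_protein(seq)
    if groupings is None:
        groupings = load_ctd_groupings()
    if len(groupings) < 7:
        raise ValueError(
            f"need 7 attribute groupings, got {len(groupings)}"
        )
    L = len(seq)
    if L < 2:
        raise ValueError("CTD needs sequence length >= 2")
    comp_names: list[str] = []
    comp_vals: list[float] = []
    trans_names: list[str] = []
    trans_vals: list[float] = []
    dist_names: list[str] = []
    dist_vals: list[float] = []
    for g in groupings:
        coded = [g.class_of(a) for a in seq]
        for c in (1, 2, 3):
            comp_names.append(f"ctd.composition.{g.attribute}.c{c}")
            comp_vals.append(coded.count(c) / L)
        for r, s in ((1, 2), (1, 3), (2, 3)):
            n_rs = sum(
                1
                for i in range(L - 1)
                if {coded[i], coded[i + 1]} == {r, s}
            )
            trans_names.append(f"ctd.transition.{g.attribute}.c{r}{s}")
            trans_vals.append(n_rs / (L - 1))
        for c in (1, 2, 3):
            positions = [i + 1 for i, x in enumerate(coded) if x == c]
            block = _distribution_positions(positions, L)
            for label, v in zip(("first", "p25", "p50", "p75", "p100"), block):
                dist_names.append(f"ctd.distribution.{g.attribute}.c{c}.{label}")
                dist_vals.append(v)
    return FeatureVector(
        comp_names + trans_names + dist_names,
        comp_vals + trans_vals + dist_vals,
    )


def conjoint_triad(seq: str) -> FeatureVector:
    """Raw counts of the 343 conjoint-triad classes over L−2 windows."""
    seq = clean_protein(seq)
    L = len(seq)
    if L < 3:
        raise ValueError("conjoint triad needs sequence length >= 3")
    class_of = {}
    for ci, cls in enumerate(CONJOINT_TRIAD_CLASSES, start=1):
        for a in cls:
            class_of[a] = ci
    counts = np.zeros(343)
    for i in range(L - 2):
        c1, c2, c3 = (class_of[a] for a in seq[i : i + 3])
        counts[(c1 - 1) * 49 + (c2 - 1) * 7 + (c3 - 1)] += 1
    names = [
        f"ct.{c1}{c2}{c3}"
        for c1 in range(1, 8)
        for c2 in range(1, 8)
        for c3 in range(1, 8)
    ]
    return FeatureVector(names, counts)


def _coupling_numbers(
    seq: str, matrix: DistanceMatrix, maxlag: int
) -> np.ndarray:
    L = len(seq)
    return np.array(
        [
            sum(matrix[seq[i], seq[i + d]] ** 2 for i in range(L - d))
            for d in range(1, maxlag + 1)
        ]
    )


def socn(
    seq: str,
    matrices: Sequence[DistanceMatrix] | None = None,
    maxlag: int = DEFAULT_MAXLAG,
) -> FeatureVector:
    """Sequence-order coupling numbers τ_d = Σ_i d(R_i, R_{i+d})².

    With the two bundled matrices and maxlag 30 the vector has 60 values.
    """
    seq = clean_protein(seq)
    if matrices is None:
        matrices = default_distance_matrices()
    L = len(seq)
    if maxlag >= L:
        raise ValueError(f"maxlag {maxlag} must be < sequence length {L}")
    names: list[str] = []
    values: list[float] = []
    for m in matrices:
        tau = _coupling_numbers(seq, m, maxlag)
        names.extend(f"socn.{m.name}.d{d}" for d in range(1, maxlag + 1))
        values.extend(tau)
    return FeatureVector(names, values)


def qso(
    seq: str,
    matrices: Sequence[DistanceMatrix] | None = None,
    maxlag: int = DEFAULT_MAXLAG,
    w: float = DEFAULT_QSO_WEIGHT,
) -> FeatureVector:
    """Quasi-sequence-order descriptors (per matrix: 20 + maxlag values).

    First 20: f_r / (Σ_s f_s + w Σ_d τ_d); remaining maxlag values:
    w τ_d / (same denominator).  Each per-matrix block sums to 1.
    """
    seq = clean_protein(seq)
    if w <= 0:
        raise ValueError("w must be positive")
    if matrices is None:
        matrices = default_distance_matrices()
    L = len(seq)
    if maxlag >= L:
        raise ValueError(f"maxlag {maxlag} must be < sequence length {L}")
    freqs = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    names: list[str] = []
    values: list[float] = []
    for m in matrices:
        tau = _coupling_numbers(seq, m, maxlag)
        denom = freqs.sum() + w * tau.sum()
        names.extend(f"qso.{m.name}.{a}" for a in AMINO_ACIDS)
        values.extend(freqs / denom)
        names.extend(f"qso.{m.name}.tau{d}" for d in range(1, maxlag + 1))
        values.extend(w * tau / denom)
    return FeatureVector(names, values)


def pseaac(
    seq: str,
    lam: int = DEFAULT_PSEAAC_LAMBDA,
    w: float = DEFAULT_PSEAAC_WEIGHT,
    properties: Sequence[PropertyTable] | None = None,
) -> FeatureVector:
    """Chou's pseudo amino acid composition (20 + λ values, default 50).

    Correlation factors θ_j = (1/(L−j)) Σ_i Θ(R_i, R_{i+j}) where Θ(a,b)
    is the mean squared difference of the z-scored property values over
    the property set (default: hydrophobicity, hydrophilicity, side-chain
    mass).  Output entries are f_r and w θ_j over the common denominator
    Σf + w Σθ, so the whole vector sums to 1.
    """
    seq = clean_protein(seq)
    if w <= 0:
        raise ValueError("w must be positive")
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if properties is None:
        properties = default_pseaac_properties()
    properties = [p.standardize() for p in properties]
    L = len(seq)
    if lam >= L:
        raise ValueError(f"lambda {lam} must be < sequence length {L}")
    series = [_property_series(seq, p) for p in properties]
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = [((s[: L - j] - s[j:]) ** 2) for s in series]
        theta[j - 1] = float(np.mean(diffs, axis=0).sum()) / (L - j)
    freqs = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    denom = freqs.sum() + w * theta.sum()
    names = [f"pseaac.{a}" for a in AMINO_ACIDS] + [
        f"pseaac.theta{j}" for j in range(1, lam + 1)
    ]
    values = np.concatenate([freqs / denom, w * theta / denom])
    return FeatureVector(names, values)


def apseaac(
    seq: str,
    lam: int = DEFAULT_APSEAAC_LAMBDA,
    w: float = DEFAULT_PSEAAC_WEIGHT,
) -> FeatureVector:
    """Amphiphilic pseudo amino acid composition (20 + 2λ, default 50).

    Per lag j the hydrophobicity and hydrophilicity correlations are kept
    separate: τ_{2(j−1)+u} = (1/(L−j)) Σ_i H_u(R_i) H_u(R_{i+j}) for the
    two z-scored scales u, giving 2λ pseudo components.
    """
    seq = clean_protein(seq)
    if w <= 0:
        raise ValueError("w must be positive")
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    L = len(seq)
    if lam >= L:
        raise ValueError(f"lambda {lam} must be < sequence length {L}")
    scales = [
        load_aa_property("hydrophobicity"),
        load_aa_property("hydrophilicity"),
    ]
    series = [_property_series(seq, p) for p in scales]
    tau = np.empty(2 * lam)
    tau_names = []
    for j in range(1, lam + 1):
        for u, (p, s) in enumerate(zip(scales, series)):
            tau[2 * (j - 1) + u] = float(s[: L - j] @ s[j:]) / (L - j)
            tau_names.append(f"apseaac.tau.{p.name}.lag{j}")
    freqs = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    denom = freqs.sum() + w * tau.sum()
    if denom == 0:
        raise ValueError("degenerate APAAC normalization (zero denominator)")
    names = [f"apseaac.{a}" for a in AMINO_ACIDS] + tau_names
    values = np.concatenate([freqs / denom, w * tau / denom])
    return FeatureVector(names, values)


#: (family name, minimum sequence length required at defaults)
_ALL_FAMILIES = (
    ("aac", 1),
    ("dpc", 2),
    ("tpc", 3),
    ("moreau_broto", DEFAULT_MAXLAG + 1),
    ("moran", DEFAULT_MAXLAG + 1),
    ("geary", DEFAULT_MAXLAG + 1),
    ("ctd", 2),
    ("conjoint_triad", 3),
    ("socn", DEFAULT_MAXLAG + 1),
    ("qso", DEFAULT_MAXLAG + 1),
    ("pseaac", DEFAULT_PSEAAC_LAMBDA + 1),
    ("apseaac", DEFAULT_APSEAAC_LAMBDA + 1),
)


def compute_family(seq: str, family: str, **params) -> FeatureVector:
    """Compute one named protein feature family (CLI entry point)."""
    if family == "aac":
        return peptide_composition(seq, 1)
    if family == "dpc":
        return peptide_composition(seq, 2)
    if family == "tpc":
        return peptide_composition(seq, 3)
    if family in ("moreau_broto", "moran", "geary"):
        return autocorrelation(seq, family, **params)
    if family == "ctd":
        return ctd(seq, **params)
    if family == "conjoint_triad":
        return conjoint_triad(seq)
    if family == "socn":
        return socn(seq, **params)
    if family == "qso":
        return qso(seq, **params)
    if family == "pseaac":
        return pseaac(seq, **params)
    if family == "apseaac":
        return apseaac(seq, **params)
    raise ValueError(
        f"unknown protein family {family!r}; "
        f"available: {[f for f, _ in _ALL_FAMILIES]}"
    )


def protein_families() -> tuple[str, ...]:
    return tuple(f for f, _ in _ALL_FAMILIES)


def protein_all(seq: str) -> FeatureVector:
    """All families at their defaults, concatenated in a fixed order.

    Requires L > 30 (the largest default lag); the error message names
    the limiting family.  Total dimension at defaults: 9890.
    """
    cleaned = clean_protein(seq)
    L = len(cleaned)
    for family, min_len in _ALL_FAMILIES:
        if L < min_len:
            raise ValueError(
                f"sequence length {L} too short for family {family!r} "
                f"(needs >= {min_len})"
            )
    parts = [compute_family(cleaned, family) for family, _ in _ALL_FAMILIES]
    # aac/dpc/tpc names are bare words; prefix to keep global uniqueness
    parts[0] = parts[0].prefixed("aac.")
    parts[1] = parts[1].prefixed("dpc.")
    parts[2] = parts[2].prefixed("tpc.")
    return FeatureVector.concat(*parts)
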