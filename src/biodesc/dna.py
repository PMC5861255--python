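"""DNA sequence descriptors.

Three families over a canonical A/C/G/T sequence of length L:

* k-mer composition, optionally collapsing each word with its reverse
  complement ("canonical" counting) and optionally normalized by the
  number of windows.
* Auto / cross covariance of z-scored oligonucleotide property series:
  with P_u(i) the property-u value of the k-mer starting at position i
  and P̄_u its mean over all L−k+1 windows,

      AC(u, d)      = Σ_{i=1}^{L−k−d+1} (P_u(i) − P̄_u)(P_u(i+d) − P̄_u) / (L−k−d+1)
      CC(u1, u2, d) = Σ_{i=1}^{L−k−d+1} (P_u1(i) − P̄_u1)(P_u2(i+d) − P̄_u2) / (L−k−d+1)

  Cross covariance iterates ordered property pairs u1 ≠ u2.  With the
  bundled 38 dinucleotide scales and maxlag 2 this yields 76 (auto),
  2812 (cross) and 2888 (auto-cross) values; the 12 trinucleotide scales
  give 24 / 264 / 288.
* Pseudo nucleotide composition: 4**k oligo frequencies plus λ global
  correlation factors, jointly normalized.  "Parallel" correlation
  averages the squared property difference over all scales per lag;
  "series" keeps one product-correlation factor per (property, lag).

Only the forward strand is scanned; reverse complements play a role only
in canonical k-mer counting.
"""

from __future__ import annotations

import itertools
from typing import Literal

import numpy as np

from .seqio import DNA_BASES, clean_dna
from .tables import OligoPropertyTable, load_oligo_properties
from .vector import FeatureVector

__all__ = [
    "reverse_complement",
    "kmer_index",
    "kmer_composition",
    "covariance",
    "pse_composition",
    "dna_all",
]

DEFAULT_COV_MAXLAG = 2
DEFAULT_PSE_LAMBDA = 2
DEFAULT_PSE_WEIGHT = 0.05

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(DNA_BASES, repeat=k)]


def kmer_index(k: int, canonical: bool = False) -> list[str]:
    """Ordered k-mer labels; canonical mode merges reverse complements.

    A canonical class is labelled by its lexicographically smaller member
    (palindromic words map to themselves), so canonical k=2 has 10
    classes and canonical k=3 has 32.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not canonical:
        return _all_kmers(k)
    seen: list[str] = []
    for w in _all_kmers(k):
        rep = min(w, reverse_complement(w))
        if rep not in seen:
            seen.append(rep)
    return seen


def kmer_composition(
    seq: str, k: int = 2, canonical: bool = False, normalize: bool = True
) -> FeatureVector:
    """Sliding-window k-mer counts (or frequencies if ``normalize``)."""
    seq = clean_dna(seq)
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    labels = kmer_index(k, canonical)
    index = {w: i for i, w in enumerate(labels)}
    if canonical:
        for w in _all_kmers(k):
            index[w] = index[min(w, reverse_complement(w))]
    counts = np.zeros(len(labels))
    for i in range(L - k + 1):
        counts[index[seq[i : i + k]]] += 1
    if normalize:
        counts = counts / (L - k + 1)
    prefix = "rckmer" if canonical else "kmer"
    return FeatureVector([f"{prefix}{k}.{w}" for w in labels], counts)


def _property_profiles(seq: str, props: OligoPropertyTable) -> np.ndarray:
    """(n_windows, n_properties) property series along the sequence."""
    k = props.k
    oligo_pos = {o: i for i, o in enumerate(props.oligos)}
    mat = props.matrix()
    rows = [mat[oligo_pos[seq[i : i + k]]] for i in range(len(seq) - k + 1)]
    return np.array(rows)


def covariance(
    seq: str,
    k: Literal[2, 3] = 2,
    mode: Literal["auto", "cross", "autocross"] = "auto",
    props: OligoPropertyTable | None = None,
    maxlag: int = DEFAULT_COV_MAXLAG,
) -> FeatureVector:
    """Auto / cross covariance of oligonucleotide property series."""
    seq = clean_dna(seq)
    if mode not in ("auto", "cross", "autocross"):
        raise ValueError(f"unknown covariance mode {mode!r}")
    if props is None:
        props = load_oligo_properties(k)
    if props.k != k:
        raise ValueError(f"property table has k={props.k}, expected {k}")
    props = props.standardize()
    n_props = len(props.property_names)
    if mode in ("cross", "autocross") and n_props < 2:
        raise ValueError("cross covariance needs at least two properties")
    L = len(seq)
    if L < k + maxlag + 1:
        raise ValueError(
            f"sequence length {L} too short for k={k}, maxlag={maxlag}"
        )
    profile = _property_profiles(seq, props)  # (W, n_props)
    dev = profile - profile.mean(axis=0)
    W = profile.shape[0]
    names: list[str] = []
    values: list[float] = []
    tag = "dac" if k == 2 else "tac"
    ctag = "dcc" if k == 2 else "tcc"
    if mode in ("auto", "autocross"):
        for u, pname in enumerate(props.property_names):
            for d in range(1, maxlag + 1):
                cov = float(dev[: W - d, u] @ dev[d:, u]) / (W - d)
                names.append(f"{tag}.{pname}.lag{d}")
                values.append(cov)
    if mode in ("cross", "autocross"):
        for u1, p1 in enumerate(props.property_names):
            for u2, p2 in enumerate(props.property_names):
                if u1 == u2:
                    continue
                for d in range(1, maxlag + 1):
                    cov = float(dev[: W - d, u1] @ dev[d:, u2]) / (W - d)
                    names.append(f"{ctag}.{p1}.{p2}.lag{d}")
                    values.append(cov)
    return FeatureVector(names, values)


def pse_composition(
    seq: str,
    k: Literal[2, 3] = 2,
    lam: int = DEFAULT_PSE_LAMBDA,
    w: float = DEFAULT_PSE_WEIGHT,
    props: OligoPropertyTable | None = None,
    correlation: Literal["parallel", "series"] = "parallel",
) -> FeatureVector:
    """Pseudo k-tuple nucleotide composition (Chou-normalized).

    parallel: λ factors θ_j = mean_i Θ(i, i+j) with Θ the mean squared
    z-scored property difference over all scales; dimension 4**k + λ.
    series: one factor per (lag, property) using the property product,
    dimension 4**k + λ·Λ for Λ scales.  Either way the frequency block
    and the w-weighted factors share one denominator, so the full vector
    sums to 1 (entries are nonnegative whenever the factors are, which
    always holds for parallel mode).
    """
    seq = clean_dna(seq)
    if w <= 0:
        raise ValueError("w must be positive")
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    if correlation not in ("parallel", "series"):
        raise ValueError(f"unknown correlation mode {correlation!r}")
    if props is None:
        props = load_oligo_properties(k)
    if props.k != k:
        raise ValueError(f"property table has k={props.k}, expected {k}")
    props = props.standardize()
    L = len(seq)
    if L < k + lam:
        raise ValueError(
            f"sequence length {L} too short for k={k}, lambda={lam}"
        )
    profile = _property_profiles(seq, props)  # (W, n_props)
    W = profile.shape[0]
    factors: list[float] = []
    factor_names: list[str] = []
    mode_tag = "pc" if correlation == "parallel" else "sc"
    if correlation == "parallel":
        for j in range(1, lam + 1):
            sq = (profile[: W - j] - profile[j:]) ** 2
            factors.append(float(sq.mean(axis=1).sum()) / (W - j))
            factor_names.append(f"pse{k}.{mode_tag}.theta{j}")
    else:
        for j in range(1, lam + 1):
            for u, pname in enumerate(props.property_names):
                factors.append(
                    float(profile[: W - j, u] @ profile[j:, u]) / (W - j)
                )
                factor_names.append(f"pse{k}.{mode_tag}.tau.{pname}.lag{j}")
    factors_arr = np.array(factors)
    labels = _all_kmers(k)
    index = {o: i for i, o in enumerate(labels)}
    counts = np.zeros(len(labels))
    for i in range(W):
        counts[index[seq[i : i + k]]] += 1
    freqs = counts / W
    denom = freqs.sum() + w * factors_arr.sum()
    if denom == 0:
        raise ValueError("degenerate pseudo-composition normalization")
    names = [f"pse{k}.{mode_tag}.{o}" for o in labels] + factor_names
    values = np.concatenate([freqs / denom, w * factors_arr / denom])
    return FeatureVector(names, values)


#: (family, callable kwargs, minimum length at defaults)
_ALL_FAMILIES: tuple[tuple[str, dict, int], ...] = (
    ("kmer2", dict(k=2), 2),
    ("rckmer2", dict(k=2, canonical=True), 2),
    ("dac", dict(k=2, mode="auto"), 5),
    ("dcc", dict(k=2, mode="cross"), 5),
    ("dacc", dict(k=2, mode="autocross"), 5),
    ("tac", dict(k=3, mode="auto"), 6),
    ("tcc", dict(k=3, mode="cross"), 6),
    ("tacc", dict(k=3, mode="autocross"), 6),
    ("psednc", dict(k=2, correlation="parallel"), 4),
    ("pc_psetnc", dict(k=3, correlation="parallel"), 5),
    ("sc_psednc", dict(k=2, correlation="series"), 4),
    ("sc_psetnc", dict(k=3, correlation="series"), 5),
)


def dna_families() -> tuple[str, ...]:
    return tuple(f for f, _, _ in _ALL_FAMILIES)


def compute_family(seq: str, family: str, **params) -> FeatureVector:
    """Compute one named DNA feature family (CLI entry point)."""
    for name, kwargs, _ in _ALL_FAMILIES:
        if family == name:
            merged = {**kwargs, **params}
            if name in ("kmer2", "rckmer2"):
                return kmer_composition(seq, **merged)
            if name in ("dac", "dcc", "dacc", "tac", "tcc", "tacc"):
                return covariance(seq, **merged)
            return pse_composition(seq, **merged)
    raise ValueError(
        f"unknown DNA family {family!r}; available: {list(dna_families())}"
    )


def dna_all(seq: str) -> FeatureVector:
    """All DNA families at defaults, fixed order (6642 values, L >= 10)."""
    cleaned = clean_dna(seq)
    L = len(cleaned)
    for family, _, min_len in _ALL_FAMILIES:
        if L < min_len:
            raise ValueError(
                f"sequence length {L} too short for family {family!r} "
                f"(needs >= {min_len})"
            )
    parts = [compute_family(cleaned, family) for family, _, _ in _ALL_FAMILIES]
    # dac/tac names repeat inside dacc/tacc; prefix per family for uniqueness
    return FeatureVector.concat(
        *[p.prefixed(f"{fam}:") for (fam, _, _), p in zip(_ALL_FAMILIES, parts)]
    )
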