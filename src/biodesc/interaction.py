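"""Interaction features for pairwise samples.

Given per-molecule descriptor vectors, five strategies build a single
feature vector for the pair.  For two molecules of the *same* type with
vectors F_a, F_b of common length p:

* ``concat``  — both orderings are produced: F_ab = (F_a, F_b) and
  F_ba = (F_b, F_a), each of dimension 2p.
* ``sumprod`` — {F_a(i) + F_b(i)} followed by {F_a(i) × F_b(i)}
  (block-concatenated), dimension 2p; symmetric in the operands.
* ``tensor``  — F(k) = F_a(i) × F_b(j) with k = (i−1)·p + j, dimension p².

For two molecules of *different* types (F_t of length p_t, F_d of p_d):

* ``concat`` — (F_t, F_d), dimension p_t + p_d.
* ``tensor`` — F(k) = F_t(i) × F_d(j), row-major k = (i−1)·p_d + j,
  dimension p_t · p_d.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .vector import FeatureVector

__all__ = ["PairFeature", "combine_same", "combine_cross"]

SAME_STRATEGIES = ("concat", "sumprod", "tensor")
CROSS_STRATEGIES = ("concat", "tensor")


@dataclasses.dataclass(frozen=True)
class PairFeature:
    """An interaction vector plus provenance of how it was built."""

    values: FeatureVector
    strategy: Literal[
        "same_concat", "same_sumprod", "same_tensor",
        "cross_concat", "cross_tensor",
    ]
    operand_a_name: str
    operand_b_name: str
    p_a: int
    p_b: int

    def __post_init__(self) -> None:
        expected = {
            "same_concat": self.p_a + self.p_b,
            "same_sumprod": 2 * self.p_a,
            "same_tensor": self.p_a * self.p_b,
            "cross_concat": self.p_a + self.p_b,
            "cross_tensor": self.p_a * self.p_b,
        }[self.strategy]
        if len(self.values) != expected:
            raise ValueError(
                f"{self.strategy}: dimension {len(self.values)} != {expected}"
            )

    def __len__(self) -> int:
        return len(self.values)


def _tensor(fa: FeatureVector, fb: FeatureVector, tag_a: str, tag_b: str) -> FeatureVector:
    outer = np.outer(fa.values, fb.values).ravel()  # row-major: k=(i-1)*p_b+j
    names = [
        f"{tag_a}.{na}*{tag_b}.{nb}" for na in fa.names for nb in fb.names
    ]
    return FeatureVector(names, outer)


def combine_same(
    fa: FeatureVector,
    fb: FeatureVector,
    strategy: Literal["concat", "sumprod", "tensor"],
    name_a: str = "a",
    name_b: str = "b",
) -> PairFeature | tuple[PairFeature, PairFeature]:
    """Combine two same-type vectors; ``concat`` returns both orderings."""
    if strategy not in SAME_STRATEGIES:
        raise ValueError(
            f"unknown same-type strategy {strategy!r}; available: {SAME_STRATEGIES}"
        )
    if len(fa) != len(fb):
        raise ValueError(
            f"same-type operands must share dimension: {len(fa)} != {len(fb)}"
        )
    if len(fa) < 1:
        raise ValueError("operands must be non-empty")
    p = len(fa)
    if strategy == "concat":
        f_ab = FeatureVector.concat(fa.prefixed("a."), fb.prefixed("b."))
        f_ba = FeatureVector.concat(fb.prefixed("a."), fa.prefixed("b."))
        return (
            PairFeature(f_ab, "same_concat", name_a, name_b, p, p),
            PairFeature(f_ba, "same_concat", name_b, name_a, p, p),
        )
    if strategy == "sumprod":
        vec = FeatureVector(
            [f"sum.{n}" for n in fa.names] + [f"prod.{n}" for n in fa.names],
            np.concatenate([fa.values + fb.values, fa.values * fb.values]),
        )
        return PairFeature(vec, "same_sumprod", name_a, name_b, p, p)
    return PairFeature(
        _tensor(fa, fb, "a", "b"), "same_tensor", name_a, name_b, p, p
    )


def combine_cross(
    ft: FeatureVector,
    fd: FeatureVector,
    strategy: Literal["concat", "tensor"],
    name_t: str = "t",
    name_d: str = "d",
) -> PairFeature:
    """Combine two different-type vectors (lengths may differ)."""
    if strategy not in CROSS_STRATEGIES:
        raise ValueError(
            f"unknown cross-type strategy {strategy!r}; available: {CROSS_STRATEGIES}"
        )
    if len(ft) < 1 or len(fd) < 1:
        raise ValueError("operands must be non-empty")
    if strategy == "concat":
        vec = FeatureVector.concat(ft.prefixed("t."), fd.prefixed("d."))
        return PairFeature(vec, "cross_concat", name_t, name_d, len(ft), len(fd))
    return PairFeature(
        _tensor(ft, fd, "t", "d"), "cross_tensor", name_t, name_d, len(ft), len(fd)
    )
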