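"""Ordered, named numeric feature vectors.

Every descriptor family in this package returns a :class:`FeatureVector`:
an immutable pairing of unique feature names with finite float values.
This is the common currency that the CLI, the table writer and the
interaction constructors all operate on.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Iterator

import numpy as np

__all__ = ["FeatureVector"]


class FeatureVector:
    """An ordered mapping of unique feature names to finite real values.

    Parameters
    ----------
    names:
        Feature names; must be unique and non-empty.
    values:
        Numeric values, same length as *names*; every value must be finite.
    """

    __slots__ = ("_names", "_values", "_index")

    def __init__(self, names: Iterable[str], values: Iterable[float]):
        names = tuple(str(n) for n in names)
        arr = np.asarray(list(values), dtype=float)
        if arr.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(names) != arr.shape[0]:
            raise ValueError(
                f"names/values length mismatch: {len(names)} != {arr.shape[0]}"
            )
        if len(set(names)) != len(names):
            seen, dups = set(), []
            for n in names:
                if n in seen:
                    dups.append(n)
                seen.add(n)
            raise ValueError(f"duplicate feature names: {dups[:5]}")
        if not np.all(np.isfinite(arr)):
            bad = [names[i] for i in np.flatnonzero(~np.isfinite(arr))[:5]]
            raise ValueError(f"non-finite feature values at: {bad}")
        self._names = names
        self._values = arr
        self._values.setflags(write=False)
        self._index = {n: i for i, n in enumerate(names)}

    # -- basic container protocol -------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    @property
    def values(self) -> np.ndarray:
        """Read-only float array of the feature values."""
        return self._values

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(self._names, self._values))

    def __getitem__(self, key: str | int) -> float:
        if isinstance(key, str):
            return float(self._values[self._index[key]])
        return float(self._values[key])

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureVector):
            return NotImplemented
        return self._names == other._names and np.array_equal(
            self._values, other._values
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        head = ", ".join(
            f"{n}={v:.4g}" for n, v in list(zip(self._names, self._values))[:4]
        )
        more = "" if len(self) <= 4 else f", … ({len(self)} total)"
        return f"FeatureVector({head}{more})"

    # -- construction helpers ------------------------------------------
    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "FeatureVector":
        return cls(mapping.keys(), mapping.values())

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in self}

    def prefixed(self, prefix: str) -> "FeatureVector":
        """Return a copy with ``prefix`` prepended to every name."""
        return FeatureVector((prefix + n for n in self._names), self._values)

    @staticmethod
    def concat(*parts: "FeatureVector") -> "FeatureVector":
        """Concatenate vectors; combined names must stay unique."""
        names: list[str] = []
        for p in parts:
            names.extend(p.names)
        values = (
            np.concatenate([p.values for p in parts]) if parts else np.empty(0)
        )
        return FeatureVector(names, values)
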