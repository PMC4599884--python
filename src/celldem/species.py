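"""Particle and boundary species, and the species interaction matrix.

A cell is built from four particle species: cell membrane with its cortex
(``M``), cytoplasm (``C``), nuclear membrane (``NM``) and nucleoplasm (``N``).
Two further species are reserved for boundary objects: a rigid testing plate
(``P``) and the basement membrane (``BM``); these are modelled as contact
lines (spheres of infinite radius), never as particles.

Which unordered species pairs exert forces on each other is recorded in an
:class:`InteractionMatrix`.  The default matrix enables the seven intra-cell
pairs ``M-M, M-C, C-C, C-NM, NM-NM, NM-N, N-N`` and the two external pairs
``M-P, M-BM``; all other combinations are inert, which is what keeps
nucleoplasm and cytoplasm confined to their compartments.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Iterable

import numpy as np

__all__ = [
    "ParticleSpecies",
    "BoundarySpecies",
    "InteractionMatrix",
    "PARTICLE_LABELS",
    "BOUNDARY_LABELS",
]


class ParticleSpecies(IntEnum):
    """The four particle species making up a cell."""

    M = 0  # cell membrane (with cell cortex)
    C = 1  # cytoplasm
    NM = 2  # nuclear membrane
    N = 3  # nucleoplasm


class BoundarySpecies(IntEnum):
    """Species reserved for boundary objects (contact lines)."""

    P = 4  # rigid plate / wall
    BM = 5  # basement membrane


PARTICLE_LABELS = ("M", "C", "NM", "N")
BOUNDARY_LABELS = ("P", "BM")
ALL_LABELS = PARTICLE_LABELS + BOUNDARY_LABELS

#: Default enabled pairs: 7 intra-cell + 2 external.
DEFAULT_ENABLED = (
    ("M", "M"),
    ("M", "C"),
    ("C", "C"),
    ("C", "NM"),
    ("NM", "NM"),
    ("NM", "N"),
    ("N", "N"),
    ("M", "P"),
    ("M", "BM"),
)


def _key(a: str, b: str) -> frozenset:
    if a not in ALL_LABELS or b not in ALL_LABELS:
        raise KeyError(f"unknown species label in pair ({a!r}, {b!r})")
    return frozenset((a, b))


class InteractionMatrix:
    """Symmetric boolean map over unordered species pairs.

    Pairs are stored as frozensets of labels, so symmetry
    ``enabled(a, b) == enabled(b, a)`` holds by construction.
    """

    def __init__(self, enabled_pairs: Iterable[tuple[str, str]] = DEFAULT_ENABLED):
        self._enabled: set[frozenset] = {_key(a, b) for a, b in enabled_pairs}

    @classmethod
    def default(cls) -> "InteractionMatrix":
        return cls(DEFAULT_ENABLED)

    def enabled(self, a: str, b: str) -> bool:
        return _key(a, b) in self._enabled

    def enable(self, a: str, b: str) -> None:
        self._enabled.add(_key(a, b))

    def disable(self, a: str, b: str) -> None:
        self._enabled.discard(_key(a, b))

    def copy(self) -> "InteractionMatrix":
        out = InteractionMatrix(())
        out._enabled = set(self._enabled)
        return out

    def pairs(self) -> set[tuple[str, str]]:
        """Enabled pairs as sorted label 2-tuples (self-pairs included)."""
        out = set()
        for k in self._enabled:
            t = tuple(sorted(k))
            out.add((t[0], t[0]) if len(t) == 1 else t)
        return out

    # -- bookkeeping -------------------------------------------------------

    def count(self, scope: str = "all_potential") -> int:
        """Count interactions in a given scope.

        ``intracell``
            enabled unordered pairs (self-pairs included) among M, C, NM, N.
        ``external``
            enabled pairs between a particle species and a boundary species.
        ``all_potential``
            every unordered particle pair (10) plus every particle x boundary
            combination (8) = 18, regardless of the enabled flags.
        """
        if scope == "intracell":
            return sum(
                1 for k in self._enabled if all(l in PARTICLE_LABELS for l in k)
            )
        if scope == "external":
            return sum(
                1 for k in self._enabled if any(l in BOUNDARY_LABELS for l in k)
                and any(l in PARTICLE_LABELS for l in k)
            )
        if scope == "all_potential":
            n = len(PARTICLE_LABELS)
            return n * (n + 1) // 2 + n * len(BOUNDARY_LABELS)
        raise ValueError(f"unknown scope {scope!r}")

    # -- array views for the numeric kernels -------------------------------

    def particle_mask(self) -> np.ndarray:
        """(4, 4) boolean array over particle species indices."""
        m = np.zeros((4, 4), dtype=np.bool_)
        for a in ParticleSpecies:
            for b in ParticleSpecies:
                m[a, b] = self.enabled(a.name, b.name)
        return m

    def boundary_mask(self) -> np.ndarray:
        """(2, 4) boolean array: rows P, BM; columns M, C, NM, N."""
        m = np.zeros((2, 4), dtype=np.bool_)
        for b in BoundarySpecies:
            for a in ParticleSpecies:
                m[b - 4, a] = self.enabled(a.name, b.name)
        return m

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionMatrix) and self._enabled == other._enabled

    def __repr__(self) -> str:
        return f"InteractionMatrix({sorted(map(tuple, map(sorted, self._enabled)))})"


def count_enabled_interactions(matrix: InteractionMatrix, scope: str) -> int:
    """Functional alias for :meth:`InteractionMatrix.count`."""
    return matrix.count(scope)
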