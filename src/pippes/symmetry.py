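"""Permutational symmetry of a molecule and its induced action on atom pairs.

A symmetry string like ``"A5B2"`` declares classes of interchangeable atoms
(five of one element, two of another).  The symmetry group is the direct
product of the symmetric groups on each class; for ``A5B2`` that is
S5 x S2 of order 240.  Since a potential expressed in interatomic distances
only sees unordered atom pairs, what matters downstream is the induced
permutation action on the N(N-1)/2 pair variables, which this module
constructs explicitly.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SymmetrySpec",
    "parse_symmetry",
    "build_pair_group",
    "pair_permutation_from_atoms",
]

_SPEC_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+)")


@dataclass(frozen=True)
class SymmetrySpec:
    """Atom classes and multiplicities defining the permutation group.

    Atoms are numbered class-by-class in the order the classes appear in the
    spec string; pairs ``(i, j)`` with ``i < j`` are ordered lexicographically.
    """

    classes: tuple[tuple[str, int], ...]
    spec: str = field(default="", compare=False)

    def __post_init__(self):
        if self.n_atoms < 2:
            raise ValueError(
                f"symmetry {self.spec or self.classes!r} has {self.n_atoms} atom(s); "
                "need at least 2 for any pair variable"
            )

    @property
    def n_atoms(self) -> int:
        return sum(c for _, c in self.classes)

    @property
    def group_order(self) -> int:
        return math.prod(math.factorial(c) for _, c in self.classes)

    @property
    def n_pairs(self) -> int:
        n = self.n_atoms
        return n * (n - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """All unordered atom pairs (i, j), i < j, lexicographic."""
        n = self.n_atoms
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    @property
    def atom_classes(self) -> np.ndarray:
        """Class index (position in ``classes``) of each atom."""
        out = np.empty(self.n_atoms, dtype=np.intp)
        k = 0
        for ci, (_, cnt) in enumerate(self.classes):
            out[k : k + cnt] = ci
            k += cnt
        return out

    @property
    def pair_class_labels(self) -> list[str]:
        """Label like ``"AA"``/``"AB"`` for each pair variable, in pair order."""
        ac = self.atom_classes
        labels = []
        for i, j in self.pairs:
            a, b = sorted((self.classes[ac[i]][0], self.classes[ac[j]][0]))
            labels.append(a + b)
        return labels

    def pair_index(self, i: int, j: int) -> int:
        """Index of the unordered pair {i, j} in the pair ordering."""
        if i == j:
            raise ValueError("a pair requires two distinct atoms")
        if i > j:
            i, j = j, i
        n = self.n_atoms
        # offset of row i in the lexicographic (i<j) listing
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    def class_elements(self) -> list[str]:
        """Element label per atom, class-by-class (e.g. A A A A A B B)."""
        out = []
        for label, cnt in self.classes:
            out.extend([label] * cnt)
        return out

    def __str__(self) -> str:
        return self.spec or "".join(f"{l}{c}" for l, c in self.classes)


def parse_symmetry(spec: str) -> SymmetrySpec:
    """Parse a symmetry string such as ``"A5B2"`` into a :class:`SymmetrySpec`.

    Each token is a capital letter (optionally followed by a lowercase letter)
    and a positive multiplicity.  Malformed tokens and zero counts are
    rejected.
    """
    if not isinstance(spec, str) or not spec:
        raise ValueError("symmetry spec must be a non-empty string like 'A5B2'")
    classes = []
    pos = 0
    while pos < len(spec):
        m = _SPEC_TOKEN.match(spec, pos)
        if m is None:
            raise ValueError(
                f"malformed symmetry spec {spec!r}: cannot parse at {spec[pos:]!r}"
            )
        label, count = m.group(1), int(m.group(2))
        if count == 0:
            raise ValueError(f"symmetry spec {spec!r}: class {label!r} has zero count")
        classes.append((label, count))
        pos = m.end()
    return SymmetrySpec(classes=tuple(classes), spec=spec)


def _atom_permutations(sym: SymmetrySpec):
    """Yield every atom permutation (as an index array p, p[i]=image of i)."""
    blocks = []
    start = 0
    for _, cnt in sym.classes:
        blocks.append(list(itertools.permutations(range(start, start + cnt))))
        start += cnt
    for combo in itertools.product(*blocks):
        p = np.fromiter(itertools.chain.from_iterable(combo), dtype=np.intp)
        yield p


def pair_permutation_from_atoms(sym: SymmetrySpec, atom_perm: np.ndarray) -> np.ndarray:
    """Induce the pair permutation pi from an atom permutation.

    ``pi[k]`` is the pair index that pair ``k = (i, j)`` is carried to,
    i.e. the index of the unordered pair ``{atom_perm[i], atom_perm[j]}``.
    """
    pi = np.empty(sym.n_pairs, dtype=np.intp)
    for k, (i, j) in enumerate(sym.pairs):
        pi[k] = sym.pair_index(int(atom_perm[i]), int(atom_perm[j]))
    return pi


def build_pair_group(sym: SymmetrySpec) -> np.ndarray:
    """All induced pair permutations, shape ``(group_order, n_pairs)``.

    The identity is the first element.  The set is closed under composition
    and inversion because it is the homomorphic image of the full direct
    product group.
    """
    perms = np.empty((sym.group_order, sym.n_pairs), dtype=np.intp)
    for g, p in enumerate(_atom_permutations(sym)):
        perms[g] = pair_permutation_from_atoms(sym, p)
    # place identity first for callers that rely on it
    ident = np.arange(sym.n_pairs)
    idx = np.flatnonzero((perms == ident).all(axis=1))[0]
    if idx != 0:
        perms[[0, idx]] = perms[[idx, 0]]
    return perms


def cycle_type(perm: np.ndarray) -> list[int]:
    """Cycle lengths of a permutation given as an image array."""
    n = len(perm)
    seen = np.zeros(n, dtype=bool)
    lengths = []
    for start in range(n):
        if seen[start]:
            continue
        ln = 0
        k = start
        while not seen[k]:
            seen[k] = True
            k = int(perm[k])
            ln += 1
        lengths.append(ln)
    return lengths
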