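"""Permutationally invariant polynomial (PIP) bases over Morse variables.

A PIP basis for a given permutational symmetry and maximum total degree M
contains one polynomial per orbit of monomials in the pair variables under
the induced pair-permutation group: each basis polynomial is the sum of the
distinct monomials in one orbit, hence exactly invariant under every group
element.  The degree-0 constant polynomial is included as the first basis
function (the counting convention of the MSA lineage of PIP software), so an
A5B2 basis at order 7 has 8717 members; fitting therefore does not need a
separate intercept by default, though one can still be requested.

Two independent routes to the basis size are provided and cross-checked:

* :func:`enumerate_pip_basis` — explicit orbit enumeration by
  canonical-representative hashing (the representative is the
  lexicographically maximal exponent vector in the orbit);
* :func:`count_invariants` — Burnside / Molien counting from the cycle types
  of the pair permutations, with no orbit ever materialised.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

from .symmetry import SymmetrySpec, build_pair_group, cycle_type, parse_symmetry

__all__ = [
    "PipPolynomial",
    "PipBasis",
    "BasisResourceError",
    "enumerate_pip_basis",
    "count_invariants",
    "symmetrize_monomial",
]

BASIS_FORMAT = "pippes-basis-1"


class BasisResourceError(RuntimeError):
    """Raised when a basis request would exceed the configured monomial cap."""


def _n_monomials(n_var: int, max_order: int) -> int:
    """Number of monomials of total degree 0..max_order in n_var variables."""
    return math.comb(n_var + max_order, max_order)


@dataclass(frozen=True)
class PipPolynomial:
    """An invariant polynomial: integer-coefficient sum of monomials.

    Orbit sums have all coefficients 1; products of orbit sums may carry
    larger integer coefficients.  Equality and hashing go through a canonical
    form (monomial rows sorted descending), so any two constructions of the
    same polynomial compare equal.
    """

    exponents: np.ndarray  # (n_mono, n_var) non-negative ints
    coeffs: np.ndarray     # (n_mono,) positive ints

    def __post_init__(self):
        E = np.asarray(self.exponents, dtype=np.int64)
        c = np.asarray(self.coeffs, dtype=np.int64)
        if E.ndim != 2 or len(c) != len(E):
            raise ValueError("exponents must be (n_mono, n_var) with matching coeffs")
        order = np.lexsort(E.T[::-1])[::-1]  # descending lexicographic rows
        object.__setattr__(self, "exponents", np.ascontiguousarray(E[order]))
        object.__setattr__(self, "coeffs", np.ascontiguousarray(c[order]))

    @property
    def n_variables(self) -> int:
        return self.exponents.shape[1]

    @property
    def degree(self) -> int:
        return int(self.exponents.sum(axis=1).max())

    @property
    def key(self) -> tuple:
        return tuple(
            (tuple(int(x) for x in row), int(c))
            for row, c in zip(self.exponents, self.coeffs)
        )

    @property
    def representative(self) -> tuple[int, ...]:
        """Lexicographically maximal monomial exponent vector."""
        return tuple(int(x) for x in self.exponents[0])

    def __eq__(self, other) -> bool:
        return isinstance(other, PipPolynomial) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __mul__(self, other: "PipPolynomial") -> "PipPolynomial":
        """Product of two invariant polynomials (again invariant)."""
        A, B = self.exponents, other.exponents
        E = (A[:, None, :] + B[None, :, :]).reshape(-1, self.n_variables)
        c = np.outer(self.coeffs, other.coeffs).ravel()
        uniq, inv = np.unique(E, axis=0, return_inverse=True)
        cc = np.bincount(inv, weights=c.astype(float)).astype(np.int64)
        return PipPolynomial(exponents=uniq, coeffs=cc)

    def evaluate(self, y: np.ndarray) -> float:
        """Value at a Morse-variable vector ``y`` (for testing/scoring)."""
        y = np.asarray(y, dtype=float)
        return float(np.sum(self.coeffs * np.prod(y ** self.exponents, axis=1)))


def symmetrize_monomial(exponents, group: np.ndarray) -> PipPolynomial:
    """Orbit sum of a monomial under a pair-permutation group.

    ``group`` is an array of permutations as produced by
    :func:`~pippes.symmetry.build_pair_group`.  Any member of the same orbit
    yields an identical polynomial (canonical form).  The all-zero (constant)
    monomial is rejected: the counted basis starts at degree 1.
    """
    e = np.asarray(exponents, dtype=np.int64)
    if e.ndim != 1 or e.shape[0] != group.shape[1]:
        raise ValueError("exponent vector length must equal the number of pairs")
    if (e < 0).any():
        raise ValueError("exponents must be non-negative")
    if e.sum() == 0:
        raise ValueError("the constant (all-zero) monomial is not a basis member")
    images = e[group]  # group closed under inversion: this sweeps the orbit
    uniq = np.unique(images, axis=0)
    return PipPolynomial(exponents=uniq, coeffs=np.ones(len(uniq), dtype=np.int64))


# ---------------------------------------------------------------------------
# enumeration machinery


def _monomial_exponents(n_var: int, max_order: int) -> np.ndarray:
    """All exponent vectors of total degree 0..max_order, as int16 rows."""
    blocks = [np.zeros((1, n_var), dtype=np.int16)]
    for d in range(1, max_order + 1):
        combos = np.fromiter(
            itertools.chain.from_iterable(
                itertools.combinations_with_replacement(range(n_var), d)
            ),
            dtype=np.intp,
        ).reshape(-1, d)
        E = np.zeros((len(combos), n_var), dtype=np.int16)
        np.add.at(E, (np.repeat(np.arange(len(combos)), d), combos.ravel()), 1)
        blocks.append(E)
    return np.vstack(blocks)


def _canonical_keys(E: np.ndarray, group: np.ndarray, base: int) -> np.ndarray:
    """Canonical (max over orbit) base-`base` key of each monomial row.

    Fast path packs each exponent vector into one uint64; lexicographic
    comparison of vectors then coincides with integer comparison of keys.
    """
    n_var = E.shape[1]
    if base ** n_var <= 2 ** 63:
        weights = [base ** (n_var - 1 - k) for k in range(n_var)]
        W = np.array(weights, dtype=np.uint64)
        canon = np.zeros(len(E), dtype=np.uint64)
        keys = np.empty(len(E), dtype=np.uint64)
        for g in group:
            keys[:] = 0
            for k in range(n_var):
                keys += E[:, g[k]].astype(np.uint64) * W[k]
            np.maximum(canon, keys, out=canon)
        return canon
    # exact big-integer fallback for very wide/high-order requests
    canon_obj = np.empty(len(E), dtype=object)
    weights = [base ** (n_var - 1 - k) for k in range(n_var)]
    rows = E.tolist()
    group_list = group.tolist()
    for i, row in enumerate(rows):
        best = -1
        for g in group_list:
            key = 0
            for k in range(n_var):
                key = key + row[g[k]] * weights[k]
            if key > best:
                best = key
        canon_obj[i] = best
    return canon_obj


def _decode_key(key: int, n_var: int, base: int) -> tuple[int, ...]:
    digits = []
    key = int(key)
    for _ in range(n_var):
        digits.append(key % base)
        key //= base
    return tuple(reversed(digits))


@dataclass
class PipBasis:
    """An ordered PIP basis stored as a flat monomial evaluation graph.

    ``exponents`` holds every monomial of every basis polynomial;
    ``poly_index`` assigns each monomial row to its polynomial and
    ``mono_coeffs`` its integer coefficient within that polynomial.
    Evaluation is one matrix product in log-Morse space followed by a
    scatter-sum over polynomials.
    """

    symmetry: SymmetrySpec
    max_order: int
    exponents: np.ndarray    # (n_mono_total, n_pairs) int16
    mono_coeffs: np.ndarray  # (n_mono_total,) float (integers)
    poly_index: np.ndarray   # (n_mono_total,) intp
    size: int
    poly_degrees: np.ndarray  # (size,) int
    _Ef: np.ndarray | None = field(default=None, repr=False, compare=False)
    _scatter: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)
    _group: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_variables(self) -> int:
        return self.symmetry.n_pairs

    @property
    def n_monomials(self) -> int:
        return len(self.exponents)

    @property
    def group(self) -> np.ndarray:
        if self._group is None:
            self._group = build_pair_group(self.symmetry)
        return self._group

    # -- evaluation ---------------------------------------------------------

    def _exponent_matrix(self) -> np.ndarray:
        if self._Ef is None:
            self._Ef = self.exponents.astype(np.float64)
        return self._Ef

    def _scatter_matrix(self) -> sparse.csr_matrix:
        if self._scatter is None:
            n = self.n_monomials
            self._scatter = sparse.csr_matrix(
                (self.mono_coeffs.astype(float),
                 (np.arange(n), self.poly_index)),
                shape=(n, self.size),
            )
        return self._scatter

    def monomial_values(self, log_y: np.ndarray) -> np.ndarray:
        """Monomial values (without orbit coefficients) from log-Morse vars."""
        return np.exp(log_y @ self._exponent_matrix().T)

    def design_row(self, log_y: np.ndarray) -> np.ndarray:
        """Values of all basis polynomials at one (or a batch of) log_y."""
        log_y = np.asarray(log_y, dtype=float)
        rows = np.asarray(self.monomial_values(np.atleast_2d(log_y))
                          @ self._scatter_matrix())
        return rows[0] if log_y.ndim == 1 else rows

    @property
    def polynomials(self) -> list[PipPolynomial]:
        """Materialised polynomial objects (intended for small bases)."""
        order = np.argsort(self.poly_index, kind="stable")
        E = self.exponents[order]
        c = self.mono_coeffs[order].astype(np.int64)
        bounds = np.searchsorted(self.poly_index[order], np.arange(self.size + 1))
        return [
            PipPolynomial(exponents=E[bounds[i]:bounds[i + 1]],
                          coeffs=c[bounds[i]:bounds[i + 1]])
            for i in range(self.size)
        ]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_polynomials(cls, symmetry: SymmetrySpec, polys: list[PipPolynomial],
                         max_order: int) -> "PipBasis":
        Es, cs, idx, degs = [], [], [], []
        for i, p in enumerate(polys):
            Es.append(p.exponents.astype(np.int16))
            cs.append(p.coeffs.astype(float))
            idx.append(np.full(len(p.exponents), i, dtype=np.intp))
            degs.append(p.degree)
        return cls(
            symmetry=symmetry,
            max_order=max_order,
            exponents=np.vstack(Es),
            mono_coeffs=np.concatenate(cs),
            poly_index=np.concatenate(idx),
            size=len(polys),
            poly_degrees=np.asarray(degs, dtype=np.intp),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready description; orbit polynomials stored by representative."""
        polys = []
        for p in self.polynomials:
            if p.degree == 0:
                polys.append({"kind": "orbit", "rep": list(p.representative)})
                continue
            orbit = symmetrize_monomial(np.asarray(p.representative), self.group)
            if orbit == p:
                polys.append({"kind": "orbit", "rep": list(p.representative)})
            else:
                polys.append({
                    "kind": "explicit",
                    "monomials": p.exponents.tolist(),
                    "coeffs": p.coeffs.tolist(),
                })
        return {
            "format": BASIS_FORMAT,
            "symmetry": str(self.symmetry),
            "max_order": self.max_order,
            "n_variables": self.n_variables,
            "pairs": [list(pr) for pr in self.symmetry.pairs],
            "polynomials": polys,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, data: dict) -> "PipBasis":
        if data.get("format") != BASIS_FORMAT:
            raise ValueError(
                f"unknown basis format {data.get('format')!r}; expected {BASIS_FORMAT!r}"
            )
        sym = parse_symmetry(data["symmetry"])
        group = build_pair_group(sym)
        polys = []
        for entry in data["polynomials"]:
            if entry["kind"] == "orbit":
                rep = np.asarray(entry["rep"])
                if rep.sum() == 0:  # the constant polynomial is its own orbit
                    polys.append(PipPolynomial(exponents=rep[None, :],
                                               coeffs=np.ones(1, dtype=np.int64)))
                else:
                    polys.append(symmetrize_monomial(rep, group))
            else:
                polys.append(PipPolynomial(
                    exponents=np.asarray(entry["monomials"], dtype=np.int64),
                    coeffs=np.asarray(entry["coeffs"], dtype=np.int64),
                ))
        basis = cls.from_polynomials(sym, polys, int(data["max_order"]))
        basis._group = group
        return basis

    @classmethod
    def load(cls, path) -> "PipBasis":
        return cls.from_dict(json.loads(Path(path).read_text()))


def enumerate_pip_basis(sym: SymmetrySpec | str, max_order: int,
                        mono_cap: int = 5_000_000) -> PipBasis:
    """Enumerate the PIP basis for ``sym`` up to total degree ``max_order``.

    Every monomial of degree 0..M is assigned to its orbit through a
    canonical representative (lexicographic maximum over the group); the
    basis has one polynomial per orbit, ordered by total degree and then by
    canonical exponent vector, with the constant polynomial first.

    Raises
    ------
    BasisResourceError
        if the monomial count C(n_var+M, M)-1 exceeds ``mono_cap``.
    """
    if isinstance(sym, str):
        sym = parse_symmetry(sym)
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    n_var = sym.n_pairs
    n_mono = _n_monomials(n_var, max_order)
    if n_mono > mono_cap:
        raise BasisResourceError(
            f"basis request needs {n_mono:,} monomials "
            f"(> cap of {mono_cap:,}); raise mono_cap to proceed"
        )
    group = build_pair_group(sym)
    E = _monomial_exponents(n_var, max_order)
    base = max_order + 1
    canon = _canonical_keys(E, group, base)
    uniq, inverse = np.unique(canon, return_inverse=True)
    deg = E.sum(axis=1).astype(np.intp)
    # degree of each orbit (same for all members): take one occurrence
    first = np.full(len(uniq), -1, dtype=np.intp)
    first[inverse[::-1]] = np.arange(len(E) - 1, -1, -1)
    orbit_deg = deg[first]
    order = np.lexsort((uniq.astype(np.float64) if uniq.dtype == object else uniq,
                        orbit_deg))
    rank = np.empty(len(uniq), dtype=np.intp)
    rank[order] = np.arange(len(uniq))
    basis = PipBasis(
        symmetry=sym,
        max_order=max_order,
        exponents=E,
        mono_coeffs=np.ones(len(E), dtype=float),
        poly_index=rank[inverse],
        size=len(uniq),
        poly_degrees=orbit_deg[order],
        _group=group,
    )
    return basis


def count_invariants(sym: SymmetrySpec | str, max_order: int) -> np.ndarray:
    """Per-degree orbit counts by Burnside / Molien, no orbit enumeration.

    For each group element with pair-permutation cycle lengths l_1..l_k, the
    monomials it fixes are counted by the series product of 1/(1 - t^l);
    averaging the truncated series over the group gives the number of orbits
    per degree.  Returns counts for degrees 0..max_order (index = degree;
    the degree-0 entry is always 1).  All arithmetic is exact.
    """
    if isinstance(sym, str):
        sym = parse_symmetry(sym)
    M = max_order
    group = build_pair_group(sym)
    total = [0] * (M + 1)
    for g in group:
        ser = [0] * (M + 1)
        ser[0] = 1
        for ln in cycle_type(g):
            for d in range(ln, M + 1):
                ser[d] += ser[d - ln]
        for d in range(M + 1):
            total[d] += ser[d]
    n_g = len(group)
    counts = []
    for d in range(0, M + 1):
        q, r = divmod(total[d], n_g)
        if r:  # Burnside averages of permutation fixed-point counts are integral
            raise AssertionError("non-integral Burnside average: group not closed?")
        counts.append(q)
    return np.asarray(counts, dtype=np.int64)
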