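import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pippes.basis import (BasisResourceError, PipPolynomial, count_invariants,
                          enumerate_pip_basis, symmetrize_monomial)
from pippes.symmetry import build_pair_group, parse_symmetry


def test_a5b2_order3_size_matches_published_count(basis_a5b2_order3):
    assert basis_a5b2_order3.size == 59


@pytest.mark.parametrize("d", [1, 2, 3, 5])
def test_single_variable_basis_is_constant_plus_powers(d):
    """A1B1 has one pair variable: the basis is 1, y, y^2, ..., y^d."""
    b = enumerate_pip_basis("A1B1", d)
    assert b.size == d + 1
    assert b.poly_degrees.tolist() == list(range(d + 1))


def test_a3_order2_orbits():
    """Degree 0 and 1 each give one orbit; degree 2 splits into the squares
    orbit and the cross-product orbit."""
    b = enumerate_pip_basis("A3", 2)
    assert b.size == 4
    assert b.poly_degrees.tolist() == [0, 1, 2, 2]


def test_count_invariants_examples():
    assert count_invariants("A5B2", 1).tolist() == [1, 3]  # AA, AB, BB at degree 1
    assert count_invariants("A3", 2).tolist() == [1, 1, 2]


@pytest.mark.parametrize("spec, orders", [
    ("A3", range(1, 5)), ("A2B1", range(1, 5)), ("A4", range(1, 4)),
    ("A2B2", range(1, 4)), ("A5B2", range(1, 5)),
])
def test_enumeration_agrees_with_burnside(spec, orders):
    """Orbit enumeration and Molien-series counting are independent routes
    to the same per-degree basis sizes."""
    for M in orders:
        b = enumerate_pip_basis(spec, M)
        counts = count_invariants(spec, M)
        assert b.size == counts.sum()
        per_degree = np.bincount(b.poly_degrees, minlength=M + 1)
        assert per_degree.tolist() == counts.tolist()


def test_basis_size_monotone_in_order():
    sizes = [enumerate_pip_basis("A2B1", M).size for M in range(1, 6)]
    assert all(a < b for a, b in zip(sizes, sizes[1:]))


def test_trivial_group_gives_binomial_count():
    """With all classes singleton the group is trivial and every monomial is
    its own orbit: size = C(n_var + M, M)."""
    for M in (1, 2, 3):
        b = enumerate_pip_basis("A1B1C1", M)  # 3 atoms, 3 pair variables
        assert b.size == math.comb(3 + M, M)


def test_every_polynomial_is_group_invariant(rng):
    """p(g.y) = p(y) for every basis polynomial and group element."""
    b = enumerate_pip_basis("A2B1", 4)
    group = b.group
    y = rng.uniform(0.1, 0.9, size=b.n_variables)
    ref = b.design_row(np.log(y))
    for g in group:
        permuted = np.empty_like(y)
        permuted[g] = y
        vals = b.design_row(np.log(permuted))
        assert np.allclose(vals, ref, rtol=1e-12, atol=0)


def test_symmetrize_monomial_orbits():
    sym = parse_symmetry("A3")
    group = build_pair_group(sym)
    p = symmetrize_monomial(np.array([1, 1, 0]), group)
    assert len(p.exponents) == 3  # y1y2 + y1y3 + y2y3
    assert (p.coeffs == 1).all()
    # canonical: any orbit member produces the identical polynomial
    assert symmetrize_monomial(np.array([0, 1, 1]), group) == p
    assert symmetrize_monomial(np.array([1, 0, 1]), group) == p


def test_symmetrize_monomial_fixed_point():
    sym = parse_symmetry("A2")
    group = build_pair_group(sym)
    p = symmetrize_monomial(np.array([2]), group)
    assert p.exponents.tolist() == [[2]]


def test_symmetrize_monomial_rejects_constant_and_negative():
    group = build_pair_group(parse_symmetry("A3"))
    with pytest.raises(ValueError):
        symmetrize_monomial(np.zeros(3, dtype=int), group)
    with pytest.raises(ValueError):
        symmetrize_monomial(np.array([1, -1, 0]), group)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(e=st.lists(st.integers(min_value=0, max_value=4), min_size=6, max_size=6))
def test_orbit_sum_invariance_property(e):
    """The orbit sum of any monomial is invariant under every group element,
    and the orbit size divides the group order."""
    if sum(e) == 0:
        return
    sym = parse_symmetry("A4")
    group = build_pair_group(sym)
    p = symmetrize_monomial(np.array(e), group)
    assert sym.group_order % _orbit_stabilizer_count(e, group) == 0
    y = np.linspace(0.2, 0.8, sym.n_pairs)
    ref = p.evaluate(y)
    g = group[len(e) % len(group)]
    permuted = np.empty_like(y)
    permuted[g] = y
    assert p.evaluate(permuted) == pytest.approx(ref, rel=1e-12)


def _orbit_stabilizer_count(e, group):
    return len({tuple(np.asarray(e)[g]) for g in group})


def test_polynomial_product_merges_duplicates():
    p = PipPolynomial(exponents=np.array([[1, 0], [0, 1]]),
                      coeffs=np.array([1, 1]))
    sq = p * p
    # (y1 + y2)^2 = y1^2 + 2 y1 y2 + y2^2
    assert sorted(map(tuple, sq.exponents.tolist())) == [(0, 2), (1, 1), (2, 0)]
    assert sq.coeffs.sum() == 4


def test_basis_round_trip(tmp_path):
    b = enumerate_pip_basis("A2B1", 3)
    path = tmp_path / "basis.json"
    b.save(path)
    b2 = type(b).load(path)
    assert b2.size == b.size
    y = np.full(b.n_variables, 0.4)
    assert np.allclose(b2.design_row(np.log(y)), b.design_row(np.log(y)))


def test_basis_format_version_checked(tmp_path):
    import json
    b = enumerate_pip_basis("A2", 2)
    d = b.to_dict()
    d["format"] = "something-else"
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(d))
    with pytest.raises(ValueError, match="format"):
        type(b).load(p)


def test_resource_cap():
    with pytest.raises(BasisResourceError):
        enumerate_pip_basis("A5B2", 7, mono_cap=1000)
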