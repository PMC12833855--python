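import numpy as np
import pytest

from conftest import random_geometry
from pippes import (Dataset, MorsePipModel, PesModel, augment_basis,
                    enumerate_pip_basis, fit_metrics, weight)
from pippes.fitting import _design_matrix
from pippes.units import HARTREE_TO_CM1


def _synthetic_dataset(sym, n, rng, spread=1.0):
    geoms = [random_geometry(sym, rng, spread=spread) for _ in range(n)]
    return geoms


# -- weights ----------------------------------------------------------------


def test_weight_values():
    assert weight(0.0, 0.1) == 1.0
    assert weight(0.1, 0.1) == 0.5
    assert weight(0.3, 0.1) == 0.25


def test_weight_monotone_decreasing():
    E = np.linspace(0, 1, 50)
    w = weight(E, 0.1)
    assert (np.diff(w) < 0).all()


def test_weight_rejects_bad_inputs():
    with pytest.raises(ValueError):
        weight(-0.01, 0.1)
    with pytest.raises(ValueError):
        weight(0.1, 0.0)


# -- energy filtering -------------------------------------------------------


def test_filter_by_energy(rng):
    rel_cm1 = np.array([10.0, 100.0, 59_999.0, 60_001.0, 110_000.0])
    geoms = _synthetic_dataset("A2B1", 5, rng)
    ds = Dataset(geometries=geoms, energies=rel_cm1 / HARTREE_TO_CM1,
                 reference_energy=0.0)
    kept = ds.filter_by_energy(60_000.0)
    assert len(kept) == 3
    assert len(ds.filter_by_energy(np.inf)) == 5
    with pytest.warns(UserWarning, match="every record"):
        empty = ds.filter_by_energy(5.0)
    assert len(empty) == 0


# -- least squares ----------------------------------------------------------


def test_noiseless_in_span_recovery(rng):
    """Data generated from known coefficients is recovered exactly."""
    basis = enumerate_pip_basis("A3", 3)
    geoms = _synthetic_dataset("A3", 80, rng)
    c_true = rng.normal(size=basis.size)
    ds0 = Dataset(geometries=geoms, energies=np.zeros(len(geoms)))
    B = _design_matrix(ds0, basis, 3.0)
    ds = Dataset(geometries=geoms, energies=B @ c_true)
    res = MorsePipModel(ds, basis).fit()
    assert np.abs(res.params - c_true).max() <= 1e-8 * (1 + np.abs(c_true).max())
    assert res.rmse_cm1 <= 1e-6


def test_constant_energies_fit_exactly(rng):
    """The constant basis polynomial absorbs a flat dataset."""
    basis = enumerate_pip_basis("A3", 2)
    geoms = _synthetic_dataset("A3", 20, rng)
    ds = Dataset(geometries=geoms, energies=np.full(20, -7.5))
    res = MorsePipModel(ds, basis).fit()
    assert res.rmse_cm1 == pytest.approx(0.0, abs=1e-6)


def test_rmse_decreases_with_order(dataset_a2b1):
    rmses = []
    for order in (2, 3, 4):
        basis = enumerate_pip_basis("A2B1", order)
        rmses.append(MorsePipModel(dataset_a2b1, basis).fit().rmse_cm1)
    assert rmses[0] > rmses[1] > rmses[2]


def test_wrmse_not_above_rmse(dataset_a2b1):
    """With w <= 1 and sum-of-weights normalization, down-weighting the
    high-energy (worst-fit) points cannot raise the weighted RMSE above the
    unweighted one on these datasets."""
    basis = enumerate_pip_basis("A2B1", 3)
    res = MorsePipModel(dataset_a2b1, basis).fit()
    assert res.wrmse_cm1 <= res.rmse_cm1


def test_normal_equations_cross_check(dataset_a2b1):
    """SVD least squares equals the normal-equations solution on a
    well-conditioned problem (two-solver consistency)."""
    basis = enumerate_pip_basis("A2B1", 2)
    model = MorsePipModel(dataset_a2b1, basis)
    res = model.fit()
    B = model.design()
    w = model.weights
    A = B.T @ (w[:, None] * B)
    b = B.T @ (w * model.dataset.energies)
    c_ne = np.linalg.solve(A, b)
    assert np.abs(c_ne - res.params).max() <= 1e-8 * (1 + np.abs(c_ne).max())


def test_residuals_weight_orthogonal_to_columns(dataset_a2b1):
    basis = enumerate_pip_basis("A2B1", 3)
    model = MorsePipModel(dataset_a2b1, basis)
    res = model.fit()
    B = model.design()
    proj = B.T @ (model.weights * res.resid)
    scale = np.abs(B.T @ (model.weights * model.dataset.energies)).max()
    assert np.abs(proj).max() <= 1e-8 * scale


def test_underdetermined_fit_warns(rng):
    basis = enumerate_pip_basis("A3", 3)
    geoms = _synthetic_dataset("A3", 5, rng)
    ds = Dataset(geometries=geoms, energies=rng.normal(size=5))
    with pytest.warns(UserWarning, match="minimum-norm"):
        MorsePipModel(ds, basis).fit()


def test_summary_reports_key_diagnostics(dataset_a2b1):
    basis = enumerate_pip_basis("A2B1", 2)
    res = MorsePipModel(dataset_a2b1, basis).fit()
    s = res.summary()
    assert "RMSE" in s and "wRMSE" in s and "A2B1" in s
    assert str(res.n_points) in s


# -- metrics ----------------------------------------------------------------


def test_perfect_model_metrics(rng):
    basis = enumerate_pip_basis("A3", 2)
    geoms = _synthetic_dataset("A3", 30, rng)
    c = rng.normal(size=basis.size)
    pes = PesModel(basis=basis, coefficients=c)
    ds = Dataset(geometries=geoms,
                 energies=np.array([pes.energy(g) for g in geoms]))
    m = fit_metrics(pes, ds)
    assert m["rmse_cm1"] == pytest.approx(0.0, abs=1e-6)
    assert m["mae_cm1"] == pytest.approx(0.0, abs=1e-6)
    assert m["r_squared"] == pytest.approx(1.0, abs=1e-12)


def test_constant_prediction_has_zero_r_squared(rng):
    """A model that predicts the dataset mean explains no variance."""
    basis = enumerate_pip_basis("A3", 1)
    geoms = _synthetic_dataset("A3", 30, rng)
    energies = rng.normal(size=30)
    ds = Dataset(geometries=geoms, energies=energies,
                 reference_energy=float(energies.min()))
    c = np.zeros(basis.size)
    c[0] = energies.mean()  # the constant polynomial
    pes = PesModel(basis=basis, coefficients=c)
    assert fit_metrics(pes, ds)["r_squared"] == pytest.approx(0.0, abs=1e-12)


def test_rmse_dominates_mae(dataset_a2b1):
    basis = enumerate_pip_basis("A2B1", 2)
    res = MorsePipModel(dataset_a2b1, basis).fit()
    assert res.rmse_cm1 >= res.mae_cm1


# -- basis augmentation -----------------------------------------------------


def test_augmented_polynomials_remain_invariant(dataset_a2b1):
    base = enumerate_pip_basis("A2B1", 2)
    grown = augment_basis(base, dataset_a2b1, base.size + 3)
    assert grown.size == base.size + 3
    y = np.full(grown.n_variables, 0.5)
    ref = grown.design_row(np.log(y))
    for g in grown.group:
        permuted = np.empty_like(y)
        permuted[g] = np.linspace(0.3, 0.7, grown.n_variables)
        orig = grown.design_row(np.log(np.linspace(0.3, 0.7, grown.n_variables)))
        assert np.allclose(grown.design_row(np.log(permuted)), orig, rtol=1e-12)
    assert ref.shape == (grown.size,)


def test_augmentation_picks_argmax_for_single_geometry(morse_a2b1):
    from pippes.fitting import Dataset
    base = enumerate_pip_basis("A2B1", 2)
    geom = morse_a2b1.minimum()
    ds = Dataset(geometries=[geom], energies=[morse_a2b1.energy(geom)])
    grown = augment_basis(base, ds, base.size + 1)
    added = grown.polynomials[-1]
    # exhaustive scoring of every candidate product
    polys = base.polynomials
    from pippes.geometry import interatomic_distances
    y = np.exp(-interatomic_distances(geom) / 3.0)
    best, best_val = None, -np.inf
    seen = set(polys)
    for i in range(len(polys)):
        if polys[i].degree == 0:
            continue
        for j in range(i, len(polys)):
            if polys[j].degree == 0:
                continue
            if polys[i].degree + polys[j].degree > base.max_order + 1:
                continue
            cand = polys[i] * polys[j]
            if cand in seen:
                continue
            seen.add(cand)
            v = abs(cand.evaluate(y))
            if v > best_val:
                best, best_val = cand, v
    assert added == best


def test_augmentation_brute_force_selection(dataset_a2b1):
    """Top-k selection agrees with exhaustive candidate scoring."""
    base = enumerate_pip_basis("A2B1", 2)
    k = 2
    grown = augment_basis(base, dataset_a2b1, base.size + k)
    added = set(grown.polynomials[-k:])
    from pippes.geometry import interatomic_distances
    Y = [np.exp(-interatomic_distances(g) / 3.0) for g in dataset_a2b1.geometries]
    polys = base.polynomials
    scored = {}
    seen = set(polys)
    for i in range(len(polys)):
        if polys[i].degree == 0:
            continue
        for j in range(i, len(polys)):
            if polys[j].degree == 0:
                continue
            if polys[i].degree + polys[j].degree > base.max_order + 1:
                continue
            cand = polys[i] * polys[j]
            if cand in seen or cand in scored:
                continue
            scored[cand] = max(abs(cand.evaluate(y)) for y in Y)
    top = sorted(scored, key=scored.get, reverse=True)[:k]
    assert added == set(top)


def test_augmentation_warns_when_candidates_exhausted(dataset_a2b1):
    base = enumerate_pip_basis("A2B1", 1)
    with pytest.warns(UserWarning, match="candidates"):
        grown = augment_basis(base, dataset_a2b1, base.size + 500, degree_cap=2)
    assert grown.size < base.size + 500
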