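"""Weighted linear least-squares fitting of PIP coefficients to energies.

The model is statsmodels-flavoured: build a :class:`MorsePipModel` from a
:class:`Dataset` and a :class:`~pippes.basis.PipBasis`, call :meth:`fit`, and
receive a :class:`PipFitResults` carrying the coefficient vector, fit
diagnostics and a ``summary()`` table; the fitted
:class:`~pippes.pes.PesModel` hangs off the results as ``.pes``.

Energies in hartree are weighted by w(E) = Delta/(E + Delta) with E measured
from the dataset minimum and Delta = 0.1 hartree by default, which
de-emphasizes high-energy points.  The solve is a rank-revealing SVD least
squares, never explicit normal equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import PipBasis, PipPolynomial
from .geometry import Geometry, interatomic_distances
from .pes import PesModel
from .units import CM1_TO_HARTREE, HARTREE_TO_CM1

__all__ = [
    "Dataset",
    "weight",
    "MorsePipModel",
    "PipFitResults",
    "fit_metrics",
    "augment_basis",
]

DATASET_HEADER = "# pippes-dataset-1 (N energy_hartree; element x y z in bohr)"


def weight(E, delta: float = 0.1):
    """Energy weight w(E) = Delta/(E + Delta), E in hartree above the minimum."""
    E = np.asarray(E, dtype=float)
    if delta <= 0:
        raise ValueError("Delta must be positive")
    if (E < 0).any():
        raise ValueError("relative energies must be non-negative")
    return delta / (E + delta)


@dataclass
class Dataset:
    """(geometry, energy) records with a common atom layout, in bohr/hartree."""

    geometries: list[Geometry]
    energies: np.ndarray
    reference_energy: float | None = None  # energy zero; dataset min if None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.geometries) != len(self.energies):
            raise ValueError("geometry and energy counts differ")
        if len(self.geometries) == 0:
            return
        n0 = self.geometries[0].n_atoms
        if any(g.n_atoms != n0 for g in self.geometries):
            raise ValueError("all records must share the same atom count")
        if self.reference_energy is None:
            self.reference_energy = float(self.energies.min())

    def __len__(self) -> int:
        return len(self.energies)

    @property
    def relative_energies(self) -> np.ndarray:
        """Energies above the reference, hartree (clipped at 0 for weights)."""
        return np.maximum(self.energies - self.reference_energy, 0.0)

    def filter_by_energy(self, emax_cm1: float) -> "Dataset":
        """Keep records with relative energy <= emax_cm1 (cm^-1)."""
        if emax_cm1 <= 0:
            raise ValueError("energy cutoff must be positive")
        keep = self.relative_energies * HARTREE_TO_CM1 <= emax_cm1
        if not keep.any():
            warnings.warn(
                f"energy cutoff {emax_cm1} cm^-1 removed every record", stacklevel=2
            )
        return Dataset(
            geometries=[g for g, k in zip(self.geometries, keep) if k],
            energies=self.energies[keep],
            reference_energy=self.reference_energy,
        )

    # -- plain-text round trip ---------------------------------------------

    def to_file(self, path) -> None:
        lines = [DATASET_HEADER]
        for geom, e in zip(self.geometries, self.energies):
            lines.append(f"{geom.n_atoms} {e:.12e}")
            for el, (x, y, z) in zip(geom.elements, geom.coords):
                lines.append(f"{el:<3s} {x:20.12f} {y:20.12f} {z:20.12f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path, order: list[int] | None = None) -> "Dataset":
        """Read the dataset table; ``order`` optionally re-indexes atoms so
        that file atom ``order[k]`` becomes atom ``k`` (class-by-class)."""
        lines = [
            ln for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        geoms, energies = [], []
        k = 0
        while k < len(lines):
            head = lines[k].split()
            try:
                n, e = int(head[0]), float(head[1])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: bad record header {lines[k]!r} (want 'N energy')"
                ) from None
            body = lines[k + 1 : k + 1 + n]
            if len(body) < n:
                raise ValueError(f"{path}: truncated record of {n} atoms")
            elements = [ln.split()[0] for ln in body]
            coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in body])
            if order is not None:
                elements = [elements[i] for i in order]
                coords = coords[order]
            geoms.append(Geometry(elements=elements, coords=coords))
            energies.append(e)
            k += 1 + n
        return cls(geometries=geoms, energies=np.asarray(energies))


def _design_matrix(ds: Dataset, basis: PipBasis, a: float) -> np.ndarray:
    ly = np.stack([-interatomic_distances(g) / a for g in ds.geometries])
    return np.asarray(basis.design_row(ly))


class MorsePipModel:
    """Linear PIP regression model V(y) = sum_a c_a p_a(y) in Morse variables.

    Parameters
    ----------
    dataset : Dataset
        Training geometries and energies (bohr / hartree).
    basis : PipBasis
        The PIP basis; its symmetry must match the dataset atom layout.
    delta : float
        Weighting parameter Delta (hartree) in w(E) = Delta/(E + Delta).
    intercept : bool
        Prepend an explicit intercept column.  Off by default because the
        basis already contains the constant polynomial.
    range_parameter : float
        Morse range parameter a in bohr.
    """

    def __init__(self, dataset: Dataset, basis: PipBasis, delta: float = 0.1,
                 intercept: bool = False, range_parameter: float = 3.0):
        if len(dataset) == 0:
            raise ValueError("cannot fit an empty dataset")
        dataset.geometries[0].check_layout(basis.symmetry)
        self.dataset = dataset
        self.basis = basis
        self.delta = delta
        self.intercept = intercept
        self.range_parameter = range_parameter

    @classmethod
    def from_file(cls, path, basis: PipBasis, **kw) -> "MorsePipModel":
        return cls(Dataset.from_file(path), basis, **kw)

    @property
    def weights(self) -> np.ndarray:
        return weight(self.dataset.relative_energies, self.delta)

    def design(self) -> np.ndarray:
        B = _design_matrix(self.dataset, self.basis, self.range_parameter)
        if self.intercept:
            B = np.column_stack([np.ones(len(B)), B])
        return B

    def fit(self, rcond: float = 1e-12) -> "PipFitResults":
        """Weighted SVD least squares; minimum-norm on rank deficiency."""
        B = self.design()
        y = self.dataset.energies
        n, p = B.shape
        if n < p:
            warnings.warn(
                f"under-determined fit ({n} points, {p} parameters): "
                "returning the minimum-norm solution",
                stacklevel=2,
            )
        sw = np.sqrt(self.weights)
        coefs, _, rank, sv = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=rcond)
        if rank < p:
            warnings.warn(
                f"rank-deficient design: effective rank {rank} of {p}", stacklevel=2
            )
        if self.intercept:
            intercept, c = float(coefs[0]), coefs[1:]
        else:
            intercept, c = 0.0, coefs
        pes = PesModel(basis=self.basis, coefficients=c, intercept=intercept,
                       range_parameter=self.range_parameter)
        pred = B @ coefs
        return PipFitResults(model=self, pes=pes, params=coefs, rank=int(rank),
                             singular_values=sv, fitted_values=pred)


@dataclass
class PipFitResults:
    """Results of a PIP least-squares fit, with statsmodels-style summary."""

    model: MorsePipModel
    pes: PesModel
    params: np.ndarray
    rank: int
    singular_values: np.ndarray
    fitted_values: np.ndarray
    _metrics: dict | None = field(default=None, repr=False)

    @property
    def resid(self) -> np.ndarray:
        return self.model.dataset.energies - self.fitted_values

    def metrics(self) -> dict:
        if self._metrics is None:
            r = self.resid
            w = self.model.weights
            y = self.model.dataset.energies
            sst = float(np.sum((y - y.mean()) ** 2))
            self._metrics = {
                "rmse_cm1": float(np.sqrt(np.mean(r ** 2))) * HARTREE_TO_CM1,
                "wrmse_cm1": float(np.sqrt(np.sum(w * r ** 2) / np.sum(w)))
                * HARTREE_TO_CM1,
                "mae_cm1": float(np.mean(np.abs(r))) * HARTREE_TO_CM1,
                "r_squared": 1.0 - float(np.sum(r ** 2)) / sst if sst > 0 else 1.0,
                "n_points": len(y),
            }
        return self._metrics

    @property
    def rmse_cm1(self) -> float:
        return self.metrics()["rmse_cm1"]

    @property
    def wrmse_cm1(self) -> float:
        return self.metrics()["wrmse_cm1"]

    @property
    def mae_cm1(self) -> float:
        return self.metrics()["mae_cm1"]

    @property
    def r_squared(self) -> float:
        return self.metrics()["r_squared"]

    @property
    def n_points(self) -> int:
        return self.metrics()["n_points"]

    def summary(self) -> str:
        m = self.metrics()
        b = self.model.basis
        lines = [
            "PIP least-squares fit",
            "=" * 46,
            f"symmetry            {str(b.symmetry):>12s}",
            f"max order           {b.max_order:>12d}",
            f"basis size          {b.size:>12d}",
            f"n points            {m['n_points']:>12d}",
            f"effective rank      {self.rank:>12d}",
            f"Delta (hartree)     {self.model.delta:>12.4g}",
            f"RMSE  (cm^-1)       {m['rmse_cm1']:>12.3f}",
            f"wRMSE (cm^-1)       {m['wrmse_cm1']:>12.3f}",
            f"MAE   (cm^-1)       {m['mae_cm1']:>12.3f}",
            f"R^2                 {m['r_squared']:>12.8f}",
        ]
        return "\n".join(lines)


def fit_metrics(pes: PesModel, ds: Dataset, delta: float = 0.1) -> dict:
    """RMSE / wRMSE / MAE (cm^-1) and R^2 of a model against a dataset.

    wRMSE = sqrt(sum w r^2 / sum w), so uniform weights reduce it to RMSE;
    R^2 = 1 - SS_res/SS_tot about the dataset mean.
    """
    pred = np.array([pes.energy(g) for g in ds.geometries])
    r = ds.energies - pred
    w = weight(ds.relative_energies, delta)
    sst = float(np.sum((ds.energies - ds.energies.mean()) ** 2))
    return {
        "rmse_cm1": float(np.sqrt(np.mean(r ** 2))) * HARTREE_TO_CM1,
        "wrmse_cm1": float(np.sqrt(np.sum(w * r ** 2) / np.sum(w))) * HARTREE_TO_CM1,
        "mae_cm1": float(np.mean(np.abs(r))) * HARTREE_TO_CM1,
        "r_squared": 1.0 - float(np.sum(r ** 2)) / sst if sst > 0 else 1.0,
        "n_points": len(ds),
    }


def augment_basis(base: PipBasis, ds: Dataset, target_size: int,
                  degree_cap: int | None = None,
                  range_parameter: float = 3.0) -> PipBasis:
    """Grow a basis with products of its own polynomials (still PIPs).

    Candidates are pairwise products of existing basis polynomials with total
    degree at most ``degree_cap`` (default: base order + 1), deduplicated
    against the base and each other.  Because Morse variables shrink with
    distance, a candidate's maximum absolute value over the dataset is large
    exactly when close atom pairs dominate it; the top-scoring candidates by
    that criterion are appended until ``target_size`` is reached.
    """
    if target_size <= base.size:
        raise ValueError("target_size must exceed the current basis size")
    cap = degree_cap if degree_cap is not None else base.max_order + 1
    polys = base.polynomials
    existing = set(polys)
    candidates: dict = {}
    for ii in range(len(polys)):
        if polys[ii].degree == 0:
            continue  # product with the constant reproduces an existing poly
        for jj in range(ii, len(polys)):
            if polys[jj].degree == 0:
                continue
            if polys[ii].degree + polys[jj].degree > cap:
                continue
            prod = polys[ii] * polys[jj]
            if prod in existing or prod in candidates:
                continue
            candidates[prod] = None
    cand_list = list(candidates)
    n_needed = target_size - base.size
    if len(cand_list) < n_needed:
        warnings.warn(
            f"only {len(cand_list)} distinct product candidates available; "
            f"returning a basis of size {base.size + len(cand_list)}",
            stacklevel=2,
        )
        n_needed = len(cand_list)
    if n_needed == 0:
        return base
    # score: max |value| over the dataset geometries
    Y = np.stack([
        np.exp(-interatomic_distances(g) / range_parameter) for g in ds.geometries
    ])
    scores = np.array([
        np.max(np.abs([p.evaluate(y) for y in Y])) for p in cand_list
    ])
    pick = np.argsort(-scores, kind="stable")[:n_needed]
    new_polys = polys + [cand_list[k] for k in pick]
    new_order = max(base.max_order, max(cand_list[k].degree for k in pick))
    out = PipBasis.from_polynomials(base.symmetry, new_polys, new_order)
    out._group = base._group
    return out
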