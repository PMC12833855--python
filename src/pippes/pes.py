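"""PES evaluation and analytic gradients by forward and reverse differentiation.

The fitted potential is the linear expansion V(y) = sum_a c_a p_a(y) in PIP
basis polynomials of Morse variables y_ij = exp(-r_ij/a).  Gradients with
respect to Cartesian coordinates are available three ways:

* ``forward`` — one chain-rule pass per Cartesian coordinate, so the total
  cost scales as 3N energy evaluations;
* ``reverse`` — a single energy evaluation that records the monomial values,
  followed by one backward sweep accumulating adjoints through
  polynomials -> monomials -> Morse variables -> distances -> Cartesians;
  its cost is a small constant multiple of one energy call, independent of N;
* ``fd`` — central finite differences, used as an independent check.

Adjoints are accumulated in log-Morse space (dV/d ln y = y dV/dy), which is
algebraically identical to chaining through dy/dr = -y/a but stays finite at
strongly stretched geometries where y underflows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .basis import PipBasis
from .geometry import Geometry, batch_distances, interatomic_distances
from .units import HARTREE_TO_CM1

__all__ = ["PesModel", "GradientResult"]

MODEL_FORMAT = "pippes-model-1"

#: distances below this (bohr) make dr/dx ill-conditioned
R_COINCIDENT = 1e-8


@dataclass
class GradientResult:
    """Energy (hartree) and 3N Cartesian gradient (hartree/bohr)."""

    energy: float
    gradient: np.ndarray  # (N, 3)
    method: str

    @property
    def flat(self) -> np.ndarray:
        return self.gradient.ravel()


@dataclass
class PesModel:
    """A fitted PIP potential: basis, linear coefficients, Morse range.

    Coefficients are in hartree.  ``intercept`` is an optional additive
    constant kept separate from the basis (the basis itself already contains
    the degree-0 polynomial, so the default is no extra intercept).
    """

    basis: PipBasis
    coefficients: np.ndarray
    intercept: float = 0.0
    range_parameter: float = 3.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.basis.size:
            raise ValueError(
                f"{len(self.coefficients)} coefficients for a basis of size "
                f"{self.basis.size}"
            )

    # -- geometry plumbing --------------------------------------------------

    def _coords(self, geom) -> np.ndarray:
        coords = geom.coords if isinstance(geom, Geometry) else np.asarray(geom, float)
        coords = coords.reshape(-1, 3)
        if len(coords) != self.basis.symmetry.n_atoms:
            raise ValueError(
                f"geometry has {len(coords)} atoms but the basis symmetry "
                f"{self.basis.symmetry} requires {self.basis.symmetry.n_atoms}"
            )
        if isinstance(geom, Geometry):
            geom.check_layout(self.basis.symmetry)
        return coords

    def _log_morse(self, r: np.ndarray) -> np.ndarray:
        return -r / self.range_parameter

    # -- energy -------------------------------------------------------------

    def energy(self, geom) -> float:
        """Potential energy in hartree at one geometry."""
        coords = self._coords(geom)
        r = interatomic_distances(coords)
        row = self.basis.design_row(self._log_morse(r))
        return float(row @ self.coefficients) + self.intercept

    def batch_energies(self, coords: np.ndarray) -> np.ndarray:
        """Energies for a batch of configurations, shape (n, N, 3) -> (n,)."""
        coords = np.asarray(coords, dtype=float)
        r = batch_distances(coords)
        rows = self.basis.design_row(self._log_morse(r))
        return np.asarray(rows @ self.coefficients).ravel() + self.intercept

    def __call__(self, geom) -> float:
        return self.energy(geom)

    # -- gradients ----------------------------------------------------------

    def _pair_geometry(self, coords: np.ndarray):
        """Distances and unit pair vectors; rejects coincident atoms."""
        i, j = np.triu_indices(len(coords), k=1)
        diff = coords[i] - coords[j]
        r = np.linalg.norm(diff, axis=1)
        if (r < R_COINCIDENT).any():
            k = int(np.argmin(r))
            raise ValueError(
                f"atoms {i[k]} and {j[k]} are coincident (r = {r[k]:.2e} bohr); "
                "the distance gradient is undefined"
            )
        return i, j, diff / r[:, None], r

    def _mono_weights(self, log_y: np.ndarray) -> np.ndarray:
        """Per-monomial contribution weight c_poly * coeff * monomial value."""
        v = self.basis.monomial_values(log_y)
        return self.coefficients[self.basis.poly_index] * self.basis.mono_coeffs * v

    def gradient_reverse(self, geom) -> GradientResult:
        """All 3N gradient components from a single backward pass."""
        coords = self._coords(geom)
        i, j, u, r = self._pair_geometry(coords)
        ly = self._log_morse(r)
        w_mono = self._mono_weights(ly)                       # forward sweep
        energy = float(w_mono.sum()) + self.intercept
        dV_dly = self.basis._exponent_matrix().T @ w_mono     # backward sweep
        dV_dr = -dV_dly / self.range_parameter
        grad = np.zeros_like(coords)
        np.add.at(grad, i, dV_dr[:, None] * u)
        np.add.at(grad, j, -dV_dr[:, None] * u)
        return GradientResult(energy=energy, gradient=grad, method="reverse")

    def gradient_forward(self, geom) -> GradientResult:
        """Gradient by one chain-rule pass per Cartesian coordinate."""
        coords = self._coords(geom)
        i, j, u, r = self._pair_geometry(coords)
        ly = self._log_morse(r)
        w_mono = self._mono_weights(ly)
        energy = float(w_mono.sum()) + self.intercept
        E = self.basis._exponent_matrix()
        n_atoms = len(coords)
        grad = np.zeros((n_atoms, 3))
        n_pairs = len(r)
        for atom in range(n_atoms):
            for ax in range(3):
                dr_dx = np.zeros(n_pairs)
                mask_i = i == atom
                mask_j = j == atom
                dr_dx[mask_i] = u[mask_i, ax]
                dr_dx[mask_j] = -u[mask_j, ax]
                dly_dx = -dr_dx / self.range_parameter
                # directional derivative of every monomial, then sum
                grad[atom, ax] = float(w_mono @ (E @ dly_dx))
        return GradientResult(energy=energy, gradient=grad, method="forward")

    def gradient_fd(self, geom, step: float = 1e-4) -> GradientResult:
        """Central finite-difference gradient (independent oracle)."""
        coords = self._coords(geom).copy()
        grad = np.zeros_like(coords)
        for atom in range(len(coords)):
            for ax in range(3):
                coords[atom, ax] += step
                ep = self.energy(coords)
                coords[atom, ax] -= 2 * step
                em = self.energy(coords)
                coords[atom, ax] += step
                grad[atom, ax] = (ep - em) / (2 * step)
        return GradientResult(energy=self.energy(coords), gradient=grad, method="fd")

    def gradient(self, geom, method: str = "reverse", **kw) -> GradientResult:
        if method == "reverse":
            return self.gradient_reverse(geom)
        if method == "forward":
            return self.gradient_forward(geom)
        if method in ("fd", "finite-difference"):
            return self.gradient_fd(geom, **kw)
        raise ValueError(f"unknown gradient method {method!r}")

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Protocol used by the optimizer, DMC and MEP drivers."""
        res = self.gradient_reverse(coords)
        return res.energy, res.gradient

    # -- Hessian ------------------------------------------------------------

    def hessian(self, geom, step: float = 1e-3) -> np.ndarray:
        """3N x 3N Hessian: central differences of reverse gradients.

        Symmetrized as (H + H^T)/2; the asymmetry before symmetrization is a
        useful consistency diagnostic and stays at finite-difference noise
        level for smooth models.
        """
        if step <= 0:
            raise ValueError("finite-difference step must be positive")
        coords = self._coords(geom).copy()
        n = coords.size
        H = np.empty((n, n))
        flat = coords.ravel()
        for k in range(n):
            flat[k] += step
            gp = self.gradient_reverse(coords).flat
            flat[k] -= 2 * step
            gm = self.gradient_reverse(coords).flat
            flat[k] += step
            H[k] = (gp - gm) / (2 * step)
        return 0.5 * (H + H.T)

    # -- cost accounting ----------------------------------------------------

    def operation_counts(self) -> dict[str, float]:
        """Floating-point operation counts for one energy / gradient call.

        Derived from the evaluation-graph array shapes (multiply-adds count
        as 2, exp as 1); used to verify that the reverse-mode gradient costs
        a small constant multiple of the energy, independent of atom count.
        """
        n_mono = self.basis.n_monomials
        n_var = self.basis.n_variables
        energy = 2 * n_mono * n_var + n_mono + 2 * n_mono + self.basis.size
        backward = 3 * n_mono + 2 * n_mono * n_var + 2 * n_var
        return {"energy": float(energy), "reverse": float(energy + backward),
                "forward": float(energy + 3 * self.basis.symmetry.n_atoms * energy)}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT,
            "basis": self.basis.to_dict(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "range_parameter": self.range_parameter,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, data: dict) -> "PesModel":
        if data.get("format") != MODEL_FORMAT:
            raise ValueError(
                f"unknown model format {data.get('format')!r}; expected {MODEL_FORMAT!r}"
            )
        return cls(
            basis=PipBasis.from_dict(data["basis"]),
            coefficients=np.asarray(data["coefficients"], dtype=float),
            intercept=float(data.get("intercept", 0.0)),
            range_parameter=float(data.get("range_parameter", 3.0)),
        )

    @classmethod
    def load(cls, path) -> "PesModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # -- downstream analyses (thin delegations) -----------------------------

    def optimize(self, start, **kw):
        from .stationary import optimize_geometry
        return optimize_geometry(self, start, **kw)

    def normal_modes(self, geom, **kw):
        from .stationary import normal_modes
        return normal_modes(self, geom, **kw)

    def run_dmc(self, start, config, **kw):
        from .dmc import run_dmc_pes
        return run_dmc_pes(self, start, config, **kw)

    def anneal_mep(self, start, pair, params, **kw):
        from .mep import anneal_trajectory
        return anneal_trajectory(self, start, pair, params, **kw)
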