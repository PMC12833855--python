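"""Stationary points and harmonic frequencies on a fitted surface.

Geometry optimization is quasi-Newton on Cartesians with reverse-mode
gradients; harmonic frequencies come from the mass-weighted Hessian
(finite differences of the analytic gradients), with imaginary frequencies
reported as negative numbers in cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import Geometry
from .units import HARTREE_TO_CM1

__all__ = [
    "ConvergenceError",
    "NormalModeResult",
    "optimize_geometry",
    "normal_modes",
    "frequency_mae",
    "hessian_from_gradient",
]

#: modes with |frequency| below this are counted as zero (translations etc.)
ZERO_MODE_CM1 = 5.0


class ConvergenceError(RuntimeError):
    pass


def _energy_and_gradient(potential, coords: np.ndarray):
    if hasattr(potential, "energy_and_gradient"):
        return potential.energy_and_gradient(coords)
    raise TypeError("potential must provide energy_and_gradient(coords)")


def optimize_geometry(potential, start: Geometry, gtol: float = 1e-8,
                      max_iter: int = 2000) -> Geometry:
    """Minimize the potential from ``start`` until max |gradient| <= gtol."""
    if gtol <= 0:
        raise ValueError("gtol must be positive (an exact zero is unreachable)")
    coords0 = start.coords if isinstance(start, Geometry) else np.asarray(start)
    shape = coords0.shape

    def fun(x):
        V, G = _energy_and_gradient(potential, x.reshape(shape))
        return V, np.asarray(G).ravel()

    res = minimize(fun, coords0.ravel(), jac=True, method="BFGS",
                   options={"gtol": 0.3 * gtol, "maxiter": max_iter})
    gmax = float(np.abs(fun(res.x)[1]).max())
    if gmax > gtol:
        raise ConvergenceError(
            f"geometry optimization stalled: max |gradient| = {gmax:.3e} "
            f"hartree/bohr after {res.nit} iterations (target {gtol:.1e})"
        )
    coords = res.x.reshape(shape)
    if isinstance(start, Geometry):
        return Geometry(elements=start.elements, coords=coords, masses=start.masses)
    return coords


def hessian_from_gradient(grad_fn, coords: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Symmetrized central-difference Hessian of a gradient function."""
    flat = np.array(coords, dtype=float).ravel()
    n = len(flat)
    shape = np.shape(coords)
    H = np.empty((n, n))
    for k in range(n):
        flat[k] += step
        gp = np.asarray(grad_fn(flat.reshape(shape))).ravel()
        flat[k] -= 2 * step
        gm = np.asarray(grad_fn(flat.reshape(shape))).ravel()
        flat[k] += step
        H[k] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


@dataclass
class NormalModeResult:
    """Harmonic frequencies (cm^-1, ascending; imaginary as negative) and
    mass-weighted eigenvectors (columns)."""

    frequencies_cm1: np.ndarray
    modes: np.ndarray
    n_zero_modes: int

    @property
    def vibrational(self) -> np.ndarray:
        """Frequencies with the near-zero (translation/rotation) modes dropped."""
        return self.frequencies_cm1[np.abs(self.frequencies_cm1) >= ZERO_MODE_CM1]


def normal_modes(potential, geom: Geometry, masses: np.ndarray | None = None,
                 step: float = 1e-3, stationarity_gtol: float = 1e-5) -> NormalModeResult:
    """Harmonic analysis of ``potential`` at (a stationary point) ``geom``.

    Eigenvalues lam of the mass-weighted Hessian give frequencies
    sign(lam) sqrt(|lam|) in cm^-1; negative entries signal saddle
    directions.  A warning is emitted if the input is visibly
    non-stationary.
    """
    coords = geom.coords
    if masses is None:
        masses = geom.masses
    _, g = _energy_and_gradient(potential, coords)
    gmax = float(np.abs(g).max())
    if gmax > stationarity_gtol:
        warnings.warn(
            f"normal-mode analysis at a non-stationary geometry "
            f"(max |gradient| = {gmax:.2e} hartree/bohr)",
            stacklevel=2,
        )
    if hasattr(potential, "hessian"):
        H = potential.hessian(coords, step=step)
    else:
        H = hessian_from_gradient(
            lambda x: _energy_and_gradient(potential, x)[1], coords, step
        )
    m = np.repeat(np.asarray(masses, dtype=float), 3)
    Hmw = H / np.sqrt(np.outer(m, m))
    lam, vec = np.linalg.eigh(Hmw)
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * HARTREE_TO_CM1
    order = np.argsort(freqs)
    freqs, vec = freqs[order], vec[:, order]
    n_zero = int((np.abs(freqs) < ZERO_MODE_CM1).sum())
    return NormalModeResult(frequencies_cm1=freqs, modes=vec, n_zero_modes=n_zero)


def frequency_mae(freqs_a, freqs_b) -> float:
    """Mean absolute difference (cm^-1) between two sorted frequency lists."""
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frequency lists differ in length: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))
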