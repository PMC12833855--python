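"""Analytic toy potentials and synthetic datasets.

These stand in for an external ab initio training set: a pairwise Morse-sum
potential over a small symmetric cluster gives energies with the same
structure the fitting pipeline expects (exact permutational invariance,
bound minimum, smooth dissociation), with analytic gradients and, where
closed forms exist, analytic zero-point energies and frequencies for the
DMC, normal-mode and MEP tests.  Sampling covers displacements around the
minimum plus a ladder of stretched configurations along a designated pair
out to very large separation, so dissociative geometries are represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fitting import Dataset
from .geometry import Geometry, batch_distances, interatomic_distances
from .symmetry import SymmetrySpec, parse_symmetry
from .units import CM1_TO_HARTREE, mass_of

__all__ = [
    "MorseSumPotential",
    "HarmonicOscillator",
    "Morse1D",
    "DoubleWell1D",
    "sample_dataset",
    "DEFAULT_STRETCH_DISTANCES",
]

#: Stretch ladder (bohr) for the designated dissociation pair, spanning the
#: near-equilibrium wall to essentially free fragments.
DEFAULT_STRETCH_DISTANCES = (300.0, 150.0, 75.0, 35.0, 20.0, 17.0, 14.0, 11.0,
                             9.0, 8.0, 7.0, 6.0, 5.0, 4.0)

#: Default element assigned to each symmetry class, in class order.
DEFAULT_CLASS_ELEMENTS = ("H", "O", "C", "N")


@dataclass
class MorseSumPotential:
    """Sum of pair Morse terms, exactly invariant under the symmetry group.

    V = sum_pairs De * [(1 - exp(-a (r - re)))^2 - 1], so each pair
    contributes -De at its own equilibrium and 0 at infinite separation.
    Parameters are shared per pair class (e.g. "HH", "HO"), which is what
    makes the potential exactly permutationally invariant.
    """

    symmetry: SymmetrySpec
    params: dict  # pair-class label -> (De, a, re) in hartree / bohr^-1 / bohr
    elements: tuple[str, ...] = ()
    _min_geom: Geometry | None = field(default=None, repr=False)

    def __post_init__(self):
        if isinstance(self.symmetry, str):
            self.symmetry = parse_symmetry(self.symmetry)
        if not self.elements:
            self.elements = tuple(
                DEFAULT_CLASS_ELEMENTS[i] for i in range(len(self.symmetry.classes))
            )
        labels = set(self.symmetry.pair_class_labels)
        missing = labels - set(self.params)
        if missing:
            raise ValueError(f"missing Morse parameters for pair classes {sorted(missing)}")
        for label, (De, a, re) in self.params.items():
            if De <= 0 or a <= 0 or re <= 0:
                raise ValueError(f"Morse parameters for {label!r} must be positive")
        pl = self.symmetry.pair_class_labels
        self._De = np.array([self.params[l][0] for l in pl])
        self._a = np.array([self.params[l][1] for l in pl])
        self._re = np.array([self.params[l][2] for l in pl])

    def element_labels(self) -> list[str]:
        out = []
        for el, (_, cnt) in zip(self.elements, self.symmetry.classes):
            out.extend([el] * cnt)
        return out

    # -- evaluation ---------------------------------------------------------

    def _pair_energy(self, r: np.ndarray) -> np.ndarray:
        g = 1.0 - np.exp(-self._a * (r - self._re))
        return self._De * (g * g - 1.0)

    def energy(self, geom) -> float:
        coords = geom.coords if isinstance(geom, Geometry) else np.asarray(geom)
        r = interatomic_distances(coords.reshape(-1, 3))
        return float(self._pair_energy(r).sum())

    def batch_energies(self, coords: np.ndarray) -> np.ndarray:
        r = batch_distances(np.asarray(coords, dtype=float))
        return self._pair_energy(r).sum(axis=-1)

    def __call__(self, geom):
        return self.energy(geom)

    def energy_and_gradient(self, coords) -> tuple[float, np.ndarray]:
        coords = (coords.coords if isinstance(coords, Geometry)
                  else np.asarray(coords, float)).reshape(-1, 3)
        i, j = np.triu_indices(len(coords), k=1)
        diff = coords[i] - coords[j]
        r = np.linalg.norm(diff, axis=1)
        e = np.exp(-self._a * (r - self._re))
        V = float((self._De * ((1.0 - e) ** 2 - 1.0)).sum())
        dV_dr = 2.0 * self._De * self._a * e * (1.0 - e)
        u = diff / r[:, None]
        grad = np.zeros_like(coords)
        np.add.at(grad, i, dV_dr[:, None] * u)
        np.add.at(grad, j, -dV_dr[:, None] * u)
        return V, grad

    def gradient(self, coords) -> np.ndarray:
        return self.energy_and_gradient(coords)[1]

    # -- minimum ------------------------------------------------------------

    def initial_geometry(self, spread: float | None = None) -> Geometry:
        """Deterministic near-compact starting cluster (not yet optimized)."""
        n = self.symmetry.n_atoms
        rng = np.random.default_rng(20220128)
        scale = spread if spread is not None else float(np.mean(self._re))
        coords = rng.normal(scale=0.6 * scale, size=(n, 3))
        coords -= coords.mean(axis=0)
        return Geometry(elements=self.element_labels(), coords=coords)

    def minimum(self, start: Geometry | None = None, gtol: float = 1e-10) -> Geometry:
        """Locally optimal geometry from ``start`` (cached for the default)."""
        if start is None and self._min_geom is not None:
            return self._min_geom
        g0 = start if start is not None else self.initial_geometry()

        def fun(x):
            V, G = self.energy_and_gradient(x.reshape(-1, 3))
            return V, G.ravel()

        res = minimize(fun, g0.coords.ravel(), jac=True, method="BFGS",
                       options={"gtol": gtol, "maxiter": 5000})
        geom = Geometry(elements=g0.elements, coords=res.x.reshape(-1, 3),
                        masses=g0.masses)
        if start is None:
            self._min_geom = geom
        return geom


# ---------------------------------------------------------------------------
# low-dimensional analytic references


@dataclass
class HarmonicOscillator:
    """Separable harmonic potential V = 1/2 sum m_i w_i^2 x_i^2 (a.u.)."""

    omegas: np.ndarray
    masses: np.ndarray
    x0: np.ndarray | None = None

    def __post_init__(self):
        self.omegas = np.atleast_1d(np.asarray(self.omegas, dtype=float))
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if self.x0 is None:
            self.x0 = np.zeros_like(self.omegas)

    @property
    def zpe(self) -> float:
        """Exact zero-point energy, hartree: sum of hbar*w/2."""
        return float(0.5 * self.omegas.sum())

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return 0.5 * ((self.masses * self.omegas ** 2) * (X - self.x0) ** 2).sum(axis=1)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return (self.masses * self.omegas ** 2) * (np.asarray(x) - self.x0)


@dataclass
class Morse1D:
    """One-dimensional Morse oscillator V = De (1 - exp(-a x))^2.

    The exact ground state is E_0 = w0/2 - w0^2/(16 De) with
    w0 = a sqrt(2 De / m), all in hartree atomic units.
    """

    De: float
    a: float
    m: float

    @property
    def omega0(self) -> float:
        return self.a * np.sqrt(2.0 * self.De / self.m)

    @property
    def zpe(self) -> float:
        return float(0.5 * self.omega0 - self.omega0 ** 2 / (16.0 * self.De))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(X)[:, 0]
        g = 1.0 - np.exp(-self.a * x)
        return self.De * g * g

    def gradient(self, x: np.ndarray) -> np.ndarray:
        e = np.exp(-self.a * np.asarray(x, dtype=float))
        return 2.0 * self.De * self.a * e * (1.0 - e)


@dataclass
class DoubleWell1D:
    """Symmetric quartic double well V = b (x^2 - x0^2)^2 / x0^4 ... simplified:

    V(x) = h * ((x/x0)^2 - 1)^2 with barrier height h at x = 0 and minima at
    +/- x0; the origin is a first-order saddle in any embedding that adds
    harmonic transverse modes.
    """

    h: float
    x0: float

    def __call__(self, X: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(X)[:, 0]
        t = (x / self.x0) ** 2 - 1.0
        return self.h * t * t

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        t = (x / self.x0) ** 2 - 1.0
        return 4.0 * self.h * t * x / self.x0 ** 2

    def curvature(self, x: float) -> float:
        t = (x / self.x0) ** 2
        return 4.0 * self.h * (3.0 * t - 1.0) / self.x0 ** 2


# ---------------------------------------------------------------------------
# dataset sampling


def sample_dataset(potential: MorseSumPotential, n_points: int,
                   energy_cap_cm1: float, seed: int,
                   displacement_scale: float = 0.35,
                   stretch_pair: tuple[int, int] | None = None,
                   stretch_distances=DEFAULT_STRETCH_DISTANCES,
                   n_per_stretch: int = 3) -> Dataset:
    """Draw a synthetic training set from an analytic potential.

    ``n_points`` geometries are normal displacements (scale in bohr) of the
    potential minimum; on top of those, each distance in
    ``stretch_distances`` contributes ``n_per_stretch`` jittered geometries
    with the designated pair pulled to that separation, mimicking coverage
    out to dissociation.  Records with energy above ``energy_cap_cm1``
    (relative to the potential minimum) are discarded.  Deterministic for a
    fixed seed.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    rng = np.random.default_rng(seed)
    min_geom = potential.minimum()
    v_min = potential.energy(min_geom)
    elements = min_geom.elements
    base = min_geom.coords

    configs = [base + rng.normal(scale=displacement_scale, size=base.shape)
               for _ in range(n_points)]
    if stretch_pair is None:
        stretch_pair = (0, potential.symmetry.n_atoms - 1)
    i, j = stretch_pair
    axis = base[i] - base[j]
    axis = axis / np.linalg.norm(axis)
    for d in stretch_distances:
        for _ in range(n_per_stretch):
            c = base + rng.normal(scale=0.25 * displacement_scale, size=base.shape)
            c[i] = c[j] + axis * d
            configs.append(c)

    coords = np.stack(configs)
    energies = potential.batch_energies(coords)
    cap = v_min + energy_cap_cm1 * CM1_TO_HARTREE
    keep = energies <= cap
    if not keep.any():
        raise ValueError(
            f"energy cap {energy_cap_cm1} cm^-1 above the minimum retained no points"
        )
    geoms = [Geometry(elements=list(elements), coords=coords[k])
             for k in np.flatnonzero(keep)]
    return Dataset(geometries=geoms, energies=energies[keep],
                   reference_energy=v_min)
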