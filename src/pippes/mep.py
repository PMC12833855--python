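"""Relaxed dissociation pathways by simulated-annealing trajectories.

A classical trajectory (velocity Verlet) is started at one end of the
pathway with a small kinetic energy; every step a fixed fraction of the
kinetic energy is removed (velocity rescale), and a "brake" halves the
kinetic energy whenever it exceeds a threshold, keeping the trajectory
close to the valley floor.  Binning the visited configurations on a
designated atom-pair distance and keeping the minimum energy per bin
yields the relaxed energy profile; trajectories started from opposite
ends are merged on their overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Geometry
from .units import CM1_TO_HARTREE, HARTREE_TO_CM1

__all__ = ["AnnealParams", "MepPath", "anneal_trajectory", "merge_paths",
           "dissociation_energy", "DivergenceError", "NoPlateauError"]


class DivergenceError(RuntimeError):
    pass


class NoPlateauError(RuntimeError):
    pass


@dataclass
class AnnealParams:
    """Annealing-trajectory controls (energies in cm^-1, time in a.u.).

    The defaults mirror the outer dissociation trajectory used for the
    Zundel-cation pathway: 12 cm^-1 of initial kinetic energy, a 5 a.u.
    time step, a loss of 0.01% of the kinetic energy per step, and a brake
    that halves any kinetic energy above 100 cm^-1.
    """

    initial_ke_cm1: float = 12.0
    dt_au: float = 5.0
    loss_fraction_per_step: float = 1e-4
    brake_threshold_cm1: float = 100.0
    brake_factor: float = 0.5
    max_steps: int = 500_000
    stop_ke_cm1: float = 1e-3
    stop_gtol: float = 1e-6          # hartree/bohr
    bin_width: float = 0.05          # bohr, for the relaxed profile

    def __post_init__(self):
        if not (0.0 < self.loss_fraction_per_step < 1.0):
            raise ValueError("loss fraction must be in (0, 1)")
        if not (0.0 < self.brake_factor < 1.0):
            raise ValueError("brake factor must be in (0, 1)")
        if self.dt_au <= 0:
            raise ValueError("time step must be positive")


@dataclass
class MepPath:
    """Relaxed energy profile along a reaction coordinate.

    ``coords`` (bohr) ascend; ``energies`` are potential energies in hartree
    of the minimum-energy configuration found in each coordinate bin, with
    the corresponding geometries kept alongside.
    """

    coords: np.ndarray
    energies: np.ndarray
    geometries: list[np.ndarray] = field(default_factory=list)
    overlap_disagreement_cm1: float | None = None
    ke_trace_cm1: np.ndarray | None = None  # post-brake KE per step, cm^-1

    @property
    def energies_cm1(self) -> np.ndarray:
        """Energies in cm^-1 relative to the path minimum."""
        return (self.energies - self.energies.min()) * HARTREE_TO_CM1

    @property
    def r_min(self) -> float:
        """Reaction coordinate at the path minimum."""
        return float(self.coords[np.argmin(self.energies)])

    def __len__(self) -> int:
        return len(self.coords)

    def save(self, path) -> None:
        lines = ["# coordinate_bohr  energy_hartree"]
        for c, e in zip(self.coords, self.energies):
            lines.append(f"{c:14.6f} {e:20.12e}")
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


def _kinetic_energy(v: np.ndarray, masses: np.ndarray) -> float:
    return float(0.5 * (masses[:, None] * v * v).sum())


def anneal_trajectory(potential, start: Geometry, pair: tuple[int, int],
                      params: AnnealParams, direction: str = "close") -> MepPath:
    """Run the annealing trajectory and return the binned relaxed profile.

    ``pair`` designates the reaction-coordinate atom pair; the initial
    kinetic energy is put into the relative motion of those two atoms,
    closing the pair by default (``direction="open"`` reverses it).
    """
    i, j = pair
    coords = np.array(start.coords, dtype=float)
    masses = np.asarray(start.masses, dtype=float)
    dt = params.dt_au

    axis = coords[j] - coords[i]
    rc = np.linalg.norm(axis)
    if rc == 0:
        raise ValueError("reaction-coordinate atoms are coincident")
    axis = axis / rc
    ke0 = params.initial_ke_cm1 * CM1_TO_HARTREE
    v = np.zeros_like(coords)
    if ke0 > 0:
        s = np.sqrt(2.0 * ke0 / (masses[i] + masses[j]))
        sgn = 1.0 if direction == "close" else -1.0
        v[i] = sgn * s * axis
        v[j] = -sgn * s * axis

    V, G = potential.energy_and_gradient(coords)
    v_ceiling = V + 1.0  # a full hartree above the start flags divergence
    keep = 1.0 - params.loss_fraction_per_step
    brake = params.brake_threshold_cm1 * CM1_TO_HARTREE

    rec_r = [rc]
    rec_E = [V]
    rec_X = [coords.copy()]
    rec_ke = [_kinetic_energy(v, masses)]
    acc = -G / masses[:, None]
    for _ in range(params.max_steps):
        coords = coords + v * dt + 0.5 * acc * dt * dt
        V, G = potential.energy_and_gradient(coords)
        if not np.isfinite(V) or V > v_ceiling:
            raise DivergenceError(
                f"trajectory energy rose to {V!r} hartree; reduce the time step"
            )
        new_acc = -G / masses[:, None]
        v = v + 0.5 * (acc + new_acc) * dt
        acc = new_acc
        # anneal, then brake
        v = v * np.sqrt(keep)
        ke = _kinetic_energy(v, masses)
        if ke > brake:
            v = v * np.sqrt(params.brake_factor)
            ke = ke * params.brake_factor
        rec_r.append(float(np.linalg.norm(coords[j] - coords[i])))
        rec_E.append(V)
        rec_X.append(coords.copy())
        rec_ke.append(ke)
        if (ke < params.stop_ke_cm1 * CM1_TO_HARTREE
                and float(np.abs(G).max()) < params.stop_gtol):
            break
    path = _bin_path(np.asarray(rec_r), np.asarray(rec_E), rec_X, params.bin_width)
    path.ke_trace_cm1 = np.asarray(rec_ke) * HARTREE_TO_CM1
    return path


def _bin_path(r: np.ndarray, E: np.ndarray, X: list[np.ndarray],
              bin_width: float) -> MepPath:
    """Minimum energy per coordinate bin; the recorded coordinate is that of
    the minimum-energy sample, not the bin center."""
    bins = np.floor(r / bin_width).astype(np.int64)
    best: dict[int, int] = {}
    for k, b in enumerate(bins):
        if b not in best or E[k] < E[best[b]]:
            best[b] = k
    idx = sorted(best.values(), key=lambda k: r[k])
    return MepPath(
        coords=r[idx],
        energies=E[idx],
        geometries=[X[k] for k in idx],
    )


def merge_paths(paths: list[MepPath]) -> MepPath:
    """Merge overlapping relaxed profiles into one monotone-coordinate path.

    The shared coordinate range must be non-empty; the maximum energy
    disagreement there (after interpolation onto the overlap) is reported on
    the merged path.
    """
    if len(paths) < 2:
        raise ValueError("need at least two paths to merge")
    lo = max(p.coords.min() for p in paths)
    hi = min(p.coords.max() for p in paths)
    if lo >= hi:
        raise ValueError(
            f"paths do not overlap: common range [{lo:.3f}, {hi:.3f}] bohr is empty"
        )
    grid = np.linspace(lo, hi, 64)
    interp = [np.interp(grid, p.coords, p.energies) for p in paths]
    disagreement = max(
        float(np.abs(a - b).max()) * HARTREE_TO_CM1
        for ai, a in enumerate(interp) for b in interp[ai + 1:]
    )
    r = np.concatenate([p.coords for p in paths])
    E = np.concatenate([p.energies for p in paths])
    X = [g for p in paths for g in (p.geometries or [None] * len(p))]
    width = min(np.diff(p.coords).min() for p in paths if len(p) > 1)
    merged = _bin_path(r, E, X, max(width, 1e-6))
    merged.overlap_disagreement_cm1 = disagreement
    return merged


def dissociation_energy(path: MepPath, slope_tol_cm1_per_bohr: float = 0.5,
                        tail_bins: int = 5) -> float:
    """D_e (cm^-1): asymptotic plateau energy minus the path minimum.

    The plateau is the mean energy of the last ``tail_bins`` points and must
    be flat: |dE/dr| below ``slope_tol_cm1_per_bohr`` across the tail.
    """
    if len(path) < tail_bins + 1:
        raise NoPlateauError("path too short to identify an asymptotic plateau")
    r = path.coords[-tail_bins:]
    E = path.energies[-tail_bins:] * HARTREE_TO_CM1
    span = r[-1] - r[0]
    if span <= 0:
        raise NoPlateauError("degenerate tail coordinates")
    slope = abs((E[-1] - E[0]) / span)
    if slope > slope_tol_cm1_per_bohr:
        raise NoPlateauError(
            f"no plateau: tail slope {slope:.3g} cm^-1/bohr exceeds "
            f"{slope_tol_cm1_per_bohr}; extend the path to larger separations"
        )
    plateau = float(E.mean())
    return plateau - float(path.energies.min()) * HARTREE_TO_CM1
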