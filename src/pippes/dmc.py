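"""Unbiased diffusion Monte Carlo for zero-point energies.

An ensemble of walkers in the full coordinate space is propagated in
imaginary time: each step every Cartesian degree of freedom diffuses by
Gaussian noise of standard deviation sqrt(dt/m), then walkers branch with
integer replication n = floor(exp(-(V - E_ref) dt) + u), u ~ U(0,1), capped
at a small maximum.  The reference energy is updated from the ensemble mean
potential with a population-feedback term,

    E_ref = <V> - alpha (N - N_target)/N_target,  alpha = 1/dt by default.

The long-time average of E_ref above the potential minimum estimates the
zero-point energy.  Replicate trajectories with independent sub-seeds give
the statistical uncertainty (standard deviation across trajectories).
Walkers whose potential falls below the known minimum flag "holes" in a
fitted surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .units import CM1_TO_HARTREE, HARTREE_TO_CM1

__all__ = ["DmcConfig", "DmcResult", "SimulationCollapseError", "dmc_step",
           "run_dmc", "run_dmc_pes", "hole_scan"]


class SimulationCollapseError(RuntimeError):
    """The walker population died out."""


@dataclass
class DmcConfig:
    """Protocol parameters.  The defaults are the production settings used
    for the Zundel-cation surfaces (30,000 walkers, 55,000 steps of 5.0 a.u.
    with 5,000 equilibration steps, 10 replicate trajectories); tests scale
    these down."""

    n_walkers: int = 30_000
    n_steps: int = 55_000
    n_equilibration: int = 5_000
    dt: float = 5.0
    n_trajectories: int = 10
    seed: int = 0
    alpha: float | None = None  # population feedback; 1/dt if None
    branch_cap: int = 3
    hole_tolerance_cm1: float = 10.0

    def __post_init__(self):
        if self.n_walkers < 1:
            raise ValueError("need at least one walker")
        if self.dt <= 0:
            raise ValueError("imaginary-time step must be positive")
        if not (0 <= self.n_equilibration < self.n_steps):
            raise ValueError("need 0 <= n_equilibration < n_steps")

    @property
    def feedback(self) -> float:
        return (1.0 / self.dt) if self.alpha is None else self.alpha


@dataclass
class DmcResult:
    """Zero-point energy estimate with across-trajectory uncertainty."""

    zpe_cm1: float
    stderr_cm1: float
    zpes_cm1: np.ndarray          # per-trajectory ZPEs
    traces: list[np.ndarray]      # per-step E_ref (hartree), one per trajectory
    v_min: float                  # hartree; the energy zero
    populations: list[np.ndarray]
    holes: list[tuple[int, int, float, np.ndarray]]  # (traj, step, V, coords)

    @property
    def n_holes(self) -> int:
        return len(self.holes)


def hole_scan(V: np.ndarray, walkers: np.ndarray, v_min: float,
              tolerance_cm1: float = 10.0) -> list[tuple[float, np.ndarray]]:
    """Flag walkers whose potential lies below v_min - tolerance.

    On a faithful surface bounded below by its global minimum the report is
    empty; entries point at unphysical "holes" in a fit.
    """
    thresh = v_min - tolerance_cm1 * CM1_TO_HARTREE
    bad = np.flatnonzero(V < thresh)
    return [(float(V[k]), walkers[k].copy()) for k in bad]


def dmc_step(walkers: np.ndarray, potential, e_ref: float, dt: float,
             masses: np.ndarray, rng: np.random.Generator,
             alpha: float, n_target: int, branch_cap: int = 3):
    """One diffuse/branch/update cycle.

    Returns ``(walkers', V', e_ref')`` where ``V'`` are the potentials of
    the post-branching ensemble.
    """
    sigma = np.sqrt(dt / masses)
    walkers = walkers + rng.normal(size=walkers.shape) * sigma
    V = np.asarray(potential(walkers), dtype=float)
    if np.isnan(V).any():
        k = int(np.flatnonzero(np.isnan(V))[0])
        raise FloatingPointError(
            f"potential returned NaN at walker configuration {walkers[k]!r}"
        )
    w = np.exp(-(V - e_ref) * dt)
    n = np.floor(w + rng.random(len(w))).astype(np.intp)
    np.clip(n, 0, branch_cap, out=n)
    if n.sum() == 0:
        raise SimulationCollapseError(
            "walker population collapsed to zero; lower dt or check E_ref feedback"
        )
    walkers = np.repeat(walkers, n, axis=0)
    V = np.repeat(V, n)
    e_ref = float(V.mean()) - alpha * (len(V) - n_target) / n_target
    return walkers, V, e_ref


def run_dmc(potential, x0: np.ndarray, masses: np.ndarray, cfg: DmcConfig,
            v_min: float | None = None, max_hole_records: int = 100) -> DmcResult:
    """Replicated DMC trajectories for an arbitrary potential callable.

    ``potential`` maps an array of walker configurations (n, n_dof) to
    energies (n,).  All walkers start exactly at ``x0`` (intended to be the
    potential minimum).  Per-trajectory ZPE = mean post-equilibration E_ref
    minus ``v_min`` (default: the potential at ``x0``).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    masses = np.broadcast_to(np.asarray(masses, dtype=float), x0.shape)
    if v_min is None:
        v_min = float(np.asarray(potential(x0[None, :]), dtype=float)[0])
    traces, populations, zpes, holes = [], [], [], []
    root = np.random.SeedSequence(cfg.seed)
    for traj, ss in enumerate(root.spawn(cfg.n_trajectories)):
        rng = np.random.default_rng(ss)
        walkers = np.tile(x0, (cfg.n_walkers, 1))
        e_ref = v_min
        trace = np.empty(cfg.n_steps)
        pop = np.empty(cfg.n_steps, dtype=np.intp)
        for step in range(cfg.n_steps):
            walkers, V, e_ref = dmc_step(
                walkers, potential, e_ref, cfg.dt, masses, rng,
                cfg.feedback, cfg.n_walkers, cfg.branch_cap,
            )
            trace[step] = e_ref
            pop[step] = len(walkers)
            if len(holes) < max_hole_records:
                for v, x in hole_scan(V, walkers, v_min, cfg.hole_tolerance_cm1):
                    if len(holes) >= max_hole_records:
                        break
                    holes.append((traj, step, v, x))
        traces.append(trace)
        populations.append(pop)
        zpes.append((trace[cfg.n_equilibration:].mean() - v_min) * HARTREE_TO_CM1)
    zpes = np.asarray(zpes)
    stderr = float(zpes.std(ddof=1)) if len(zpes) > 1 else 0.0
    return DmcResult(
        zpe_cm1=float(zpes.mean()),
        stderr_cm1=stderr,
        zpes_cm1=zpes,
        traces=traces,
        v_min=v_min,
        populations=populations,
        holes=holes,
    )


def run_dmc_pes(model, start: Geometry, cfg: DmcConfig, **kw) -> DmcResult:
    """DMC on a fitted PES, starting all walkers at ``start``."""
    n_atoms = start.n_atoms

    def potential(X):
        return model.batch_energies(X.reshape(-1, n_atoms, 3))

    masses = np.repeat(start.masses, 3)
    return run_dmc(potential, start.coords.ravel(), masses, cfg, **kw)
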