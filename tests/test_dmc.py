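import numpy as np
import pytest

from pippes.dmc import (DmcConfig, SimulationCollapseError, dmc_step, hole_scan,
                        run_dmc)
from pippes.synthetic import HarmonicOscillator, Morse1D
from pippes.units import HARTREE_TO_CM1

# deliberately small settings so each simulation runs in a couple of seconds
SMALL = dict(n_walkers=600, n_steps=6000, n_equilibration=1000, dt=5.0,
             n_trajectories=4)


def _tolerance(result, exact_cm1):
    """3x the across-trajectory spread, with a 1.5 cm^-1 floor for the
    residual time-step bias at these settings."""
    return max(3 * result.stderr_cm1, 1.5)


def test_constant_potential_reference_energy():
    """With V = c and no feedback, E_ref equals c exactly every step."""
    rng = np.random.default_rng(0)
    c = -0.25
    walkers = np.zeros((200, 1))
    e_ref = c
    for _ in range(20):
        walkers, V, e_ref = dmc_step(
            walkers, lambda X: np.full(len(X), c), e_ref, 1.0,
            np.ones(1), rng, alpha=0.0, n_target=200,
        )
        assert e_ref == pytest.approx(c, abs=1e-14)
    assert 100 < len(walkers) < 400  # population a martingale, not drifting far


def test_free_particle_zpe_is_zero():
    pot = lambda X: np.zeros(len(X))
    cfg = DmcConfig(seed=5, **SMALL)
    res = run_dmc(pot, np.zeros(1), np.ones(1), cfg)
    assert abs(res.zpe_cm1) <= max(3 * res.stderr_cm1, 1.0)


def test_harmonic_oscillator_zpe():
    ho = HarmonicOscillator(omegas=[0.005], masses=[1.0])
    cfg = DmcConfig(seed=7, **SMALL)
    res = run_dmc(ho, np.zeros(1), np.ones(1), cfg)
    exact = ho.zpe * HARTREE_TO_CM1
    assert abs(res.zpe_cm1 - exact) <= _tolerance(res, exact)


def test_separable_modes_add():
    """A 2-mode quadratic potential has ZPE = (w1 + w2)/2."""
    ho = HarmonicOscillator(omegas=[0.004, 0.008], masses=[1.0, 1.0])
    cfg = DmcConfig(seed=9, **SMALL)
    res = run_dmc(ho, np.zeros(2), np.ones(2), cfg)
    exact = ho.zpe * HARTREE_TO_CM1
    assert abs(res.zpe_cm1 - exact) <= _tolerance(res, exact)


def test_morse_oscillator_zpe():
    mo = Morse1D(De=0.02, a=1.0, m=1000.0)
    cfg = DmcConfig(seed=13, **SMALL)
    res = run_dmc(mo, np.zeros(1), np.array([1000.0]), cfg)
    exact = mo.zpe * HARTREE_TO_CM1
    assert exact < 0.5 * mo.omega0 * HARTREE_TO_CM1  # anharmonicity lowers it
    assert abs(res.zpe_cm1 - exact) <= _tolerance(res, exact)


def test_seed_reproducibility_and_population_band():
    ho = HarmonicOscillator(omegas=[0.005], masses=[1.0])
    cfg = DmcConfig(seed=21, n_walkers=300, n_steps=1500, n_equilibration=300,
                    dt=5.0, n_trajectories=2)
    a = run_dmc(ho, np.zeros(1), np.ones(1), cfg)
    b = run_dmc(ho, np.zeros(1), np.ones(1), cfg)
    assert a.zpe_cm1 == b.zpe_cm1  # bit-for-bit
    assert all(np.array_equal(x, y) for x, y in zip(a.traces, b.traces))
    for pop in a.populations:
        assert pop.min() > 0.5 * cfg.n_walkers
        assert pop.max() < 2.0 * cfg.n_walkers


def test_population_collapse_raises():
    """A potential far above E_ref kills every walker."""
    pot = lambda X: np.full(len(X), 1e3)
    cfg = DmcConfig(seed=3, n_walkers=50, n_steps=100, n_equilibration=10, dt=5.0,
                    n_trajectories=1, alpha=0.0)
    with pytest.raises(SimulationCollapseError):
        run_dmc(pot, np.zeros(1), np.ones(1), cfg, v_min=0.0)


def test_nan_potential_aborts():
    def pot(X):
        V = np.zeros(len(X))
        V[0] = np.nan
        return V

    cfg = DmcConfig(seed=3, n_walkers=20, n_steps=10, n_equilibration=1, dt=1.0,
                    n_trajectories=1)
    with pytest.raises(FloatingPointError):
        run_dmc(pot, np.zeros(1), np.ones(1), cfg, v_min=0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        DmcConfig(n_walkers=0)
    with pytest.raises(ValueError):
        DmcConfig(dt=-1.0)
    with pytest.raises(ValueError):
        DmcConfig(n_steps=10, n_equilibration=10)


# -- hole detection ---------------------------------------------------------


def test_hole_scan_flags_sub_minimum_walkers():
    V = np.array([0.0, -0.001, 0.002, -0.01])
    walkers = np.arange(8.0).reshape(4, 2)
    report = hole_scan(V, walkers, v_min=0.0, tolerance_cm1=10.0)
    flagged = [v for v, _ in report]
    assert flagged == [-0.001, -0.01]
    # tolerance larger than the pocket depth: nothing flagged
    assert hole_scan(V, walkers, v_min=0.0, tolerance_cm1=3000.0) == []


def test_bounded_potential_has_no_holes():
    ho = HarmonicOscillator(omegas=[0.005], masses=[1.0])
    cfg = DmcConfig(seed=17, n_walkers=200, n_steps=500, n_equilibration=100,
                    dt=5.0, n_trajectories=1)
    res = run_dmc(ho, np.zeros(1), np.ones(1), cfg)
    assert res.n_holes == 0


def test_artificial_pocket_is_detected():
    """A pocket dug below the nominal minimum is flagged with its geometry."""
    def pot(X):
        x = X[:, 0]
        V = 0.5 * 1e-4 * x * x
        V[np.abs(x) > 4.0] = -0.01  # ~ -2200 cm^-1 hole
        return V

    cfg = DmcConfig(seed=19, n_walkers=200, n_steps=800, n_equilibration=100,
                    dt=5.0, n_trajectories=1)
    res = run_dmc(pot, np.zeros(1), np.ones(1), cfg, v_min=0.0)
    assert res.n_holes > 0
    traj, step, v, x = res.holes[0]
    assert v < 0.0
    assert abs(x[0]) > 4.0


def test_dt_halving_reduces_harmonic_bias():
    """The time-step bias of the branching scheme shrinks when dt is halved
    (same total imaginary time)."""
    ho = HarmonicOscillator(omegas=[0.01], masses=[1.0])
    exact = ho.zpe * HARTREE_TO_CM1
    biases = []
    for dt, steps in ((20.0, 4000), (10.0, 8000)):
        cfg = DmcConfig(seed=42, n_walkers=1500, n_steps=steps,
                        n_equilibration=steps // 6, dt=dt, n_trajectories=5)
        res = run_dmc(ho, np.zeros(1), np.ones(1), cfg)
        biases.append(res.zpe_cm1 - exact)
    assert abs(biases[1]) < abs(biases[0])
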