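# pippes

Permutationally invariant polynomial (PIP) potential energy surfaces with
fast reverse-mode analytic gradients — and the analyses a fitted surface is
built for: diffusion Monte Carlo zero-point energies, harmonic frequencies
at stationary points, and annealed minimum-energy dissociation paths.

## The problem

High-accuracy studies of floppy molecules and clusters (the protonated
water dimer H5O2+ is the canonical example) need a global potential energy
surface V(x) fitted to tens of thousands of ab initio energies.  Two
requirements dominate the design:

1. **Exact permutational symmetry.**  Exchanging identical nuclei (the five
   H atoms, the two O atoms) must leave V unchanged exactly, not just
   approximately — quantum simulations such as diffusion Monte Carlo sample
   permuted configurations freely.
2. **Cheap analytic gradients.**  Classical trajectories, geometry
   optimization and Hessians all need dV/dx; finite differences cost 6N
   energy calls and numerical noise.

The PIP ansatz solves both with a linear model

```
V(y) = Σ_α c_α p_α(y),      y_ij = exp(−r_ij / a),
```

where r_ij are the N(N−1)/2 internuclear distances, a is a range parameter
(3.0 bohr here), and each basis function p_α is the sum of one orbit of
monomials in the Morse variables y under the group of permutations of
identical atoms — hence exactly invariant by construction.  For an "A5B2"
system (5 + 2 atoms, group S5 × S2 of order 240 acting on 21 pair
variables) the basis contains 59, 218, 772, 2651, 8717 polynomials at
maximum total degree 3, 4, 5, 6, 7.

`pippes` implements the full toolchain natively:

* **symmetry & basis** — parse symmetry strings ("A5B2"), build the induced
  pair-permutation group, enumerate the PIP basis by canonical-representative
  orbit hashing, and cross-check every count against an independent
  Burnside/Molien generating-function oracle;
* **fitting** — weighted linear least squares in a statsmodels-style
  Model/Results API, with weights w(E) = Δ/(E+Δ) (Δ = 0.1 hartree) that
  de-emphasize high-energy points, energy-cutoff filtering, and basis
  augmentation by products of PIPs ranked by their maximum value over the
  training set;
* **gradients** — forward differentiation (one chain-rule pass per
  coordinate, cost ∝ 3N energy calls) and reverse differentiation (a single
  backward sweep through the polynomial evaluation graph, cost a small
  constant multiple of one energy call, independent of N), plus Hessians
  from finite differences of the reverse gradients;
* **diffusion Monte Carlo** — the standard unbiased walker-branching
  protocol for zero-point energies, with replicate trajectories for error
  bars and a "hole" scan for regions a fit dips below its global minimum;
* **stationary analysis** — quasi-Newton optimization on reverse gradients
  and mass-weighted normal modes;
* **minimum-energy paths** — simulated-annealing trajectories with
  fractional kinetic-energy loss and a KE brake, binned into relaxed energy
  profiles, merged across overlapping runs, with plateau-based dissociation
  energies;
* **synthetic fixtures** — analytic Morse-sum cluster potentials and
  dataset samplers so the entire pipeline is testable without any external
  data.

## Worked example

Fit an order-5 PIP surface to a synthetic water-like A2B1 (H2O-flavoured)
Morse-sum dataset, then analyse it:

```python
import numpy as np
from pippes import DmcConfig, MorsePipModel, enumerate_pip_basis, normal_modes
from pippes.dmc import run_dmc_pes
from pippes.synthetic import MorseSumPotential, sample_dataset

pot = MorseSumPotential("A2B1", params={"AA": (0.02, 1.0, 2.8),
                                        "AB": (0.18, 1.2, 1.8)})
ds = sample_dataset(pot, 400, energy_cap_cm1=60000.0, seed=3)
res = MorsePipModel(ds, enumerate_pip_basis("A2B1", 5)).fit()
print(res.summary())

pes = res.pes                       # the fitted PesModel
gmin = pes.optimize(pot.minimum())  # relax on the fitted surface
nm = normal_modes(pes, gmin)
print("vibrational frequencies (cm^-1):", np.round(nm.vibrational, 1))

cfg = DmcConfig(n_walkers=2000, n_steps=20000, n_equilibration=2000,
                dt=5.0, n_trajectories=5, seed=1)
dmc = run_dmc_pes(pes, gmin, cfg)
print(f"DMC ZPE: {dmc.zpe_cm1:.1f} +/- {dmc.stderr_cm1:.1f} cm^-1")
```

which prints

```
PIP least-squares fit
==============================================
symmetry                    A2B1
max order                      5
basis size                    34
n points                     398
effective rank                34
Delta (hartree)              0.1
RMSE  (cm^-1)            139.533
wRMSE (cm^-1)            115.161
MAE   (cm^-1)             88.785
R^2                   0.99990073

vibrational frequencies (cm^-1): [ 964.8 3843.4 3989.5]
DMC ZPE: 4297.1 +/- 1.5 cm^-1
```

The 34-term fit reproduces the toy training energies to ~140 cm^-1 RMSE
(tighter with higher order), the three vibrational modes of the triatomic
sit on top of six near-zero translation/rotation modes, and the DMC
zero-point energy lands ~100 cm^-1 below the harmonic estimate
(½Σω = 4398.8 cm^-1), as anharmonicity demands.

The same operations are available from a shell:

```sh
pippes basis count --symmetry A5B2 --order 7      # -> 8717
pippes basis build --symmetry A2B1 --order 3 --out basis.json
pippes fixtures --symmetry A2B1 --n 2000 --seed 7 --out train.dat
pippes fit --basis basis.json --data train.dat --emax-cm1 60000 --out model.json
pippes eval model.json geom.xyz
pippes grad model.json geom.xyz --method reverse
pippes dmc --model model.json --start min.xyz --seed 1 ...
pippes mep --model model.json --start far.xyz --pair 0 1 --out path.dat
```

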