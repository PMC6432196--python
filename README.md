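# samcpoly

Flat-histogram Monte Carlo for single **sterically stiff square-well polymer
chains**: estimate the density of states g(E) with Stochastic Approximation
Monte Carlo (SAMC), and derive from it the chain's complete thermodynamics —
micro-canonical transition classification, canonical specific heat and
structural averages, contact matrices, and knot identification of collapsed
morphologies.

## The model

A single chain of N fused hard spheres (diameter σ = 1) on rigid bonds of
length L ∈ (0.5, 1]. Non-bonded monomers (|i−j| ≥ 2) interact through a
square well,

    U(r) = ∞    for r < 1        (hard core)
         = −ε   for 1 ≤ r ≤ λ    (attraction, ε = 1)
         = 0    for r > λ,

with λ = 1.1 by default. Because next-nearest neighbours must stay a sphere
diameter apart, short bonds restrict the bond angle to
θ ≥ θ_min = 2 arcsin(1/2L): stiffness of purely *entropic* (steric) origin,
tuned by the single geometric parameter L. For 2L ≤ λ (L ≤ 0.55 at λ = 1.1)
next-nearest neighbours sit permanently inside the well — the *stiff*
regime, whose energy spectrum is rigidly shifted by −(N−2); L = 1 is the
flexible tangent-sphere limit.

Energies are exact non-positive integers (−1 per contact), so g(E) lives on
an integer grid. SAMC performs an unbiased move walk (pivot, crankshaft,
end rotation — all bond-preserving and symmetric), accepts with
min(1, g(E_old)/g(E_new)), and updates after every step

    ln g(E) ← ln g(E) + γ_t (δ_{E,E'} − 1/M),      γ_t = γ₀ min(1, t₀/t),

where E' is the post-decision energy and M the number of energy levels seen
so far. The 1/t gain satisfies Σγ_t = ∞ and Σγ_t^ν < ∞ (1 < ν < 2), the
two convergence conditions of stochastic approximation. From the converged
S(E) = ln g(E) the analysis layer computes β_micro = dS/dE,
γ(E) = d²S/dE², Z(T) = Σ_E g(E)e^{−E/T}, C_N(T), canonical averages
⟨O⟩(T) = Σ_E Ō(E) g(E) e^{−E/T}/Z, and P(E|T). A γ(E) peak above zero
signals a first-order pseudo phase transition (convex intruder in S), below
zero a second-order one; P(E|T) double peaks are the canonical first-order
fingerprint. Low-energy conformations are classified topologically by
closing the chain end-to-end and evaluating the Alexander determinant
|Δ(−1)| (1 = unknot, 3 = trefoil, 5 = figure-eight).

An independent brute-force oracle (uniform bond-direction sampling with
hard-core rejection — exact for the rigid-bond measure) anchors the engine
at small N, including the closed form for the trimer contact probability
(λ²−1)/(4L²−1).

## Worked example

Collapse of the flexible N = 20 chain (λ = 1.1):

```python
import numpy as np
import samcpoly as sp
from samcpoly.thermo import canonical_curves, locate_transitions_canonical

params = sp.ModelParams(n_monomers=20, bond_length=1.0, well_width=1.1)
res = sp.run_samc(params, n_steps=10**7, seed=7,
                  schedule=sp.SAMCSchedule(gamma0=0.1, t0=10**5),
                  collect_contacts=False, observable_stride=10)
dos = res.dos.restricted_to_visited()
grid = np.arange(0.2, 2.0001, 0.01)
curves = canonical_curves(dos, grid, res.observables)
rec = locate_transitions_canonical({"C_N": (grid, curves.specific_heat),
                                    "dRg2/dT": (grid, curves.drg2_dt)})
```

prints (via the obvious `print` lines):

```
levels: 14  E in [-13, 0]  ground state E=-13
transition: T = 0.545  interval [0.53, 0.56]
per-observable peaks: {'C_N': 0.53, 'dRg2/dT': 0.56}
P(E|T_c) bimodal: False
<Rg^2>(T_c) = 4.37 sigma^2   (rod bound 33.25)
```

The chain collapses near T ≈ 0.55 in units of ε/k_B; the transition
temperature is the consensus of the specific-heat and dR_g²/dT peaks and
the interval their spread. The unimodal energy distribution at T_c is the
second-order (continuous) signature expected for a flexible chain at this
well width. A stiff chain (`bond_length=0.53`) instead has every energy
below −18: the straight rod already carries the 18 permanent next-nearest
contacts,

```python
rod = sp.ChainConformation.straight_rod(sp.ModelParams(20, 0.53))
sp.total_energy(rod, sp.ModelParams(20, 0.53))   # -18
```

The same machinery is scriptable from the shell:

```sh
samcpoly simulate --n 20 --bond-length 1.0 --steps 1e7 --seed 7 \
         --out dos.tsv --obs-out obs.tsv
samcpoly analyze transitions --dos dos.tsv --obs obs.tsv --out transitions.json
samcpoly knot --xyz conformation.xyz
samcpoly oracle --n 4 --bond-length 0.8 --samples 1e6 --out oracle.tsv
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's two headline reference
numbers from scratch — the straight-rod energy of the stiff N = 20 chain
(by enumerating all non-bonded pair distances, confirmed by a seeded SAMC
run that never visits a higher finite energy) and the upper bond-length
boundary of the stiff regime at λ = 1.1 (by bisection on the regime
classifier). Run it from the repository root:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `samcpoly.model` | parameters, conformations, square-well Hamiltonian |
| `samcpoly.moves` | pivot / crankshaft / end-rotation proposals |
| `samcpoly.samc` | SAMC engine, gain schedule, DOS container |
| `samcpoly.observables` | R_g², contact maps, per-energy accumulation |
| `samcpoly.thermo` | micro-canonical + canonical analysis, transition calls |
| `samcpoly.topology` | chain closure, polygon reduction, Alexander determinant |
| `samcpoly.oracle` | brute-force uniform-sampling ground truth |
| `samcpoly.io`, `samcpoly.cli` | TSV/XYZ/YAML formats and the `samcpoly` CLI |

See `docs/methods.md` for the scientific and numerical choices, schedule
guidance and known limitations.
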