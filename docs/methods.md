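# Methods

## Model and conventions

A single chain of N hard spheres (diameter σ = 1, the length unit) on rigid
bonds of length L. Bonded pairs are "fused": their separation L < 1 carries
no penalty and they are excluded from the pair potential entirely. All
non-bonded pairs (|i−j| ≥ 2) interact via the square well with depth ε = 1
(the energy unit) and range λ (default 1.1); temperatures are in ε/k_B.

The potential's strict inequalities leave r = 1 and r = λ formally
undefined (a measure-zero set). We adopt the inclusive-well convention:
r < 1 forbidden, 1 ≤ r ≤ λ in-well, r > λ free. This makes the straight
rod at 2L = λ (L = 0.55) a valid −(N−2) state, so the stiff regime is the
closed interval 2L ≤ λ, matching the regime boundary L = λ/2. Distances are
compared as squares against 1 and λ²; ties at the thresholds resolve per
the same convention.

Steric stiffness: monomers i−1 and i+1 sit at 2L sin(θ/2), so hard-core
avoidance requires θ ≥ θ_min = 2 arcsin(1/2L). At L = 0.5, θ_min = π (rigid
rod, not simulable); at L = 1, θ_min = π/3. `classify_regime` labels
2L ≤ λ stiff, L = 1 flexible, the rest semi-flexible.

Energies are exact integers (−1 per contact), stored and filed as integers
throughout. The energy grid is therefore a set of integer labels, never a
real-valued binning.

## Monte Carlo moves

The move set — pivot (rigid rotation of the tail about a random axis
through a pivot monomer), crankshaft (rotation of one interior monomer
about the axis through its neighbours) and end rotation — is the minimal
standard ergodic set for fixed-bond continuum chains; all three are rigid
rotations, hence exactly bond-preserving, and the proposal density is
symmetric (uniform angle in [−a, +a], inversion-symmetric axis), so the
flat-histogram acceptance rule needs no proposal-ratio correction. Default
selection weights are equal; default maximum angles are π, appropriate for
flexible chains. For stiff chains (L ≲ 0.6) the accessible angular cone is
narrow and large rotations are almost always rejected by the hard core;
maximum angles of ~0.2–0.5 rad raise the acceptance rate by orders of
magnitude and are strongly recommended there (configurable per move kind).

A crankshaft axis degenerates when the chain folds exactly back
(r_{i−1} = r_{i+1}); the move then falls back to rotating monomer i about a
random axis through monomer i−1, which preserves both neighbour distances
because they are equal in that configuration.

## SAMC engine

Starting from the prior g₀(E) = 1 (ln g ≡ 0), each step proposes a move,
auto-rejects hard-core violations (equivalent to g(∞) = ∞), otherwise
accepts with min(1, g(E_old)/g(E_new)) evaluated in log space, and applies
the gain update at the *post-decision* energy E' (the old energy on
rejection — "update-on-rejection", required for correct flat-histogram
statistics):

    ln g(E') += γ_t (1 − 1/M),   ln g(E) −= γ_t/M  for all other levels,

which conserves Σ ln g exactly. The gain is γ_t = γ₀ min(1, t₀/t); the 1/t
tail gives Σγ_t = ∞ and Σγ_t^ν < ∞ for any ν ∈ (1, 2), the two
convergence conditions of stochastic approximation. There is no
Wang–Landau-style flatness-triggered gain halving; the schedule alone
drives convergence.

Grid policy. "adaptive" (default) starts from the initial conformation's
level and extends the grid when a new integer energy is first visited,
resetting M accordingly; a new level enters at its prior ln g = 0. The
alternative "fixed" policy pre-declares [E_min, E_max] so M is constant.
The initial conformation is the straight rod, legal for every L ≥ 0.5. The
stiff-chain spectrum shift (no state above −(N−2)) emerges from the energy
function; nothing is special-cased.

Schedule guidance. Defaults are γ₀ = 1, t₀ = 10⁶, sized for production
runs of ≥ 10⁸ steps. Two rules of thumb from the oracle-anchored
convergence study in the test suite: (i) t₀ should be a small fraction
(~0.1–1%) of the run length, since the residual error scales with the final
gain; (ii) γ₀ should be small against the typical ln g spacing of adjacent
levels (~1 here) — large early gains imprint distortions that the 1/t tail
erases only slowly. Desk-scale validation runs (10⁷ steps, N ≤ 5) use
γ₀ = 0.01, t₀ = 10⁴; the 10⁸-step N = 20 runs use γ₀ = 0.1, t₀ = 10⁶.

Determinism and checkpointing. One seeded PCG64 generator drives the whole
run; its state persists across kernel calls, so chunked execution and
checkpoint/resume are bit-identical to a monolithic run. Checkpoints carry
the DOS arrays, current and ground-state conformations, step index and the
full RNG state.

## Observables and canonical analysis

R_g² and the contact matrix (1 iff 1 ≤ r_ij ≤ λ, |i−j| ≥ 2 — the well
itself, so contact count × (−1) always equals the energy) are accumulated
as arithmetic means per energy level, by default only during the second
half of the run (small-gain phase) to limit the bias from a still-moving
g-estimate, at a configurable stride (an estimator-variance tradeoff, not a
change of estimand; stride 1 from step 1 reproduces the visit histogram
exactly). Canonical curves follow by reweighting with the converged DOS:
everything goes through log-sum-exp; no raw partition function is formed.
C_N(T) is computed from the energy-fluctuation form (manifestly ≥ 0); the
literal Z-derivative form is kept as an independent dual route and agrees
to 10⁻⁶ relative wherever both are stable (it loses digits to cancellation
below T ≈ 0.2 on 50-level test tables).

Micro-canonical derivatives use central differences on the unit-spaced
integer grid: β_micro(E) = (S(E+1) − S(E−1))/2, γ(E) = S(E+1) − 2S(E) +
S(E−1); exact for quadratics. Optional Savitzky–Golay smoothing of S is
off by default and always recorded in the output. Interior unpopulated
levels are refused by default (differencing across gaps can fabricate
transitions); `allow_gaps=True` switches to nonuniform stencils.

Transition calls. γ(E) peaks above a prominence threshold (default 5% of
the curve range — screening the small oscillations finite sampling
produces) are classified first-order if the peak value is positive (convex
intruder in S), second-order if negative. P(E|T) is called bimodal when two
local maxima (end levels may host a mode) bracket a minimum at least 20%
below the smaller peak (`depth_factor=0.2`). Canonical transition location
takes each observable's most prominent peak (ties toward lower T), reports
the mean as the transition temperature and the min–max spread as its
uncertainty.

## Knot identification

The chain is closed by one straight end-to-end segment (no stochastic
closure ensemble). The polygon is reduced by triangle elimination — a
vertex is removed when the triangle with its neighbours is pierced by no
other edge, an ambient isotopy — with all numerically ambiguous
intersection tests resolved conservatively (keep the vertex), so reduction
can stall but never change the knot type. The invariant is the Alexander
determinant |Δ(−1)|: projection along a seeded random direction, re-drawn
on any degeneracy (crossing at a vertex, tangency, triple point, ambiguous
over/under, even determinant); one generator per arc between underpasses;
the (n−1)×(n−1) minor's determinant is computed in exact integer
arithmetic (fraction-free Bareiss). |Δ(−1)| is 1 for the unknot, 3 for the
trefoil, 5 for the figure-eight; it does not separate all knots (5 also
matches the 5₁ torus knot), so the figure-eight label is flagged as
determinant-based. `random_unknot_polygon` grows certified unknots by
inverse triangle eliminations — each insertion satisfies exactly the
condition under which the reduction could undo it, so every intermediate
polygon is isotopic to a triangle; these are the negative controls.

## Brute-force oracle

With rigid bonds the configuration integral factorizes over independent
bond directions, so drawing each direction uniformly on the sphere and
rejecting hard-core violations samples exactly the finite-energy
configuration measure; surviving-sample energy frequencies are ∝ g(E)
restricted to self-avoiding states. This is the anti-regression anchor for
the engine (ln-frequency differences vs SAMC ln g differences at N ≤ 5).
The multinomial standard error of a ln-frequency difference is
√(1/c_a + 1/c_b) (the covariance term cancels). A cost guard refuses N > 8
by default — the survivor fraction and level count explode — and is
overridable. For N = 3 the closed form is exact: r₁₃² of two isotropic
bonds is uniform on [0, 4L²], so P(contact | no overlap) = (λ²−1)/(4L²−1)
for 2L > λ, and 1 in the stiff regime.

SAMC uncertainty in the oracle comparisons is the spread of three
independent seeded replicates (the schedule is not run to infinite time;
replicate spread captures the residual transient), combined in quadrature
with the oracle's multinomial error.

## What the test suite establishes — and what it does not

Green tests establish: correct geometry and Hamiltonian (closed forms,
brute-force enumeration, rigid-motion invariance), exact arithmetic of the
gain update, bit-reproducibility, agreement of the full engine with the
independent uniform-sampling measure at N ∈ {3,4,5} across three bond
lengths, the thermodynamic identities on synthetic tables, the
transition-order classifier on constructed first/second-order entropies,
exact knot invariants, and the qualitative second-order collapse signature
of the flexible N = 20 chain at desk scale (10⁸ steps). They do *not*
establish publication-statistics phase diagrams: those require
cluster-scale sampling, many independent runs per (L, T) point, and for
N = 40 stiff chains far longer runs than any test here performs.

## Known limitations

- **Stiff-chain kinetics.** For L ≤ 0.55 the exchange between the rodlike
  E = −(N−2) manifold and states with extra contacts is proposal-limited
  (an extra contact needs two near-maximal bends), and the entropy step at
  that energy — the model's hallmark — is correspondingly hard to
  converge: an aggressive early gain inflates ln g of the rod manifold and
  the error freezes once re-entry becomes acceptance-suppressed. Use small
  move amplitudes (~0.3 rad), γ₀ ≤ 10⁻², and long runs; the step's
  *location* (E = −(N−2)) is exact regardless, only its magnitude is
  sampling-limited.
- The adaptive grid initializes newly discovered levels at the prior
  ln g = 0, which transiently overestimates rarely-visited deep levels
  until the gain corrects them.
- The Alexander determinant cannot distinguish knots sharing |Δ(−1)|
  (granny vs square composites, 4₁ vs 5₁, ...); sufficient for the
  unknot/trefoil/figure-eight calls made here.
- The uniform-sampling oracle is exponentially inefficient in N and is a
  validation device, not a production sampler.
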