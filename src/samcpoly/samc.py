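"""Stochastic Approximation Monte Carlo estimation of the density of states.

SAMC is a flat-histogram method: configurations are proposed by unbiased
symmetric moves and accepted with probability min(1, g(E_old)/g(E_new)),
while the running estimate of ln g is nudged after every step at the
retained energy,

    ln g(E) <- ln g(E) + gamma_t * (delta_{E,E'} - 1/M),

with M the number of energy levels on the current grid.  The gain sequence
gamma_t = gamma0 * min(1, t0/t) decreases like 1/t, which satisfies the two
convergence conditions sum_t gamma_t = infinity and
sum_t gamma_t^nu < infinity for any nu in (1, 2).  Unlike Wang-Landau there
is no flatness-triggered gain halving; the schedule alone drives
convergence.

The chain's energies are exact non-positive integers (minus the square-well
contact count), so the energy grid is a set of integer labels.  The default
"adaptive" grid starts from the straight-rod energy and extends whenever a
new level is first visited ("update-on-rejection": the update is applied to
the post-decision energy, i.e. the old energy when the proposal is
rejected, including hard-core auto-rejections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import _kernels
from .model import ChainConformation, ModelParams, total_energy
from .moves import MoveSet
from .observables import EnergyResolvedObservables

__all__ = [
    "SAMCSchedule",
    "DOSEstimate",
    "RunResult",
    "RunCheckpoint",
    "OffGridError",
    "gamma_schedule",
    "acceptance_probability",
    "samc_update",
    "run_samc",
]


class OffGridError(ValueError):
    """An energy outside the declared grid was visited under a fixed grid."""


@dataclass(frozen=True)
class SAMCSchedule:
    """Gain schedule gamma_t = gamma0 for t <= t0, then gamma0 * t0 / t.

    The 1/t tail makes sum gamma_t diverge (logarithmically) while
    sum gamma_t^nu converges for every nu in (1, 2); ``nu`` is stored only
    for diagnostics of the convergence conditions.
    """

    gamma0: float = 1.0
    t0: int = 10**6
    nu: float = 1.5

    def __post_init__(self) -> None:
        if self.gamma0 <= 0:
            raise ValueError(f"gamma0 must be positive, got {self.gamma0}")
        if self.t0 < 1:
            raise ValueError(f"t0 must be a positive integer, got {self.t0}")
        if not 1.0 < self.nu < 2.0:
            raise ValueError(f"nu must lie in (1, 2), got {self.nu}")

    def gamma(self, t):
        """Gain at step t (t >= 1); accepts scalars or arrays."""
        t = np.asarray(t)
        if np.any(t < 1):
            raise ValueError("step index t starts at 1")
        return self.gamma0 * np.minimum(1.0, self.t0 / t)


def gamma_schedule(t, schedule: SAMCSchedule):
    """Modification factor gamma_t of the given schedule."""
    return schedule.gamma(t)


def acceptance_probability(ln_g_old: float, ln_g_new: float) -> float:
    """min(1, g(E_old)/g(E_new)) evaluated in log space."""
    if not (math.isfinite(ln_g_old) and math.isfinite(ln_g_new)):
        raise ValueError("ln g values must be finite")
    if ln_g_new <= ln_g_old:
        return 1.0
    return math.exp(ln_g_old - ln_g_new)


@dataclass
class DOSEstimate:
    """Discrete energy grid with ln g values and a visit histogram.

    ``energies`` are strictly increasing integers; ``ln_g`` is the running
    estimate of the micro-canonical entropy S(E) = ln g(E) (only differences
    are physically meaningful); ``visits`` counts update events per level.
    """

    energies: np.ndarray
    ln_g: np.ndarray
    visits: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.int64)
        self.ln_g = np.asarray(self.ln_g, dtype=np.float64)
        self.visits = np.asarray(self.visits, dtype=np.int64)
        if not (len(self.energies) == len(self.ln_g) == len(self.visits)):
            raise ValueError("energies, ln_g and visits must have equal length")
        if len(self.energies) > 1 and np.any(np.diff(self.energies) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.visits < 0):
            raise ValueError("visit counts must be non-negative")

    @property
    def n_levels(self) -> int:
        return len(self.energies)

    def index(self, energy: int) -> int:
        k = int(np.searchsorted(self.energies, energy))
        if k >= len(self.energies) or self.energies[k] != energy:
            raise OffGridError(f"energy {energy} is not on the grid")
        return k

    def ln_g_diff(self, e_a: int, e_b: int) -> float:
        """ln g(e_a) - ln g(e_b); normalization-free."""
        return float(self.ln_g[self.index(e_a)] - self.ln_g[self.index(e_b)])

    def restricted_to_visited(self) -> "DOSEstimate":
        m = self.visits > 0
        return DOSEstimate(
            self.energies[m], self.ln_g[m], self.visits[m], dict(self.metadata)
        )


def samc_update(
    dos: DOSEstimate, accepted_energy: int, gamma: float, grid_policy: str = "error"
) -> DOSEstimate:
    """Apply one gain update at the post-decision energy, in place.

    Adds gamma*(1 - 1/M) at the accepted level and subtracts gamma/M from
    every other level, so the sum of ln g over the grid is exactly
    conserved.  Off-grid energies either extend the grid (policy
    "extend", new level initialized at the prior ln g = 0) or raise.
    """
    accepted_energy = int(accepted_energy)
    try:
        k = dos.index(accepted_energy)
    except OffGridError:
        if grid_policy != "extend":
            raise
        pos = int(np.searchsorted(dos.energies, accepted_energy))
        dos.energies = np.insert(dos.energies, pos, accepted_energy)
        dos.ln_g = np.insert(dos.ln_g, pos, 0.0)
        dos.visits = np.insert(dos.visits, pos, 0)
        k = pos
    m = dos.n_levels
    dos.ln_g -= gamma / m
    dos.ln_g[k] += gamma
    dos.visits[k] += 1
    return dos


@dataclass
class RunResult:
    """Everything a SAMC run produces."""

    dos: DOSEstimate
    observables: EnergyResolvedObservables
    ground_state: ChainConformation
    ground_state_energy: int

    def __post_init__(self) -> None:
        visited = self.dos.energies[self.dos.visits > 0]
        if len(visited) and self.ground_state_energy != int(visited.min()):
            raise ValueError(
                "ground-state energy does not match the minimum visited energy"
            )


@dataclass
class RunCheckpoint:
    """Bit-exact resume point: DOS arrays, conformation, step and RNG state."""

    step: int
    energies: list
    ln_g: list
    visits: list
    coords: list
    current_energy: int
    ground_state_energy: int
    ground_state_coords: list
    rng_state: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _resolve_weights(move_set: MoveSet, n: int) -> tuple[np.ndarray, np.ndarray]:
    w = move_set.weights(n).astype(np.float64)
    cum = np.cumsum(w / w.sum())
    return cum, move_set.max_angles().astype(np.float64)


def run_samc(
    params: ModelParams,
    n_steps: int,
    seed: int,
    schedule: SAMCSchedule | None = None,
    move_set: MoveSet | None = None,
    grid_policy: str = "adaptive",
    fixed_range: tuple[int, int] | None = None,
    collect_from: int | None = None,
    observable_stride: int = 1,
    collect_contacts: bool = True,
    initial: ChainConformation | None = None,
    checkpoint_every: int | None = None,
    checkpoint_callback: Callable[[RunCheckpoint], None] | None = None,
) -> RunResult:
    """Run SAMC and return the DOS estimate, observables and ground state.

    Parameters
    ----------
    params, n_steps, seed
        Model, number of elementary MC steps (>= 1) and RNG seed; the run is
        fully reproducible given the seed.
    schedule, move_set
        Gain schedule (default gamma0=1, t0=1e6) and proposal move set
        (default pivot/crankshaft/end-rotation with equal weights).
    grid_policy, fixed_range
        "adaptive" (default) starts from the initial conformation's energy
        and extends the grid as new integer levels are first visited;
        "fixed" pre-declares all levels in ``fixed_range`` = (e_min, e_max)
        so M stays constant.
    collect_from, observable_stride, collect_contacts
        Observables are accumulated from step ``collect_from`` on (default:
        the second half of the run, when the gain is small) at the given
        stride; contact-matrix accumulation can be switched off for speed.
    initial
        Starting conformation (default: the straight rod, valid for every
        L >= 0.5).
    checkpoint_every, checkpoint_callback
        Invoke the callback with a :class:`RunCheckpoint` every K steps.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if schedule is None:
        schedule = SAMCSchedule()
    if move_set is None:
        move_set = MoveSet()
    if grid_policy not in ("adaptive", "fixed"):
        raise ValueError(f"unknown grid policy {grid_policy!r}")
    if grid_policy == "fixed" and fixed_range is None:
        raise ValueError("fixed grid policy requires fixed_range=(e_min, e_max)")

    n = params.n_monomers
    p_max = params.n_nonbonded_pairs
    lam2 = params.well_width**2

    conf = initial if initial is not None else ChainConformation.straight_rod(params)
    conf.validate_bonds(params.bond_length)
    e0 = total_energy(conf, params)
    coords = np.ascontiguousarray(conf.coords, dtype=np.float64)

    ln_g = np.zeros(p_max + 1)  # index c = -E; prior g0(E) = 1
    visits = np.zeros(p_max + 1, dtype=np.int64)
    discovered = np.zeros(p_max + 1, dtype=np.bool_)
    disc_list = np.zeros(p_max + 1, dtype=np.int64)
    state = np.zeros(3, dtype=np.int64)

    state[0] = -e0
    if grid_policy == "fixed":
        e_min, e_max = fixed_range
        if not (-p_max <= e_min <= e_max <= 0):
            raise ValueError(f"fixed_range {fixed_range} outside [-{p_max}, 0]")
        if not e_min <= e0 <= e_max:
            raise ValueError("initial energy outside the fixed grid")
        m = 0
        for e in range(e_max, e_min - 1, -1):
            discovered[-e] = True
            disc_list[m] = -e
            m += 1
        state[1] = m
    else:
        discovered[-e0] = True
        disc_list[0] = -e0
        state[1] = 1
    state[2] = -e0
    gs_coords = coords.copy()

    cum, max_angles = _resolve_weights(move_set, n)
    if collect_from is None:
        collect_from = n_steps // 2 + 1
    if observable_stride < 1:
        raise ValueError("observable_stride must be >= 1")

    obs_count = np.zeros(p_max + 1, dtype=np.int64)
    obs_rg2_sum = np.zeros(p_max + 1)
    obs_contact_sum = np.zeros(
        (p_max + 1 if collect_contacts else 1, n, n), dtype=np.int64
    )

    rng = np.random.default_rng(seed)
    t = 1
    chunk = checkpoint_every if checkpoint_every else n_steps
    while t <= n_steps:
        this_chunk = min(chunk, n_steps - t + 1)
        _kernels.samc_chunk(
            rng,
            coords,
            this_chunk,
            t,
            float(schedule.gamma0),
            float(schedule.t0),
            lam2,
            cum,
            max_angles,
            ln_g,
            visits,
            discovered,
            disc_list,
            state,
            collect_from,
            observable_stride,
            collect_contacts,
            obs_count,
            obs_rg2_sum,
            obs_contact_sum,
            gs_coords,
        )
        t += this_chunk
        if checkpoint_callback is not None and t <= n_steps:
            ck = _make_checkpoint(t - 1, ln_g, visits, discovered, coords, state, gs_coords, rng)
            checkpoint_callback(ck)

    order = np.argsort(disc_list[: state[1]])[::-1]  # ascending energy
    idx = disc_list[: state[1]][order]
    energies = -idx
    metadata = {
        "n_monomers": n,
        "bond_length": params.bond_length,
        "well_width": params.well_width,
        "n_steps": n_steps,
        "seed": seed,
        "gamma0": schedule.gamma0,
        "t0": schedule.t0,
        "grid_policy": grid_policy,
        "move_set": {
            "pivot_weight": move_set.pivot_weight,
            "crankshaft_weight": move_set.crankshaft_weight,
            "end_weight": move_set.end_weight,
        },
    }
    dos = DOSEstimate(energies, ln_g[idx], visits[idx], metadata)
    observables = EnergyResolvedObservables.from_sums(
        -np.arange(p_max + 1),
        obs_count,
        obs_rg2_sum,
        obs_contact_sum if collect_contacts else None,
        n_monomers=n,
        well_width=params.well_width,
    )
    return RunResult(
        dos=dos,
        observables=observables,
        ground_state=ChainConformation(gs_coords.copy()),
        ground_state_energy=int(-state[2]),
    )


def _make_checkpoint(step, ln_g, visits, discovered, coords, state, gs_coords, rng):
    idx = np.flatnonzero(discovered)
    return RunCheckpoint(
        step=int(step),
        energies=(-idx).tolist(),
        ln_g=ln_g[idx].tolist(),
        visits=visits[idx].tolist(),
        coords=coords.tolist(),
        current_energy=int(-state[0]),
        ground_state_energy=int(-state[2]),
        ground_state_coords=gs_coords.tolist(),
        rng_state=rng.bit_generator.state,
    )
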