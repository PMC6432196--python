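"""Micro-canonical and canonical analysis of a converged density of states.

Micro-canonical route: S(E) = ln g(E), inverse temperature
beta_micro(E) = dS/dE, and gamma(E) = d^2 S/dE^2.  On the unit-spaced
integer energy grid the derivatives are central differences,

    beta_micro(E) = (S(E+1) - S(E-1)) / 2,
    gamma(E)      = S(E+1) - 2 S(E) + S(E-1).

A local maximum of gamma(E) with a positive peak value signals a first-order
pseudo phase transition (a convex intruder in S); a peak below zero a
second-order one.

Canonical route: Z(T) = sum_E g(E) exp(-E/T), the specific heat, canonical
averages of energy-resolved observables and the energy distribution
P(E|T) proportional to g(E) exp(-E/T), whose double-peak structure is the
canonical fingerprint of a first-order transition.  All reweighting is done
in log space with the log-sum-exp shift; no raw partition function is ever
formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.special import logsumexp

from .observables import EnergyResolvedObservables
from .samc import DOSEstimate

__all__ = [
    "MicroCanonicalCurves",
    "CanonicalCurves",
    "TransitionRecord",
    "EnergyGapError",
    "micro_curves",
    "classify_transitions_micro",
    "log_partition_function",
    "canonical_moments",
    "specific_heat",
    "specific_heat_literal",
    "canonical_average",
    "canonical_curves",
    "energy_distribution",
    "detect_bimodality",
    "locate_transitions_canonical",
]

FIRST_ORDER = "first"
SECOND_ORDER = "second"


class EnergyGapError(ValueError):
    """Interior unpopulated energy levels: derivatives would be fabricated."""


@dataclass
class MicroCanonicalCurves:
    """S(E) with its first two energy derivatives on the interior grid."""

    energies: np.ndarray          # full populated grid
    entropy: np.ndarray           # S(E) = ln g(E), possibly smoothed
    interior_energies: np.ndarray  # grid minus the two end points
    beta_micro: np.ndarray        # dS/dE on the interior grid
    gamma_e: np.ndarray           # d2S/dE2 on the interior grid
    smoothing: str = "none"


@dataclass
class CanonicalCurves:
    """Canonical observables on a temperature grid (units eps/kB)."""

    temperatures: np.ndarray
    ln_z: np.ndarray
    e_mean: np.ndarray
    specific_heat: np.ndarray
    rg2_mean: np.ndarray | None = None
    drg2_dt: np.ndarray | None = None


@dataclass
class TransitionRecord:
    """A located pseudo phase transition with its diagnostics.

    ``location`` is an energy (variable "E", micro-canonical route) or a
    temperature (variable "T", canonical route).  ``order`` follows the
    gamma(E) peak-sign rule where available.
    """

    location: float
    variable: str
    order: str | None
    diagnostics: dict = field(default_factory=dict)
    interval: tuple[float, float] | None = None


# --------------------------------------------------------------------------
# micro-canonical route
# --------------------------------------------------------------------------


def _populated(dos: DOSEstimate) -> tuple[np.ndarray, np.ndarray]:
    mask = dos.visits > 0
    if mask.sum() == 0:  # synthetic tables may carry no visit counts
        mask = np.ones(len(dos.energies), dtype=bool)
    return dos.energies[mask], dos.ln_g[mask]


def micro_curves(
    dos: DOSEstimate,
    smoothing: tuple[int, int] | None = None,
    allow_gaps: bool = False,
) -> MicroCanonicalCurves:
    """Central-difference beta_micro(E) and gamma(E) from S(E) = ln g(E).

    ``smoothing=(window, polyorder)`` applies a Savitzky-Golay filter to S
    before differentiating (off by default, and recorded in the result).
    Interior gaps in the populated grid are refused unless ``allow_gaps``,
    in which case nonuniform central differences span them.
    """
    energies, entropy = _populated(dos)
    if len(energies) < 5:
        raise ValueError(f"need >= 5 populated levels, got {len(energies)}")
    gaps = np.any(np.diff(energies) != 1)
    if gaps and not allow_gaps:
        raise EnergyGapError(
            "interior energy levels are unpopulated; sample longer or pass "
            "allow_gaps=True to difference across gaps"
        )
    desc = "none"
    if smoothing is not None:
        window, order = smoothing
        entropy = savgol_filter(entropy, window, order)
        desc = f"savgol(window={window}, polyorder={order})"
    e = energies.astype(np.float64)
    if not gaps:
        beta = (entropy[2:] - entropy[:-2]) / 2.0
        gamma = entropy[2:] - 2.0 * entropy[1:-1] + entropy[:-2]
    else:
        h1 = e[1:-1] - e[:-2]
        h2 = e[2:] - e[1:-1]
        beta = (entropy[2:] - entropy[:-2]) / (h1 + h2)
        gamma = 2.0 * (
            h1 * entropy[2:] - (h1 + h2) * entropy[1:-1] + h2 * entropy[:-2]
        ) / (h1 * h2 * (h1 + h2))
    return MicroCanonicalCurves(
        energies=energies,
        entropy=entropy,
        interior_energies=energies[1:-1],
        beta_micro=beta,
        gamma_e=gamma,
        smoothing=desc,
    )


def classify_transitions_micro(
    curves: MicroCanonicalCurves, peak_prominence: float | None = None
) -> list[TransitionRecord]:
    """Find gamma(E) peaks and classify their order by the peak-value sign.

    ``peak_prominence`` is an absolute prominence threshold; by default 5%
    of the gamma(E) range, screening out the small oscillations a finite run
    produces.  Records are ordered by increasing energy.
    """
    g = curves.gamma_e
    if peak_prominence is None:
        rng = float(np.ptp(g))
        peak_prominence = 0.05 * rng if rng > 0 else 0.0
    peaks, props = find_peaks(g, prominence=peak_prominence)
    records = []
    for k, p in enumerate(peaks):
        val = float(g[p])
        records.append(
            TransitionRecord(
                location=float(curves.interior_energies[p]),
                variable="E",
                order=FIRST_ORDER if val > 0 else SECOND_ORDER,
                diagnostics={
                    "gamma_peak_value": val,
                    "gamma_peak_sign": 1 if val > 0 else -1,
                    "prominence": float(props["prominences"][k]),
                },
            )
        )
    return records


# --------------------------------------------------------------------------
# canonical route
# --------------------------------------------------------------------------


def _check_temperature(temperature: float) -> None:
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")


def _log_weights(dos: DOSEstimate, temperature: float) -> tuple[np.ndarray, np.ndarray]:
    energies, ln_g = _populated(dos)
    return energies.astype(np.float64), ln_g - energies / temperature


def log_partition_function(dos: DOSEstimate, temperature: float) -> float:
    """ln Z(T) = ln sum_E g(E) exp(-E/T), via log-sum-exp."""
    _check_temperature(temperature)
    _, lw = _log_weights(dos, temperature)
    return float(logsumexp(lw))


def canonical_moments(dos: DOSEstimate, temperature: float) -> tuple[float, float]:
    """Canonical <E> and <E^2> at temperature T."""
    _check_temperature(temperature)
    e, lw = _log_weights(dos, temperature)
    lw = lw - logsumexp(lw)
    w = np.exp(lw)
    return float(np.sum(w * e)), float(np.sum(w * e * e))


def specific_heat(dos: DOSEstimate, temperature: float) -> float:
    """C_N(T) = (<E^2> - <E>^2) / T^2 (canonical energy-fluctuation form).

    Equivalent to the temperature-derivative form
    2T Z'/Z + T^2 (Z'' Z - Z'^2)/Z^2 (see :func:`specific_heat_literal`),
    but manifestly non-negative.
    """
    e_mean, e2_mean = canonical_moments(dos, temperature)
    var = max(e2_mean - e_mean * e_mean, 0.0)
    return var / temperature**2


def specific_heat_literal(dos: DOSEstimate, temperature: float) -> float:
    """C_N(T) from the Z-derivative form 2T Z'/Z + T^2 (Z''Z - Z'^2)/Z^2.

    Z'(T) and Z''(T) are evaluated analytically from the level sum (each
    temperature derivative pulls down powers of E/T^2), carried in log space
    with explicit signs.  Kept as the independent dual route to
    :func:`specific_heat`.
    """
    _check_temperature(temperature)
    t = temperature
    e, lw = _log_weights(dos, t)
    ln_z = logsumexp(lw)
    # Z' = sum g e^{-E/T} (E/T^2);  Z'' = sum g e^{-E/T} (E^2/T^4 - 2E/T^3)
    lz1, s1 = _signed_lse(lw, e / t**2)
    lz2, s2 = _signed_lse(lw, e * e / t**4 - 2.0 * e / t**3)
    zp_over_z = s1 * np.exp(lz1 - ln_z)
    zpp_over_z = s2 * np.exp(lz2 - ln_z)
    return 2.0 * t * zp_over_z + t * t * (zpp_over_z - zp_over_z**2)


def _signed_lse(log_w: np.ndarray, coeff: np.ndarray) -> tuple[float, float]:
    """log |sum_i coeff_i exp(log_w_i)| and its sign."""
    val, sign = logsumexp(log_w, b=coeff, return_sign=True)
    return float(val), float(sign)


def canonical_average(
    obs: EnergyResolvedObservables,
    dos: DOSEstimate,
    temperature: float,
    fieldname: str = "rg2",
    missing_weight_tol: float = 1e-6,
):
    """Reweight a per-energy observable into the canonical ensemble.

    <O>(T) = sum_E Obar(E) g(E) exp(-E/T) / Z(T) over the levels where the
    observable was populated.  If the uncovered levels carry more Boltzmann
    weight than ``missing_weight_tol``, a warning is issued and the average
    is renormalized over the covered levels.  fieldname "contact" yields the
    temperature-dependent contact probability matrix.
    """
    _check_temperature(temperature)
    energies, ln_g = _populated(dos)
    values, mask = obs.values_on(energies, fieldname)
    lw = ln_g - energies / temperature
    lw = lw - logsumexp(lw)
    w = np.exp(lw)
    missing = float(w[~mask].sum())
    if missing > missing_weight_tol:
        warnings.warn(
            f"observable missing on levels carrying {missing:.2e} of the "
            "canonical weight; renormalizing over covered levels",
            stacklevel=2,
        )
    w = w[mask] / w[mask].sum()
    vals = values[mask]
    if vals.ndim == 1:
        return float(np.sum(w * vals))
    return np.tensordot(w, vals, axes=(0, 0))


def canonical_curves(
    dos: DOSEstimate,
    t_grid: np.ndarray,
    obs: EnergyResolvedObservables | None = None,
) -> CanonicalCurves:
    """Evaluate ln Z, <E>, C_N and optionally <R_g^2> on a temperature grid.

    d<R_g^2>/dT is a central difference on the grid (one-sided at the ends).
    """
    t_grid = np.asarray(t_grid, dtype=np.float64)
    ln_z = np.array([log_partition_function(dos, t) for t in t_grid])
    e_mean = np.empty_like(t_grid)
    cv = np.empty_like(t_grid)
    for k, t in enumerate(t_grid):
        m1, m2 = canonical_moments(dos, t)
        e_mean[k] = m1
        cv[k] = max(m2 - m1 * m1, 0.0) / t**2
    rg2 = drg2 = None
    if obs is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rg2 = np.array(
                [canonical_average(obs, dos, t, "rg2") for t in t_grid]
            )
        drg2 = np.gradient(rg2, t_grid)
    return CanonicalCurves(
        temperatures=t_grid,
        ln_z=ln_z,
        e_mean=e_mean,
        specific_heat=cv,
        rg2_mean=rg2,
        drg2_dt=drg2,
    )


def energy_distribution(dos: DOSEstimate, temperature: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized canonical energy distribution P(E|T) on the populated grid."""
    _check_temperature(temperature)
    energies, ln_g = _populated(dos)
    lw = ln_g - energies / temperature
    lw -= logsumexp(lw)
    return energies, np.exp(lw)


def detect_bimodality(
    probabilities: np.ndarray, depth_factor: float = 0.2
) -> tuple[bool, list[int]]:
    """Double-peak test on P(E|T): the canonical first-order fingerprint.

    Bimodal iff there are two local maxima whose intervening minimum lies at
    least ``depth_factor`` below the smaller of the two peaks
    (valley <= (1 - depth_factor) * smaller_peak).  Returns the flag and the
    indices of the dominant peaks.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    peaks, _ = find_peaks(p)
    # end points can host a mode (e.g. the ground-state level)
    if len(p) >= 2 and p[0] > p[1]:
        peaks = np.concatenate(([0], peaks))
    if len(p) >= 2 and p[-1] > p[-2]:
        peaks = np.concatenate((peaks, [len(p) - 1]))
    if len(peaks) < 2:
        return False, peaks.astype(int).tolist()
    order = np.argsort(p[peaks])[::-1]
    a, b = sorted((int(peaks[order[0]]), int(peaks[order[1]])))
    valley = float(p[a : b + 1].min())
    smaller = float(min(p[a], p[b]))
    return valley <= (1.0 - depth_factor) * smaller, [a, b]


def locate_transitions_canonical(
    curve_family: dict[str, tuple[np.ndarray, np.ndarray]],
    peak_prominence_frac: float = 0.05,
) -> TransitionRecord | None:
    """Consensus transition temperature from several canonical observables.

    For each named curve (T, y) the main peak (largest prominence, ties
    toward lower T) is located; the transition temperature is the mean of
    the per-observable peak temperatures and the uncertainty interval their
    min-max spread.  Returns ``None`` when no observable shows a peak.
    """
    peak_temps: dict[str, float] = {}
    for name, (t, y) in curve_family.items():
        y = np.asarray(y, dtype=np.float64)
        rng = float(np.ptp(y))
        if rng == 0:
            continue
        peaks, props = find_peaks(y, prominence=peak_prominence_frac * rng)
        if len(peaks) == 0:
            continue
        best = peaks[int(np.argmax(props["prominences"]))]
        peak_temps[name] = float(np.asarray(t)[best])
    if not peak_temps:
        return None
    temps = np.array(list(peak_temps.values()))
    return TransitionRecord(
        location=float(temps.mean()),
        variable="T",
        order=None,
        diagnostics={"peak_temperatures": peak_temps},
        interval=(float(temps.min()), float(temps.max())),
    )
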