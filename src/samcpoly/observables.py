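"""Structural observables accumulated per energy level during sampling.

A flat-histogram run visits all energies, so equilibrium observables are
recorded as arithmetic averages over the visited configurations *at each
energy level* (squared radius of gyration, pair contact frequencies).
Canonical averages at any temperature follow afterwards by reweighting with
the converged density of states (see ``thermo.canonical_average``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ChainConformation, ModelParams, total_energy

__all__ = [
    "EnergyResolvedObservables",
    "radius_of_gyration_sq",
    "contact_map",
    "accumulate",
]


def radius_of_gyration_sq(conf: ChainConformation | np.ndarray) -> float:
    """Mean squared distance of the monomers from their centroid (sigma^2).

    For a straight rod of N monomers at spacing L this equals
    L^2 (N^2 - 1)/12, the upper bound over all conformations at fixed N, L.
    """
    coords = conf.coords if isinstance(conf, ChainConformation) else np.asarray(conf)
    centered = coords - coords.mean(axis=0)
    return float(np.einsum("ij,ij->", centered, centered) / coords.shape[0])


def contact_map(conf: ChainConformation | np.ndarray, well_width: float = 1.1) -> np.ndarray:
    """Binary symmetric N x N matrix: 1 iff |i-j| >= 2 and 1 <= r_ij <= lambda.

    The contact definition reuses the energy well, so the contact count
    times -1 always equals the square-well energy -- a built-in cross-check.
    """
    coords = conf.coords if isinstance(conf, ChainConformation) else np.asarray(conf)
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    mat = ((d2 >= 1.0) & (d2 <= well_width * well_width)).astype(np.int8)
    # blank self, bonded and first off-diagonal pairs
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    mat[sep < 2] = 0
    return mat


@dataclass
class _LevelAccumulator:
    count: int = 0
    rg2_mean: float = 0.0
    contact_mean: np.ndarray | None = None


@dataclass
class EnergyResolvedObservables:
    """Running per-energy means of R_g^2 and of the contact matrix.

    Means are maintained with the numerically stable incremental rule
    ``mean += (x - mean)/count``.  Contact frequencies live in [0, 1] with a
    symmetric matrix whose diagonal and first off-diagonal are identically
    zero (self and bonded pairs carry no square-well interaction).
    """

    n_monomers: int
    well_width: float = 1.1
    track_contacts: bool = True
    _levels: dict[int, _LevelAccumulator] = field(default_factory=dict, repr=False)

    @property
    def energies(self) -> np.ndarray:
        return np.array(sorted(self._levels), dtype=np.int64)

    def count(self, energy: int) -> int:
        acc = self._levels.get(int(energy))
        return acc.count if acc else 0

    def rg2_mean(self, energy: int) -> float:
        return self._levels[int(energy)].rg2_mean

    def contact_mean(self, energy: int) -> np.ndarray:
        acc = self._levels[int(energy)]
        if acc.contact_mean is None:
            raise ValueError("contact tracking was disabled for this run")
        return acc.contact_mean

    def accumulate(
        self,
        energy: int,
        conf: ChainConformation | np.ndarray,
        check_params: ModelParams | None = None,
    ) -> None:
        """Fold one configuration at the stated energy into the running means.

        With ``check_params`` given (debug mode) the energy is recomputed
        from the coordinates and a mismatch raises -- guarding against
        accumulating under a stale energy label.
        """
        energy = int(energy)
        if check_params is not None:
            conf_obj = (
                conf
                if isinstance(conf, ChainConformation)
                else ChainConformation(np.asarray(conf))
            )
            recomputed = total_energy(conf_obj, check_params)
            if recomputed != energy:
                raise ValueError(
                    f"energy label {energy} does not match recomputed {recomputed}"
                )
        acc = self._levels.get(energy)
        if acc is None:
            acc = _LevelAccumulator()
            if self.track_contacts:
                acc.contact_mean = np.zeros((self.n_monomers, self.n_monomers))
            self._levels[energy] = acc
        acc.count += 1
        acc.rg2_mean += (radius_of_gyration_sq(conf) - acc.rg2_mean) / acc.count
        if self.track_contacts:
            cmap = contact_map(conf, self.well_width)
            acc.contact_mean += (cmap - acc.contact_mean) / acc.count

    # ---- bulk construction from the kernel's sum arrays -----------------

    @classmethod
    def from_sums(
        cls,
        energies: np.ndarray,
        counts: np.ndarray,
        rg2_sums: np.ndarray,
        contact_sums: np.ndarray | None,
        n_monomers: int,
        well_width: float,
    ) -> "EnergyResolvedObservables":
        obs = cls(
            n_monomers=n_monomers,
            well_width=well_width,
            track_contacts=contact_sums is not None,
        )
        for k, e in enumerate(energies):
            c = int(counts[k])
            if c == 0:
                continue
            acc = _LevelAccumulator(count=c, rg2_mean=float(rg2_sums[k]) / c)
            if contact_sums is not None:
                upper = contact_sums[k].astype(np.float64) / c
                acc.contact_mean = upper + upper.T
            obs._levels[int(e)] = acc
        return obs

    def values_on(self, energies: np.ndarray, fieldname: str = "rg2"):
        """Per-energy values aligned with ``energies`` plus a coverage mask.

        fieldname 'rg2' yields a float vector; 'contact' yields an
        (len(energies), N, N) stack of frequency matrices.
        """
        energies = np.asarray(energies)
        mask = np.array([int(e) in self._levels for e in energies])
        if fieldname == "rg2":
            vals = np.zeros(len(energies))
            for k, e in enumerate(energies):
                if mask[k]:
                    vals[k] = self._levels[int(e)].rg2_mean
        elif fieldname == "contact":
            vals = np.zeros((len(energies), self.n_monomers, self.n_monomers))
            for k, e in enumerate(energies):
                if mask[k]:
                    vals[k] = self.contact_mean(int(e))
        else:
            raise ValueError(f"unknown observable field {fieldname!r}")
        return vals, mask


def accumulate(
    obs: EnergyResolvedObservables,
    energy: int,
    conf: ChainConformation | np.ndarray,
    check_params: ModelParams | None = None,
) -> EnergyResolvedObservables:
    """Functional wrapper around :meth:`EnergyResolvedObservables.accumulate`."""
    obs.accumulate(energy, conf, check_params=check_params)
    return obs
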