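"""Fused-hard-sphere square-well chain: geometry and Hamiltonian.

The polymer is a single chain of N hard spheres of diameter sigma = 1
connected by rigid bonds of length L <= 1, so consecutive spheres overlap
("fused") for L < 1.  Non-bonded monomers interact through a square-well
potential: an impenetrable core at r < 1 and a constant attraction -eps for
1 <= r <= lambda.  Because next-nearest neighbours must stay at least one
diameter apart, short bonds restrict the accessible bond angles -- stiffness
of purely steric (entropic) origin, controlled by the single parameter L.

Units: sigma = 1 (length), eps = 1 (energy), temperatures in eps/kB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SIGMA",
    "Regime",
    "GeometryError",
    "HardCoreOverlapError",
    "ModelParams",
    "ChainConformation",
    "min_bond_angle",
    "classify_regime",
    "pair_potential",
    "total_energy",
    "is_self_avoiding",
    "pairwise_distances",
]

#: Hard-sphere diameter, the unit of length.
SIGMA = 1.0


class GeometryError(ValueError):
    """No valid conformation exists for the requested geometry."""


class HardCoreOverlapError(ValueError):
    """A non-bonded pair overlaps its hard cores (forbidden conformation)."""


class Regime:
    """Stiffness regimes set by the bond length at a given well width."""

    STIFF = "stiff"
    SEMI_FLEXIBLE = "semi-flexible"
    FLEXIBLE = "flexible"


def min_bond_angle(bond_length: float) -> float:
    """Smallest internal bond angle free of next-nearest-neighbour overlap.

    Monomers i-1 and i+1 sit at distance 2 L sin(theta/2); the hard core
    requires this to be at least 1, giving theta_min = 2 arcsin(1/(2L)).
    At L = 0.5 the only allowed angle is pi (rigid rod); below that no
    conformation exists at all.

    Parameters
    ----------
    bond_length : float
        Bond length L in units of sigma, 0.5 <= L <= 1.

    Returns
    -------
    float
        theta_min in radians; monotonically decreasing in L.
    """
    if bond_length < 0.5:
        raise GeometryError(
            f"bond length {bond_length} < 0.5: next-nearest neighbours "
            "cannot avoid hard-core overlap at any bond angle"
        )
    if bond_length > 1.0:
        raise ValueError(f"bond length {bond_length} > 1 (sphere diameter)")
    return 2.0 * math.asin(1.0 / (2.0 * bond_length))


def classify_regime(bond_length: float, well_width: float = 1.1) -> str:
    """Classify the chain stiffness regime for bond length L, well width lambda.

    *stiff*: 2L <= lambda, so next-nearest neighbours sit permanently inside
    the attractive well (their distance is confined to [1, 2L]) and each
    (i, i+2) pair contributes -eps in every conformation.  *flexible*: L = 1,
    tangent spheres with unrestricted bond angles.  *semi-flexible*:
    everything in between.
    """
    _validate_lengths(bond_length, well_width)
    if 2.0 * bond_length <= well_width:
        return Regime.STIFF
    if bond_length == 1.0:
        return Regime.FLEXIBLE
    return Regime.SEMI_FLEXIBLE


def _validate_lengths(bond_length: float, well_width: float) -> None:
    if not bond_length > 0.5:
        raise GeometryError(
            f"bond length must exceed 0.5 (rigid-rod limit), got {bond_length}"
        )
    if bond_length > 1.0:
        raise ValueError(f"bond length {bond_length} > 1")
    if not well_width > 1.0:
        raise ValueError(f"well width must exceed 1, got {well_width}")


def pair_potential(r: float, well_width: float = 1.1, well_depth: float = 1.0) -> float:
    """Square-well pair energy for a non-bonded pair at distance r.

    Returns ``inf`` inside the hard core (r < 1), ``-well_depth`` inside the
    well (1 <= r <= lambda, both boundaries inclusive) and 0 beyond.  The
    inclusive-well convention makes the straight rod at 2L = lambda a valid
    bound state, consistent with the stiff-regime boundary L = lambda/2.
    """
    if r < 0:
        raise ValueError(f"negative distance {r}")
    if r < 1.0:
        return math.inf
    if r <= well_width:
        return -well_depth
    return 0.0


@dataclass(frozen=True)
class ModelParams:
    """Model parameters defining the Hamiltonian of a single chain.

    Attributes
    ----------
    n_monomers : int
        Chain length N >= 2.
    bond_length : float
        Rigid bond length L in (0.5, 1.0] (units of sigma).
    well_width : float
        Square-well range lambda > 1 (default 1.1).
    well_depth : float
        Well depth eps, the unit of energy (default 1).
    """

    n_monomers: int
    bond_length: float
    well_width: float = 1.1
    well_depth: float = 1.0

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError(f"need at least 2 monomers, got {self.n_monomers}")
        _validate_lengths(self.bond_length, self.well_width)
        if self.well_depth <= 0:
            raise ValueError(f"well depth must be positive, got {self.well_depth}")

    @property
    def regime(self) -> str:
        return classify_regime(self.bond_length, self.well_width)

    @property
    def min_bond_angle(self) -> float:
        return min_bond_angle(self.bond_length)

    @property
    def n_nonbonded_pairs(self) -> int:
        """Number of pairs |i-j| >= 2; the deepest conceivable energy is
        -well_depth times this count."""
        n = self.n_monomers
        return (n - 1) * (n - 2) // 2


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Dense symmetric matrix of pair distances."""
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


@dataclass(frozen=True)
class ChainConformation:
    """An ordered set of 3D monomer coordinates (one point per monomer)."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError(f"coordinates must be (N, 3), got {c.shape}")
        object.__setattr__(self, "coords", c)

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[0]

    @property
    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.coords, axis=0)

    @property
    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors, axis=1)

    @classmethod
    def straight_rod(cls, params: ModelParams) -> "ChainConformation":
        """The all-angles-pi rod along z: valid for every L >= 0.5."""
        z = np.arange(params.n_monomers) * params.bond_length
        coords = np.zeros((params.n_monomers, 3))
        coords[:, 2] = z
        return cls(coords)

    def validate_bonds(self, bond_length: float, atol: float = 1e-9) -> None:
        dev = np.max(np.abs(self.bond_lengths - bond_length)) if self.n_monomers > 1 else 0.0
        if dev > atol:
            raise ValueError(f"bond lengths deviate from L={bond_length} by {dev:.3e}")


def _nonbonded_distances(conf: ChainConformation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = conf.n_monomers
    i, j = np.triu_indices(n, k=2)
    d = np.linalg.norm(conf.coords[i] - conf.coords[j], axis=1)
    return i, j, d


def is_self_avoiding(conf: ChainConformation) -> bool:
    """True iff every non-bonded pair (|i-j| >= 2) is at distance >= 1.

    Bonded pairs are exempt: the spheres are fused and their separation is
    fixed at L < 1 without penalty.
    """
    _, _, d = _nonbonded_distances(conf)
    return bool(np.all(d >= 1.0))


def total_energy(conf: ChainConformation, params: ModelParams) -> int:
    """Total square-well energy: -eps per non-bonded pair inside the well.

    With eps = 1 the energy is the negative of the contact count, always an
    integer in {-P, ..., 0} with P the number of non-bonded pairs.

    Raises
    ------
    HardCoreOverlapError
        If any non-bonded pair sits at r < 1; forbidden conformations never
        get a finite energy.
    """
    if conf.n_monomers != params.n_monomers:
        raise ValueError(
            f"conformation has {conf.n_monomers} monomers, params say {params.n_monomers}"
        )
    i, j, d = _nonbonded_distances(conf)
    if np.any(d < 1.0):
        k = int(np.argmin(d))
        raise HardCoreOverlapError(
            f"hard-core overlap: pair ({i[k]}, {j[k]}) at r = {d[k]:.6f} < 1"
        )
    n_contacts = int(np.count_nonzero(d <= params.well_width))
    # well_depth = 1 keeps the spectrum on exact integers
    return -n_contacts
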