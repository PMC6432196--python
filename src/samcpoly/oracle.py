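"""Brute-force ground truth for small chains by uniform direction sampling.

With rigid bonds the configuration integral factorizes over independent
bond directions, so drawing each successive bond direction uniformly on the
unit sphere and discarding chains with hard-core overlaps samples exactly
the finite-energy configuration measure.  The surviving-sample energy
frequencies are therefore proportional to g(E) restricted to self-avoiding
states, and ln-frequency differences are unbiased estimates of ln g
differences -- an independent anchor for the SAMC engine at small N.

For N = 3 there is a closed form: r13^2 of two isotropic unit bonds of
length L is uniform on [0, 4L^2], so the probability of a (1,3) contact
given no overlap is (lambda^2 - 1)/(4L^2 - 1) when 2L > lambda, and 1 when
2L <= lambda (the stiff regime's permanent contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = ["OracleDOS", "uniform_dos", "n3_contact_fraction"]

#: sampling beyond this N is refused unless explicitly overridden
DEFAULT_MAX_N = 8


@dataclass
class OracleDOS:
    """Energy-level frequencies from uniform sampling, with binomial errors."""

    energies: np.ndarray
    frequencies: np.ndarray
    std_errors: np.ndarray
    counts: np.ndarray
    n_valid: int
    n_samples: int
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def survival_fraction(self) -> float:
        return self.n_valid / self.n_samples

    def index(self, energy: int) -> int:
        k = int(np.searchsorted(self.energies, energy))
        if k >= len(self.energies) or self.energies[k] != energy:
            raise ValueError(f"energy {energy} not observed by the oracle")
        return k

    def ln_g_diff(self, e_a: int, e_b: int) -> tuple[float, float]:
        """ln g(e_a) - ln g(e_b) with its multinomial standard error.

        var(ln p_a - ln p_b) = (1/c_a + 1/c_b) to leading order (the
        covariance of multinomial counts cancels the -2/n cross term).
        """
        ca = self.counts[self.index(e_a)]
        cb = self.counts[self.index(e_b)]
        diff = float(np.log(ca / cb))
        return diff, float(np.sqrt(1.0 / ca + 1.0 / cb))


def uniform_dos(
    n_monomers: int,
    bond_length: float,
    well_width: float = 1.1,
    n_samples: int = 10**6,
    seed: int = 0,
    max_n: int = DEFAULT_MAX_N,
) -> OracleDOS:
    """Estimate relative g(E) for a small chain by direct uniform sampling.

    The cost guard ``max_n`` (default 8) exists because the survivor
    fraction and the level count explode with N; raise it knowingly.
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    if n_monomers > max_n:
        raise ValueError(
            f"N={n_monomers} exceeds the oracle cost guard max_n={max_n}"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    p_max = (n_monomers - 1) * (n_monomers - 2) // 2
    counts = np.zeros(p_max + 1, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_valid = int(
        _kernels.uniform_chain_energies(
            rng, n_monomers, bond_length, well_width**2, n_samples, counts
        )
    )
    if n_valid == 0:
        raise RuntimeError(
            "no self-avoiding sample survived; this cannot occur for L >= 0.51 "
            "at oracle-sized N"
        )
    observed = np.flatnonzero(counts)[::-1]  # descending contact count
    freqs = counts[observed] / n_valid
    errs = np.sqrt(freqs * (1.0 - freqs) / n_valid)
    return OracleDOS(
        energies=-observed.astype(np.int64),
        frequencies=freqs,
        std_errors=errs,
        counts=counts[observed],
        n_valid=n_valid,
        n_samples=n_samples,
        seed=seed,
        metadata={
            "n_monomers": n_monomers,
            "bond_length": bond_length,
            "well_width": well_width,
        },
    )


def n3_contact_fraction(bond_length: float, well_width: float = 1.1) -> float:
    """Exact P(E = -1) for a trimer with isotropic bonds, given no overlap."""
    if not 0.5 < bond_length <= 1.0:
        raise ValueError(f"bond length must be in (0.5, 1], got {bond_length}")
    if not well_width > 1.0:
        raise ValueError(f"well width must exceed 1, got {well_width}")
    if 2.0 * bond_length <= well_width:
        return 1.0
    return (well_width**2 - 1.0) / (4.0 * bond_length**2 - 1.0)
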