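"""Shared fixtures and independent mini-oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from samcpoly.model import ChainConformation, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def energy_by_enumeration(coords: np.ndarray, well_width: float) -> int | None:
    """Independent brute-force energy: explicit loops, no numpy tricks.

    Returns None for forbidden (hard-core overlapping) conformations.
    """
    n = len(coords)
    contacts = 0
    for i in range(n):
        for j in range(i + 2, n):
            r = math.dist(coords[i], coords[j])
            if r < 1.0:
                return None
            if r <= well_width:
                contacts += 1
    return -contacts


def random_valid_conformation(
    params: ModelParams, rng: np.random.Generator, max_tries: int = 10_000
) -> ChainConformation:
    """Uniform-measure self-avoiding chain by direction sampling + rejection."""
    n, L = params.n_monomers, params.bond_length
    for _ in range(max_tries):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            v = rng.standard_normal(3)
            coords[i] = coords[i - 1] + L * v / np.linalg.norm(v)
            for j in range(i - 1):
                if np.linalg.norm(coords[i] - coords[j]) < 1.0:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return ChainConformation(coords)
    raise RuntimeError("rejection sampling failed")


def three_monomer_at_angle(bond_length: float, theta: float) -> ChainConformation:
    """Explicit trimer with internal bond angle theta at the middle monomer."""
    a = np.array([bond_length, 0.0, 0.0])
    b = np.zeros(3)
    c = bond_length * np.array([math.cos(theta), math.sin(theta), 0.0])
    return ChainConformation(np.array([a, b, c]))
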