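"""Bond-length-preserving Monte Carlo proposal moves.

Three symmetric moves form the default set for a fixed-bond-length continuum
chain: *pivot* (rigid rotation of the tail about an axis through a pivot
monomer), *crankshaft* (rotation of one interior monomer about the axis
through its two neighbours) and *end rotation* (rotation of a terminal
monomer about its single neighbour).  Every move preserves all bond lengths
exactly (rigid rotations) and the proposal density is symmetric — the angle
is drawn uniformly in [-max_angle, +max_angle] and the axis distribution is
inversion-symmetric — so the flat-histogram acceptance rule applies without
proposal-ratio corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MoveSet",
    "rotation_matrix",
    "pivot_move",
    "crankshaft_move",
    "end_rotation",
    "propose_move",
]

_DEGENERATE_AXIS = 1e-12


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    one_c = 1.0 - c
    return np.array(
        [
            [c + x * x * one_c, x * y * one_c - z * s, x * z * one_c + y * s],
            [y * x * one_c + z * s, c + y * y * one_c, y * z * one_c - x * s],
            [z * x * one_c - y * s, z * y * one_c + x * s, c + z * z * one_c],
        ]
    )


@dataclass(frozen=True)
class MoveSet:
    """Selection weights and maximum rotation angles for the proposal moves.

    Weights need not be normalized; a weight of zero disables a move kind.
    For chains with N < 3 the pivot and crankshaft moves are inapplicable and
    are skipped regardless of weight.
    """

    pivot_weight: float = 1.0
    crankshaft_weight: float = 1.0
    end_weight: float = 1.0
    pivot_max_angle: float = np.pi
    crankshaft_max_angle: float = np.pi
    end_max_angle: float = np.pi

    def __post_init__(self) -> None:
        w = (self.pivot_weight, self.crankshaft_weight, self.end_weight)
        if any(x < 0 for x in w):
            raise ValueError(f"move weights must be non-negative, got {w}")
        if sum(w) <= 0:
            raise ValueError("at least one move weight must be positive")
        for a in (self.pivot_max_angle, self.crankshaft_max_angle, self.end_max_angle):
            if a < 0:
                raise ValueError("max angles must be non-negative")

    def weights(self, n_monomers: int) -> np.ndarray:
        w = np.array([self.pivot_weight, self.crankshaft_weight, self.end_weight])
        if n_monomers < 3:
            w[0] = 0.0
            w[1] = 0.0
        if w.sum() <= 0:
            raise ValueError(f"no applicable move for N={n_monomers} with these weights")
        return w

    def max_angles(self) -> np.ndarray:
        return np.array(
            [self.pivot_max_angle, self.crankshaft_max_angle, self.end_max_angle]
        )


def pivot_move(
    coords: np.ndarray, pivot_index: int, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rigidly rotate monomers after ``pivot_index`` about an axis through it.

    Monomers 0..pivot_index are untouched; all bond lengths are preserved
    because the moved segment rotates as a rigid body about a point on the
    bond joining it to the fixed segment.
    """
    n = coords.shape[0]
    if not 0 <= pivot_index < n:
        raise IndexError(f"pivot index {pivot_index} out of range for N={n}")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    out = coords.copy()
    if pivot_index == n - 1:
        return out
    rot = rotation_matrix(axis, angle)
    origin = coords[pivot_index]
    out[pivot_index + 1 :] = (coords[pivot_index + 1 :] - origin) @ rot.T + origin
    return out


def crankshaft_move(
    coords: np.ndarray,
    i: int,
    angle: float,
    fallback_axis: np.ndarray | None = None,
) -> np.ndarray:
    """Rotate interior monomer ``i`` about the axis through monomers i-1, i+1.

    Both neighbour distances are preserved (the rotation axis passes through
    both neighbours).  When the chain folds exactly back on itself
    (|r_{i+1} - r_{i-1}| below tolerance) the axis is undefined; we then fall
    back to rotating monomer i about ``fallback_axis`` through monomer i-1,
    which still preserves both neighbour distances because r_{i-1} = r_{i+1}.
    """
    n = coords.shape[0]
    if not 1 <= i <= n - 2:
        raise IndexError(f"crankshaft index {i} must be interior (1..{n - 2})")
    axis = coords[i + 1] - coords[i - 1]
    norm = np.linalg.norm(axis)
    if norm < _DEGENERATE_AXIS:
        if fallback_axis is None:
            fallback_axis = np.array([1.0, 0.0, 0.0])
        axis = np.asarray(fallback_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    else:
        axis = axis / norm
    rot = rotation_matrix(axis, angle)
    out = coords.copy()
    origin = coords[i - 1]
    out[i] = (coords[i] - origin) @ rot.T + origin
    return out


def end_rotation(
    coords: np.ndarray, end: str, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rotate a terminal monomer about an axis through its neighbour."""
    n = coords.shape[0]
    if n < 2:
        raise ValueError("end rotation needs at least 2 monomers")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = rotation_matrix(axis, angle)
    out = coords.copy()
    if end == "head":
        out[0] = (coords[0] - coords[1]) @ rot.T + coords[1]
    elif end == "tail":
        out[n - 1] = (coords[n - 1] - coords[n - 2]) @ rot.T + coords[n - 2]
    else:
        raise ValueError(f"end must be 'head' or 'tail', got {end!r}")
    return out


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def propose_move(
    coords: np.ndarray, rng: np.random.Generator, move_set: MoveSet | None = None
) -> tuple[np.ndarray, str]:
    """Draw one move from the set and apply it; returns (candidate, label).

    Validity (hard core) and energy are the caller's business; the proposal
    itself is symmetric and always bond-preserving.
    """
    if move_set is None:
        move_set = MoveSet()
    n = coords.shape[0]
    w = move_set.weights(n)
    kind = int(rng.choice(3, p=w / w.sum()))
    max_angle = move_set.max_angles()[kind]
    angle = rng.uniform(-max_angle, max_angle)
    if kind == 0:
        k = int(rng.integers(1, n - 1))
        return pivot_move(coords, k, random_unit_vector(rng), angle), "pivot"
    if kind == 1:
        i = int(rng.integers(1, n - 1))
        return (
            crankshaft_move(coords, i, angle, fallback_axis=random_unit_vector(rng)),
            "crankshaft",
        )
    end = "head" if rng.random() < 0.5 else "tail"
    return end_rotation(coords, end, random_unit_vector(rng), angle), f"end-{end}"
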