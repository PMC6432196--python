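"""Numba kernels for the SAMC inner loop and the uniform-sampling oracle.

Energies are exact integers (minus the square-well contact count), so the
density-of-states arrays are indexed by the contact count c = -E, running
from 0 to P = (N-1)(N-2)/2.  All kernels take a ``numpy.random.Generator``
whose state persists across calls, which makes chunked runs bit-identical
to single monolithic runs and enables exact checkpoint/resume.

Move proposals, the acceptance rule and the Eq.-style ln g update here are
the fast mirror of the pure-Python implementations in ``moves`` and
``samc``; the test suite cross-checks the two routes.
"""

import math

import numpy as np
from numba import njit

# well boundaries are inclusive: forbidden iff r < 1, in-well iff 1 <= r <= lambda


@njit(cache=True)
def _rand_unit_vector(rng):
    # Marsaglia (1972) rejection method: uniform on the unit sphere
    while True:
        a = 2.0 * rng.random() - 1.0
        b = 2.0 * rng.random() - 1.0
        s = a * a + b * b
        if s < 1.0:
            break
    root = math.sqrt(1.0 - s)
    return 2.0 * a * root, 2.0 * b * root, 1.0 - 2.0 * s


@njit(cache=True)
def _rotate_point(px, py, pz, ux, uy, uz, c, s):
    # Rodrigues rotation of p about unit axis u by angle with cos c, sin s
    one_c = 1.0 - c
    rx = (
        (c + ux * ux * one_c) * px
        + (ux * uy * one_c - uz * s) * py
        + (ux * uz * one_c + uy * s) * pz
    )
    ry = (
        (uy * ux * one_c + uz * s) * px
        + (c + uy * uy * one_c) * py
        + (uy * uz * one_c - ux * s) * pz
    )
    rz = (
        (uz * ux * one_c - uy * s) * px
        + (uz * uy * one_c + ux * s) * py
        + (c + uz * uz * one_c) * pz
    )
    return rx, ry, rz


@njit(cache=True)
def total_contacts(coords, lam2):
    """(forbidden, contact count) over all non-bonded pairs |i-j| >= 2."""
    n = coords.shape[0]
    contacts = 0
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < 1.0:
                return True, 0
            if d2 <= lam2:
                contacts += 1
    return False, contacts


@njit(cache=True)
def _cross_delta(coords, trial, lo, hi, lam2):
    """Contact-count change from replacing coords[lo:hi+1] by trial[lo:hi+1].

    Only pairs with one monomer inside [lo, hi] and one outside can change:
    the moved block is displaced rigidly, so its internal distances are
    untouched.  Returns (forbidden, delta) with delta exact (integers).
    """
    n = coords.shape[0]
    d_new = 0
    d_old = 0
    for a in range(lo, hi + 1):
        for b in range(n):
            if lo <= b <= hi:
                continue
            sep = a - b if a > b else b - a
            if sep < 2:
                continue
            dx = trial[a, 0] - coords[b, 0]
            dy = trial[a, 1] - coords[b, 1]
            dz = trial[a, 2] - coords[b, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < 1.0:
                return True, 0
            if d2 <= lam2:
                d_new += 1
            dx = coords[a, 0] - coords[b, 0]
            dy = coords[a, 1] - coords[b, 1]
            dz = coords[a, 2] - coords[b, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= lam2:
                d_old += 1
    return False, d_new - d_old


@njit(cache=True)
def _rg_squared(coords):
    n = coords.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(n):
        cx += coords[i, 0]
        cy += coords[i, 1]
        cz += coords[i, 2]
    cx /= n
    cy /= n
    cz /= n
    s = 0.0
    for i in range(n):
        dx = coords[i, 0] - cx
        dy = coords[i, 1] - cy
        dz = coords[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return s / n


@njit(cache=True)
def samc_chunk(
    rng,
    coords,
    n_steps,
    t_start,
    gamma0,
    t0,
    lam2,
    weights_cum,
    max_angles,
    ln_g,
    visits,
    discovered,
    disc_list,
    state,
    collect_start,
    stride,
    collect_contacts,
    obs_count,
    obs_rg2_sum,
    obs_contact_sum,
    gs_coords,
):
    """Advance the SAMC chain by ``n_steps`` elementary steps.

    state (int64[3]): [current contact count, M = number of discovered
    levels, best (ground-state) contact count so far].  disc_list holds the
    indices of discovered levels, first M entries valid.  All arrays are
    modified in place; the Generator carries the RNG state across chunks.
    """
    n = coords.shape[0]
    trial = np.empty((n, 3))
    cur = state[0]
    m = state[1]
    for step in range(n_steps):
        t = t_start + step
        # ---- propose: pick a move kind, draw axis and angle -------------
        u = rng.random()
        if u < weights_cum[0]:
            kind = 0
        elif u < weights_cum[1]:
            kind = 1
        else:
            kind = 2
        ux, uy, uz = _rand_unit_vector(rng)
        angle = (2.0 * rng.random() - 1.0) * max_angles[kind]
        c = math.cos(angle)
        s = math.sin(angle)
        if kind == 0:
            # pivot: rotate the tail k+1..N-1 about a random axis through k
            k = 1 + int(rng.integers(0, n - 2))
            lo = k + 1
            hi = n - 1
            ox = coords[k, 0]
            oy = coords[k, 1]
            oz = coords[k, 2]
            for j in range(lo, hi + 1):
                rx, ry, rz = _rotate_point(
                    coords[j, 0] - ox, coords[j, 1] - oy, coords[j, 2] - oz,
                    ux, uy, uz, c, s,
                )
                trial[j, 0] = rx + ox
                trial[j, 1] = ry + oy
                trial[j, 2] = rz + oz
        elif kind == 1:
            # crankshaft: rotate monomer i about the i-1 -> i+1 axis
            i = 1 + int(rng.integers(0, n - 2))
            lo = i
            hi = i
            ax = coords[i + 1, 0] - coords[i - 1, 0]
            ay = coords[i + 1, 1] - coords[i - 1, 1]
            az = coords[i + 1, 2] - coords[i - 1, 2]
            norm = math.sqrt(ax * ax + ay * ay + az * az)
            if norm < 1e-12:
                # chain folded exactly back: any axis through i-1 works
                ax, ay, az = ux, uy, uz
            else:
                ax /= norm
                ay /= norm
                az /= norm
            ox = coords[i - 1, 0]
            oy = coords[i - 1, 1]
            oz = coords[i - 1, 2]
            rx, ry, rz = _rotate_point(
                coords[i, 0] - ox, coords[i, 1] - oy, coords[i, 2] - oz,
                ax, ay, az, c, s,
            )
            trial[i, 0] = rx + ox
            trial[i, 1] = ry + oy
            trial[i, 2] = rz + oz
        else:
            # end rotation: rotate a terminal monomer about its neighbour
            if rng.random() < 0.5:
                lo = 0
                hi = 0
                pivot = 1
            else:
                lo = n - 1
                hi = n - 1
                pivot = n - 2
            ox = coords[pivot, 0]
            oy = coords[pivot, 1]
            oz = coords[pivot, 2]
            rx, ry, rz = _rotate_point(
                coords[lo, 0] - ox, coords[lo, 1] - oy, coords[lo, 2] - oz,
                ux, uy, uz, c, s,
            )
            trial[lo, 0] = rx + ox
            trial[lo, 1] = ry + oy
            trial[lo, 2] = rz + oz

        # ---- evaluate: hard-core auto-reject, else flat-histogram rule --
        forbidden, delta = _cross_delta(coords, trial, lo, hi, lam2)
        if not forbidden:
            cand = cur + delta
            # accept with min(1, g(old)/g(new)), in log space
            if ln_g[cand] <= ln_g[cur] or rng.random() < math.exp(
                ln_g[cur] - ln_g[cand]
            ):
                for j in range(lo, hi + 1):
                    coords[j, 0] = trial[j, 0]
                    coords[j, 1] = trial[j, 1]
                    coords[j, 2] = trial[j, 2]
                cur = cand

        # ---- update ln g at the retained energy (update-on-rejection) ---
        if not discovered[cur]:
            discovered[cur] = True
            disc_list[m] = cur
            m += 1
        gamma = gamma0 if t <= t0 else gamma0 * t0 / t
        ln_g[cur] += gamma
        sub = gamma / m
        for b in range(m):
            ln_g[disc_list[b]] -= sub
        visits[cur] += 1

        if cur > state[2]:
            state[2] = cur
            for j in range(n):
                gs_coords[j, 0] = coords[j, 0]
                gs_coords[j, 1] = coords[j, 1]
                gs_coords[j, 2] = coords[j, 2]

        # ---- energy-resolved observables --------------------------------
        if t >= collect_start and (t - collect_start) % stride == 0:
            obs_count[cur] += 1
            obs_rg2_sum[cur] += _rg_squared(coords)
            if collect_contacts:
                for i in range(n - 2):
                    for j in range(i + 2, n):
                        dx = coords[i, 0] - coords[j, 0]
                        dy = coords[i, 1] - coords[j, 1]
                        dz = coords[i, 2] - coords[j, 2]
                        d2 = dx * dx + dy * dy + dz * dz
                        if 1.0 <= d2 <= lam2:
                            obs_contact_sum[cur, i, j] += 1
    state[0] = cur
    state[1] = m


@njit(cache=True)
def uniform_chain_energies(rng, n, bond_length, lam2, n_samples, counts):
    """Histogram energies of uniformly drawn fixed-bond-length chains.

    Each chain is grown by placing successive bond directions uniformly on
    the unit sphere; chains with any hard-core overlap are discarded.  With
    rigid bonds the configuration measure factorizes over independent bond
    directions, so surviving-sample frequencies are proportional to g(E)
    restricted to self-avoiding states.  counts is indexed by the contact
    count c = -E.  Returns the number of surviving samples.
    """
    pos = np.empty((n, 3))
    n_valid = 0
    for _ in range(n_samples):
        pos[0, 0] = 0.0
        pos[0, 1] = 0.0
        pos[0, 2] = 0.0
        valid = True
        contacts = 0
        for i in range(1, n):
            bx, by, bz = _rand_unit_vector(rng)
            pos[i, 0] = pos[i - 1, 0] + bond_length * bx
            pos[i, 1] = pos[i - 1, 1] + bond_length * by
            pos[i, 2] = pos[i - 1, 2] + bond_length * bz
            for j in range(i - 1):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < 1.0:
                    valid = False
                    break
                if d2 <= lam2:
                    contacts += 1
            if not valid:
                break
        if valid:
            counts[contacts] += 1
            n_valid += 1
    return n_valid
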