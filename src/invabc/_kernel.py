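"""Jitted Gillespie kernel for the 3D lattice cellular automaton.

State layout shared with :mod:`invabc.lattice`:

``grid``   int8 (L, L, L): 0 empty, 1 clone A, 2 clone B.
``idx``    int32 (L, L, L): index of the occupying cell in its clone's
           position list, -1 when empty.
``pos``    int32 (2, cap, 3): per-clone position lists; only the first
           ``counts[c]`` rows of ``pos[c]`` are live.
``counts`` int64 (2,): live cells per clone (always equals grid tallies).

Sites outside the grid are treated as permanently occupied (no-flux
boundary). Randomness comes from numba's global NumPy-compatible RNG,
seeded once per simulation through :func:`seed_rng`; all event draws
inside one simulation then form a single deterministic stream.

Counter layout (``counters`` int64 (2, 5), one row per clone):
columns = divisions drawn, divisions executed, deaths, moves drawn,
moves executed. A drawn event whose execution is blocked by crowding is
a null event: it consumes the SSA draw (time advances, state unchanged).

Flag layout (``flags`` int64 (2,)): [boundary contact seen, overflow].
"""

import numpy as np
from numba import njit


def _moore_offsets() -> np.ndarray:
    offs = [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]
    return np.array(offs, dtype=np.int64)


#: The 26 offsets of the 3D Moore neighbourhood of length 1.
MOORE = _moore_offsets()

DIV_DRAWN, DIV_DONE, DEATH, MOVE_DRAWN, MOVE_DONE = 0, 1, 2, 3, 4
F_BOUNDARY, F_OVERFLOW = 0, 1


@njit(cache=False)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _place(grid, idx, pos, counts, clone, x, y, z, flags):
    """Append a new cell of ``clone`` at (x, y, z). Returns False on overflow."""
    j = counts[clone]
    if j >= pos.shape[1]:
        flags[F_OVERFLOW] = 1
        return False
    pos[clone, j, 0] = x
    pos[clone, j, 1] = y
    pos[clone, j, 2] = z
    idx[x, y, z] = j
    grid[x, y, z] = clone + 1
    counts[clone] = j + 1
    L = grid.shape[0]
    if x == 0 or y == 0 or z == 0 or x == L - 1 or y == L - 1 or z == L - 1:
        flags[F_BOUNDARY] = 1
    return True


@njit(cache=False)
def try_move(grid, idx, pos, counts, clone, i, flags):
    """Move cell ``i`` of ``clone`` to a uniformly chosen empty Moore
    neighbour; null event (returns False) when all 26 are occupied."""
    L = grid.shape[0]
    x = pos[clone, i, 0]
    y = pos[clone, i, 1]
    z = pos[clone, i, 2]
    ex = np.empty(26, dtype=np.int64)
    ey = np.empty(26, dtype=np.int64)
    ez = np.empty(26, dtype=np.int64)
    n_empty = 0
    for k in range(26):
        nx = x + MOORE[k, 0]
        ny = y + MOORE[k, 1]
        nz = z + MOORE[k, 2]
        if 0 <= nx < L and 0 <= ny < L and 0 <= nz < L:
            if grid[nx, ny, nz] == 0:
                ex[n_empty] = nx
                ey[n_empty] = ny
                ez[n_empty] = nz
                n_empty += 1
    if n_empty == 0:
        return False
    k = np.random.randint(n_empty)
    grid[x, y, z] = 0
    idx[x, y, z] = -1
    nx, ny, nz = ex[k], ey[k], ez[k]
    grid[nx, ny, nz] = clone + 1
    idx[nx, ny, nz] = i
    pos[clone, i, 0] = nx
    pos[clone, i, 1] = ny
    pos[clone, i, 2] = nz
    if nx == 0 or ny == 0 or nz == 0 or nx == L - 1 or ny == L - 1 or nz == L - 1:
        flags[F_BOUNDARY] = 1
    return True


@njit(cache=False)
def try_divide(grid, idx, pos, counts, clone, i, aggression, flags):
    """Divide cell ``i`` of ``clone``.

    The daughter goes to a uniformly chosen empty Moore neighbour. If the
    shell is full and ``aggression > 1``, the nearest empty site within
    Chebyshev distance ``aggression`` along one of the 26 lattice rays is
    found; ties between rays are broken uniformly, and the contiguous run
    of cells on the chosen ray is pushed outward by one site (clone labels
    travel with the pushed cells). Otherwise the division is a null event.
    """
    L = grid.shape[0]
    x = pos[clone, i, 0]
    y = pos[clone, i, 1]
    z = pos[clone, i, 2]
    ex = np.empty(26, dtype=np.int64)
    ey = np.empty(26, dtype=np.int64)
    ez = np.empty(26, dtype=np.int64)
    n_empty = 0
    for k in range(26):
        nx = x + MOORE[k, 0]
        ny = y + MOORE[k, 1]
        nz = z + MOORE[k, 2]
        if 0 <= nx < L and 0 <= ny < L and 0 <= nz < L:
            if grid[nx, ny, nz] == 0:
                ex[n_empty] = nx
                ey[n_empty] = ny
                ez[n_empty] = nz
                n_empty += 1
    if n_empty > 0:
        k = np.random.randint(n_empty)
        return _place(grid, idx, pos, counts, clone, ex[k], ey[k], ez[k], flags)
    if aggression <= 1:
        return False
    # Full shell: search rays for the nearest empty site within reach.
    best_k = aggression + 1
    dirs = np.empty(26, dtype=np.int64)
    n_dirs = 0
    for d in range(26):
        for k in range(2, aggression + 1):
            if k > best_k:
                break  # cannot improve on or tie the current nearest site
            nx = x + k * MOORE[d, 0]
            ny = y + k * MOORE[d, 1]
            nz = z + k * MOORE[d, 2]
            if not (0 <= nx < L and 0 <= ny < L and 0 <= nz < L):
                break  # ray leaves the grid: boundary blocks the push
            if grid[nx, ny, nz] == 0:
                if k < best_k:
                    best_k = k
                    dirs[0] = d
                    n_dirs = 1
                elif k == best_k:
                    dirs[n_dirs] = d
                    n_dirs += 1
                break
    if n_dirs == 0:
        return False
    d = dirs[np.random.randint(n_dirs)]
    dx, dy, dz = MOORE[d, 0], MOORE[d, 1], MOORE[d, 2]
    # Shift the occupied run outward into the empty site, far end first.
    for j in range(best_k - 1, 0, -1):
        sx, sy, sz = x + j * dx, y + j * dy, z + j * dz
        tx, ty, tz = x + (j + 1) * dx, y + (j + 1) * dy, z + (j + 1) * dz
        c2 = grid[sx, sy, sz] - 1
        ci = idx[sx, sy, sz]
        grid[tx, ty, tz] = c2 + 1
        idx[tx, ty, tz] = ci
        pos[c2, ci, 0] = tx
        pos[c2, ci, 1] = ty
        pos[c2, ci, 2] = tz
        if (tx == 0 or ty == 0 or tz == 0
                or tx == L - 1 or ty == L - 1 or tz == L - 1):
            flags[F_BOUNDARY] = 1
        grid[sx, sy, sz] = 0
        idx[sx, sy, sz] = -1
    return _place(grid, idx, pos, counts, clone,
                  x + dx, y + dy, z + dz, flags)


@njit(cache=False)
def do_death(grid, idx, pos, counts, clone, i):
    """Remove cell ``i`` of ``clone`` (the site empties immediately)."""
    x = pos[clone, i, 0]
    y = pos[clone, i, 1]
    z = pos[clone, i, 2]
    grid[x, y, z] = 0
    idx[x, y, z] = -1
    last = counts[clone] - 1
    if i != last:
        pos[clone, i, 0] = pos[clone, last, 0]
        pos[clone, i, 1] = pos[clone, last, 1]
        pos[clone, i, 2] = pos[clone, last, 2]
        idx[pos[clone, i, 0], pos[clone, i, 1], pos[clone, i, 2]] = i
    counts[clone] = last


@njit(cache=False)
def ssa_advance(grid, idx, pos, counts, t, until,
                prolif, motil, death_frac, aggression, inter,
                counters, flags):
    """Advance the state to time ``until`` by Gillespie's direct method.

    Per-cell rates: division at the clone's proliferation rate, movement
    at the clone's effective motility ``max(0, m_i + r_j * I_ij)`` with
    global clone proportions ``r_j``, death at ``death_frac * p_i``.
    Returns the new time (always ``until``; an empty lattice or zero
    total rate fast-forwards).
    """
    while True:
        na = counts[0]
        nb = counts[1]
        n = na + nb
        if n == 0:
            return until
        ra = na / n
        rb = nb / n
        ma = motil[0] + rb * inter[0, 1]
        if ma < 0.0:
            ma = 0.0
        mb = motil[1] + ra * inter[1, 0]
        if mb < 0.0:
            mb = 0.0
        r_div_a = prolif[0] * na
        r_mov_a = ma * na
        r_die_a = death_frac[0] * prolif[0] * na
        r_div_b = prolif[1] * nb
        r_mov_b = mb * nb
        r_die_b = death_frac[1] * prolif[1] * nb
        total = r_div_a + r_mov_a + r_die_a + r_div_b + r_mov_b + r_die_b
        if total <= 0.0:
            return until
        dt = np.random.exponential(1.0 / total)
        if t + dt > until:
            return until
        t = t + dt
        u = np.random.random() * total
        if u < r_div_a:
            clone, ev = 0, 0
        elif u < r_div_a + r_mov_a:
            clone, ev = 0, 1
        elif u < r_div_a + r_mov_a + r_die_a:
            clone, ev = 0, 2
        elif u < r_div_a + r_mov_a + r_die_a + r_div_b:
            clone, ev = 1, 0
        elif u < r_div_a + r_mov_a + r_die_a + r_div_b + r_mov_b:
            clone, ev = 1, 1
        else:
            clone, ev = 1, 2
        i = np.random.randint(counts[clone])
        if ev == 0:
            counters[clone, DIV_DRAWN] += 1
            if try_divide(grid, idx, pos, counts, clone, i,
                          aggression[clone], flags):
                counters[clone, DIV_DONE] += 1
            if flags[F_OVERFLOW] != 0:
                return t
        elif ev == 1:
            counters[clone, MOVE_DRAWN] += 1
            if try_move(grid, idx, pos, counts, clone, i, flags):
                counters[clone, MOVE_DONE] += 1
        else:
            counters[clone, DEATH] += 1
            do_death(grid, idx, pos, counts, clone, i)
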