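"""Lattice state and the elementary events of the invasion automaton.

The automaton lives on an L^3 grid whose sites are empty or hold a
single cell of clone A or B. Cells divide into, move into, and die out
of their 3D Moore neighbourhood of length 1; crowding-blocked divisions
can push a run of neighbours outward when the dividing clone carries a
proliferation-aggression distance > 1. Everything here wraps the jitted
primitives in :mod:`invabc._kernel`, so unit-level events and the full
Gillespie loop exercise the same code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .config import GLOBAL, CLONES, InteractionMatrix, PhenotypeParams, SimulationConfig

logger = logging.getLogger(__name__)

EMPTY = 0


class LatticeOverflowError(RuntimeError):
    """Raised when the lattice has no empty site left for a new cell."""


@dataclass
class LatticeState:
    """Mutable simulation state: occupancy grid plus per-clone bookkeeping."""

    grid: np.ndarray          # int8 (L, L, L)
    idx: np.ndarray           # int32 (L, L, L), -1 where empty
    pos: np.ndarray           # int32 (2, cap, 3)
    counts: np.ndarray        # int64 (2,)
    time: float = 0.0
    counters: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 5), dtype=np.int64))
    flags: np.ndarray = field(
        default_factory=lambda: np.zeros(2, dtype=np.int64))
    rng_seed: int | None = None
    _rng_seeded: bool = False
    _py_rng: object = None

    @property
    def lattice_edge(self) -> int:
        return self.grid.shape[0]

    @property
    def total_cells(self) -> int:
        return int(self.counts.sum())

    @property
    def boundary_contact(self) -> bool:
        return bool(self.flags[K.F_BOUNDARY])

    def count(self, clone: str) -> int:
        return int(self.counts[CLONES.index(clone)])

    def positions(self, clone: str) -> np.ndarray:
        c = CLONES.index(clone)
        return self.pos[c, : self.counts[c]].copy()

    def event_counts(self) -> dict:
        """Realized/drawn event tallies accumulated by :func:`advance`."""
        c = self.counters
        return {
            "divisions_drawn": int(c[:, K.DIV_DRAWN].sum()),
            "divisions": int(c[:, K.DIV_DONE].sum()),
            "deaths": int(c[:, K.DEATH].sum()),
            "moves_drawn": int(c[:, K.MOVE_DRAWN].sum()),
            "moves": int(c[:, K.MOVE_DONE].sum()),
        }

    def check_consistency(self) -> None:
        """Assert the grid, index and position bookkeeping agree."""
        for c in range(2):
            n = int(self.counts[c])
            tally = int(np.count_nonzero(self.grid == c + 1))
            if tally != n:
                raise AssertionError(
                    f"clone {CLONES[c]}: count {n} != grid tally {tally}")
            for i in range(n):
                x, y, z = self.pos[c, i]
                if self.grid[x, y, z] != c + 1 or self.idx[x, y, z] != i:
                    raise AssertionError(f"bookkeeping mismatch at {(x, y, z)}")

    def _ensure_rng(self) -> None:
        if not self._rng_seeded:
            seed = 0 if self.rng_seed is None else int(self.rng_seed)
            K.seed_rng(seed % (2 ** 31))
            self._rng_seeded = True


def initialize_spheroid(config: SimulationConfig) -> LatticeState:
    """Seed a well-mixed spheroid: every site within ``seed_radius`` of the
    lattice centre is occupied, clone A with probability ``seeding_ratio``
    i.i.d. per site."""
    L = config.lattice_edge
    r = config.seed_radius
    cx, cy, cz = config.center
    ax = np.arange(L)
    d2 = ((ax[:, None, None] - cx) ** 2
          + (ax[None, :, None] - cy) ** 2
          + (ax[None, None, :] - cz) ** 2)
    sites = np.argwhere(d2 <= r * r).astype(np.int32)
    rng = np.random.default_rng(config.rng_seed)
    is_a = rng.random(len(sites)) < config.seeding_ratio

    cap = L ** 3
    grid = np.zeros((L, L, L), dtype=np.int8)
    idx = np.full((L, L, L), -1, dtype=np.int32)
    pos = np.zeros((2, cap, 3), dtype=np.int32)
    counts = np.zeros(2, dtype=np.int64)
    for site, a in zip(sites, is_a):
        c = 0 if a else 1
        j = counts[c]
        pos[c, j] = site
        idx[tuple(site)] = j
        grid[tuple(site)] = c + 1
        counts[c] = j + 1
    state = LatticeState(grid=grid, idx=idx, pos=pos, counts=counts,
                         rng_seed=config.rng_seed)
    if np.any(sites == 0) or np.any(sites == L - 1):
        state.flags[K.F_BOUNDARY] = 1
    return state


def effective_motility(clone: str, base: float, proportions: dict,
                       model: InteractionMatrix) -> float:
    """Effective motility ``max(0, m_i + sum_{j != i} r_j * I_ij)``.

    ``proportions`` maps clone labels to their fraction of living cells
    (global by default; pass locally computed fractions for a finite
    interaction neighbourhood). A mono-culture (all other proportions
    zero) returns the base rate; negative results clamp to zero.
    """
    if base < 0:
        raise ValueError("base motility must be >= 0")
    i = CLONES.index(clone)
    m = model.matrix
    eff = base
    for j, other in enumerate(CLONES):
        if j != i:
            eff += proportions.get(other, 0.0) * m[i, j]
    return max(0.0, eff)


def global_proportions(state: LatticeState) -> dict:
    n = state.total_cells
    if n == 0:
        return {c: 0.0 for c in CLONES}
    return {c: float(state.counts[k]) / n for k, c in enumerate(CLONES)}


def local_proportions(state: LatticeState, site, size: int) -> dict:
    """Clone proportions within the Moore neighbourhood of ``size`` around
    ``site`` (the site itself included), for finite-range interactions."""
    L = state.lattice_edge
    x, y, z = site
    sl = tuple(slice(max(0, v - size), min(L, v + size + 1)) for v in (x, y, z))
    block = state.grid[sl]
    n = int(np.count_nonzero(block))
    if n == 0:
        return {c: 0.0 for c in CLONES}
    return {c: float(np.count_nonzero(block == k + 1)) / n
            for k, c in enumerate(CLONES)}


def enumerate_propensities(state: LatticeState, params, model=None) -> dict:
    """Per-clone event rates and the total propensity (events/day).

    Each living cell contributes division at its proliferation rate,
    movement at its effective motility, and death at ``death_fraction``
    times its proliferation rate. Returns a dict with per-clone rate
    triples under ``rates[clone] = {division, movement, death}`` (totals
    over the clone's cells) and the grand ``total``.
    """
    params = _as_pair(params)
    model = model or InteractionMatrix.none()
    props = global_proportions(state)
    rates = {}
    total = 0.0
    for k, clone in enumerate(CLONES):
        n = int(state.counts[k])
        p = params[k]
        if model.neighborhood_size == GLOBAL:
            eff_m = effective_motility(clone, p.motility_rate, props, model)
            mov = eff_m * n
        else:
            mov = 0.0
            size = int(model.neighborhood_size)
            for i in range(n):
                site = state.pos[k, i]
                loc = local_proportions(state, site, size)
                mov += effective_motility(clone, p.motility_rate, loc, model)
        div = p.proliferation_rate * n
        die = p.death_rate * n
        rates[clone] = {"division": div, "movement": mov, "death": die}
        total += div + mov + die
    return {"rates": rates, "total": total}


def sample_next_event(state: LatticeState, params, model=None,
                      rng: np.random.Generator | None = None):
    """Draw (dt, clone, event) for the next SSA event without executing it.

    ``dt`` is exponential in the total propensity; the (clone, event)
    pair is chosen with probability proportional to its aggregate rate.
    Returns ``None`` when the total propensity is zero.
    """
    rng = rng or np.random.default_rng()
    prop = enumerate_propensities(state, params, model)
    total = prop["total"]
    if total <= 0:
        return None
    dt = rng.exponential(1.0 / total)
    labels, weights = [], []
    for clone in CLONES:
        for ev, r in prop["rates"][clone].items():
            labels.append((clone, ev))
            weights.append(r)
    k = rng.choice(len(labels), p=np.asarray(weights) / total)
    clone, ev = labels[k]
    return dt, clone, ev


def _as_pair(params):
    if isinstance(params, PhenotypeParams):
        return (params, params)
    a, b = params
    return (a, b)


def _site_index(state: LatticeState, site):
    x, y, z = site
    c = int(state.grid[x, y, z])
    if c == EMPTY:
        raise ValueError(f"site {tuple(site)} is empty")
    return c - 1, int(state.idx[x, y, z])


def execute_move(state: LatticeState, site, seed: int | None = None) -> bool:
    """Relocate the cell at ``site`` to a uniformly chosen empty Moore
    neighbour; a fully blocked cell is a null event (state unchanged)."""
    if seed is not None:
        K.seed_rng(int(seed) % (2 ** 31))
        state._rng_seeded = True
    state._ensure_rng()
    clone, i = _site_index(state, site)
    return bool(K.try_move(state.grid, state.idx, state.pos, state.counts,
                           clone, i, state.flags))


def execute_division(state: LatticeState, site, aggression: int = 1,
                     seed: int | None = None) -> bool:
    """Divide the cell at ``site``; see :func:`invabc._kernel.try_divide`."""
    if seed is not None:
        K.seed_rng(int(seed) % (2 ** 31))
        state._rng_seeded = True
    state._ensure_rng()
    clone, i = _site_index(state, site)
    ok = bool(K.try_divide(state.grid, state.idx, state.pos, state.counts,
                           clone, i, int(aggression), state.flags))
    if state.flags[K.F_OVERFLOW]:
        raise LatticeOverflowError("no empty site anywhere on the lattice")
    return ok


def execute_death(state: LatticeState, site) -> None:
    """Remove the cell at ``site``; the site becomes empty immediately."""
    clone, i = _site_index(state, site)
    K.do_death(state.grid, state.idx, state.pos, state.counts, clone, i)


def advance(state: LatticeState, params, model=None, until: float = None,
            rng_seed: int | None = None) -> LatticeState:
    """Advance the SSA trajectory in place to time ``until`` (days).

    Exact Gillespie direct method: exponential waiting times from the
    total propensity, event and cell chosen proportionally to their
    rates. Blocked moves/divisions consume their draw. With zero total
    propensity the clock simply fast-forwards.
    """
    if until is None or until < state.time:
        raise ValueError("until must be >= state.time")
    if rng_seed is not None:
        K.seed_rng(int(rng_seed) % (2 ** 31))
        state._rng_seeded = True
    state._ensure_rng()
    params = _as_pair(params)
    model = model or InteractionMatrix.none()
    if model.neighborhood_size != GLOBAL:
        return _advance_local(state, params, model, until)
    prolif = np.array([p.proliferation_rate for p in params])
    motil = np.array([p.motility_rate for p in params])
    dfrac = np.array([p.death_fraction for p in params])
    aggr = np.array([p.aggression for p in params], dtype=np.int64)
    state.time = float(K.ssa_advance(
        state.grid, state.idx, state.pos, state.counts,
        float(state.time), float(until),
        prolif, motil, dfrac, aggr, model.matrix,
        state.counters, state.flags))
    if state.flags[K.F_OVERFLOW]:
        raise LatticeOverflowError("no empty site anywhere on the lattice")
    return state


def _advance_local(state: LatticeState, params, model, until: float):
    """Reference SSA with finite interaction neighbourhoods.

    Movement propensities depend on each cell's local clone proportions,
    so they are recomputed every event (O(N) per event); intended for
    small lattices and validation, not production runs.
    """
    if state._py_rng is None:
        state._py_rng = np.random.default_rng(state.rng_seed)
    rng = state._py_rng
    while True:
        prop = enumerate_propensities(state, params, model)
        total = prop["total"]
        if total <= 0:
            state.time = until
            return state
        dt = rng.exponential(1.0 / total)
        if state.time + dt > until:
            state.time = until
            return state
        state.time += dt
        labels, weights = [], []
        for clone in CLONES:
            for ev, r in prop["rates"][clone].items():
                labels.append((clone, ev))
                weights.append(r)
        k = rng.choice(len(labels), p=np.asarray(weights) / total)
        clone, ev = labels[k]
        c = CLONES.index(clone)
        if ev == "movement" and model.neighborhood_size != GLOBAL:
            # cell chosen proportionally to its own effective motility
            size = int(model.neighborhood_size)
            n = int(state.counts[c])
            per = np.array([
                effective_motility(
                    clone, params[c].motility_rate,
                    local_proportions(state, state.pos[c, i], size), model)
                for i in range(n)])
            if per.sum() <= 0:
                continue
            i = rng.choice(n, p=per / per.sum())
        else:
            i = rng.integers(int(state.counts[c]))
        site = tuple(state.pos[c, i])
        if ev == "division":
            state.counters[c, K.DIV_DRAWN] += 1
            if execute_division(state, site, params[c].aggression):
                state.counters[c, K.DIV_DONE] += 1
        elif ev == "movement":
            state.counters[c, K.MOVE_DRAWN] += 1
            if execute_move(state, site):
                state.counters[c, K.MOVE_DONE] += 1
        else:
            state.counters[c, K.DEATH] += 1
            execute_death(state, site)


def collapse_to_2d(state: LatticeState) -> dict:
    """Project the 3D occupancy to one 2D binary mask per clone: pixel
    (x, y) is set iff any z-column site holds a cell of that clone."""
    return {clone: np.any(state.grid == k + 1, axis=2)
            for k, clone in enumerate(CLONES)}
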