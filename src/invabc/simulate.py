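"""Run whole spheroid-invasion simulations and collect 2D snapshots.

A snapshot emulates one microscope acquisition: the 3D configuration is
collapsed along z into one binary mask per clone, the way fluorescence
images of an embedded spheroid flatten a 3D object into 2D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import CLONES, InteractionMatrix, PhenotypeParams, SimulationConfig
from .lattice import LatticeState, advance, collapse_to_2d, initialize_spheroid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Snapshot:
    """One imaging time point: per-clone masks plus true 3D cell counts."""

    time: float
    masks: dict          # clone label -> 2D bool array (L, L)
    counts: dict         # clone label -> int, true 3D count

    def mask(self, clone: str) -> np.ndarray:
        return self.masks[clone]


def take_snapshot(state: LatticeState) -> Snapshot:
    return Snapshot(
        time=float(state.time),
        masks=collapse_to_2d(state),
        counts={c: state.count(c) for c in CLONES},
    )


def run_simulation(config: SimulationConfig, params, model=None,
                   return_state: bool = False):
    """Simulate one spheroid and return its snapshot stack.

    Parameters
    ----------
    config : SimulationConfig
    params : PhenotypeParams or (PhenotypeParams, PhenotypeParams)
        A single phenotype is applied to both clones.
    model : InteractionMatrix, optional
        Defaults to no interaction.
    return_state : bool
        Also return the final :class:`LatticeState` (for event tallies).

    Snapshots are taken at ``t = 0, snapshot_interval, ..., end_time``.
    Identical configs (including ``rng_seed``) give bit-identical stacks.
    Boundary contact is logged as a warning: the fitted spheroids of the
    assay never reach the image frame, so contact marks an undersized
    lattice. A lattice with no empty site aborts with
    :class:`~invabc.lattice.LatticeOverflowError`.
    """
    model = model or InteractionMatrix.none()
    state = initialize_spheroid(config)
    snapshots = [take_snapshot(state)]
    for t in config.snapshot_times()[1:]:
        advance(state, params, model, until=float(t))
        snapshots.append(take_snapshot(state))
    if state.boundary_contact:
        logger.warning(
            "simulation touched the lattice boundary (edge %d); "
            "results near the frame are unreliable", config.lattice_edge)
    if return_state:
        return snapshots, state
    return snapshots
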