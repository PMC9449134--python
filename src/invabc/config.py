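"""Parameter containers for the spheroid-invasion cellular automaton.

Units follow the assay convention: proliferation rates are divisions per
day (d/day), motility rates are cell widths per day (x/day), and lattice
distances are in cell widths (one lattice site = one cell width = one
mask pixel). Cell death is never an independent rate: it is a fixed
fraction (10% by default) of the proliferation rate, which permits
turnover while guaranteeing net growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

#: Sentinel for an interaction neighbourhood spanning the whole lattice.
GLOBAL = "global"

#: Clone labels used throughout the package; internally clone A occupies
#: grid value 1 and clone B grid value 2.
CLONES = ("A", "B")


@dataclass(frozen=True)
class PhenotypeParams:
    """Per-clone phenotype: proliferation, motility and crowding behaviour.

    Parameters
    ----------
    proliferation_rate : float
        Divisions per day (d/day), >= 0.
    motility_rate : float
        Lattice steps per day (x/day), >= 0. Every executed movement event
        is one step to a Moore-adjacent site regardless of direction.
    aggression : int
        Maximum Chebyshev distance over which a dividing cell may push a
        run of neighbours to reach an empty site when its own Moore shell
        is full. ``1`` is equivalent to no pushing (the Moore shell itself).
    death_fraction : float
        Death rate as a fraction of the proliferation rate; default 0.1.
    """

    proliferation_rate: float
    motility_rate: float
    aggression: int = 1
    death_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.proliferation_rate < 0:
            raise ValueError("proliferation_rate must be >= 0")
        if self.motility_rate < 0:
            raise ValueError("motility_rate must be >= 0")
        if self.aggression < 0 or int(self.aggression) != self.aggression:
            raise ValueError("aggression must be a non-negative integer")
        if not 0 <= self.death_fraction < 1:
            raise ValueError("death_fraction must be in [0, 1)")

    @property
    def death_rate(self) -> float:
        """Death rate in events/day: always ``death_fraction * proliferation_rate``."""
        return self.death_fraction * self.proliferation_rate


@dataclass(frozen=True)
class InteractionMatrix:
    """Pairwise motility interactions between clones.

    ``strengths[i, j]`` is the interaction received by clone *i* from
    clone *j* (x/day per unit proportion of clone *j*); the effective
    motility of clone *i* is ``max(0, m_i + sum_j r_j * I_ij)`` where
    ``r_j`` is the proportion of clone *j* among living cells. Diagonal
    entries are zero (a clone does not interact with itself through this
    channel). The proportions are computed over ``neighborhood_size``:
    the :data:`GLOBAL` sentinel (default, as used for chemokine-like
    long-range signalling) means the whole lattice.
    """

    strengths: tuple = ((0.0, 0.0), (0.0, 0.0))
    neighborhood_size: int | str = GLOBAL

    def __post_init__(self) -> None:
        m = np.asarray(self.strengths, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("strengths must be a 2x2 matrix")
        if not np.all(np.isfinite(m)):
            raise ValueError("interaction strengths must be finite")
        if m[0, 0] != 0.0 or m[1, 1] != 0.0:
            raise ValueError("diagonal interaction entries must be zero")
        if self.neighborhood_size != GLOBAL:
            if int(self.neighborhood_size) <= 0:
                raise ValueError("neighborhood_size must be positive or GLOBAL")
        object.__setattr__(self, "strengths", tuple(map(tuple, m.tolist())))

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.strengths, dtype=float)

    @classmethod
    def none(cls) -> "InteractionMatrix":
        return cls()

    @classmethod
    def received(cls, by_a: float = 0.0, by_b: float = 0.0) -> "InteractionMatrix":
        """Interaction received by A from B (``by_a``) and by B from A (``by_b``)."""
        return cls(strengths=((0.0, by_a), (by_b, 0.0)))


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, seeding and scheduling of one spheroid simulation.

    The spheroid is seeded as a ball of radius ``seed_radius`` (lattice
    units) centred in an ``lattice_edge``-cubed grid; each seeded site is
    assigned clone A with probability ``seeding_ratio`` independently
    (well-mixed seeding). Snapshots (2D collapsed masks) are taken at
    ``t = 0, snapshot_interval, ..., end_time`` days.
    """

    lattice_edge: int = 120
    seed_radius: int = 5
    seeding_ratio: float = 1.0
    end_time: float = 3.0
    snapshot_interval: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_edge < 3:
            raise ValueError("lattice_edge must be >= 3")
        if self.seed_radius < 0:
            raise ValueError("seed_radius must be >= 0")
        center = self.lattice_edge // 2
        if (center - self.seed_radius <= 0
                or center + self.seed_radius >= self.lattice_edge - 1):
            raise ValueError(
                "seed ball of radius %d touches the boundary of a %d^3 lattice"
                % (self.seed_radius, self.lattice_edge))
        if not 0.0 <= self.seeding_ratio <= 1.0:
            raise ValueError("seeding_ratio must be in [0, 1]")
        if self.end_time < 0:
            raise ValueError("end_time must be >= 0")
        if self.snapshot_interval <= 0 or self.snapshot_interval > max(self.end_time, 1e-12):
            raise ValueError("snapshot_interval must be in (0, end_time]")

    @property
    def center(self) -> tuple[int, int, int]:
        c = self.lattice_edge // 2
        return (c, c, c)

    def snapshot_times(self) -> np.ndarray:
        n = int(round(self.end_time / self.snapshot_interval))
        times = np.arange(n + 1) * self.snapshot_interval
        return np.minimum(times, self.end_time)


def _phenotype_from_dict(d: Mapping) -> PhenotypeParams:
    return PhenotypeParams(
        proliferation_rate=float(d["proliferation_rate"]),
        motility_rate=float(d["motility_rate"]),
        aggression=int(d.get("aggression", 1)),
        death_fraction=float(d.get("death_fraction", 0.1)),
    )


def load_run_config(path) -> dict:
    """Load a YAML/JSON run configuration.

    Expected keys: ``simulation`` (SimulationConfig fields), ``clone_a``
    and optionally ``clone_b`` (PhenotypeParams fields), optionally
    ``interaction`` with ``received_by_a`` / ``received_by_b`` and
    ``neighborhood_size``. Returns a dict with instantiated objects under
    keys ``config``, ``params`` (tuple A, B) and ``interaction``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    config = SimulationConfig(**raw.get("simulation", {}))
    a = _phenotype_from_dict(raw["clone_a"])
    b = _phenotype_from_dict(raw["clone_b"]) if "clone_b" in raw else a
    inter = raw.get("interaction", {})
    interaction = InteractionMatrix.received(
        by_a=float(inter.get("received_by_a", 0.0)),
        by_b=float(inter.get("received_by_b", 0.0)),
    )
    if "neighborhood_size" in inter:
        interaction = InteractionMatrix(
            strengths=interaction.strengths,
            neighborhood_size=inter["neighborhood_size"],
        )
    return {"config": config, "params": (a, b), "interaction": interaction}


def dump_run_config(path, config: SimulationConfig, params, interaction=None) -> None:
    a, b = params
    doc = {
        "simulation": asdict(config),
        "clone_a": asdict(a),
        "clone_b": asdict(b),
    }
    if interaction is not None:
        m = interaction.matrix
        doc["interaction"] = {
            "received_by_a": float(m[0, 1]),
            "received_by_b": float(m[1, 0]),
            "neighborhood_size": interaction.neighborhood_size,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
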