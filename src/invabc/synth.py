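"""Synthetic invasion experiments with known ground truth.

Emulates the spheroid co-culture assay design end to end: two clones
grown as mono-cultures and as co-cultures at set seeding ratios, each
condition replicated, imaged at 24-hour intervals, with the simulator's
2D-collapsed snapshots standing in for segmented fluorescence masks and
optional segmentation-like noise (dropped pixels, spurious pixels near
the spheroid). Because the generating phenotype and interaction matrix
are recorded alongside the data, these datasets drive validation of the
whole inference pipeline.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.morphology import convex_hull_image

from .config import CLONES, InteractionMatrix, PhenotypeParams, SimulationConfig
from .lattice import advance, initialize_spheroid
from .maskio import write_manifest, write_mask
from .simulate import Snapshot, take_snapshot


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Complete specification of a synthetic co-culture experiment.

    Defaults mirror the assay design: co-cultures at 75:25, 50:50 and
    25:75 seeding ratios alongside both mono-cultures, six replicates per
    condition, imaged daily from day 0 to day 3, noiseless masks.
    """

    params_a: PhenotypeParams
    params_b: PhenotypeParams
    interaction: InteractionMatrix = field(default_factory=InteractionMatrix.none)
    ratios: tuple = (0.25, 0.5, 0.75)
    days: tuple = (0.0, 1.0, 2.0, 3.0)
    replicates: int = 6
    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0
    master_seed: int = 0
    lattice_edge: int = 120
    seed_radius: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.false_negative_rate < 1:
            raise ValueError("false_negative_rate must be in [0, 1)")
        if not 0 <= self.false_positive_rate < 1:
            raise ValueError("false_positive_rate must be in [0, 1)")
        if any(not 0 < r < 1 for r in self.ratios):
            raise ValueError("co-culture ratios must lie strictly in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def conditions(self) -> list:
        """(condition label, seeding ratio, clones imaged) triples."""
        conds = [("mono_A", 1.0, ("A",)), ("mono_B", 0.0, ("B",))]
        for r in self.ratios:
            conds.append((f"co_{r:g}", float(r), ("A", "B")))
        return conds


def condition_seed(master_seed: int, condition: str, replicate: int) -> int:
    """Stable per-condition seed derived from the master seed by hashing."""
    key = f"{master_seed}:{condition}:{replicate}".encode()
    return zlib.crc32(key) % (2 ** 31 - 1)


def apply_segmentation_noise(mask: np.ndarray, false_negative_rate: float,
                             false_positive_rate: float, seed: int
                             ) -> np.ndarray:
    """Corrupt a mask the way imperfect segmentation would.

    Occupied pixels are dropped independently with the false-negative
    rate; empty pixels inside the mask's convex hull are set with the
    false-positive rate (segmentation artefacts arise near the spheroid,
    not in empty matrix). Rates of zero return the mask unchanged.
    """
    if not 0 <= false_negative_rate < 1 or not 0 <= false_positive_rate < 1:
        raise ValueError("noise rates must be in [0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if (false_negative_rate == 0 and false_positive_rate == 0) or not mask.any():
        return mask.copy()
    rng = np.random.default_rng(seed)
    out = mask.copy()
    if false_negative_rate > 0:
        drop = rng.random(mask.shape) < false_negative_rate
        out &= ~(mask & drop)
    if false_positive_rate > 0:
        hull = convex_hull_image(mask)
        candidates = hull & ~mask
        add = rng.random(mask.shape) < false_positive_rate
        out |= candidates & add
    return out


@dataclass
class SyntheticDataset:
    """In-memory synthetic experiment: manifest rows plus mask arrays."""

    manifest: pd.DataFrame
    masks: dict                    # path -> bool array
    truth: SyntheticGroundTruth

    def mask(self, well: str, day: float, clone: str) -> np.ndarray:
        sel = self.manifest[(self.manifest.well == well)
                            & (self.manifest.day == day)
                            & (self.manifest.clone == clone)]
        if len(sel) != 1:
            raise KeyError((well, day, clone))
        return self.masks[sel.iloc[0]["path"]]

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for path, mask in self.masks.items():
            write_mask(os.path.join(out_dir, path), mask)
        write_manifest(self.manifest, os.path.join(out_dir, "manifest.csv"))
        doc = asdict(self.truth)
        doc["interaction"] = {
            "strengths": [list(r) for r in self.truth.interaction.strengths],
            "neighborhood_size": self.truth.interaction.neighborhood_size,
        }
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(doc, fh, indent=1, default=str)


def generate_synthetic_experiment(truth: SyntheticGroundTruth,
                                  out_dir=None) -> SyntheticDataset:
    """Simulate every condition and replicate of a synthetic experiment.

    Each (condition, replicate) gets an independent simulation whose seed
    is a stable hash of the master seed, so the dataset is byte-identical
    across regenerations. Mono-culture conditions record only their own
    clone's masks; co-cultures record both channels.
    """
    days = sorted(float(d) for d in truth.days)
    records = []
    masks = {}
    for condition, ratio, clones in truth.conditions():
        for rep in range(truth.replicates):
            seed = condition_seed(truth.master_seed, condition, rep)
            cfg = SimulationConfig(
                lattice_edge=truth.lattice_edge,
                seed_radius=truth.seed_radius,
                seeding_ratio=ratio,
                end_time=max(days[-1], 1e-9),
                snapshot_interval=max(days[-1], 1e-9),
                rng_seed=seed,
            )
            state = initialize_spheroid(cfg)
            well = f"{condition}_r{rep}"
            for day in days:
                if day > state.time:
                    advance(state, (truth.params_a, truth.params_b),
                            truth.interaction, until=day)
                snap = take_snapshot(state)
                for clone in clones:
                    mask = snap.masks[clone]
                    noise_seed = condition_seed(
                        truth.master_seed, f"noise:{condition}:{clone}:{day}", rep)
                    mask = apply_segmentation_noise(
                        mask, truth.false_negative_rate,
                        truth.false_positive_rate, noise_seed)
                    path = f"{well}_{clone}_d{day:g}.png"
                    masks[path] = mask
                    records.append({
                        "path": path, "well": well, "day": day,
                        "clone": clone, "ratio": ratio, "replicate": rep,
                        "condition": condition,
                    })
    manifest = pd.DataFrame.from_records(records)
    ds = SyntheticDataset(manifest=manifest, masks=masks, truth=truth)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
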