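"""Invasion summary statistics computed from per-clone binary masks.

Four mask-level statistics quantify an invading spheroid:

* **wave-front coefficient** ``w`` (pixels) and **diffusion coefficient**
  ``a`` (density/distance): the location and inverse steepness of a
  logistic front ``C(r) = 1 / (1 + exp((r - w) / (2 a)))`` fitted to the
  radial occupancy profile. ``w`` measures the extent of the dense core,
  ``a`` how dispersed the invading margin is. These are descriptive
  coefficients of a static configuration, not PDE constants.
* **invaded area** (pixels^2): the convex-hull area of occupied pixels.
* **cell density** (cells/pixel^2): a cell count divided by the invaded
  area; set pixels serve as the 2D count proxy when the true 3D count is
  unavailable.

Co-culture experiments are reduced further to a **ratio curve**: a
clone's invaded area normalised to its mono-culture value, as a function
of its seeding ratio, with a quadratic fit whose area under the curve
(AUC) on [0, 1] summarises the interaction it receives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError


@dataclass(frozen=True)
class RadialProfile:
    """Occupancy fraction per annulus around the spheroid centre."""

    bin_centers: np.ndarray   # pixels from center
    occupancy: np.ndarray     # fraction of annulus pixels occupied, in [0, 1]
    center: tuple             # (x, y) used
    bin_width: float


@dataclass(frozen=True)
class WaveFit:
    """Fitted logistic front; ``converged`` is False on optimizer failure."""

    wave_front: float     # w, pixels
    diffusion: float      # a, density/distance, > 0
    rss: float
    converged: bool = True

    def predict(self, r):
        return logistic_front(np.asarray(r, dtype=float),
                              self.wave_front, self.diffusion)


@dataclass(frozen=True)
class InvasionSummary:
    """All per-mask statistics for one clone at one time point."""

    clone: str
    time: float
    area: float
    density: float
    wave_front: float
    diffusion: float
    n_pixels: int
    count: int | None = None
    wave_converged: bool = True


@dataclass(frozen=True)
class RatioCurve:
    """Mono-culture-normalised area versus seeding ratio, with quadratic fit."""

    ratios: np.ndarray
    normalized_area: np.ndarray
    coeffs: np.ndarray        # quadratic coefficients, highest power first
    auc: float


def logistic_front(r, w, a):
    """Traveling-wave density profile ``1 / (1 + exp((r - w) / (2 a)))``."""
    return 1.0 / (1.0 + np.exp((r - w) / (2.0 * a)))


def radial_profile(mask: np.ndarray, center=None, bin_width: float = 1.0,
                   rmax: float | None = None) -> RadialProfile:
    """Annular occupancy fractions from ``center`` out to the farthest
    occupied pixel (or to ``rmax`` when given, e.g. to include empty
    annuli beyond the front so a compact spheroid still shows a falling
    profile). ``center`` defaults to the mask frame centre (the lattice
    centre for simulated masks)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot profile an empty mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if center is None:
        center = ((mask.shape[0] - 1) / 2.0, (mask.shape[1] - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx < mask.shape[0] and 0 <= cy < mask.shape[1]):
        raise ValueError("center must lie inside the mask frame")
    xs = np.arange(mask.shape[0], dtype=float)[:, None] - cx
    ys = np.arange(mask.shape[1], dtype=float)[None, :] - cy
    dist = np.sqrt(xs ** 2 + ys ** 2)
    if rmax is None:
        rmax = dist[mask].max()
    n_bins = int(np.floor(rmax / bin_width)) + 1
    which = np.minimum((dist / bin_width).astype(int), n_bins)  # overflow bin
    total = np.bincount(which.ravel(), minlength=n_bins + 1)[:n_bins]
    occ = np.bincount(which[mask].ravel(), minlength=n_bins + 1)[:n_bins]
    centers = (np.arange(n_bins) + 0.5) * bin_width
    frac = np.divide(occ, total, out=np.zeros(n_bins), where=total > 0)
    return RadialProfile(bin_centers=centers, occupancy=frac,
                         center=(cx, cy), bin_width=bin_width)


def fit_travelling_wave(profile: RadialProfile) -> WaveFit:
    """Nonlinear least squares of the logistic front in (w, a), a > 0.

    The initial wave-front guess is the half-occupancy crossing; the
    initial diffusion guess is a quarter of the profile extent. A failed
    fit returns a flagged result (``converged=False``) instead of raising.
    """
    r = np.asarray(profile.bin_centers, dtype=float)
    c = np.asarray(profile.occupancy, dtype=float)
    if len(r) < 4:
        raise ValueError("need at least 4 radial bins to fit a front")
    if np.allclose(c, c[0]):
        raise ValueError("occupancy profile is constant; front undefined")
    below = np.nonzero(c < 0.5)[0]
    w0 = r[below[0]] if len(below) else r[-1]
    a0 = max(0.25 * (r[-1] - r[0]) / 4.0, 0.1)
    try:
        popt, _ = curve_fit(
            logistic_front, r, c, p0=(w0, a0),
            bounds=((0.0, 1e-6), (np.inf, np.inf)), maxfev=10000)
        w, a = popt
        rss = float(np.sum((logistic_front(r, w, a) - c) ** 2))
        return WaveFit(wave_front=float(w), diffusion=float(a), rss=rss)
    except RuntimeError:
        return WaveFit(wave_front=float(w0), diffusion=float(a0),
                       rss=float("nan"), converged=False)


def invaded_area(mask: np.ndarray) -> float:
    """Convex-hull area (pixels^2) of occupied pixel centres; fewer than
    three non-collinear pixels give area 0."""
    pts = np.argwhere(np.asarray(mask, dtype=bool)).astype(float)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear or degenerate
    return float(hull.volume)  # in 2D, .volume is the area


def cell_density(count: float, area: float) -> float:
    """Cells per pixel^2; requires a positive area."""
    if area <= 0:
        raise ValueError("area must be > 0 for a density")
    if count < 0:
        raise ValueError("count must be >= 0")
    return float(count) / float(area)


def summarize_mask(mask: np.ndarray, clone: str = "A", time: float = 0.0,
                   center=None, bin_width: float = 1.0,
                   count: int | None = None, pad_bins: int = 3
                   ) -> InvasionSummary:
    """All invasion statistics for one mask.

    ``count`` supplies the true 3D cell number when known (simulated
    snapshots); otherwise the number of set pixels is the 2D proxy.
    The radial profile is extended ``pad_bins`` empty annuli past the
    farthest occupied pixel so a compact (fully dense) spheroid still
    presents a falling front to the wave fit.
    """
    mask = np.asarray(mask, dtype=bool)
    n_pix = int(mask.sum())
    area = invaded_area(mask)
    n_for_density = n_pix if count is None else int(count)
    density = cell_density(n_for_density, area) if area > 0 else 0.0
    try:
        prof = radial_profile(mask, center, bin_width)
        if pad_bins:
            prof = radial_profile(
                mask, center, bin_width,
                rmax=prof.bin_centers[-1] + (pad_bins + 0.5) * bin_width)
        fit = fit_travelling_wave(prof)
        w, a, conv = fit.wave_front, fit.diffusion, fit.converged
    except ValueError:
        w, a, conv = float("nan"), float("nan"), False
    return InvasionSummary(clone=clone, time=time, area=area, density=density,
                           wave_front=w, diffusion=a, n_pixels=n_pix,
                           count=count, wave_converged=conv)


def summarize_snapshots(snapshots, clones=("A",), bin_width: float = 1.0,
                        use_true_counts: bool = True) -> pd.DataFrame:
    """Tidy table of :class:`InvasionSummary` rows for a snapshot stack."""
    rows = []
    for snap in snapshots:
        for clone in clones:
            mask = snap.masks[clone]
            if not mask.any():
                continue
            count = snap.counts[clone] if use_true_counts else None
            rows.append(summarize_mask(mask, clone=clone, time=snap.time,
                                       bin_width=bin_width, count=count))
    return pd.DataFrame([vars(r) for r in rows])


def normalized_ratio_curve(ratios, co_areas, mono_areas) -> RatioCurve:
    """Mono-culture-normalised area curve over seeding ratios.

    Parameters
    ----------
    ratios : sequence of float
        Seeding fractions of the focal clone, each in (0, 1).
    co_areas : mapping or sequence
        Per ratio, the focal clone's co-culture invaded areas
        (replicates are averaged).
    mono_areas : sequence of float
        Matched same-day mono-culture areas of the focal clone.

    The point (1, 1) — a clone normalised to itself — is appended by
    construction before the quadratic least-squares fit.
    """
    ratios = np.asarray(ratios, dtype=float)
    if isinstance(co_areas, dict):
        co_means = np.array([np.mean(co_areas[r]) for r in ratios])
    else:
        co_means = np.array([np.mean(a) for a in co_areas])
    mono_areas = np.asarray(mono_areas, dtype=float)
    if mono_areas.size == 0:
        raise ValueError("no mono-culture reference areas")
    mono_mean = float(np.mean(mono_areas))
    if not mono_mean > 0:
        raise ValueError("mono-culture area must be positive")
    norm = co_means / mono_mean
    x = np.append(ratios, 1.0)
    y = np.append(norm, 1.0)
    deg = min(2, len(np.unique(x)) - 1)
    coeffs = np.polyfit(x, y, deg)
    coeffs = np.concatenate([np.zeros(3 - len(coeffs)), coeffs])
    curve = RatioCurve(ratios=x, normalized_area=y, coeffs=coeffs, auc=0.0)
    return RatioCurve(ratios=x, normalized_area=y, coeffs=coeffs,
                      auc=auc_of_curve(curve))


def auc_of_curve(curve: RatioCurve) -> float:
    """Analytic integral of the fitted quadratic over ratio in [0, 1]."""
    c2, c1, c0 = curve.coeffs
    return float(c2 / 3.0 + c1 / 2.0 + c0)
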