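"""Rejection approximate Bayesian computation over simulation databanks.

The likelihood of the lattice automaton is intractable, so inference is
simulation-based: a databank of forward simulations is drawn from a
uniform prior, each reduced to named summary statistics, and parameter
vectors whose summaries fall within a weighted Euclidean distance
threshold of the observed summaries form the posterior sample. As the
threshold shrinks on an ever larger databank the accepted set converges
to the true parameter value; at practical sizes the posterior is
reported through a fitted truncated normal, a 95% highest-density
interval and the modal histogram interval.

Summaries are standardized by the databank standard deviation before
weighting so that weights compare information content rather than units
(areas in pixels^2 would otherwise dominate front coefficients in
pixels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class InsufficientAcceptanceError(RuntimeError):
    """Fewer accepted simulations than the configured minimum; enlarge the
    databank or relax the threshold."""


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: parameter name -> (lo, hi)."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r} needs lo < hi")

    @property
    def names(self) -> tuple:
        return tuple(self.bounds)

    def width(self, name: str) -> float:
        lo, hi = self.bounds[name]
        return hi - lo

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        return pd.DataFrame({
            name: rng.uniform(lo, hi, size=n)
            for name, (lo, hi) in self.bounds.items()})

    def contains(self, theta: dict) -> bool:
        return all(lo <= theta[name] <= hi
                   for name, (lo, hi) in self.bounds.items())


#: Default rate priors (d/day and x/day), validated by exploratory runs
#: to span the posteriors the assay produces.
DEFAULT_RATE_PRIOR = PriorSpec({"proliferation": (0.05, 2.0),
                                "motility": (0.0, 20.0)})
#: Default interaction-strength prior (x/day per unit proportion).
DEFAULT_INTERACTION_PRIOR = PriorSpec({"interaction": (-30.0, 30.0)})


@dataclass
class Databank:
    """Sampled parameters with their simulated summaries."""

    params: pd.DataFrame      # one column per parameter
    summaries: pd.DataFrame   # one column per summary statistic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.params) != len(self.summaries):
            raise ValueError("params and summaries must align row-wise")
        if self.summaries.isna().any().any():
            raise ValueError("databank contains missing summaries")

    def __len__(self) -> int:
        return len(self.params)

    @property
    def summary_names(self) -> tuple:
        return tuple(self.summaries.columns)

    def save(self, path) -> None:
        df = pd.concat(
            [self.params.add_prefix("param_"),
             self.summaries.add_prefix("stat_")], axis=1)
        df.to_csv(path, index=False)
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "Databank":
        df = pd.read_csv(path)
        params = df[[c for c in df if c.startswith("param_")]].rename(
            columns=lambda c: c[len("param_"):])
        stats_ = df[[c for c in df if c.startswith("stat_")]].rename(
            columns=lambda c: c[len("stat_"):])
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(params=params, summaries=stats_, meta=meta)


def build_databank(prior: PriorSpec, forward, n: int, seed: int,
                   meta: dict | None = None) -> Databank:
    """Draw ``n`` parameter vectors from ``prior`` and simulate each once.

    ``forward(theta: dict, seed: int) -> dict`` runs the simulator and
    returns named summaries; each row gets an independent child seed so
    the whole databank is reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = prior.sample(n, rng)
    row_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    rows = [forward(dict(thetas.iloc[i]), int(row_seeds[i])) for i in range(n)]
    summaries = pd.DataFrame(rows)
    bank_meta = {"prior": {k: list(v) for k, v in prior.bounds.items()},
                 "seed": int(seed), "n": int(n)}
    bank_meta.update(meta or {})
    thetas["_seed"] = row_seeds
    params = thetas.drop(columns="_seed")
    return Databank(params=params, summaries=summaries, meta=bank_meta)


@dataclass(frozen=True)
class WeightVector:
    """Non-negative summary-statistic weights on the unit simplex."""

    names: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.names):
            raise ValueError("one weight per summary name")
        if np.any(v < 0):
            raise ValueError("weights must be >= 0")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "values", v)

    @classmethod
    def equal(cls, names) -> "WeightVector":
        names = tuple(names)
        return cls(names=names, values=simplex_project(np.ones(len(names))))


def simplex_project(v: np.ndarray) -> np.ndarray:
    """Clip to non-negative and renormalise so the float sum is exactly 1."""
    v = np.clip(np.asarray(v, dtype=float), 0.0, None)
    s = v.sum()
    if s <= 0:
        v = np.ones_like(v)
        s = v.sum()
    v = v / s
    # nudge the largest entry so the floating-point sum is exact
    for _ in range(3):
        resid = 1.0 - v.sum()
        if resid == 0.0:
            break
        v[np.argmax(v)] += resid
    return v


def weighted_distance(obs, sim, weights: WeightVector) -> float:
    """Weighted Euclidean distance ``sqrt(sum_i w_i (obs_i - sim_i)^2)``."""
    o = _vectorize(obs, weights.names)
    s = _vectorize(sim, weights.names)
    return float(np.sqrt(np.sum(weights.values * (o - s) ** 2)))


def _vectorize(x, names) -> np.ndarray:
    if isinstance(x, dict):
        return np.array([x[n] for n in names], dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(names),):
        raise ValueError("summary vector length mismatch")
    return x


def databank_distances(databank: Databank, obs, weights: WeightVector | None,
                       standardize: bool = True) -> np.ndarray:
    """Weighted distances of every databank row from ``obs``."""
    names = databank.summary_names
    w = weights or WeightVector.equal(names)
    if tuple(w.names) != names:
        raise ValueError("weight names do not match databank summaries")
    S = databank.summaries.to_numpy(dtype=float)
    o = _vectorize(obs, names)
    if standardize:
        sd = S.std(axis=0)
        sd[sd == 0] = 1.0
        S = S / sd
        o = o / sd
    return np.sqrt(((S - o) ** 2 * w.values).sum(axis=1))


@dataclass(frozen=True)
class PosteriorSample:
    """Accepted parameter rows from rejection ABC."""

    theta: pd.DataFrame
    distances: np.ndarray
    epsilon: float
    accepted: np.ndarray       # boolean mask into the databank

    @property
    def n_accepted(self) -> int:
        return len(self.theta)


def abc_reject(databank: Databank, obs, weights: WeightVector | None = None,
               epsilon: float | None = None, quantile: float = 0.005,
               min_accept: int = 200, standardize: bool = True
               ) -> PosteriorSample:
    """Accept databank rows whose summaries lie within ``epsilon`` of ``obs``.

    With ``epsilon=None`` the threshold is the ``quantile`` of the
    databank's distances, floored so that at least ``min_accept`` rows
    (or the whole bank, if smaller) are accepted. An explicit absolute
    ``epsilon`` that accepts fewer than ``min_accept`` rows raises
    :class:`InsufficientAcceptanceError`.
    """
    if len(databank) == 0:
        raise ValueError("databank is empty")
    d = databank_distances(databank, obs, weights, standardize=standardize)
    if epsilon is None:
        floor = min(min_accept, len(d))
        eps = max(np.quantile(d, quantile), np.sort(d)[floor - 1])
        accept = d <= eps
    else:
        eps = float(epsilon)
        accept = d <= eps
        if accept.sum() < min(min_accept, len(d)):
            raise InsufficientAcceptanceError(
                f"{int(accept.sum())} accepted < minimum "
                f"{min(min_accept, len(d))}; enlarge the databank or raise "
                "the threshold")
    return PosteriorSample(theta=databank.params.loc[accept].reset_index(drop=True),
                           distances=d[accept], epsilon=float(eps),
                           accepted=accept)


@dataclass(frozen=True)
class TruncNormFit:
    """Normal distribution truncated to the prior bounds, fitted by ML."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.lower >= self.upper:
            raise ValueError("lower must be < upper")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    def pdf(self, x) -> np.ndarray:
        return self._frozen().pdf(x)


def fit_truncated_normal(samples, bounds) -> TruncNormFit:
    """Maximum-likelihood (mean, sd) of a normal truncated to ``bounds``."""
    x = np.asarray(samples, dtype=float)
    lo, hi = map(float, bounds)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("samples outside the truncation bounds")
    mu0 = float(np.mean(x))
    sd0 = float(np.std(x))
    sd0 = max(sd0, 1e-3 * (hi - lo), 1e-9)

    def nll(p):
        mu, log_sd = p
        sd = np.exp(log_sd)
        a, b = (lo - mu) / sd, (hi - mu) / sd
        ll = stats.truncnorm.logpdf(x, a, b, loc=mu, scale=sd)
        if not np.all(np.isfinite(ll)):
            return 1e300
        return -ll.sum()

    res = optimize.minimize(nll, x0=(mu0, np.log(sd0)), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 2000})
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    return TruncNormFit(mean=mu, sd=max(sd, 1e-9), lower=lo, upper=hi)


def hdi(samples, level: float = 0.95) -> tuple:
    """Shortest contiguous interval holding ``ceil(level * n)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for an HDI")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    k = int(np.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def modal_interval(samples, bin_width: float) -> tuple:
    """Bounds of the most populated histogram bin on a grid anchored at 0;
    ties go to the lowest bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    x = np.asarray(samples, dtype=float)
    if len(x) == 0:
        raise ValueError("no samples")
    bins = np.floor(x / bin_width).astype(int)
    keys, counts = np.unique(bins, return_counts=True)
    k = keys[np.argmax(counts)]  # unique() sorts, argmax takes first max
    return float(k * bin_width), float((k + 1) * bin_width)
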