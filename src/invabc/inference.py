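"""Two-stage inference of invasion phenotypes and subclonal interactions.

Stage one (:class:`MonocultureModel`) recovers a clone's proliferation
and motility rates from mono-culture mask time series by rejection ABC
against a databank of mono-culture simulations, summarised per day by
the wave-front and diffusion coefficients, invaded area and density. The
accepted sample is described by truncated-normal fits so the full
posterior uncertainty can be propagated downstream.

Stage two (:class:`CocultureModel`) infers the interaction strength a
focal clone receives from its partner in co-culture. Databank rows draw
both clones' rates from the stage-one truncated normals and the
interaction strength from its prior, simulate the co-culture design
across seeding ratios, and are summarised by the AUC of the
mono-culture-normalised area-versus-ratio curve; ABC on the observed AUC
yields the interaction posterior, its 95% HDI and modal interval, and a
sign call (an HDI overlapping zero is insufficient evidence for any
interaction).

Both models follow the Model/Results convention: construct from data,
call ``fit()``, read estimates and diagnostics off the Results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abc import (DEFAULT_INTERACTION_PRIOR, DEFAULT_RATE_PRIOR, Databank,
                  PriorSpec, TruncNormFit, WeightVector, abc_reject,
                  build_databank, fit_truncated_normal, hdi, modal_interval)
from .config import CLONES, InteractionMatrix, PhenotypeParams, SimulationConfig
from .ga import ga_optimize_weights
from .simulate import run_simulation
from .summaries import invaded_area, normalized_ratio_curve, summarize_mask

_STATS = ("wave_front", "diffusion", "area", "density")


def _summary_vector(masks_by_day: dict, clone: str = "A") -> dict:
    """Per-day invasion statistics flattened into one named vector.

    Day 0 is the seeding state, identical in distribution across all
    parameters, and is excluded. Empty masks and failed wave fits fall
    back to zeros (an extinct or degenerate realisation carries the
    information that it invaded nothing).
    """
    out = {}
    for day in sorted(masks_by_day):
        if day == 0:
            continue
        mask = np.asarray(masks_by_day[day], dtype=bool)
        if mask.any():
            s = summarize_mask(mask, clone=clone, time=day)
            vals = {"wave_front": s.wave_front, "diffusion": s.diffusion,
                    "area": s.area, "density": s.density}
            for k, v in vals.items():
                out[f"{k}_d{day:g}"] = 0.0 if not np.isfinite(v) else float(v)
        else:
            for k in _STATS:
                out[f"{k}_d{day:g}"] = 0.0
    return out


def _mono_masks(snapshots, clone: str) -> dict:
    return {snap.time: snap.masks[clone] for snap in snapshots}


class MonocultureModel:
    """ABC model for the phenotype of a pure clonal population.

    Parameters
    ----------
    observed : dict or sequence of dict
        ``{day: mask}`` for one replicate, or several such dicts whose
        summary vectors are averaged (parallel replicates).
    prior : PriorSpec
        Uniform bounds on ``proliferation`` (d/day) and ``motility``
        (x/day); defaults to :data:`~invabc.abc.DEFAULT_RATE_PRIOR`.
    lattice_edge, seed_radius, aggression, death_fraction :
        Simulator settings for the forward model; the lattice should
        match the frame of the observed masks.
    """

    def __init__(self, observed, prior: PriorSpec = DEFAULT_RATE_PRIOR,
                 lattice_edge: int = 120, seed_radius: int = 5,
                 aggression: int = 1, death_fraction: float = 0.1):
        if isinstance(observed, dict):
            observed = [observed]
        vectors = [_summary_vector(rep) for rep in observed]
        self.observed = pd.DataFrame(vectors).mean(axis=0).to_dict()
        days = sorted({float(d) for rep in observed for d in rep if d != 0})
        if not days:
            raise ValueError("need at least one observation day after day 0")
        self.days = days
        self.prior = prior
        self.lattice_edge = lattice_edge
        self.seed_radius = seed_radius
        self.aggression = aggression
        self.death_fraction = death_fraction

    @classmethod
    def from_dataset(cls, dataset, clone: str, **kwargs):
        """Build from a :class:`~invabc.synth.SyntheticDataset` (or any
        object with the same manifest/masks layout), pooling replicates
        of the clone's mono-culture condition."""
        condition = f"mono_{clone}"
        sub = dataset.manifest[(dataset.manifest.condition == condition)
                               & (dataset.manifest.clone == clone)]
        reps = []
        for _, group in sub.groupby("replicate"):
            reps.append({float(r.day): dataset.masks[r.path]
                         for r in group.itertuples()})
        kwargs.setdefault("lattice_edge", dataset.truth.lattice_edge)
        kwargs.setdefault("seed_radius", dataset.truth.seed_radius)
        return cls(reps, **kwargs)

    def _config(self, seed: int) -> SimulationConfig:
        end = max(self.days)
        interval = float(np.gcd.reduce(
            [max(int(round(d * 24)), 1) for d in self.days])) / 24.0
        return SimulationConfig(
            lattice_edge=self.lattice_edge, seed_radius=self.seed_radius,
            seeding_ratio=1.0, end_time=end, snapshot_interval=interval,
            rng_seed=seed)

    def simulate_summaries(self, theta: dict, seed: int) -> dict:
        """Forward model: one mono-culture simulation reduced to summaries."""
        params = PhenotypeParams(
            proliferation_rate=float(theta["proliferation"]),
            motility_rate=float(theta["motility"]),
            aggression=self.aggression,
            death_fraction=self.death_fraction)
        snaps = run_simulation(self._config(seed), params)
        masks = {s.time: s.masks["A"] for s in snaps if s.time in self.days}
        return _summary_vector(masks)

    def build_databank(self, n: int, seed: int) -> Databank:
        return build_databank(self.prior, self.simulate_summaries, n, seed,
                              meta={"model": "monoculture",
                                    "days": list(self.days),
                                    "lattice_edge": self.lattice_edge})

    def optimize_weights(self, databank: Databank, n_validation: int = 5,
                         seed: int = 0, **ga_kwargs) -> WeightVector:
        """GA-optimised summary weights from self-generated validation
        pairs (known truths drawn from the prior)."""
        rng = np.random.default_rng(seed)
        truths = self.prior.sample(n_validation, rng)
        validation = []
        for i in range(n_validation):
            theta = dict(truths.iloc[i])
            obs = self.simulate_summaries(
                theta, int(rng.integers(2 ** 31 - 1)))
            validation.append((theta, obs))
        return ga_optimize_weights(databank, validation, prior=self.prior,
                                   seed=int(rng.integers(2 ** 31 - 1)),
                                   **ga_kwargs)

    def fit(self, databank: Databank | None = None, n_sims: int = 1000,
            weights: WeightVector | None = None, epsilon: float | None = None,
            quantile: float = 0.005, min_accept: int = 200,
            seed: int = 0) -> "MonocultureResults":
        """Run rejection ABC and package the posterior."""
        if databank is None:
            databank = self.build_databank(n_sims, seed)
        posterior = abc_reject(databank, self.observed, weights=weights,
                               epsilon=epsilon, quantile=quantile,
                               min_accept=min_accept)
        fits, hdis, modals = {}, {}, {}
        for name in self.prior.names:
            samples = posterior.theta[name].to_numpy()
            fits[name] = fit_truncated_normal(samples, self.prior.bounds[name])
            hdis[name] = hdi(samples)
            modals[name] = modal_interval(samples, bin_width=0.5)
        return MonocultureResults(model=self, databank=databank,
                                  posterior=posterior, fits=fits,
                                  hdi_=hdis, modal_=modals, weights=weights)


@dataclass
class MonocultureResults:
    """Posterior phenotype of one clone, with parametric fits."""

    model: MonocultureModel
    databank: Databank
    posterior: object
    fits: dict              # param -> TruncNormFit
    hdi_: dict              # param -> (lo, hi), 95%
    modal_: dict            # param -> modal histogram bin
    weights: WeightVector | None = None

    @property
    def params_(self) -> dict:
        """Posterior medians."""
        return {k: float(np.median(self.posterior.theta[k]))
                for k in self.fits}

    def sample_phenotype(self, rng: np.random.Generator,
                         aggression: int | None = None) -> PhenotypeParams:
        """Draw one phenotype from the fitted truncated normals (the
        uncertainty-propagation path into co-culture simulations)."""
        return PhenotypeParams(
            proliferation_rate=float(self.fits["proliferation"].rvs(1, rng)[0]),
            motility_rate=float(self.fits["motility"].rvs(1, rng)[0]),
            aggression=self.model.aggression if aggression is None else aggression,
            death_fraction=self.model.death_fraction)

    def summary(self) -> str:
        lines = ["Mono-culture phenotype posterior",
                 "=" * 56,
                 f"{'parameter':<16}{'median':>8}{'tn mean':>9}{'tn sd':>8}"
                 f"{'95% HDI':>15}",
                 "-" * 56]
        med = self.params_
        for name, fit in self.fits.items():
            lo, hi = self.hdi_[name]
            lines.append(f"{name:<16}{med[name]:>8.3f}{fit.mean:>9.3f}"
                         f"{fit.sd:>8.3f}{'':>2}[{lo:6.3f},{hi:6.3f}]")
        lines.append("-" * 56)
        lines.append(f"accepted {self.posterior.n_accepted} of "
                     f"{len(self.databank)} simulations "
                     f"(epsilon={self.posterior.epsilon:.4g})")
        return "\n".join(lines)

    def plot_posterior(self, param: str, ax=None, bins: int = 30):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        samples = self.posterior.theta[param]
        ax.hist(samples, bins=bins, density=True, alpha=0.6,
                label="ABC posterior")
        lo, hi = self.model.prior.bounds[param]
        xs = np.linspace(lo, hi, 200)
        ax.plot(xs, self.fits[param].pdf(xs), "k--", label="truncated normal")
        ax.axhline(1.0 / (hi - lo), color="grey", lw=1, label="prior")
        ax.set_xlabel(param)
        ax.set_ylabel("density")
        ax.legend()
        return ax


class CocultureModel:
    """ABC model for the interaction strength received by a focal clone.

    Parameters
    ----------
    observed_auc : float
        AUC of the observed mono-culture-normalised area curve for the
        focal clone at the analysis day (see :func:`observed_ratio_curve`).
    mono_results : mapping
        ``{"A": MonocultureResults, "B": MonocultureResults}`` from stage
        one (anything with ``sample_phenotype`` works).
    focal : str
        The clone whose received interaction is inferred; the reverse
        interaction is fixed at zero (one-clone-at-a-time inference).
    ratios : sequence
        Focal-clone seeding fractions of the co-culture design.
    day : float
        Analysis day (the last common imaging day by default upstream).
    """

    def __init__(self, observed_auc: float, mono_results, focal: str = "A",
                 ratios=(0.25, 0.5, 0.75), day: float = 3.0,
                 prior: PriorSpec = DEFAULT_INTERACTION_PRIOR,
                 lattice_edge: int = 120, seed_radius: int = 5):
        if focal not in CLONES:
            raise ValueError(f"focal must be one of {CLONES}")
        self.observed = {"auc": float(observed_auc)}
        self.mono_results = mono_results
        self.focal = focal
        self.partner = "B" if focal == "A" else "A"
        self.ratios = tuple(float(r) for r in ratios)
        self.day = float(day)
        self.prior = prior
        self.lattice_edge = lattice_edge
        self.seed_radius = seed_radius

    def _config(self, ratio_a: float, seed: int) -> SimulationConfig:
        return SimulationConfig(
            lattice_edge=self.lattice_edge, seed_radius=self.seed_radius,
            seeding_ratio=ratio_a, end_time=self.day,
            snapshot_interval=self.day, rng_seed=seed)

    def simulate_summaries(self, theta: dict, seed: int) -> dict:
        """Forward model: a full ratio-curve experiment at interaction
        strength ``theta['interaction']``, with both clones' rates drawn
        from the stage-one posteriors (uncertainty propagation)."""
        rng = np.random.default_rng(seed)
        pheno = {c: self.mono_results[c].sample_phenotype(rng) for c in CLONES}
        params = (pheno["A"], pheno["B"])
        strength = float(theta["interaction"])
        inter = (InteractionMatrix.received(by_a=strength) if self.focal == "A"
                 else InteractionMatrix.received(by_b=strength))
        focal_areas = {}
        for r in self.ratios:
            ratio_a = r if self.focal == "A" else 1.0 - r
            cfg = self._config(ratio_a, int(rng.integers(2 ** 31 - 1)))
            snaps = run_simulation(cfg, params, inter)
            focal_areas[r] = invaded_area(snaps[-1].masks[self.focal])
        mono_cfg = self._config(1.0 if self.focal == "A" else 0.0,
                                int(rng.integers(2 ** 31 - 1)))
        mono_snaps = run_simulation(mono_cfg, params)
        mono_area = invaded_area(mono_snaps[-1].masks[self.focal])
        if mono_area <= 0:
            return {"auc": 0.0}
        curve = normalized_ratio_curve(self.ratios, focal_areas, [mono_area])
        return {"auc": curve.auc}

    def build_databank(self, n: int, seed: int) -> Databank:
        return build_databank(self.prior, self.simulate_summaries, n, seed,
                              meta={"model": "coculture", "focal": self.focal,
                                    "day": self.day,
                                    "ratios": list(self.ratios)})

    def fit(self, databank: Databank | None = None, n_sims: int = 300,
            epsilon: float | None = None, quantile: float = 0.005,
            min_accept: int = 50, seed: int = 0) -> "CocultureResults":
        if databank is None:
            databank = self.build_databank(n_sims, seed)
        posterior = abc_reject(databank, self.observed, epsilon=epsilon,
                               quantile=quantile, min_accept=min_accept)
        samples = posterior.theta["interaction"].to_numpy()
        interval = hdi(samples)
        return CocultureResults(
            model=self, databank=databank, posterior=posterior,
            hdi_=interval, modal_=modal_interval(samples, bin_width=1.0),
            observed_auc=self.observed["auc"])


def interaction_sign(hdi_interval: tuple) -> str:
    """'positive' / 'negative' when the 95% HDI excludes 0, else 'neutral'."""
    lo, hi = hdi_interval
    if lo > 0:
        return "positive"
    if hi < 0:
        return "negative"
    return "neutral"


@dataclass(frozen=True)
class InteractionCall:
    """Pairwise classification from the two received-interaction signs."""

    sign_a: str    # interaction received by clone A
    sign_b: str    # interaction received by clone B
    label: str


_PAIR_LABELS = {
    frozenset(["positive"]): "mutualism",
    frozenset(["positive", "neutral"]): "commensalism",
    frozenset(["positive", "negative"]): "exploitation",
    frozenset(["negative"]): "competition",
    frozenset(["neutral"]): "neutral",
    frozenset(["negative", "neutral"]): "amensalism",
}


def classify_interaction(hdi_a: tuple, hdi_b: tuple) -> InteractionCall:
    """Ecological label for a clone pair from their received-interaction
    HDIs: (+,+) mutualism, (+,0) commensalism, (+,-) exploitation,
    (-,-) competition, (0,0) neutral, (0,-) amensalism."""
    sign_a = interaction_sign(hdi_a)
    sign_b = interaction_sign(hdi_b)
    label = _PAIR_LABELS[frozenset([sign_a, sign_b])]
    return InteractionCall(sign_a=sign_a, sign_b=sign_b, label=label)


def maximal_effect(motility_fit: TruncNormFit, interaction_samples,
                   n: int = 10000, rng: np.random.Generator | None = None,
                   seed: int | None = None) -> dict:
    """Maximal interaction effect on motility: m versus max(0, m + I).

    Compares the stage-one motility posterior against the motility each
    cell would have if the partner clone filled the whole neighbourhood
    (proportion 1, the upper bound of the interaction term). Returns the
    two sample arrays and the fraction of shifted draws exceeding the
    baseline median.
    """
    rng = rng or np.random.default_rng(seed)
    interaction_samples = np.asarray(interaction_samples, dtype=float)
    m = motility_fit.rvs(n, rng)
    i = rng.choice(interaction_samples, size=n, replace=True)
    shifted = np.maximum(0.0, m + i)
    med = float(np.median(m))
    return {"motility": m, "motility_plus_interaction": shifted,
            "fraction_above_baseline_median": float(np.mean(shifted > med))}


@dataclass
class CocultureResults:
    """Interaction-strength posterior received by the focal clone."""

    model: CocultureModel
    databank: Databank
    posterior: object
    hdi_: tuple
    modal_: tuple
    observed_auc: float

    @property
    def interaction_samples(self) -> np.ndarray:
        return self.posterior.theta["interaction"].to_numpy()

    @property
    def sign(self) -> str:
        return interaction_sign(self.hdi_)

    @property
    def interaction_(self) -> float:
        return float(np.median(self.interaction_samples))

    def maximal_effect(self, n: int = 10000, seed: int | None = None) -> dict:
        fit = self.model.mono_results[self.model.focal].fits["motility"]
        return maximal_effect(fit, self.interaction_samples, n=n, seed=seed)

    def summary(self) -> str:
        lo, hi = self.hdi_
        mlo, mhi = self.modal_
        lines = [
            f"Interaction received by clone {self.model.focal} "
            f"(from clone {self.model.partner})",
            "=" * 56,
            f"observed AUC            {self.observed_auc:10.4f}",
            f"posterior median I      {self.interaction_:10.3f} x/day",
            f"95% HDI                 [{lo:8.3f}, {hi:8.3f}]",
            f"modal interval          [{mlo:8.3f}, {mhi:8.3f}]",
            f"call                    {self.sign}",
            "-" * 56,
            f"accepted {self.posterior.n_accepted} of {len(self.databank)} "
            f"simulations (epsilon={self.posterior.epsilon:.4g})",
        ]
        return "\n".join(lines)

    def plot_posterior(self, ax=None, bins: int = 30):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.interaction_samples, bins=bins, density=True, alpha=0.6)
        ax.axvline(0.0, color="k", lw=1)
        for v in self.hdi_:
            ax.axvline(v, color="C1", ls="--", lw=1)
        ax.set_xlabel("interaction strength (x/day)")
        ax.set_ylabel("posterior density")
        return ax


def observed_ratio_curve(dataset, focal: str, day: float):
    """Ratio curve and AUC for a clone in a synthetic (or equivalently
    structured) dataset at the analysis day: per-ratio mean focal area in
    co-culture divided by the mean mono-culture area."""
    man = dataset.manifest
    mono = man[(man.condition == f"mono_{focal}") & (man.clone == focal)
               & (man.day == day)]
    mono_areas = [invaded_area(dataset.masks[p]) for p in mono.path]
    co = man[man.condition.str.startswith("co_") & (man.clone == focal)
             & (man.day == day)]
    ratios, co_areas = [], {}
    for ratio_a, group in co.groupby("ratio"):
        focal_ratio = float(ratio_a) if focal == "A" else 1.0 - float(ratio_a)
        areas = [invaded_area(dataset.masks[p]) for p in group.path]
        ratios.append(focal_ratio)
        co_areas[focal_ratio] = areas
    order = np.argsort(ratios)
    ratios = [ratios[i] for i in order]
    return normalized_ratio_curve(ratios, co_areas, mono_areas)
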