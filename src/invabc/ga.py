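"""Genetic-algorithm optimisation of ABC summary-statistic weights.

The weighted Euclidean distance needs per-summary weights on the unit
simplex. The optimal weights are those that minimise the squared error
between known ground-truth parameters and the parameters recovered from
the posterior when ABC is run on validation data simulated at that
ground truth. Errors are normalised by the prior widths so parameters on
different scales contribute comparably, and the posterior point estimate
is the per-parameter median of the accepted sample.

The optimiser is a plain generational GA on the simplex: tournament
selection, blend crossover, Gaussian mutation followed by projection
back onto the simplex, elitism, and several independent restarts whose
best results are compared to guard against local optima. Equal weights
are always included as a candidate, so optimisation can never end up
worse than the unweighted distance on the validation set.
"""

from __future__ import annotations

import numpy as np

from .abc import Databank, PriorSpec, WeightVector, simplex_project


def _error_matrix(databank: Databank, obs_list, standardize=True):
    """Standardized squared-difference matrices, one per validation obs."""
    S = databank.summaries.to_numpy(dtype=float)
    if standardize:
        sd = S.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        sd = np.ones(S.shape[1])
    names = databank.summary_names
    mats = []
    for obs in obs_list:
        o = np.array([obs[n] for n in names], dtype=float)
        mats.append(((S - o) / sd) ** 2)
    return mats


def recovery_error(weights: np.ndarray, sqdiff_mats, theta_mat,
                   truths, widths, n_keep: int) -> float:
    """Validation loss of one weight vector.

    For each validation pair the ``n_keep`` nearest databank rows under
    the candidate weights are accepted and the per-parameter medians
    compared to the ground truth, normalised by prior width.
    """
    err = 0.0
    for mat, truth in zip(sqdiff_mats, truths):
        d = mat @ weights
        idx = np.argpartition(d, n_keep - 1)[:n_keep]
        est = np.median(theta_mat[idx], axis=0)
        err += float((((est - truth) / widths) ** 2).sum())
    return err / len(sqdiff_mats)


def ga_optimize_weights(databank: Databank, validation, prior: PriorSpec | None = None,
                        n_pop: int = 50, n_gen: int = 100, n_restarts: int = 5,
                        mutation_sd: float = 0.1, tournament: int = 3,
                        accept_fraction: float = 0.05, min_accept: int = 20,
                        seed: int | None = None, standardize: bool = True
                        ) -> WeightVector:
    """Optimise summary weights against validation data with known truth.

    Parameters
    ----------
    databank : Databank
    validation : sequence of (theta_true, obs)
        ``theta_true`` and ``obs`` are dicts keyed by parameter and
        summary names respectively; the observations come from
        simulations at the known parameters.
    prior : PriorSpec, optional
        Used for error normalisation; defaults to the bounds recorded in
        ``databank.meta``.
    accept_fraction, min_accept :
        The ABC acceptance used inside the fitness (fraction of the
        databank, floored at ``min_accept`` rows).

    Returns weights on the simplex (non-negative, summing to 1 exactly).
    A single summary statistic returns weight 1 trivially.
    """
    names = databank.summary_names
    if len(names) == 0:
        raise ValueError("databank has no summaries")
    if len(names) == 1:
        return WeightVector(names=names, values=np.array([1.0]))
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    if prior is None:
        prior = PriorSpec({k: tuple(v)
                           for k, v in databank.meta["prior"].items()})
    pnames = tuple(databank.params.columns)
    widths = np.array([prior.width(p) for p in pnames])
    theta_mat = databank.params.to_numpy(dtype=float)
    truths = [np.array([t[p] for p in pnames], dtype=float)
              for t, _ in validation]
    mats = _error_matrix(databank, [obs for _, obs in validation],
                         standardize=standardize)
    n_keep = max(min(min_accept, len(databank)),
                 int(accept_fraction * len(databank)))

    def fitness(w):
        return recovery_error(w, mats, theta_mat, truths, widths, n_keep)

    k = len(names)
    rng = np.random.default_rng(seed)
    best_w = simplex_project(np.ones(k))   # equal weights as the fallback
    best_f = fitness(best_w)
    for _ in range(max(1, n_restarts)):
        pop = rng.dirichlet(np.ones(k), size=n_pop)
        pop[0] = simplex_project(np.ones(k))
        for j in range(min(k, n_pop - 1)):
            v = np.full(k, 1e-3)
            v[j] = 1.0
            pop[j + 1] = simplex_project(v)
        fit = np.array([fitness(w) for w in pop])
        for _gen in range(n_gen):
            order = np.argsort(fit)
            new_pop = [pop[order[0]].copy()]   # elitism
            while len(new_pop) < n_pop:
                cands = rng.integers(0, n_pop, size=tournament)
                p1 = pop[cands[np.argmin(fit[cands])]]
                cands = rng.integers(0, n_pop, size=tournament)
                p2 = pop[cands[np.argmin(fit[cands])]]
                u = rng.random()
                child = u * p1 + (1 - u) * p2
                child = child + rng.normal(0.0, mutation_sd, size=k)
                new_pop.append(simplex_project(child))
            pop = np.array(new_pop)
            fit = np.array([fitness(w) for w in pop])
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_f = float(fit[i])
            best_w = pop[i].copy()
    return WeightVector(names=names, values=simplex_project(best_w))
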