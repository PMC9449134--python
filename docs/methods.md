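# Methods

This note documents the model, the numerical choices, and the validation
scale of `invabc`, in the spirit of a simulator/inference package's model
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The cellular automaton

Space is an L³ lattice (default L = 120, configurable); each site is empty
or holds exactly one cell of clone A or B. One lattice unit is one cell
width and one mask pixel; no micron calibration is applied because the
inference is unit-relative. Three event types act on the 3D Moore
neighbourhood of length 1 (the 26 sites within Chebyshev distance 1):

- **Division** at the clone's proliferation rate *p* (divisions/day). The
  daughter occupies a uniformly chosen empty Moore neighbour. If the shell
  is full and the clone's *proliferation aggression* distance exceeds 1,
  the nearest empty site within that Chebyshev distance along one of the 26
  lattice rays is located (ties between rays broken uniformly at random)
  and the contiguous run of cells on the ray is pushed outward by one site;
  clone labels travel with the pushed cells. Otherwise the division is a
  null event. The default aggression is 1, i.e. no pushing beyond the
  Moore shell itself.
- **Movement** at the clone's effective motility (cell widths/day), one
  step to a uniformly chosen empty Moore neighbour; a fully blocked cell
  is a null event. Every executed movement counts as one step regardless
  of direction (diagonal steps are not weighted by length): motility is
  defined as events per day, not path length.
- **Death** at a fixed fraction (default 10%) of the proliferation rate.
  Death is never an independent parameter; the fraction guarantees
  turnover with positive net growth. Dead cells vacate their site
  immediately.

**Interactions.** The effective motility of clone *i* is
`M_i = max(0, m_i + r_j · I_ij)`, where `r_j` is the proportion of clone
*j* among living cells and `I_ij` (x/day per unit proportion) the
interaction received by *i* from *j*. Proportions are computed globally by
default — long-range, chemokine-like signalling — and recomputed from O(1)
counters at every event. A finite Moore-neighbourhood mode is available
through the reference propensity path (`enumerate_propensities`,
`advance` with a finite `neighborhood_size`), which recomputes per-cell
motility each event at O(N) cost; it is intended for small validation
problems, not production runs. Negative effective motility is clamped to
zero: rates cannot be negative, and the prior admits interaction strengths
(down to −30) that would otherwise make the total propensity ill-defined.

**Gillespie sampling.** The direct method: waiting times are exponential
in the total propensity, the (clone, event) pair is chosen proportionally
to its aggregate rate, and the cell uniformly within the clone. Because
per-cell rates within a clone are identical under global interactions,
event selection is O(1) per event; the inner loop is a numba-jitted kernel
sharing its primitives with the unit-level operations. A crowding-blocked
move or division consumes its draw (time advances, state unchanged); this
keeps propensities exact without per-cell neighbourhood-dependent rates.
Consequently the ratio of *drawn* death events to *drawn* division events
is 10% in expectation by construction, while the ratio of deaths to
*placed* daughters sits slightly higher in crowded spheroids; the
acceptance script reports the drawn-event ratio, which is the quantity the
10% rule fixes.

**Boundaries and seeding.** Sites outside the lattice are permanently
occupied (no flux). Any cell reaching the outermost site layer sets a flag
and the run logs a warning — assay spheroids never reach the image frame,
so contact means the lattice was undersized for the parameter draw; such
draws remain in databanks (the forward model is applied uniformly).
Seeding fills every site within `seed_radius` (default 5, 515 sites) of
the lattice centre, assigning clone A with probability equal to the
seeding ratio i.i.d. per site (a well-mixed spheroid, not spatially
sorted). A seed ball touching the boundary is a configuration error.

**Randomness.** One seeded generator per simulation; the kernel RNG is
seeded at simulation start, so identical configurations give bit-identical
snapshot stacks. Synthetic-experiment conditions derive per-condition
seeds by CRC-hashing (master seed, condition, replicate), making datasets
reproducible while keeping conditions independent.

## Summary statistics

- **Radial profile**: occupancy fraction in 1-pixel annuli around the
  spheroid centre (the lattice/frame centre for simulations; for
  experimental stacks a day-0 centroid can be passed explicitly). The
  occupancy fraction, bounded by 1, plays the role of the cellular
  density `C(r)`.
- **Traveling-wave fit**: nonlinear least squares of
  `C(r) = 1/(1 + exp((r − w)/2a))` with `a > 0`, initialised at the
  half-occupancy crossing. `w` (pixels) measures the dense-core extent and
  `a` (density/distance) the front steepness. These are descriptive
  coefficients of a static configuration, not reaction-diffusion PDE
  constants, and the package deliberately does no PDE estimation. When a
  mask is fully dense out to its last pixel the raw profile is constant
  (occupancy ≡ 1), so the pipeline extends the profile three empty annuli
  past the farthest occupied pixel — legitimately part of the image — to
  expose the falling front. Non-convergent fits are returned flagged, and
  flagged or empty-mask summaries enter inference as zeros: an extinct or
  degenerate realisation carries the information that nothing invaded.
  The symbol *m* is conventional for both motility and the wave front;
  the code names the wave front `w` throughout to avoid the clash.
- **Invaded area**: convex-hull area of occupied pixel centres (scipy
  Qhull); fewer than three non-collinear pixels give 0. Mask pixel count
  is retained as `n_pixels` for the optional alternative statistic.
- **Cell density**: count / area. From masks the set-pixel count is the
  2D proxy; simulated snapshots can use the true 3D count (the collapse
  merges z-columns, so the true count is never smaller).
- **Ratio curve and AUC**: per seeding ratio, mean focal-clone co-culture
  area divided by the mean same-day mono-culture area; the point (1, 1) —
  a clone normalised to itself — is appended by construction; an ordinary
  quadratic least-squares fit is integrated analytically over [0, 1].
  "Same-day, same-experiment" normalisation mirrors the parallel-culture
  design that cancels batch noise.

## ABC engine

Databanks draw parameters from independent uniform priors (defaults:
proliferation 0.05–2 d/day, motility 0–20 x/day, interaction −30 to
+30 x/day, all configurable and validated by exploratory runs to span the
posteriors encountered). Summaries are standardized by the databank
standard deviation before the weighted Euclidean distance
`sqrt(Σ w_i (obs_i − sim_i)²)`, `Σ w_i = 1`, so weights compare
information content rather than units. The acceptance threshold defaults
to the 0.5% distance quantile with a floor of a minimum accepted count
(200 by default, scaled down with databank size); an explicit absolute
threshold that accepts fewer rows raises an error rather than silently
returning a thin posterior.

Posteriors are reported three ways: a maximum-likelihood truncated-normal
fit bounded by the prior (Nelder–Mead on the exact truncated likelihood),
used to propagate stage-one uncertainty into stage-two simulation; the
95% highest-density interval, computed as the shortest contiguous window
of sorted samples; and the modal histogram interval on a grid anchored at
zero (bin width 0.5 for rates, 1.0 for interaction strengths, matching
the granularity at which such intervals are conventionally reported),
ties resolved to the lowest bin.

**Weight optimisation.** The genetic algorithm (population 50, 100
generations, tournament selection, blend crossover, Gaussian mutation
projected back onto the simplex, elitism, 5 restarts by default) minimises
the prior-width-normalised squared error between known validation truths
and the median of the accepted sample. Equal weights are always evaluated
as a candidate, so optimisation can never return weights worse than the
unweighted distance on the validation set. The fitness point estimate is
the accepted-sample median (robust to the skewed, truncated posteriors
rejection ABC produces). The GA itself is implemented in-package; its test
oracle is a dense simplex grid search.

## Two-stage inference

Stage one compares observed per-day summary vectors (wave front,
diffusion, area, density for each imaging day after day 0; replicate
vectors averaged) against a mono-culture databank and fits truncated
normals to the accepted (p, m). Stage two builds a co-culture databank in
which each row draws both clones' rates from those fits and the focal
clone's received interaction from its prior, simulates the full ratio
design plus a mono-culture reference with the same drawn rates, and is
summarised by the ratio-curve AUC alone (extra per-ratio summaries can be
added by the caller; AUC is the default and sufficient summary for the
strength of the received interaction). Inference is one clone at a time:
the reverse interaction is fixed at zero while the focal clone's is
inferred, mirroring per-clone posteriors; a joint 2D treatment would
square the databank cost for little gain at assay-typical signal.

The analysis day defaults to the last common imaging day of the design
(assays here are analysed at day 2 or 3). A clone's call is *positive* or
*negative* only when its 95% HDI excludes zero; an HDI overlapping zero is
insufficient evidence for any interaction (no point-null Bayes factors).
Pair labels follow the ecological table — (+,+) mutualism, (+,0)
commensalism, (+,−) exploitation, (−,−) competition, (0,−) amensalism,
(0,0) neutral. The *maximal effect* diagnostic compares the stage-one
motility posterior m against max(0, m + I), the motility a cell would have
were the partner the entire neighbourhood (proportion 1), reporting both
sample sets and the fraction of shifted draws above the baseline median.

## Synthetic experiments

`SyntheticGroundTruth` defaults encode the assay design: co-cultures at
25:75, 50:50 and 75:25 seeding ratios alongside both mono-cultures, six
replicates per condition, imaged every 24 h from day 0 to day 3, masks
noiseless. Optional segmentation-like noise drops occupied pixels with a
false-negative rate and sets empty pixels *within the mask's convex hull*
with a false-positive rate — segmentation errors cluster near the
spheroid, not in empty matrix. Real segmentation error rates are not
quantified; the rates used in robustness tests (fnr 0.05, fpr 0.01) are
placeholders for sensitivity analysis only. What the generator does not
emulate: fluorescence rendering, uneven illumination, registration drift,
labelling inefficiency, spatial engulfment artefacts in segmentation, or
biological replicate-to-replicate phenotype drift — so passing recovery
tests demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to every failure mode of real
imaging.

## Validation scale

The test suite validates at sizes chosen for a single-CPU run, as the
package's own validation budget: mono-culture recovery coverage on a 3×3
grid of (p, m) with two trials per cell against a 600-row databank on a
48³ lattice over 2 days; interaction recovery at strengths
{0, ±5, ±10} with twelve trials against a 250-row databank of full ratio
experiments on a 40³ lattice; monotonicity and AUC-linearity sweeps with
10–20 replicates per level. The acceptance script runs twenty 80³
replicates over 5 simulated days (roughly 9 × 10⁵ death/division draws
pooled). Larger lattices and databanks only tighten posteriors; all
coverage thresholds (≥90% truth-in-HDI, ≤10% false exclusion of zero) are
properties of the method, not of the scale.

## Known limitations

- Death is tied to proliferation by a fixed fraction; an independently
  measured death rate would slot in via `death_fraction` but cannot be
  inferred from masks alone.
- No quiescence / go-or-grow phenotype switching, nutrient fields, or
  off-lattice mechanics; the interaction acts on motility only.
- Spatial engulfment can mask interactions in real co-cultures (a clone
  surrounded by the other cannot invade regardless of signalling); the
  simulator reproduces the competition side of this but the inference does
  not correct for it.
- Global-proportion interactions are a deliberate simplification; the
  finite-neighbourhood mode exists but is O(N) per event and off by
  default.
- Blocked events consuming SSA draws makes the drawn-event clock exact at
  the cost of a realized-division rate that is density-dependent; both
  tallies are reported by the state's event counters.
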