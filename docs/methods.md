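# Methods

## Rate inference

Tumor burden is assumed proportional to caliper volume at constant
cellularity, so `N(t) = N0·e^{rt}` and the net per-day rate `r` is the
ordinary least-squares slope of `ln V` against time (closed-form,
deterministic; a nonlinear `V0·e^{rt}` fit is available as `method="nls"`).
Proliferation is read from the BrdU labeling index under the standard
assumption of a roughly invariant S-phase duration (default 8 h): a pulse
labels exactly the cells currently in S, hence `p = index · 24/s` per day.
Death closes the balance, `d = p − r`, which is the only direction of the
identity that is observable: `r` comes from volumetrics, `p` from labeling,
and `d` cannot be measured directly in tissue.  Per-animal series are
fitted separately and averaged by default, since pooled fits weight animals
by their number of measurements.

## Radial distribution function

Stroma segmentations are tiled into 15 µm pixels (one average tumor-cell
diameter); a tile counts as stroma when at least half of the raster pixels
inside it are stroma (unbiased rounding of the polygonal mask).  Around
every stroma-pixel center, annuli `(r − w/2, r + w/2]` of width `w = 5` µm
are laid out on the midpoint grid `r = w/2, 3w/2, …` up to 150 µm (ten cell
diameters); boundary ties go to the outer annulus.  Counts of
marker-positive (or negative) cells are pooled over stroma points and
divided by a CSR expectation.  Ties in the arg-max of g(r) break toward the
smaller radius.

Two CSR expectations are implemented, and the choice matters:

* **Area normalization (default).**  Expected count = overall marker
  density × annulus area, with no edge correction.  Because stroma and
  excluded regions cannot host cells, near-stroma annuli are partly
  "dead" area, so g rises from the stroma edge, peaks where enrichment
  meets geometric availability — the outer edge of the protected niche —
  and decays to background.  This reproduces the canonical
  rising-peaking-falling enrichment curve whose maximum location is the
  distance readout of the protective effect.

* **Shuffle normalization.**  Expected count = the exact mean under
  uniform marker-label permutation (equivalently the limit of infinitely
  many shuffles), per annulus.  Under this normalization g(r) is precisely
  the enrichment of the marker *fraction* among cells at distance r, equal
  to 1 everywhere for random labels.  It is the cleaner null for
  hypothesis testing, but for an enrichment that is uniform inside a niche
  the curve is a flat plateau across the whole niche — its arg-max carries
  no distance information.  It is therefore not the default for peak
  localization.

Both modes pool counts over stroma points before dividing (ratio of sums).
In area mode this is algebraically identical to averaging per-point ratios;
in shuffle mode it avoids undefined 0/0 ratios at stroma points whose
annuli contain no cells (blob interiors).

Significance uses label permutations in either mode: positions of cells and
stroma fixed, the multiset of labels preserved, 39 shuffles by default.
The pointwise min–max envelope of `n` exchangeable curves is exceeded by
the observed curve with probability `2/(n+1)` — 5% for `n = 39`.  Discrete
counts introduce ties that make the empirical rejection rate slightly
conservative (about 4–4.5% in the Monte Carlo check at the counts used);
the envelope never anti-conservatively inflates significance.

## Agent-based model

A 100 × 100 square lattice, 15 µm per site, one step per 24 h.  Site
states: empty, tumor cell, stroma (active or inactivated), excluded
(micronecrosis; takes part in nothing).  Stroma is static.  Cells are
updated asynchronously in a fresh uniform random order each step (avoids
synchronous conflict resolution); each cell draws at most one event with
precedence **death → division → migration** as mutually exclusive draws, so
a dying cell cannot also divide.  Division and migration target a uniformly
chosen empty Moore neighbor and are silently skipped when none exists;
lattice boundaries are fixed (the window is a tissue quadrant, not a
torus).  A von Neumann neighborhood is available by configuration.

Simulations start from empty sites occupied independently at density 0.5
and run a 350-step baseline that both randomizes the spatial configuration
within the given stromal topology and settles the proliferation–death
equilibrium (any reasonable seeding converges to the same equilibrium; the
tests check stationarity directly).  Therapy then runs 500 steps; the
population at the final step is the residual disease size.

**Protection niche.**  Non-stroma sites within `niche_distance = 3` lattice
cells (Chebyshev, i.e. a 7 × 7 block; Euclidean available) of at least one
*active* stroma site.  Under therapy, division probability is
`p_div_therapy_niche` on niche sites and `p_div_therapy_out` elsewhere;
death (`p_die_therapy`) and migration (`p_move`) are uniform in space.
Protection is binary on/off — no gradients.  Inactivating a fraction of
stroma removes its niche contribution without freeing its space.

**Rates versus probabilities.**  Probabilities are per 24 h step, so they
are numerically per-day event probabilities; but realized per-day *rates*
differ because division requires free space and at most one event fires per
cell per step.  Two structural facts shape calibration:

* The realized death rate equals `p_die` exactly (death is drawn first,
  unconditionally).
* At any dynamic equilibrium divisions equal deaths, and together they
  cannot exceed one event per cell per day, so realized equilibrium
  turnover is capped below 0.5 events/cell/day (precisely,
  `(1 − d)·p_div·f = d` with `f ≤ 1` the fraction of division draws that
  find space).  Experimental baseline proliferation estimates above this
  cap (rapidly cycling xenografts can exceed 0.6/day) cannot be realized
  by any probability combination in this update scheme; `calibrate()`
  refuses such targets rather than silently under-delivering.  The default
  baseline (`p_div_base = 1.0`, `p_die_base = 0.45`, `p_move = 0.3`) holds
  a dynamic equilibrium at 0.45 events/cell/day — the practical ceiling —
  at ≈ 72% occupancy of tumor-capable sites.

**Calibration.**  Therapy targets are matched on realized dynamics:
given an on-therapy proliferation target `p*` (events/cell/day) and a
fitted net decay target `k` (per day), the death probability follows from
the exact discrete-time relation `d = p* + 1 − e^{−k}` (one step per day,
so the fitted log-slope of the mean trajectory is `ln(1 − d + p*)`), and
the out-of-niche division probability is iterated against short simulations
until the realized division rate over the first 20 therapy steps hits `p*`
(the space-availability factor is ≈ 0.95 there, so one or two iterations
suffice).  The niche division probability is iterated until the protected
subpopulation is stationary late in therapy (|log-slope| ≤ 0.0015/step).
Calibrated defaults for the targets `p* = 0.026/day`, `k = 0.113/day`:
`p_div_therapy_out = 0.030`, `p_die_therapy = 0.133`,
`p_div_therapy_niche = 0.219`.

## Perturbation experiments

Aspects are swept on a level axis `λ ∈ [0, 1]` (1 = calibrated full
effect): magnitude interpolates the niche division probability linearly
between the unprotected and protected values; distance maps `λ` to
`round(3λ)` cells; producer fraction inactivates `1 − λ` of stroma
uniformly at random per replicate.  Residual size is normalized to the mean
baseline population (mean over the last 50 baseline steps and replicates;
baseline dynamics are unaffected by the aspects, so levels share it).
Sensitivity is the decay rate `k` of `R(x) = R0 e^{−kx}` fitted log-linearly
against the reduction fraction `x = 1 − λ`; residuals below one cell are
floored at 0.5 cells before the log so extinction points remain defined
(flagged by the floor parameter).  Replicates default to 100 per condition.

## Synthetic-data generators

* **Topologies.**  `n_seeds` stroma nuclei placed uniformly, then grown by
  stochastic dilation (each stroma-adjacent free site converts with
  probability 0.5 per sweep — a single roughness knob) until the abundance
  target is met exactly at lattice resolution.  Dispersal — operationalized
  as the boundary fraction of stroma pixels in the 8-neighborhood, since
  fragmentation metrics for tissue are not standardized — is controlled by
  the seed count (many small blobs ⇒ high boundary fraction) and can be
  targeted by search; infeasible combinations fail loudly, naming the
  achieved metrics.  Out-of-window neighbors do not count as boundary, so
  truncated blobs are not artificially dispersed.
* **Point patterns.**  Cells occupy distinct free lattice sites uniformly
  and are jittered uniformly *within* their site: nucleus centers in tissue
  are continuous, and lattice-center placement would put all pair distances
  on a 15 µm comb that aliases the 5 µm annuli.  Labels are Bernoulli with
  probability `base × enrichment` inside the niche (clipped at 1) and
  `base` outside.  The labeling niche is **Euclidean** by default: the
  paracrine range being emulated is isotropic in tissue.  (A Chebyshev
  labeling niche reaches 3√2 cells diagonally and, together with anchor
  pixels inside blobs, smears the apparent RDF peak well beyond the niche
  width.)  Ground-truth niche membership and probabilities ride along in
  `pattern.meta` for recovery tests.
* **Volumes.**  `V0 e^{rt}` times mean-one log-normal noise of given CV.

What the generators do *not* emulate: fibroblast/collagen morphology,
stromal remodeling under therapy, anisotropic or graded paracrine fields,
segmentation error, and 3-D tissue.  Passing tests therefore demonstrate
that the statistics and the simulator recover what the generators encode —
binary, isotropic, stationary protection around static stroma — not that
real tissue obeys those idealizations.

## Known limitations and honest caveats

* One event per cell per day caps realizable equilibrium turnover at
  0.5 events/cell/day (above).  Matching faster-cycling baselines would
  require sub-day steps or multiple events per step.
* Baseline equilibrium occupancy is *not* perfectly independent of stromal
  topology: sites adjacent to stroma have fewer division targets, so a
  peristromal band equilibrates at slightly lower occupancy and total
  occupancy decreases with stroma boundary length (≈ 2.7% relative between
  15% and 6% abundance at matched dispersal).  The effect is negligible
  next to the order-of-magnitude therapy-phase differences, but it is
  systematic, so a high-powered no-difference significance test across
  topologies will reject; the corresponding suite check documents this
  rather than papering over it.
* No cell-intrinsic resistance, heterogeneity or evolution: with
  protection disabled, therapy eradicates every replicate, which is what
  isolates the contribution of the microenvironment.
* The RDF uses no edge correction; with a 150 µm range on a 1500 µm window
  the bias is small and identical across compared curves.

## Problem sizes

Defaults follow the modeled experiment: 100 × 100 grid, 350 + 500 steps,
100 replicates per condition, 39 shuffles, 5 µm annuli to 150 µm.  The test
suite uses the full grid and replicate count where the measured quantity
demands it (therapy decay, extinction, baseline-occupancy comparison) and
smaller grids (60 × 60) or 25 replicates for qualitative orderings, with
two-standard-error slack; the envelope Monte Carlo uses 1,000 repetitions
of a 40-stroma/4,000-cell null pattern.  The whole suite runs in a few
minutes on one CPU.
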