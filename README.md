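# emdr — spatial dissection of environment-mediated drug resistance

Targeted therapies (e.g. ALK inhibitors in ALK+ NSCLC) induce deep tumor
regressions but rarely eradicate disease.  Part of the escape is not
cell-intrinsic: cancer-associated fibroblasts secrete paracrine factors that
locally protect tumor cells, so survival and residual proliferation under
therapy concentrate in *peristromal niches* — narrow bands of parenchyma
within a few cell diameters of the stroma.  `emdr` is a toolkit for
quantifying this environment-mediated drug resistance (EMDR) and for asking,
in silico, which of its spatial aspects — magnitude, distance, fraction of
protective stroma, stromal abundance and dispersal — controls the size of
residual disease.  It is aimed at computational oncologists working with
segmented histology and xenograft volumetrics.

The pipeline has four linked parts:

1. **Rate inference** (`emdr.rates`).  Tumor volume follows
   `N(t) = N0·e^{rt}`; the net growth rate `r` is the least-squares slope of
   `ln V` vs `t`.  The proliferation rate comes from the BrdU labeling
   index: with an S phase of `s` hours, `p = index · 24/s` (factor 3 for
   8 h).  The death rate closes the balance, `d = p − r` — for a regressing
   tumor with `r = −0.113/day` and `p = 0.026/day`, `d ≈ 0.14/day`.

2. **Spatial statistics** (`emdr.spatialstats`).  The radial distribution
   function g(r) counts marker-positive cells in 5 µm annuli around every
   stroma pixel (stroma is tiled into 15 µm pixels, one average cell
   diameter) and divides by the expectation under complete spatial
   randomness.  Significance comes from 39 marker-label shuffles: positions
   fixed, label counts preserved, giving a pointwise min–max envelope with
   nominal 95% coverage.  `g_max` measures the magnitude of peristromal
   enrichment; its radius measures the distance of the protective effect.

3. **Agent-based model** (`emdr.abm`).  A 100 × 100 lattice (15 µm/site,
   24 h/step) of tumor cells and static stroma.  Per step each cell draws at
   most one event — death, division into an empty Moore neighbor, or
   migration.  After a 350-step baseline equilibration, therapy raises death
   and collapses division *except* within the niche (≤ 3 cells from active
   stroma), where protection keeps the local population at equilibrium.
   `calibrate()` searches per-step probabilities so the realized dynamics
   match experimentally inferred rates (on-therapy proliferation 0.026/day,
   net decay 11.3%/day).

4. **Perturbation experiments** (`emdr.experiments` + `emdr.synth`).
   Synthetic stroma topologies with controlled abundance (6–22%) and
   dispersal (boundary fraction, 50–90%) feed sweeps of protection
   magnitude, distance and producer fraction; residual disease is
   summarized per topology by the decay rate of `R(x) = R0·e^{−kx}` against
   the reduction fraction `x`.

## Worked example

```python
import numpy as np
from emdr import (TopologySpec, EnrichmentSpec, gen_stroma_topology,
                  gen_labeled_pattern, gen_volume_series, fit_exponential,
                  proliferation_from_brdu, death_rate, csr_envelope, gmax)

# --- rates from (synthetic) volumetric + BrdU data -----------------------
series = gen_volume_series(120.0, -0.113, [0, 7, 14, 21, 28], noise_cv=0.05,
                           rng=np.random.default_rng(0))
r = fit_exponential(series)            # -0.114/day
p = proliferation_from_brdu(0.0087)    #  0.026/day
d = death_rate(p, r)                   #  0.140/day

# --- RDF of a treated-tissue-like pattern --------------------------------
grid = gen_stroma_topology(TopologySpec(abundance_target=0.10,
                                        n_seeds=150, seed=2))
pattern = gen_labeled_pattern(grid, EnrichmentSpec(
    base_positive_fraction=0.05, niche_width=3, enrichment_factor=5.0,
    n_cells=5000, seed=12))
result = csr_envelope(pattern, "positive", n_shuffles=39,
                      rng=np.random.default_rng(3))
peak = gmax(result)
```

This prints (via `print(f"...")` on the objects above):

```
net growth rate r = -0.114/day
proliferation  p = 0.026/day
death rate     d = p - r = 0.140/day
g_max = 1.37 at r = 47.5 um (3.17 cell diameters)
CSR envelope at the peak: [0.81, 0.98]
```

The observed curve exceeds the shuffle envelope at its peak: marker-positive
cells are significantly enriched about three cell diameters from the stroma
edge — the signature of spatially restricted protection.  Running the
simulator on the same class of topology:

```python
from emdr.abm import ABMParams, run_replicates, mean_trajectory
from dataclasses import replace

topo = gen_stroma_topology(TopologySpec(abundance_target=0.10,
                                        n_seeds=40, seed=1))
trajs = run_replicates(topo, ABMParams(n_reps=20, seed=0))
```

```
baseline population  6474 cells
residual after 500 therapy steps  2414 +/- 77 cells (37.3% of baseline)
without protection: residual 0 cells
```

With the peristromal niche active the tumor plateaus at an on-therapy
equilibrium (persisters sheltered by stroma); with `producer_fraction=0`
therapy eradicates every replicate.

The same operations are available from the shell, e.g.

```sh
emdr gen topology --abundance 0.10 --dispersal 0.9 --out topo.png
emdr gen pattern --mask topo.png --out pattern.csv
emdr rdf --pattern pattern.csv --marker pos --shuffles 39 --seed 1
emdr calibrate --mask topo.png --out params.yaml
emdr sweep --mask topo.png --aspect producer_fraction --reps 100 --seed 1
```

## Layout

- `src/emdr/tissue.py` — lattice grids, label-mask IO, stroma pixelation,
  niche maps, abundance/dispersal metrics
- `src/emdr/rates.py` — exponential fits, BrdU conversion, rate closure
- `src/emdr/spatialstats.py` — RDF, label shuffles, CSR envelopes, g_max
- `src/emdr/abm.py` (+ `_kernels.py`) — the simulator and its calibration
- `src/emdr/synth.py` — topology / point-pattern / volumetric generators
- `src/emdr/experiments.py` — perturbation sweeps and decay-rate comparisons
- `docs/methods.md` — model assumptions, parameters, numerical choices and
  known limitations
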