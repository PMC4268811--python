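# retmosaic

Spatial and expression statistics for the *Drosophila* retinal mosaic.

The fly compound eye is a hexagonal lattice of 700–950 ommatidia of
distinct types: stochastically specified **pale (p)** and **odd-coupled
(OC)** ommatidia (Rh3 in R7), **yellow (y)** ommatidia (Rh4 in R7), and a
fixed dorsal rim band of **DRA** ommatidia.  The frequency and spatial
arrangement of these types vary between sexes, strains and species, with
direct consequences for colour and polarised-light vision.  `retmosaic`
provides the statistical toolkit for whole-retina ommatidium-type maps
and for rhodopsin qPCR expression data:

* **Mosaic maps** — a TSV+JSON format for per-ommatidium records (hex
  grid position, pixel centroid, type) with equator and midline
  annotations; conversion to marked point patterns in a convex-hull
  window; type counts and the pale percentage
  `100 · n_p / (n_p + n_y)` (DRA and untyped ommatidia excluded).
* **Join-count autocorrelation** — contiguity graphs (exact hexagonal
  6-neighbour rule, or Dirichlet-tessellation adjacency for raw point
  patterns) and the multi-type join-count test under the fixed-counts
  randomisation ("nonfree sampling") null.  For binary weights with
  sums S0, S1 = 2·S0 and S2 = 4·Σdᵢ², the same-type count has

      E[J_aa] = (S0/2) · n_a(n_a−1)/(n(n−1)),

  with the classical second-moment expansions for the variances;
  z-scores with two-sided normal p-values, or a seeded permutation
  test.  The analytic moments are validated exactly against exhaustive
  enumeration over all labellings of small graphs.
* **Density surfaces** — Gaussian kernel intensity estimates of the
  pale (or yellow) pattern with Diggle edge correction (surface
  integrates to the point count) on a fixed display scale for
  cross-retina comparison.
* **Region enrichment** — dorsal/ventral and anterior/posterior
  partitioning at the equator and midline column; per-half deviations
  from the whole-retina pale percentage; repeated G-tests of
  goodness-of-fit per (strain, sex) group with the decomposition
  `G_total = G_pooled + G_heterogeneity` (df k = 1 + (k−1)).
* **Cohort models** — sequential ANOVA of the pale percentage on sex
  and strain, additive models of ommatidium totals, and simple
  regression of percentage on total.
* **qPCR indexes** — primer efficiency `E = 10^(−1/slope)` from
  dilution series, efficiency-corrected quantities `Q = E^(−Cq)`, the
  rh3 index `100·rh3/(rh3+rh4)` and rh5 index `100·rh5/(rh5+rh6)`, and
  maximum-likelihood random-intercept linear mixed models (species and
  sex fixed; strain and biological replicate random) compared by
  likelihood-ratio χ² tests.
* **Synthetic data** — generators for retinal mosaics (elliptical hex
  lattice, DRA rim, logistic pale/yellow switch with optional
  dorsal-posterior patch and anterior–posterior gradient) and qPCR Cq
  plates with strain, replicate and technical noise, so every analysis
  stage runs and is testable without external data.

## Worked example

Detecting the clustered pale patch of a *D. simulans* ZOM4-like retina
(from `examples/02_join_counts.py`):

```python
import retmosaic as rm
from retmosaic.synthetic_data import zom4_like_params

retina = rm.generate_hex_retina(zom4_like_params(seed=2))
graph, marks = rm.strip_marks(rm.hex_adjacency(retina), retina)
result = rm.join_count_test(graph, marks, method="both", n_perm=999, seed=0)
for pair, st in result.pairs.items():
    print(f"{pair}: J_obs={st.j_obs:4d}  E[J]={st.e_j:6.1f}  "
          f"z={st.z:+5.2f}  p_perm={st.p_perm:.4f}")
```

```
pp: J_obs= 391  E[J]= 349.7  z= +3.48  p_perm=0.0020
yy: J_obs= 805  E[J]= 762.0  z= +3.38  p_perm=0.0010
py: J_obs= 951  E[J]=1035.3  z= -3.77  p_perm=0.0010
```

Same-type neighbour pairs (pp, yy) exceed their randomisation
expectations and mixed pairs (py) fall short — the signature of a
non-stochastic patch of pale ommatidia.  An exchangeable retina
(`SyntheticRetinaParams(n_target=800, p0=0.35)`) gives |z| < 2 for all
three pairs.  The remaining `examples/` scripts walk through cohort
simulation, density surfaces, region G-tests, cohort ANOVA and the qPCR
index pipeline, each printing the numbers it computes.

A thin CLI mirrors the library:

```bash
retmosaic simulate --seed 0 --out cohort/
retmosaic analyze --input cohort/ --out results/ --seed 0
retmosaic qpcr-index --input cohort/qpcr.tsv \
    --efficiencies cohort/efficiencies.json --out results/
```

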