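# Methods

This note records the statistical models implemented in `retmosaic`,
the conventions and defaults chosen where the underlying study design
left them open, and what the synthetic-data generator does and does not
emulate.

## Mosaic maps and conventions

A retinal mosaic map stores one record per ommatidium: hex-grid position
`(col, row)`, pixel centroid `(x, y)` on a standardised 1400×1400 px
canvas, and type `P_OC | Y | DRA | UNKNOWN`.  Conventions fixed by the
package (the recording procedure itself does not dictate them):

* **Hex layout** — odd-row offset ("odd-r"): rows are horizontal, odd
  rows shifted +½ column in pixel space, row spacing `pitch·√3/2`.
  This makes the 6-neighbour rule closed-form: a site's neighbours are
  the two same-row columns plus two sites in each adjacent row, with
  the column offset depending on row parity.
* **Orientation** — `x`/`col` increase anterior→posterior, `y`/`row`
  increase ventral→dorsal.
* **Equator** — a mirror line *between* ommatidial rows, stored as a
  non-integer row coordinate (e.g. 17.5) and extended horizontally to
  the periphery.  Validation rejects integer equators so no ommatidium
  can sit on the boundary.
* **UNKNOWN ommatidia** are kept in the map but excluded from every
  proportion denominator and every spatial test; **DRA** ommatidia are
  excluded from spatial tests (they are deterministically clustered at
  the dorsal rim) and from proportion denominators.

## Join-count inference

With binary symmetric contiguity weights, `S0 = 2m`, `S1 = 2·S0`,
`S2 = 4·Σdᵢ²`, and labels randomised holding the type counts fixed
(hypergeometric/nonfree sampling), the implemented moments are, with
`x⁽ᵏ⁾` the falling factorial and `n = n_a + n_b`:

    E[J_aa]  = (S0/2)·n_a⁽²⁾/n⁽²⁾
    E[J_aa²] = ¼[ S1·n_a⁽²⁾/n⁽²⁾ + (S2−2S1)·n_a⁽³⁾/n⁽³⁾
                 + (S0²+S1−S2)·n_a⁽⁴⁾/n⁽⁴⁾ ]
    E[J_ab]  = S0·n_a·n_b/n⁽²⁾
    E[J_ab²] = ¼[ 2S1·n_a n_b/n⁽²⁾ + (S2−2S1)·n_a n_b(n_a+n_b−2)/n⁽³⁾
                 + 4(S0²+S1−S2)·n_a⁽²⁾n_b⁽²⁾/n⁽⁴⁾ ]

The different-type second moment was derived from the ordered-pair
decomposition (pairs sharing two, one or zero indices) and both formulas
are verified *exactly* (rational arithmetic) against exhaustive
enumeration over all `C(n, n_a)` labellings of every graph on ≤ 6 nodes
plus random 7–8-node graphs; this enumeration oracle is part of the
public API (`enumerate_join_count_moments`) and of the test suite.
Second moments need `n ≥ 4`; smaller graphs fall back to enumeration.

Inference defaults to the analytic z with a **two-sided** normal
p-value, reporting the direction separately (clustering is read from
z > 0 for same-type pairs, z < 0 for the mixed pair).  A label
permutation test (default 999 permutations, seeded, `p = (1+#extreme)/
(1+n_perm)` with extremeness measured by |J − E[J]|) serves as the
model-free check; on 800-ommatidium exchangeable mosaics the two agree
to ~0.014 mean absolute difference in p, and the permutation test's
type-I error at α = 0.05 is within [0.03, 0.07].  When `Var J = 0`
(single-type patterns) the analytic p is reported as undefined with an
explanatory note rather than a number.

Two contiguity constructions are provided: `hex_adjacency` (the exact
6-neighbour rule; the default for mosaic maps) and
`dirichlet_contiguity` (positive-length shared Voronoi-cell boundary
after clipping to the window) for point-only input.  Cocircular ties in
the tessellation are resolved by a deterministic 1e-9 px jitter with a
fixed seed; away from ties the construction coincides with Delaunay
adjacency, and on hex-lattice interiors it reproduces `hex_adjacency`.

## Kernel density surfaces

Isotropic Gaussian kernel, default bandwidth σ = 70 px on the 1400 px
canvas (the bandwidth is a package default — no reference value exists —
and is recorded in all output metadata), cell 10 px, evaluated by
separable Gaussian filtering of the binned points.  Edge correction
default is **Diggle** (each point's kernel divided by its own
inside-window mass), which conserves total mass to machine precision;
the classical **uniform** correction (divide the field by the local
inside-window kernel mass) is available but conserves mass only to
~1–2% on realistic windows, which is why it is not the default.  The
display range is fixed at 0.0001–0.0007 points/px² (a seven-fold span)
so surfaces from different retinas are directly comparable.

## Region enrichment and G-tests

Partitions: dorsal = `row > equator`, ventral otherwise (exhaustive);
anterior = `col < midline`, posterior = `col > midline`, with
midline-column ommatidia labelled `midline` and **excluded from both
halves** (symmetric treatment; the midline is a marked row, not a
half).  Enrichment of a half is its pale percentage minus the
whole-retina pale percentage; both axes of one retina share the same
whole-retina reference, so opposite halves mirror each other exactly
when their denominators are equal and approximately otherwise.

`g_test_2x2` uses the independence (intrinsic) expectation from the
table's own marginals, `G = 2ΣO·ln(O/E)`, df 1, zero observed cells
contributing 0.  Options: Williams small-sample correction, and an
extrinsic variant testing each half against a fixed external ratio
(df 2) for sensitivity analysis — "goodness of fit" is ambiguous
between the two readings and the intrinsic form is the default.
`repeated_g_test` combines replicate retinas: individual G per table
(df 1 each), pooled G on the summed table (df 1), heterogeneity
`G_total − G_pooled` (df k−1), total `ΣG` (df k).  The additivity
identity holds to 1e-9 by construction and is asserted on random
tables.  Heterogeneity is screened and flagged at p < 0.05 before the
pooled result is read; the pipeline reports pooled results regardless.

## Cohort fixed-effect models

The pale-percentage model is a sequential (type-I) ANOVA of
`pct ~ sex + strain + sex:strain` with sex entered first (the order is
configurable); with a 22-retina cohort over 4 strains × 2 sexes this
yields the df layout (1, 14), (3, 14), (3, 14).  Percentages are
modelled on the identity scale (a logit option exists for sensitivity
analysis).  The totals model is additive, `n_total ~ strain + sex`; the
overall regression F has (4, 17) df and the sex effect is summarised by
its treatment coefficient (male minus female) and its marginal
(drop-one) F on (1, 17) df.  The DRA count is checked with the same
additive model — in the emulated cohort it carries no group structure.
OLS fitting and the sequential decomposition are delegated to
statsmodels; simple regression reports `F = (n−2)R²/(1−R²)`.

## Linear mixed models and likelihood-ratio tests

Expression indexes are analysed with a Gaussian random-intercept LMM:
species and sex fixed (no interaction), random intercepts for strain
and for biological replicate.  Replicates are modelled **nested within
strain** (grouping column `strain:bio_rep`): replicate "a" of one
strain is a different fly collection from replicate "a" of another, and
the synthetic generator draws replicate effects per strain accordingly.

Estimation is maximum likelihood (not REML) because the fits feed
likelihood-ratio tests of *fixed* effects.  The marginal covariance is
`σ²(I + r₁Z₁Z₁' + r₂Z₂Z₂')`; β and σ² are profiled out in closed form
given the variance ratios r, and log r is optimised by bounded L-BFGS-B
(ftol 1e-8) from a documented 6-point start grid, returning the best of
all starts with a convergence flag.  Variance components are
non-negative by the log parametrisation (a ratio of e⁻³⁰ is an
effective zero).  On a fixed reference dataset the fit matches an
independent lme4 ML fit to ~1e-6 in log-likelihood and ~1e-6 in the
fixed effects, and on balanced one-way layouts it reproduces the
closed-form ML variance components.  `lrt` requires nested fixed
structures on identical data and clamps `X² = 2Δℓ` at 0; sex tests have
1 df, species tests (three species) 2 df.

Calibration under the synthetic-cohort conditions (8 strains × 2
sexes × 2 replicates, generator noise defaults): a known sex effect is
recovered within 2 SE in ≈95% of simulations, and the sex LRT rejects
at ≈6% at nominal α = 5% (the mild liberality expected of ML-based
LRTs at n = 32).

## qPCR quantification

Primer efficiency is `E = 10^(−1/slope)` from the least-squares slope
of Cq on log10 relative concentration over a 1:4…1:64 dilution series;
perfect doubling gives slope −3.3219 and E = 2.  Estimates outside
(1, 2.2] are flagged.  Quantities are `Q = E^(−Cq)`; technical
replicates are averaged **on the Cq scale** before transformation for
the headline per-replicate index (the alternative order — averaging
per-tech-rep indexes — is implemented and agrees exactly in the
noiseless limit; the default follows the convention that Cq is the
measured quantity).  Indexes are `100·Q_num/(Q_num+Q_partner)` for the
pairs (rh3, rh4) and (rh5, rh6); they are invariant to global quantity
rescaling, complements sum to exactly 100, and per-tech-rep indexes are
retained for the within-replicate spread.  A three-gene representation
`rh3 : (rh3+rh4+rh6)` is emitted alongside for cross-study comparison.
Negative-control rows (`no_rt`, `water`, `ntc`) are accepted in input
and excluded from quantification.  Groups missing a partner gene are
skipped with a logged reason.  Note that with unequal per-gene
efficiencies the constant-offset term `E^(−C0)` does not cancel between
genes; exact index recovery therefore holds when paired genes share an
efficiency, which the defaults do.

## Synthetic-data generator

**Retinas.** A hex lattice is clipped to a centred ellipse (aspect 1.1,
filling 90% of the canvas) whose pitch is solved so the ellipse holds
≈ `n_target` sites; the realised count is within a few percent of
target.  The dorsal `dra_count` sites (default 40, constant — the DRA
count is treated as the invariant it empirically is; no scatter is
added) become DRA, filling rows top-down.  Remaining sites switch to
pale independently with probability

    π(x,y) = logistic( c + β·exp(−d²/(2s²)) + γ·a(x) ),

where d is distance to the patch centre, `a(x) ∈ [−1, 1]` spans the
anterior–posterior axis, and c is either `logit(p0)` (default) or, with
`p0_is_mean=True`, solved so that the lattice mean of π equals `p0` —
the cohort generator uses the latter so that cell means quote group-mean
percentages even for patch-bearing strains.  A fraction ε (default
0.005) of non-DRA sites is relabelled UNKNOWN after assignment.  The
equator is placed in the central row gap and the midline at the central
column.  One root seed per generator call; cohorts spawn per-retina
streams via `SeedSequence` so both the cohort and each retina are
individually reproducible.  Any change to the stream layout is a
breaking change.

With β = γ = 0 the marks are i.i.d. given the lattice — exchangeable —
which is the null condition for all calibration studies.  The
**ZOM4-like** condition (`zom4_like_params`) is β = 1.5 logit, patch
scale s = 450 px centred at (0.8, 0.8) canvas fractions, plus a
γ = 0.6 logit anterior→posterior gradient.  The patch geometry is a
calibration choice (no quantitative reference exists): it was set,
once, so that synthetic ZOM4 retinas reproduce the strain's documented
phenotype — near-universal global autocorrelation (mixed-pair join
deficit in ~97% of retinas) and a consistently pale-enriched posterior
half — rather than to any printed patch dimensions.

The default 22-retina cohort covers 4 strains × 2 sexes with cell-mean
pale percentages set to the observed group means (Oregon-R 38.3/29.3,
Zi372 40.5/31.5, ZOM4 44.3/40.7, TAM16 41.6/29.6 for F/M), total-count
means reproducing the observed ordering (TAM16 females ≈ 924 highest,
Oregon-R females ≈ 762 lowest among females, males ≈ 50–100 below
females in the dimorphic strains), and replicate counts 3/3, 2/1, 3/3,
3/4 summing to 22.

What the generator does **not** emulate: per-retina biological scatter
in the pale percentage beyond binomial sampling (cell percentages vary
only through the stochastic switch, so cohort F statistics run larger
than on real data, where replicate retinas scatter by ±1–5 points);
irregular eye outlines and local lattice defects; ectopic ventral DRA
(available via `ectopic_dra`, default 0, emulating its rare
occurrence); and any developmental mechanism behind the pale/yellow
switch.  Passing calibration tests therefore demonstrates correctness
of the statistics under the stated sampling models, not biological
realism of any single retina.

**qPCR plates.**  `Cq = C0 − log(Q_g)/log(E_g) + u_strain,g + u_rep,g +
e_tech`, with relative quantities proportional to the pair fractions,
gene-specific Gaussian strain and replicate intercepts (defaults 0.25
and 0.15 cycles — gene-specific so they do not cancel identically from
the indexes, mimicking gene-by-extraction variation) and technical
noise 0.12 cycles, four technical replicates, two biological
replicates.  Default per-strain index fractions use the measured values
where available and order-preserving interpolations for the remaining
strains (Zi86 ≈ Zi372; Tana10 < Kib32 < ZOM4 within *D. simulans*;
MAV1 > TAM16 within *D. mauritiana*).

## Numerical choices and degenerate inputs

* Exact rational arithmetic (`fractions.Fraction`) for join-count
  moments; floats only at the interface.
* Permutation p-values use the add-one estimator; `n_perm ≥ 99`
  enforced.
* Degenerate geometry (collinear centroids, duplicate points) raises
  typed errors; degenerate contingency tables (zero marginals) raise
  errors naming the offending retinas.
* LMM non-convergence is flagged on the returned fit, never silent.
* G heterogeneity is not clamped (the identity is exact); its p-value
  clamps the statistic at 0.
* All generator and analysis entry points that consume randomness take
  explicit integer seeds; no global RNG state is used anywhere.
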