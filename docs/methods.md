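# Methods

## Scope

`gmvnet` analyzes longitudinal structural covariance: how the correlation
structure of regional gray matter volumes (RGMV) across subjects — viewed as
a weighted brain graph — changes between two scans ~7 years apart, as a
function of baseline age.  The pipeline starts from a subject × scan × region
volume table; image acquisition, segmentation and parcellation are upstream
and out of scope.

## Synthetic cohort generator

The generator emulates the cohort the design was built for: n = 380 subjects,
baseline ages truncated-normal in [21, 80] with mean 51.1 and SD 11.7 years
(reject-and-resample, which honors the hard range at the cost of a small
(<3%) shrinkage of the realized SD), scan interval normal with mean 7.41 and
SD 0.54 years, 157/380 male.

Per region (90 AAL regions, hemispheres interleaved so left/right homologues
are adjacent), a subject's structural component is the unit-variance latent

    a·F_block + b·H_pair + c·ε,   a² = r_block,  a² + b² = r_homotopic,

with a shared factor per lobe block (default within-block r = 0.3), a shared
factor per homotopic pair (default r = 0.65), and region noise.  The loading
construction gives closed-form control of the inter-region correlations the
pipeline must recover.  On top of the latent come confounds — a global size
factor (loading 0.5, reflected in total gray matter volume), age (−0.015
cm³/y, centered at 50 y), sex (+0.3 cm³, M−F) and age×sex (−0.004 cm³/y) —
plus per-scan measurement noise (SD 0.25 cm³) around a region mean of
10 cm³.  Defaults without a stated source (block/homotopic correlations,
volume scales, confound sizes) were chosen once as field-typical magnitudes:
homotopic correlations in volumetric covariance data are strong (~0.6–0.8),
within-lobe correlations moderate, and the confounds are small relative to
the latent SD so that residualization is corrective rather than dominant.

Longitudinal change has two channels:

* **volume drift** — per region, `(lin·(age−50) + quad·(age−50)²) × interval`
  added at follow-up.  This changes volumes but barely moves *correlations*
  in a controlled direction: its deterministic part is removed by the age
  regressor, and its interval-randomness part only adds (unsigned)
  idiosyncratic variance.
* **loading modulation** (`strength_trajectory`) — per region, the shared
  loadings a, b are multiplied at follow-up by `1 + g(age)·interval` (then
  renormalized to unit variance), with `g(age) = d0 + d1(age−50) +
  d2(age−50)²` per year.  Because node strength is a covariance-level
  quantity, this is the channel that plants signed, age-dependent ground
  truth for ARC_NS; it was verified against its closed-form correlation
  predictions at n = 4000.

Defaults for both channels are zero (no true longitudinal change) — the null
condition needed to calibrate the permutation test.  What the generator does
**not** emulate: spatially realistic region-volume means, scanner drift,
non-Gaussian volume distributions, subject dropout, or registration error.
Passing tests therefore demonstrate correctness of the pipeline's statistics
under a faithful covariance model, not robustness to MRI artifacts.

## Residualization and its side effect

Within each group and scan, volumes are residualized by OLS against
[1, total_gmv, age, sex, age·sex] (sex coded F = 0, M = 1; scan-specific
total volume and age; rank-deficient designs drop collinear columns with a
warning).  One consequence, inherent to the design and visible in the tests:
because total gray matter volume is the *sum* of the regions, regressing it
out removes part of the shared block factors themselves.  Within-block
correlations are attenuated (more for larger blocks) and cross-block
correlations are pushed slightly negative — the familiar global-signal-
regression effect.  The ordering homotopic > within-block > cross-block
survives, and that ordering, not exact recovery, is what the residualized
tests assert.  A corollary used by the inference tests: a longitudinal change
*uniform across all regions* is global and is absorbed by the total-volume
regressor; only subsystem-specific change is detectable.

## Networks and metrics

Edges at cost t are the top `round(t·N(N−1)/2)` region pairs by |r|
(half-up rounding; ties broken by ascending (i, j) node order, making
thresholds nested and runs bit-reproducible), weighted by |r|.  Efficiency
uses 1/w edge lengths, Dijkstra shortest paths, and the Latora–Marchiori
convention 1/d = 0 for disconnected pairs; local efficiency keeps original
weights in the neighbor subgraph (no rescaling), and nodes with < 2
neighbors contribute zero.  Sums run over ordered pairs with divisor
N(N−1).  Inside permutation loops the whole cost-grid GE profile is computed
by one batched Floyd–Warshall pass over the nested graphs; the unit tests
pin its equality (≤1e−12) to the per-network Dijkstra route, and both to an
exhaustive path-enumeration oracle on small graphs.

## Null models

Surrogates rewire the binary topology by double-edge swaps (10 attempts per
edge, rejecting self-loops/multi-edges) and then permute the original weight
multiset onto the rewired edges: degree sequence and weight distribution are
preserved exactly; node strength deliberately is not.  The economical
small-world verdict requires LE_real/LE_null > 1.1 and GE_real/GE_null in
[0.8, 1.2]; the margins are reporting conventions (the qualitative claim
"much higher LE, similar GE" has no canonical cutoff) and are logged with
every run.

## Inference

* **Permutation test** (per group): the statistic is the follow-up minus
  baseline summary metric; each permutation swaps every subject's two scan
  rows (volumes *and* covariates) with probability 1/2 and re-runs
  residualization → correlation → thresholding → metric, respecting the
  paired design.  p = (1 + #{|Δ*| ≥ |Δ|})/(1 + n_perm).  Calibration:
  rejection rate 0.038 at α = 0.05 over 500 null cohorts (reduced scale,
  window 40, 20 regions, 199 permutations).
* **Paired t** over groups on (scan2 − scan1); BH-FDR across the 90 regions
  at q = 0.05.  The boxcar groups overlap by 90%, so the 29 per-group values
  are strongly dependent; they are treated as observations exactly as the
  design prescribes, and this caveat is recorded in the run metadata rather
  than corrected.
* **Trajectories**: Models I–III fitted by OLS on raw age powers; overall F
  against the intercept-only model; AIC = n·ln(RSS/n) + 2k with RSS floored
  at 1e−12 (so exact fits select the smallest exactly-fitting model
  deterministically); selected model = argmin AIC; quadratic vertex
  −a₁/(2a₂) reported as peak age whichever the curvature sign.

### Known limitation: AIC among nested polynomials

Under a true lower-order model, AIC selects the next-order model whenever
the nested RSS improvement exceeds the +2 penalty — asymptotically a ~16%
event (P(χ²₁ > 2)), ~19% at n = 29, *independent of the noise scale*.  Model
recovery rates therefore plateau around 80–85% no matter how clean the data,
and the 90%-overlap dependence of the boxcar groups worsens this for the
regional screen: smooth inter-group noise mimics curvature and favors the
cubic model.  Consequences, measured and accepted rather than patched: the
quadratic-recovery rate at n = 29 is ~0.84, and in the planted regional
screen the inverted-U signal in IPL.R is recovered exactly while the
negative-linear plants are frequently relabeled by an overfitted cubic.
A small-sample-corrected criterion (AICc) or BIC would reduce the
overselection, and prespecifying the candidate shapes would remove it; the
plain-AIC convention is kept as the method under study.

## Problem sizes

Chosen as the package's test sizing: unit tests run cohorts of 40–120
subjects (20–90 regions); oracle comparisons use 200 random graphs of ≤ 6
nodes; small-world assessment uses one 100-subject group × 15 costs × 100
nulls; the type-I study uses 500 cohorts at window 40 / 20 regions / 199
permutations; the planted screen runs the full 380-subject, 29-group design
(node strength only, so no shortest paths are needed).  The full suite
completes in ~8 minutes on one CPU.  A paper-scale run with n_null = n_perm
= 1000 across all 29 groups × 2 scans × 15 costs is hours of compute and is
exposed through the CLI/config rather than the tests.
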