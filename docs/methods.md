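# Methods

This note documents the models behind `sporegate`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that affect results.

## Signal model and transform

Cytometric pulse areas (FSC-A, SSC-A, FL1-A) are treated as near
log-normal. All model fitting happens after the inverse-hyperbolic-sine
transform `y = asinh(x / c)`, which is `log(2x/c)` for large signals but
linear through zero, so negative baseline noise needs no clipping. The
default cofactor is `c = 1` (the plain asinh); instruments whose baseline
noise spans hundreds of channels typically need `c` in the 150–1000 range,
and the cofactor is exposed in `TransformSpec` and the pipeline config. No
compensation/spillover handling is attempted: the intended use is
single-dye staining.

## Agglomerate exclusion

Doublets pass the laser as one event with roughly additive pulse area and
height but a stretched pulse width. For each configured height/width pair
(FSC-H/FSC-W and SSC-H/SSC-W by default) a bivariate normal is fitted
robustly and events outside a Mahalanobis-distance cutoff on any pair are
excluded.

The robust fit is the minimum covariance determinant (MCD) estimator with
`h = ⌊(n+d+1)/2⌋`: among all h-subsets, the one whose sample covariance has
the smallest determinant. The best subset's covariance systematically
underestimates the clean-data scatter (in 2-D the half-sample factor is
≈ 3.26), so the raw estimate is multiplied by the asymptotic consistency
factor `α / P(χ²_{d+2} ≤ χ²_d(α))` with `α = h/n`, then refined by one
reweighting step (recompute mean/covariance from points inside the
χ²₀.₉₇₅ ellipse, times the corresponding trimming factor) — the standard
covMcd recipe. `scale_factor` multiplies the final covariance; its default
of 1 means the gating ellipse is not scaled beyond the calibrated estimate.
The raw best-subset covariance is retained on the result object because the
determinant-minimisation objective is stated in terms of it.

Search strategy: when the number of h-subsets is at most ~3·10⁴ they are
enumerated and the global optimum is exact; otherwise FAST-MCD is used
(500 random (d+1)-point starts, two concentration steps each, full
refinement of the best 10), and for n > 5000 the search runs on a seeded
5000-event subsample with final concentration steps on all events. All
draws come from one seed, so fits are reproducible; degenerate data
(collinear or zero-variance channels) raise an explicit error rather than
fall back to a pseudo-inverse.

Two deliberate choices:

* **Distances are computed on asinh-transformed H/W values by default**
  (`asinh_pairs=True`). The MCD model assumes an elliptically symmetric
  core; raw pulse signals are log-normal, and on the raw scale the skew
  alone pushes the false-exclusion rate of genuine singlets to ~10–20% per
  pair at the default cutoff, versus the nominal ~2.5% on the transformed
  scale. Raw-scale gating remains available via the flag.
* **The default cutoff is `"chi2_0.975"`** (distance √χ²₀.₉₇₅(2) ≈ 2.716),
  the usual robust-distance outlier convention. It is a documented
  package default, configurable per run, not a claim about any particular
  upstream tool's internal constant.

With these defaults, on synthetic cultures with 5% doublets and 2× width
inflation, essentially all doublets are removed at ≈ 4% singlet loss
(tests assert ≥ 90% removal at ≤ 5% loss).

## Mixture models

Gaussian mixtures are fitted by EM with full covariance flexibility:
unequal variances in one dimension, full per-component covariance matrices
in d > 1. (Model-family selection by information criteria is out of scope;
fixing the most flexible family is the single safest choice and is
reported as such.)

* **Initialisation** is deterministic: in 1-D, component means start at the
  g quantile midpoints of the data with the overall variance; in d > 1,
  seeded k-means on lexicographically sorted rows supplies centers, shares
  and a shared covariance. Sorting makes the initialisation — and hence the
  fit to ~10⁻¹² — invariant to row order.
* **Convergence**: relative log-likelihood change < 1e-8 (default), cap
  1000 iterations. The full likelihood trace is recorded on the model; EM
  guarantees it is non-decreasing and the tests check every fit.
* **Degeneracy**: a component whose covariance eigenvalue falls below
  1e-6 × the average per-dimension data variance, or whose effective size
  drops below d+1, raises `DegeneracyError` with a diagnostic instead of
  silently regularising.
* **Ordering**: components are sorted by ascending first-dimension mean, so
  in the stain fit component 0 is the low-permeability (LP) and component 1
  the high-permeability (HP) population.

## Separation statistics and threshold

For the g = 2 stain fit, quality is reported as `mu_diff = mu_HP − mu_LP`
and `sigma_pooled = sqrt((sigma_HP² + sigma_LP²)/2)`. The threshold is the
root of `f(x) = λ_HP·N(x; μ_HP, σ_HP) − λ_LP·N(x; μ_LP, σ_LP)` between the
two means, found by bisection (tol 1e-8) after a 2048-point sign scan of
the bracket. Whether the subtracted densities carry the mixture weights is
a genuine modelling choice; both are implemented (`weighted=True` default —
the crossover of the fitted mixture's actual component contributions).
With unequal variances two crossovers can exist inside the bracket; the one
nearest the midpoint of the means is returned with a warning. The
threshold is for visualisation and QC only — classification never uses it.

## Classification and label transfer

The reference model (g = 3, default feature space = asinh SSC-A ×
asinh FL1-A; FSC-A adds little discrimination and can be added by config)
is fitted on one user-designated sample that contains all three
populations; at least 300 events are required and a QC warning fires if any
fitted weight is below 2%. Cluster naming follows the staining mechanism:
lowest FL1 mean → spore; of the remaining two, higher SSC mean → endospore;
remainder → vegetative. Exact ties on either criterion raise a mapping
error rather than guessing.

All samples of an experiment set are then labelled with this single model.
The default rule is Euclidean distance to the component means; maximum
posterior is available (`rule="posterior"`). The two agree when
populations do not drift between samples; posterior assignment weights
distances by each cluster's fitted shape, Euclidean assignment is more
robust to a reference whose covariances are poorly estimated. Ties break
to the lowest cluster index. Fractions are exact counts divided by the
per-sample total.

## Synthetic data generator

Each subpopulation is a multivariate log-normal over the seven channels
(FSC/SSC × A/H/W, FL1-A). The default preset (all values in log detector
a.u., chosen once as plausible magnitudes; only the orderings carry
meaning):

| population | FSC-A | SSC-A | FL1-A |
|---|---|---|---|
| vegetative | 7.0 | 6.6 | 8.7 |
| endospore | 7.2 | 7.25 | 7.8 |
| spore | 7.1 | 7.0 | 5.0 |

with log-SDs 0.18 (scatter areas), 0.22 (FL1), 0.35 (heights), 0.05
(widths); heights sit 0.15 below their areas and correlate 0.9 with them,
scatter families correlate 0.5 with each other and 0.2 with FL1; widths are
independent with log-mean 4.6. In the (asinh SSC-A, asinh FL1-A) feature
plane the pairwise center separations are ≈ 5.5 (vegetative–endospore),
≈ 17 (vegetative–spore) and ≈ 13 (endospore–spore) pooled SDs — i.e. FL1
separates strongly, SSC somewhat, FSC barely. Doublets (default 5% of
events) sum the area/height signals of two random singlets and multiply
widths by 2; their truth label is the first constituent's.

What the generator does **not** emulate: detector saturation/censoring,
spillover, debris, time drift, non-log-normal tails, and density-dependent
coincidence rates. Passing tests therefore demonstrate correctness of the
algorithms under the stated signal model, not instrument-level robustness;
on real data the asinh cofactor and the gate cutoff are the knobs to
revisit.

## Problem sizes in tests and acceptance

Unit tests run on 2·10³–5·10⁴ events. The acceptance script and the
end-to-end tests use the design sizes of the method: 10⁵-event cultures
(20 independent seeds) for fraction recovery, 50 simulated datasets of
n = 2000 for EM recovery, 20 enumerable n = 12 instances for MCD
optimality, and 5·10⁴ events for the doublet-gate operating point.

## FCS I/O

Files are written as FCS 3.1 list mode, `$DATATYPE F` (little-endian
float32), one data segment, with sample metadata mirrored into
non-standard TEXT keywords; readers accept FCS 3.0/3.1 with float32/64
data. Integer+gain dialects, FCS 2.0 and analysis segments are out of
scope. Experimental design (strain, time, replicate) travels in a sidecar
CSV sample sheet, since instrument TEXT segments rarely carry it.

## Known limitations

* One covariance family per dimensionality (V / VVV analogues); no BIC
  model selection.
* The g = 2 stain fit assumes exactly two populations; on a
  three-population culture it pools the two bright ones, which is the
  intended reading for spore/non-spore QC but not a three-way separation
  score.
* MCD gating assumes the singlet cloud is a single elliptical core per
  channel pair; strongly multimodal scatter (populations far apart in H)
  erodes the nominal false-exclusion rate.
* Fractions are reported per labelled event; no correction for
  differential loss at the singlet gate is attempted (on the synthetic
  preset this bias is ≤ 0.005).
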