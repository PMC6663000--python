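# sporegate

Automated flow-cytometric gating and quantification of sporulation
subpopulations in *Bacillus subtilis* cultures.

Sporulating cultures contain three subpopulations — vegetative cells,
endospore-containing mother cells, and free spores. After staining with a
nucleic-acid dye (SYBR Green), the three separate in the plane of side
scatter (SSC) and green fluorescence (FL1): vegetative cells are
dye-permeable (high FL1, low SSC), the developing coat of an endospore
raises granularity (high FL1, high SSC), and the finished coat of a free
spore blocks the dye (low FL1). `sporegate` replaces hand-drawn gates with
model-based ones so that spore fractions can be tracked over time,
operator-independently, across strains and replicates.

## Method

For each FCS sample the pipeline:

1. **subsamples** to 10⁵ events (uniform without replacement, seeded);
2. **transforms** the signal areas to near-normal form with the inverse
   hyperbolic sine, `y = asinh(x / c)` (cofactor `c = 1` by default);
3. **excludes agglomerates**: a robust bivariate normal is fitted to each
   height/width pair (FSC-H/FSC-W, SSC-H/SSC-W) with the fast minimum
   covariance determinant (MCD) estimator — minimise det Σ over subsets of
   h = ⌊(n+d+1)/2⌋ points, apply the asymptotic consistency factor, then
   reweight — and events with Mahalanobis distance above
   √χ²₀.₉₇₅(2) ≈ 2.716 on any pair are dropped (doublets carry roughly
   additive area/height but inflated width, so they stand far outside the
   singlet ellipse);
4. **scores stain quality** by fitting a univariate two-component Gaussian
   mixture (EM) on the stained channel and reporting the distance between
   the high- and low-signal populations, μ_HP−LP = μ_HP − μ_LP, on the
   scale of the pooled standard deviation
   σ_HP−LP = √((σ²_HP + σ²_LP)/2), plus a visualisation threshold at the
   root of the weighted component-density difference
   λ_HP·N(x; μ_HP, σ_HP) − λ_LP·N(x; μ_LP, σ_LP) between the two means;
5. **classifies subpopulations**: a g = 3 Gaussian mixture is fitted once on
   a reference sample containing all three populations in the
   (asinh SSC-A, asinh FL1-A) plane; clusters are named by the staining
   mechanism (lowest FL1 mean → spore; higher SSC of the remaining two →
   endospore; remainder → vegetative) and every other sample of the
   experiment set is labelled with this one model by Euclidean distance to
   the cluster centers (maximum posterior available as an option);
6. **reports** per-sample counts and fractions of
   {vegetative, endospore, spore} keyed by strain, time and replicate.

A synthetic-data module generates cultures with correlated log-normal
scatter/fluorescence signals per subpopulation, ground-truth labels and
width-inflated doublets, so the entire pipeline is testable without
instrument data.

## Worked example

```sh
# a synthetic culture: 25% vegetative, 35% endospore, 40% spore, 5% doublets
sporegate simulate --n 100000 --seed 1 --proportions 0.25,0.35,0.40 \
    --out culture.fcs --truth culture_truth.csv

sporegate qc-stain --sample culture.fcs --dye SYBR1 --out qc
# mu_diff=3.1720  sigma_pooled=0.3842  threshold=6.6810
# (events: 100000 read -> 100000 subsampled -> 90778 singlets)
```

The stain-QC fit pools the two dye-permeable populations against the dim
spores: their asinh-FL1 means sit 3.17 apart — about eight pooled standard
deviations, a cleanly resolved staining — and the density-crossover
threshold at 6.68 is where a rendered histogram would be split.

```sh
# classify a time point against a balanced reference sample
sporegate simulate --n 100000 --seed 2 --proportions 0.34,0.33,0.33 --out ref.fcs
# sheet.csv lists: sample_id,path,strain,time_h,replicate  (ref + c48)
sporegate classify --reference ref --samples sheet.csv --out fractions.csv
```

`fractions.csv` then contains (printed with pandas):

```text
sample_id  n_total  frac_vegetative  frac_endospore  frac_spore
      ref    90939           0.3375          0.3301      0.3325
      c48    90778           0.2450          0.3477      0.4073
```

i.e. the requested 0.25/0.35/0.40 composition of `c48` is recovered within
±0.01 after subsampling, singlet gating and label transfer. The same
library calls are available in Python (`simulate_culture`, `run_stain_qc`,
`run_experiment`); `sporegate report` summarises a fractions table across
replicates and can plot the time course.

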