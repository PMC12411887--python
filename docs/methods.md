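# Methods

## Labeling model and enrichment scales

Every carbon of a molecule is assumed independently ¹³C with the same
probability *p* (uniform labeling), so the isotopologue envelope of a
compound with n_C carbons is Binomial(n_C, *p*). `p` is the **total** ¹³C
atom fraction: unlabeled material sits at natural abundance
(p_nat = 0.0107) and the labeled litter default is 0.524, the measured
enrichment of the amendment. Uniform labeling is the standard SIAM working
assumption; it makes enrichment identifiable from the envelope mean and is
exact when label was incorporated at steady state during growth. Real
plant material is a mixture of pools labeled at different rates, so real
envelopes are overdispersed relative to a single binomial; the generator
does not emulate that (see Limitations).

Natural-abundance correction solves `f_obs = C · f_corr` by non-negative
least squares, where `C[i, j] = P(Binomial(n_C − j, p_nat) = i − j)` — a
molecule with *j* tracer carbons shows *j* plus naturally heavy atoms on
the remaining carbons. The corrected envelope is a **tracer** (excess)
distribution: its mean over n_C is the excess atom fraction
p_t = (p − p_nat)/(1 − p_nat). Two scales therefore coexist:

- `estimate_enrichment` → excess atom percent, `100 · Σ k f_corr[k] / n_C`
  (the "fractional label incorporation");
- `total_atom_percent` → `100 · (p_t + (1 − p_t) p_nat)`, the total atom
  percent comparable to bulk IRMS measurements.

The second exactly inverts the forward map: correcting a 52.4 at-%
envelope and converting back recovers 52.4 in expectation. Reported
enrichments use the scale stated at each call site; the acceptance
protocol reports total atom percent because that is the scale on which
bulk enrichment of the litter is quoted.

Only carbon isotopes are modeled. ¹⁵N/¹⁸O/³⁴S envelopes are ignored — the
tracer design follows carbon — and the mass of a k-labeled isotopologue is
`M + k · 1.0033548` Da.

## Carbon-count estimation and its identifiability limit

The mass-bounded grid search (`estimate_n_carbon`) scores candidate
carbon counts in `[round(M/30), floor(M/12)]` by the NNLS residual of the
corrected fit, bounded below by the largest observed heavy-atom count, and
returns the smallest candidate within `1e-9` of the minimal residual. On
full-support noiseless envelopes this is exact. Its limit: because
p_nat is small, `C` is close to the identity, and an *under*-estimated
n_C is absorbed into the tracer distribution with near-zero residual — the
residual surface is flat below the truth once envelope tails are
truncated. The pipeline therefore prefers `estimate_n_carbon_natural`,
which exploits the paired design: unlabeled control samples show every
compound's pure natural envelope, whose shape (k₁/k₀ ≈ n_C·p_nat, …) pins
n_C; the grid search is the fallback when controls carry no signal.

Envelope proportions for estimation use within-sample member ratios
(geometric mean of per-sample ratios to the most intense member,
`paired_ratio_envelope`): compound abundance varies between samples but
scales all isotopologues together, so within-sample ratios cancel it.
Members detected in fewer than 3 common samples fall back to summed
ratios; the estimator reduces to the summed envelope on noiseless data.

## Label classification

A cluster is called labeled iff its corrected excess heavy fraction
`Σ_{k≥1} f_corr[k]` reaches `min_incorporation` (default 0.02) **and** the
cluster has at least two members — a singleton carries no isotopologue
evidence. The exact diagnostic rule used by vendor stable-isotope
workflows is not public; this thresholded excess fraction is this
package's documented stand-in.

## Two-pool flux partition

Ratios are ¹³C atom fractions of total carbon throughout; δ-notation
inputs are converted at the I/O boundary with
`R = (δ/1000 + 1) · 0.0111802`, atom fraction `R/(1+R)`. R_Soil is the
per-day mean over unamended jars (not pooled over the series) so priming
is time-resolved; the priming reference is the per-day mean unamended
total flux. Mixtures pushed outside `[R_Soil, R_Litter]` by measurement
noise are clamped to `[0, F_Net]` with a logged warning rather than
rejected. Days without an unamended observation are flagged and skipped,
never interpolated. Cumulative components integrate each jar's series by
the trapezoid rule over its sampling days. Fluxes are carried as
µmol CO₂ g⁻¹ dry peat d⁻¹ in a header unit string and never silently
converted. R_Litter is a parameter (default 0.524): whether the effective
end-member of litter-derived CO₂ equals the bulk litter enrichment is an
assumption the caller can override.

## Multivariate workflow

The statistics operate on the **compound-level** matrix (summed member
intensities per cluster per sample). Summing an isotopologue family
collapses the mass-shift pattern, which is what makes labeled and
unlabeled samples of the same material replicates; raw isotopologue rows
differ radically between label states.

- Median normalization: divide each sample by its median of nonzero
  values, rescale by the grand median of those medians. Zeros are kept as
  true zeros (absence below detection), never imputed.
- Pareto scaling: per-feature centering, division by √SD (n−1 SD);
  constant features map to zero.
- PCoA: Gower centering of −D²/2, eigendecomposition; coordinates on
  positive eigenvalues only; negative eigenvalues (expected for Manhattan
  distances) are reported but excluded from variance proportions; no
  Cailliez correction.
- Hierarchical clustering: UPGMA by default (the linkage is configurable);
  ties merge the lowest-index pair first, deterministically.
- PERMANOVA: Anderson's pseudo-F computed directly from the distance
  matrix; p = (1 + #{F_perm ≥ F_obs}) / (1 + m), never exactly zero;
  seed-reproducible. One-way tests per factor are exposed; no crossed
  designs.

## Multiblock sparse PLS-DA

Classes are dummy-coded into an outcome block. Per component, each data
block's loading vector is updated toward the sum of the outcome scores
plus `design_weight` (default 0.1) times the other data blocks' scores,
soft-thresholded so at most `keep_per_block` loadings stay nonzero, and
normalized to unit norm. Initialization is the leading singular vector of
each block's cross-covariance with the outcome, with a deterministic sign
convention, so fits are reproducible without randomness. Data blocks are
deflated by regression on their own scores; the outcome block is never
deflated, which keeps successive scores within a block orthogonal.
Explained variance per block is redundancy (‖t pᵀ‖²/‖X‖²). `keep_per_block`
defaults to (20, 6) and `n_components` to 2; keep values are parameters,
not tuned by cross-validation. With one dense block and zero coupling the
first component equals the dominant singular direction of the class
cross-covariance (verified against a direct SVD in the tests).

Fold-change trajectories are `log2((mean + ε)/(ref_mean + ε))` per feature
and treatment×timepoint group, referenced to unamended peat at T0, with
ε = half the smallest nonzero value of the matrix by default.

## What the generator emulates — and what it does not

The generator reproduces the incubation design (litter-only at T0;
unamended peat at T0–T3; amended peat harvested at days 7, 18, 40; two
replicates per cell; labeled/unlabeled variants), species pools with
distinct dynamics, and gas sampling on days 1, 3, 5, then every 5 days to
day 40.

Species origins and abundance trajectories (multipliers on a per-species
base abundance):

| origin | unamended | amended | rationale |
|---|---|---|---|
| litter | absent | exp(−0.15 t) | fast depletion of labile litter compounds |
| peat_native | 1 | 1 | stable background |
| microbial_product | 0.05 | 0.05 + 3·(t/7)·e^(1−t/7) | transient pulse peaking at day 7 — the amended-T1 excursion |
| peat_primed | 1 | exp(−0.04 t) | slow depletion of primed peat compounds |

Flux: peat baseline 2, litter component 8·exp(−0.099 t) (half-life ≈ 7 d),
priming pulse 0.35·t·e^(−t/7) (peak ≈ 0.9 at day 7), all in
µmol CO₂ g⁻¹ d⁻¹; pool ratios 0.0108 (soil) and 0.524 (litter).

Noise model: 0.5 ppm mass error (ultra-high-resolution MS), 0.02 min RT
jitter, compound-level log-normal CV 0.2 per sample (shared across a
compound's isotopologues), per-cell envelope CV 0.05, 5% random dropout,
a 10⁵ per-cell detection floor, and 10% unassigned noise rows. Base
abundances are log-normal(ln 2·10⁸, 1), placing envelope members
predominantly above the 2·10⁶ feature-detection threshold — emulating
that a real post-threshold feature list contains only detectable
compounds. Isotopologue rows are emitted when their expected proportion
reaches 10⁻⁴ (detector dynamic range); row emission considers both the
labeled and the natural envelope, since both materials contribute rows.

Not emulated: adducts and in-source fragments, chromatographic peak
shapes, between-compound enrichment heterogeneity (a per-compound
enrichment spread is biologically expected but no value is reported to
calibrate against), intensity-dependent censoring (dropout is random),
matrix effects, and NMR spectral fitting (the NMR block enters as a
concentration table). Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not robustness to every
artifact of real data.

## Numerical and protocol choices

- Filter bounds: mass window inclusive on both ends; S/N strictly greater
  than the threshold.
- Clustering: two passes — greedy lowest-mass seeding, then each non-seed
  feature joins the seed minimizing (ppm error + RT error/rt_tol); ties on
  a k-slot keep the better score, displaced features become singletons.
  `rt_tol` defaults to 0.2 min, tight relative to a 70-min gradient.
- Reported percentages round half-up to two decimals, matching the style
  of published detection summaries.
- Simulation sizes: studies of 60 species × 24 samples, flux series of 2
  jars per treatment × 10 days, 200 envelopes at 10⁴ ions for enrichment
  recovery, 1000 null datasets × 199 permutations for PERMANOVA
  calibration, 10 replicate simulations for recall and unbiasedness
  checks. These sizes give stable statistics while keeping the full suite
  fast on one CPU.

## Known limitations

- Compounds whose base mass sits near the top of the 100–1200 Da window
  can have their entire labeled envelope shifted beyond it (a 52 at-%
  label moves a 50-carbon compound ~26 Da). Such labels are undetectable
  by construction; the classification benchmarks condition on clusters
  with observable labeled-sample signal and this coverage gap is the
  price of a fixed analytical window.
- n_C estimation from the residual grid alone is weakly identified (see
  above); reliable carbon counts require either the paired-control
  envelope or external formula annotation.
- The diagnostic threshold (0.02 excess fraction) is a stand-in; with very
  large compounds (n_C ≳ 70) envelope-ratio noise approaches it, so calls
  at that extreme are less reliable.
- PERMANOVA assumes exchangeability under the null; with 2 replicates per
  cell, pairwise group contrasts cannot reach p < 0.05 and only pooled
  contrasts are informative.
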