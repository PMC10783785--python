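# Methods

This note documents the models behind `wsisurv`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data can and
cannot establish.

## Synthetic slides

A tile is a square RGB image with elliptical "nuclei" over a textured
background. Nucleus semi-axes are drawn log-normally with mean
`axis_mean = (12, 8)` px and coefficient of variation `heterogeneity`
(default 0.2); log-normal (rather than normal) keeps every length and area
strictly positive, so the min/max-rate contrast statistic is always
defined, and `heterogeneity = 0` degenerates to identical nuclei. Centers
are uniform with a margin that keeps ellipses inside the tile; when
overlaps are forbidden, placement retries up to 200 times per nucleus and
then raises a placement error rather than silently dropping nuclei.

Colors come from the same transmission model the analysis inverts:
`RGB = 256·10^(−OD) − 1` with nucleus OD `0.85·H` and background OD
`0.25·E` along the standard Ruifrok–Johnston hematoxylin/eosin vectors.
The background adds a Gaussian-blurred low-frequency luminance texture
(amplitude 6 gray levels, blur σ = size/16) so the global first-order
features are non-degenerate, plus i.i.d. pixel noise (sd 3).

What the tiles deliberately do **not** emulate: real chromatin texture,
touching/overlapping nuclei at clinically realistic densities, stain
variation between labs, multiple tissue classes, out-of-focus regions.
Segmentation scores on these tiles are therefore upper bounds: they verify
that the pipeline is *correct* (it finds what was planted, with accurate
shape), not that it would reach the same accuracy on clinical slides.

## Synthetic cohorts

Event times follow a Cox model with Weibull baseline
`h(t|x) = (k/λ)(t/λ)^{k−1} exp(βᵀx_c)`, k = 1.1, λ = 900 days — a mild
acceleration of early recurrences at a scale consistent with resected-HCC
follow-up. `x_c` are sample-mean-centered covariates, so `true_beta` reads
as log-hazard per unit of a unit-variance feature. Marker-gene expression
is multivariate normal on the log scale (66 genes, AR(1) correlation
ρ = 0.4 as a simple stand-in for co-regulated marker panels, mean 2.0
mimicking log(FPKM+1) magnitudes); simulated image features are correlated
Gaussians (20 features, ρ = 0.3) unless actual tiles are supplied, in which
case the 153-feature extraction runs per patient.

Censoring is the minimum of an exponential loss-to-follow-up time and a
10-year administrative cap, mirroring the two censoring mechanisms of a
retrospective registry cohort without distinguishing their causes. The
default rate (1/1080 per day) was calibrated once, as part of the generator
design, to give a realized event fraction near 53% at the default effect
sizes — the event rate of the motivating cohort scale (231 patients).
Default effects are sparse — three genes (+0.45, −0.45, +0.40) and one
image feature (−0.55) — mirroring a four-variable final model with both
protective and hazardous markers; at these defaults the stacked integration
reaches a test C-index in the mid-0.6s, the regime the method is meant to
operate in.

All randomness flows through named substreams ("placement", "stain-noise",
"expression", "survival", "wsi-sampling", "cv-folds", "splits",
"permutation") of one master seed, so any stage can be regenerated
independently and every result is reproducible from (params, seed).

## Image feature extraction

*Global features.* Tissue is the darker Otsu class of the ITU-R 601 luma,
closed with a 3-px disk. The foreground block maximizes tissue coverage
over a stride grid (stride = block/4, first maximum wins); block and ROI
sides adapt to the image (block capped at 4000 px, ROI at 1000 px, never
upscaled). The ROI is an area-averaged 8-bit gray image summarized by the
standard 18-statistic first-order panel; histogram statistics (entropy in
bits, uniformity) use a fixed bin width of 25 gray levels.

*Nuclei.* Color deconvolution uses `OD = −log10((I+1)/256)` and the
unit-normalized H&E stain matrix (third row = orthogonal residual), with
negative concentrations clipped. Segmentation sharpens the lightly
smoothed H channel with a 3×3 Laplacian, takes the bright Otsu class,
intersects it with a local Gaussian-mean adaptive threshold (window 51 px,
offset 2 gray levels), applies opening (1-px disk) and hole filling, and
keeps connected components with area ≥ 40 px that (a) carry real
hematoxylin (mean H OD ≥ 0.15 — rejects background-texture blobs, which
have essentially zero H) and (b) do not touch the block border (clipped
shapes would corrupt min-based contrast features). Ellipse and convex-hull
fits feed descriptors only; the pixel mask is never altered by them.

*Descriptors.* 27 per nucleus: area, perimeter, perimeter/area, equivalent
diameter, circularity, convex area, solidity, convexity, extent,
eccentricity, fitted major/minor axis, aspect ratio, ellipse-fit residual,
max/min Feret diameter and their ratio, bounding-box aspect, compactness,
2-D sphericity, and the seven Hu-moment magnitudes exported as
`log10(|m|+1e−12)+13`. Everything is floored at 1e−6 so all descriptors are
strictly positive and `mrate = min/max ∈ (0, 1]` for each of them, with
`mrate = 1` exactly iff the descriptor is constant across sampled nuclei.
Aggregation uses the population sd (a single nucleus has sd 0). Twenty
random blocks × up to twenty random nuclei per block (all, if fewer) are
pooled per slide; a slide with zero nuclei across all blocks is flagged as
an error, never imputed.

## Survival modeling

The Lasso-Cox path is glmnet-style coordinate descent
(scikit-survival's Coxnet): 100 log-spaced penalties from the null-model
penalty down to 0.001 of it. Features are standardized internally and
coefficients returned on the original scale. The penalty minimizing the
mean 3-fold cross-validated partial-likelihood deviance
(Verweij–van Houwelingen: −2·[ℓ(all) − ℓ(train)] per fold) is selected —
the minimum rule, not 1-SE, with ties going to the larger penalty. Event
ties use Breslow's approximation inside the penalized path (what the
coordinate-descent solver implements) and Efron's approximation in all
unpenalized fits (stacking level, continuous-score hazard ratio); at the
event-tie rates of this data the numerical difference is negligible.

Stacking fits the unpenalized second-level Cox on the *same* training
split that produced the domain scores; this reuses training data twice and
is therefore mildly optimistic on the training side — test-split metrics,
which all reported numbers use, are unaffected. Domain scores with zero
variance (fully shrunk base models) are dropped from the second level; if
the unpenalized fit fails to converge a small ridge (0.1) is used as a
fallback. Interaction terms, when enabled, are pairwise products of domain
scores, not of raw features.

The Harrell C-index counts pairs where the shorter observed time ends in an
event; concordance 1, score ties ½, and it raises when no pair is
comparable. The time-dependent AUC is cumulative/dynamic with censoring
weights from the training Kaplan–Meier, evaluated on deciles of training
event times between the 10th and 80th follow-up percentiles (clipped to the
test follow-up range); its summary is the unweighted grid mean. Final-model
selection takes the simplest model (fewest nonzero coefficients, both
stacking levels counted) among those with test C-index in the inclusive
[median, Q3] interval of the splits — linear-interpolation quantiles; with
at least two splits the interval always contains a realized value.
Permutations reshuffle whole (time, event) rows against the covariates, so
the marginal censoring pattern is preserved; the null normal is
moment-matched and the p-value is the one-sided upper tail.

## Stratification

The sample median (midpoint of central order statistics for even n) splits
the cohort, ties at the median going to the lower-risk arm; with distinct
scores the arms differ by at most one patient (116/115 at n = 231).
Kaplan–Meier bands use Greenwood variance on the log(−log) scale — chosen
for comparability with standard survival software, since the band method is
otherwise a free choice — and the median CI inverts the band
(Brookmeyer–Crowley). The log-rank test is the two-group 1-df
hypergeometric-variance form; the continuous-score hazard ratio is a
univariate Cox fit with Wald CI.

## Problem sizes and defaults used in tests

Tests and the reproduction script run everything at desk scale, chosen as
sizes at which each property is statistically decidable: tiles of
320–1024 px with 20–150 nuclei; cohorts of 231 (pipeline conditions), 1000
(support recovery), 2000–5000 (consistency and closed-form checks);
repeated-split evaluation at 5–20 splits; the permutation null at 20
permutations × 5 splits with a 30-penalty grid. These are deliberate
scale-downs of the full design (20 splits, 100 permutations, 100
penalties), which the API exposes unchanged.

## Known limitations

- Synthetic tiles are far easier than clinical H&E; segmentation metrics do
  not transfer to real slides without revalidation.
- The cohort generator has no unmeasured confounding, no treatment effects,
  no non-proportional hazards and independent censoring by construction.
- The stacked second level is fit without an internal validation split.
- Statistical comparison *between* integration modes is out of scope: the
  20 test sets overlap, so split-level C-indices are not independent.
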