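# Methods

## Generative cohort model

Each dosimetric quantity q ∈ {TV, TLV, TD, THLD} is modelled independently
on the log scale:

    log x_ijq = μ_q + B_iq + b_jq + E_ijq,
    B_iq ~ N(0, σ_b,q²),   E_ijq ~ N(0, σ_w,q²),

with i the treatment, j the observer, b_jq a fixed per-observer bias
(default 0).  THLV is always derived as TLV − TV per row, never simulated.
Multiplicative (log-normal) observer error is an assumption, not an
observed fact: no published multi-reader dosimetry dataset characterizes
the error distribution.  It is the natural choice here because the
reproducibility coefficient is a max/min *ratio* statistic, which is only
scale-free under multiplicative error, and because all four quantities are
strictly positive with SDs comparable to their means (so additive normal
error would produce negative volumes/doses at realistic spread).

**Calibration.**  μ_q and σ_b,q are derived from natural-scale marginal
targets typical of an HCC glass-microsphere series — TV 179 ± 208 ml,
TLV 1749 ± 507 ml, TD 238 ± 120 Gy, THLD 45.3 ± 30.2 Gy — by moment
matching of the log-normal (σ_total² = log(1 + (SD/mean)²),
μ = log(mean) − σ_total²/2, σ_b² = σ_total² − σ_w²).  The default
observer-error SDs are pinned at

    σ_w: TD 0.14, THLD 0.05, TV 0.18, TLV 0.02,

which encode the defining feature of multi-reader liver dosimetry: tumor
quantities (manual slice-by-slice contours, misregistration corrections)
carry several times the observer error of whole-liver quantities
(semi-automated organ segmentation).  These values are calibration, not
ground truth; for small σ_w the implied pairwise CV is ≈ 100·σ_w percent
and the implied RDC is exp(3.31·σ_w) for three observers (≈1.59 for TD,
≈1.18 for THLD).

**Degenerate draws.**  A draw with TV ≥ TLV for any observer is resampled
(whole treatment row, bounded retries with a warning); systematic failure
raises an error naming the parameters as incompatible.  Under the default
calibration roughly 0.3% of treatments are resampled.

**Optional correlation knob.**  `tv_thld_error_corr` couples the TV and
THLD observer errors (a larger tumor contour removes hot voxels from the
healthy liver, so the two errors are physically linked).  It defaults to 0
because no joint covariance has been published to calibrate it against.

## Voxel phantoms and dosimetry

Phantoms live on a (z, y, x) voxel grid, default 4 × 4 × 4 mm.  The liver
is an axis-aligned ellipsoid (defaults sized to ~1.7 L), tumors are spheres
fully inside it (a second lesion appears with probability 0.24, mirroring
the multifocal fraction of typical cohorts; per-lesion masks are combined
by union at extraction).  Activity is partitioned voxel-wise with
tumor:liver uptake ratio r (tumor voxels get weight r, healthy voxels 1,
then normalized to the injected activity, default 1.98 GBq; lung shunt is
fixed at 0).  Optional seeded log-normal voxel texture emulates microsphere
clustering (the phantom pipeline default is σ = 0.25); optional Gaussian
blur (FWHM 8 mm, off by default) emulates PET resolution.  Both preserve
total activity.

Dose uses the **local-deposition method** — each decay deposits its energy
in its own voxel:

    dose = K · activity / (ρ · voxel volume),
    K = E_mean · T½ / ln 2 = 0.9267 MeV · 1.602177e-13 J/MeV
        · (64.05 h · 3600 / 0.693147) · 1e9 decays/(s·GBq)
      = 49.39 J per GBq,

with tissue density ρ = 1.05 kg/L (configurable).  Energy conservation
(Σ dose·mass = K·Σ activity) holds to float round-off by construction and
is asserted in the tests.  No dose kernel, scatter, or partial-volume
modelling: the point of the phantom layer is to propagate *segmentation*
differences into dose differences, not to reproduce PET physics, which is
out of scope.

**Observer emulation.**  Each observer's mask is the true mask after (1) a
signed morphological margin (6-connected dilation/erosion; non-integer
margins apply the fractional part as a seeded random subset of the next
boundary shell, giving sub-voxel systematic over-/under-contouring), then
(2) random flips of boundary voxels, then (3) re-clipping of tumors to that
observer's liver.  Pipeline defaults: tumor margins (0, +1, −1) per
observer plus N(0, 0.4) per-case jitter and flip probability 0.25; liver
margins 0 plus N(0, 0.18) jitter and flip probability 0.05.  These produce
liver-volume CVs of ~2% and tumor-volume CVs of ~25–35%, the ordering that
characterizes real multi-reader data.  Volumes are voxel count × voxel
volume with no partial-volume weighting, matching the granularity of
slice-wise manual contouring.

## Agreement battery

* **ICC.**  The variant is two-way random effects, absolute agreement,
  single rater — ICC(A,1): observers are treated as a random sample of
  possible readers and systematic observer offsets count against
  agreement, which is what matters clinically.  Estimate and 95% CI come
  from the mean squares of the treatments × observers layout (McGraw &
  Wong F-based interval, Satterthwaite df).  The variant label is stored in
  the result so alternates can be compared.  Perfect-agreement matrices
  (zero residual and observer mean squares) return estimate 1 with the
  degenerate CI (1, 1); zero total variance is an error.  n < 5 sets a
  low-n flag rather than refusing.
* **CV.**  Root-mean-square within-pair CV (the standard test-retest form
  for ratio-scale data): scale-invariant, zero iff the two series are
  identical.
* **Bland–Altman.**  Multiplier 2 (not 1.96) on the SD of differences —
  the convention used when the limits are drawn on the plots this mirrors.
* **RDC.**  Log-transform; σ̂_w² is the one-way random-effects residual
  mean square (equivalently the mean of per-treatment variances across
  observers), so fixed observer bias inflates σ̂_w — intended, since the
  statistic describes the spread between *actual* readers.  The 95th
  percentile of the range of k standard normals is computed by numeric
  quadrature of the range CDF
  F(r) = k ∫ φ(u)[Φ(u+r) − Φ(u)]^{k−1} du (3.3145 for k = 3, and
  √2·z₀.₉₇₅ = 2.7718 for k = 2, the closed-form cross-check).  The CI is a
  seeded nonparametric bootstrap over treatments (percentile method,
  B = 2000 default) — the construction is a package choice, as no standard
  interval exists for this estimator.  An empirical cross-check (the 95th
  percentile of per-treatment max/min ratios) is kept in the tests as an
  independent oracle, not as the estimator.
* **Location tests.**  Shapiro–Wilk per observer column; the parametric
  family (paired t per pair + additive two-way ANOVA observer effect) is
  used only when *all* columns pass at α = 0.05, otherwise Wilcoxon
  signed-rank + Friedman.  With one reading per cell the two-way layout has
  no estimable interaction, hence the additive model.  All-zero pairwise
  differences are reported as degenerate flags, not p-values.  Pairwise
  p-values are raw by default; a Bonferroni switch exists and defaults off.
* **Concordance.**  A treatment is discordant under a rule iff its
  observers' target-reached classifications are not all equal.  Inequalities
  are strict; a value exactly at the cutoff counts as target-not-reached
  (a determinism convention — continuous doses never hit the cutoff
  exactly in practice).

## Pipeline and determinism

Two entry modes (`table`, `phantom`) share the analysis stage, so the
statistics core is testable without the imaging layer.  Every run is fully
determined by the config (which embeds the seed): the cohort draw, the
phantom geometry stream (per-treatment child seeds from a SeedSequence),
the perturbations and the bootstrap all derive from it, and the JSON report
records the config, its SHA-256 hash, the seed and the package version.
The only non-reproducible field is the timestamp.  Reports embed units on
every quantity block; table input is validated (schema, complete blocks,
positivity, TV < TLV, THLV = TLV − TV within 0.5 ml — a tolerance for
rounded exported volumes) with named error types, and the CLI exits
non-zero on validation failure.

## Problem sizes and what the tests show

The default study design is 25 treatments × 3 observers, matching the
cohort scale this kind of analysis is run at; recovery tests use larger
simulated cohorts (n = 500–10,000) where Monte-Carlo error is small, and
repeated-run checks use 100 seeds at n = 25.  Passing tests demonstrate
that the estimators recover the generative parameters of *this* model —
log-normal, complete blocks, independent quantities — and that the voxel
pipeline propagates segmentation perturbations into the expected
variability ordering.  They do not show that real observer error is
log-normal, that real segmentation differences are morphological-plus-noise,
or that the calibrated σ values equal any particular clinic's; with
heavy-tailed real errors the variance-component RDC will understate the
empirical max/min ratio.

## Known limitations

* No intra-observer (repeat-reading) analysis and no per-lesion dosimetry.
* Quantities are simulated independently in table mode; real TV/TD/THLD
  readings are correlated through the shared contours (the phantom mode
  does induce these correlations mechanically).
* The phantom layer does no PET reconstruction, registration, or CT
  simulation; the "injected liver" thresholding step of clinical practice
  is not reproduced.
* ICC is computed on the natural scale (as practitioners do); under the
  log-normal model its large-sample value is (e^{σ_b²}−1)/(e^{σ_b²+σ_w²}−1),
  marginally below the log-scale ratio σ_b²/(σ_b²+σ_w²) — at the default
  calibrations the difference is under 0.01.
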