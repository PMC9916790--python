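# Methods

This note records the models, parameter choices and limitations behind
`thyromsi`. It documents what the code computes and why the defaults are
what they are; every empirical number quoted here is one the test suite or
`scripts/acceptance.py` computes itself.

## Data model

A datacube is a set of pixels on a 0-based integer grid, each with one
profile-mode mass spectrum. Continuous-mode data share a single m/z axis
(the only acquisition mode supported; the synthetic instrument emulates a
TOF acquiring m/z 700–3000). ROI annotations are per-pixel region labels
(`NIFTP`, `HP`, `THYP`, unannotated) plus nodule ids restricted to nodular
regions, and a nodule → RAS-status table. Readers reject invalid files
(non-ascending m/z, out-of-range masses, shape mismatches) rather than
repairing them, because every downstream stage assumes the invariants.

The on-disk text dialect (JSON header line + TSV of
`pixel_x, pixel_y, mz, intensity`) exists to make fixtures diffable and
hand-editable; imzML is supported for interoperability. ROI masks are
stored as one-character-per-pixel grids with a parallel nodule-id grid —
a pixel grid rather than polygon records, so that any mask, however
irregular, round-trips exactly.

## Synthetic study generator

The generator is the package's validation instrument: it produces data
whose statistical structure matches what the analysis assumes, with the
truth recorded.

**Spectral model.** Each pixel spectrum is

    s(m) = T · [ Σ_p A_p(region) · exp(−(m − μ_p)² / 2σ_p²) + b(m) + ε(m) ]

truncated at zero, with Gaussian peaks (σ = 0.3 Da by default, TOF-like at
this mass range), a smooth baseline b(m) (exponentially decaying sum of
long-period cosines, amplitude 3, length-scale 400 Da — smooth at the
TopHat structuring scale by construction), white noise ε (sd 1.0) and a
log-normal per-pixel factor T (mean 1, CV 0.2). T models per-pixel
ablation/ionisation efficiency and therefore multiplies the *whole*
measured spectrum, noise included; this makes total-ion-current
normalisation exactly the right correction. (With noise added outside the
factor, a pixel's total is T·C + K where the noise-floor term K dominates
a sparse 30-peak spectrum ~3:1; TIC normalisation then cancels only ~25 %
of the variation and chance region-level imbalances in the drawn factors
leak into every feature. The multiplicative placement is the physically
sensible choice and avoids attributing that artefact to the analysis.)

**Study layout.** 60×40 grid; a hyperplastic-nodule band (520 px),
nine NIFTP discs (377 px total) and surrounding parenchyma as the
remainder (1503 px). Nodules 1–4 are planted RAS-mutant, 5–8 wild-type;
nodule 9 is RAS-mutant by genotype but built from a RAS-profile core under
a wild-type-profile rim of near-equal area — the synthetic analogue of a
histologically mixed bilateral case.

**Peptide panel.** 30 tryptic peptides. Eight are differential between
NIFTP and HP: the four RAS-interactome signature genes (PPIA 1505.83,
ATP1A1 1584.90, CANX 1002.40, BCAP31 944.50 — elevated in all NIFTPs and
doubly so in RAS-mutant nodules), two NIFTP markers (RBMX 815.39,
PRDX1 894.42) and two nodule-suppressed signals (SFPQ 952.35,
HNRNPM 1063.57, high in HP). Two collagens (COL1A1/COL1A2) mark the
parenchyma, four housekeeping-like peptides are redistributed *within*
NIFTP (down in RAS-mutant, up in wild-type, pooled mean equal to HP —
nulls for the pooled comparison), and sixteen peptides are flat
everywhere. The four region profiles are configured to equal total signal
(940 intensity units each), so region totals differ only instrumentally
and TIC normalisation cannot conflate total-abundance differences with
per-peptide ones. Real tissue is not TIC-balanced; this is a deliberate
simplification so that recovery tests isolate the per-feature statistics
(see *Limitations*).

**Ground truth.** A peptide is differential for a region pair iff its
configured label-level means differ (NIFTP's mean taken unweighted over
its RAS/WT profiles). The generator also exposes the expected sampled apex
(configured amplitude × the Gaussian factor of the sub-grid-step snap) and
a closed-form population AUC under the additive-noise model (normal CDF of
the profile-mean gaps, mixed over profile weights) — exact with TIC and
baseline off, a close approximation otherwise.

**Companion tables.** The identification table carries one synthetic
tryptic sequence per panel peptide with measured m/z jittered uniformly
within ±50 ppm of theoretical, plus three extra same-gene peptides
co-matching signature features so the four common interactors carry seven
identified peptides in total. The interactome gives both baits the
four-gene common core, disjoint shares of the remaining panel, and decoy
identifiers. The cohort table reproduces the published ten-nodule series
verbatim (nine patients; one contributed bilateral nodules).

## Preprocessing

Order of operations: TopHat per pixel → TIC normalisation → peak picking
on the dataset mean spectrum → apex extraction → spatial denoising of the
feature matrix. Denoising the small matrix rather than the raw profiles is
the cheaper and more testable placement; the chain exposes the choice.

* **TopHat** subtracts the morphological opening (erosion–dilation with a
  flat element, edge-replicated). Output is pointwise in [0, input] and
  invariant to additive constants. Default width 101 m/z points (25 Da ≈
  5× the widest expected peak); a narrower element would eat peak flanks,
  a much wider one would track baseline curvature poorly.
* **TIC normalisation** rescales each pixel to a common total; the default
  target is the dataset mean TIC so intensities keep their scale. A
  zero-total pixel is an error naming the pixel, not a silent skip.
* **Peak picking** detrends the mean spectrum with a 51-point running
  median, estimates noise as 1.4826 × MAD of the detrended residual, and
  keeps local maxima ≥ `snr_min` × noise (≥ 1 Da apart). Default
  `snr_min` = 5: with ~2400 averaged spectra the noise floor is ~σ/50,
  and over a 9201-point axis a 3σ cut would admit several pure-noise
  maxima by multiple comparison (expected count ≈ points × P(N > 3σ) ≈
  12), while 5σ ≈ √(2 ln n) admits none and every planted peak clears it
  by two orders of magnitude. Apex positions are refined by three-point
  log-parabolic interpolation, which is exact for Gaussian peaks; on the
  default cube the refined positions land within ~1 mDa (≲ 1.5 ppm) of
  the planted masses — what makes 100-ppm identity transfer meaningful
  from a 0.25 Da grid.
* **Extraction** takes the per-pixel maximum within ±0.25 Da of each
  candidate, after merging candidates closer than 2×tol (keeping the
  higher mean apex). **Denoising** replaces each value by the median over
  the edge-truncated (2r+1)² neighbourhood, r = 1 by default; radius 0 is
  the identity.

## Segmentation

Bisecting K-Means always splits the leaf with the largest within-cluster
sum of squares (ties by size), using scikit-learn 2-means with 10
restarts; all randomness derives from an explicit seed. The WCSS rule is
one of several defensible bisection targets; it greedily maximises
inertia reduction. The `correlation` metric row-standardises pixel
vectors first, grouping spectra by shape irrespective of overall
intensity. PCA drops zero-variance features, then centres and (by
default) unit-variance scales before a full SVD.

## Discovery

Pixels are pooled across nodules within a region label — the unit of
observation is the spectrum, as in pixel-level imaging analyses. This
pseudo-replicates nodules; a `per_nodule` mode (mean per nodule first) is
provided but off by default to match the pixel-level convention, and the
p-values should be read accordingly. Significance is the symmetric
published rule (AUC ≥ 0.75 or ≤ 0.25, p ≤ 0.001, raw); a
Benjamini–Hochberg column is informational only. The exact Wilcoxon route
is used for pooled sizes ≤ 20 without ties, otherwise the
continuity-corrected, tie-corrected normal approximation. The two routes
agree within 0.01 at the hand-over sizes (pooled 18–20); at very small
sizes (e.g. 3+3) the normal approximation deviates from exact enumeration
by up to ~0.04 at extreme statistics, which is a property of the
approximation itself — hence the size-dependent routing.

## Identification

[M+H]⁺ masses are monoisotopic residue sums (via pyteomics) plus water
and one proton; modifications are explicit named mass shifts, with the
FFPE formaldehyde-chemistry shifts carried as nominal +12.000 / +30.011 Da
(configurable — their exact values are protocol-dependent). Matching is
strict (< tolerance, default 100 ppm) against the LC–MS/MS *measured* m/z
(the denominator), because both sides of the comparison are measurements;
matching against theoretical masses is an option. Candidate sets grow
monotonically with tolerance by construction.

## Proteogenomic signature and nodule calls

Identified genes are intersected with every bait's interactor set
(exclusive Venn counts are emitted alongside). Only uniquely identified
features whose gene lies in the intersection enter the signature, which
keeps one feature per gene: by default the most discriminative one
(largest |AUC − 0.5| from the discovery pass), ties to the lower m/z; a
lowest-ppm rule is available. NIFTP pixels are then re-clustered with
2-means on signature features only. The cluster with the higher mean PPIA
feature intensity is oriented as the RAS-like pole (PPIA is selectively
elevated in RAS-mutant nodules); each nodule is called from its pixel
fractions, with calls below a 0.7 dominance threshold flagged MIXED. The
threshold is a reporting choice: it must sit clearly above ½ (so noise
cannot flip a homogeneous nodule to MIXED) and clearly below 1 (so a
half-and-half nodule is not forced into a class); 0.7 makes a 54/46
core/rim composition report as MIXED while 8 homogeneous nodules report
their class, and it is configurable.

Cohort statistics separate patient-level quantities (age, sex — a
bilateral case de-duplicated by patient id) from nodule-level ones
(diameter, mutation tallies); percentages are recomputed from raw counts.

## Validation on the synthetic study (seed 42)

The acceptance suite checks, end to end: all 30 planted peptides surface
as exactly 30 features within one peak-sigma of their masses; TIC sums
conserve to 1e-9 relative; the 8 planted differential peptides — and none
of the 22 nulls — pass the significance rule; the null rate of p ≤ 0.001
stays ≤ 0.002 over 10,000 simulated null features; 3-region bisecting
K-Means reaches ARI ≥ 0.9 against the planted labels; the 7 signature
peptides reduce to a 4-entry signature; and the signature classifier calls
all 8 pure nodules correctly while flagging the mixed nodule. Problem
sizes (2400 pixels, 30 features, 9 nodules) were chosen as the smallest
cube on which all planted effects are statistically unambiguous
(≥ 200 pixels per region for the rank tests).

## Limitations

* The generator omits isotope envelopes, charge states > 1, detector
  saturation, mass-calibration drift and within-region intensity
  gradients (except the configured core/rim device). Peak shapes are
  Gaussian; real TOF peaks are asymmetric. Additive white noise is a
  stand-in for undocumented detector noise.
* The TIC-balanced panel means the tests do not probe how TIC
  normalisation behaves when regions genuinely differ in total peptide
  load; on real tissue, normalisation can transfer total-abundance
  differences into individual features.
* The spatial median filter is an explicit stand-in for proprietary
  denoising in commercial software; at region boundaries it votes
  convex-corner pixels toward the surrounding tissue (visible as the
  ~0.99 rather than 1.0 segmentation ARI).
* Passing recovery tests on this generator demonstrates correctness of
  the implementation under its stated model, not performance on real
  spectra; pixel-level p-values inherit the pseudo-replication caveat
  above.
* Processed-mode imzML, vendor raw formats and per-pixel mass
  recalibration are out of scope.
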