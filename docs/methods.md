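# Methods

## Data model and preprocessing

A study is a collection of sections; each section is an `MSIDataset` with a
pixel grid (0-based, x = column, y = row; imzML's 1-based coordinates are
shifted on read), an m/z axis, a per-pixel intensity matrix, section
metadata (biological sample, technical replicate — which equals the
measurement day in the supported design — and treatment arm), and a
closed-vocabulary ROI mask (`tumor`, `necrosis`, `off_tissue`,
`excluded`).  Continuous-mode imzML is the primary path; processed-mode
spectra are binned onto a uniform axis (0.1 Da over m/z 500–1300, nearest
bin, intensities summed) before any cross-pixel statistics, which keeps
per-bin means and CVs well defined.

TIC normalization scales every pixel to the *dataset-mean* total ion
count rather than to 1.  This keeps intensities on a count-like scale so
that the master-list gate "mean intensity > 1" retains meaning; the gate
threshold is scale dependent and meaningless after normalizing to unit
TIC.  Zero-TIC pixels are left untouched and counted.

Peak picking operates on baseline-corrected ROI mean spectra.  The
baseline is a rolling minimum (5 Da) smoothed by a rolling mean (5 Da);
output is clipped at zero, with a global-minimum fallback when the window
exceeds the axis.  Noise is estimated per bin in a sliding 10 Da window
as max(MAD × 1.4826, P84.1 − median): the MAD term is the standard robust
sigma, and the one-sided percentile term protects zero-inflated windows
(clipping concentrates > 50 % of values at zero, where the MAD collapses
and would otherwise admit noise spikes with spurious S/N).  Local maxima
pass when S/N ≥ 10, intensity ≥ 0.14, and intensity ≥ rel_min × base
peak (rel_min defaults to 0); the reported m/z is the intensity-weighted
centroid over the apex's FWHM support, and secondary maxima inside the
support of a larger accepted peak are removed as shoulders.  The
"picking height" parameter is interpreted as centroiding at the apex
(100 % height); the exact semantics in the original desktop tool are not
recoverable, and apex centroiding is the simplest faithful reading.

## Master peak list

All ppm comparisons use one tolerance (220 ppm), matching the observed
inter-section calibration drift.  Clustering is single-linkage over the
pooled sorted masses, breaking where the gap between consecutive values
exceeds the tolerance relative to the smaller value: deterministic,
order-free, and equal to the transitive closure of all pairwise ≤ 220 ppm
relations (property-tested against a brute-force union-find oracle).
Chains can therefore span more than 220 ppm end to end; the span is
recorded per cluster.  Cluster representatives are intensity-weighted
mean masses, favouring high-signal calibration.

Per biological sample, three candidate routes feed the list: tumor-common
masses (present in all technical replicates, intensity CV < 45 %),
necrosis-common masses (same rule), and log₂FC-consistent masses
(present in both regions in all replicates, CV of the per-replicate
log₂(tumor/necrosis) < 60 %).  CV uses the n−1 denominator and the
absolute mean (fold changes are signed); a zero mean makes the CV
undefined and fails the gate.  Boundary semantics are strict throughout:
CV < 45/60, AUC > 0.9, mean intensity > 1; "at least two biological
samples" is inclusive.

Matrix-derived ions are removed when the ROC AUC of off-tissue versus
on-tissue pixel intensities (Mann–Whitney rank formulation, ties ½)
exceeds 0.9 *and* the off-tissue mean is higher.  Isotope removal scans
ascending: a peak is dropped when a retained peak sits 1.00335 Da below
it (within tolerance) with strictly greater intensity, so monoisotopic
peaks always survive and a larger peak above a smaller one is treated as
a chance overlap.  The original workflow's manual "low-quality signal"
inspection is automated as a detection-frequency gate: masses detected
(above the absolute-intensity threshold) in < 1 % of the contributing ROI
pixels are dropped.  One shared configuration drives both the per-sample
pass and the final re-check on the assembled list.

## CV reproducibility metrics

The whole-dataset CV is computed per mass by first averaging the section
mean intensities over the biological samples within each measurement day
and then taking the CV across the three day-level means; the report is
the mean ± SD over masses.  This is the only reading of the source
procedure that yields one CV per mass, as the reference table prints;
the alternative per-sample averaging wording is ambiguous.  Interday and
intraday CVs take three sections of one biological sample (different
days / same day) and compute the per-mass CV across their section mean
intensities.  All CVs are scale invariant by construction.

## Tumor vs necrosis: iterative subsampled LMM

MSI pixels are spatially autocorrelated, so a pixel-level test with
nominal degrees of freedom is anti-conservative.  Per technical
replicate, the pipeline therefore draws 1 % of the tumor and necrosis
pixels (stratified per section and region, at least one pixel each),
fits, per mass, `intensity = β₀ + β₁·1[tumor] + u_sample + ε` with
`u ~ N(0, σ_b²)` by REML, BH-adjusts the Wald p-values across masses
within the iteration, and repeats 100 times; reported values are means
(and ranges) over iterations.  Fold changes are computed from the drawn
pixel means, not from β₁, and intensities enter untransformed — log₂FC
and the LMM p are deliberately separate quantities.

The random-intercept REML fit is implemented natively: β and σ² have
closed forms given the variance ratio ψ = σ_b²/σ², computed from group
sums, and the profiled REML criterion is minimized over log ψ with a
bounded 1-D search.  This runs in ~1 ms against ~50 ms for a
general-purpose mixed-model fit, which matters at 100 iterations × masses
× replicates; the implementation is validated in the test suite against
statsmodels' `MixedLM` (coefficients to 1e-4, p-values to 5e-3) and by
type-I (rejection rate 0.03–0.07 at α = 0.05 under the null) and power
simulations.  When ψ̂ collapses to zero — or only one group is present —
the fit degenerates to OLS and is flagged.  p-values use the normal
(Wald) reference, as is conventional for mixed models at these sizes.

A mass is called significant when |mean log₂FC| > 0.5 and mean adjusted
p < 0.05 in at least two technical replicates with a consistent sign;
sign conflicts leave the mass uncalled and flagged.

## Treated vs control

The Wilcoxon rank-sum test compares the tumor-ROI mean intensities of
the treated sections against the control sections within each technical
replicate (exact null distribution for ≤ 10 per group without ties,
normal approximation with tie correction otherwise; a fully tied input
returns p = 1; the test is skipped with adjusted denominators when an
arm has fewer than three sections).  Arm fold changes are
log₂(mean treated / mean control), so positive means treated-up.  The
per-sample AUC contrasts a biological sample's tumor pixels (own arm as
positive class) against all opposite-arm tumor pixels of the same
replicate on equally sized subsets of 15 000 spectra (all pixels, with a
warning, when fewer); this resolves the inherent ambiguity of assigning
an arm-level contrast to a single sample.  A marker requires Wilcoxon
p < 0.05 in ≥ 2 of the available replicates *and* AUC ≥ 0.7 in ≥ 2/3
replicates for ≥ 3/4 samples of one arm; the reported AUC averages the
qualifying replicate values.  Wilcoxon p-values are left unadjusted, as
in the source workflow.  PCA of the section × mass tumor mean-intensity
matrix uses SVD of the column-centered data; constant columns are
dropped with a warning, and each component is oriented so its
largest-magnitude loading is positive.

Randomness fans out from one master seed per (stage, technical
replicate) through numpy's sequence seeding, so results are reproducible
and independent of execution order.

## Lipid annotation

Monoisotopic masses are sums of most-abundant-isotope masses (C, H, N,
O, P, S, Na) computed with pyteomics.  Adduct deltas subtract the
electron mass (0.000549 Da ≈ 0.7 ppm at m/z 800 — without it the strict
tier is unreachable): [M+H]⁺ = M + 1.007276, [M+Na]⁺ = M + 22.989221,
[M+H−H₂O]⁺ = M − 17.003288.  Matches within 10 ppm are tiered: < 1 ppm
(`sub_ppm`), 8–10 ppm (`loose`), otherwise `within_10`; unmatched masses
report `none`.  The bundled table holds the curated species of the
reference master list plus ~290 decoy glycerophospholipids and
sphingomyelins generated from standard class composition rules
(e.g. PE x:y = C₅₊ₓH₁₀₊₂ₓ₋₂ᵧNO₈P); species never observed experimentally
are flagged `theoretical_only`.  No online database is queried.  Note
that "PI 20:1" in the reference list only reproduces its printed
accurate mass as the *lyso* species (C₂₉H₅₅O₁₂P, [M+H−H₂O]⁺ = 609.3399).

## Synthetic study generator

The generator emulates the supported design: 8 biological samples
(4 treated, 4 control) × 3 technical replicates measured on different
days, 40 × 40 pixels per section, m/z 500–1300 at 0.1 Da.  Each section
has an off-tissue border ring, a contiguous necrosis disc (jittered
center), a tumor band around it (up to the configured fraction), and a
mixed margin labeled `excluded`.  Per lipid and pixel,

    intensity = base · 2^(Δtn·1[tumor]) · 2^(Δarm·1[treated]) · d_{ℓ,day} · b_{ℓ,sample} · s_{ℓ,section} · ε_pixel

with unit-mean lognormal factors: day effects d (CV 0.20, shared across
samples within a day — a measurement session affects every slide),
biological-sample effects b (CV 0.15, giving the LMM random intercept a
real target), section effects s (CV 0.12, the intraday component), and a
spatially correlated pixel field ε (CV 0.5, Gaussian-filtered white
noise, correlation length 3 px — precisely the autocorrelation the
iterative LMM is designed to counter).  These defaults were chosen once
to reproduce the reproducibility ranges reported for this kind of FFPE
workflow (whole-dataset CV in the twenties of percent, interday roughly
twice intraday).  Peaks render as Gaussians (FWHM 0.3 Da); +1
isotopologues appear at ratio 0.4 (≈ the ¹³C M+1 fraction of a C₄₀
lipid) inheriting their parent's factors; matrix ions are present
everywhere and boosted 12× off-tissue; every section's masses shift by a
uniform ±100 ppm calibration offset (pairwise ≤ 200 ppm, inside the
220 ppm merge window by design); a Gaussian noise floor (σ 0.05) is
added and clipped at zero.

The default truth masses are the 26 masses of the bundled reference
master list, with six tumor-up lipids planted at log₂FC +1.0, two
necrosis-up at −0.8, three treated-up at +0.5 and one control-up at
−1.1.  Two high-abundance structural lipids (m/z 576.7 and 826.6)
dominate the TIC, as a few phosphatidylcholines do in real MALDI lipid
spectra; because TIC normalization divides by total signal, planted fold
changes compress by log₂ of the tumor/necrosis TIC ratio — under the
defaults < 0.06 log₂ units, visible in the worked example's recovered
values.  Base intensities cycle deterministically through 10–40 so that
neighbouring masses stay within a 2.5× ratio, keeping the (wide,
220 ppm) isotope-matching tolerance from ever flagging a true lipid 2 Da
above a much stronger one.

What the generator does **not** model: ionization suppression and other
matrix chemistry, isotope fine structure, peak-shape changes with m/z,
within-region biological gradients, and registration error between ROI
annotations and pixels.  Passing tests therefore demonstrate the
correctness and calibration of the *statistical pipeline* under a
realistic noise budget, not instrument-level fidelity.

## Problem sizes used in the test suite

The acceptance-grade checks run the full default study (24 sections,
40 × 40, 100 LMM iterations, all three replicates) for five seeds —
about 30 s per seed — sharing one set of runs across the recall/
precision, matrix-removal, fold-change-recovery and false-discovery
checks; the day/intraday ordering check uses ten seeds of a reduced
single-sample configuration, and the type-I simulation uses 1000 null
fits.  The CLI smoke tests use a 14 × 14 grid with 6 samples.

## Known limitations

* The per-sample AUC construction for arm markers is one of several
  defensible readings of the multi-replicate criterion; it is isolated
  behind `treatment_analysis` so alternatives can be swapped in.
* The iterative LMM reports the mean of BH-adjusted p-values over
  iterations; this is a summary, not a formally calibrated p-value.
* Exact Wilcoxon p-values switch to the normal approximation in the
  presence of ties even at small n.
* Processed-mode imzML is supported through binning only; no peak
  alignment or recalibration is performed.
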