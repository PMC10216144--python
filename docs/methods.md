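# Methods

## Scope and model

`clmsi` implements a cardiolipin (CL)-targeted analysis chain for negative-mode
imaging mass spectrometry of brain tissue, together with a synthetic-data
generator that emulates the tissue-class profile structure of normal cortex
and astrocytoma. The chain is: sum-composition enumeration and exact-mass
chemistry → profile-mode peak picking and centroiding → charge-state
inference from isotopologue spacing → ppm-tolerance species matching with
S/N → region-of-interest extraction and per-patient median profile matrices
→ chain-length ratio, PCA, and nonparametric group statistics. Tandem-MS
helpers assign acyl chains from carboxylate fragment ions and compute
Δ9/Δ11 double-bond isomer ratios from UVPD diagnostic-ion pairs.

### Chemistry

CL(X:Y), with X total acyl carbons and Y total C=C double bonds across the
four chains, has neutral formula **C(X+9) H(2X−2Y+14) O17 P2**;
monolysocardiolipin MLCL(X:Y) (three chains) follows by ester hydrolysis of
one acyl residue: **C(X+9) H(2X−2Y+16) O16 P2**. The dominant ion is the
doubly deprotonated dianion, m/z = (M − 2·1.00727646688)/2, where M is the
monoisotopic neutral mass (C 12 exactly, H 1.00782503207, O 15.9949146196,
P 30.97376163 Da). Fatty-acid carboxylate anions [CaH(2a−2b−1)O2]⁻ include
the electron mass.

Isotope envelopes are computed by element-wise convolution of natural
isotope distributions, aggregated at nominal (unit) mass — fine structure
is irrelevant at resolving power 70,000, where only the 1.0033548/|z|
spacing and gross abundances matter. At z = −2 the spacing is 0.50168 m/z,
the signature used to attribute CL peaks.

UVPD diagnostic pairs for a chain with one localized double bond at Δn are
modeled as the two carboxylate-retaining fragments from cleavage of the C–C
bonds flanking the double bond, separated by exactly two carbon atoms
(24.0000 Da). Terminal-atom bookkeeping convention: the lighter fragment is
the saturated carboxylate [C(n−1)H(2n−3)O2]⁻; the heavier one adds the two
hydrogen-free sp² carbons. Any consistent hydrogen-transfer convention
shifts both pair members together, so the 24-Da gap and the Δ9/Δ11
disjointness do not depend on it.

### Published identification table

Computed exact m/z values reproduce the published CL table at printed
precision once the table's rounding is matched: the printed 3-decimal
values were evidently rounded twice (5 → 4 → 3 decimals, half-up), e.g.
computed 713.49449 → printed 713.495. "Printed precision" therefore means
|Δ| ≤ 6×10⁻⁴. Three rows of the table are internally inconsistent and are
reported, not repaired:

* MLCL(52:2): printed formula C61H114O16P2 gives 581.372, but the printed
  exact m/z 582.379 matches the ester-hydrolysis rule (C61H116O16P2,
  582.3797); the other MLCL rows show similar formula/attribution
  mismatches.
* CL(78:13): printed formula C87H148O17P2 and exact m/z 762.502 correspond
  to CL(78:11); the (X:Y) attribution would give 760.487.

The (X,Y)-route exact-mass checks therefore cover the nine self-consistent
CL rows; the printed-formula route covers all rows.

## Synthetic-data generator

The generator defines the study conditions for every downstream test.

**Panels.** Normal grey matter carries 46 CL species in seven carbon-number
clusters (X = 68…80, cluster sizes 4/6/8/10/8/6/4 over Y ranges spanning
2–14 double bonds) plus 12 MLCL species (X = 50…60, Y = 1…9). Within a
cluster, abundance is a discretized Gaussian over Y (unimodal, symmetric
about the cluster mode); across clusters, a Gaussian over X centered at 74
carbons puts the global mode at CL(74:8). Astrocytoma grades 1–2 keep the
structure without the 80-carbon cluster at 0.6× overall abundance, centered
at 73 carbons. GBM retains only the 68–74-carbon clusters (21 species; both
CL(76:10) and CL(78:12) are absent, i.e. abundance exactly 0), centered at
72 carbons with mode CL(72:6), at 0.4× abundance. Pure white matter has no
CL at all (myelin-lipid ion suppression); necrotic tissue is the viable-GBM
profile at 20% abundance; infiltrating tumor is an even normal/GBM mixture.

**Chain-ratio calibration.** The abundances of the long-chain block
(X ≥ 78) are rescaled so that the *expected measured* S/N ratio
S/N(CL 78:12)/S/N(CL 72:8) equals the class target (0.48 normal cortex,
0.05 grade 1, 0.10 grade 2). "Measured" matters: at resolving power 70,000
the M+2 isotopologue of the cluster neighbour one double bond up lies only
4.5 mDa below a species' monoisotopic peak (FWHM ≈ 10 mDa) and merges into
its apex, so calibrating raw abundances alone would leave the measured
ratio several percent high. Because interference at the CL(78:12) apex
comes only from the long-chain block itself and interference at the
CL(72:8) apex only from the shorter-chain block, the block factor has a
closed-form solution from expected apex heights (sums of envelope
Gaussians). Block scaling preserves within-cluster unimodality. GBM has no
CL(78:12), so its measured ratio is ≈ 0 (the reported 0.01 for real GBM
tissue is at the noise floor of the original measurement; no attempt is
made to engineer that value, and the generator records 0 as GBM's expected
ratio).

**Rendering.** Each species contributes its z = −2 isotope envelope (first
4 isotopologues) as Gaussian peaks of FWHM = m/z / R on a shared m/z axis
(default 100–1500 at 0.003 m/z steps, R = 70,000), with peak height =
abundance × class attenuation × `intensity_scale`. Baseline noise is i.i.d.
Gaussian (mean 0, sd 1). `intensity_scale` defaults to 6000, which places
the weakest normal-cortex panel species at ≈ 15× the noise sd and the mode
near 240× — chosen so the full 46+12 panel sits above the S/N = 3 detection
threshold, the stated condition of a normal-cortex acquisition in which all
panel species are detectable. Between-patient biological variability is
per-species log-normal jitter with unit mean and CV 15% (the source data
report no inter-patient variance; this is a free parameter surfaced in
`GeneratorConfig`).

**Determinism.** `GeneratorConfig.seed` fully determines the truth tables
(profiles and jitter); the baseline noise uses a separate `noise_seed`
derived from it by default, so re-rolling noise never changes ground truth.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue: matrix/ion-suppression effects beyond the
all-or-none white-matter rule, FAIMS transmission physics (emulated only as
clean S/N), heteroscedastic and correlated (pink/shot) noise, spatial
autocorrelation within regions, isobaric interference from non-CL lipid
classes, chemical mass-calibration drift, and the actual biological
covariance between species abundances (jitter is independent per species).
The end-to-end annotation counts (46 CL / 12 MLCL) certify the annotation
chain against the generator's truth, not the biology.

## Annotation

* Noise: 1.4826 × median absolute deviation of intensities in configured
  signal-free windows (default m/z 850–1000, empty of CL/MLCL signal).
* Peak picking: local maxima above 3× noise; centroids by three-point
  parabolic interpolation on log-intensities (exact for Gaussian peaks),
  falling back to the apex sample if a bracketing intensity is non-positive
  or the interpolated apex leaves the bracket.
* Charge: for z = 3, 2, 1 (largest first, so the true M+1 partner at the
  smallest spacing wins over the M+2 peak that would also fit z = 1), the
  nearest higher-m/z centroid to seed + 1.0033548/z within 10 ppm of the
  seed m/z; no match ⇒ undetermined (a value, not an error).
* Matching: z = 2 centroids against the enumerated space (sorted by m/z)
  within 5 ppm, minimizing |ppm|; ties broken CL before MLCL, then lower
  double-bond count. One annotation per species (highest S/N centroid).
  "Detected" = S/N ≥ 3 **and** confirmed charge 2. The S/N threshold is
  this pipeline's choice — the original work never states its detection
  criterion — and is exposed in `AnnotationConfig`.
* Dataset-level detection (the per-sample species counts) uses the
  across-pixel **median** S/N ≥ threshold, the same statistic the profile
  matrix is built from; a single-pixel criterion would admit rare noise
  false positives.
* On noiseless data, recall and precision against generator truth are 1.0;
  mass errors stay below 1 ppm only for species free of the cluster-neighbour
  isotopologue overlap described above (overlapped apexes shift by ~1–2 ppm,
  comparable to the 0.4–1.7 ppm errors of the original measurements).

## Statistics

* **Chain ratio**: per patient, S/N(CL 78:12)/S/N(CL 72:8) from the median
  matrix; zero-denominator patients are excluded and counted. The source
  text calls this "short/long" yet reports it falling from 0.48 (normal) to
  0.01 (GBM) while long chains are depleted in GBM — only the long/short
  orientation makes the values and the biology agree, so that is what is
  implemented (and the numerator species is CL(72:8) at m/z 723.480 per the
  identification table, not m/z 725, which belongs to CL(72:6)). Class
  summaries use the per-patient ratio mean.
* **PCA**: log10(S/N + 1) (pseudocount for zero S/N, exposed in the API),
  column centering, no unit-variance scaling; species contribution % to a
  component is 100·loading²/Σloading². Backed by scikit-learn's SVD PCA;
  an independent eigendecomposition oracle checks it in the tests.
* **Group comparisons**: Shapiro–Wilk gate per group at α = 0.05 (a
  zero-range group counts as non-normal); all-normal ⇒ two-sample *t*
  (paired on request), otherwise Wilcoxon rank-sum (signed-rank when
  paired); all pairwise comparisons, Holm step-down adjustment.

Published tissue-scale statistics — PCA variance fractions (72.5%/10.8%,
themselves inconsistent with the 75.2% in the corresponding figure),
per-sample species medians (26/15/10), and IDH1 comparisons — depend on the
original 76 specimens and are not reproducible from synthetic data; the
suite certifies the machinery by invariants instead (mass additivity,
brute-force chain-combination and ion-image oracles, binomial isotope
oracle, Holm monotonicity, PCA centering/duplication invariance, detection
monotonicity, ratio scale invariance).

## Problem sizes

Deterministic end-to-end runs use a 20×20-pixel section (400 spectra);
cohort recovery uses 25 patients per class, each one 4×4-pixel pure-region
section — the per-patient statistic is a median over pixels, and 16 pixels
already make pixel noise negligible against the 15% between-patient CV.
With those sizes a full acceptance run completes in about two minutes.

## Known limitations

* Continuous-mode imzML only (one shared m/z axis); processed mode is
  rejected loudly.
* No sn-positional isomers, oxidized/acylated CL variants, or positive-ion
  adducts; MS³ evidence is represented only as a provenance flag.
* The charge-spacing tolerance (10 ppm of the seed m/z) and the uniform
  0.003-m/z axis are matched to the synthetic peak widths; very noisy real
  data may need wider tolerances.
* `assign_chains` requires every chain of a candidate to have a fragment
  match, so missing MS² peaks eliminate candidates rather than down-rank
  them.
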