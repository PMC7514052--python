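# Methods

## The measurement model

A field is one 2-D widefield image of an 8 μm muscle cryosection,
1388×1040 px at ~2 px/μm (694×520 μm, 360,880 μm²). Three channels are
analysed: a nuclear stain and two probe channels targeting 5' and 3'
sequence of one long transcript. Because probe-binding sequence for the
3' region emerges only minutes before transcription terminates, the 3'
channel reports essentially mature transcripts while the 5' channel
reports nascent + mature; this temporal encoding is what every
downstream quantity exploits.

Fluorescence cannot resolve the physical size of a transcript; detected
"areas" are point-spread-function footprints above threshold. They are
still discriminative: single transcripts give compact spots (the 0.5–10
μm² "small" class, mode 1–3 μm²) whereas concerted nascent transcription
deposits broad heterogeneous signal over one nucleus (the 10–100 μm²
"large" class). The size bins are half-open ([0.5, 10) and [10, 100] μm²)
because the two published ranges touch at 10 μm² and a convention is
needed; areas outside both bins are kept as `rejected` so that
total = small + large + rejected is an invariant, never a silent filter.

## Detection and compartmenting

Nuclei: automatic threshold (Huang's fuzzy-entropy method, implemented
here because scikit-image does not provide it, or Yen's method from
scikit-image), one binary watershed pass seeded from local maxima of the
smoothed distance transform, then connected components. A blank image is
zero nuclei, not an error.

Probe channels: threshold → connected components → one record per
component (apparent area in μm², background-subtracted integrated
intensity, weighted centroid). The automatic threshold is the image
median + 3·(1.4826·MAD): foci occupy a small pixel fraction, so
median/MAD estimate the background level and noise SD robustly. On a
noiseless image (MAD = 0) the threshold falls back to background + 2% of
the dynamic range so PSF tails do not merge adjacent spots. Fixed and
Otsu thresholds are available as overrides.

Compartmenting follows the masking route rather than centroid lookup:
the nuclear mask (or its inverse) zeroes the probe channel and detection
is rerun with the *same* threshold and background resolved on the
unmasked image. A boundary-straddling focus may therefore split across
compartments; the per-class |total − (nuclear + sarcoplasmic)|
discrepancy is reported, not hidden. A centroid-assignment shortcut is
deliberately not the default. Counts are reported per image and never
normalized to nuclei, because nuclear density is systematically higher
in dystrophic tissue and per-nucleus normalization would bias against it.

## Co-localization and nulls

For sarcoplasmic small foci, each 5' focus's distance to the nearest 3'
focus (and vice versa) is measured with no edge correction; summaries
report fractions within/beyond 1, 4 and 30 μm, both directions computed
separately and pooled for "fraction of all foci" statements. Two nulls
destroy cross-channel pairing at matched density:

* rotation: the target channel rotated 90° about the field centre in
  unit-square coordinates ((u,v) → (v, 1−u), rescaled), so every point
  stays in-field on a non-square camera; four applications are the
  identity.
* random: uniform point sets of matched counts in the field rectangle,
  averaged over 1000 seeded virtual fields (default).

Edge effects are part of the published null fractions, so the primary
random null is bounded. A toroidal variant exists purely as an analytic
oracle: for intensity λ, P(nearest neighbour > r) = exp(−λπr²) exactly,
and the Monte-Carlo implementation is checked against it to 3 SE.

## Intensity calibration

Small sarcoplasmic foci are single transcripts, so their
background-subtracted mean integrated intensity is the per-transcript
unit; a large focus's intensity divided by the unit estimates its
nucleus's nascent load (reported continuous and rounded; totals use the
continuous value). Quantification is restricted to exposures where
signal is linear: a through-origin fit to the two lowest exposures flags
a series saturated when the top reading falls below (1 − tolerance,
default 20%) of the prediction. Separate fluorophores make 5'↔3'
intensity comparison meaningless, so calibration is per-channel;
dystrophic large foci are calibrated against a healthy-derived unit by
default because dystrophic sections carry too few small foci.

Sampling adequacy uses the normal-approximation post-hoc size
n = (z·CV/E)² (E = 0.10, z = 1.96 at 95%): for the observed unit spreads
(CV ≈ 0.42–0.45) this gives 67–78 foci, hence the package's "70–80 foci"
rule of thumb.

Known bias: thresholded integration loses the PSF tail below threshold,
≈ threshold_excess·2πσ² per focus, which depresses the unit by ~5–10% at
default settings and slightly inflates nascent counts (large foci lose
relatively less). The per-focus recovery requirement (≤15% mean absolute
error) is met with this bias included.

## Steady-state kinetics

Assumptions: constant sequence-independent elongation (2.3 Mbp / 16 h ≈
40 bases·s⁻¹), co-transcriptional splicing, export immediately after the
3'-most probe region completes, first-order decay of mature mRNA, and
steady state. Then 5'/3' = (T + L)/L with T the inter-probe transcription
time and L the mean lifetime, so L = T/(ratio − 1), T½ = 0.693·L (0.693
kept verbatim rather than ln 2; the difference is negligible) and
nascent fraction = 1 − 1/ratio. Ratios may come from per-ng abundances
or per-field counts — both funnel into the same estimator. The default
gene model places the 5' probe region at 190–715 kb and the 3' region
ending 1,550 kbp later (~11 h apart); the alternative 1,950 kbp
separation (~13.5 h) describes amplicon-based assays near exons 1–2 and
62–63. No pausing, premature termination or circadian modulation is
modelled.

Field-to-mass normalization: field volume = area × thickness
(2,887,040 μm³ — computed, not the slightly different published rounding),
mass = volume × 1.06 mg/mm³ ≈ 3.06 μg, RNA = mass × 0.25–0.5 μg/mg ≈
0.77–1.53 ng per field.

Occupancy arithmetic: initiation interval = residence time / occupancy.
The residence time is an explicit parameter (full 16 h transit vs ~11 h
of 5'-labelled residence are both defensible readings); with 20–40
nascent transcripts per nucleus and ~11 h residence this gives one
initiation every ~20–30 min in healthy muscle.

## The synthetic-field generator

The generator is first-class, tested code; its defaults define the study
conditions rather than a tunable benchmark. Counts are Poisson draws
around configured means, placement is uniform within the allowed
compartment, and all randomness flows through one seeded generator
(equal seeds ⇒ bit-identical fields; no global state).

* Nuclei: soft-edged disks, radius 5.5 ± 0.75 μm. The radius is chosen
  so a 10–100 μm² nascent-transcription deposit can sit wholly inside a
  nucleus (sampled deposit areas are additionally capped at the host's
  area minus a 1.7 μm boundary margin, so deposits never leak into the
  sarcoplasmic pass).
* Small foci: isotropic Gaussians of σ = 0.35 μm, integrated intensity
  truncated-normal 6.0 ± 2.7 AU (AU are arbitrary linear units; the
  camera scale is not modelled). At the default threshold this yields
  apparent areas with the observed 1–3 μm² mode.
* Mature transcripts: 5'+3' pairs separated by ≤1 μm; the healthy-like
  preset plants 250 pairs + 335/460 orphan 5'/3' foci per full field
  (small-focus totals ≈585/710), so ~40% of sarcoplasmic foci pair
  within 1 μm, as observed.
* Large nuclear foci: the ground-truth transcript count (healthy-like
  20–40, dystrophic-like 8–25) is rendered as per-transcript spots
  clustered around 2–6 sub-domain centres plus a broad pedestal and one
  PSF-width transcription-site core (35% / 45% / 20% of total signal).
  Total intensity therefore equals transcripts × unit intensity by
  construction, the deposit is connected (one detected particle), and
  the bright core pixels are what clip first in an exposure series —
  reproducing the published pattern where large-focus ROIs attenuate
  above ~200 ms while small foci and background stay linear.
* Noise: Poisson shot noise (1000 photons/AU) plus Gaussian read noise
  (SD 0.05 AU) on a 2.0 AU background; at these defaults detection F1
  exceeds 0.98. Exposure series are rendered noise-free so linearity and
  clipping are exact.
* Per-field density effect: an optional lognormal multiplier on
  small-focus means (CV 0.3 in the presets) emulates the regional
  variation that makes per-image 5' and 3' counts co-vary strongly in
  healthy muscle (Pearson r ≳ 0.9); the dystrophic preset draws
  channel-independent multipliers, reproducing the weak, variable
  correlation seen there.
* Presets: per full field, healthy-like = 300 nuclei / 80 large foci
  (≈27% expressing) and dystrophic-like = 600 nuclei / 90 large foci
  (≈15% expressing), pairs ≈0, small foci concentrated in/near nuclei
  (60%). Counts scale with field area when a smaller camera frame is
  requested, preserving densities. Rare 3'-only nuclei (a short
  3'-sharing isoform in non-myonuclei) are available but default off.

What the generator does **not** emulate: 3-D structure (sections are
treated as true 2-D fields), fibre boundaries and sarcolemmal enrichment
of transcripts, macrophage-like non-specific patches, chromatic shift,
uneven illumination, and out-of-focus loss. Passing tests therefore
demonstrate correctness of the measurement operations under the stated
image-formation model, not robustness to every artefact of real
microscopy.

## Problem sizes and numerical choices

Tests run on quarter-area fields (694×520 px at 2 px/μm) with densities
preserved, 20-field detection benchmarks, 150–1000 virtual fields per
random null, and cohorts of 4 + 4 animals × 4 fields; the acceptance
script uses the full 1388×1040 px geometry and 1000 virtual fields per
null. Watershed seeds require a 5 px minimum peak separation on a
σ = 2 px smoothed distance transform (nuclei are ≥ 2 μm apart by
construction). Cohort statistics are two-tailed Mann-Whitney U tests on
per-animal means (significance 0.05) — never per-image values, which
would inflate n — and Pearson/Spearman correlations on per-image
metrics. Detection evaluation matches detections to planted centroids
greedily, nearest first, one-to-one, within 1.5 μm (1.0 μm in noise-free
exactness checks).

## Limitations

* The steady-state estimator is undefined at ratios ≤ 1 (it raises); it
  cannot distinguish slow decay from non-steady-state accumulation.
* Apparent areas, and hence the small/large split, depend on the
  threshold policy; the defaults are documented choices, not measured
  constants of the instrument.
* Straddling foci are counted in both compartments by the masking route;
  the discrepancy column quantifies the effect instead of resolving it.
* Intensity calibration assumes one fluorophore, linear gain and a flat
  background at the matched exposure; cross-channel intensity ratios are
  out of scope.
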