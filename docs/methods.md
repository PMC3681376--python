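# Methods

`thermocomplexity` quantifies the complexity of continuously monitored body
temperature in systemic inflammation and tests whether complexity features
separate noninfectious inflammation (SIRS) from sepsis and septic shock. This
note documents the models, the numerical choices, and what the synthetic
cohorts do and do not establish.

## Signals and preprocessing

A recording is a single-channel skin-temperature series sampled at 0.1 Hz
(one sample per 10 s) over about 24 h (N ≈ 8640), with a hardware resolution
of 0.05 °C. Artifact intervals (sensor contact loss, handling) are annotated
as half-open sample-index intervals; second-based annotation files are
converted with floor(start·fs), ceil(end·fs) so the mask always covers the
annotated span.

Preprocessing is fixed to the order: (1) artifact repair by linear
interpolation between the bracketing clean samples (boundary-touching masks
are filled flat with the nearest clean value, with a warning; a mask covering
the whole record is an error); (2) mean subtraction (`sign_m`), so features
are not biased by absolute temperature; (3) removal of the ordinary
least-squares line over the full record (`sign_mdetr`). Both variants are
analyzed throughout. Whether mean removal precedes artifact repair is not
observable downstream; repair-first is implemented. Automatic flagging of
single-sample jumps above 0.5 °C exists but is off by default — annotation
of real recordings is a manual step.

## Wavelet features

**Discrete transform.** Nine dyadic scales of a Meyer discrete wavelet
transform; scale *i* occupies the band [fs/2^(i+1), fs/2^i] Hz (scale 1 =
neurogenic 0.025–0.05 Hz, scales 2–3 = metabolic, scales ≥ 4 = ultradian).
The Meyer wavelet is band-limited with a closed-form Fourier transform, so
the filter bank is implemented exactly in the frequency domain: the
conjugate-mirror filter H(ω) = √2·φ̂(2ω) (with the standard ν-polynomial
transition) satisfies |H(ω)|² + |H(ω+π)|² = 2 identically, and with periodic
boundary handling the transform is orthonormal to machine precision —
Parseval's identity holds to ~1e-16 and a sinusoid's energy lands in its
nominal scale to > 95%. The widespread FIR approximation of the Meyer filter
was rejected because its truncation error (energy-conservation error ~5e-3
per decomposition) would dominate the invariants this package asserts.
Signals whose length is not a multiple of 2^9 are reflection-padded at the
end (8640 → 8704); the padded samples stay in the coefficient vectors and
affect features negligibly.

Per scale, two features: wavelet energy WE(s_i) = Σ_j w²(s_i,j)/L_i (band
variability) and wavelet entropy WEn(s_i) = −Σ_j p_j log p_j with
p_j = w²(s_i,j)/Σ_j w²(s_i,j) (temporal irregularity of the band's activity;
0 for a single active coefficient, log L_i for uniform activity). The
logarithm is natural by default (`log_base` accepts base-2/base-10); a
normalized variant WEn/log L_i is also emitted because printed entropy values
in this literature are often far below log L and the normalization convention
is rarely stated. Zero-energy scales define entropy 0 with a warning.

**Continuous transform.** A Meyer CWT over 64 log-spaced pseudo-frequencies
spanning [fs/2^10, fs/2], computed by frequency-domain multiplication with
the dilated ψ̂. Normalization is L1-style (no √a factor): oscillations of
equal amplitude produce coefficients of equal magnitude at any frequency, so
the maximal-response row identifies the oscillation frequency directly.
Energy and entropy are computed over the whole map and over four bands —
neurogenic [0.025, 0.05], metabolic [0.00625, 0.025], lower
metabolic/ultradian [0.0015625, 0.00625] and ultradian [fs/2^10, 0.0015625]
Hz (band edges configurable; the lower two are dyadic continuations of the
published scale map, whose exact printed edges are inconsistent between the
table and a figure caption). Band entropies are normalized by log(number of
cells) into a [0, 1] irregularity index by default, with raw values emitted
under a `_raw` suffix.

## Multiscale entropy

Sample entropy SampEn(m, r) = −ln(A/B), where B counts pairs of m-length
templates within Chebyshev distance r (self-matches excluded) and A the same
at length m+1. Defaults m = 2, r = 0.15 after the series is normalized once
to SD 1; the absolute tolerance is then held fixed across all coarse-graining
scales (the standard convention; re-estimating r per scale would remove the
variance-reduction effect that makes white noise's curve decrease). The MSE
curve evaluates SampEn on non-overlapping-window averages at τ = 1..36;
`sumEn` sums the defined values and the count of undefined scales (A or B
zero) is reported rather than propagating infinities. A zero-variance series
is an error ("zero-variance series"). The O(N²) template counter is a numba
kernel (~0.1 s at N = 8640); a brute-force counter in the test suite verifies
exact agreement.

## Statistical battery

Lilliefors normality screening (KS statistic with estimated mean/SD) uses a
seeded Monte-Carlo null of 10 000 draws, cached per sample size since the
null is distribution-free given n. Pairwise Wilcoxon rank-sum tests are exact
(full enumeration) when the combined sample is ≤ 20 and tie-free, otherwise
normal approximation with tie correction. Kruskal-Wallis (tie-corrected H,
χ² p, per-group mean ranks) is followed by Dunn-type rank-mean comparisons
with Bonferroni correction over exactly the three group pairs — not across
features, matching the original analysis, which applied no cross-feature
correction. Spearman ρ quantifies the association of each feature with the
SOFA severity score. One-way ANOVA is included for the variables that pass
the normality screen (age, mean temperature). Summary tables report
median (25th–75th percentile) per group.

## Clustering

Euclidean distances over a chosen feature subset (raw units by default —
a z-score option exists, but the published distance magnitudes indicate
unstandardized features) feed 2-cluster k-means (50 restarts, seeded, labels
canonicalized so cluster 1 is the larger). Geometric quality: c_k = mean
within-cluster pairwise distance; d_kl = mean distance of cluster k's members
to cluster l's centroid, computed from the distance matrix alone via
|p − centroid(C)|² = mean_q d(p,q)² − ½·mean_{q,q'} d(q,q')²; cost =
(c1+c2)/(d12+d21), lower is better. These definitions are recorded in the
output because the source tables never define them algebraically; the
printed cost values could not be reproduced from any definition tried.
Class agreement maps each cluster to its majority class (ties → infected)
and scores sensitivity/specificity/accuracy against the SIRS-vs-infected
(sepsis ∪ septic shock) split, with infected as the positive class.

## Classification

Binary LDA from class means and a pooled covariance with a small
trace-scaled ridge (λ = 1e-3·trace(S)/p), which leaves well-conditioned
problems untouched and keeps the discriminant defined when n < p + 2 — the
usual situation at these cohort sizes. Priors are empirical. The wrapper
draws random 4-feature subsets, scores each by leave-one-out cross-validated
balanced accuracy (mean of sensitivity and specificity, chosen over raw
accuracy because the groups are unbalanced), and counts each feature's
appearances in subsets at or above the 80% threshold; the top-count features
("randset", ties broken by name) are re-evaluated at sizes 1..4 and the best
balanced accuracy is reported. Subsets are scored by LOOCV during the search
(the more conservative of the two plausible readings). The positive class is
SIRS in pairs containing it — the only assignment consistent with all the
published pairwise results — and the more severe group otherwise. The
iteration count is configurable (10 000 by default in `WrapperConfig`; the
pipeline default is 1000 and the reproduction experiments use 300, which is
enough for every informative feature to be drawn ~40 times in a 30-feature
pool).

## Synthetic cohorts

No recordings are distributed with the analysis this package reimplements,
so a cohort generator provides the test substrate. Each signal is
baseline + linear trend + three band components + white noise, quantized
round-half-even to the 0.05 °C grid. A band component mixes brick-wall
band-passed Gaussian noise with a phase-jittered sinusoid under a single
`regularity` knob in [0, 1]; the tone frequency is subject-specific
(log-uniform over the slow part of the band — a patient's dominant slow
rhythm, e.g. a 1–2 h ultradian cycle, is not a population constant).

Two findings from constructing the generator shaped its defaults:

1. For stationary signals, per-scale wavelet entropy barely separates noise
   from a steady tone (both spread energy evenly over time; a tone's
   normalized entropy is in fact slightly *higher*). The low printed entropy
   magnitudes are only reachable in the quantization-sparse regime: when
   oscillation amplitudes sit near the sensor resolution, a near-periodic
   low-variability signal becomes a staircase whose mid-scale energy is
   carried by sparse level-crossing transients (low entropy), while a
   broadband signal crosses levels densely (high entropy). Group amplitudes
   therefore default to 1–2 quantization steps.
2. With group-constant amplitudes, band energies separate groups more
   sharply than entropies, contrary to the reported pattern in which
   energies and mean temperature did not discriminate. Realistic
   between-subject variation restores that pattern: per-subject baseline
   spread (SD 0.6 °C), log-normal amplitude and noise jitter, the random
   rhythm frequency above, and small unannotated transient disturbances
   (Poisson rate 5/day, ~0.2 °C, identical law in every group) smear the
   amplitude-dependent features while the scale-free entropies keep the
   group contrast.

Default profiles share the neurogenic/metabolic structure and differ mainly
in ultradian regularity (SIRS 0.1, sepsis 0.85, septic shock 0.9) and noise
level; synthetic SOFA scores are uniform integers over [8, 12], [9, 13],
[13, 18] so only the ordering is meaningful. Annotated artifact segments
(flat dropouts or 0.5–2 °C steps, Poisson rate 1/recording) exercise the
repair stage. Oscillation amplitudes per band are free parameters — the
source reports none — and are chosen once for structural plausibility
(signal SDs fall in the reported 0.03–0.7 °C range).

What passing tests on these cohorts shows: the pipeline recovers a
complexity contrast that is present by construction, ranks the correct
feature family, and is calibrated under the null. What they cannot show:
that real febrile-response dynamics match this signal model (no circadian
component, no thermoregulatory feedback, Gaussian band noise), nor the
original study's exact feature medians, which depend on 22 unavailable
recordings.

## Reproduction experiments

`scripts/acceptance.py` recomputes, from scratch at run time: the dyadic
band map (against the published 9-row table); the published
accuracy/sensitivity/specificity values reconstructed from group sizes and
per-class counts through the package's confusion code (81.81%/86.36% cluster
agreement on 22 subjects; 93.33% and 91.67% LOOCV accuracy on 15 and 12);
exact SampEn agreement with a brute-force counter (50 series, N ≤ 300);
DWT energy conservation; parameter recovery on 10 seeded default cohorts of
20 subjects per group (fraction of runs whose top wrapper feature is an
ultradian-band entropy, and the median SIRS-vs-shock LOOCV balanced
accuracy, which the source summarizes as "more than 80%"); and the rank-sum
type-I error over 2000 null simulations. Problem sizes (300 wrapper
iterations, MSE excluded from the recovery pool) are the package's own
choices for a desk-scale reproduction; the full-size settings remain
available through the configuration objects.

## Known limitations

- The generator's "regularity" knob couples spectral concentration with
  entropy; it cannot produce a signal with broadband energy *and* low
  per-scale temporal entropy (no stationary Gaussian process can).
- CWT band entropies depend on the normalization convention and grid
  density; comparisons are meaningful within a fixed configuration only.
- The clustering cost and interclass-distance definitions are one reasonable
  reading of an underspecified original; alternatives (centroid-to-centroid,
  minimum linkage) would change absolute values but not the ranking behavior
  the tests assert.
- Lilliefors p-values are Monte-Carlo estimates with a floor of
  1/(B+1) = 1e-4 at the default B.
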