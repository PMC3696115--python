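# Methods

This note documents the models, conventions, and design choices behind
`nirsconn`, and what the synthetic-cohort benchmarks do and do not
demonstrate.

## Modified Beer–Lambert conversion

Continuous-wave optical topography measures optical-density (OD) changes at
two wavelengths. For small concentration changes,

    ΔOD_λ = ε_λ,HbO · Δ[HbO]·L + ε_λ,HbR · Δ[HbR]·L,

a 2×2 linear system per time sample and channel. The differential
pathlength factor L for the neonatal head is uncertain and is never divided
out: all hemoglobin quantities are concentration × pathlength in mM·mm.
This only rescales each channel and, because Pearson correlation is
invariant to positive affine rescaling, has no effect on connectivity.

The default extinction matrix (mM⁻¹·mm⁻¹, rows 785/830 nm, columns
HbO/HbR) is converted from the standard in-vitro hemoglobin compilations
(785 nm: 735 / 1098 cm⁻¹·M⁻¹; 830 nm: 974 / 693). These are conventions,
not results; `ExtinctionTable` accepts any replacement and rejects matrices
with condition number ≥ 100, where oxy/deoxy separation becomes unstable.

## Band-pass filter

The analysis band is 0.01–0.08 Hz, the conventional low-frequency RSFC
range. Only the band is a fixed convention; the realization is a design
choice: 3rd-order Butterworth with −3 dB corners at the band edges, applied
forward–backward (`sosfiltfilt`) so band-interior features are not
time-shifted. Zero-phase application squares the magnitude response, giving
≈ 103 dB attenuation at 0.5 Hz and < 0.01 dB passband ripple at 0.04 Hz.
The residual mean left by edge transients is subtracted exactly (DC lies
outside the band by construction). Filtering a series shorter than two
cycles of the low edge (200 s) is refused. Family and order are exposed in
`FilterSpec`.

## Motion-artifact detection

Neonatal motion (Moro reflexes, smiles) produces two morphologies: sudden
baseline jumps and slow U / inverted-U spikes. Both move Δ[oxy-Hb] and
Δ[deoxy-Hb] *in the same direction*, whereas neurovascular fluctuations are
anti-correlated; this sign flip is the primary detection signal.

Detection runs on the unfiltered hemoglobin series — artifacts are
broadband, and the narrow analysis band would smear jumps — and flags
samples where both of the following hold:

* the 10 s sliding-window oxy/deoxy correlation, pooled across channels by
  the median, exceeds +0.5;
* the robust amplitude excursion exceeds 5 MAD units. The amplitude path
  uses a 30 s moving-average-detrended signal, because a jump's slow
  exponential relaxation would otherwise inflate the per-channel MAD and
  mask later events; a 0.5 s-smoothed derivative path catches the step
  itself.

Flagged runs closer than 10 s are merged; each merged run yields one event
at its maximal excursion (so the per-infant artifact count refers to merged
events). Events are classified as jumps when the channel-median signal
stays displaced (> 2 robust SDs) from 5–15 s before to 5–15 s after the
peak, otherwise spikes. Each peak excises the fixed window [peak − 20 s,
peak + 30 s], clamped at the recording edges and unioned across events;
excision is global across channels because motion moves the whole probe
set. Subjects retaining < 150 s are excluded (the minimum analyzable window
observed in cohorts of this kind). All thresholds live in `ArtifactPolicy`;
the correlation principle is fixed, the numbers are tunable defaults. A
manual-review override file (add/remove events by peak time) replaces
visual inspection reproducibly.

## Connectivity and group statistics

Per subject, Pearson r is computed between the band-passed Δ[oxy-Hb]
series of every channel pair over the retained samples, concatenated into a
single pooled estimate (one r per pair per subject; at least 100 retained
samples required). Fisher's z(r) = atanh(r) stabilizes the variance;
degenerate |r| ≥ 1 inputs are clipped to ±(1 − 10⁻⁷) with a warning, and
zero-variance channels are masked. Deoxy-based connectivity is available
behind a flag but the analysis convention is oxy-Hb.

Group statistics standardize t by the null t-distribution's moments,

    z = (t − E[t]) / σ[t] = t / √(df/(df−2)),   df > 2,

the only parameter-free reading that makes z unit-variance under the null.
One-sample maps use df = n − 1; the two-sample comparison uses the pooled
df = n₁ + n₂ − 2 by default (Welch available in `InferenceConfig`); PMA
trends use the exact t transform of the Pearson correlation with df = n − 2
and two-tailed p. No multiple-testing correction is applied by default
(a Bonferroni option exists), matching the uncorrected |z| > 3.29 and
p < 0.005 screening conventions.

**Calibration caveat.** The moment conversion standardizes the variance of
t, not its shape, so the converted statistic is a scaled t, not a normal.
At df = 47 the exact null exceedance beyond |z| > 3.29 is
2·P(T₄₇ > 3.29·√(47/45)) = 1.54×10⁻³, about 1.5× the two-sided normal tail
of 1.0×10⁻³. The null-calibration benchmark reproduces this exact value; a
user wanting exact normal calibration at small df should threshold the t
statistic at its own quantile instead.

## Synthetic cohort generator

The generator emulates the study conditions so every downstream stage can
be validated against ground truth:

* **Cohort**: 25 preterm (GA 23.1–36.7 wk) + 24 full-term (GA 37–41.3 wk)
  infants, all scanned at PMA 37.1–42.1 wk; preterm CA follows from
  PMA − GA, full-term infants are scanned 2–8 days after birth. PMA is
  drawn uniformly over the observed range.
* **Signal**: per subject, white noise is band-passed to 0.01–0.08 Hz,
  standardized, and mixed through the Cholesky factor of a target
  correlation matrix — unit diagonal, homotopic (mirror-channel) background
  r = 0.5, plus arbitrary per-edge effects
  r = base + Δr·[preterm] + slope·(PMA − 39.5 wk), with an
  eigenvalue-clipping repair to the nearest positive-definite correlation
  matrix when needed. Δ[deoxy-Hb] = −0.4·Δ[oxy-Hb] + independent
  band-limited noise at half the signal scale.
* **Amplitude**: no published value exists for infant hemodynamic
  fluctuation amplitude in these units; the signal scale is a free
  parameter defaulting to 0.02 mM·mm. Every amplitude-like quantity
  (nuisance, noise, artifacts) is expressed relative to it, so the choice
  is inert.
* **Nuisance and noise**: cardiac 2.5 Hz and respiratory 0.8 Hz sinusoids
  (common phase, per-channel gain jitter) at 0.5× / 0.3× signal scale —
  deliberately outside the analysis band to test filter rejection — plus
  white measurement noise at 0.25×.
* **Artifacts**: a whole-head Poisson process (1.1 events per recording,
  matching the observed per-infant mean), each event either a step with
  120 s exponential relaxation ("jump", 40%) or a ±raised-cosine pulse of
  4 s half-width ("spike"), amplitude 8× signal SD with ±25% jitter and
  per-channel gains in [0.6, 1.4]; the deoxy excursion is +0.5× the oxy
  excursion, giving the positive oxy/deoxy correlation the detector keys
  on. Ground-truth event times and per-edge target correlations are
  emitted.
* **Duration**: 300 s (the acquisitions ran 3–6.5 min); with the default
  artifact rate the retained window averages ≈ 245 s, close to the ≈ 233 s
  analyzable windows reported for such cohorts.
* **Determinism**: one `SeedSequence` root spawned per subject; identical
  spec + seed is bit-identical.

What the generator does *not* emulate: photon transport and scalp/skull
layering, realistic probe geometry (the channel→region registry is an
even split across eight bilateral regions, replaceable by a layout CSV),
1/f physiological drift inside the analysis band, spatially local motion,
and inter-subject variance beyond sampling error. Passing benchmarks
therefore demonstrate that the pipeline recovers what it is designed to
recover under its own assumptions — not performance on real infant data.

## Benchmark problem sizes

The validation benchmarks (`nirsconn.evaluation`) balance statistical
resolution against runtime on a single CPU:

* detector: 20 seeds × (4 recordings with ~2 planted events + 4 clean
  recordings) at the full 94 channels;
* planted-effect recovery: 20 seeds × 49 subjects at 24 channels —
  per-edge statistics do not depend on the number of channels carried
  along, and 24 channels preserve the full eight-region homotopic
  structure;
* null calibration: 20 seeds × 49 subjects at 94 channels (4371 pairs per
  seed), since this benchmark pools across pairs.

Recovery benchmarks run artifact-free: excision only shrinks the effective
sample count, and the detector is benchmarked separately.

## Known limitations

* The detector's MAD-based amplitude criterion loses sensitivity when the
  realized artifact amplitude approaches the 5-MAD policy threshold
  (events planted at 5× signal SD with downward jitter fall below it);
  performance figures hold at the default 8× amplitude scale.
* Jump/spike classification is heuristic and not used by any downstream
  statistic; only event times and exclusion windows matter.
* With very short recordings (near the 200 s filter minimum) band-edge
  transients are proportionally larger; the generator's 300 s default
  keeps them negligible.
* The default channel→region registry is an approximation; analyses that
  depend on exact anatomy must supply their own layout file.
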