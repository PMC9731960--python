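# Methods

## The analysis

`plvnet` measures resting-state functional connectivity between cortical
regions of interest (ROIs) as band-limited phase synchronization and asks
whether edge strength differs between two groups defined by a trait
questionnaire score.

For two narrowband signals with instantaneous phases φ_i(t), φ_j(t) over an
epoch of T samples, the phase-locking value is

    PLV_ij = | (1/T) Σ_t exp( i·(φ_i(t) − φ_j(t)) ) | ∈ [0, 1].

PLV is invariant to amplitude scaling and to any constant phase lag, and for
T independent uniform phases its expectation is the Rayleigh chance level
√(π/(4T)). One PLV matrix is computed per epoch and per band; the subject's
connectivity is the arithmetic mean of per-epoch matrices over kept epochs
(epoch-wise PLV first, averaging second — never sample pooling across
epochs). The diagonal is set to 1 by convention and excluded from every
statistical family.

The processing chain per subject is:

1. **Common-average reference** — subtract the per-sample channel mean.
2. **Broadband band-pass 0.5–45 Hz** — odd-length Hamming-window FIR
   (≈3.3·fs/0.5 taps) applied centred, i.e. linear phase with the group
   delay exactly compensated.
3. **Epoching** — consecutive non-overlapping epochs (4096 samples at
   1 kHz full scale; 1024 at 250 Hz desk scale); the trailing remainder is
   discarded.
4. **Epoch screening** — epochs whose peak absolute amplitude on any
   channel exceeds 100 µV (configurable) are dropped. This deterministic
   criterion is the standard automated proxy for manual visual artifact
   inspection, which is not implementable in software.
5. **Band decomposition** — 6th-order Butterworth band-pass per band
   (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–45 Hz), applied
   forward–backward (zero phase; effective 12th-order magnitude). Band
   edges are the −3 dB corners; adjacent bands share an edge.
6. **Phase extraction** — analytic-signal (Hilbert) phase computed
   epoch-wise so nothing leaks across epoch boundaries. The first and last
   `edge_trim` samples (100 at 1 kHz, scaled with fs) are excluded from PLV
   to suppress end effects.

### Statistics

Subjects are split at the empirical median of the questionnaire total;
scores below the median form the Low group, ties at the median go High
(with the documented trait distribution this reproduces a Low 6–16 /
High 17–24 split at median 17). Each (ROI pair, band) hypothesis is tested
with a label-permutation test on the pooled-variance two-sample t statistic
(two-sided); Monte-Carlo p-values use the add-one estimator
p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), so p ∈ (0, 1]. A full-enumeration
(`exact=True`) path exists for small groups. Each edge derives its own
random stream from (master seed, i, j, band index), making results
independent of evaluation order.

Hypotheses form two families — intra-network (both endpoints in one
network) and inter-network — each pooled across all five bands, and
Benjamini–Hochberg FDR at q = 0.05 is applied within each family. With the
bundled 40-ROI parcellation the families hold 785 and 3115 tests. The
"raw significant" count uses an uncorrected 0.05 threshold; that threshold
is an assumption of this package, chosen as the conventional default.
FDR-significant edges are supplemented with the whole-sample Pearson
correlation between the trait score and edge PLV (stars at 0.05/0.01/0.001).
Demographics use the pooled-variance t with Cohen's d (pooled SD) and, for
sex, the Pearson χ² on the 2×2 table without continuity correction, with
effect size r = √(χ²/N).

## The atlas

Forty ROIs are partitioned into five networks: Default Mode (13),
Fronto-Parietal (8), Sensory-Motor (7), Cingulo-Opercular (6), Salience (6).
The bundled table (`data/atlas40_synthetic.tsv`) is a **synthetic
reconstruction**: the published group-difference tables reveal only a
subset of the membership, and the remaining slots are filled with canonical
members of each network. The sizes are chosen so the intra/inter family
sizes (157 and 623 pairs per band) match the published test counts exactly.
One revealed edge (Frontal_Sup L—Thalamus L, labelled CON–FPN in the source
without saying which endpoint is CON) falls intra-FPN here; edge-family
classification of that pair therefore differs from the source table.
Hemisphere is carried as reporting metadata only.

## The synthetic cohort generator

No recordings are publicly available for this design, so validation runs on
simulated cohorts. Per band each ROI carries unit-variance white noise
filtered by the same zero-phase Butterworth band filter the analysis uses —
guaranteeing the planted structure lives inside the analysis bands. A
coupled edge (i, j) with strength κ ∈ [0, 1] rebuilds j's band component as
κ·(phase-lagged copy of i) + √(1−κ²)·(independent process); the lag
(default π/4, deliberately nonzero) is applied by rotating the analytic
signal, so PLV ≈ κ-monotone with PLV = 1 at κ = 1 and chance level at
κ = 0. Band components are scaled by a coarse 1/f-like amplitude profile
(delta 1.0, theta 0.9, alpha 1.0, beta 0.7, gamma 0.5 — a resting spectrum
with a preserved alpha peak) and summed with broadband white noise
(SD 0.5).

Questionnaire totals are rounded, clipped normal draws (mean 16.22,
SD 3.64, range 5–30 — the documented trait distribution). Each planted
edge's realised κ is the subject's group baseline (κ_low or κ_high by
median split) plus `trait_slope`·(standardised score), clipped to [0, 1],
and is stored in a truth table for recovery tests. Demographic covariates
(age, education, nonverbal-reasoning percentile, sex) are drawn
independently of the trait, so groups are balanced in expectation. A single
seed sequence spawns one stream for cohort-level draws and one per subject,
making cohorts bit-reproducible.

The default "signature" configuration plants the qualitative pattern the
pipeline is designed to detect: within-DMN delta/theta coupling lower in
the High-trait group with negative trait slopes, and sensorimotor /
cingulo-opercular / cross-network coupling in faster bands higher in the
High group with positive slopes, at κ baselines typical of published
group-mean PLV magnitudes.

**What the simulator does not emulate:** volume conduction / source
leakage (signals are generated at ROI level), non-stationarity, realistic
artifact morphology (only the amplitude-threshold path is exercised by
explicit spikes in tests), 1/f-continuous spectra (band components are
piecewise), or any empirical coupling topology beyond the planted edges.
Passing tests therefore demonstrate the pipeline's correctness and
operating characteristics under these idealised conditions, not fidelity to
any particular recorded dataset.

## Scales and runtime choices

Two presets enumerate all scale parameters:

| preset | fs (Hz) | epoch (samples) | epochs | n_perm |
|--------|--------:|----------------:|-------:|-------:|
| desk   | 250     | 1024            | 20     | 2000   |
| paper  | 1000    | 4096            | 150    | 20000  |

The desk preset is the package's default study condition: it keeps a full
66-subject, 40-ROI, five-band run (simulation → PLV → 3900 permutation
tests) around a minute, while preserving every structural property of the
full-scale condition. The test suite and the acceptance script run at desk
scale; the full scale is available by configuration.

A consequence of desk-scale permutation resolution worth knowing: the
add-one p-value cannot go below 1/2001 ≈ 5.0·10⁻⁴, while the BH threshold
in the 3115-test inter family is k·0.05/3115 ≈ k·1.6·10⁻⁵ — so fewer than
32 floor-level edges can never be FDR-flagged there. Detecting a handful of
inter-network effects post-FDR requires the full 20 000 permutations. The
same arithmetic caps post-FDR power for small planted subsets of the
785-test intra family at 2000 permutations.

## Numerical contracts and edge cases

- All accumulation in double precision; identical config + seed gives
  byte-identical outputs.
- Zero pooled variance in a permutation test: equal means → t = 0, p = 1;
  unequal means → t = ±∞, still well-ordered by |t|.
- Zero-variance PLV or trait vectors have no defined Pearson r and are
  reported as missing ("n/a"), never as a number.
- A recording shorter than one epoch yields zero epochs with a warning;
  rejecting all epochs is an error.
- Bands at or above Nyquist raise a configuration error naming the band.
- Median-split ties go High; a single-member group warns (group tests
  require ≥ 2 per group).
- Per-epoch PLV matrices are computed via Z Z^H with Z = e^{iφ}, one
  complex matrix product per epoch — algebraically identical to the scalar
  loop (tested to 1e-12).

## Known limitations

- The ROI parcellation is a reconstruction (above); analyses keyed to
  specific placeholder ROIs are only as meaningful as the placement.
- Plain PLV is used with no leakage-robust variant (imaginary coherence,
  wPLI); at ROI level with simulated data there is no leakage to correct,
  but applying the pipeline to sensor-space data would conflate zero-lag
  leakage with coupling.
- The epoch screening threshold is a crude stand-in for expert visual
  rejection.
- Whole-epoch PLV only; no windowed or time-resolved variant.
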