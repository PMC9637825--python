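# Methods

## Trial design and sampling

A trial alternates non-regulation (22.5 s) and regulation (45 s) phases —
seven and six of them respectively, starting and ending with non-regulation —
sampled at TR = 1.5 s for 258 volumes. The nominal schedule sums to 427.5 s
(285 samples), which is longer than the 258 samples actually acquired; the
two cannot both hold. We treat the sample count as authoritative, lay the
schedule out from t = 0 and truncate it at the last sample: the final
regulation phase keeps 18 of its 30 samples and the closing non-regulation
phase receives none. All downstream analysis operates on the 258-sample
matrix, so nothing depends on the unreachable tail. `sample_map` assigns
every sample to the phase whose onset window contains it.

## Synthetic cohort generator

Each ROI time series is

    x_i(t) = b + u · m_i(t) + u · ( Σ_k a_ik s_k(t) + ε_i(t) )

with baseline b = 100 signal units, u = b/100 so that amplitudes read in
%BOLD, white Gaussian latents s_k ~ N(0, σ_k²) and noise ε_i ~ N(0, σ_ε,i²),
and a block modulation m_i(t) = amp_i,trial · (boxcar ⊛ HRF).

**HRF.** Canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6),
sampled at TR with 32 s support, normalised to unit sum (unit DC gain) so a
45-s block convolves to a plateau of exactly 1 and `modulation_amp` is the
plateau %BOLD change. Unit-*sum* rather than unit-*peak* normalisation is a
deliberate choice: it is the only convention under which the generator's
amplitude parameter means what the feedback computation measures.

**Coupling structure.** Three latent factors:

| factor | ROIs (loading) | groups | purpose |
|---|---|---|---|
| global | all 7 (0.3) | both | baseline coherence floor |
| pain triad | pInsL, pInsR, SII (0.8) | both | the triangle observed in every group |
| Learner | rACC, pInsL (1.5) | Learners | the connection successful regulation recruits |
| non-Learner | aInsL, pInsL (1.2) | non-Learners | the anterior-insula coupling that marks unsuccessful regulation |

(the last two share one factor slot; each subject has exactly three
factors). σ_k = σ_ε = 1 throughout. With white latents the theoretical
magnitude-squared coherence of pair (i, j) is frequency-flat:

    Coh²_ij = (Σ_k a_ik a_jk σ_k²)² / ((Σ_k a_ik² σ_k² + σ_ε,i²)(Σ_k a_jk² σ_k² + σ_ε,j²))

e.g. ≈ 0.41 for rACC–pInsL in Learners and ≈ 0.29 for aInsL–pInsL in
non-Learners, against a background of ≤ 0.01 for global-only pairs. HRF
smoothing applies only to the modulation term by default (configurable via
`smooth_latents`), keeping this oracle exact.

**Modulation profiles.** Learners: direction · 2% · (0.5, 0.6, 0.7, 0.8,
0.9, 1.0) — correct sign in 6/6 trials and strict trial-1→6 improvement.
Non-Learners: direction · 2% · (0.9, −0.7, 0.5, −0.6, 0.4, −0.8) — correct
sign in only 3/6 trials and trial 6 worse than trial 1, so both criteria
fail with wide margins. The 2% scale sits roughly 6 standard errors above
the per-trial noise of the feedback difference, which is what makes
ground-truth labels recoverable at the ≥95% level; halving it degrades
recovery gracefully rather than abruptly.

**Cohort layout.** 10 subjects × 4 conditions (ACCD/ACCU down/up-regulate
rACC, INSD/INSU down/up-regulate pInsL, always against UNR) × 6 trials.
The default Learner/non-Learner assignment uses the study's observed splits
(6/4, 5/5, 8/2, 5/5). Ratings (0–10 verbal scale, half-point resolution)
are drawn from the same N(5.5, 1.2) for both groups, matching the null
group difference in pain ratings. Child generators are derived from the
master seed via numpy `SeedSequence` keyed on (seed, condition index,
subject index): reproducible, independent across subjects, and all derived
seeds stay well-defined for any 32-bit master seed.

**What the generator does not emulate.** Volumetric images, physiological
(cardiac/respiratory) noise, scanner drift beyond what per-segment mean
removal absorbs, 1/f BOLD spectra (latents are white by design, to keep the
oracle exact), and between-subject variability in HRF shape or coupling
strength. Passing tests therefore demonstrate that the pipeline recovers
known structure under the stated noise model — not that it would behave
identically on real recordings.

## Coherence estimation

Welch's method: 64-sample segments, 50% overlap, Hann taper, per-segment
mean removal (block modulation otherwise leaks broadband power), one-sided
spectra. On 258 samples this gives K = 7 segments and a grid step of
1/(64·1.5) ≈ 0.0104 Hz. The expectation in the coherence ratio is the
segment average; K = 1 makes the ratio identically 1 and is rejected. The
printed acquisition-level grid step (1/N per Nyquist, ≈ 0.0012 Hz) is a
property of the full-length FFT grid, not of a segmented estimator; since
the analysis consumes only band averages, the band is defined on the
estimator grid with inclusive bounds. The DC bin is excluded from every
band. Estimates are clipped into [0, 1] only against float overshoot
(1e−12); values beyond that tolerance raise.

Known small-sample behaviour: for independent series E[Coh²] ≈ 1/K, so
single-trial matrices have a bias floor ≈ 0.14 at K = 7. This is why group
graphs are built from normalised, group-averaged matrices, and why the
calibration tests run at n = 4096 (K = 127) where the floor is ≈ 0.008.

The band default is [0.15, 0.33] Hz. 0.33 Hz is the Nyquist frequency for
TR = 1.5 s to two decimals; the upper bound is taken at that printed value.
UNR is excluded from the 6×6 connectivity matrix; it participates only in
the feedback signal.

## Network extraction

Per subject: min–max normalise the 15 unique off-diagonal values into
[0, 1] (the diagonal zeros are placeholders and stay outside the min–max
domain; a constant off-diagonal is degenerate and the subject is dropped
from averaging with a warning). Per group: element-wise mean of the
normalised matrices, then threshold. Ordering: normalise → average →
threshold, matching the stage order of the analysis; single-subject graphs
threshold that subject's own matrix.

Thresholding uses the nearest-rank percentile — the value at rank
⌈p·n/100⌉ of the ascending values — with strict `>` retention. At p = 70
and n = 15 the threshold is the 11th value and exactly the 4 strongest
connections survive when values are distinct; a linear-interpolation
percentile would retain 5, contradicting the four-strongest rule, which we
treat as binding. Values tied with the threshold are excluded
deterministically; an ambiguous tie (several pairs at the threshold value)
emits a warning listing the pairs. Graph weights are the matrix entries
themselves; the node set is always all six ROIs, isolated or not, and edges
are label-sorted so the graph is independent of input row order.

The per-edge retention summary (`edge_summary`) counts a subject as
retained when the named connection survives the percentile cut of that
subject's own normalised matrix, and reports mean ± SD of the edge weight
over retained subjects. This subject-level-threshold reading of "data from
k/m subjects remained" is one plausible interpretation of a procedure whose
retention rule is not fully specified upstream; it is flagged as such here.

## Regulation assessment

%BOLD signal change uses the mean over non-regulation samples of the same
trial as baseline (per-trial baselines absorb slow drift between trials).
Phase attribution is shifted by a configurable haemodynamic delay, default
3 samples = 4.5 s, before any averaging: a step at a phase onset has its
first 3 samples attributed to the previous phase. The feedback difference
of a trial is the regulation-sample mean of psc(target) − psc(UNR).

The Learner rule takes "improved" strictly: signed modulation at trial 6
must exceed trial 1; equality is non-improvement. The rule is invariant to
positive rescaling of all differences.

Paired t (t = mean(d)/(sd(d)/√n), df = n−1) and one-way ANOVA
(F = (SSB/df_b)/(SSW/df_w)) are computed from their sums-of-squares
definitions and cross-checked in the tests against brute-force oracles and
scipy to 1e−10. p-values are reported but never used for gating, and no
multiple-testing correction is applied. On the packaged published ratings
table the Learner-vs-non-Learner ANOVA has df (1, 8) in every condition and
the maximum unpleasantness F is ≈ 2.28; the maximum intensity F computes to
≈ 0.521, which rounds to the printed bound of 0.52 but is not strictly
below it, so only the unpleasantness bound is asserted.

## Pipeline and reproducibility

`run_pipeline` simulates a cohort, classifies every (subject, condition)
from the six trials, builds connectivity matrices for trials 1 and 6,
averages by *classified* (not ground-truth) group, thresholds, and runs the
ratings ANOVA — so a planted group difference must survive classification
errors to appear in a group graph. All outputs are a pure function of
(config, seed); artifacts are written atomically (temp file + rename) and
listed in a sha256 manifest, and two runs with the same seed produce
byte-identical checksums. The staged CLI commands (`simulate`, `coherence`,
`classify`, `network`, `report`) operate on TSV files and compose to the
same numbers as `run_pipeline`.

Problem sizes used in the test and acceptance runs: 1000 random matrices
for the threshold-cardinality law; 100 seeds at n = 4096 (K = 127) for
estimator calibration; 100 cohorts (4000 subject-conditions) for label
recovery; 20 full pipeline runs for planted-edge detection. These sizes
give Monte-Carlo standard errors comfortably below the asserted margins
while keeping a full run in the tens of seconds.

## Known limitations

- Coherence is undirected and phase-blind; no directed-connectivity
  measures are provided.
- No surrogate-based significance testing of coherence values; the
  percentile cut is a fixed-rank rule, not an inferential threshold.
- The white-latent noise model understates the autocorrelation of real
  BOLD; estimator variance on real data will be higher than the
  calibration suggests.
- With K = 7 segments per trial, single-trial connectivity matrices are
  noisy by construction; conclusions should rest on the group-averaged
  matrices, as implemented.
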