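# Methods

## Signal model

Raw fluorescence of a cell is modeled as

    F(t) = F0 · (1 + d(t) + Σᵢ aᵢ · kᵢ(t − tᵢ)) + ε(t)

with baseline `F0` (arbitrary units), slow drift `d(t)` (sinusoid, amplitude
`drift_amplitude·F0`, period 90 s), unit-peak transient kernels `kᵢ`,
injected amplitudes `aᵢ` in dF/F units, and white Gaussian noise with sd
`noise_sd·F0`. Noise and drift scale with the baseline, so every dF/F
quantity is invariant to the fluorescence scale — only ratios are
meaningful.

Two kernel families are generated. *Short* (sensory-like) kernels default to
a 0.5 s time-to-peak and τ = 1.2 s, decaying below 5 % of peak within 5 s on
a 5 s support. *Long* (dopaminergic-like) kernels default to a 6.5 s
time-to-peak and τ = 8 s on a 30 s support. The requested peak time is
snapped to the 2.3 Hz frame grid so the sampled maximum is exactly 1; the
rise up to the peak is the alpha shape `(t/t_pk)·e^(1−t/t_pk)` and the decay
after the peak is exactly `e^(−(t−t_pk)/τ)`. The exact post-peak exponential
is deliberate: it makes decay-constant recovery well-posed, so fitting tests
have a known truth. The alpha rise (rather than a calibrated
difference-of-exponentials) reaches any requested peak time for any decay τ,
which matters when pharmacology scalars shorten τ below the rise time; the
two shapes are practically indistinguishable at 2.3 Hz sampling. The hard
truncation at the support end leaves a ≤5 % step, which the median baseline
absorbs.

## Baseline and dF/F

`F0(t)` is the median of raw samples whose frame index lies within
`⌊W·fps⌋` frames of `t`; the window truncates at the recording boundaries
(no padding — the simplest convention that is exactly testable against a
per-sample sort-and-median oracle, which the suite enforces bit-exactly).
W = 40 s is used for slow VTA-evoked transients and W = 2.5 s for fast
V2L-evoked ones. Note that with W = 2.5 s a 5 s transient occupies roughly
half the window, so the local median sits slightly above baseline and peak
dF/F underestimates the injected amplitude by a fixed fraction; this is a
property of the windowed-median definition itself, is shared by all
conditions, and cancels in every ratio, gain and similarity comparison. All
windows are half-open `[start, end)` on timestamps; frame k is at `k/fps` s.

## Transient metrics

* Summed response: sum of dF/F samples in the window (a trapezoidal variant
  would differ only by edge terms at 2.3 Hz; sums are used throughout).
* Peak: maximum in the window, ties broken earliest.
* Decay: one-parameter nonlinear least squares on
  `dF/F_max·e^(−t/τ)` with `dF/F_max` fixed to the observed peak; a
  log-linear fit is available as an option and serves as the test oracle.
  The default fit window runs from the peak to the first sample below 5 % of
  peak, capped at 40 s. Noise-free bias is < 2 % across τ ∈ {3, 8, 13, 20} s
  at 2.3 Hz; with noise sd 0.02 the median of 200 fits stays within 10 %.
* Occurrence: max dF/F in the 5 s post-stimulus window > k·SD of the 5 s
  pre-stimulus dF/F, k = 3 by default and exposed as config. With ~11-sample
  windows on both sides this rule's null rate is a few percent (max
  statistic over the window, noisy SD estimate), not the single-sample
  Gaussian tail; the suite checks it against a Monte-Carlo oracle of the
  rule itself and verifies that k = 5 pushes the rate below 1 %.

## Population statistics

Response vectors take the per-cell **peak dF/F within 5 s** of stimulus
onset (matching the < 5 s sensory kinetics); a mean-over-window summary is
available. Pattern similarity is the mean of the three pairwise cosines
between the repetition vectors. Zero-norm vectors raise rather than return
0 — silently mapping them to a value would bias averaged similarities.
Negative dF/F entries are kept; the cosine may be negative.

Cronbach's alpha treats repetitions as items and cells as subjects, on the
binary occurrence matrix by default (graded response values are supported).
The 95 % CI is Feldt's F interval with df (n−1) and (n−1)(k−1) — the
conventional choice when a CI method is not otherwise dictated.

The two-sample KS p-value uses the asymptotic Kolmogorov distribution with
effective size nm/(n+m), adequate at the 50–80 cells per animal this package
targets; tests verify D against an exhaustive ECDF-difference oracle.

## Inference

The mixed (split-plot) ANOVA tests the paradigm between subjects against
the subjects-within-groups stratum and the time effect and interaction
against the subject × time residual. The design must be balanced and
complete; missing cells raise rather than being imputed, because the
closed-form sums of squares assume balance. No sphericity correction is
applied by default (Greenhouse–Geisser is available behind a flag and is
reported alongside, not instead of, the uncorrected p).

Ryan's stepwise procedure tests a pair spanning r of the k ordered means at
the nominal level `2α/(k(r−1))`, with closure: a pair is significant only if
every enclosing span was rejected. This makes the rejection set a superset
of Bonferroni-all-pairs and a subset of unadjusted testing (verified as a
property test), and controls the familywise error at α under the complete
null (verified by simulation). Because "Ryan's test" is ambiguous across
literatures, the Ryan–Einot–Gabriel–Welsch nominal levels
`1−(1−α)^(r/k)` are available behind a flag.

For the per-paradigm similarity time course, the post hoc error term is the
subject × time residual from that paradigm's one-way repeated-measures
ANOVA (n−1)(t−1) df; for the between-paradigm dF/F-change comparison it is
the one-way within-group mean square.

## Synthetic experiment generator

Per animal, a fixed population of cells is drawn: a responder subset
(fraction 0.8) with non-negative Gaussian base amplitudes (mean 0.12, sd
0.05 dF/F — calibrated so baseline responses sit mostly below the 0.2
high-responder criterion). At each test time point the latent population
vector is gain × base (deterministic), and each of the three repetitions
applies latent + Gaussian jitter with sd `rep_jitter_sd·(1−coupling)`,
clipped at zero. The coupling parameter therefore raises the expected
inter-repetition cosine monotonically (verified by Monte Carlo); gain and
coupling are recorded in the ground truth together with every applied
amplitude and occurrence flag (a cell "responds" on a repetition iff its
applied amplitude is > 0).

The default effect table encodes the study conditions: only T1 (sensory
0.5 s before the dopaminergic burst) carries an effect — gain 1.5 and
coupling 0.8 at 2 hr, intermediate values at 1 hr — while V2L-only,
VTA-only and T2 keep gain 1 and the baseline coupling 0.3 throughout. A
separate 90 s phasic-VTA recording per animal carries long transients with
amplitudes drawn independently of the sensory responses, so the per-animal
correlation between dopaminergic calcium influx and response gain is null
by construction.

Default problem sizes are 8 animals per paradigm and 50–80 cells per animal
at 2.3 Hz; test recordings are 80 s with the three sensory repetitions at
20/40/60 s (20 s spacing is ample for transients that decay within 5 s).
Inter-animal variance enters only through the per-animal amplitude draws;
variance components beyond that are not asserted and are exposed as free
parameters.

What the generator does **not** emulate: photon statistics, scanning
artifacts, neuropil contamination, bleaching beyond the slow drift, or
correlated noise across cells. Passing tests therefore demonstrate
correctness of the estimators and inference under the stated signal model,
not robustness to every pathology of real recordings.

## Movies and the imaging front end

Synthetic movies render neurons as green disks whose pixels share the
simulated trace value frame by frame, astrocytes as red-bright (and
moderately green, static) disks, on a uint16 background; a pixel belongs to
a disk iff its center distance is ≤ r — the same membership rule ROI
extraction uses, so noise-free extraction is exact up to quantization
(≤ 0.5 counts). Registration is translation-only (integer-pixel phase
correlation, borders filled with the frame median): rotation/scaling are
out of scope and integer shifts keep the oracle exact. Detection smooths the
mean image, takes local maxima above an intensity percentile, and places
fixed-radius disks greedily without overlap; supplying seed points bypasses
detection (the "semi-automatic" path, one ROI per seed). An ROI is labeled
astrocyte iff its mean red intensity exceeds the 75th percentile of ROI-wise
red intensities. Coordinates are 0-based (row, col).

## Pipeline

The orchestrator runs generator → dF/F → response vectors → per-animal
similarity/reliability → group inference, writing 12 CSV tables and a
manifest (config hash, seed, version, file inventory); identical config and
seed reproduce byte-identical tables. The population dF/F per animal and
time point averages across cells first, then across the three repetitions.
The first 10 s of each recording are excluded from display traces
(mechanical onset artifacts in the raw data this emulates); all analysis
windows start later anyway. The end-to-end checks use 8 animals × 4
paradigms × 60 cells per replicate, 20 replicates per condition — small
enough to iterate on while leaving the group-level tests well powered; at
these sizes the pipeline detects the default T1 effect in essentially every
replicate and flags a null interaction at the nominal ~5 % rate (the
dF/F interaction is the primary null readout).

## Known limitations

* The split-plot ANOVA requires balance; unequal group sizes need a
  different error structure (out of scope, as is REML mixed modeling).
* The asymptotic KS p-value is anti-conservative below ~20 samples; use the
  exact statistic D (oracle-verified) for tiny samples.
* The occurrence criterion's false-positive rate depends on the window
  lengths; k_sd should be recalibrated if windows change.
* Registration is integer-pixel; subpixel motion leaves residual jitter
  that the median baseline must absorb.
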