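# Methods

## Scope and data model

The pipeline operationalises a prognostic fall-risk analysis of daily-life
trunk accelerometry. Its unit of data is the *locomotion bout*: a contiguous
triaxial acceleration series (AP/ML/VT axes, in g, clipped to the ±6 g sensor
range) attributed to one subject. Bouts are cut into fixed 10-s windows; a
network scores each window; a subject's prediction is the **median** of their
window scores; subject medians against faller labels give the ROC and AUC.
Because real cohort data of this kind is not redistributable, the package
ships a generative stand-in whose statistical structure carries exactly the
properties the analysis needs: per-subject gait signatures, a configurable
faller effect, and non-gait contamination.

## The synthetic cohort generator

**Subjects.** `generate_cohort(n, faller_fraction)` draws exactly
`round(n·faller_fraction)` fallers (default prevalence 0.341; 296 subjects
yield 101 fallers). Attributes are independent draws: age ~ N(75.3, 6.8²) y,
height ~ N(170.6, 8.8²) cm, one gender category with probability 0.741.
The emulated population's printed weight summary is internally inconsistent
(mean 49.2 kg versus quartiles 64.0/81.8 kg); the default follows the
quartile-implied centre, N(72.9, 13.3²) kg, and the mean is config-exposed so
either reading can be used. Neither is treated as ground truth.

**Gait signal.** Each subject owns a signature: step frequency f ~ U(1.2,
2.4) Hz, per-axis amplitudes (≈0.25/0.18/0.35 g for AP/ML/VT, subject spread
0.06 g), relative harmonic powers for harmonics 2–4, per-axis phase offsets,
a variability coefficient v ~ U(0.02, 0.08), and sensor noise (σ = 0.05 g).
A bout is a harmonic series over a stride phase whose per-cycle frequency and
amplitude are jittered by v; the ML fundamental sits at f/2, reflecting
left/right stride alternation; VT carries a +1 g gravity offset. This is the
minimal model that produces cyclic, subject-identifiable walking traces; it
does **not** emulate turning, dual tasks, surface changes, sensor drift,
non-wear, or postural transitions, so a passing test shows the pipeline's
mechanics, not clinical validity.

**Faller effect.** Fallers get variability multiplied by δ (default 1.5) and
step frequency shifted by −Δf (default 0.2 Hz, clipped to the band). Both are
configurable; δ = 1 with Δf = 0 yields a null cohort in which labels carry no
signal. On true parameters, logistic scoring of variability alone gives an
oracle subject AUC near 0.9 at δ = 1.5 — the label is recoverable in
principle, while window-level estimation noise keeps the learned task
realistically hard.

**Non-gait contamination.** With probability `contamination_rate` a bout is a
slow cyclic trunk movement (dominant VT frequency drawn at or below 0.2 Hz)
plus noise — the kind of cycling- or kitchen-movement segment a bout detector
mislabels as walking. These windows carry the subject's label but no
label-relevant information.

## Preprocessing

Windows are consecutive and non-overlapping (overlap is config-only, for
sensitivity checks); a trailing remainder is discarded. The *dominant
vertical frequency* is the argmax of the rectangular-window periodogram of
the mean-removed VT channel, DC bin excluded, giving 0.1 Hz resolution for
10-s windows; a constant channel is defined as 0 Hz and flagged degenerate.
The gait filter excludes windows with dominant frequency ≤ threshold
(default 0.2 Hz, boundary inclusive) and degenerate windows. The estimator
choice (no taper, mean removal, argmax) is ours; single tones in
(0.3 Hz, Nyquist) are recovered within one bin.

Optional input standardization: `window` z-scores each window per channel
(removing amplitude scale and the gravity offset — this suppresses
subject-amplitude shortcuts and is used by the filter-benefit profile);
`global` standardizes with training-partition statistics only.

## Splits

Splits stratify on the faller label at both levels. The test fraction is 10%;
the remaining 90% block is split 80/20 into train/validation for early
stopping (the internal ratio is our choice; it is config-exposed). K-fold
plans use stratified folds with the same 80/20 rule inside each fold. With
small partitions the achievable faller ratio is quantised, so the ±5
percentage-point stratification tolerance is enforced up to the 1/size
rounding granularity; truly infeasible stratifications (e.g. a single faller)
are rejected with the violated constraint named.

## Networks and training

The reference ConvLSTM topology is five 1-D convolutional layers — filter
counts [N, N, N, ¾N, ¾N] (the ¾ taper reads an ambiguous printed "34N" as
3/4·N, since 34·N filters is implausible; the taper is configurable) — each
followed by dropout, then one LSTM layer of width N, then dense heads. The
CNN family replaces the LSTM with global average pooling; the LSTM family
stacks ≥2 recurrent layers on the raw signal. Kernel size (9 samples),
stride 1, ReLU, dropout rate, Adam, learning rate 10⁻³, batch 64, epoch
budget and patience are all defaults of this package, not claims about the
original study's settings; everything is config-exposed.

The main head is a 2-unit softmax with cross-entropy; ŷ is the faller-class
probability. Auxiliary heads: identity — softmax over the cohort vocabulary
with categorical cross-entropy; gender — 1-unit sigmoid with binary
cross-entropy; age/weight/height — linear unit with squared error on targets
standardized by training-set statistics. The total loss is
Σ_heads weight·loss; training history records the realized total *and* each
head's unweighted loss every epoch so the decomposition is auditable to
float precision. Early stopping monitors the weighted validation loss and
restores the best epoch's parameters. With 10⁴:1 main:auxiliary weights the
optimizer still behaves because Adam's per-parameter normalisation absorbs
the scale; the *mix* of gradients, not their magnitude, changes.

Everything runs on a small numpy layer engine written for this package
(im2col convolution, backpropagation-through-time LSTM, inverted dropout,
Adam); gradients are verified against central finite differences in the test
suite. Training is deterministic given the spec seed.

### Desk-scale profiles

The experiment defaults target a single CPU: 25 Hz sampling (250-sample
windows), N = 8–12 filters, tens of subjects, 2 folds, tens of epochs. Two
pooling stages (stride-2 average pooling after the first two conv layers)
shorten the recurrent sequence while keeping the decimated rate (6.25 Hz)
above twice the gait band, so cycle-level structure survives; profiles that
rely only on low-frequency envelope information (identity memorisation) may
pool after every layer. A full-scale profile (296 subjects, 100 Hz, N = 128,
no pooling) is reachable through the same configs given cluster time.

Where a phenomenon needs a margin measurable at this scale, the profile says
so explicitly: the filter-benefit comparison uses an exaggerated faller
effect (δ = 5, i.e. class-separable variability) because at δ = 1.5 the
desk-scale network's subject-level AUC (~0.59) leaves the filter's gain
inside fold noise; the leakage and null profiles use δ = 1 so that any
sample-level skill is pure identity leakage.

## Evaluation

AUC is the trapezoidal area under the ROC over all thresholds and equals the
concordant-pair fraction with half credit for ties; the test suite asserts
this equivalence against a brute-force oracle. Single-class label vectors
flag the AUC undefined rather than returning a number. Identity heads are
scored one-versus-all per subject at the window level; all-tied score columns
fall back to 0.5 by the tie convention. Arm comparisons: a two-sample z-test
on fold-AUC summary statistics (mean, sd, n) — degenerate zero-variance
cases return p = 1 for equal means and are rejected otherwise — and paired or
unpaired t-tests on fold-AUC vectors (unpaired by default; whether pairing
across folds is appropriate is left to the caller, and both are provided).
Hanley–McNeil intervals accompany single AUCs but drive no decisions.

## Known limitations

* The generator's harmonic gait model has no biomechanical fidelity beyond
  cyclicity, per-subject stability and the configured faller effect;
  magnitudes of AUCs on synthetic cohorts are not comparable to clinical
  values, only directions and invariants are meaningful.
* Desk-scale stochastic checks (leakage gap, loss-weight trade-off, filter
  benefit) are fixed-seed directional tests with margins, not calibrated
  power analyses; fold-to-fold AUC variance at 20–80 subjects is large.
* The numpy engine is single-threaded and unsuitable for full-scale (100 Hz,
  N = 128) training; the configs express that scale but the compute budget
  must come from elsewhere.
* Bout detection from continuous raw recordings, survival-style time-to-fall
  modeling and the biomechanical-feature baseline are out of scope.
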