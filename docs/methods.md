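# Methods

This note records the models, conventions and design choices behind
`emgresp`, in the spirit of a statistical-software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

After cervical spinal cord injury, functional electrical stimulation (FES)
therapy improves strength in some upper-extremity muscles and not others.
The pipeline's target quantity is a binary muscle-level label — *responder*
vs *non-responder* — defined from the manual muscle testing (MMT) score
(ordinal 0–5) recorded before each therapy session, and predicted from
surface-EMG (sEMG) features of baseline voluntary contractions plus
clinical covariates.

## Responder labeling

For each muscle the MMT trajectory {(sessionᵢ, scoreᵢ)} is summarized by
Kendall's tau-b between score and session number. Tau-b is used because MMT
scores are heavily tied; the tie-corrected denominator keeps |τ| ≤ 1 under
ties. The muscle is a responder iff τ > 0 **and** p < α = 0.01. The p-value
is two-sided — the τ > 0 condition supplies the direction — and computed
by exact permutation enumeration below 10 sessions (ties make the standard
exact tables inapplicable; the tie structure is permutation-invariant, so
enumeration runs on the concordance numerator) and by the tie-corrected
normal approximation otherwise. Degenerate all-tied trajectories are
defined as τ = 0, p = 1 (non-responder). Muscles whose baseline MMT is
already 5 cannot improve on the scale and are excluded before labeling.

A positive τ requires at least one score increase between some pair of
sessions; the labeling tests assert this implication on every labeled
cohort.

## Signal preprocessing

Recordings are modelled as 4 kHz, 20–450 Hz band-limited sEMG in mV.
Preprocessing applies, in order: offset removal; a 4th-order Butterworth
20–450 Hz bandpass run forward–backward (zero phase), which makes the
pipeline self-contained when the acquisition hardware has not already
band-limited the signal; a second-order IIR notch at 60 Hz with Q = 30
(single fundamental only); and a final mean subtraction, because
zero-phase filtering of a finite record leaves an O(10⁻³ · RMS) edge
offset and downstream features assume a mean-free signal.

The analysis segment is the 3 s window of the filtered MVC trial with the
lowest sample standard deviation, searched at a 0.05 s stride (the final
admissible start is always a candidate); ties resolve to the earliest
window. The stride is a speed/exactness compromise — the tests verify
agreement with exhaustive per-sample search on short fixtures.

## Feature bank

With samples x₁…x_N and Δxᵢ = xᵢ₊₁ − xᵢ:

- p2p = max − min; MAV = mean|x|; RMS = √(mean x²); VAR = Σ(x−x̄)²/(N−1);
  logD = exp(mean log max(|x|, 10⁻¹² mV)) (floor guards log 0).
- wLen = Σ|Δx|; DAMV = wLen/(N−1); M2 = Σ(Δx)²; DVARV = M2/(N−2).
- Deadzone counts with shared threshold ε = 10 µV (configurable):
  ZERC counts sign changes with |Δx| ≥ ε; SSC counts interior samples with
  (xᵢ−xᵢ₋₁)(xᵢ−xᵢ₊₁) ≥ ε (a product of slopes, so its natural threshold
  scale is amplitude²); wAmp counts |Δx| ≥ ε.
- MeanF and MedF from a Welch PSD (Hann, 1024-sample blocks, 50 % overlap):
  spectral centroid and the lowest frequency reaching half the cumulative
  power.
- ARCO1–4: Yule–Walker AR(4) coefficients in predictor convention
  (x_t = Σ a_k x_{t−k} + e_t). Ceps1–4: cepstrum of the fitted AR model via
  the LPC recursion on the polynomial coefficients (−a_k); the recursion is
  tested against an independent inverse-FFT-of-log-spectrum oracle to
  1 × 10⁻⁶ rather than trusted.
- EMGH: 9 equal-width bins spanning ±3 SD, counts divided by N
  (out-of-range samples excluded, so masses sum to ≤ 1); a zero-variance
  segment puts all mass in the centre bin by convention.
- Card: distinct sample values after identifying values within 10⁻⁶ mV,
  via a greedy anchored pass over the sorted samples (a new cluster starts
  when a value exceeds the current anchor by more than the tolerance).

Exact thresholds, bin counts and Welch parameters are not canonical in the
literature; all are exposed in `FeatureConfig` with the defaults above.

## Feature curation

*Hudgins* and *MD* are fixed column subsets (EMGH expands to its bins).
*PCA* z-scores the full bank with training statistics and keeps the
smallest number of components whose cumulative explained variance reaches
0.90. *FWD* is greedy forward selection starting from the empty set,
adding at each step the column that maximizes muscle-level MCC under
grouped cross-validation nested inside the training partition
(leave-one-group-out by default), stopping when no candidate strictly
improves; score ties break lexicographically so selection is
deterministic. Clinical categoricals (AIS, NLI, myotome) are encoded
ordinally (A<B<C<D, C2<…<C8) because responder prevalence is treated as
monotone across both scales; one-hot encoding is available by flag.

Both PCA and FWD are fitted per outer fold by the harness (no
evaluation-fold leakage); a `fwd_global` option reproduces a single
all-data selection for comparison with externally reported selections.

## Classification harness

Leave-one-participant-out: each fold holds out *all* trials of one
participant, since trials of a muscle — and muscles of a participant — are
not exchangeable. Grids are intentionally small: k-NN with k ∈ 2…7,
Euclidean and cosine metrics, distance weighting; random forest and
gradient boosting with 100 and 200 estimators; SVM with linear and
Gaussian kernels (library-default width); unpenalized-grid logistic
regression. Distance- and margin-based families are z-scored with
training-fold statistics; tree ensembles consume raw features. The grid
winner per fold is chosen by nested grouped-CV MCC on the training side
with min(5, #training participants) group folds (full inner LOPO would be
quadratic in participants for no measurable benefit at these grid sizes);
an explicit `select_on_test` mode instead picks the configuration by
held-out performance, mirroring a selection protocol that does not
describe its selection data — it is provided for comparison, never the
default. Per-trial predictions aggregate to one muscle label by majority
vote; an exact tie (possible with a 4th MVC trial) resolves to
non-responder, conservative toward the majority class. Folds whose
training side is single-class are skipped with a logged diagnostic.
Subgroup runs (AIS A-B motor complete, C-D motor incomplete) simply
restrict the participant set before folding.

## Metrics

All counts tally at muscle level. MCC, macro F1 (mean of the two
per-class F1 values), accuracy, precision, recall/TPR and TNR follow a
uniform zero-denominator convention: an undefined ratio is 0 (so a
participant with no responder muscles has recall 0, and a single-class
prediction vector has MCC 0). The chance baseline formalizes a random
predictor whose positive rate matches the prevalence π and is independent
of the truth: accuracy π² + (1−π)², precision = recall = π, TNR = 1 − π,
macro F1 = ½ exactly (F1⁺ = π, F1⁻ = 1 − π), MCC = 0. These closed forms
are verified against a 10⁵-replicate Monte-Carlo in the tests.

`reconstruct_confusion` inverts printed two-decimal metrics back to
integer confusion counts by exhaustive search over TP and FP given n and
the number of positives, using half-up rounding to the printed precision;
it errors on zero or multiple solutions, so a successful return certifies
uniqueness.

## Synthetic cohort generator

The generator exists because comparable clinical datasets are shareable
only on request; it emulates the study conditions so every downstream
stage is testable without any download. Defaults: 17 participants, AIS
A/B/C/D apportioned 2/5/2/8 (largest remainder for other cohort sizes),
NLI drawn from C2–C6 and per-muscle myotome from C5–C8 (never above the
NLI) with weights shaped after the emulated cohort's composition tables,
4–10 muscles per participant, baseline MMT drawn from 0–4 (grade-5
muscles are excluded by design, so none are generated as targets), one
60 s rest and three 5 s MVC trials at 4 kHz (a 4th MVC attempt by
probability flag), ~30 sessions, responder prevalence 0.33.

**Signal model.** MVC trials are white Gaussian noise shaped by a
4th-order Butterworth bandpass of width 120 Hz centred at 80 Hz
(non-responders), scaled to an RMS of (0.02 + 0.03·grade) mV, plus
0.004 mV white sensor noise and a 0.005 mV 60 Hz line component with
random phase; rest trials carry only the noise and line terms. This is a
band-shaped-noise stand-in sufficient to drive every feature in the bank,
*not* a physiological motor-unit model — conclusions about real sEMG
morphology cannot be drawn from it. Responder muscles receive a joint
planted effect: the spectral centre shifts by `effect_medf_shift`
(default +40 Hz) and the amplitude scales by `effect_amp_gain` (default
1.5). Effect sizes are test knobs, not physiological estimates.

**Trajectory model.** Responders follow a monotone staircase gaining
between `responder_gain` (default 1) and (5 − baseline) grades, with one
step placed uniformly in each equal block of the central 60 % of the
cycle; non-responders stay at baseline. Both classes receive transient
±1-grade fluctuations with per-session probability 0.10 (rater
variability). Gains are confined to the central portion because an
improvement appearing only in the first or last couple of sessions is
statistically indistinguishable from rater jitter — no rank test could
certify it — and the jitter rate is set so that the tau rule recovers
planted labels reliably (≥ 90 % per class; the acceptance suite measures
~96–98 % responder and 100 % non-responder recovery over 200 replicates).

**Determinism.** Every random draw comes from a generator keyed by
(seed, participant, muscle, trial, stream tag), so any sub-entity can be
re-derived independently and identical configurations serialize to
byte-identical manifests.

## Problem sizes in tests and the acceptance script

The generator's defaults are the study conditions above; the test suite
and the acceptance script run it at reduced size — typically 10
participants with 4–6 muscles each, 2 kHz sampling, 3 s MVC trials with a
2 s analysis window, 2 s rest trials — which preserves every pipeline
property being tested while keeping the whole suite in the tens of
seconds. The acceptance script reports the problem size (`n`) next to
every value it computes.

## Known limitations

- The closed-form and reconstruction results are exact arithmetic; the
  synthetic end-to-end results characterize the pipeline under the planted
  effect model only. A strong planted effect yields near-perfect LOPO MCC;
  nothing about real-data performance follows from that beyond the absence
  of leakage (checked separately and exactly).
- The signal model has no motor-unit structure, no fatigue, no
  within-trial nonstationarity beyond the steady-state assumption, no
  electrode placement or skin-impedance variation, and no FES artifacts.
- Clinical covariates are sampled independently per participant/muscle
  (apart from the myotome ≥ NLI constraint); real cohorts correlate AIS,
  NLI and baseline MMT.
- The exact-permutation p-value enumerates all orderings and is intended
  for short trajectories (< 10 sessions); longer trajectories use the
  asymptotic approximation.
- Lower-motor-neuron categories from intramuscular EMG are carried as an
  optional participant covariate only; no iEMG analysis is implemented.
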