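# Methods

`kicksyn` reproduces, on synthetic data with known ground truth, a
muscle-synergy analysis of surface EMG (sEMG) recorded during a maximal
martial-arts side kick performed after three post-activation performance
enhancement (PAPE) conditioning protocols, together with the accompanying
vertical-jump analysis.  This note records the model, the defaults, and the
design decisions, in the package's own terms.

## Study design emulated

A fully within-subject crossover: 18 athletes each complete three
conditioning protocols — ESG (squat plus neuromuscular electrical
stimulation), RBG (resistance-band lateral steps), SQG (heavy barbell
squat).  Per protocol session: 6 maximal side kicks recorded on 15 sEMG
channels at 2000 Hz (12 kicking-side muscles, 3 supporting-side muscles,
`muscles.MUSCLES` order), and three countermovement jumps at 6, 8 and
10 min post intervention, best of three retained.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

**Synergy ground truth.**  Non-negative weights `W` (15 × 3, unit-norm
columns) with squared-exponential entries, rejection-sampled until all
pairwise column cosines are below 0.8 so the synergies are genuinely
distinct; activation coefficients `C` (3 × 100) are single Gaussian bumps
with distinct centers spread over the normalized cycle (centers near
15/50/85% ± 5, widths 6–10% of cycle).  Single bumps match the unimodal
activation curves typical of discrete maximal efforts and make the temporal
features well defined.

**Protocol effects** are multiplicative per-muscle weight modifiers: ESG
boosts the hip/knee extensors GM, RF and RFR by ×1.3, RBG boosts the
lateral chain VL and GMed by ×1.3, SQG is the reference.  Directions mirror
the between-protocol weight differences of the emulated study; the
magnitude is configuration, not a claim.  Because fitted weight columns are
renormalized to unit length, boosting some muscles necessarily *lowers* the
relative weights of all others under that protocol; on low-noise data the
group comparison therefore flags many non-boosted muscles in the opposite
direction.  This is a property of the generative design plus the unit-norm
convention, not a statistical artifact.

**Raw-EMG surrogate.**  A trial is `E(t) · c(t) + noise`, where `E` is the
ground-truth envelope `W·C` placed over the movement cycle `[a, e]` of a
duration-jittered trial (1.5 s ± 10%), and `c` is a zero-mean, 20–400 Hz
band-limited carrier with unit mean rectified amplitude.  The carrier is
*constant-amplitude, random-phase*: band-limited Gaussian noise divided by
its own Hilbert envelope.  A plain Gaussian carrier was tried first; its
rectified amplitude fluctuates below 20 Hz and survives the envelope
low-pass as multiplicative noise, capping single-trial envelope recovery
near r ≈ 0.94.  With amplitude stabilization the rectified carrier varies
only at twice the carrier frequencies, the full preprocessing chain
recovers `E` at r ≈ 0.985–0.99 per channel, and the generator's envelopes
are exactly what the pipeline is supposed to estimate.  Additive Gaussian
noise has SD equal to `noise_sd` × mean envelope amplitude (default 5%).
Matrix-level surrogates (`synthesize_activation_matrix`) add the same noise
directly to `W·C` and clip at zero to remain valid factorization input.

**Between-subject variability**: each subject's weights are jittered
multiplicatively (SD 5%) and renormalized; MVC references sit 10% above the
subject's largest envelope.  **Jump heights**: the best-of-three height per
cell is drawn as `mean + √ρ·sd·z_subject + √(1−ρ)·sd·ε` (ρ = 0.5, shared
subject factor), so cell means/SDs match the configured table (defaults:
ESG 49.1 ± 2.8 cm at 6 min, etc.) while repeated measures correlate at ρ;
the two remaining jumps are the best minus exponential gaps, and flight
times invert h = g·t²/8.  Seeding fans out from one integer through
`numpy.random.SeedSequence`, making datasets byte-reproducible.

What the generator does **not** emulate: motor-unit physiology, fatigue or
learning across trials, electrode/crosstalk artifacts, kinematic events
(cycle marks are placed at fixed trial fractions), or protocol effects on
the *temporal* coefficients.  Passing tests therefore certify the analysis
chain — preprocessing fidelity, factorization, order selection, statistics
— under a controlled signal model, not the physiological claims themselves.

## Preprocessing

Per trial: 4th-order Butterworth band-pass 20–400 Hz, full-wave
rectification, 4th-order 20 Hz low-pass (linear envelope), amplitude
normalization, piecewise-linear interpolation of the cycle onto 100 points,
then the 6 trials of a session are averaged elementwise into the activation
matrix `D` (15 × 100).  Filters are applied forward–backward
(`sosfiltfilt`), so the effective attenuation is squared and no phase lag
biases onset/offset estimates; the stated order is the design order before
doubling.  Linear interpolation is used because it is monotone and
preserves non-negativity.  Normalization defaults to the MVC reference
(per-muscle maximum voluntary contraction amplitude), with a `task_max`
mode (divide by the channel's session maximum) as the alternative; the mode
is recorded in the run log.  Tiny filter undershoots are clipped at zero so
`D` is valid NMF input.

## Factorization and model order

`D ≈ W·C` with all factors non-negative, fitted by Lee–Seung
multiplicative updates for the squared Frobenius loss: 20 seeded random
restarts (uniform (0, 1] scaled to the data), up to 1000 iterations each,
stopping when the relative loss change falls below 1e-6; the best restart
is kept.  Fitted weight columns are rescaled to unit Euclidean norm (scale
moved into `C`), which keeps weights comparable across subjects and
protocols and in [0, 1].

Variance accounted for is uncentered: `VAF = 1 − SSE/SST` with
`SST = ΣD²`, the standard convention for non-negative envelope data (a zero
reconstruction scores 0); a mean-centered variant is available by flag.
Model order is the smallest synergy count with VAF ≥ 0.90.  Order selection
walks orders upward and warm-starts each order with the previous solution
padded by a small random extra synergy, which makes the best-of-restarts
VAF curve monotone up to solver tolerance; the full curve is kept for
reporting.

**Labeling and matching.**  Within a model, synergies are numbered by
ascending coefficient peak time (SYN1 peaks first).  Across protocols,
synergies are paired by maximizing total weight-column cosine similarity
(linear assignment); each subject's RBG/SQG models are aligned to that
subject's ESG model before any group statistic.  When selected orders
disagree across sessions, all sessions are refitted at the modal order so
group tables are well defined.

## Temporal activation features

On the 0–100% cycle timeline a synergy is active where its coefficient is
at or above 20% of its own maximum (configurable; the threshold appears in
every output row).  Duration `T` is the count of active samples (bounded by
100 under this definition — duration values exceeding the cycle length are
not representable and not a target of this package), `T_max` is the argmax
position, `T_start`/`T_stop` the first/last active samples.  Plateau ties
resolve to the first sample for onset and peak, the last for offset.
All-zero curves are flagged inactive (duration 0, onset/offset NaN).
Features are scale-invariant and shift-equivariant by construction.

## Jump heights and statistics

Heights come from flight time via h = g·t²/8 (g = 9.81 m/s², output in
cm); the best of three jumps per subject × protocol × time point enters
analysis.

**Normality gate.**  Each outcome is Shapiro–Wilk tested per cell at
α = 0.05; the parametric branch is taken only if no cell rejects.  Constant
cells are degenerate and force the non-parametric branch.

**Parametric branch.**  Fully within-subject RM-ANOVA: jump height uses
the two-way 3 (protocol) × 3 (time) partition, synergy outcomes the
one-way partition.  Each effect is tested against its own
subject × effect interaction (standard univariate error terms; with 18
subjects the dfs are (2, 34) for main effects and (4, 68) for the
interaction), sphericity ε = 1 (no Greenhouse–Geisser correction, matching
the integer dfs; a correction hook exists in the power spec only).  Effect
size is partial eta squared, `SS_effect/(SS_effect + SS_error)`, with
0.01/0.06/0.14 used as small/medium/large *labels* only.  Post hoc paired t
tests use Bonferroni correction.

**Non-parametric branch.**  Friedman's rank test (midranks for ties, the
standard tie-corrected chi-square, df = k−1; Kendall's W reported
descriptively), then Wilcoxon signed-rank post hocs (zeros dropped —
Wilcoxon's original rule — normal approximation without continuity
correction) with Holm correction.  Cohen's d for these comparisons is
converted from the Z statistic: `r = Z/√n`, `d = 2r/√(1−r²)`, with the Z
sign oriented by the median paired difference.

**Gating.**  Post hoc families run only when the omnibus effect is
significant (for jumps: the two-way protocol main effect or interaction;
per muscle × synergy: that family's omnibus).  Under a null configuration
this keeps spurious table annotations rare; with 45 weight families at
α = 0.05 each, *some* family-wise false positive is still expected in most
null runs — the calibration claim is therefore stated for the jump table,
and per-family error control is the guarantee for the weight table.

**A priori power.**  Within-factor repeated-measures power uses the
noncentral F with numerator df (m−1)·ε, denominator df (N−1)(m−1)·ε and
noncentrality λ = N·f²·m·ε/(1−ρ).  This convention reproduces the
canonical worked example (f = 0.25, α = 0.05, power 0.80, m = 3, ρ = 0.5 →
N = 28).  For f = 0.30 with the same settings it first reaches 0.80 power
at N = 20 (power 0.706 at N = 16); published sample-size statements of 16
for these inputs are not reproducible under this convention — they would
require ρ ≈ 0.6 or f ≈ 0.34 — and the package reports what the formula
yields.

## Problem sizes and reproducibility

Default analysis runs use the full design (18 subjects × 3 protocols × 6
trials, 2000 Hz, 20 NMF restarts; `analysis/03_run_study_pipeline.py`
completes in well under a minute).  The test suite exercises the same code
paths on reduced configurations chosen as the smallest designs that still
express each property (3–6 subjects, 1–2 trials, 1000 Hz, 5 restarts);
Monte-Carlo calibrations use 50–1000 seeded replicates as stated in each
test.  Every stochastic step derives from one integer seed via
`SeedSequence`, and `run_pipeline` writes a manifest of content hashes:
identical configurations reproduce identical outputs byte for byte.

## Known limitations

* The generator's cycle events are metronomic (fixed trial fractions); no
  event-detection code exists, so segmentation robustness to annotation
  error is untested.
* Temporal features assume a single activation burst per synergy;
  multi-burst curves would report the envelope of all bursts.
* VAF is global only; per-muscle VAF is not computed.
* The NMF landscape is non-convex: equivalence with other solvers is
  asserted at matched budgets within 1%, not to the global optimum.
* Protocol metadata: the stimulation protocol is specified inconsistently
  in its source material (75 Hz vs 80 Hz carrier); the generator does not
  model stimulation waveforms, so nothing here depends on the resolution.
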