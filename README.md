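# kicksyn

Muscle-synergy analysis of surface EMG (sEMG) from a martial-arts side
kick performed under three post-activation performance enhancement (PAPE)
conditioning protocols, with the accompanying vertical-jump analysis — 
implemented as a tested, seeded pipeline over a synthetic-data generator
with known ground truth.

**Who it is for.**  Researchers in neuromuscular biomechanics who want a
reproducible reference implementation of the standard synergy-extraction
chain (envelope preprocessing → non-negative matrix factorization →
variance-accounted-for model selection → temporal features → repeated-
measures statistics), and who need to validate every stage against data
whose generative structure is known exactly — something undeposited human
recordings cannot offer.

## The model

Each session's 15-muscle activation matrix **D** (muscles × 100 normalized
time points, built by 20–400 Hz band-pass, rectification, 20 Hz low-pass,
MVC normalization, 100-point time normalization and 6-trial averaging) is
factorized as

    D(t) ≈ Σᵢ Wᵢ Cᵢ(t),   W, C ≥ 0

with time-invariant synergy weights `W` (unit-norm columns) and activation
coefficients `C`, fitted by Lee–Seung multiplicative updates.  The number
of synergies `N_syn` is the smallest order whose reconstruction achieves

    VAF = 1 − SSE/SST ≥ 0.90,   SSE = Σ(D − WC)²,  SST = ΣD².

Jump height follows the flight-time law `h = g·t²/8`.  Group comparisons
use Shapiro–Wilk-gated RM-ANOVA with partial η² (or Friedman), and
Bonferroni- or Holm-corrected post hocs.  Details and all design decisions
are in [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
tables under `results/`:

```bash
python analysis/01_simulate_study.py      # build the synthetic crossover
python analysis/02_validate_recovery.py   # check ground-truth recovery
python analysis/03_run_study_pipeline.py  # full pipeline -> results/study/
python analysis/04_summarize_synergies.py
python analysis/05_jump_statistics.py
```

`02_validate_recovery.py` prints (seeded, reproduced exactly):

```
envelope recovery (noise-free trial): per-channel r min=0.9881 median=0.9950
noise 0.00: selected order 3, VAF 100.00%, weight cosines [0.997 1.    1.   ]
noise 0.05: selected order 3, VAF 99.98%, weight cosines [0.999 1.    1.   ]
```

i.e. the preprocessing chain recovers the generative envelope per channel,
the VAF ≥ 90% criterion selects exactly the three generative synergies, and
the fitted weight columns match the ground truth at cosine ≥ 0.997 even
with 5% noise.  `05_jump_statistics.py` prints the jump branch:

```
two-way RM-ANOVA on best-of-3 jump height:
  protocol: F(2, 34) = 25.13, p = 0.0000, eta_p^2 = 0.597 (large)
  time: F(2, 34) = 17.74, p = 0.0000, eta_p^2 = 0.511 (large)
  protocol x time: F(4, 68) = 2.62, p = 0.0427, eta_p^2 = 0.133 (medium)

per time point (mean +/- SD cm; Bonferroni post hocs):
  6 min: ESG 49.5+/-3.6  RBG 46.0+/-2.8  SQG 45.9+/-2.7   F = 11.97, p = 0.0001   ESG > RBG; ESG > SQG
  8 min: ESG 48.6+/-2.8  RBG 45.3+/-2.9  SQG 47.6+/-3.3   F = 16.64, p = 0.0000   ESG > RBG; SQG > RBG
  10 min: ESG 46.5+/-2.5  RBG 44.4+/-3.1  SQG 44.3+/-3.7   F = 5.19, p = 0.0108
```

The ESG advantage recovered here is the effect injected by the generator's
configured jump-height table; the dfs (2, 34)/(4, 68) are those of the
18-subject 3 × 3 fully within-subject design.

## Layout

```
src/kicksyn/        library: synthgen, preprocess, synergy, timing,
                    jumpstats, interface (I/O + pipeline), muscles
analysis/           numbered study drivers (thin, narrative)
tests/              pytest suite incl. acceptance criteria
scripts/            acceptance.py
docs/methods.md     models, defaults, design decisions, limitations
```
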