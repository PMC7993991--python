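# wmazeseq

Multi-timescale ensemble-sequence analysis of hippocampal (CA1) and
prefrontal (PFC) recordings from a W-maze continuous-alternation task,
together with a synthetic-session generator that provides full ground
truth for every analysis stage.

## What it does

Given a session (spike trains with region tags, a 30 Hz position trace,
1.5 kHz LFP channels, and a trial table), the pipeline computes:

- **behavior** — position linearization onto idealized paths for the four
  trajectory types (C-to-L, L-to-C, C-to-R, R-to-C), speed, well
  entry/exit refinement, locomotion (>5 cm/s) / immobility (≤4 cm/s)
  masks, and before/after choice-point segmentation;
- **ratemaps** — 2-cm linearized firing-rate maps (4-cm-SD Gaussian
  smoothing), the 3 Hz place-cell criterion, the trajectory selectivity
  index (|SI| > 0.4 CA1 / 0.2 PFC), spatial-field detection, and the
  field asymmetry index;
- **lfp** — 6–12 Hz theta phase, population-defined theta-cycle
  segmentation, ripple-band (150–250 Hz) SWR detection during
  immobility, spike phase locking (Rayleigh test), and theta band
  power/coherence summaries;
- **decode** — the memoryless Poisson Bayesian decoder over
  (position × trajectory), at the behavioral timescale (τ = 120 ms,
  60 ms steps) with per-window MAP choice accuracy;
- **thetaseq** — candidate theta cycles (≥5 active cells, >10 cm/s,
  100–200 ms), 20 ms / 10 ms event decoding, weighted-correlation and
  best-fit-line (R_max) sequence scores with space-circular shuffle
  significance, forward/reverse classification, distance index,
  actual-vs-alternative choice representation, and CA1–PFC coherence;
- **cycleskip** — triangular-corrected spike autocorrelograms and the
  cycle-skipping index CSI = (p2 − p1)/max(p1, p2);
- **phaseprec** — circular-linear regression of spike theta phase on
  within-field position;
- **replay** — Bayesian replay detection inside ≥50 ms SWRs (10 ms bins,
  R² of MAP-position regression vs circular time shuffles) and CA1–PFC
  reactivation strength (C_RUN vs C_SWR matrix correlation);
- **predict** — trial-by-trial RBF-SVM classifiers: choice from
  theta-sequence counts and correct/incorrect outcome from pre-trial
  reactivation strength, with permutation nulls and ROC/AUC.

The `synthio` module simulates complete sessions (alternation behavior,
trajectory-selective place/PFC cells with phase precession and optional
cycle skipping, theta/ripple LFP, planted SWR replay content) with every
planted parameter recorded, so all estimators can be validated against
ground truth.

## CLI

```bash
# simulate a session with ground truth
wmazeseq simulate --out sess/ --seed 1 [--config cfg.yaml]

# run the full pipeline, write result tables + summary.json
wmazeseq run --session sess/ --out results/ --seed 0

# individual stages and a figure report
wmazeseq thetaseq --session sess/ --out results/
wmazeseq cycleskip --session sess/ --out results/
wmazeseq report --session sess/ --out results/
```

A config YAML may set any `SimConfig` field (`n_trials`, `n_ca1`,
`selectivity_frac`, `theta_hz`, `swr_rate_hz`, ...).

## Layout

```
src/wmazeseq/      one module per pipeline stage (see above), plus
                   config.py (maze/sim parameters), io.py (session
                   container), pipeline.py (orchestration), cli.py,
                   testing.py (planted-event constructors)
tests/             pytest suite; test_acceptance.py holds the
                   acceptance criteria
scripts/           acceptance.py
```
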