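# divekin

A pipeline for analyzing soccer-goalkeeper penalty diving saves from
center-of-mass (CM) trajectories and force-plate signals: event detection,
Butterworth filtering with residual-analysis cutoff selection, the 14
kinematic/kinetic outcome variables, and paired statistical comparisons
(rule effect, laterality effect, rule-within-side) — plus a mechanistic
synthetic-dive generator with an exact analytic truth channel so every
stage is testable without any external data.

## What it computes

Per trial, from a 3-D CM path (nominally 400 Hz) and a 3-D ground reaction
force (nominally 2000 Hz, ipsilateral lower limb):

| Group | Variables | Units |
| --- | --- | --- |
| Displacement (CM z-min → z-max window) | VD, MLD, APD, RD | m |
| Velocity | AV (RD / window duration), PV (peak resultant speed) | m/s |
| Peak force (push-off phase) | VPF, MLPF, APPF, RPF | ×BW |
| Impulse (trapezoidal, push-off phase) | VI, MLI, API, RI | ×BW·s |

Across trials, every variable is compared under four paired designs: old vs
new rule, dominant- vs non-dominant-side dives (IPLAG 1–2 left-footed, 4–5
right-footed), and rule within each relative side — Shapiro–Wilk per group,
paired Student t, Cohen's d, significance at p ≤ 0.05, plus a clearly
non-primary Holm-adjusted column.

## CLI

```bash
divekin simulate --config cfg.json --out data/ --seed 1   # synthetic session
divekin process  --in data/ --out results.csv             # 14 variables/trial
divekin stats    --in results.csv --out report.csv        # 56 comparisons
divekin run      --config cfg.json --out out/ --seed 1    # all of the above
```

`divekin simulate` writes one `cm.csv`/`grf.csv` pair per trial (unit-bearing
headers), a `trials.json` manifest, and `truth.csv` with the generator's
exact per-trial outcome values. `--cutoff auto` on `process` selects the
low-pass cutoff by residual analysis instead of the 10 Hz default;
`--cutoff none` disables filtering (appropriate for noise-free synthetic
data).

A minimal session config:

```json
{"subjects": [{"subject_id": "S1", "body_mass_kg": 81.6, "iplag_score": 5}],
 "n_per_cell": 5, "noise_sd_pos_m": 0.002, "noise_sd_force_n": 5.0}
```

## Synthetic generator

`simulate_dive` builds a continuous-time dive (quiet stance →
countermovement → push-off → ballistic flight) from piecewise polynomials
with continuous position/velocity; during contact the force satisfies
F = m(a + g·ẑ) exactly and reaches zero at takeoff, and after takeoff the CM
is ballistic. Both channels are sampled on independent clocks with optional
white Gaussian noise. Ground truth (all 14 variables plus event times) is
computed from the continuous model — polynomial extrema/integrals in closed
form — never from the samples, so recovery error is attributable to the
processing pipeline. The new-rule condition is injected via a configurable
frontal-step anteroposterior excursion; a laterality effect can be injected
via extra non-dominant-side reach.

`simulate_outcome_table` provides a fast outcome-level session generator
(trial outcomes drawn around the analytic truth) for large replicate studies
such as null-calibration and power checks.

## Conventions

Axes: X transversal (mediolateral), Y sagittal (anteroposterior),
Z longitudinal (vertical); positions m, forces N, time s; g = 9.81 m/s².
Filtering is zero-phase (forward–backward) 4th-order Butterworth with the
per-pass cutoff widened so the combined −3 dB point equals the requested
cutoff; a single-pass option exists. Displacements and per-axis force
integrands are reported as absolute values (signed integration available).
Pairing for the t-tests defaults to per-subject condition means
(`--pairing trial_matched` emulates pooled trial-level pairing).
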