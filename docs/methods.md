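# Methods

## Design generation

A stimulus inventory has 12 characters: 3 consistent (CC) and 9
inconsistent, the latter split into orthographically (IOr), phonologically
(IPh) and semantically (ISe) inconsistent triples; every category spans the
three phonetic-radical sets exactly once. The synthetic inventory draws
corpus frequencies log-uniformly on [1, 300] per million and 1–7
consistency ratings centred at 6 (consistent dimensions) or 2 (the
category's inconsistent dimension) with 0.5 SD jitter, clipped to the
scale.

Sequences enforce **exact counts** rather than sampling probabilities: a
420-trial oddball block has exactly 315 standards (CC, 105 per character)
and 105 deviants (35 per character of one inconsistent category); the
480-trial equal-probability block has exactly 40 trials per character.
Deviant positions are drawn uniformly over all non-adjacent placements via
the bijection between k non-adjacent choices from n slots and k unordered
choices from n − k + 1, so no rejection loop is needed there. Colour-change
targets (round(0.1·n)) are placed by shuffled greedy selection (retry cap
200) on positions whose predecessor is a non-target standard (oddball) or
any non-target (equal-probability — the target rule is only stated for
oddball blocks, so the weaker form is used there); targets in oddball
blocks sit on standard trials. Onsets accumulate 200 ms stimulus + uniform
500–600 ms blank. `validate_sequence` re-derives every invariant and is run
over fresh seeds in the tests.

Target trials are excluded from all ERP/RSA selections by default
(configurable via `include_targets`), since their task relevance makes
them atypical.

## The synthetic EEG generator

Each subject is a continuous float32 recording (61 scalp channels on the
10–10 system, positions from the MNE standard montage; 1000 Hz) containing:

- a **common evoked complex** for every stimulus: Gaussian components at
  120 ms (+3 μV, σ 25), 170 ms (−4 μV, σ 30) and 240 ms (+2.5 μV, σ 45),
  weighted toward posterior channels;
- **representational effects**: for dimension d with window [a, b] and
  amplitude A, each trial adds `p_d · A · sin(π·(t−a)/(b−a)) · f_d(char)`,
  where `p_d` is a seeded unit-norm spatial pattern and `f_d` is 0/1
  category membership (consistency) or the standardised log₁₀ frequency;
- a **deviance response**: −A μV at the six ROI channels over its window,
  on deviant-role trials only;
- **noise**: `σ·(√(1−π)·w + √π·pink)` with w white and pink a one-pole
  AR(1) filter (a = 0.98) of an independent white series scaled to unit
  asymptotic variance; σ = 8 μV, π = 0.5 by default.

Spatial patterns are constrained to be **zero at the six ROI channels and
zero-sum**. Zero-sum makes them invariant under average referencing;
keeping them out of the ROI makes the deviance ground truth separable from
the representational ground truth (an unconstrained random pattern projects
up to ±4 μV onto a 6-channel ROI mean, which would swamp — or sign-flip —
the −2 μV deviance response). RSA is indifferent to which channels carry a
pattern, so nothing about the representational ground truth is lost.

Default effects: consistency patterns over 150–500 ms injected **in the
oddball condition only** (base amplitude 0, oddball boost 6 μV), a
frequency pattern over an underlying 140–240 ms window in both conditions
(6 μV), and a −2 μV deviance response over 150–300 ms. Two calibration
choices deserve comment:

- **Amplitudes** target the weak-effect regime of time-resolved RSA
  (subject-mean partial ρ ≈ 0.1–0.3 in-window). Much stronger effects are
  not only unrealistic; they break the max-cluster-size permutation test,
  because sign-flip permutations of a near-deterministic effect regenerate
  its own footprint under unbalanced sign draws and the cluster *p*
  saturates near the nominal level.
- The **frequency window** is wider than the ~150–220 ms footprint it is
  meant to produce: the half-cosine taper means the grid points at the
  window edges carry almost no signal, so the *detectable* cluster of a
  140–240 ms injection is ≈150–230 ms. The observed footprint, not the
  injected support, is the quantity to match.

Between-subject variability scales each effect amplitude by a truncated
normal (SD 1.5 μV by default in the pipeline). Per-subject designs, seeds
and noise derive from one master seed; cohorts are generated lazily
(`iter_cohort`) because study-scale continuous recordings run to hundreds
of MB each.

What the generator does **not** emulate: eye/muscle artifacts, line noise,
bad channels, volume conduction, trial-to-trial latency jitter of the
evoked response, or any correlation structure between noise and signal.
Passing recovery tests therefore demonstrates the correctness and
statistical behaviour of the analysis chain — not robustness to real-world
artifacts, which the out-of-scope artifact-removal stage (the `raw_hook`
in `extract_epochs`) would handle on real data.

## Preprocessing

Second-order (12 dB/oct) Butterworth band-pass 0.1–40 Hz applied
forward-backward (`sosfiltfilt`, zero phase; computed in float32 —
the deviation from float64 filtering is orders of magnitude below the
noise floor), average reference then per-channel mean detrend, epoching
−300…700 ms (sample-exact: event at sample s spans s−300…s+699), baseline
= the first 100 ms of the epoch ([−300, −200) ms — a literal reading of
"first 100 ms"; `baseline_ms` accepts the conventional [−100, 0) instead),
and ±100 μV amplitude rejection with per-condition retained counts logged.
On artifact-free synthetic noise the rejection stage rarely fires; the
tests exercise it with planted excursions.

## RDMs and RSA

Neural RDMs use individual trials, all cross-character pairs, no averaging
and no cross-validated distances; the oddball condition pools deviants
across the three oddball blocks. The lower-triangle vector order is fixed
(row-major strictly-lower: (1,0), (2,0), (2,1), …). Partial Spearman uses
average ranks for ties and least-squares residualisation with intercept;
a vector that is constant after ranking yields NaN, while a vector fully
explained by its controls yields 0 (no residual variance to correlate).
The default control scheme pits lexical against sub-lexical: frequency is
partialled out of each consistency test and the three consistency models
out of the frequency test; the radical-control model runs as an
uncontrolled standalone screen; an explicit control list overrides the
scheme.

## Cluster inference

Both tests build their null by flipping whole subject time courses with
independent random signs, and both include the observed statistic in the
null (add-one rule), so p ≥ 1/(n_perm + 1) and results are bit-reproducible
given a seed.

- **RSA (size statistic, one-sided):** cluster-forming threshold = the
  pointwise 95th percentile of the permutation *t* distribution; clusters
  are maximal supra-threshold runs scored by length; null = per-permutation
  maximum run length. On iid null data this statistic is intrinsically
  conservative: null max runs are almost always 1–2 points, so the
  achievable family-wise error jumps from ≈0.16 (size ≥ 2) to ≈0.009
  (size ≥ 3) and no rejection rule lands at 0.05 exactly. The acceptance
  report computes both tests' Monte-Carlo false-positive rates so this is
  visible rather than hidden.
- **vMMN (mass statistic, two-tailed):** fixed threshold at the *t*
  quantile for per-tail p = 0.025, clusters need ≥ 2 neighbouring points of
  common sign, statistic = signed Σt, null = maximum |mass|; this
  continuous statistic calibrates at the nominal level. Effect size is
  Cohen's *d* of the subject means over the cluster's time window.
- The condition-difference test (oddball minus equal-probability) reuses
  the RSA size statistic.

The vMMN sign convention is deviant − equiprobable, so a deviance response
is negative; the classical deviant − standard contrast is available via
`contrast="deviant_minus_standard"`. The per-category contrasts mirror the
usual reporting layout; the pooled all-deviant contrast is the most
powerful measurement of a single injected deviance response and is what
the recovery checks use.

## Problem sizes

The package defaults reproduce the full design (45 subjects, 420/480-trial
blocks, 10,000 permutations). The test-suite and the acceptance script run
scaled-down versions chosen as the smallest sizes at which the recovery
properties hold with comfortable power: a 20-subject cohort with 240-trial
blocks and 1,000 permutations for recovery; 6–8 subject cohorts with
24–36-trial blocks for null-specificity repeats; 500 Monte-Carlo draws for
calibration.

## Known limitations

- No real-data reader is wired in (EDF/BrainVision ingestion would slot in
  front of `preprocess`; recordings persist via the HDF5 container and TSV
  event tables).
- The radical-control screen, being uncontrolled, will genuinely detect
  injected frequency structure whenever the sampled frequencies correlate
  by chance with the radical partition — a property of the stimulus
  sample, not an error of the test; the acceptance report lists its
  detections separately.
- Rating-based model RDMs are implemented and tested at the unit level but
  the recovery experiments exercise the binary predictors, which are the
  sharper instruments.
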