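# oddrsa

Time-resolved representational similarity analysis (RSA) and visual
mismatch negativity (vMMN) for event-related EEG from visual-word oddball
and equal-probability designs — together with a synthetic-EEG generator
that gives every stage of the pipeline a known, recoverable ground truth.

## The problem

Skilled readers absorb the statistical structure of their writing system:
how often a word occurs (lexical frequency), and how reliably a character's
form predicts its pronunciation and meaning (orthographic, phonological and
semantic consistency — salient dimensions for Chinese phonograms, where a
semantic and a phonetic radical compose each character). Whether the brain
*represents* these statistics during passive viewing, and whether short-term
prediction (an oddball context) modulates those representations, can be
asked with two tools this package implements end to end:

- **Time-resolved RSA.** At each time point *t* (−100…600 ms, 10 ms grid),
  each trial is summarised by a spatiotemporal feature vector: all 61 scalp
  channels over an 11-sample window centred on *t* (671 features). The
  neural representational dissimilarity matrix (RDM) over the nine
  inconsistent characters has entries
  `D_ij(t) = mean over cross-character trial pairs of (1 − Pearson r)`.
  Its lower triangle (36 pairs) is compared with model RDMs — binary
  between/within-category predictors, |Δ log₁₀ frequency|, rating
  distances, a phonetic-radical control — by **partial Spearman
  correlation**: rank-transform, residualise the ranks on the control
  models, correlate the residuals. Testing a sub-lexical (consistency)
  model controls for frequency, and vice versa.
- **Group inference** is a one-sided sign-permutation test with
  maximum-cluster-size correction: each of the permutations flips whole
  subject time courses; the cluster-forming threshold at each time point is
  the 95th percentile of its permutation *t* distribution; cluster *p*
  values come from the permutation distribution of the maximum cluster
  size.
- **vMMN.** The deviance response is the deviant ERP minus the
  equal-probability ERP of *physically identical* stimuli, averaged over
  left (P7, PO7, O1) or right (P8, PO8, O2) posterior ROIs, 0–600 ms.
  Inference is a two-tailed cluster-mass sign-permutation test (per-tail
  cluster threshold p = 0.025, clusters ≥ 2 points of common sign,
  statistic = Σt, null = max |mass|), with Cohen's *d* over each cluster's
  time window.

Because real recordings for this paradigm are not publicly deposited, the
package's first-class data path is synthetic: `oddrsa.simulate` renders
61-channel, 1000 Hz continuous EEG from generated trial sequences
(420-trial oddball blocks with 315 standards / 105 deviants, a 480-trial
equal-probability block, colour-change targets at p = 0.1), injecting
category-specific spatial patterns, a frequency-graded pattern, a posterior
deviance negativity and white + pink noise. Every analysis claim in the
test-suite is a recovery or calibration statement about this ground truth.

## Worked example

`examples/04_vmmn.py` simulates an 8-subject cohort (120-trial blocks),
preprocesses it (0.1–40 Hz zero-phase Butterworth, average reference,
−300…700 ms epochs, ±100 μV rejection), forms pooled deviant-minus-
equiprobable ROI waveforms and runs the cluster-mass test:

```text
left ROI: grand-mean 150-300 ms = -1.12 μV
  cluster 165-275 ms  mass   -444.5  p = 0.0340  d = -1.48 *
right ROI: grand-mean 150-300 ms = -1.13 μV
  cluster 168-280 ms  mass   -518.9  p = 0.0005  d = -1.68 *
```

The simulator injected a −2 μV deviance response at 150–300 ms on deviant
trials (≈ −1.1 μV window mean after the half-cosine taper and average
reference); both hemispheres show a significant negative cluster inside
that window — the ground truth is recovered, with its mass (sum of
per-time-point *t* values), permutation *p* and effect size.

The other scripts in `examples/` cover sequence design, simulation +
preprocessing, RSA time courses, behavioural scoring and the full
config-driven pipeline; the same pipeline is scriptable from the shell:

```bash
oddrsa all --seed 7 --n-subjects 8 --n-perm 500 --out runs/demo
```

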