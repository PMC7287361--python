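# dyadsync

Does an observer's physiology *synchronising* with a demonstrator's predict
how well the observer learns from them? `dyadsync` implements the complete
analysis pipeline for that question in observational threat conditioning:
two participants sit together, the **demonstrator** receives electric shocks
paired with one of two images (CS+, never the CS−) while the **observer**
watches; afterwards the observer faces the same images under shock threat,
and the difference between their skin-conductance responses to CS+ and CS−
(**CS differentiation**) measures what they learned. Interpersonal synchrony
of the two phasic electrodermal signals during learning is quantified with
**cross-recurrence quantification analysis (CRQA)** and tested as a
predictor of that learning.

The package is aimed at psychophysiologists and methodologists who want a
fully inspectable, tested implementation of each stage — and a synthetic
dyad generator with known ground truth, so every stage has a
parameter-recovery test surface even without access to human data.

## The method

For each dyad-block, the learning-phase signals of demonstrator (x) and
observer (y) are downsampled to 8 Hz and z-scored, then lifted into a common
phase space by time-delay embedding,
x_k = (x(k), x(k+τ), …, x(k+(m−1)τ)). The cross-recurrence matrix

    R[i, j] = 1  iff  ‖x_i − y_j‖ ≤ ε

marks every pair of moments at which the two trajectories visit the same
neighbourhood. τ is chosen per pair by the first local minimum of average
mutual information, m by false-nearest-neighbour collapse, and ε by
bisection so the recurrence rate RR = ΣR/(n·n) lands between 2% and 4%.
Four line metrics summarise the matrix: **DET** (fraction of recurrent
points on diagonal lines ≥ 2 — co-evolving stretches), **LAM** (vertical
lines — shared dwelling), **maxL** (longest diagonal line) and **rENTR**
(normalised entropy of the diagonal line-length distribution). The four
metrics are reduced to one **synchrony component** (first principal
component of their correlation matrix, pooled over dyad-blocks, sign-fixed
to load positively).

Inference is a trial-level multilevel regression of transformed
testing-phase SCR amplitudes on deviation-coded CS status (±0.5), the
standardised synchrony component, and their interaction, with varying
intercepts and CS slopes (and their correlation) by observer — fitted by
REML with Wald 95% intervals. `CS × PC1 > 0` is the synchrony-predicts-
learning effect. Two guards accompany it: a **specificity model** that
adds three rival predictors (observer's response to the social UCS,
learning-phase CS differentiation, maximal lagged correlation) with their
CS interactions, and a **pseudo-dyad permutation test** that re-pairs every
observer with a demonstrator from a different dyad (block-preserving
derangements) and re-runs the whole CRQA → PCA → regression chain per
pairing to show the effect vanishes for false pairings.

## A worked example

`examples/03_synchrony_and_fit.py` simulates 16 dyads × 2 blocks under a
strong coupling→learning link and runs the full chain:

```
CRQA metrics for 32 dyad-blocks (0 calibration failures)
PC1 captures 63% of the metric variance; loadings:
det      0.59
lam      0.57
maxl     0.36
rentr    0.45

cs model (mixedlm, 448 trials, 32 observers):
             estimate     se  ci_lo  ci_hi
Intercept       0.813  0.013  0.788  0.839
cs_code         0.615  0.057  0.503  0.727
pc1            -0.009  0.013 -0.035  0.017
cs_code:pc1     0.286  0.057  0.174  0.397
```

`cs_code` is overall threat learning (CS+ responses exceed CS− by 0.62 on
the log(1+µS) scale here); `cs_code:pc1` is the synchrony effect on that
differentiation — positive with an interval well clear of zero, as it
should be when coupling truly drives learning. The other examples cover
simulation (`01`), single-dyad CRQA (`02`) and the pseudo-dyad permutation
(`04`); each prints a line or two explaining its numbers.

A thin CLI mirrors the stages for shell use:

```bash
dyadsync simulate --dyads 8 --seed 7 --out run/
dyadsync crqa --in run/
dyadsync synchrony --in run/   # needs `preprocess` outputs too
dyadsync run-all --dyads 8 --blocks 4 --seed 7 --n-permutations 200 --out run/
```

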