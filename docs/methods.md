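# Methods

## Problem and representation

Splicing branchpoints (BPs) are the intronic nucleotides — usually
adenines — that attack the 5' splice site during lariat formation.  Most
human BPs sit a few dozen nucleotides upstream of the 3' splice site
(3SS), and a single intron can carry several of them.  `bpmll` treats BP
prediction as a *multi-label* problem: each intron is one instance, and
the 40 candidate positions 50..11 nt upstream of the 3SS are 40 binary
labels predicted jointly, so correlations between candidate positions are
available to the model (unlike per-nonamer binary classifiers).

The encoder input is the *information region*: the 55 nt immediately
upstream of the 3SS.  Offsets count upstream from the 3SS (offset 1 = last
intronic base); label index `j` corresponds to offset `50 − j`.  Introns
shorter than 55 nt are rejected at ingestion, as are ambiguous bases
(N etc.): every encoder is defined on {A,C,G,T} only.  Annotated BPs
outside offsets [11, 50] are dropped with a warning rather than an error —
the label space simply does not cover them.

## Feature encoders

Five per-intron profiles, concatenable in any nonempty combination
(canonical order SP, DN, PWM, MARKOV, PPT):

| profile | dims | content |
|---|---|---|
| SP | 220 | per-base one-hot (55 × 4): A=1000, C=0100, G=0010, T=0001 |
| DN | 216 | 54 overlapping dinucleotides × fixed 4-bit codes |
| PWM | 45 | log2-odds sum of the nonamer centred at each scanned offset |
| MARKOV | 45 | ln P_pos − ln P_neg under per-class first-order chains |
| PPT | 135 | 3 polypyrimidine-tract scores per scanned offset |

The scan covers the 45 positions that can centre a full nonamer (9-mer
with the candidate BP at its 6th base): offsets 50..6.  The same
45-position window is used for PWM, MARKOV, and PPT for internal
consistency — it is what makes the PPT profile 45 × 3 = 135-dimensional.

PWM and Markov tables are *training-derived*: nonamers are harvested from
training introns only (positive = BP at the 6th base; every other scanned
position is a negative, with no subsampling), and the encoders receive the
fitted model, so a test fold can never leak into feature construction.
Numerical conventions, chosen here because standard motif practice leaves
them open: PWM scores are log2 odds against a uniform background with
Laplace pseudocount 1; Markov chains use Laplace pseudocount 1 on every
count cell and natural log for the class log-ratio.  A 4 × 9 PWM is used
(4-letter alphabet over 9 positions).

The PPT profile operationalises the polypyrimidine tract as a maximal
C/T run of length ≥ 5 downstream of the putative BP, scored
`run_length + 0.5 × #C`; the three per-position scores are (1) the
pyrimidine fraction between the putative BP and the 3SS, (2) the distance
to the start of the closest downstream tract (0 inside one, sentinel 45 —
the maximum possible within the region — when none exists), and (3) that
tract's score.  Minimum run length and C bonus are arguments of
`encode_ppt`.

## Multi-label learners

Three matrix-projection learners share a fit/predict contract on
X (n × m) and Y (n × 40).  Both matrices are column-mean-centred before
fitting (means stored and restored at prediction) — the classical setting
for PLS and CCA.  Determinism across linear-algebra backends is enforced
by a sign convention: the largest-magnitude entry of every eigenvector is
made positive (for CCA the paired Y-side vector is flipped with it).

**PLS regression** extracts components iteratively: p = leading
eigenvector of XᵀYYᵀX (computed as the leading left singular vector of
XᵀY), score u = Xp, loadings c = Xᵀu/‖u‖², r = Yᵀu/‖u‖², then deflation
X ← X − ucᵀ.  Y is deflated by the *regression* residue Y − urᵀ, i.e. by
the part of Y the extracted component explains: because successive scores
u are mutually orthogonal, this makes the fitted expansion Σ uᵢrᵢᵀ the
exact projection of Y onto their span.  Prediction uses the
corrected-weights identity X_new P (CᵀP)⁻¹ Rᵀ, which coincides with the
plain X_new P Rᵀ whenever CᵀP = I (orthogonal loadings) and reproduces
the training regression exactly in general; with the literal form, the
defining identity Y = URᵀ = XPRᵀ fails outright (O(1) errors on
noise-free data), so the corrected form is the one consistent with the
model's own derivation.  Deflation stops early when the residual X norm
falls below 1e-10 of its initial value.  Default τ = 40.

**CCA** solves the paired eigenproblems of (XᵀX)⁻¹XᵀY(YᵀY)⁻¹YᵀX via the
whitened cross-covariance SVD, pairs ordered by descending eigenvalue,
τ = min(m, k) by default.  Both Gram matrices receive a ridge
`ridge_eps` (default 1e-8) before inversion: one-hot feature blocks are
*exactly* collinear, so the unridged problem is singular.  With a
positive ridge the matrix is positive-definite by construction and
eigenvalues are floored at the ridge to absorb eigensolver rounding; with
`ridge_eps = 0` a singular Gram matrix is a hard error.  Prediction is
Y = X P Q⁻¹ (exact inverse when Q is square, minimum-norm pseudo-inverse
otherwise).

**LS-CCA** is the L2-regularised least-squares objective
Σⱼ ‖XWⱼ − Yⱼ‖² + λ‖Wⱼ‖², solved in closed form by the ridge normal
equations (the stated objective's exact minimiser), default λ = 0.01.

On full-rank noise-free linear data all three (PLS at full τ, CCA, ridge
with λ → 0) agree with ordinary least squares to < 1e-4 — this is the
oracle equivalence the acceptance suite checks.

## Ensembles

The base-predictor grid crosses every nonempty subset of {SP, DN, PWM,
MARKOV} with the three learners: K = 3 × (2⁴ − 1) = 45 predictors in a
fixed canonical order (subsets in binary-mask order, learners PLS, CCA,
LSCCA).  PPT is excluded from the pool — it is by far the weakest
profile — but remains available as an encoder.  Each predictor's n × 40
score matrix is min-max rescaled to [0, 1] over the scoring set so
heterogeneous learner output scales are commensurable; the rescaling is
monotone, hence per-predictor AUC/AUPR-neutral (a constant-score
predictor maps to 0.5).

**GAEM** combines scores as Σₖ wₖSₖ / K with w on the probability
simplex.  Weights are tuned by an elitist genetic algorithm (population
100, at most 100 generations) whose fitness is the AUPR of the combined
scores on held-out tuning data.  Operator details, configurable in
`GAConfig`: chromosomes are raw nonnegative reals normalised on
evaluation (negatives clipped, then renormalised); tournament selection
of size 2; uniform crossover with probability 0.8; per-gene Gaussian
mutation (σ = 0.05) with probability 0.05; elitism of 2; stall stop after
50 generations of < 1e-6 improvement.  Elitism makes the best fitness
non-decreasing by construction.  The fitness loop evaluates the whole
population in one batched matrix product and batched sort, in float32 —
the fitness only ranks candidate weight vectors, and the combined scores
are O(1) quantities, so single precision is ample there; all reported
metrics are computed in float64.

**LREM** is a logistic stacker σ(θ₀ + Σₖ θₖSₖ) fitted by maximum
likelihood on flattened (intron, position) instances — one shared θ
across all 40 labels.  The mean negative log-likelihood (scale-free
gradients) is minimised by L-BFGS with analytic gradients from θ = 0,
with a tiny ridge (1e-6) on the weights for stability; non-convergence is
an error, not a silent result.

Both rules are tuned on an *inner* 75/25 split of each training fold:
base predictors are fitted on the inner-train part and scored on the
inner-tune part, then refitted on the full training fold for test-time
scoring.  Tuning the combination rule on base-predictor resubstitution
scores would reward overfit predictors, so the held-out tuning split is
load-bearing, not cosmetic.

## Evaluation

All metrics are micro-averaged: every out-of-fold (intron, position) pair
contributes one entry to flat score/label vectors, matching the single
confusion-matrix formulas ACC = (TP+TN)/all, recall = TP/(TP+FN),
precision = TP/(TP+FP), F = 2PR/(P+R).  AUC is the rank statistic (ties
half); AUPR the average-precision estimator (step interpolation, chosen
over trapezoidal PR which is optimistic).  Thresholded metrics are
reported at the cutoff maximising F over all distinct score values
(positive iff score ≥ cutoff, ties broken toward the higher cutoff).
Cross-validation is intron-level (all 40 labels travel together):
seeded shuffle, then block partition into 5 folds differing by at most
one intron.  Per-fold reports are kept alongside the pooled one.

Top-k identification mirrors how the predictions would be used at the
bench: for each test intron the k highest-scoring positions are called
(ties broken toward the more-upstream offset) and a BP counts as
identified if its position is called, with a per-nucleotide breakdown of
hits read from the intron sequence.

## Synthetic benchmark

The simulator generates the statistical structure the predictors exploit,
at defaults meant to resemble the real mapping: 1–3 BPs per intron
(probabilities 0.8/0.15/0.05), positions from a discretised triangular
distribution peaked at offset 24 (half-width 20) truncated to [11, 50]
and drawn with ≥ 4 nt spacing, a TACTAAC-like heptamer planted around
each BP (its 6th base on the BP) with per-position fidelity 0.85, branch
nucleotide A/C/G/T with probabilities 0.8/0.1/0.03/0.07, a
pyrimidine-enriched 10-nt tract downstream of the most-3' BP (pyrimidine
probability 0.8), AG dinucleotides between that BP and the 3SS rewritten
with probability 0.9, all on a T-rich background (A/C/G/T =
0.27/0.21/0.21/0.31).  A triangular peak is used rather than an empirical
position histogram so the distribution is fully specified by two
interpretable parameters.  Motif heptamers are planted after the
tract/AG rewrites so the motif signal is never eroded by them (planting
introduces no new AG and no G inside the heptamer); when two BPs lie
closer than 7 nt their heptamers overlap and the later-planted (more
downstream) one wins, so an exact consensus around *every* BP is only
guaranteed for single-BP introns.

The null control strips every *learnable* signal: motif off, branch base
and tract at background composition, no AG suppression — and, crucially,
a uniform position distribution.  A nonuniform positional prior is itself
learnable through the label column means and pushes micro-averaged AUC
well above 0.5 even with no sequence information, so flattening it is
required for a meaningful chance-level control.

What passing on synthetic data does and does not show: the simulator
reproduces motif, composition, tract, and positional structure, but not
genome-scale heterogeneity (intron length and GC variation, splice-site
context, conservation, annotation noise).  Synthetic results validate the
machinery and its relative ordering (ensembles ≥ typical base predictor,
signal ≥ null), not absolute real-data performance.

## Problem sizes and reproducibility

The shipped evaluation runs use 2,000 introns for the benchmark CV and
1,000 for the null control — large enough that prevalence (≈ 0.031) and
the ensemble margins are stable across seeds, while a full joint CV of
both ensembles stays in the minutes range on one core.  Every stochastic
component (simulator, fold assignment, inner tuning split, GA) is driven
by explicit seeds; fixed seeds reproduce simulator output, fitted models,
and metric reports byte-identically.  Serialized models and run
directories carry their full configuration including seeds.

## Known limitations

* The PPT scoring scheme is a declared operationalisation; published
  tract scores vary and no single formula is canonical.
* CCA with heavily collinear inputs leans on the ridge floor; canonical
  directions in the near-null space are regularisation artefacts, ranked
  last by construction.
* The GAEM rule is linear in the base scores; LREM adds only a logistic
  link.  Neither models interactions between base predictors.
* LREM's single shared θ assumes the stacking relationship is identical
  across the 40 positions.
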