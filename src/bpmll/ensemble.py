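"""Base-predictor grid and the two ensemble rules (GAEM and LREM).

With N features and M learners the grid holds K = M * (2^N - 1) base
predictors, one per (nonempty feature subset, learner) pair.  For the
branchpoint task the feature pool is {SP, DN, PWM, MARKOV} (the PPT
profile is kept as an encoder but excluded from the pool, where it
consistently underperforms) and the learner pool is {PLS, CCA, LSCCA},
giving the canonical 45 predictors.

Each base predictor emits an n x 40 score matrix, min-max rescaled to
[0, 1] per predictor so that heterogeneous learner output scales are
commensurable (the rescaling is monotone, hence AUC/AUPR-neutral).  Two
rules combine the stacked scores S_1..S_K:

* GAEM — a weighted average sum_k w_k S_k / K with the weight vector on
  the probability simplex, tuned by an elitist genetic algorithm whose
  fitness is the AUPR on held-out tuning scores;
* LREM — a logistic stacker sigma(theta_0 + sum_k theta_k S_k) fitted by
  maximum likelihood on flattened (intron, position) instances.

To keep the ensemble-rule tuning honest, both rules are tuned on an inner
split of the training introns (default 75/25): base predictors are fitted
on the inner-train part and scored on the inner-tune part; the base
predictors used at test time are then refitted on the full training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize
from scipy.special import expit

from . import evaluate, features, learners
from .seqmodel import N_LABELS, label_matrix

logger = logging.getLogger("bpmll")

#: feature pool for the ensemble grid (canonical subset-mask bit order)
ENSEMBLE_FEATURES = ("SP", "DN", "PWM", "MARKOV")
LEARNER_ORDER = ("PLS", "CCA", "LSCCA")


def enumerate_base_predictors(feature_pool=ENSEMBLE_FEATURES,
                              learner_pool=LEARNER_ORDER) -> list:
    """Canonical (feature_subset, learner) pairs: subsets in binary-mask
    order (bit i = i-th pool feature), learners in PLS, CCA, LSCCA order."""
    feature_pool = tuple(feature_pool)
    learner_pool = tuple(learner_pool)
    if not feature_pool or not learner_pool:
        raise ValueError("feature and learner pools must be nonempty")
    pairs = []
    for mask in range(1, 2 ** len(feature_pool)):
        subset = tuple(f for i, f in enumerate(feature_pool) if mask >> i & 1)
        for lk in learner_pool:
            pairs.append((subset, lk))
    return pairs


def predictor_label(pair) -> str:
    subset, learner_kind = pair
    return "+".join(subset) + "/" + learner_kind


@dataclass
class BasePredictor:
    """One fitted (feature subset, learner) pair with its fold's feature models."""

    feature_subset: tuple
    learner_kind: str
    learner: object
    pwm: features.PWMModel = None
    markov: features.MarkovModel = None

    @property
    def label(self) -> str:
        return predictor_label((self.feature_subset, self.learner_kind))


def _fit_feature_models(train_records):
    pos, neg = features.extract_nonamers(train_records)
    pwm = features.fit_pwm(pos)
    markov = features.fit_markov(pos, neg)
    return pwm, markov


def _full_matrix_and_slices(records, pwm, markov, pool):
    """Encode every pool feature once; return (X_all, {feature: column slice})."""
    blocks, slices, start = [], {}, 0
    for kind in features.FEATURE_ORDER:
        if kind not in pool:
            continue
        block = features.encode_feature(records, kind, pwm=pwm, markov=markov)
        slices[kind] = slice(start, start + block.shape[1])
        start += block.shape[1]
        blocks.append(block)
    return np.hstack(blocks), slices


def _subset_columns(slices, subset):
    cols = []
    for kind in features.FEATURE_ORDER:
        if kind in subset:
            cols.extend(range(slices[kind].start, slices[kind].stop))
    return np.array(cols)


def fit_base_predictors(train_records, pairs=None,
                        learner_params=None) -> list:
    """Fit one predictor per (subset, learner) pair on the training introns.

    PWM/Markov feature models are fitted on the same introns, so nothing
    from a held-out fold leaks into the encoders.
    """
    pairs = enumerate_base_predictors() if pairs is None else list(pairs)
    learner_params = learner_params or {}
    pwm, markov = _fit_feature_models(train_records)
    pool = {f for subset, _ in pairs for f in subset}
    X_all, slices = _full_matrix_and_slices(train_records, pwm, markov, pool)
    Y = label_matrix(train_records).astype(np.float64)
    fitted = []
    for subset, kind in pairs:
        X = X_all[:, _subset_columns(slices, subset)]
        learner = learners.make_learner(kind, **learner_params.get(kind, {}))
        learner.fit(X, Y)
        fitted.append(BasePredictor(subset, kind, learner, pwm, markov))
    return fitted


def score_base_predictors(predictors, records) -> np.ndarray:
    """Stack per-predictor score matrices into the (K, n, 40) ScoreTensor.

    Each predictor's scores are min-max rescaled to [0, 1] over the scoring
    set; a constant-score predictor maps to all 0.5 by convention.
    """
    pool = {f for p in predictors for f in p.feature_subset}
    pwm, markov = predictors[0].pwm, predictors[0].markov
    X_all, slices = _full_matrix_and_slices(records, pwm, markov, pool)
    S = np.empty((len(predictors), len(records), N_LABELS))
    for ki, p in enumerate(predictors):
        raw = p.learner.predict(X_all[:, _subset_columns(slices, p.feature_subset)])
        S[ki] = minmax_rescale(raw)
    return S


def minmax_rescale(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi - lo <= 0:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# GAEM: genetic-algorithm weighted average
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    population_size: int = 100
    max_generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    mutation_sigma: float = 0.05
    elite: int = 2
    stall_tol: float = 1e-6
    stall_generations: int = 50
    seed: int = 0


@dataclass
class GAEMModel:
    weights: np.ndarray          # K nonnegative, summing to 1
    ga_config: GAConfig = field(default_factory=GAConfig)
    fitness_history: list = field(default_factory=list)
    predictor_labels: list = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("GAEM weights must be nonnegative and sum to 1")
        self.weights = w

    def weights_tsv(self) -> str:
        lines = ["predictor\tweight"]
        labels = (self.predictor_labels
                  or [str(i) for i in range(self.weights.size)])
        lines += [f"{l}\t{float(w)!r}" for l, w in zip(labels, self.weights)]
        return "\n".join(lines) + "\n"


def gaem_combine(S: np.ndarray, weights) -> np.ndarray:
    """Weighted average sum_k w_k S_k / K (the 1/K factor is a monotone
    rescaling kept for fidelity to the combination rule as defined)."""
    S = np.asarray(S, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if S.ndim != 3 or w.shape != (S.shape[0],):
        raise ValueError("need S of shape (K, n, 40) and K weights")
    return np.tensordot(w, S, axes=1) / S.shape[0]


def _repair(chrom: np.ndarray) -> np.ndarray:
    """Project a raw chromosome onto the simplex: clip negatives, renormalise."""
    w = np.clip(chrom, 0.0, None)
    total = w.sum()
    if total <= 0:
        return np.full_like(w, 1.0 / w.size)
    return w / total


def gaem_fit(S_tune: np.ndarray, Y_tune, ga_config: GAConfig = None,
             predictor_labels=None) -> GAEMModel:
    """Search the simplex weight vector maximising tuning AUPR with an
    elitist GA (tournament selection, uniform crossover, Gaussian mutation).

    ``S_tune`` must be scores on introns not used to fit the base
    predictors, otherwise the fitness rewards overfit predictors.
    """
    cfg = ga_config or GAConfig()
    S = np.asarray(S_tune, dtype=np.float64)
    y = np.asarray(Y_tune).ravel()
    if y.sum() == 0:
        raise ValueError("tuning labels contain no positives")
    K = S.shape[0]
    # float32 in the fitness hot path: the fitness only ranks candidate
    # weight vectors, and combined scores are O(1) with O(1e3) summands
    flatS = S.reshape(K, -1).astype(np.float32)
    rng = np.random.default_rng(cfg.seed)

    y_arr = y.astype(np.int8)

    def fitness_batch(chroms):
        W = np.clip(chroms, 0.0, None)
        sums = W.sum(axis=1, keepdims=True)
        W = np.where(sums > 0, W / np.where(sums > 0, sums, 1.0), 1.0 / K)
        return evaluate.average_precision_batch(
            W.astype(np.float32) @ flatS, y_arr)

    pop = rng.random((cfg.population_size, K))
    fits = fitness_batch(pop)
    history = [float(fits.max())]
    stall = 0
    for gen in range(1, cfg.max_generations):
        order = np.argsort(-fits)
        elite = pop[order[: cfg.elite]].copy()
        # tournament selection (size 2)
        a = rng.integers(cfg.population_size, size=cfg.population_size - cfg.elite)
        b = rng.integers(cfg.population_size, size=cfg.population_size - cfg.elite)
        parents = pop[np.where(fits[a] >= fits[b], a, b)].copy()
        # uniform crossover on consecutive pairs
        for i in range(0, len(parents) - 1, 2):
            if rng.random() < cfg.crossover_prob:
                mask = rng.random(K) < 0.5
                p0, p1 = parents[i].copy(), parents[i + 1].copy()
                parents[i, mask], parents[i + 1, mask] = p1[mask], p0[mask]
        # per-gene Gaussian mutation
        mut = rng.random(parents.shape) < cfg.mutation_prob
        parents = parents + mut * rng.normal(0.0, cfg.mutation_sigma, parents.shape)
        pop = np.vstack([elite, parents])
        new_fits = fitness_batch(pop[cfg.elite:])
        fits = np.concatenate([fits[order[: cfg.elite]], new_fits])
        best = float(fits.max())
        stall = stall + 1 if best - history[-1] < cfg.stall_tol else 0
        history.append(max(best, history[-1]))
        if stall >= cfg.stall_generations:
            logger.debug("GA stalled at generation %d (best AUPR %.6f)", gen, best)
            break
    best_w = _repair(pop[int(np.argmax(fits))])
    return GAEMModel(best_w, cfg, history,
                     list(predictor_labels or []))


# ---------------------------------------------------------------------------
# LREM: logistic-regression stacking
# ---------------------------------------------------------------------------

@dataclass
class LREMModel:
    theta: np.ndarray   # K+1 coefficients, theta[0] = intercept
    predictor_labels: list = field(default_factory=list)

    def __post_init__(self):
        t = np.asarray(self.theta, dtype=np.float64)
        if not np.all(np.isfinite(t)):
            raise ValueError("LREM coefficients must be finite")
        self.theta = t


def lrem_fit(S_tune: np.ndarray, Y_tune, l2: float = 1e-6,
             tol: float = 1e-6, max_iter: int = 5000,
             predictor_labels=None) -> LREMModel:
    """Maximum-likelihood logistic stacker on flattened (intron, position)
    instances, L-BFGS from theta = 0 with a tiny ridge (on the weights,
    not the intercept) for numerical stability.

    The objective is the *mean* negative log-likelihood so the gradient
    tolerance is independent of the number of instances.
    """
    S = np.asarray(S_tune, dtype=np.float64)
    K = S.shape[0]
    D = S.reshape(K, -1).T                      # (n*40, K)
    y = np.asarray(Y_tune).ravel().astype(np.float64)
    if D.shape[0] != y.size:
        raise ValueError("score tensor and labels are misaligned")
    n = float(y.size)

    def nll_grad(theta):
        z = theta[0] + D @ theta[1:]
        # mean of log(1+e^z) - y z, numerically via logaddexp
        nll = (np.logaddexp(0.0, z).sum() - y @ z) / n
        resid = (expit(z) - y) / n
        grad = np.empty_like(theta)
        grad[0] = resid.sum()
        grad[1:] = D.T @ resid + l2 * theta[1:]
        return nll + 0.5 * l2 * theta[1:] @ theta[1:], grad

    res = scipy.optimize.minimize(
        nll_grad, np.zeros(K + 1), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > 100 * tol:
        raise learners.NumericalError(
            f"LREM did not converge: {res.message} (grad inf-norm {grad_norm:.3g})")
    return LREMModel(res.x, list(predictor_labels or []))


def lrem_predict(model: LREMModel, S: np.ndarray) -> np.ndarray:
    """Per-entry sigmoid of theta . (1, S_1..S_K); outputs in (0, 1)."""
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 3 or S.shape[0] != model.theta.size - 1:
        raise ValueError(
            f"score tensor must have K={model.theta.size - 1} predictors")
    z = model.theta[0] + np.tensordot(model.theta[1:], S, axes=1)
    return expit(z)


# ---------------------------------------------------------------------------
# High-level models with a common fit(records)/predict(records) contract
# ---------------------------------------------------------------------------

class SinglePredictorModel:
    """One (feature subset, learner) pair as a standalone model."""

    def __init__(self, feature_subset=("SP",), learner_kind: str = "PLS",
                 learner_params: dict = None):
        self.feature_subset = tuple(feature_subset)
        self.learner_kind = learner_kind
        self.learner_params = learner_params or {}
        self.predictor = None

    def fit(self, records):
        [self.predictor] = fit_base_predictors(
            records, [(self.feature_subset, self.learner_kind)],
            learner_params={self.learner_kind: self.learner_params})
        return self

    def predict(self, records) -> np.ndarray:
        if self.predictor is None:
            raise RuntimeError("model is not fitted")
        return score_base_predictors([self.predictor], records)[0]


class _EnsembleBase:
    """Shared machinery: inner tuning split, base grid fitting, scoring."""

    def __init__(self, feature_pool=ENSEMBLE_FEATURES,
                 learner_pool=LEARNER_ORDER, inner_tune_frac: float = 0.25,
                 seed: int = 0, learner_params: dict = None):
        if not 0.0 < inner_tune_frac < 1.0:
            raise ValueError("inner_tune_frac must be in (0, 1)")
        self.pairs = enumerate_base_predictors(feature_pool, learner_pool)
        self.inner_tune_frac = inner_tune_frac
        self.seed = seed
        self.learner_params = learner_params or {}
        self.predictors = None

    def base_labels(self) -> list:
        return [predictor_label(p) for p in self.pairs]

    def _tune_scores(self, records):
        rng = np.random.default_rng(self.seed)
        records = list(records)
        perm = rng.permutation(len(records))
        n_tune = max(1, int(round(self.inner_tune_frac * len(records))))
        tune_idx = set(perm[:n_tune].tolist())
        inner_train = [r for i, r in enumerate(records) if i not in tune_idx]
        inner_tune = [r for i, r in enumerate(records) if i in tune_idx]
        inner_predictors = fit_base_predictors(
            inner_train, self.pairs, self.learner_params)
        S_tune = score_base_predictors(inner_predictors, inner_tune)
        return S_tune, label_matrix(inner_tune)

    def _fit_rule(self, S_tune, Y_tune):
        raise NotImplementedError

    def _combine(self, S):
        raise NotImplementedError

    def fit(self, records):
        records = list(records)
        S_tune, Y_tune = self._tune_scores(records)
        self._fit_rule(S_tune, Y_tune)
        self.predictors = fit_base_predictors(records, self.pairs,
                                              self.learner_params)
        return self

    def predict_base(self, records) -> np.ndarray:
        if self.predictors is None:
            raise RuntimeError("model is not fitted")
        return score_base_predictors(self.predictors, records)

    def predict(self, records) -> np.ndarray:
        return self._combine(self.predict_base(records))


class GAEMEnsemble(_EnsembleBase):
    """Genetic-algorithm weighted-average ensemble over the 45-predictor grid."""

    def __init__(self, ga_config: GAConfig = None, **kw):
        super().__init__(**kw)
        self.ga_config = ga_config or GAConfig(seed=self.seed)
        self.model = None

    def _fit_rule(self, S_tune, Y_tune):
        self.model = gaem_fit(S_tune, Y_tune, self.ga_config,
                              predictor_labels=self.base_labels())

    def _combine(self, S):
        return gaem_combine(S, self.model.weights)


class LREMEnsemble(_EnsembleBase):
    """Logistic-regression stacking ensemble over the 45-predictor grid."""

    def __init__(self, l2: float = 1e-6, tol: float = 1e-6, **kw):
        super().__init__(**kw)
        self.l2 = l2
        self.tol = tol
        self.model = None

    def _fit_rule(self, S_tune, Y_tune):
        self.model = lrem_fit(S_tune, Y_tune, l2=self.l2, tol=self.tol,
                              predictor_labels=self.base_labels())

    def _combine(self, S):
        return lrem_predict(self.model, S)
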