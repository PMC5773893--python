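"""Evaluation: threshold-free metrics, best-F operating point, 5-fold CV,
and top-k branchpoint identification.

All metrics are micro-averaged: every (intron, position) pair contributes
one score/label entry to flat vectors before any metric is computed, which
matches the single confusion-matrix formulas (ACC, recall, precision, F).
AUPR uses the average-precision estimator (step interpolation); AUC is the
rank statistic (ties count one half).  The operating point for the
thresholded metrics is the cutoff maximising F over all distinct score
values, predictions being positive iff score >= cutoff.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .seqmodel import N_LABELS, index_to_offset, label_matrix


def _flat(scores, labels):
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(np.int8)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have matching shapes")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite entries")
    return s, y


def auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    s, y = _flat(scores, labels)
    if y.min() == y.max():
        raise ValueError("AUC requires at least one positive and one negative")
    return float(roc_auc_score(y, s))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (average precision)."""
    s, y = _flat(scores, labels)
    if y.sum() == 0:
        raise ValueError("AUPR requires at least one positive")
    return float(average_precision_score(y, s))


def average_precision_fast(scores: np.ndarray, labels: np.ndarray) -> float:
    """Low-overhead average precision on flat arrays (equals :func:`aupr`).

    Step-interpolated PR area over the distinct score values, used where
    the metric sits inside a hot loop (the GA fitness).  Ties share a
    threshold, as in the reference estimator.
    """
    order = np.argsort(-scores, kind="stable")
    ys = labels[order]
    ss = scores[order]
    tp = np.cumsum(ys)
    n_pos = tp[-1]
    if n_pos == 0:
        raise ValueError("AUPR requires at least one positive")
    last = np.flatnonzero(np.diff(ss, append=-np.inf) != 0)
    prec = tp[last] / (last + 1)
    rec = tp[last] / n_pos
    return float(np.sum(prec * np.diff(rec, prepend=0.0)))


def average_precision_batch(score_rows: np.ndarray,
                            labels: np.ndarray) -> np.ndarray:
    """Average precision of each row of a (B, n) score matrix against one
    flat label vector; one batched sort instead of B separate calls."""
    B, n = score_rows.shape
    order = np.argsort(-score_rows, axis=1)
    ss = np.take_along_axis(score_rows, order, axis=1)
    ys = labels[order]
    tp = np.cumsum(ys, axis=1)
    n_pos = tp[:, -1]
    if np.any(n_pos == 0):
        raise ValueError("AUPR requires at least one positive")
    # each sorted entry contributes ys * precision-at-the-end-of-its-tie-group;
    # group ends located by a reversed running minimum over "is last of group"
    is_last = np.diff(ss, axis=1, append=-np.inf) != 0
    idx = np.where(is_last, np.arange(n), n)
    g = np.minimum.accumulate(idx[:, ::-1], axis=1)[:, ::-1]
    prec_g = np.take_along_axis(tp, g, axis=1) / (g + 1)
    return (ys * prec_g).sum(axis=1) / n_pos


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics at the best-F cutoff."""

    tp: int
    tn: int
    fp: int
    fn: int
    recall: float
    precision: float
    acc: float
    f: float
    auc: float
    aupr: float
    cutoff: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    def to_tsv(self) -> str:
        d = self.to_dict()
        keys = list(d)
        return ("\t".join(keys) + "\n"
                + "\t".join(repr(d[k]) for k in keys) + "\n")


def confusion_at(scores, labels, cutoff: float):
    """(tp, tn, fp, fn) with predictions positive iff score >= cutoff."""
    s, y = _flat(scores, labels)
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, tn, fp, fn


def best_f_report(scores, labels) -> MetricsReport:
    """Report at the F-maximising cutoff (ties broken toward higher cutoff)."""
    s, y = _flat(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("best_f_report requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # candidate cutoffs = distinct score values; cum counts at the last
    # occurrence of each distinct value give the >=cutoff confusion
    tp_cum = np.cumsum(y_sorted)
    last = np.flatnonzero(np.diff(s_sorted, append=-np.inf) != 0)
    tp = tp_cum[last].astype(np.float64)
    npred = (last + 1).astype(np.float64)
    prec = tp / npred
    rec = tp / n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tp > 0, 2 * prec * rec / (prec + rec), 0.0)
    best = int(np.argmax(f))  # argmax returns the first (highest-cutoff) tie
    cutoff = float(s_sorted[last][best])
    tp_b, tn_b, fp_b, fn_b = confusion_at(s, y, cutoff)
    total = tp_b + tn_b + fp_b + fn_b
    precision = tp_b / (tp_b + fp_b) if tp_b + fp_b else 0.0
    recall = tp_b / (tp_b + fn_b)
    f_best = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
    auc_val = auc(s, y) if 0 < n_pos < y.size else float("nan")
    return MetricsReport(
        tp=tp_b, tn=tn_b, fp=fp_b, fn=fn_b,
        recall=recall, precision=precision, acc=(tp_b + tn_b) / total,
        f=f_best, auc=auc_val, aupr=aupr(s, y), cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(records, n_folds: int = 5, seed: int = 0) -> dict:
    """Intron-level fold assignment: seeded shuffle, then block partition.

    Returns {intron_id: fold}; fold sizes differ by at most one and every
    intron appears exactly once.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate intron IDs in records")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} introns for {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = {}
    for fold, block in enumerate(np.array_split(perm, n_folds)):
        for idx in block:
            assignment[ids[idx]] = fold
    return assignment


@dataclass
class CVResult:
    """Out-of-fold scores plus per-fold and pooled metric reports."""

    pooled: MetricsReport
    fold_reports: list
    assignment: dict
    oof_scores: np.ndarray          # n x 40, aligned with the input records
    base_auprs: dict = field(default_factory=dict)  # predictor label -> pooled AUPR


def cross_validate(records, model_factory, n_folds: int = 5, seed: int = 0,
                   collect_base: bool = False) -> CVResult:
    """Intron-level k-fold CV of any model with fit(records)/predict(records).

    The model is refitted from scratch inside every fold on the training
    introns only (including its feature models), then scored on the held-out
    introns; pooled metrics are computed on the concatenated out-of-fold
    (intron, position) scores.  If ``collect_base`` and the model exposes
    ``predict_base``, per-base-predictor out-of-fold scores are pooled too.
    """
    records = list(records)
    Y = label_matrix(records)
    assignment = make_folds(records, n_folds=n_folds, seed=seed)
    folds = np.array([assignment[r.id] for r in records])
    oof = np.full((len(records), N_LABELS), np.nan)
    fold_reports = []
    base_scores = None
    base_labels = []
    for fold in range(n_folds):
        test_mask = folds == fold
        train_recs = [r for r, m in zip(records, test_mask) if not m]
        test_recs = [r for r, m in zip(records, test_mask) if m]
        model = model_factory()
        model.fit(train_recs)
        scores = np.asarray(model.predict(test_recs), dtype=np.float64)
        oof[test_mask] = scores
        fold_reports.append(best_f_report(scores, Y[test_mask]))
        if collect_base and hasattr(model, "predict_base"):
            S = model.predict_base(test_recs)  # (K, n_test, 40)
            if base_scores is None:
                base_scores = [[] for _ in range(S.shape[0])]
            for ki in range(S.shape[0]):
                base_scores[ki].append(S[ki].ravel())
            base_labels.append(Y[test_mask].ravel())
    pooled = best_f_report(oof, Y)
    base_auprs = {}
    if base_scores is not None:
        flat_y = np.concatenate(base_labels)
        labels = model.base_labels() if hasattr(model, "base_labels") else [
            str(i) for i in range(len(base_scores))]
        for lbl, chunks in zip(labels, base_scores):
            base_auprs[lbl] = aupr(np.concatenate(chunks), flat_y)
    return CVResult(pooled, fold_reports, assignment, oof, base_auprs)


def cross_validate_ensembles(records, n_folds: int = 5, seed: int = 0,
                             ga_config=None, inner_tune_frac: float = 0.25) -> dict:
    """Joint k-fold CV of GAEM, LREM, and the 45 base predictors.

    Fits the base-predictor grid once per fold (inner-train for tuning the
    two ensemble rules, full training fold for test-time scoring) so all
    three result sets are computed on identical folds.  Returns pooled
    reports for both ensembles, per-base-predictor pooled AUPRs, and the
    out-of-fold score matrices.
    """
    from . import ensemble  # local import; ensemble depends on this module

    records = list(records)
    Y = label_matrix(records)
    assignment = make_folds(records, n_folds=n_folds, seed=seed)
    folds = np.array([assignment[r.id] for r in records])
    pairs = ensemble.enumerate_base_predictors()
    labels = [ensemble.predictor_label(p) for p in pairs]
    oof = {"gaem": np.full((len(records), N_LABELS), np.nan),
           "lrem": np.full((len(records), N_LABELS), np.nan)}
    base_chunks = [[] for _ in pairs]
    for fold in range(n_folds):
        test_mask = folds == fold
        train = [r for r, m in zip(records, test_mask) if not m]
        test = [r for r, m in zip(records, test_mask) if m]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(train))
        n_tune = max(1, int(round(inner_tune_frac * len(train))))
        tune_idx = set(perm[:n_tune].tolist())
        inner_train = [r for i, r in enumerate(train) if i not in tune_idx]
        inner_tune = [r for i, r in enumerate(train) if i in tune_idx]
        inner_grid = ensemble.fit_base_predictors(inner_train, pairs)
        S_tune = ensemble.score_base_predictors(inner_grid, inner_tune)
        Y_tune = label_matrix(inner_tune)
        gaem = ensemble.gaem_fit(S_tune, Y_tune, ga_config,
                                 predictor_labels=labels)
        lrem = ensemble.lrem_fit(S_tune, Y_tune, predictor_labels=labels)
        grid = ensemble.fit_base_predictors(train, pairs)
        S_test = ensemble.score_base_predictors(grid, test)
        oof["gaem"][test_mask] = ensemble.gaem_combine(S_test, gaem.weights)
        oof["lrem"][test_mask] = ensemble.lrem_predict(lrem, S_test)
        for ki in range(len(pairs)):
            base_chunks[ki].append(S_test[ki].ravel())
    flat_y = np.concatenate([Y[folds == f].ravel() for f in range(n_folds)])
    return {
        "gaem": best_f_report(oof["gaem"], Y),
        "lrem": best_f_report(oof["lrem"], Y),
        "base_auprs": {lbl: aupr(np.concatenate(chunks), flat_y)
                       for lbl, chunks in zip(labels, base_chunks)},
        "oof": oof,
        "assignment": assignment,
    }


# ---------------------------------------------------------------------------
# Top-k identification
# ---------------------------------------------------------------------------

@dataclass
class TopKResult:
    identified: int
    total: int
    ratio: float
    by_nucleotide: dict   # base -> (identified, total)


def top_k_identification(scores, Y, k: int, records=None) -> TopKResult:
    """Count true branchpoints among each intron's k top-scoring positions.

    Ties are broken toward the smaller label index (more-upstream offset).
    With ``records`` supplied, counts are additionally broken down by the
    branchpoint nucleotide read from each intron's sequence.
    """
    scores = np.asarray(scores, dtype=np.float64)
    Y = np.asarray(Y)
    if scores.shape != Y.shape or scores.ndim != 2 or scores.shape[1] != N_LABELS:
        raise ValueError(f"scores and Y must both be n x {N_LABELS}")
    if not 1 <= k <= N_LABELS:
        raise ValueError(f"k must be in [1, {N_LABELS}]")
    top = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    called = np.zeros_like(Y, dtype=bool)
    np.put_along_axis(called, top, True, axis=1)
    hit = called & (Y == 1)
    identified = int(hit.sum())
    total = int(Y.sum())
    by_nuc = {}
    if records is not None:
        if len(records) != scores.shape[0]:
            raise ValueError("records must align with score rows")
        by_nuc = {b: [0, 0] for b in "ACGT"}
        for i, rec in enumerate(records):
            for j in np.flatnonzero(Y[i]):
                base = rec.base_at_offset(index_to_offset(int(j)))
                by_nuc[base][1] += 1
                if called[i, j]:
                    by_nuc[base][0] += 1
        by_nuc = {b: tuple(v) for b, v in by_nuc.items()}
    ratio = identified / total if total else float("nan")
    return TopKResult(identified, total, ratio, by_nuc)
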