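"""Intron sequence-derived feature encoders.

Five per-intron feature profiles are computed on the 55-nt information
region:

* sparse profile (SP): per-base one-hot, 55 x 4 = 220 dims;
* dinucleotide profile (DN): 54 overlapping dinucleotides, each a fixed
  4-bit code, 216 dims;
* PWM profile: a 4 x 9 log-odds position weight matrix, fitted on the
  branchpoint-centred nonamers of the training introns, scored along a
  45-position scan, 45 dims;
* Markov profile: first-order position-specific Markov chains fitted on
  positive (branchpoint at 6th base) and negative nonamers; each scanned
  nonamer is scored log P_pos(s) - log P_neg(s), 45 dims;
* polypyrimidine-tract profile (PPT): three scores (pyrimidine content
  down to the 3SS, distance to the closest downstream pyrimidine run,
  score of that run) per scanned position, 135 dims.

The scan covers the 45 information-region positions that can centre a full
nonamer, i.e. offsets 50..6 upstream of the 3SS (excluding the first five
and last five positions); output entry ``j`` corresponds to offset
``50 - j``.  PWM and Markov tables are *training-derived*: they must be
fitted on training introns only and passed to the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqmodel import (
    ALPHABET,
    INFO_LEN,
    DataError,
    IntronRecord,
    records_to_int_matrix,
    seq_to_ints,
)

NONAMER_LEN = 9
#: 1-based position of the candidate branchpoint inside a nonamer
BP_POS_IN_NONAMER = 6
#: scanned offsets upstream of 3SS, most-upstream first
SCAN_OFFSETS = tuple(range(50, 5, -1))
N_SCAN = len(SCAN_OFFSETS)  # 45

FEATURE_DIMS = {"SP": 220, "DN": 216, "PWM": 45, "MARKOV": 45, "PPT": 135}
FEATURE_ORDER = ("SP", "DN", "PWM", "MARKOV", "PPT")

# fixed 4-bit codes for the 16 dinucleotides
DINUC_CODES = {
    "AA": "0000", "AC": "0001", "CA": "0010", "AG": "0011",
    "GA": "0100", "AT": "0101", "TA": "0110", "CC": "0111",
    "CG": "1000", "GC": "1001", "CT": "1010", "TC": "1011",
    "GG": "1100", "GT": "1101", "TG": "1110", "TT": "1111",
}
# 16 x 4 bit table indexed by 4*b1+b2 with b in integer code order A,C,G,T
_DINUC_BITS = np.zeros((16, 4), dtype=np.float64)
for _d, _code in DINUC_CODES.items():
    _i = 4 * ALPHABET.index(_d[0]) + ALPHABET.index(_d[1])
    _DINUC_BITS[_i] = [int(c) for c in _code]

# scan window j covers info_seq indices j..j+8 (6th base at index j+5,
# i.e. offset 50-j); precomputed for vectorised gathers
_WINDOWS = np.arange(N_SCAN)[:, None] + np.arange(NONAMER_LEN)[None, :]


def _as_int_matrix(records_or_seqs) -> np.ndarray:
    if isinstance(records_or_seqs, np.ndarray):
        return records_or_seqs
    if records_or_seqs and isinstance(records_or_seqs[0], IntronRecord):
        return records_to_int_matrix(records_or_seqs)
    return np.array([seq_to_ints(s) for s in records_or_seqs], dtype=np.int64)


# ---------------------------------------------------------------------------
# Composition-based profiles
# ---------------------------------------------------------------------------

def encode_sparse(info_seq: str) -> np.ndarray:
    """One-hot sparse profile: A=1000, C=0100, G=0010, T=0001; 220 dims."""
    codes = seq_to_ints(info_seq)
    if codes.size != INFO_LEN:
        raise DataError(f"information region must be {INFO_LEN} nt")
    out = np.zeros((INFO_LEN, 4))
    out[np.arange(INFO_LEN), codes] = 1.0
    return out.ravel()


def encode_dinucleotide(info_seq: str) -> np.ndarray:
    """Dinucleotide profile: 54 overlapping pairs x 4-bit codes; 216 dims."""
    codes = seq_to_ints(info_seq)
    if codes.size != INFO_LEN:
        raise DataError(f"information region must be {INFO_LEN} nt")
    pair_idx = 4 * codes[:-1] + codes[1:]
    return _DINUC_BITS[pair_idx].ravel()


# ---------------------------------------------------------------------------
# Nonamer extraction and motif models (training-derived)
# ---------------------------------------------------------------------------

def extract_nonamers(records) -> tuple:
    """Scan training introns into positive and negative nonamers.

    For each intron and each scanned offset o in {50..6}, the 9-mer whose
    6th base sits at offset o is emitted; it is positive iff o is an
    annotated branchpoint.  Returns (positive, negative) lists of strings.
    """
    positive, negative = [], []
    for rec in records:
        for j, o in enumerate(SCAN_OFFSETS):
            nonamer = rec.info_seq[j:j + NONAMER_LEN]
            if o in rec.bp_offsets:
                positive.append(nonamer)
            else:
                negative.append(nonamer)
    return positive, negative


@dataclass
class PWMModel:
    """Log2-odds position weight matrix over nonamer positions 1..9.

    ``matrix[b, i]`` scores base ``b`` (A,C,G,T order) at position ``i``:
    log2 of the pseudocounted positive frequency over the background.
    """

    matrix: np.ndarray  # 4 x 9
    pseudocount: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.shape != (4, NONAMER_LEN):
            raise ValueError(f"PWM must be 4 x {NONAMER_LEN}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM entries must be finite")
        if abs(self.background.sum() - 1.0) > 1e-12:
            raise ValueError("background must sum to 1")

    def to_text(self) -> str:
        lines = [f"# PWMModel v1\npseudocount\t{float(self.pseudocount)!r}",
                 "background\t" + "\t".join(repr(float(x)) for x in self.background)]
        for bi, b in enumerate(ALPHABET):
            lines.append(b + "\t" + "\t".join(repr(float(x)) for x in self.matrix[bi]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PWMModel":
        rows = {}
        pseudocount, background = 1.0, np.full(4, 0.25)
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split("\t")
            if key == "pseudocount":
                pseudocount = float(vals[0])
            elif key == "background":
                background = np.array([float(v) for v in vals])
            else:
                rows[key] = [float(v) for v in vals]
        matrix = np.array([rows[b] for b in ALPHABET])
        return cls(matrix, pseudocount, background)


def fit_pwm(positive_nonamers, pseudocount: float = 1.0,
            background=None) -> PWMModel:
    """Fit the PWM from branchpoint-centred (positive) nonamers."""
    if len(positive_nonamers) == 0:
        raise ValueError("fit_pwm requires at least one positive nonamer")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    background = (np.full(4, 0.25) if background is None
                  else np.asarray(background, dtype=np.float64))
    mat = _as_int_matrix(list(positive_nonamers))
    if mat.shape[1] != NONAMER_LEN:
        raise ValueError("nonamers must have length 9")
    n = mat.shape[0]
    counts = np.zeros((4, NONAMER_LEN))
    for i in range(NONAMER_LEN):
        counts[:, i] = np.bincount(mat[:, i], minlength=4)
    freq = (counts + pseudocount) / (n + 4 * pseudocount)
    matrix = np.log2(freq / background[:, None])
    return PWMModel(matrix, pseudocount, background)


def encode_pwm(info_seq, model: PWMModel) -> np.ndarray:
    """PWM profile: summed log-odds of each scanned nonamer; 45 dims."""
    return _encode_pwm_many(_as_int_matrix([info_seq] if isinstance(info_seq, str)
                                           else [info_seq]), model)[0]


def _encode_pwm_many(int_seqs: np.ndarray, model: PWMModel) -> np.ndarray:
    # (n, 45, 9) gather of base codes, scored against matrix columns
    bases = int_seqs[:, _WINDOWS]
    return model.matrix[bases, np.arange(NONAMER_LEN)].sum(axis=-1)


@dataclass
class MarkovModel:
    """Per-class first-order position-specific Markov chains on nonamers.

    ``*_init[b]`` is P_1(b); ``*_trans[i-2, a, b]`` is P_i(b | a) for
    positions i = 2..9.  Probabilities are Laplace-pseudocounted, hence
    strictly positive, and every conditional row sums to 1.
    """

    pos_init: np.ndarray   # (4,)
    pos_trans: np.ndarray  # (8, 4, 4)
    neg_init: np.ndarray
    neg_trans: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self):
        for name in ("pos_init", "pos_trans", "neg_init", "neg_trans"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        for init in (self.pos_init, self.neg_init):
            if init.shape != (4,) or abs(init.sum() - 1.0) > 1e-12:
                raise ValueError("initial distributions must be 4-vectors summing to 1")
        for trans in (self.pos_trans, self.neg_trans):
            if trans.shape != (NONAMER_LEN - 1, 4, 4):
                raise ValueError("transition tables must be (8, 4, 4)")
            if np.abs(trans.sum(axis=-1) - 1.0).max() > 1e-12:
                raise ValueError("every transition row must sum to 1")
        if min(self.pos_init.min(), self.neg_init.min(),
               self.pos_trans.min(), self.neg_trans.min()) <= 0:
            raise ValueError("probabilities must be strictly positive")

    def log_prob(self, nonamer_codes: np.ndarray, positive: bool) -> np.ndarray:
        init = self.pos_init if positive else self.neg_init
        trans = self.pos_trans if positive else self.neg_trans
        codes = np.atleast_2d(nonamer_codes)
        lp = np.log(init[codes[:, 0]])
        for i in range(1, NONAMER_LEN):
            lp = lp + np.log(trans[i - 1, codes[:, i - 1], codes[:, i]])
        return lp

    def to_text(self) -> str:
        lines = [f"# MarkovModel v1\npseudocount\t{float(self.pseudocount)!r}"]
        for cls_name, init, trans in (("pos", self.pos_init, self.pos_trans),
                                      ("neg", self.neg_init, self.neg_trans)):
            lines.append(f"{cls_name}_init\t" + "\t".join(repr(float(x)) for x in init))
            for i in range(NONAMER_LEN - 1):
                for a in range(4):
                    lines.append(
                        f"{cls_name}_trans\t{i}\t{ALPHABET[a]}\t"
                        + "\t".join(repr(float(x)) for x in trans[i, a]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MarkovModel":
        init = {"pos": None, "neg": None}
        trans = {"pos": np.zeros((NONAMER_LEN - 1, 4, 4)),
                 "neg": np.zeros((NONAMER_LEN - 1, 4, 4))}
        pseudocount = 1.0
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split("\t")
            if key == "pseudocount":
                pseudocount = float(vals[0])
            elif key.endswith("_init"):
                init[key[:3]] = np.array([float(v) for v in vals])
            elif key.endswith("_trans"):
                i, a = int(vals[0]), ALPHABET.index(vals[1])
                trans[key[:3]][i, a] = [float(v) for v in vals[2:]]
        return cls(init["pos"], trans["pos"], init["neg"], trans["neg"], pseudocount)


def fit_markov(positive_nonamers, negative_nonamers,
               pseudocount: float = 1.0) -> MarkovModel:
    """Fit positive- and negative-class Markov chains from nonamers."""
    if len(positive_nonamers) == 0 or len(negative_nonamers) == 0:
        raise ValueError("fit_markov requires non-empty positive and negative sets")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    def _fit_class(nonamers):
        mat = _as_int_matrix(list(nonamers))
        if mat.shape[1] != NONAMER_LEN:
            raise ValueError("nonamers must have length 9")
        n = mat.shape[0]
        init = (np.bincount(mat[:, 0], minlength=4) + pseudocount) / (n + 4 * pseudocount)
        trans = np.zeros((NONAMER_LEN - 1, 4, 4))
        for i in range(1, NONAMER_LEN):
            counts = np.zeros((4, 4))
            np.add.at(counts, (mat[:, i - 1], mat[:, i]), 1.0)
            counts += pseudocount
            trans[i - 1] = counts / counts.sum(axis=1, keepdims=True)
        return init, trans

    pos_init, pos_trans = _fit_class(positive_nonamers)
    neg_init, neg_trans = _fit_class(negative_nonamers)
    return MarkovModel(pos_init, pos_trans, neg_init, neg_trans, pseudocount)


def encode_markov(info_seq, model: MarkovModel) -> np.ndarray:
    """Markov profile: ln P_pos - ln P_neg of each scanned nonamer; 45 dims."""
    return _encode_markov_many(_as_int_matrix([info_seq]), model)[0]


def _encode_markov_many(int_seqs: np.ndarray, model: MarkovModel) -> np.ndarray:
    bases = int_seqs[:, _WINDOWS]  # (n, 45, 9)
    lp = np.log(model.pos_init[bases[..., 0]]) - np.log(model.neg_init[bases[..., 0]])
    for i in range(1, NONAMER_LEN):
        a, b = bases[..., i - 1], bases[..., i]
        lp = lp + np.log(model.pos_trans[i - 1, a, b]) - np.log(model.neg_trans[i - 1, a, b])
    return lp


# ---------------------------------------------------------------------------
# Polypyrimidine tract profile
# ---------------------------------------------------------------------------

def _pyrimidine_runs(is_pyr: np.ndarray, min_run: int):
    """Maximal runs of pyrimidines of length >= min_run as (start, end) index
    pairs, inclusive, in 5'->3' sequence-index order."""
    runs = []
    i, L = 0, is_pyr.size
    while i < L:
        if is_pyr[i]:
            j = i
            while j + 1 < L and is_pyr[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def encode_ppt(info_seq, min_run: int = 5, c_bonus: float = 0.5) -> np.ndarray:
    """Polypyrimidine tract profile: 3 scores per scanned position; 135 dims.

    Per putative branchpoint offset o in {50..6}: (1) pyrimidine fraction
    over offsets o-1..1 (the stretch strictly between the branchpoint and
    the 3SS); (2) distance in nt from o to the start (most-upstream base)
    of the closest downstream pyrimidine run of length >= ``min_run`` (0 if
    o lies inside one, sentinel 45 if none exists); (3) the score of that
    run, run_length + c_bonus * (#C in run), 0 if none.
    """
    codes = seq_to_ints(info_seq) if isinstance(info_seq, str) else np.asarray(info_seq)
    if codes.size != INFO_LEN:
        raise DataError(f"information region must be {INFO_LEN} nt")
    is_pyr = (codes == 1) | (codes == 3)  # C or T
    is_c = codes == 1
    # suffix pyrimidine counts: pyr_after[i] = #pyrimidines at indices > i
    pyr_cum = np.concatenate([[0], np.cumsum(is_pyr)])
    runs = _pyrimidine_runs(is_pyr, min_run)
    run_scores = [(e - s + 1) + c_bonus * is_c[s:e + 1].sum() for s, e in runs]

    out = np.zeros((N_SCAN, 3))
    for j, o in enumerate(SCAN_OFFSETS):
        c = INFO_LEN - o  # sequence index of the putative BP
        window = INFO_LEN - 1 - c  # length of offsets o-1..1
        out[j, 0] = (pyr_cum[INFO_LEN] - pyr_cum[c + 1]) / window
        dist, score = N_SCAN, 0.0  # sentinel when no downstream run exists
        for (s, e), rscore in zip(runs, run_scores):
            if s <= c <= e:
                dist, score = 0, rscore
                break
            if s > c:  # run lies downstream (closer to 3SS)
                dist, score = s - c, rscore
                break
        out[j, 1] = dist
        out[j, 2] = score
    return out.ravel()


# ---------------------------------------------------------------------------
# Feature matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """The X_{n x m} input matrix with per-column feature names."""

    X: np.ndarray
    feature_names: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("X must be 2-D with one name per column")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_tsv(self, path, intron_ids=None) -> None:
        ids = (intron_ids if intron_ids is not None
               else [str(i) for i in range(self.X.shape[0])])
        with open(path, "w") as fh:
            fh.write("intron_id\t" + "\t".join(self.feature_names) + "\n")
            for rid, row in zip(ids, self.X):
                fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _feature_names(kind: str) -> list:
    if kind == "SP":
        return [f"SP_pos{i + 1}_{b}" for i in range(INFO_LEN) for b in ALPHABET]
    if kind == "DN":
        return [f"DN_pos{i + 1}_bit{j}" for i in range(INFO_LEN - 1) for j in range(4)]
    if kind in ("PWM", "MARKOV"):
        return [f"{kind}_off{o}" for o in SCAN_OFFSETS]
    if kind == "PPT":
        return [f"PPT_off{o}_{s}" for o in SCAN_OFFSETS
                for s in ("pyr_frac", "tract_dist", "tract_score")]
    raise ValueError(f"unknown feature kind {kind!r}")


def encode_feature(records, kind: str, pwm: PWMModel = None,
                   markov: MarkovModel = None) -> np.ndarray:
    """Encode one feature kind for many records (vectorised where it pays)."""
    if kind == "SP":
        return np.stack([encode_sparse(r.info_seq) for r in records])
    if kind == "DN":
        return np.stack([encode_dinucleotide(r.info_seq) for r in records])
    if kind == "PWM":
        if pwm is None:
            raise ValueError("PWM feature requires a fitted PWMModel")
        return _encode_pwm_many(records_to_int_matrix(records), pwm)
    if kind == "MARKOV":
        if markov is None:
            raise ValueError("MARKOV feature requires a fitted MarkovModel")
        return _encode_markov_many(records_to_int_matrix(records), markov)
    if kind == "PPT":
        return np.stack([encode_ppt(r.info_seq) for r in records])
    raise ValueError(f"unknown feature kind {kind!r}")


def build_feature_matrix(records, feature_subset, pwm: PWMModel = None,
                         markov: MarkovModel = None) -> FeatureMatrix:
    """Concatenate the selected encoders in canonical SP,DN,PWM,MARKOV,PPT order.

    PWM/Markov models must have been fitted on training introns only; the
    encoder never sees test-fold labels.
    """
    subset = set(feature_subset)
    unknown = subset - set(FEATURE_ORDER)
    if unknown:
        raise ValueError(f"unknown feature kinds {sorted(unknown)}")
    if not subset:
        raise ValueError("feature subset must be nonempty")
    blocks, names = [], []
    for kind in FEATURE_ORDER:
        if kind in subset:
            blocks.append(encode_feature(records, kind, pwm=pwm, markov=markov))
            names.extend(_feature_names(kind))
    return FeatureMatrix(np.hstack(blocks), names)
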