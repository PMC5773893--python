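"""Synthetic-intron generator with the sequence structure branchpoint
predictors exploit.

Each simulated intron is a 55-nt information region carrying 1-3 planted
branchpoints in the 50..11 offset window, with:

* a unimodal (discretised triangular) branchpoint position distribution
  peaking a couple of dozen nt upstream of the 3SS;
* a consensus-like heptamer (TACTAAC, branchpoint at its 6th base)
  written around each branchpoint with per-position fidelity
  ``motif_strength``;
* an adenine-biased branch nucleotide;
* a pyrimidine-enriched tract in the 10 nt downstream of the most-3'
  branchpoint;
* probabilistic suppression of AG dinucleotides between that branchpoint
  and the 3SS;

on an intron-like T-rich background.  ``null_config`` neutralises every
signal (motif off, branch base and tract at background composition, no AG
suppression) so labels carry no sequence information — the negative
control for calibration tests.  Generation is fully seeded and emits the
same records the rest of the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqmodel import (
    ALPHABET,
    INFO_LEN,
    TARGET_MAX_OFFSET,
    TARGET_MIN_OFFSET,
    IntronRecord,
)

#: branchpoint consensus heptamer; the branch adenine is its 6th base
CONSENSUS_HEPTAMER = "TACTAAC"
_BP_POS_IN_HEPTAMER = 6  # 1-based
#: minimum spacing between two planted branchpoints (nt)
MIN_BP_SPACING = 4
#: width of the enriched pyrimidine tract downstream of the most-3' BP (nt)
PPT_WIDTH = 10


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the study conditions."""

    n_introns: int = 1000
    seed: int = 0
    #: distribution of the number of branchpoints per intron (1, 2, 3)
    bp_count_probs: tuple = (0.8, 0.15, 0.05)
    #: mode and half-width of the triangular position distribution (offsets)
    position_mode: int = 24
    position_width: int = 20
    #: per-position probability of writing the consensus heptamer base
    motif_strength: float = 0.85
    #: branch-nucleotide distribution in A,C,G,T order
    bp_base_probs: tuple = (0.8, 0.1, 0.03, 0.07)
    #: pyrimidine probability inside the downstream tract window
    ppt_strength: float = 0.8
    #: probability of rewriting the G of an AG dinucleotide between BP and 3SS
    ag_depletion: float = 0.9
    #: background nucleotide distribution in A,C,G,T order (T-rich, intron-like)
    background: tuple = (0.27, 0.21, 0.21, 0.31)

    def __post_init__(self):
        for name in ("bp_count_probs", "bp_base_probs", "background"):
            p = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a normalised distribution")
        for name in ("motif_strength", "ppt_strength", "ag_depletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not TARGET_MIN_OFFSET <= self.position_mode <= TARGET_MAX_OFFSET:
            raise ValueError("position_mode must lie in the target region")
        if self.position_width < 1:
            raise ValueError("position_width must be >= 1")
        if self.n_introns < 1:
            raise ValueError("n_introns must be >= 1")


def null_config(config: SimConfig) -> SimConfig:
    """Strip every learnable signal from ``config``.

    Besides neutralising the sequence signals (motif off, branch base and
    tract at background composition, no AG suppression), the branchpoint
    position distribution is flattened: a nonuniform positional prior is
    itself learnable through the label means and would push micro-averaged
    AUC above chance even with no sequence information.
    """
    bg = np.asarray(config.background)
    pyr = bg[1] + bg[3]
    return replace(
        config,
        motif_strength=0.0,
        bp_base_probs=tuple(bg),
        ppt_strength=float(pyr),
        ag_depletion=0.0,
        position_width=float("inf"),  # triangular -> uniform over [11, 50]
    )


def _position_weights(config: SimConfig) -> np.ndarray:
    offsets = np.arange(TARGET_MIN_OFFSET, TARGET_MAX_OFFSET + 1)
    w = np.maximum(0.0, 1.0 - np.abs(offsets - config.position_mode)
                   / config.position_width)
    if w.sum() <= 0:
        raise ValueError("position distribution has empty support")
    return w / w.sum()


def _draw_offsets(rng, n_bp: int, weights: np.ndarray) -> list:
    offsets = np.arange(TARGET_MIN_OFFSET, TARGET_MAX_OFFSET + 1)
    support = offsets[weights > 0]
    # feasibility of n_bp points with pairwise spacing >= MIN_BP_SPACING
    if support.max() - support.min() < (n_bp - 1) * MIN_BP_SPACING:
        raise ValueError(
            f"cannot place {n_bp} branchpoints with spacing {MIN_BP_SPACING} "
            "inside the position distribution's support")
    for _ in range(1000):
        chosen: list = []
        for _ in range(n_bp):
            o = int(rng.choice(offsets, p=weights))
            if all(abs(o - c) >= MIN_BP_SPACING for c in chosen):
                chosen.append(o)
        if len(chosen) == n_bp:
            return chosen
    raise ValueError("failed to draw spaced branchpoint offsets")


def _pyr_split(background) -> tuple:
    """Conditional C/T and A/G splits of the background distribution."""
    bg = np.asarray(background)
    pyr = np.array([bg[1], bg[3]])  # C, T
    pur = np.array([bg[0], bg[2]])  # A, G
    return pyr / pyr.sum(), pur / pur.sum()


def simulate_introns(config: SimConfig) -> list:
    """Generate ``config.n_introns`` seeded synthetic intron records."""
    rng = np.random.default_rng(config.seed)
    weights = _position_weights(config)
    bg = np.asarray(config.background)
    pyr_frac, pur_frac = _pyr_split(bg)
    base_codes = np.arange(4)
    records = []
    for i in range(config.n_introns):
        seq = list(rng.choice(list(ALPHABET), size=INFO_LEN, p=bg))
        n_bp = int(rng.choice([1, 2, 3], p=config.bp_count_probs))
        bp_offsets = _draw_offsets(rng, n_bp, weights)
        # pyrimidine tract in the PPT_WIDTH nt downstream of the most-3' BP
        o_min = min(bp_offsets)
        bp_idx_min = INFO_LEN - o_min
        for j in range(bp_idx_min + 1, min(bp_idx_min + 1 + PPT_WIDTH, INFO_LEN)):
            if rng.random() < config.ppt_strength:
                seq[j] = "C" if rng.random() < pyr_frac[0] else "T"
            else:
                seq[j] = "A" if rng.random() < pur_frac[0] else "G"
        # AG suppression between the most-3' BP and the 3SS
        if config.ag_depletion > 0:
            for j in range(bp_idx_min + 1, INFO_LEN - 1):
                if seq[j] == "A" and seq[j + 1] == "G":
                    if rng.random() < config.ag_depletion:
                        seq[j + 1] = "C" if rng.random() < pyr_frac[0] else "T"
        # plant the consensus heptamer around each branchpoint last, so the
        # motif signal is never eroded by the tract/AG rewrites (planting
        # introduces no new AG and cannot produce a G inside the heptamer)
        for o in sorted(bp_offsets, reverse=True):
            bp_idx = INFO_LEN - o
            start = bp_idx - (_BP_POS_IN_HEPTAMER - 1)
            for j, base in enumerate(CONSENSUS_HEPTAMER):
                if rng.random() < config.motif_strength:
                    seq[start + j] = base
            seq[bp_idx] = ALPHABET[int(rng.choice(base_codes,
                                                  p=config.bp_base_probs))]
        records.append(IntronRecord(f"sim_{i:06d}", "".join(seq),
                                    frozenset(bp_offsets)))
    return records


def null_introns(config: SimConfig) -> list:
    """Generate label-signal-free introns (see :func:`null_config`)."""
    return simulate_introns(null_config(config))
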