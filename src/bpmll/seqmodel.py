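"""Intron records, coordinate conventions, and the 40-position branchpoint label space.

Coordinates are expressed as offsets upstream of the 3' splice site (3SS):
offset 1 is the last intronic base, offset 55 the first base of the
*information region* (the 55 nt immediately upstream of the 3SS that all
feature encoders consume).  Branchpoints are modelled only inside the
*target region*, offsets 50..11, giving a 40-dimensional binary label
vector per intron: label index ``j`` corresponds to offset ``50 - j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("bpmll")

#: length of the information region (nt upstream of 3SS used for encoding)
INFO_LEN = 55
#: most-upstream / most-downstream offsets of the target region
TARGET_MAX_OFFSET = 50
TARGET_MIN_OFFSET = 11
#: number of candidate branchpoint positions (labels)
N_LABELS = TARGET_MAX_OFFSET - TARGET_MIN_OFFSET + 1  # 40

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class IntronRecord:
    """One intron's 55-nt information region and its branchpoint offsets.

    ``info_seq`` is oriented 5'->3'; its last character is the nucleotide
    immediately upstream of the 3SS.  ``bp_offsets`` holds offsets upstream
    of the 3SS, each within the target region [11, 50].
    """

    id: str
    info_seq: str
    bp_offsets: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.info_seq) != INFO_LEN:
            raise DataError(
                f"intron {self.id!r}: information region must be exactly "
                f"{INFO_LEN} nt, got {len(self.info_seq)}"
            )
        bad = set(self.info_seq) - set(ALPHABET)
        if bad:
            raise DataError(
                f"intron {self.id!r}: ambiguous/invalid nucleotides {sorted(bad)}; "
                f"only A/C/G/T are supported"
            )
        object.__setattr__(self, "bp_offsets", frozenset(int(o) for o in self.bp_offsets))
        for o in self.bp_offsets:
            if not TARGET_MIN_OFFSET <= o <= TARGET_MAX_OFFSET:
                raise DataError(
                    f"intron {self.id!r}: branchpoint offset {o} outside target "
                    f"region [{TARGET_MIN_OFFSET}, {TARGET_MAX_OFFSET}]"
                )

    def base_at_offset(self, offset: int) -> str:
        """Nucleotide at ``offset`` nt upstream of the 3SS."""
        if not 1 <= offset <= INFO_LEN:
            raise ValueError(f"offset {offset} outside information region [1, {INFO_LEN}]")
        return self.info_seq[INFO_LEN - offset]


def offset_to_index(offset: int) -> int:
    """Map an upstream offset in [11, 50] to a label index in [0, 39]."""
    if not TARGET_MIN_OFFSET <= offset <= TARGET_MAX_OFFSET:
        raise ValueError(
            f"offset {offset} outside target region "
            f"[{TARGET_MIN_OFFSET}, {TARGET_MAX_OFFSET}]"
        )
    return TARGET_MAX_OFFSET - offset


def index_to_offset(index: int) -> int:
    """Inverse of :func:`offset_to_index`."""
    if not 0 <= index < N_LABELS:
        raise ValueError(f"label index {index} outside [0, {N_LABELS - 1}]")
    return TARGET_MAX_OFFSET - index


def to_label_vector(rec: IntronRecord) -> np.ndarray:
    """40-bit binary target vector of one intron (index 0 <-> offset 50)."""
    y = np.zeros(N_LABELS, dtype=np.int8)
    for o in rec.bp_offsets:
        y[offset_to_index(o)] = 1
    return y


def from_label_vector(bits) -> frozenset:
    """Recover the branchpoint offsets encoded in a 40-bit label vector."""
    bits = np.asarray(bits)
    if bits.shape != (N_LABELS,):
        raise ValueError(f"label vector must have shape ({N_LABELS},), got {bits.shape}")
    return frozenset(index_to_offset(int(j)) for j in np.flatnonzero(bits))


def label_matrix(records) -> np.ndarray:
    """Stack label vectors into the n x 40 target matrix Y."""
    return np.array([to_label_vector(r) for r in records], dtype=np.int8)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as integer codes 0..3."""
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as e:
        raise DataError(f"invalid nucleotide {e.args[0]!r} in sequence") from None


def records_to_int_matrix(records) -> np.ndarray:
    """n x 55 integer-coded sequence matrix for vectorised encoders."""
    return np.array([seq_to_ints(r.info_seq) for r in records], dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O: FASTA sequences + 2-column annotation TSV
# ---------------------------------------------------------------------------

def _parse_annotations(annot_path) -> dict:
    """Read ``intron_id<TAB>offset_upstream`` lines into {id: set(offsets)}.

    A header line is tolerated (detected by a non-integer second column);
    ``#`` comment lines and blank lines are ignored.
    """
    annots: dict = {}
    with open(annot_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(
                    f"{annot_path}:{lineno}: expected 2 tab-separated columns"
                )
            intron_id, raw_offset = parts[0].strip(), parts[1].strip()
            try:
                offset = int(raw_offset)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise DataError(
                    f"{annot_path}:{lineno}: non-integer offset {raw_offset!r}"
                ) from None
            annots.setdefault(intron_id, set()).add(offset)
    return annots


def read_introns(fasta_path, annot_path) -> list:
    """Load introns from FASTA + annotation TSV as :class:`IntronRecord` s.

    The information region is the final 55 nt of each FASTA record; shorter
    records are a hard error.  Branchpoint offsets outside the target region
    [11, 50] are dropped with a warning, mirroring the restriction of the
    label space to offsets 50..11.  Records identical in both sequence and
    retained annotation are collapsed to the first occurrence.
    """
    seqs: dict = {}
    order: list = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise DataError(f"duplicate FASTA record ID {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) < INFO_LEN:
            raise DataError(
                f"FASTA record {rec.id!r} is {len(seq)} nt, shorter than the "
                f"{INFO_LEN}-nt information region"
            )
        seqs[rec.id] = seq[-INFO_LEN:]
        order.append(rec.id)

    annots = _parse_annotations(annot_path)
    unknown = set(annots) - set(seqs)
    if unknown:
        raise DataError(
            f"annotations reference unknown intron IDs: {sorted(unknown)[:5]}"
        )

    records = []
    seen = set()
    for intron_id in order:
        offsets = set()
        for o in annots.get(intron_id, ()):  # keep only target-region offsets
            if TARGET_MIN_OFFSET <= o <= TARGET_MAX_OFFSET:
                offsets.add(o)
            else:
                logger.warning(
                    "intron %s: branchpoint offset %d outside target region "
                    "[%d, %d]; dropped", intron_id, o,
                    TARGET_MIN_OFFSET, TARGET_MAX_OFFSET,
                )
        key = (seqs[intron_id], frozenset(offsets))
        if key in seen:
            logger.warning("intron %s: exact duplicate (sequence, annotation) "
                           "record removed", intron_id)
            continue
        seen.add(key)
        records.append(IntronRecord(intron_id, seqs[intron_id], frozenset(offsets)))
    return records


def write_introns(records, fasta_path, annot_path) -> None:
    """Write records in the FASTA + TSV dialects :func:`read_introns` accepts."""
    SeqIO.write(
        (SeqRecord(Seq(r.info_seq), id=r.id, description="") for r in records),
        str(fasta_path), "fasta",
    )
    with open(annot_path, "w") as fh:
        fh.write("intron_id\toffset_upstream\n")
        for r in records:
            for o in sorted(r.bp_offsets):
                fh.write(f"{r.id}\t{o}\n")
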