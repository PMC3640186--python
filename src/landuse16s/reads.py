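"""Demultiplexing, primer removal and quality trimming of read pairs.

Pairs carry an inline sample barcode as an exact prefix of the forward
read.  Trimming first removes a fixed 11-base primer region from the 5'
end of each mate, then keeps the contiguous segment maximizing
sum(q_i - quality_floor); ties resolve to the leftmost, then longest
segment.  A mate is rejected if the kept segment is shorter than
``min_length``, and a pair survives only if both mates survive — the
per-sample count of surviving pairs is the normalization denominator
used downstream.

Quality strings are kept Phred+33 encoded (as in FASTQ) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from numba import njit
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PRIMER_PREFIX_LENGTH = 11
PHRED_OFFSET = 33


def encode_quals(quals: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in quals)


def decode_quals(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - PHRED_OFFSET


@dataclass(frozen=True)
class ReadPair:
    """One paired read; ``*_qual`` are Phred+33 strings."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"pair {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class TrimPolicy:
    primer_prefix: int = PRIMER_PREFIX_LENGTH
    quality_floor: int = 20
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.primer_prefix < 0:
            raise ValueError("primer_prefix must be >= 0")


def read_fastq_pairs(fwd_path, rev_path) -> list[ReadPair]:
    pairs = []
    fwd = SeqIO.parse(str(fwd_path), "fastq")
    rev = SeqIO.parse(str(rev_path), "fastq")
    for f, r in zip(fwd, rev, strict=True):
        pairs.append(
            ReadPair(
                id=f.id,
                fwd_seq=str(f.seq).upper(),
                rev_seq=str(r.seq).upper(),
                fwd_qual=encode_quals(f.letter_annotations["phred_quality"]),
                rev_qual=encode_quals(r.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], fwd_path, rev_path) -> None:
    fwd_records = []
    rev_records = []
    for p in pairs:
        fwd_records.append(_to_record(p.id, p.fwd_seq, p.fwd_qual))
        rev_records.append(_to_record(p.id, p.rev_seq, p.rev_qual))
    SeqIO.write(fwd_records, str(fwd_path), "fastq")
    SeqIO.write(rev_records, str(rev_path), "fastq")


def _to_record(rid: str, seq: str, qual: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=rid, description="")
    rec.letter_annotations["phred_quality"] = list(decode_quals(qual))
    return rec


def demultiplex(
    pairs: Iterable[ReadPair], barcode_map: dict[str, str]
) -> tuple[dict[str, list[ReadPair]], int]:
    """Assign pairs to samples by exact forward-prefix barcode match.

    Returns ``(per_sample_pairs, discarded_count)``; the barcode prefix is
    stripped from assigned forward reads.  One mismatch anywhere in the
    barcode discards the pair (exact-match policy).
    """
    if not barcode_map:
        raise ValueError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate samples in barcode map")
    blen = lengths.pop()
    if blen == 0:
        raise ValueError("barcodes must be non-empty")

    out: dict[str, list[ReadPair]] = {s: [] for s in barcode_map.values()}
    discarded = 0
    for p in pairs:
        sample = barcode_map.get(p.fwd_seq[:blen])
        if sample is None:
            discarded += 1
            continue
        out[sample].append(
            replace(p, fwd_seq=p.fwd_seq[blen:], fwd_qual=p.fwd_qual[blen:], sample=sample)
        )
    return out, discarded


@njit(cache=True)
def _best_segment(diffs: np.ndarray):  # pragma: no cover - numba
    """Maximum-sum contiguous segment over prefix sums.

    Returns (start, end) half-open; ties -> smallest start, then largest end.
    """
    n = diffs.shape[0]
    best_val = -(1 << 60)
    best_s = 0
    best_e = 0
    min_pref = 0  # min of prefix sums P[0..j-1], earliest index on ties
    min_idx = 0
    pref = 0
    for j in range(1, n + 1):
        pref += diffs[j - 1]
        val = pref - min_pref
        if (
            val > best_val
            or (val == best_val and min_idx < best_s)
            or (val == best_val and min_idx == best_s and j > best_e)
        ):
            best_val = val
            best_s = min_idx
            best_e = j
        if pref < min_pref:
            min_pref = pref
            min_idx = j
    return best_s, best_e


def quality_trim(seq: str, qual: str, policy: TrimPolicy) -> tuple[str, str] | None:
    """Trim one mate; returns (seq, qual) or None if rejected."""
    if len(seq) <= policy.primer_prefix:
        return None
    seq = seq[policy.primer_prefix :]
    qual = qual[policy.primer_prefix :]
    diffs = decode_quals(qual) - policy.quality_floor
    s, e = _best_segment(diffs)
    if e - s < policy.min_length:
        return None
    return seq[s:e], qual[s:e]


def trim_pairs(pairs: Iterable[ReadPair], policy: TrimPolicy) -> list[ReadPair]:
    """Trim both mates of every pair; keep pairs where both mates survive."""
    kept = []
    for p in pairs:
        f = quality_trim(p.fwd_seq, p.fwd_qual, policy)
        if f is None:
            continue
        r = quality_trim(p.rev_seq, p.rev_qual, policy)
        if r is None:
            continue
        kept.append(replace(p, fwd_seq=f[0], fwd_qual=f[1], rev_seq=r[0], rev_qual=r[1]))
    return kept


def count_trimmed_pairs(per_sample: dict[str, list[ReadPair]]) -> dict[str, int]:
    """Per-sample surviving-pair counts: the normalization denominators."""
    return {sample: len(pairs) for sample, pairs in per_sample.items()}
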