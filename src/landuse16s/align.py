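"""Read-to-reference local alignment with fixed, documented scoring.

Scoring: match +1, mismatch -1, gap -2 (linear).  Both read and reference
ends clip without penalty, so the reported ``length_fraction`` — read bases
inside the alignment divided by read length — is meaningful and can fall
below 1 when noisy read ends are clipped.

Identity is matches / alignment columns, with gap columns counted in the
denominator (a strict, unambiguous definition).

Determinism: among equal-scoring alignments the endpoint with the smallest
read index, then the smallest reference index wins, and the traceback
prefers diagonal over up (read-consuming gap) over left moves.  Alignments
of score 0 are reported as empty (identity 0, length_fraction 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of one read against one reference."""

    ref_id: str
    score: int
    identity: float
    length_fraction: float


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _align_stats(read: np.ndarray, ref: np.ndarray):  # pragma: no cover - numba
    """Fill the local DP matrix and trace back one canonical optimum.

    Returns (score, matches, columns, read_span).
    """
    m = read.shape[0]
    n = ref.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            s = MATCH if ri == ref[j - 1] else MISMATCH
            h = H[i - 1, j - 1] + s
            up = H[i - 1, j] + GAP
            if up > h:
                h = up
            left = H[i, j - 1] + GAP
            if left > h:
                h = left
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0
    # canonical traceback: diagonal > up > left
    i = bi
    j = bj
    matches = 0
    cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == MATCH:
                matches += 1
            cols += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    read_span = bi - i
    return int(best), matches, cols, read_span


def align_read(read: str, ref: str, ref_id: str = "") -> AlignmentHit:
    """Best-scoring local alignment of ``read`` against ``ref``."""
    if not read or not ref:
        raise ValueError("align_read requires non-empty sequences")
    score, matches, cols, span = _align_stats(encode(read), encode(ref))
    if cols == 0:
        return AlignmentHit(ref_id=ref_id, score=0, identity=0.0, length_fraction=0.0)
    return AlignmentHit(
        ref_id=ref_id,
        score=score,
        identity=matches / cols,
        length_fraction=span / len(read),
    )


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
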