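"""Independent reference implementations used only as test oracles.

These deliberately recompute results with different algorithms/code paths
from the package: a row-vectorized numpy DP (and a naive triple-loop DP)
for local alignment, a literal rule-by-rule pair classifier, an O(n^2)
all-substrings trimming search, permutation enumeration for Spearman p,
and a direct sum-of-squares two-way ANOVA decomposition.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats as sps

from landuse16s.align import revcomp
from landuse16s.taxonomy import TaxonomicLineage

MATCH, MISMATCH, GAP = 1, -1, -2


def dp_matrix_numpy(read: str, ref: str) -> np.ndarray:
    """Local-alignment score matrix via vectorized rows (accumulate trick)."""
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(ref.encode(), dtype=np.uint8)
    m, n = len(r), len(t)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    idx2 = 2 * np.arange(n + 1)
    for i in range(1, m + 1):
        s = np.where(t == r[i - 1], MATCH, MISMATCH)
        base = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + GAP)
        base = np.maximum(base, 0)
        row = np.zeros(n + 1, dtype=np.int64)
        row[1:] = base
        # fold in left-gap moves: H[i,j] = max_k<=j (cand[k] - 2(j-k))
        acc = np.maximum.accumulate(row + idx2) - idx2
        acc[0] = 0
        H[i] = np.maximum(acc, 0)
    return H


def dp_matrix_naive(read: str, ref: str) -> np.ndarray:
    """Triple-branch scalar DP, for tiny cross-checks of both fills."""
    m, n = len(read), len(ref)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + GAP, H[i, j - 1] + GAP)
    return H


def traceback_stats(H: np.ndarray, read: str, ref: str):
    """Canonical traceback (diag > up > left; earliest max endpoint)."""
    best = int(H.max())
    if best == 0:
        return 0, 0, 0, 0
    bi, bj = np.unravel_index(int(np.argmax(H)), H.shape)  # row-major = smallest i then j
    i, j = int(bi), int(bj)
    matches = cols = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += s == MATCH
            cols += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, matches, cols, int(bi) - i


def oracle_align(read: str, ref: str):
    """(score, identity, length_fraction) from the numpy DP oracle."""
    H = dp_matrix_numpy(read, ref)
    score, matches, cols, span = traceback_stats(H, read, ref)
    if cols == 0:
        return 0, 0.0, 0.0
    return score, matches / cols, span / len(read)


def oracle_best_hits(read: str, refs: list, lf_floor: float):
    """Literal filter: lf-passing hits restricted to maximal identity."""
    hits = []
    for rec in sorted(refs, key=lambda r: r.id):
        score, ident, lf = oracle_align(read, rec.sequence)
        if lf >= lf_floor - 1e-12:
            hits.append((rec.id, ident))
    if not hits:
        return {}
    best = max(i for _, i in hits)
    return {rid: ident for rid, ident in hits if ident >= best - 1e-12}


def _lcp(lineages):
    labels = []
    for ranks in zip(*(l.labels for l in lineages)):
        if len(set(ranks)) != 1:
            break
        labels.append(ranks[0])
    return TaxonomicLineage(tuple(labels))


def oracle_classify_pair(pair, db, floors, lf_floor):
    """Literal application of the concordant / LCA / unclassified rules."""
    lineage_of = {r.id: r.lineage for r in db}
    fwd = oracle_best_hits(pair.fwd_seq, list(db), lf_floor)
    rev = oracle_best_hits(revcomp(pair.rev_seq), list(db), lf_floor)
    shared = set(fwd) & set(rev)
    if shared:
        status = "concordant"
        eff = min(min(fwd[r] for r in shared), min(rev[r] for r in shared))
        lineage = _lcp([lineage_of[r] for r in sorted(shared)])
    elif fwd and rev:
        status = "lca"
        eff = min(min(fwd.values()), min(rev.values()))
        lineage = _lcp([lineage_of[r] for r in sorted(set(fwd) | set(rev))])
    else:
        return "unclassified", TaxonomicLineage(), 0.0
    depth = 0
    for f in floors:
        if eff + 1e-12 >= f:
            depth += 1
        else:
            break
    lineage = TaxonomicLineage(lineage.labels[: min(depth, lineage.depth)])
    if lineage.depth == 0:
        return "unclassified", lineage, eff
    return status, lineage, eff


def oracle_best_trim_segment(quals, floor):
    """All O(n^2) substrings; max sum, ties -> leftmost then longest."""
    n = len(quals)
    best = None
    for s in range(n):
        total = 0
        for e in range(s + 1, n + 1):
            total += quals[e - 1] - floor
            key = (total, -s, e - s)
            if best is None or key > best[0]:
                best = (key, (s, e))
    return best[1] if best else (0, 0)


def oracle_spearman_exact_p(x, y):
    """Two-sided permutation p by explicit enumeration (<= 8 obs)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    hits = total = 0
    for perm in permutations(ry):
        rho = np.corrcoef(rx, perm)[0, 1]
        hits += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


def oracle_two_way_ss(values, a, b):
    """Direct balanced two-way decomposition; returns F per effect."""
    values = np.asarray(values, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = values.mean()
    lev_a, lev_b = np.unique(a), np.unique(b)
    r = values.size // (lev_a.size * lev_b.size)
    ss_a = sum(
        (values[a == la].size) * (values[a == la].mean() - grand) ** 2 for la in lev_a
    )
    ss_b = sum(
        (values[b == lb].size) * (values[b == lb].mean() - grand) ** 2 for lb in lev_b
    )
    ss_cells = 0.0
    ss_within = 0.0
    for la in lev_a:
        for lb in lev_b:
            cell = values[(a == la) & (b == lb)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_within += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = lev_a.size - 1, lev_b.size - 1
    df_ab = df_a * df_b
    df_w = values.size - lev_a.size * lev_b.size
    msw = ss_within / df_w
    return {
        "A": (ss_a / df_a) / msw,
        "B": (ss_b / df_b) / msw,
        "A:B": (ss_ab / df_ab) / msw,
    }
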