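"""Paired-read taxonomic classification against a lineage-annotated reference.

Each mate is aligned locally to every reference; hits must cover at least
80% of the read (length fraction) and only hits tying the maximal identity
are kept.  If the mates' best-hit sets share a reference the pair is
*concordant* and takes that reference's lineage (ties resolve to their
LCA); otherwise, if both mates have hits, the pair takes the LCA of all
hit lineages; otherwise it is *unclassified*.  The assigned lineage is
finally truncated to the deepest rank whose identity floor is met by the
pair's effective identity (the minimum identity over the hits used):

    domain 0.80, phylum 0.80, class 0.90, order 0.90, family 0.90,
    genus 0.95, species 0.99

Two exact shortcuts keep classification fast without changing results:

* a mate that is an exact substring of a reference scores the maximum
  possible (all-match, full-length), so references containing the mate
  form the best-hit set outright — unless another reference shares a
  common substring of >= ceil(0.8*m) bases (the only way to tie identity
  1.0 while passing the length-fraction filter), in which case the
  exhaustive path runs;
* a reference sharing no 14-mer with the mate cannot contain a match run
  of >= 14 columns, which bounds the identity of any length-fraction-
  passing alignment (see :func:`screen_identity_bound`); when a screened
  candidate already exceeds that bound the remaining references are
  provably out of the running.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentHit, align_read, revcomp
from .reads import ReadPair
from .taxonomy import RANKS, ReferenceDatabase, TaxonomicLineage, lca_many

SCREEN_K = 14  # k-mer size for the sound candidate screen
EXACT_K = 32  # k-mer size for the exact-substring shortcut screen


@dataclass(frozen=True)
class RankThresholds:
    """Per-rank identity floors plus the length-fraction floor."""

    floors: tuple[float, ...] = (0.80, 0.80, 0.90, 0.90, 0.90, 0.95, 0.99)
    length_fraction_floor: float = 0.80

    def __post_init__(self) -> None:
        if len(self.floors) != len(RANKS):
            raise ValueError("need one identity floor per rank")
        if any(not (0 < f <= 1) for f in self.floors) or list(self.floors) != sorted(
            self.floors
        ):
            raise ValueError("floors must be in (0,1] and non-decreasing toward species")
        if not (0 < self.length_fraction_floor <= 1):
            raise ValueError("length_fraction_floor must be in (0,1]")

    def max_depth(self, identity: float) -> int:
        """Deepest rank count supported by an effective identity."""
        depth = 0
        for f in self.floors:
            if identity + 1e-12 >= f:
                depth += 1
            else:
                break
        return depth


@dataclass(frozen=True)
class PairAssignment:
    pair_id: str
    sample: str | None
    status: str  # concordant | lca | unclassified
    lineage: TaxonomicLineage
    effective_identity: float

    def __post_init__(self) -> None:
        if self.status not in ("concordant", "lca", "unclassified"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "unclassified") != (self.lineage.depth == 0):
            raise ValueError("status unclassified iff lineage depth 0")


def screen_identity_bound(read_len: int, lf_floor: float, k: int = SCREEN_K) -> float:
    """Upper bound on identity for a reference sharing no k-mer with the read.

    With no shared k-mer every run of match columns is <= k-1 long, so an
    alignment with E error columns has M <= (E+1)(k-1) matches, and covering
    R0 = ceil(lf_floor * read_len) read bases forces E >= (R0 - k + 1) / k.
    Identity M/(M+E) is maximized at minimal E and maximal M.
    """
    r0 = math.ceil(lf_floor * read_len - 1e-9)
    e_min = max(math.ceil((r0 - k + 1) / k), 0)
    if e_min == 0:
        return 1.0
    m_max = (e_min + 1) * (k - 1)
    return m_max / (m_max + e_min)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class PairClassifier:
    """Classifies trimmed read pairs against a reference database."""

    def __init__(
        self,
        db: ReferenceDatabase,
        thresholds: RankThresholds | None = None,
        *,
        use_fast_paths: bool = True,
    ) -> None:
        self.db = db
        self.thresholds = thresholds or RankThresholds()
        self.use_fast_paths = use_fast_paths
        # deterministic iteration order irrespective of record order
        self._refs = sorted(db.records, key=lambda r: r.id)
        self._lineage = {r.id: r.lineage for r in self._refs}
        self._screen_kmers = [_kmers(r.sequence, SCREEN_K) for r in self._refs]
        self._exact_kmers = [_kmers(r.sequence, EXACT_K) for r in self._refs]

    # ------------------------------------------------------------------ hits

    def _exhaustive_hits(self, read: str, idxs: Sequence[int]) -> list[AlignmentHit]:
        lf = self.thresholds.length_fraction_floor
        hits = [
            h
            for i in idxs
            if (h := align_read(read, self._refs[i].sequence, self._refs[i].id)).length_fraction
            >= lf - 1e-12
        ]
        if not hits:
            return []
        best = max(h.identity for h in hits)
        return [h for h in hits if h.identity >= best - 1e-12]

    def best_hits(self, read: str) -> list[AlignmentHit]:
        """Length-fraction-passing hits at maximal identity (tie set)."""
        all_idx = range(len(self._refs))
        if not self.use_fast_paths:
            return self._exhaustive_hits(read, all_idx)

        m = len(read)
        min_span = math.ceil(self.thresholds.length_fraction_floor * m - 1e-9)

        # exact-substring shortcut
        full = [i for i, r in enumerate(self._refs) if read in r.sequence]
        if full:
            if not self._partial_exact_elsewhere(read, set(full), min_span):
                return [
                    AlignmentHit(self._refs[i].id, score=m, identity=1.0, length_fraction=1.0)
                    for i in full
                ]
            return self._exhaustive_hits(read, all_idx)

        # k-mer screen with identity bound
        if m > SCREEN_K:
            read_kmers = _kmers(read, SCREEN_K)
            cand = [i for i in all_idx if read_kmers & self._screen_kmers[i]]
            if cand:
                hits = self._exhaustive_hits(read, cand)
                bound = screen_identity_bound(m, self.thresholds.length_fraction_floor)
                if hits and hits[0].identity > bound:
                    return hits
        return self._exhaustive_hits(read, all_idx)

    def _partial_exact_elsewhere(self, read: str, full: set[int], min_span: int) -> bool:
        """Could a non-containing reference tie identity 1.0 with lf >= floor?

        True iff some other reference shares a common substring of
        >= min_span bases with the read.
        """
        if min_span <= 0:
            return True
        if min_span < EXACT_K:
            others = [i for i in range(len(self._refs)) if i not in full]
        else:
            read_kmers = _kmers(read, EXACT_K)
            others = [
                i
                for i in range(len(self._refs))
                if i not in full and read_kmers & self._exact_kmers[i]
            ]
        for i in others:
            seq = self._refs[i].sequence
            if any(
                read[off : off + min_span] in seq for off in range(len(read) - min_span + 1)
            ):
                return True
        return False

    # ------------------------------------------------------------ pair rules

    def classify_pair(self, pair: ReadPair) -> PairAssignment:
        """Apply the concordant / LCA / unclassified rules to one pair."""
        fwd_hits = self.best_hits(pair.fwd_seq)
        rev_hits = self.best_hits(revcomp(pair.rev_seq))
        fids = {h.ref_id for h in fwd_hits}
        rids = {h.ref_id for h in rev_hits}
        shared = fids & rids

        if shared:
            status = "concordant"
            used = [h for h in fwd_hits + rev_hits if h.ref_id in shared]
            lineage = lca_many([self._lineage[r] for r in sorted(shared)])
        elif fids and rids:
            status = "lca"
            used = list(fwd_hits) + list(rev_hits)
            lineage = lca_many([self._lineage[h.ref_id] for h in used])
        else:
            return PairAssignment(pair.id, pair.sample, "unclassified", TaxonomicLineage(), 0.0)

        eff = min(h.identity for h in used)
        lineage = lineage.truncate(min(self.thresholds.max_depth(eff), lineage.depth))
        if lineage.depth == 0:
            return PairAssignment(pair.id, pair.sample, "unclassified", TaxonomicLineage(), eff)
        return PairAssignment(pair.id, pair.sample, status, lineage, eff)

    def classify_pairs(self, per_sample: dict[str, list[ReadPair]]) -> list[PairAssignment]:
        out: list[PairAssignment] = []
        for sample in per_sample:
            for pair in per_sample[sample]:
                out.append(self.classify_pair(pair))
        return out


# --------------------------------------------------------------- tabulation


def tabulate(
    assignments: Iterable[PairAssignment],
    rank: str,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Taxon x sample counts of pairs classified at least down to ``rank``.

    Pairs whose assigned lineage stops above the rank are excluded here
    (they still count at shallower ranks).
    """
    rank_idx = RANKS.index(rank)
    counts: dict[tuple[str, str], int] = {}
    seen_samples: dict[str, None] = {}
    for a in assignments:
        if a.sample is not None:
            seen_samples.setdefault(a.sample, None)
        label = a.lineage.label_at(rank)
        if label is None or a.sample is None:
            continue
        counts[(label, a.sample)] = counts.get((label, a.sample), 0) + 1
    cols = list(samples) if samples is not None else list(seen_samples)
    taxa = sorted({t for t, _ in counts})
    mat = pd.DataFrame(0, index=taxa, columns=cols, dtype=int)
    for (t, s), c in counts.items():
        if s in mat.columns:
            mat.loc[t, s] = c
    mat.index.name = rank
    return mat


def normalize(matrix: pd.DataFrame, denominators: dict[str, int]) -> pd.DataFrame:
    """Relative abundance: counts over per-sample trimmed-pair totals."""
    out = matrix.astype(float).copy()
    for sample in matrix.columns:
        denom = denominators.get(sample)
        if denom is None:
            raise ValueError(f"no trimmed-pair denominator for sample {sample!r}")
        if denom <= 0:
            raise ValueError(f"zero trimmed-pair denominator for sample {sample!r}")
        out[sample] = matrix[sample] / denom
    return out
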