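"""Pair classification rules, tabulation and normalization."""

import numpy as np
import pandas as pd
import pytest

from landuse16s.align import revcomp
from landuse16s.classify import (
    PairAssignment,
    PairClassifier,
    RankThresholds,
    normalize,
    screen_identity_bound,
    tabulate,
)
from landuse16s.reads import ReadPair, encode_quals
from landuse16s.taxonomy import TaxonomicLineage

from oracles import oracle_classify_pair


def _pair(fwd, rev, pid="p1", sample="s1"):
    return ReadPair(
        id=pid,
        fwd_seq=fwd,
        rev_seq=rev,
        fwd_qual=encode_quals([40] * len(fwd)),
        rev_qual=encode_quals([40] * len(rev)),
        sample=sample,
    )


def _mutate(rng, seq, k):
    out = list(seq)
    for pos in rng.choice(np.arange(2, len(seq) - 2), size=k, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


class TestThresholds:
    def test_defaults_match_rank_table(self):
        t = RankThresholds()
        assert t.floors == (0.80, 0.80, 0.90, 0.90, 0.90, 0.95, 0.99)
        assert t.max_depth(0.97) == 6  # through genus, species withheld
        assert t.max_depth(0.92) == 5  # through family
        assert t.max_depth(0.82) == 2  # domain + phylum only
        assert t.max_depth(0.5) == 0

    def test_decreasing_floors_rejected(self):
        with pytest.raises(ValueError):
            RankThresholds(floors=(0.9, 0.8, 0.9, 0.9, 0.9, 0.95, 0.99))


class TestClassifyPair:
    def test_concordant_pair_truncated_at_genus(self, small_db, rng):
        rec = small_db.records[0]
        fwd = _mutate(rng, rec.sequence[:120], 3)  # identity ~0.975
        rev = revcomp(_mutate(rng, rec.sequence[-120:], 2))
        a = PairClassifier(small_db).classify_pair(_pair(fwd, rev))
        assert a.status == "concordant"
        assert a.lineage.depth == 6  # species needs 0.99
        assert a.lineage.label_at("genus") == rec.genus

    def test_no_hits_is_unclassified(self, small_db, rng):
        junk = "".join(rng.choice(list("ACGT"), size=100))
        a = PairClassifier(small_db).classify_pair(_pair(junk, junk))
        assert a.status == "unclassified"
        assert a.lineage.depth == 0

    def test_discordant_family_mates_resolve_by_lca(self, small_db):
        # two genera in the same family -> LCA at family, truncated by identity
        by_family = {}
        for r in small_db.records:
            by_family.setdefault(r.lineage.label_at("family"), []).append(r)
        fam, recs = next((f, rs) for f, rs in by_family.items() if len(rs) >= 2)
        a = PairClassifier(small_db).classify_pair(
            _pair(recs[0].sequence[:120], revcomp(recs[1].sequence[-120:]))
        )
        # mates match different references exactly -> no shared best hit
        assert a.status == "lca"
        assert a.lineage.label_at("genus") is None
        assert a.lineage.label_at("family") == fam

    def test_status_lineage_consistency_enforced(self):
        with pytest.raises(ValueError):
            PairAssignment("p", "s", "unclassified", TaxonomicLineage(("Bacteria",)), 0.9)


class TestOracleEquivalence:
    def test_matches_brute_force_on_randomized_pairs(self, small_db, rng):
        t = RankThresholds()
        clf = PairClassifier(small_db)
        for i in range(40):
            rec = small_db.records[int(rng.integers(len(small_db)))]
            kind = i % 3
            if kind == 0:
                fwd = _mutate(rng, rec.sequence[:110], int(rng.integers(0, 8)))
                rev = revcomp(_mutate(rng, rec.sequence[-110:], int(rng.integers(0, 8))))
            elif kind == 1:  # heavy noise
                fwd = _mutate(rng, rec.sequence[:110], 25)
                rev = revcomp(_mutate(rng, rec.sequence[-110:], 25))
            else:  # random junk forward
                fwd = "".join(rng.choice(list("ACGT"), size=100))
                rev = revcomp(rec.sequence[-100:])
            pair = _pair(fwd, rev, pid=f"p{i}")
            got = clf.classify_pair(pair)
            status, lineage, eff = oracle_classify_pair(
                pair, small_db, t.floors, t.length_fraction_floor
            )
            assert (got.status, got.lineage) == (status, lineage)
            assert got.effective_identity == pytest.approx(eff, abs=1e-12)

    def test_fast_paths_change_nothing(self, small_db, rng):
        fast = PairClassifier(small_db, use_fast_paths=True)
        slow = PairClassifier(small_db, use_fast_paths=False)
        for i in range(15):
            rec = small_db.records[int(rng.integers(len(small_db)))]
            fwd = _mutate(rng, rec.sequence[:115], int(rng.integers(0, 5)))
            rev = revcomp(_mutate(rng, rec.sequence[-115:], int(rng.integers(0, 5))))
            pair = _pair(fwd, rev, pid=f"p{i}")
            assert fast.classify_pair(pair) == slow.classify_pair(pair)

    def test_record_order_does_not_matter(self, small_db, rng):
        from landuse16s.taxonomy import ReferenceDatabase

        shuffled = ReferenceDatabase(list(small_db.records[::-1]))
        a = PairClassifier(small_db)
        b = PairClassifier(shuffled)
        rec = small_db.records[2]
        pair = _pair(rec.sequence[:100], revcomp(rec.sequence[-100:]))
        assert a.classify_pair(pair) == b.classify_pair(pair)


def test_screen_bound_is_conservative():
    # 139-nt read, no shared 14-mer, 80% coverage: identity can never be high
    assert screen_identity_bound(139, 0.8) < 0.94
    assert screen_identity_bound(10, 0.8) == 1.0  # too short to screen


class TestTabulate:
    def _assignments(self):
        full = TaxonomicLineage(("B", "P", "C", "O", "F", "X", "X sp"))
        fam_only = TaxonomicLineage(("B", "P", "C", "O", "F"))
        mk = lambda i, lin, st: PairAssignment(f"p{i}", "s1", st, lin, 0.96)
        return [mk(0, full, "concordant"), mk(1, full, "concordant"),
                mk(2, full, "concordant"), mk(3, fam_only, "lca")]

    def test_truncation_semantics(self):
        a = self._assignments()
        genus = tabulate(a, "genus", ["s1"])
        family = tabulate(a, "family", ["s1"])
        assert genus.loc["X", "s1"] == 3
        assert family.loc["F", "s1"] == 4

    def test_empty_assignments_zero_matrix(self):
        assert tabulate([], "genus", ["s1"]).shape == (0, 1)

    def test_rank_monotonicity(self):
        a = self._assignments()
        assert tabulate(a, "genus", ["s1"]).sum().sum() <= tabulate(a, "phylum", ["s1"]).sum().sum()


class TestNormalize:
    def test_division_by_trimmed_pairs(self):
        m = pd.DataFrame({"s1": [90]}, index=["X"])
        out = normalize(m, {"s1": 1000})
        assert out.loc["X", "s1"] == pytest.approx(0.09)

    def test_zero_denominator_names_sample(self):
        m = pd.DataFrame({"s1": [1]}, index=["X"])
        with pytest.raises(ValueError, match="s1"):
            normalize(m, {"s1": 0})

    def test_column_sums_bounded_by_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, size=(5, 3)), columns=list("abc"))
        denoms = {c: int(counts[c].sum()) + 10 for c in counts}
        assert (normalize(counts, denoms).sum() <= 1).all()
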