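import numpy as np
import pytest

from oracles import brute_overlap_components

from partstree.projection import (DEFAULT_AGE_BANDS, HelixMap, Relic, band_of,
                                  build_relics, coevolution_correlation,
                                  coevolution_table, isoacceptor_census,
                                  project_oldest_helix)
from partstree.scan import HomologyHit
from partstree.synthetic import TRNAQuery


def hit(start, end, qid="q1", target="rRNA", score=50):
    return HomologyHit(query_id=qid, target_id=target, start=start, end=end,
                       score=score, zscore=3.0, pvalue=0.005, query_start=1,
                       query_end=end - start + 1, ops=[])


def query(qid, iso="Leu", group=1, nd=0.1):
    return TRNAQuery(id=qid, sequence="ACGT" * 20, isoacceptor=iso,
                     group=group, nd_trna=nd)


class TestBuildRelics:
    def test_overlapping_hits_merge(self):
        relics = build_relics([hit(10, 80), hit(50, 120, "q2")])
        assert len(relics) == 1
        assert relics[0].target_interval == (10, 120)
        assert len(relics[0].member_hits) == 2

    def test_abutting_hits_do_not_merge(self):
        relics = build_relics([hit(10, 80), hit(81, 120)])
        assert len(relics) == 2

    def test_transitive_chain_merges(self):
        relics = build_relics([hit(1, 10), hit(5, 20), hit(15, 30)])
        assert len(relics) == 1
        assert relics[0].target_interval == (1, 30)

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError, match="multiple targets"):
            build_relics([hit(1, 10), hit(5, 20, target="other")])

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(1, 12))
            intervals = []
            for _ in range(n):
                s = int(rng.integers(1, 300))
                intervals.append((s, s + int(rng.integers(0, 60))))
            hits = [hit(s, e, qid=f"q{k}")
                    for k, (s, e) in enumerate(intervals)]
            relics = build_relics(hits)
            comps = brute_overlap_components(intervals)
            got = [frozenset(int(h.query_id[1:]) for h in r.member_hits)
                   for r in relics]
            assert got == list(comps)

    def test_min_overlap_convention(self):
        assert len(build_relics([hit(10, 20), hit(20, 30)],
                                min_overlap=1)) == 1
        assert len(build_relics([hit(10, 20), hit(20, 30)],
                                min_overlap=2)) == 2


class TestProjection:
    @pytest.fixture
    def hmap(self) -> HelixMap:
        return HelixMap(target_id="rRNA", intervals=[
            (1, 100, "H1", 0.04), (101, 200, "H2", 0.5),
            (201, 300, "H3", 0.29)])

    def test_oldest_nd_is_minimum_spanned(self, hmap):
        relic = build_relics([hit(80, 150)])[0]
        project_oldest_helix(relic, hmap)
        assert relic.oldest_nd == 0.04
        assert [h for h, _ in relic.projection] == ["H1", "H2"]

    def test_single_old_helix(self, hmap):
        relic = build_relics([hit(10, 50)])[0]
        assert project_oldest_helix(relic, hmap).oldest_nd == 0.04

    def test_ptc_band_assignment(self, hmap):
        relic = build_relics([hit(210, 260)])[0]
        project_oldest_helix(relic, hmap)
        assert 0.28 <= relic.oldest_nd <= 0.30
        assert band_of(relic.oldest_nd) == "ptc"

    def test_gap_error_outside_coverage(self, hmap):
        relic = build_relics([hit(250, 350)])[0]
        with pytest.raises(ValueError, match="gap"):
            project_oldest_helix(relic, hmap)

    def test_added_hit_never_raises_oldest_nd(self, hmap):
        one = build_relics([hit(120, 150)])[0]
        project_oldest_helix(one, hmap)
        grown = build_relics([hit(120, 150), hit(90, 130, "q2")])[0]
        project_oldest_helix(grown, hmap)
        assert grown.oldest_nd <= one.oldest_nd

    def test_helix_map_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            HelixMap(target_id="r", intervals=[(1, 10, "a", 0.1),
                                               (5, 20, "b", 0.2)])
        with pytest.raises(ValueError, match="nd"):
            HelixMap(target_id="r", intervals=[(1, 10, "a", 1.4)])


class TestCoevolution:
    def _relics(self, hmap):
        hits = [hit(10, 90, "qA"), hit(60, 140, "qB"), hit(220, 280, "qC")]
        relics = build_relics(hits)
        for r in relics:
            project_oldest_helix(r, hmap)
        return relics

    @pytest.fixture
    def hmap(self) -> HelixMap:
        return HelixMap(target_id="rRNA", intervals=[
            (1, 100, "H1", 0.02), (101, 200, "H2", 0.8),
            (201, 300, "H3", 0.6)])

    def test_table_rows_and_flags(self, hmap):
        relics = self._relics(hmap)
        queries = [query("qA", "Leu", 1, 0.0), query("qB", "Ser", 2, 0.1),
                   query("qC", "Lys", 3, 0.9)]
        table = coevolution_table(relics, queries)
        assert len(table) == 3  # one row per (hit, relic) membership
        assert table[table.query_id == "qA"].old_segment.all()
        assert table[table.query_id == "qB"].old_segment.all()
        assert not table[table.query_id == "qC"].old_segment.any()

    def test_missing_metadata_is_an_error(self, hmap):
        relics = self._relics(hmap)
        with pytest.raises(KeyError, match="qB"):
            coevolution_table(relics, [query("qA"), query("qC")])

    def test_empty_relics_empty_table(self):
        table = coevolution_table([], [query("qA")])
        assert len(table) == 0

    def test_monotone_table_gives_perfect_rho(self):
        import pandas as pd
        table = pd.DataFrame({
            "nd_trna": [0.1, 0.3, 0.5, 0.9],
            "oldest_nd": [0.05, 0.2, 0.4, 0.8],
            "old_segment": [True] * 4})
        res = coevolution_correlation(table, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.pvalue is not None and res.pvalue < 0.1

    def test_constant_column_reported_undefined(self):
        import pandas as pd
        table = pd.DataFrame({"nd_trna": [0.5] * 4,
                              "oldest_nd": [0.1, 0.2, 0.3, 0.4],
                              "old_segment": [True] * 4})
        res = coevolution_correlation(table, seed=0)
        assert res.rho is None and "undefined" in res.note

    def test_too_few_rows_rejected(self):
        import pandas as pd
        table = pd.DataFrame({"nd_trna": [0.1, 0.2],
                              "oldest_nd": [0.1, 0.2],
                              "old_segment": [True, True]})
        with pytest.raises(ValueError, match="3 rows"):
            coevolution_correlation(table, seed=0)


class TestCensus:
    def test_counts_per_isoacceptor(self):
        hmap = HelixMap(target_id="rRNA",
                        intervals=[(1, 1000, "H1", 0.29)])
        hits = ([hit(i * 100 + 1, i * 100 + 50, f"Leu{i}") for i in range(6)]
                + [hit(i * 100 + 60, i * 100 + 90, f"Ser{i}")
                   for i in range(5)])
        relics = build_relics(hits)
        for r in relics:
            project_oldest_helix(r, hmap)
        queries = ([query(f"Leu{i}", "Leu", 1, 0.0) for i in range(6)]
                   + [query(f"Ser{i}", "Ser", 2, 0.1) for i in range(5)])
        census = isoacceptor_census(relics, queries)
        totals = census.groupby("isoacceptor")["n_hits"].sum()
        assert totals["Leu"] == 6 and totals["Ser"] == 5
        assert set(census["band"]) == {"ptc"}

    def test_no_hits_empty_census(self):
        census = isoacceptor_census([], [])
        assert len(census) == 0
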