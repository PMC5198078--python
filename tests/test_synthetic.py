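import numpy as np
import pytest
from scipy.stats import spearmanr

from partstree.synthetic import (AccretionTruth, TRNAQuery,
                                 simulate_abundance_matrix,
                                 simulate_helix_map,
                                 simulate_rrna_with_relics,
                                 simulate_trna_queries)


class TestAbundanceGenerator:
    def test_zero_signal_rows_identical(self):
        m, truth = simulate_abundance_matrix(5, 3, growth_rate=0.0,
                                             loss_prob=0.0, noise_sd=0.0,
                                             seed=1)
        assert (m.counts == m.counts[0, 0]).all()
        assert truth.taxon_order == tuple(m.part_ids)

    def test_row_sums_track_truth_rank(self):
        m, truth = simulate_abundance_matrix(20, 10, growth_rate=3.0,
                                             loss_prob=0.3, noise_sd=0.2,
                                             seed=7)
        sums = m.counts.sum(axis=1)
        ranks = [truth.rank_of(p) for p in m.part_ids]
        rho = spearmanr(ranks, sums).statistic
        assert abs(rho) >= 0.9 and rho < 0

    def test_deterministic_given_seed(self):
        a, _ = simulate_abundance_matrix(20, 10, 3.0, 0.3, 0.2, seed=7)
        b, _ = simulate_abundance_matrix(20, 10, 3.0, 0.3, 0.2, seed=7)
        assert (a.counts == b.counts).all()
        c, _ = simulate_abundance_matrix(20, 10, 3.0, 0.3, 0.2, seed=8)
        assert (a.counts != c.counts).any()

    def test_noiseless_lossless_strictly_decreasing(self):
        m, _ = simulate_abundance_matrix(15, 6, growth_rate=3.0,
                                         loss_prob=0.0, noise_sd=0.0, seed=2)
        assert (np.diff(m.counts.sum(axis=1)) < 0).all()

    def test_birth_time_invariants(self):
        _, truth = simulate_abundance_matrix(10, 4, 2.0, 0.1, 0.1, seed=3)
        bt = [truth.birth_time[t] for t in truth.taxon_order]
        assert bt[0] == 1.0 and bt[-1] == 0.0
        assert all(a > b for a, b in zip(bt, bt[1:]))

    @pytest.mark.parametrize("kwargs", [
        dict(n_parts=3), dict(n_proteomes=0), dict(loss_prob=1.5),
        dict(noise_sd=-1.0)])
    def test_domain_validation(self, kwargs):
        base = dict(n_parts=8, n_proteomes=4, growth_rate=1.0,
                    loss_prob=0.1, noise_sd=0.1, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_abundance_matrix(**base)

    def test_accretion_truth_rejects_nonmonotone_birth(self):
        with pytest.raises(ValueError, match="strictly decrease"):
            AccretionTruth(taxon_order=("a", "b"),
                           birth_time={"a": 0.2, "b": 0.8})


class TestRelicPlanting:
    @pytest.fixture
    def queries(self) -> list[TRNAQuery]:
        return simulate_trna_queries(3, seed=5)

    def test_zero_divergence_plants_exact_substrings(self, queries):
        target, truths = simulate_rrna_with_relics(queries, 1500, 2, 0.0,
                                                   seed=9)
        by_id = {q.id: q.sequence for q in queries}
        for t in truths:
            assert target[t.start - 1:t.end] == by_id[t.query_id]

    def test_truth_count_and_disjointness(self, queries):
        _, truths = simulate_rrna_with_relics(queries, 1500, 2, 0.1, seed=9)
        assert len(truths) == 6
        ordered = sorted((t.start, t.end) for t in truths)
        assert all(b[0] > a[1] for a, b in zip(ordered, ordered[1:]))
        assert all(1 <= t.start <= t.end <= 1500 for t in truths)

    def test_divergence_half_gives_binomial_hamming(self, queries):
        target, truths = simulate_rrna_with_relics(queries, 3000, 2, 0.5,
                                                   seed=13)
        by_id = {q.id: q.sequence for q in queries}
        for t in truths:
            q = by_id[t.query_id]
            planted = target[t.start - 1:t.end]
            ham = sum(a != b for a, b in zip(q, planted))
            n = len(q)
            sd = (n * 0.5 * 0.5) ** 0.5
            assert abs(ham - 0.5 * n) <= 4 * sd

    def test_insufficient_room_is_an_error(self, queries):
        with pytest.raises(ValueError, match="insufficient room"):
            simulate_rrna_with_relics(queries, 300, 2, 0.0, seed=9)

    def test_deterministic_given_seed(self, queries):
        a = simulate_rrna_with_relics(queries, 1500, 2, 0.2, seed=4)
        b = simulate_rrna_with_relics(queries, 1500, 2, 0.2, seed=4)
        assert a == b


class TestHelixMap:
    @pytest.fixture
    def planted(self):
        queries = simulate_trna_queries(4, seed=5)
        return simulate_rrna_with_relics(queries, 2000, 2, 0.0, seed=9)

    def test_tiles_target_exactly(self, planted):
        _, truths = planted
        hmap = simulate_helix_map(2000, truths, 0.5, seed=1)
        assert hmap.tiles(2000)
        assert hmap.length_covered == 2000

    def test_full_old_fraction_puts_relics_in_old_bands(self, planted):
        _, truths = planted
        hmap = simulate_helix_map(2000, truths, 1.0, seed=1)
        for t in truths:
            oldest = min(nd for _, _, _, nd in hmap.overlapping(t.start, t.end))
            assert oldest <= 0.30

    def test_zero_old_fraction_with_young_floor(self, planted):
        _, truths = planted
        hmap = simulate_helix_map(2000, truths, 0.0, seed=1,
                                  young_range=(0.5, 1.0))
        for t in truths:
            oldest = min(nd for _, _, _, nd in hmap.overlapping(t.start, t.end))
            assert oldest >= 0.3

    def test_trna_query_metadata_validation(self):
        with pytest.raises(ValueError, match="group"):
            TRNAQuery(id="q", sequence="ACGT", isoacceptor="Leu", group=4,
                      nd_trna=0.5)
        with pytest.raises(ValueError, match="nd_trna"):
            TRNAQuery(id="q", sequence="ACGT", isoacceptor="Leu", group=1,
                      nd_trna=1.5)

    def test_query_specs_respected(self):
        specs = [{"isoacceptor": "Leu", "group": 1, "nd_trna": 0.05}] * 3
        qs = simulate_trna_queries(3, seed=0, specs=specs)
        assert all(q.isoacceptor == "Leu" and q.group == 1 for q in qs)
        assert len({q.id for q in qs}) == 3
        assert all(70 <= len(q.sequence) <= 95 for q in qs)
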