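"""m6A filtering, aggregation, metagene mapping and set comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncscape.m6a import (
    M6ASite,
    aaach_fraction,
    call_methylated,
    compare_genotypes,
    differential_modification,
    filter_sites,
    metagene_position,
    methylation_table,
    motif_usage,
    pool_sites,
    site_density,
    transcript_modification_ratio,
)

from conftest import make_transcript


def site(tid="T.1", pos=10, m=0.5, r=10, kmer="AAACA", lib=""):
    return M6ASite(tid, pos, kmer, m, r, lib)


class TestFilter:
    def test_read_support_boundary(self):
        kept = filter_sites([site(r=4), site(pos=11, r=5)], min_reads=5)
        assert [s.n_reads for s in kept] == [5]

    def test_empty_input(self):
        assert filter_sites([]) == []

    def test_matches_brute_force_on_mixed_table(self):
        rng = np.random.default_rng(5)
        sites = [site(pos=i, r=int(rng.integers(1, 30))) for i in range(100)]
        kept = filter_sites(sites, 5)
        assert kept == [s for s in sites if s.n_reads >= 5]
        # order preserved
        assert [s.position for s in kept] == sorted(s.position for s in kept)

    def test_filter_and_call_commute(self):
        rng = np.random.default_rng(6)
        sites = [
            site(pos=i, r=int(rng.integers(1, 30)),
                 m=float(rng.choice([0.0, rng.uniform(0, 1)])))
            for i in range(200)
        ]
        meth_then_filter = filter_sites(call_methylated(sites)[0], 5)
        filter_then_meth = call_methylated(filter_sites(sites, 5))[0]
        assert meth_then_filter == filter_then_meth


class TestMethylationCall:
    def test_zero_ratio_is_unmethylated(self):
        meth, unmeth = call_methylated([site(m=0.0), site(pos=11, m=0.001)])
        assert [s.position for s in meth] == [11]
        assert [s.position for s in unmeth] == [10]

    def test_partition_covers_input(self):
        sites = [site(pos=i, m=float(i % 3) / 4) for i in range(30)]
        meth, unmeth = call_methylated(sites)
        assert len(meth) + len(unmeth) == 30
        assert set(s.position for s in meth).isdisjoint(s.position for s in unmeth)

    def test_all_zero_transcript_is_unmethylated(self):
        table = methylation_table([site(m=0.0), site(pos=11, m=0.0)])
        assert float(table.M.iloc[0]) == 0.0


class TestTranscriptM:
    def test_single_site(self):
        assert transcript_modification_ratio([site(m=0.5, r=10)]).M == 0.5

    def test_equal_weights(self):
        tm = transcript_modification_ratio([site(m=0.2, r=10), site(pos=11, m=0.4, r=10)])
        assert tm.M == pytest.approx(0.3, abs=1e-12)

    def test_read_weighted_hand_value(self):
        tm = transcript_modification_ratio([site(m=0.2, r=30), site(pos=11, m=0.8, r=10)])
        assert tm.M == pytest.approx(0.35, abs=1e-12)

    def test_no_sites_returns_absent_record(self):
        assert transcript_modification_ratio([]) is None
        assert transcript_modification_ratio([site(m=0.0)], include_zero_sites=False) is None

    def test_include_zero_sites_switch(self):
        sites = [site(m=0.0, r=10), site(pos=11, m=0.4, r=10)]
        assert transcript_modification_ratio(sites, True).M == pytest.approx(0.2)
        assert transcript_modification_ratio(sites, False).M == pytest.approx(0.4)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False),
                st.integers(1, 1000),
            ),
            min_size=1,
            max_size=20,
        ),
        st.integers(2, 7),
    )
    @settings(deadline=None, max_examples=60)
    def test_invariances(self, pairs, k):
        """M is order-invariant, bounded by [min m, max m], and unchanged
        when every read count is scaled by a constant."""
        sites = [site(pos=i, m=m, r=r) for i, (m, r) in enumerate(pairs)]
        M = transcript_modification_ratio(sites).M
        ms = [m for m, _ in pairs]
        assert min(ms) - 1e-9 <= M <= max(ms) + 1e-9
        shuffled = list(reversed(sites))
        assert transcript_modification_ratio(shuffled).M == pytest.approx(M)
        scaled = [site(pos=i, m=m, r=r * k) for i, (m, r) in enumerate(pairs)]
        assert transcript_modification_ratio(scaled).M == pytest.approx(M)


class TestPooling:
    def test_reads_summed_and_ratio_weighted(self):
        pooled = pool_sites([
            site(m=0.2, r=30, lib="a"),
            site(m=0.8, r=10, lib="b"),
        ])
        assert len(pooled) == 1
        assert pooled[0].n_reads == 40
        assert pooled[0].mod_ratio == pytest.approx(0.35, abs=1e-12)

    def test_kmer_mismatch_raises(self):
        with pytest.raises(ValueError, match="kmer"):
            pool_sites([site(kmer="AAACA"), site(kmer="GGACT")])


class TestMetagene:
    def test_full_length_endpoints(self):
        t = make_transcript("L.1", [(0, 100)])
        assert metagene_position(0, t) == (0.0, "full")
        assert metagene_position(99, t) == (1.0, "full")

    def test_length_one_maps_to_midpoint(self):
        t = make_transcript("L.1", [(5, 6)])
        assert metagene_position(0, t)[0] == 0.5

    def test_mrna_band_boundaries(self):
        # utr5=100, cds=500, utr3=300 on a single 900-nt exon
        t = make_transcript(
            "M.1", [(0, 900)], cds=(100, 600), biotype="protein_coding"
        )
        assert metagene_position(100, t)[0] == pytest.approx(0.2)
        rel_599, region = metagene_position(599, t)
        assert region == "cds" and 0.69 < rel_599 < 0.7
        assert metagene_position(600, t) == (pytest.approx(0.7), "utr3")
        assert metagene_position(0, t) == (0.0, "utr5")

    def test_mrna_positions_stay_in_bands(self):
        t = make_transcript(
            "M.1", [(0, 900)], cds=(100, 600), biotype="protein_coding"
        )
        for pos in range(900):
            rel, region = metagene_position(pos, t)
            lo, hi = {"utr5": (0, 0.2), "cds": (0.2, 0.7), "utr3": (0.7, 1.0)}[region]
            assert lo <= rel < hi

    def test_zero_length_utr_degenerates_to_cds_band(self):
        t = make_transcript(
            "M.1", [(0, 500)], cds=(0, 500), biotype="protein_coding"
        )
        rels = [metagene_position(p, t) for p in (0, 250, 499)]
        assert all(region == "cds" for _, region in rels)
        assert all(0.2 <= rel < 0.7 for rel, _ in rels)

    def test_spliced_minus_strand_cds_projection(self):
        # minus strand: transcript 5' end is the genomically last base
        t = make_transcript(
            "M.1", [(0, 300), (500, 1100)], strand="-",
            cds=(100, 800), biotype="protein_coding",
        )
        utr5, cds, utr3 = t.utr_cds_utr_lengths()
        assert (utr5, cds, utr3) == (300, 500, 100)
        assert metagene_position(utr5, t)[1] == "cds"
        assert metagene_position(utr5 - 1, t)[1] == "utr5"

    def test_position_out_of_range(self):
        t = make_transcript("L.1", [(0, 100)])
        with pytest.raises(ValueError):
            metagene_position(100, t)

    def test_mrna_mode_without_cds(self):
        t = make_transcript("L.1", [(0, 100)])
        with pytest.raises(ValueError, match="CDS"):
            metagene_position(10, t, mode="mrna")


class TestMotifUsage:
    def test_pure_aaach(self):
        assert aaach_fraction([site(kmer="AAACA"), site(pos=11, kmer="AAACT")]) == 1.0

    def test_mixture_fraction(self):
        sites = [site(pos=i, kmer="AAACC") for i in range(40)]
        sites += [site(pos=100 + i, kmer="GGACT") for i in range(60)]
        assert aaach_fraction(sites) == pytest.approx(0.4)

    def test_non_drach_rejected_and_counted(self):
        usage, rejects = motif_usage([site(kmer="CCCCC"), site(pos=11, kmer="AAACA")])
        assert rejects == 1
        assert usage.fraction.sum() == pytest.approx(1.0)

    def test_planted_distribution_recovered(self):
        rng = np.random.default_rng(8)
        kmers = ["AAACA"] * 30 + ["AAACT"] * 10 + ["GGACC"] * 60
        rng.shuffle(kmers)
        sites = [site(pos=i, kmer=k) for i, k in enumerate(kmers)]
        usage, _ = motif_usage(sites)
        by_kmer = dict(zip(usage.kmer, usage.fraction))
        assert by_kmer == {"GGACC": 0.6, "AAACA": 0.3, "AAACT": 0.1}


class TestDensity:
    def test_per_100nt(self):
        t = make_transcript("T.1", [(0, 600)])
        assert site_density(6, t) == 1.0
        assert site_density(0, t) == 0.0


class TestGenotypes:
    def test_two_set_example(self):
        part = compare_genotypes({"wildtype": {"a", "b"}, "mut": {"b", "c"}})
        assert part.wildtype_only == {"a"}
        assert part.shared_all == {"b"}
        assert part.novel_by_mutant["mut"] == {"c"}

    def test_identical_sets(self):
        part = compare_genotypes({"wildtype": {1, 2}, "m1": {1, 2}, "m2": {1, 2}})
        assert part.wildtype_only == set()
        assert part.shared_all == {1, 2}
        assert all(not s for s in part.novel_by_mutant.values())

    def test_missing_wildtype_raises(self):
        with pytest.raises(KeyError):
            compare_genotypes({"mut": {1}})

    def test_planted_overlaps_match_enumeration(self):
        """Four mutant sets with known membership patterns: each category
        equals a brute-force enumeration over all 2^5 patterns."""
        rng = np.random.default_rng(9)
        genotypes = ["wildtype", "m1", "m2", "m3", "m4"]
        universe = list(range(300))
        membership = {u: set(g for g in genotypes if rng.random() < 0.5) for u in universe}
        sets = {g: {u for u in universe if g in membership[u]} for g in genotypes}
        part = compare_genotypes(sets)
        wt_only = {u for u, m in membership.items() if m == {"wildtype"}}
        shared = {u for u, m in membership.items() if m == set(genotypes)}
        assert part.wildtype_only == wt_only
        assert part.shared_all == shared
        for g in genotypes[1:]:
            expected = {u for u, m in membership.items() if g in m and "wildtype" not in m}
            assert part.novel_by_mutant[g] == expected
        # disjoint patterns reconstruct the universe of occupied sites
        occupied = {u for u, m in membership.items() if m}
        assert sum(part.pattern_counts.values()) == len(occupied)


class TestDifferentialModification:
    def _table(self, rows):
        return methylation_table(
            [site(tid=t, pos=p, m=m, r=10, lib=lib) for t, p, m, lib in rows],
            by_library=True,
        )

    def test_stage_difference_hand_value(self):
        rows = [("T", 1, 0.2, "s1"), ("T", 1, 0.2, "s2"),
                ("T", 1, 0.3, "f1"), ("T", 1, 0.5, "f2")]
        groups = {"s1": "seedling", "s2": "seedling",
                  "f1": "floral_bud", "f2": "floral_bud"}
        dm = differential_modification(self._table(rows), groups)
        assert dm.delta_M.iloc[0] == pytest.approx(0.2, abs=1e-12)

    def test_equal_means_give_zero(self):
        rows = [("T", 1, 0.4, "s1"), ("T", 1, 0.4, "f1")]
        dm = differential_modification(
            self._table(rows), {"s1": "seedling", "f1": "floral_bud"}
        )
        assert dm.delta_M.iloc[0] == 0.0

    def test_transcripts_missing_a_group_are_excluded_and_counted(self):
        rows = [("A", 1, 0.4, "s1"), ("A", 1, 0.6, "f1"), ("B", 1, 0.4, "s1")]
        dm = differential_modification(
            self._table(rows), {"s1": "seedling", "f1": "floral_bud"}
        )
        assert list(dm.transcript_id) == ["A"]
        assert dm.attrs["n_excluded"] == 1
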