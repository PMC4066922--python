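"""Polymorphic-site detection, mutation classification and the spectrum."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polykaryo.polymorphism import (
    classify_mutation,
    find_polymorphic_sites,
    group_haplotypes,
    haplotype_matrix,
    polymorphism_frequency,
    round_half_away,
    spectrum_from_counts,
    spectrum_table,
    truncate_percent,
)
from polykaryo.seqio import MultipleAlignment, Region, RegionMap
from polykaryo.simulate import SimConfig, simulate_parental_pool
from polykaryo.tables import (
    ITS_ALIGNMENT_LENGTH,
    alignment_from_site_matrix,
    load_its_matrix,
)


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("T", "C", "transition"),
            ("A", "G", "transition"),
            ("A", "-", "indel"),
            ("AC", "--", "indel"),
            ("C", "G", "transversion"),
            ("A", "T", "transversion"),
        ],
    )
    def test_classes(self, a, b, expect):
        assert classify_mutation(a, b) == expect

    @given(
        st.sampled_from("ACGT"), st.sampled_from("ACGT")
    )
    @settings(derandomize=True)
    def test_symmetric_and_total_over_distinct_bases(self, a, b):
        if a == b:
            with pytest.raises(ValueError):
                classify_mutation(a, b)
        else:
            assert classify_mutation(a, b) == classify_mutation(b, a)
            assert classify_mutation(a, b) in ("transition", "transversion")

    def test_identical_states_error(self):
        with pytest.raises(ValueError):
            classify_mutation("A", "A")


class TestFindPolymorphicSites:
    def test_all_identical_gives_empty(self, single_region):
        aln = MultipleAlignment((("a", "ACGT"), ("b", "ACGT")))
        assert find_polymorphic_sites(aln, single_region(4)) == []

    def test_agrees_with_column_scan_oracle(self, rng, single_region):
        """Random gap-free 8x30 alignment: positions match a brute scan."""
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(8)]
        aln = MultipleAlignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        sites = find_polymorphic_sites(aln, single_region(30))
        expected = [
            pos
            for pos in range(1, 31)
            if len({s[pos - 1] for s in seqs}) > 1
        ]
        assert [s.position for s in sites] == expected
        # minimum-events convention: n_distinct - 1 events per site
        for s in sites:
            distinct = {q[s.position - 1] for q in seqs}
            assert len(s.events) == len(distinct) - 1

    def test_gap_run_merged_into_one_indel(self, single_region):
        aln = MultipleAlignment(
            (("a", "ACGTACGT"), ("b", "AC--ACGT"), ("c", "ACGTACGT"))
        )
        sites = find_polymorphic_sites(aln, single_region(8))
        assert len(sites) == 1
        site = sites[0]
        assert site.position == 3 and site.span == 2
        assert [e.kind for e in site.events] == ["indel"]
        assert site.events[0].state_b == "--"

    def test_distinct_gap_patterns_not_merged(self, single_region):
        aln = MultipleAlignment(
            (("a", "AC-TACGT"), ("b", "ACG-ACGT"), ("c", "ACGTACGT"))
        )
        sites = find_polymorphic_sites(aln, single_region(8))
        assert [s.position for s in sites] == [3, 4]
        assert all(e.kind == "indel" for s in sites for e in s.events)

    def test_n_columns_excluded(self, single_region):
        aln = MultipleAlignment((("a", "ANGT"), ("b", "AAGA")))
        sites = find_polymorphic_sites(aln, single_region(4))
        assert [s.position for s in sites] == [4]

    def test_multiallelic_conventions(self, single_region):
        # column: A,A,G,T -> majority A; minimum pairs (G,A),(T,A)
        aln = MultipleAlignment(
            (("a", "AA"), ("b", "AA"), ("c", "GA"), ("d", "TA"))
        )
        sites = find_polymorphic_sites(aln, single_region(2))
        assert len(sites) == 1 and len(sites[0].events) == 2
        kinds = sorted(e.class_name for e in sites[0].events)
        assert kinds == ["A-G", "A-T"]
        all_pairs = find_polymorphic_sites(aln, single_region(2), multiallelic="all_pairs")
        assert len(all_pairs[0].events) == 3

    def test_recovers_simulator_injected_units(self):
        """Sites found == latent units actually carried by >=1 parent."""
        pool = simulate_parental_pool(SimConfig(seed=77))
        sites = find_polymorphic_sites(pool.alignment, pool.regions)
        carried = set()
        for units in pool.truth.parent_units.values():
            carried.update(units)
        expected = set()
        for j in sorted(carried):
            u = pool.truth.units[j]
            # monomorphic if every parent carries the derived allele
            n_carriers = sum(
                j in units for units in pool.truth.parent_units.values()
            )
            if n_carriers < len(pool.truth.parent_units):
                expected.add(u.position)
        assert {s.position for s in sites} == expected


class TestSpectrumTable:
    EXON = {"A-G": 5, "C-T": 22, "A-C": 2, "A-T": 1, "C-G": 2, "G-T": 0, "indel": 0}
    INTRON = {"A-G": 7, "C-T": 44, "A-C": 9, "A-T": 12, "C-G": 6, "G-T": 7, "indel": 12}

    @pytest.fixture
    def printed_table(self):
        counts = {
            k: {"exon": self.EXON[k], "intron": self.INTRON[k]} for k in self.EXON
        }
        return spectrum_from_counts(counts, {"exon": 586, "intron": 207})

    def test_totals_and_percentages(self, printed_table):
        t = printed_table
        assert t.transitions("exon") == 27
        assert round_half_away(t.percent(t.transitions("exon"), "exon")) == 84
        assert t.transversions("exon") == 5
        assert t.total("exon") == 32
        assert t.transitions("intron") == 51
        assert t.transversions("intron") == 34
        assert t.total("intron") == 97
        assert t.total() == 129
        assert t.transitions() == 78
        assert round_half_away(t.percent(t.transitions())) == 60

    def test_frequencies(self, printed_table):
        assert truncate_percent(polymorphism_frequency(printed_table, "intron")) == 46.8
        assert truncate_percent(polymorphism_frequency(printed_table, "exon")) == 5.4

    def test_zero_length_region_errors(self, printed_table):
        with pytest.raises(ValueError):
            polymorphism_frequency(printed_table, "nope")

    def test_empty_site_list_all_zero(self, toy_regions):
        t = spectrum_table([], toy_regions)
        assert t.total() == 0 and t.transitions() == 0

    def test_class_sum_conservation(self, rng, single_region):
        """Sum over classes equals the region total for arbitrary data."""
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        aln = MultipleAlignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        rmap = RegionMap((Region(1, 25, "exon"), Region(26, 40, "intron")))
        sites = find_polymorphic_sites(aln, rmap)
        t = spectrum_table(sites, rmap)
        for region in ("exon", "intron"):
            assert (
                t.transitions(region) + t.transversions(region) + t.indels(region)
                == t.total(region)
            )
        assert t.total() == t.total("exon") + t.total("intron")
        assert t.total() == sum(len(s.events) for s in sites)


class TestHaplotypeMatrix:
    def test_its_matrix_ten_variants(self, single_region):
        """The bundled ITS table yields 4 sites and 10 variants."""
        matrix = load_its_matrix(include_reference=False)
        aln = alignment_from_site_matrix(matrix, ITS_ALIGNMENT_LENGTH)
        rmap = RegionMap((Region(1, ITS_ALIGNMENT_LENGTH, "intron"),))
        sites = find_polymorphic_sites(aln, rmap)
        assert [s.position for s in sites] == [195, 338, 538, 669]
        mat = haplotype_matrix(aln, sites)
        assert len(group_haplotypes(mat)) == 10

    def test_single_sequence_single_row(self, single_region):
        aln = MultipleAlignment((("only", "ACGT"),))
        mat = haplotype_matrix(aln, [])
        assert list(mat.index) == ["only"]

    def test_grouping_equals_hash_oracle(self, rng, single_region):
        seqs = [
            "".join(rng.choice(list("ACGT"), size=12)) for _ in range(4)
        ]
        seqs = seqs + [seqs[0], seqs[2]]  # known duplicates
        aln = MultipleAlignment(tuple((f"s{i}", s) for i, s in enumerate(seqs)))
        sites = find_polymorphic_sites(aln, single_region(12))
        mat = haplotype_matrix(aln, sites)
        groups = group_haplotypes(mat)
        oracle: dict[str, list[str]] = {}
        for i, s in enumerate(seqs):
            oracle.setdefault(s, []).append(f"s{i}")
        assert sorted(tuple(m) for _, m in groups) == sorted(
            tuple(v) for v in oracle.values()
        )
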