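"""Synthetic-data generator: reproducibility, truth consistency, calibration."""

import numpy as np
import pytest

from polykaryo.clone_haplotypes import collapse_clones, filter_singletons
from polykaryo.pipeline import analyze_basidioma
from polykaryo.recombination import min_crossovers
from polykaryo.seqio import MultipleAlignment, SampleSheet
from polykaryo.simulate import (
    SimConfig,
    simulate_basidioma,
    simulate_dataset,
    simulate_parental_pool,
)


class TestParentalPool:
    def test_zero_rates_all_parents_equal_ancestor(self):
        cfg = SimConfig(seed=1, exon_poly_rate=0.0, intron_poly_rate=0.0)
        pool = simulate_parental_pool(cfg)
        for _, seq in pool.alignment.records:
            assert seq == pool.truth.ancestor

    def test_layout_dimensions(self):
        pool = simulate_parental_pool(SimConfig(seed=2))
        assert pool.regions.region_length("exon") == 586
        intron_regions = [r for r in pool.regions.regions if r.label == "intron"]
        assert len(intron_regions) == 4
        assert all(50 <= r.length <= 58 for r in intron_regions)
        assert pool.alignment.length == pool.regions.length

    def test_indels_restricted_to_introns(self):
        pool = simulate_parental_pool(SimConfig(seed=3))
        for u in pool.truth.units:
            if u.kind == "indel":
                assert u.region == "intron"
                assert 1 <= u.span <= 4

    def test_reproducibility_byte_identical(self):
        cfg = SimConfig(seed=11)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.clones.records == b.clones.records
        assert a.sheet == b.sheet
        assert a.truth.parents_of == b.truth.parents_of

    def test_degenerate_pool_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_parental_pool=1)


class TestBasidioma:
    def _one(self, seed, **kwargs):
        cfg = SimConfig(seed=seed, **kwargs)
        rng = np.random.default_rng(cfg.seed)
        pool = simulate_parental_pool(cfg, rng)
        clones, rows, truth = simulate_basidioma(pool, cfg, "G1", rng)
        return cfg, pool, clones, rows, truth

    def test_noise_free_clones_match_parents_exactly(self, sheet_factory):
        cfg, pool, clones, rows, truth = self._one(
            21, pcr_error_rate=0.0, chimera_rate=0.0, p_three_parents=0.0
        )
        parent_seqs = {pool.alignment[p] for p in truth.parents_of["G1"]}
        assert all(seq in parent_seqs for _, seq in clones)
        aln = MultipleAlignment(tuple(clones))
        sheet = SampleSheet(tuple(rows))
        group = collapse_clones(aln, sheet, "G1")
        assert len(group.haplotypes) == len(parent_seqs)

    def test_every_clone_has_one_provenance_record(self):
        _, _, clones, _, truth = self._one(22)
        assert set(truth.clone_parent) == {cid for cid, _ in clones}

    def test_chimeras_are_single_switch_zero_unexplained(self):
        cfg, pool, clones, rows, truth = self._one(
            23, chimera_rate=1.0, pcr_error_rate=0.0, p_three_parents=0.0
        )
        parents = [(p, pool.alignment[p]) for p in truth.parents_of["G1"]]
        for cid, seq in clones:
            if cid not in truth.chimera_of:
                continue
            res = min_crossovers((cid, seq), parents)
            assert res.unexplained_sites == ()
            # a uniform breakpoint can fall outside the informative span,
            # in which case the chimera equals a parent (0 switches)
            assert res.k_switches <= 1

    def test_chimera_rate_one_most_clones_recombinant(self):
        _, _, clones, _, truth = self._one(
            24, chimera_rate=1.0, pcr_error_rate=0.0
        )
        assert len(truth.chimera_of) == len(clones)

    def test_pcr_error_count_calibrated(self):
        """Injected errors over many clones match rate x length x clones
        within 3 binomial SE."""
        rate = 2e-4
        total_errors = 0
        total_bases = 0
        for seed in range(30):
            cfg, pool, clones, rows, truth = self._one(
                100 + seed, pcr_error_rate=rate, chimera_rate=0.0
            )
            total_errors += sum(len(v) for v in truth.errors_of.values())
            total_bases += sum(len(s) for _, s in clones)
        expected = rate * total_bases
        se = np.sqrt(expected)
        assert abs(total_errors - expected) < 3 * se

    def test_g25_pattern_recovers_three_parents(self, sheet_factory):
        """Supports {7,7,2} with a private-site-bearing rare parent."""
        cfg = SimConfig(seed=31)
        pool = simulate_parental_pool(cfg)
        # choose a triple whose third member has >=2 sites matching neither
        # of the first two (private states)
        ids = list(pool.alignment.ids)
        chosen = None
        for c in ids:
            for a, b in [(x, y) for x in ids for y in ids if x < y]:
                if c in (a, b):
                    continue
                sa, sb, sc = (pool.alignment[i] for i in (a, b, c))
                private = sum(
                    1 for x, y, z in zip(sa, sb, sc) if z not in (x, y)
                )
                if private >= 2:
                    chosen = (a, b, c)
                    break
            if chosen:
                break
        assert chosen is not None
        a, b, c = chosen
        aln = MultipleAlignment(
            ((a, pool.alignment[a]), (b, pool.alignment[b]), (c, pool.alignment[c]))
        )
        sheet = sheet_factory([(a, "G25", "loc", 7), (b, "G25", "loc", 7), (c, "G25", "loc", 2)])
        analysis = analyze_basidioma(aln, sheet, "G25")
        assert analysis.parent_call.n_parents == 3


class TestDatasetCalibration:
    def test_intron_exon_ratio_and_transition_share(self):
        """Realized polymorphism densities and exon transition share match
        the configured targets within Monte-Carlo error (30 pools)."""
        from polykaryo.polymorphism import find_polymorphic_sites

        ratios, ts_shares = [], []
        for seed in range(30):
            pool = simulate_parental_pool(SimConfig(seed=500 + seed))
            sites = find_polymorphic_sites(pool.alignment, pool.regions)
            per = {"exon": 0, "intron": 0}
            ts = tv = 0
            for s in sites:
                per[s.region_label] += 1
                if s.region_label == "exon":
                    for e in s.events:
                        ts += e.kind == "transition"
                        tv += e.kind == "transversion"
            exon_f = per["exon"] / pool.regions.region_length("exon")
            intron_f = per["intron"] / pool.regions.region_length("intron")
            ratios.append(intron_f / exon_f)
            ts_shares.append(ts / (ts + tv))
        target_ratio = 0.468 / 0.054
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - target_ratio) < 3 * sem
        target_ts = 27 / 32
        sem_ts = np.std(ts_shares, ddof=1) / np.sqrt(len(ts_shares))
        assert abs(np.mean(ts_shares) - target_ts) < 3 * sem_ts

    def test_dataset_smoke_and_truth_channels(self):
        ds = simulate_dataset(SimConfig(seed=8, n_basidiomata=4))
        assert set(ds.truth.parents_of) == set(ds.sheet.basidioma_ids)
        assert set(ds.truth.population_of) == set(ds.sheet.basidioma_ids)
        assert len(ds.clones) == 4 * 16
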