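"""Clone collapsing, singleton exclusion and the shared-error model."""

from collections import Counter
from math import comb

import numpy as np
import pytest

from polykaryo.clone_haplotypes import (
    DOMINANT,
    MINOR_SUPPORTED,
    SINGLETON_EXCLUDED,
    ErrorModel,
    call_parent_count,
    collapse_clones,
    filter_singletons,
    shared_error_probability,
)
from polykaryo.recombination import min_crossovers
from polykaryo.seqio import MultipleAlignment


def make_clone_set(sheet_factory, seq_of: dict[str, str], counts: dict[str, int],
                   bid="G25", loc="locA"):
    aln = MultipleAlignment(tuple(seq_of.items()))
    sheet = sheet_factory([(sid, bid, loc, counts[sid]) for sid in seq_of])
    return aln, sheet


class TestCollapse:
    def test_seven_seven_two(self, sheet_factory):
        """Three distinct clone types at supports 7, 7 and 2."""
        aln, sheet = make_clone_set(
            sheet_factory,
            {"h1": "AAAA", "h2": "CCCC", "h3": "AACC"},
            {"h1": 7, "h2": 7, "h3": 2},
        )
        group = collapse_clones(aln, sheet, "G25")
        assert [h.support for h in group.haplotypes] == [7, 7, 2]
        assert group.total_clones == 16

    def test_all_identical(self, sheet_factory):
        aln = MultipleAlignment(tuple((f"c{i}", "ACGT") for i in range(5)))
        sheet = sheet_factory([(f"c{i}", "G9", "loc", 1) for i in range(5)])
        group = collapse_clones(aln, sheet, "G9")
        assert len(group.haplotypes) == 1
        assert group.haplotypes[0].support == 5

    def test_supports_equal_counting_oracle(self, rng, sheet_factory):
        seqs = ["AAAA", "CCCC", "GGGG", "TTTT"]
        draws = [seqs[int(i)] for i in rng.integers(0, 4, size=30)]
        aln = MultipleAlignment(tuple((f"c{i}", s) for i, s in enumerate(draws)))
        sheet = sheet_factory([(f"c{i}", "B", "loc", 1) for i in range(30)])
        group = collapse_clones(aln, sheet, "B")
        oracle = Counter(draws)
        assert {h.sequence: h.support for h in group.haplotypes} == dict(oracle)

    def test_unknown_basidioma(self, sheet_factory):
        aln, sheet = make_clone_set(sheet_factory, {"h1": "AAAA"}, {"h1": 2})
        with pytest.raises(Exception, match="nope"):
            collapse_clones(aln, sheet, "nope")


class TestFilterSingletons:
    BASES = ["AAAA", "CCCC", "GGGG", "TTTT", "ACGT", "TGCA"]

    def _statuses(self, sheet_factory, supports):
        seqs = {f"h{i}": self.BASES[i] for i in range(len(supports))}
        counts = {f"h{i}": s for i, s in enumerate(supports)}
        aln, sheet = make_clone_set(sheet_factory, seqs, counts)
        group = collapse_clones(aln, sheet, "G25")
        return [c.status for c in filter_singletons(group)]

    def test_seven_seven_two(self, sheet_factory):
        assert self._statuses(sheet_factory, [7, 7, 2]) == [
            DOMINANT,
            DOMINANT,
            MINOR_SUPPORTED,
        ]

    def test_threshold_boundary(self, sheet_factory):
        assert self._statuses(sheet_factory, [2, 1]) == [DOMINANT, SINGLETON_EXCLUDED]

    def test_all_singletons_excluded(self, sheet_factory):
        assert self._statuses(sheet_factory, [1, 1, 1]) == [SINGLETON_EXCLUDED] * 3

    def test_clone_count_conserved_across_statuses(self, rng, sheet_factory):
        supports = list(rng.integers(1, 9, size=5))
        statuses_supports = zip(
            self._statuses(sheet_factory, supports), sorted(supports, reverse=True)
        )
        assert sum(s for _, s in statuses_supports) == sum(supports)


class TestSharedErrorProbability:
    def test_single_occurrence_is_certain(self):
        model = ErrorModel(n_clones=16, n_polymorphic_regions=16)
        assert shared_error_probability(model, 1, "transition") == 1.0

    def test_k_above_n_impossible(self):
        model = ErrorModel(n_clones=3, n_polymorphic_regions=10)
        assert shared_error_probability(model, 4, "transition") == 0.0

    def test_halving_rule_exact(self):
        model = ErrorModel(n_clones=16, n_polymorphic_regions=15)
        for k in (2, 3, 4):
            ts = shared_error_probability(model, k, "transition")
            tv = shared_error_probability(model, k, "transversion")
            assert tv == pytest.approx(ts / 2)

    @pytest.mark.parametrize("variant", ["halved", "weighted", "binomial_tail"])
    def test_monotone_in_k_and_L(self, variant):
        for L in (8, 15, 30):
            model = ErrorModel(16, L, variant=variant)
            probs = [shared_error_probability(model, k, "transition") for k in (2, 3, 4, 5)]
            assert probs == sorted(probs, reverse=True)
        for k in (2, 3):
            by_L = [
                shared_error_probability(ErrorModel(16, L, variant=variant), k, "transition")
                for L in (8, 15, 30, 60)
            ]
            assert by_L == sorted(by_L, reverse=True)

    def test_weighted_variant_matches_monte_carlo_coincidences(self, rng):
        """Closed form C(n,k) q^k equals the expected number of k-clone
        coincidences of one specific mutation, simulated at 1e5 reps.

        Each clone scatters one random mutation over L sites with
        transition:transversion:transversion weights 2:1:1.
        """
        n, L, k = 12, 10, 2
        reps = 100_000
        # clone hits: site uniform, class with probs (.5,.25,.25)
        sites = rng.integers(0, L, size=(reps, n))
        classes = rng.choice(3, p=[0.5, 0.25, 0.25], size=(reps, n))
        for mut_class, class_idx in (("transition", 0), ("transversion", 1)):
            target = (sites == 0) & (classes == class_idx)
            x = target.sum(axis=1)
            coincidences = np.array([comb(int(v), k) for v in x])
            est, se = coincidences.mean(), coincidences.std(ddof=1) / np.sqrt(reps)
            model = ErrorModel(n, L, variant="weighted")
            closed = shared_error_probability(model, k, mut_class)
            assert abs(closed - est) < 3 * se

    def test_binomial_tail_variant_matches_monte_carlo_tail(self, rng):
        n, L, k = 12, 10, 2
        reps = 100_000
        sites = rng.integers(0, L, size=(reps, n))
        classes = rng.choice(3, p=[0.5, 0.25, 0.25], size=(reps, n))
        x = ((sites == 0) & (classes == 0)).sum(axis=1)
        est = (x >= k).mean()
        se = np.sqrt(est * (1 - est) / reps)
        model = ErrorModel(n, L, variant="binomial_tail")
        closed = shared_error_probability(model, k, "transition")
        assert abs(closed - est) < 3 * se


class TestCallParentCount:
    def _analyze(self, sheet_factory, seq_of, counts, bid="G25"):
        aln, sheet = make_clone_set(sheet_factory, seq_of, counts, bid=bid)
        group = collapse_clones(aln, sheet, bid)
        calls = filter_singletons(group)
        dominants = [c for c in calls if c.status == DOMINANT]
        minors = [c for c in calls if c.status == MINOR_SUPPORTED]
        xov = {}
        if len(dominants) == 2:
            parents = [(c.haplotype.haplotype_id, c.haplotype.sequence) for c in dominants]
            for m in minors:
                xov[m.haplotype.haplotype_id] = min_crossovers(
                    (m.haplotype.haplotype_id, m.haplotype.sequence), parents
                )
        return group, calls, xov

    def test_third_parent_with_private_sites(self, sheet_factory):
        """A 2-clone haplotype with two private mutations (one transition,
        one transversion) that recombination cannot explain counts as a
        third parent."""
        # dominants differ at 16 sites; minor mosaics them but adds two
        # private states at the end
        p1 = "A" * 16 + "CT"
        p2 = "G" * 16 + "CT"
        # one crossover mosaic of the dominants plus a C-T transition (17)
        # and a T-A transversion (18) private to the minor
        minor = "A" * 8 + "G" * 8 + "TA"
        seq_of = {"h1": p1, "h2": p2, "h3": minor}
        group, calls, xov = self._analyze(
            sheet_factory, seq_of, {"h1": 7, "h2": 7, "h3": 2}
        )
        model = ErrorModel(n_clones=16, n_polymorphic_regions=16)
        result = call_parent_count(group, calls, xov, error_model=model)
        assert result.n_parents == 3
        minor_ev = [e for e in result.evidence if e.get("status") == MINOR_SUPPORTED][0]
        assert minor_ev["unique_polymorphisms"] == 2
        assert minor_ev["shared_error_p"] < 0.05
        assert not minor_ev["recombinant_of_dominants"]

    def test_single_haplotype_one_parent_with_caveat(self, sheet_factory):
        group, calls, xov = self._analyze(
            sheet_factory, {"h1": "ACGTACGT"}, {"h1": 9}, bid="G9"
        )
        result = call_parent_count(group, calls, xov)
        assert result.n_parents == 1
        assert any("note" in e for e in result.evidence)

    def test_pure_recombinant_not_counted(self, sheet_factory):
        """Minor fully explained by one crossover of the dominants."""
        p1 = "A" * 10 + "C" * 10
        p2 = "G" * 10 + "T" * 10
        minor = "A" * 10 + "T" * 10  # one switch, zero unique sites
        group, calls, xov = self._analyze(
            sheet_factory, {"h1": p1, "h2": p2, "h3": minor},
            {"h1": 7, "h2": 7, "h3": 2},
        )
        result = call_parent_count(group, calls, xov)
        assert result.n_parents == 2

    def test_empty_retained_set_uncallable(self, sheet_factory):
        aln, sheet = make_clone_set(
            sheet_factory, {"h1": "AAAA", "h2": "CCCC"}, {"h1": 1, "h2": 1}
        )
        group = collapse_clones(aln, sheet, "G25")
        calls = filter_singletons(group)
        result = call_parent_count(group, calls, {})
        assert result.n_parents is None and not result.callable
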