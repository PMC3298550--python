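"""Grouping, SARF ordering, map assembly and nrBC confirmation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tigmap import (Chromosome, CrossConfig, GenomeModel, build_map,
                    confirm_with_nrbc, group_markers, kosambi, order_group,
                    pairwise_estimates, simulate_f2, simulate_nrbc)
from tigmap.mapbuild import GeneticMap, LinkageGroup, _sarf, _PairTable


def pairs(rows):
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "r_hat",
                                       "lod", "n", "n_impossible"])


class TestGrouping:
    def test_two_clusters(self):
        rows = []
        for a, b in itertools.combinations("12345", 2):
            within = {a, b} <= {"1", "2", "3"} or {a, b} <= {"4", "5"}
            rows.append((a, b, 0.05 if within else 0.5,
                         10.0 if within else 0.0, 100, 0))
        groups = group_markers(list("12345"), pairs(rows))
        assert groups == [["1", "2", "3"], ["4", "5"]]

    def test_high_lod_but_high_r_not_joined(self):
        table = pairs([("a", "b", 0.45, 2.0, 100, 0)])
        assert group_markers(["a", "b"], table) == [["a"], ["b"]]

    def test_low_lod_not_joined(self):
        table = pairs([("a", "b", 0.05, 0.5, 10, 0)])
        assert group_markers(["a", "b"], table) == [["a"], ["b"]]

    def test_invariant_to_marker_input_order(self, pairwise_clean, f2_clean):
        forward = group_markers(f2_clean.markers, pairwise_clean)
        reverse = group_markers(f2_clean.markers[::-1], pairwise_clean)
        assert forward == reverse

    def test_empty_input(self):
        assert group_markers([], pairs([])) == []

    def test_study_scale_simulation_recovers_twelve_groups(
            self, study_genome, f2_clean, pairwise_clean):
        groups = group_markers(f2_clean.markers, pairwise_clean)
        assert len(groups) == 12
        truth = {c.chrom_id: set(c.markers) for c in study_genome.chromosomes}
        for g in groups:
            assert set(g) in truth.values()


class TestOrdering:
    def test_three_markers_match_exhaustive_minimum(self):
        table = pairs([("1", "2", 0.05, 10, 100, 0),
                       ("2", "3", 0.05, 10, 100, 0),
                       ("1", "3", 0.10, 10, 100, 0)])
        assert order_group(["3", "1", "2"], table) == ["1", "2", "3"]
        # exhaustive oracle over the 3 distinct orders
        dist = _PairTable(table).distance
        best = min((tuple(p) for p in itertools.permutations("123")),
                   key=lambda o: _sarf(list(o), dist))
        assert _sarf(order_group(["1", "2", "3"], table), dist) == \
            pytest.approx(_sarf(list(best), dist))

    def test_two_markers_canonical_orientation(self):
        table = pairs([("b", "a", 0.1, 5, 100, 0)])
        assert order_group(["b", "a"], table) == ["a", "b"]

    def test_order_recovery_on_simulated_chromosome(self):
        genome = GenomeModel([Chromosome(
            "c", [f"m{i}" for i in range(1, 9)],
            np.linspace(0, 28, 8))])
        truth = genome.chromosomes[0].markers
        hits = 0
        for seed in range(100):
            f2 = simulate_f2(genome, CrossConfig(n_f2=2000, rng_seed=seed))
            order = order_group(truth, pairwise_estimates(f2))
            hits += order in (truth, truth[::-1])
        assert hits >= 95

    def test_sarf_not_worse_than_true_order(self, study_genome, f2_clean,
                                            pairwise_clean):
        dist = _PairTable(pairwise_clean).distance
        for chrom in study_genome.chromosomes[:3]:
            order = order_group(chrom.markers, pairwise_clean)
            assert _sarf(order, dist) <= _sarf(chrom.markers, dist) + 1e-9


class TestBuildMap:
    def test_cumulative_kosambi_positions(self):
        table = pairs([("a", "b", 0.05, 10, 100, 0),
                       ("b", "c", 0.05, 10, 100, 0),
                       ("a", "c", 0.10, 10, 100, 0)])
        gmap = build_map([["a", "b", "c"]], table)
        d = kosambi(0.05)
        assert gmap.groups[0].positions_cM == pytest.approx([0, d, 2 * d])
        assert d == pytest.approx(5.017, abs=0.001)

    def test_single_marker_group_has_zero_length(self):
        gmap = build_map([["solo"]], pairs([]))
        assert gmap.groups[0].length_cM == 0.0

    def test_unlinked_adjacent_pair_clamped_with_warning(self):
        table = pairs([("a", "b", 0.5, 0.0, 100, 0)])
        with pytest.warns(UserWarning, match="clamp"):
            gmap = build_map([["a", "b"]], table, order=False)
        assert np.isfinite(gmap.groups[0].length_cM)

    def test_total_length_near_generating_genome(self, study_genome,
                                                 f2_clean, pairwise_clean):
        groups = group_markers(f2_clean.markers, pairwise_clean)
        gmap = build_map(groups, pairwise_clean)
        truth = study_genome.total_length_cM
        assert abs(gmap.summed_length_cM - truth) / truth < 0.10

    def test_positions_reversal_symmetric(self):
        table = pairs([("a", "b", 0.05, 10, 100, 0),
                       ("b", "c", 0.10, 10, 100, 0),
                       ("a", "c", 0.14, 10, 100, 0)])
        fwd = build_map([["a", "b", "c"]], table, order=False).groups[0]
        rev = build_map([["c", "b", "a"]], table, order=False).groups[0]
        mirrored = rev.positions_cM[-1] - rev.positions_cM[::-1]
        assert fwd.positions_cM == pytest.approx(mirrored)

    def test_marker_cannot_be_in_two_groups(self):
        with pytest.raises(ValueError, match="more than one group"):
            GeneticMap([LinkageGroup(1, ["a"], [0.0]),
                        LinkageGroup(2, ["a"], [0.0])])


class TestNrbcConfirmation:
    def true_map(self, genome):
        return GeneticMap([
            LinkageGroup(i + 1, c.markers, c.positions_cM)
            for i, c in enumerate(genome.chromosomes)])

    def test_clean_nrbc_confirms_all_groups(self, study_genome, nrbc_clean):
        report = confirm_with_nrbc(self.true_map(study_genome), nrbc_clean)
        assert report.all_consistent
        assert report.flagged_pairs == []
        assert report.n_bb_calls == 0

    def test_split_group_fragments_flagged_as_cosegregating(
            self, study_genome, nrbc_clean):
        gmap = self.true_map(study_genome)
        first = gmap.groups[0]
        split = GeneticMap(
            [LinkageGroup(1, first.markers[:6], first.positions_cM[:6]),
             LinkageGroup(99, first.markers[6:],
                          first.positions_cM[6:] - first.positions_cM[6])]
            + gmap.groups[1:])
        report = confirm_with_nrbc(split, nrbc_clean)
        assert (1, 99) in report.flagged_pairs

    def test_single_discordant_call_breaks_strict_consistency(
            self, study_genome):
        nrbc = simulate_nrbc(study_genome, CrossConfig(n_nrbc=19, rng_seed=4))
        calls = nrbc.calls.copy()
        calls[0, 0] = 1 - calls[0, 0]   # flip one call in group 1's marker
        corrupted = type(nrbc)(nrbc.markers, nrbc.individuals, calls)
        gmap = self.true_map(study_genome)
        report = confirm_with_nrbc(gmap, corrupted)
        group_of_marker = next(g.group_id for g in gmap.groups
                               if nrbc.markers[0] in g.markers)
        assert not report.consistent[group_of_marker]
        # a permissive mismatch rate restores consistency
        relaxed = confirm_with_nrbc(gmap, corrupted, max_mismatch_rate=0.2)
        assert relaxed.consistent[group_of_marker]

    def test_bb_calls_warned_and_counted(self, study_genome, nrbc_clean):
        calls = nrbc_clean.calls.copy()
        calls[3, 2] = 2
        bad = type(nrbc_clean)(nrbc_clean.markers, nrbc_clean.individuals,
                               calls)
        with pytest.warns(UserWarning, match="BB"):
            report = confirm_with_nrbc(self.true_map(study_genome), bad)
        assert report.n_bb_calls == 1
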