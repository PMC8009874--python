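import logging
import math

import numpy as np
import pytest

from _oracles import (
    oracle_close_matches,
    oracle_kmer_counts,
    oracle_repetitiveness,
    oracle_tm_nn,
)
from conftest import random_genome
from exomekit import probe_design as pdz
from exomekit import synthetic_fixtures as sf
from exomekit.reference_io import Feature, TargetRegion, consolidate_targets


class TestKmerIndex:
    def test_two_offsets_of_a_homopolymer(self):
        index = pdz.build_kmer_index({"c1": "A" * 16}, k=15)
        assert index.counts[pdz.canonical_kmer("A" * 15)] == 2

    def test_n_in_every_window_gives_empty_index(self, caplog):
        with caplog.at_level(logging.WARNING):
            index = pdz.build_kmer_index({"c1": "ACGTACGNACGTACGTAC"[:16]}, k=15)
        assert not index.counts

    def test_matches_bruteforce_recount_on_random_genome(self, rng):
        genome = random_genome(rng, {"c1": 1000})
        index = pdz.build_kmer_index(genome, k=15)
        assert dict(index.counts) == oracle_kmer_counts(genome, 15)
        # uniform-random 1 kb: nearly all 15-mers unique
        assert np.mean([c == 1 for c in index.counts.values()]) > 0.99

    def test_total_count_equals_valid_positions(self, rng):
        genome = random_genome(rng, {"c1": 300, "c2": 120})
        index = pdz.build_kmer_index(genome, k=15)
        assert sum(index.counts.values()) == (300 - 14) + (120 - 14)


class TestRepetitiveness:
    def test_unique_region_scores_one(self, rng):
        genome = random_genome(rng, {"c1": 2000})
        index = pdz.build_kmer_index(genome, k=15)
        probe = genome["c1"][500:560]
        assert pdz.probe_repetitiveness(probe, index) == pytest.approx(1.0)

    def test_mean_over_exact_window_count(self, rng):
        genome = random_genome(rng, {"c1": 500})
        index = pdz.build_kmer_index(genome, k=15)
        probe = genome["c1"][100:120]  # 20 bases -> 6 windows
        got = pdz.probe_repetitiveness(probe, index)
        assert got == pytest.approx(oracle_repetitiveness(probe, genome), abs=1e-9)

    def test_repeat_array_flags_repetitive(self, spec, reference):
        genome, _ = reference
        index = pdz.build_kmer_index(genome, k=15)
        ch, start, end = sf.repeat_array_interval(spec)
        probe = genome[ch].sequence[start + 90 : start + 170]
        rep = pdz.probe_repetitiveness(probe, index)
        assert rep > 100
        assert rep == pytest.approx(
            oracle_repetitiveness(probe, {k: v.sequence for k, v in genome.items()}),
            abs=1e-9,
        )

    def test_probe_shorter_than_k_errors(self):
        index = pdz.build_kmer_index({"c1": "ACGT" * 10}, k=15)
        with pytest.raises(ValueError):
            pdz.probe_repetitiveness("ACGTACGT", index)


class TestCloseMatches:
    def test_probe_from_unique_genome_counts_self_locus_only(self, rng):
        genome = random_genome(rng, {"c1": 5000})
        probe = genome["c1"][2000:2060]
        assert pdz.count_close_matches(probe, genome) == 1

    def test_exact_duplicate_on_second_chromosome_counts_two(self, rng):
        genome = random_genome(rng, {"c1": 3000, "c2": 2000})
        probe = genome["c1"][1000:1060]
        central = probe[15:45]
        genome["c2"] = genome["c2"][:800] + central + genome["c2"][830:]
        assert pdz.count_close_matches(probe, genome) == 2

    def test_decoy_with_six_edits_per_window_not_counted(self, rng):
        genome = random_genome(rng, {"c1": 3000})
        probe = genome["c1"][1000:1060]
        # mutate every 5th base of a copy: any 30-base window has 6 mismatches
        decoy = list(probe)
        for i in range(2, 60, 5):
            old = decoy[i]
            decoy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
        decoy = "".join(decoy)
        genome["c1"] = genome["c1"][:2500] + decoy  # replaces the tail
        searcher = pdz.CloseMatchSearcher(genome)
        got = searcher.count(probe)
        assert got == oracle_close_matches(probe, genome)
        assert got == 1

    def test_reverse_complement_hit_is_found(self, rng):
        genome = random_genome(rng, {"c1": 3000})
        probe = genome["c1"][1000:1060]
        rc = pdz.reverse_complement(probe[10:40])
        genome["c1"] = genome["c1"][:2200] + rc + genome["c1"][2230:]
        assert pdz.count_close_matches(probe, genome) == 2

    def test_probe_shorter_than_match_length_errors(self, rng):
        genome = random_genome(rng, {"c1": 500})
        with pytest.raises(ValueError):
            pdz.count_close_matches("ACGTACGTACGT", genome)

    def test_matches_bruteforce_on_randomized_probes(self, rng):
        """Seeded search equals the full-scan DP oracle on a small genome."""
        genome = random_genome(rng, {"c1": 2500, "c2": 1200})
        searcher = pdz.CloseMatchSearcher(genome)
        bases = np.array(list("ACGT"))
        for trial in range(12):
            L = int(rng.integers(50, 101))
            if trial % 2 == 0:
                s = int(rng.integers(0, 2500 - L))
                probe = list(genome["c1"][s : s + L])
                for _ in range(int(rng.integers(0, 8))):
                    probe[int(rng.integers(0, L))] = str(bases[rng.integers(0, 4)])
                probe = "".join(probe)
            else:
                probe = "".join(bases[rng.integers(0, 4, L)])
            assert searcher.count(probe) == oracle_close_matches(probe, genome)


class TestMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert pdz.melting_temperature("GC" * 25) > pdz.melting_temperature("AT" * 25)

    def test_reverse_complement_symmetry(self, rng):
        genome = random_genome(rng, {"c1": 60})
        seq = genome["c1"]
        assert pdz.melting_temperature(seq) == pytest.approx(
            pdz.melting_temperature(pdz.reverse_complement(seq)), abs=1e-6
        )

    def test_matches_independent_nearest_neighbor_implementation(self, rng):
        genome = random_genome(rng, {"c1": 100})
        for probe in (genome["c1"][:50], genome["c1"][20:90], genome["c1"]):
            assert pdz.melting_temperature(probe) == pytest.approx(
                oracle_tm_nn(probe), abs=0.5
            )

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            pdz.melting_temperature("ACGTN" * 10)


class TestCompositionPenalty:
    def test_balanced_probe_scores_zero(self):
        assert pdz.composition_penalty("ACGT" * 12 + "AC") == 0.0

    def test_poly_a_closed_form(self):
        p = pdz.DesignParameters()
        expected = p.comp_gc_weight * 0.5 + p.comp_homopolymer_weight * 45
        assert pdz.composition_penalty("A" * 50, p) == pytest.approx(expected)

    def test_reverse_complement_invariance(self, rng):
        genome = random_genome(rng, {"c1": 80})
        seq = genome["c1"]
        assert pdz.composition_penalty(seq) == pytest.approx(
            pdz.composition_penalty(pdz.reverse_complement(seq))
        )


class TestTiling:
    def test_single_length_enumeration(self, rng):
        genome = random_genome(rng, {"c1": 400})
        params = pdz.DesignParameters(probe_len_min=50, probe_len_max=50)
        target = TargetRegion("c1", 100, 150)
        cands = pdz.tile_candidates(target, genome, params)
        assert [c.start for c in cands] == list(range(70, 131, 5))
        assert len(cands) == 13

    def test_small_target_with_flanks(self, rng):
        genome = random_genome(rng, {"c1": 400})
        params = pdz.DesignParameters(probe_len_min=50, probe_len_max=50)
        cands = pdz.tile_candidates(TargetRegion("c1", 100, 110), genome, params)
        assert len(cands) == 5

    def test_target_too_short_without_flanks_warns_empty(self, rng, caplog):
        genome = random_genome(rng, {"c1": 400})
        params = pdz.DesignParameters(
            probe_len_min=50, probe_len_max=50, flank_allowance=0
        )
        with caplog.at_level(logging.WARNING):
            cands = pdz.tile_candidates(TargetRegion("c1", 100, 130), genome, params)
        assert cands == []
        assert "too short" in caplog.text

    def test_candidates_with_n_dropped(self):
        genome = {"c1": "ACGT" * 40 + "N" + "ACGT" * 40}
        params = pdz.DesignParameters(probe_len_min=50, probe_len_max=50)
        cands = pdz.tile_candidates(TargetRegion("c1", 130, 190), genome, params)
        assert all("N" not in c.sequence for c in cands)


def _scored(chrom="c1", start=0, length=50, rep=1.0, cm=1, tm=72.0, comp=0.0):
    c = pdz.CandidateProbe(chrom, start, length, "A" * length)
    c.repetitiveness, c.close_matches, c.tm, c.composition_penalty = rep, cm, tm, comp
    return c


class TestScoring:
    def test_clean_probe_closed_form(self):
        p = pdz.DesignParameters()
        c = _scored(rep=1.0, cm=1, tm=p.tm_target, comp=0.0)
        assert pdz.score_probe(c, p) == pytest.approx(math.log10(2))

    def test_more_close_matches_scores_worse(self):
        p = pdz.DesignParameters()
        assert pdz.score_probe(_scored(cm=1), p) < pdz.score_probe(_scored(cm=3), p)

    def test_nonunique_probe_is_ineligible(self):
        p = pdz.DesignParameters()
        c = _scored(cm=6)
        c.nonunique = c.close_matches > p.max_close_matches
        assert not c.passed

    def test_unscored_candidate_errors(self):
        c = pdz.CandidateProbe("c1", 0, 50, "A" * 50)
        with pytest.raises(ValueError):
            pdz.score_probe(c, pdz.DesignParameters())


class TestSelection:
    def test_equal_scores_select_leftmost(self):
        p = pdz.DesignParameters()
        target = TargetRegion("c1", 100, 150)
        cands = [_scored(start=s) for s in (70, 75, 80)]
        for c in cands:
            c.score = 1.0
        chosen = pdz.select_probes(target, cands, p)
        assert chosen[0].start == 70

    def test_window_count_over_200_base_target(self):
        # span 260 bases -> window starts at offsets 0,40,...,240: 7 windows
        p = pdz.DesignParameters()
        target = TargetRegion("c1", 100, 300)
        cands = [_scored(start=s) for s in range(70, 331, 5)]
        for c in cands:
            c.score = 1.0
        chosen = pdz.select_probes(target, cands, p)
        assert len(chosen) == 7
        assert [c.start for c in chosen] == [70 + 40 * i for i in range(7)]

    def test_all_repetitive_selects_nothing(self):
        p = pdz.DesignParameters()
        target = TargetRegion("c1", 100, 150)
        cands = [_scored(start=s, rep=500.0) for s in (70, 90, 110)]
        for c in cands:
            c.repetitive = True
            c.score = None
        assert pdz.select_probes(target, cands, p) == []

    def test_selected_probes_respect_flank_bounds(self, rng):
        genome = random_genome(rng, {"c1": 2000})
        params = pdz.DesignParameters()
        target = TargetRegion("c1", 500, 700)
        cands = pdz.tile_candidates(target, genome, params)
        kindex = pdz.build_kmer_index(genome, params.k)
        searcher = pdz.CloseMatchSearcher(genome, params)
        pdz.evaluate_candidates(cands, kindex, searcher, params)
        chosen = pdz.select_probes(target, cands, params)
        assert chosen
        for c in chosen:
            assert c.start >= target.start - params.flank_allowance
            assert c.end <= target.end + params.flank_allowance

    def test_eligibility_monotone_in_thresholds(self, rng):
        genome = random_genome(rng, {"c1": 2000})
        params = pdz.DesignParameters()
        target = TargetRegion("c1", 500, 650)
        cands = pdz.tile_candidates(target, genome, params)
        kindex = pdz.build_kmer_index(genome, params.k)
        searcher = pdz.CloseMatchSearcher(genome, params)
        pdz.evaluate_candidates(cands, kindex, searcher, params)

        def n_eligible(rep_thresh, max_cm):
            return sum(
                1
                for c in cands
                if c.repetitiveness <= rep_thresh
                and c.close_matches is not None
                and c.close_matches <= max_cm
            )

        assert n_eligible(100, 5) <= n_eligible(200, 5)
        assert n_eligible(100, 5) <= n_eligible(100, 10)


class TestCoverage:
    def test_probe_spanning_target_is_all_direct(self):
        probes = [pdz.CandidateProbe("c1", 100, 50, "A" * 50)]
        targets = consolidate_targets([Feature("c1", 100, 150)])
        rep = pdz.coverage_report(probes, targets, indirect_reach=100)
        assert (rep.direct_bases, rep.indirect_bases, rep.uncovered_bases) == (50, 0, 0)

    def test_gap_within_reach_is_indirect(self):
        probes = [pdz.CandidateProbe("c1", 100, 50, "A" * 50)]
        targets = consolidate_targets([Feature("c1", 100, 160)])
        rep = pdz.coverage_report(probes, targets, indirect_reach=100)
        assert (rep.direct_bases, rep.indirect_bases, rep.uncovered_bases) == (50, 10, 0)

    def test_no_probes_all_uncovered(self):
        targets = consolidate_targets([Feature("c1", 100, 160)])
        rep = pdz.coverage_report([], targets, indirect_reach=100)
        assert rep.uncovered_bases == rep.total_bases == 60

    def test_partition_sums_to_target_bases(self, rng):
        genome = random_genome(rng, {"c1": 3000})
        feats = [Feature("c1", s, s + 80, gene_id=f"g{s}") for s in (200, 600, 1200)]
        targets = consolidate_targets(feats)
        probes = [pdz.CandidateProbe("c1", 210, 60, "A" * 60)]
        rep = pdz.coverage_report(probes, targets, indirect_reach=50)
        assert rep.total_bases == targets.total_bases
        for _ch, s, e, d, i, u in rep.per_target:
            assert d + i + u == e - s


@pytest.fixture(scope="module")
def small_design():
    """A compact design problem: unique genes plus one exon sitting
    inside a 150-copy tandem repeat."""
    rng = np.random.default_rng(7)
    genome = random_genome(rng, {"c1": 9000})
    unit = genome["c1"][4000:4060]
    array = unit * 150
    seq = genome["c1"][:4000] + array + genome["c1"][4000 + len(array) - 5000 :]
    genome = {"c1": seq[:13000]}
    feats = [
        Feature("c1", 500, 700, "+", "CDS", "gene_u1"),
        Feature("c1", 1500, 1650, "+", "CDS", "gene_u2"),
        Feature("c1", 4200, 4400, "+", "CDS", "gene_rep"),  # inside repeat
    ]
    return genome, feats


class TestDesignExome:
    def test_unique_exons_probed_repeat_exon_skipped(self, small_design):
        genome, feats = small_design
        probes, _ = pdz.design_exome(genome, feats)
        probed_genes = set()
        for entry in probes.selection_log:
            if entry["n_selected"]:
                probed_genes.update(entry["genes"])
        assert {"gene_u1", "gene_u2"} <= probed_genes
        assert "gene_rep" not in probed_genes

    def test_rerun_is_byte_identical(self, small_design, tmp_path):
        genome, feats = small_design
        pdz.design_exome(genome, feats, out_prefix=str(tmp_path / "run1"))
        pdz.design_exome(genome, feats, out_prefix=str(tmp_path / "run2"))
        for suffix in (".probes.bed", ".probes.fasta", ".targets.bed",
                       ".coverage.tsv", ".design.log"):
            a = (tmp_path / f"run1{suffix}").read_bytes()
            b = (tmp_path / f"run2{suffix}").read_bytes()
            assert a == b, suffix

    def test_empty_annotation_gives_empty_design(self, small_design):
        genome, _ = small_design
        probes, report = pdz.design_exome(genome, [])
        assert len(probes) == 0
        assert report.total_bases == 0

    def test_windowed_coverage_reaches_all_selectable_bases(self, small_design):
        """With indirect reach >= window advance, every target base of a
        probed target is directly or indirectly covered."""
        genome, feats = small_design
        params = pdz.DesignParameters()
        assert params.indirect_reach >= params.window_advance
        probes, report = pdz.design_exome(genome, feats, params)
        probed = {
            tuple(e["target"]) for e in probes.selection_log if e["n_selected"]
        }
        for ch, s, e, d, i, u in report.per_target:
            if (ch, s, e) in probed:
                assert u == 0
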