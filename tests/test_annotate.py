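"""Extremity annotation: tract detection, Y'/X detection, maps, lengths."""

import numpy as np
import pytest

from subtel.annotate import (LengthDistribution, build_extremity_map,
                             detect_telomere_tract, detect_x_element,
                             detect_yprime_instances, extract_anchor_library,
                             measure_assembly_telomere_lengths,
                             read_length_distribution)
from subtel.grammar import gen_telomere_repeats
from subtel.io import Genome, arm_extremity, revcomp
from subtel.simulate import (ReadSimConfig, SimConfig, YPrimeLibrary,
                             YPrimeLibraryVariant, build_reference_genome,
                             simulate_reads, _mutate, _random_dna)


def _truth_canonical(ledger, genome, ext_name, window_len):
    """Planted feature intervals translated into a W-sized canonical frame."""
    ext = ledger.extremities[ext_name]
    clen = len(genome.chromosomes[ext.chromosome])
    off = clen - window_len
    return {k: (s - off, e - off)
            for k, (s, e) in ext.feature_intervals(clen).items()}


class TestTelomereTract:
    def test_planted_tract_recovered_within_20bp(self, rng, run_config):
        for planted in (120, 300, 2000):
            seq = _random_dna(rng, 3000) + gen_telomere_repeats(planted, rng)
            tract = detect_telomere_tract(seq, run_config)
            assert tract is not None
            assert abs(tract.length - planted) <= 20
            assert tract.interval.end == len(seq)

    def test_random_sequence_yields_none(self, rng, run_config):
        assert detect_telomere_tract(_random_dna(rng, 2000), run_config) is None

    def test_recall_and_accuracy_on_planted_tracts(self, run_config):
        """Recall >= 0.99 and |error| <= 20 bp for planted tracts >= 100 bp."""
        rng = np.random.default_rng(77)
        errors = []
        for _ in range(60):
            planted = int(rng.integers(100, 3000))
            seq = _random_dna(rng, 1500) + gen_telomere_repeats(planted, rng)
            tract = detect_telomere_tract(seq, run_config)
            assert tract is not None  # recall
            errors.append(abs(tract.length - planted))
        assert max(errors) <= 20

    def test_short_terminal_run_rejected(self, rng, run_config):
        seq = _random_dna(rng, 1000) + gen_telomere_repeats(30, rng)
        assert detect_telomere_tract(seq, run_config) is None


class TestYPrimeDetection:
    def test_planted_truth_exact_on_control(self, control, control_maps):
        """Precision = recall = 1 for full-length planted elements."""
        genome, ledger = control
        total_found = 0
        for m in control_maps:
            truth = _truth_canonical(ledger, genome, m.name,
                                     len(m.extremity.canonical_sequence))
            planted = [truth[f"Y{i}"]
                       for i in range(len(ledger.extremities[m.name].yprimes))]
            found = [(i.interval.start, i.interval.end) for i in m.yprime_instances]
            assert len(found) == len(planted)
            for (ps, pe), (fs, fe) in zip(planted, found):
                assert abs(ps - fs) <= 15 and abs(pe - fe) <= 15
            total_found += len(found)
        assert total_found == 34
        assert sum(1 for m in control_maps if m.yprime_instances) == 20

    def test_fragment_below_threshold_not_reported(self, control, run_config, rng):
        _, ledger = control
        lib = ledger.library
        fragment = lib.variants[0].sequence[:199]
        seq = _random_dna(rng, 8000) + fragment + gen_telomere_repeats(350, rng)
        g = Genome("frag", {"c": seq})
        ext = arm_extremity(g, "c", "R", run_config.extremity_window)
        assert detect_yprime_instances(ext, lib, run_config) == []

    def test_zero_yprime_extremity_empty(self, control, control_maps):
        _, ledger = control
        empties = [m for m in control_maps
                   if not ledger.extremities[m.name].yprimes]
        assert empties and all(not m.yprime_instances for m in empties)

    def test_union_invariant_under_redundant_library_variant(
            self, control, run_config):
        """Adding an overlapping redundant variant never changes intervals."""
        genome, ledger = control
        name = next(n for n, e in ledger.extremities.items() if len(e.yprimes) >= 2)
        chrom, side = name.rsplit("-", 1)
        ext = arm_extremity(genome, chrom, side, run_config.extremity_window)
        base = detect_yprime_instances(ext, ledger.library, run_config)
        v0 = ledger.library.variants[0]
        redundant = YPrimeLibrary(
            ledger.library.variants
            + [YPrimeLibraryVariant("redundant", v0.family, v0.sequence[100:4100])])
        again = detect_yprime_instances(ext, redundant, run_config)
        assert [(i.interval.start, i.interval.end) for i in base] == \
            [(i.interval.start, i.interval.end) for i in again]


class TestXElement:
    def test_planted_x_within_10bp(self, control, control_maps):
        genome, ledger = control
        for m in control_maps:
            assert m.x_interval is not None
            truth = _truth_canonical(ledger, genome, m.name,
                                     len(m.extremity.canonical_sequence))["X"]
            assert abs(m.x_interval.start - truth[0]) <= 10
            assert abs(m.x_interval.end - truth[1]) <= 10

    def test_no_x_yields_none(self, run_config, rng):
        g = Genome("g", {"c": _random_dna(rng, 40000)})
        ext = arm_extremity(g, "c", "R", run_config.extremity_window)
        x = _random_dna(rng, 1200)
        assert detect_x_element(ext, [("X", x)], run_config) is None

    def test_mutated_x_still_detected(self, run_config, rng):
        x = _random_dna(rng, 1200)
        planted = _mutate(x, rng, 0.01)
        seq = _random_dna(rng, 20000) + planted + gen_telomere_repeats(350, rng)
        g = Genome("g", {"c": seq})
        ext = arm_extremity(g, "c", "R", run_config.extremity_window)
        iv = detect_x_element(ext, [("X", x)], run_config)
        assert iv is not None
        start_true = len(ext.canonical_sequence) - 350 - 1200
        assert abs(iv.start - start_true) <= 10


class TestExtremityMap:
    def test_feature_order_core_x_yprime_tract(self, control_maps):
        # ordering with a 10 bp boundary tolerance (detected boundaries are
        # alignment/score derived, so adjacent features may abut fuzzily)
        for m in control_maps:
            assert m.status == "resolved"
            pos = m.x_interval.end
            for inst in m.yprime_instances:
                assert inst.interval.start >= pos - 15
                pos = inst.interval.end
            if m.telomere_tract is not None:
                assert m.telomere_tract.interval.start >= pos - 15
                assert m.telomere_tract.interval.end == len(m.extremity.canonical_sequence)

    def test_six_duplicate_yprime_end_is_undetermined(self, run_config, rng):
        lib = YPrimeLibrary([YPrimeLibraryVariant("v1", "short", _random_dna(rng, 5200))])
        seed = gen_telomere_repeats(100, rng)
        arm = _random_dna(rng, 60000)
        for _ in range(6):
            arm += seed + lib.variants[0].sequence
        arm += gen_telomere_repeats(350, rng)
        g = Genome("g", {"c": arm})
        maps = build_extremity_map(g, lib, [], run_config)
        m = {mm.name: mm for mm in maps}["c-R"]
        assert len(m.yprime_instances) == 6
        assert m.status == "undetermined"


class TestLengths:
    def test_assembly_lengths_near_350(self, control, run_config):
        genome, ledger = control
        dist = measure_assembly_telomere_lengths(genome, run_config)
        for ext_name, vals in dist.lengths.items():
            planted = len(ledger.extremities[ext_name].tract)
            assert abs(vals[0] - planted) <= 20

    def test_telomere_free_chromosome_scores_zero(self, run_config, rng):
        g = Genome("g", {"c": _random_dna(rng, 50000)})
        dist = measure_assembly_telomere_lengths(g, run_config)
        assert dist.lengths["c-L"] == [0]
        assert dist.lengths["c-R"] == [0]

    def test_summary_whiskers_follow_iqr_convention(self):
        dist = LengthDistribution()
        vals = [100, 200, 300, 400, 1000]
        for v in vals:
            dist.add("e", v)
        row = dist.summary().iloc[0]
        q1, q3 = np.percentile(vals, [25, 75])
        assert row["Q1"] == q1 and row["Q3"] == q3
        assert row["whisker_low"] == q1 - 1.5 * (q3 - q1)
        assert row["whisker_high"] == q3 + 1.5 * (q3 - q1)


class TestReadLengths:
    def test_per_extremity_means_recovered(self, small_genome, run_config):
        genome, ledger, _ = small_genome
        maps = build_extremity_map(
            genome, ledger.library, [("X_ancestor", ledger.x_ancestor)], run_config)
        anchors = extract_anchor_library(genome, maps, run_config)
        reads = simulate_reads(genome, ReadSimConfig(coverage=30, mean_length=6000),
                               seed=5)
        dist = read_length_distribution(reads, anchors, run_config)
        planted = {e.name: len(e.tract) for e in ledger.extremities.values()}
        measured = {k: v for k, v in dist.lengths.items() if len(v) >= 3}
        assert len(measured) >= 8
        for ext_name, vals in measured.items():
            assert abs(np.mean(vals) - planted[ext_name]) <= 0.1 * planted[ext_name]

    def test_no_anchors_no_reads(self, run_config):
        assert read_length_distribution([], [], run_config).lengths == {}
        assert read_length_distribution(
            [("r", "ACGT" * 300)], [], run_config).lengths == {}
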