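"""Rearrangement calling: positional diff, mosaics, terminal duplications,
circularization, summaries and group statistics."""

import itertools
import math

import numpy as np
import pytest

from subtel.annotate import ExtremityMap
from subtel.catalog import label_instances
from subtel.io import Extremity, Genome, Interval, revcomp
from subtel.pipeline import analyze_survivor
from subtel.rearrange import (AlterationEvent, detect_circularization,
                              detect_terminal_duplication, diff_extremity,
                              explain_mosaic, fisher, mann_whitney,
                              students_t, summarize_clone)
from subtel.simulate import (CassetteSpec, SimConfig, build_reference_genome,
                             plant_rearrangements, _random_dna)


def _map_with_labels(name, labels):
    ext = Extremity(*name.rsplit("-", 1), canonical_sequence="A" * 10, window=10)
    instances = []
    for i, lab in enumerate(labels):
        from subtel.annotate import YPrimeInstance
        instances.append(YPrimeInstance(
            extremity=name, interval=Interval(i * 2, i * 2 + 1), index=i,
            sequence="A", label=lab))
    return ExtremityMap(extremity=ext, telomere_tract=None, x_interval=None,
                        yprime_instances=instances)


class TestDiffExtremity:
    def test_identical_maps_fixed_point(self):
        for labels in ([], ["a"], ["a", "b", "a"]):
            m1 = _map_with_labels("c-R", labels)
            m2 = _map_with_labels("c-R", labels)
            assert diff_extremity(m1, m2, {"a", "b"}) == []

    def test_missing_middle_element_is_one_loss(self):
        ctrl = _map_with_labels("c-R", ["a", "b", "c"])
        surv = _map_with_labels("c-R", ["a", "c"])
        events = diff_extremity(ctrl, surv, {"a", "b", "c"})
        assert [(e.kind, e.payload["label"]) for e in events] == [("loss", "b")]

    def test_gain_adjacent_to_identical_neighbour_is_tandem(self):
        ctrl = _map_with_labels("c-R", ["a", "b"])
        surv = _map_with_labels("c-R", ["a", "a", "b"])
        events = diff_extremity(ctrl, surv, {"a", "b"})
        kinds = sorted(e.kind for e in events)
        assert kinds == ["gain", "tandem_amplification"]

    def test_novel_label_flagged(self):
        ctrl = _map_with_labels("c-R", ["a"])
        surv = _map_with_labels("c-R", ["a", "zz"])
        events = diff_extremity(ctrl, surv, {"a"})
        gains = [e for e in events if e.kind == "gain"]
        assert len(gains) == 1 and gains[0].payload["novel"]

    def test_substitution_counted_as_loss_plus_gain(self):
        ctrl = _map_with_labels("c-R", ["a", "b", "c"])
        surv = _map_with_labels("c-R", ["a", "x", "c"])
        events = diff_extremity(ctrl, surv, {"a", "b", "c"})
        kinds = sorted(e.kind for e in events)
        assert kinds == ["gain", "loss", "substitution"]

    def test_mismatched_extremities_rejected(self):
        with pytest.raises(ValueError):
            diff_extremity(_map_with_labels("c-R", []), _map_with_labels("d-R", []))


class TestMosaic:
    def test_two_donor_halves_fully_explained(self, rng):
        a, b = _random_dna(rng, 6000), _random_dna(rng, 6000)
        new = a[:3000] + b[3000:]
        dec = explain_mosaic(new, {"A": a, "B": b})
        assert dec is not None
        assert dec.coverage == 1.0
        assert dec.donors == ["A", "B"]
        assert dec.is_mosaic

    def test_random_sequence_unexplained(self, rng):
        donors = {"A": _random_dna(rng, 5000)}
        assert explain_mosaic(_random_dna(rng, 5000), donors) is None

    def test_reverse_orientation_segment_found(self, rng):
        a, b = _random_dna(rng, 4000), _random_dna(rng, 4000)
        new = a[:2000] + revcomp(b[:2000])
        dec = explain_mosaic(new, {"A": a, "B": b})
        assert dec is not None and dec.coverage == 1.0
        assert any(s["strand"] == "-" for s in dec.segments)

    def test_monotone_in_catalog(self, rng):
        a, b, c = (_random_dna(rng, 4000) for _ in range(3))
        new = a[:2000] + b[2000:]
        assert explain_mosaic(new, {"A": a, "B": b}) is not None
        assert explain_mosaic(new, {"A": a, "B": b, "C": c}) is not None

    def test_greedy_cover_matches_exhaustive_on_small_case(self, rng):
        """Greedy full-cover decision agrees with exhaustive segment search."""
        a, b = _random_dna(rng, 1200), _random_dna(rng, 1200)
        new = a[:400] + b[300:700] + a[700:]
        donors = {"A": a, "B": b}
        dec = explain_mosaic(new, donors, min_exact=51)
        from subtel.align import maximal_exact_matches
        segs = []
        for name, d in donors.items():
            for strand, ds in (("+", d), ("-", revcomp(d))):
                for ts, _, ln in maximal_exact_matches(new, ds, 51):
                    segs.append((ts, ts + ln))
        coverable = False
        for r in range(1, min(len(segs), 5) + 1):
            for combo in itertools.combinations(segs, r):
                covered = np.zeros(len(new), dtype=bool)
                for s, e in combo:
                    covered[s:e] = True
                if covered.all():
                    coverable = True
                    break
            if coverable:
                break
        assert (dec is not None) == coverable

    def test_below_threshold_fragments_do_not_explain(self, rng):
        a = _random_dna(rng, 1000)
        # 50 bp pieces of a separated by foreign sequence: exact matches of
        # exactly 50 < min_exact of 51 must not count
        new = "".join(a[i : i + 50] + _random_dna(rng, 10) for i in range(0, 500, 50))
        assert explain_mosaic(new, {"A": a}, min_exact=51) is None


@pytest.fixture(scope="module")
def dup_setup():
    cassettes = [
        CassetteSpec("bir1", "chrII-R", 4000, "chrVI-R", 6000, 1000, "arm"),
        CassetteSpec("circ3", "chrIII-L", 10000, "chrIII-R", 12000, 1500, "original"),
    ]
    genome, ledger = build_reference_genome(SimConfig(cassettes=cassettes), seed=11)
    return genome, ledger


class TestTerminalDuplication:
    def test_untouched_survivor_no_events(self, dup_setup, control_maps, run_config):
        genome, ledger = dup_setup
        from subtel.annotate import build_extremity_map
        maps = build_extremity_map(genome, ledger.library,
                                   [("X_ancestor", ledger.x_ancestor)], run_config)
        events, skipped = detect_terminal_duplication(
            genome, genome, maps, maps, run_config)
        assert events == []

    def test_planted_duplication_recovered_exactly(self, dup_setup, run_config):
        genome, ledger = dup_setup
        surv, sled = plant_rearrangements(
            genome, ledger,
            [{"kind": "terminal_duplication", "extremity": "chrII-R",
              "cassette_id": "bir1"}], seed=0)
        from subtel.annotate import build_extremity_map
        xlib = [("X_ancestor", ledger.x_ancestor)]
        cmaps = build_extremity_map(genome, ledger.library, xlib, run_config)
        smaps = build_extremity_map(surv, ledger.library, xlib, run_config)
        events, _ = detect_terminal_duplication(genome, surv, cmaps, smaps, run_config)
        dups = [e for e in events if e.kind == "terminal_duplication"]
        assert len(dups) == 1
        planted = next(e for e in sled.events if e.kind == "terminal_duplication")
        assert dups[0].extremity == "chrII-R"
        assert dups[0].payload["donor"] == planted.payload["donor"] == "chrVI-R"
        assert dups[0].payload["span"] == planted.payload["span"]
        assert dups[0].payload["homology"] == planted.payload["homology"] == 1000

    def test_nested_duplications_two_events(self, run_config):
        cassettes = [
            CassetteSpec("outer", "chrII-R", 4000, "chrVI-R", 6000, 800, "arm"),
            # inner cassette pairs a locus on the donor arm (copied into the
            # recipient by the outer event) with a second donor
            CassetteSpec("inner", "chrVI-R", 3000, "chrIX-R", 5000, 500, "arm"),
        ]
        genome, ledger = build_reference_genome(SimConfig(cassettes=cassettes), seed=13)
        surv, sled = plant_rearrangements(
            genome, ledger,
            [{"kind": "terminal_duplication", "extremity": "chrII-R",
              "cassette_id": "outer"},
             {"kind": "terminal_duplication", "extremity": "chrII-R",
              "cassette_id": "inner", "donor": "chrIX-R"}], seed=0)
        from subtel.annotate import build_extremity_map
        xlib = [("X_ancestor", ledger.x_ancestor)]
        cmaps = build_extremity_map(genome, ledger.library, xlib, run_config)
        smaps = build_extremity_map(surv, ledger.library, xlib, run_config)
        events, _ = detect_terminal_duplication(genome, surv, cmaps, smaps, run_config)
        dups = [e for e in events if e.kind == "terminal_duplication"
                and e.extremity == "chrII-R"]
        assert len(dups) == 2
        assert dups[0].payload["donor"] == "chrVI-R"
        assert dups[0].payload["homology"] == 800
        assert dups[1].payload["donor"] == "chrIX-R"
        assert dups[1].payload["homology"] == 500


class TestCircularization:
    def test_normal_survivor_none(self, dup_setup, run_config):
        genome, _ = dup_setup
        events, anomalies = detect_circularization(genome, genome, run_config)
        assert events == [] and anomalies == []

    def test_planted_circular_chromosome_called(self, dup_setup, run_config):
        genome, ledger = dup_setup
        surv, sled = plant_rearrangements(
            genome, ledger,
            [{"kind": "circularization", "chromosome": "chrIII",
              "cassette_id": "circ3"}], seed=5)
        events, anomalies = detect_circularization(surv, genome, run_config)
        assert len(events) == 1
        assert events[0].payload["control_chromosome"] == "chrIII"
        assert events[0].payload["homology"] == 1500

    def test_single_telomere_free_end_is_anomaly(self, dup_setup, run_config, rng):
        genome, _ = dup_setup
        surv = Genome("s", dict(genome.chromosomes))
        # strip the right telomere only
        tract_len = 500
        surv.chromosomes["chrI"] = surv.chromosomes["chrI"][:-tract_len]
        events, anomalies = detect_circularization(surv, genome, run_config)
        assert events == []
        assert "chrI" in anomalies


class TestSummaries:
    def test_empty_events_all_zero(self, control_maps):
        s = summarize_clone("c", [], control_maps)
        assert s.n_lost == s.n_gained == s.affected_extremities == 0
        assert s.fraction_altered == 0.0
        assert s.n_considered == 32

    def test_losses_counted_per_extremity(self, control_maps):
        names = [m.name for m in control_maps[:3]]
        events = [AlterationEvent("loss", names[0], {"label": "x"})] * 3 \
            + [AlterationEvent("loss", names[1], {"label": "y"})] \
            + [AlterationEvent("loss", names[2], {"label": "z"})]
        s = summarize_clone("c", events, control_maps)
        assert s.n_lost == 5
        assert s.affected_extremities == 3

    def test_class_split_uses_control_map(self, control, control_maps):
        _, ledger = control
        y_end = next(m.name for m in control_maps if m.yprime_instances)
        x_end = next(m.name for m in control_maps if not m.yprime_instances)
        events = [AlterationEvent("loss", y_end, {}),
                  AlterationEvent("gain", x_end, {})]
        s = summarize_clone("c", events, control_maps)
        assert s.altered_by_class["yprime"]["altered"] == 1
        assert s.altered_by_class["x_only"]["altered"] == 1
        assert s.altered_by_class["yprime"]["total"] == 20
        assert s.altered_by_class["x_only"]["total"] == 12


def _mannwhitney_permutation_oracle(x, y):
    """Two-sided p by full enumeration of group assignments of the U stat
    (twice the smaller one-sided tail, clipped at 1; exact under ties)."""
    pooled = list(x) + list(y)
    n = len(x)

    def ustat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    obs = ustat(x, y)
    m = len(pooled)
    ge = le = total = 0
    for combo in itertools.combinations(range(m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(m) if i not in combo]
        u = ustat(xs, ys)
        ge += u >= obs - 1e-9
        le += u <= obs + 1e-9
        total += 1
    return min(1.0, 2 * min(ge / total, le / total))


def _fisher_hypergeom_oracle(table):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestStatistics:
    def test_mannwhitney_equals_permutation_enumeration(self):
        cases = [
            ([1, 2, 3, 4], [5, 6, 7, 8]),
            ([1.5, 2.5, 9.0, 3.0], [2.0, 2.5, 4.0]),
            ([0, 0, 1, 1, 2], [1, 2, 2, 3]),
        ]
        for x, y in cases:
            assert mann_whitney(x, y) == pytest.approx(
                _mannwhitney_permutation_oracle(x, y), abs=1e-9)

    def test_identical_small_groups_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fisher_equals_hypergeometric_enumeration(self):
        for table in ([[18, 12], [5, 21]], [[1, 9], [11, 3]], [[5, 0], [1, 4]]):
            assert fisher(table) == pytest.approx(
                _fisher_hypergeom_oracle(table), abs=1e-10)

    def test_degenerate_groups_reported_na(self):
        assert math.isnan(mann_whitney([1], [2, 3]))
        assert math.isnan(mann_whitney([2, 2], [2, 2]))
        assert math.isnan(students_t([1], [1, 2]))

    def test_t_test_basic_sanity(self):
        p_same = students_t([1, 2, 3, 4], [1.1, 2.1, 2.9, 4.0])
        p_diff = students_t([1, 2, 3, 4], [11, 12, 13, 14])
        assert p_diff < 0.001 < p_same
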