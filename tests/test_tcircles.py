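"""Tandem arrays, circle consolidation, matching, specificity and origins."""

import numpy as np
import pytest

from subtel.grammar import gen_telomere_repeats, is_telomeric_string
from subtel.simulate import _random_dna, roll_circle
from subtel.tcircles import (TandemArray, circular_containment,
                             circular_similarity, consolidate_circles,
                             find_perfect_tandem_arrays, match_circle,
                             nested_circle_relations,
                             specificity_filter_and_origin, tandem_fraction)


def brute_force_tandem_arrays(seq, min_unit=30, min_copies=2, max_unit=None):
    """Independent O(n^2 L) reference scanner: every start x unit length,
    maximal copies, left-maximality, primitive-unit canonicalization."""
    n = len(seq)
    max_unit = max_unit or n // min_copies
    found = set()
    for u in range(min_unit, max_unit + 1):
        for i in range(0, n - 2 * u + 1):
            unit = seq[i : i + u]
            if "N" in unit:
                continue
            c = 1
            while seq[i + c * u : i + (c + 1) * u] == unit:
                c += 1
            if c < min_copies:
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + u]:
                continue  # not the leftmost phase of this run
            # primitive-period canonical representation
            p = next((d for d in range(1, u + 1)
                      if u % d == 0 and unit[:d] * (u // d) == unit), u)
            if p < u and p * -(-min_unit // p) != u:
                continue
            found.add((i, u, c))
    return found


class TestTandemArrayScanner:
    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(4242)
        for _ in range(30):
            n = int(rng.integers(100, 800))
            seq = gen_telomere_repeats(n, rng)
            if rng.random() < 0.7:  # plant an array
                u = int(rng.integers(30, 90))
                copies = int(rng.integers(2, 5))
                unit = gen_telomere_repeats(u, rng)
                pos = int(rng.integers(0, max(1, n - u * copies)))
                seq = seq[:pos] + unit * copies + seq[pos + u * copies:]
            got = {(a.start, a.unit_length, a.copies)
                   for a in find_perfect_tandem_arrays(seq, 30, 2)}
            assert got == brute_force_tandem_arrays(seq, 30, 2)

    def test_planted_sixty_bp_unit_four_copies(self, rng):
        unit = gen_telomere_repeats(60, rng)
        tel = gen_telomere_repeats(400, rng) + unit * 4 + gen_telomere_repeats(150, rng)
        arrays = [a for a in find_perfect_tandem_arrays(tel, 30, 2)
                  if a.copies >= 4 and a.unit_length >= 55]
        assert any(a.unit_length == 60 and a.copies == 4 for a in arrays) or \
            any(a.copies == 4 and abs(a.unit_length - 60) <= 2 for a in arrays)

    def test_periodic_unit_reduced_to_primitive(self):
        unit30 = "TGTGGTGGGTGTGGGTGTTGGGTGGTGTGG"
        assert len(unit30) == 30
        seq = "ACGCATCGAT" + unit30 * 4 + "CATGCATCGA"
        arrays = find_perfect_tandem_arrays(seq, 30, 2)
        units = {(a.unit_length, a.copies) for a in arrays}
        assert (30, 4) in units
        assert not any(ul == 60 for ul, _ in units)

    def test_empty_and_tiny_input(self):
        assert find_perfect_tandem_arrays("", 30, 2) == []
        assert find_perfect_tandem_arrays("ACGT", 30, 2) == []

    def test_pure_telomerase_tract_has_no_long_units(self, rng):
        """Telomerase-emitted tracts carry no >= 50 bp perfect tandem units."""
        for seed in range(5):
            tract = gen_telomere_repeats(2000, np.random.default_rng(seed))
            arrays = find_perfect_tandem_arrays(tract, 50, 2)
            assert arrays == []


class TestCircularAlignment:
    def test_rotation_scores_one(self, rng):
        unit = gen_telomere_repeats(139, rng)
        for phase in (0, 1, 70, 138):
            rot = unit[phase:] + unit[:phase]
            assert circular_similarity(unit, rot) == pytest.approx(1.0)

    def test_unrelated_units_score_low(self, rng):
        a = _random_dna(rng, 200)
        b = _random_dna(rng, 200)
        assert circular_similarity(a, b) < 0.8

    def test_containment_of_subunit(self, rng):
        large = _random_dna(rng, 332)
        small = large[100:239]  # 139 bp inside
        assert circular_containment(small, large) > 0.98
        # and across the wrap junction of the large circle
        wrapped = large[300:] + large[:107]
        assert circular_containment(wrapped, large) > 0.98


class TestMatchCircle:
    def test_planted_array_six_copies_exact_phase(self, rng):
        unit = gen_telomere_repeats(120, rng)
        array = roll_circle(unit, 6, phase=37)
        # flank bases chosen so they cannot extend the periodic array
        pre = _random_dna(rng, 199) + ("A" if array[-1] != "A" else "C")
        post = ("A" if array[0] != "A" else "C") + _random_dna(rng, 99)
        tel = pre + array + post
        runs = match_circle(unit, tel, 0.98)
        assert len(runs) == 1
        run = runs[0]
        assert run.start == 200
        assert run.copies == 6
        assert run.phase == 37
        assert run.score == pytest.approx(1.0)

    def test_rotating_query_leaves_matches_invariant(self, rng):
        unit = gen_telomere_repeats(100, rng)
        tel = _random_dna(rng, 150) + roll_circle(unit, 4, 10) + _random_dna(rng, 80)
        base = match_circle(unit, tel, 0.98)
        for rot in (13, 57, 99):
            rotated = unit[rot:] + unit[:rot]
            runs = match_circle(rotated, tel, 0.98)
            assert [(r.start, r.end, r.copies) for r in runs] == \
                [(r.start, r.end, r.copies) for r in base]
            # phases shift by the rotation
            assert runs[0].phase == (base[0].phase - rot) % 100

    def test_no_match_in_unrelated_telomere(self, rng):
        unit = gen_telomere_repeats(139, rng)
        tel = gen_telomere_repeats(3000, rng)
        assert match_circle(unit, tel, 0.98) == []

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            match_circle("", "ACGT", 0.98)


class TestConsolidation:
    def test_same_unit_two_phases_one_circle(self, rng):
        unit = gen_telomere_repeats(139, rng)
        a1 = TandemArray("e1", 0, roll_circle(unit, 1, 0), 4)
        a2 = TandemArray("e2", 0, roll_circle(unit, 1, 77)[:139], 5)
        circles = consolidate_circles([a1, a2], clone="c")
        assert len(circles) == 1
        assert circles[0].circle_id == "Circle_139"
        assert len(circles[0].supporting_arrays) == 2

    def test_unit_below_use_threshold_ignored(self, rng):
        a = TandemArray("e", 0, gen_telomere_repeats(40, rng), 5)
        assert consolidate_circles([a], clone="c") == []

    def test_two_unrelated_units_two_circles(self, rng):
        a = TandemArray("e1", 0, gen_telomere_repeats(80, rng), 3)
        b = TandemArray("e2", 0, gen_telomere_repeats(200, rng), 4)
        circles = consolidate_circles([a, b], clone="c")
        assert len(circles) == 2

    def test_three_copy_requirement(self, rng):
        a = TandemArray("e", 0, gen_telomere_repeats(100, rng), 2)
        assert consolidate_circles([a], clone="c", min_copies=3) == []

    def test_representative_is_most_supported(self, rng):
        u1 = gen_telomere_repeats(100, rng)
        u2 = u1[13:] + u1[:13]  # rotation, different phase
        arrays = [TandemArray("e1", 0, u1, 3), TandemArray("e2", 0, u2, 7)]
        circles = consolidate_circles(arrays, clone="c")
        assert len(circles) == 1
        assert circles[0].unit == u2


class TestSpecificityAndOrigin:
    def _tract_sets(self, rng, unit):
        origin_tract = (gen_telomere_repeats(60, rng) + unit
                        + gen_telomere_repeats(150, rng))
        own = [("s1-ext1", gen_telomere_repeats(200, rng) + roll_circle(unit, 5, 3)
                + gen_telomere_repeats(100, rng))]
        control = [("chrV-L", origin_tract),
                   ("chrV-R", gen_telomere_repeats(400, rng))]
        return own, control

    def test_origin_traced_to_single_control_copy(self, rng):
        unit = gen_telomere_repeats(139, rng)
        own, control = self._tract_sets(rng, unit)
        from subtel.tcircles import TCircle
        circle = TCircle("Circle_139", unit, clone="s1")
        out = specificity_filter_and_origin(
            circle, {"s1": own, "control": control}, "control")
        assert not out.discarded
        assert out.origin == "chrV-L"

    def test_multicopy_in_other_survivor_discarded(self, rng):
        unit = gen_telomere_repeats(100, rng)
        own, control = self._tract_sets(rng, unit)
        other = [("s2-ext", gen_telomere_repeats(100, rng) + roll_circle(unit, 3, 0)
                  + gen_telomere_repeats(100, rng))]
        from subtel.tcircles import TCircle
        circle = TCircle("Circle_100", unit, clone="s1")
        out = specificity_filter_and_origin(
            circle, {"s1": own, "s2": other, "control": control}, "control")
        assert out.discarded

    def test_absent_from_control_origin_unknown(self, rng):
        unit = gen_telomere_repeats(120, rng)
        own = [("s1-e", roll_circle(unit, 4, 0) + gen_telomere_repeats(100, rng))]
        control = [("chrI-L", gen_telomere_repeats(500, rng))]
        from subtel.tcircles import TCircle
        circle = TCircle("Circle_120", unit, clone="s1")
        out = specificity_filter_and_origin(
            circle, {"s1": own, "control": control}, "control")
        assert not out.discarded
        assert out.origin is None


class TestNestedRelations:
    def test_planted_containment(self, rng):
        from subtel.tcircles import TCircle
        large = gen_telomere_repeats(332, rng)
        small = large[100:239]
        c_small = TCircle("Circle_139", small, "c")
        c_large = TCircle("Circle_332", large, "c")
        rels = nested_circle_relations([c_small, c_large])
        assert ("Circle_139", "Circle_332") in rels

    def test_unrelated_units_none_and_no_self_pairs(self, rng):
        from subtel.tcircles import TCircle
        a = TCircle("Circle_100", gen_telomere_repeats(100, rng), "c")
        b = TCircle("Circle_200", gen_telomere_repeats(200, rng), "c")
        assert nested_circle_relations([a, b]) == []


class TestTandemFraction:
    def test_planted_fraction_recovered(self, rng):
        unit = gen_telomere_repeats(100, rng)
        array = roll_circle(unit, 6, 0)  # 600 bp
        tract = gen_telomere_repeats(700, rng) + array + gen_telomere_repeats(700, rng)
        arrays = find_perfect_tandem_arrays(tract, 30, 2, extremity="e")
        rep = tandem_fraction("c", [("e", tract)], {"e": arrays}, [])
        assert rep.perfect_fraction == pytest.approx(600 / 2000, abs=0.02)

    def test_extended_at_least_perfect_and_single_occurrence_counted(self, rng):
        from subtel.tcircles import TCircle
        unit = gen_telomere_repeats(100, rng)
        t1 = gen_telomere_repeats(100, rng) + roll_circle(unit, 4, 0) \
            + gen_telomere_repeats(100, rng)
        t2 = gen_telomere_repeats(50, rng) + unit + gen_telomere_repeats(250, rng)
        arrays = {n: find_perfect_tandem_arrays(t, 30, 2, extremity=n)
                  for n, t in [("e1", t1), ("e2", t2)]}
        circle = TCircle("Circle_100", unit, "c")
        rep = tandem_fraction("c", [("e1", t1), ("e2", t2)], arrays, [circle])
        assert rep.extended_fraction >= rep.perfect_fraction
        # the single unit occurrence on e2 only counts in the extended set
        assert rep.extended_bp >= rep.perfect_bp + 100

    def test_no_telomeric_dna_reported_na(self):
        rep = tandem_fraction("c", [], {}, [])
        assert np.isnan(rep.perfect_fraction) and np.isnan(rep.extended_fraction)
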