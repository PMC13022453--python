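"""T-circle signatures: perfect tandem arrays in telomeres, consolidation
into circle units, circular-permutation-aware matching, specificity
filtering and origin tracing.

Rolling-circle copying of an extrachromosomal telomeric circle into a
telomere leaves a perfect tandem array whose unit is a rotation of the
circle; the same unit recurring at several telomeres with different phases
is the hallmark sought here.  Units are matched with a local aligner
(match 1, mismatch -1, gap open -1, gap extend -0.9) against sliding
windows of unit size, the circle doubled beforehand so every rotation is
available; the normalized score is the raw score divided by the unit
length, and matches require a normalized score above 0.98.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align

from .config import RunConfig


@dataclass
class TandemArray:
    extremity: str
    start: int          # within the scanned telomere tract
    unit: str
    copies: int
    perfect: bool = True

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def end(self) -> int:
        return self.start + len(self.unit) * self.copies


@dataclass
class CircleMatchRun:
    genome: str
    extremity: str
    start: int
    end: int
    phase: int          # rotation of the query unit at the run start
    copies: int
    score: float        # minimum normalized score over the run


@dataclass
class TCircle:
    circle_id: str
    unit: str
    clone: str
    supporting_arrays: list[TandemArray] = field(default_factory=list)
    matches: list[CircleMatchRun] = field(default_factory=list)
    origin: str | None = None
    discarded: bool = False

    @property
    def unit_length(self) -> int:
        return len(self.unit)


# ---------------------------------------------------------------------------
# Perfect tandem arrays


def _primitive_period(unit: str) -> int:
    """Smallest period p with p | len(unit) (classic failure-function)."""
    n = len(unit)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and unit[i] != unit[k]:
            k = fail[k - 1]
        if unit[i] == unit[k]:
            k += 1
        fail[i] = k
    p = n - fail[n - 1]
    return p if n % p == 0 else n


def find_perfect_tandem_arrays(
    telomere_seq: str,
    min_unit: int = 30,
    min_copies: int = 2,
    max_unit: int | None = None,
    extremity: str = "",
) -> list[TandemArray]:
    """All maximal perfect tandem arrays with primitive units >= min_unit.

    An array is the leftmost phase of a maximal run of period-u matches;
    a unit that is itself periodic is reported at the smallest unit length
    >= min_unit compatible with its primitive period, so every array
    appears exactly once.
    """
    n = len(telomere_seq)
    out: list[TandemArray] = []
    if n < 2 * min_unit:
        return out
    arr = np.frombuffer(telomere_seq.encode(), dtype=np.uint8)
    max_unit = max_unit or n // min_copies
    for u in range(min_unit, max_unit + 1):
        eq = arr[: n - u] == arr[u:]
        if not eq.any():
            continue
        # maximal runs of True
        padded = np.concatenate([[False], eq, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            span = (e - s) + u
            copies = span // u
            if copies < min_copies:
                continue
            unit = telomere_seq[s : s + u]
            p = _primitive_period(unit)
            if p < u:
                # canonical representation: smallest multiple of p >= min_unit
                canonical = p * -(-min_unit // p)
                if canonical != u:
                    continue
            if "N" in unit:
                continue
            out.append(TandemArray(extremity=extremity, start=int(s),
                                   unit=unit, copies=int(copies)))
    out.sort(key=lambda a: (a.start, a.unit_length))
    return out


# ---------------------------------------------------------------------------
# Circular-permutation-aware alignment


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -1
    al.extend_gap_score = -0.9
    return al


def circular_similarity(a: str, b: str) -> float:
    """Normalized local alignment score of doubled(a) vs b, over max length.

    1.0 iff b is a rotation of a (equal lengths); rotation-invariant in
    both arguments.
    """
    if not a or not b:
        raise ValueError("empty unit")
    score = _aligner().score(a + a, b)
    return float(score) / max(len(a), len(b))


def circular_containment(small: str, large: str) -> float:
    """Normalized score of the small unit inside the circularized large one."""
    if not small or not large:
        raise ValueError("empty unit")
    score = _aligner().score(large + large, small)
    return float(score) / len(small)


def _kmer_positions(seq: str, kmers: set[str], k: int) -> np.ndarray:
    hits = [i for i in range(len(seq) - k + 1) if seq[i : i + k] in kmers]
    return np.asarray(hits, dtype=int)


def _window_score(doubled: str, window: str, unit_len: int) -> tuple[float, int]:
    """(normalized score, phase) of a unit-sized telomere window."""
    al = _aligner()
    alns = al.align(doubled, window)
    if len(alns) == 0:
        return 0.0, 0
    aln = alns[0]
    q0 = int(aln.aligned[0][0][0])
    t0 = int(aln.aligned[1][0][0])
    phase = (q0 - t0) % unit_len
    return float(aln.score) / unit_len, phase


def match_circle(
    circle_unit: str,
    telomere_seq: str,
    match_threshold: float = 0.98,
    genome: str = "",
    extremity: str = "",
) -> list[CircleMatchRun]:
    """Match a circle unit against one telomere, all rotations considered.

    The doubled unit is aligned against unit-sized windows (step 1,
    restricted to k-mer-sharing candidate regions for speed; a window can
    reach the threshold only if it shares long exact stretches with the
    unit).  Non-overlapping matches are reported; contiguous matches merge
    into copy counts, with the phase of the run start.
    """
    u = len(circle_unit)
    n = len(telomere_seq)
    if u == 0:
        raise ValueError("empty circle unit")
    if n < u:
        return []
    doubled = circle_unit + circle_unit
    # a window scoring > threshold can carry at most e edits (each costs
    # ~1.9-2 score), hence contains an exact stretch of >= (u - e)/(e + 1)
    # bases shared with the doubled unit; seed on k-mers of that length
    e = int(u * (1 - match_threshold) / 1.8) + 1
    k = max(12, (u - e) // (e + 1))
    k = min(k, 64, u)
    unit_kmers = {doubled[i : i + k] for i in range(len(doubled) - k + 1)}
    hits = _kmer_positions(telomere_seq, unit_kmers, k)
    if hits.size == 0:
        return []
    candidate = np.zeros(n - u + 1, dtype=bool)
    for h in hits:
        lo = max(0, h - u)
        hi = min(n - u, h) + 1
        candidate[lo:hi] = True
    runs: list[CircleMatchRun] = []
    i = 0
    limit = n - u
    current: CircleMatchRun | None = None
    while i <= limit:
        if not candidate[i]:
            if current is not None:
                runs.append(current)
                current = None
            i += 1
            continue
        score, phase = _window_score(doubled, telomere_seq[i : i + u], u)
        if score <= match_threshold:
            if current is not None:
                runs.append(current)
                current = None
            i += 1
            continue
        # hill-climb to the best-scoring start of this match
        best_i, best = i, (score, phase)
        j = i + 1
        while best[0] < 1.0 and j <= limit and j < i + u:
            s2 = _window_score(doubled, telomere_seq[j : j + u], u)
            if s2[0] > best[0]:
                best_i, best = j, s2
            j += 1
        score, phase = best
        i = best_i
        if current is not None and i == current.end:
            current.end = i + u
            current.copies += 1
            current.score = min(current.score, score)
        else:
            if current is not None:
                runs.append(current)
            current = CircleMatchRun(
                genome=genome, extremity=extremity, start=i, end=i + u,
                phase=phase, copies=1, score=score)
        i += u
    if current is not None:
        runs.append(current)
    return runs


# ---------------------------------------------------------------------------
# Consolidation, specificity, origins


def _smallest_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def consolidate_circles(
    arrays: list[TandemArray],
    clone: str = "",
    min_unit_use: int = 50,
    min_copies: int = 3,
    merge_score: float = 0.98,
) -> list[TCircle]:
    """Candidate circle units from one clone's tandem arrays.

    Units shorter than ``min_unit_use`` are ignored; candidacy requires an
    array of >= ``min_copies`` copies.  Identical or highly similar units
    (circular similarity > merge_score) are grouped, and each group is
    represented by the unit with the largest total copy support (ties:
    longest unit, then lexicographically smallest rotation).
    """
    usable = [a for a in arrays if a.unit_length >= min_unit_use]
    seeds = [a for a in usable if a.copies >= min_copies]
    if not seeds:
        return []
    units = sorted({a.unit for a in seeds})
    n = len(units)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if circular_similarity(units[i], units[j]) > merge_score:
                a, b = find(i), find(j)
                if a != b:
                    parent[b] = a
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(units[i])
    circles = []
    for members in groups.values():
        support: dict[str, int] = {m: 0 for m in members}
        supporting: list[TandemArray] = []
        for a in usable:
            for m in members:
                if a.unit == m or (a.unit_length == len(m)
                                   and circular_similarity(m, a.unit) > merge_score):
                    support[m] = support.get(m, 0) + a.copies
                    supporting.append(a)
                    break
        rep = max(members,
                  key=lambda m: (support[m], len(m), _revsort(_smallest_rotation(m))))
        circles.append(TCircle(
            circle_id=f"Circle_{len(rep)}", unit=rep, clone=clone,
            supporting_arrays=supporting))
    circles.sort(key=lambda c: (c.unit_length, c.unit))
    return circles


def _revsort(s: str) -> tuple[int, ...]:
    # max() picks the largest key; invert char ranks so the lexicographically
    # smallest rotation wins ties
    return tuple(-ord(c) for c in s)


def match_circle_everywhere(
    circle: TCircle,
    tracts_by_clone: dict[str, list[tuple[str, str]]],
    match_threshold: float = 0.98,
) -> dict[str, list[CircleMatchRun]]:
    """Match one circle against every telomere of every provided assembly."""
    out: dict[str, list[CircleMatchRun]] = {}
    for clone, tracts in tracts_by_clone.items():
        runs: list[CircleMatchRun] = []
        for ext_name, tract in tracts:
            if not tract:
                continue
            runs.extend(match_circle(
                circle.unit, tract, match_threshold, genome=clone,
                extremity=ext_name))
        out[clone] = runs
    return out


def specificity_filter_and_origin(
    circle: TCircle,
    tracts_by_clone: dict[str, list[tuple[str, str]]],
    control_clone: str,
    match_threshold: float = 0.98,
) -> TCircle:
    """Discard non-specific circles; trace specific ones to a control origin.

    A circle found in more than one copy in any *other* assembly is not
    specific to its clone and is discarded.  Exactly one copy in the control
    marks that telomere as the locus of origin; zero copies leaves the
    origin unknown.  The circle is annotated in place and returned.
    """
    matches = match_circle_everywhere(circle, tracts_by_clone, match_threshold)
    circle.matches = [r for runs in matches.values() for r in runs]
    for clone, runs in matches.items():
        if clone == circle.clone:
            continue
        copies = sum(r.copies for r in runs)
        if copies > 1:
            circle.discarded = True
            return circle
    control_runs = matches.get(control_clone, [])
    if sum(r.copies for r in control_runs) == 1:
        circle.origin = control_runs[0].extremity
    return circle


def nested_circle_relations(
    circles: list[TCircle], threshold: float = 0.98,
) -> list[tuple[str, str]]:
    """(smaller_id, larger_id) pairs where the smaller unit is contained in
    the circularized larger unit; self-pairs excluded."""
    out = []
    for small in circles:
        for large in circles:
            if small is large or small.unit_length >= large.unit_length:
                continue
            if circular_containment(small.unit, large.unit) > threshold:
                out.append((small.circle_id, large.circle_id))
    return out


# ---------------------------------------------------------------------------
# Tandem fraction of telomeric DNA


@dataclass
class TandemFractionReport:
    clone: str
    total_telomeric_bp: int
    perfect_bp: int
    extended_bp: int
    perfect_fraction: float
    extended_fraction: float


def tandem_fraction(
    clone: str,
    tracts: list[tuple[str, str]],
    arrays_by_tract: dict[str, list[TandemArray]],
    circles: list[TCircle],
    min_unit_use: int = 50,
    match_threshold: float = 0.98,
) -> TandemFractionReport:
    """Fractions of telomeric DNA inside tandem arrays.

    Perfect fraction: union of perfect-array intervals (units >=
    min_unit_use).  Extended fraction additionally counts single or
    imperfect occurrences of the consolidated circle units (same score
    threshold, any copy count).  NaN fractions when there is no telomeric
    DNA.
    """
    total = sum(len(t) for _, t in tracts)
    if total == 0:
        return TandemFractionReport(clone, 0, 0, 0, float("nan"), float("nan"))
    perfect = 0
    extended = 0
    for ext_name, tract in tracts:
        n = len(tract)
        mask = np.zeros(n, dtype=bool)
        for a in arrays_by_tract.get(ext_name, []):
            if a.unit_length >= min_unit_use:
                mask[a.start : a.end] = True
        perfect += int(mask.sum())
        ext_mask = mask.copy()
        for c in circles:
            if c.discarded:
                continue
            # reuse precomputed matches when the circle was already scanned
            runs = [r for r in c.matches
                    if r.genome == clone and r.extremity == ext_name]
            if not c.matches:
                runs = match_circle(c.unit, tract, match_threshold,
                                    genome=clone, extremity=ext_name)
            for run in runs:
                ext_mask[run.start : run.end] = True
        extended += int(ext_mask.sum())
    return TandemFractionReport(
        clone=clone, total_telomeric_bp=total, perfect_bp=perfect,
        extended_bp=extended, perfect_fraction=perfect / total,
        extended_fraction=extended / total)


def collect_tracts(genome, config: RunConfig | None = None) -> list[tuple[str, str]]:
    """(extremity, terminal tract sequence) for every extremity of a genome."""
    from .annotate import detect_telomere_tract
    from .io import arm_extremity

    config = config or RunConfig()
    out = []
    for chrom, side in genome.extremities():
        ext = arm_extremity(genome, chrom, side, config.extremity_window)
        tract = detect_telomere_tract(ext.canonical_sequence, config, ext.name)
        if tract is not None:
            out.append((ext.name, ext.canonical_sequence[tract.interval.start:]))
    return out
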