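"""Annotation of chromosome extremities: telomere tracts, X elements, Y'
elements, and telomere length distributions from assemblies and reads.

Telomere tracts are found by sliding a 20 bp window (step 1) from the
chromosome end and scoring each window by *telomericity* -- the fraction of
its 6-mers generable by the degenerate TG(1-3) grammar.  Y' and X elements
are located by local alignment (blastn) against element libraries, keeping
Y' alignments longer than 200 bp and taking their union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from . import align
from .config import RunConfig
from .grammar import telomericity, telomericity_profile
from .io import Extremity, Genome, Interval, arm_extremity, revcomp
from .simulate import YPrimeLibrary


@dataclass
class TelomereTract:
    extremity: str
    interval: Interval
    interstitial: bool = False

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class YPrimeInstance:
    extremity: str
    interval: Interval
    index: int
    sequence: str
    label: str | None = None

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ExtremityMap:
    extremity: Extremity
    telomere_tract: TelomereTract | None
    x_interval: Interval | None
    yprime_instances: list[YPrimeInstance]
    status: str = "resolved"  # "resolved" | "undetermined"

    @property
    def name(self) -> str:
        return self.extremity.name

    def labels(self) -> list[str]:
        return [i.label for i in self.yprime_instances]


# ---------------------------------------------------------------------------
# Telomere tract detection


def detect_telomere_tract(
    sequence: str, config: RunConfig | None = None, name: str = "",
) -> TelomereTract | None:
    """Maximal terminal telomeric run on a canonical-frame sequence.

    Windows of ``telomericity_window`` bp (step 1) scoring >=
    ``telomericity_threshold`` are telomeric; gaps of up to ``tract_bridge``
    bp between telomeric windows are bridged.  Returns None when the
    terminal run is shorter than ``min_tract``.
    """
    config = config or RunConfig()
    w = config.telomericity_window
    n = len(sequence)
    if n < w:
        return None
    profile = telomericity_profile(sequence, w)
    mask = profile >= config.telomericity_threshold
    if not mask.any():
        return None
    last = len(mask) - 1
    # the tract must abut the sequence end: the last window (covering the
    # final w bases) must be telomeric, allowing a bridged terminal gap
    idx = last
    if not mask[idx]:
        back = 0
        while idx > 0 and not mask[idx] and back <= config.tract_bridge:
            idx -= 1
            back += 1
        if not mask[idx]:
            return None
    # walk left over telomeric windows, bridging short gaps
    start = idx
    i = idx
    while i > 0:
        j = i - 1
        gap = 0
        while j >= 0 and not mask[j] and gap <= config.tract_bridge:
            j -= 1
            gap += 1
        if j >= 0 and mask[j] and gap <= config.tract_bridge:
            i = j
            start = j
        else:
            break
    length = n - start
    if length < config.min_tract:
        return None
    return TelomereTract(extremity=name, interval=Interval(start, n))


# ---------------------------------------------------------------------------
# Y' and X detection


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _gap_is_telomeric_seed(seq: str, start: int, end: int,
                           config: RunConfig) -> bool:
    """True when [start, end) contains a telomeric stretch >= 30 bp."""
    if end - start < 30:
        return False
    gap = seq[start:end]
    prof = telomericity_profile(gap, min(30, len(gap)))
    return bool(len(prof) and prof.max() >= config.telomericity_threshold)


def yprime_instances_from_hits(
    canonical_seq: str, hits: list[align.Hit], config: RunConfig, ext_name: str,
) -> list[YPrimeInstance]:
    """Union of filtered alignments, split into instances at interstitial
    telomeric seeds; centromere->telomere indexing."""
    # Y' elements are oriented relative to the telomere: only plus-strand
    # alignments in the canonical frame count
    kept = [(h.sstart, h.send) for h in hits
            if h.strand == "+" and h.length > config.yprime_min_aln_len]
    unions = _union_intervals(kept)
    # join consecutive unions unless separated by a telomeric seed
    joined: list[list[int]] = []
    for s, e in unions:
        if joined and not _gap_is_telomeric_seed(canonical_seq, joined[-1][1], s, config) \
           and s - joined[-1][1] <= 500:
            joined[-1][1] = e
        else:
            joined.append([s, e])
    instances = []
    for idx, (s, e) in enumerate(joined):
        # alignments can extend a few bases into the flanking interstitial
        # telomeric seeds; trim terminal {T,G}-only runs (capped) so the two
        # copies of one variant always excise with identical content
        s0, e0 = s, e
        while e > s and e0 - e < 30 and canonical_seq[e - 1] in "TG":
            e -= 1
        while e > s and s - s0 < 30 and canonical_seq[s] in "TG":
            s += 1
        if e - s < 100:
            s, e = s0, e0
        instances.append(YPrimeInstance(
            extremity=ext_name, interval=Interval(s, e), index=idx,
            sequence=canonical_seq[s:e]))
    return instances


def detect_yprime_instances(
    extremity: Extremity, yprime_library: YPrimeLibrary,
    config: RunConfig | None = None,
) -> list[YPrimeInstance]:
    """Y' instances on one extremity (library vs arm local alignment)."""
    config = config or RunConfig()
    if not yprime_library.variants:
        raise ValueError("empty Y' library")
    hits = align.blastn(
        queries=[(v.variant_id, v.sequence) for v in yprime_library.variants],
        subjects=[(extremity.name, extremity.canonical_sequence)])
    return yprime_instances_from_hits(
        extremity.canonical_sequence, hits, config, extremity.name)


def detect_x_element(
    extremity: Extremity, x_library: list[tuple[str, str]],
    config: RunConfig | None = None,
) -> Interval | None:
    """Best local alignment of an X library element covering >= 60 % of it."""
    config = config or RunConfig()
    hits = align.blastn(
        queries=x_library,
        subjects=[(extremity.name, extremity.canonical_sequence)])
    return _x_interval_from_hits(hits, {q: len(s) for q, s in x_library}, config)


def _x_interval_from_hits(
    hits: list[align.Hit], x_lengths: dict[str, int], config: RunConfig,
) -> Interval | None:
    best = None
    for h in hits:
        if h.strand != "+" or h.length < config.x_min_cov * x_lengths[h.query]:
            continue
        if best is None or h.bitscore > best.bitscore:
            best = h
    if best is None:
        return None
    return Interval(best.sstart, best.send)


def _condensed_equal(a: str, b: str, max_run: int = 4) -> bool:
    from .catalog import condense_homopolymers
    return condense_homopolymers(a, max_run) == condense_homopolymers(b, max_run)


def build_extremity_map(
    genome: Genome,
    yprime_library: YPrimeLibrary,
    x_library: list[tuple[str, str]],
    config: RunConfig | None = None,
) -> list[ExtremityMap]:
    """Annotate all 2N extremities of a genome in one pass.

    A single blastn run against all arms keeps the cost flat; an extremity
    with more than 5 Y' copies two of which are adjacent near-identical
    (equal after homopolymer condensation) is flagged "undetermined".
    """
    config = config or RunConfig()
    arms: dict[str, Extremity] = {}
    for chrom, side in genome.extremities():
        arms[f"{chrom}-{side}"] = arm_extremity(
            genome, chrom, side, config.extremity_window)
    subjects = [(name, ext.canonical_sequence) for name, ext in arms.items()]
    queries = [(v.variant_id, v.sequence) for v in yprime_library.variants] \
        if yprime_library.variants else []
    y_ids = {v.variant_id for v in yprime_library.variants}
    x_lengths = {q: len(s) for q, s in x_library}
    hits = align.blastn(queries=queries + list(x_library), subjects=subjects) \
        if (queries or x_library) else []
    by_arm: dict[str, list[align.Hit]] = {name: [] for name in arms}
    for h in hits:
        by_arm[h.subject].append(h)
    maps = []
    for name, ext in arms.items():
        seq = ext.canonical_sequence
        arm_hits = by_arm[name]
        tract = detect_telomere_tract(seq, config, name)
        y_hits = [h for h in arm_hits if h.query in y_ids]
        instances = yprime_instances_from_hits(seq, y_hits, config, name)
        x_hits = [h for h in arm_hits if h.query in x_lengths]
        if instances:  # X lies centromere-proximal to the Y' block
            x_hits = [h for h in x_hits if h.send <= instances[0].interval.start + 50]
        x_iv = _x_interval_from_hits(x_hits, x_lengths, config) if x_lengths else None
        status = "resolved"
        if len(instances) > 5:
            for a, b in zip(instances, instances[1:]):
                if _condensed_equal(a.sequence, b.sequence, config.condensation_max_run):
                    status = "undetermined"
                    break
        maps.append(ExtremityMap(
            extremity=ext, telomere_tract=tract, x_interval=x_iv,
            yprime_instances=instances, status=status))
    return maps


# ---------------------------------------------------------------------------
# Length distributions


@dataclass
class LengthDistribution:
    """Per-extremity telomere length samples with box-plot style summaries."""

    lengths: dict[str, list[int]] = field(default_factory=dict)

    def add(self, extremity: str, length: int) -> None:
        self.lengths.setdefault(extremity, []).append(length)

    def mean(self, extremity: str) -> float:
        vals = self.lengths.get(extremity, [])
        return float(np.mean(vals)) if vals else float("nan")

    def all_values(self) -> list[int]:
        return [v for vals in self.lengths.values() for v in vals]

    def summary(self) -> pd.DataFrame:
        rows = []
        for ext, vals in sorted(self.lengths.items()):
            arr = np.asarray(vals, dtype=float)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            iqr = q3 - q1
            rows.append({
                "extremity": ext, "n": len(arr), "mean": arr.mean(),
                "Q1": q1, "median": med, "Q3": q3,
                "whisker_low": q1 - 1.5 * iqr, "whisker_high": q3 + 1.5 * iqr,
            })
        return pd.DataFrame(rows)


def measure_assembly_telomere_lengths(
    genome: Genome, config: RunConfig | None = None,
) -> LengthDistribution:
    """One terminal tract length per extremity (0 when none is found)."""
    config = config or RunConfig()
    dist = LengthDistribution()
    for chrom, side in genome.extremities():
        ext = arm_extremity(genome, chrom, side, config.extremity_window)
        tract = detect_telomere_tract(ext.canonical_sequence, config, ext.name)
        dist.add(ext.name, tract.length if tract else 0)
    return dist


# ---------------------------------------------------------------------------
# Read-based telomere lengths


def extract_anchor_library(
    control_genome: Genome, control_maps: list[ExtremityMap],
    config: RunConfig | None = None,
) -> list[tuple[str, str]]:
    """One subtelomeric anchor per extremity, just centromere-proximal to the
    terminal telomere tract of the control assembly.

    Anchors that are near-identical to another extremity's anchor (>= the
    read-matching identity) cannot assign reads uniquely; they are still
    returned, and read assignment drops multi-anchor reads downstream.
    """
    config = config or RunConfig()
    anchors = []
    for emap in control_maps:
        if emap.telomere_tract is None:
            continue
        seq = emap.extremity.canonical_sequence
        end = emap.telomere_tract.interval.start
        start = end - config.anchor_length
        if start < 0:
            continue
        anchors.append((emap.name, seq[start:end]))
    return anchors


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def read_length_distribution(
    reads: list[tuple[str, str]],
    anchor_library: list[tuple[str, str]],
    config: RunConfig | None = None,
) -> LengthDistribution:
    """Per-extremity telomere lengths measured from anchored reads.

    A read contributes when exactly one anchor matches it (>= 90 % identity
    over the anchor) and the read runs from that anchor to its end through
    telomeric sequence; the contribution is the read's terminal tract
    length.  Reads matching zero or several anchors are dropped.
    """
    config = config or RunConfig()
    dist = LengthDistribution()
    if not reads or not anchor_library:
        return dist
    k = 21
    anchor_kmers = {name: _kmer_set(seq, k) for name, seq in anchor_library}
    anchor_seqs = dict(anchor_library)
    for _, read in reads:
        for oriented in (read, revcomp(read)):
            matches = _match_anchors(oriented, anchor_kmers, anchor_seqs, config, k)
            if not matches:
                continue
            if len(matches) > 1:
                break  # ambiguous read: drop
            name, anchor_end = matches[0]
            tract = detect_telomere_tract(oriented, config, name)
            if tract is None:
                break
            if tract.interval.start < anchor_end - 50 or \
               tract.interval.start > anchor_end + 100:
                break  # terminal tract does not abut the anchor
            dist.add(name, tract.length)
            break
    return dist


def _match_anchors(
    read: str, anchor_kmers: dict[str, set[str]], anchor_seqs: dict[str, str],
    config: RunConfig, k: int,
) -> list[tuple[str, int]]:
    read_kmers = _kmer_set(read, k)
    out = []
    for name, kmers in anchor_kmers.items():
        shared = len(read_kmers & kmers)
        if shared < 5:
            continue
        anchor = anchor_seqs[name]
        max_dist = int(len(anchor) * (1 - config.anchor_min_identity))
        res = edlib.align(anchor, read, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            continue
        matched = len(anchor) - res["editDistance"]
        if matched < config.anchor_min_match:
            continue
        end = res["locations"][0][1] + 1
        out.append((name, end))
    return out
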