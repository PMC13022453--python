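"""Control-vs-survivor rearrangement calling at chromosome ends.

Per-extremity Y' label strings (centromere->telomere) are aligned by
minimum edit distance; unmatched control labels are losses, unmatched
survivor labels are gains.  A gained label identical to its telomere-
adjacent neighbour is additionally a tandem amplification; a gained label
absent from the control catalog is a new variant, which is then tested for
mosaicism (full coverage by perfect >50 bp matches to known elements).
Terminal duplications (BIR-like) and chromosome circularization are called
at the sequence level, and clone summaries feed the group statistics
(Mann-Whitney, Student's t, Fisher's exact; all two-sided, uncorrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import align
from .annotate import ExtremityMap, detect_telomere_tract
from .config import RunConfig
from .io import Genome, revcomp


@dataclass
class AlterationEvent:
    kind: str  # loss | gain | tandem_amplification | new_variant |
    #            terminal_duplication | circularization | substitution
    extremity: str
    payload: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Positional Y' comparison


def _align_label_strings(a: list[str], b: list[str]) -> list[tuple[int | None, int | None]]:
    """Minimum-edit-distance alignment of two label strings.

    Costs: match 0, mismatch 1, indel 1.  Returns aligned index pairs
    (i, j) with None marking an indel.  Ties prefer diagonal moves, then
    deletion, keeping the traceback deterministic.
    """
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dp[i - 1, j - 1] + (0 if a[i - 1] == b[j - 1] else 1)
            dp[i, j] = min(sub, dp[i - 1, j] + 1, dp[i, j - 1] + 1)
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (0 if a[i - 1] == b[j - 1] else 1):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return pairs


def diff_extremity(
    control_map: ExtremityMap,
    survivor_map: ExtremityMap,
    control_labels: set[str] | None = None,
) -> list[AlterationEvent]:
    """Y' structure events at one extremity (control vs survivor)."""
    if control_map.name != survivor_map.name:
        raise ValueError(
            f"maps from different extremities: {control_map.name} vs {survivor_map.name}")
    if control_map.status != "resolved" or survivor_map.status != "resolved":
        return []
    ext = control_map.name
    a = [i.label or "?" for i in control_map.yprime_instances]
    b = [i.label or "?" for i in survivor_map.yprime_instances]
    if control_labels is None:
        control_labels = set(a)
    events: list[AlterationEvent] = []
    for i, j in _align_label_strings(a, b):
        if i is not None and j is not None:
            if a[i] != b[j]:
                events.append(AlterationEvent("loss", ext, {"label": a[i], "position": i}))
                events.append(_gain_event(ext, b, j, control_labels))
                events.append(AlterationEvent(
                    "substitution", ext,
                    {"lost": a[i], "gained": b[j], "position": j}))
        elif i is not None:
            events.append(AlterationEvent("loss", ext, {"label": a[i], "position": i}))
        else:
            events.append(_gain_event(ext, b, j, control_labels))
            # a gained label identical to its telomere-adjacent neighbour
            if j + 1 < len(b) and b[j + 1] == b[j]:
                events.append(AlterationEvent(
                    "tandem_amplification", ext, {"label": b[j], "position": j}))
    return events


def _gain_event(ext: str, b: list[str], j: int, control_labels: set[str]) -> AlterationEvent:
    return AlterationEvent("gain", ext, {
        "label": b[j], "position": j, "novel": b[j] not in control_labels})


def diff_genomes(
    control_maps: list[ExtremityMap],
    survivor_maps: list[ExtremityMap],
    control_labels: set[str] | None = None,
) -> tuple[list[AlterationEvent], list[str]]:
    """All per-extremity Y' events; returns (events, skipped_extremities)."""
    by_name = {m.name: m for m in survivor_maps}
    if control_labels is None:
        control_labels = {i.label for m in control_maps
                          for i in m.yprime_instances if i.label}
    events: list[AlterationEvent] = []
    skipped: list[str] = []
    for cm in control_maps:
        sm = by_name.get(cm.name)
        if sm is None:
            continue
        if cm.status != "resolved" or sm.status != "resolved":
            skipped.append(cm.name)
            continue
        events.extend(diff_extremity(cm, sm, control_labels))
    new_events = [e for e in events if e.kind == "gain" and e.payload.get("novel")]
    for e in new_events:
        events.append(AlterationEvent("new_variant", e.extremity,
                                      {"label": e.payload["label"]}))
    return events, skipped


# ---------------------------------------------------------------------------
# Mosaic explanation


@dataclass
class MosaicDecomposition:
    segments: list[dict[str, Any]]  # donor, donor_start, target_start, length
    coverage: float
    donors: list[str]
    is_mosaic: bool


def explain_mosaic(
    new_sequence: str,
    catalog_sequences: dict[str, str],
    min_exact: int = 51,
) -> MosaicDecomposition | None:
    """Cover a new Y' sequence with perfect >=51 bp matches to known elements.

    Maximal exact matches are enumerated against every catalog sequence in
    both orientations, then a greedy longest-first (leftmost tie-break)
    interval cover is built on the target.  A decomposition is returned only
    when the cover is complete.
    """
    candidates: list[tuple[int, int, int, str, int, str]] = []
    # (length, target_start, -, donor, donor_start, strand)
    for donor, seq in catalog_sequences.items():
        for strand, dseq in (("+", seq), ("-", revcomp(seq))):
            for ts, ds, ln in align.maximal_exact_matches(new_sequence, dseq, min_exact):
                candidates.append((ln, ts, ts + ln, donor, ds, strand))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
    n = len(new_sequence)
    covered = np.zeros(n, dtype=bool)
    chosen = []
    for ln, ts, te, donor, ds, strand in candidates:
        if covered[ts:te].all():
            continue
        covered[ts:te] = True
        chosen.append((ts, te, donor, ds, strand, ln))
    coverage = float(covered.mean())
    if coverage < 1.0:
        return None
    # trim overlaps so reported segments partition the target
    chosen.sort()
    segments = []
    prev_end = 0
    for ts, te, donor, ds, strand, ln in chosen:
        s = max(ts, prev_end)
        if s >= te:
            continue
        segments.append({
            "donor": donor, "strand": strand,
            "donor_start": ds + (s - ts), "target_start": s, "length": te - s,
        })
        prev_end = te
    donors = sorted({s["donor"] for s in segments})
    in_order = all(
        segments[i]["donor_start"] <= segments[i + 1]["donor_start"]
        for i in range(len(segments) - 1)) and len(donors) == 1
    is_mosaic = len(donors) >= 2 or (len(donors) == 1 and not in_order)
    return MosaicDecomposition(
        segments=segments, coverage=coverage, donors=donors, is_mosaic=is_mosaic)


# ---------------------------------------------------------------------------
# Terminal duplications


def _arm_view(genome: Genome, ext_name: str) -> str:
    chrom, side = ext_name.rsplit("-", 1)
    seq = genome.chromosomes[chrom]
    return seq if side == "R" else revcomp(seq)


def _x_start_in_arm(emap: ExtremityMap, arm_len: int) -> int | None:
    if emap.x_interval is None:
        return None
    w = len(emap.extremity.canonical_sequence)
    return arm_len - (w - emap.x_interval.start)


def detect_terminal_duplication(
    control_genome: Genome,
    survivor_genome: Genome,
    control_maps: list[ExtremityMap],
    survivor_maps: list[ExtremityMap],
    config: RunConfig | None = None,
) -> tuple[list[AlterationEvent], list[str]]:
    """BIR-like terminal duplications, one extremity at a time.

    The ``upstream_window`` bp centromere-proximal to the X element are
    compared with the control; on deviation the divergent terminal segment
    is walked junction by junction: each junction is located by maximal
    exact extension from an upstream anchor, mapped onto a donor arm, and
    its homology measured as the longest exact match spanning the junction.
    Nested duplications yield one event per junction.  Extremities lacking
    an X on either genome are skipped and reported.
    """
    config = config or RunConfig()
    cmaps = {m.name: m for m in control_maps}
    smaps = {m.name: m for m in survivor_maps}
    donor_views = {f"{c}-{s}": _arm_view(control_genome, f"{c}-{s}")
                   for c, s in control_genome.extremities()}
    events: list[AlterationEvent] = []
    skipped: list[str] = []
    for name, cm in cmaps.items():
        sm = smaps.get(name)
        if sm is None:
            continue
        chrom = name.rsplit("-", 1)[0]
        if chrom not in survivor_genome.chromosomes:
            continue
        ctrl_view = donor_views[name]
        surv_view = _arm_view(survivor_genome, name)
        cx = _x_start_in_arm(cm, len(ctrl_view))
        sx = _x_start_in_arm(sm, len(surv_view))
        if cx is None or sx is None:
            skipped.append(name)
            continue
        w = config.upstream_window
        if ctrl_view[max(0, cx - w):cx] == surv_view[max(0, sx - w):sx]:
            continue
        events.extend(_walk_junctions(
            name, ctrl_view, cx, surv_view, donor_views, config))
    return events, skipped


def _find_anchor(ctrl_view: str, cx: int, surv_view: str,
                 config: RunConfig) -> tuple[int, int] | None:
    """Locate a control-specific anchor upstream of X on the survivor arm.

    Returns (control_pos, survivor_pos) of the anchor start, stepping
    centromere-proximal until the anchor is found exactly once.
    """
    probe_len = 2000
    off = config.upstream_window
    while True:
        start = cx - off - probe_len
        if start < 0:
            return None
        probe = ctrl_view[start : start + probe_len]
        pos = surv_view.find(probe)
        if pos >= 0 and surv_view.find(probe, pos + 1) < 0:
            return start, pos
        off += config.upstream_window
    return None


def _walk_junctions(
    name: str, ctrl_view: str, cx: int, surv_view: str,
    donor_views: dict[str, str], config: RunConfig,
) -> list[AlterationEvent]:
    anchor = _find_anchor(ctrl_view, cx, surv_view, config)
    if anchor is None:
        return []
    p, q = anchor
    events: list[AlterationEvent] = []
    src_view, src_name, src_pos = ctrl_view, name, p
    surv_pos = q
    for _depth in range(8):  # nesting depth bound
        # maximal exact extension to the junction
        _, right = align.extend_match(src_view, surv_view, src_pos, surv_pos)
        jc = src_pos + right     # junction on the current source arm
        js = surv_pos + right    # junction on the survivor arm
        tail = surv_view[js:]
        if not tail:
            break
        t = detect_telomere_tract(surv_view, config, name)
        if t is not None and js >= t.interval.start:
            break  # remaining divergence is the terminal telomere itself
        probe = tail[:1000]
        if len(probe) < 200:
            break
        donor_hit = None
        for dname, dview in donor_views.items():
            pos = dview.find(probe)
            if pos >= 0:
                donor_hit = (dname, pos)
                break
        if donor_hit is None:
            events.append(AlterationEvent(
                "unexplained_divergence", name, {"survivor_pos": js}))
            break
        dname, b = donor_hit
        dview = donor_views[dname]
        # junction homology: longest exact match spanning the junction
        h = 0
        while jc - 1 - h >= 0 and b - 1 - h >= 0 and \
                src_view[jc - 1 - h] == dview[b - 1 - h] != "N":
            h += 1
        events.append(AlterationEvent(
            "terminal_duplication", name,
            {"donor": dname, "span": len(dview) - b, "homology": h,
             "survivor_junction": js}))
        src_view, src_name, src_pos = dview, dname, b
        surv_pos = js
    return events


# ---------------------------------------------------------------------------
# Circularization


def detect_circularization(
    survivor_genome: Genome,
    control_genome: Genome,
    config: RunConfig | None = None,
) -> tuple[list[AlterationEvent], list[str]]:
    """Chromosomes with both telomeres missing whose sequence is a rotation
    of a control-chromosome interior joined through shared homology."""
    config = config or RunConfig()
    events: list[AlterationEvent] = []
    anomalies: list[str] = []
    for chrom, seq in survivor_genome.chromosomes.items():
        tl = detect_telomere_tract(revcomp(seq[: config.extremity_window]), config)
        tr = detect_telomere_tract(seq[-config.extremity_window:], config)
        if tl is not None and tr is not None:
            continue
        if (tl is None) != (tr is None):
            anomalies.append(chrom)
            continue
        ss = seq + seq
        called = False
        for cname, cseq in control_genome.chromosomes.items():
            mid = len(cseq) // 2
            half = min(5000, len(cseq) // 4)
            anchor = cseq[mid - half : mid + half]
            pos = ss.find(anchor)
            if pos < 0:
                continue
            left, right = align.extend_match(cseq, ss, mid - half, pos)
            span = left + right  # right includes the anchor itself
            if span >= len(seq):
                events.append(AlterationEvent(
                    "circularization", f"{cname}-L/{cname}-R",
                    {"survivor_chromosome": chrom, "control_chromosome": cname,
                     "homology": span - len(seq)}))
                called = True
                break
        if not called:
            anomalies.append(chrom)
    return events, anomalies


# ---------------------------------------------------------------------------
# Clone summaries and group statistics

Y_STRUCTURE_KINDS = ("loss", "gain", "tandem_amplification", "new_variant")


@dataclass
class CloneSummary:
    clone: str
    n_lost: int
    n_gained: int
    n_tandem: int
    n_new: int
    n_terminal_dup: int
    n_circularization: int
    affected_extremities: int
    n_considered: int
    fraction_altered: float
    altered_by_class: dict[str, dict[str, int]]
    # {"x_only": {"altered": a, "total": t}, "yprime": {...}} from CONTROL maps


def summarize_clone(
    clone: str,
    events: Sequence[AlterationEvent],
    control_maps: list[ExtremityMap],
    skipped: Sequence[str] = (),
) -> CloneSummary:
    """Per-clone event totals and per-extremity-class alteration indicators.

    Extremity class (X-only vs Y'-bearing) comes from the control map;
    undetermined extremities are excluded from all denominators.
    """
    kinds = [e.kind for e in events]
    affected = {e.extremity for e in events if e.kind in Y_STRUCTURE_KINDS}
    considered = [m for m in control_maps
                  if m.status == "resolved" and m.name not in set(skipped)]
    klass = {m.name: ("yprime" if m.yprime_instances else "x_only")
             for m in considered}
    by_class = {"x_only": {"altered": 0, "total": 0},
                "yprime": {"altered": 0, "total": 0}}
    structural_ext = {e.extremity for e in events
                      if e.kind in Y_STRUCTURE_KINDS + ("terminal_duplication",)}
    for name, kl in klass.items():
        by_class[kl]["total"] += 1
        if name in structural_ext:
            by_class[kl]["altered"] += 1
    n_considered = len(considered)
    return CloneSummary(
        clone=clone,
        n_lost=kinds.count("loss"),
        n_gained=kinds.count("gain"),
        n_tandem=kinds.count("tandem_amplification"),
        n_new=kinds.count("new_variant"),
        n_terminal_dup=kinds.count("terminal_duplication"),
        n_circularization=kinds.count("circularization"),
        affected_extremities=len(affected),
        n_considered=n_considered,
        fraction_altered=(len(structural_ext & set(klass)) / n_considered
                          if n_considered else float("nan")),
        altered_by_class=by_class,
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value; exhaustive permutation null for
    small samples (exact even with ties); NaN for degenerate input."""
    x, y = list(x), list(y)
    if len(x) < 2 or len(y) < 2:
        return float("nan")
    if len(set(x) | set(y)) == 1:
        return float("nan")
    if len(x) <= 8 and len(y) <= 8:
        method = sps.PermutationMethod(n_resamples=200_000, rng=0)
    else:
        method = "auto"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def students_t(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = list(x), list(y)
    if len(x) < 2 or len(y) < 2 or (np.std(x) == 0 and np.std(y) == 0):
        return float("nan")
    return float(sps.ttest_ind(x, y).pvalue)


def fisher(table: Sequence[Sequence[int]]) -> float:
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def class_alteration_frequencies(summaries: Sequence[CloneSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for kl, d in s.altered_by_class.items():
            rows.append({"clone": s.clone, "class": kl,
                         "altered": d["altered"], "total": d["total"],
                         "frequency": d["altered"] / d["total"] if d["total"] else np.nan})
    return pd.DataFrame(rows)


def compare_groups(
    summaries_by_group: dict[str, list[CloneSummary]],
    type_counts: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Statistics table across clone groups.

    Per-clone X-only vs Y'-bearing alteration frequencies are compared with
    a two-sided Mann-Whitney test within each group; fraction-altered is
    compared between groups with Student's t; optional survivor-type counts
    (e.g. elongated vs not, per genotype) with Fisher's exact test.  All
    p-values are two-sided and uncorrected.
    """
    rows = []
    for group, summaries in summaries_by_group.items():
        freqs = class_alteration_frequencies(summaries)
        x_only = freqs[freqs["class"] == "x_only"]["frequency"].dropna().tolist()
        yp = freqs[freqs["class"] == "yprime"]["frequency"].dropna().tolist()
        rows.append({
            "comparison": f"{group}: altered frequency, Y'-bearing vs X-only",
            "test": "mannwhitney",
            "value_a": float(np.mean(yp)) if yp else np.nan,
            "value_b": float(np.mean(x_only)) if x_only else np.nan,
            "p": mann_whitney(yp, x_only),
        })
    groups = list(summaries_by_group)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            fa = [s.fraction_altered for s in summaries_by_group[ga]]
            fb = [s.fraction_altered for s in summaries_by_group[gb]]
            rows.append({
                "comparison": f"fraction altered: {ga} vs {gb}",
                "test": "t",
                "value_a": float(np.nanmean(fa)) if fa else np.nan,
                "value_b": float(np.nanmean(fb)) if fb else np.nan,
                "p": students_t(fa, fb),
            })
    if type_counts:
        names = list(type_counts)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                rows.append({
                    "comparison": f"type proportions: {a} vs {b}",
                    "test": "fisher",
                    "value_a": np.nan, "value_b": np.nan,
                    "p": fisher([list(type_counts[a]), list(type_counts[b])]),
                })
    return pd.DataFrame(rows)
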