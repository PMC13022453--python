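"""Y' variant catalog: condensation, similarity, labels, clusters.

Nanopore assemblies make most residual errors in homopolymers, so Y'
sequences are first *condensed* (every base run longer than 4 collapsed to
4).  Pairwise similarity between condensed sequences is

    sim = %identity * alignment_length / alignment_span,

where the span is the alignment length plus the unaligned flanking regions
of both sequences, so length differences are penalized symmetrically.  Two
elements share a *label* (sequence variant) when sim > 99.9; labels are the
connected components of that graph.  Variants are then grouped by
agglomerative clustering (average linkage on 100 - sim), with the cluster
count chosen at the elbow of the silhouette-vs-k curve.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from . import align
from .annotate import YPrimeInstance

_RUN_RE = re.compile(r"(.)\1*")


def condense_homopolymers(seq: str, max_run: int = 4) -> str:
    """Collapse every homopolymer run longer than ``max_run`` to ``max_run``."""
    return _RUN_RE.sub(lambda m: m.group(0)[: max_run], seq)


def _sim_from_hit(h: align.Hit) -> float:
    span = h.length + (h.qstart + h.qlen - h.qend) + (h.sstart + h.slen - h.send)
    return h.pident * h.length / span


def pairwise_similarity(a: str, b: str) -> float:
    """sim in [0, 100] between two condensed sequences (best local alignment)."""
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 100.0
    hits = align.blastn([("a", a)], [("b", b)])
    if not hits:
        return 0.0
    best = align.best_hit_per_pair(hits)[("a", "b")]
    return min(100.0, _sim_from_hit(best))


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 100, range [0, 100]

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def submatrix(self, keep: list[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(k) for k in keep]
        return SimilarityMatrix(list(keep), self.values[np.ix_(idx, idx)])


def similarity_matrix(sequences: dict[str, str]) -> SimilarityMatrix:
    """All-vs-all similarity of condensed sequences in one blastn run."""
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences")
    records = [(i, sequences[i]) for i in ids]
    hits = align.blastn(records, records)
    best = align.best_hit_per_pair(hits)
    n = len(ids)
    values = np.zeros((n, n))
    np.fill_diagonal(values, 100.0)
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            b = ids[j]
            if sequences[a] == sequences[b]:
                s = 100.0
            else:
                cand = [best.get((a, b)), best.get((b, a))]
                cand = [c for c in cand if c is not None]
                s = min(100.0, max((_sim_from_hit(c) for c in cand), default=0.0))
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids, values)


@dataclass
class YPrimeVariant:
    label: str
    members: list[str]                 # instance ids
    representative: str                # condensed sequence of the longest member
    representative_length: int         # length of the longest *uncondensed* member
    family: str                        # "short" | "long" | "intermediate"
    fragile: bool = False              # component with internal sim < threshold


SHORT_BAND = (4800, 5700)
LONG_BAND = (6300, 7100)


def family_from_length(length: int) -> str:
    if SHORT_BAND[0] <= length <= SHORT_BAND[1]:
        return "short"
    if LONG_BAND[0] <= length <= LONG_BAND[1]:
        return "long"
    return "intermediate"


def assign_labels(
    matrix: SimilarityMatrix,
    sequences: dict[str, str],
    raw_lengths: dict[str, int] | None = None,
    threshold: float = 99.9,
    prefix: str = "V",
) -> list[YPrimeVariant]:
    """Labels = connected components of the sim > threshold graph.

    sim > threshold is not transitive; single-linkage closure is used, and a
    component whose minimum internal similarity falls below the threshold is
    flagged ``fragile``.  Label ids are deterministic: components ordered by
    their smallest member id.
    """
    raw_lengths = raw_lengths or {i: len(sequences[i]) for i in matrix.ids}
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] > threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j])
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    variants = []
    for k, comp in enumerate(comps):
        members = sorted(comp)
        rep = max(members, key=lambda m: (len(sequences[m]), m))
        sub = matrix.submatrix(members)
        internal = sub.values[np.triu_indices(len(members), k=1)]
        fragile = bool(len(internal) and internal.min() <= threshold)
        length = raw_lengths[rep]
        variants.append(YPrimeVariant(
            label=f"{prefix}{k + 1:02d}", members=members,
            representative=sequences[rep], representative_length=length,
            family=family_from_length(length), fragile=fragile))
    return variants


def label_instances(
    instances: list[YPrimeInstance],
    threshold: float = 99.9,
    max_run: int = 4,
    prefix: str = "V",
) -> tuple[list[YPrimeVariant], SimilarityMatrix]:
    """Catalog a control genome's Y' instances; writes labels onto them."""
    ids = [f"{inst.extremity}:{inst.index}" for inst in instances]
    condensed = {i: condense_homopolymers(inst.sequence, max_run)
                 for i, inst in zip(ids, instances)}
    raw_lengths = {i: inst.length for i, inst in zip(ids, instances)}
    matrix = similarity_matrix(condensed)
    variants = assign_labels(matrix, condensed, raw_lengths, threshold, prefix)
    by_member = {m: v.label for v in variants for m in v.members}
    for i, inst in zip(ids, instances):
        inst.label = by_member[i]
    return variants, matrix


def label_survivor_instances(
    instances: list[YPrimeInstance],
    catalog: list[YPrimeVariant],
    threshold: float = 99.9,
    max_run: int = 4,
) -> list[YPrimeInstance]:
    """Transfer control labels to survivor instances; unmatched instances get
    fresh ``new*`` labels (grouped among themselves at the same threshold)."""
    if not instances:
        return instances
    cond = [condense_homopolymers(inst.sequence, max_run) for inst in instances]
    reps = [(v.label, v.representative) for v in catalog]
    queries = [(f"q{i}", c) for i, c in enumerate(cond)]
    hits = align.blastn(queries, reps) if reps else []
    best = align.best_hit_per_pair(hits)
    rep_seqs = dict(reps)
    unmatched: list[int] = []
    for i, inst in enumerate(instances):
        best_label, best_sim = None, 0.0
        for label, rep in reps:
            if cond[i] == rep_seqs[label]:
                best_label, best_sim = label, 100.0
                break
            h = best.get((f"q{i}", label))
            if h is None:
                continue
            s = min(100.0, _sim_from_hit(h))
            if s > best_sim:
                best_label, best_sim = label, s
        if best_label is not None and best_sim > threshold:
            inst.label = best_label
        else:
            unmatched.append(i)
    if unmatched:
        if len(unmatched) == 1:
            instances[unmatched[0]].label = "new01"
        else:
            sub = {f"n{i}": cond[i] for i in unmatched}
            m = similarity_matrix(sub)
            novel = assign_labels(m, sub, threshold=threshold, prefix="new")
            by_member = {mm: v.label for v in novel for mm in v.members}
            for i in unmatched:
                instances[i].label = by_member[f"n{i}"]
    return instances


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]          # variant label -> cluster id (1-based)
    chosen_k: int
    silhouette_by_k: dict[int, float]
    argmax_k: int
    linkage_method: str = "average"


def cluster_variants(matrix: SimilarityMatrix) -> ClusterAssignment:
    """Agglomerative clustering of variants on distance = 100 - sim.

    Average linkage; k chosen at the elbow (maximum negative curvature) of
    the silhouette-vs-k curve, falling back to the silhouette argmax when
    the curve has no interior bend; ties go to the smaller k.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("clustering needs >= 3 variants")
    dist = 100.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method="average")
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(2, n):
        labels = fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(set(labels)) < 2:
            sil[k] = float("nan")
            continue
        sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    ks = sorted(k for k in sil if np.isfinite(sil[k]))
    argmax_k = max(ks, key=lambda k: (sil[k], -k))
    vals = [sil[k] for k in ks]
    # The elbow is where the silhouette stops improving with k: the interior
    # local maximum with the highest silhouette (raw second-difference
    # maxima latch onto spurious low-k spikes on multi-scale similarity
    # structures).  A unimodal profile has no interior peak; use its argmax.
    interior_peaks = [
        ks[i] for i in range(1, len(ks) - 1)
        if vals[i] > vals[i - 1] and vals[i] >= vals[i + 1]
    ]
    if interior_peaks:
        chosen = max(interior_peaks, key=lambda k: (sil[k], -k))
    else:
        chosen = argmax_k
    labels = labels_by_k[chosen]
    # renumber clusters deterministically by first appearance
    order: dict[int, int] = {}
    assignment = {}
    for vid, lab in zip(matrix.ids, labels):
        if lab not in order:
            order[lab] = len(order) + 1
        assignment[vid] = order[lab]
    return ClusterAssignment(
        assignment=assignment, chosen_k=chosen,
        silhouette_by_k=sil, argmax_k=argmax_k)


@dataclass
class FamilyLengthStats:
    family: str
    n: int
    min: int
    max: int
    mean: float


def variant_length_stats(
    variants: list[YPrimeVariant],
) -> tuple[list[FamilyLengthStats], list[str]]:
    """Per-family min/max/mean of variant lengths, plus intermediates.

    Returns (stats, flagged) where ``flagged`` lists labels outside both
    family length bands.
    """
    stats = []
    flagged = [v.label for v in variants if v.family == "intermediate"]
    for family in ("short", "long"):
        lengths = [v.representative_length for v in variants if v.family == family]
        if not lengths:
            continue
        stats.append(FamilyLengthStats(
            family=family, n=len(lengths), min=min(lengths), max=max(lengths),
            mean=float(np.mean(lengths))))
    return stats, flagged
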