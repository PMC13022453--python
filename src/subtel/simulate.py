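"""Synthetic control/survivor genomes with a planted-truth ledger.

Emulates the telomere/subtelomere architecture of a laboratory budding
yeast strain: 16 chromosomes, an X element at every extremity, 0-6 tandem
Y' elements (short ~5.2 kb / long ~6.7 kb families) separated by short
interstitial telomeric seeds, and terminal tracts of degenerate TG(1-3)
repeats (~350 bp in a control-like genome).  Rearrangements are planted on
top: Y' loss/gain/tandem duplication, mosaic Y' creation, BIR-like terminal
duplications through planted homology cassettes, chromosome circularization,
and rolling-circle telomere amplification from 50-600 bp circle units.

Every planted feature is recorded in a :class:`TruthLedger` that describes
the emitted FASTA exactly, so downstream detectors can be scored against
known truth without external data.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .grammar import gen_telomere_repeats
from .io import Genome, revcomp

ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]

BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitute bases at the given per-base rate (length preserved)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Y' library


@dataclass(frozen=True)
class YPrimeLibraryVariant:
    variant_id: str
    family: str  # "short" | "long"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class YPrimeLibrary:
    variants: list[YPrimeLibraryVariant]

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant_ids must be unique")

    def by_id(self, variant_id: str) -> YPrimeLibraryVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    @property
    def ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


@dataclass
class LibraryConfig:
    """Hierarchical Y' library: families -> subfamilies -> variants.

    Subfamily ancestors diverge from the family ancestor at
    ``subfamily_divergence`` (singleton subfamilies are genuine outliers and
    diverge ``singleton_divergence_mult`` times as much); variants diverge
    from their subfamily ancestor at ``variant_divergence``.  Subfamily
    lengths are graded deterministically around the family mean.  Defaults
    give 20 variants in 11 subfamilies (6 short + 5 long), mirroring a
    control strain with two tight size classes, finer sub-structure, and
    outliers alongside the larger groups.
    """

    short_mean_length: int = 5470
    long_mean_length: int = 6670
    short_subfamily_sizes: tuple[int, ...] = (2, 2, 2, 2, 1, 1)
    long_subfamily_sizes: tuple[int, ...] = (2, 2, 2, 2, 2)
    subfamily_divergence: float = 0.06
    singleton_divergence_mult: float = 2.0
    variant_divergence: float = 0.001
    subfamily_length_step: int = 60
    variant_length_jitter: int = 10
    explicit_lengths: dict[str, int] | None = None  # variant_id -> length override


def build_yprime_library(config: LibraryConfig, rng: np.random.Generator) -> YPrimeLibrary:
    variants: list[YPrimeLibraryVariant] = []
    idx = 0
    for family, mean_len, sizes in (
        ("short", config.short_mean_length, config.short_subfamily_sizes),
        ("long", config.long_mean_length, config.long_subfamily_sizes),
    ):
        # Family ancestor slightly longer than any emitted variant so that
        # variant lengths can be realized by trimming.
        ancestor = _random_dna(rng, mean_len + 4 * config.subfamily_length_step + 200)
        for s, n_var in enumerate(sizes):
            div = config.subfamily_divergence
            if n_var == 1:
                div *= config.singleton_divergence_mult
            sub_anc = _mutate(ancestor, rng, div)
            sub_len = mean_len + (s - len(sizes) // 2) * config.subfamily_length_step
            for _ in range(n_var):
                vid = f"Yp{idx + 1:02d}"
                idx += 1
                length = sub_len + int(
                    rng.integers(-config.variant_length_jitter,
                                 config.variant_length_jitter + 1))
                if config.explicit_lengths and vid in config.explicit_lengths:
                    length = config.explicit_lengths[vid]
                seq = _mutate(sub_anc[:length], rng, config.variant_divergence)
                variants.append(YPrimeLibraryVariant(vid, family, seq))
    return YPrimeLibrary(variants)


# ---------------------------------------------------------------------------
# Truth ledger


@dataclass
class PlantedYPrime:
    variant_id: str
    sequence: str


@dataclass
class PlantedExtremity:
    chromosome: str
    side: str
    x_sequence: str
    seeds: list[str] = field(default_factory=list)       # seeds[i] precedes yprimes[i]
    yprimes: list[PlantedYPrime] = field(default_factory=list)
    tract: str = ""

    @property
    def name(self) -> str:
        return f"{self.chromosome}-{self.side}"

    def arm_sequence(self) -> str:
        """Canonical-frame arm: X + (seed + Y')* + terminal tract."""
        parts = [self.x_sequence]
        for seed, yp in zip(self.seeds, self.yprimes):
            parts.append(seed)
            parts.append(yp.sequence)
        parts.append(self.tract)
        return "".join(parts)

    def labels(self) -> list[str]:
        return [yp.variant_id for yp in self.yprimes]

    def feature_intervals(self, chrom_length: int) -> dict[str, tuple[int, int]]:
        """Canonical full-chromosome-frame intervals of planted features.

        Keys: 'X', 'Y0'..'Yn', 'seed0'.., 'tract'.  Position ``chrom_length``
        is the chromosome end in the canonical frame.
        """
        arm = self.arm_sequence()
        end = chrom_length
        start = end - len(arm)
        out: dict[str, tuple[int, int]] = {}
        pos = start
        out["X"] = (pos, pos + len(self.x_sequence))
        pos += len(self.x_sequence)
        for i, (seed, yp) in enumerate(zip(self.seeds, self.yprimes)):
            out[f"seed{i}"] = (pos, pos + len(seed))
            pos += len(seed)
            out[f"Y{i}"] = (pos, pos + len(yp.sequence))
            pos += len(yp.sequence)
        out["tract"] = (pos, pos + len(self.tract))
        return out


@dataclass
class PlantedEvent:
    kind: str
    extremity: str  # "<chrom>-<side>"; circularization uses "<chrom>-L/<chrom>-R"
    payload: dict[str, Any] = field(default_factory=dict)


@dataclass
class PlantedCircle:
    circle_id: str
    unit: str
    origin: str | None  # extremity name in the control, if excised from it
    placements: list[dict[str, Any]] = field(default_factory=list)
    # each placement: {"extremity", "phase", "copies"}


@dataclass
class TruthLedger:
    genome_name: str
    extremities: dict[str, PlantedExtremity]
    cores: dict[str, str]  # chromosome -> core sequence between the two arms
    library: YPrimeLibrary
    cassettes: dict[str, dict[str, Any]] = field(default_factory=dict)
    events: list[PlantedEvent] = field(default_factory=list)
    circles: list[PlantedCircle] = field(default_factory=list)
    circular_chromosomes: list[str] = field(default_factory=list)
    x_ancestor: str = ""

    def assemble(self) -> Genome:
        """Rebuild the FASTA from planted parts (arms + cores)."""
        chroms: dict[str, str] = {}
        for chrom, core in self.cores.items():
            if chrom in self.circular_chromosomes:
                continue  # assembled separately during planting
            left = self.extremities[f"{chrom}-L"].arm_sequence()
            right = self.extremities[f"{chrom}-R"].arm_sequence()
            chroms[chrom] = revcomp(left) + core + right
        return Genome(name=self.genome_name, chromosomes=chroms)

    def verify(self, genome: Genome) -> None:
        """Assert that every planted interval re-extracts identically."""
        for ext in self.extremities.values():
            if ext.chromosome in self.circular_chromosomes:
                continue
            chrom_seq = genome.chromosomes[ext.chromosome]
            canon = chrom_seq if ext.side == "R" else revcomp(chrom_seq)
            arm = ext.arm_sequence()
            if canon[len(canon) - len(arm):] != arm:
                raise AssertionError(f"ledger mismatch at {ext.name}")

    def expected_counts(self) -> dict[str, int]:
        n_inst = sum(len(e.yprimes) for e in self.extremities.values())
        n_ends = sum(1 for e in self.extremities.values() if e.yprimes)
        return {"yprime_instances": n_inst, "ends_with_yprime": n_ends}

    def to_json(self, path: str | Path) -> None:
        data = {
            "genome_name": self.genome_name,
            "extremities": {k: asdict(v) for k, v in self.extremities.items()},
            "cassettes": self.cassettes,
            "events": [asdict(e) for e in self.events],
            "circles": [asdict(c) for c in self.circles],
            "circular_chromosomes": self.circular_chromosomes,
            "library": [asdict(v) for v in self.library.variants],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# Simulation configuration


@dataclass
class CassetteSpec:
    """A homology cassette planted at two loci of the control genome.

    Distances are measured centromere-proximal from the X element start, in
    the canonical frame of each extremity.  ``frame='arm'`` writes the same
    sequence in both canonical arm views (terminal-duplication donors);
    ``frame='original'`` writes the same sequence in original chromosome
    orientation at both loci (direct repeats, as needed for intrachromosomal
    circularization).  Flanking bases of the two copies are forced to differ
    so the planted homology length is exact.
    """

    cassette_id: str
    ext_a: str  # "<chrom>-<side>"
    upstream_a: int
    ext_b: str
    upstream_b: int
    length: int
    frame: str = "arm"


@dataclass
class SimConfig:
    n_chromosomes: int = 16
    core_length: int = 60000
    core_length_jitter: int = 8000
    x_length: int = 1200
    # X elements vary considerably between extremities; enough per-extremity
    # divergence keeps the subtelomeric read anchors distinguishable while
    # the shared ancestor still aligns for X detection.
    x_divergence: float = 0.08
    tract_mean: float = 350.0
    tract_sd: float = 35.0
    tract_min: int = 250
    tract_max: int = 450
    seed_min: int = 50
    seed_max: int = 150
    n_yprime_ends: int = 20
    n_yprime_instances: int = 34
    max_yprime_per_end: int = 6
    library: LibraryConfig = field(default_factory=LibraryConfig)
    cassettes: list[CassetteSpec] = field(default_factory=list)
    genome_name: str = "control"


# ---------------------------------------------------------------------------
# Reference genome construction


def _chromosome_names(n: int) -> list[str]:
    if n <= len(ROMAN):
        return [f"chr{ROMAN[i]}" for i in range(n)]
    return [f"chr{i + 1}" for i in range(n)]


def _assign_yprime_occupancy(
    config: SimConfig, library: YPrimeLibrary, rng: np.random.Generator,
    ext_names: list[str],
) -> dict[str, list[str]]:
    """Distribute Y' instances over extremities; every variant used >= once
    when the instance budget allows, counts capped at max_yprime_per_end."""
    n_ends = min(config.n_yprime_ends, len(ext_names))
    chosen = list(rng.choice(len(ext_names), size=n_ends, replace=False))
    counts = {ext_names[i]: 1 for i in chosen}
    extra = config.n_yprime_instances - n_ends
    if extra < 0:
        raise ValueError("n_yprime_instances must be >= n_yprime_ends")
    pool = [ext_names[i] for i in chosen]
    while extra > 0:
        cand = pool[rng.integers(0, len(pool))]
        if counts[cand] < config.max_yprime_per_end:
            counts[cand] += 1
            extra -= 1
    ids = list(library.ids)
    n_total = config.n_yprime_instances
    if n_total >= len(ids):
        # every variant instantiated at least once, extras drawn at random
        assignment = list(ids)
        assignment += [ids[rng.integers(0, len(ids))] for _ in range(n_total - len(ids))]
    else:
        assignment = [ids[i] for i in rng.choice(len(ids), size=n_total, replace=False)]
    perm = rng.permutation(len(assignment))
    assignment = [assignment[i] for i in perm]
    occupancy: dict[str, list[str]] = {}
    pos = 0
    for ext in ext_names:
        c = counts.get(ext, 0)
        if c:
            occupancy[ext] = assignment[pos : pos + c]
            pos += c
    # An extremity with >5 Y' and adjacent identical variants would be
    # reported "undetermined" downstream; rotate such lists into a
    # duplicate-free adjacency when possible.
    for ext, labs in occupancy.items():
        if len(labs) > 5:
            occupancy[ext] = _separate_adjacent(labs)
    return occupancy


def _separate_adjacent(labels: list[str]) -> list[str]:
    out = list(labels)
    for _ in range(len(out) * len(out)):
        bad = [i for i in range(len(out) - 1) if out[i] == out[i + 1]]
        if not bad:
            return out
        i = bad[0]
        for j in range(len(out)):
            if j not in (i, i + 1) and out[j] != out[i] and (j == 0 or out[j - 1] != out[i]) \
               and (j == len(out) - 1 or out[j + 1] != out[i]):
                out[i + 1], out[j] = out[j], out[i + 1]
                break
        else:
            return out
    return out


def _draw_tract(config: SimConfig, rng: np.random.Generator) -> str:
    length = int(np.clip(rng.normal(config.tract_mean, config.tract_sd),
                         config.tract_min, config.tract_max))
    return gen_telomere_repeats(length, rng)


def build_reference_genome(
    config: SimConfig | None = None, seed: int = 0,
    library: YPrimeLibrary | None = None,
) -> tuple[Genome, TruthLedger]:
    """Emit a control-like genome and its exact truth ledger."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    if library is None:
        library = build_yprime_library(config.library, rng)
    # arms are appended to the core; the core only needs to leave room for
    # chromosome-specific upstream windows and planted cassettes
    if config.core_length - config.core_length_jitter < 20000:
        raise ValueError("core_length (minus jitter) must be >= 20 kb")

    names = _chromosome_names(config.n_chromosomes)
    ext_names = [f"{c}-{s}" for c in names for s in ("L", "R")]
    x_ancestor = _random_dna(rng, config.x_length)
    occupancy = _assign_yprime_occupancy(config, library, rng, ext_names)

    extremities: dict[str, PlantedExtremity] = {}
    cores: dict[str, str] = {}
    for chrom in names:
        core_len = config.core_length + int(
            rng.integers(-config.core_length_jitter, config.core_length_jitter + 1))
        cores[chrom] = _random_dna(rng, core_len)
        for side in ("L", "R"):
            ext_name = f"{chrom}-{side}"
            x_seq = _mutate(x_ancestor, rng, config.x_divergence)
            labels = occupancy.get(ext_name, [])
            seeds = [
                gen_telomere_repeats(
                    int(rng.integers(config.seed_min, config.seed_max + 1)), rng)
                for _ in labels
            ]
            yprimes = [PlantedYPrime(vid, library.by_id(vid).sequence) for vid in labels]
            extremities[ext_name] = PlantedExtremity(
                chromosome=chrom, side=side, x_sequence=x_seq,
                seeds=seeds, yprimes=yprimes, tract=_draw_tract(config, rng))

    ledger = TruthLedger(
        genome_name=config.genome_name, extremities=extremities,
        cores=cores, library=library, x_ancestor=x_ancestor)
    genome = ledger.assemble()
    for spec in config.cassettes:
        _plant_cassette(genome, ledger, spec, rng)
    ledger.verify(genome)
    return genome, ledger


def _arm_view(genome: Genome, ext_name: str) -> str:
    chrom, side = ext_name.rsplit("-", 1)
    seq = genome.chromosomes[chrom]
    return seq if side == "R" else revcomp(seq)


def _set_arm_view(genome: Genome, ext_name: str, view: str) -> None:
    chrom, side = ext_name.rsplit("-", 1)
    genome.chromosomes[chrom] = view if side == "R" else revcomp(view)


def _plant_cassette(
    genome: Genome, ledger: TruthLedger, spec: CassetteSpec, rng: np.random.Generator
) -> None:
    """Write one shared homology cassette at two control loci.

    The cassette lands ``upstream`` bp centromere-proximal of the planted X
    element in each arm's canonical view.  Flanks are forced to mismatch
    between the two copies so downstream homology measurements are exact.
    """
    cassette = _random_dna(rng, spec.length)
    loci = []
    for ext_name, upstream in ((spec.ext_a, spec.upstream_a), (spec.ext_b, spec.upstream_b)):
        view = _arm_view(genome, ext_name)
        ext = ledger.extremities[ext_name]
        x_start = len(view) - len(ext.arm_sequence())
        end = x_start - upstream
        start = end - spec.length
        if start < 2000:
            raise ValueError(f"cassette {spec.cassette_id} does not fit at {ext_name}")
        loci.append((ext_name, start, end))
    flank_pairs = [("A", "C"), ("G", "T")]  # (left flanks), (right flanks)
    for i, (ext_name, start, end) in enumerate(loci):
        view = _arm_view(genome, ext_name)
        chrom, side = ext_name.rsplit("-", 1)
        body = cassette
        if spec.frame == "original" and side == "L":
            body = revcomp(cassette)
        # in "original" frame the cassette must read identically in original
        # coordinates; an L-side arm view is reverse-complemented, so write
        # the reverse complement there.
        lf = flank_pairs[0][i]
        rf = flank_pairs[1][i]
        if spec.frame == "original" and side == "L":
            lf, rf = {"A": "T", "C": "G", "G": "C", "T": "A"}[flank_pairs[1][i]], \
                     {"A": "T", "C": "G", "G": "C", "T": "A"}[flank_pairs[0][i]]
        new = view[: start - 1] + lf + body + rf + view[end + 1:]
        _set_arm_view(genome, ext_name, new)
        # cassettes live in the core; keep the ledger's core in sync so
        # reassembly from parts reproduces the emitted sequence
        chrom_name = ext_name.rsplit("-", 1)[0]
        ledger.cores[chrom_name] = _core_from_chrom(
            genome.chromosomes[chrom_name], ledger, chrom_name)
    ledger.cassettes[spec.cassette_id] = {
        "sequence": cassette, "frame": spec.frame,
        "loci": [
            {"extremity": e, "arm_start": s, "arm_end": en} for e, s, en in loci
        ],
    }


# ---------------------------------------------------------------------------
# Rolling circles


def roll_circle(circle_unit: str, n_copies: int, phase: int = 0,
                cap_length: int | None = None) -> str:
    """Tandem expansion of a circular unit entering at the given phase."""
    if not circle_unit:
        raise ValueError("empty circle unit")
    if not (0 <= phase < len(circle_unit)):
        raise ValueError("phase must satisfy 0 <= phase < unit length")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rotated = circle_unit[phase:] + circle_unit[:phase]
    out = rotated * n_copies
    if cap_length is not None:
        out = out[:cap_length]
    return out


# ---------------------------------------------------------------------------
# Rearrangement planting


class EventSpecError(ValueError):
    pass


def make_mosaic(
    library: YPrimeLibrary, donors: Sequence[str], rng: np.random.Generator,
    n_segments: int | None = None,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Concatenate large chunks of >= 2 donor variants into a new Y' sequence.

    Returns (sequence, segments) with segments as (donor_id, start, end) on
    the donor.  Chunks are multi-kb so exact-match decomposition is
    unambiguous.
    """
    if len(donors) < 2:
        raise EventSpecError("a mosaic needs >= 2 donors")
    n_segments = n_segments or len(donors)
    order = [donors[i % len(donors)] for i in range(n_segments)]
    segments: list[tuple[str, int, int]] = []
    parts: list[str] = []
    for i, vid in enumerate(order):
        seq = library.by_id(vid).sequence
        span = len(seq) // n_segments
        start = i * span
        end = len(seq) if i == n_segments - 1 else (i + 1) * span
        segments.append((vid, start, end))
        parts.append(seq[start:end])
    return "".join(parts), segments


def plant_rearrangements(
    genome: Genome,
    ledger: TruthLedger,
    event_spec: Sequence[dict[str, Any]],
    seed: int = 0,
    survivor_name: str = "survivor",
) -> tuple[Genome, TruthLedger]:
    """Realize a list of typed events on a copy of the control genome.

    Extremities not named in any event stay byte-identical to the control.
    The returned ledger describes the survivor exactly and carries the
    planted event list.
    """
    rng = np.random.default_rng(seed)
    ledger = copy.deepcopy(ledger)
    ledger.genome_name = survivor_name
    ledger.events = []
    ledger.circles = []
    genome = Genome(name=survivor_name, chromosomes=dict(genome.chromosomes))

    structural_kinds = ("loss", "gain", "tandem_amplification", "new_variant",
                        "circle_amplification", "telomere_elongation")
    sequence_kinds = ("terminal_duplication", "circularization")
    unknown = [e["kind"] for e in event_spec
               if e["kind"] not in structural_kinds + sequence_kinds]
    if unknown:
        raise EventSpecError(f"unknown event kinds: {unknown}")
    structural = [e for e in event_spec if e["kind"] in structural_kinds]
    sequence_level = [e for e in event_spec if e["kind"] in sequence_kinds]

    touched = set()
    for ev in structural:
        _apply_structural(ledger, ev, rng)
        touched.add(ev.get("extremity"))

    # reassemble chromosomes whose arms changed
    rebuilt = ledger.assemble()
    for chrom in genome.chromosomes:
        if chrom not in ledger.circular_chromosomes:
            genome.chromosomes[chrom] = rebuilt.chromosomes[chrom]

    for ev in sequence_level:
        if ev["kind"] == "terminal_duplication":
            _apply_terminal_duplication(genome, ledger, ev)
        else:
            _apply_circularization(genome, ledger, ev, rng)

    ledger.verify(genome)
    return genome, ledger


def _get_ext(ledger: TruthLedger, ev: dict[str, Any]) -> PlantedExtremity:
    name = ev.get("extremity")
    if name not in ledger.extremities:
        raise EventSpecError(f"event references unknown extremity {name!r}")
    return ledger.extremities[name]


def _seed_for(ledger: TruthLedger, rng: np.random.Generator, ev: dict[str, Any]) -> str:
    length = int(ev.get("seed_length", rng.integers(50, 151)))
    return gen_telomere_repeats(length, rng)


def _apply_structural(ledger: TruthLedger, ev: dict[str, Any], rng: np.random.Generator) -> None:
    kind = ev["kind"]
    if kind == "circle_amplification":
        _apply_circle_amplification(ledger, ev, rng)
        return
    ext = _get_ext(ledger, ev)
    if kind == "loss":
        index = ev["index"]
        if not (0 <= index < len(ext.yprimes)):
            raise EventSpecError(f"loss index {index} out of range at {ext.name}")
        lost = ext.yprimes.pop(index)
        ext.seeds.pop(index)
        ledger.events.append(PlantedEvent("loss", ext.name,
                                          {"index": index, "label": lost.variant_id}))
    elif kind == "gain":
        vid = ev["variant_id"]
        seq = ev.get("sequence")
        if seq is None:
            try:
                seq = ledger.library.by_id(vid).sequence
            except KeyError as exc:
                raise EventSpecError(f"gain references unknown variant {vid!r}") from exc
        index = ev.get("index", len(ext.yprimes))
        ext.yprimes.insert(index, PlantedYPrime(vid, seq))
        ext.seeds.insert(index, _seed_for(ledger, rng, ev))
        ledger.events.append(PlantedEvent("gain", ext.name, {"index": index, "label": vid}))
    elif kind == "tandem_amplification":
        index = ev["index"]
        copies = int(ev.get("copies", 1))
        if not (0 <= index < len(ext.yprimes)):
            raise EventSpecError(f"tandem index {index} out of range at {ext.name}")
        src = ext.yprimes[index]
        for c in range(copies):
            ext.yprimes.insert(index + 1, PlantedYPrime(src.variant_id, src.sequence))
            ext.seeds.insert(index + 1, _seed_for(ledger, rng, ev))
        ledger.events.append(PlantedEvent(
            "tandem_amplification", ext.name,
            {"index": index, "label": src.variant_id, "copies": copies}))
    elif kind == "new_variant":
        index = ev.get("index", len(ext.yprimes))
        if ev.get("mode") == "mutated":
            base = ledger.library.by_id(ev["base_variant"]).sequence
            seq = _mutate(base, rng, float(ev.get("divergence", 0.1)))
            payload = {"index": index, "mode": "mutated", "base": ev["base_variant"]}
        else:
            donors = ev.get("donors")
            if donors is None:
                raise EventSpecError("new_variant needs donors or mode='mutated'")
            for d in donors:
                try:
                    ledger.library.by_id(d)
                except KeyError as exc:
                    raise EventSpecError(
                        f"mosaic references unknown donor {d!r}") from exc
            seq, segments = make_mosaic(ledger.library, donors, rng,
                                        ev.get("n_segments"))
            payload = {"index": index, "mode": "mosaic", "donors": list(donors),
                       "segments": segments}
        new_id = ev.get("new_id", f"new_{ext.name}_{index}")
        ext.yprimes.insert(index, PlantedYPrime(new_id, seq))
        ext.seeds.insert(index, _seed_for(ledger, rng, ev))
        payload["label"] = new_id
        ledger.events.append(PlantedEvent("new_variant", ext.name, payload))
    elif kind == "telomere_elongation":
        length = int(ev["length"])
        ext.tract = gen_telomere_repeats(length, rng)
        ledger.events.append(PlantedEvent("telomere_elongation", ext.name,
                                          {"length": length}))


def _circularly_telomeric(unit: str) -> bool:
    """True when the unit is valid TG(1-3) grammar *around the circle*
    (no TT or GGGG, including across the wrap junction)."""
    from .grammar import is_telomeric_string

    return is_telomeric_string(unit + unit)


def _telomeric_pad(length: int, rng: np.random.Generator,
                   left_of: str | None = None,
                   right_of: str | None = None) -> str:
    """Grammar-emitted pad whose seams with neighbouring segments stay valid
    TG(1-3) (no TT or GGGG across either join)."""
    from .grammar import is_telomeric_string

    if length == 0:
        return ""
    for _ in range(200):
        base = gen_telomere_repeats(length + 6, rng)
        # sliding the start lets pads begin mid-block (with G), which is
        # required when the left neighbour ends in T
        for off in range(6):
            pad = base[off : off + length]
            probe = (right_of[-8:] if right_of else "") + pad + \
                (left_of[:8] if left_of else "")
            if is_telomeric_string(probe):
                return pad
    raise EventSpecError("could not emit a grammar-compatible telomeric pad")


def _apply_circle_amplification(
    ledger: TruthLedger, ev: dict[str, Any], rng: np.random.Generator
) -> None:
    """Plant rolling-circle arrays of one unit into one or more telomeres.

    The unit must be telomeric around the circle (a t-circle is a circular
    telomeric molecule); excised origin windows are shifted by a few bases
    when the requested window would break the grammar at the wrap junction.
    """
    unit = ev.get("unit")
    origin = None
    if unit is None:
        src = ev["origin"]  # {"extremity", "offset", "length"}
        tract = ledger.extremities[src["extremity"]].tract
        off, length = int(src["offset"]), int(src["length"])
        found = None
        for delta in sorted(range(-30, 31), key=abs):
            o = off + delta
            if o < 0 or o + length > len(tract):
                continue
            cand = tract[o : o + length]
            if _circularly_telomeric(cand):
                found = cand
                break
        if found is None:
            raise EventSpecError(
                "no circularly telomeric origin window near the requested offset")
        unit = found
        origin = src["extremity"]
    else:
        if not _circularly_telomeric(unit):
            raise EventSpecError("circle unit must be telomeric around the circle")
    if not (50 <= len(unit) <= 600):
        raise EventSpecError("circle units must be 50-600 bp")
    circle = PlantedCircle(
        circle_id=f"Circle_{len(unit)}", unit=unit, origin=origin)
    for tgt in ev["targets"]:
        ext = ledger.extremities[tgt["extremity"]]
        copies = int(tgt["copies"])
        phase = int(tgt.get("phase", rng.integers(0, len(unit))))
        pre_len = int(tgt.get("pre_pad", rng.integers(100, 400)))
        post_len = int(tgt.get("post_pad", rng.integers(50, 200)))
        array = roll_circle(unit, copies, phase)
        pre = _telomeric_pad(pre_len, rng, left_of=array)
        post = _telomeric_pad(post_len, rng, right_of=array)
        ext.tract = pre + array + post
        circle.placements.append(
            {"extremity": ext.name, "phase": phase, "copies": copies,
             "array_start": len(pre), "array_end": len(pre) + len(array)})
    ledger.circles.append(circle)
    ledger.events.append(PlantedEvent(
        "circle_amplification",
        ",".join(t["extremity"] for t in ev["targets"]),
        {"circle_id": circle.circle_id, "origin": origin}))


def _apply_terminal_duplication(genome: Genome, ledger: TruthLedger, ev: dict[str, Any]) -> None:
    """Replace a recipient terminal segment with a donor-arm copy through a
    planted homology cassette (BIR-like)."""
    cid = ev["cassette_id"]
    if cid not in ledger.cassettes:
        raise EventSpecError(f"unknown cassette {cid!r}")
    cas = ledger.cassettes[cid]
    recipient = ev["extremity"]
    loci = {l["extremity"]: l for l in cas["loci"]}
    donor = ev.get("donor")
    if donor is None:
        # the recipient itself need not be a cassette locus (a previous
        # duplication may have copied the cassette onto it); default donor is
        # the locus that is not the recipient, if unambiguous
        others = [e for e in loci if e != recipient]
        if len(others) != 1:
            raise EventSpecError(
                f"cassette {cid}: donor ambiguous for recipient {recipient}")
        donor = others[0]
    if donor not in loci:
        raise EventSpecError(f"cassette {cid} has no locus at donor {donor}")
    cassette_seq = cas["sequence"]
    rec_view = _arm_view(genome, recipient)
    pos = rec_view.find(cassette_seq)
    if pos < 0 or rec_view.find(cassette_seq, pos + 1) >= 0:
        raise EventSpecError(f"cassette {cid} not unique on {recipient} arm")
    junction = pos + len(cassette_seq)
    donor_view = _arm_view(genome, donor)
    # locate the cassette in the *current* donor view: coordinates recorded
    # at build time go stale once other events change chromosome lengths
    dpos = donor_view.find(cassette_seq)
    if dpos < 0 or donor_view.find(cassette_seq, dpos + 1) >= 0:
        raise EventSpecError(f"cassette {cid} not unique on {donor} arm")
    b = dpos + len(cassette_seq)
    new_view = rec_view[:junction] + donor_view[b:]
    _set_arm_view(genome, recipient, new_view)
    # recipient terminal structure is now the donor's
    dext = ledger.extremities[donor]
    rext = ledger.extremities[recipient]
    rext.x_sequence = dext.x_sequence
    rext.seeds = list(dext.seeds)
    rext.yprimes = copy.deepcopy(dext.yprimes)
    rext.tract = dext.tract
    # keep cores consistent with the new chromosome sequence
    chrom, _side = recipient.rsplit("-", 1)
    ledger.cores[chrom] = _core_from_chrom(genome.chromosomes[chrom], ledger, chrom)
    ledger.events.append(PlantedEvent(
        "terminal_duplication", recipient,
        {"donor": donor, "span": len(donor_view) - b,
         "homology": len(cassette_seq), "cassette_id": cid}))


def _core_from_chrom(full: str, ledger: TruthLedger, chrom: str) -> str:
    left = ledger.extremities[f"{chrom}-L"].arm_sequence()
    right = ledger.extremities[f"{chrom}-R"].arm_sequence()
    return full[len(left) : len(full) - len(right)]


def _apply_circularization(
    genome: Genome, ledger: TruthLedger, ev: dict[str, Any], rng: np.random.Generator
) -> None:
    """Fuse the two arms of one chromosome through a shared direct-repeat
    cassette and emit the circle linearized at an arbitrary junction."""
    cid = ev["cassette_id"]
    cas = ledger.cassettes.get(cid)
    if cas is None:
        raise EventSpecError(f"unknown cassette {cid!r}")
    if cas["frame"] != "original":
        raise EventSpecError("circularization needs an 'original'-frame cassette")
    chrom = ev["chromosome"]
    exts = [l["extremity"] for l in cas["loci"]]
    if set(e.rsplit("-", 1)[0] for e in exts) != {chrom}:
        raise EventSpecError(f"cassette {cid} is not intrachromosomal on {chrom}")
    seq = genome.chromosomes[chrom]
    cassette_seq = cas["sequence"]
    first = seq.find(cassette_seq)
    second = seq.find(cassette_seq, first + 1)
    if first < 0 or second < 0:
        raise EventSpecError(f"cassette {cid} copies not found on {chrom}")
    circle = seq[first:second]  # one cassette copy + everything between
    phase = int(ev.get("phase", rng.integers(0, len(circle))))
    genome.chromosomes[chrom] = circle[phase:] + circle[:phase]
    ledger.circular_chromosomes.append(chrom)
    for e in (f"{chrom}-L", f"{chrom}-R"):
        ledger.extremities[e].yprimes = []
        ledger.extremities[e].seeds = []
        ledger.extremities[e].tract = ""
    ledger.events.append(PlantedEvent(
        "circularization", f"{chrom}-L/{chrom}-R",
        {"chromosome": chrom, "homology": len(cassette_seq),
         "circle_length": len(circle), "phase": phase, "cassette_id": cid}))


# ---------------------------------------------------------------------------
# Reads


@dataclass
class ReadSimConfig:
    coverage: float = 30.0
    mean_length: int = 6000
    sd_length: int = 1500
    min_length: int = 1000
    substitution_rate: float = 0.0
    homopolymer_rate: float = 0.0  # per eligible homopolymer run


def homopolymer_jitter(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Nanopore-style homopolymer length errors, +-1 base per affected run.

    Only perturbations that homopolymer condensation (runs > 4 collapsed to
    4) fully absorbs are emitted: runs of length >= 5 may gain or lose one
    base, runs of exactly 4 may only gain one.  This models the dominant
    nanopore error mode while keeping the condensed sequence invariant.
    """
    if rate <= 0 or not seq:
        return seq
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        new_run = run
        if run >= 4 and rng.random() < rate:
            if run == 4:
                new_run = 5
            else:
                new_run = run + (1 if rng.random() < 0.5 else -1)
        out.append(seq[i] * new_run)
        i = j
    return "".join(out)


def simulate_reads(
    genome: Genome, config: ReadSimConfig | None = None, seed: int = 0,
) -> list[tuple[str, str]]:
    """Sample (name, sequence) reads uniformly with strand flips.

    Reads are substrings truncated at chromosome ends; substitution and
    homopolymer-length errors are applied per the config.  Deterministic
    under the seed.
    """
    config = config or ReadSimConfig()
    rng = np.random.default_rng(seed)
    total = genome.total_length()
    target_bases = config.coverage * total
    chrom_names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    reads: list[tuple[str, str]] = []
    emitted = 0
    idx = 0
    while emitted < target_bases:
        c = chrom_names[rng.choice(len(chrom_names), p=probs)]
        seq = genome.chromosomes[c]
        rl = max(config.min_length,
                 int(rng.normal(config.mean_length, config.sd_length)))
        # allow reads to overhang the left edge (truncated at 0) so both
        # chromosome ends receive full coverage
        start = int(rng.integers(-(rl - 1), len(seq)))
        read = seq[max(0, start) : start + rl]
        if len(read) < config.min_length:
            continue
        if rng.random() < 0.5:
            read = revcomp(read)
        if config.homopolymer_rate > 0:
            read = homopolymer_jitter(read, rng, config.homopolymer_rate)
        if config.substitution_rate > 0:
            read = _mutate(read, rng, config.substitution_rate)
        reads.append((f"read_{idx}", read))
        idx += 1
        emitted += len(read)
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
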