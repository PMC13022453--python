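"""Shared data model and sequence/annotation I/O.

Coordinates are 0-based half-open throughout.  Every per-extremity analysis
runs in the *canonical frame*: the extremity read 5'->3' on the G-rich strand
toward the chromosome end, so the telomere always sits at the right edge.
Left-arm extremities are reverse-complemented into this frame; only I/O
de-canonicalizes back to original chromosome coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Malformed FASTA input."""


@dataclass
class Genome:
    """A named assembly: ordered map of chromosome name -> uppercase sequence."""

    name: str
    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} contains invalid bases {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.chromosomes)

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def extremities(self) -> list[tuple[str, str]]:
        """All (chromosome, side) pairs, two per chromosome, L then R."""
        out = []
        for chrom in self.chromosomes:
            out.append((chrom, "L"))
            out.append((chrom, "R"))
        return out


@dataclass(frozen=True)
class Interval:
    """Half-open interval on the canonical extremity frame."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Extremity:
    """One chromosome end viewed in the canonical (telomere-rightward) frame.

    ``canonical_sequence`` covers the terminal ``window`` bases of the
    chromosome; position ``len(canonical_sequence)`` is the chromosome end.
    """

    chromosome: str
    side: str  # "L" | "R"
    canonical_sequence: str
    window: int

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")

    @property
    def name(self) -> str:
        return f"{self.chromosome}-{self.side}"

    def __len__(self) -> int:
        return len(self.canonical_sequence)


def read_fasta(path: str | Path, name: str | None = None) -> Genome:
    """Parse a FASTA file into a :class:`Genome`.

    Sequences are uppercased; Ns preserved; record order preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chromosomes: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in chromosomes:
                raise FastaError(f"duplicate record name {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaError(f"record {rec.id!r} in {path} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaError(
                    f"record {rec.id!r} in {path} has invalid bases {sorted(bad)}"
                )
            chromosomes[rec.id] = seq
    except FastaError:
        raise
    except Exception as exc:  # Bio.SeqIO parse failures
        raise FastaError(f"cannot parse FASTA {path}: {exc}") from exc
    if not chromosomes:
        raise FastaError(f"no FASTA records in {path}")
    return Genome(name=name or path.stem, chromosomes=chromosomes)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in genome.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def canonical_extremity(
    genome: Genome, chromosome: str, side: str, window: int
) -> Extremity:
    """Extract one chromosome end in the canonical frame.

    R side: the terminal ``window`` bases as-is.  L side: the reverse
    complement of the initial ``window`` bases, so the telomere again sits at
    the right edge of the returned sequence.
    """
    if chromosome not in genome.chromosomes:
        raise KeyError(f"unknown chromosome {chromosome!r} in genome {genome.name!r}")
    seq = genome.chromosomes[chromosome]
    if window > len(seq):
        raise ValueError(
            f"window {window} exceeds chromosome {chromosome!r} length {len(seq)}")
    if side == "R":
        canon = seq[len(seq) - window :]
    elif side == "L":
        canon = revcomp(seq[:window])
    else:
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    return Extremity(chromosome=chromosome, side=side, canonical_sequence=canon, window=window)


def arm_extremity(genome: Genome, chromosome: str, side: str, window: int) -> Extremity:
    """Canonical extremity clamped to half the chromosome so the two arm
    views never overlap (elements of one arm cannot leak into the other)."""
    w = min(window, len(genome.chromosomes[chromosome]) // 2)
    return canonical_extremity(genome, chromosome, side, w)


def canonical_to_original(
    extremity: Extremity, chrom_length: int, interval: Interval
) -> Interval:
    """Map a canonical-frame interval back to original chromosome coordinates."""
    w = len(extremity.canonical_sequence)
    if extremity.side == "R":
        off = chrom_length - w
        return Interval(off + interval.start, off + interval.end)
    return Interval(w - interval.end, w - interval.start)


def original_to_canonical(
    extremity: Extremity, chrom_length: int, interval: Interval
) -> Interval:
    """Inverse of :func:`canonical_to_original` (an involution for L sides)."""
    w = len(extremity.canonical_sequence)
    if extremity.side == "R":
        off = chrom_length - w
        return Interval(interval.start - off, interval.end - off)
    return Interval(w - interval.end, w - interval.start)


def write_annotations(
    extremity_maps: Iterable,  # list[ExtremityMap]; kept loose to avoid import cycle
    genome: Genome,
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Write BED-style annotations (original coordinates) plus a TSV report.

    BED columns: chrom, start, end, feature, label, side.  Output order is
    deterministic (chromosome order of the genome, then start), so identical
    inputs give bit-stable files.
    """
    rows: list[tuple[str, int, int, str, str, str]] = []
    for emap in extremity_maps:
        ext = emap.extremity
        clen = len(genome.chromosomes[ext.chromosome])

        def add(interval: Interval, feature: str, label: str) -> None:
            orig = canonical_to_original(ext, clen, interval)
            rows.append((ext.chromosome, orig.start, orig.end, feature, label, ext.side))

        if emap.telomere_tract is not None:
            add(emap.telomere_tract.interval, "telomere", f"len={emap.telomere_tract.length}")
        if emap.x_interval is not None:
            add(emap.x_interval, "X_element", "X")
        for inst in emap.yprime_instances:
            add(inst.interval, "Y_prime", inst.label or f"idx{inst.index}")

    chrom_order = {c: i for i, c in enumerate(genome.chromosomes)}
    rows.sort(key=lambda r: (chrom_order.get(r[0], len(chrom_order)), r[1], r[2], r[3]))

    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tfeature\tlabel\tside\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    if tsv_path is not None:
        with open(tsv_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["extremity", "status", "telomere_bp", "x_present", "n_yprime", "yprime_labels"]
            )
            for emap in extremity_maps:
                writer.writerow(
                    [
                        emap.extremity.name,
                        emap.status,
                        emap.telomere_tract.length if emap.telomere_tract else 0,
                        int(emap.x_interval is not None),
                        len(emap.yprime_instances),
                        ",".join(i.label or "?" for i in emap.yprime_instances),
                    ]
                )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    """Read back a BED file written by :func:`write_annotations`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, feature, label, side = line.rstrip("\n").split("\t")
            out.append((chrom, int(start), int(end), feature, label, side))
    return out
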