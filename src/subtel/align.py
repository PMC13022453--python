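"""Alignment backends.

Local alignments between multi-kb sequences (Y' detection, pairwise
similarity, X detection) go through BLAST+ (``blastn``), the standard tool
for this job; short near-exact matching of circle units uses Biopython's
``PairwiseAligner``; exact maximal matches for mosaic decomposition are
seeded on k-mers and extended.  N bases never match anywhere.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

_OUTFMT = "6 qseqid sseqid pident length qstart qend sstart send qlen slen bitscore"


class AlignmentError(RuntimeError):
    pass


@dataclass(frozen=True)
class Hit:
    """One blastn HSP, coordinates converted to 0-based half-open.

    ``sstart < send`` always; ``strand`` is "+" or "-" (query reversed hits).
    """

    query: str
    subject: str
    pident: float
    length: int
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int
    bitscore: float
    strand: str


def _require_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise AlignmentError("blastn executable not found on PATH")
    return exe


def _write_fasta(path: Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def blastn(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    task: str = "blastn",
    evalue: float = 1e-6,
    perc_identity: float | None = None,
) -> list[Hit]:
    """All-vs-all local alignment of query records against subject records.

    Uses a temporary BLAST database when there are multiple subjects, a
    plain ``-subject`` run otherwise.  Deterministic for fixed inputs.
    """
    if not queries or not subjects:
        return []
    for name, seq in list(queries) + list(subjects):
        if not seq:
            raise AlignmentError(f"empty sequence for record {name!r}")
    exe = _require_blastn()
    with tempfile.TemporaryDirectory(prefix="subtel_blast_") as tmp:
        tmp = Path(tmp)
        qpath = tmp / "query.fa"
        spath = tmp / "subject.fa"
        _write_fasta(qpath, queries)
        _write_fasta(spath, subjects)
        cmd = [exe, "-query", str(qpath), "-task", task, "-outfmt", _OUTFMT,
               "-evalue", str(evalue), "-dust", "no", "-soft_masking", "false"]
        if perc_identity is not None:
            cmd += ["-perc_identity", str(perc_identity)]
        if len(subjects) > 1:
            db = tmp / "db"
            mk = subprocess.run(
                [shutil.which("makeblastdb") or "makeblastdb", "-in", str(spath),
                 "-dbtype", "nucl", "-out", str(db)],
                capture_output=True, text=True)
            if mk.returncode != 0:
                raise AlignmentError(f"makeblastdb failed: {mk.stderr.strip()}")
            cmd += ["-db", str(db)]
        else:
            cmd += ["-subject", str(spath)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AlignmentError(f"blastn failed: {proc.stderr.strip()}")
        return _parse_outfmt6(proc.stdout)


def _parse_outfmt6(text: str) -> list[Hit]:
    hits = []
    for line in text.splitlines():
        if not line.strip():
            continue
        (qseqid, sseqid, pident, length, qstart, qend,
         sstart, send, qlen, slen, bitscore) = line.split("\t")
        qs, qe = int(qstart) - 1, int(qend)
        ss, se = int(sstart), int(send)
        if ss <= se:
            strand = "+"
            ss, se = ss - 1, se
        else:
            strand = "-"
            ss, se = se - 1, ss
        hits.append(Hit(
            query=qseqid, subject=sseqid, pident=float(pident), length=int(length),
            qstart=qs, qend=qe, sstart=ss, send=se,
            qlen=int(qlen), slen=int(slen), bitscore=float(bitscore), strand=strand))
    return hits


def best_hit_per_pair(hits: Iterable[Hit]) -> dict[tuple[str, str], Hit]:
    """Best HSP (by bitscore, then alignment length) for every (query, subject)."""
    best: dict[tuple[str, str], Hit] = {}
    for h in hits:
        key = (h.query, h.subject)
        cur = best.get(key)
        if cur is None or (h.bitscore, h.length) > (cur.bitscore, cur.length):
            best[key] = h
    return best


# ---------------------------------------------------------------------------
# Exact maximal matches (mosaic decomposition, junction homology)

def maximal_exact_matches(
    target: str, donor: str, min_length: int, k: int = 21
) -> list[tuple[int, int, int]]:
    """All maximal exact matches >= min_length between target and donor.

    Returns (target_start, donor_start, length) triples, deduplicated.
    Matches containing N are split (N never matches).  Seeds on donor
    k-mers and extends both ways; ``k`` must be <= min_length.
    """
    k = min(k, min_length)
    if len(target) < k or len(donor) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(donor) - k + 1):
        kmer = donor[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    seen: set[tuple[int, int]] = set()  # (tstart - dstart, tstart) canonical per diagonal
    out: list[tuple[int, int, int]] = []
    for t in range(len(target) - k + 1):
        kmer = target[t : t + k]
        if "N" in kmer:
            continue
        for d in index.get(kmer, ()):  # extend seed maximally
            diag = t - d
            # extend left
            ts, ds = t, d
            while ts > 0 and ds > 0 and target[ts - 1] == donor[ds - 1] != "N":
                ts -= 1
                ds -= 1
            if (diag, ts) in seen:
                continue
            seen.add((diag, ts))
            te, de = t + k, d + k
            while te < len(target) and de < len(donor) and target[te] == donor[de] != "N":
                te += 1
                de += 1
            if te - ts >= min_length:
                out.append((ts, ds, te - ts))
    out.sort()
    return out


def longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    lo = 0
    for i in range(n):
        if a[i] != b[i] or a[i] == "N":
            return i
    return n


def extend_match(a: str, b: str, ai: int, bi: int) -> tuple[int, int]:
    """Maximal exact extension around seed positions; returns (left, right)
    extension lengths such that a[ai-left:ai+right] == b[bi-left:bi+right]."""
    left = 0
    while ai - left > 0 and bi - left > 0 and a[ai - left - 1] == b[bi - left - 1] != "N":
        left += 1
    right = 0
    while (ai + right < len(a) and bi + right < len(b)
           and a[ai + right] == b[bi + right] != "N"):
        right += 1
    return left, right
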