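"""The degenerate TG(1-3) telomere repeat grammar.

Budding-yeast telomeres are ~350 bp of degenerate TG(1-3) repeats on the
G-rich strand: single T's separating runs of 1-3 G's.  Equivalently, a
telomeric string over {T, G} contains no "TT" and no "GGGG".  That
characterization gives an exact 6-mer dictionary used for telomericity
scoring: a 6-mer is telomeric iff it can occur inside a valid TG(1-3)
string, i.e. iff it avoids both forbidden substrings.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

KMER = 6


@lru_cache(maxsize=1)
def telomere_kmer_dictionary(k: int = KMER) -> frozenset[str]:
    """All k-mers over {T,G} with no 'TT' and no 'GGGG' substring."""
    valid = []
    for tup in product("TG", repeat=k):
        w = "".join(tup)
        if "TT" not in w and "GGGG" not in w:
            valid.append(w)
    return frozenset(valid)


def is_telomeric_string(seq: str) -> bool:
    """True iff seq matches the TG(1-3) grammar (interior of a tract)."""
    return (
        len(seq) > 0
        and set(seq) <= {"T", "G"}
        and "TT" not in seq
        and "GGGG" not in seq
    )


def telomericity(window: str, k: int = KMER) -> float:
    """Fraction of overlapping k-mers of ``window`` in the TG(1-3) dictionary."""
    n = len(window) - k + 1
    if n <= 0:
        return 0.0
    dic = telomere_kmer_dictionary(k)
    hits = sum(1 for i in range(n) if window[i : i + k] in dic)
    return hits / n


def gen_telomere_repeats(length: int, rng: np.random.Generator, p_extra_g: float = 0.5) -> str:
    """Emit exactly ``length`` bases of degenerate TG(1-3) repeats.

    Blocks are 'T' + 'G'*k with k grown from 1 by appending an extra G with
    probability ``p_extra_g``, capped at 3.  Deterministic under the rng
    state; truncation at the requested length never violates the grammar.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    parts: list[str] = []
    total = 0
    while total < length:
        g = 1
        while g < 3 and rng.random() < p_extra_g:
            g += 1
        block = "T" + "G" * g
        parts.append(block)
        total += len(block)
    return "".join(parts)[:length]


def telomericity_profile(seq: str, window: int, k: int = KMER) -> np.ndarray:
    """Telomericity of each ``window``-sized sliding window (step 1).

    Vectorized over k-mer membership so multi-kb tracts scan quickly.
    """
    n = len(seq)
    if n < window:
        return np.zeros(0)
    dic = telomere_kmer_dictionary(k)
    nk = n - k + 1
    hit = np.fromiter(
        (seq[i : i + k] in dic for i in range(nk)), dtype=np.float64, count=nk
    )
    per_window = window - k + 1
    csum = np.concatenate([[0.0], np.cumsum(hit)])
    # window starting at i covers k-mers i .. i+per_window-1
    starts = np.arange(0, n - window + 1)
    return (csum[starts + per_window] - csum[starts]) / per_window
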