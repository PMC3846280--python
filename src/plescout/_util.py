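"""Low-level sequence utilities shared by the generator and the annotators.

Everything here works on plain upper-case DNA strings; coordinates are
0-based half-open throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_DNA = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """i.i.d. uniform ACGT background of length ``n``."""
    if n <= 0:
        return ""
    return _DNA[rng.integers(0, 4, n)].tobytes().decode()


def random_dna_at_rich(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    """Background with a configurable A+T fraction (AT-rich target model)."""
    if n <= 0:
        return ""
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return _DNA[idx].tobytes().decode()


def mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: frozenset[int] | set[int] = frozenset(),
) -> str:
    """Per-site substitution at ``rate``; each hit becomes a different base.

    ``protected`` positions are never touched (used e.g. to keep a TSD motif
    intact in the empty-site allele).
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    codes = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    for i in hits:
        if int(i) in protected:
            continue
        old = codes.get(arr[i].tobytes(), 0)
        arr[i] = _DNA[(old + int(rng.integers(1, 4))) % 4]
    return arr.tobytes().decode()


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def child_rng(seed: int, *tags: int) -> np.random.Generator:
    """Deterministic sub-stream derived from an integer seed and tags."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(t) for t in tags]])


# ---------------------------------------------------------------------------
# seed-and-extend machinery
#
# All similarity searches in the package (terminal-repeat pairs, library
# hits, flank anchoring) share one primitive: exact k-mer seeds joined by
# ungapped extension.  Extension tolerates isolated mismatches but stops at
# ``max_mm_run`` consecutive mismatches, and the reported boundary is then
# trimmed back to the end of the last run of >= ``commit_run`` consecutive
# matches.  The trim keeps boundaries of high-identity repeats exact: a
# single chance match just past a true boundary is never committed.
# ---------------------------------------------------------------------------

MAX_MM_RUN = 5
COMMIT_RUN = 8


def extend_seed(
    a: str,
    b: str,
    i: int,
    j: int,
    k: int,
    max_mm_run: int = MAX_MM_RUN,
    commit_run: int = COMMIT_RUN,
) -> tuple[int, int, int, int]:
    """Extend an exact seed ``a[i:i+k] == b[j:j+k]`` ungapped in both
    directions.  Returns committed coordinates ``(ai, aj, bi, bj)`` with the
    alignment covering ``a[ai:aj]`` against ``b[bi:bj]`` (equal lengths)."""
    # right
    ri, rj = i + k, j + k
    ci, cj = ri, rj
    run, mm = k, 0
    while ri < len(a) and rj < len(b):
        if a[ri] == b[rj]:
            run += 1
            mm = 0
            if run >= commit_run:
                ci, cj = ri + 1, rj + 1
        else:
            run = 0
            mm += 1
            if mm >= max_mm_run:
                break
        ri += 1
        rj += 1
    # left
    li, lj = i - 1, j - 1
    si, sj = i, j
    run, mm = k, 0
    while li >= 0 and lj >= 0:
        if a[li] == b[lj]:
            run += 1
            mm = 0
            if run >= commit_run:
                si, sj = li, lj
        else:
            run = 0
            mm += 1
            if mm >= max_mm_run:
                break
        li -= 1
        lj -= 1
    return si, ci, sj, cj


@dataclass(frozen=True)
class Hit:
    """An ungapped local alignment of ``query`` against ``target``.

    ``strand`` is '+' when the query matches the target forward strand.  For
    '-' hits the query interval refers to the reverse-complemented query.
    """

    t_start: int
    t_end: int
    q_start: int
    q_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _identity(a: str, b: str, ai: int, aj: int, bi: int) -> float:
    n = aj - ai
    if n <= 0:
        return 0.0
    m = sum(a[ai + t] == b[bi + t] for t in range(n))
    return m / n


def find_hits(
    target: str,
    query: str,
    k: int = 12,
    min_len: int = 30,
    min_identity: float = 0.8,
    both_strands: bool = True,
) -> list[Hit]:
    """All ungapped seed-and-extend hits of ``query`` in ``target``."""
    hits: list[Hit] = []
    strands = [("+", query)]
    if both_strands:
        strands.append(("-", revcomp(query)))
    for strand, q in strands:
        if len(q) < k or len(target) < k:
            continue
        index = _kmer_index(q, k)
        covered: dict[int, int] = {}  # diagonal -> committed target end
        for i in range(len(target) - k + 1):
            positions = index.get(target[i : i + k])
            if not positions:
                continue
            for j in positions:
                diag = i - j
                if covered.get(diag, -1) > i:
                    continue
                ti, tj, qi, qj = extend_seed(target, q, i, j, k)
                covered[diag] = tj
                if tj - ti >= min_len:
                    ident = _identity(target, q, ti, tj, qi)
                    if ident >= min_identity:
                        hits.append(Hit(ti, tj, qi, qj, strand, ident))
    hits.sort(key=lambda h: (h.t_start, h.t_end, h.strand))
    # drop hits fully contained in a longer hit on the same strand
    keep: list[Hit] = []
    for h in sorted(hits, key=lambda h: -h.length):
        if any(
            o.strand == h.strand and o.t_start <= h.t_start and h.t_end <= o.t_end
            for o in keep
        ):
            continue
        keep.append(h)
    keep.sort(key=lambda h: (h.t_start, h.t_end, h.strand))
    return keep


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
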