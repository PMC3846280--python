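"""Terminal-repeat (pLTR) detection and arrangement resolution.

pLTR units are found by exact k-mer seeding of the locus against itself and
its reverse complement, followed by ungapped extension.  Extension tolerates
isolated mismatches (diverged copies) but commits boundaries only at runs of
consecutive matches, so unit coordinates of high-identity repeats are exact
— which is what makes overlap, truncation and tail lengths of a clean locus
well-defined quantities rather than approximations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._util import Hit, _identity, _kmer_index, extend_seed, interval_overlap, revcomp

__all__ = [
    "RepeatUnit",
    "RepeatPair",
    "PltrAnnotation",
    "find_terminal_repeats",
    "resolve_arrangement",
    "detect_tail",
    "pltr_orf_codon_coverage",
]

DEFAULT_MIN_UNIT = 50
DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_SEED_K = 12


@dataclass(frozen=True)
class RepeatUnit:
    """One resolved terminal-repeat unit.

    ``strand`` is the unit's strand in locus coordinates; ``orientation``
    is relative to the element ORF strand (a '+' unit of a '-' element is
    'inverted').
    """

    start: int
    end: int
    strand: str
    orientation: str
    identity_to_consensus: float = 1.0

    @property
    def unit_len(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RepeatPair:
    """A maximal ungapped repeat pair; ``a`` precedes ``b`` on the locus."""

    a: tuple[int, int]
    b: tuple[int, int]
    orientation: str  # 'direct' (plus/plus) or 'inverted' (plus/minus)
    length: int
    identity: float


@dataclass
class PltrAnnotation:
    units: list[RepeatUnit]
    overlap_5p: int = 0
    truncation_5p: int = 0
    tail_len: int = 0
    arrangement_label: str = "none"
    full_unit_len: int = 0
    warnings: list[str] = field(default_factory=list)


def find_terminal_repeats(
    locus: str,
    min_unit: int = DEFAULT_MIN_UNIT,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_SEED_K,
) -> list[RepeatPair]:
    """All maximal direct (plus/plus) and inverted (plus/minus) repeat pairs
    with unit length >= ``min_unit`` and identity >= ``min_identity``, sorted
    by unit length descending.  A locus shorter than ``2 * min_unit`` yields
    an empty list."""
    n = len(locus)
    if n < 2 * min_unit or n < k:
        return []
    pairs: list[RepeatPair] = []
    seen: set[tuple] = set()

    # direct pairs: locus vs itself, j > i, skipping the self-diagonal
    index = _kmer_index(locus, k)
    covered: dict[int, int] = {}
    for i in range(n - k + 1):
        for j in index.get(locus[i : i + k], ()):
            if j - i < min_unit:  # self / near-tandem diagonal
                continue
            diag = j - i
            if covered.get(diag, -1) > i:
                continue
            ai, aj, bi, bj = extend_seed(locus, locus, i, j, k)
            covered[diag] = aj
            if aj - ai >= min_unit:
                ident = _identity(locus, locus, ai, aj, bi)
                key = ("d", ai, aj, bi, bj)
                if ident >= min_identity and key not in seen:
                    seen.add(key)
                    pairs.append(RepeatPair((ai, aj), (bi, bj), "direct", aj - ai, ident))

    # inverted pairs: locus vs its reverse complement
    rc = revcomp(locus)
    index_rc = _kmer_index(rc, k)
    covered = {}
    for i in range(n - k + 1):
        for j in index_rc.get(locus[i : i + k], ()):
            diag = j - i
            if covered.get(diag, -1) > i:
                continue
            ai, aj, bi, bj = extend_seed(locus, rc, i, j, k)
            covered[diag] = aj
            if aj - ai >= min_unit:
                iv_a = (ai, aj)
                iv_b = (n - bj, n - bi)
                if iv_b < iv_a:
                    iv_a, iv_b = iv_b, iv_a
                if iv_a == iv_b:
                    continue  # a palindrome matching itself
                ident = _identity(locus, rc, ai, aj, bi)
                key = ("i", *iv_a, *iv_b)
                if ident >= min_identity and key not in seen:
                    seen.add(key)
                    pairs.append(RepeatPair(iv_a, iv_b, "inverted", aj - ai, ident))

    pairs.sort(key=lambda p: (-p.length, p.a, p.b))
    return pairs


def _same_unit(a: tuple[int, int], b: tuple[int, int], frac: float = 0.8) -> bool:
    ov = interval_overlap(a, b)
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def _contained(iv: tuple[int, int], units, frac: float = 0.9) -> bool:
    return any(interval_overlap(iv, u) >= frac * (iv[1] - iv[0]) for u in units)


def resolve_arrangement(
    pairs: list[RepeatPair],
    orf_strand: str = "+",
    extra_units: list[tuple[int, int, str]] = (),
) -> PltrAnnotation:
    """Merge repeat pairs into a unit set and label the pLTR arrangement.

    Direct pairs define the full unit length.  An inverted hit whose partner
    interval extends beyond a direct unit's end is clipped by that overhang
    (the overhang is tail evidence, quantified separately by
    :func:`detect_tail`).  ``extra_units`` (``(start, end, strand)``, e.g.
    from a pLTR-library scan) seed the unit set when self-comparison finds no
    partner — the solo-pLTR case.
    """
    warnings: list[str] = []
    direct = [p for p in pairs if p.orientation == "direct"]
    inverted = [p for p in pairs if p.orientation == "inverted"]

    plus_units: list[tuple[int, int]] = []
    minus_units: list[tuple[int, int]] = []
    identities: dict[tuple[int, int], float] = {}

    for p in sorted(direct, key=lambda p: (-p.length, p.a)):
        for iv in (p.a, p.b):
            if not any(_same_unit(iv, u) for u in plus_units):
                if not _contained(iv, plus_units):
                    plus_units.append(iv)
                    identities[iv] = p.identity

    for p in sorted(inverted, key=lambda p: (-p.length, p.a)):
        for iv_self, iv_other in ((p.a, p.b), (p.b, p.a)):
            anchor = next((u for u in plus_units if _same_unit(iv_other, u, 0.6)), None)
            if anchor is None:
                continue
            # clip the overhang of the partner beyond the anchored unit;
            # the inverted mapping sends the partner's right overhang to this
            # interval's left edge and vice versa
            e_right = max(0, iv_other[1] - anchor[1])
            e_left = max(0, anchor[0] - iv_other[0])
            clipped = (iv_self[0] + e_right, iv_self[1] - e_left)
            if clipped[1] - clipped[0] <= 0:
                continue
            if _contained(clipped, plus_units) or _contained(clipped, minus_units):
                continue
            if not any(_same_unit(clipped, u) for u in minus_units):
                minus_units.append(clipped)
                identities[clipped] = p.identity
        if not plus_units:
            # no direct pairs at all: take the pair as-is, 3'-most unit on '+'
            a, b = sorted((p.a, p.b))
            if not (plus_units or minus_units):
                minus_units.append(a)
                plus_units.append(b)
                identities[a] = identities[b] = p.identity

    for (s, e, strand) in extra_units:
        iv = (s, e)
        pool = plus_units if strand == "+" else minus_units
        if not any(_same_unit(iv, u, 0.6) for u in plus_units + minus_units):
            pool.append(iv)
            identities[iv] = 1.0

    all_ivs = [(iv, "+") for iv in plus_units] + [(iv, "-") for iv in minus_units]
    all_ivs.sort(key=lambda t: t[0])

    # nested units are contradictory
    for i, (iv1, _) in enumerate(all_ivs):
        for iv2, _ in all_ivs[i + 1 :]:
            if iv1[0] <= iv2[0] and iv2[1] <= iv1[1] and iv1 != iv2:
                warnings.append(f"nested units {iv1} / {iv2}")

    flip = orf_strand == "-"
    units = [
        RepeatUnit(
            iv[0],
            iv[1],
            strand,
            ("direct" if (strand == "+") != flip else "inverted"),
            identities.get(iv, 1.0),
        )
        for iv, strand in all_ivs
    ]

    ann = PltrAnnotation(units=units, warnings=warnings)
    if warnings:
        ann.arrangement_label = "none"
        return ann

    d = sum(1 for u in units if u.orientation == "direct")
    v = len(units) - d
    n_units = len(units)
    direct_lens = [u.unit_len for u in units if u.orientation == "direct"]
    ann.full_unit_len = max(direct_lens) if direct_lens else (
        max((u.unit_len for u in units), default=0)
    )
    inv_units = [u for u in units if u.orientation == "inverted"]
    if inv_units:
        ann.truncation_5p = max(0, ann.full_unit_len - min(u.unit_len for u in inv_units))
        ann.overlap_5p = max(
            (
                interval_overlap(iu.interval, du.interval)
                for iu in inv_units
                for du in units
                if du.orientation == "direct"
            ),
            default=0,
        )

    if n_units == 0:
        ann.arrangement_label = "none"
    elif n_units == 1:
        ann.arrangement_label = "solo"
    elif d >= 2 and v >= 1:
        ann.arrangement_label = "DD_plus_inverted5p"
    elif d == 2 and v == 0:
        ann.arrangement_label = "DD_only"
    elif d >= 3 and v == 0:
        ann.arrangement_label = "tandem_partial"
    elif d == 1 and v == 1:
        ann.arrangement_label = "inverted_pair"
    else:
        ann.arrangement_label = "none"
        ann.warnings.append(f"unclassifiable unit pattern d={d} v={v}")
    return ann


def _ext3(unit: RepeatUnit, locus: str, cap: int) -> str:
    """Sequence beyond a unit's 3' end, read in the unit's own orientation."""
    if unit.strand == "+":
        return locus[unit.end : unit.end + cap]
    return revcomp(locus[max(0, unit.start - cap) : unit.start])


def detect_tail(
    unit: RepeatUnit,
    locus: str,
    other_units: list[RepeatUnit],
    cap: int = 200,
) -> int:
    """Length of the shared extension ("tail") beyond ``unit``'s 3' end.

    The tail is the longest common prefix of the sequence running off this
    unit's 3' end and off any other unit's 3' end (each read in its own
    orientation); 0 when absent.
    """
    best = 0
    e1 = _ext3(unit, locus, cap)
    for other in other_units:
        if other.interval == unit.interval:
            continue
        e2 = _ext3(other, locus, cap)
        lce = 0
        for x, y in zip(e1, e2):
            if x != y:
                break
            lce += 1
        best = max(best, lce)
    return best


def pltr_orf_codon_coverage(unit: RepeatUnit, tail_len: int, orf_interval: tuple[int, int]) -> int:
    """Number of ORF codons covered by the pLTR unit plus its tail:
    ``floor((ORF bases inside the unit + tail_len) / 3)``; 0 when the ORF
    does not intersect the unit at all."""
    bases = interval_overlap(unit.interval, orf_interval)
    if bases <= 0:
        return 0
    return (bases + max(0, tail_len)) // 3
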