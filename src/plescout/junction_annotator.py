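"""Insertion-boundary characterisation: target-site duplications,
junction microhomology, palindromes, and pLTR promoter motifs.

Endonuclease-mediated PLE insertion duplicates 8-10 bp of target sequence
(TSD); copies lacking a TSD may instead join via short microhomology, and
the pLTR 5' ends carry (near-)palindromes and TATA/Inr core-promoter
motifs, optionally on both strands.
"""
from __future__ import annotations

from dataclasses import dataclass

from ._util import complement, revcomp
from .locus_forge import PromoterSpec

__all__ = [
    "TSD",
    "Palindrome",
    "PromoterHit",
    "JunctionReport",
    "detect_tsd",
    "detect_microhomology",
    "find_palindromes",
    "scan_promoter",
]

TSD_MIN_LEN = 4
TSD_MAX_LEN = 25
TSD_MAX_MISMATCH = 0
PALINDROME_MIN_LEN = 10
PALINDROME_MAX_MISMATCH = 2
PALINDROME_MAX_SPACER = 4
PROMOTER_MAX_SPACING = 50
TERMINAL_WINDOW = 5  # a palindrome starting within 5 bp of a unit start is "terminal"


@dataclass(frozen=True)
class TSD:
    """A target-site duplication: ``motif`` occurs as a suffix of the left
    flank (at ``left_pos``) and a prefix of the right flank (at
    ``right_pos``); positions are flank-relative."""

    motif: str
    length: int
    left_pos: int
    right_pos: int
    mismatches: int = 0
    truncated_search: bool = False


@dataclass(frozen=True)
class Palindrome:
    start: int
    end: int
    length: int
    mismatches: int
    spacer: int
    terminal: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class PromoterHit:
    """A TATA box with a downstream initiator on one strand; positions are
    in the coordinates of the scanned strand (for '-' hits, of the reverse
    complement of the input)."""

    strand: str
    tata_pos: int
    inr_pos: int
    spacing: int
    inr_motif: str


@dataclass
class JunctionReport:
    tsd: TSD | None
    microhomology_len: int
    palindromes: list[Palindrome]
    promoter_hits: list[PromoterHit]


def detect_tsd(
    left_flank: str,
    right_flank: str,
    min_len: int = TSD_MIN_LEN,
    max_len: int = TSD_MAX_LEN,
    max_mismatch: int = TSD_MAX_MISMATCH,
) -> TSD | None:
    """Longest suffix of ``left_flank`` matching (<= ``max_mismatch``
    mismatches) a prefix of ``right_flank``, with length in
    ``[min_len, max_len]``; ``None`` when no qualifying match.

    Flanks shorter than ``max_len`` are searched up to their available
    length and the result flagged.  Anchoring at the element boundary makes
    the candidate unique per length, so no tie-breaking is needed.
    """
    avail = min(len(left_flank), len(right_flank))
    truncated = avail < max_len
    for k in range(min(max_len, avail), min_len - 1, -1):
        mism = sum(a != b for a, b in zip(left_flank[-k:], right_flank[:k]))
        if mism <= max_mismatch:
            return TSD(
                motif=right_flank[:k],
                length=k,
                left_pos=len(left_flank) - k,
                right_pos=0,
                mismatches=mism,
                truncated_search=truncated,
            )
    return None


def detect_microhomology(element_end: str, target_flank: str, min_len: int = 2) -> int:
    """Longest exact overlap across a junction: ``element_end`` reads into
    the junction (suffix side), ``target_flank`` reads away from it (prefix
    side).  Returns the overlap length when >= ``min_len``, else 0."""
    best = 0
    for k in range(1, min(len(element_end), len(target_flank)) + 1):
        if element_end[-k:] == target_flank[:k]:
            best = k
    return best if best >= min_len else 0


def find_palindromes(
    seq: str,
    min_len: int = PALINDROME_MIN_LEN,
    max_mismatch: int = PALINDROME_MAX_MISMATCH,
    max_spacer: int = PALINDROME_MAX_SPACER,
) -> list[Palindrome]:
    """All maximal (near-)palindromes of ``seq``.

    An interval qualifies when, for some central spacer ``s <= max_spacer``
    of matching parity, the left arm equals the reverse complement of the
    right arm up to ``max_mismatch`` mismatched pairs, with the outermost
    pair an exact match.  Only intervals not strictly contained in another
    qualifying interval are reported, sorted by position.  ``terminal`` flags
    palindromes starting within 5 bp of the sequence start.
    """
    n = len(seq)
    found: dict[tuple[int, int], tuple[int, int]] = {}  # interval -> (mism, spacer)
    for s in range(0, max_spacer + 1):
        for c in range(0, n - s + 1):
            # spacer occupies [c, c+s); expand arms outwards
            mism = 0
            a = 0
            best_a = 0
            best_mism = 0
            l, r = c - 1, c + s
            while l >= 0 and r < n:
                if seq[l] == complement(seq[r]):
                    a += 1
                    best_a, best_mism = a, mism
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                    a += 1
                l -= 1
                r += 1
            # best_a is only advanced on matching pairs, so the outermost
            # pair of the reported interval always matches exactly
            if best_a < 1:
                continue
            iv = (c - best_a, c + s + best_a)
            if iv[1] - iv[0] < min_len:
                continue
            prev = found.get(iv)
            if prev is None or best_mism < prev[0]:
                found[iv] = (best_mism, s)
    # containment filter
    ivs = sorted(found)
    keep = []
    for iv in ivs:
        if any(
            o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in ivs
        ):
            continue
        keep.append(iv)
    return [
        Palindrome(
            start=a,
            end=b,
            length=b - a,
            mismatches=found[(a, b)][0],
            spacer=found[(a, b)][1],
            terminal=a <= TERMINAL_WINDOW,
        )
        for a, b in keep
    ]


def _occurrences(hay: str, needle: str) -> list[int]:
    return [
        i for i in range(len(hay) - len(needle) + 1) if hay[i : i + len(needle)] == needle
    ]


def scan_promoter(
    pltr_seq: str,
    promoter: PromoterSpec | None = None,
    max_spacing: int = PROMOTER_MAX_SPACING,
) -> list[PromoterHit]:
    """TATA/Inr promoter hits on both strands of a pLTR.

    A hit is a TATA-box occurrence with a downstream initiator at spacing
    <= ``max_spacing``.  The forward strand uses the spec's Inr motif
    (default TCACT); the reverse orientation uses its own Inr alphabet
    (default ACATT).  '-' hit positions refer to the reverse complement of
    the input."""
    promoter = promoter or PromoterSpec()
    hits: list[PromoterHit] = []
    for strand, s, inr in (
        ("+", pltr_seq, promoter.inr_motif),
        ("-", revcomp(pltr_seq), promoter.rev_inr_motif),
    ):
        if len(promoter.tata_motif) >= len(s):
            continue
        tata_positions = _occurrences(s, promoter.tata_motif)
        inr_positions = _occurrences(s, inr)
        for t in tata_positions:
            t_end = t + len(promoter.tata_motif)
            for i in inr_positions:
                if i >= t_end and i - t_end <= max_spacing:
                    hits.append(PromoterHit(strand, t, i, i - t_end, inr))
    hits.sort(key=lambda h: (h.strand, h.tata_pos, h.inr_pos))
    return hits
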