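"""Detection of pLTR-mediated host-gene capture.

A PLE can mobilise host sequence in trans: a cassette (for instance an
intron-containing NRPS gene) framed by element pLTRs and flanked by a
target-site duplication, with no element-internal sequence between the
repeats.  The decisive evidence for transposition (rather than
recombination) is the allelic "empty site": the partner locus carries the
same flanks, diverged by a few percent, with the would-be TSD motif present
exactly once at the junction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._util import Hit, find_hits, interval_overlap
from .junction_annotator import TSD, detect_tsd
from .repeat_annotator import RepeatUnit

__all__ = [
    "CaptureEvent",
    "EmptySiteEvidence",
    "detect_capture",
    "verify_empty_site",
    "classify_solo_pltrs",
    "allelic_divergence",
    "element_orf_hits",
]

ELEMENT_FREE_K = 20  # "no internal sequences in common" = no shared 20-mer
MIN_ANCHOR = 200
FLANK_IDENTITY_THRESHOLD = 0.90
JUNCTION_WINDOW = 50
ADJACENT_BP = 1000  # a unit within this of an element ORF hit is element_terminal


@dataclass
class EmptySiteEvidence:
    allele_id: str
    junction_pos: int
    motif_occurrences_in_empty_allele: int
    flank_identity: float
    passed: bool
    tsd_len: int = 0


@dataclass
class CaptureEvent:
    cassette_interval: tuple[int, int]
    framing_units: list[RepeatUnit]
    tsd: TSD | None
    cassette_is_element_free: bool
    empty_site: EmptySiteEvidence | None = None
    element_hit_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(u.start for u in self.framing_units),
            max(u.end for u in self.framing_units),
        )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def element_orf_hits(
    locus: str, element_orf_library: list[str], min_len: int = 50
) -> list[tuple[int, int]]:
    """Intervals of the locus similar to any element ORF in the library."""
    ivs: list[tuple[int, int]] = []
    for orf in element_orf_library:
        for h in find_hits(locus, orf, min_len=min_len):
            ivs.append((h.t_start, h.t_end))
    return sorted(ivs)


def _pltr_units(locus: str, pltr_library: list[str], min_identity: float) -> list[RepeatUnit]:
    units: list[RepeatUnit] = []
    for pltr in pltr_library:
        for h in find_hits(locus, pltr, min_len=max(50, len(pltr) // 2), min_identity=min_identity):
            iv = (h.t_start, h.t_end)
            dup = any(
                interval_overlap(iv, u.interval) >= 0.8 * (iv[1] - iv[0]) and u.strand == h.strand
                for u in units
            )
            if not dup:
                orientation = "direct" if h.strand == "+" else "inverted"
                units.append(RepeatUnit(h.t_start, h.t_end, h.strand, orientation, h.identity))
    units.sort(key=lambda u: u.start)
    return units


def detect_capture(
    locus: str,
    pltr_library: list[str],
    element_orf_library: list[str],
    min_identity: float = 0.8,
    flank: int = 60,
) -> list[CaptureEvent]:
    """Find pLTR-framed cassettes with TSD evidence.

    pLTR-library hits (>= ``min_identity``) are grouped into co-oriented
    adjacent pairs; the intervening cassette is tested for element content
    (shared 20-mers with the ORF library, either strand) and the outer
    flanks of the whole framed structure for a TSD.  Events are sorted by
    position."""
    if not pltr_library or not element_orf_library:
        raise ValueError("pltr_library and element_orf_library must be non-empty")
    units = _pltr_units(locus, pltr_library, min_identity)
    orf_ivs = element_orf_hits(locus, element_orf_library)
    orf_kmers: set[str] = set()
    for orf in element_orf_library:
        orf_kmers |= _kmers(orf, ELEMENT_FREE_K)
        from ._util import revcomp

        orf_kmers |= _kmers(revcomp(orf), ELEMENT_FREE_K)

    events: list[CaptureEvent] = []
    for u, v in zip(units, units[1:]):
        if u.strand != v.strand or v.start - u.end < 1:
            continue
        cassette = (u.end, v.start)
        cass_seq = locus[cassette[0] : cassette[1]]
        element_free = not (_kmers(cass_seq, ELEMENT_FREE_K) & orf_kmers)
        framing = [u, v]
        # an adjacent opposite-strand unit completes the frame
        for w in units:
            if w in framing:
                continue
            if w.strand != u.strand and (
                abs(w.end - u.start) <= 5 or abs(w.start - v.end) <= 5
                or interval_overlap(w.interval, u.interval) > 0
                or interval_overlap(w.interval, v.interval) > 0
            ):
                framing.append(w)
        span0 = min(x.start for x in framing)
        span1 = max(x.end for x in framing)
        tsd = detect_tsd(locus[max(0, span0 - flank) : span0], locus[span1 : span1 + flank])
        events.append(
            CaptureEvent(
                cassette_interval=cassette,
                framing_units=sorted(framing, key=lambda x: x.start),
                tsd=tsd,
                cassette_is_element_free=element_free,
                element_hit_intervals=[
                    iv for iv in orf_ivs if interval_overlap(iv, cassette) > 0
                ],
            )
        )
    events.sort(key=lambda e: e.cassette_interval)
    return events


def _best_hit(hits: list[Hit]) -> Hit | None:
    plus = [h for h in hits if h.strand == "+"]
    return max(plus, key=lambda h: h.length * h.identity, default=None)


def verify_empty_site(
    insertion_locus: str,
    insertion: CaptureEvent,
    candidate_allele: str,
    min_anchor: int = MIN_ANCHOR,
    identity_threshold: float = FLANK_IDENTITY_THRESHOLD,
    window: int = JUNCTION_WINDOW,
    allele_id: str = "allele",
) -> EmptySiteEvidence:
    """Verify an insertion against a candidate allelic empty site.

    The insertion's outer flanks (excluding the TSD copies) are anchored in
    the allele; the anchors must land adjacently (within a TSD length), the
    TSD motif must occur exactly once in the junction neighbourhood, and
    both flanks must align at >= ``identity_threshold``."""
    span0, span1 = insertion.span
    tsd_len = insertion.tsd.length if insertion.tsd else 0
    motif = insertion.tsd.motif if insertion.tsd else ""
    la0 = max(0, span0 - tsd_len - min_anchor)
    left_anchor = insertion_locus[la0 : span0 - tsd_len]
    right_anchor = insertion_locus[span1 + tsd_len : span1 + tsd_len + min_anchor]
    fail = EmptySiteEvidence(allele_id, -1, 0, 0.0, False, tsd_len)
    if len(left_anchor) < min_anchor // 2 or len(right_anchor) < min_anchor // 2:
        return fail
    hl = _best_hit(find_hits(candidate_allele, left_anchor, min_len=min_anchor // 3, min_identity=0.75))
    hr = _best_hit(find_hits(candidate_allele, right_anchor, min_len=min_anchor // 3, min_identity=0.75))
    if hl is None or hr is None:
        return fail
    # extrapolate committed hit ends to the anchor boundaries
    el = hl.t_end + (len(left_anchor) - hl.q_end)
    sr = hr.t_start - hr.q_start
    gap = sr - el
    ident = min(hl.identity, hr.identity)
    count = 0
    if motif:
        neigh = candidate_allele[max(0, el - window) : sr + window]
        count = sum(
            1
            for i in range(len(neigh) - len(motif) + 1)
            if neigh[i : i + len(motif)] == motif
        )
    passed = (
        abs(gap - tsd_len) <= 3
        and ident >= identity_threshold
        and (count == 1 if motif else True)
    )
    return EmptySiteEvidence(allele_id, el, count, ident, passed, tsd_len)


def classify_solo_pltrs(
    units: list[RepeatUnit],
    events: list[CaptureEvent],
    element_hits: list[tuple[int, int]],
    locus: str,
    flank: int = 60,
) -> list[str]:
    """Label each unit element_terminal / capture_framing / solo_with_tsd /
    solo_bare."""
    framing = {u.interval for e in events for u in e.framing_units}
    labels: list[str] = []
    for u in units:
        if u.interval in framing:
            labels.append("capture_framing")
            continue
        near_element = any(
            interval_overlap(u.interval, iv) > 0
            or min(abs(u.start - iv[1]), abs(iv[0] - u.end)) <= ADJACENT_BP
            for iv in element_hits
        )
        if near_element:
            labels.append("element_terminal")
            continue
        tsd = detect_tsd(
            locus[max(0, u.start - flank) : u.start], locus[u.end : u.end + flank]
        )
        labels.append("solo_with_tsd" if tsd is not None else "solo_bare")
    return labels


# --- anchored divergence ---------------------------------------------------


def _unique_kmer_anchors(a: str, b: str, k: int) -> list[tuple[int, int]]:
    def unique_index(s: str) -> dict[str, int]:
        seen: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if w in seen:
                dup.add(w)
            else:
                seen[w] = i
        for w in dup:
            seen.pop(w, None)
        return seen

    ia, ib = unique_index(a), unique_index(b)
    anchors = [(ia[w], ib[w]) for w in ia.keys() & ib.keys()]
    anchors.sort()
    return anchors


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing second coordinate."""
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(anchors)
    for idx, (_, j) in enumerate(anchors):
        p = bisect.bisect_left(tails, j)
        if p == len(tails):
            tails.append(j)
            tails_idx.append(idx)
        else:
            tails[p] = j
            tails_idx[p] = idx
        prev[idx] = tails_idx[p - 1] if p > 0 else -1
    chain = []
    cur = tails_idx[-1] if tails_idx else -1
    while cur != -1:
        chain.append(anchors[cur])
        cur = prev[cur]
    chain.reverse()
    return chain


def allelic_divergence(a: str, b: str, anchor_k: int = 12) -> float | None:
    """Anchored p-distance between two collinear sequences.

    Unique shared k-mers are chained collinearly; inter-anchor gaps
    contribute per-column mismatch counts (length differences count as
    mismatched columns).  Returns mismatches / aligned columns, or ``None``
    when the pair cannot be anchored — including when anchors cover less
    than 20% of the shorter sequence, where the sampled columns would no
    longer be representative (with k=12 this bounds the usable range to
    roughly <= 15% divergence; beyond it the pair is simply "too diverged
    to anchor").  Symmetric by construction (the argument order is
    canonicalised internally).
    """
    if (len(b), b) < (len(a), a):
        a, b = b, a
    anchors = _lis_chain(_unique_kmer_anchors(a, b, anchor_k))
    if not anchors:
        return None
    # merge same-diagonal runs into segments
    segs: list[list[int]] = []  # [a0, a1, b0, b1]
    for i, j in anchors:
        if segs and i - (segs[-1][1] - anchor_k) <= anchor_k and (i - segs[-1][0]) == (j - segs[-1][2]):
            segs[-1][1] = max(segs[-1][1], i + anchor_k)
            segs[-1][3] = max(segs[-1][3], j + anchor_k)
        else:
            segs.append([i, i + anchor_k, j, j + anchor_k])
    anchor_cols = sum(s[1] - s[0] for s in segs)
    if anchor_cols < 0.2 * min(len(a), len(b)):
        return None
    mism = 0
    cols = segs[0][1] - segs[0][0]
    for s1, s2 in zip(segs, segs[1:]):
        ga = s2[0] - s1[1]
        gb = s2[2] - s1[3]
        if ga < 0 or gb < 0:
            continue  # overlapping off-diagonal anchors; skip the gap
        m = min(ga, gb)
        mism += sum(
            a[s1[1] + t] != b[s1[3] + t] for t in range(m)
        )
        mism += abs(ga - gb)
        cols += max(ga, gb)
        cols += s2[1] - s2[0]
    if cols <= 0:
        return None
    return mism / cols
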