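"""ORF discovery, defect classification, domain-motif scans and
asparagine-rich insert detection.

PLE ORFs (usually 800-900 aa; 1,300-1,500 aa with an N-rich insert) encode
an RT domain and a GIY-YIG endonuclease.  Genomic copies decay through
frameshifts, in-frame stops, indels, truncations and microhomology-mediated
deletions; this module calls those defects against a family reference and
locates the long in-frame inserts with 25-30% asparagine content that
distinguish several families.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from ._util import extend_seed, revcomp

__all__ = [
    "OrfRecord",
    "Defect",
    "NRichSegment",
    "find_orfs",
    "classify_defects",
    "scan_giy_yig",
    "scan_cys_motif",
    "detect_n_rich",
    "detect_aay_bias",
    "is_intact",
]

DEFAULT_MIN_AA = 300  # element ORFs are 830+ aa
NRICH_WINDOW = 50
NRICH_THRESHOLD = 0.25
NRICH_MIN_LEN = 100
TRUNC_THRESHOLD_AA = 30
INTACT_LEN_TOLERANCE = 0.05


@dataclass(frozen=True)
class Defect:
    kind: str
    position: int  # aa coordinate in the reference protein
    evidence: str = ""


@dataclass
class OrfRecord:
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    defects: list[Defect] = field(default_factory=list)
    intact: bool = False

    @property
    def aa_len(self) -> int:
        return len(self.protein)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class NRichSegment:
    aa_start: int
    aa_end: int
    asn_fraction: float

    @property
    def length_aa(self) -> int:
        return self.aa_end - self.aa_start


def find_orfs(seq: str, min_aa: int = DEFAULT_MIN_AA) -> list[OrfRecord]:
    """All ATG-initiated, stop-terminated ORFs of >= ``min_aa`` residues in
    all six frames (nested starts sharing a stop are all reported).
    ``aa_len`` excludes the stop; intervals are locus coordinates and
    include the stop codon."""
    n = len(seq)
    out: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            starts: list[int] = []
            for p in range(frame, len(s) - 2, 3):
                codon = s[p : p + 3]
                if codon == "ATG":
                    starts.append(p)
                elif codon in ("TAA", "TAG", "TGA"):
                    for a in starts:
                        if (p - a) // 3 >= min_aa:
                            lo, hi = a, p + 3
                            if strand == "-":
                                lo, hi = n - (p + 3), n - a
                            prot = str(Seq(s[a:p]).translate())
                            out.append(OrfRecord(lo, hi, strand, frame, prot))
                    starts = []
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


# --- defect classification -------------------------------------------------


@dataclass(frozen=True)
class _Block:
    r0: int
    r1: int
    q0: int
    q1: int
    frame: int

    @property
    def nt0(self) -> int:
        return self.frame + 3 * self.q0

    @property
    def nt1(self) -> int:
        return self.frame + 3 * self.q1


def _match_blocks(copy_dna: str, ref: str, k: int = 8, min_block: int = 10) -> list[_Block]:
    blocks: list[_Block] = []
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)
    for frame in range(3):
        prot = str(Seq(copy_dna[frame : frame + 3 * ((len(copy_dna) - frame) // 3)]).translate())
        covered: dict[int, int] = {}
        for q in range(len(prot) - k + 1):
            for r in index.get(prot[q : q + k], ()):
                diag = r - q
                if covered.get(diag, -1) > q:
                    continue
                q0, q1, r0, r1 = extend_seed(prot, ref, q, r, k, max_mm_run=3, commit_run=4)
                covered[diag] = q1
                if q1 - q0 >= min_block:
                    blocks.append(_Block(r0, r1, q0, q1, frame))
    return blocks


def _chain_blocks(blocks: list[_Block]) -> list[_Block]:
    chain: list[_Block] = []
    for b in sorted(blocks, key=lambda b: (b.r0, b.q0)):
        if not chain:
            chain.append(b)
            continue
        prev = chain[-1]
        ov = prev.r1 - b.r0
        if ov > 10 or b.nt1 <= prev.nt1:
            continue
        if ov > 0:  # trim overlapping head (ambiguous junction residues)
            b = _Block(b.r0 + ov, b.r1, b.q0 + ov, b.q1, b.frame)
        if b.r1 > b.r0 and b.nt0 >= prev.nt1 - 3 * 10:
            chain.append(b)
    return chain


def _junction_ambiguity(
    copy_dna: str, ref_dna: str, b1: "_Block", b2: "_Block"
) -> tuple[int, int]:
    """Exact-DNA junction analysis of a deletion between two chained blocks.

    The left block maps copy position c to reference c + shift_l, the right
    block to c + shift_r.  Scanning the left diagonal rightwards and the
    right diagonal leftwards gives the maximal exact extents; their overlap
    is the junction ambiguity — the breakpoint microhomology length.
    Returns (microhomology_len, deletion_size)."""
    shift_l = 3 * b1.r0 - b1.nt0
    shift_r = 3 * b2.r0 - b2.nt0
    size = shift_r - shift_l
    if size <= 0:
        return 0, size
    c = max(b1.nt0, b1.nt1 - 30)
    while c < len(copy_dna) and c + shift_l < len(ref_dna) and copy_dna[c] == ref_dna[c + shift_l]:
        c += 1
    c_max = c
    c = min(b2.nt1, b2.nt0 + 30)
    while c > 0 and c - 1 + shift_r >= 0 and copy_dna[c - 1] == ref_dna[c - 1 + shift_r]:
        c -= 1
    c_min = c
    return max(0, c_max - c_min), size


def classify_defects(
    copy_dna: str,
    reference_protein: str,
    reference_dna: str | None = None,
    trunc_threshold: int = TRUNC_THRESHOLD_AA,
) -> list[Defect]:
    """Classify ORF defects of a genomic copy against a full-length family
    reference.

    The three forward-frame translations of the copy are tiled onto the
    reference by exact 8-aa seed words with ungapped extension.  A frame
    switch between adjacent blocks is a frameshift; a stop codon inside a
    matched frame is a premature stop; a missing reference prefix/suffix of
    >= ``trunc_threshold`` aa is a 5'/3' truncation; a deletion whose
    reference breakpoints share >= 2 bp is a microhomology-mediated deletion
    (breakpoint homology needs ``reference_dna``; without it the call falls
    back to a plain indel).  A copy with no recognizable block yields a
    combined trunc5+trunc3 record.
    """
    ref = reference_protein
    chain = _chain_blocks(_match_blocks(copy_dna, ref))
    if not chain:
        return [
            Defect("trunc5", 0, "unrecognizable"),
            Defect("trunc3", len(ref), "unrecognizable"),
        ]
    defects: list[Defect] = []

    def frame_prot_of(frame: int) -> str:
        return str(
            Seq(copy_dna[frame : frame + 3 * ((len(copy_dna) - frame) // 3)]).translate()
        )

    # stops inside matched blocks (the mismatch-tolerant extension runs
    # straight through an isolated in-frame stop)
    for b in chain:
        seg = frame_prot_of(b.frame)[b.q0 : b.q1]
        for off, aa in enumerate(seg):
            if aa == "*":
                defects.append(
                    Defect("premature_stop", b.r0 + off, f"stop at aa {b.r0 + off}")
                )

    first, last = chain[0], chain[-1]
    if first.r0 >= trunc_threshold:
        defects.append(Defect("trunc5", first.r0, f"missing first {first.r0} aa"))
    if len(ref) - last.r1 >= trunc_threshold:
        defects.append(Defect("trunc3", last.r1, f"missing last {len(ref) - last.r1} aa"))

    for b1, b2 in zip(chain, chain[1:]):
        ref_gap = b2.r0 - b1.r1
        copy_gap = b2.nt0 - b1.nt1
        pos = b1.r1
        if b1.frame != b2.frame:
            defects.append(
                Defect("frameshift", pos, f"frame {b1.frame}->{b2.frame} at aa {pos}")
            )
            continue
        between = frame_prot_of(b1.frame)[b1.q1 : b2.q0]
        if "*" in between:
            stop_at = pos + between.index("*")
            defects.append(Defect("premature_stop", stop_at, f"stop at aa {stop_at}"))
            continue
        if ref_gap - copy_gap // 3 >= 2:  # deletion relative to the reference
            mh, size = 0, 3 * ref_gap - copy_gap
            if reference_dna:
                mh, size = _junction_ambiguity(copy_dna, reference_dna, b1, b2)
            if mh >= 2:
                defects.append(
                    Defect(
                        "microhomology_deletion",
                        pos,
                        f"deletion of {size} bp, microhomology {mh} bp",
                    )
                )
            else:
                defects.append(Defect("indel", pos, f"deletion of {size} bp"))
        elif copy_gap - 3 * ref_gap >= 3:
            defects.append(Defect("indel", pos, f"insertion of {copy_gap - 3 * ref_gap} bp"))
    defects.sort(key=lambda d: (d.position, d.kind))
    return defects


def microhomology_of_defect(d: Defect) -> int | None:
    m = re.search(r"microhomology (\d+) bp", d.evidence)
    return int(m.group(1)) if m else None


def is_intact(
    copy_dna: str,
    reference_protein: str,
    reference_dna: str | None = None,
    require_giy_yig: bool = True,
) -> bool:
    """A copy is intact when it shows no defects against the family
    reference, its longest ORF is within 5% of the reference length, and
    (for EN+ families) the GIY-YIG motif is present."""
    if classify_defects(copy_dna, reference_protein, reference_dna):
        return False
    orfs = find_orfs(copy_dna, min_aa=max(30, int(0.5 * len(reference_protein))))
    if not orfs:
        return False
    best = max(orfs, key=lambda o: o.aa_len)
    if abs(best.aa_len - len(reference_protein)) > INTACT_LEN_TOLERANCE * len(reference_protein):
        return False
    if require_giy_yig and scan_giy_yig(best.protein) is None:
        return False
    return True


# --- motif scans -----------------------------------------------------------


def scan_giy_yig(protein: str, min_gap: int = 8, max_gap: int = 12) -> tuple[int, int] | None:
    """First occurrence of literal GIY followed by YIG with an 8-12 aa gap;
    returns ``(giy_pos, yig_pos)`` or ``None``."""
    for m in re.finditer("GIY", protein):
        g = m.start()
        lo, hi = g + 3 + min_gap, g + 3 + max_gap
        for y in range(lo, hi + 1):
            if protein[y : y + 3] == "YIG":
                return (g, y)
    return None


CYS_MOTIF = re.compile(r"(?=([CH].{1,3}C.{10}C.{2}C))")


def scan_cys_motif(protein: str) -> list[tuple[int, int]]:
    """All (overlapping) matches of the Cys-rich insert motif
    Cys/His-X(1-3)-Cys-X(10)-Cys-X(2)-Cys, as ``(start, end)`` spans (the
    greedy, longest-gap variant per start position)."""
    return [(m.start(), m.start() + len(m.group(1))) for m in CYS_MOTIF.finditer(protein)]


# --- compositional bias ----------------------------------------------------


def detect_n_rich(
    protein: str,
    window: int = NRICH_WINDOW,
    threshold: float = NRICH_THRESHOLD,
    min_len: int = NRICH_MIN_LEN,
) -> list[NRichSegment]:
    """Maximal asparagine-rich segments: the union of all ``window``-sized
    windows with Asn fraction >= ``threshold``, merged and filtered to
    >= ``min_len`` aa, each reported with its exact Asn fraction."""
    n = len(protein)
    if window > n or window < 1:
        return []
    is_n = np.frombuffer(protein.encode(), dtype="S1") == b"N"
    csum = np.concatenate([[0], np.cumsum(is_n)])
    counts = csum[window:] - csum[:-window]
    starts = np.nonzero(counts >= threshold * window)[0]
    segments: list[NRichSegment] = []
    if len(starts) == 0:
        return segments
    # union of the qualifying windows, merging overlapping intervals
    cur_a, cur_b = int(starts[0]), int(starts[0]) + window
    bounds: list[tuple[int, int]] = []
    for i in starts[1:]:
        if i <= cur_b:
            cur_b = int(i) + window
        else:
            bounds.append((cur_a, cur_b))
            cur_a, cur_b = int(i), int(i) + window
    bounds.append((cur_a, cur_b))
    for a, b in bounds:
        if b - a >= min_len:
            frac = float(csum[b] - csum[a]) / (b - a)
            segments.append(NRichSegment(a, b, frac))
    return segments


def detect_aay_bias(dna: str, window: int = 150) -> tuple[np.ndarray, list[int], bool]:
    """Sliding-window density of Asn codons (AAT/AAC) along an in-frame
    coding sequence.

    ``window`` is in bp and is rounded down to whole codons.  Returns the
    per-start densities (one per codon offset), the start positions (codon
    index) of the maxima — candidate insertion-prone sites — and a flag set
    when trailing bases were ignored.
    """
    w = max(1, window // 3)
    trailing = len(dna) % 3 != 0
    codons = [dna[i : i + 3] for i in range(0, len(dna) - 2, 3)]
    if len(codons) < w:
        return np.zeros(0), [], trailing
    flags = np.array([c in ("AAT", "AAC") for c in codons], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    dens = (csum[w:] - csum[:-w]) / w
    peak = dens.max()
    maxima = [int(i) for i in np.nonzero(dens == peak)[0]]
    return dens, maxima, trailing
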