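"""Seeded generator of synthetic Penelope-like element (PLE) loci.

PLEs are retroelements whose single ORF (reverse transcriptase plus a
GIY-YIG endonuclease) is bounded by "pseudo-LTRs" (pLTRs): terminal repeats
that, unlike true LTRs, may occur in direct and/or inverted arrangements,
overlap the ORF start, and optionally carry a short 3' "tail" extension.
Insertion through the element endonuclease duplicates the target site,
leaving short identical TSD copies on both flanks.

This module emits such loci (plus allelic pairs, pLTR-framed gene-capture
loci and small-RNA read libraries) together with machine-readable ground
truth, so that every downstream detector can be exercised against known
coordinates.

Ground-truth coordinates are 0-based half-open.  Planted structures are
*maximal* by construction: the generator constrains the bases immediately
outside a planted repeat/tail/TSD so that exact extension stops precisely at
the planted boundary, and rejection-samples promoter motifs to be unique
within the pLTR.  This makes the annotated values of a defect-free locus
well defined rather than merely likely.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from ._util import child_rng, complement, random_dna, random_dna_at_rich, revcomp

__all__ = [
    "LocusSpec",
    "InsertSpec",
    "DefectSpec",
    "PromoterSpec",
    "SmallRnaLibrarySpec",
    "Feature",
    "GroundTruth",
    "SpecValidationError",
    "forge_locus",
    "forge_orf",
    "forge_pltr",
    "forge_capture_locus",
    "forge_allelic_pair",
    "forge_smallrna_library",
]

# --- genetic code tables ---------------------------------------------------

STOP_CODONS = ("TAA", "TAG", "TGA")
CODON_TO_AA = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product("ACGT", repeat=3)
}
SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
ASN_CODONS = ("AAT", "AAC")
NON_ASN_SENSE = [c for c in SENSE_CODONS if c not in ASN_CODONS]
AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_c)

#: placeholder catalytic motifs embedded in every forged element protein;
#: YxDD is the canonical RT active-site signature, GIY-(10aa)-YIG the
#: endonuclease superfamily signature scanned by the ORF annotator.
RT_MOTIF_AA = "YVDD"
GIY_YIG_GAP = 10

ARRANGEMENTS = (
    "DD_plus_inverted5p",
    "DD_only",
    "inverted_pair",
    "solo",
    "tandem_partial",
)
INSERT_POSITIONS = ("RT_EN_linker", "RT_thumb_linker")
DEFECT_KINDS = (
    "frameshift",
    "stop",
    "trunc5",
    "trunc3",
    "indel",
    "microhomology_deletion",
)


class _ForgeRetry(Exception):
    """Internal: a rejection-sampling budget ran out; retry the whole locus
    with a fresh random stream."""


class SpecValidationError(ValueError):
    """Raised when a generator spec violates an invariant; names the field."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"{fld}: {message}")


# --- spec dataclasses ------------------------------------------------------


@dataclass(frozen=True)
class PromoterSpec:
    """TATA/Inr core-promoter motifs planted inside the pLTR.

    The defaults reproduce the motif pair observed in Pen2a-type pLTRs: a
    TATATATA box separated by 20 bp from a TCACT initiator, with the reverse
    orientation carrying its own downstream ACATT initiator (the TATA box
    itself is reverse-complement symmetric, so one planted box serves both
    strands).
    """

    tata_motif: str = "TATATATA"
    inr_motif: str = "TCACT"
    spacing: int = 20
    bidirectional: bool = True
    rev_inr_motif: str = "ACATT"

    def validate(self) -> None:
        if not self.tata_motif or not self.inr_motif:
            raise SpecValidationError("tata_motif/inr_motif", "motifs must be non-empty")
        if self.spacing < 0:
            raise SpecValidationError("spacing", "must be >= 0")


@dataclass(frozen=True)
class InsertSpec:
    """In-frame asparagine-rich segment inserted into the element ORF."""

    aa_len: int = 467
    asn_fraction: float = 0.30
    position: str = "RT_EN_linker"
    in_frame: bool = True

    def validate(self) -> None:
        if self.aa_len < 1:
            raise SpecValidationError("insert.aa_len", "must be >= 1")
        if not 0.0 <= self.asn_fraction <= 1.0:
            raise SpecValidationError("insert.asn_fraction", "must be in [0, 1]")
        if self.position not in INSERT_POSITIONS:
            raise SpecValidationError("insert.position", f"one of {INSERT_POSITIONS}")


@dataclass(frozen=True)
class DefectSpec:
    """A planted ORF defect.

    position is a 1-based residue number for kinds ``stop`` (the codon of
    that residue becomes a stop, so translation yields position-1 residues)
    and ``frameshift``, and a 0-based nucleotide offset into the ORF for
    ``indel`` and ``microhomology_deletion``; ``size`` is in bp (for
    ``indel`` a negative size means an insertion of ``|size|`` random
    bases).
    """

    kind: str
    position: int = 0
    size: int = 0
    microhomology_len: int = 0

    def validate(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise SpecValidationError("defects.kind", f"one of {DEFECT_KINDS}")
        if self.kind == "microhomology_deletion" and self.microhomology_len < 2:
            raise SpecValidationError(
                "defects.microhomology_len", "must be >= 2 for microhomology_deletion"
            )


@dataclass(frozen=True)
class LocusSpec:
    """Blueprint for one synthetic PLE insertion locus.

    Defaults reproduce the Pen2a-type structure: an 842-aa ORF bounded by two
    218-bp direct pLTRs plus an adjacent 5' inverted pLTR that overlaps the
    direct one by 15 bp and is truncated by 37 bp (181 bp), a 31-bp tail, a
    9-bp TSD, an 18-bp terminal palindrome and a bidirectional TATA/Inr
    promoter; the pLTR encodes the first 12 ORF residues.
    """

    seed: int = 0
    flank_len: int = 300
    pltr_len: int = 218
    pltr_identity: float = 1.0
    arrangement: str = "DD_plus_inverted5p"
    overlap_5p: int = 15
    trunc_5p_inverted: int = 37
    tail_len: int = 31
    tsd_len: int = 9
    tsd_motif: str | None = None
    orf_aa: int = 842
    insert: InsertSpec | None = None
    defects: tuple[DefectSpec, ...] = ()
    palindrome_len: int = 18
    palindrome_mismatches: int = 0
    promoter: PromoterSpec | None = PromoterSpec()
    spacer_len: int = 0
    orf_lead_aa: int = 12
    at_rich_flanks: float | None = None  # AT fraction of flanks; None = uniform

    def validate(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise SpecValidationError("arrangement", f"one of {ARRANGEMENTS}")
        if not self.pltr_len > self.tail_len >= 0:
            raise SpecValidationError("tail_len", "need pltr_len > tail_len >= 0")
        if not 0 <= self.overlap_5p < self.pltr_len:
            raise SpecValidationError("overlap_5p", "must satisfy 0 <= overlap < pltr_len")
        if not 0 <= self.tsd_len <= 25:
            raise SpecValidationError("tsd_len", "must be in [0, 25]")
        if self.tsd_motif is not None and len(self.tsd_motif) != self.tsd_len:
            raise SpecValidationError("tsd_motif", "length must equal tsd_len")
        if self.orf_aa < 1:
            raise SpecValidationError("orf_aa", "must be >= 1")
        if not 0 <= self.trunc_5p_inverted < self.pltr_len:
            raise SpecValidationError("trunc_5p_inverted", "must be in [0, pltr_len)")
        if not 0.0 <= self.pltr_identity <= 1.0:
            raise SpecValidationError("pltr_identity", "must be in [0, 1]")
        if self.palindrome_len < 0 or self.palindrome_len > self.pltr_len:
            raise SpecValidationError("palindrome_len", "must be in [0, pltr_len]")
        if self.arrangement == "DD_plus_inverted5p" and self.overlap_5p > 0:
            if self.trunc_5p_inverted < self.palindrome_len:
                raise SpecValidationError(
                    "trunc_5p_inverted",
                    "must be >= palindrome_len so the overlap mirror region does "
                    "not collide with the terminal palindrome",
                )
        if self.tail_len > 0 and self.arrangement in ("DD_only", "solo", "tandem_partial"):
            raise SpecValidationError(
                "tail_len", "tails attach to inverted pLTRs; arrangement has none"
            )
        if self.insert is not None:
            self.insert.validate()
        for d in self.defects:
            d.validate()
            if self.arrangement in ("DD_plus_inverted5p", "DD_only", "tandem_partial"):
                lead_nt = 3 * self.orf_lead_aa
                pos_nt = (d.position - 1) * 3 if d.kind in ("stop", "frameshift") else d.position
                if d.kind == "trunc5" or pos_nt < lead_nt:
                    raise SpecValidationError(
                        "defects.position",
                        "defects inside the pLTR-encoded ORF lead are not "
                        "representable in this arrangement",
                    )
        if self.promoter is not None:
            self.promoter.validate()
        if self.spacer_len < 0:
            raise SpecValidationError("spacer_len", "must be >= 0")


@dataclass(frozen=True)
class SmallRnaLibrarySpec:
    """Spec for a synthetic 25-32 nt small-RNA (piRNA-like) library."""

    n_reads: int = 10000
    len_range: tuple[int, int] = (25, 32)
    antisense_fraction: float = 0.9
    u5_bias: float = 0.8
    source_interval: tuple[int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.len_range
        if not (15 <= lo <= hi <= 50):
            raise SpecValidationError("len_range", "must lie within [15, 50]")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise SpecValidationError("antisense_fraction", "must be in [0, 1]")
        if not 0.0 <= self.u5_bias <= 1.0:
            raise SpecValidationError("u5_bias", "must be in [0, 1]")
        if self.n_reads < 0:
            raise SpecValidationError("n_reads", "must be >= 0")


# --- ground truth ----------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """One annotated interval of a forged locus (0-based half-open)."""

    type: str
    start: int
    end: int
    strand: str = "+"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("feature end < start")


@dataclass
class GroundTruth:
    locus_id: str
    length: int
    features: list[Feature]
    meta: dict

    def of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def validate(self) -> None:
        for f in self.features:
            if not (0 <= f.start <= f.end <= self.length):
                raise ValueError(f"feature {f} outside locus of length {self.length}")


# --- ORF forging -----------------------------------------------------------


def _aa_to_codon(rng: np.random.Generator, aa: str) -> str:
    codons = AA_TO_CODONS[aa]
    return codons[int(rng.integers(0, len(codons)))]


def _random_sense_codon(rng: np.random.Generator, exclude_asn: bool = False) -> str:
    pool = NON_ASN_SENSE if exclude_asn else SENSE_CODONS
    return pool[int(rng.integers(0, len(pool)))]


def _insert_codons(rng: np.random.Generator, spec: InsertSpec) -> list[str]:
    # Asn positions are stratified per 10-aa block (exact count per block,
    # random placement within it): the inserts are *uniformly* N-rich, so a
    # window of any reasonable size sees close to the target composition.
    # Asn codons split evenly between AAT and AAC; non-Asn positions draw
    # from the 59 non-Asn sense codons so the realised fraction is unbiased.
    out: list[str] = []
    block = 10
    for start in range(0, spec.aa_len, block):
        size = min(block, spec.aa_len - start)
        expect = spec.asn_fraction * size
        n_asn = int(expect) + (1 if rng.random() < expect - int(expect) else 0)
        n_asn = min(n_asn, size)
        asn_pos = set(rng.choice(size, n_asn, replace=False).tolist())
        for i in range(size):
            if i in asn_pos:
                out.append(ASN_CODONS[int(rng.integers(0, 2))])
            else:
                out.append(_random_sense_codon(rng, exclude_asn=True))
    return out


def _core_codons(rng: np.random.Generator, orf_aa: int) -> list[str]:
    codons = ["ATG"] + [_random_sense_codon(rng) for _ in range(orf_aa - 1)]
    if orf_aa >= 60:
        rt_pos = round(0.40 * orf_aa)
        for off, aa in enumerate(RT_MOTIF_AA):
            codons[rt_pos + off] = _aa_to_codon(rng, aa)
        giy_pos = round(0.78 * orf_aa)
        en = "GIY" + "".join(
            "ACDEFHKLMNPQRSTVW"[int(rng.integers(0, 17))] for _ in range(GIY_YIG_GAP)
        ) + "YIG"
        for off, aa in enumerate(en):
            codons[giy_pos + off] = _aa_to_codon(rng, aa)
    return codons


def insert_offset_aa(orf_aa: int, position: str) -> int:
    """Fixed relative position of an N-rich insert within the core ORF."""
    frac = 0.60 if position == "RT_EN_linker" else 0.50
    return round(frac * orf_aa)


def _forge_orf_full(
    orf_aa: int,
    insert: InsertSpec | None,
    defects: tuple[DefectSpec, ...],
    rng: np.random.Generator,
    stop_codon: str = "TAA",
) -> tuple[str, str, list[dict], tuple[int, int] | None]:
    """Build the ORF; returns (defective_dna, intact_reference_dna, defect_truth).

    The intact reference already carries any microhomology repeat planted at
    deletion breakpoints, so it is the correct family reference for defect
    classification.
    """
    codons = _core_codons(rng, orf_aa)
    insert_iv_aa = None
    if insert is not None:
        insert.validate()
        pos = insert_offset_aa(orf_aa, insert.position)
        ins = _insert_codons(rng, insert)
        if not insert.in_frame:
            # a frame-breaking insert: one stray base at the junction
            ins[-1] = ins[-1] + "ACGT"[int(rng.integers(0, 4))]
        codons = codons[:pos] + ins + codons[pos:]
        insert_iv_aa = (pos, pos + insert.aa_len)
    dna = "".join(codons) + stop_codon

    truth: list[dict] = []
    intact = dna
    for d in defects:
        d.validate()
        dna, intact, rec = _apply_defect(dna, intact, d, rng)
        truth.append(rec)
    return dna, intact, truth, insert_iv_aa


def _apply_defect(dna, intact, d: DefectSpec, rng):
    n = len(dna)
    if d.kind == "stop":
        p = 3 * (d.position - 1)
        if not 0 <= p <= n - 3:
            raise SpecValidationError("defects.position", "outside ORF")
        dna = dna[:p] + "TAA" + dna[p + 3 :]
        rec = {"kind": "stop", "nt": p, "aa": d.position}
    elif d.kind == "frameshift":
        p = 3 * (d.position - 1)
        if not 0 <= p < n:
            raise SpecValidationError("defects.position", "outside ORF")
        if d.size > 0:
            dna = dna[:p] + "ACGT"[int(rng.integers(0, 4))] + dna[p:]
        else:
            dna = dna[:p] + dna[p + 1 :]
        rec = {"kind": "frameshift", "nt": p, "aa": d.position}
    elif d.kind == "trunc5":
        if not 0 < d.size < n:
            raise SpecValidationError("defects.size", "outside ORF")
        dna = dna[d.size :]
        rec = {"kind": "trunc5", "nt": 0, "size": d.size}
    elif d.kind == "trunc3":
        if not 0 < d.size < n:
            raise SpecValidationError("defects.size", "outside ORF")
        dna = dna[: n - d.size]
        rec = {"kind": "trunc3", "nt": len(dna), "size": d.size}
    elif d.kind == "indel":
        p = d.position
        if not 0 <= p < n:
            raise SpecValidationError("defects.position", "outside ORF")
        if d.size < 0:
            dna = dna[:p] + random_dna(rng, -d.size) + dna[p:]
        else:
            if p + d.size > n:
                raise SpecValidationError("defects.size", "runs past ORF end")
            dna = dna[:p] + dna[p + d.size :]
        rec = {"kind": "indel", "nt": p, "size": d.size}
    elif d.kind == "microhomology_deletion":
        p, size, m = d.position, d.size, d.microhomology_len
        if not (0 <= p and p + size + m <= n):
            raise SpecValidationError("defects.position", "deletion outside ORF")
        if size <= m:
            raise SpecValidationError("defects.size", "must exceed microhomology_len")
        # plant the repeat at both breakpoints of the *intact* sequence, then
        # delete one period; constrain the bases just outside the repeat so
        # the planted microhomology length is maximal.
        s = list(dna)
        s[p + size : p + size + m] = dna[p : p + m]
        if p + size + m < len(s) and s[p + m] == s[p + size + m]:
            s[p + m] = _other_base(rng, s[p + m])
        if p > 0 and s[p - 1] == s[p + size - 1]:
            s[p + size - 1] = _other_base(rng, s[p + size - 1])
        planted = "".join(s)
        dna = planted[:p] + planted[p + size :]
        intact = planted
        rec = {
            "kind": "microhomology_deletion",
            "nt": p,
            "size": size,
            "microhomology_len": m,
        }
        return dna, intact, rec
    else:  # pragma: no cover
        raise SpecValidationError("defects.kind", d.kind)
    return dna, intact, rec


def _other_base(rng, b: str) -> str:
    pool = [x for x in "ACGT" if x != b]
    return pool[int(rng.integers(0, 3))]


def forge_orf(
    orf_aa: int,
    insert: InsertSpec | None = None,
    defects: tuple[DefectSpec, ...] = (),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> str:
    """Forge an element ORF: ATG-initiated, single terminal stop, RT and
    GIY-YIG placeholder motifs at fixed relative positions, optional in-frame
    N-rich insert and planted defects.  Returns the (possibly defective) DNA.
    """
    if orf_aa < 1:
        raise SpecValidationError("orf_aa", "must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dna, _, _, _ = _forge_orf_full(orf_aa, insert, tuple(defects), rng)
    return dna


# --- pLTR forging ----------------------------------------------------------


def _count(hay: str, needle: str) -> int:
    # overlapping occurrence count
    return sum(
        1 for i in range(len(hay) - len(needle) + 1) if hay[i : i + len(needle)] == needle
    )


def forge_pltr(
    rng: np.random.Generator,
    pltr_len: int,
    palindrome_len: int = 18,
    palindrome_mismatches: int = 0,
    promoter: PromoterSpec | None = None,
    orf_head: str = "",
    mirror: tuple[int, int] | None = None,
) -> str:
    """Forge one pLTR sequence.

    Layout (5'->3'): terminal palindrome, optional overlap mirror region
    (``mirror=(trunc, overlap)`` writes revcomp of the unit start at the
    position where a truncated inverted copy will overlap the direct copy),
    optional promoter motifs, random body, and the first ORF codons at the
    3' end.  Promoter motifs are rejection-sampled to be unique in the unit.
    """
    for _ in range(200):
        s = list(random_dna(rng, pltr_len))
        # terminal palindrome: left arm + optional centre + revcomp(arm)
        if palindrome_len >= 2:
            arm = (palindrome_len - palindrome_len % 2) // 2
            left = random_dna(rng, arm)
            centre = random_dna(rng, palindrome_len % 2)
            pal = left + centre + revcomp(left)
            s[:palindrome_len] = pal
            if palindrome_mismatches:
                lo, hi = arm + (palindrome_len % 2), palindrome_len - 1
                if hi - lo < palindrome_mismatches:
                    raise SpecValidationError(
                        "palindrome_mismatches", "too many for arm length"
                    )
                picks = rng.choice(np.arange(lo, hi), palindrome_mismatches, replace=False)
                for p in picks:
                    s[p] = _other_base(rng, s[p])
        if mirror is not None:
            trunc, overlap = mirror
            s[trunc : trunc + overlap] = revcomp("".join(s[:overlap]))
            # The mirror region lets the truncated inverted copy and the
            # direct copy share the overlap bases exactly.  It also means the
            # inverted-repeat alignment could run on past the truncation
            # point, so force a run of mismatching positions right after it:
            # the alignment then stops at the annotated boundary on every
            # seed instead of most of them.
            for w in range(5):
                lo_pos, hi_pos = overlap + w, trunc - 1 - w
                if 0 <= lo_pos < hi_pos < pltr_len:
                    while s[hi_pos] == complement(s[lo_pos]):
                        s[hi_pos] = _other_base(rng, s[hi_pos])
            if trunc + overlap < pltr_len:
                if s[trunc + overlap] == complement(s[overlap]):
                    s[trunc + overlap] = _other_base(rng, s[trunc + overlap])
        prom_end = 0
        if promoter is not None:
            base = palindrome_len
            if mirror is not None:
                base = max(base, mirror[0] + mirror[1] + 2)
            pos = base
            if promoter.bidirectional:
                rev_inr = revcomp(promoter.rev_inr_motif)
                pos = base + len(rev_inr) + promoter.spacing
                s[base : base + len(rev_inr)] = rev_inr
            tata_pos = pos + 2
            inr_pos = tata_pos + len(promoter.tata_motif) + promoter.spacing
            prom_end = inr_pos + len(promoter.inr_motif)
            if prom_end > pltr_len - len(orf_head) - 2:
                raise SpecValidationError(
                    "pltr_len", "too short for palindrome + promoter + ORF head"
                )
            s[tata_pos : tata_pos + len(promoter.tata_motif)] = promoter.tata_motif
            s[inr_pos : inr_pos + len(promoter.inr_motif)] = promoter.inr_motif
        if orf_head:
            if len(orf_head) > pltr_len - max(palindrome_len, prom_end):
                raise SpecValidationError("pltr_len", "too short for the ORF head")
            s[pltr_len - len(orf_head) :] = orf_head
        unit = "".join(s)
        # motif uniqueness: exactly one promoter motif set (or none at all)
        tata = promoter.tata_motif if promoter else "TATATATA"
        want_tata = 1 if promoter else 0
        if _count(unit, tata) != want_tata:
            continue
        if promoter:
            if _count(unit, promoter.inr_motif) != 1:
                continue
            if promoter.bidirectional and _count(revcomp(unit), promoter.rev_inr_motif) != 1:
                continue
            if not promoter.bidirectional and _count(revcomp(unit), "ACATT") > 0:
                continue
        return unit
    raise _ForgeRetry("could not satisfy pLTR motif-uniqueness constraints")


# --- locus assembly --------------------------------------------------------


def _draw_tsd(rng, spec: LocusSpec, forbidden_first: str = "") -> str:
    if spec.tsd_motif is not None:
        return spec.tsd_motif
    while True:
        m = random_dna(rng, spec.tsd_len)
        if spec.tsd_len == 0:
            return m
        # keep the tail / inverted-pair extension maximal: the base entering
        # from the right flank must not complement the one leaving on the
        # left, must differ from the base after the 5' direct unit (or the
        # exact direct-pair run would extend into the TSD), and the last
        # base must not complement that same base (or the inverted-pair run
        # would extend across the 5' junction)
        if (
            m[0] != complement(m[-1])
            and (not forbidden_first or (m[0] != forbidden_first and m[-1] != complement(forbidden_first)))
        ):
            return m


def _copy(rng, seq: str, identity: float) -> str:
    if identity >= 1.0:
        return seq
    from ._util import mutate

    return mutate(rng, seq, 1.0 - identity)


def forge_locus(spec: LocusSpec, locus_id: str = "locus") -> tuple[str, GroundTruth]:
    """Forge a complete PLE insertion locus from ``spec``.

    Returns the DNA sequence and a :class:`GroundTruth` listing pLTR units,
    tail, TSD copies, ORF, N-rich insert, cassette and defect intervals.
    Identical specs (including the seed) give byte-identical output.
    """
    spec.validate()
    for attempt in range(50):
        rng = child_rng(spec.seed, attempt)
        try:
            seq, truth = _forge_locus_once(spec, rng, locus_id)
        except _ForgeRetry:
            continue
        if _tsd_is_maximal(seq, truth, spec):
            truth.validate()
            return seq, truth
    raise RuntimeError("could not forge a locus satisfying maximality constraints")


def _bg(rng, spec: LocusSpec, n: int) -> str:
    if spec.at_rich_flanks is not None:
        return random_dna_at_rich(rng, n, spec.at_rich_flanks)
    return random_dna(rng, n)


def _forge_locus_once(spec: LocusSpec, rng, locus_id):
    lead_nt = 3 * spec.orf_lead_aa
    feats: list[Feature] = []
    meta: dict = {"arrangement": spec.arrangement, "seed": spec.seed}

    has_body = spec.arrangement != "solo"
    orf_dna = orf_ref = ""
    defect_truth: list[dict] = []
    insert_iv_aa = None
    if has_body:
        # pick the stop codon so the base preceding the 3' direct unit differs
        # from the base preceding the 5' one (keeps the direct pair maximal)
        orf_dna, orf_ref, defect_truth, insert_iv_aa = _forge_orf_full(
            spec.orf_aa, spec.insert, spec.defects, rng, stop_codon="TAA"
        )
    head = orf_ref[:lead_nt] if spec.arrangement in (
        "DD_plus_inverted5p",
        "DD_only",
        "tandem_partial",
    ) else ""

    mirror = None
    if spec.arrangement == "DD_plus_inverted5p" and spec.overlap_5p > 0:
        mirror = (spec.trunc_5p_inverted, spec.overlap_5p)
    P = forge_pltr(
        rng,
        spec.pltr_len,
        spec.palindrome_len,
        spec.palindrome_mismatches,
        spec.promoter,
        orf_head=head,
        mirror=mirror,
    )
    meta["pltr_seq"] = P

    # the base just outside the element's 3' boundary must differ from the
    # base following the 5' direct unit's end, or a chance match would
    # contiguously extend the exact direct-pair run past the planted
    # boundary (a committed extension, since the run never breaks)
    after_d1 = ""
    if head and len(orf_dna) > lead_nt:
        after_d1 = orf_dna[lead_nt]

    tail = ""
    if spec.tail_len:
        tail = random_dna(rng, spec.tail_len)
        while after_d1 and tail[0] == after_d1:
            tail = _other_base(rng, tail[0]) + tail[1:]
    tsd = _draw_tsd(rng, spec, forbidden_first="" if tail else after_d1)

    lf = _bg(rng, spec, spec.flank_len)
    rf = _bg(rng, spec, spec.flank_len)
    if after_d1 and not tail and not spec.tsd_len:
        if rf and rf[0] == after_d1:
            rf = _other_base(rng, rf[0]) + rf[1:]
        if lf and lf[-1] == complement(after_d1):
            lf = lf[:-1] + _other_base(rng, lf[-1])
    spacer = _bg(rng, spec, spec.spacer_len)
    if spec.spacer_len == 0 and has_body:
        # stop codon choice keeps the direct-pair left boundary maximal
        if mirror:
            pre_d1 = complement(P[spec.trunc_5p_inverted + spec.overlap_5p])
        else:
            pre_d1 = tsd[-1] if spec.tsd_len else lf[-1]
        if orf_dna.endswith("TAA") and pre_d1 == "A":
            orf_dna = orf_dna[:-3] + "TAG"
            orf_ref = orf_ref[:-3] + "TAG" if orf_ref.endswith("TAA") else orf_ref
    elif spec.spacer_len and mirror:
        if spacer[-1] == complement(P[spec.trunc_5p_inverted + spec.overlap_5p]):
            spacer = spacer[:-1] + _other_base(rng, spacer[-1])

    parts: list[str] = [lf]
    pos = len(lf)

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        start = pos
        pos += len(s)
        return start, pos

    if spec.tsd_len:
        a, b = emit(tsd)
        feats.append(Feature("tsd", a, b, "+", {"motif": tsd, "side": "left"}))

    arr = spec.arrangement
    orf_iv = None
    if arr == "DD_plus_inverted5p":
        if tail:
            a, b = emit(revcomp(tail))
            feats.append(Feature("tail", a, b, "-", {"side": "5p_inverted", "seq": tail}))
        X = revcomp(_copy(rng, P, spec.pltr_identity)[spec.trunc_5p_inverted :])
        a, b = emit(X[: len(X) - spec.overlap_5p])
        inv_iv = (a, b + spec.overlap_5p)
        a, b = emit(P)
        d1_iv = (b - spec.pltr_len, b)
        feats.append(Feature("pltr", *inv_iv, "-", {"unit": "inverted", "len": inv_iv[1] - inv_iv[0]}))
        feats.append(Feature("pltr", *d1_iv, "+", {"unit": "direct"}))
        orf_start = d1_iv[1] - lead_nt
        a, b = emit(orf_dna[lead_nt:])
        orf_iv = (orf_start, b)
        if spacer:
            emit(spacer)
        a, b = emit(_copy(rng, P, spec.pltr_identity))
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
        if tail:
            a, b = emit(tail)
            feats.append(Feature("tail", a, b, "+", {"side": "3p", "seq": tail}))
    elif arr == "DD_only":
        a, b = emit(P)
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
        orf_start = b - lead_nt
        a, b = emit(orf_dna[lead_nt:])
        orf_iv = (orf_start, b)
        if spacer:
            emit(spacer)
        a, b = emit(_copy(rng, P, spec.pltr_identity))
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
    elif arr == "inverted_pair":
        if tail:
            a, b = emit(revcomp(tail))
            feats.append(Feature("tail", a, b, "-", {"side": "5p_inverted", "seq": tail}))
        a, b = emit(revcomp(_copy(rng, P, spec.pltr_identity)))
        feats.append(Feature("pltr", a, b, "-", {"unit": "inverted"}))
        a, b = emit(orf_dna)
        orf_iv = (a, b)
        if spacer:
            emit(spacer)
        a, b = emit(P)
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
    elif arr == "solo":
        a, b = emit(P)
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
    elif arr == "tandem_partial":
        a, b = emit(P)
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
        orf_start = b - lead_nt
        a, b = emit(orf_dna[lead_nt:])
        orf_iv = (orf_start, b)
        if spacer:
            emit(spacer)
        a, b = emit(_copy(rng, P, spec.pltr_identity))
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
        # 5'-truncated second copy: a short ORF remnant plus the terminal unit
        remnant = orf_dna[-40:]
        a, b = emit(remnant)
        feats.append(Feature("defect", a, b, "+", {"kind": "trunc5", "copy": 2}))
        a, b = emit(_copy(rng, P, spec.pltr_identity))
        feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))

    if spec.tsd_len:
        a, b = emit(tsd)
        feats.append(Feature("tsd", a, b, "+", {"motif": tsd, "side": "right"}))
    parts.append(rf)

    seq = "".join(parts)

    if orf_iv is not None:
        feats.append(Feature("orf", *orf_iv, "+", {"aa_len": (orf_iv[1] - orf_iv[0]) // 3 - 1}))
        if insert_iv_aa is not None:
            a = orf_iv[0] + 3 * insert_iv_aa[0]
            b = orf_iv[0] + 3 * insert_iv_aa[1]
            feats.append(Feature("n_rich_insert", a, b, "+", {"aa_len": insert_iv_aa[1] - insert_iv_aa[0]}))
        for rec in defect_truth:
            p = orf_iv[0] + rec["nt"]
            feats.append(Feature("defect", p, min(p + max(rec.get("size", 1), 1), len(seq)), "+", dict(rec)))

    meta.update(
        {
            "overlap_5p": spec.overlap_5p if arr == "DD_plus_inverted5p" else 0,
            "truncation_5p": spec.trunc_5p_inverted if arr == "DD_plus_inverted5p" else 0,
            "tail_len": spec.tail_len,
            "tsd_len": spec.tsd_len,
            "tsd_motif": tsd if spec.tsd_len else None,
            "orf_reference_dna": orf_ref,
            "orf_reference_protein": str(Seq(orf_ref).translate()).rstrip("*") if orf_ref else "",
        }
    )
    truth = GroundTruth(locus_id, len(seq), feats, meta)
    return seq, truth


def _element_span(truth: GroundTruth) -> tuple[int, int]:
    ivs = [(f.start, f.end) for f in truth.features if f.type in ("pltr", "tail")]
    if not ivs:
        return (0, truth.length)
    return (min(a for a, _ in ivs), max(b for _, b in ivs))


def _tsd_is_maximal(seq: str, truth: GroundTruth, spec: LocusSpec) -> bool:
    """No flank suffix/prefix match longer than the planted TSD (and none at
    all >= 4 bp when no TSD was planted)."""
    s0, s1 = _element_span(truth)
    left = seq[max(0, s0 - spec.tsd_len - 30) : s0]
    right = seq[s1 : s1 + spec.tsd_len + 30]
    limit = min(len(left), len(right), 25)
    for k in range(limit, max(spec.tsd_len, 3), -1):
        if k != spec.tsd_len and left[-k:] == right[:k]:
            return False
    if spec.tsd_len == 0:
        for k in range(min(limit, 25), 3, -1):
            if left[-k:] == right[:k]:
                return False
    return True


# --- capture loci and allelic pairs ---------------------------------------


def forge_capture_locus(
    cassette_exons: list[str],
    intron_lens: list[int],
    pltr: str,
    tsd_len: int,
    tsd_motif: str | None = None,
    flank_len: int = 300,
    seed: int = 0,
) -> tuple[str, GroundTruth]:
    """Forge a pLTR-framed gene-capture locus (NRPS-style event).

    The intron-containing cassette sits between two direct pLTRs, with an
    adjacent 5' inverted pLTR completing the structure; identical TSD copies
    flank the whole insert.  No element ORF sequence occurs between the
    direct units.  With ``flank_len=0`` and ``tsd_len=0`` the returned
    sequence is the bare insert, usable as an insertion payload for
    :func:`forge_allelic_pair`.
    """
    if not cassette_exons:
        raise SpecValidationError("cassette_exons", "cassette must have >= 1 exon")
    if len(intron_lens) != len(cassette_exons) - 1:
        raise SpecValidationError("intron_lens", "need len(exons) - 1 introns")
    if tsd_motif is not None and len(tsd_motif) != tsd_len:
        raise SpecValidationError("tsd_motif", "length must equal tsd_len")
    rng = child_rng(seed, 97)
    exon_ivs, intron_ivs = [], []
    cass_parts: list[str] = []
    off = 0
    for i, ex in enumerate(cassette_exons):
        cass_parts.append(ex)
        exon_ivs.append((off, off + len(ex)))
        off += len(ex)
        if i < len(intron_lens):
            ln = intron_lens[i]
            if ln < 4:
                raise SpecValidationError("intron_lens", "introns need >= 4 bp (GT..AG)")
            intron = "GT" + random_dna(rng, ln - 4) + "AG"
            cass_parts.append(intron)
            intron_ivs.append((off, off + ln))
            off += ln
    cassette = "".join(cass_parts)

    if tsd_motif is None and tsd_len:
        while True:
            tsd_motif = random_dna(rng, tsd_len)
            if tsd_motif[0] != complement(tsd_motif[-1]):
                break
    tsd = tsd_motif or ""

    lf = random_dna(rng, flank_len)
    rf = random_dna(rng, flank_len)

    feats: list[Feature] = []
    parts = [lf]
    pos = len(lf)

    def emit(s):
        nonlocal pos
        parts.append(s)
        a = pos
        pos += len(s)
        return a, pos

    if tsd:
        a, b = emit(tsd)
        feats.append(Feature("tsd", a, b, "+", {"motif": tsd, "side": "left"}))
    a, b = emit(revcomp(pltr))
    feats.append(Feature("pltr", a, b, "-", {"unit": "inverted"}))
    a, b = emit(pltr)
    feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
    ca, cb = emit(cassette)
    feats.append(
        Feature(
            "cassette",
            ca,
            cb,
            "+",
            {
                "n_exons": len(cassette_exons),
                "exons": [(ca + x, ca + y) for x, y in exon_ivs],
                "introns": [(ca + x, ca + y) for x, y in intron_ivs],
            },
        )
    )
    a, b = emit(pltr)
    feats.append(Feature("pltr", a, b, "+", {"unit": "direct"}))
    if tsd:
        a, b = emit(tsd)
        feats.append(Feature("tsd", a, b, "+", {"motif": tsd, "side": "right"}))
    parts.append(rf)
    seq = "".join(parts)
    meta = {"tsd_motif": tsd or None, "tsd_len": tsd_len, "pltr_seq": pltr}
    truth = GroundTruth("capture_locus", len(seq), feats, meta)
    truth.validate()
    return seq, truth


def forge_allelic_pair(
    sequence: str,
    divergence: float,
    insertion: tuple[str, int, str] | None = None,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """Derive an allelic pair from ``sequence``.

    allele_A optionally carries an insertion ``(ins_seq, position, tsd_motif)``
    with the target motif duplicated on both sides; allele_B keeps exactly one
    copy of the motif at the junction and diverges from the shared backbone by
    per-site substitutions at rate ``divergence`` (no indels).  The junction
    motif itself is protected from mutation, mirroring the observed empty
    sites where the would-be TSD is still present once.
    """
    if not 0.0 <= divergence <= 0.25:
        raise SpecValidationError("divergence", "must be in [0, 0.25]")
    from ._util import mutate

    truth: dict = {"divergence": divergence}
    if insertion is not None:
        ins_seq, p, motif = insertion
        if not 0 <= p <= len(sequence):
            raise SpecValidationError("insertion", "position outside sequence")
        allele_a = sequence[:p] + motif + ins_seq + motif + sequence[p:]
        empty = sequence[:p] + motif + sequence[p:]
        protected = set(range(p, p + len(motif)))
        truth.update(
            {
                "junction": p,
                "motif": motif,
                "insertion_interval_A": (p + len(motif), p + len(motif) + len(ins_seq)),
            }
        )
    else:
        allele_a, empty, protected = sequence, sequence, set()

    for attempt in range(20):
        rng = child_rng(seed, 11, attempt)
        allele_b = mutate(rng, empty, divergence, frozenset(protected))
        if insertion is None:
            break
        p, motif = truth["junction"], truth["motif"]
        if motif and _count(allele_b[max(0, p - 50) : p + len(motif) + 50], motif) == 1:
            break
    return allele_a, allele_b, truth


# --- small-RNA libraries ---------------------------------------------------


def forge_smallrna_library(
    element: str, spec: SmallRnaLibrarySpec
) -> list[tuple[str, str]]:
    """Draw a piRNA-like read library from ``element``.

    Read lengths are uniform over ``len_range``; ``antisense_fraction`` of
    reads come from the reverse complement; ``u5_bias`` of reads are placed so
    their 5' base is U (T in DNA space), emulating the Piwi-bound small-RNA
    signature.  Returns ``(name, sequence)`` pairs.
    """
    spec.validate()
    lo, hi = spec.len_range
    if len(element) < hi:
        raise SpecValidationError("len_range", "element shorter than max read length")
    iv0, iv1 = spec.source_interval or (0, len(element))
    if not (0 <= iv0 < iv1 <= len(element)) or iv1 - iv0 < hi:
        raise SpecValidationError("source_interval", "must fit the longest read")
    rng = np.random.default_rng(spec.seed)
    reads: list[tuple[str, str]] = []
    for i in range(spec.n_reads):
        length = int(rng.integers(lo, hi + 1))
        antisense = bool(rng.random() < spec.antisense_fraction)
        want_u5 = bool(rng.random() < spec.u5_bias)
        p = None
        for _ in range(80):
            cand = int(rng.integers(iv0, iv1 - length + 1))
            if not want_u5:
                p = cand
                break
            five = element[cand + length - 1] if antisense else element[cand]
            want = "A" if antisense else "T"
            if five == want:
                p = cand
                break
        if p is None:
            p = int(rng.integers(iv0, iv1 - length + 1))
        seq = element[p : p + length]
        if antisense:
            seq = revcomp(seq)
        strand = "-" if antisense else "+"
        reads.append((f"read{i}|pos={p}|strand={strand}", seq))
    return reads


def default_pen2a_spec(seed: int = 0, **overrides) -> LocusSpec:
    """The default Pen2a-type worked-example spec (see :class:`LocusSpec`)."""
    return replace(LocusSpec(seed=seed), **overrides)
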