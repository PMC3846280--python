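"""Formats and the end-to-end per-locus annotation pipeline.

FASTA in (Biopython), GFF3 / TSV / JSON out; feature types are limited to
pltr, tail, tsd, orf, n_rich_insert, cassette and defect.  GFF3 output is
1-based inclusive; everything in memory is 0-based half-open.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import capture_detector, junction_annotator, orf_annotator, repeat_annotator
from .config import default_config
from .junction_annotator import JunctionReport
from .locus_forge import Feature, GroundTruth
from .orf_annotator import NRichSegment, OrfRecord
from .repeat_annotator import PltrAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationBundle",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "write_gff3",
    "read_gff3",
    "write_report",
    "annotate",
]

GFF_TYPES = ("pltr", "tail", "tsd", "orf", "n_rich_insert", "cassette", "defect")
VALID_DNA = set("ACGTN")


@dataclass
class AnnotationBundle:
    locus_id: str
    length: int
    pltr: PltrAnnotation
    junction: JunctionReport
    orfs: list[OrfRecord]
    n_rich: list[NRichSegment]
    captures: list
    features: list[Feature] = field(default_factory=list)


# --- formats ---------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    """FASTA records as ``{id: upper-case sequence}``; tolerates wrapped
    lines and mixed case, rejects records with non-ACGTN characters."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_DNA
        if bad:
            raise ValueError(
                f"malformed FASTA record {rec.id!r}: invalid characters {sorted(bad)}"
            )
        if seq != str(rec.seq):
            logger.info("read_fasta: upcased record %s", rec.id)
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    """Reads with a constant dummy quality of 'I' (Q40)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_gff3(features: list[Feature], locus_id: str, length: int, path: str) -> None:
    """0-based half-open features to 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {locus_id} 1 {length}\n")
        for i, f in enumerate(sorted(features, key=lambda f: (f.start, f.end, f.type))):
            if f.type not in GFF_TYPES:
                raise ValueError(f"unknown feature type {f.type!r}")
            attrs = ";".join(
                [f"ID={f.type}{i}"]
                + [f"{k}={v}" for k, v in sorted(f.attrs.items()) if isinstance(v, (str, int, float))]
            )
            fh.write(
                f"{locus_id}\tple-scout\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, _, attr_col = cols
            a, b = int(start) - 1, int(end)
            if b < a:
                raise ValueError(f"malformed GFF interval in line: {line!r}")
            attrs = {}
            for item in attr_col.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    if k != "ID":
                        attrs[k] = v
            feats.append(Feature(ftype, a, b, strand, attrs))
    return feats


def write_report(bundle: AnnotationBundle, path: str, fmt: str = "tsv") -> None:
    """Per-locus summary; TSV columns: locus, arrangement, n_units,
    full_unit_len, overlap_5p, truncation_5p, tail_len, tsd_len, tsd_motif,
    microhomology_len, n_orfs, longest_orf_aa, n_nrich, n_captures."""
    longest = max((o.aa_len for o in bundle.orfs), default=0)
    row = {
        "locus": bundle.locus_id,
        "arrangement": bundle.pltr.arrangement_label,
        "n_units": len(bundle.pltr.units),
        "full_unit_len": bundle.pltr.full_unit_len,
        "overlap_5p": bundle.pltr.overlap_5p,
        "truncation_5p": bundle.pltr.truncation_5p,
        "tail_len": bundle.pltr.tail_len,
        "tsd_len": bundle.junction.tsd.length if bundle.junction.tsd else 0,
        "tsd_motif": bundle.junction.tsd.motif if bundle.junction.tsd else "",
        "microhomology_len": bundle.junction.microhomology_len,
        "n_orfs": len(bundle.orfs),
        "longest_orf_aa": longest,
        "n_nrich": len(bundle.n_rich),
        "n_captures": len(bundle.captures),
    }
    if fmt == "json":
        Path(path).write_text(json.dumps(row, indent=2) + "\n")
    else:
        with open(path, "w") as fh:
            fh.write("\t".join(row.keys()) + "\n")
            fh.write("\t".join(str(v) for v in row.values()) + "\n")


# --- end-to-end annotation -------------------------------------------------


def element_span(ann: PltrAnnotation, tail_len: int) -> tuple[int, int] | None:
    """Outermost extent of the resolved units, extended by the tail on each
    terminal unit's 3' side."""
    if not ann.units:
        return None
    s0 = min(u.start for u in ann.units)
    s1 = max(u.end for u in ann.units)
    first = min(ann.units, key=lambda u: u.start)
    last = max(ann.units, key=lambda u: u.end)
    if tail_len:
        if first.strand == "-":
            s0 -= tail_len
        if last.strand == "+":
            s1 += tail_len
    return (max(0, s0), s1)


def annotate(
    locus: str,
    locus_id: str = "locus",
    pltr_library: list[str] | None = None,
    element_orf_library: list[str] | None = None,
    allele: str | None = None,
    config: dict | None = None,
) -> AnnotationBundle:
    """Run all detectors on one locus and assemble an annotation bundle.

    Deterministic given inputs and config; thresholds come from the config
    mapping (see :mod:`plescout.config`), decisions are logged at info
    level."""
    cfg = config or default_config()
    rc, tc, pc, oc = cfg["repeat"], cfg["tsd"], cfg["palindrome"], cfg["orf"]

    pairs = repeat_annotator.find_terminal_repeats(
        locus, min_unit=rc["min_unit"], min_identity=rc["min_identity"], k=rc["seed_k"]
    )
    extra_units = []
    if pltr_library:
        for u in capture_detector._pltr_units(locus, pltr_library, rc["min_identity"]):
            extra_units.append((u.start, u.end, u.strand))
    ann = repeat_annotator.resolve_arrangement(pairs, extra_units=extra_units)
    logger.info(
        "annotate %s: %d repeat pairs, arrangement=%s", locus_id, len(pairs), ann.arrangement_label
    )

    tail = 0
    for u in ann.units:
        if u.orientation == "inverted":
            tail = max(
                tail, repeat_annotator.detect_tail(u, locus, [x for x in ann.units if x is not u])
            )
    ann.tail_len = tail

    span = element_span(ann, tail)
    tsd = None
    mh = 0
    if span:
        s0, s1 = span
        left = locus[max(0, s0 - 60) : s0]
        right = locus[s1 : s1 + 60]
        tsd = junction_annotator.detect_tsd(
            left, right, tc["min_len"], tc["max_len"], tc["max_mismatch"]
        )
        if tsd is None:
            mh = max(
                junction_annotator.detect_microhomology(locus[max(0, s0 - 20) : s0], locus[s0 : s0 + 20]),
                junction_annotator.detect_microhomology(locus[max(0, s1 - 20) : s1], locus[s1 : s1 + 20]),
            )

    palindromes = []
    promoter_hits = []
    if ann.units:
        first = min(
            (u for u in ann.units if u.orientation == "direct"),
            key=lambda u: u.start,
            default=ann.units[0],
        )
        unit_seq = locus[first.start : first.end]
        palindromes = junction_annotator.find_palindromes(
            unit_seq, pc["min_len"], pc["max_mismatch"], pc["max_spacer"]
        )
        promoter_hits = junction_annotator.scan_promoter(
            unit_seq, max_spacing=cfg["promoter"]["max_spacing"]
        )
    junction = JunctionReport(tsd, mh, palindromes, promoter_hits)

    orfs = orf_annotator.find_orfs(locus, min_aa=oc["min_aa"])
    n_rich: list[NRichSegment] = []
    if orfs:
        main = max(orfs, key=lambda o: o.aa_len)
        n_rich = orf_annotator.detect_n_rich(
            main.protein, oc["nrich_window"], oc["nrich_threshold"], oc["nrich_min_len"]
        )

    captures = []
    if pltr_library and element_orf_library:
        captures = capture_detector.detect_capture(
            locus, pltr_library, element_orf_library, min_identity=rc["min_identity"]
        )
        if allele is not None:
            for ev in captures:
                ev.empty_site = capture_detector.verify_empty_site(
                    locus,
                    ev,
                    allele,
                    min_anchor=cfg["capture"]["min_anchor"],
                    identity_threshold=cfg["capture"]["flank_identity_threshold"],
                    window=cfg["capture"]["junction_window"],
                )

    features: list[Feature] = []
    for u in ann.units:
        features.append(
            Feature("pltr", u.start, u.end, u.strand, {"unit": u.orientation})
        )
    if span and tail:
        s0, s1 = span
        features.append(Feature("tail", s1 - tail, s1, "+", {"len": tail}))
    if span and tsd:
        s0, s1 = span
        features.append(Feature("tsd", s0 - tsd.length, s0, "+", {"motif": tsd.motif}))
        features.append(Feature("tsd", s1, s1 + tsd.length, "+", {"motif": tsd.motif}))
    if orfs:
        main = max(orfs, key=lambda o: o.aa_len)
        features.append(Feature("orf", main.start, main.end, main.strand, {"aa_len": main.aa_len}))
        for seg in n_rich:
            a = main.start + 3 * seg.aa_start if main.strand == "+" else main.start
            b = main.start + 3 * seg.aa_end if main.strand == "+" else main.end
            features.append(
                Feature("n_rich_insert", a, b, main.strand, {"asn_fraction": round(seg.asn_fraction, 4)})
            )
    for ev in captures:
        features.append(
            Feature(
                "cassette",
                ev.cassette_interval[0],
                ev.cassette_interval[1],
                "+",
                {"element_free": str(ev.cassette_is_element_free)},
            )
        )

    return AnnotationBundle(
        locus_id=locus_id,
        length=len(locus),
        pltr=ann,
        junction=junction,
        orfs=orfs,
        n_rich=n_rich,
        captures=captures,
        features=features,
    )
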