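"""ORF discovery (six-frame oracle), defect calls, motif scans and
compositional bias."""
import numpy as np
import pytest
from Bio.Seq import Seq

from plescout import (
    DefectSpec,
    InsertSpec,
    LocusSpec,
    forge_locus,
    forge_orf,
)
from plescout._util import child_rng, random_dna, revcomp
from plescout.locus_forge import _forge_orf_full, insert_offset_aa
from plescout.orf_annotator import (
    classify_defects,
    detect_aay_bias,
    detect_n_rich,
    find_orfs,
    is_intact,
    microhomology_of_defect,
    scan_cys_motif,
    scan_giy_yig,
)

CODE = {
    str(Seq("".join(c)).translate()): None
    for c in []
}


def oracle_six_frame_orfs(seq, min_aa):
    """Independent oracle: explicit codon walk on both strands."""
    stops = {"TAA", "TAG", "TGA"}
    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            i = frame
            starts = []
            while i + 3 <= len(s):
                c = s[i : i + 3]
                if c == "ATG":
                    starts.append(i)
                if c in stops:
                    for a in starts:
                        if (i - a) // 3 >= min_aa:
                            lo, hi = a, i + 3
                            if strand == "-":
                                lo, hi = n - hi, n - a
                            found.add((lo, hi, strand))
                    starts = []
                i += 3
    return found


def test_trivial_orf_mk():
    orfs = find_orfs("ATGAAATAA", min_aa=1)
    assert len(orfs) == 1
    assert orfs[0].protein == "MK"
    assert orfs[0].aa_len == 2


@pytest.mark.parametrize("seed", range(20))
def test_find_orfs_equals_six_frame_bruteforce(seed):
    rng = child_rng(800 + seed)
    s = random_dna(rng, int(rng.integers(300, 900)))
    got = {(o.start, o.end, o.strand) for o in find_orfs(s, min_aa=20)}
    assert got == oracle_six_frame_orfs(s, 20)


def test_intact_838aa_element_orf():
    seq, truth = forge_locus(LocusSpec(seed=2, orf_aa=838))
    orfs = find_orfs(seq, min_aa=300)
    planted = truth.of_type("orf")[0]
    assert (planted.start, planted.end, "+") in {(o.start, o.end, o.strand) for o in orfs}
    main = max(orfs, key=lambda o: o.aa_len)
    assert main.aa_len == 838


# --- defect classification -------------------------------------------------


def _ref(intact_dna):
    return str(Seq(intact_dna).translate()).rstrip("*")


def test_planted_stop_is_called_near_position():
    bad, intact, _, _ = _forge_orf_full(600, None, (DefectSpec("stop", position=400),), child_rng(3))
    defects = classify_defects(bad, _ref(intact), intact)
    assert [d.kind for d in defects] == ["premature_stop"]
    assert abs(defects[0].position - 400) <= 2


def test_planted_frameshift_is_called_near_position():
    bad, intact, _, _ = _forge_orf_full(600, None, (DefectSpec("frameshift", position=200),), child_rng(4))
    defects = classify_defects(bad, _ref(intact), intact)
    assert any(d.kind == "frameshift" and abs(d.position - 200) <= 3 for d in defects)


@pytest.mark.parametrize("seed", range(20))
def test_microhomology_deletion_length_recovered(seed):
    spec = DefectSpec("microhomology_deletion", position=600, size=300, microhomology_len=3)
    bad, intact, _, _ = _forge_orf_full(600, None, (spec,), child_rng(900 + seed))
    defects = classify_defects(bad, _ref(intact), intact)
    mh = [d for d in defects if d.kind == "microhomology_deletion"]
    assert len(mh) == 1
    assert microhomology_of_defect(mh[0]) == 3


def test_clean_copy_no_defects_and_intact():
    dna = forge_orf(600, seed=5)
    assert classify_defects(dna, _ref(dna), dna) == []
    assert is_intact(dna, _ref(dna), dna)


def test_unrecognizable_copy_gets_trunc_pair():
    ref = _ref(forge_orf(400, seed=6))
    junk = random_dna(child_rng(61), 900)
    kinds = {d.kind for d in classify_defects(junk, ref)}
    assert kinds == {"trunc5", "trunc3"}


def test_truncated_copy_flagged():
    dna = forge_orf(600, seed=7)
    defects = classify_defects(dna[400:], _ref(dna), dna)
    assert any(d.kind == "trunc5" for d in defects)


# --- motif scans -----------------------------------------------------------


def test_giy_yig_in_forged_protein():
    prot = _ref(forge_orf(842, seed=8))
    hit = scan_giy_yig(prot)
    assert hit is not None
    giy, yig = hit
    assert prot[giy : giy + 3] == "GIY" and prot[yig : yig + 3] == "YIG"
    assert 8 <= yig - (giy + 3) <= 12


def test_giy_yig_absent_and_constructed_gap():
    assert scan_giy_yig("A" * 100) is None
    prot = "LLL" + "GIY" + "A" * 10 + "YIG" + "KKK"
    giy, yig = scan_giy_yig(prot)
    assert yig - (giy + 3) == 10


def test_cys_motif_constructed_and_absent():
    pep = "HAAC" + "A" * 10 + "C" + "AA" + "C"
    assert scan_cys_motif(pep) == [(0, len(pep))]
    assert scan_cys_motif("ALMNPQ" * 30) == []


def oracle_cys(prot):
    out = []
    for i in range(len(prot)):
        if prot[i] not in "CH":
            continue
        for g in (3, 2, 1):  # greedy: longest gap first, like the regex
            j = i + 1 + g
            if (
                j + 15 <= len(prot)
                and prot[j] == "C"
                and prot[j + 11] == "C"
                and prot[j + 14] == "C"
            ):
                out.append((i, j + 15))
                break
    return out


@pytest.mark.parametrize("seed", range(10))
def test_cys_motif_equals_bruteforce(seed):
    rng = child_rng(950 + seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    prot = "".join(aa[i] for i in rng.integers(0, 20, 1000))
    assert scan_cys_motif(prot) == oracle_cys(prot)


# --- N-rich ----------------------------------------------------------------


def test_n1_insert_detected_with_composition():
    dna = forge_orf(842, InsertSpec(aa_len=467, asn_fraction=0.30), seed=11)
    prot = _ref(dna)
    assert len(prot) == 1309
    segs = detect_n_rich(prot)
    assert len(segs) == 1
    (seg,) = segs
    assert abs(seg.asn_fraction - 0.30) <= 0.03
    assert abs(seg.length_aa - 467) <= 60
    pos = insert_offset_aa(842, "RT_EN_linker")
    assert abs(seg.aa_start - pos) <= 50 and abs(seg.aa_end - (pos + 467)) <= 50


def test_poly_n_is_single_full_segment():
    segs = detect_n_rich("N" * 200, window=50, threshold=0.25, min_len=100)
    assert len(segs) == 1 and segs[0].asn_fraction == 1.0


def test_low_asn_background_yields_nothing():
    rng = child_rng(70)
    aa = "ACDEFGHIKLMPQRSTVWY"  # no N
    prot = list("".join(aa[i] for i in rng.integers(0, 19, 2000)))
    for i in rng.choice(2000, 100, replace=False):  # 5% N
        prot[i] = "N"
    assert detect_n_rich("".join(prot)) == []


# --- AAY bias --------------------------------------------------------------


def test_aat_repeat_full_density():
    dens, maxima, trailing = detect_aay_bias("AAT" * 10, window=30)
    assert dens.max() == 1.0 and not trailing


def test_uniform_codons_near_baseline():
    rng = child_rng(71)
    from plescout.locus_forge import SENSE_CODONS

    dna = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 20000))
    dens, _, _ = detect_aay_bias(dna, window=60000)
    assert abs(dens.mean() - 2 / 61) < 0.01


def test_planted_aay_stretch_is_local_maximum():
    rng = child_rng(72)
    from plescout.locus_forge import NON_ASN_SENSE

    codons = [NON_ASN_SENSE[i] for i in rng.integers(0, len(NON_ASN_SENSE), 400)]
    site = 200
    codons[site : site + 6] = ["AAT", "AAC"] * 3
    dens, maxima, _ = detect_aay_bias("".join(codons), window=30)
    assert any(site - 10 <= m <= site + 10 for m in maxima)
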