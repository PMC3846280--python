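"""Generator tests: structural fidelity, determinism, composition."""
import numpy as np
import pytest
from Bio.Seq import Seq

from plescout import (
    DefectSpec,
    InsertSpec,
    LocusSpec,
    SmallRnaLibrarySpec,
    SpecValidationError,
    forge_allelic_pair,
    forge_capture_locus,
    forge_locus,
    forge_orf,
    forge_smallrna_library,
)
from plescout._util import hamming, random_dna, child_rng
from plescout.locus_forge import forge_pltr


def test_default_locus_truth_matches_printed_structure(pen2a):
    seq, truth = pen2a
    pltrs = truth.of_type("pltr")
    lens = sorted(f.end - f.start for f in pltrs)
    assert lens == [181, 218, 218]
    inv = next(f for f in pltrs if f.attrs["unit"] == "inverted")
    assert inv.strand == "-"
    tails = truth.of_type("tail")
    assert {f.end - f.start for f in tails} == {31}
    tsds = truth.of_type("tsd")
    assert len(tsds) == 2
    left, right = sorted(tsds, key=lambda f: f.start)
    assert seq[left.start : left.end] == seq[right.start : right.end]  # byte-identical
    orf = truth.of_type("orf")[0]
    prot = str(Seq(seq[orf.start : orf.end]).translate())
    assert prot.endswith("*") and "*" not in prot[:-1]
    assert len(prot) - 1 == 842


def test_truth_intervals_inside_sequence(pen2a):
    seq, truth = pen2a
    for f in truth.features:
        assert 0 <= f.start <= f.end <= len(seq)


def test_determinism_same_seed_same_bytes():
    a = forge_locus(LocusSpec(seed=42))
    b = forge_locus(LocusSpec(seed=42))
    assert a[0] == b[0]
    assert a[1].features == b[1].features


def test_different_seed_differs():
    assert forge_locus(LocusSpec(seed=1))[0] != forge_locus(LocusSpec(seed=2))[0]


@pytest.mark.parametrize(
    "kwargs, fld",
    [
        (dict(overlap_5p=218), "overlap_5p"),
        (dict(tsd_len=30), "tsd_len"),
        (dict(tsd_motif="ACGT"), "tsd_motif"),  # length != tsd_len
        (dict(tail_len=218), "tail_len"),
        (dict(arrangement="DD_only", tail_len=10), "tail_len"),
        (dict(orf_aa=0), "orf_aa"),
        (dict(arrangement="sideways"), "arrangement"),
    ],
)
def test_validation_errors_name_the_field(kwargs, fld):
    with pytest.raises(SpecValidationError) as exc:
        forge_locus(LocusSpec(seed=0, **kwargs))
    assert exc.value.field == fld


def test_solo_without_tsd_has_single_unit_and_no_tsd():
    seq, truth = forge_locus(LocusSpec(seed=3, arrangement="solo", tsd_len=0, tail_len=0))
    assert len(truth.of_type("pltr")) == 1
    assert truth.of_type("tsd") == []


@pytest.mark.parametrize("arrangement,n_direct,n_inverted", [
    ("DD_only", 2, 0),
    ("inverted_pair", 1, 1),
    ("tandem_partial", 3, 0),
])
def test_other_arrangements_emit_expected_units(arrangement, n_direct, n_inverted):
    spec = LocusSpec(seed=5, arrangement=arrangement, tail_len=0 if arrangement != "inverted_pair" else 31)
    seq, truth = forge_locus(spec)
    pltrs = truth.of_type("pltr")
    assert sum(1 for f in pltrs if f.attrs["unit"] == "direct") == n_direct
    assert sum(1 for f in pltrs if f.attrs["unit"] == "inverted") == n_inverted


# --- ORFs ------------------------------------------------------------------


def test_orf_with_n1_insert_translates_to_1309_aa():
    dna = forge_orf(842, InsertSpec(aa_len=467, asn_fraction=0.30), seed=7)
    prot = str(Seq(dna).translate())
    assert prot.endswith("*")
    assert len(prot) - 1 == 1309
    assert "*" not in prot[:-1]


def test_stop_defect_truncates_translation():
    dna = forge_orf(10, defects=(DefectSpec("stop", position=5),), seed=0)
    prot = str(Seq(dna).translate())
    assert prot.index("*") == 4  # translation terminates after 4 residues


def test_insert_asn_fraction_converges():
    from plescout.locus_forge import insert_offset_aa

    pos = insert_offset_aa(100, "RT_EN_linker")
    fracs = []
    for seed in range(20):
        dna = forge_orf(100, InsertSpec(aa_len=500, asn_fraction=0.30), seed=seed)
        ins = str(Seq(dna).translate())[pos : pos + 500]
        fracs.append(ins.count("N") / 500)
    assert abs(np.mean(fracs) - 0.30) < 0.03
    # law-of-large-numbers check at insert length 5000
    dna = forge_orf(100, InsertSpec(aa_len=5000, asn_fraction=0.30), seed=99)
    ins = str(Seq(dna).translate())[pos : pos + 5000]
    assert abs(ins.count("N") / 5000 - 0.30) < 0.01


def test_defect_position_outside_orf_raises():
    with pytest.raises(SpecValidationError):
        forge_orf(50, defects=(DefectSpec("stop", position=99),), seed=0)


# --- capture loci ----------------------------------------------------------


def test_capture_locus_truth_tsd_motif():
    rng = child_rng(1)
    pltr = forge_pltr(rng, 200, promoter=None)
    exons = [random_dna(rng, n) for n in (300, 250, 200)]
    seq, truth = forge_capture_locus(exons, [90, 80], pltr, tsd_len=8, tsd_motif="GAATTAAT", seed=1)
    tsds = truth.of_type("tsd")
    assert len(tsds) == 2
    for f in tsds:
        assert seq[f.start : f.end] == "GAATTAAT"
    cass = truth.of_type("cassette")[0]
    assert cass.attrs["n_exons"] == 3
    for a, b in cass.attrs["introns"]:
        assert seq[a : a + 2] == "GT" and seq[b - 2 : b] == "AG"


def test_capture_locus_single_exon_tsd10():
    rng = child_rng(2)
    pltr = forge_pltr(rng, 200, promoter=None)
    seq, truth = forge_capture_locus([random_dna(rng, 500)], [], pltr, tsd_len=10, seed=2)
    assert all(f.end - f.start == 10 for f in truth.of_type("tsd"))


def test_capture_locus_tsd0_no_duplication():
    from plescout import detect_tsd

    rng = child_rng(3)
    pltr = forge_pltr(rng, 200, promoter=None)
    seq, truth = forge_capture_locus([random_dna(rng, 500)], [], pltr, tsd_len=0, flank_len=100, seed=3)
    assert truth.of_type("tsd") == []
    span0 = min(f.start for f in truth.of_type("pltr"))
    span1 = max(f.end for f in truth.of_type("pltr"))
    assert detect_tsd(seq[:span0], seq[span1:]) is None


def test_capture_locus_empty_cassette_errors():
    with pytest.raises(SpecValidationError):
        forge_capture_locus([], [], "ACGT" * 50, tsd_len=8)


# --- allelic pairs ---------------------------------------------------------


def test_allelic_pair_divergence_recovery():
    base = random_dna(child_rng(11), 10000)
    a, b, _ = forge_allelic_pair(base, 0.02, seed=4)
    assert a == base
    assert abs(hamming(a, b) / len(a) - 0.02) < 0.004  # binomial SE tolerance


def test_allelic_pair_zero_divergence_identical():
    base = random_dna(child_rng(12), 2000)
    a, b, _ = forge_allelic_pair(base, 0.0, seed=0)
    assert a == b == base


def test_allelic_pair_insertion_motif_once_at_junction():
    base = random_dna(child_rng(13), 4000)
    ins = random_dna(child_rng(14), 1500)
    a, b, truth = forge_allelic_pair(base, 0.02, insertion=(ins, 2000, "GAATTAAT"), seed=6)
    p = truth["junction"]
    assert a[p : p + 8] == "GAATTAAT"
    assert a.count("GAATTAAT") >= 2
    window = b[p - 50 : p + 58]
    assert window.count("GAATTAAT") == 1
    assert b[p : p + 8] == "GAATTAAT"


# --- small RNA -------------------------------------------------------------


def test_smallrna_library_fractions_and_lengths():
    elem = random_dna(child_rng(20), 3000)
    spec = SmallRnaLibrarySpec(n_reads=10000, antisense_fraction=0.9, u5_bias=0.8, seed=5)
    reads = forge_smallrna_library(elem, spec)
    assert len(reads) == 10000
    anti = sum(1 for name, _ in reads if name.endswith("-"))
    assert abs(anti / 10000 - 0.9) < 0.01
    u5 = sum(1 for _, s in reads if s[0] == "T") / 10000
    assert u5 >= 0.8 - 0.02
    assert all(25 <= len(s) <= 32 for _, s in reads)


def test_smallrna_all_sense_and_empty():
    elem = random_dna(child_rng(21), 500)
    reads = forge_smallrna_library(elem, SmallRnaLibrarySpec(n_reads=200, antisense_fraction=0.0, seed=1))
    assert all("+" in name for name, _ in reads)
    assert all(s in elem for _, s in reads)  # sense reads are substrings
    assert forge_smallrna_library(elem, SmallRnaLibrarySpec(n_reads=0, seed=1)) == []


def test_smallrna_source_interval_restriction():
    elem = random_dna(child_rng(22), 3000)
    spec = SmallRnaLibrarySpec(n_reads=500, antisense_fraction=0.0, source_interval=(1000, 1500), seed=2)
    reads = forge_smallrna_library(elem, spec)
    region = elem[1000:1500]
    assert all(s in region for _, s in reads)
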