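"""Terminal-repeat detection: planted-structure recovery, brute-force
oracle equivalence, mirror symmetry."""
import numpy as np
import pytest

from plescout import LocusSpec, forge_locus
from plescout._util import child_rng, random_dna, revcomp
from plescout.repeat_annotator import (
    RepeatUnit,
    detect_tail,
    find_terminal_repeats,
    pltr_orf_codon_coverage,
    resolve_arrangement,
)


def oracle_exact_repeat_pairs(s: str, min_unit: int):
    """Independent oracle: maximal exact-match runs over every diagonal of
    the locus against itself (direct, separation >= min_unit) and against
    its reverse complement (inverted)."""
    n = len(s)
    out = set()
    for d in range(min_unit, n):
        run = 0
        for i in range(n - d + 1):
            if i < n - d and s[i] == s[i + d]:
                run += 1
            else:
                if run >= min_unit:
                    out.add((("direct"), (i - run, i), (i - run + d, i + d)))
                run = 0
    b = revcomp(s)
    for e in range(-(n - 1), n):
        run = 0
        lo = max(0, -e)
        hi = min(n, n - e)
        for i in range(lo, hi + 1):
            if i < hi and s[i] == b[i + e]:
                run += 1
            else:
                if run >= min_unit:
                    ai, aj = i - run, i
                    bi, bj = ai + e, aj + e
                    iv_a, iv_b = (ai, aj), (n - bj, n - bi)
                    if iv_a != iv_b:
                        out.add(("inverted", min(iv_a, iv_b), max(iv_a, iv_b)))
                run = 0
    return out


@pytest.mark.parametrize("seed", range(30))
def test_oracle_equivalence_exact_planted_repeats(seed):
    rng = child_rng(1000 + seed)
    n = int(rng.integers(200, 400))
    s = list(random_dna(rng, n))
    unit = random_dna(rng, int(rng.integers(50, 80)))
    p1 = int(rng.integers(0, n // 3))
    p2 = int(rng.integers(n // 2, n - len(unit)))
    s[p1 : p1 + len(unit)] = unit
    copy = unit if rng.random() < 0.5 else revcomp(unit)
    s[p2 : p2 + len(unit)] = copy
    s = "".join(s)
    got = {
        (p.orientation, p.a, p.b)
        for p in find_terminal_repeats(s, min_unit=50, min_identity=1.0)
    }
    assert got == oracle_exact_repeat_pairs(s, 50)


def test_random_background_yields_no_pairs():
    s = random_dna(child_rng(77), 2000)
    assert find_terminal_repeats(s, min_unit=50) == []


def test_short_locus_empty_not_error():
    assert find_terminal_repeats("ACGT" * 10, min_unit=50) == []


def test_planted_60bp_direct_repeat_in_300bp():
    rng = child_rng(5)
    s = list(random_dna(rng, 300))
    unit = random_dna(rng, 60)
    s[10:70] = unit
    s[200:260] = unit
    s = "".join(s)
    pairs = find_terminal_repeats(s, min_unit=50, min_identity=1.0)
    assert len(pairs) == 1
    (p,) = pairs
    # the planted pair, possibly extended by chance-matching flank bases
    assert p.a[0] <= 10 and p.a[1] >= 70 and p.b[0] <= 200 and p.b[1] >= 260
    assert {("direct", p.a, p.b)} == oracle_exact_repeat_pairs(s, 50)


def test_mirror_symmetry_under_reverse_complement():
    seq, _ = forge_locus(LocusSpec(seed=9))
    n = len(seq)
    fwd = find_terminal_repeats(seq)
    rev = find_terminal_repeats(revcomp(seq))

    def mirror(iv):
        return (n - iv[1], n - iv[0])

    fwd_set = {(p.orientation, p.a, p.b) for p in fwd}
    rev_set = {
        (p.orientation, *sorted([mirror(p.a), mirror(p.b)])) for p in rev
    }
    assert fwd_set == rev_set


def test_recall_and_precision_on_diverged_units():
    from plescout._util import mutate, interval_overlap

    hits = 0
    spurious = 0
    total = 0
    for seed in range(100):
        rng = child_rng(4000 + seed)
        n = 1500
        s = list(random_dna(rng, n))
        unit = random_dna(rng, 120)
        copy = mutate(rng, unit, 0.05)  # pair identity ~0.9
        s[100:220] = unit
        s[1000:1120] = copy
        s = "".join(s)
        pairs = find_terminal_repeats(s, min_unit=50, min_identity=0.8)
        total += 1
        found = any(
            interval_overlap(p.a, (100, 220)) >= 60 and interval_overlap(p.b, (1000, 1120)) >= 60
            for p in pairs
        )
        hits += found
        spurious += sum(
            1
            for p in pairs
            if interval_overlap(p.a, (100, 220)) < 10 and interval_overlap(p.b, (1000, 1120)) < 10
        )
    assert hits == total  # recall 1.0
    assert spurious / max(1, total) <= 0.05  # precision >= 0.95


# --- arrangement resolution ------------------------------------------------


def test_pen2a_arrangement_overlap_truncation(pen2a, pen2a_annotation):
    ann = pen2a_annotation
    assert ann.arrangement_label == "DD_plus_inverted5p"
    assert ann.overlap_5p == 15
    assert ann.truncation_5p == 37
    assert ann.full_unit_len == 218
    lens = sorted(u.unit_len for u in ann.units)
    assert lens == [181, 218, 218]


def test_single_extra_unit_is_solo():
    ann = resolve_arrangement([], extra_units=[(100, 300, "+")])
    assert ann.arrangement_label == "solo"
    assert len(ann.units) == 1


def test_empty_pairs_give_none():
    assert resolve_arrangement([]).arrangement_label == "none"


@pytest.mark.parametrize("arrangement,label", [
    ("DD_only", "DD_only"),
    ("inverted_pair", "inverted_pair"),
    ("tandem_partial", "tandem_partial"),
])
def test_other_arrangements_are_recovered(arrangement, label):
    tail = 31 if arrangement == "inverted_pair" else 0
    seq, truth = forge_locus(LocusSpec(seed=21, arrangement=arrangement, tail_len=tail))
    ann = resolve_arrangement(find_terminal_repeats(seq))
    assert ann.arrangement_label == label


# --- tail ------------------------------------------------------------------


def _pen2a_units(ann):
    inv = next(u for u in ann.units if u.orientation == "inverted")
    others = [u for u in ann.units if u is not inv]
    return inv, others


def test_detect_tail_31(pen2a, pen2a_annotation):
    seq, _ = pen2a
    inv, others = _pen2a_units(pen2a_annotation)
    assert detect_tail(inv, seq, others) == 31


def test_detect_tail_absent_is_zero():
    seq, _ = forge_locus(LocusSpec(seed=13, tail_len=0))
    ann = resolve_arrangement(find_terminal_repeats(seq))
    inv, others = _pen2a_units(ann)
    assert detect_tail(inv, seq, others) == 0


def test_detect_tail_equals_brute_force_lce():
    # planted 12-bp shared extension beyond two direct units
    rng = child_rng(31)
    unit = random_dna(rng, 80)
    ext = random_dna(rng, 12)
    filler = random_dna(rng, 150)
    locus = random_dna(rng, 40) + unit + ext + filler + unit + ext + random_dna(rng, 40)
    u1 = RepeatUnit(40, 120, "+", "direct")
    u2 = RepeatUnit(40 + 80 + 12 + 150, 40 + 80 + 12 + 150 + 80, "+", "direct")
    got = detect_tail(u1, locus, [u2])
    e1, e2 = locus[u1.end :], locus[u2.end :]
    lce = 0
    while lce < min(len(e1), len(e2)) and e1[lce] == e2[lce]:
        lce += 1
    assert got == lce
    assert got >= 12


# --- codon coverage --------------------------------------------------------


def test_pltr_orf_codon_coverage_values():
    unit = RepeatUnit(0, 218, "+", "direct")
    orf = (182, 182 + 2529)  # starts 36 bases before the unit end
    assert pltr_orf_codon_coverage(unit, 31, orf) == 22
    assert pltr_orf_codon_coverage(unit, 0, orf) == 12
    assert pltr_orf_codon_coverage(unit, 31, (5000, 6000)) == 0
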