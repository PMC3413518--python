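"""Breakpoint repeats, mechanism calls, TIR elements, duplications, motifs."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasstruct._seq import revcomp
from grasstruct.repeatmotif import (
    RepeatHit,
    classify_loss_mechanism,
    find_exon_duplication,
    find_tir_elements,
    scan_breakpoint_repeats,
    scan_cis_elements,
)


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# breakpoint repeats


def brute_force_repeats(seq, junction, window, min_arm):
    """Independent enumeration of every substring pair straddling the junction."""
    seq = seq.upper()
    found = set()
    for i in range(max(0, junction - window), junction):
        for j in range(junction, min(len(seq), junction + window)):
            for L in range(min_arm, window + 1):
                if i + L > junction or j + L > min(len(seq), junction + window):
                    continue
                if i < junction - window:
                    continue
                a1, a2 = seq[i : i + L], seq[j : j + L]
                if a1 == a2:
                    found.add(("direct", i, j, L))
                if a2 == revcomp(a1):
                    found.add(("inverted", i, j, L))
    return found


def test_breakpoint_motifs_tgg_cca_and_cgg_ccg():
    rng = np.random.default_rng(0)
    for arm in ("TGG", "CGG"):
        seq = rand_seq(rng, 40) + arm + revcomp(arm) + rand_seq(rng, 40)
        junction = 43
        hits = scan_breakpoint_repeats(seq, junction, window=15, min_arm=3)
        inverted = [h for h in hits if h.kind == "inverted" and h.distance == 0]
        assert any(h.arm1_seq == arm and h.arm2_seq == revcomp(arm) for h in inverted)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(20, 200), st.integers(3, 6), st.integers(4, 15))
def test_scanner_equals_brute_force_enumeration(seed, n, min_arm, window):
    if window < min_arm:
        window = min_arm
    rng = np.random.default_rng(seed)
    seq = rand_seq(rng, n)
    junction = int(rng.integers(0, n + 1))
    hits = scan_breakpoint_repeats(seq, junction, window=window, min_arm=min_arm)
    got = {(h.kind, h.arm1[0], h.arm2[0], h.arm_len) for h in hits}
    assert got == brute_force_repeats(seq, junction, window, min_arm)


def test_hits_sorted_by_arm_length_then_distance():
    seq = "AAAATGGCCATTTT"
    hits = scan_breakpoint_repeats(seq, 7, window=7, min_arm=3)
    for a, b in zip(hits, hits[1:]):
        assert (-a.arm_len, a.distance) <= (-b.arm_len, b.distance)


def test_scan_revcomp_symmetry():
    rng = np.random.default_rng(5)
    seq = rand_seq(rng, 80) + "TGG" + "CCA" + rand_seq(rng, 80)
    junction = 83
    fwd = scan_breakpoint_repeats(seq, junction)
    rev = scan_breakpoint_repeats(revcomp(seq), len(seq) - junction)
    assert {(h.kind, h.arm_len, h.distance) for h in fwd} == {
        (h.kind, h.arm_len, h.distance) for h in rev
    }


def test_junction_bounds_checked():
    with pytest.raises(ValueError):
        scan_breakpoint_repeats("ACGT", 10)
    with pytest.raises(ValueError):
        scan_breakpoint_repeats("ACGTACGT", 4, window=2, min_arm=3)


# ---------------------------------------------------------------------------
# mechanism classifier: pure function of (multiplicity, repeat evidence)


def _abutting_hit():
    return [RepeatHit("inverted", (40, 43), (43, 46), "TGG", "CCA", 3, 0, 0)]


def _distant_hit():
    return [RepeatHit("direct", (30, 33), (50, 53), "TTT", "TTT", 3, 17, 10)]


@pytest.mark.parametrize(
    "multiplicity, repeats, expected",
    [
        (1, _abutting_hit(), "repeat_mediated"),
        (1, [], "simple_deletion"),
        (1, _distant_hit(), "simple_deletion"),
        (1, None, "indeterminate"),
        (2, _abutting_hit(), "mrna_mediated"),
        (2, [], "mrna_mediated"),
        (3, None, "mrna_mediated"),
    ],
)
def test_mechanism_grid(multiplicity, repeats, expected):
    assert classify_loss_mechanism(multiplicity, repeats) == expected


def test_conflicting_evidence_is_indeterminate():
    # an intron record supplied for a site the event claims lost
    assert classify_loss_mechanism(1, _abutting_hit(), splice=object()) == "indeterminate"


# ---------------------------------------------------------------------------
# MITE-like TIR elements


def planted_element(rng, tir_len=14, inner_len=120):
    tir = rand_seq(rng, tir_len)
    return tir + rand_seq(rng, inner_len) + revcomp(tir)


def test_planted_tir_element_recovered_at_exact_coordinates():
    rng = np.random.default_rng(8)
    elem = planted_element(rng)
    # neutral flanks: A cannot pair with A, so extension stops at the element
    seq = rand_seq(rng, 500) + "AAAA" + elem + "AAAA" + rand_seq(rng, 500)
    hits = find_tir_elements(seq, min_tir=12, max_len=300, max_mismatch=0)
    assert len(hits) == 1
    h = hits[0]
    assert (h.arm1[0], h.arm2[1]) == (504, 504 + len(elem))
    # chance complementary bases just inside the element may extend the arm
    assert h.arm_len >= 14


def test_inverted_copy_found_with_opposite_orientation():
    rng = np.random.default_rng(9)
    elem = planted_element(rng)
    seq = (rand_seq(rng, 300) + "AAAA" + elem + "AAAA" + rand_seq(rng, 400)
           + "AAAA" + revcomp(elem) + "AAAA" + rand_seq(rng, 300))
    hits = find_tir_elements(seq, min_tir=12, max_len=300, max_mismatch=0)
    assert len(hits) == 2
    assert [h.orientation for h in sorted(hits, key=lambda h: h.arm1[0])] == ["+", "-"]


def test_poly_a_has_no_tir_elements():
    assert find_tir_elements("A" * 400, min_tir=10, max_len=200, max_mismatch=1) == []


def test_tir_mismatch_tolerance():
    rng = np.random.default_rng(10)
    tir = rand_seq(rng, 14)
    right = list(revcomp(tir))
    right[7] = "A" if right[7] != "A" else "C"  # one internal TIR mismatch
    elem = tir + rand_seq(rng, 100) + "".join(right)
    seq = "AAAA" + elem + "AAAA"
    assert find_tir_elements(seq, min_tir=14, max_len=300, max_mismatch=0) == []
    hits = find_tir_elements(seq, min_tir=14, max_len=300, max_mismatch=1)
    assert len(hits) == 1


# ---------------------------------------------------------------------------
# exon duplication


def test_exact_downstream_copy():
    rng = np.random.default_rng(11)
    exon = rand_seq(rng, 200)
    genomic = rand_seq(rng, 400) + exon + rand_seq(rng, 300) + exon + rand_seq(rng, 100)
    stop_end = 600
    recs = find_exon_duplication(genomic, exon, stop_end)
    assert len(recs) == 1
    r = recs[0]
    assert r.orientation == "+"
    assert r.offset_from_stop == 301
    assert r.deletions == ()
    assert r.identity == pytest.approx(1.0)


def test_planted_internal_deletion_with_tactgg_flanks():
    rng = np.random.default_rng(12)
    exon = list(rand_seq(rng, 260))
    a, b = 40, 194  # deletion of 154 nt
    exon[a - 6 : a] = "TACTGG"
    exon[b - 6 : b] = "TACTGG"
    exon = "".join(exon)
    copy = revcomp(exon[:a] + exon[b:])
    genomic = rand_seq(rng, 200) + rand_seq(rng, 500) + copy + rand_seq(rng, 100)
    recs = find_exon_duplication(genomic, exon, 200, min_identity=0.3)
    assert len(recs) == 1
    r = recs[0]
    assert r.orientation == "-"
    assert r.offset_from_stop == 501
    assert r.deletions == ((154, "TACTGG"),)


def test_no_copy_gives_empty_list():
    rng = np.random.default_rng(13)
    assert find_exon_duplication(rand_seq(rng, 2000), rand_seq(rng, 100), 0) == []


# ---------------------------------------------------------------------------
# cis-elements


def test_gbox_palindrome_hits_both_strands():
    rng = np.random.default_rng(14)
    promoter = rand_seq(rng, 100).replace("ACGT", "AAAA") + "CACGTG" + "TTTT" * 10
    hits = [h for h in scan_cis_elements(promoter) if h.name == "G-box"]
    assert {h.strand for h in hits} == {"+", "-"}
    assert len({h.start for h in hits}) == 1  # same palindromic site


def test_no_acgt_core_means_no_abre():
    promoter = "TTTTCCCCTTTTCCCC" * 20
    assert [h for h in scan_cis_elements(promoter) if h.name == "ABRE"] == []


def test_planted_motifs_recalled_exactly():
    rng = np.random.default_rng(15)
    base = "TTCCTTCCTTCC" * 100
    planted = {"ABRE": 100, "G-box": 400, "CE1": 700, "CE3": 950}
    motifs = {"ABRE": "ACGTG", "G-box": "CACGTG", "CE1": "TGCCACCGG", "CE3": "ACGCGTGTC"}
    chars = list(base)
    for name, pos in planted.items():
        chars[pos : pos + len(motifs[name])] = motifs[name]
    promoter = "".join(chars)
    hits = scan_cis_elements(promoter, motifs)
    for name, pos in planted.items():
        assert any(h.name == name and h.start == pos and h.strand == "+" for h in hits)
        # ATG-anchored coordinate round-trips
        hit = [h for h in hits if h.name == name and h.start == pos][0]
        assert hit.position_from_3p == pos - len(promoter)


def test_unknown_iupac_code_raises():
    with pytest.raises(ValueError, match="IUPAC"):
        scan_cis_elements("ACGTACGT", {"bad": "ACGZ"})


def test_cis_scan_revcomp_symmetry():
    rng = np.random.default_rng(16)
    promoter = rand_seq(rng, 300) + "TGCCACCGG" + rand_seq(rng, 300)
    fwd = scan_cis_elements(promoter)
    rev = scan_cis_elements(revcomp(promoter))
    assert {(h.name, h.strand, h.start) for h in fwd} == {
        (h.name, "+-"[h.strand == "+"], len(promoter) - h.end) for h in rev
    }
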