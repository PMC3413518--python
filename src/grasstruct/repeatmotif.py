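"""Breakpoint repeats, loss-mechanism calls, MITE-like TIR elements,
downstream exon duplications and promoter cis-element scanning.

Short direct or inverted repeats straddling an exon-fusion junction are
the sequence signature of repeat-mediated deletion (illegitimate
recombination / replication slippage); their absence at a single-intron
loss suggests simple genomic deletion, and the simultaneous loss of
several adjacent introns on one branch points to recombination with a
reverse-transcribed spliced mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import iupac_regex, revcomp

__all__ = [
    "RepeatHit",
    "MotifHit",
    "DuplicationRecord",
    "DEFAULT_MOTIFS",
    "scan_breakpoint_repeats",
    "classify_loss_mechanism",
    "find_tir_elements",
    "find_exon_duplication",
    "scan_cis_elements",
]

#: ABA-response cis-element consensus strings (standard literature definitions;
#: the elements' presence, not these exact strings, is the biological claim).
DEFAULT_MOTIFS = {
    "ABRE": "ACGTG",
    "G-box": "CACGTG",
    "CE1": "TGCCACCGG",
    "CE3": "ACGCGTGTC",
}


@dataclass(frozen=True)
class RepeatHit:
    """A direct or inverted repeat pair; intervals are 0-based half-open."""

    kind: str                 # direct | inverted
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    arm1_seq: str
    arm2_seq: str
    arm_len: int
    spacer: int               # nt between the two arms
    distance: int             # largest gap between an arm and the junction
    orientation: str = "+"    # for element-scale hits: relative orientation


@dataclass(frozen=True)
class MotifHit:
    name: str
    consensus: str
    start: int                # 0-based on the given sequence
    end: int
    strand: str
    matched: str
    position_from_3p: int     # negative offset of the hit start from the 3' end


@dataclass(frozen=True)
class DuplicationRecord:
    copy_start: int           # 0-based on the genomic sequence
    copy_end: int
    orientation: str          # '+' same strand as the source exon, '-' inverted
    offset_from_stop: int     # 1-based distance from the base after the stop codon
    identity: float
    deletions: tuple          # of (length, flank_motif-or-None)


# ---------------------------------------------------------------------------
# breakpoint repeats


def scan_breakpoint_repeats(
    seq: str, junction: int, window: int = 15, min_arm: int = 3
) -> list[RepeatHit]:
    """All direct/inverted repeat pairs with one arm on each side of ``junction``.

    Arms lie entirely within ``window`` nt of the junction and have length
    >= ``min_arm``.  Hits are sorted by arm length (desc) then distance to
    the junction (asc).
    """
    seq = seq.upper()
    if not (0 <= junction <= len(seq)):
        raise ValueError("junction outside the sequence")
    if window < min_arm:
        raise ValueError("window must be >= min_arm")
    lo = max(0, junction - window)
    hi = min(len(seq), junction + window)
    hits = []
    for L in range(min_arm, window + 1):
        for i in range(lo, junction - L + 1):
            a1 = seq[i : i + L]
            for j in range(junction, hi - L + 1):
                a2 = seq[j : j + L]
                if a2 == a1:
                    kind = "direct"
                elif a2 == revcomp(a1):
                    kind = "inverted"
                else:
                    continue
                hits.append(
                    RepeatHit(
                        kind, (i, i + L), (j, j + L), a1, a2, L,
                        spacer=j - (i + L),
                        distance=max(junction - (i + L), j - junction),
                    )
                )
    hits.sort(key=lambda h: (-h.arm_len, h.distance, h.arm1[0], h.arm2[0]))
    return hits


def classify_loss_mechanism(
    event,
    repeats: list[RepeatHit] | None,
    splice=None,
    min_arm: int = 3,
    max_distance: int = 0,
) -> str:
    """Mechanism hypothesis for one intron-loss event.

    * multiplicity >= 2 (adjacent sites lost together on one branch) ->
      ``mrna_mediated``;
    * single loss with a repeat pair abutting the junction (arm length >=
      ``min_arm``, each arm within ``max_distance`` nt of the junction) ->
      ``repeat_mediated``;
    * single loss with no such repeat -> ``simple_deletion``;
    * conflicting evidence (an intron record is supplied for a site the
      event claims lost, or no repeat scan is available) ->
      ``indeterminate``.

    The default ``max_distance=0`` requires the arms to flank the fusion
    junction directly, the geometry of the TGG|CCA and CGG|CCG motifs
    observed at grass PSY3 deletion breakpoints.
    """
    multiplicity = event if isinstance(event, int) else getattr(event, "multiplicity", 1)
    if splice is not None:
        return "indeterminate"
    if multiplicity >= 2:
        return "mrna_mediated"
    if repeats is None:
        return "indeterminate"
    spanning = [h for h in repeats if h.arm_len >= min_arm and h.distance <= max_distance]
    return "repeat_mediated" if spanning else "simple_deletion"


# ---------------------------------------------------------------------------
# MITE-like elements


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _tir_extend(seq, i, j, k, max_mismatch):
    """Grow an inverted seed (left window [i, i+k) paired with [j, j+k))
    in both directions; left position x pairs with y = j + k - 1 - (x - i).

    Returns the left-arm inclusive bounds (lo, hi).
    """
    mism = 0
    lo, hi = i, i + k - 1
    x = i - 1  # outward first: both arms grow away from the element body
    while x >= 0:
        y = j + k - 1 - (x - i)
        if y >= len(seq):
            break
        if _COMP.get(seq[x]) != seq[y]:
            if mism + 1 > max_mismatch:
                break
            mism += 1
        lo = x
        x -= 1
    x = i + k  # then inward: left arm grows right, right arm grows left
    while True:
        y = j + k - 1 - (x - i)
        if y <= x or x >= len(seq):
            break
        if _COMP.get(seq[x]) != seq[y]:
            if mism + 1 > max_mismatch:
                break
            mism += 1
        hi = x
        x += 1
    return lo, hi


def find_tir_elements(
    seq: str,
    min_tir: int = 10,
    max_len: int = 600,
    max_mismatch: int = 1,
    min_len: int = 30,
) -> list[RepeatHit]:
    """Candidate MITE-like elements: terminal inverted repeats bounding a span.

    A hit pairs a left arm starting the element with a right arm ending
    it, ``revcomp``-matching with at most ``max_mismatch`` mismatches and
    arm length >= ``min_tir``; the element span is within
    [``min_len``, ``max_len``].  Overlapping candidates are merged keeping
    the longest TIR.  Elements whose internal sequence matches an earlier
    element's reverse complement are flagged with orientation '-'.
    """
    seq = seq.upper()
    if min(min_tir, max_len, max_mismatch + 1, min_len) <= 0:
        raise ValueError("parameters must be positive")
    k = max(4, min_tir // (max_mismatch + 1))
    index: dict[str, list[int]] = {}
    for g in range(len(seq) - k + 1):
        index.setdefault(seq[g : g + k], []).append(g)
    raw = []
    seen = set()
    for i in range(len(seq) - k + 1):
        probe = revcomp(seq[i : i + k])
        for j in index.get(probe, ()):
            if j <= i or j + k - i > max_len + 2 * k:
                continue
            lo, hi = _tir_extend(seq, i, j, k, max_mismatch)
            arm = hi - lo + 1
            if arm < min_tir:
                continue
            r_end = j + k - 1 - (lo - i) + 1  # right arm end pairing with lo
            r_start = r_end - arm
            span = r_end - lo
            if span < min_len or span > max_len or r_start < lo + arm:
                continue
            key = (lo, r_end)
            if key in seen:
                continue
            seen.add(key)
            raw.append(
                RepeatHit(
                    "inverted", (lo, lo + arm), (r_start, r_end),
                    seq[lo : lo + arm], seq[r_start:r_end], arm,
                    spacer=r_start - (lo + arm), distance=0,
                )
            )
    # merge overlapping candidates, keeping the longest TIR
    raw.sort(key=lambda h: (-h.arm_len, h.arm1[0]))
    kept: list[RepeatHit] = []
    for h in raw:
        s, e = h.arm1[0], h.arm2[1]
        if any(s < k2.arm2[1] and k2.arm1[0] < e for k2 in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.arm1[0])
    # orientation relative to the first matching earlier element
    out = []
    for h in kept:
        inner = seq[h.arm1[0] : h.arm2[1]]
        orient = "+"
        for prev in out:
            pseq = seq[prev.arm1[0] : prev.arm2[1]]
            same = _shifted_identity(pseq, inner)
            anti = _shifted_identity(revcomp(pseq), inner)
            if anti > 0.9 and anti > same:
                orient = "-"
                break
        out.append(
            RepeatHit(h.kind, h.arm1, h.arm2, h.arm1_seq, h.arm2_seq,
                      h.arm_len, h.spacer, h.distance, orient)
        )
    return out


# ---------------------------------------------------------------------------
# downstream exon duplication


def _shifted_identity(a: str, b: str, max_shift: int = 4) -> float:
    """Best base-wise identity of a vs b over small relative offsets."""
    if abs(len(a) - len(b)) > max_shift:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0.0
    for off in range(len(long_) - len(short) + 1):
        ident = sum(x == y for x, y in zip(short, long_[off : off + len(short)])) / len(short)
        best = max(best, ident)
    return best


def _anchor_segments(query: str, target: str, k: int):
    """Exact k-mer anchors of query in target, merged per diagonal."""
    index: dict[str, list[int]] = {}
    for g in range(len(target) - k + 1):
        index.setdefault(target[g : g + k], []).append(g)
    diagonals: dict[int, list[int]] = {}
    for q in range(len(query) - k + 1):
        for g in index.get(query[q : q + k], ()):
            diagonals.setdefault(g - q, []).append(q)
    segments = []  # (q_start, q_end, diag)
    for diag, qs in diagonals.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q - prev > 3 * k:
                segments.append((start, prev + k, diag))
                start = q
            prev = q
        segments.append((start, prev + k, diag))
    return segments


def _flank_motif(exon: str, a: int, b: int) -> str | None:
    """Identical k-mer (k 8..4) abutting both boundaries of deleted exon[a:b]."""
    for k in range(8, 3, -1):
        if a - k >= 0 and b - k >= a and exon[a - k : a] == exon[b - k : b]:
            return exon[a - k : a]
        if b + k <= len(exon) and a + k <= b and exon[a : a + k] == exon[b : b + k]:
            return exon[a : a + k]
    return None


def find_exon_duplication(
    genomic: str,
    exon: str,
    stop_codon_end: int,
    min_identity: float = 0.8,
    k: int = 12,
) -> list[DuplicationRecord]:
    """Find copies of ``exon`` downstream of the stop codon, both orientations.

    ``stop_codon_end`` is the 0-based position just past the stop codon's
    last base; the reported offset is the 1-based distance from that
    position to the copy's first base.  Internal deletions in the copy are
    reported with the identical flanking k-mer motif (k in [4, 8]) when
    one abuts the deleted source segment on both sides.
    """
    genomic, exon = genomic.upper(), exon.upper()
    if len(exon) < 30:
        raise ValueError("exon must be >= 30 nt")
    region = genomic[stop_codon_end:]
    records = []
    for orientation in ("+", "-"):
        query = exon if orientation == "+" else revcomp(exon)
        segments = _anchor_segments(query, region, k)
        if not segments:
            continue
        # cluster colinear segments into one copy (greedy: all segments whose
        # diagonals are within len(exon) of the dominant one)
        segments.sort(key=lambda s: s[1] - s[0], reverse=True)
        d0 = segments[0][2]
        cluster = [s for s in segments if abs(s[2] - d0) <= len(exon)]
        cluster.sort(key=lambda s: s[0])
        covered = sum(e - s for s, e, _ in cluster)
        if covered < min_identity * len(exon):
            continue
        g_lo = cluster[0][0] + cluster[0][2]
        g_hi = cluster[-1][1] + cluster[-1][2]
        deletions = []
        for (s1, e1, d1), (s2, e2, d2) in zip(cluster, cluster[1:]):
            q_gap = s2 - e1
            g_gap = (s2 + d2) - (e1 + d1)
            del_len = q_gap - g_gap
            if del_len >= 10:
                # deleted segment in query coordinates -> exon coordinates
                qa, qb = e1, e1 + del_len
                if orientation == "+":
                    a, b = qa, qb
                else:
                    a, b = len(exon) - qb, len(exon) - qa
                deletions.append((del_len, _flank_motif(exon, a, b)))
        records.append(
            DuplicationRecord(
                copy_start=stop_codon_end + g_lo,
                copy_end=stop_codon_end + g_hi,
                orientation=orientation,
                offset_from_stop=g_lo + 1,
                identity=covered / len(exon),
                deletions=tuple(deletions),
            )
        )
    records.sort(key=lambda r: r.offset_from_stop)
    return records


# ---------------------------------------------------------------------------
# promoter cis-elements


def scan_cis_elements(promoter: str, motif_table: dict[str, str] | None = None) -> list[MotifHit]:
    """Scan both strands of a promoter for IUPAC consensus motifs.

    Positions are also reported relative to the sequence 3' end (the
    ATG-anchored convention for promoters given 5'->3' ending just before
    the start codon).
    """
    if not promoter:
        raise ValueError("promoter sequence is empty")
    promoter = promoter.upper()
    motifs = DEFAULT_MOTIFS if motif_table is None else motif_table
    n = len(promoter)
    hits = []
    for name, consensus in motifs.items():
        pattern = iupac_regex(consensus)
        rc_pattern = iupac_regex(revcomp(consensus))
        for strand, pat in (("+", pattern), ("-", rc_pattern)):
            pos = 0
            while True:
                m = pat.search(promoter, pos)
                if m is None:
                    break
                hits.append(
                    MotifHit(
                        name=name, consensus=consensus, start=m.start(), end=m.end(),
                        strand=strand, matched=m.group(0), position_from_3p=m.start() - n,
                    )
                )
                pos = m.start() + 1
    hits.sort(key=lambda h: (h.start, h.name, h.strand))
    return hits
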