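"""HSP rebuilding and cumulative homology statistics (AL, CIP, CALP).

Local-alignment hits (BLASTN tabular style) between a query gene and a
subject gene are chained into a single rebuilt pairwise alignment and
summarized by three cumulative statistics:

* ``AL``   -- aligned length, the sum of all retained HSP lengths (bp);
* ``CIP``  -- cumulative identity percentage, 100 * (sum of identical
  positions over all HSPs) / AL;
* ``CALP`` -- cumulative alignment length percentage, AL / query length.

Gene relationships against a subject genome are then classified as COS
(one conserved ortholog), CNV (two or more tandem-duplicated homologs)
or PAV (no conserved homolog).

Query-coordinate overlaps between HSPs are resolved, by default, by
trimming the HSP with the lower identity fraction so that every query
position is counted once; this keeps CIP a true percentage and CALP <= 1.
Pass ``policy="raw"`` to sum raw HSP lengths without trimming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "HspRecord",
    "PairScore",
    "ConservationCall",
    "rebuild_pair_alignment",
    "score_pair",
    "classify_conservation",
    "read_hsp_table",
    "score_all",
    "classify_all",
]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class HspRecord:
    """One local-alignment hit; coordinates are 1-based inclusive."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_length: int
    identity_count: int
    e_value: float = 0.0
    strand: str = "+"

    def __post_init__(self):
        if not (1 <= self.query_start <= self.query_end):
            raise ValueError(f"invalid query coordinates {self.query_start}..{self.query_end}")
        if self.aligned_length <= 0:
            raise ValueError("aligned_length must be positive")
        if not (0 <= self.identity_count <= self.aligned_length):
            raise ValueError("identity_count must be in [0, aligned_length]")

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1

    @property
    def identity_fraction(self) -> float:
        return self.identity_count / self.aligned_length


@dataclass(frozen=True)
class PairScore:
    query_id: str
    subject_id: str
    al: int
    cip: float
    calp: float
    n_hsps_used: int


@dataclass(frozen=True)
class ConservationCall:
    query_id: str
    klass: str  # COS | CNV | PAV
    subjects: tuple[str, ...]
    scores: tuple[PairScore, ...]
    others: tuple[str, ...] = ()


def _priority(h: HspRecord):
    # higher identity fraction wins; ties: longer, then leftmost on query/subject
    return (-h.identity_fraction, -h.aligned_length, h.query_start, h.subject_start, h.subject_id)


def rebuild_pair_alignment(hsps: list[HspRecord], policy: str = "trim") -> list[HspRecord]:
    """Chain the HSPs of one query-subject pair into a query-disjoint set.

    Overlapping query intervals are resolved by trimming the HSP with the
    lower identity fraction; trimmed identity counts are rescaled
    proportionally to the retained length and rounded half-up.  A trimmed
    HSP whose middle is occupied may split into several retained segments.
    """
    if not hsps:
        raise ValueError("rebuild_pair_alignment requires at least one HSP")
    pair = {(h.query_id, h.subject_id) for h in hsps}
    if len(pair) != 1:
        raise ValueError(f"HSPs span multiple query-subject pairs: {sorted(pair)}")
    if policy == "raw":
        return sorted(hsps, key=lambda h: (h.query_start, h.query_end))
    if policy != "trim":
        raise ValueError(f"unknown overlap policy {policy!r}")

    occupied: list[tuple[int, int]] = []  # disjoint, sorted, 1-based inclusive
    out: list[HspRecord] = []
    for h in sorted(hsps, key=_priority):
        segments = _subtract(h.query_start, h.query_end, occupied)
        for s, e in segments:
            retained = e - s + 1
            if retained == h.query_span:
                out.append(h)
            else:
                ident = min(retained, _round_half_up(h.identity_count * retained / h.query_span))
                # subject coordinates shifted with the retained query window
                off_l = s - h.query_start
                off_r = h.query_end - e
                out.append(
                    replace(
                        h,
                        query_start=s,
                        query_end=e,
                        subject_start=h.subject_start + off_l,
                        subject_end=h.subject_end - off_r,
                        aligned_length=retained,
                        identity_count=ident,
                    )
                )
            occupied = _insert(occupied, (s, e))
    return sorted(out, key=lambda h: h.query_start)


def _subtract(start: int, end: int, occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of [start, end] not covered by the occupied intervals."""
    free = []
    cur = start
    for s, e in occupied:
        if e < cur:
            continue
        if s > end:
            break
        if s > cur:
            free.append((cur, s - 1))
        cur = max(cur, e + 1)
        if cur > end:
            break
    if cur <= end:
        free.append((cur, end))
    return free


def _insert(occupied: list[tuple[int, int]], iv: tuple[int, int]) -> list[tuple[int, int]]:
    merged = sorted(occupied + [iv])
    out = [merged[0]]
    for s, e in merged[1:]:
        if s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def score_pair(chain: list[HspRecord], query_length: int) -> PairScore:
    """Compute AL, CIP and CALP from a rebuilt (query-disjoint) HSP chain."""
    if not chain:
        raise ValueError("score_pair requires a non-empty chain")
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if query_length < max(h.query_end for h in chain):
        raise ValueError("query_length smaller than the rightmost HSP end")
    al = sum(h.aligned_length for h in chain)
    ident = sum(h.identity_count for h in chain)
    return PairScore(
        query_id=chain[0].query_id,
        subject_id=chain[0].subject_id,
        al=al,
        cip=100.0 * ident / al,
        calp=al / query_length,
        n_hsps_used=len(chain),
    )


def classify_conservation(
    scores: list[PairScore],
    cip_min: float = 60.0,
    calp_min: float = 0.7,
    tandem_window: int = 5,
    subject_positions: dict[str, int] | None = None,
) -> ConservationCall:
    """Classify one query against a subject genome as COS, CNV or PAV.

    Subjects passing both thresholds are candidates.  No candidate gives
    PAV; exactly one gives COS; two or more candidates within
    ``tandem_window`` gene positions of each other on the subject genome
    give CNV; dispersed candidates give COS to the best-scoring subject
    (by CALP, then CIP, then lexicographically smaller subject id) with
    the remainder reported in ``others``.
    """
    if not scores:
        raise ValueError("classify_conservation requires at least one PairScore")
    query = scores[0].query_id
    cands = [s for s in scores if s.cip >= cip_min and s.calp >= calp_min]
    if not cands:
        return ConservationCall(query, "PAV", (), ())
    if len(cands) == 1:
        return ConservationCall(query, "COS", (cands[0].subject_id,), (cands[0],))
    if subject_positions is None or any(s.subject_id not in subject_positions for s in cands):
        raise ValueError(
            f"{query}: {len(cands)} candidate subjects; subject gene-order positions are "
            "required to separate tandem (CNV) from dispersed homologs"
        )
    pos = [subject_positions[s.subject_id] for s in cands]
    if max(pos) - min(pos) <= tandem_window:
        subs = tuple(sorted(s.subject_id for s in cands))
        return ConservationCall(query, "CNV", subs, tuple(cands))
    best = max(cands, key=lambda s: (s.calp, s.cip, _NegStr(s.subject_id)))
    others = tuple(sorted(s.subject_id for s in cands if s is not best))
    return ConservationCall(query, "COS", (best.subject_id,), (best,), others)


class _NegStr(str):
    """Reverses lexicographic order so max() prefers the smaller subject id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# tabular front-end

BLAST6_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aligned_length", "mismatches",
    "gap_opens", "query_start", "query_end", "subject_start", "subject_end",
    "e_value", "bit_score",
]


def read_hsp_table(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-style TSV (12 columns, optional 13th identity count).

    When the identity-count column is absent it is derived as
    ``round_half_up(pct_identity/100 * aligned_length)``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = BLAST6_COLUMNS + ["identity_count"]
    elif df.shape[1] == 12:
        df.columns = BLAST6_COLUMNS
        df["identity_count"] = [
            _round_half_up(p / 100.0 * l) for p, l in zip(df.pct_identity, df.aligned_length)
        ]
    else:
        raise ValueError(f"{path}: expected 12 or 13 columns, got {df.shape[1]}")
    return df


def _records_from_frame(df: pd.DataFrame) -> list[HspRecord]:
    recs = []
    for row in df.itertuples(index=False):
        qs, qe = int(row.query_start), int(row.query_end)
        ss, se = int(row.subject_start), int(row.subject_end)
        strand = "+" if se >= ss else "-"
        recs.append(
            HspRecord(
                query_id=str(row.query_id),
                subject_id=str(row.subject_id),
                query_start=min(qs, qe),
                query_end=max(qs, qe),
                subject_start=ss,
                subject_end=se,
                aligned_length=int(row.aligned_length),
                identity_count=int(row.identity_count),
                e_value=float(getattr(row, "e_value", 0.0)),
                strand=strand,
            )
        )
    return recs


def score_all(hsp_df: pd.DataFrame, query_lengths: dict[str, int], policy: str = "trim") -> pd.DataFrame:
    """Rebuild and score every query-subject pair in a hit table."""
    rows = []
    for (q, s), grp in hsp_df.groupby(["query_id", "subject_id"], sort=True):
        chain = rebuild_pair_alignment(_records_from_frame(grp), policy=policy)
        sc = score_pair(chain, query_lengths[str(q)])
        rows.append(
            {"query_id": q, "subject_id": s, "AL": sc.al, "CIP": sc.cip,
             "CALP": sc.calp, "n_hsps_used": sc.n_hsps_used}
        )
    return pd.DataFrame(rows)


def classify_all(
    scores_df: pd.DataFrame,
    subject_taxa: dict[str, str],
    subject_positions: dict[str, int] | None = None,
    cip_min: float = 60.0,
    calp_min: float = 0.7,
    tandem_window: int = 5,
) -> pd.DataFrame:
    """Classify every query against every subject genome present in the scores."""
    rows = []
    scores_df = scores_df.assign(subject_taxon=[subject_taxa[s] for s in scores_df.subject_id])
    for (q, taxon), grp in scores_df.groupby(["query_id", "subject_taxon"], sort=True):
        scores = [
            PairScore(str(q), str(r.subject_id), int(r.AL), float(r.CIP), float(r.CALP), int(r.n_hsps_used))
            for r in grp.itertuples(index=False)
        ]
        call = classify_conservation(
            scores, cip_min=cip_min, calp_min=calp_min,
            tandem_window=tandem_window, subject_positions=subject_positions,
        )
        rows.append(
            {"query_id": q, "subject_taxon": taxon, "class": call.klass,
             "subjects": ",".join(call.subjects), "others": ",".join(call.others)}
        )
    return pd.DataFrame(rows)
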