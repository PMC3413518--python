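"""Exon-intron structure inference by spliced alignment, and in-silico PCR.

A CDS is aligned onto its genomic template by anchoring exact k-mer
seeds, merging them into colinear diagonal blocks (one block per exon),
and resolving each exon-exon junction so that, among placements of equal
match score, splice sites fall on GT..AG, then GC..AG, then leftmost.
Introns are annotated with donor/acceptor dinucleotides, length and
phase (cumulative coding bases upstream, mod 3).

The alignment model assumes exons diverge by point substitutions only
(no indels within exons), which is the regime of closely related
orthologs and homoeologs this pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import hamming, revcomp

__all__ = [
    "GeneStructure",
    "IntronRecord",
    "PcrProduct",
    "NoStructureFound",
    "spliced_align",
    "annotate_introns",
    "splice",
    "insilico_pcr",
]


class NoStructureFound(Exception):
    """Raised when too little of the CDS can be placed on the genomic template."""


@dataclass
class GeneStructure:
    """Exon chain of one gene on a genomic sequence.

    ``exons`` are 0-based half-open intervals in forward genomic
    coordinates, ordered 5'->3' along the coding strand (ascending for
    '+', descending for '-').
    """

    gene_id: str
    taxon: str
    genomic_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_length: int
    mismatches: int = 0

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class IntronRecord:
    """One intron; index 1 is closest to the 5' end of the gene."""

    index: int
    start: int          # 0-based half-open, forward genomic coordinates
    end: int
    length: int
    donor: str
    acceptor: str
    phase: int
    canonical: bool
    splice_class: str   # canonical | non-canonical-GC | non-canonical


@dataclass
class PcrProduct:
    template_id: str
    start: int          # 0-based half-open product interval on the template
    end: int
    product_length: int
    forward_mismatches: int
    reverse_mismatches: int
    orientation: str = "+"   # '+' : forward primer on the plus strand


# ---------------------------------------------------------------------------
# spliced alignment


def _matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _seed_blocks(cds: str, genomic: str, k: int, max_hits: int) -> list[list[int, int, int]]:
    """Exact k-mer anchors merged into diagonal blocks [c_start, c_end, diag]."""
    index: dict[str, list[int]] = {}
    for g in range(len(genomic) - k + 1):
        index.setdefault(genomic[g : g + k], []).append(g)
    # anchors per diagonal: diag -> sorted cds positions
    diagonals: dict[int, list[int]] = {}
    for c in range(len(cds) - k + 1):
        hits = index.get(cds[c : c + k], ())
        if len(hits) > max_hits:  # repeat-derived seed, uninformative
            continue
        for g in hits:
            diagonals.setdefault(g - c, []).append(c)
    blocks = []
    merge_gap = 6 * k  # bridge runs of point substitutions on one diagonal
    for diag, cs in diagonals.items():
        cs.sort()
        start = prev = cs[0]
        for c in cs[1:]:
            if c - prev > merge_gap:
                blocks.append([start, prev + k, diag])
                start = c
            prev = c
        blocks.append([start, prev + k, diag])
    return blocks


def _chain_blocks(blocks: list[list[int]], k: int) -> list[list[int]]:
    """Best colinear chain (increasing cds position and diagonal) by DP.

    Blocks on different diagonals may overlap by up to ``k`` CDS bases:
    splice-site bases (e.g. the acceptor AG) can coincide with exon
    sequence, letting seed anchors spill across a junction.
    """
    blocks = sorted(blocks, key=lambda b: (b[0], b[2]))
    n = len(blocks)
    score = [b[1] - b[0] for b in blocks]
    back = [-1] * n
    for j in range(n):
        cj_s, _, dj = blocks[j]
        for i in range(j):
            ci_s, ci_e, di = blocks[i]
            if di > dj or (di == dj and ci_e > cj_s):
                continue
            if di < dj and ci_e > cj_s + k:  # new exon must advance on the cds
                continue
            gain = blocks[j][1] - max(blocks[j][0], ci_e)
            if score[i] + gain > score[j]:
                score[j] = score[i] + gain
                back[j] = i
    best = max(range(n), key=lambda j: score[j])
    chain = []
    while best != -1:
        chain.append(blocks[best])
        best = back[best]
    chain.reverse()
    # drop same-diagonal repeats and trim cds overlaps left over from chaining
    out = [chain[0][:]]
    for b in chain[1:]:
        if b[2] == out[-1][2]:
            out[-1][1] = max(out[-1][1], b[1])
        else:
            b = b[:]
            b[0] = max(b[0], out[-1][1])
            if b[1] > b[0]:
                out.append(b)
    return out


def _resolve_junction(cds, genomic, lo, hi, d1, d2, donors=("GT", "GC")):
    """Choose the junction cds-coordinate j in [lo, hi] between two diagonals.

    Maximizes matches; equal-score candidates prefer a GT..AG intron,
    then GC..AG, then leftmost.
    """
    best = None
    for j in range(lo, hi + 1):
        left = _matches(cds[lo:j], genomic[lo + d1 : j + d1])
        right = _matches(cds[j:hi], genomic[j + d2 : hi + d2])
        donor = genomic[j + d1 : j + d1 + 2]
        acceptor = genomic[j + d2 - 2 : j + d2]
        if acceptor == "AG" and donor == donors[0]:
            rank = 2
        elif acceptor == "AG" and donor in donors:
            rank = 1
        else:
            rank = 0
        key = (left + right, rank, -j)
        if best is None or key > best[0]:
            best = (key, j)
    return best[1]


def _align_forward(cds: str, genomic: str, k: int, max_hits: int):
    blocks = _seed_blocks(cds, genomic, k, max_hits)
    if not blocks:
        return None
    chain = _chain_blocks(blocks, k)
    # junction resolution between consecutive blocks
    bounds = [0]
    for i in range(len(chain) - 1):
        c_prev_end = chain[i][1]
        c_next_start = chain[i + 1][0]
        d1, d2 = chain[i][2], chain[i + 1][2]
        lo = max(bounds[-1], min(c_prev_end, c_next_start) - k)
        hi = min(len(cds), max(c_prev_end, c_next_start) + k)
        lo = max(lo, 0 if d1 >= 0 else -d1)
        hi = min(hi, len(genomic) - d2)
        if hi < lo:
            return None
        bounds.append(_resolve_junction(cds, genomic, lo, hi, d1, d2))
    bounds.append(len(cds))
    exons = []
    total_matches = 0
    for i, blk in enumerate(chain):
        c0, c1, d = bounds[i], bounds[i + 1], blk[2]
        if c1 <= c0 or c0 + d < 0 or c1 + d > len(genomic):
            return None
        exons.append((c0 + d, c1 + d))
        total_matches += _matches(cds[c0:c1], genomic[c0 + d : c1 + d])
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:  # negative-length intron: chain was inconsistent
            return None
    return exons, total_matches


def spliced_align(
    cds: str,
    genomic: str,
    gene_id: str = "gene",
    taxon: str = "",
    genomic_id: str = "genomic",
    k: int = 15,
    max_seed_hits: int = 20,
    min_coverage: float = 0.9,
    mismatch_budget: float = 0.02,
) -> GeneStructure:
    """Infer the exon chain of ``cds`` on ``genomic``; both strands are tried.

    Raises :class:`NoStructureFound` when fewer than ``min_coverage`` of
    the CDS bases can be matched, or the matched chain exceeds the
    ``mismatch_budget`` (a fraction of CDS length).
    """
    cds, genomic = cds.upper(), genomic.upper()
    if not cds or not genomic:
        raise ValueError("empty sequence")
    if len(genomic) < len(cds):
        raise ValueError("genomic template shorter than the CDS")
    results = []
    for strand, template in (("+", genomic), ("-", revcomp(genomic))):
        res = _align_forward(cds, template, k, max_seed_hits)
        if res is not None:
            results.append((res[1], strand, res[0]))
    if not results:
        raise NoStructureFound(f"{gene_id}: no seed chain found on either strand")
    total_matches, strand, exons = max(results, key=lambda r: r[0])
    if strand == "-":
        L = len(genomic)
        exons = [(L - e, L - s) for s, e in exons]  # forward coords, coding order kept
    structure = GeneStructure(gene_id, taxon, genomic_id, strand, exons, len(cds))
    spliced = splice(genomic, structure)
    if len(spliced) != len(cds):
        raise NoStructureFound(f"{gene_id}: chained exons cover {len(spliced)}/{len(cds)} CDS bases")
    mism = hamming(spliced, cds)
    structure.mismatches = mism
    if total_matches < min_coverage * len(cds):
        raise NoStructureFound(
            f"{gene_id}: only {total_matches}/{len(cds)} CDS bases alignable (<{min_coverage:.0%})"
        )
    if mism > mismatch_budget * len(cds):
        raise NoStructureFound(f"{gene_id}: {mism} mismatches exceed budget")
    return structure


def splice(genomic: str, structure: GeneStructure) -> str:
    """Concatenate the exon intervals along the coding strand."""
    parts = [genomic[s:e] for s, e in structure.exons]
    if structure.strand == "-":
        return "".join(revcomp(p) for p in parts)
    return "".join(parts)


def annotate_introns(structure: GeneStructure, genomic: str) -> list[IntronRecord]:
    """One record per inter-exon gap, numbered from the 5' end of the gene."""
    genomic = genomic.upper()
    records = []
    coding = 0
    exons = structure.exons
    for i in range(len(exons) - 1):
        coding += exons[i][1] - exons[i][0]
        if structure.strand == "+":
            start, end = exons[i][1], exons[i + 1][0]
            if end <= start:
                raise ValueError(f"adjacent exons {i + 1}/{i + 2} have zero gap; merge them")
            seq = genomic[start:end]
        else:
            start, end = exons[i + 1][1], exons[i][0]
            if end <= start:
                raise ValueError(f"adjacent exons {i + 1}/{i + 2} have zero gap; merge them")
            seq = revcomp(genomic[start:end])
        donor, acceptor = seq[:2], seq[-2:]
        if (donor, acceptor) == ("GT", "AG"):
            klass, canonical = "canonical", True
        elif (donor, acceptor) == ("GC", "AG"):
            klass, canonical = "non-canonical-GC", False
        else:
            klass, canonical = "non-canonical", False
        records.append(
            IntronRecord(
                index=i + 1, start=start, end=end, length=end - start,
                donor=donor, acceptor=acceptor, phase=coding % 3,
                canonical=canonical, splice_class=klass,
            )
        )
    return records


# ---------------------------------------------------------------------------
# in-silico PCR


def _primer_sites(primer: str, template: str, max_mismatches: int, minus: bool):
    """Binding sites of a primer; the primer's 3'-terminal base must match exactly.

    Returns (position, mismatches) where position is the 0-based start of
    the site on the plus strand of the template.
    """
    probe = revcomp(primer) if minus else primer
    L = len(probe)
    three_prime = 0 if minus else L - 1  # index of the primer's 3' base within the site
    sites = []
    for i in range(len(template) - L + 1):
        window = template[i : i + L]
        if window[three_prime] != probe[three_prime]:
            continue
        mm = hamming(window, probe)
        if mm <= max_mismatches:
            sites.append((i, mm))
    return sites


def insilico_pcr(
    forward: str,
    reverse: str,
    template: str,
    template_id: str = "template",
    max_mismatches: int = 0,
    max_product: int = 5000,
    min_primer_len: int = 15,
) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on a template, smallest first.

    Product lengths are primer-inclusive.  Both amplicon orientations are
    searched (forward primer on either strand, reverse primer on the
    other).  A primer whose 3'-terminal base mismatches never primes,
    regardless of ``max_mismatches``.
    """
    template = template.upper()
    forward, reverse = forward.upper(), reverse.upper()
    for name, p in (("forward", forward), ("reverse", reverse)):
        if len(p) < min_primer_len:
            raise ValueError(f"{name} primer shorter than {min_primer_len} nt")
    products = []
    combos = [(forward, reverse, "+"), (reverse, forward, "-")]
    for plus_primer, minus_primer, orientation in combos:
        plus_sites = _primer_sites(plus_primer, template, max_mismatches, minus=False)
        minus_sites = _primer_sites(minus_primer, template, max_mismatches, minus=True)
        for i, mm_f in plus_sites:
            for j, mm_r in minus_sites:
                end = j + len(minus_primer)
                length = end - i
                if length < len(forward) + len(reverse) or length > max_product:
                    continue
                fw_mm, rv_mm = (mm_f, mm_r) if orientation == "+" else (mm_r, mm_f)
                products.append(
                    PcrProduct(template_id, i, end, length, fw_mm, rv_mm, orientation)
                )
    products.sort(key=lambda p: (p.product_length, p.start))
    # a palindromic pairing can be found in both orientations; keep one
    seen = set()
    unique = []
    for p in products:
        key = (p.start, p.end)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique
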