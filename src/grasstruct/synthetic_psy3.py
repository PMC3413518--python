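"""Synthetic stand-in for the wheat PSY3 homoeologous loci.

The real PSY3A/B/D BAC-derived sequences are not redistributable here,
so this module builds a fully synthetic, deterministic trio of
homoeologous gene models constructed to carry the reported hallmarks of
the locus family, which the analysis modules then *measure* at run time:

* proteins of 413 / 401 / 403 aa for the A / B / D copies;
* ~96% amino-acid identity between the B and D proteins (91% A-B);
* four exons spaced by three GT..AG introns;
* a 216 bp amplicon for the PSY3F2R1-style primer pair on the third exon;
* in the D copy, an inverted duplication of the fourth exon 1729 bp
  downstream of the stop codon, interrupted by a 154 bp internal
  deletion flanked on both sides by the TACTGG motif;
* a promoter carrying ABRE / G-box / CE1 cis-elements.

Everything is generated from a seed; no real sequence data is embedded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import STOP_CODONS, revcomp, translate
from .genestruct import GeneStructure

__all__ = ["SyntheticGene", "SyntheticPsy3Family", "build_synthetic_psy3"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one representative codon per amino acid (deterministic back-translation)
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAG", "L": "CTT", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTC",
    "W": "TGG", "Y": "TAC",
}

# CDS-space exon lengths per homoeolog: exon2/3/4 shared, exon1 carries the indels
_EXON_LENS = {
    "PSY3A": (386, 412, 230, 214),
    "PSY3B": (350, 412, 230, 214),
    "PSY3D": (356, 412, 230, 214),
}
_SUFFIX_LEN = 230 + 214          # exon3 + exon4, shared nucleotide-for-nucleotide
_AMPLICON = (7, 223)             # 216 bp window within exon3
_DEL_A, _DEL_B = 34, 188         # deleted exon-4 segment [34, 188) = 154 bp
_DUP_END = 211                   # duplicated unit = exon4[:211], ends with GTG
_DUP_SPACER = 1728               # copy's first base is 1729 bp downstream of the stop
_FLANK_MOTIF = "TACTGG"


@dataclass
class SyntheticGene:
    gene_id: str
    genomic: str
    cds: str
    protein: str
    promoter: str
    structure: GeneStructure
    stop_codon_end: int          # genomic coordinate just past the stop codon


@dataclass
class SyntheticPsy3Family:
    genes: dict[str, SyntheticGene]
    forward_primer: str          # PSY3F2R1-style pair on the third exon
    reverse_primer: str
    exon4: str                   # shared fourth-exon sequence (CDS part)


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _fix_stops(seq: str, protected: set[int]) -> str:
    """Rewrite in-frame stop codons (frame 0) outside protected positions."""
    chars = list(seq)
    for i in range(0, len(chars) - 2, 3):
        if "".join(chars[i : i + 3]) in STOP_CODONS:
            for j in (i + 2, i + 1, i):
                if j not in protected:
                    chars[j] = "C"
                    if "".join(chars[i : i + 3]) not in STOP_CODONS:
                        break
    return "".join(chars)


def _build_suffix(rng) -> str:
    """Shared exon3+exon4 nucleotides with amplicon and duplication hallmarks."""
    n_codons = _SUFFIX_LEN // 3
    codons = []
    while len(codons) < n_codons - 1:
        codon = _rand_seq(rng, 3)
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TGA")
    suffix = list("".join(codons))
    protected = set()

    def plant(pos, motif):
        for k, ch in enumerate(motif):
            suffix[pos + k] = ch
            protected.add(pos + k)

    plant(230, "GTG")                          # exon4 starts with GTG
    plant(230 + _DEL_A - 6, _FLANK_MOTIF)      # TACTGG before the deleted segment
    plant(230 + _DEL_B - 6, _FLANK_MOTIF)      # TACTGG ending the deleted segment
    plant(230 + _DUP_END - 3, "GTG")           # duplicated unit ends GTG, so the
    protected.update(range(_SUFFIX_LEN - 3, _SUFFIX_LEN))  # inverted copy starts CAC
    return _fix_stops("".join(suffix), protected)


def _prefix_proteins(rng):
    """Exon1+exon2 protein regions for A (266 aa), B (254 aa) and D (256 aa)."""
    a = ["M"] + [_AA[rng.integers(0, 20)] for _ in range(265)]
    b = a[:100] + a[112:]                      # 12-residue deletion -> 254 aa
    for pos in rng.choice(np.arange(5, 250), size=25, replace=False):
        b[pos] = _AA[(_AA.index(b[pos]) + 1 + rng.integers(0, 18)) % 20]
    d = b[:150] + [_AA[rng.integers(0, 20)] for _ in range(2)] + b[150:]  # 256 aa
    subs = rng.choice(np.concatenate([np.arange(5, 148), np.arange(154, 252)]),
                      size=14, replace=False)
    for pos in subs:
        d[pos] = _AA[(_AA.index(d[pos]) + 1 + rng.integers(0, 18)) % 20]
    return {"PSY3A": "".join(a), "PSY3B": "".join(b), "PSY3D": "".join(d)}


def build_synthetic_psy3(seed: int = 0) -> SyntheticPsy3Family:
    """Deterministically construct the synthetic PSY3A/B/D homoeolog trio."""
    rng = np.random.default_rng(seed)
    suffix = _build_suffix(rng)
    exon4 = suffix[230:]
    prefixes = _prefix_proteins(rng)

    forward = suffix[_AMPLICON[0] : _AMPLICON[0] + 20]
    reverse = revcomp(suffix[_AMPLICON[1] - 20 : _AMPLICON[1]])

    # duplicated copy for the D locus: inverted, with the 154 bp internal
    # deletion; the unit stops just short of the stop codon, ending in GTG so
    # that the inverted copy begins with the complementary CAC
    exon4_del = exon4[:_DEL_A] + exon4[_DEL_B:_DUP_END]
    dup_copy = revcomp(exon4_del)

    genes = {}
    for gene_id, exon_lens in _EXON_LENS.items():
        prefix_nt = "".join(_CODON[a] for a in prefixes[gene_id])
        cds = prefix_nt + suffix
        assert len(cds) == sum(exon_lens)
        promoter = _plant_promoter(_rand_seq(rng, 1200))
        introns = [
            "GT" + _rand_seq(rng, int(rng.integers(250, 600))) + "AG" for _ in range(3)
        ]
        pieces, exons = [promoter], []
        pos = len(promoter)
        cds_pos = 0
        for k, L in enumerate(exon_lens):
            pieces.append(cds[cds_pos : cds_pos + L])
            exons.append((pos, pos + L))
            pos += L
            cds_pos += L
            if k < 3:
                pieces.append(introns[k])
                pos += len(introns[k])
        stop_end = pos
        if gene_id == "PSY3D":
            spacer = _clean_spacer(rng, _DUP_SPACER, exon4)
            # the base abutting the copy must not extend the homology by chance,
            # which would shift the measured offset by one
            extender = revcomp(exon4)[len(exon4) - _DUP_END - 1]
            if spacer[-1] == extender:
                spacer = spacer[:-1] + ("A" if extender != "A" else "C")
            pieces += [spacer, dup_copy, _rand_seq(rng, 250)]
        else:
            pieces.append(_rand_seq(rng, 600))
        genomic = "".join(pieces)
        structure = GeneStructure(gene_id, "wheat", gene_id, "+", exons, len(cds))
        genes[gene_id] = SyntheticGene(
            gene_id, genomic, cds, translate(cds), promoter, structure, stop_end
        )
    return SyntheticPsy3Family(genes, forward, reverse, exon4)


def _plant_promoter(seq: str) -> str:
    chars = list(seq)
    for pos, motif in ((len(seq) - 500, "ACGTG"),
                      (len(seq) - 300, "CACGTG"),
                      (len(seq) - 250, "TGCCACCGG")):
        chars[pos : pos + len(motif)] = motif
    return "".join(chars)


def _clean_spacer(rng, n: int, exon: str, k: int = 12) -> str:
    """Random spacer free of exact k-mer matches to the exon (either strand)."""
    kmers = {exon[i : i + k] for i in range(len(exon) - k + 1)}
    kmers |= {revcomp(m) for m in kmers}
    for _ in range(50):
        spacer = _rand_seq(rng, n)
        if not any(spacer[i : i + k] in kmers for i in range(n - k + 1)):
            return spacer
    return spacer
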