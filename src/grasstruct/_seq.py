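"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC nucleotide ambiguity codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(consensus: str) -> re.Pattern:
    """Compile an IUPAC consensus into a regex; unknown codes raise ValueError."""
    parts = []
    for ch in consensus.upper():
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {ch!r} in consensus {consensus!r}")
        parts.append(bases if len(bases) == 1 else "[" + bases + "]")
    return re.compile("".join(parts))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def translate(cds: str) -> str:
    """Translate a CDS (standard code); trailing stop is dropped, '*' marks stops."""
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot
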