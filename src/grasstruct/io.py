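"""Readers and writers for the flat-file formats the pipeline touches.

FASTA (60-column wrap), GFF3 (1-based inclusive coordinates, per the
standard), Newick species trees and tab-delimited tables.  Internal
coordinates everywhere else in the package are 0-based half-open; the
conversion happens here and only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "Gff3Feature",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "read_tsv",
    "write_tsv",
]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    """Write ``{id: sequence}`` as FASTA with fixed-width line wrapping."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass
class Gff3Feature:
    """One GFF3 feature line; ``start``/``end`` are 1-based inclusive."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str = "."
    strand: str = "+"
    phase: str = "."
    attributes: dict = field(default_factory=dict)

    @property
    def interval0(self) -> tuple[int, int]:
        """The feature interval as 0-based half-open coordinates."""
        return self.start - 1, self.end

    @classmethod
    def from_interval0(cls, seqid, source, type, start0, end0, **kw):
        return cls(seqid, source, type, start0 + 1, end0, **kw)


def _parse_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path) -> list[Gff3Feature]:
    """Parse a GFF3 file; malformed lines raise ValueError naming the line."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
                attrs = _parse_attributes(cols[8])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid coordinates start={start} end={end}")
            if cols[6] not in "+-.":
                raise ValueError(f"{path}:{lineno}: invalid strand {cols[6]!r}")
            features.append(
                Gff3Feature(cols[0], cols[1], cols[2], start, end, cols[5], cols[6], cols[7], attrs)
            )
    return features


def write_gff3(features: list[Gff3Feature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                "\t".join(
                    [f.seqid, f.source, f.type, str(f.start), str(f.end), f.score, f.strand, f.phase, attrs]
                )
                + "\n"
            )


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = Path(source).read_text()
    else:
        data = str(source)
    tree = dendropy.Tree.get(data=data, schema="newick", suppress_internal_node_taxa=False)
    tree.is_rooted = True
    return tree


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_tsv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, **kw)
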