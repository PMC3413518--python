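"""Homologous intron sites, Dollo-parsimony loss inference, exon fusions.

Intron positions from several orthologous gene structures are projected
into a common coordinate system through codon-aware pairwise alignments
(translated CDS aligned globally, positions projected back to
nucleotides), and merged into homologous *sites* only when both the
projected coordinate and the intron phase agree exactly; near-miss
positions (within one codon, same phase) raise a warning but are never
merged, since intron sliding is contentious and conservative merging
avoids false homology.

Loss events are inferred per site under Dollo parsimony: the intron is
gained once, at the root (ancestral state present whenever at least one
taxon retains it), and the minimum set of loss branches is found by
placing one loss on every maximal edge whose subtree shows no presence.
Adjacent sites lost on the same branch merge into one multi-intron event
(the signature of mRNA-mediated loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import Align

from ._seq import translate
from .genestruct import GeneStructure

__all__ = [
    "IntronSiteMatrix",
    "LossEvent",
    "FusionRecord",
    "map_intron_sites",
    "infer_loss_events",
    "detect_exon_fusions",
]

PRESENT, ABSENT, UNALIGNABLE = "present", "absent", "unalignable"


@dataclass
class IntronSiteMatrix:
    """Presence/absence of homologous intron sites across genes.

    ``sites`` holds (reference CDS coordinate, phase) pairs, 5'->3'.
    ``cells`` is a sites x genes DataFrame over {present, absent,
    unalignable}; ``local_coords`` gives each site's projected coordinate
    in every gene's own CDS (NaN where unalignable).
    """

    sites: list[tuple[int, int]]
    cells: pd.DataFrame
    local_coords: pd.DataFrame
    reference: str

    @property
    def taxa(self) -> list[str]:
        return list(self.cells.columns)

    def pattern(self, gene: str) -> tuple[str, ...]:
        return tuple(self.cells[gene])


@dataclass(frozen=True)
class LossEvent:
    sites: tuple[int, ...]      # 1-based site indices, adjacent, 5'->3'
    branch: str                 # label of the child node of the losing branch
    multiplicity: int
    mechanism: str              # mrna_mediated for multi-site events, else indeterminate


@dataclass(frozen=True)
class FusionRecord:
    gene_id: str
    fused_exon_index: int             # 1-based index in the modern structure
    contributing_exons: tuple[int, ...]  # 1-based ancestral (reference) exon indices
    junctions: tuple[int, ...]        # coordinates of lost introns within the modern exon


def _intron_offsets(structure: GeneStructure) -> list[int]:
    lens = structure.exon_lengths()
    return list(np.cumsum(lens)[:-1])


def _protein_maps(ref_prot: str, prot: str):
    """Forward/backward residue maps between one protein and the reference."""
    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-5, extend_gap_score=-0.5,
    )
    aln = aligner.align(ref_prot, prot)[0]
    to_ref = {}
    from_ref = {}
    for (rs, re), (qs, qe) in zip(*aln.aligned):
        for k in range(re - rs):
            to_ref[qs + k] = rs + k
            from_ref[rs + k] = qs + k
    return to_ref, from_ref


def map_intron_sites(
    structures: list[GeneStructure],
    cds_map: dict[str, str],
    reference: str | None = None,
) -> IntronSiteMatrix:
    """Project intron positions of >=2 structures onto homologous sites.

    The reference defaults to the gene with the most introns (the taxon
    closest to the ancestral complement).  An untranslatable CDS
    (internal stop codon) raises ValueError naming the gene.
    """
    if len(structures) < 2:
        raise ValueError("need at least two gene structures")
    if reference is None:
        reference = max(structures, key=lambda s: (s.n_introns, -structures.index(s))).gene_id
    proteins = {}
    for s in structures:
        prot = translate(cds_map[s.gene_id])
        if "*" in prot:
            raise ValueError(f"{s.gene_id}: internal stop codon; CDS untranslatable")
        proteins[s.gene_id] = prot
    ref_prot = proteins[reference]

    maps = {}
    for s in structures:
        if s.gene_id == reference:
            ident = {i: i for i in range(len(ref_prot))}
            maps[s.gene_id] = (ident, dict(ident))
        else:
            maps[s.gene_id] = _protein_maps(ref_prot, proteins[s.gene_id])

    # project each intron to a (reference coordinate, phase) pair
    projections: dict[str, dict[tuple[int, int], int]] = {}
    for s in structures:
        to_ref, _ = maps[s.gene_id]
        proj = {}
        for off in _intron_offsets(s):
            aa, phase = divmod(off, 3)
            ref_aa = to_ref.get(min(aa, len(proteins[s.gene_id]) - 1))
            if ref_aa is None:
                continue  # falls in a gap: keep the intron unplaced
            proj[(ref_aa * 3 + phase, phase)] = off
        projections[s.gene_id] = proj

    sites = sorted({key for proj in projections.values() for key in proj})
    _warn_near_misses(sites)
    cells = {}
    local = {}
    for s in structures:
        _, from_ref = maps[s.gene_id]
        col, loc = [], []
        for coord, phase in sites:
            if (coord, phase) in projections[s.gene_id]:
                col.append(PRESENT)
                loc.append(projections[s.gene_id][(coord, phase)])
            else:
                ref_aa = coord // 3
                gene_aa = from_ref.get(ref_aa)
                if gene_aa is None:
                    col.append(UNALIGNABLE)
                    loc.append(np.nan)
                else:
                    col.append(ABSENT)
                    loc.append(gene_aa * 3 + phase)
        cells[s.gene_id] = col
        local[s.gene_id] = loc
    index = pd.Index([f"site{i + 1}" for i in range(len(sites))], name="site")
    return IntronSiteMatrix(
        sites=list(sites),
        cells=pd.DataFrame(cells, index=index),
        local_coords=pd.DataFrame(local, index=index),
        reference=reference,
    )


def _warn_near_misses(sites) -> None:
    for (c1, p1), (c2, p2) in zip(sites, sites[1:]):
        if p1 == p2 and 0 < c2 - c1 <= 3:
            warnings.warn(
                f"intron sites at reference coordinates {c1} and {c2} (phase {p1}) are "
                "within one codon; kept separate (possible intron sliding)",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Dollo parsimony


def _clade_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


def infer_loss_events(matrix: IntronSiteMatrix, tree: dendropy.Tree) -> list[LossEvent]:
    """Minimal Dollo loss sets per site, merged into per-branch events.

    Unalignable cells are missing data: they neither demand presence nor
    force a loss.  Polytomies are handled by placing losses on the
    polytomy's child edges exactly as on any other edge.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaves != set(matrix.taxa):
        raise ValueError(f"tree leaves {sorted(leaves)} != matrix taxa {sorted(matrix.taxa)}")
    site_losses: dict[str, list[int]] = {}
    for si, _ in enumerate(matrix.sites):
        states = {g: matrix.cells.iloc[si][g] for g in matrix.taxa}
        if PRESENT not in states.values():
            continue  # never observed: no single-gain reconstruction to make
        has_present = {}
        has_absent = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                st = states[node.taxon.label]
                has_present[node] = st == PRESENT
                has_absent[node] = st == ABSENT
            else:
                has_present[node] = any(has_present[c] for c in node.child_nodes())
                has_absent[node] = any(has_absent[c] for c in node.child_nodes())
        stack = [tree.seed_node]
        while stack:
            node = stack.pop()
            for child in node.child_nodes():
                if has_present[child]:
                    stack.append(child)
                elif has_absent[child]:
                    site_losses.setdefault(_clade_label(child), []).append(si + 1)
                # all-unalignable subtree: no evidence, no loss
    events = []
    for branch in sorted(site_losses):
        run: list[int] = []
        for s in sorted(site_losses[branch]):
            if run and s == run[-1] + 1:
                run.append(s)
            else:
                if run:
                    events.append(_make_event(run, branch))
                run = [s]
        if run:
            events.append(_make_event(run, branch))
    return events


def _make_event(sites: list[int], branch: str) -> LossEvent:
    return LossEvent(
        sites=tuple(sites), branch=branch, multiplicity=len(sites),
        mechanism="mrna_mediated" if len(sites) >= 2 else "indeterminate",
    )


# ---------------------------------------------------------------------------
# exon fusions


def detect_exon_fusions(
    matrix: IntronSiteMatrix,
    structures: list[GeneStructure],
    reference_taxon: str | None = None,
) -> list[FusionRecord]:
    """Report modern exons formed by fusion of adjacent ancestral exons.

    The reference is a gene retaining every site; when none exists the
    Dollo root reconstruction (all sites ancestral) is used, so ancestral
    exon ``k`` lies between sites ``k-1`` and ``k`` in either case.
    """
    by_id = {s.gene_id: s for s in structures}
    n_sites = len(matrix.sites)
    if reference_taxon is not None:
        if list(matrix.cells[reference_taxon]).count(PRESENT) != n_sites:
            raise ValueError(f"{reference_taxon} does not retain all {n_sites} sites")
    records = []
    for gene in matrix.taxa:
        s = by_id[gene]
        bounds = np.cumsum(s.exon_lengths())  # modern exon end coordinates in the CDS
        absent: dict[int, list[tuple[int, int]]] = {}
        for si in range(n_sites):
            if matrix.cells.iloc[si][gene] != ABSENT:
                continue
            coord = matrix.local_coords.iloc[si][gene]
            if np.isnan(coord):
                continue
            exon_idx = int(np.searchsorted(bounds, coord, side="right"))
            exon_start = 0 if exon_idx == 0 else int(bounds[exon_idx - 1])
            absent.setdefault(exon_idx, []).append((si + 1, int(coord) - exon_start))
        for exon_idx, lost in sorted(absent.items()):
            site_ids = [si for si, _ in lost]
            contributing = tuple(range(site_ids[0], site_ids[-1] + 2))
            records.append(
                FusionRecord(
                    gene_id=gene,
                    fused_exon_index=exon_idx + 1,
                    contributing_exons=contributing,
                    junctions=tuple(j for _, j in lost),
                )
            )
    return records
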