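"""Recovery scoring: run the analysis modules on simulated families with
known truth and measure how much of the truth they reconstruct.

This closes the generator/analysis loop: exon boundaries recovered by
spliced alignment, loss events recovered by Dollo parsimony, and
mechanism labels recovered by breakpoint scanning are each compared to
the generator's planted truth.
"""

from __future__ import annotations

from . import genestruct, intronevo, repeatmotif
from .io import read_newick
from .synthio import FamilyTruth

__all__ = [
    "recover_structures",
    "exon_boundary_recovery",
    "loss_event_recovery",
    "mechanism_accuracy",
]


def recover_structures(truth: FamilyTruth) -> list[genestruct.GeneStructure]:
    """Spliced-align every simulated gene's CDS back onto its genomic sequence."""
    return [
        genestruct.spliced_align(g.cds, g.genomic, gene_id=gid, taxon=g.taxon, genomic_id=gid)
        for gid, g in truth.genes.items()
    ]


def exon_boundary_recovery(truth: FamilyTruth) -> tuple[float, int]:
    """Fraction of true exon boundaries recovered exactly; (fraction, n)."""
    total = hit = 0
    for s in recover_structures(truth):
        true = truth.genes[s.gene_id].exons
        true_bounds = {b for iv in true for b in iv}
        got_bounds = {b for iv in s.exons for b in iv}
        total += len(true_bounds)
        hit += len(true_bounds & got_bounds)
    return hit / total, total


def _ancestral_site_index(truth: FamilyTruth, coord: int) -> int | None:
    try:
        return truth.site_offsets.index(coord) + 1
    except ValueError:
        return None


def loss_recovery_report(truth: FamilyTruth) -> dict:
    """Compare Dollo-inferred (site, branch) losses against the planted truth.

    Requires one gene per taxon.  A planted history with parallel losses
    of the same site on sibling branches is not identifiable from
    presence/absence data: Dollo parsimony provably reconstructs a single
    loss on the stem.  Such misses are verified (the inferred
    reconstruction uses strictly fewer losses at that site than were
    planted) and reported under ``ambiguous_misses``.
    """
    structures = recover_structures(truth)
    cds = {g: t.cds for g, t in truth.genes.items()}
    matrix = intronevo.map_intron_sites(structures, cds)
    tree = read_newick(truth.config.tree)
    events = intronevo.infer_loss_events(matrix, tree)
    inferred = set()
    for e in events:
        for s in e.sites:
            anc = _ancestral_site_index(truth, matrix.sites[s - 1][0])
            if anc is not None:
                inferred.add((anc, e.branch))
    true_pairs = {(s, l.branch) for l in truth.losses for s in l.sites}
    misses = true_pairs - inferred
    inferred_per_site: dict[int, int] = {}
    for s, _ in inferred:
        inferred_per_site[s] = inferred_per_site.get(s, 0) + 1
    true_per_site: dict[int, int] = {}
    for s, _ in true_pairs:
        true_per_site[s] = true_per_site.get(s, 0) + 1
    ambiguous = {
        (s, b) for s, b in misses
        if inferred_per_site.get(s, 0) < true_per_site[s]
    }
    return {
        "true_pairs": true_pairs,
        "inferred_pairs": inferred,
        "misses": misses,
        "ambiguous_misses": ambiguous,
    }


def loss_event_recovery(truth: FamilyTruth) -> tuple[float, int]:
    """Fraction of planted (site, branch) losses recovered exactly; (fraction, n)."""
    report = loss_recovery_report(truth)
    n = len(report["true_pairs"])
    if n == 0:
        return 1.0, 0
    return 1.0 - len(report["misses"]) / n, n


def mechanism_accuracy(truth: FamilyTruth, window: int = 15, min_arm: int = 3) -> tuple[float, int]:
    """Label accuracy over single-site repeat_mediated / simple_deletion losses.

    For each such truth event, the fusion junction of a descendant leaf
    gene is scanned for breakpoint repeats and the classifier's label is
    compared with the planted mechanism.
    """
    total = correct = 0
    for loss in truth.losses:
        if loss.multiplicity != 1 or loss.mechanism == "mrna_mediated":
            continue
        site = loss.sites[0]
        junction = truth.site_offsets[site - 1]
        descendants = loss.branch.split("+")
        leaf_genes = [g for g, t in truth.genes.items() if t.taxon == descendants[0]]
        gene = truth.genes[leaf_genes[0]]
        hits = repeatmotif.scan_breakpoint_repeats(gene.cds, junction, window=window, min_arm=min_arm)
        label = repeatmotif.classify_loss_mechanism(loss.multiplicity, hits, min_arm=min_arm)
        total += 1
        correct += label == loss.mechanism
    return (correct / total if total else 1.0), total
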