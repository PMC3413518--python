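"""Synthetic multi-species gene families, HSP tables and qPCR Cq tables.

The gene-family generator emulates the comparative setting of a grass
ortholog family: a single ancestral exon-intron architecture generated
at the root of a rooted species tree, lineage-specific intron losses
drawn along branches (each with a mechanism: repeat-mediated deletion
planting an inverted-repeat pair across the fusion junction,
simple genomic deletion with a junction scrubbed of chance repeats, or
mRNA-mediated loss removing a 3'-biased run of adjacent introns), and
optional near-identical within-taxon (homoeologous) copies.  Every
generated gene carries its truth: exon intervals, CDS, loss events and
planted repeat coordinates, so that recovery by the analysis modules can
be scored exactly.

The Cq-table generator plants per-gene amplification efficiencies and
fold-change profiles:  Cq = Cq0 - log_E(relative abundance) + noise,
with flat abundance for reference genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as gio
from ._seq import STOP_CODONS, revcomp

__all__ = [
    "FamilyConfig",
    "GeneTruth",
    "LossTruth",
    "FamilyTruth",
    "CqConfig",
    "simulate_gene_family",
    "simulate_hsp_table",
    "simulate_cq_table",
    "simulate_standard_curve",
    "write_family",
]

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

MECHANISMS = ("repeat_mediated", "simple_deletion", "mrna_mediated")


@dataclass
class FamilyConfig:
    """Study conditions for one simulated ortholog family."""

    taxa: tuple[str, ...] = ("rice", "maize", "sorghum", "brachypodium", "wheat")
    tree: str = "(rice,((maize,sorghum),(brachypodium,wheat)));"
    n_introns_ancestral: int = 5
    exon_length_range: tuple[int, int] = (90, 450)
    intron_length_range: tuple[int, int] = (80, 900)
    loss_prob_per_branch: float = 0.05
    mechanism_mix: dict = field(
        default_factory=lambda: {"repeat_mediated": 0.4, "simple_deletion": 0.4, "mrna_mediated": 0.2}
    )
    planted_repeat_arm_len: int = 3
    homoeolog_divergence: float = 0.005
    n_copies_per_taxon: int = 1
    gc_donor_fraction: float = 0.1
    branch_substitution_prob: float = 0.0
    mrna_run_mean: float = 2.0
    forced_losses: tuple = ()  # of (site_index_1based, branch_child_label, mechanism)
    flank_length: int = 200
    seed: int = 0

    def validate(self) -> None:
        for name in ("loss_prob_per_branch", "homoeolog_divergence",
                     "gc_donor_fraction", "branch_substitution_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise ValueError("mechanism_mix must sum to 1")
        if set(self.mechanism_mix) - set(MECHANISMS):
            raise ValueError(f"unknown mechanisms {set(self.mechanism_mix) - set(MECHANISMS)}")
        for name in ("exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo or hi < 1:
                raise ValueError(f"{name}=({lo}, {hi}) must be positive and ordered")
        if self.intron_length_range[0] < 10:
            raise ValueError("introns shorter than 10 bp are not representable")
        if self.n_introns_ancestral < 0:
            raise ValueError("n_introns_ancestral must be >= 0")
        if self.planted_repeat_arm_len < 3:
            raise ValueError("planted_repeat_arm_len must be >= 3")
        if self.n_copies_per_taxon < 1:
            raise ValueError("n_copies_per_taxon must be >= 1")


@dataclass
class GeneTruth:
    gene_id: str
    taxon: str
    genomic: str
    cds: str
    exons: list[tuple[int, int]]          # 0-based half-open on the genomic, '+' strand
    present_sites: tuple[int, ...]        # ancestral site indices (1-based) retained


@dataclass
class LossTruth:
    sites: tuple[int, ...]                # ancestral site indices (1-based), adjacent
    branch: str                           # child-node label of the branch carrying the loss
    mechanism: str

    @property
    def multiplicity(self) -> int:
        return len(self.sites)


@dataclass
class FamilyTruth:
    config: FamilyConfig
    tree_newick: str
    site_offsets: tuple[int, ...]         # CDS offset of each ancestral intron site
    genes: dict[str, GeneTruth]
    losses: list[LossTruth]
    planted_repeats: list[dict]

    def taxa_genes(self) -> dict[str, list[str]]:
        by_taxon: dict[str, list[str]] = {}
        for gid, g in self.genes.items():
            by_taxon.setdefault(g.taxon, []).append(gid)
        return by_taxon


# ---------------------------------------------------------------------------
# gene-family simulation


class _NodeState:
    __slots__ = ("exons", "introns", "present")

    def __init__(self, exons, introns, present):
        self.exons = list(exons)
        self.introns = list(introns)
        self.present = list(present)

    def clone(self):
        return _NodeState(self.exons, self.introns, self.present)


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _mutate(rng, seq: str, prob: float, protect_head: int = 0, protect_tail: int = 0) -> str:
    if prob <= 0 or not seq:
        return seq
    chars = list(seq)
    for i in range(protect_head, len(chars) - protect_tail):
        if rng.random() < prob:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[rng.integers(0, 3)]
    return "".join(chars)


def _junction_has_repeat(up: str, down: str, min_arm: int = 3, max_arm: int = 8) -> bool:
    for L in range(min_arm, min(max_arm, len(up), len(down)) + 1):
        a1, a2 = up[-L:], down[:L]
        if a1 == a2 or a2 == revcomp(a1):
            return True
    return False


def _junction_makes_stop(up: str, down: str, junction_offset: int, window: int = 9) -> bool:
    """True if the fused junction context contains an in-frame stop codon.

    ``junction_offset`` is the CDS coordinate of the fusion point; exon
    piece lengths are invariant under substitution, so it equals the
    ancestral cumulative exon length at the site.
    """
    w_up = min(window, len(up))
    ctx = up[-w_up:] + down[: min(window, len(down))]
    start = junction_offset - w_up
    first = (-start) % 3
    for i in range(first, len(ctx) - 2, 3):
        if ctx[i : i + 3] in STOP_CODONS:
            return True
    return False


def _label_nodes(tree: dendropy.Tree) -> None:
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.annotations["clade"] = node.taxon.label
        else:
            leaves = sorted(l.taxon.label for l in node.leaf_iter())
            node.annotations["clade"] = "+".join(leaves)


def _node_label(node) -> str:
    return node.annotations["clade"].value


def simulate_gene_family(config: FamilyConfig) -> FamilyTruth:
    """Simulate one ortholog family along a rooted species tree.

    Deterministic given ``config.seed``.  Raises ValueError for an
    unrooted tree (basal polytomy) or a leaf set not matching
    ``config.taxa``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = gio.read_newick(config.tree)
    if tree.seed_node.num_child_nodes() != 2:
        raise ValueError("species tree must be rooted (bifurcating at the root)")
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaf_labels != set(config.taxa):
        raise ValueError(f"tree leaves {sorted(leaf_labels)} != taxa {sorted(config.taxa)}")
    _label_nodes(tree)

    n_sites = config.n_introns_ancestral
    exon_lens = []
    for _ in range(n_sites + 1):
        while True:
            L = int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
            if L > 0:
                break
        exon_lens.append(L)
    # make the CDS a whole number of codons by padding the last exon
    total = sum(exon_lens)
    exon_lens[-1] += (-total) % 3
    total = sum(exon_lens)
    n_codons = total // 3
    codons = ["ATG"] + [
        _NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS))] for _ in range(n_codons - 2)
    ] + ["TGA"]
    cds = "".join(codons)
    exon_seqs = []
    pos = 0
    for L in exon_lens:
        exon_seqs.append(cds[pos : pos + L])
        pos += L
    intron_seqs = []
    for _ in range(n_sites):
        L = int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1))
        donor = "GC" if rng.random() < config.gc_donor_fraction else "GT"
        intron_seqs.append(donor + _random_seq(rng, L - 4) + "AG")

    site_offsets = tuple(np.cumsum(exon_lens)[:-1].tolist())
    root_state = _NodeState(exon_seqs, intron_seqs, [True] * n_sites)

    losses: list[LossTruth] = []
    planted: list[dict] = []
    forced = {}
    for site, branch, mech in config.forced_losses:
        forced.setdefault(branch, []).append((int(site), mech))

    states = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        state = states[id(node.parent_node)].clone()
        label = _node_label(node)
        # substitutions along the branch (splice dinucleotides protected)
        state.exons = [_mutate(rng, e, config.branch_substitution_prob) for e in state.exons]
        state.introns = [
            _mutate(rng, i, config.branch_substitution_prob, protect_head=2, protect_tail=2)
            for i in state.introns
        ]
        # forced, then stochastic, losses
        events: list[tuple[list[int], str]] = []
        for site, mech in forced.get(label, ()):
            if not (1 <= site <= n_sites):
                raise ValueError(f"forced loss at unknown site {site}")
            if state.present[site - 1]:
                events.append(([site], mech))
        for site in range(1, n_sites + 1):
            if not state.present[site - 1]:
                continue
            if any(site in ev[0] for ev in events):
                continue
            if rng.random() < config.loss_prob_per_branch:
                mech = rng.choice(list(config.mechanism_mix), p=list(config.mechanism_mix.values()))
                events.append(([site], str(mech)))
        for sites, mech in events:
            site = sites[0]
            if not state.present[site - 1]:
                continue
            if mech == "mrna_mediated":
                run = 2 + rng.geometric(1.0 / max(config.mrna_run_mean, 1.0)) - 1
                run_sites = [site]
                s = site + 1
                while len(run_sites) < run and s <= n_sites and state.present[s - 1]:
                    run_sites.append(s)
                    s += 1
                for s in run_sites:
                    state.present[s - 1] = False
                losses.append(LossTruth(tuple(run_sites), label, mech))
                continue
            arm = config.planted_repeat_arm_len
            offset = site_offsets[site - 1]
            up, down = state.exons[site - 1], state.exons[site]
            if mech == "repeat_mediated":
                for _ in range(200):
                    arm_seq = _random_seq(rng, arm)
                    new_up = up[:-arm] + arm_seq
                    new_down = revcomp(arm_seq) + down[arm:]
                    if not _junction_makes_stop(new_up, new_down, offset):
                        break
                state.exons[site - 1], state.exons[site] = new_up, new_down
                planted.append(
                    {"branch": label, "site": site, "arm": arm_seq,
                     "junction_cds_offset": offset}
                )
            else:  # simple_deletion: scrub chance junction repeats
                tries = 0
                while (
                    _junction_has_repeat(up, down) or _junction_makes_stop(up, down, offset)
                ) and tries < 200:
                    down = _random_seq(rng, 3) + down[3:]
                    tries += 1
                state.exons[site] = down
            state.present[site - 1] = False
            losses.append(LossTruth((site,), label, mech))
        states[id(node)] = state

    genes: dict[str, GeneTruth] = {}
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        taxon = leaf.taxon.label
        state = states[id(leaf)]
        for c in range(config.n_copies_per_taxon):
            if config.n_copies_per_taxon == 1:
                gene_id, copy = taxon, state
            else:
                gene_id = f"{taxon}_{chr(65 + c)}"
                copy = state.clone()
                copy.exons = [_mutate(rng, e, config.homoeolog_divergence) for e in copy.exons]
                copy.introns = [
                    _mutate(rng, i, config.homoeolog_divergence, protect_head=2, protect_tail=2)
                    for i in copy.introns
                ]
            genes[gene_id] = _finalize_gene(rng, gene_id, taxon, copy, config)
    return FamilyTruth(config, tree.as_string(schema="newick").strip(), site_offsets, genes, losses, planted)


def _finalize_gene(rng, gene_id, taxon, state: _NodeState, config: FamilyConfig) -> GeneTruth:
    # modern exons: ancestral pieces merged across absent intron sites
    merged = [state.exons[0]]
    kept_introns = []
    for i in range(len(state.introns)):
        if state.present[i]:
            kept_introns.append(state.introns[i])
            merged.append(state.exons[i + 1])
        else:
            kept_introns.append(None)
            merged[-1] += state.exons[i + 1]
    cds = "".join(merged)
    cds, merged = _repair_internal_stops(cds, merged)
    flank5 = _random_seq(rng, config.flank_length)
    flank3 = _random_seq(rng, config.flank_length)
    parts = [flank5]
    exons = []
    pos = len(flank5)
    introns_present = [i for i in kept_introns if i is not None]
    for k, exon in enumerate(merged):
        parts.append(exon)
        exons.append((pos, pos + len(exon)))
        pos += len(exon)
        if k < len(introns_present):
            parts.append(introns_present[k])
            pos += len(introns_present[k])
    parts.append(flank3)
    present = tuple(i + 1 for i, p in enumerate(state.present) if p)
    return GeneTruth(gene_id, taxon, "".join(parts), cds, exons, present)


def _repair_internal_stops(cds: str, merged: list[str]) -> tuple[str, list[str]]:
    """Rewrite internal stop codons (possible after substitutions/planting)."""
    fix = {"TAA": "TAC", "TAG": "TAC", "TGA": "TGC"}
    chars = list(cds)
    for i in range(0, len(chars) - 3, 3):
        codon = "".join(chars[i : i + 3])
        if codon in STOP_CODONS:
            chars[i : i + 3] = list(fix[codon])
    repaired = "".join(chars)
    if repaired != cds:
        out, pos = [], 0
        for exon in merged:
            out.append(repaired[pos : pos + len(exon)])
            pos += len(exon)
        merged = out
    return repaired, merged


def write_family(truth: FamilyTruth, outdir) -> None:
    """Write a simulated family as FASTA + GFF3 + Newick + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_fasta({g: t.genomic for g, t in truth.genes.items()}, outdir / "genomic.fasta")
    gio.write_fasta({g: t.cds for g, t in truth.genes.items()}, outdir / "cds.fasta")
    feats = []
    for gid, g in truth.genes.items():
        feats.append(
            gio.Gff3Feature.from_interval0(
                gid, "grasstruct", "gene", g.exons[0][0], g.exons[-1][1],
                attributes={"ID": gid, "taxon": g.taxon},
            )
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            feats.append(
                gio.Gff3Feature.from_interval0(
                    gid, "grasstruct", "exon", s, e,
                    attributes={"ID": f"{gid}.exon{i}", "Parent": gid},
                )
            )
    gio.write_gff3(feats, outdir / "structures.gff3")
    (outdir / "tree.nwk").write_text(truth.tree_newick + "\n")
    gio.write_tsv(
        pd.DataFrame(
            [{"sites": ",".join(map(str, l.sites)), "branch": l.branch,
              "mechanism": l.mechanism, "multiplicity": l.multiplicity}
             for l in truth.losses]
        ),
        outdir / "loss_events.tsv",
    )
    gio.write_tsv(pd.DataFrame(truth.planted_repeats), outdir / "planted_repeats.tsv")


# ---------------------------------------------------------------------------
# HSP tables


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def simulate_hsp_table(
    truth: FamilyTruth,
    fragmentation: int = 1,
    noise: float = 0.0,
    n_decoys: int = 0,
    seed: int = 0,
):
    """Emit a BLAST-outfmt-6-style hit table for every homolog pair in a family.

    Every true homolog pair appears as ``fragmentation`` non-overlapping
    HSP rows whose identity counts follow the per-base mismatch ``noise``.
    Decoy queries (labelled PAV in the truth) hit subjects at 30-55%
    identity.  Returns (hsp table, truth classes, query lengths,
    subject gene-order positions, subject taxa).
    """
    if fragmentation < 1:
        raise ValueError("fragmentation must be >= 1")
    rng = np.random.default_rng(seed)
    by_taxon = truth.taxa_genes()
    positions = {g: i + 1 for genes in by_taxon.values() for i, g in enumerate(genes)}
    subject_taxa = {g: t.taxon for g, t in truth.genes.items()}
    rows, truth_rows = [], []
    lengths = {g: len(t.cds) for g, t in truth.genes.items()}
    for q, qt in truth.genes.items():
        L = lengths[q]
        for taxon, subjects in by_taxon.items():
            if taxon == qt.taxon:
                continue
            for s in subjects:
                cuts = np.linspace(0, L, fragmentation + 1).astype(int)
                for a, b in zip(cuts[:-1], cuts[1:]):
                    seg = b - a
                    ident = _round_half_up((1.0 - noise) * seg)
                    rows.append(
                        {"query_id": q, "subject_id": s,
                         "pct_identity": 100.0 * ident / seg, "aligned_length": seg,
                         "mismatches": seg - ident, "gap_opens": 0,
                         "query_start": a + 1, "query_end": b,
                         "subject_start": a + 1, "subject_end": b,
                         "e_value": 0.0, "bit_score": 2.0 * seg,
                         "identity_count": ident}
                    )
            truth_rows.append(
                {"query_id": q, "subject_taxon": taxon,
                 "class": "CNV" if len(subjects) >= 2 else "COS"}
            )
    mean_len = int(np.mean(list(lengths.values()))) if lengths else 600
    for d in range(n_decoys):
        q = f"decoy{d + 1}"
        lengths[q] = mean_len
        for taxon, subjects in by_taxon.items():
            s = subjects[0]
            frac = rng.uniform(0.30, 0.55)
            seg = mean_len
            ident = _round_half_up(frac * seg)
            rows.append(
                {"query_id": q, "subject_id": s,
                 "pct_identity": 100.0 * ident / seg, "aligned_length": seg,
                 "mismatches": seg - ident, "gap_opens": 0,
                 "query_start": 1, "query_end": seg,
                 "subject_start": 1, "subject_end": seg,
                 "e_value": 1e-5, "bit_score": 0.5 * seg,
                 "identity_count": ident}
            )
            truth_rows.append({"query_id": q, "subject_taxon": taxon, "class": "PAV"})
    return (
        pd.DataFrame(rows),
        pd.DataFrame(truth_rows),
        lengths,
        positions,
        subject_taxa,
    )


# ---------------------------------------------------------------------------
# qPCR tables


@dataclass
class CqConfig:
    """Conditions of a simulated ABA-treatment qPCR experiment."""

    genes: tuple[str, ...] = ("PSY1", "PSY2", "PSY3")
    references: tuple[str, ...] = ("spastin", "RLI")
    tissues: tuple[str, ...] = ("leaf", "root")
    timepoints: tuple[float, ...] = (0, 1, 2, 5, 8)
    treatments: tuple[float, ...] = (50, 100, 150)
    replicates: int = 3
    efficiencies: dict = field(default_factory=dict)   # gene -> E in (1, 2]
    fold_profile: dict = field(default_factory=dict)   # (gene, tissue, treatment, time) -> fold
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for g in (*self.genes, *self.references):
            e = self.efficiencies.get(g, 2.0)
            if not (1.0 < e <= 2.0):
                raise ValueError(f"efficiency of {g} must be in (1, 2], got {e}")

    def efficiency(self, gene: str) -> float:
        return self.efficiencies.get(gene, 2.0)

    def fold(self, gene, tissue, treatment, time_h) -> float:
        return self.fold_profile.get((gene, tissue, treatment, time_h), 1.0)


def simulate_cq_table(config: CqConfig):
    """Generate a replicate-level Cq table with planted fold changes.

    Cq = Cq0(gene) - log_E(planted relative abundance) + Normal(0, sd);
    reference genes have flat abundance in every condition.  Returns the
    table and the truth fold-change profile.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cq0 = {g: rng.uniform(22.0, 28.0) for g in (*config.genes, *config.references)}
    rows = []
    sample = 0
    for tissue in config.tissues:
        for treatment in config.treatments:
            for t in config.timepoints:
                for rep in range(1, config.replicates + 1):
                    sample += 1
                    for gene in (*config.genes, *config.references):
                        is_ref = gene in config.references
                        abundance = 1.0 if is_ref else config.fold(gene, tissue, treatment, t)
                        e = config.efficiency(gene)
                        cq = (
                            cq0[gene]
                            - math.log(abundance, e)
                            + (rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0)
                        )
                        rows.append(
                            {"sample_id": f"S{sample:04d}", "gene": gene,
                             "role": "reference" if is_ref else "target",
                             "tissue": tissue, "treatment": treatment, "time_h": t,
                             "replicate": rep, "Cq": cq}
                        )
    truth = pd.DataFrame(
        [{"gene": g, "tissue": ti, "treatment": tr, "time_h": t,
          "fold": config.fold(g, ti, tr, t)}
         for g in config.genes for ti in config.tissues
         for tr in config.treatments for t in config.timepoints]
    )
    return pd.DataFrame(rows), truth


def simulate_standard_curve(
    efficiency: float, cq0: float = 30.0, n_points: int = 5,
    step: float = 1.0, noise_sd: float = 0.0, seed: int = 0,
):
    """Serial-dilution standard curve (log10 amount, Cq) for one gene."""
    rng = np.random.default_rng(seed)
    pts = []
    for i in range(n_points):
        log_amount = -i * step
        cq = cq0 - log_amount / math.log10(efficiency)
        if noise_sd:
            cq += rng.normal(0.0, noise_sd)
        pts.append((log_amount, cq))
    return pts
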