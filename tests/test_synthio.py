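"""Generator contracts: determinism, truth consistency, forced scenarios, I/O."""

import filecmp

import numpy as np
import pytest

from grasstruct import io as gio
from grasstruct import synthio


def test_no_loss_limit_shares_ancestral_structure():
    cfg = synthio.FamilyConfig(loss_prob_per_branch=0.0, seed=1)
    truth = synthio.simulate_gene_family(cfg)
    assert truth.losses == []
    counts = {len(t.exons) for t in truth.genes.values()}
    assert counts == {cfg.n_introns_ancestral + 1}


def test_forced_losses_reproduce_printed_exon_counts():
    """Rice keeps 6 exons; sorghum and Brachypodium drop to 5 via third-intron
    loss; wheat drops to 4 after losing introns 1 and 3."""
    cfg = synthio.FamilyConfig(
        taxa=("rice", "sorghum", "brachypodium", "wheat"),
        tree="(rice,(sorghum,(brachypodium,wheat)));",
        loss_prob_per_branch=0.0,
        forced_losses=((3, "brachypodium", "simple_deletion"),
                       (3, "sorghum", "simple_deletion"),
                       (1, "wheat", "repeat_mediated"),
                       (3, "wheat", "repeat_mediated")),
        seed=7,
    )
    truth = synthio.simulate_gene_family(cfg)
    exon_counts = {g: len(t.exons) for g, t in truth.genes.items()}
    assert exon_counts == {"rice": 6, "sorghum": 5, "brachypodium": 5, "wheat": 4}


def test_cds_consistency_invariant():
    cfg = synthio.FamilyConfig(seed=3, loss_prob_per_branch=0.15,
                               branch_substitution_prob=0.01,
                               n_copies_per_taxon=2, homoeolog_divergence=0.005)
    truth = synthio.simulate_gene_family(cfg)
    for gid, g in truth.genes.items():
        spliced = "".join(g.genomic[s:e] for s, e in g.exons)
        assert spliced == g.cds, gid
        assert len(g.cds) % 3 == 0


def test_every_loss_event_has_intron_present_in_parent():
    cfg = synthio.FamilyConfig(seed=5, loss_prob_per_branch=0.2)
    truth = synthio.simulate_gene_family(cfg)
    # no site is lost twice on the same root-to-leaf path
    for leaf, gene in truth.genes.items():
        path_losses = []
        for loss in truth.losses:
            if leaf in loss.branch.split("+"):
                path_losses.extend(loss.sites)
        assert len(path_losses) == len(set(path_losses))
        assert set(gene.present_sites).isdisjoint(path_losses)


def test_seeded_determinism_byte_identical(tmp_path):
    cfg = synthio.FamilyConfig(seed=9, loss_prob_per_branch=0.1)
    for d in ("a", "b"):
        synthio.write_family(synthio.simulate_gene_family(cfg), tmp_path / d)
    for name in ("genomic.fasta", "cds.fasta", "structures.gff3", "tree.nwk", "loss_events.tsv"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


def test_unrooted_tree_rejected():
    cfg = synthio.FamilyConfig(taxa=("a", "b", "c"), tree="(a,b,c);")
    with pytest.raises(ValueError, match="rooted"):
        synthio.simulate_gene_family(cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        synthio.FamilyConfig(loss_prob_per_branch=1.5).validate()
    with pytest.raises(ValueError):
        synthio.FamilyConfig(mechanism_mix={"repeat_mediated": 0.5}).validate()
    with pytest.raises(ValueError):
        synthio.FamilyConfig(exon_length_range=(100, 50)).validate()


# ---------------------------------------------------------------------------
# HSP tables


def test_single_fragment_zero_noise_hsp_is_perfect():
    truth = synthio.simulate_gene_family(synthio.FamilyConfig(seed=2, loss_prob_per_branch=0.0))
    hsp, classes, lengths, _, _ = synthio.simulate_hsp_table(truth, fragmentation=1, noise=0.0)
    assert (hsp.identity_count == hsp.aligned_length).all()
    assert (hsp.pct_identity == 100.0).all()
    assert set(classes["class"]) == {"COS"}


def test_fragmentation_conserves_total_aligned_length():
    truth = synthio.simulate_gene_family(synthio.FamilyConfig(seed=2, loss_prob_per_branch=0.0))
    one, *_ = synthio.simulate_hsp_table(truth, fragmentation=1)
    three, *_ = synthio.simulate_hsp_table(truth, fragmentation=3)
    key = ["query_id", "subject_id"]
    merged = (
        one.groupby(key).aligned_length.sum().rename("al1").to_frame()
        .join(three.groupby(key).aligned_length.sum().rename("al3"))
    )
    assert (merged.al1 == merged.al3).all()


def test_decoys_labelled_pav_with_low_identity():
    truth = synthio.simulate_gene_family(synthio.FamilyConfig(seed=2, loss_prob_per_branch=0.0))
    hsp, classes, *_ = synthio.simulate_hsp_table(truth, n_decoys=3, seed=1)
    decoy_rows = hsp[hsp.query_id.str.startswith("decoy")]
    assert ((decoy_rows.pct_identity >= 30) & (decoy_rows.pct_identity <= 55)).all()
    assert (classes[classes.query_id.str.startswith("decoy")]["class"] == "PAV").all()


# ---------------------------------------------------------------------------
# Cq tables


def test_flat_profile_zero_noise_gives_unit_ratios():
    cfg = synthio.CqConfig(noise_sd=0.0, seed=1)
    table, truth = synthio.simulate_cq_table(cfg)
    assert (truth.fold == 1.0).all()
    from grasstruct.qpcr import fold_change_table

    eff = {g: cfg.efficiency(g) for g in (*cfg.genes, *cfg.references)}
    folds = fold_change_table(table, eff)
    assert np.allclose(folds.fold_change, 1.0)


def test_cq_config_validation():
    with pytest.raises(ValueError):
        synthio.CqConfig(replicates=1).validate()
    with pytest.raises(ValueError):
        synthio.CqConfig(efficiencies={"PSY1": 2.5}).validate()
    with pytest.raises(ValueError):
        synthio.CqConfig(noise_sd=-0.1).validate()


# ---------------------------------------------------------------------------
# file-format round trips


def test_fasta_round_trip_and_wrapping(tmp_path):
    records = {"a": "ACGT" * 50, "b": "GATTACA"}
    path = tmp_path / "x.fasta"
    gio.write_fasta(records, path)
    lines = path.read_text().splitlines()
    assert max(len(l) for l in lines if not l.startswith(">")) <= 60
    assert gio.read_fasta(path) == records


def test_gff3_round_trip_and_validation(tmp_path):
    feats = [gio.Gff3Feature("chr1", "test", "exon", 10, 50, attributes={"ID": "e1"})]
    path = tmp_path / "x.gff3"
    gio.write_gff3(feats, path)
    back = gio.read_gff3(path)
    assert back[0].interval0 == (9, 50)
    assert back[0].attributes == {"ID": "e1"}
    bad = tmp_path / "bad.gff3"
    bad.write_text("chr1\tt\texon\t50\t10\t.\t+\t.\tID=e1\n")
    with pytest.raises(ValueError, match="bad.gff3:1"):
        gio.read_gff3(bad)


def test_newick_branch_lengths_preserved(tmp_path):
    tree = gio.read_newick("(a:0.1,(b:0.2,c:0.3):0.4);")
    out = tree.as_string(schema="newick", suppress_rooting=True).strip()
    assert "0.2" in out and "0.4" in out
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == {"a": 0.1, "b": 0.2, "c": 0.3}
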