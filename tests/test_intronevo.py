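"""Intron-site homology, Dollo loss inference, exon-fusion detection."""

from itertools import product

import pytest

from grasstruct import genestruct, intronevo, synthio
from grasstruct.io import read_newick
from grasstruct.intronevo import ABSENT, PRESENT, IntronSiteMatrix

import pandas as pd


def structures_from_truth(truth):
    out = []
    for gid, g in truth.genes.items():
        out.append(genestruct.spliced_align(g.cds, g.genomic, gene_id=gid, taxon=g.taxon))
    return out


def matrix_from_patterns(patterns: dict, phases=None):
    """Build a site matrix directly from presence/absence strings ('1'/'0')."""
    n = len(next(iter(patterns.values())))
    phases = phases or [0] * n
    sites = [(30 * (i + 1) + phases[i], phases[i]) for i in range(n)]
    cells = {
        taxon: [PRESENT if c == "1" else ABSENT for c in pat]
        for taxon, pat in patterns.items()
    }
    idx = pd.Index([f"site{i + 1}" for i in range(n)], name="site")
    local = {t: [c for c, _ in sites] for t in patterns}
    return IntronSiteMatrix(sites, pd.DataFrame(cells, index=idx),
                            pd.DataFrame(local, index=idx), next(iter(patterns)))


def test_identical_genes_give_all_present_matrix(grass_family):
    structures = structures_from_truth(grass_family)
    rice = [s for s in structures if s.gene_id == "rice"][0]
    maize = [s for s in structures if s.gene_id == "maize"][0]
    cds = {g: t.cds for g, t in grass_family.genes.items()}
    m = intronevo.map_intron_sites([rice, maize], cds)
    assert (m.cells == PRESENT).all().all()
    assert len(m.sites) == 5


def test_zero_noise_matrix_equals_generator_truth(grass_family):
    structures = structures_from_truth(grass_family)
    cds = {g: t.cds for g, t in grass_family.genes.items()}
    m = intronevo.map_intron_sites(structures, cds)
    assert len(m.sites) == 5
    assert [c for c, _ in m.sites] == list(grass_family.site_offsets)
    for gid, g in grass_family.genes.items():
        present = {i + 1 for i, cell in enumerate(m.cells[gid]) if cell == PRESENT}
        assert present == set(g.present_sites)


def test_internal_stop_names_the_gene():
    s1 = genestruct.GeneStructure("good", "", "g", "+", [(0, 30)], 30)
    s2 = genestruct.GeneStructure("broken", "", "g", "+", [(0, 30)], 30)
    cds = {"good": "ATG" + "GCT" * 9, "broken": "ATG" + "GCT" * 4 + "TAA" + "GCT" * 4}
    with pytest.raises(ValueError, match="broken"):
        intronevo.map_intron_sites([s1, s2], cds)


def test_grass_psy3_worked_example():
    """Printed exon/intron counts: rice/maize 6-5, sorghum/Brachypodium 5-4,
    wheat 4-3 -> two independent third-intron losses plus a wheat-specific
    first-intron loss; wheat carries two absences."""
    m = matrix_from_patterns(
        {"rice": "11111", "maize": "11111", "sorghum": "11011",
         "brachypodium": "11011", "wheat": "01011"},
        phases=[1, 2, 0, 0, 1],
    )
    tree = read_newick("(rice,((maize,sorghum),(brachypodium,wheat)));")
    events = intronevo.infer_loss_events(m, tree)
    assert len(events) == 3
    by_branch = {e.branch: e for e in events}
    assert by_branch["sorghum"].sites == (3,)
    assert by_branch["brachypodium+wheat"].sites == (3,)
    assert by_branch["wheat"].sites == (1,)
    wheat_absent = sum(c == ABSENT for c in m.cells["wheat"])
    assert wheat_absent == 2
    third_intron_losses = [e for e in events if e.sites == (3,)]
    assert len(third_intron_losses) == 2  # independent events


def test_all_present_matrix_yields_no_events():
    m = matrix_from_patterns({t: "1111" for t in "abcd"})
    events = intronevo.infer_loss_events(m, read_newick("(a,(b,(c,d)));"))
    assert events == []


# ---------------------------------------------------------------------------
# exhaustive Dollo oracle


def brute_force_dollo(tree, leaf_states):
    """Minimum losses over all single-gain (no-regain) internal labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for assign in product([1, 0], repeat=len(internals)):
        state = dict(zip(internals, assign))
        if state[tree.seed_node] != 1:
            continue
        ok = True
        losses = []
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = state[node.parent_node]
            s = leaf_states[node.taxon.label] if node.is_leaf() else state[node]
            if parent == 0 and s == 1:  # regain: forbidden under Dollo
                ok = False
                break
            if parent == 1 and s == 0:
                losses.append(node)
        if ok and (best is None or len(losses) < len(best)):
            best = losses
    return best


@pytest.mark.parametrize("pattern", ["".join(p) for p in product("01", repeat=4)])
def test_dollo_matches_exhaustive_minimum_on_four_leaf_tree(pattern):
    taxa = ["a", "b", "c", "d"]
    tree = read_newick("(a,(b,(c,d)));")
    m = matrix_from_patterns({t: pattern[i] for i, t in enumerate(taxa)})
    events = intronevo.infer_loss_events(m, tree)
    n_inferred = sum(e.multiplicity for e in events)
    if "1" not in pattern:
        assert n_inferred == 0  # site never observed: nothing to reconstruct
        return
    leaf_states = {t: int(pattern[i]) for i, t in enumerate(taxa)}
    minimal = brute_force_dollo(tree, leaf_states)
    assert n_inferred == len(minimal)
    inferred_branches = {e.branch for e in events}
    from grasstruct.intronevo import _clade_label
    assert inferred_branches == {_clade_label(n) for n in minimal}


def test_adding_all_present_taxon_never_increases_losses():
    tree4 = read_newick("(a,(b,(c,d)));")
    tree5 = read_newick("((a,e),(b,(c,d)));")
    for bits in product("01", repeat=4):
        pattern = dict(zip("abcd", bits))
        if "1" not in bits:
            continue
        m4 = matrix_from_patterns({t: p for t, p in pattern.items()})
        m5 = matrix_from_patterns({**pattern, "e": "1"})
        n4 = sum(e.multiplicity for e in intronevo.infer_loss_events(m4, tree4))
        n5 = sum(e.multiplicity for e in intronevo.infer_loss_events(m5, tree5))
        assert n5 <= n4


def test_gene_order_permutation_leaves_results_invariant(grass_family):
    structures = structures_from_truth(grass_family)
    cds = {g: t.cds for g, t in grass_family.genes.items()}
    m1 = intronevo.map_intron_sites(structures, cds, reference="rice")
    m2 = intronevo.map_intron_sites(structures[::-1], cds, reference="rice")
    assert m1.sites == m2.sites
    assert m1.cells.sort_index(axis=1).equals(m2.cells.sort_index(axis=1))
    tree = read_newick(grass_family.config.tree)
    assert intronevo.infer_loss_events(m1, tree) == intronevo.infer_loss_events(m2, tree)


def test_adjacent_sites_on_one_branch_merge_into_multi_loss_event():
    m = matrix_from_patterns({"a": "1111", "b": "1111", "c": "1001", "d": "1111"})
    events = intronevo.infer_loss_events(m, read_newick("(a,(b,(c,d)));"))
    assert len(events) == 1
    e = events[0]
    assert e.sites == (2, 3)
    assert e.multiplicity == 2
    assert e.mechanism == "mrna_mediated"


# ---------------------------------------------------------------------------
# exon fusions


def test_no_absences_means_no_fusions(grass_family):
    structures = structures_from_truth(grass_family)
    cds = {g: t.cds for g, t in grass_family.genes.items()}
    rice = [s for s in structures if s.gene_id == "rice"][0]
    maize = [s for s in structures if s.gene_id == "maize"][0]
    m = intronevo.map_intron_sites([rice, maize], cds)
    assert intronevo.detect_exon_fusions(m, [rice, maize]) == []


def test_wheat_fusions_recover_truth_junctions(grass_family):
    structures = structures_from_truth(grass_family)
    cds = {g: t.cds for g, t in grass_family.genes.items()}
    m = intronevo.map_intron_sites(structures, cds, reference="rice")
    fusions = intronevo.detect_exon_fusions(m, structures, reference_taxon="rice")
    wheat = [f for f in fusions if f.gene_id == "wheat"]
    # wheat lost ancestral sites 1 and 3: modern exon 1 fuses ancestral exons
    # 1+2, modern exon 2 fuses ancestral exons 3+4
    assert {(f.fused_exon_index, f.contributing_exons) for f in wheat} == {
        (1, (1, 2)), (2, (3, 4)),
    }
    offs = grass_family.site_offsets
    by_idx = {f.fused_exon_index: f for f in wheat}
    assert by_idx[1].junctions == (offs[0],)
    assert by_idx[2].junctions == (offs[2] - offs[1],)
    # sorghum / brachypodium each fuse ancestral exons 3+4
    for taxon in ("sorghum", "brachypodium"):
        recs = [f for f in fusions if f.gene_id == taxon]
        assert len(recs) == 1
        assert recs[0].contributing_exons == (3, 4)
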