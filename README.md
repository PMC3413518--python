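# grasstruct

Comparative genomics of grass gene families: how a gene's exon–intron
architecture evolves across species, and how to reconstruct that history
from sequence alone.  The package grew out of the analysis style used to
characterize the phytoene synthase (*PSY*) family in cereals — a
three-member paralog family in which *PSY3*, the stress-responsive copy,
shows lineage-specific **intron losses** and consequent **exon fusions**
across rice, maize, sorghum, *Brachypodium* and wheat — but every step
is a general, reusable operation.

## What it computes

**Pairwise homology from tabular HSPs** (`grasstruct.cipcalp`).  BLASTN-style
local hits between a query gene and a subject gene are rebuilt into one
query-disjoint chain and summarized by

```
AL   = Σ HSP lengths                    (aligned length, bp)
CIP  = 100 · Σ identities / AL          (cumulative identity percentage)
CALP = AL / query length                (cumulative alignment length percentage)
```

Subjects passing CIP/CALP thresholds classify each query against a
genome as **COS** (one conserved ortholog), **CNV** (≥2 tandem
homologs) or **PAV** (no conserved homolog).

**Exon–intron structure by spliced alignment** (`grasstruct.genestruct`).
A CDS is placed on its genomic template by exact k-mer seeding, colinear
chaining and junction resolution that prefers GT..AG, then GC..AG splice
sites.  Introns are annotated with donor/acceptor dinucleotides, length
and phase (cumulative coding bases mod 3).  Includes in-silico PCR with
a strict 3′-anchor rule.

**Intron-loss history by Dollo parsimony** (`grasstruct.intronevo`).
Intron positions are projected through codon-aware pairwise alignments
onto homologous *sites* (merged only on exact coordinate + phase match),
and each site's minimal loss set is placed on a rooted species tree under
the single-gain (Dollo) model.  Adjacent sites lost on one branch merge
into a multi-intron event — the signature of mRNA-mediated loss.  Exon
fusions are reported with the lost-intron junction coordinate inside the
modern exon.

**Breakpoint and promoter scanning** (`grasstruct.repeatmotif`).  Short
direct/inverted repeats straddling a fusion junction (the TGG|CCA-style
signature of illegitimate recombination / replication slippage),
MITE-like terminal-inverted-repeat elements, downstream exon
duplications with internal deletions and their flanking motifs, and
IUPAC scans for ABA-response promoter elements (ABRE, G-box, CE).

**Efficiency-normalized qPCR** (`grasstruct.qpcr`).  Per-gene
amplification efficiency `E = 10^(−1/slope)` from a dilution standard
curve; normalized ratio `E_t^−CqT / E_r^−CqR` with the geometric mean
over two reference genes; fold changes versus untreated controls; and
one-way ANOVA with pairwise t-tests.

**Synthetic data with known truth** (`grasstruct.synthio`).  A seeded
generator simulates ortholog families along a rooted tree — one
ancestral architecture, per-branch intron losses with planted mechanisms
(inverted repeats at repeat-mediated junctions, scrubbed junctions for
simple deletions, 3′-biased runs for mRNA-mediated loss), homoeologous
copies — plus HSP tables and Cq tables with planted fold changes, so
every analysis module can be validated against exact truth.

## Worked example

Simulate the grass *PSY3* scenario — third intron lost independently on
the sorghum branch and the *Brachypodium*+wheat stem, first intron lost
in wheat via a planted junction repeat — then reconstruct it:

```python
from grasstruct import synthio, genestruct, intronevo, repeatmotif
from grasstruct.io import read_newick

tree = "(rice,((maize,sorghum),(brachypodium,wheat)));"
cfg = synthio.FamilyConfig(
    taxa=("rice", "maize", "sorghum", "brachypodium", "wheat"),
    tree=tree,
    forced_losses=((3, "sorghum", "simple_deletion"),
                   (3, "brachypodium+wheat", "simple_deletion"),
                   (1, "wheat", "repeat_mediated")),
    loss_prob_per_branch=0.0,
    seed=42,
)
family = synthio.simulate_gene_family(cfg)

structures = [genestruct.spliced_align(g.cds, g.genomic, gene_id=gid, taxon=g.taxon)
              for gid, g in family.genes.items()]
cds = {gid: g.cds for gid, g in family.genes.items()}
matrix = intronevo.map_intron_sites(structures, cds, reference="rice")
events = intronevo.infer_loss_events(matrix, read_newick(tree))

for s in sorted(structures, key=lambda s: s.gene_id):
    print(f"{s.gene_id:13s} {len(s.exons)} exons / {s.n_introns} introns")
for e in events:
    print(f"loss of site {e.sites} on branch {e.branch!r} ({e.mechanism})")

wheat = family.genes["wheat"]
hits = repeatmotif.scan_breakpoint_repeats(wheat.cds, family.site_offsets[0])
top = hits[0]
print(f"wheat junction repeat: {top.arm1_seq}|{top.arm2_seq} ({top.kind}) -> "
      f"{repeatmotif.classify_loss_mechanism(1, hits)}")
```

which prints:

```
brachypodium  5 exons / 4 introns
maize         6 exons / 5 introns
rice          6 exons / 5 introns
sorghum       5 exons / 4 introns
wheat         4 exons / 3 introns
loss of site (3,) on branch 'brachypodium+wheat' (indeterminate)
loss of site (3,) on branch 'sorghum' (indeterminate)
loss of site (1,) on branch 'wheat' (indeterminate)
wheat junction repeat: GAC|GTC (inverted) -> repeat_mediated
```

Rice and maize keep the ancestral six-exon architecture; sorghum and
*Brachypodium* drop to five exons; wheat, having lost two introns,
carries four.  Dollo parsimony recovers all three loss events, placing
two *independent* third-intron losses, and the wheat fusion junction
shows the inverted-repeat signature that upgrades the mechanism call to
repeat-mediated.

A command-line interface mirrors the library:
`grasstruct simulate family|hsp|cq`, `grasstruct cipcalp`,
`grasstruct structure`, `grasstruct pcr`, `grasstruct losses`,
`grasstruct breakpoints|mite|promoter`, `grasstruct qpcr`.

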