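# Methods

This note records the models behind each module, the parameters that
matter, the numerical conventions, and what the synthetic validation
does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open.  GFF3 and BLAST tabular
coordinates (1-based inclusive) are converted at the I/O boundary and
nowhere else.  FASTA is wrapped at 60 columns; Newick trees are handled
by dendropy and must be rooted (bifurcating at the root) wherever a tree
drives inference or simulation.

## Cumulative homology statistics (cipcalp)

For one query–subject pair the rebuilt alignment is a query-disjoint
chain of HSPs.  Overlaps on the query are resolved by trimming the HSP
with the lower identity fraction (ties: shorter, then rightmost);
trimmed identity counts are rescaled proportionally to the retained
length and rounded half-up.  Trimming — rather than summing raw HSP
lengths — keeps CIP a true percentage and CALP ≤ 1; the raw behaviour
remains available as `policy="raw"` since either convention appears in
practice.  Statistics: AL = Σ lengths, CIP = 100·Σ identities/AL,
CALP = AL/query length.

Classification thresholds default to CIP ≥ 60% and CALP ≥ 0.7 and are
plain configuration, not claims about any dataset; the tandem window for
CNV calls is 5 gene positions.  With several dispersed candidates the
best subject is chosen by CALP, then CIP, then the lexicographically
smaller subject id — CALP first because coverage, not per-base identity,
is what separates a full-length ortholog from a high-identity fragment.
When a 12-column hit table lacks identity counts they are derived as
round-half-up(pct_identity × length).

## Spliced alignment (genestruct)

The aligner assumes the CDS and its template differ by point
substitutions only (no indels inside exons) — the regime of close
orthologs and homoeologs.  Exact k-mer seeds (k = 15; k-mers occurring
more than 20 times in the template are skipped) are merged into
diagonal blocks, chained by dynamic programming (blocks on different
diagonals may overlap by up to k CDS bases, because splice-site bases
such as the acceptor AG can coincide with exon sequence), and each
junction is then placed exactly: among junction positions of equal match
score the GT..AG placement wins, then GC..AG, then the leftmost.  Both
strands are tried and the better kept.  A structure is rejected
(`NoStructureFound`) when matched coverage falls below 90% of the CDS or
mismatches exceed 2% of CDS length (the homoeolog-divergence budget);
both are parameters.

Intron phase is the cumulative coding length upstream mod 3.  GT..AG is
canonical; GC..AG is reported as the distinct non-canonical-GC class
because GC donors are processed by the ordinary spliceosome and occur in
real grass PSY genes; anything else is non-canonical.

In-silico PCR reports primer-inclusive product lengths, requires an
exact 3′-terminal base on both primers regardless of the mismatch
allowance, and searches both amplicon orientations.  Product sizes are
primer-inclusive because that is the standard convention for reported
amplicon lengths; exact matching is the default since primers are
normally designed on the very sequences being screened.

## Intron-site homology and Dollo parsimony (intronevo)

Intron positions are expressed as CDS offsets, translated through a
global protein alignment (match 2 / mismatch −1 / gap open −5 /
extend −0.5) of each gene against a reference (default: the gene with
the most introns), and merged into one site only when the projected
coordinate *and* the phase agree exactly.  Near-misses within one codon
at equal phase raise a warning and are never merged: intron sliding is
contentious, and conservative merging avoids manufacturing false
homology.  Cells are present/absent, or unalignable where the gene has
no residue aligned at the site; unalignable cells are missing data and
never force a loss.

Dollo parsimony gives each site a single gain at the root (ancestral
state present whenever any leaf retains the intron) and finds the
minimal loss set by placing one loss on every maximal edge whose subtree
contains no presence but at least one observed absence.  Polytomies need
no special casing.  Adjacent sites lost on one branch merge into a
single event whose multiplicity ≥ 2 earns the mRNA-mediated label
(recombination with a reverse-transcribed spliced transcript removes
runs of adjacent introns); single-site events stay indeterminate until
the breakpoint scanner weighs in.

**Identifiability ceiling.**  Exact event recovery is bounded by the
data, not the algorithm: parallel losses of the same site on two sibling
branches are indistinguishable from one loss on their stem, and
parsimony must choose the stem.  With loss probability p per site per
branch such configurations affect ≈ 2p of planted events (measured:
94.4% exact recovery at p = 0.05 over 789 events, 97.1% at p = 0.03 over
485).  The validation batches therefore plant sparse losses (p = 0.03)
so that exact recovery is a meaningful yardstick, and every residual
miss is programmatically verified to be such a forced merge (the
inferred reconstruction uses strictly fewer losses at that site than
were planted).  The simulator's descriptive default stays at p = 0.05,
which is the ballpark of the observed grass PSY3 history (a handful of
events over ~40 site-branch opportunities).

## Breakpoint repeats, mechanisms, elements (repeatmotif)

The breakpoint scanner enumerates every direct and inverted arm pair
with one arm on each side of a fusion junction, arms ≥ 3 nt within a
15 nt window (defaults sized to the observed 3-nt TGG|CCA and CGG|CCG
exemplars).  The mechanism classifier is a pure function of
(multiplicity, repeat evidence): multiplicity ≥ 2 → mRNA-mediated; a
repeat pair whose arms directly abut the junction → repeat-mediated;
otherwise simple deletion; an intron record supplied for a supposedly
lost site, or no scan at all, → indeterminate.  The abutting-arms
requirement (`max_distance = 0`) matches the geometry of the observed
breakpoint motifs and keeps the call specific: within a 15-nt window a
chance 3-mer pair appears in most random junctions, abutting pairs in
only ~3%.  Mirroring this, the simulator scrubs simple-deletion
junctions of chance abutting repeats, so the planted contrast is the
signature being tested.

MITE-like elements are found by seeding inverted k-mer pairs and
extending the pairing outward first (toward the element boundaries),
then inward, under a shared mismatch budget; candidates keep the longest
TIR among overlaps, and elements whose body matches an earlier element's
reverse complement (>90% identity, small boundary offsets tolerated) are
flagged with the opposite orientation.  Chance complementary bases just
inside or outside a planted element can extend an arm by a base or two;
element spans, not arm lengths, are the recovered quantity.

Exon-duplication search anchors exact 12-mers of the exon (both
orientations) downstream of the stop codon, clusters colinear diagonal
segments into one copy, and reads internal deletions from query-gap vs
template-gap differences; a deletion's flanking motif is the identical
k-mer (k from 8 down to 4) abutting the deleted source segment on both
sides.  The reported offset is the 1-based distance from the base after
the stop codon to the first aligned base of the copy.  When a large
internal deletion is expected the identity floor should be set
accordingly (the fraction of the source that survives), e.g. 0.25 for a
copy that lost 154 of ~210 bp.

Promoter scanning compiles IUPAC consensus strings to regexes, scans
both strands with overlapping matches, and reports positions both
0-based from the 5′ end and negatively from the 3′ end (the ATG-anchored
convention).  The default table — ABRE core ACGTG, G-box CACGTG, CE1
TGCCACCGG, CE3 ACGCGTGTC — follows standard ABA-response definitions
and is configuration, not a claim about any particular promoter.

## qPCR quantification (qpcr)

Efficiency comes from the least-squares regression of Cq on log10
template amount: E = 10^(−1/slope); a non-negative slope is an assay
failure.  The normalized ratio is E_t^(−CqT)/E_r^(−CqR); with two
reference genes the final ratio is the geometric mean of the
per-reference ratios — the standard multi-reference aggregation, chosen
because instrument software hides its own.  Ratios are computed per
biological replicate and then averaged (a `mean_cq` mode averages Cq
first); fold change is the condition mean over the control mean, with
the SD of replicate-level fold changes reported alongside.  With E = 2
everywhere the ratio reduces to the classic 2^−ΔΔCq.

One-way ANOVA is computed from the between/within mean squares with the
p-value from the F distribution; two groups reduce to the pooled t-test
(F = t²).  Pairwise stage comparisons use uncorrected two-sample t-tests
at α = 0.05 by default — matching the two-by-two, 95%-confidence
description such experiments usually report — with a Bonferroni option.
All-zero within-group variance with unequal means is reported as p = 0
with a `degenerate` flag rather than a spurious finite value.

## Synthetic data (synthio) — what it does and does not emulate

One ancestral gene (exons drawn uniform from 90–450 bp, padded to a
whole codon count; introns 80–900 bp, GT..AG with a 10% GC-donor
fraction) evolves along a rooted tree by per-site substitutions and
per-branch intron losses.  Repeat-mediated losses plant an inverted arm
pair (default 3 nt) across the fusion junction; simple deletions scrub
the junction of chance abutting repeats; mRNA-mediated losses remove a
3′-extending run of ≥ 2 adjacent introns with geometric run length.
Planting and scrubbing are rejection-sampled so they never create
in-frame stop codons, and any stop arising from substitutions is
repaired deterministically, keeping every CDS translatable.
Homoeologous copies are leaf-level duplicates at a configurable per-site
divergence.  All outputs are deterministic in the seed, byte for byte.

Cq tables follow Cq = Cq0(gene) − log_E(planted abundance) + N(0, sd)
with flat reference-gene abundance; inverting the analysis pipeline on a
noise-free table returns planted fold changes exactly, for any per-gene
efficiencies — which is the point of the closure test.

Not emulated: exon-length evolution by indel, intron gain, alternative
splicing, transposon insertions beyond breakpoint repeats and planted
TIR elements, sequencing error, and primer-efficiency drift.  Passing
the closure tests therefore shows the pipeline inverts its own
generative model faithfully at realistic noise levels — not that it is
robust to every artefact of real BAC or expression data.

## Synthetic PSY3 stand-in (synthetic_psy3)

The real wheat PSY3A/B/D BAC sequences are not redistributable, so a
deterministic synthetic trio is built to carry the locus family's
reported hallmarks (protein lengths 413/401/403 aa, ~96% B–D identity
with all length differences confined to the first exon, four exons and
three GT..AG introns, a 216 bp third-exon amplicon shared by all three
copies, the D-locus inverted exon-4 copy 1729 bp downstream of the stop
with a 154 bp internal deletion flanked by TACTGG, and an
ABRE/G-box/CE1-bearing promoter).  The pipeline *measures* these
properties at run time; the builder guards only against coincidences
that would corrupt the measurement (spacer sequence free of exon
12-mers, no chance one-base homology extension at the copy boundary).
These genes are stand-ins for validating the measuring instruments, not
reconstructions of the real loci.

## Problem sizes

The default validation batch is 24 five-taxon families (~130 genes
spliced-aligned, ~30 loss events) plus one 15-gene HSP table, one
synthetic homoeolog trio and one 450-row Cq table; the whole acceptance
script runs in a few seconds, the test suite in well under a minute.
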