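# Methods

`paleowgd` infers paleopolyploidy (whole-genome duplication, WGD) from
annotated genomes: it finds homologous gene pairs, chains them into collinear
blocks, measures synonymous divergence (Ks) per block, locates WGD peaks in
the Ks distribution, converts peaks to ages under a synonymous clock, and
tests whether duplications are lineage-specific or shared using gene trees
built from syntenic anchor groups. A built-in genome-evolution simulator
provides ground truth for every stage.

## The model

Two coding sequences that diverged `t` years ago accumulate an expected
`Ks = 2 r t` synonymous substitutions per synonymous site, where `r` is the
synonymous substitution rate per site per year. A WGD duplicates every gene
at one instant, so the surviving duplicate pairs share a common divergence
time and their Ks values cluster in a peak; a speciation does the same for
ortholog pairs. Three consequences drive the pipeline:

* **Syntenic depth.** After `k` WGDs in lineage B absent from lineage A,
  each A region is covered by up to `2^k` collinear B regions: the modal
  per-gene block coverage ("1:4", "1:1", ...) diagnoses the number of
  duplications on each side of a comparison.
* **Ks peaks.** Each WGD leaves a peak in the distribution of block-median
  Ks among within-genome paralogs; a peak below the ortholog-divergence peak
  must postdate the speciation (lineage-specific), one above must predate it.
* **Gene-tree topology.** For an outgroup gene O with two syntenic copies in
  a once-duplicated genome M and four in a twice-duplicated genome I, the
  rooted gene tree is `(O,(M1,M2),((I..),(I..)))` when all WGDs are
  lineage-specific, whereas a WGD predating the M/I split nests each M copy
  with the I copies of one ancestral sub-genome.

## Stages and parameters

**Homology** (`homology`). Translated CDS are compared all-vs-all by exact
global Needleman–Wunsch/Gotoh alignment (BLOSUM62; affine gaps with
open 11, extend 1, a gap of length L costing `open + (L-1)*extend`; `X`
scores 0). No heuristic seeding is used — scores are provably optimal — with
a numba kernel batched across equal-length targets making millions of
comparisons feasible on one CPU. A pair is kept when each gene ranks the
other within its `top_n_hits` (default 5) best scores for that target genome
— a reciprocal reading of the usual "top 5 hits" convention that also bounds
the partner count per gene — and when alignment identity reaches
`min_identity` (default 0.3).

**Synteny** (`synteny`). Chaining happens in gene-rank space (order index per
chromosome), as in MCScanX, whose defaults are adopted: `min_anchors` 5,
`max_gap` 25 ranks, match score 50, gap penalty 1 per skipped rank.  Chains
must be strictly monotone on both chromosomes (plus or minus orientation)
and are extracted best-score-first per chromosome pair across both
orientations jointly, each homolog pair joining at most one block.  Tandem
arrays (anchors sharing a partner within 2 ranks) collapse to their
best-scoring representative before chaining.  Depth counts a gene as covered
by a block when it lies inside the block's anchor span on the reference
side; genes with zero coverage are excluded from the modal depth.  Where an
inversion is bridged by a flanking chain, the spans of the bridge and of the
inversion block overlap, so depth histograms carry a small tail above the
true copy number — the mode is the robust statistic.  The "orthologous"
depth between two species filters blocks to a Ks window `[0, m + 2w]`, with
`m`, `w` the location and width of the lowest-Ks mixture component of the
cross-genome block medians.

**Ks** (`ks_engine`). Codon alignments are obtained by aligning translated
proteins and back-translating; columns with gaps are dropped. The
Nei–Gojobori (NG86) estimator counts synonymous sites per codon position as
synonymous one-step changes over valid one-step changes (changes to or from
stop codons excluded, so `N + S = 3 * n_codons` holds exactly), averages
observed differences over all substitution pathways that avoid stops (equal
weighting; if every pathway of a 2–3 difference codon pair crosses a stop,
all pathways are used with stop-crossing steps counted nonsynonymous), and
applies the Jukes–Cantor correction `d = -(3/4) ln(1 - (4/3) p)` to both
`pS` and `pN`. Estimates with `pS >= 3/4` are flagged saturated and excluded
from distributions; distribution fitting additionally drops Ks > 3, where
the correction is unreliable. Standard genetic code only. Block medians use
the mean-of-central-pair convention and need at least 3 non-saturated
anchors; otherwise the block is uninformative.

**Dating** (`wgd_dating`). Peaks are fitted as a Gaussian mixture on log-Ks
with the component count (1..4 by default) chosen by minimum BIC; fits are
seeded and reproducible (`n_init=3`). Peak location is the exponential of
the component mean; width is mapped to the Ks scale by the delta method
(location x log-sd). Calibration takes an ortholog median Ks and a known
divergence time: `r = Ks / 2T`; dating inverts it: `T = Ks / 2r`. Both an
externally supplied median (so published numbers are injectable exactly) and
an internal calibration (median of the cross-genome block medians inside the
lowest-Ks component) are supported. Display ages round to the nearest MY,
half up. Note that dating with a published *printed* rate can differ by 1 MY
from dating with the exactly recomputed rate — a truncation artifact of the
printed value, not of the arithmetic.

**Topology test** (`phylo_test`). Anchor groups are assembled by transitive
closure over block anchors sharing an outgroup gene; informative groups have
2 mid copies and 3–4 ingroup copies (the 1:2:4 pattern; over-full groups are
ambiguous and dropped). Per group, every member is aligned to the outgroup
protein, and only outgroup codon positions aligned in *all* members are kept
(complete deletion), avoiding missing-data distance bias. A neighbor-joining
tree is built from nucleotide p-distances on the concatenation — NJ on
p-distances rather than ML is a deliberate substitution: it is
deterministic, fast, and the deep splits being classified are robust to the
tree method. Classification works on the clades induced by rooting at the
outgroup leaf: `lineage_specific` iff the mid copies and the ingroup copies
are each monophyletic; `shared` iff some clade joins exactly one mid copy
with a nonempty strict subset of the ingroup copies; anything else (including
star-like trees from tied distances) is `unresolved`, a first-class outcome.
The published analysis did not define which configurations counted as
"supporting" lineage specificity; this monophyly rule is an explicit
operationalization.

## The simulator

`synthetic_data` evolves an ancestral genome (random stop-free CDS of fixed
codon count, genes evenly partitioned over chromosomes, GFF3-style 1-based
coordinates) through a scripted event list. A WGD duplicates every
chromosome and deletes each gene on the *new* copies independently with
probability `loss_fraction` (fractionation without pseudogene traces; ranks
recompute after loss), so an `n`-gene genome expects `n(2-q)` genes after
one WGD. Speciations fork the lineage. After each event the affected
lineage(s) suffer Poisson-many segmental inversions and translocations of
2–20 adjacent genes (default 0.5 ops per 100 genes per event — chosen so
each event erodes roughly 5% of gene adjacencies, producing the
block-splitting the chaining stage must tolerate without overwhelming
desk-scale genomes).

Sequences evolve by Poisson substitution: synonymous events occur at rate
`r` per NG86 synonymous site (choosing only amino-acid-preserving changes),
nonsynonymous events at their own rate (default `0.2 r`, a typical
purifying-selection Ka/Ks for plant proteomes); site weights are refreshed
after every hit, so multiple hits occur and realized NG86 Ks saturates
naturally. Because the simulator and the estimator share the NG86 *site
definition* (they share no code path — the estimator is validated against an
independent pathway-enumeration oracle), the clock identity `E[Ks] = 2rt` is
exact by construction for `Ks` well below saturation; realized estimates
match within a few percent at 300+ pairs.

The truth log records, per extant gene, its ancestor and the ordered branch
choices (WGD copy / speciation side) of its copy lineage; the divergence
time of any two genes is the age of the first event where their histories
differ, giving exact expected Ks for every pair.

What the simulator does **not** emulate: tandem duplication, transposable
elements, introns, base-composition or codon-usage bias, rate variation
across genes or lineages, gene conversion between duplicates. Passing tests
therefore demonstrate the inference machinery under clock-like, bias-free
evolution; on real genomes, rate heterogeneity widens Ks peaks and biased
fractionation can push depth modes below `2^k`.

## Study scenarios and problem sizes

The canned scenarios mirror the real configurations the pipeline targets:
an unduplicated outgroup vs. a twice-duplicated ingroup (WGDs 80/60 MY,
20% loss, split 120 MY — the "1:4" design), two sisters sharing both WGDs
and splitting 30 MY ago (the "1:1" design and the calibration source), and
1:2:4 three-genome designs with splits at 150/120 MY and WGDs at 82/59 MY
(ingroup) and 65 MY (mid) for the lineage-specific case, or a WGD at 80 MY
predating a 50-MY mid/ingroup split for the shared case. Simulations in the
test suite and acceptance script use 120–1000 ancestral genes and 100–300
codons per gene — desk-scale sizes at which every stage, including exact
all-vs-all alignment, runs on a single CPU while leaving hundreds of blocks
and tens of anchor groups for the statistics.

## Numerical choices and degenerate inputs

* Score ties in chaining break toward the earlier anchor and the plus
  orientation; co-optimal chains are possible and either is acceptable
  (oracle tests compare scores, not members).
* The mixture fit guards the zero-variance case (all Ks equal) with a
  degenerate single component; fewer than 20 values is an error.
* Depth modes tie-break toward the more frequent count, then the smaller
  depth; genomes with no covered genes report modal depth 0.
* `X` residues align at score 0; untranslatable CDS (frame violations,
  internal stops) are skipped in homology search with a logged warning but
  are hard errors in codon alignment, naming the gene.
* NJ leaf order is lexicographic on gene id, making tie-breaks
  deterministic; reruns of any stage with the same seed are byte-identical.

## Known limitations

* NG86 only; no YN00/ML estimator, no gamma rate variation or codon
  frequency corrections. The dating arithmetic is estimator-agnostic given a
  median Ks, and the calibration accepts external medians for that reason.
* Depth ratios on heavily rearranged or fractionated genomes depend on
  coverage thresholds; the histogram, not just the mode, should be read.
* The topology test classifies deep monophyly only; it does not reconcile
  gene trees with species trees nor compute support values.
* All-vs-all exact alignment scales quadratically in gene count; beyond
  ~5k genes per genome a seeded search tool is the practical substitute.
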