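# Methods

## Scope and model

`triadkit` implements the desk-scale half of a polyploid gene-family
census.  The organism model is an allohexaploid genome in the style of bread
wheat: three subgenomes (A, B, D) arranged in seven homoeologous chromosome
groups, plus an unplaced pseudo-chromosome `Un`.  Upstream, compute-heavy
steps — homology search, multiple alignment, tree inference, GWAS — are out
of scope and enter the pipeline as their artifacts: candidate hit tables,
per-subfamily Newick trees, GFF3 gene models, TPM expression tables and SNP
marker tables.

The pipeline stages, in execution order:

1. **Catalogue curation** (`family_catalog`).  Two candidate-evidence
   streams (conserved-domain retrieval and profile search) are merged by set
   union on gene id; a gene found by both is flagged dual-evidence and its
   confidence is the maximum across streams.  Curation removes
   low-confidence candidates, collapses splice variants onto their canonical
   gene (explicit canonical ids, plus stripping of `.N` transcript
   suffixes), and drops candidates without a gene model.  The original
   census also involved manual curation, which is not algorithmically
   reproducible; it is replaced here by these deterministic rules plus an
   audit report listing everything dropped, so a human can review the same
   decisions.  Curation is idempotent.

2. **Homoeolog grouping** (`homoeolog_map`).  Within a subfamily, a
   homoeolog group is a clade of the subfamily gene tree whose 2–4 leaves
   satisfy the composition constraints — at most one gene per subgenome for
   groups of up to three, exactly one duplicated subgenome (1:1:2 patterns)
   for tetrads — and share a chromosome group.  Genes on `Un` can never
   satisfy the shared-chromosome constraint and always become singletons.
   Among all selections of disjoint valid clades the algorithm maximises
   the number of grouped genes (dynamic programming over the tree; clade
   candidates in a tree are laminar, so this is exact and the test suite
   checks it against an exhaustive oracle on trees of up to 12 leaves).
   Ties are broken deterministically: prefer the clade with more distinct
   subgenomes, then the smaller clade, then the lexicographically smallest
   member id.  Bootstrap support values are ignored — the upstream trees
   carry them but no support threshold is defined for grouping.

3. **Nomenclature** (`nomenclature`).  Group ids are
   `<prefix><subfamily>-<T|D|S|TT><ordinal>` with ordinals per (subfamily,
   category) in positional order (chromosome group with `Un` last, then
   minimum member start, then smallest member id).  Gene names are
   `<prefix><subfamily>-<group><subgenome><serial>[x|y]`.  Serial counters
   run per (subfamily, chromosome group) and are shared across subgenomes:
   one group consumes one serial, homoeologs differ only in the subgenome
   letter, groups missing a subgenome still advance the counter, and
   numbering restarts at 1 in every chromosome group.  Duplicated copies
   within a subgenome take `x`/`y` by ascending start position; `Un`
   members draw from a per-subfamily `Un` counter.  Serial order follows
   physical position (the alternative — id order — coincides with it in
   reference-style ids in virtually all published rows).  The species
   prefix defaults to `Ta` and is configurable, so the scheme transfers to
   other polyploids.

4. **Expression bias** (`expression_profiles`).  Stages and cultivars are
   aggregated by maximum TPM per (gene, tissue) before any computation —
   the source analyses pool developmental stages per tissue without stating
   an aggregation rule, and the maximum is the least surprising choice for
   presence calls.  A (triad, tissue) pair is retained when the summed TPM
   of the three homoeologs is ≥ 1 (the filter can be switched to
   per-homoeolog for sensitivity analysis; the sum is the default reading
   of "triads with expression below one tpm were excluded").  Retained
   pairs are normalized to fractions on the 2-simplex and assigned the
   nearest of seven centroids by Euclidean distance: Balanced (⅓,⅓,⅓),
   A/B/D-dominant at the corners, A/B/D-suppressed with the suppressed
   subgenome at 0 and the rest split equally.  The centroid coordinates
   follow the standard wheat triad-bias methodology; they are the module's
   single imported assumption, since the census itself names the categories
   without printing coordinates.  Exact distance ties resolve in fixed
   category order (Balanced, dominants A/B/D, suppressed A/B/D).
   Tissue specificity uses three tissue classes — root, leaf/shoot,
   spike+grain — and calls a gene X-specific when it reaches 1 TPM only in
   class X, not-expressed when it never does, ubiquitous otherwise.

5. **SNP proximity** (`mta_proximity`).  Distances are |gene − SNP| / 10⁶
   on raw 1-based integer coordinates, printed to six decimals (exact for
   coordinates < 2⁴⁰).  A pair on different chromosomes is an error, never
   a silent large distance.  "Close proximity" has no canonical
   definition; the window is a required, logged parameter defaulting to
   15 Mb, chosen to cover the largest distance printed in the transcribed
   proximity table (14.51 Mb).  Printed range tokens
   (`TaNPF5-3B3–TaNPF5-3B10`, any dash variant) expand over consecutive
   serials; typographic variants in the source are preserved, never
   corrected silently, so discrepancies surface as diagnostics.

## Packaged fixtures

Two tables transcribed from the published census ship with the package,
tab-separated with SHA-256 checksums verified on read.

* `table2_catalogue.tsv` — the full catalogue: 412 named genes in 173
  groups.  All headline counts hold on the transcription: families
  292/46/34/40 (NPF/NRT2/CLC/SLAC), largest subfamily NPF5 with 97 genes,
  72 NPF triads covering 74 % of NPF genes.  One reference id appears in
  two groups in the printed source; both occurrences are kept.
* `table4_proximity.tsv` — the SNP proximity table.  The source rendering
  prints 65 marker rows (its prose reports 67; no further rows are legible,
  and none are guessed — the fixture header flags this).  Every printed
  distance is reproducible from printed coordinates once positions are
  pooled per chromosome: four rows print a minimum distance computed
  against a gene position printed on a *different* row of the same
  chromosome.  The last printed digit is rounded on some rows and
  truncated on others; the reproduction check accepts either.  Serial
  expansion of the printed range tokens yields 84 distinct gene names
  (53 NPF, 16 NRT2, 11 CLC, 4 SLAC); the CLC and SLAC counts match the
  prose, the NPF/NRT2/total counts printed in the prose (63/15/93) are not
  derivable from the printed tokens under any expansion rule we could
  state, and the package reports what the rule actually yields.

## Synthetic data

The generator (`synthetic_data`) plants ground truth for every downstream
stage.  Defaults are the study conditions of the census being emulated:

* group categories triad:diad:tetrad:singleton = 103:26:2:48 (the census
  totals row); 19 % of singletons unplaced on `Un`;
* tetrad duplicate copies placed within 100 kb on one subgenome, mirroring
  the tandem clusters at distal chromosome ends;
* bias categories 60 % balanced, remainder uniform over the six biased
  classes, matching the reported balanced range (55.6–65.2 %);
* homoeolog fractions drawn from a Dirichlet distribution centred on the
  category centroid; the concentration parameter (default 200) sets the
  noise and the `inf` limit lands exactly on the centroid.  Centroid
  components equal to zero stay exactly zero (the Dirichlet is drawn on
  the positive support only), so suppressed/dominant categories are
  sharply defined;
* TPM magnitudes log-normal with ln-scale mean 2.3 and sd 1.0 (median
  ≈ 10 TPM, bulk within the reported 1–100 TPM range); totals of active
  pairs are floored at 1.0001 TPM so that fraction arithmetic and
  6-decimal rounding can never push an active pair below the 1-TPM filter;
* tissue-specificity classes with defaults 5/3/4 % root-, leaf/shoot- and
  spike/grain-specific, 30 % not expressed (the census reports ≈ 68 % of
  genes expressed somewhere), remainder ubiquitous;
* a 322-marker panel of which 20 % are planted within the 15 Mb window of
  a random gene (uniform or explicitly supplied offsets), the rest uniform
  — emulating the reported 322 trait associations of which 65 printed rows
  fell near catalogue genes.

One integer seed drives everything through per-stage streams
(`SeedSequence((seed, stream))`, streams 0/1/2 for catalogue, expression,
SNPs), so runs are byte-identical and stages reproducible in isolation.

Two generator choices matter for interpreting test results.  First,
consecutive groups of a subfamily are placed on different chromosome
groups, so no clade spanning two planted groups can satisfy the
shared-chromosome constraint and planted groups are exactly recoverable;
real trees do not offer this guarantee, and on real data the extractor's
maximisation can merge adjacent compatible clades that a curator might keep
separate.  Second, for triad members the recorded specificity truth is the
class implied by the emitted TPMs rather than the drawn class, because a
strongly biased triad legitimately silences one homoeolog even in an
active tissue.  Passing recovery tests therefore demonstrate that the
pipeline inverts the generative model exactly — not that real RNA-seq, with
its correlated noise, mapping artefacts and cross-homoeolog read
assignment, would be classified with the same accuracy.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere; BED export converts to
  0-based half-open at the boundary.
* Expression is stored linear-TPM; log2(tpm+1) is applied only in the
  heatmap-matrix export.
* Normalizing an all-zero triad is an error by contract — the 1-TPM filter
  must run first.
* Classification ties (measure zero, but reachable — (⅔,⅙,⅙) is exactly
  equidistant from Balanced and A-dominant) resolve in fixed category
  order; centroid distances are quantized to 12 decimals before the argmin
  so that boundary points classify identically however their fractions
  were computed.  The permutation-equivariance property is asserted off
  the mirror planes.
* Percentages are reported rounded to one decimal, the census's own style.
* The chromosome-token grammar `[1-7][ABD]|Un` is closed: any other token
  is rejected at parse time (skip-with-warning for gene records, hard error
  elsewhere).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
statistical checks sharp while staying instantaneous: 180-group default
catalogues, 500 triads (≈ 2 000 classified points) for the
concentration-200 recovery rate, 200 triads for the zero-noise limit,
100-marker panels for proximity recovery, and 60 random ≤ 12-leaf trees
for the exhaustive-oracle comparison.  The full suite runs in a few
seconds; `scripts/acceptance.py` in about one.

## Known limitations

* The census's manual-curation arithmetic (403 + 38 high/low candidates to
  the final 412) is not reproduced; curation here is rule-based.
* A handful of published catalogue rows contradict the stated naming
  scheme (one diad pairs genes from chromosome groups 2 and 7 under
  group-7 names); the implementation enforces the shared-chromosome rule
  and logs such conflicts rather than reproducing them.
* No differential-expression testing, no nitrogen-starvation response
  calls (no stated criterion upstream), no tree inference, no synteny, no
  plotting beyond TSV/BED exports.
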