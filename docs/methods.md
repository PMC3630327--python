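# Methods

## Model and procedure

The analysis treats a ChIP-Seq compendium as a binary relation between a
fixed universe of genomic regions and a set of datasets (one transcription
factor in one cell type each). The universe is the bp-merged union of all
peaks: two intervals belong to the same universe region iff they are
connected by chains of ≥ 1 bp overlaps. Coordinates are 0-based half-open
(the BED dialect), so intervals that merely touch ([100, 200) and
[200, 300)) remain distinct regions — they share no base pair and are
treated as distinct binding events. Occupancy is any-bp overlap between a
dataset peak and a universe region, with no minimum-fraction threshold.
Consolidation of same-factor samples from related cell types is driven by a
user-supplied grouping table, because "related" is a curation judgment, not
an algorithm; groups must be same-TF and merge to the union of their peaks.

Peak-to-gene assignment gives each region at most two genes. A region
overlapping a gene span, or the span extended upstream of the strand-aware
TSS by the promoter extent, is assigned to the overlapped gene(s); when
more than two qualify, the two with the smallest edge distance to the
transcribed span win, with gene-body overlap outranking a promoter-only
overlap at tied distance and alphabetical symbol order as the final
tie-break (without the body-over-promoter rule, a promoter adjacent at
distance 0 could displace the gene the region actually lies in). A region
overlapping no extended span is intergenic: it takes the nearest gene on
each side whose span lies within the window of the region's nearest edge —
one candidate per side, hence again at most two genes. Distances are
edge-to-edge, not midpoint-based.

The enrichment statistic for one dataset is the one-sided upper tail
P(X ≥ k) of X ~ Hypergeom(N, n, m): N universe regions, n assigned to the
query genes, m occupied by the dataset, k both. Using merged regions as the
test unit (rather than raw peaks) keeps N coherent across datasets, and
counting every region of a locus individually weights loci by their number
of binding events — a locus with five bound regions contributes five to n.
Only over-representation is tested; depletion is out of scope. Raw
p-values are Bonferroni-corrected across the D datasets of one query (the
correction is dispatched by name, so other standard methods are available),
and a dataset is called significant when the corrected p falls below alpha
(default 0.001).

The combinatorial stage asks whether enriched factors share sites rather
than merely genes. It takes the occupancy columns of the enriched datasets,
restricts rows to the query gene set's regions by default (the genome-wide
row universe is a switch — restriction is what makes the output a statement
about the gene set), removes rows with column sum < 2, and clusters columns
agglomeratively with d = 1 − r (Pearson) as the distance. Cluster labels
come from cutting the tree either into k groups or at a height on the
1 − r scale (default 0.5).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 50,000 | max intergenic distance (bp) from region edge to gene span |
| `promoter_bp` | 2,000 | upstream promoter extent from the strand-aware TSS (bp) |
| `alpha` | 0.001 | corrected p cutoff for calling a dataset enriched |
| `correction` | bonferroni | multiplicity correction across one query's datasets |
| `linkage` | average | agglomeration rule (complete and single also available) |
| `cut_height` | 0.5 | tree cut on the 1 − r scale when no k is given |

The 50 kb window, the 0.001 cutoff and the Bonferroni correction are the
method's defining constants. The promoter extent is a common convention and
deliberately a knob, as is the linkage: neither is pinned down by the
method itself, so both are exposed and recorded in every run's echoed
configuration.

## Numerical choices

- The hypergeometric tail is evaluated through SciPy's log-gamma based
  survival function; below 1e−12 the few remaining pmf terms are re-summed
  in log space (logsumexp), because the generic 1 − cdf route loses absolute
  accuracy deep in the tail. The result is clamped into (0, 1]; universes of
  several hundred thousand regions pose no overflow risk.
- Agglomeration uses Lance–Williams updates; the minimum-distance pair is
  chosen by (distance, lower id, higher id), making tied merges — routine
  with binary columns — deterministic. Merge heights are non-decreasing for
  all three offered linkages. A from-scratch O(K³) re-computation over
  explicit member sets and SciPy's `linkage` on tie-free data both serve as
  independent cross-checks in the test suite.
- Zero-variance columns (all 0 or all 1 over retained rows) have no defined
  correlation. Convention: distance 0 to element-wise identical columns,
  distance 1 to everything else, with a logged warning. Identical columns
  are therefore never split, and an all-identical matrix collapses to one
  cluster at height 0.
- Degenerate inputs fail loudly and early: empty compendia, a peak-gene map
  built against a different universe, fewer than two enriched datasets, or
  a binary matrix with no informative rows are errors with stage-named
  diagnostics. A query mapping to zero regions is not an error: the report
  is produced with all raw p-values equal to 1 and a warning.
- Reports are sorted by (raw p, dataset id); all writers emit fixed column
  orders and fixed float formats, so identical inputs produce byte-identical
  TSV/JSON outputs. Figures are best-effort renderings of the tables and
  are excluded from that guarantee.

## The synthetic-data generator

The generator emulates the statistical structure the method assumes, not
ChIP-Seq signal. Genes of fixed length are placed with positive uniform
gaps on a small number of chromosomes. Background datasets draw fixed-width
peaks uniformly over the genome. A planted dataset places a deterministic
fraction f = fold·L_t / (L_b + fold·L_t) of its peaks uniformly inside the
target loci (gene span ± the mapping window, so planted peaks are always
mappable) and the rest uniformly outside, which realizes a per-bp density
ratio of `enrichment_fold` between target loci and background. Within a
co-occupancy group, a stated fraction of the in-locus peak positions is
drawn once and shared verbatim by all members. Optional occupancy
bit-flip noise is applied on a provisional universe and translated back
into peak lists, so files and matrices stay consistent. All randomness
derives from one integer seed with fixed per-component offsets; a fixture
written twice from the same seed is byte-identical.

Default condition: 2 chromosomes × 25 Mb, 300 genes of 10 kb, 20 datasets
× 130 peaks of 400 bp (≈ 2,300 merged regions), a 200-gene target set,
five datasets planted at fold 3, split into two groups ({D00, D01, D02},
{D03, D04}) sharing 90% of in-locus positions. The geometry was chosen so
that the target territory is a minority of the genome and the planted
signal is unambiguous at the Bonferroni 0.001 cutoff while the matched null
(fold 1, nothing planted) stays calibrated: across 100 seeds the null
produces at most one family-wise false call and per-run raw p-values
consistent with uniformity, and the planted condition is recovered exactly
in ≥ 95 of 100 seeds.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level signal, fragment-size effects,
peak-caller artifacts, peak-width variation (widths are fixed by default so
the density arithmetic is exact), chromatin accessibility confounding, gene
length/density biases, and correlated binding of *non*-planted factors.
Real compendia also exhibit far larger universes and much smaller
gene-set-to-genome ratios; the benchmark is a scaled-down analogue, chosen
to run in seconds, not a quantitative model of any organism.

The 10% bit-flip robustness property is evaluated at the combinatorial
stage (the matrix is built from the true planted datasets on the noisy
compendium). Uniform occupancy flips dilute every dataset's enrichment
toward the null, so pushing that noise through the enrichment stage first
would measure the planting's detectability, not clustering robustness —
the quantity of interest there is the partition recovery.

## Design choices where the design was open

- **Test unit = merged region, not raw peak.** The margins (N, n, m, k) are
  all counted over one fixed universe; the raw-peak alternative makes the
  2×2 table incoherent across datasets.
- **Row restriction in the combinatorial stage defaults to the gene set's
  regions**, with a genome-wide switch; restriction makes the clusters a
  statement about the query.
- **Average linkage by default**; the clustering method is otherwise
  unconstrained, so it is a flag rather than a constant.
- **Consolidation grouping is explicit metadata** (a `group` column in the
  manifest), never inferred from cell-type strings.
- **Cross-species queries are explicit** (`--orthologs`); species
  auto-detection from symbol casing is error-prone and not attempted.
- **Singleton consolidation groups pass through unchanged** — consolidation
  merges samples, it does not re-normalize a single sample's peak list.

## Known limitations

- Gene spans are transcript-union loci; no isoform-aware assignment.
- The ≤ 2 genes cap discards information in dense gene clusters where a
  region genuinely sits in more than two loci.
- Bonferroni across one query's datasets is conservative when datasets are
  correlated (same factor profiled in several cell types).
- No significance test on the cluster structure itself; the dendrogram and
  its cut are descriptive.
- The enrichment test conditions on the universe, so datasets contributing
  many regions to the universe slightly shift every other dataset's margins;
  this is inherent to the shared-universe design.
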