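# Methods

## The model

The package implements gene-centric comparison of annotated (meta)genome
assemblies. The central modelling assumption is that a contig's mean read
depth is proportional to the abundance of the population it derives from, so
that weighting each gene by its contig's depth turns per-gene annotation
counts into community-level functional abundances:

    a_u = Σ_{g ∈ u} d_c(g)        (abundance of unit u in one sample)

This assumes roughly uniform genome sizes across the two communities being
compared (a large systematic genome-size difference would bias all per-unit
ratios in the same direction); the `average_genome_size` check, based on
single-copy marker COGs, exists to verify that assumption on real inputs. A
gene annotated to several units of the same namespace contributes its full
weight to each — units are treated as independent counting classes, with no
fractional splitting. Partial genes at contig edges are weighted like any
other gene.

## The differential statistic

Each unit is compared between samples A and B through the 2×2 table
(unit mass, rest-of-namespace mass) × (A, B):

- LOR = ln[(a/(A−a)) / (b/(B−b))]
- SE(LOR) = sqrt(1/a + 1/(A−a) + 1/b + 1/(B−b))   (Woolf's estimator)
- Z-LOR = LOR / SE, two-sided normal p-value, Benjamini–Hochberg FDR.

Choices worth stating:

- **Weighted masses in the cells.** The cells are depth-weighted real numbers,
  not integer gene counts — the weighting is the method's point and Woolf's
  formula is well-defined for positive reals. Because the weights inflate the
  cells by roughly the mean depth, the nominal SE is only approximately
  calibrated; the no-effect simulation in the test suite measures the realized
  false-positive proportion at q < 0.05 and finds it well under the nominal
  level at the default simulation conditions (200 units, 100 replicates,
  depth-noise sigma 0.2).
- **Continuity correction.** A Haldane–Anscombe cc = 0.5 is added to all four
  cells, but only when some cell is exactly zero — this keeps LOR finite for
  absent units while leaving fully-observed tables untouched.
- **Exact antisymmetry.** LOR is computed as ln(a/(A−a)) − ln(b/(B−b)) so that
  swapping the samples negates LOR and Z bit-for-bit and leaves p and q
  identical.
- **Ordering.** Results are sorted lexicographically by unit id; ties never
  depend on dict ordering.

Expression comparison reuses the same machinery with per-unit summed median
coverages as the masses. A gene's expression is the median per-base coverage
(even-length vectors: mean of the middle pair); genes with eukaryote
similarity strictly greater than 0.30 are excluded before aggregation
(a gene exactly at 0.30, or with no recorded similarity, is kept). The
similarity is consumed as an opaque precomputed fraction in [0, 1]; what
"similarity" means (identity vs score ratio) is the annotation pipeline's
concern, and the threshold is configurable.

## GH inventory

The shipped `gh_mapping.tsv` lists 33 glycoside hydrolase families of plant
cell wall degradation in five categories, with their diagnostic pfam domains.
Three families (GH44, GH51, GH74) have no diagnostic pfam domain and are
identified upstream by sequence search; the pipeline consumes them as explicit
per-gene `GH_family` annotations rather than running homology search itself.
A gene carrying several pfam domains of the same family (e.g. the three GH2
domains) counts once. Percentages are carried at full precision internally
and rounded to one decimal only at output. The heatmap filter keeps families
reaching the threshold (default 2 %, inclusive) in at least one sample.
Profile clustering defaults to Bray–Curtis distance with average linkage
(both configurable; Euclidean and correlation distances and complete linkage
are also supported), delegating to scipy's agglomerative clustering with the
column order fixing tie-breaks.

When published tables print both per-family percentages and category
subtotals at one-decimal precision, the subtotal of independently rounded
members can differ from the printed subtotal by up to half an ulp per member;
the acceptance checks treat the termite columns (which reproduce exactly) at
one-decimal tolerance and allow that propagation bound for re-normalised
reference columns.

## Average genome size

AGS = [Σ_c length(c)·depth(c)] / [(1/|M|)·Σ_{m∈M} a_m] over single-copy
marker COGs M. The numerator is the total depth-weighted assembly mass; the
denominator estimates "genomes worth of depth". For markers present exactly
once per complete genome this is exact: a single-genome community returns the
genome length identically (at zero depth noise), and a mixed community
returns the depth-weighted mean genome length. The marker list is
user-supplied (the canonical 38-family marker set is a database artifact, not
shipped); synthetic communities define their own markers.

## Diversity and taxonomy

- Shannon H is reported in nats (the log base is a convention; natural log is
  the package's).
- Rarefaction is the exact hypergeometric expectation
  E[S_n] = S − Σ_i C(N−N_i, n)/C(N, n), evaluated with log-gamma binomial
  coefficients for overflow safety. It is deterministic; resampling-based
  curves from other tools will wobble around it.
- The LCA assigner is a strict longest-common-prefix over all provided hit
  lineages — no bit-score or top-percent pre-filtering heuristics; any hit
  filtering is the data producer's job. Genes with no hits, or hits that
  disagree at the domain rank, are pooled as `unclassified`.
- Weighted taxonomy truncates each gene's lineage at the requested rank
  (domain/phylum/class), accumulates the gene's depth or expression weight,
  and normalises to fractions.
- Habitat categories follow an inclusiveness precedence: any record from a
  non-gut anoxic environment ⇒ `other_anoxic`; else any animal gut/feces
  record ⇒ `animal_gut`; else any lower-termite record ⇒ `termite_only`;
  else `higher_termite_only`. Mapping free-text habitat descriptions to the
  four-label input vocabulary is input preparation, not pipeline logic.
- Major OTUs are those strictly above 0.5 % of the sample's community.

## The synthetic-data generator

The generator emulates the structure of two assembled, annotated gut
metagenomes of differing composition, not their sequence content:

- **Depths.** Contig depth = (genome's per-sample relative abundance) ×
  LogNormal(meanlog = ln 10, sdlog = 0.5 by default) — lognormal noise
  matches the right-skewed coverage of real assemblies. sdlog 0.2 is used for
  the calibration and recovery suites (the condition also used for the
  stated-fold recovery checks).
- **Contigs.** Per genome, contig lengths are drawn uniform (default range
  5–50 kb) and rescaled to partition the genome length exactly, which makes
  the AGS identity testable.
- **Spikes.** Sample A's copy number for unit u is round(c·fold). Pick copy
  numbers that make c·fold integral (the helpers pin spiked units at 4
  copies) so realized and nominal folds coincide. The truth table records the
  odds-based expected LOR from expected depth masses; with equal compositions
  and a single spiked unit this equals ln(fold) exactly at zero noise. With
  several units spiked simultaneously the rest-of-namespace mass shifts, so
  even non-spiked units have slightly non-zero expected LOR — visible as the
  small offsets from ln(fold) in the recovery outputs.
- **Expression.** Per-base coverage is negative-binomial with variance
  μ + φμ² (dispersion φ = 0.3 by default, a typical RNA-seq overdispersion);
  φ = 0 is the deterministic no-noise limit. Base mean 20× with fold changes
  applied to sample A at the unit level.
- **OTU tables.** One Dirichlet community draw shared across samples,
  multinomial counts per sample, habitat records sampled per OTU.
- **Reproducibility.** Every generator takes an explicit seed and owns one
  RNG stream; no global state. Same seed ⇒ byte-identical output files.

What the generator does *not* emulate: sequence content, assembly chimerism
and fragmentation biases, strain-level depth heterogeneity within a genome,
annotation error, or correlated copy-number variation between units. Passing
tests therefore demonstrate correctness of the computations and calibration
under the generative model, not robustness to real-data artifacts.

Recovery-suite problem sizes (chosen as the package's standard quick-check
conditions): 10–20 genomes, 100–200 units, 25–100 replicates, folds
{0.25, 1, 4}, depth sigma 0.2, expression dispersion 0.3, coverage vectors of
40 positions. For the balanced (equal-composition) designs used there, spike
folds map to expected LORs analytically; distinct-composition communities are
used where compositional difference itself is the thing being recovered
(weighted-taxonomy checks).

## Known limitations

- Woolf SE on depth-weighted masses has no finite-sample guarantee; with very
  high mean depth and strong depth noise the test can become anti-conservative.
  Re-run the null simulation at your own depth scale if calibration matters.
- The COG→category mapping is not shipped; `cog_category_profile` takes it as
  an argument.
- No read- or alignment-level processing: coverage and annotations arrive
  pre-summarised in TSV tables.
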