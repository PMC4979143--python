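# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Quantification

Expression is normalized as RPKM, RPKM_g = 10⁹ · c_g / (N · L_g), where c_g
is the number of reads mapped to gene g, L_g its transcript length in bp
and N the library's total mapped reads. `library_size` is taken as given
(it is the uniquely-mapped read total of whatever mapper produced the
counts) and is *not* required to equal the column sum of counts.  Gene
identity is the uppercased symbol — the only identifier that survives
joining annotations from different genomes — and duplicate symbols after
uppercasing are an error rather than being silently merged.  RPKM is stored
at full float precision; 2-decimal rounding (half-up, matching how such
tables are usually printed) happens only at presentation time.  Whether
transcript lengths are exon-union or isoform lengths is the annotation
provider's choice; lengths are accepted as input.

## Joining, filtering and fold changes

Species tables are joined on the intersection of their symbol sets; genes
absent from any table are dropped (absence is more often an annotation
failure than true zero expression), and gene order is lexicographic for
determinism.  The expression floor defaults to **strict** RPKM > 5 in all
species, with a `greater_equal` mode, since single-library comparisons are
unreliable for weakly expressed genes.  The signed fold difference is
fold(a,b) = a/b when a ≥ b, else −b/a; it is antisymmetric with |fold| ≥ 1
and undefined at zero (hence the floor comes first).  Differential gene
selection at the twofold threshold is inclusive (fold ≥ 2 counts).  With
one library per species there are no replicates, so no variance-based
differential test is attempted — ranking and thresholding are explicitly
descriptive.

## Overrepresentation test

For query size n and a term covering K of the N reference genes, the
observed overlap k is scored with binomial tails at p₀ = K/N:
p_over = P(X ≥ k), p_under = P(X ≤ k), X ~ Bin(n, p₀).  Tails are summed
exactly in log space (gammaln + logsumexp), so values like 10⁻²³ are
representable without underflow; tests verify agreement with exhaustive
rational enumeration to 10⁻¹² for n ≤ 12 and with an independent binomial
implementation elsewhere.  The binomial model treats query genes as
sampled with replacement; a hypergeometric (without-replacement,
Fisher-style) mode is provided for sensitivity analysis and is slightly
more conservative for large n/N.  The reported direction is "over" when
k ≥ n·p₀ and "under" otherwise, and the tail for that direction enters the
Bonferroni correction with family size m = number of terms actually tested
(terms with K = 0 are skipped); m can be overridden when the caller wants
to correct over a larger family.  The annotation is a flat term → genes
map; ontology hierarchy and propagation to ancestor terms are not modeled
— use pre-propagated gene sets if that semantics is wanted.

## Composition correction

Bulk samples confound per-cell expression with cell-type proportions.  The
two-marker proxy uses ratio_s = RPKM_GFAP / RPKM_RBFOX3 per sample s (any
markers can be substituted; a per-species neuronal override such as SNAP25
supports genomes where RBFOX3 is unannotated).  For a predominantly glial
target the corrected value is RPKM_target / ratio_s — expression per unit
of glial signal.  Division (rather than multiplication) is the appropriate
direction for a glial target: if a sample has twice the glial content, both
the target and the glial marker double, and the quotient is unchanged.  A
`multiply` mode exists for neuronal targets.  Correction should only be
applied to genes with a known dominant cell type; genes expressed in both
compartments (e.g. clusterin) should be compared uncorrected, so the
package corrects only genes the caller designates.  The group comparison is
a two-tailed two-sample t-test on untransformed values, pooled-variance
Student by default with a Welch option; identical degenerate groups return
t = 0, p = 1, while zero pooled variance with unequal means is an error
rather than an infinite statistic.

## Expression phylogeny

Pearson correlations are computed between species over the shared
(optionally corrected) gene vector, by default on untransformed expression
values; a log₂(x+1) mode is available because linear-scale correlations are
dominated by the most highly expressed genes.  Correlations become
distances via d = 1 − r (default) or the metric variant d = √(2(1−r)).
Neighbor joining follows Saitou–Nei with the Studier–Keppler criterion
Q_ij = (n−2)d_ij − R_i − R_j; ties in Q are broken by the lowest
(row, column) pair in the current working order, making results independent
of input order up to the unrooted topology.  Negative branch-length
estimates (possible on non-additive input) are clamped to zero with the
deficit moved to the sibling edge so the joined pair's distance is
preserved — the convention of classic NEIGHBOR-compatible software — with a
`raw` mode that keeps the estimates.  On additive matrices the
implementation is exact (path lengths reproduce the input to 10⁻⁹ in
tests), and its topologies match an independent NJ implementation
(dendropy) on random non-additive matrices.  Trees are emitted as Newick
with 6-decimal branch lengths; distance matrices can be written in PHYLIP
square format (taxon-count header, names padded to 10 characters).

## Synthetic data generator

The generator is the test bed for everything above.  Per gene, a baseline
log₂ expression is drawn N(`baseline_log2_mean`, `baseline_log2_sd`) and
evolved along a user-supplied Newick species tree by Brownian motion with
rate `bm_sigma` (log₂ units per √branch-length), so
cov(log₂x_a, log₂x_b) = bm_sigma² × shared path length from the root — the
covariance structure under which "transcriptome similarity reflects
phylogeny" is literally true.  Tip values are exponentiated to true RPKM.
Spikes multiply chosen genes in a species or a named species group.
Marker genes (glia/neuron) are set from a configured per-species glia
fraction f so that their RPKM ratio equals f/(1−f) exactly; "confounded"
genes have constant per-glial-unit expression, i.e. bulk RPKM proportional
to the marker ratio.  Markers and confounded genes sit outside the
Brownian gene set so the composition signal is clean unless the user opts
otherwise.  Counts are Poisson around RPKM·N·L/10⁹ by default (single
libraries provide no replicate-level overdispersion estimate; a
negative-binomial dispersion knob exists but is off), and RPKM is then
recomputed from the sampled counts, which preserves the count–RPKM
conservation identity.  Everything is reproducible from (config, seed).

Defaults (chosen once as the simulated study conditions):

| parameter | default | rationale |
|---|---|---|
| tree | 6 species: (seal,ferret), ((minke_whale,bowhead_whale),cow), mouse outgroup | mirrors the carnivore/cetartiodactyl/rodent layout of a mammal brain panel; internal branches 0.12–0.20 |
| n_genes | 5,000 | order of a filtered one-to-one ortholog set (RPKM > 5) |
| bm_sigma | 1.0 | tip-to-tip log₂ divergences of ~1 unit on this tree — a few-fold typical expression divergence between orders |
| baseline_log2_mean / sd | 5.0 / 1.5 | expression-filtered bulk sets span roughly two orders of magnitude of RPKM; heavier baseline spread makes linear-scale Pearson estimates dominated by a handful of genes, which is exactly the regime the log mode exists for |
| library_size / gene_length | 10⁷ reads / 1,000 bp | mid-size bulk library; mean counts ≈ 10 × RPKM |
| count_noise | poisson | counting noise only; no biological replicates to calibrate overdispersion |

The annotation simulator draws every term's members uniformly from the
reference; the query is sampled without replacement with odds
`enrichment_odds` on the designated term's genes (odds 1 is the exact
null).  The composition test regime uses marker ratios geometrically
spanning 0.1–20 (a 200-fold range) and a confounded target at 100 RPKM per
glial unit.

What the generator does **not** emulate: gene-length variation and
GC/mappability bias, annotation asymmetries between genomes (all species
share the full symbol space), correlated gene modules beyond the
phylogenetic covariance, library-preparation batch effects, and
overdispersion beyond Poisson by default.  Passing tests therefore show the
pipeline's correctness and its behavior under phylogeny-shaped signal with
counting noise — not robustness to every artifact of real cross-species
mappings.

## Numerical conventions and limitations

* Display rounding is half-up to 2 decimals; all computation is full float.
* Correlation matrices are symmetrized and clipped to [−1, 1]; a constant
  expression column is an error naming the species.
* Binomial edge cases: P(X ≥ 0) = 1 and P(X ≤ n) = 1 exactly; p₀ ∈ {0, 1}
  handled explicitly.
* The NJ tie-break (lowest index pair) makes results deterministic but, on
  exactly tied non-additive input, possibly different from input-order-
  dependent implementations.
* Fold changes are undefined at zero RPKM by design; filter first.
* With n = 1 library per species, every comparison inherits that library's
  biological idiosyncrasies; the group t-test treats species as independent
  samples and ignores phylogenetic non-independence.
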