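# Methods

This note documents the models, statistics, conventions and design choices
behind bionetkit, and what the synthetic-data tests do and do not establish
about real data.

## Name registry

Each source database contributes (source, entity, name) assertions. An
incoming record merges into an existing entity when it shares at least one
normalized name (case-insensitive, whitespace-trimmed) with it within the
same organism and entity type; otherwise a new entity is created. A name's
weight is the number of *distinct* sources asserting it for that entity, so
re-registering a source never inflates support. Ranking is descending by
support with two deterministic tie-breaks: names involved in a shared-name
conflict sink below equally supported unconflicted names, then
case-insensitive lexicographic order.

Two conflict kinds are reported, never auto-resolved by deletion:
*shared_name* (one name pointing at ≥ 2 distinct entities — e.g. a gene-level
and a protein-level record re-using a synonym) and *divergent_names* (one
entity for which two sources assert disjoint name sets; a third source that
knows both names is what merged them, which is the resolvable
cross-database-naming case).

Assigning an ontology term to an uncharacterized table uses a binomial
over-representation test: for each candidate term, the count k of its label
word (or adjacent word pair) among the table's n words is scored as
P(X ≥ k | n, p_background) and Bonferroni-corrected over the candidate
terms; the winner is reported when the corrected p clears a 0.01 cutoff.
The binomial choice is this package's own (any over-representation statistic
on word counts would serve); the monotonicity and closed-form tests pin its
behavior.

## Expression compendium

An experiment is a genes × conditions matrix; widths differ across
experiments. Normalization z-scores each gene's vector with the *sample*
standard deviation (ddof = 1; conventional at small condition counts).
Constant vectors are flagged and excluded from correlation rather than
divided by zero. Missing values are NaN; correlations use pairwise-complete
observations with the effective n in the p-value, and pairs with effective
n < 4 are skipped.

Significance of a Pearson coefficient uses t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom, two-sided — this is what makes p-values comparable
across experiments of different vector lengths. The FDR family is all pairs
tested *within one experiment* (Benjamini–Hochberg step-up), keeping q
interpretable per experiment; whether to pool across experiments instead is
genuinely open, and per-experiment correction was chosen because the
correction is tied to that experiment's n.

A pair is called co-expressed in an experiment when q ≤ α and |r| ≥ r_min; a
triple when all three member pairs are called in the same experiment.
Support is the number of calling experiments; results keep support >
min_support. Defaults: α = 0.05, r_min = 0.5, min_support = 10 (the
retention rule "co-expressed in more than 10 experiments"), z_cut = 2 for
differential calls. α and r_min have no canonical value and are explicit
stand-ins; every search exposes them.

Differential search ("default mode") calls a gene over-expressed in an
experiment when the mean of its normalized values over the experiment's
declared case conditions is ≥ z_cut (under: ≤ −z_cut). Case conditions are
experiment metadata — the headless equivalent of selecting conditions
interactively. Note the structural ceiling: after z-normalization the case
mean cannot exceed √((1−f)/f) for case fraction f, so a z_cut of 2 requires
the case block to be a minority of conditions (f < 0.2).

## Theme enrichment

k hits in a query of n against a term of M genes in a background of N is
scored P(X ≥ k), X ~ Hypergeometric(N, M, n). The background defaults to the
union of annotated genes; query genes outside it are dropped with a warning.
Terms with M < 2 are skipped as uninformative. The Bonferroni family is all
terms tested in one invocation across all eight categories (one analysis =
one family). Annotations are taken as given — no DAG propagation; if the
input file is pre-propagated, the results reflect that.

## Genome intervals

Coordinates are 0-based half-open internally; BED is read natively and GFF3
(1-based closed) converted on read/write, so the conversion is isolated in
one layer. Overlap is `a.start < b.end and b.start < a.end` on the same
chromosome; abutting half-open intervals do not overlap; zero-length
intervals are invalid (end > start). `next` uses ascending (start, end,
element_id) genomic order and returns the first element starting at or after
the probe's end. TSS-relative coordinates (negative = upstream in
transcription direction) recalibrate to [tss+rel_start, tss+rel_end) on '+'
and reflect to [tss−rel_end, tss−rel_start) on '−'; '.' is treated as '+'
with a warning. Windows straddling the origin are clipped at 0 with a
warning; windows entirely before the origin raise. The default promoter
window is −6000 .. +500 around the TSS. The index is an interval tree per
chromosome (`intervaltree`) plus a sorted list for `next` navigation.

## Regulatory networks

Three composable prediction filters:

- *p-value*: keep strictly below the threshold (default 1e-3);
- *conservation* (phylogenetic footprinting): a (TF, ortholog group) pair is
  conserved when the TF has a site in the promoters of at least
  `min_species` member genes — default all species in the group, i.e. strict
  footprinting, and configurable because conservation stringency is a
  user-facing knob. With order checking on (default), the relative 5'→3'
  order of conserved TFs (by first-site position in transcription-relative
  coordinates) must agree pairwise across all species where both TFs occur;
  an inconsistent pair removes both TFs. Spacing conservation beyond order
  is not enforced — an exact spacing tolerance has no principled default and
  site identity is motif-free (same tf_id across species), since predictions
  arrive pre-called with TF identity.
- *tissue*: items restricted to tissues must intersect the requested labels;
  unrestricted items always pass (absence of annotation is not evidence of
  absence).

Conservation is computed from the prediction set it receives, so it commutes
with the pointwise filters only when the p-filter does not change species
coverage; `build_tf_gene_network` therefore fixes the canonical order
p → conservation → tissue. Surviving predictions become directed `tf_dna`
edges (target genes mapped back from orthologs through the group), annotated
with the minimum evidence p-value (`best_p` — how multiple evidences combine
into one edge score is not canonical; the minimum is used and labeled),
conservation flag, site count and species list. Supplied interactions are
added only between already included nodes; candidate TFs without a surviving
edge never enter the network.

## Graph queries

Paths are simple (no repeated node — the regulatory-path reading) and
enumerated up to max_len edges, deduplicated, sorted by (length, node ids),
with a hard cap (default 10⁵) and an explicit truncation flag because path
counts explode on dense graphs. Direction semantics: `directed` honours each
edge's flag (undirected edges traversable both ways); `undirected` and
`either` traverse every edge both ways (`either` deliberately relaxes
directed edges, and `undirected` then coincides with it, making the query
symmetric in sources/targets). Common regulators/targets use directed
regulation edges only (tf_dna or any directed edge). Attribute search
evaluates an AND/OR/NOT condition tree (or a small infix string) with exact
semantics; numeric comparators demand numeric fields and unknown fields are
errors, not silent misses. Overlays only add attributes — co-expression
support/r on edges (adding coexpression edges between already present
nodes), per-node z values, theme memberships — and never change the node
set.

## Synthetic data

Co-expression modules use a latent factor: in a designated experiment each
module gene is x = √ρ·f + √(1−ρ)·ε with f, ε i.i.d. standard normal per
condition, giving pairwise correlation exactly ρ in expectation with O(n)
generation. Condition counts are drawn uniformly from (16, 24) by default: a
power analysis of the t-test shows that below ~12 conditions even a perfect
ρ = 0.9 cannot reach p ≤ 1e-3, so shorter experiments would make planted
modules statistically invisible by construction; 16–24 conditions is
representative of multi-condition expression series and makes recovery a
property of the method rather than of luck.

The regulatory fixture plants, for each chosen (TF, ortholog group), one
site per species at a shared 5'→3' layout with p log-uniform in (1e-6,
1e-4); decoys have p ~ U(0,1), a single random species and random positions,
so the 1e-3 p-filter retains them at rate ≈ 1e-3 and strict conservation
essentially never does. An optional flag plants order-violating control
groups that the order check must reject. The annotation generator plants one
term containing a chosen number of query genes over a random membership
background. All generators are deterministic per seed and write their ground
truth as a JSON sidecar.

What the generators do *not* emulate: probe/batch effects, platform-specific
normalization, heavy-tailed expression noise, motif-level binding-site
similarity, promoter sequence content, or incomplete orthology. Passing the
planted-recovery tests therefore shows the machinery is correct and
well-calibrated under its stated model, not that the thresholds are optimal
for any particular real compendium.

## Workflow

The composed pipeline is a pure function of (inputs, configuration): select
over-expressed genes in the index experiment (the under-expressed branch is
implemented but off by default), mine the compendium for pairs with support
> min_support, extract −6 kb..+500 bp promoters for the surviving genes and
their orthologs, filter binding sites at p < 1e-3 plus strict conservation,
assemble the TF→gene network with supplied interactions, overlay
co-expression evidence, and compare the fraction of network TFs carrying a
disease keyword against the background fraction with a hypergeometric p
(population = TFs + background, marked = keyword carriers). Any stage with
empty output halts with a stage-named diagnostic. Reports and intermediates
are written with sorted keys and fixed float formats so reruns are
byte-identical.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by design: interval
oracle checks at 10⁴ elements × 10³ probes; mining oracle checks at ≤ 15
genes × 6 experiments; hypergeometric exactness for all populations N ≤ 25;
null FDR calibration over 200 replicate 10-gene compendia; planted-module
recovery at 40 genes × 40 experiments; conservation recovery at 20–40
ortholog groups × 3 species. Floating-point tolerances: normalization
idempotence and mean/SD checks at 1e-10–1e-12; closed-form oracle
comparisons at rel 1e-9. Ties everywhere break lexicographically so all
outputs are order-deterministic.

## Known limitations

- Name resolution is string-based; modification-state names (e.g.
  "p53(modified:Thr:212)") are distinct strings and stay unmerged, which is
  the safe but unhelpful reading.
- Per-experiment FDR does not control the compendium-wide error rate; the
  support filter is the practical guard against cross-experiment false
  positives.
- Conservation treats site identity as tf_id equality; paralog
  cross-mapping or motif similarity would need motif-level input.
- The keyword-association stage searches plain text; it is a stand-in for a
  curated disease-term lookup.
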