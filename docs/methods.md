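# Methods

## The analysis model

`bcrnet` analyzes heavy-chain BCR repertoires sampled from several anatomical
sites and/or several therapy timepoints of the same participant. The unit of
observation is a unique rearranged VDJ nucleotide sequence in a sample, with
a UMI count as its abundance (one UMI ≈ one original mRNA molecule). All
cross-sample statements are made within a participant: repertoires of
different participants are treated as disjoint.

### Clone definition

A clone is a set of sequences descending from one pre-B cell: identical CDR3
and IGHV gene, or related by single point mutations. Two clustering rules are
combined and their union's connected components are the clones:

1. **Sequence network.** Vertices are unique full-VDJ sequences; an edge
   joins two vertices iff they have equal length and Hamming distance exactly
   1 (non-indel single substitutions; identical sequences collapse at
   distance 0). The pairwise scan is restricted to records sharing a
   gene-level V call — two rearrangements using different V genes cannot be
   one substitution apart — which also bounds the quadratic cost.
2. **CDR3 identity.** Single-linkage over pairs with the same gene-level
   V call and equal CDR3 length at amino-acid identity ≥ 0.95 (matches /
   length). Unequal-length CDR3s never cluster at this stage, consistent
   with the substitution-only edge rule.

V calls are normalized to gene level (allele suffixes stripped). Clone ids
are deterministic (lexicographically smallest member id), so results are
independent of row order.

### Depth-matched sharing

Sequencing depth varies strongly between samples, so raw overlap counts are
not comparable. For each sample pair both unique-VDJ sets are repeatedly
subsampled (without replacement) to a common depth of
`floor(0.9 × min(unique counts))`; the shared count |A∩B| and Jaccard
coefficient |A∩B|/|A∪B| are recorded per iteration and summarized by the
median over 10,000 iterations (lower-median convention for even counts; the
convention is unstated in common practice and immaterial at 10⁴ iterations).
Subsampling acts on unique sequences, not UMI weights; the clone-sharing
variant intersects clone-id sets instead. Every pair uses a deterministic RNG
substream derived from (seed, i, j), so the matrix does not depend on the
order pairs are computed in.

### Tree concordance

A sharing matrix J becomes a dendrogram by Ward-D2 agglomeration on
D = 1 − J (bounded, monotone; the similarity→distance map is a package
choice). scipy's `linkage(..., method="ward")` on a precomputed condensed
distance matrix applies the Lance–Williams Ward update to unsquared
dissimilarities and therefore reproduces R `hclust`'s `ward.D2`; the tests
verify merge-by-merge agreement against an independent Lance–Williams
implementation.

Concordance between two trees on the same samples is the **cophenetic
correlation**: Pearson correlation of the inter-leaf cophenetic distance
vectors, paired by leaf pair. Dendrograms use the merge-height convention;
externally supplied tumor phylogenies (Newick with branch lengths) use
path-sums of edge weights. Significance is a one-sided permutation test: the
second tree's leaf labels are shuffled (default 100 times) with both
topologies fixed, and p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm). The add-one
form keeps p ≥ 1/(n_perm+1) and makes the test valid at finite permutation
counts; shuffling one tree rather than both is sufficient because only the
relative labelling matters. Constant cophenetic vectors (e.g. a star
topology) carry no ordering information and are assigned r = 0, which makes
all permutations tie and p = 1.

### Clone classes and the expansion threshold

Within a participant with ≥2 samples, a clone is *stem* (all samples),
*clade* (>1 but not all) or *private* (exactly 1); stem and clade clones are
the immunosurveilling / temporally persistent ones. Clone size is the clone's
share of a sample's UMIs. A single global expansion cutoff is fitted on the
pooled log₁₀ percent sizes of all clone-sample observations: a Gaussian
mixture (2 components by default, k-means++ initialization, 10 restarts,
seeded; BIC-selected up to 4 behind a flag), cutoff at the posterior-equality
crossing between the top-mean component and the rest. Two guards apply:

- *Degeneracy*: if the component means are closer than half the pooled s.d.,
  or a single-component fit has no worse BIC, the mixture carries no
  expansion signal and the cutoff falls back to the 90th percentile (with a
  warning).
- *Minority constraint*: expanded clones must remain <10% of the repertoire.
  The constraint is evaluated at the clone level (fraction of clones above
  the cutoff in ≥1 sample) when clone ids accompany the pooled values,
  otherwise at the observation level; if violated the cutoff is raised to the
  matching quantile. The clone-level reading is used because expansion is a
  property of clones, and shared clones contribute several observations each.

A clone is *expanded* iff its size exceeds the cutoff in at least one sample
(max-over-samples rule). Classes: A = private expanded, B = shared expanded,
C = private unexpanded, D = shared unexpanded. The immunosurveilling-clone
site profile retains clones present in >1 site with ≥4 unique VDJs in at
least one sample, normalizes each clone's per-sample VDJ counts to sum to 1,
and reports the per-site mean.

### Diversity, SHM, isotypes

Diversity indices are computed per sample on clone UMI counts after
subsampling to a common UMI depth (UMI-weighted, multivariate hypergeometric;
mean of 1,000 iterations): Gini in the mean-absolute-difference form
Σ|xᵢ−xⱼ| / (2n²x̄), Shannon entropy with natural log (normalized variant
H/ln K behind a flag), and a normalized mean clone size. The exact formula of
the latter is a known ambiguity; two candidates are implemented behind a
flag — `arithmetic` (mean UMIs per clone / total UMIs, = 1/K at fixed depth)
as the default and `weighted` (Σpᵢ², the clone share seen by a random UMI).

SHM categories are *no* (≤1 mutation), *low* (2–10), *high* (11–33),
*very high* (>33); the printed bin edges overlap at 1 and 33, resolved here
as right-closed intervals. A refit mode fits a 4-component Gaussian mixture
on log(shm+1) and derives the three adjacent-component posterior crossings
(falling back to the fixed bins below 200 records). "Highly mutated" = high ∪
very high. Isotype usage is UMI-weighted per sample; unswitched = IgD + IgM.
Antigen-experienced BCRs are class switched (IgA/IgG/IgE) with >4 mutations;
inexperienced are unswitched with ≤4; everything else is unclassified. The
per-sample mean SHM is a two-stage mean (per clone, then across clones) so
large clones are not over-represented.

### Degree centrality

For every clone observed in ≥2 samples with ≥10 unique BCR sequences:

1. Members are aligned (substitution-related clone members of equal length
   are already aligned; mixed lengths go through mafft when available, and
   the alignment route is logged). Sequences containing N are excluded —
   their Hamming distance is undefined; they still count in abundance
   statistics elsewhere.
2. The alignment's ends are trimmed inward until the terminal columns have
   ≥95% non-gap occupancy; clones shorter than 80 nt after trimming are
   skipped.
3. Identical trimmed sequences are grouped into one variant *before* the
   tree; per-sample abundance (UMI share) is aggregated per variant.
4. A minimum spanning tree is built on the pairwise Hamming matrix
   (residual internal gaps count as ordinary symbols: gap vs base = 1, gap
   vs gap = 0). Kruskal's algorithm with edges sorted by (weight, i, j)
   makes tie-breaking deterministic — equal integer Hamming weights are
   common, and an implementation-dependent tie order must not leak into
   degrees. Tests check the MST against exhaustive Prüfer-sequence
   enumeration (n ≤ 8) and an independent algorithm (n ≤ 200).
5. A variant's degree is its number of incident MST edges; degree 1 means no
   detected progeny. Variants are labelled immunosurveilling if observed in
   ≥2 sites and persistent if observed at ≥2 timepoints, and the classifier
   "positive iff degree > cutoff" is scored (sensitivity, specificity,
   accuracy) at cutoffs 1, 2 and 10. The MST is computed over unique
   variants, not duplicate-weighted multi-edges, consistent with grouping
   identical sequences first.

### Antigen screening

Tumor CDR3 amino-acid sequences are screened against a reference antibody
table with known anti-pathogen binding. A match requires equal length and
Hamming distance ≤3 (substitution-only "fuzzy" matching; a Levenshtein
variant would additionally allow length differences and is intentionally not
the default since CDR3 length is part of clonal identity). At load time,
synthetic-fusion entries and non-human (animal-derived) entries are excluded,
malformed rows are dropped with counts, and exact (CDR3, source) duplicates
are deduplicated. The packaged table generator is *synthetic*: random
sequences carrying a realistic per-source composition (5,800 retained
entries; HIV-1 3,525, C. tetani 817, influenza A 486, vaccinia 92, HCV 80,
S. pneumoniae 59, S. aureus 38, HHV-5 32, plus a mixed remainder), used to
exercise the loader and matcher; a curated user table can be supplied
instead.

## The synthetic-data generator

The generator defines the study conditions the test-suite benchmarks run
under. Defaults: 2 participants × 8 sites (lymph node, liver, lung/pleura,
breast, brain, skin, bone, peritoneum; timepoints 0/1/2 cycle over sites),
300 clones per participant, germline length 351 nt with a codon-aligned
20-aa CDR3 window, 20,000 UMIs per sample.

- **Clone sizes** are two-component lognormal on the log₁₀ percent scale:
  unexpanded mean −1.45 (s.d. 0.30), expanded mean +0.30 (s.d. 0.25),
  expanded fraction 0.06 — matching the published breast-cancer clone-class
  proportions in which expanded classes make up ≈7% of clones. A clone's
  abundance in each site it occupies is drawn from its component with 0.10
  log₁₀ per-site jitter and shared among the variants present there (hubs
  6× over-represented); this is exactly the statistical structure the
  expansion mixture model assumes, so the planted component boundary is
  well-defined on the realized scale.
- **Lineages** grow by sequential random attachment: new variants attach to
  planted hubs (weight 6), otherwise to a chain tip (weight 1), rarely to a
  chain interior (weight 0.03); a hub with fewer than two children takes the
  next arrivals with priority so every planted hub is a genuine branch
  point. A pure Galton–Watson offspring process cannot simultaneously hit a
  target clone size and concentrate branching on planted hubs, which is why
  attachment replaces literal Poisson offspring; the interior weight plays
  the role of the residual branching rate. Per-edge mutation counts are
  geometric with mean 1.2 at uniform random positions (substitution-only, no
  indels; stop codons in the CDR3 are re-drawn) — densely sampled expanded
  clones have near-unit substitution steps between adjacent *observed*
  variants.
- **Baseline SHM.** Each clone's observed root already carries
  Poisson(Gamma(1.2, 14)) mutations relative to its germline, reflecting the
  high and highly variable SHM of tumor-infiltrating B cells. This
  between-clone variance is what makes MST degree independent of SHM across
  the pooled repertoire even though, within a lineage, children are always
  more mutated than their parents.
- **Dissemination.** Hubs (5% of variants in eligible clones, positions
  drawn uniformly and independently of depth) are observed in
  2 + Poisson(0.7) sites; all other variants inherit a single site along
  their chain (with a small 0.08 migration probability per step). Shared
  clones without hubs are seeded by their founder in every clone site.
  Half of all clones originate in the lymph node, making it the main source
  of exploratory (degree-1) variants.
- **Class switching** occurs with probability 1 − exp(−0.25 × depth),
  unswitched cells split 80/20 between IgM and IgD, switched isotypes follow
  a fixed realistic usage vector.

What the generator does *not* emulate: germline V/D/J recombination and
junctional diversity (germlines are random sequences; generation
probabilities are not meaningful), indels, biased/hotspot SHM targeting,
selection on amino-acid fitness, cross-participant convergence, and
sequencing error. Passing benchmarks therefore demonstrate that the pipeline
recovers planted clonal structure, expansion boundaries and hub
dissemination under a faithful substitution-only model — not that it is
robust to indel-rich or error-rich data.

## Benchmark problem sizes

The packaged benchmarks run the full pipeline on the default conditions
above (~4,000 records, ~2,600 network variants, ~800 pooled clone-size
observations), check permutation-test calibration on 500 simulated tree
pairs (100 permutations each), and verify every core primitive against
brute-force oracles on ≥100 random fixtures. One full run of the test suite
or the reproduction script completes in well under a minute on one CPU.

## Known limitations

- Clone assembly can split a lineage when one observed step changes ≥2 CDR3
  amino acids (identity drops below 0.95 with no observed intermediate);
  at the default conditions this affects ~1% of lineage edges.
- The MST is a parsimony-style surrogate for the true lineage tree; with
  back-mutation collisions (rare at 351 nt) or large unsampled gaps the MST
  can shortcut, perturbing degrees.
- The expansion cutoff depends on pooled-cohort composition; per-dataset
  refitting is available but changes comparability across samples.
- `mean_clone_size` has two defensible definitions (see above); comparisons
  should state which was used.
- Participants with a single sample cannot receive topology classes; their
  clones are excluded from class analyses rather than imputed.
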