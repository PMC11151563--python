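# Methods

## Scope and model

`salnc` re-implements, as a reusable and tested pipeline, a
fold-change-rule analysis of salt-responsive long non-coding RNAs:
candidate filtering from transcript models, TMM/FPKM normalization of
raw counts, compound-rule classification into short-term and long-term
salt-associated (SA) lncRNAs, chromosome-window densities, structural
and tissue-specificity characterization, and guilt-by-association
functional annotation through co-expressed mRNAs. Read quantification
(e.g. Salmon), coding-potential prediction and GO/KEGG annotation
generation are upstream of the package: counts, a coding flag sidecar
and a flat term map are inputs.

The classification is deliberately not a statistical test: a lncRNA is
called from the point estimates of its four log₂ fold changes alone.
The package therefore treats replicate handling, pseudocounts and
normalization as the places where care is needed, and keeps the rules
themselves exact and strict.

## Candidate filter

A lncRNA candidate is retained iff

1. mature length (sum of exon widths) > `min_length` (200 bp, strict);
2. exon count ≥ `min_exons` (2);
3. no exon shares ≥ 1 bp with any mRNA exon (closed intervals, strand
   ignored — antisense overlap also disqualifies);
4. `coding_flag` is false.

Mature length rather than genomic span is used because lncRNA length
conventions refer to the transcript sequence; both quantities are in the
feature output so either can be inspected. Transcripts lacking a biotype
attribute are treated as mRNA, which can only enlarge the overlap mask
(conservative for the lncRNA set). The rejection report names the first
failing criterion in the fixed order above, so reported reasons are
deterministic. The filter is idempotent and order-independent; overlap
queries use per-chromosome sorted exon arrays with a running maximum of
interval ends (binary search per query).

## Normalization and fold changes

TMM follows the edgeR reference algorithm step for step: the reference
sample is the one whose 0.75 count quantile over library size is closest
to the mean of that statistic; pairwise M and A values are computed over
rows positive in both samples; rows in the top/bottom 30 % of M or 5 %
of A (rank-based, average ties) are trimmed; the factor is the
precision-weighted mean of the remaining M values (inverse asymptotic
variance weights); factors are geometric-mean-centered. Agreement with
the reference implementation is pinned by frozen fixtures to 10⁻⁶.
Degenerate cases: identical columns return exactly 1; a pair with fewer
than two untrimmed rows falls back to factor 1 with a warning; an
all-zero column is an error.

FPKM uses TMM-effective library sizes (column sum × factor), so
"normalize, then transform to FPKM" composes in that order. Fold changes
are log₂ of the ratio of per-condition means of FPKM with a pseudocount
(default 1.0 FPKM) added to both means — this bounds fold changes of
weakly expressed transcripts and makes them finite everywhere. A
transcript with zero FPKM in every replicate of both conditions gets
fc = 0 by default (it can then never satisfy a strict rule), or NA under
`drop_unexpressed`.

## Classification rules

With thresholds s = 1 (strong) and w = 0 (weak), both printed regime
rules reduce to one kernel: *up* iff a > w ∧ b > w ∧ (a > s ∨ b > s),
*down* mirrored with negated thresholds. The equivalence of the
disjunctive wording for the short regime and the compact wording for the
long regime is property-tested; the kernel is shared. All comparisons
are strict: values equal to a threshold never qualify. NA in either
member of a regime pair yields *none* for that regime. A transcript may
carry contradictory labels across regimes (e.g. short-up, long-down);
both are kept, since regimes are classified separately. Crosstalk
correlations are computed over all lncRNAs with both fold changes
defined (SA and SNA alike), for each of the four short×long pairs, and
reported as NA with a warning below 3 finite pairs.

## Windows, features, tissue specificity

Chromosomes are tiled with non-overlapping bins (default 200 kb; the
last bin truncates at the chromosome end). Each called lncRNA increments
exactly one bin per category it belongs to, anchored at its 5′-most
genomic coordinate regardless of strand (`midpoint` is available as an
alternative anchor). A transcript qualifying in both regimes counts in
both the short_SA and long_SA categories — category totals therefore
need not sum to the number of transcripts.

Tissue specificity: per-tissue expression is the mean FPKM over that
tissue's samples; fractions are per-tissue expression over the total
across tissues; the score is the maximum fraction; *leaf-specific* means
the leaf fraction strictly exceeds the cutoff (0.6). For any cutoff
above 0.5 this is equivalent to "score > cutoff attained in leaf", since
such a fraction is necessarily the maximum. Zero-total transcripts get
NA fractions and score, are never called specific, and are excluded from
sweep denominators (avoiding 0/0). KS statistics in the group comparison
are descriptive only.

## Co-expression and enrichment

Pearson correlations are computed on **log₂(FPKM + 1)**: on the linear
scale a single high-expression sample dominates the product-moment sum,
which both misrepresents co-regulation and makes edge recovery fragile.
The generic `coexpression_edges` routine is scale-agnostic; the
transform is applied by the pipeline layer. P-values are two-sided via
the t transform with n − 2 degrees of freedom (|r| = 1 ⇒ p = 0);
zero-variance rows are skipped with a warning. BH adjustment is applied
jointly over all tested pairs, and an edge is retained iff r > 0.5
(one-sided positive — anti-correlated mRNAs are not co-expression
partners) and adjusted p < 0.05.

Enrichment uses the hypergeometric upper tail P(X ≥ k) (scipy's
log-space-stable survival function; validated against exact rational
enumeration for all feasible configurations with N ≤ 12). The
background universe is the set of annotated mRNAs in the term map — the
hypergeometric model needs a closed universe — configurable to any
superset of the query. Terms are tested only with ≥ 1 query hit and ≥ 2
background hits (singleton terms are uninformative and inflate the BH
family). Rows are ranked by ascending p, ties broken by descending k,
then lexicographic term id, making output order fully deterministic;
the top 20 are flagged. Both annotation modes are implemented: pooled
group queries (union of partners over the group's lncRNAs) and
per-lncRNA enrichment with terms ranked by the number of lncRNAs
supporting them; the choice is a flag because the source analysis is
ambiguous between them.

## Synthetic studies and what they show

The generator emulates the *structure* of the real study: 5 conditions
× replicates, 5 tissues, lncRNA/mRNA transcript models on a
multi-chromosome genome, negative-binomial counts (gamma–Poisson:
variance m + φm²), per-sample depth factors log-uniform in [0.5, 2] so
TMM is load-bearing, planted fold-change effects that satisfy the
classification rules at the mean, Dirichlet tissue weights with a
planted leaf-specific subset, co-expression blocks induced by a shared
per-sample Gaussian log₂ factor, and planted term annotations on block
mRNAs. One integer seed reproduces every artifact byte for byte.

Default study conditions: 2 000 lncRNAs (six of them deliberate filter
failures), 1 000 mRNAs, 3 replicates per condition, dispersion φ = 0.1,
baseline means log-uniform in [50, 500], planted effect ±2 log₂ units in
10 % up and 10 % down of lncRNAs per regime, tissue Dirichlet
concentration 3 (typical specificity scores 0.25–0.35), planted leaf
weight 0.9 in 20 % of lncRNAs, co-expression latent σ = 2 log₂ units
(population r ≈ 0.95 between block members — the regime the
r > 0.5 ∧ adjusted-p < 0.05 edge rule actually selects), term background
rate 5 %.

What passing recovery tests shows: the pipeline's stages compose
correctly and recover planted signals under a well-specified NB model
with moderate depth variation. What they do not show: robustness to
features of real data the generator omits — outlier samples, batch
effects, length-dependent biases, overlapping isoforms, correlated
(GO-graph) terms, or composition effects stronger than the planted
10 %+10 % asymmetry. Headline counts from any particular real study are
functions of its data and are not reproduced by simulation.

Problem sizes in the test suite are chosen to keep the full run in the
tens of seconds: unit fixtures use tens of transcripts, recovery tests
use the full default study, enrichment recovery uses 100 + 100 small
single-block studies, and the end-to-end determinism check runs the CLI
twice on a 400-lncRNA configuration.

## Known limitations

- GTF only (no GFF3 dialect); only `exon` rows are consumed.
- No differential-expression testing (by design — the classifier is the
  printed fold-change rule), no dispersion estimation, no time-course
  modelling.
- Flat term maps: no ancestor closure over the GO graph.
- Window analysis is non-overlapping tiling only; no sliding windows.
- The per-transcript coding flag is trusted as given; no coding
  potential computation.
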