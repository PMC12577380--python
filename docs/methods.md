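# Methods

This note documents the models, estimators, defaults and numerical
choices behind `cprkit`, and what its synthetic-data validation does
and does not establish about real data.

## Absolute abundance model

Amplicon counts are compositional: a sample's reads inform only the
relative abundances p_i (total-sum scaling, rows summing to 1 within
1e-9; all-zero samples stay zero and are logged). Anchoring multiplies
each composition by the sample's total bacterial 16S gene copy number
per liter measured by qPCR, giving estimated absolute abundances
N_i = p_i · T in copies per liter. Row sums of the anchored table equal
the qPCR totals exactly up to floating-point error — anchoring rescales,
it never redistributes. No 16S operon copy-number correction is applied;
abundances are gene copies, not cells.

Fold enrichment of an ASV in an experiment is max over later time
points of (mean absolute abundance across replicates at t) divided by
the mean across the experiment's Start (t = 0) replicates. Replicates
are aggregated by arithmetic mean before the ratio because the mean is
linear in the multinomial expectation. ASVs with zero Start baseline
have no defined fold and are excluded with a log entry rather than
assigned infinity; only increases (fold > 1) are reported. Field
("InSitu") samples, collected days before incubations start, carry a
configurable negative time offset (default −4 days) and never serve as
baseline by default.

## Growth-rate estimation

Exponential growth N_i(t) = N_i(0)e^{kt} makes ln N_i linear in time,
so k is estimated by ordinary least squares of ln(copies/L) on
incubation time in days, independently per (ASV, experiment).
Conventions, chosen where the procedure is genuinely open:

- **Occurrence conditioning.** Observations with zero abundance are
  dropped (the ASV "did not occur"; ln 0 is undefined). No pseudocounts
  are added — imputation would bias slopes for sparse ASVs.
- **Three time points** means three *distinct* time values; replicates
  at one time all enter the regression but count once toward the
  threshold. This is the stricter of the two possible readings.
- **Pooled replicates** by default; a per-replicate mode is available
  via the `replicate_id` argument.
- A single slope spans the whole incubation (InSitu excluded); no
  windowing or changepoint fitting. Because real enrichments pass
  through lag, growth and stationary phases, the single slope is a
  conservative lower bound on peak growth — a property asserted in the
  tests on piecewise trajectories.
- No r² or slope-significance filter is applied beyond rate
  positivity: doubling times T_d = ln 2 / k are defined only for
  k > 0, and negative rates are discarded from all summaries.

## In-silico PCR

Primers are IUPAC-degenerate strings matched ungapped at every offset
of the target strand; a position mismatches when the primer and target
nucleotide sets do not intersect (U ≡ T; degenerate-vs-degenerate
scores by set intersection, no fractional mismatches). A placement is
valid when mismatches ≤ budget (default 2) **and** the primer's
3'-terminal dinucleotide pairs perfectly, where "perfectly" also
requires the target base there to be a concrete A/C/G/T inside the
primer base's set — polymerase extension needs true base pairing, so
target ambiguity codes are not credited at the anchor (switchable).
For a primer pair, the reverse primer is reverse-complemented and must
place downstream of the forward site; after reverse-complementing, the
reverse primer's 3' anchor lies at the *left* end of its target
window, which the matcher accounts for. Amplicon length (forward 5'
end to the reverse site's 3' end) must fall within configurable bounds
(default 50–2000 nt; unstated in the original protocol). Coordinates
are 0-based half-open internally. The matcher is validated against an
exhaustive pure-Python enumeration on a thousand random primer/target
pairs, and a strand-symmetry property (reverse-complement the database,
swap primer roles) guards the anchor geometry.

## Oxygen-related metabolic profiling

Genomes are gated inclusively at completeness ≥ 50% and contamination
≤ 10%. From each genome's gene annotations, only genes carrying
exactly one EC number contribute; genes with several ECs are excluded
entirely (their reaction assignment is ambiguous), and the surviving
ECs are deduplicated per genome. The resulting set is mapped onto a
three-way reaction partition: oxic (requires oxygen or
oxygen-derived metabolites), anoxic (strictly oxygen-free), augmented
(anaerobic reactions replaced by aerobic alternatives); unmapped ECs
are counted as unclassified, so the four categories always partition
the EC set. EC strings are matched exactly after normalization
(whitespace, `EC:` prefix); partial ECs like `1.4.3.-` match only
identical partial keys, avoiding over-claimed specificity.

The packaged reaction-class table (`cprkit/data/
reaction_classes_synthetic.tsv`) is a synthetic stand-in with the real
table's structure; swap in a full EC→category network export for
production use. The directly oxygen-utilizing enzyme catalog defaults
to six enzymes (l-aspartate oxidase 1.4.3.16, kynurenine
3-monooxygenase 1.14.13.9, pyridoxamine 5'-phosphate oxidase 1.4.3.5,
catechol 2,3-dioxygenase 1.13.11.2, 4-hydroxyphenylpyruvate
dioxygenase 1.13.11.27, d-amino-acid oxidase 1.4.3.3); the EC
assignments are standard-nomenclature choices and overridable.

Function-prevalence comparison between focal CPR classes and all other
genomes uses a Kruskal–Wallis omnibus test followed by Dunn's pairwise
z tests with midrank tie correction and Bonferroni multiplication;
functions with corrected p < 0.05 are selected. Groups with fewer than
two genomes are skipped with a log entry. When every observation is
tied the statistic is 0 and p is 1 by definition rather than NaN.

## Co-occurrence networks

The default estimator is pairwise Spearman correlation of total-sum
scaled abundances — deterministic and adequate for rule testing; ASVs
constant across the subset have undefined rank correlation and their
edges are omitted. The alternative implements the compositional
log-ratio procedure: with pseudocount-1 fractions x, the variation
matrix t_ij = var(log(x_i/x_j)) is solved for approximate basis
variances w under the sparse-correlation assumption
(E[t_ij] ≈ w_i + w_j), correlations follow as
(w_i + w_j − t_ij) / (2√(w_i w_j)) clipped to [−1, 1], and the most
strongly correlated pair above threshold 0.1 is iteratively excluded
from the linear system (up to 10 pairs, 20-iteration cap moot in the
deterministic variant: Dirichlet resampling is off by default so
identical inputs give identical networks; basis variances are floored
at 1e-12 before the square root). These defaults are configurable; the
original protocol specifies none of them.

Edge rules: networks are estimated per treatment from ≥ 4 samples
after removing ASVs present in fewer than 20% of the subset's samples
(standard practice; configurable); kept edges need at least one CPR
endpoint and weight strictly greater than 0.1 ("edge weight" is the
correlation value itself). For order-level counting, CPR–CPR edges are
excluded, at most the 200 highest-weight edges are counted (ties broken
by the canonical edge id for determinism), and non-CPR orders with
fewer than three links in total are dropped.

## Community statistics

Shannon diversity uses the natural log on the CPR sub-composition
renormalized to sum to 1, so H measures CPR evenness independent of the
CPR fraction; samples without CPR abundance are omitted with a log
entry (renormalization is the documented choice; the alternative —
unrenormalized CPR proportions — conflates evenness with total CPR
load).

The Spearman association branch correlates each CPR ASV's relative
abundance with binary indicators for each supplement and for oxic
status, using midranks for ties, asymptotic two-sided p values for
n > 9 and exact permutation p values for n ≤ 9. Significance uses a
stringent raw-p cutoff of 0.001 with no multiplicity correction: rank
correlations on compositional data are fragile, and the stringent
cutoff is the guard. The branch's empirical type-I error at this
cutoff is verified to lie in [0.0005, 0.002] over 10,000 null pairs.
Compositional-bias-aware differential abundance is not reimplemented;
externally computed results (ASV, parameter, log2 fold change,
adjusted p) can be ingested and merged, with the conventional adjusted
p < 0.05 rule applied to that branch. Oxygen status is modeled as its
own binary parameter, separate from the supplements.

## Synthetic data generator

The generator emulates the statistical structure of the enrichment
study so every stage can be scored against planted truth:

- **Counts.** Latent N_i(t) = N_i(0)e^{k_i t}·ε with ε lognormal
  (σ default 0.25); true totals are the latent row sums; reported qPCR
  is the true total times a lognormal error (σ default 0.2 —
  measurement-error magnitudes are rarely reported for these assays, so
  both are explicit overridable choices); reads are multinomial at fixed depth (default
  30,000, MiSeq scale), so each sample's counts sum exactly to depth.
  `depth=None` is an infinite-depth surrogate (counts = rounded latent
  copies) used for noise-free exactness tests.
- **Rates.** Doubling times lognormal around 15 days for CPR and 13.5
  days for non-CPR (medians typical of groundwater enrichment
  communities), spread 0.6 on the
  log scale, with a quarter of ASVs declining — incubations kill as
  well as grow. Experiments alternate thiosulfate/ammonium-amended
  oxic and methylamine-amended anoxic treatments, the two families
  with qPCR anchoring; t = 0 samples form the Start group.
- **Reference sequences** carry a realized forward-primer site and
  reverse-complemented reverse site separated by a random insert
  (300–400 nt, matching the amplicon scale), with planted mismatch
  patterns per class: perfect, two internal mismatches (amplifiable at
  budget 2), one 3'-anchor mismatch, or three internal mismatches.
  True coverage is forced by construction. Mismatches are planted only
  at primer positions that are not fully degenerate.
- **MAG annotations** plant per-genome EC counts per category plus
  duplicate-EC genes (dedup check), two-EC genes (exclusion check) and
  quality values straddling the 50%/10% gates.
- **Determinism.** One seed feeds named spawned sub-streams (rates,
  initial abundances, latent noise, qPCR noise, counts, reference
  database, MAGs), so adding one simulation never perturbs another and
  identical configurations serialize byte-identically.

What passing on synthetic data does **not** show: the generator has no
lag phases, no treatment-specific growth responses, no chimeras or
sequencing error models, no structural zeros, and independent noise
across samples — so validation certifies the estimators and the rule
bookkeeping under the stated generative model, not robustness to every
pathology of real amplicon data.

## Problem sizes

Default validation sizes were chosen to make Monte-Carlo checks sharp
yet quick: 100-ASV communities across 60 samples for pipeline runs,
200 replicate simulations for growth-rate recovery, 100 seeds for
planted co-occurrence detection (100 samples each), 1,000
primer/target pairs against the exhaustive oracle, and 10,000 null
pairs for type-I calibration. The whole test suite runs in well under
a minute.

## Known limitations

- The growth model fits one slope; organisms with strongly phasic
  dynamics are summarized by a conservative average rate.
- SparCC basis correlations are approximate for small numbers of taxa
  or dense correlation structure; the sparsity assumption is inherited
  from the method. Under the null (independent lognormal taxa, n = 100
  samples) the off-diagonal estimate occasionally exceeds |0.15|.
- Spearman associations on compositional data can reflect co-varying
  factors; the stringent cutoff reduces, but cannot eliminate, spurious
  hits, and no compositional bias correction is applied in that branch.
- Exact permutation p values are computed only for n ≤ 9 (cost grows
  factorially); above that the asymptotic approximation is used.
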