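# Methods

This note documents the statistical model, the conventions and numerical
choices behind `hipred`, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one reading was
defensible.

## Loss-of-function calling

Coordinates are 0-based half-open throughout (BED convention); GFF3 input
is converted on read. Five disruption criteria are evaluated per
(transcript, deletion) pair in a fixed order, and the first satisfied one
is reported:

1. **over_half_cds** — deleted CDS bp strictly greater than 50% of total
   CDS bp. "Over half" is read literally: exactly half is not LOF.
2. **start_codon** — the deletion removes any of the three 5′-most CDS
   bases (strand-aware; the three bases may span a splice junction).
3. **first_exon** — the deletion fully contains the 5′-most exon. Partial
   5′ overlaps are not counted here; when they matter they are usually
   caught by the start-codon rule. Full containment avoids double-counting
   ambiguous partial hits.
4. **splice_signal** — the deletion overlaps either 2-bp intronic window
   flanking any intron (donor and acceptor of every intron). Sequence
   content is not checked: the pipeline is annotation-only and needs no
   FASTA. For pathological introns shorter than 4 bp the windows are
   clipped to the intron.
5. **frameshift** — the deletion overlaps the CDS partially (neither
   contains it all — that case is over_half — nor misses it) and the
   deleted CDS length is not a multiple of 3.

A gene is LOF in an individual iff **every** coding transcript carries at
least one disrupting deletion from that individual (different transcripts
may be hit by different deletions). Non-coding transcripts of a coding
gene are ignored; a gene with no coding transcript is not evaluated.
The haplosufficient (HS) catalog contains genes whose gene-level LOF
holds in at least `min_individuals` (default 2) **distinct** individuals;
the ≥1-individual "putative" set is reported alongside, as is a
per-criterion tally of LOF events (one transcript in one individual).

The source material describes the scenario list once as five criteria and
once as "four scenarios"; all five are implemented and the tally makes
any collapse auditable.

## Predictor variables

- **Promoter conservation**: the promoter is the [−100, 100) bp half-open
  window around the TSS (the transcript's 5′ end; for − strand the window
  is reflected so −100 is upstream in transcription direction). A
  per-base conservation track (chrom/pos/score TSV) is summed over the
  window; per-transcript sums reduce to gene level by the **median**.
  Computing the conservation score itself is out of scope.
- **Tissue specificity**: each gene's expression row is normalised to sum
  1 before the SD across tissues (n−1 denominator) is taken. The
  normalisation is deliberate: the SD of an unnormalised row confounds
  expression magnitude with profile shape. Zero-total genes are missing.
- **Embryonic expression**: binary; 1 iff the gene is ≥ 8-fold
  over-expressed (embryonic/reference) in *any* of the supplied embryonic
  datasets (union rule). A zero reference with positive embryonic signal
  counts as satisfying the fold; 0/0 does not.
- **Network proximity**: in a weighted functional network (edge weights =
  log-likelihood scores), the shipped feature is the summed weight of
  direct edges to the known-HI seed set, with leave-one-out for genes
  that are themselves seeds (prevents label leakage into training).
  Unweighted shortest-path hops to the nearest seed and node degree are
  carried as alternative columns. A gene absent from the network is
  missing, not zero; an isolated listed gene has degree 0.

Group comparisons (HI vs HS) use the two-tailed Mann–Whitney U test for
continuous properties and two-sided Fisher's exact for binary ones, with
group means expressed as z-scores against the genome average and error
bars of 2 × SEM. The Mann–Whitney p is exact for small untied samples and
uses the tie-corrected normal approximation otherwise.

Feature selection enumerates candidate subsets under two hard screens —
joint non-missing coverage of at least half the genes, and pairwise
|Spearman ρ| < 0.3 (average ranks for ties, computed on jointly
non-missing genes) — then ranks survivors by repeated-CV AUC, preferring
category diversity on ties. The output is deterministic in the candidate
set, independent of its ordering.

## The discriminant model

Features are divided by their training SD (unit variance) so coefficient
magnitudes are comparable across predictors; the contribution chart is
|w| per feature. With pooled within-class covariance S (unbiased,
(n₁−1)S₁+(n₀−1)S₀ over n₁+n₀−2) the discriminant is w = S⁻¹(μ_HI − μ_HS)
and the posterior is the logistic of wᵀx + b with
b = −½wᵀ(μ_HI + μ_HS) + log(π_HI/π_HS). Priors default to training class
frequencies and are configurable (equal priors shift the bimodal p(HI)
distribution; the choice is recorded in the serialized model). Training
uses complete cases, with the dropped-row count kept in the model;
imputation is opt-in.

Numerical notes: a constant feature (zero scale) and a singular pooled
covariance are hard errors with a collinearity hint; identical class
means yield a zero discriminant with a degeneracy warning. Multiplying a
raw feature by a positive constant leaves p(HI) unchanged (absorbed by
the scaling), which is tested.

**Cross-validation**: stratified folds are drawn by per-class shuffled
round-robin assignment from the package's own seeded RNG; per repeat,
held-out posteriors are pooled across the 10 folds and AUC/MCC computed
on the pool, then averaged over 30 repeats. MCC uses the posterior-0.5
operating threshold (configurable; the pooled-per-repeat averaging is one
of two defensible readings and is flagged here). AUC is the rank
statistic U/(n₁n₀) with ties counted ½; MCC returns 0 by convention when
a denominator factor vanishes.

**Imputation (PMM)**: per feature with missingness, a linear regression
on the other features over complete cases; each missing cell takes the
observed value of one of the 5 nearest complete cases by predicted value
(uniformly at random among them, seeded). Imputed rows carry a provenance
flag. Recipients missing several features are predicted with
complete-case means substituted for their other missing regressors.

**Enrichment**: "predicted HI" = top 10% of scored genes by p(HI) (the
fraction is a parameter). Two labelled fold definitions coexist because
published fold values of this kind mix them: set-vs-set mode reports the
odds ratio of the 2×2 table (both the sample OR and the conditional MLE
that exact-test software prints) with Fisher's two-sided p; baseline mode
reports (predicted-HI fraction in the set)/baseline with a two-sided
binomial p.

## Deletion LOD scores

With per-gene probabilities p_i clamped into [ε, 1−ε], ε = 10⁻⁶ (several
training genes saturate at p(HI) = 1; clamping keeps scores finite and ε
is configurable and recorded), q = Π(1−p_i) is accumulated in log space
and LOD = log₁₀((1−q)/q). Base 10 matches the magnitudes of the published
control percentiles and the term "LOD". Gene independence is assumed.

By default a deletion contributes the genes it renders LOF under the
rules above ("LOF mode"); `--overlap-mode` includes any overlapped gene.
Genes without p(HI) are skipped and counted — never treated as p = 0. An
empty scorable set is an undefined score, not 0. The genome-wide burden
score pools the unique LOF genes across all of an individual's deletions
(a gene hit twice counts once) and applies the same formula.

The empirical pathogenicity probability of a deletion is the fraction of
control individuals whose **maximal** deletion LOD is ≥ the query ("same
or greater" implemented literally as ≥). Controls can be supplied as raw
per-individual maxima or as a percentile table; in table mode the
survival fraction is linearly interpolated between tabulated percentiles
and clamped to the table's resolution (a query beyond the highest
tabulated percentile cannot resolve probabilities below 1 − max
percentile). The packaged tables are the published control summaries for
African-American (n=889) and European-American (n=1433) GWAS cohorts.

`roc_compare` benchmarks LOD against deletion length and gene count: the
per-individual control representative is the maximum of each metric, and
the AUC is computed with cases as positives.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of a `SimulationConfig`; each draws
from its own RNG stream (`default_rng([seed, k])`) so adding a generator
never perturbs existing fixtures, and fixed seeds give byte-identical
files.

- **Toy genome**: 3-exon genes, 156-bp CDS starting in the second exon
  (so a pure first-exon deletion is plantable), 1–2 transcripts per gene,
  ± strands, 2 kb spacing. Deletions are constructed from each
  transcript's own geometry to realise one requested criterion and are
  *verified against the caller at construction*; an infeasible request
  (e.g. first-exon on a transcript whose first exon holds the start
  codon) raises a spec error naming the conflict. Default conditions: 200
  genes, 50 individuals, 60 genes LOF in ≥2 samples, 30 in one, 40 with
  benign deletions. What this does not emulate: realistic human CNV
  length/frequency distributions, overlapping genes, or genotyping noise
  — planted-recovery tests show rule correctness, not robustness to call
  errors.
- **Feature classes**: class-conditional Gaussians with shared covariance
  (identity by default, configurable), class sizes defaulting to the real
  training contrast (234 HI vs 326 HS), mean difference along the
  all-ones direction scaled so the Mahalanobis separation Δ satisfies
  Φ(Δ/√2) = 0.81 — the model's real-data operating point, and the exact
  distributional family the LDA assumes. Passing CV tests therefore
  certify the estimator, not the realism of real gene properties (which
  are non-Gaussian, correlated with missingness, and not MCAR).
- **Network**: a uniform random background graph (500 nodes, 2000 edges
  by default) with Gamma(2, 1) edge weights, plus 4 extra seed edges for
  each of 50 class-1 genes. This plants a direct-weight-sum signal; it
  does not reproduce scale-free degree structure or the modularity of
  real functional networks.
- **Control cohort**: per-individual maximal LODs drawn from a Gumbel
  (a maximum statistic), located near the published control medians.

Test and acceptance problem sizes (200-gene genomes, 1000 genes/class for
CV, 500-node networks) are chosen so the full suite runs in well under a
minute while keeping Monte-Carlo error comfortably inside the asserted
tolerances.

## Known limitations

- The LOF rules never inspect sequence, so "splice signal" and "start
  codon" are annotation-geometric proxies.
- p(HI) calibration cannot be assessed absolutely (the genome-wide HI
  fraction is unknown); the posterior scale depends on the prior choice,
  which is therefore surfaced rather than hidden.
- The percentile-table lookup cannot resolve empirical probabilities
  below 0.01 (the tables stop at the 99th percentile); raw control values
  resolve to 1/N.
- The deletion score assumes independence between co-deleted genes; no
  epistasis beyond the pooled genome-wide burden is modelled.
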