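# Methods

## Spectrum model

Every somatic SNV is classified into one of 96 channels: six
pyrimidine-referenced substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) ×
16 combinations of the 5' and 3' flanking bases. Purine-referenced
mutations are reverse-complemented onto the pyrimidine strand before
lookup, so classification is strand-symmetric (this is asserted
exhaustively over all 192 raw triples). Channel order is fixed: classes in
the order above, contexts sorted by 5' then 3' base — the layout of
COSMIC-v2 signature files. Records carrying a pre-computed context bypass
the reference genome entirely; when a genome accessor is supplied it may be
any object supporting `genome[chrom][start:end]` (a dict of strings or a
`pyfaidx.Fasta`). N-containing contexts are skipped, not errors, matching
practice at assembly gaps; contig-edge positions and reference-base
mismatches are dropped and counted in a reconciliation report.

## Refitting

A sample's normalized spectrum *p* is decomposed against a catalog *S* by

minimize ‖p − Sᵀw‖² subject to w ≥ 0, Σw ≤ 1.

The solver is greedy forward selection: start with the single signature
minimizing SSE, then repeatedly add the signature whose inclusion — with
*all* active weights re-solved jointly by NNLS and rescaled when Σw > 1 —
most reduces SSE, stopping when the relative improvement falls below `tol`
(default 1e-3). Weights below the contribution cutoff (default 0.06, the
same value used as the "observed" threshold downstream) are zeroed and the
survivors re-solved; the re-solve loop iterates until every surviving
weight clears the cutoff, so the output contract (each weight is 0 or
≥ cutoff) holds exactly. Ties on SSE break toward the lowest catalog
index for determinism. Joint re-solving (rather than a one-dimensional
line search per added signature) makes the result order-robust and directly
comparable with `nnls_subset_oracle`, the exhaustive-subset reference
solver used in tests (feasible up to 12 signatures). Unexplained spectrum
mass appears as `residual_error` (SSE), not as an explicit
pseudo-signature.

## De novo extraction

Cohort spectra (rows normalized) are factorized by NMF with multiplicative
updates and Frobenius loss (scikit-learn's `mu` solver; max 2,000
iterations, tolerance 1e-6), keeping the best of `n_restarts` seeded random
initializations (default 10). Signature rows are renormalized to sum 1 with
loadings rescaled compensatorily. Each de novo signature maps to the
catalog entry of maximal cosine similarity when that similarity is strictly
above 0.75, else it is reported unmapped. The factorization rank *k* is a
user parameter; reconstruction error per *k* is reported, with no automatic
choice.

## Cancer-type-specific signatures and markers

For one type versus the pooled rest, a signature is type-specific when its
prevalence (fraction of the type's samples with contribution strictly
> 0.06) is ≥ 0.20, the fold change of mean contributions exceeds 1.5 and
the absolute mean difference exceeds 0.1. Fold change uses a symmetric
pseudo-count ε = 1e-3 to guard zero rest-means; means are the default
center (medians behind `center="median"`). "Pooled rest" (one-vs-rest)
matches the classifier design; the thresholds are deliberately plain
cutoffs, not corrected hypothesis tests. Mutation markers are analogous on
the binary gene matrix: within-type frequency strictly > 0.05 and absolute
frequency difference > 0.1.

## Classifiers

One-vs-rest logistic regression per type over its CTS-MS, with
bidirectional stepwise selection by AIC from the intercept-only model: each
step evaluates every single addition and removal and applies the best
AIC-decreasing move. The likelihood engine is an effectively unpenalized
lbfgs fit; when the final coefficients blow up (|β| > 30, the signature of
perfect separation on small synthetic cohorts) the fit falls back to a weak
L2 ridge (strength 1e-4) and flags it in the training metadata. AUC is the
Mann-Whitney probability P(s₊ > s₋) + ½P(tie).

The origin model is deliberately the smallest reproducible neural network:
one logistic hidden layer (default 8 units), softmax output, cross-entropy
loss, full-batch gradient descent (learning rate 0.5, 5,000 iterations,
seeded Gaussian initialization) — deterministic per seed. Its input is the
concatenation of the candidate origins' CTS-MS exposures and those types'
model scores. The cascade first applies the liver model at threshold 0.5
(configurable; the choice is a convention, not a fitted quantity), then the
origin network to the lesions called non-liver.

cfDNA calls compare two types' model scores and pick the larger, ties
breaking toward the first model with a logged flag. The combined models add
mutation-marker indicators to the CTS-MS candidate pool under the same
stepwise selection.

## Connection score

For one sample, score = n_connected / n_mutated where n_connected counts
mutated genes with degree ≥ 1 in the subgraph of the PPI network induced on
the sample's mutated gene set; genes absent from the network count 0.
The induced-subgraph reading is the default because the alternative
("any interaction anywhere in the network") reduces to network coverage;
it remains available as `reading="global"`. Gene symbols are matched
case-insensitively after trimming. Group comparisons use the two-sided
Wilcoxon rank-sum test: exact null for pooled n ≤ 20, tie-corrected normal
approximation otherwise.

## Similarity

Pairwise similarity of two samples is the cosine of their exposure vectors;
a cohort-level similarity averages the m × n pairwise matrix. The plain
mean is the default aggregate — it reproduces the expected scale (≈ 1 for
same-type cohorts) — with the mean-of-squares variant behind
`variant="mean_square"`; a scaled-sum reading (Σρ/2mn) is excluded because
it cannot reach 1 for identical cohorts. The display normalization of a
type-by-type aggregate matrix applies, strictly in order: row centering,
column centering, within-row average ranks / n_cols, within-column average
ranks / n_rows (the sequential reading; ranks use average tie handling).

## Synthetic data

The generator *is* the model the refit assumes, which is what makes
end-to-end recovery a meaningful check:

- exposures ~ Dirichlet(c·mean) per sample (default concentration c = 50;
  c = ∞ degenerates to the mean exactly);
- burden ~ log-normal(log 200, 0.8) with floor 10 — exome-scale counts, the
  floor avoiding empty spectra. The default study raises the burden to
  log-normal(log 500, 0.3) because that is the scale at which classifier
  and cascade performance is evaluated;
- channel counts ~ Multinomial(burden, Sᵀ·exposures);
- gene mutations ~ Bernoulli: 500-symbol pool, background rate 0.01
  (keeping the matrix exome-sparse), planted drivers at 0.4 per type
  (3 genes each);
- default profiles: 10 types named after common TCGA cohorts, each with one
  planted specific signature at mean 0.4 (comfortably above the 0.15 floor
  the |diff| > 0.1 selection rule needs) and the remaining 0.6 split over
  two background signatures shared by all types;
- metastases re-draw the primary's exposures from Dirichlet(exposures /
  drift) — drift 0.05 default; zero exposure components keep zero mass
  since a Dirichlet cannot take zero concentrations — then resample counts;
- cfDNA spectra are per-channel binomial thinnings at `dilution` (default
  0.3) with each driver mutation dropped at `dropout` (default 0.1);
- the PPI generator plants a dense module (edge rate p_in = 0.3) in a
  sparse background (p_out = 0.01), and mutation-set sampling draws half of
  a "clustered" sample's genes from the module versus uniform draws for
  "random" samples.

What a green synthetic test establishes: the pipeline recovers structure
that is actually generated by its own model class, at stated burdens and
separations. What it does not: performance on real cohorts, where
signatures are correlated, burdens heavy-tailed, exposures not exactly
Dirichlet, and sequencing artifacts present. Headline numbers from real
cohorts are therefore not reproduced here; the synthetic analogues are
property checks, not benchmark claims.

## Orchestration and determinism

The full study (`RunConfig`, default 10 types × 100 train + 100 test
samples) derives every stage's seed from the single config seed by fixed
offsets, so stages rerun standalone reproducibly. Reports are
JSON-serialized with sorted keys; two runs with one config are
byte-identical. The default-scale study completes in well under a minute on
one CPU.

## Known limitations

- Only SNVs and the 96-channel classification: no indel/doublet signatures,
  no transcription-strand split.
- The exhaustive refit oracle is limited to catalogs of ≤ 12 signatures.
- Stepwise AIC selection admits a pure-noise feature with probability
  ≈ 0.157 per candidate (P(χ²₁ > 2)); with several candidates the
  intercept-only rate under the null drops accordingly — this is a property
  of AIC, not a defect of the implementation.
- The origin network's architecture and training schedule are fixed
  conventions chosen for reproducibility, not tuned hyperparameters.
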