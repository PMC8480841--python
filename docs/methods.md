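# Methods

## The ontotype encoding

The package maps genotype to phenotype through a hierarchy of biological
systems rather than through individual variants.  Three nested encodings are
built from annotated non-synonymous variants:

1. **SNV matrix** `S ∈ {0,1}^{strains × variants}` — 1 when the strain
   carries any non-reference allele at a coding missense or nonsense site.
   Isolates are treated as haploid-like: heterozygous calls score 1, because
   the encoding records presence/absence of a protein-altering variant, not
   dosage.  Missing genotypes score 0 (reference) by default, with a
   `drop`-variant alternative; the binary presence encoding has no natural
   missing state.
2. **Gene matrix** `G` — OR gate over each gene's variant columns:
   `G[s,g] = 1` iff gene *g* carries ≥ 1 qualifying variant in strain *s*.
   The maximum score for a gene is 1 however many variants it carries.
3. **Ontotype matrix** `O` — for every ontology term *t* with propagated
   gene set `A(t)`, `O[s,t] = |A(t) ∩ mutated(s)|`, the number of the
   strain's mutated genes inside the system.  Counts are raw integers: the
   encoding is deliberately parameter-free mutational burden.  Per-size
   normalisation and term-size filters exist but are off by default — the
   models are trained on all retained terms.

Annotation propagation follows the DAG: `A(t)` is the union of *t*'s direct
annotations and those of all its descendants, so every parent's count
dominates each child's (`O[s,parent] ≥ O[s,child]`) and the root counts all
mutated genes known to the ontology.

`is_a` and `part_of` edges are treated identically for propagation; gene
identifiers are verbatim case-sensitive strings with no symbol/ORF mapping.

### Pruning

Terms with no propagated genes carry no signal and are removed.  A term
whose propagated set is *identical to at least one of its children* is also
removed (parents of a removed term are rewired to its children), because the
parent is information-free relative to the more specific term.  "Redundant"
could alternatively be read as "equal to the union of the children"; the
per-child rule was chosen because it keeps the most specific term while
never discarding a term that aggregates information across children.
Pruning never removes the root and never changes the root's gene content.
Multiple ontology branches (e.g. the BP/MF/CC branches of GO) are joined
under a single artificial root.

## Prediction models

All models are evaluated by 5-fold cross-validation: a seeded shuffle
partitions strains into five near-equal contiguous blocks (remainders to the
earliest folds), each fold is held out once, and the score is the mean
held-out R².

* **Random forest** (`rf`) — 1000 bootstrap-sampled regression trees by
  default, `mtry = √p` and minimum node size 5 (the regression defaults of
  the ranger package).  Two engines produce the forest: scikit-learn (the
  reference; exposes out-of-bag predictions) and LightGBM in random-forest
  mode (row subsampling 0.632 per tree, per-tree feature subsampling √p/p).
  The LightGBM engine grows trees several-fold faster and is used wherever
  hundreds of forests must be fitted (permutation nulls).
* **Mixed random forest** (`mixed_rf`) — `y = f(X) + g + ε` with
  `g ~ N(0, σ²_g K)` for a genomic relationship matrix K.  Fitted by
  alternating (i) a forest on `y − ĝ` and (ii) single-kinship REML plus BLUP
  of `g` on the forest's *out-of-bag* residuals.  OOB residuals are essential
  here: in-sample forest residuals are near zero by construction and would
  swallow σ²_g.  The forest seed is held fixed across iterations so the
  alternation is a deterministic fixed-point iteration; it stops when the
  relative change in σ²_g falls below 1e−4 or after 20 iterations (warning +
  last iterate on non-convergence).  Held-out strains are predicted as
  `f(X*) + σ²_g K*ᵗ (σ²_g K + σ²_e I)⁻¹ r`.  The kinship defaults to the
  additive GRM of the model's own SNV set.
* **GBLUP** (`blup`) — features are standardised into Z, `K = ZZᵀ/m`, and
  `ĝ = K (K + δI)⁻¹ (y − ȳ)` with `δ = σ²_e/σ²_g` REML-estimated unless
  supplied.  Algebraically identical to ridge regression on Z with penalty
  `m·δ` (verified to 1e−6 in the tests).  At δ = 0 the system is solved by
  least squares on K's range, since column standardisation always puts the
  ones vector in K's null space.
* **Ridge / lasso** — penalty chosen by inner 3-fold cross-validation over a
  log-spaced grid (1e−6 … 1e6, 25 points); no penalty values are prescribed
  by the method itself.
* **MLP** (optional) — three sigmoid hidden layers of 1000, 400 and 100
  units; excluded from the acceptance checks because its training variance
  is too high at the problem sizes used there.

All backends are deterministic given (inputs, config, seed); every source of
randomness in the package derives from one root seed through named
substreams (folds, forest fits, permutations, scrambles, gene-set draws).

## Importance, consensus and empirical FDR

Feature importance uses response-permutation nulls: for each
cross-validation fold, the model is fitted to the training split and the
null distribution of each feature's importance is built from 100 refits on
permuted copies of the training response.  The empirical P value is
`(1 + #{null ≥ observed}) / (1 + R)` — one added to numerator and
denominator so P is never zero (the floor at R = 100 is 1/101 ≈ 0.0099).
Features with P < 0.01 in **all** folds form the consensus selection,
ordered by mean importance (ties lexicographic).  Reported importances are
min–max normalised to [0, 1] per model.

The importance *measure* inside forests is impurity (gain) importance, the
default measure of the ranger package.  OOB permutation importance (mean
OOB-MSE increase per permuted feature) is implemented on the scikit-learn
engine and can be selected per config; the empirical-P machinery is
invariant to any monotone rescaling of the measure, so the choice affects
compute cost far more than selection.  Gain importance keeps the
permutation-null pipeline (101 forest fits per fold) tractable on one CPU.

The **empirical FDR** scrambles the feature matrix — each column permuted
independently across strains with per-column seeded streams, destroying
feature–phenotype and inter-feature structure while preserving marginals
(a joint row-permutation alternative is available) — reruns the identical
importance pipeline, and reports `FDR = n_null / n_observed`, capped at 1.0.
When nothing is selected on either matrix the statistic is reported as 0
(an empty discovery set contains no false discoveries); when the real matrix
selects nothing but the scrambled one does, 1.0 is reported with a warning.
The scrambled run repeats the full permutation-null procedure rather than
reusing thresholds — the more conservative reading.

Top-k feature lists from two models are compared by the 2×2 membership
table over the feature universe: odds ratio with a Haldane 0.5 correction
when a cell is zero, and the two-sided Fisher exact P (point-probability
rule).  GO-style over-representation of a gene selection uses the one-sided
hypergeometric tail on propagated annotations restricted to the universe,
with Benjamini–Hochberg adjustment alongside.

## Burden validation, heritability and variance explained

* **Burden test** — strains are stratified by their count of mutated genes
  in a system; strata with fewer than 5 strains are merged into the nearest
  lower stratum (Tukey needs adequately filled groups; the merge rule keeps
  the low-burden reference intact).  One-way ANOVA with Tukey's HSD
  correction compares strata.  As a reference, 1000 same-size gene sets are
  drawn (without replacement per draw) from genes *outside* the system and
  the per-stratum mean phenotype of each draw is recorded.
* **Relationship matrices** — additive GRM `K = ZZᵀ/m` from column-
  standardised genotypes (monomorphic columns dropped, logged); epistatic
  matrix `K∘K` (Hadamard square; PSD by the Schur product theorem).
* **Heritability** — REML fit of `y = μ + g_a + g_i + ε` with
  `cov(g_a) = σ²_a K`, `cov(g_i) = σ²_i (K∘K)`.  Narrow-sense heritability
  is the additive share of the total: `h² = σ²_a / (σ²_a + σ²_i + σ²_e)`.
  The two-kinship model cannot be diagonalised jointly, so the REML
  log-likelihood is evaluated by Cholesky factorisation and maximised by
  derivative-free Nelder–Mead search over log-variances from three starts
  (log parameterisation keeps variances positive; boundary solutions appear
  as numerically negligible values; non-convergence warns and returns the
  best iterate).  The single-kinship case (GBLUP δ, mixed-forest variance
  step) instead profiles the likelihood over the heritability ratio after
  one eigendecomposition.  h² is invariant to affine rescaling of the trait.
* **Variance explained** — in-sample OLS R² of the trait on the indicator
  columns of a gene set (intercept included; collinearity handled by the
  pseudoinverse).  In the pipeline, "key genes" are the genes of the top-10
  consensus systems ranked by absolute univariate correlation with the
  trait, capped at 29.

## Synthetic studies

The generator emulates the statistical structure of a natural-isolate
association panel:

* **Population** — haploid strains in `n_subpops` subpopulations; ancestral
  allele frequencies Uniform(0.05, 0.5); per-subpopulation frequencies from
  the Balding–Nichols beta model with drift parameter F
  (`Beta(p(1−F)/F, (1−p)(1−F)/F)`); binary calls sampled per strain; each
  SNV assigned a uniformly random gene (≈Poisson gene sizes), 10% of SNVs
  labelled nonsense.
* **Ontology** — a rooted random DAG with geometric level sizes set by
  (n_terms, depth, branching); each term has one parent in the level above
  plus a 20% chance of a second parent; genes attach to one leaf (10% to a
  second), so every gene is reachable from the root.
* **Phenotype** — `y = Σ_planted sign·β·burden + polygenic + subpop offset +
  noise`: per-gene effects on a random 10% of genes form the polygenic
  background (creating a non-zero heritability floor), subpopulation offsets
  are Gaussian with variance `structure_effect`, and the noise variance is
  solved so the realised genetic fraction of total variance matches
  `target_h2` (floored with a warning when structure variance alone exceeds
  the implied budget).  At `target_h2 = 0` the genetic terms are dropped
  entirely.  The output is affinely rescaled to colony-area-like pixel units
  (mean 5000, SD 800), which changes no variance ratio.  A truth record
  stores planted terms, effect sizes, per-component variances and the
  realised heritability.

Default conditions — 500 strains, 3 subpopulations, drift 0.15, 3000 SNVs
over 600 genes, a 150-term DAG of depth 4, one planted system of moderate
size with a deleterious effect of 0.5 per mutated gene, target h² 0.4,
structure variance 0.3 — describe a modestly structured panel in which the
planted system explains a large minority of the variance.  What the
generator does **not** emulate: linkage disequilibrium and recombination
maps, clonal phylogenetic relatedness beyond the block structure, diploidy
and dosage, non-coding variation, and measurement error structure of real
colony-size assays.  Passing tests therefore demonstrate correctness and
calibration of the machinery under the stated generative model, not
performance guarantees on real panels.

## Numerical and design notes

* Kinship PSD checks tolerate eigenvalues down to −1e−8 (relative).
* Empirical P, consensus filtering and FDR are pure counting — no
  asymptotics anywhere in the selection path.
* Fold assignment is identical across feature levels for a given seed, so
  SNV-, gene- and ontotype-level runs are directly comparable.
* Problem sizes in the test suite and acceptance script (hundreds of strains,
  tens to a hundred terms, 100-permutation nulls, 200-tree forests) were
  chosen as the smallest sizes at which the statistical claims are stable;
  forests in the null-replication loops use the LightGBM engine for that
  reason.
* Known limitations: the mixed forest estimates variance components on OOB
  residuals, which is slightly conservative (σ²_g absorbs some signal when
  features and kinship are correlated); the burden-test merge rule can leave
  a single merged high-burden stratum with heterogeneous counts; REML with
  two highly correlated kinships (K and K∘K on inbred-like panels) can split
  variance between them — h² reflects the additive share under that split;
  and because the synthetic study's genetic architecture is concentrated in
  one system (an OR-gate nonlinearity over few genes), the GRM-based h² of a
  simulated trait is itself a high-variance estimate at a few hundred
  strains — the calibrated check is heritability recovery under the additive
  generative model, which lands within ±0.1 of the simulated value.
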