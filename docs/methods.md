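# Methods

## Model

`cnsnv` treats SNV discovery in a tumour genome as posterior inference
in a panel of Binomial mixture models, one per discrete copy-number
state. The copy-number state `C_i ∈ {2 (NEUT/LOSS), 3 (GAIN), 4 (AMP),
5 (HLAMP)}` of every position is taken as known input (any segmentation
algorithm can provide it); deletions are analysed with the neutral
diploid state space because hemizygous loss raises identifiability
questions that two-allele genotype labels cannot express. A state of
ploidy `c` induces `K_c = c + 1` genotypes ordered by decreasing
reference-allele count; index 0 is the unique non-variant genotype.

Observed data at position `i` are the reference-matching read count
`a_i` and depth `N_i` (strand-collapsed; no base-quality weighting).
Conditional on genotype `k` in state `c`,

    a_i ~ Binomial(N_i, μ_{c,k}),

and genotypes are drawn from a state-specific prior `π_c`. The genotype
posterior follows from Bayes' rule over the `K_c` components, computed
entirely in the log domain with log-sum-exp; `p(SNV)` is the posterior
mass off the all-reference component. The MAP genotype breaks exact
ties toward the more reference-rich genotype, the conservative choice
(fewer false variant labels).

## Priors and defaults

All priors are conjugate: `π_c ~ Dirichlet(δ_c)` and
`μ_{c,k} ~ Beta(α_{c,k}, β_{c,k})`.

* Beta means: for a genotype with `r` reference alleles at ploidy `c`,
  `m = (1−ε)·(r/c) + ε·(1−r/c)` with `ε = 0.01`, a typical
  short-read mismatch rate after base-quality filtering. Homozygous
  reference is therefore nearly pure (0.99) and the means decrease
  linearly to 0.01 at homozygous variant. Encoded as `α = m·s`,
  `β = (1−m)·s` with concentration `s = 100` (a weight equivalent to
  ~100 observed reads — informative enough to pin component identity,
  weak enough for ~1000 training positions to dominate where data
  exist).
* Dirichlet pseudocounts: 1000 on the all-reference genotype, 2 on each
  variant genotype, encoding that the overwhelming majority of genomic
  positions are wild type (~99% prior weight).

All four values (`epsilon`, `concentration`, `delta_ref`, `delta_var`)
are overridable programmatically and via the CLI `--config key=value`.
These defaults are repository choices: they follow the qualitative
design of the original model family, whose exact published settings are
not recoverable.

## Fitting

Each copy-number stratum is fitted independently by MAP
expectation-maximization. Parameters start at the prior means
(deterministic; the conjugate posterior surface at this scale is
benign, and determinism simplifies validation). The E-step computes
genotype responsibilities; the M-step applies the standard conjugate
MAP updates — Dirichlet: responsibility sums plus `δ − 1`, normalized;
Beta: responsibility-weighted reference counts plus `α − 1` over
responsibility-weighted depths plus `α + β − 2`. `μ` is clamped to
`[1e-6, 1 − 1e-6]`. Iteration stops when the complete-data log
posterior (observed-data log likelihood plus log prior densities)
improves by less than `tol = 1e-6` relative, or after `max_iter = 100`
iterations; the trace is recorded and is non-decreasing by
construction, which the test suite verifies to 1e-8 slack. After each
M-step the strict decrease of `μ` along the genotype order is asserted
but not enforced; a violation is logged as a label-switching warning
rather than silently re-sorted, so pathologies stay visible. A stratum
with no usable positions keeps its prior means and is flagged in the
fit report. Positions below `min_depth` (default 1) are excluded from
fitting and emitted as no-calls rather than prior-only calls.

## Thresholding

Calls require `p(SNV) ≥ 0.77`, the operating point used for the tumour
genome this model family was developed on. The comparison is inclusive;
the threshold is configurable.

## Coordinates and formats

Positions and segment intervals are 1-based and inclusive on both ends;
abutting segments are legal, overlapping ones are rejected. Positions
outside every segment default to the neutral state (configurable).
Counts and segments are plain TSV; calls are TSV (exact round-trip via
17-significant-digit floats) or minimal VCF 4.2 with
`QUAL = −10·log10(1 − p(SNV))` capped at 255. A pysam-based pileup
extractor (mapping quality ≥ 10, base quality ≥ 20 by default) is
provided as a convenience, but the supported interface is the TSV
counts file.

## Synthetic data

The generator mirrors the model's own sampling story: per stratum, a
genotype from `π_c` (the Dirichlet prior mean, or a Dirichlet draw with
`--sample-params`), a depth from a zero-truncated Poisson (mean 30 by
default — typical whole-genome coverage; zero-depth positions carry no
information and are resampled), and a reference count from
`Binomial(N, μ)` at the Beta prior means. Truth labels record the
generating genotype and a binary variant flag (genotype ≠
all-reference). Because generator and model share one distributional
family, passing benchmarks demonstrate correct inference and the value
of the expanded state space — not robustness to alignment artefacts,
mapping bias, normal-cell admixture, overdispersion or depth
autocorrelation, none of which are emulated.

## Benchmark design

`run_simulation_study` trains on one simulated dataset (1000 positions
per stratum) and evaluates on 100 independent test sets of the same
size, reporting per-stratum trapezoidal AUC and sensitivity at false
positive rates 0.01, 0.05 and 0.1, averaged over test sets with
percentile 95% confidence intervals. Sensitivity at an FPR target uses
the step-function convention (TPR at the largest achieved FPR not
exceeding the target, no interpolation). Negatives are the positions
whose true genotype is all-reference; FPR denominators are per test
set. Test sets in which a stratum happens to contain no variant
position (expected occasionally in the neutral stratum, where variants
average ~4 per 1000 positions) have no ROC and are excluded from that
cell's average; the per-cell replicate count is reported.

The diploid comparator in the study is fitted per stratum on the same
training rows but with the neutral three-genotype space. This isolates
the contribution of the state-space expansion from training-set
composition effects and makes the two callers literally the same model
in the neutral stratum, where their metrics coincide
replicate-by-replicate. The package also provides `diploid_baseline`,
the fully copy-number-blind variant (one pooled fit with every position
forced neutral), which is bit-identical to the full pipeline whenever
all input states are neutral.

Under these conditions the benchmark regime is mild: adjacent genotype
components differ by ≈ 0.2 in expected reference fraction while a
depth-30 Binomial has an sd of ≈ 0.09 in `a/N`, so both callers operate
near sensitivity 0.99 in the five-copy stratum and the copy-number-aware
caller's advantage, though consistent in direction across essentially
every replicate, is a few tenths of a percentage point. Separating the
callers more strongly requires lower depths or tighter component
spacing than these defaults.

## Validation statistics

* Presence: the null error rate at a target is the pooled non-reference
  fraction of the ten flanking positions (five per side), floored at
  `1e-6`; pooling stabilises the estimate when per-position flank depth
  is low. The p-value is the exact Binomial upper tail
  `P(X ≥ nonref | depth, p0)`. Benjamini–Hochberg correction is applied
  within each sample's family of targets (via statsmodels); presence
  means `q < 0.01` (configurable — the threshold is a repository
  default). Somatic: absent in normal, present in a tumour sample.
  Germline: present in normal and metastatic. A greater than 10-fold
  normal-vs-metastatic depth imbalance makes the target inconclusive
  regardless of the tests.
* Skew: a 2×2 chi-squared test without continuity correction on
  (non-reference, reference) × (normal, tumour), falling back to
  Fisher's exact test when any expected cell is below 1. A site is
  flagged skewed when the BH-corrected p-value is below 0.01 **and**
  the non-reference frequencies show at least 10% disparity. The
  disparity is relative by default — `|f_n − f_t| / max(f_n, f_t)` —
  because reference panels of validated skewed germline sites include
  sites whose absolute frequency difference is below 0.10 (e.g. 0.28
  vs 0.20) while the proportional change is large; an absolute-
  difference mode is available.

## Known limitations

The Binomial likelihood is underdispersed at very high depths, letting
the reference-heavy prior dominate borderline sites; a Beta-Binomial
alternative is deliberately out of scope. Copy-number states are taken
as given — wrong segmentation propagates directly into the genotype
space. Tumour–normal joint calling, read-level simulation and
base-quality-weighted counts are out of scope.
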