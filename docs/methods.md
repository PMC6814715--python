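# Methods

This note documents the models, numerical choices and limitations behind
`chondrax`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The anabolic-axis model

The screen assumes that cartilage matrix-gene co-expression across a
reference population of inbred strains is driven by a single latent
anabolic state per strain.  The synthetic generator makes that assumption
explicit as a one-factor linear-Gaussian model

    x_{g,s} = mu_g + lambda_g * f_s + eps_{g,s},
    f_s ~ N(0,1),   eps_{g,s} ~ N(0, sigma^2),

with matrix genes loading positively (default lambda = 1), planted
regulators loading with their stated sign, and background genes loading
zero.  Under this model, PCA on the correlation matrix of the matrix genes
is a consistent estimator of f, which is why "Factor 1" extraction is
implemented as unrotated PCA on z-scored genes: the population statistical
package named by the study reports, by default, principal-component
extraction, and PCA is the only extraction for which "the first axis" is
unambiguous.  A rotation hook is deliberately not implemented — varimax of
a one-factor solution is the identity, and nothing downstream consumes more
than one factor.

Numerical conventions:

- Genes are z-scored with sample variance (ddof = 1); scores are
  re-standardized to mean 0, sample variance 1.
- Loadings are reported on the factor-analysis scale, loading_g =
  corr(x_g, scores) = v1_g * sqrt(lambda1); this makes the loading plot
  directly comparable to per-gene correlations with the axis.
- Sign convention: the axis is flipped so the mean matrix-gene loading is
  positive, which makes "negatively correlated with the anabolic axis" a
  reproducible statement.
- Missing data: correlations are pairwise-complete (>= 3 shared strains);
  PCA drops any strain with a missing matrix-gene value, because with ~16
  strains imputation is more fragile than deletion.
- Screen p-values use the exact t null, t = r * sqrt((n-2)/(1-r^2)) on
  n-2 df, two-sided; valid under bivariate normality, which the generator
  satisfies and microarray log-intensities approximate.

The intercorrelated-core rule (no published criterion exists for reducing a
candidate matrix-gene list to its tightly co-expressed core) is a greedy
backward elimination: repeatedly drop the gene with the lowest mean pairwise
correlation to the other retained genes until every retained gene's mean is
>= tau (default 0.5, exposed as a parameter).  Ties break alphabetically so
the result is deterministic.  `rank_within_category` defaults to ordering by
|r| descending, with a signed option, since either reading of "highest
correlate within a pathway" is defensible.

## Tankyrase-targeting score

TTS of an octapeptide is its summed PSSM score divided by the sum of
per-position maxima — the unique normalization under which the
per-position-argmax peptide scores exactly 1.  Matrices with negative
entries are accepted and TTS is reported unclipped (it can be negative);
the [0,1] range is guaranteed only for non-negative matrices.  Scanning
slides a stride-1 window; a window containing a non-standard residue
(X, U, B, Z, ...) is skipped and counted, without invalidating the rest of
the protein — the behavior of standard motif scanners.  A protein's max TTS
is 0 when it has no valid window, and the funnel additionally requires at
least one valid window to pass, so window-less proteins cannot pass at
cutoff 0.

The screening cutoff defaults to 0.385, the score of the weakest
well-established substrate motifs (mouse AXIN1/AXIN2); `derive_cutoff`
recomputes it from reference peptides and, if they disagree, takes the
minimum with a warning — the conservative choice that keeps every reference
above cutoff.  The published 8 x 20 matrix and the AXIN motif sequences are
external inputs and are not bundled.

MS-hit filtering reads "detected only once" as a within-replicate singleton
(spectral count < 2), because the source procedure scopes the rule per
biological replicate; proteins in any IgG-control row are excluded
outright, and retention requires detection in >= 2 biological replicates.
Motif disorder is aggregated over the eight residues by arithmetic mean
(min/max exposed), since no aggregation is stated; no disorder threshold is
applied by default — disorder is an annotation for ranking, with an
optional cutoff in the config.

## Signature filters

All fold-change thresholds written as plain numbers ("fold change > 5/3/2")
are applied on the linear scale with strict inequality; the SOX9-target
rule is applied on the log2 scale exactly as stated.  The two-contrast
cartilage signature is up-only by default (the signature is genes *higher*
in chondrocytes), with a flag to accept shared-direction changes.  Ortholog
mapping is a supplied one-to-one lookup; unmapped symbols are dropped with
a logged count.  The three-way consistency partition counts a gene as
consistent only if it is a DEG in all contrasts with one direction;
`percent` reports the consistent share of the DEG union to two decimals.

## Preranked enrichment

The enrichment score is the signed extremum (largest magnitude, earliest on
ties) of the weighted KS running sum: hits add |score|^weight normalized
over in-list set members (weight default 1; an all-zero-score set falls
back to equal increments), misses subtract 1/(N - n).  Internally the
extremum is computed in O(n_set) from the values at and immediately before
each hit — the running sum is linear between hits — and the dense trace is
only materialized on request; a test asserts both paths agree.  Ties in
scores are broken by gene id before the walk, so results are deterministic.
A set covering the whole list has no miss steps and the sum climbs
monotonically to 1; ES is reported as 1.0 with a warning.

The permutation null draws random same-size gene sets (the preranked
gene-label convention).  Two p-values are reported because the field uses
both and only one of them satisfies all calibration properties at once:

- `p` (primary): (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm), sign-blind.
  Uniform under the null, and attains exactly 1/(n_perm + 1) when the set
  occupies the top of the list.
- `p_signed`: (1 + #{same-sign |ES_perm| >= |ES|}) / (1 + #same-sign
  permutations), the classic GSEA nominal p.  Also uniform under the null,
  but its floor depends on the random sign split.

A direction-matched exceedance count over a both-signs denominator — a
formulation sometimes seen — is anti-conservative by roughly a factor of
two and is not used.  NES divides ES by the mean same-sign null magnitude.
The +1 corrections bound p away from zero.  BH correction across sets is
optional.  The SOX9-target comparison uses Welch's t (unequal variances) on
log2 fold changes, with box statistics (quartiles, 1.5 x IQR whiskers
clipped to the data).

## Synthetic data: what a green test establishes

Generators are pure functions of (spec, seed); one global seed fans out to
per-generator streams via fixed `SeedSequence` spawn keys, so adding a
generator cannot perturb existing draws.  Defaults encode the emulated
study's stated world: 16 strains, 14 matrix genes, one lambda = -0.8
regulator, sigma = 0.3; 3 biological replicates with replication-structured
noise in MS tables; planted DE signatures at FC = 10, q = 1e-8 among ~1000
background genes; ranked lists of 1000 genes with a 50-gene planted set.

Motif planting constructs a peptide at a target TTS by greedy descent from
the argmax peptide, accepting the single-residue substitution that brings
the score closest to the target; the absolute error strictly decreases, so
the procedure terminates for any level reachable at the matrix's score
granularity (+-0.02 by default).  Coarse matrices (e.g. a 0/1 consensus
matrix, granularity 1/8) only support levels near multiples of their step.

What the generators do **not** emulate: BXD kinship and linkage structure,
probe-level microarray noise, correlated multi-factor expression programs,
spectral-count abundance biases, and DE-table p/q dependence on expression
level.  A green acceptance suite therefore establishes that the pipeline's
inference is correct *under its own model assumptions* — not that those
assumptions hold in any particular real dataset, and not the study's
dataset-specific numbers (which require external accessions and the
externally published PSSM).

## Known limitations

- No downloaders: GeneNetwork/GEO matrices, the published PSSM, disorder
  profiles and pathway membership lists are user-supplied files.
- The axis screen is single-factor; multi-factor confounding (e.g. tissue
  composition) is out of scope.
- Permutation p granularity is 1/(n_perm + 1); with the default 1000
  permutations the smallest attainable p is ~1e-3.
- `select_intercorrelated` is greedy, not optimal; with adversarial
  correlation structure a different retained core of the same size can
  exist.
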