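# Methods

## Data model

The unit of analysis is the mature miRNA arm (5p and 3p counted
separately; multi-copy arms with identical mature sequence are collapsed
by summation before anything else). A dataset is an integer count matrix
(miRNA × sample) with two pieces of per-sample metadata: the *stage* (the
ordered reprogramming series MEF → Thy1− → SSEA1+ → Oct4-GFP+, plus
piPSC, iPSC and mES reference lines) and the *replicate*, which doubles
as the library-preparation batch — the two replicates are assumed to have
been prepared with different kits, producing systematic per-miRNA log
offsets between them.

## Normalization and filtering

Library-size scaling uses TMM: against a reference library, per-gene
log₂ expression ratios M and average log₂ abundances A are computed over
genes detected in both libraries; the most extreme 30 % of M (each tail)
and 5 % of A are trimmed; the scaling factor is 2 to the
inverse-asymptotic-variance-weighted mean of the surviving M values, and
factors are rescaled to geometric mean 1. The reference under `ref="auto"`
is the library whose upper-quartile cpm is closest to the mean upper
quartile. These trim fractions and the reference rule are the method's
published defaults; no installed Python package provides TMM, so it is
implemented here and was verified against Bioconductor edgeR's
`calcNormFactors` (agreement to 12 printed digits on Poisson test data).

The abundance filter keeps a miRNA if it reaches `min_cpm` (default 4)
in at least one library of **every** replicate group. The cpm used for
filtering is computed against raw column sums, not TMM-effective sizes.
The boundary is inclusive (≥ 4). log₂ cpm uses a pseudo-count prior of
0.5 in both numerator and (doubled) denominator so all-zero rows stay
finite.

## Differential expression

Counts are modeled as NB(μ, φ) with Var = μ + φμ² and log link,
log μ = offset + stage mean + replicate effect, where the offset is the
log TMM-effective library size. The design is cell-means (one indicator
per stage level, no intercept) plus replicate indicators, which makes a
two-group contrast a difference of two coefficients and its null model a
merge of the two levels. Group contrasts (e.g. MEF versus the combined
stem-cell class) relabel the member stages into one class first.

Fitting is Fisher-scoring IRLS at fixed φ, vectorized across genes (the
per-gene p×p normal equations are stacked and solved in one batched
call); linear predictors are clipped to ±30 so all-zero genes degrade to
zero fitted means and zero deviance rather than diverging. Convergence is
declared at a relative deviance change below 1e-8, with a 100-iteration
cap and a per-gene convergence flag. The implementation is cross-checked
in the tests against statsmodels' NB GLM (fixed alpha), which plays no
role in the pipeline itself.

A single **common dispersion** is estimated by maximizing the summed
Cox–Reid adjusted profile likelihood, Σ_g [ℓ_g(β̂_g(φ), φ) − ½ log det
XᵀW_gX], over log φ ∈ [log 1e-6, log 10] by bounded scalar minimization;
the CR term corrects the downward bias of plain ML when each gene spends
several degrees of freedom on its own means. Estimates at the lower bound
are reported as φ = 0 (Poisson). Tagwise/trended shrinkage is deliberately
out of scope: with thousands of genes sharing one φ the common estimate is
precise, and the acceptance checks are calibration properties (type-I
error, p-value uniformity, FDR control, power), not equality with any
particular external implementation.

Contrasts are tested by the likelihood-ratio statistic (deviance
difference of the nested fits, χ² with 1 df), two-sided; log₂FC is the
coefficient difference divided by ln 2, with no prior in the fit offsets
(the 0.5 prior appears only in the reported average log₂ cpm).
Benjamini–Hochberg adjustment is applied per contrast table
(`scipy.stats.false_discovery_control`, property-tested against a direct
step-up oracle).

Per-transition summaries count significant up/down calls at the FDR
cutoff and report the fraction of significant upregulations with
log₂FC > `large_fc` (default 5); that fraction is NaN — not zero — when
nothing is significantly up. The temporal-pattern classifier looks at the
sign sequence of significant calls over ordered transitions: a
significant down followed later by a significant up is `transient_down`
(the imprinted-cluster archetype), the mirror is `transient_up`, both
reversal orders present is `mixed`, single-direction-only is
`monotone_up`/`monotone_down`, and no calls is `stable`. Cluster
enrichment is the exact hypergeometric upper tail P(X ≥ a) on the 2×2
table of cluster membership versus DE membership, with the sample-odds
ratio; an empty DE set returns p = 1 and an undefined odds ratio.

## Profiles

Rows of the log₂-cpm matrix are centered and scaled to unit sample
standard deviation (ddof = 1); constant rows are dropped with a warning.
The most-variant selection takes a fraction of rows (default 0.5) by
descending variance, rounding half-*down* (581 rows → 290) with
lexicographic tie-breaking. PCA treats samples as observations and
miRNAs as variables (full SVD); each component's sign is fixed so its
largest-magnitude loading is positive. Plot generation is intentionally
left to the user; scores and loadings are written as TSV.

## Co-expression networks

Edge weights are the positive part of the Pearson correlation of
expression profiles across **all** samples (both replicates jointly),
with zero diagonal; anti-correlations are dropped rather than modeled by
a signed null. Partitions are scored by Newman–Girvan modularity with
the Reichardt–Bornholdt resolution term (γ scales the configuration-model
null), evaluated exactly from the weight matrix.

Optimization is greedy multi-level maximization — the Leiden refinement
of the Louvain scheme via `leidenalg`'s RBConfiguration partition — run
`n_restarts` times from seeded RNG states, keeping the best Q; this is a
standard optimizer choice, and on exhaustively enumerable graphs (n ≤ 8,
20 restarts) it attains the global optimum in ≥ 95 % of random instances.
Partition similarity is the z-Rand score: the pair count w of
co-classified node pairs standardized by its mean and variance under the
permutation null with both partitions' group sizes fixed (the closed-form
hypergeometric moments); the variance formula was verified against
permutation Monte Carlo. The **representative** partition of an ensemble
of seeded runs is the run with maximal mean pairwise z-Rand to the
others, ties broken by higher Q then lower run index.

Submodules re-run the whole construction (correlation network on the
subset, consensus) on each module's members alone; submodule letters
(1A, 1B, …) order by the stage of peak mean expression, earliest first —
the lettering rule is this package's convention. The γ sweep maps each
low-γ module onto the high-γ modules holding its members: it `splits`
when more than one high-γ module receives > 10 % of the members,
`persists` when a single module holds > 50 %, otherwise `dissolves`.
Cross-dataset comparison restricts partition pairs to shared nodes and
reports contingency tables plus z-Rand, flagging absent nodes.

## isomiRs

The 5′ offset of a read against the canonical start is signed so that
positive always means a *shortened* 5′ end: read start − canonical start
on the + strand, canonical end − read end on the − strand (half-open
coordinates). Reads farther than ±10 nt from every canonical start on
their chromosome/strand are discarded and tallied; when several
annotations are in range the smallest |offset| wins. Switching uses
the rule: a (miRNA, sample) with ≥ `min_reads` reads (default 50, a
small-count guard this package adds) is flagged when the read fraction
at |offset| > 1 nt strictly exceeds 10 %; a miRNA is *switched* when it
is flagged somewhere and its dominant start site differs between sample
groups. The seed of a shifted isomiR is nucleotides 2–8 of the shifted
read; negative offsets are rejected because the extended sequence is not
derivable from the mature sequence alone.

## Synthetic data

The generator emulates the study design: 7 stage groups × 2 replicates,
library sizes defaulting to 15 × 10⁶ and 25 × 10⁶ reads (the two kits'
order of magnitude; tests scale these down), NB counts with
edgeR-parameterized dispersion (default φ = 0.1, a typical bulk value),
per-miRNA baseline log₂ cpm uniform on (2, 9), and a per-miRNA
N(0, 0.3²) log₂ batch offset applied to replicate-2 samples. Expected
counts are lib_size × 2^(baseline + program offset + batch)/10⁶ — no
per-sample renormalization, so compositional load (e.g. the stem-cell
ramp dominating late libraries) is visible to TMM exactly as in real
data. φ = 0 draws Poisson counts; `deterministic=True` rounds the means
(zero noise), which makes worked examples exact. isomiR read allocation
is multinomial over a background distribution with ≥ 95 % of reads at
offsets {0, ±1}, overridden by planted (offset, fraction) switches per
stage group; its deterministic mode uses largest-remainder rounding.

Default programs (per-stage log₂ offsets relative to MEF) encode the
staged fold-change regime — many small-magnitude changes at the first
transition, few large ones at the last: `imprinted_down_up` (60 members,
−2.0 at Thy1− recovering to −0.2, tagged Dlk1-Dio3), `met_spike`
(10 members, +4 at SSEA1+), `stem_ramp` (15 members, +7.2 by Oct4-GFP+,
so the third-transition jump of +6 exceeds the log₂FC > 5 bar),
`decline` (30 members, −1.2 per early step), and a 185-member null
background. Members are independent given the program, so co-expression
arises solely from shared trajectories.

What the generator does **not** emulate: single-cell heterogeneity
within a stage (ensemble means only), mapping artifacts, adapter or
color-space effects, correlated noise beyond the batch term, and 3′
heterogeneity or non-templated additions for isomiRs. Recovery tests
therefore demonstrate that the estimators find the planted structure
under the assumed noise model, not that real libraries satisfy that
model.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down libraries (1–3 × 10⁶ reads) and
300–5000 miRNAs; calibration checks use 5000 all-null genes at
4 stages × 2 replicates, where the common-φ LRT's type-I error at
p < 0.05 falls in [0.04, 0.06] and BH keeps the realized false-discovery
proportion near the nominal 5 %. The module-recovery check generates at
low noise (φ = 0.02, batch sd 0.1) so the planted programs meet a median
within-program correlation of 0.8, which it asserts; under the standard
noise defaults the shallow imprinted trajectory is less coherent
(~0.6–0.7) and recovery is still typically exact but not guaranteed.
Degenerate inputs are handled explicitly: constant rows are dropped with
warnings before standardization/correlation; all-zero genes fit to zero
means with zero deviance; empty DE sets give p = 1; z-Rand of degenerate
(zero-variance) partition pairs is NaN; isolated network nodes become
singleton communities. All stochastic steps take explicit seeds, and
ensemble runs derive per-run seeds deterministically from the base seed.
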