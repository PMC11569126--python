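# Methods

This note records the models behind the package, the defaults that
matter, and the design decisions taken where more than one reasonable
reading existed.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Mechanism-integrated group-wise pre-imputation (MGpI)

**Model.**  Observed log2 intensities of gene *i* within group *k* are
treated as approximately normal, N(x̄ₖ(i), σₖ(i)²), fitted from observed
entries only (missing cells never enter any estimate).  A single global
detection floor ε is the minimum over all observed log2 values of the
matrix.  The probability that a missing value of gene *i* in group *k*
was lost to LLOD censoring is the lower normal tail at the floor,
αₖ(i) = Φ((ε − x̄ₖ(i))/σₖ(i)); its complement is attributed to MAR/MCAR.
Every missing cell of (*i*, *k*) receives the same mechanism-weighted
fill αₖ(i)·ε/2 + (1 − αₖ(i))·x̄ₖ(i) — a blend of the classical
"overall-min/2" MNAR fill and the group-mean MAR fill.

**Degenerate cells** follow the continuous limits of the blend: a group
with no observation gets α = 1 (pure floor fill ε/2); a group with one
observation uses that value as its mean and the gene's pooled
across-group SD as its spread; zero SD yields α = 1 if the mean sits at
or below the floor and α = 0 otherwise.

**Numerical choices.**
- The floor fill is ε/2 *in log space* by default (`llod_fill =
  "half_log_min"`).  The alternative reading — half the minimum linear
  intensity, i.e. ε − 1 in log2 — is available as
  `"log_of_half_linear_min"`.
- Group statistics use the ddof = 1 sample SD.
- An optional complete-gene normalization (per-sample additive offsets
  in log space matching each sample's median over fully observed genes
  to the grand median) can run before the fit; it is off by default so
  observed values pass through untouched, and the statistic
  (median/mean) is configurable.  ε is computed after normalization when
  normalization is requested, following the procedure's step order.
- A linear-space input is moved to log2 with pseudocount 1 internally
  (zeros are legal linear intensities) and returned in its input space.

**Comparators.**  min/2 operates per gene in linear space; mean, swKNN
and the four low-rank methods operate in log2 space, matching each
method's classical formulation.  swKNN weights neighbours by
1/(d + 10⁻⁶) with d the Euclidean distance over co-observed features.
The low-rank family (PPCA via EM with closed-form M-steps, NIPALS with
missing-tolerant score/loading regressions, EM-SVD, and singular value
thresholding by dual ascent with τ = 0.1·σ₁ of the mean-filled matrix
and step size 1) iterates reconstruction/overwrite until the imputed
cells move less than 10⁻⁶ (Frobenius) or 500 iterations, then restores
observed entries exactly.  Default rank: smallest rank explaining 90% of
the mean-filled variance.  PPCA requires an explicit seed.  Note that
SVT with a small τ converges to the Frobenius-regularized completion,
which is biased toward small fills; exact nuclear-norm recovery of
low-rank matrices needs τ on the order of the top singular value
(exposed as a parameter).

## Cosine one-sample tests (COT for SGs, the extension for DSGs)

The unit of analysis is the *super-sample* x(i): the vector of observed
linear-space group means of gene *i* (genes with a fully missing group
are excluded rather than silently imputed; run imputation first).  The
statistic is the maximum over the K enumerated references of the cosine
between x(i) and the reference — ê_k for SGs, its XOR complement
ê_k ⊕ 1 (zero at k, one elsewhere) for DSGs.  The max-over-k form gives
the printed ranges on nonnegative profiles: [1/√K, 1] for SGs and
[1/√(K−1), 1] for DSGs, with the lower DSG bound attained exactly by a
vertex pattern (an ideal SG is maximally non-DSG).  Ties in the argmax
resolve to the smallest group index.

**Empirical null.**  Under the assumption that the large majority of
genes obey the null hypothesis, the null distribution is approximated by
the empirical histogram of the statistics themselves; the p-value is the
self-inclusive upper-tail proportion #{tⱼ ≥ tᵢ}/N — conservative and
never zero.  Benjamini–Hochberg q-values are appended as the optional
multiplicity layer.  Two consequences are worth knowing: p-values are
exactly uniform on the ranked table by construction, so BH over the full
table is maximally conservative (q ≈ 1); and the approximation degrades
when signatures are a large fraction of the panel.  Rank and score
thresholds (`detect`) are therefore the primary selection tools.

**Baselines.**  The one-versus-rest t-test uses Welch's unequal-variance
form in log2 space (group sizes are imbalanced by design); the DSG score
is max_k(−t_k).  The one-versus-rest fold change uses linear-space means
with a pseudocount of 10⁻⁶ × grand mean; its known failure mode — a gene
silent in *several* groups still earns a huge "DSG" ratio in one of
them — is exactly what the cosine statistic fixes, and is covered by a
regression test.

## Unified heatmap layout

Eq-style summary: each gene's sample values are divided by the sum of
its group means (perspective projection onto the scatter simplex; the
projected group means of each gene sum to one), clamped below at a
single matrix-wide floor, log2-transformed, and standardized per gene by
the mean of its K log-space group means and the pooled within-group
log-space SD with *equal group weighting* — the group-centric analogue
of z-scoring.  The clamp floor defaults to half the smallest positive
projected value of the matrix, so the zero-expression origin is
data-adaptive yet identical for every gene; classical per-gene z-scoring
(provided as `classical_zscore` for comparison) breaks exactly this
property.  Rows are ordered by (assigned group, score descending, id);
columns by (group, sample-averaged cosine descending, id), where a
sample's cosine for a gene is computed on the gene's group-mean profile
with the sample's own projected value substituted into its group's slot.
The combining rule for the standardization (mean of group means, pooled
within-group SD) is not uniquely determined by the design's description;
the equal-group-weight choice matches the method's group-centric
philosophy and is configurable in code.  Between-sample normalization in
linear space remains a documented prerequisite, not performed here.

## Simulation designs

**Simplex profile design** (detection benchmark).  For K ∈ {3, 4, 5}:
1200 null profiles from the flat symmetric Dirichlet (α = 1), 1200 from
the centre-peaked Dirichlet (α = 4), 20 SGs per group clustered at the
simplex vertices and 50 DSGs per group at the facet centres.  Clusters
are "centre + zero-mean Gaussian, reflected at zero, renormalized onto
the simplex".  The cluster noise SD defaults to **0.01** for both vertex
and facet clusters: the benchmark's stated operating regime is
high-quality signatures nearly at their ideal patterns, with the hard
negatives supplied by flat-Dirichlet nulls that drift close to facet
centres; at substantially larger spreads (≈ 0.05) the signature clusters
merge into that null background and no statistic — including an oracle
on the noiseless profiles — can separate them at low false-positive
rates, which is not the regime the benchmark describes.  Profiles are
expanded to samples (10 per group by default) as mᵢ · max(0, p_ik +
N(0, 0.02²)) with per-gene magnitudes mᵢ ~ LogNormal(meanlog 5,
sdlog 1).  All of these are config fields, not constants.

**Signature panel design** (imputation benchmark).  A proteomics-style
panel: 4 groups with sizes (10, 20, 30, 10), 30 SGs per group drawn at
*exact* target cosines uniform on [0.7, 0.95] (on-target component c,
off-target mass a random nonnegative direction of norm √(1 − c²)), plus
flat-Dirichlet background genes filling the panel to 713 features.

**Missingness injection.**  Eligible entries (observed; optionally
nonzero-only for count data) are masked to an overall rate of 40–60%, of
which 30–50% is MAR; the counts are exact by construction:
n_miss = round(rate·|eligible|), n_llod = round((1 − mar)·n_miss).  In
`threshold_llod` mode the LLOD set is exactly the n_llod lowest-valued
entries (ties by position), then the MAR set is uniform over the
remainder — so a signature gene automatically loses values by LLOD in
its silent groups and by MAR in its expressed group, the pattern MGpI
exploits.  `probabilistic_llod` samples the LLOD set with logistic
weights decreasing in intensity, matched in count.  Every gene keeps at
least one observed entry (`min_observed_per_gene`, default 1): without
the guard, whole low-magnitude genes fall below the global threshold and
every per-gene method (and the evaluation itself) becomes undefined.

**What the generators do not emulate.**  Real proteomics and single-cell
data carry correlated noise across genes, batch structure, non-normal
intensity distributions, and missingness mechanisms beyond a sharp or
logistic intensity threshold.  Passing benchmarks here show that each
method behaves as designed under its stated model, and how the methods
rank under mixed-mechanism censoring — not that the same margins will
hold on any particular real dataset.

## Evaluation

RMSE and NRMSE are computed strictly over the masked set Ω, with NRMSE
normalized by the population (divisor-|Ω|) SD of the true masked values
(sample variance available by flag).  The partial ROC uses descending
scores with tied scores grouped into single diagonal segments
(order-independent), trapezoidal area over FPR ∈ [0, fpr_max] with the
crossing point interpolated.  Both the raw area and the McClish
standardization 0.5·(1 + (pAUC − min)/(max − min)) — which maps chance
to 0.5 and perfection to 1 — are reported, plus the plain ratio
pAUC/fpr_max; the standardized form is the headline number at
fpr_max = 0.05.

## Problem sizes

The bundled benchmarks run the full printed designs (2610 × 30 to
2610 × 50 matrices for detection, 713 × 70 for imputation) over ten
seeds each; both complete in seconds on one CPU, so no scaling-down of
the study conditions was needed.

## Known limitations

- MGpI assumes within-group normality of log intensities and a single
  global detection floor; heavy-tailed groups or platform-specific
  floors violate both.
- The empirical-histogram null is only as good as the "mostly null"
  assumption; panels dominated by signatures need an external null.
- swKNN is O(samples² · genes) and intended for the bulk-sized matrices
  this package targets, not for tens of thousands of cells.
- The PPCA/NIPALS/SVD/SVT implementations are matrix-completion tools,
  not full probabilistic model fits; their convergence flags should be
  checked on hard instances.
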