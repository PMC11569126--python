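# abds

Analysis tools for **biologically diverse samples** — expression matrices
whose samples belong to several distinct phenotypic groups (tissue types,
cell types, disease stages).  Three problems dominate this setting and the
package addresses each:

1. **Informative missingness.**  A signature gene is highly expressed in
   one group and near-silent in the others, so its missing values arise
   from *different mechanisms per group*: censoring below the lower limit
   of detection (LLOD, an MNAR mechanism) where it is silent, and random
   (MAR/MCAR) dropout where it is expressed.  `abds.imputation` provides
   **MGpI** (mechanism-integrated group-wise pre-imputation): within each
   group *k*, the observed log-intensities of gene *i* are modelled as
   normal with mean x̄ₖ(i) and SD σₖ(i); the LLOD probability is the lower
   tail at the global observed floor ε, αₖ(i) = Φ((ε − x̄ₖ(i))/σₖ(i)), and
   a missing cell is imputed by the mechanism-weighted blend

   ```
   x̃ₖ(i) = αₖ(i)·ε/2 + (1 − αₖ(i))·x̄ₖ(i)
   ```

   Seven classical comparators are included: half-minimum (min/2), per-gene
   mean, sample-wise weighted kNN, PPCA, NIPALS, EM-SVD, and singular value
   thresholding.

2. **Downregulated signature genes.**  A gene uniquely *silent* in one
   group (a DSG) is as informative as a classically upregulated signature
   (SG), but one-versus-rest statistics cannot see the difference between
   "low in group k" and "low in several groups".  `abds.signatures`
   implements the cosine one-sample test: with x(i) the group-averaged
   expression vector, the statistic is

   ```
   t(i) = max_k cos(x(i), r_k),    r_k = ê_k (SG)  or  ê_k ⊕ 1 (DSG)
   ```

   where ê_k ⊕ 1 is the XOR complement of the unit vector (zero at k, one
   elsewhere).  The DSG statistic is magnitude-invariant and ranges over
   [1/√(K−1), 1]; p-values come from the empirical null histogram of the
   statistics themselves.  One-versus-rest Welch t and fold-change
   baselines are provided for benchmarking.

3. **Comparable heatmaps.**  Classical per-gene z-scoring maps zero
   expression to a different negative value for every gene, so colour no
   longer ranks signature quality.  `abds.unihm` projects each gene onto
   the scatter simplex (dividing by the sum of its group means, x̂(i) =
   x(i)/Σₖ xₖ(i)), clamps at a gene-invariant floor, and standardizes in
   log space with group-centric statistics — preserving a common
   zero-expression origin across genes and ordering rows/columns by their
   cosine scores.

`abds.simulation` and `abds.evaluation` supply the ground-truth generators
(Dirichlet-mixture simplex profiles, signature panels with exact target
cosines, mixed LLOD/MAR missingness injection) and the metrics (RMSE and
NRMSE over the masked set, partial ROC/pAUC at FPR 0.05) used to
benchmark all of the above.

## Worked example

```python
from abds import (SimplexSimConfig, MissingnessConfig, simulate_dataset,
                  inject_missingness, mgpi_impute, halfmin_impute,
                  mean_impute, rmse, nrmse, score_genes, to_log2)

# 1. simulate the standard 3-group design: 2400 Dirichlet null genes,
#    20 vertex SGs and 50 facet DSGs per group, 10 samples per group
cfg = SimplexSimConfig(K=3, seed=7)
matrix, labels, truth = simulate_dataset(cfg)        # 2610 genes x 30 samples

# 2. inject 50% missingness, 40% of it MAR and the rest LLOD censoring
masked, omega = inject_missingness(
    to_log2(matrix, 1.0),
    MissingnessConfig(overall_rate=0.5, mar_proportion=0.4, seed=7))
len(omega)                                           # 39150 masked entries

# 3. impute and evaluate over the masked set
for name, res in [("MGpI", mgpi_impute(masked, labels)),
                  ("half-min", halfmin_impute(masked)),
                  ("mean", mean_impute(masked))]:
    print(f"{name:9s} RMSE={rmse(res, omega):.3f}  NRMSE={nrmse(res, omega):.3f}")
# MGpI      RMSE=1.460  NRMSE=0.714
# half-min  RMSE=2.016  NRMSE=0.986
# mean      RMSE=2.283  NRMSE=1.117

# 4. detect downregulated signature genes on the clean matrix
scores = score_genes(matrix, labels, direction="DSG", method="ecot")
scores.head(3)
# gene_id direction assigned_group    score  p_value  rank
#  g02534       DSG             G2 0.999971 0.000383     1
#  g02494       DSG             G1 0.999968 0.000766     2
#  g02603       DSG             G3 0.999961 0.001149     3
```

The RMSE/NRMSE lines show the mechanism-weighted group-wise fill beating
both single-mechanism fills; the score table ranks genes by how closely
their cross-group profile matches an ideal one-group-silent pattern (the
top 450 genes recover all 150 true DSGs in this run).

The same steps are available from the shell:

```sh
abds simulate profiles --k 3 --seed 7 --out-prefix sim
abds simulate missingness --in sim.matrix.tsv --rate 0.5 --mar 0.4 \
     --seed 7 --out-prefix simmiss
abds impute --in simmiss.masked.tsv --labels sim.labels.tsv \
     --method mgpi --out imputed.tsv
abds detect --in sim.matrix.tsv --labels sim.labels.tsv \
     --direction dsg --method ecot --out scores.tsv
abds heatmap --in sim.matrix.tsv --labels sim.labels.tsv \
     --scores scores.tsv --out-prefix hm --png
abds pipeline --seed 7 --out-dir run/           # the whole chain
```

## Layout

```
src/abds/
  matrix.py      core containers (OmicsMatrix, GroupLabels, MissingnessTruth)
  io.py          TSV/CSV/MatrixMarket readers and writers
  imputation.py  MGpI + seven comparator methods
  signatures.py  cosine SG/DSG tests, empirical null, OVR baselines
  unihm.py       unified heatmap layout
  simulation.py  ground-truth generators
  evaluation.py  RMSE/NRMSE, partial AUC, benchmark harnesses
  config.py      pipeline configuration and driver
  cli.py         `abds` command-line entry points
docs/methods.md  modelling assumptions, defaults, and design notes
```
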