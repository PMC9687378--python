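# bayesabc

Bayesian mixture normalization and computed ABC analysis for screening
cluster-of-differentiation (CD) surface-marker genes in acute myeloid
leukemia (AML) expression cohorts.

Immunophenotyping by flow cytometry rests on a small panel of CD
surface molecules. Given a gene × sample expression matrix (microarray
intensities or RNA-Seq quantifications) for AML patients and controls,
this package reconstructs the surface-marker landscape from expression
data: it discovers sample subgroups (e.g., the promyelocytic subtype
APL versus other AML) and extracts "the important few" CD genes that
discriminate each pair of subgroups — candidates for diagnostic marker
panels. It is aimed at computational biologists who want a
reproducible, parameter-explicit implementation of this analysis, with
a synthetic-data generator for validation.

## Method

1. **Pooled mixture model.** All log₁₀ expression values of a dataset
   are pooled and modelled as a Gaussian mixture

   GMM(x) = Σᵢ wᵢ N(x | mᵢ, sᵢ),  Σᵢ wᵢ = 1,

   fitted by expectation–maximization; the number of components M is
   chosen by the Akaike information criterion (AIC = 2(3M−1) − 2·logL).
   On AML expression data this yields M = 2: an "unexpressed" (low)
   and an "expressed" (high) mode. A binned χ² statistic reports
   goodness of fit.

2. **Bayes-posterior normalization.** Every expression value x is
   replaced by the posterior probability of the expressed component,
   p(c_high | x) = w_high N(x|m_high, s_high) / GMM(x) ∈ [0, 1]. The
   *decision border* is the log-expression value where this posterior
   is 0.5; it separates unexpressed from expressed genes and is also
   reported on the raw scale (10^x).

3. **Subgroup discovery.** Leukemia samples (controls held out) are
   clustered as posterior vectors with Ward's minimum-variance linkage
   on Euclidean distances; the dendrogram is cut where successive top
   fusion levels jump the most, giving K subgroups G₁..G_K.

4. **Effect statistics per dichotomy.** For every pair of subgroups
   (and each subgroup versus controls), each gene gets

   - p_deg = p̄_Gk(c_high) − p̄_Gj(c_high), the difference of
     group-average posteriors, in [−1, 1], sign = direction;
   - Cohen's D with pooled standard deviation for unequal group sizes
     and variances.

5. **Computed ABC selection.** The |p_deg| values pooled over all
   dichotomies are submitted to computed ABC analysis — a Lorenz-curve
   split of items into set A ("the important few"), B, and C ("the
   trivial many") — applied recursively three times. The smallest
   value surviving the third round (set A, or A∪B) is the selection
   threshold; genes whose |p_deg| reaches it are reported per
   dichotomy, and Cohen's D values below the threshold are zeroed in
   the published-style tables.

## Worked example

The package ships a synthetic-data generator whose default
configuration mimics an AML cohort: 417 CD genes × 190 samples (15
APL-like, 106 + 29 AML-like, 40 normal-like), bimodal pooled log
expression, 70 planted discriminating genes and 250 genes with mild
subgroup heterogeneity. A full run on that reference dataset:

```sh
$ bayesabc run --out-dir results/demo
M=2 K=3 border=2.596 threshold=0.9233
  G1_vs_G2: 41 genes selected
  G1_vs_G3: 41 genes selected
  G2_vs_G3: 49 genes selected
  G1_vs_normal: 18 genes selected
  G2_vs_normal: 26 genes selected
  G3_vs_normal: 23 genes selected
recovery vs planted truth: sensitivity=0.943 FDP=0.000
```

Reading the output: the pooled mixture got M = 2 components with a
decision border at log₁₀ x = 2.596 (raw expression ≈ 394 — values
above it count as expressed); Ward clustering of the 150 leukemia
samples found K = 3 subgroups whose contingency with the planted
labels is diagonal:

```
cluster  AML1  AML2  APL
G1        106     0    0
G2          0     0   15
G3          0    29    0
```

Recursive ABC analysis of all |p_deg| values derived the selection
threshold 0.923, and the per-dichotomy tables list the selected genes,
e.g. `results/demo/selected/G1_vs_G2.tsv` (G2 is the pure APL-like
cluster):

```
gene    pdeg     cohen_d  mean_a  mean_b  n_a  n_b
CD001  -0.992   -46.0     0.007   0.999   106   15
CD006   0.990    25.1     0.991   0.001   106   15
...
```

CD001 is definitively expressed in the APL-like cluster and absent in
AML1-like samples (p_deg ≈ −1 relative to G1); 94% of all planted
discriminating genes are recovered with no false discoveries.

Every stage is also available separately (`bayesabc simulate`,
`fit-gmm`, `normalize`, `cluster`, `deg`, `select`), reading and
writing plain TSV/JSON, and as library functions (`bayesabc.run`,
`bayesabc.fit_gmm`, ...).

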