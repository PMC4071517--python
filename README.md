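# kinscape

Individual-based tests of **isolation by distance (IBD)**, **isolation by
environment (IBE)** and **isolation by community (IBC)** for plant (or other
sessile-organism) populations genotyped with dominant binary markers such as
AFLPs.

Within a single population, genetic relatedness between individuals can
decline with geographic separation (dispersal limitation), with environmental
dissimilarity (divergent selection / local adaptation) or with differences in
the surrounding community of co-occurring species. `kinscape` quantifies and
disentangles these three signals in one regression framework:

1. **Kinship** — pairwise kinship coefficients F<sub>ij</sub> are estimated
   from band presence/absence data under Hardy–Weinberg equilibrium. The band
   frequency f at a locus gives the presence-allele frequency
   p = 1 − √(1 − f); each phenotype maps to an expected per-copy allele dosage
   x (band absent → 0, band present → 1/(2 − p)), and a Loiselle-type moment
   estimator with a small-sample correction produces a kinship matrix that is
   exactly centred on zero for an unstructured sample.
2. **Predictors** — pairwise great-circle distance ("geography"), Euclidean
   environmental distances (per variable, or one combined matrix of distances
   between PCA scores of the standardized variables), and Jaccard
   dissimilarity between the species sets of the individuals' vegetation
   associations ("community"). Predictors with variance inflation factor
   greater than 5 are removed iteratively.
3. **Multiple-matrix regression with model averaging** — the unfolded kinship
   vector is regressed on every subset of the predictor vectors (2^p OLS
   fits); submodels are weighted by AICc, w<sub>g</sub> ∝ exp(−Δ<sub>g</sub>/2),
   and each term's estimate is averaged over the submodels containing it with
   a Burnham–Anderson unconditional standard error and a 95% CI.
4. **Permutation inference** — Mantel-style permutations of the kinship
   matrix (rows and columns jointly, predictors fixed) give a null
   distribution for every averaged coefficient: z-scores, empirical p-values
   and Benjamini–Hochberg FDR control at 0.05. A term is significant only
   when its CI excludes zero **and** it survives the permutation/FDR test;
   significant negative terms are classified *isolation*, positive ones
   *counter-gradient* (individuals more related across dissimilar sites).

A fully deterministic synthetic-data generator produces landscapes with
controllable IBD/IBE/IBC signal (Gaussian random fields on the logit of
per-locus allele frequencies, environmental clines, association-level
effects, dominant Bernoulli phenotypes), so the whole pipeline is testable
and its power measurable without any field data.

## Worked example

Simulate a 60-individual dataset with a strong spatial-autocorrelation (IBD)
signal and run the three-matrix analysis:

```sh
kinscape simulate --n 60 --loci 250 --gamma-g 0.7 --seed 4 --out demo
kinscape run --genotypes demo/genotypes.csv --samples demo/samples.csv \
    --associations demo/associations.csv --mode three -B 999 --seed 4 \
    --outdir demo_run
```

which prints (columns abridged):

```
run_id            predictor  estimate       se     ci_lo     ci_hi  significant_ci          z     p     q  significant_final direction
   run            geography -0.368201 0.022119 -0.411554 -0.324847            True -18.079648 0.001 0.003               True isolation
   run environment_combined  0.011200 0.022271 -0.032452  0.054852           False   0.555719 0.532 0.734              False      none
   run            community  0.008524 0.022281 -0.035147  0.052195           False   0.331381 0.734 0.734              False      none
```

Geography has a strongly negative model-averaged coefficient (−0.37 standard
deviations of kinship per standard deviation of distance), its CI excludes
zero and the permutation p survives FDR — relatedness declines with distance,
so the term is classified **isolation**. The environmental and community
terms are indistinguishable from noise, matching how the data were generated.
Effect sizes are comparable across runs because response and predictors are
standardized to unit variance on the unfolded pair scale.

The same library surface is available from Python
(`kinscape.run_analysis`, `kinscape.SimulationConfig`, ...), and
`kinscape compare` tabulates the concordance of the D/E/C isolation classes
between the three-matrix and twelve-matrix designs of the same dataset.

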