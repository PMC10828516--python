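# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Study design being modelled

An epiHybrid panel crosses one recurrent, male-sterile wild-type
maternal line (msCol) to many paternal epiRILs.  The epiRILs descend
from a *ddm1* × wild-type founder cross: the F1 was backcrossed as a
female to the wild type and the progeny propagated through six rounds of
single-seed descent (SSD).  Each line is therefore an epihomozygous
mosaic of wild-type-methylated (MM) and *ddm1*-hypomethylated (UU)
epihaplotypes, and every hybrid family shares the same maternal genome,
so family-to-family variation can only come from the paternal
methylome.

## Pedigree simulator

The pedigree is simulated generation by generation: F1 (one all-U, one
all-M haplotype) → backcross gamete paired with an all-M wild-type
gamete → six SSD selfings, each offspring formed from two independent
parental gametes.  Recombination at every meiosis follows the Haldane
map function `r(d) = (1 − e^(−2d/100))/2` on the marker cM distances,
independently across intervals (no interference).  Exact consequences
of this process, used as test oracles:

- P(UU) at a segregating locus = 63/256 before heterozygote resolution
  and exactly 1/4 after;
- the heterozygote fraction entering resolution is (1/2)·(1/2)^6 =
  1/128 ≈ 0.78%;
- the terminal two-locus distribution follows from composing the gamete
  transition kernel, which the test suite enumerates exactly.

Residual heterozygous segments are resolved by drawing one further
gamete (the real population was propagated beyond six generations), so
linked heterozygous loci resolve coherently and two markers at zero
genetic distance always carry identical calls.

Because recombination accumulates over the backcross and the six
selfings, the terminal recombination fraction between two markers
exceeds the single-meiosis Haldane fraction of their map distance (map
expansion).  Interval mapping nevertheless uses single-meiosis Haldane
probabilities for P(genotype | flanking markers) — the standard
approximation, matching how such maps are used in practice; its only
effect here is a slightly conservative interpolation between markers.

## Marker map

The default map emulates the published 144-marker epihaplotype map: five
chromosomes with genetic lengths (180, 115, 135, 105, 160) cM and one
marker every 5 cM, which yields exactly 144 markers.  Physical
positions are linear at 200 kb/cM.  Pericentromeres default to the
middle 40% of each chromosome (no published coordinates exist for a
synthetic genome); they are part of the region configuration and are
written as BED.

## Region and methylome generator

Regions are 200 bp wide on a 50-bp step, laid out in 25 blocks of 8
overlapping regions per chromosome so that arms and pericentromere are
both represented while the total region count stays at desk scale
(1,000 regions).  A block is *segregating* with higher probability in
the pericentromere (0.30 vs 0.08), reflecting where *ddm1*-induced
hypomethylation segregates; in segregating regions msCol is methylated
and an epiRIL is unmethylated iff it is UU at the nearest marker.
Background regions are methylated with probability 0.8 (pericentromere)
or 0.3 (arms), identically in both parents, with a 1% state-call flip
noise on the paternal side.

Hybrids default to the additive expectation — MPV of the binary parents
mapped directly onto states {0, 0.5, 1}; parents are never intermediate.
Planted QTL remodel hybrid states at target regions: with probability
`penetrance` per family, a positive-effect QTL adds +0.5 (TCM) in
UU-parent families and −0.5 (TCdM) in MM-parent families (reversed for
negative effects), skipping impossible moves outside [0, 1].  An
independent 2% background non-additivity rate provides private NADs.
This rate is deliberately low so that planted, family-correlated
signals dominate the shared-NAD filters; real panels show a higher
overall NAD frequency with family-correlated structure that the
generator only produces through planted effects.

## Phenotype generator

Plant value = grand mean (100 units) + fixed covariate effects
(experiment, block, germination date) + group mean + residual.  The F1
group mean is `MPV · (1 + MPH/100)` where a family's expected MPH sums
marker effects (added to MM-parent families, matching the direction
observed at the mapped loci) and a Gaussian family effect.  Defaults
plant a 30:70 between:within family variance split (σ²_family = 30,
σ²_residual = 70, in squared MPH points), 18 siblings per group, and
three phenotype QTL of +2.7 MPH points each — jointly ≈12% of the
between-family variance.  Parents receive an independent family-level
divergence (SD 5% of the grand mean) so MPV varies across families.

## Analysis choices

- **State calling**: upstream HMM-based callers are out of scope; the
  package discretises levels at t_low = 0.2 / t_high = 0.8, resolving
  parental middle-band calls to the nearer bound (ties to methylated)
  with an ambiguity flag.
- **%MPDiv**: ratio form `(H − MPV)/MPV × 100`; at MPV = 0 (SMR-gain
  regions) it falls back to the difference form and flags the record,
  since the ratio is undefined there.
- **ORQ normalisation**: ranks (average ties) mapped to normal
  quantiles at `(rank − ½)/n`; invariant to monotone transforms.
- **LOD and p-values**: `LOD = (n/2)log10(RSS0/RSS1)`; numerically
  perfect fits are capped at a LOD 50 sentinel rather than infinity.
  Cross-trait correction converts each trait's best peak to a p-value
  via `2·ln(10)·LOD ~ χ²(1)` and applies Benjamini–Yekutieli; the
  permutation threshold and the FDR filter are applied conjunctively.
- **Peaks**: highest pseudomarker per chromosome above the per-trait
  permutation threshold, leftmost on ties; CI extends contiguously
  while LOD ≥ peak − drop (drop = 2); cM→bp by piecewise-linear
  interpolation between flanking markers.  cis requires the target
  region's body to be contained in the CI; anything else is trans.
- **Genotype coding**: MM = 0, UU = 1 everywhere, so a positive slope
  means larger trait values in UU-parent families.
- **Environmental adjustment**: the covariates are all fixed factors,
  so adjustment is fixed-effects least squares on outlier-trimmed
  (>3 SD) values, returning residuals plus the grand mean;
  rank-deficient designs fall back to the pseudoinverse.
- **Transgression**: Gaussian AIC comparison of an F1-mean-pinned-at-MPV
  model against a free-mean model; a winning free model is classed
  high- or low-parent only when the fitted F1 mean falls outside the
  parental range, otherwise the additive call is retained.
- **Variance components**: one-way method-of-moments on the ANOVA mean
  squares with the unbalanced-design n₀; negative between-family
  estimates truncate to zero with a flag.
- **Conditional EWAS**: core model = MPH ~ mapped QTL epigenotypes;
  each de novo NAD is tested by a 1-df LRT against core + NAD, BY-
  adjusted; significant NADs are clustered on PCA scores (Ward), the
  cluster count chosen by maximal average silhouette over k = 2..10
  (the published analysis reports four clusters on its data but states
  no rule), and the NAD with the largest added R² represents each
  cluster; collinear proxies are dropped greedily.
- **TMM**: implemented in-package with the standard parameters (30%
  M-trim, 5% A-trim, precision weights, reference = library with upper
  quartile closest to the mean); factors are normalised to geometric
  mean 1.  The test suite cross-checks the factors against edgeR via
  Rscript on a fixed matrix (2% tolerance).
- **Gene linking**: edge-to-edge bp distance between region and gene
  intervals, strand-ignored, cutoff 1 kb; GFF3 is converted to 0-based
  half-open coordinates at parse time.  All interval arithmetic is
  half-open; distances between intervals are 0 when they overlap.
- **Causal models**: every conditional is a Gaussian OLS regression;
  AIC = −2logL + 2k with k counting coefficients plus error variances.
  Selection competes the three directed structures (independent,
  expression-mediated, methylation-mediated); the saturated
  no-direction model is fitted and reported but excluded from the
  default competition because it nests the others and AIC would hand
  it a ~16% spurious win rate under any simple truth.  A numerically
  perfect conditional has its variance floored at 1e-12 so determinism
  contributes the same likelihood in every structure.  Ties go to the
  fewer-parameter model, then fixed order.  Selection accuracy is high
  at n = 200 with strong effects (the acceptance suite verifies ≥90%);
  at n = 36 — a realistic trio count for the omics subset — accuracy
  degrades substantially and bootstrap support values should be read
  with that in mind.
- **Quantitative-genetic contrast**: the p-integrated decomposition
  `2β_D − ½β_AxA + 2β_AxD − 2β_DxA` is treated as normative (the
  pre-integration display is typographically ambiguous); internal
  consistency is checked by Gauss–Kronrod quadrature of explicit
  polynomial integrands.  The forward simulator uses allele-count
  coding (x_A = g − 1, x_D = 1[g = 1]); under that documented coding a
  dominance-only map gives a contrast of −d independent of the
  background frequency p, which is the property the oracle asserts —
  quantitative agreement with the 2β_D scale would require the
  (unstated) effect coding behind the analytic form.

## Randomness and reproducibility

All randomness flows from one integer root seed through named
substreams (`SeedSequence` keyed by CRC-32 of the label), so stages are
reproducible independently of execution order; writers record the seed
in a header comment and the pipeline manifest records the SHA-256 of
every output.  Re-running with the same seed is byte-identical.

## Problem sizes

The default synthetic panel uses 169 lines, 1,000 regions, 144 markers,
a 2-cM scan grid and 1,000 permutations per trait; the pipeline caps
the correlation and QTL stages at 60 regions/traits to keep the demo
interactive (a few seconds end to end).  Calibration and recovery
checks use 500 null traits, 20 mapping replicates, 500 phenotype
families and 10 causal replicates per structure.

## Limitations

- The generator plants block-structured, marker-linked remodeling; it
  does not model sequence-dependent context (CG/CHG/CHH differences are
  labels only), TE mobilisation, or sRNA spreading mechanics, so
  passing tests demonstrate the statistical machinery, not biological
  realism of methylation landscapes.
- The pipeline runs stages on in-memory results of the preceding
  stages; stage flags control which artifacts are written rather than
  allowing disconnected partial runs.
- Counts are negative-binomial with a single dispersion; no
  gene-length, GC or batch structure.
- The epihaplotype map is fully observed and epihomozygous; missing or
  heterozygous marker calls are out of scope.
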