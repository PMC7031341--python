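# Methods

## The quantification model

A qPCR assay is summarized by a standard curve Cq = intercept + slope ·
log10(copies/µl), fitted by ordinary least squares to a plasmid serial
dilution restricted to a per-assay *included range* (default 10²–10⁷
copies/µl for the Frischella, Snodgrassella, Bartonella, Firm-4 and Firm-5
assays, whose lowest dilution is indistinguishable from the water control,
and 10¹–10⁷ for Gilliamella, Bifidobacterium and actin). The amplification
efficiency is E = 10^(−1/slope); a perfect doubling assay has slope
−3.32 and E = 2. The Cq of the lowest quantifiable dilution defines the
limit of detection (LOD): any measurement with a larger Cq (or no signal at
all) is recorded as `below_lod` and carries an abundance of exactly 0
through every downstream sum, mean, diversity value and test.

Quantification inverts the curve, n_raw = E^(intercept − Cq), normalizes by
the host actin signal of the same extract and rescales to copies per gut:
n_abs = (n_raw / n_actin) · median(n_actin) · 200 µl. Actin normalization
absorbs gut-size and extraction-efficiency variation; the median is taken
over the batch of samples processed together (overridable, since batch
boundaries are an analysis decision). Genome equivalents divide n_abs by the
16S operon number of the target genome; the universal bacterial assay is
reported as n_abs because operon number varies across the community.

Decisions that the underlying protocol leaves open, fixed here for
reproducibility:

* technical replicates are averaged **on the Cq scale** before conversion
  (conventional qPCR practice); a replicate set that is entirely undetected
  is undetected;
* a sample whose actin assay fails (below its LOD) cannot be normalized and
  is excluded with a warning; a sample with no actin measurement at all is a
  hard error;
* undetected wells may be encoded as an empty field, `NA`, `NaN` or
  `Undetermined` in input tables;
* abundances are kept as real numbers, never rounded;
* 16S operon numbers per phylotype are configuration with shipped defaults
  in the range reported by rrnDB-style surveys — they are placeholders, not
  measurements, and should be replaced per assay panel for real data.

## Amplicon → absolute conversion (QMP)

The pipeline consumes an already-denoised, already-annotated ASV count
table. The stage order is part of the method and is enforced by tests:

1. exclude off-target rows (mitochondria, chloroplast, eukaryotes);
2. abundance filter: keep ASVs present in ≥ 2 samples **and** with ≥ 10
   total reads (read as a conjunction of a prevalence and an abundance
   predicate; the alternative reading "≥10 reads in each of ≥2 samples" was
   rejected as inconsistent with the two-predicate filter construction);
3. collapse ASVs to phylotypes (column totals conserved);
4. proportions per sample, renormalized over the retained community;
5. absolute abundance abs_GE[s,t] = prop[s,t] · total16S[s] / loci[t],
   where total16S comes from the universal qPCR assay.

Filtering precedes collapsing because the filter operates on sequence
variants; proportions are computed after filtering. The defining identity
Σ_t abs_GE[s,t] · loci[t] = total16S[s] holds to numerical precision, and a
taxon with zero reads in a sample has abs_GE = 0 there (the amplicon LOD).

## Statistics

* **Alpha diversity** is the effective number of species exp(H) with
  Shannon H in natural log (required so that exp(H) of an S-taxon even
  community is S). Abundance *plots and PCA* use log10 — two deliberately
  distinct conventions.
* **PERMANOVA** (one-way): SS_total = Σ_{i<j} d²_ij / N, SS_within summed
  per group, pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)). Labels are
  permuted freely (no strata; the design tests bee type only). The observed
  configuration is counted: p = (#{F_perm ≥ F_obs} + 1)/(B + 1), floor
  1/(B+1) — with B = 999 the smallest p is 0.001, matching vegan's adonis.
* **Dispersion** embeds the dissimilarity matrix by principal coordinates
  (Gower centring). Negative eigenvalues of semi-metric dissimilarities
  (Bray–Curtis) are kept as *imaginary* axes: squared distance to the group
  centroid is ‖real‖² − ‖imag‖², clipped at zero when the imaginary part
  dominates numerically. The group effect on the distances is a one-way F
  with p by permutation of the distances, observed configuration counted.
* **Permutation ANOVA / t-tests**: the response is permuted B = 10,000
  times; p = max(exceed, 1)/B. The floor convention (smallest reportable
  p = 1/B = 1e-4) avoids impossible zero p-values while matching the
  "proportion of randomized statistics ≥ observed" definition. Two-group
  tests permute |Welch t| (two-sided; direction is reported separately).
  Permutations are sampled with replacement from the permutation group
  (plain Monte Carlo, not guaranteed-distinct). A constant response leaves
  the statistic undefined (0/0); by convention nothing exceeds it and p = 1,
  with a warning. Note the two conventions — add-one for the multivariate
  tests, floor-1/B for the univariate ones — are both intentional; each
  matches the R function it mirrors (vegan vs. hand-rolled randomization).
* **Pairwise comparisons**: classical Tukey HSD on the one-way fit
  (studentized range, pooled variance; Tukey–Kramer for unbalanced designs),
  verified against an R `aov` + `multcomp::glht` computation frozen into the
  tests. A permutation alternative (pairwise Welch tests with Bonferroni
  p_adj = min(1, m·p)) is provided because omnibus tests are themselves
  permutation-based.
* **PCA** is an SVD of the centred (optionally unit-scaled; default off, as
  a config switch) log10 abundance matrix, with zeros replaced by 1 before
  the log. Signs are fixed so each loading vector's largest-magnitude entry
  is positive; constant columns are dropped with a warning.
* **Welch's t** uses the plain formula; when both group variances are
  exactly zero the statistic is defined as its limit: 0 for equal means,
  signed infinity otherwise.

## What the generators emulate

`gen_hive` draws, per bee and taxon, Bernoulli(detectability) colonization
and lognormal loads 10^N(µ, σ) (genome equivalents per gut). Load
distributions are not published as distributions — only fold-changes,
prevalences and log-scale scatter — so lognormality and the σ values are
modelling choices: σ = 0.3 (log10) for core phylotypes, whose loads vary
little between bees sampled together, 0.55 for the erratic colonizers
Frischella and Bartonella, 0.35–0.45 elsewhere.

The **anchored quantities** are: winter:forager expected total-load ratio
10 (the winter means were solved analytically from the lognormal mean
formula det · 10^µ · exp((σ ln10)²/2) so the closed-form ratio is 9.97;
Firm-5 winter µ = 8.17, Bartonella winter µ = 7.55); 10–100× winter
increases for Firm-4, Firm-5, Bifidobacterium and Bartonella; a small
Snodgrassella increase; unchanged Gilliamella; reduced Frischella;
Firm-4 detectability 0.984; Frischella and Bartonella below-LOD fractions
0.269 and 0.053, applied uniformly across bee types because they are
study-wide fractions over a mixed-season dataset; winter loss of minor taxa
(Apibacter mostly gone, L. kunkeii absent) and a Commensalibacter rise. The
absolute scale (forager total ≈ 10^7.5 GE) is a free parameter; only ratios
and prevalences are anchored.

`gen_cq` inverts the quantification chain exactly — copies/µl =
GE · loci · actin/(median(actin) · 200) — and adds N(0, σ_cq) cycle noise
per technical replicate (default σ_cq = 0.1, two replicates; the recovered
log10 load then has sd σ_cq/|slope| per replicate, the delta-method value
verified in tests). True zeros are emitted as undetected; sub-LOD signals
are emitted as their Cq and censored downstream, so LOD semantics are
exercised end to end.

`gen_amplicon` draws multinomial reads with probabilities ∝ GE · loci
(default depth 27,000 reads/sample, the order of magnitude of a typical
MiSeq run after filtering), splits each major phylotype into two ASVs (70/30)
to exercise collapsing, and adds 2% organelle reads plus two spurious rare
ASVs (~0.05 expected reads/sample) that the exclusion and abundance filters
must remove. Pooled samples are arithmetic means of per-gut GE (equal-mass
pooling assumed).

`gen_colonization` encodes the gnotobiotic diet experiment: without pollen
(SW) Bartonella colonizes 75% and Frischella 45% of bees and loads are
lower and more variable; with pollen (SW+P) everything colonizes and guts
are ~2× heavier. A per-bee latent factor shared between gut weight and all
log-loads (Gaussian copula, Pearson 2·sin(πρ/6) for target Spearman ρ,
default 0.7) produces the gut-weight/load correlation; the knob is
approximate — because the factor is shared across taxa, the realized
correlation of the *total* load is somewhat above the per-taxon target.

**What passing tests do not show:** the generators draw months/bees
independently (no temporal autocorrelation over a sampling series), model
no sequence-level errors or chimeras, no inter-plate calibration drift, and
their variances are plausible placeholders. Recovery results therefore
validate the pipeline's arithmetic and statistical calibration, not
field-data robustness.

## Numerical and testing choices

* Problem sizes in the test suite (e.g. 100–1,000 simulated bees, 1,000
  null simulations at B = 499 for type-I calibration, depth 50,000 for QMP
  recovery) were chosen so each check has the statistical resolution it
  claims while the whole suite stays fast.
* QMP recovery is asserted per taxon (mean recovered vs mean true abundance
  across samples, tolerance 5% for taxa above 1% mean proportion): at depth
  50,000 the per-sample multinomial relative s.e. at a proportion of 0.01
  is 4.4%, so a per-sample 5% bound would fail by chance for taxa at the
  threshold; per-sample errors are bounded at 20% instead.
* Below-LOD censoring makes generator detectability and pipeline prevalence
  agree only because default load means sit several σ above the LOD in GE
  units (LOD_GE = lod_copies · 200/loci); profiles were checked for this.
* Bray–Curtis, rank, OLS, studentized-range and Spearman computations are
  delegated to scipy; PERMANOVA, dispersion, the permutation engine and the
  quantification chain are implemented here and cross-checked in tests
  against independent implementations (scikit-bio's PERMANOVA, classical
  one-way ANOVA, exhaustive enumeration, frozen R multcomp output).
* All randomness flows through a single `numpy.random.Generator` per call;
  identical (inputs, seed) give bit-identical results, and the full-pipeline
  manifest (config echo, seed, input SHA-256s, versions) makes runs
  byte-reproducible.

## Known limitations

* One-way designs only (the study tests bee type / treatment); no strata,
  mixed models, or multi-factor PERMANOVA.
* No rarefaction or compositional (log-ratio) alternatives; the QMP scaling
  assumes the universal assay measures the same community the amplicon
  sees.
* The dispersion test permutes raw distances (not model residuals), the
  simplest of the permutest schemes.
* NMDS and MANOVA on PCA scores are intentionally out of scope; PERMANOVA
  carries the inferential content.
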