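# Methods

This note documents the models behind `xqtlmap`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that affect results.

## The mapping model

X-QTL designs detect loci by selecting a large recombinant population on a
phenotype and comparing pooled allele/haplotype frequencies between selected
and control pools across replicates. In an 8-founder multiparental
population every locus carries one of 8 known founder haplotypes, so the
pool is summarised not by per-SNP frequencies but by an 8-vector of founder
haplotype frequencies per genomic window — a far better-conditioned object
for detecting selection, since the founders' SNP alleles are known.

### Haplotype deconvolution

Within a window, let `A` (SNPs × founders) hold the founders' REF-allele
indicators and `y` the pool's observed REF frequencies. The founder
frequency vector solves

    min ‖A h − y‖²  subject to  h ≥ 0, Σ h = 1.

This quadratic program is solved by non-negative least squares on an
augmented system: the equality constraint enters as an extra row with weight
1e6 (large enough that the constraint holds to ~1e-12 relative; the result
is clamped and renormalised, with a testable bound of 1e-6 on the simplex
sum). When `A` stacked with the sum row has rank < F the minimizer is not
unique; ridge rows √1e-6·I are then added, which selects the minimum-norm
minimizer (uniform 1/F in the fully symmetric case), and the estimate is
flagged non-identifiable. Flags propagate into the scan table so peaks
supported only by degenerate windows are visible.

Defaults and rationale:

- **Window width 1.5 cM, step 0.5 cM.** Width matches the scale at which
  linkage makes founder mosaics locally constant in these designs; the
  0.5-cM step gives 3× overlap, balancing grid resolution against cost.
- **Minimum 25 informative SNPs per window**, else the window is flagged
  and excluded from the scan. Guards the conditioning of `A`.
- **SNPs with any missing founder call are dropped** from `A` rather than
  imputed: imputation would fabricate haplotype structure.
- **Rows are not depth-weighted** by default (an optional flag-level choice
  a caller can implement by pre-scaling); at the coverages these designs
  use, depth variation contributes little relative to pool sampling noise.
- **Minimum per-pool depth 5 reads** for a SNP to contribute a frequency.

### The genome scan

Estimated frequencies are variance-stabilised with ASF = arcsin(√h) and
each window is analysed with the balanced three-way ANOVA

    ASF ~ Treatment + Haplotype + Treatment×Haplotype,

testing MS(Treatment×Haplotype) against MS(Replicate×Treatment×Haplotype)
— replicates are blocks, and the error term asks whether the
treatment-by-haplotype pattern is consistent across replicates. With r
replicates, 2 treatments and 8 haplotypes, df = (7, 7(r−1)). The
implementation computes the balanced decomposition directly from cell means
(vectorised across windows); the test suite checks it to 1e-10 against an
independent projection-based oracle.

Replicates with duplicate (A/B) control pools contribute the average of the
two frequency estimates per window, keeping the r × 2 layout balanced
(policy `average`; `first` and `error` are available). The same machinery
re-run with the A/B label as the treatment factor gives an empirical-null
scan: if haplotype estimation is accurate, duplicate pools from the same
population should never produce a signal.

The −log10(P) series is LOESS smoothed per chromosome in cM coordinates:
tricube weights over the nearest span·n windows, local polynomial of
degree 2, evaluated at each window center. The default span is **5 cM**
converted to a per-chromosome fraction. The span was chosen so that
smoothing suppresses single-window noise but does not flatten peaks of the
1–3 cM width that strong viability loci produce; at 10 cM the smoother
measurably eroded such peaks in simulation (costing 1–1.5 −log10 units at a
planted locus), so the smaller default was adopted and the parameter left
config-exposed. Whether smoothing should run per chromosome or genome-wide
is a genuine open choice; per chromosome was adopted so chromosome ends do
not borrow strength across linkage groups.

Peaks are local maxima of the smoothed series at or above the fixed
threshold −log10(P) = 4 (the threshold comparison is inclusive: a boundary
value is called). The fixed threshold plays the role of multiplicity
control — p-values are not otherwise adjusted — and its justification is
empirical: the package's null-calibration study (see below) measures the
genome-wide false-positive rate it implies. Each peak's confidence interval
extends outward to the first window center whose smoothed value is at least
3 units below the peak (or to the terminal window); no interpolation
between window centers is attempted, since the window grid is much finer
than interval widths. Candidate peaks falling inside a stronger peak's
interval merge into it. Intervals where the local recombination rate
(finite differences on the genetic map) is below 0.5 cM/Mb for the majority
of windows are flagged low-recombination: such peaks implicate physically
enormous regions and are reported separately rather than suppressed.

### Per-founder frequency change

At any window, Δ_f = mean over replicates of (h_f selected − h_f control)
(duplicate controls averaged first). Because every estimate lies on the
simplex, ΣΔ = 0; the founders driving a QTL appear as the large-|Δ|
entries, with sign giving the direction of selection.

## Phenotype statistics

- **Emergence** is the fraction of a vial's eggs that produced adults
  within the 30-day observation window; flies not emerged by day 30 are
  treated as not emerged, never as day-30 emergers. The emergence ANOVA
  uses vial-level fractions (the vial is the unit of replication);
  fractions are not transformed by default, matching how such models are
  usually reported, though callers can pre-transform.
- **Development time** is per-fly egg-to-adult days (1–30); its ANOVA uses
  fly-level observations by default because the measurement unit is the
  individual adult. Vial-mean analysis is possible by aggregating first.
- **Factorial ANOVA**: two-way fixed-effects with interaction via OLS
  (statsmodels). The interaction direction for 2×2 designs is the sign of
  (knockdown: zinc−water) − (control: zinc−water), the slope-difference
  reading of an interaction plot.
- **RNAi hit rule**: with k control genotypes (default 4), a construct is a
  hit for a phenotype iff at least one interaction p is below the strict
  level 0.05/(constructs × controls × phenotypes), all k are below 0.05,
  and all k interaction directions agree. The rule is monotone in every
  p-value. Experimental batch is accepted as an optional covariate but
  omitted by default — the factorial layout already randomises genotypes
  over batches, and adding a batch main effect changes none of the
  package-level conclusions on synthetic data.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes —
not fly biology:

- **Founder panel**: biallelic SNPs on a cM-jittered grid; founder alleles
  iid Bernoulli(1/2) with monomorphic draws resampled, so essentially all
  SNPs are informative (the informative fraction is configurable).
- **Base population**: each individual is an independent founder mosaic;
  crossovers per homolog ~ Poisson(generations × length in Morgans),
  positions uniform in cM (no interference), founder segment labels iid
  from the base-population founder weights. This matches the first and
  second moments a neutrally mixing population accumulates, without
  simulating the pedigree. Founder weights default to a Dirichlet(α = 1)
  draw per chromosome, emulating the strong departure from uniform 1/8
  frequencies that multiparental base populations show; the generation
  count (default 33) and weights are config-exposed because real designs
  vary in both.
- **Viability selection**: per-copy multiplicative genic selection. An
  individual's fitness factor is Π over loci and over its two homologs of
  (1 + s_founder), clamped at zero; survival probabilities are rescaled to
  hit the target survival fraction (default 0.07) in expectation. The
  per-copy form was chosen over averaging the two copies' effects because
  it makes s a standard genic selection coefficient: the first-order
  frequency change of a haplotype is exactly p·q·s, and s = −1 is a true
  dominant lethal. Selection is multiplicative across loci; no epistasis.
- **Sequencing**: per-SNP depth ~ Poisson(mean coverage); each read
  samples a uniformly random member homolog and flips with the error rate
  (default 0.001), implemented as the equivalent binomial draw.
- **Design**: 12 replicates; per replicate an egg cohort sized so expected
  survivor counts land in the configured pool range (default 190–476; the
  studies below fix 300) is selected, all survivors form the selected
  pool, and a fresh matched-size cohort forms the control pool; replicates
  in the duplicate set (default 5 of 12) get a second independent control
  pool, giving the 29-pool layout. All randomness flows through named
  streams derived from one master seed recorded in the truth object.

What it deliberately does not emulate: founder sequence evolution
(alleles are drawn, not descended), larval density or dose–response,
linkage disequilibrium structure inherited from the RIL construction
(mosaic segments are iid in founder label), sex (female-only pools make the
X effectively autosomal here, so all chromosomes are simulated diploid),
mapping/SNP-calling artefacts, and index hopping or other library
artefacts. Passing tests therefore demonstrate that the estimator and scan
behave correctly when their model assumptions hold, and calibration results
transfer to real data only to the extent those assumptions do.

## Simulation studies and problem sizes

`xqtlmap.studies` packages three repeated-simulation studies, run at a
desk scale chosen to keep hundreds of repetitions tractable on one CPU
while preserving the factor structure and degrees of freedom of the
full-size design (one 50-cM chromosome, ~2,000 informative SNPs, pools of
300, 12 replicates):

- **Null calibration**: 200 neutral experiments; the fraction whose
  genome-wide max smoothed −log10(P) reaches 4 estimates the false-positive
  rate of the fixed threshold (observed: 0% with the development seeds,
  against the ≤5% design target).
- **Power/localization**: 100 experiments with one planted QTL (one founder
  at base frequency 0.25 with s = +0.5, 67× coverage); measures detection,
  peak-to-truth distance (≤1 cM), and the sign of the favoured founder's
  frequency change.
- **Duplicate-pool null**: 100 experiments with 5 duplicate-control
  replicates; the A/B contrast should stay below threshold.

## Numerical conventions

- Frequencies within −1e-9 of 0 are clamped to 0 and vectors renormalised;
  every returned haplotype vector satisfies Σh = 1 ± 1e-6, h ≥ 0.
- ANOVA sums of squares below 1e-20 of the total variation are structural
  zeros (identical inputs give F = 0, p = 1 exactly, rather than a 0/0
  rounding artefact); a zero error mean square with nonzero interaction
  yields p floored at 1e-300 with a warning, keeping −log10(P) finite.
- The −log10(P) grid keeps NaN entries for windows excluded by filters, so
  scan tables stay aligned with the window grid.
- TSV outputs use 1-based inclusive physical coordinates; BED output is
  0-based half-open; bp ↔ cM conversions interpolate the genetic map
  linearly between anchors (the inverse returns the left edge inside
  zero-recombination stretches).
- Degenerate LOESS neighbourhoods (all distances zero) return the local
  mean; a span providing fewer points than polynomial coefficients is a
  configuration error.

## Known limitations

- Windows are estimated independently; no smoothing of haplotype
  frequencies across windows (deliberate — the scan smooths the statistic,
  not the estimates).
- The factorial phenotype ANOVAs assume homoscedastic Gaussian errors;
  emergence fractions near 0 or 1 violate this, and the arcsine option (or
  a GLM outside this package) is advisable in extreme regimes.
- The simulator's iid-segment mosaics understate long-range founder
  correlations present in RIL-derived populations, which mildly flatters
  localization accuracy.
- Effect sizes are reported only as Δ frequency vectors; no per-founder
  effect estimation or fine-mapping within intervals.
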