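# Methods

`metabopk` implements the analysis chain of a single-dose
pharmacometabolomics study: a cohort of healthy volunteers receives one oral
dose of a drug; plasma drug concentrations are sampled over time for
non-compartmental pharmacokinetics (NCA); untargeted LC-MS metabolomics is
run on paired samples at baseline (pre-dose) and at the time of maximum drug
concentration (post-dose), with pooled quality-control (QC) injections
interleaved; and the differential metabolites are related to the PK
parameters and to clinical/laboratory traits through a signed
distance-correlation network with community discovery. Because studies of
this kind rarely publish raw data, the package ships a synthetic-study
generator with exported ground truth, and every stage is validated by
recovery of what was planted.

## Synthetic study generator (`simulate`)

**Pharmacokinetics.** Concentration–time profiles follow the one-compartment
oral-absorption model

C(t) = F·D·k_a / (V·(k_a − k_e)) · (e^(−k_e·t) − e^(−k_a·t)),

the simplest model consistent with the single-dose parameter set the
pipeline estimates; the analysis stages never assume it. Population defaults
are calibrated to the reference regime of a 500 mg dose in healthy adults:
k_e = 0.09 h⁻¹ (elimination), k_a = 1.3 h⁻¹ (absorption), V = 11.5 L,
F = 1, which give an analytic Tmax ≈ 2.2 h and Cmax ≈ 35.6 µg/mL.
Between-subject variability is lognormal with CVs 0.30 (k_a), 0.22 (k_e,
matching an SD of 0.02 h⁻¹ around 0.09), 0.20 (V); assay noise is
multiplicative lognormal with CV `noise_cv` (default 10%). Draws with
k_a ≈ k_e (the model's removable singularity) are rejected and resampled.
The default sampling grid (0–48 h, 20 points) covers more than three
population half-lives, which the config validates. Note that the published
regime this calibration targets is not jointly satisfiable by a
one-compartment model: matching Cmax ≈ 35.5 µg/mL and k_e = 0.09 h⁻¹
implies AUC0–48 ≈ 480 h·µg/mL, larger than the reported AUC0-t. Only the
Kel/Cmax/Tmax regime is treated as a calibration target.

**Feature matrix.** Intensities are multiplicative:
lognormal per-feature baseline (log₁₀ intensity uniform on [4, 7]) ×
pre/post effect × association term × injection-order drift × noise.

* *Differential features* (default 70 of 2000): the post-dose sample is
  multiplied by e^δ with |δ| uniform on [0.5, 1.5] natural-log units and a
  random sign. At the default noise level this is a ≥ 2-SD effect on the
  paired-difference scale.
* *Planted associations* (default 10): chosen among the differential
  features (the network stage only sees differential metabolites, so an
  association planted elsewhere would be unrecoverable by design, not by
  failure). Targets are drawn from the smoothly estimable PK parameters
  (AUC0-t, Cmax, Kel, T1/2) and the quantitative traits. Tmax is excluded
  as a target: its measured counterpart is the argmax on the sampling grid,
  a coarse discretization that cannot carry a planted continuous
  association (it still enters the network as a tested node). Two
  functional forms alternate: *linear* — the multiplier is affine in the
  parameter, anchored at the cohort minimum for positivity and rescaled to
  cohort mean one so it neither shifts the pre/post contrast nor breaks the
  noiseless Pearson r = ±1; and *rank-monotone* — multiplier
  e^(±0.5·z), which exercises the regime where distance correlation
  detects what a linear statistic understates.
* *Drift*: each feature gets a monotone trend plus a low-frequency sine in
  injection order, applied as e^(g) with amplitude set by
  `drift_magnitude` (default 0.3) — the multiplicative smooth-drift
  structure QC-based corrections assume.
* *QC injections* start from the per-feature mean of all study samples
  before drift and noise, so correction quality is measurable against an
  exact target. One pooled QC precedes every block of `qc_interval`
  (default 10) study injections and one closes the run.

**Traits.** Sex (Bernoulli ½) plus a 12-variable clinical panel (age
28 ± 6.8 y, BMI 24.2 ± 2.7 kg/m², blood pressure, lipids, liver enzymes,
renal and hematological measures) drawn normal around those centers.
Hemoglobin and hematocrit are generated with r = 0.9 — one deliberately
correlated trait pair, so tests must confront induced (non-planted but
real) associations. PK parameters are likewise mutually dependent
(T1/2 = ln2/Kel exactly), so "retained edges ⊇ planted edges" is the
correct recovery expectation, not set equality.

**Pathways.** A GMT database of 20 pathways with sizes uniform on
[5, min(150, n_features)]. The first pathway is planted: 10 of its 12
members are differential features, an overlap whose exact hypergeometric
tail is < 1e-10 under the defaults. In null configurations (no
differential features) the planting degrades gracefully and no enrichment
is claimed.

**Randomness.** One integer seed; each stage draws from its own
`SeedSequence` sub-stream, so outputs are byte-identical across runs and
stable under partial re-runs.

What the generator does **not** emulate: m/z–retention-time structure,
adducts/isotopes, censoring at the detection limit, correlated feature
blocks (beyond the planted structure), batch effects other than smooth
drift, and missing injections. A green recovery test therefore establishes
correctness of the statistical machinery on data satisfying its stated
assumptions — not robustness to raw-data pathology, which is upstream of
this package's scope.

## Non-compartmental PK (`pknca`)

AUC0-t is the linear trapezoid over all observed points (a lin-up/log-down
variant is available; which one the field's closed-source tools used in any
given report is usually unstated, and the difference is ~1% at this
sampling density). Cmax/Tmax are the observed maximum and its time. Kel is
−slope of the OLS fit of ln C on t over a terminal window that starts
strictly after Tmax and **ends at the last measurable observation**; among
window lengths ≥ 3 the highest adjusted R² wins, with ties within 1e-4
resolved toward more points — the conventional automated "best fit" rule.
A free-floating window search (any contiguous interior window) was
evaluated and rejected: with 10% multiplicative noise, short interior
windows reach adjusted R² ≈ 1 by luck, and because only negative slopes
qualify, the selection systematically steepens, biasing cohort-mean Kel by
up to 18%; the anchored rule stays within ~2%. Trailing zeros are treated
as below the quantification limit for the terminal fit only; zeros before
Tmax are true zeros. An undefined Kel (too few terminal points, or no
negative slope) yields NaN Kel/T1/2, flagged and excluded pairwise from
cohort summaries — never an exception.

## Preprocessing (`preprocess`)

Fixed chain order: drift correction → zero imputation → IQR filter → QC-RSD
filter → log+Pareto, matching the order in which these steps are applied in
untargeted workflows (filters on corrected raw intensities, transforms
last).

* **Drift correction** (default `loess`): per feature, a LOWESS curve of QC
  intensity vs injection order, interpolated to all injections, normalized
  to mean one over the QC injections, divides every intensity. The span is
  chosen once per matrix by leave-one-out cross-validation on the QC
  points, pooled over a subsample of ≤ 200 features. Reference workflows
  use a random-forest QC correction (SERRF); the contract is the same —
  remove smooth QC-anchored multiplicative drift — and `median-ratio` and
  `rf` alternatives are selectable. Flat or all-zero QC features pass
  through unchanged; fitted curves are floored at 1e-6 so output stays
  non-negative.
* **Imputation**: zeros become half the smallest positive value of the
  *original full matrix* (the literal global reading of the half-minimum
  rule), nothing else changes.
* **IQR filter**: the ⌊0.10·n⌋ features with the smallest interquartile
  range across *study* injections are dropped (QC excluded so pooled
  samples cannot mask biological variance); ties resolve by row order.
* **RSD filter**: features with QC relative standard deviation
  (100·sd/mean, sample SD) above 20% are dropped; zero-mean features are
  dropped and flagged.
* **Scaling**: log₁₀, then Pareto — center and divide by √sd, statistics
  over study injections (QC columns are carried along on the study scale);
  constant features become all-zero and are flagged. The container records
  that it is on the analysis scale and refuses a second transform.

## Differential abundance (`diffabund`)

The paired two-timepoint design is blocked exactly by within-subject
differencing: per feature, post − pre differences are regressed on an
intercept plus mean-centered subject-level covariates (sex, age, BMI, study
period). Centering keeps the intercept equal to the covariate-adjusted mean
paired difference. A duplicate-correlation mixed model adds nothing for two
timepoints and one block level. Singular designs raise with the collinear
columns named; subjects missing a timepoint are dropped with a warning.

Variances are moderated empirically: s² is modeled as s₀²·F(d, d₀); (d₀,
s₀²) come from the closed-form method of moments on log sample variances
(digamma/trigamma bias corrections, Newton inversion of the trigamma), and
posterior variances s̃² = (d₀·s₀² + d·s²)/(d₀ + d) give moderated t on
d₀ + d degrees of freedom. When the spread of log variances is no more
than chance under a common variance, d₀ = ∞ and every s̃² collapses to
s₀² = exp(mean(e)) — note this is the common s² *times the chi-square
log-bias correction* exp(log(d/2) − digamma(d/2)), not s² itself; the
normal reference is used for the resulting statistic. All-zero variances
fall back to ordinary t with a warning. Selection is BH-FDR ≤ 0.05;
NaN p-values are excluded from ranking and propagate as NaN q.

Two ionization modes, when present, are two independent matrices: test
within mode, BH within mode, pass the union downstream.

## Enrichment (`enrich`)

One-sided upper-tail hypergeometric (≡ one-sided Fisher) per pathway,
testable when database size ∈ [5, 150] and ≥ 1 selected hit; BH across
tested pathways; sorted by (q, p, id). The background universe is the
measured features (post-preprocessing) that occur anywhere in the database
— the defensible default when the reference tool's background is
version-dependent and unstated — with an override to use the whole
database. Membership counts inside the test are taken within the
background, so the 2×2 table is internally consistent. Sources
(KEGG/Reactome/WikiPathways-style labels) are kept as a column; cross-source
near-duplicate pathways are *not* merged, mirroring how multi-source
databases report.

## Association network (`network`)

For each differential metabolite × parameter pair (parameters = the five PK
parameters plus quantitative traits), the V-statistic sample distance
correlation is computed from double-centered Euclidean distance matrices:
dCov² = mean(A∘B), d = dCov/√(dVarX·dVarY), with d := 0 for constant
input. The sign is the sign of Pearson's r on the same values; |r| < 1e-10
is flagged ambiguous (e.g. y = x² on a symmetric design) rather than
guessed.

Significance is a permutation test of d (permuting the parameter across
subjects), exact per pair, with BH across the entire metabolite × parameter
grid of one timepoint — the conservative reading when the FDR's scope is
unstated. Permutations are shared across metabolites within a parameter,
which is what makes the grid affordable (the permuted parameter's centered
distance matrix is the expensive object). **Permutation resolution:** the
smallest achievable p is 1/(B+1); with m simultaneous tests and k true
edges, BH needs p ≲ α·k/m, so B must exceed m/(α·k). The default
B = 4999 resolves q < 0.05 for ~10 true edges among ~900 tests, where the
conventional B = 999 mathematically cannot (min q = 0.001·900/10 = 0.09).

Edges are retained when d > 0.5 **and** q < 0.05. Graphs are tripartite by
construction and validated structurally: metabolites are the only
connectors; PK–PK, trait–trait, PK–trait and metabolite–metabolite edges
are forbidden. The network is computed at both timepoints — pre-dose pairs
baseline abundances with traits *and* PK parameters (an absent pre-dose PK
association is a computed result, not an assumption); post-dose uses the
Tmax-sample abundances.

Communities come from the Leiden algorithm (igraph/leidenalg,
RB-configuration objective, resolution 1.0, fixed seed) on the d-weighted
graph; the sign is an attribute, not a weight, because modularity is
ill-defined for negative weights. Isolated nodes are dropped before
partitioning; module ids are renumbered by descending size for stable
reports. Reported Q is the weighted Newman modularity.

## Integration (`report`)

A left join of retained edges onto enriched-pathway membership: one record
per edge with the metabolite's module and every enriched pathway containing
it; metabolites in no enriched pathway are kept and flagged, since the
interesting output shape includes exactly such entries. Fully disjoint id
spaces raise, as that indicates a mapping misconfiguration rather than an
empty result. The report is a pure function of its inputs (byte-identical
on re-run).

## Numerical choices and degenerate inputs

* Permutation p-values use the add-one estimator (1 + #{d* ≥ d})/(1 + B)
  with a 1e-12 tolerance on the ≥ comparison; they are super-uniform under
  the null by construction.
* dCov² is clipped at 0 before the square root (it can be −1e-17 in
  floating point).
* Adjusted-R² tie tolerance in the terminal fit: 1e-4.
* BH is delegated to `statsmodels.multipletests` with NaN handling wrapped
  around it; hypergeometric tails to `scipy.stats.hypergeom.sf`.
* Leiden runs `n_iterations=-1` (to convergence) with an explicit seed;
  identical seed ⇒ identical partition.

## Known limitations

* The generator plants associations at the post-dose timepoint only, so the
  default pre-dose network is null; trait-associated baseline structure
  would need additional planting.
* The LOESS drift correction assumes ≥ 5 QC injections and smooth drift;
  step changes (batch boundaries) are better served by the `median-ratio`
  method per batch, which the pipeline does not automate.
* The moderated model assumes (after log transform) roughly Gaussian
  within-pair noise; heavy-tailed contamination would call for the robust
  moderation variants deliberately left out of scope.
* Runtime of the network stage grows linearly in B and in the number of
  parameters; at the default B = 4999 a 60 × 18 grid takes a few seconds
  on one CPU.
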