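# Methods

This note documents the models and procedures the package implements, the
choices made where conventions differ between software traditions, and what
the synthetic-data generators do and do not emulate.

## Spectral processing

The processing chain is fixed in order: **bin → PQN → noise filter → glog →
mean-centred PCA**.  Each stage consumes the previous stage's matrix.

**Binning.**  Bins are half-open intervals [lo, lo + w) tiled upward from the
range minimum (default 0.2–10 ppm, w = 0.005 ppm).  A bin's value is the
*sum* of the intensities of the grid points it contains; summation preserves
total signal under grid refinement, unlike averaging, and makes the binned
value independent of the acquisition grid density for well-resolved peaks.
Bins whose centre lies inside an exclusion window are dropped; with the
default residual-water window (4.38–5.22 ppm) both edges coincide exactly
with bin edges, and 168 of the 1,960 tiled bins are removed, leaving 1,792
candidates.  Partial overlaps are resolved by the centre rule.

**Probabilistic quotient normalization.**  The per-sample dilution factor is
estimated as the median of the ratios of the sample's bins to a reference
spectrum, restricted to bins where the reference is positive, and divided
out.  The default reference is the median spectrum across samples — the
canonical choice when no pooled QC spectrum is available.  When samples are
exact scalar multiples of a common profile (zero noise), PQN removes the
scalars exactly; the test suite asserts this to 1e-10.  PQN is idempotent on
dilution-structured data; on arbitrary matrices a second pass can still move
samples slightly because the reference itself changes, which is a property
of the method, not of this implementation.

**Noise filter.**  The noise floor is a per-spectrum quantity: threshold =
k × sd of that sample's bins inside the signal-free region (defaults: k = 3,
region 9.5–10 ppm).  The sd uses the sample (n−1) convention.  A bin is kept
iff at least `min_samples` (default 10) samples exceed *their own* threshold
in that bin.  The number of retained bins can only decrease.

**Generalized logarithm.**  glog(y) = ln(y + √(y² + λ)), default
λ = 1.38 × 10⁻⁹, natural log.  It is strictly increasing, defined for all
real y (normalized spectra can contain small negatives), and has the
analytic inverse y = (e^g − λe^{−g})/2.  For y < 0 the direct expression
cancels catastrophically in floating point, so the implementation evaluates
ln λ − ln(√(y²+λ) − y) there; the round trip is then exact to machine
precision over the full intensity range.

**PCA.**  Columns are mean-centred; scores and loadings come from the
covariance eigendecomposition (via SVD).  Sign convention: the
largest-magnitude loading of each component is made positive.  Explained
fractions are relative to total variance, so a truncated summary sums to
≤ 1.

**Technical reproducibility** is summarised as the median over retained bins
of 100 × sd/mean across technical replicates (sample sd; zero-mean bins
skipped).

## Discrimination

**Model.**  PLS-DA is partial-least-squares regression of a dummy-coded
class response on the processed matrix: two classes use a single 0/1
response with a 0.5 decision threshold, more classes one-hot coding with
argmax.  The engine is an in-package NIPALS implementation (mean-centring,
regression-mode deflation) whose predictions match
`sklearn.cross_decomposition.PLSRegression` to numerical precision (exact
for a single response); the test suite keeps sklearn as the independent
cross-check.  A compact engine matters because the permutation study below
refits the model tens of thousands of times.

**VIP.**  Variable importance on projection,
VIP_j = √( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ), with SS_a the response
variance captured by component a.  Mean VIP² over variables is identically
1; the tests assert the identity on every fitted model.

**Cross-validation.**  Venetian blinds: sample i (in current order) joins
fold i mod k; each repeat re-randomizes the sample order with the seeded
generator, so "repeated" cross-validation has genuine replication despite
the deterministic pattern.  k defaults to 7 and is configurable (the
calibration study uses k = 5 with 20 samples, giving folds of 4).  A repeat
whose training split loses a class is redrawn with bounded retries.  Errors
are balanced error rates — the mean over classes of each class's
misclassification fraction, which generalizes the two-class average of
false-positive and false-negative rates to multi-group comparisons.

**Forward selection.**  Variables are ranked by VIP; prefixes of size
1..min(p, cap) are each cross-validated, and the smallest prefix attaining
the minimum BER is selected.  The cap (default 50) bounds cost and is
configurable.

**Permutation test.**  Class labels are shuffled; the *entire* chain — PLS
fit, VIP ranking, forward selection, cross-validation — is rerun on the
permuted labels, and the permuted optimal BER recorded.  Re-running the
selection inside the null is essential: the observed BER is optimised over
prefixes, and a null that skips selection would be stochastically larger,
inflating the type-I error.  The p-value is the paper-of-record convention
#{permuted BER < observed}/n_perm with strict inequality and no +1
correction; the conventional (b+1)/(m+1) estimator is available via
`plus_one=True`.  Because BERs are discrete, ties between permuted and
observed errors make the strict-inequality p conservative.

**Component count**, when not supplied, is chosen by CV BER over
1..min(10, rank) before selection and recorded in the result.

## Population genetics

**Distances.**  AMOVA uses the absolute number of pairwise nucleotide
differences (the standard Arlequin-style choice for haplotypic data);
divergence summaries and D_a use the uncorrected p-distance.  Sites with N
or a gap are excluded pairwise, never listwise; polymorphic-site counts
ignore ambiguous states.

**Diversity.**  H_e = n/(n−1)(1 − Σ p_i²) over haplotype frequencies;
π is the mean pairwise per-site difference proportion; both are invariant to
sequence order.

**AMOVA.**  Sums of squared pairwise differences are decomposed into
among-group, among-population-within-group and within-population components
with the standard unbalanced-design expected-mean-square coefficients;
Φ_ST = (σ²_a+σ²_b)/σ²_T, Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c).  A brute
force plain-Python evaluation of the same identities serves as the oracle in
the tests (agreement to 1e-10 on every small fixture).  Zero total variance
(monomorphic data) reports Φ = 0 with a warning rather than NaN.  Negative
component estimates are possible and are reported as computed; a population
compared against its exact copy, for example, has the finite-sample value
Φ_ST = −1/(m−1) because between-population averages include zero
self-distances.

**Permutation nulls** (upper tail, p = fraction of permuted Φ ≥ observed,
default 10,000): Φ_ST permutes individuals among populations; Φ_SC permutes
individuals among populations within their group; Φ_CT permutes whole
populations among groups.  With few populations the Φ_CT null is coarse —
six populations in three groups admit only 90 distinct regroupings — so its
p-values are bounded below and the test is conservative; this is a property
of the design, not the implementation.

**Tree and network.**  The population tree is neighbour joining
(scikit-bio's implementation; negative branch lengths truncated to zero) on
D_a = D_xy − (π_X + π_Y)/2, optionally rooted on an outgroup.  The haplotype
network is a minimum-spanning *network* over mutational-step counts:
Kruskal-style construction in which every edge of a weight class that joins
two components distinct at the class boundary is retained, so equal-weight
ties all survive (a cycle where a spanning tree would break one).  A
configurable connection limit (default unlimited) removes long edges and can
disconnect the network — a deliberate, documented simplification of the
statistical-parsimony connection criterion, which is not implemented.

**Accession workflow.**  `fetch_genbank_sequences` +
`trim_to_common_region` + the analysis surface above reproduce the
deposited-data workflow (download, trim to the common clean region, collapse,
AMOVA).  It requires live access to GenBank; no sequence data ships with the
package.

## Trend fitting

Ordinary least squares for the linear and quadratic forms, compared by
AIC = n ln(RSS/n) + 2(k+1) with k fitted coefficients (+1 for the error
variance).  Ties break toward fewer parameters, and an exact fit of both
forms (data on a line) therefore selects the linear form.  AICc
(`corrected=True`) adds the small-sample correction; with six populations it
is the appropriate criterion — plain AIC retains a ~16% (asymptotic, worse
at n = 6) probability of selecting a spurious quadratic under a true linear
model, so the package's recovery study runs under AICc.  The reported r is
the sign-adjusted √R² for the linear form and the multiple correlation for
the quadratic; residual df = n − k is reported alongside, and p comes from
the regression F test.

## Synthetic data

The generators provide controllable ground truth, not physical realism.

* **Spectra** are sums of Gaussian peaks (truncated at 4σ) on a ppm grid —
  defaults: 8 peaks with concentrations spanning 15–100 units over
  0.2–10 ppm, 2 groups × 10 samples.  Group effects multiply designated
  metabolite concentrations by effect^g for group g.  A per-sample dilution
  factor is drawn log-uniformly (default 0.7–1.4) so PQN has a well-defined
  multiplicative artefact to remove, and i.i.d. Gaussian noise
  (default sd 1.0 intensity unit) is added.  Not emulated: lineshape
  distortions, phase and baseline errors, J-coupling, peak-position jitter,
  correlated biological variation between metabolites, or tank/replicate
  structure.  Passing tests therefore demonstrate correctness of the
  statistical machinery under clean multiplicative/additive artefacts, not
  robustness to real spectral pathology.
* **Haplotypes** come from a template-based mutation placer, not a
  coalescent: an ancestral sequence (default 598 bp, matching a COI
  amplicon), one derived haplotype per group (`between_group_mutations`
  exact substitutions at distinct sites), one private haplotype per
  population on top of its group template (`within_pop_mutations`
  substitutions), individuals drawn uniformly from the population's
  two-template pool (default 3 regions × 2 populations × 10 individuals).
  The distinct-haplotype count is therefore bounded by the number of
  templates, and estimated Φ_CT rises monotonically with the between-group
  mutation count — the properties the tests exercise.  No recombination,
  homoplasy beyond chance collisions, or realistic site-frequency spectra.
* **Clines** are value = β₀ + β₁·lat + β₂·lat² + N(0, σ) at six latitudes
  spanning the 42–70° N study transect.

All generators draw every random quantity from a single
`numpy.random.Generator` seeded per call; fixed seed means bit-identical
output.

## Study problem sizes

The packaged reproducibility studies (`littorina.studies`, also run by
`scripts/acceptance.py`) use desk-scale sizes chosen as the smallest designs
that give the binomial intervals meaning: permutation-test calibration runs
100 datasets × 200 permutations per arm (null and 3× effect) with the
generator defaults above; trend recovery runs 200 clines per arm (strong
curvature: β₂ = 0.05, σ = 0.1; null: β₂ = 0, σ = 2) under AICc; the Φ_CT
sweep uses 20 replicates per divergence level.  The field campaign the
defaults emulate was larger (≈ 30 extracts per site × treatment, 10,000
AMOVA permutations); all sizes are plain function arguments.

## Known limitations

* The exact statistical-parsimony connection probability for the haplotype
  network is not implemented; the step-limit approximation is documented
  above.
* Hierarchical AMOVA assumes every population is assigned to exactly one
  group; nested designs deeper than two levels are out of scope.
* PLS-DA assumes more variables than components and at least two samples per
  class in every training fold; the CV machinery redraws degenerate folds
  rather than stratifying.
* The spectra reader expects a ppm/intensity table or pre-binned matrix;
  vendor raw formats (FID processing, Fourier transform, phasing) are out of
  scope.
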