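# Methods

`epistascape` analyzes how a small set of mutations in an allosteric
transcription factor reshapes its dose-response behaviour, using the 4-site
TtgR inducer-specificity switch as the motivating system. Genotypes are
binary strings over the mutable loci (0 = wild-type residue, 1 = mutant;
for TtgR the left-to-right order is positions 137, 141, 167, 168). The
2^n genotypes form a hypercube whose edges are single mutations.

## Dose-response model and functional parameters

Reporter fluorescence as a function of ligand concentration x is modelled
with the Hill equation

    f(x) = F_baseline + (F_max - F_baseline) * x^n / (EC50^n + x^n)

fit by weighted nonlinear least squares (`scipy.optimize.curve_fit`) to
per-concentration replicate means, with replicate standard deviations as
sigma. Zero sds (single replicates, identical values) are replaced by the
curve's median positive sd so such points are neither infinitely trusted
nor dropped. Initialization uses the observed curve ends for F_baseline and
F_max, the geometric mean of the nonzero concentrations for EC50, and n = 1;
bounds keep all parameters positive and n within [0.1, 10], with up to five
jittered restarts before a fit is flagged non-converged. Two quality flags
are reported rather than censored: `saturated` is false when the top assayed
concentration is below 2 x EC50 (the plateau, and hence EC50, is then poorly
constrained), and `ec50_identifiable` is false for flat curves.

Four functional parameters summarize each (variant, ligand):

* **basal** — observed replicate mean at 0 uM;
* **maximum** — observed replicate mean at the *highest assayed*
  concentration (250 uM resveratrol / 2000 uM naringenin by default), not
  the fitted asymptote, so non-saturating curves are summarized by what was
  measured;
* **fold induction** — maximum / basal, with the ratio error propagated
  from the two replicate sds;
* **EC50** — from the Hill fit, sd from the covariance diagonal (recorded
  in the fit JSON metadata).

Before fitting, raw values can be divided by the fold change of a
constitutive sfGFP positive control at the same concentration (mean over
its six replicates, relative to its own 0 uM mean), which removes
ligand-dependent fluorescence effects unrelated to the regulator.

## Landscapes and fitness

A `ParameterLandscape` holds one parameter's value and sd for all 2^n
genotypes. Fitness for the decomposition is `log10(value / wild-type
value)`: order-preserving, zero at wild type, symmetric in fold changes.
Standard deviations are carried into log space with the delta method
(sd / (value ln 10)); this is used for display and Monte-Carlo setup only.

## Viable pathways

A pathway from wild type to an endpoint adds one mutation per step. A step
u -> v is viable when the parameter moves toward the endpoint: for an
endpoint above the start, `value(v) >= (1 - tol) * value(u)`; mirrored for
decreasing landscapes. The tolerance (default 0, typically swept to 0.25)
is multiplicative on the raw parameter scale per step; the raw rather than
log scale was chosen because a fractional "loss of function" reads most
naturally as a ratio of raw values, and the chosen scale is recorded in the
output metadata. Ties are viable at zero tolerance (weak inequality), a
deliberate tie-break that makes the rule deterministic at exact equality;
measured data have no exact ties. The endpoint is configurable, including
an `auto` mode that targets the landscape's global optimum, because on some
parameters the optimum is not the full mutant. Enumeration is exhaustive
over the d! mutation orderings, which is exact and trivially cheap for
d <= 6; tests cross-check it against an independent graph traversal.

## Interaction decomposition

The landscape is expanded in the orthonormal (Bahadur/Walsh-type) basis of
+/-1 interaction terms: with z_i = -1 for wild type and +1 for mutant at
locus i, the term for locus subset S is phi_S(x) = prod_{i in S} z_i(x),
ordered by cardinality then lexicographically. Coefficients are the exact
projection w_S = 2^-n sum_x f(x) phi_S(x); no regularization is used
because the design is complete and orthogonal. Truncating at a maximum
interaction order and computing R^2 against the data quantifies how much of
the landscape is explained by additive, pairwise, and higher-order effects;
the full-order reconstruction is exact (R^2 = 1) up to floating point, and
the terminal profile value is snapped to 1.0 when within 1e-9.

R^2 is the coefficient of determination (1 - SS_res/SS_tot), not the
squared Pearson correlation; for these projection reconstructions the two
coincide (both are reported by the verbose API), and the determination form
guarantees monotonicity in the included order.

Each of the C(n,2) * 2^(n-2) two-locus subnetworks (background, two single
mutants, double mutant) is scored the same way with n = 2 and fitness
recomputed relative to the subnetwork's *own background*. The background
convention is required for backgrounds other than all-zeros and treats
every square identically; it is a package choice, documented here rather
than inferred.

## Epistasis classification

On the log scale the interaction term of a square is
eps = f11 - f10 - f01 + f00. Significance is a two-sided z-test on eps with
a delta-method sd (corners independent), alpha = 0.05 by default; with all
sds zero the test reduces to |eps| above float tolerance. Insignificant
squares are "none"; otherwise the category follows sign behaviour of the
two single-mutation effects across backgrounds: both flip -> reciprocal
sign, exactly one flips -> sign, neither -> magnitude. Zero effects count
as no flip (determinism at boundaries). The classification is invariant to
relabeling the two loci. The first-order subnetwork R^2 and its Monte-Carlo
CI are reported alongside as a complementary, continuous epistasis measure;
the z-test is authoritative for the category.

## Uncertainty

Monte-Carlo error propagation samples each variant's parameter from
Normal(mean, sd) on the raw measurement scale (the scale on which the sds
were estimated), recomputes log fitness, refits the coefficients on the
sampled landscape, and scores the truncated reconstruction against that
same sampled landscape; the default is 500 draws. Sampled values <= 0
(where the log is undefined) are floored at 1e-6 times the smallest
landscape mean and counted in the output rather than resampled, keeping
draws independent. Each draw consumes a child stream spawned from the seed
(`numpy.random.SeedSequence`), so results are bit-reproducible and
parallel-safe. A raw-scale versus log-scale sampling switch is exposed via
the landscape transform; raw is the default.

The R^2 distribution is summarized by a 95% bias-corrected bootstrap
interval of its mean (10,000 resamples by default). "Bias-corrected
adjusted" is implemented as BCa — bias correction z0 from the fraction of
bootstrap means below the estimate, acceleration from the jackknife — with
a plain bias-corrected (BC) variant as a switch, since the phrase is
ambiguous between the two. Constant samples yield a degenerate (c, c)
interval. The implementation is checked against `scipy.stats.bootstrap`'s
BCa interval in the test suite.

Two different intervals answer two different questions. The BCa interval of
the mean is a precision statement about the Monte-Carlo summary itself: it
shrinks like 1/sqrt(draws) and does *not* widen with measurement noise. The
2.5-97.5% spread of the Monte-Carlo R^2 samples is the parameter-uncertainty
interval; on synthetic landscapes it covers the noise-free first-order R^2
about 90% of the time at 1% CV (verified in the test suite), with the
shortfall from nominal reflecting the mild bias of scoring a sampled model
against sampled data. Both are available from `MonteCarloResult`.

## Synthetic data generator

The generator runs the analysis chain backwards so every stage can be
tested against known truth:

1. a true fitness landscape is specified by interaction coefficients (the
   expansion used generatively); the helper `random_coefficients` draws
   Gaussian coefficients whose magnitude decays geometrically with
   interaction order (factor 0.5 per order, first-order scale 0.4 in log10
   units), reflecting landscapes dominated by low-order effects;
2. fitness is realized as Hill parameters around a wild-type-like anchor
   (basal 100 AU, F_max 3000 AU, EC50 50 uM, n = 2; about 29-fold induction
   at the top of the resveratrol series). Exactly one functional parameter
   carries the fitness signal per dataset (a mode switch), keeping ground
   truth unambiguous. In fold-induction and maximum modes F_max is adjusted
   so the *observed* top-concentration readout hits the target exactly; in
   basal mode the whole curve is scaled (fold induction stays constant); in
   EC50 mode EC50 is scaled directly. The constant coefficient is not
   identifiable through the pipeline, since log-relative fitness pins wild
   type to zero; recovery tests compare non-constant coefficients;
3. measurements are drawn as hill(x) * (1 + eps), eps ~ Normal(0, CV),
   with CV 5% by default (multiplicative noise matches how flow-cytometry
   median fluorescence scales). Defaults mirror the real assay: the 12-point
   naringenin (0-2000 uM) and resveratrol (0-250 uM) series, 3 biological
   replicates with an optional top-up to 6 for variants whose sd exceeds
   10% of the mean, and a 6-replicate constitutive control with an optional
   linear drift ramp.

The generator does not emulate cytometer event-level distributions, gating,
growth effects, or replicate correlations; passing tests demonstrate that
the analysis recovers truth under the stated noise model, not that the
model captures every feature of real flow-cytometry data.

## Problem sizes and numerical choices

The test and acceptance workloads use n = 4 (the system's size): 16
variants, 24 subnetworks, 24 pathway orderings. Recovery sweeps use 100
seeds at CV 2% for coefficient recovery and 50 seeds per category (about
0.01 relative noise) for classification; Monte-Carlo determinism is checked
at the default 500 draws / 10,000 bootstrap iterations. Orthogonality is
verified up to n = 8. Hill refits on noise-free curves recover parameters
to better than 1e-6 relative error; full-order reconstruction errors are at
machine precision (< 1e-10).

## Known limitations

* The pathway rule is a deterministic viability filter; no origin-fixation
  or probabilistic weighting of trajectories.
* Higher-than-pairwise epistasis is quantified through the R^2-by-order
  profile but not categorized.
* The significance criterion for calling a subnetwork epistatic (z-test on
  eps) is one defensible choice among several; reported epistatic fractions
  depend on it.
* Non-saturating curves yield imprecise EC50 values; they are flagged, not
  censored, and downstream landscape values inherit that imprecision.
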