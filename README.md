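# epistascape

Fitness-landscape and epistasis analysis for combinatorial variants of
allosteric transcription-factor biosensors.

When a few binding-pocket mutations jointly switch a regulator's inducer
specificity — the motivating system is a 4-mutation switch in the TtgR
repressor — the interesting questions are combinatorial: how does each of
the 2^4 = 16 mutational intermediates respond to each ligand, which of the
4! = 24 mutation orderings could evolution actually traverse, and how much
of the landscape is shaped by epistasis rather than additive mutation
effects? `epistascape` implements that analysis end to end for anyone
working with dose-response data over a complete set of combinatorial
variants: protein engineers mapping biosensor design space and molecular
evolution groups studying epistatic constraint.

## What it computes

1. **Dose-response parameterization.** Per variant and ligand, reporter
   fluorescence is normalized by a constitutive sfGFP control and fit to
   the Hill equation
   `f(x) = F_baseline + (F_max − F_baseline)·x^n/(EC50^n + x^n)`,
   yielding four functional parameters: fold induction (maximum/basal),
   basal expression, maximum expression, and EC50.
2. **Parameter landscapes.** Each parameter's values over all 2^n genotypes
   form a hypercube landscape; fitness is `log10(value / wild-type value)`.
3. **Viable pathways.** Mutation orderings from wild type to an endpoint
   are viable when every step moves the parameter toward the endpoint,
   optionally tolerating a bounded per-step loss (e.g. 25%).
4. **Interaction decomposition.** The landscape is expanded exactly in the
   orthonormal ±1 (Bahadur/Walsh) basis: with z_i = −1 for wild type and
   +1 for mutant, coefficients are `w_S = 2^-n Σ_x f(x)·Π_{i∈S} z_i(x)`,
   and R² of order-truncated reconstructions quantifies additive, pairwise
   and higher-order contributions. Every 2-locus subnetwork (background,
   two singles, double) gets a first-order R².
5. **Epistasis classification.** Each subnetwork's interaction term
   `ε = f11 − f10 − f01 + f00` is z-tested; significant squares are
   labelled magnitude, sign, or reciprocal-sign epistasis by whether the
   single-mutation effects change sign across backgrounds.
6. **Uncertainty.** Measurement sds propagate into R² by Monte-Carlo
   resampling (500 draws) summarized with BCa bootstrap 95% intervals
   (10,000 iterations), all seeded and bit-reproducible.

A synthetic-data module generates dose-response datasets with known ground
truth (true interaction coefficients → Hill parameters → noisy replicate
measurements on the real assay's concentration series), so the entire
pipeline is testable without external data.

## Worked example

```python
import epistascape as ep

# simulate a 16-variant resveratrol assay with known interaction structure
coeffs = {(0,): 0.30, (2,): 0.25, (0, 2): 0.20,
          (1,): -0.04, (3,): 0.05, (1, 2): 0.10}
assay = ep.AssaySpec(ligand="resveratrol", cv=0.02, seed=11)
data, truth = ep.simulate_dataset(coefficients=coeffs,
                                  mode="fold_induction", assay=assay, seed=11)

landscape = ep.analyze(data, "resveratrol")["fold_induction"]

for tol in (0.0, 0.25):
    spec = ep.PathwaySpec.from_landscape(landscape, end="1111", tolerance=tol)
    res = ep.enumerate_viable_paths(landscape, spec)
    print(f"viable paths at {int(tol*100)}% tolerance: {res.count} of {res.total_paths}")

basis = ep.build_basis(4)
fitness = ep.bahadur_fitness(landscape)
model = ep.fit_coefficients(fitness, basis)
print("R2 by max order:", {k: round(v, 3) for k, v in ep.r2_profile(model, fitness).items()})
print("pairwise 137x167 coefficient:", round(model.coefficient((0, 2)), 3))
print("categories:", ep.summary_counts(ep.classify_all(landscape)))

mc = ep.monte_carlo_r2(landscape, max_order=1, draws=500, seed=11)
print(f"first-order R2 = {mc.mean:.3f}, 95% CI [{mc.ci_low:.3f}, {mc.ci_high:.3f}]")
```

Output:

```
viable paths at 0% tolerance: 4 of 24
viable paths at 25% tolerance: 12 of 24
R2 by max order: {1: 0.756, 2: 1.0, 3: 1.0, 4: 1.0}
pairwise 137x167 coefficient: 0.202
categories: {'none': 16, 'magnitude': 2, 'sign': 4, 'reciprocal_sign': 2}
first-order R2 = 0.756, 95% CI [0.755, 0.756]
```

Reading this: the deleterious I141W mutation closes most strict pathways
(4 of 24 orderings remain); tolerating 25% per-step losses reopens 8 more.
Additive effects explain 76% of the fold-induction landscape; including
pairwise terms explains it fully, and the planted C137I×M167L interaction
(true coefficient 0.20) is recovered as 0.202 from noisy data. Eight of the
24 subnetworks are significantly epistatic, including the sign and
reciprocal-sign squares induced by the I141W×M167L interaction.

The same pipeline is available from the shell:

```sh
epistascape simulate --out sim --seed 7
epistascape fit --input sim/data.csv --out params.tsv
epistascape landscape --params params.tsv --parameter fold_induction \
    --ligand resveratrol --out land.tsv
epistascape paths --landscape land.tsv --tolerance 0.25 --end 1111
epistascape bahadur --landscape land.tsv --subnetworks
epistascape classify --landscape land.tsv
epistascape mc-r2 --landscape land.tsv --draws 500 --bootstrap 10000 --seed 17
```

See `docs/methods.md` for the model details, defaults, and numerical
choices.

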