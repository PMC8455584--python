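import io

import numpy as np
import pytest

from epistascape.bahadur import build_basis, fit_coefficients
from epistascape.dose_response import curves_from_frame, read_long_csv
from epistascape.epistasis_classify import classify, compute_effects
from epistascape.genotype_space import Genotype, enumerate_genotypes, enumerate_subnetworks
from epistascape.landscape import bahadur_fitness
from epistascape.pipeline import analyze, fit_dataset, landscapes_from_parameters
from epistascape.synthetic_data import (
    AssaySpec,
    DEFAULT_ANCHOR,
    HillParams,
    TrueLandscapeSpec,
    hill_params_from_fitness,
    landscape_from_coefficients,
    random_coefficients,
    simulate_assay,
    simulate_dataset,
    top_up_replicates,
)

G = Genotype.from_label


class TestLandscapeFromCoefficients:
    def test_intercept_only_gives_constant(self):
        spec = TrueLandscapeSpec(3, {(): 2.0})
        fitness = landscape_from_coefficients(spec)
        assert all(v == pytest.approx(2.0) for v in fitness.values())

    def test_pairwise_term_checkerboard(self):
        w = 0.7
        spec = TrueLandscapeSpec(2, {(0, 1): w})
        fitness = landscape_from_coefficients(spec)
        assert fitness[G("00")] == pytest.approx(w)   # (-1)(-1)
        assert fitness[G("11")] == pytest.approx(w)
        assert fitness[G("10")] == pytest.approx(-w)
        assert fitness[G("01")] == pytest.approx(-w)

    def test_round_trip_through_projection(self, rng):
        coeffs = random_coefficients(4, rng)
        spec = TrueLandscapeSpec(4, coeffs)
        fitness = landscape_from_coefficients(spec)
        basis = build_basis(4)
        model = fit_coefficients(fitness, basis)
        for subset, value in coeffs.items():
            assert model.coefficient(subset) == pytest.approx(value, abs=1e-12)

    def test_invalid_subset_rejected(self):
        with pytest.raises(ValueError):
            TrueLandscapeSpec(2, {(0, 5): 1.0})


class TestHillParamsFromFitness:
    def test_zero_fitness_reproduces_anchor(self):
        fitness = {g: 0.0 for g in enumerate_genotypes(4)}
        params = hill_params_from_fitness(fitness)
        assert all(hp == DEFAULT_ANCHOR for hp in params.values())

    def test_plus_one_fitness_is_tenfold_fold_induction(self):
        fitness = {g: 0.0 for g in enumerate_genotypes(2)}
        fitness[G("11")] = 1.0
        params = hill_params_from_fitness(fitness, mode="fold_induction", top_concentration=250.0)
        top = 250.0
        fi = {g: float(hp.predict(top)) / hp.f_baseline for g, hp in params.items()}
        assert fi[G("11")] == pytest.approx(10.0 * fi[G("00")])

    @pytest.mark.parametrize("mode", ["fold_induction", "basal", "maximum", "ec50"])
    def test_log_relative_parameter_matches_fitness_exactly(self, mode, rng):
        fitness = {g: float(rng.normal(0, 0.5)) for g in enumerate_genotypes(4)}
        top = 250.0
        params = hill_params_from_fitness(fitness, mode=mode, top_concentration=top)
        wt = G("0000")

        def readout(hp):
            if mode == "fold_induction":
                return float(hp.predict(top)) / hp.f_baseline
            if mode == "basal":
                return hp.f_baseline
            if mode == "maximum":
                return float(hp.predict(top))
            return hp.ec50

        for g, hp in params.items():
            got = np.log10(readout(hp) / readout(params[wt]))
            assert got == pytest.approx(fitness[g] - fitness[wt], abs=1e-9)

    def test_non_finite_fitness_rejected(self):
        with pytest.raises(ValueError):
            hill_params_from_fitness({G("0"): float("nan"), G("1"): 0.0})


class TestSimulateAssay:
    def test_zero_cv_replicates_equal_hill_means(self):
        params = {G("0"): DEFAULT_ANCHOR, G("1"): HillParams(50.0, 4000.0, 25.0, 1.5)}
        assay = AssaySpec(cv=0.0)
        df = simulate_assay(params, assay)
        for (variant, _), curve in curves_from_frame(df).items():
            hp = params[G(variant)]
            for x, vals in curve.points.items():
                assert np.ptp(vals) == 0.0
                assert vals[0] == pytest.approx(float(hp.predict(x)))

    def test_sample_cv_matches_target_on_average(self):
        params = {G("0"): DEFAULT_ANCHOR}
        cvs = []
        for seed in range(200):
            assay = AssaySpec(cv=0.05, replicates=3)
            df = simulate_assay(params, assay, rng=np.random.default_rng(seed))
            data = df[~df.is_control]
            stats = data.groupby("concentration_uM")["fluorescence"].agg(["mean", "std"])
            cvs.append((stats["std"] / stats["mean"]).mean())
        assert 0.03 < np.mean(cvs) < 0.07

    def test_csv_round_trip_lossless(self, tmp_path):
        df, _ = simulate_dataset(seed=4)
        path = tmp_path / "data.csv"
        df.to_csv(path, index=False)
        back = read_long_csv(path)
        assert back.shape == df.shape
        assert np.allclose(back["fluorescence"], df["fluorescence"])
        assert curves_from_frame(back).keys() == curves_from_frame(df).keys()

    def test_control_series_present_with_six_replicates(self):
        df, _ = simulate_dataset(seed=4)
        ctrl = df[df.is_control]
        assert set(ctrl.groupby("concentration_uM").size()) == {6}

    def test_deterministic_under_seed(self):
        a, _ = simulate_dataset(seed=12)
        b, _ = simulate_dataset(seed=12)
        assert np.array_equal(a["fluorescence"], b["fluorescence"])

    def test_top_up_adds_replicates_for_noisy_variants(self):
        params = {G("0"): DEFAULT_ANCHOR}
        assay = AssaySpec(cv=0.25, replicates=3, seed=3)
        rng = np.random.default_rng(3)
        df = simulate_assay(params, assay, rng=rng)
        topped = top_up_replicates(df, params, assay, rng)
        reps = topped[~topped.is_control].groupby(["variant", "concentration_uM"]).size()
        assert set(reps) == {6}


class TestEndToEnd:
    def test_noise_free_pipeline_recovers_fitness(self):
        rng = np.random.default_rng(21)
        coeffs = random_coefficients(4, rng)
        assay = AssaySpec(cv=0.0)
        df, truth = simulate_dataset(coefficients=coeffs, mode="fold_induction",
                                     assay=assay, seed=21)
        land = analyze(df, "resveratrol")["fold_induction"]
        recovered = bahadur_fitness(land)
        true_fit = truth["record"]["fitness"]
        wt_true = true_fit["0000"]
        for g, f in recovered.items():
            assert f == pytest.approx(true_fit[g.label] - wt_true, abs=1e-9)

    def test_noisy_pipeline_recovers_first_order_coefficients(self):
        # CV 2%: first-order coefficients land within 3 propagated sds of
        # truth in >= 90% of seeded runs
        basis = build_basis(4)
        hits = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            coeffs = random_coefficients(4, rng)
            assay = AssaySpec(cv=0.02, seed=seed)
            df, truth = simulate_dataset(coefficients=coeffs, mode="fold_induction",
                                         assay=assay, seed=seed)
            land = analyze(df, "resveratrol")["fold_induction"]
            model = fit_coefficients(bahadur_fitness(land), basis)
            # delta-method sd of each coefficient from per-variant log-sds
            log_sd = np.array([
                land.sd(g) / (land.value(g) * np.log(10)) for g in basis.genotypes
            ])
            coef_sd = float(np.sqrt((log_sd**2).sum()) / 16)
            ok = all(
                abs(model.coefficient((i,)) - coeffs[(i,)]) < 3 * coef_sd
                for i in range(4)
            )
            hits += ok
        assert hits / runs >= 0.90

    def test_epistasis_categories_recovered_when_well_separated(self):
        # squares with |eps| >= 5 sd classified correctly in >= 95% of runs
        cases = {
            "none": {(0,): 0.4, (1,): 0.3},
            "magnitude": {(0,): 0.4, (1,): 0.35, (0, 1): 0.15},
            "sign": {(0,): 0.4, (1,): 0.1, (0, 1): 0.3},
            "reciprocal_sign": {(0, 1): 0.5},
        }
        sub = enumerate_subnetworks(2)[0]
        correct = total = 0
        for category, coeffs in cases.items():
            for seed in range(40):
                rng = np.random.default_rng(seed)
                fitness = landscape_from_coefficients(TrueLandscapeSpec(2, coeffs))
                values, sds = {}, {}
                for g, f in fitness.items():
                    v = 10.0 ** f
                    noisy = v * (1 + rng.normal(0, 0.01))
                    values[g.label] = noisy
                    sds[g.label] = 0.01 * v
                from conftest import make_landscape

                land = make_landscape(values, sds=sds)
                eff = compute_effects(land, sub)
                if category != "none" and abs(eff.interaction) < 5 * eff.interaction_sd:
                    continue  # only score well-separated squares
                call = classify(eff)
                total += 1
                correct += call.category == category
        assert total > 60
        assert correct / total >= 0.95
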