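"""Mixed-effects estimation: OFV oracle checks, fitting, selection, validation ops."""

import math

import numpy as np
import pytest

from teicopk import (
    CovariateEffect,
    Dataset,
    DoseEvent,
    PopulationModel,
    StructuralParams,
    bootstrap,
    compute_diagnostics,
    conc_at,
    covariate_step,
    fit,
    ofv,
    pcvpc,
)
from teicopk.cohort import Observation, SubjectRecord
from teicopk.population import typical_params

from _oracles import quadrature_ofv_1d

TV = {"CL": 1.03, "V1": 20.1, "Q": 3.12, "V2": 101.0}
DOSES = [DoseEvent(t, 400.0, 1.0) for t in (0.0, 12.0, 24.0, 48.0, 72.0)]
TIMES = [24.0, 48.0, 72.0, 73.0]

FAST_FIT = dict(multi_start=1, maxiter=120, exclude_blq=False)


def _one_subject_dataset(eta_cl: float, noise_seed: int, sigma2=0.030276):
    rng = np.random.default_rng(noise_seed)
    p = StructuralParams(TV["CL"] * math.exp(eta_cl), TV["V1"], TV["Q"], TV["V2"])
    f = np.asarray(conc_at(p, DOSES, np.asarray(TIMES)))
    y = f * (1 + rng.normal(0, math.sqrt(sigma2), size=f.shape))
    sub = SubjectRecord(id=1, covariates={"GFR": 71.88}, doses=DOSES,
                        observations=[Observation(t, c) for t, c in zip(TIMES, y)])
    return Dataset(subjects=[sub]), y


class TestOfv:
    @pytest.mark.parametrize("eta_seed", [(0.3, 11), (-0.5, 12), (0.0, 13)])
    def test_matches_gauss_hermite_quadrature_1d(self, eta_seed):
        """IIV on CL only: Laplace OFV within 0.1 of the quadrature oracle."""
        eta, seed = eta_seed
        ds, y = _one_subject_dataset(eta, seed)
        m = PopulationModel(typical_values=TV,
                            omega2={"CL": 0.29, "V1": 0, "Q": 0, "V2": 0},
                            sigma2_prop=0.030276)
        lap = ofv(m, ds)
        exact = quadrature_ofv_1d(TV, 0.29, 0.030276, DOSES, TIMES, y)
        assert lap == pytest.approx(exact, abs=0.1)

    def test_zero_iiv_reduces_to_weighted_least_squares(self):
        ds, y = _one_subject_dataset(0.0, 21)
        sigma2 = 0.02
        m = PopulationModel(typical_values=TV,
                            omega2={p: 0.0 for p in TV}, sigma2_prop=sigma2)
        p = StructuralParams(**TV)
        f = np.asarray(conc_at(p, DOSES, np.asarray(TIMES)))
        var = sigma2 * f ** 2
        expected = float(np.sum((y - f) ** 2 / var + np.log(2 * np.pi * var)))
        assert ofv(m, ds) == pytest.approx(expected, rel=1e-10)

    def test_duplicated_subject_doubles_contribution(self, published_model):
        ds, _ = _one_subject_dataset(0.2, 31)
        twin = SubjectRecord(id=2, covariates=dict(ds.subjects[0].covariates),
                             doses=list(ds.subjects[0].doses),
                             observations=list(ds.subjects[0].observations))
        doubled = Dataset(subjects=[ds.subjects[0], twin])
        assert ofv(published_model, doubled) == pytest.approx(
            2 * ofv(published_model, ds), rel=1e-9)

    def test_observation_without_prior_dose_is_diagnosed(self, published_model):
        sub = SubjectRecord(id=7, covariates={"GFR": 60.0},
                            doses=[DoseEvent(0.0, 0.0, 1.0)],
                            observations=[Observation(24.0, 5.0)])
        with pytest.raises(ValueError, match="subject 7.*24"):
            ofv(published_model, Dataset(subjects=[sub]))


class TestFit:
    def test_noise_free_identifiability(self):
        """Noise-free data: structural parameters recovered within 0.1%."""
        truth = PopulationModel(typical_values=TV,
                                covariate_effects=(CovariateEffect(
                                    "CL", "GFR", 0.437, 71.88, "power"),),
                                omega2={p: 0.0 for p in TV}, sigma2_prop=0.0)
        rng = np.random.default_rng(3)
        subs = []
        for i in range(10):
            gfr = rng.uniform(20, 120)
            p = typical_params(truth, {"GFR": gfr})
            ts = np.array([6.0, 24.0, 48.0, 72.0, 73.5])
            f = np.asarray(conc_at(p, DOSES, ts))
            subs.append(SubjectRecord(
                id=i + 1, covariates={"GFR": gfr}, doses=DOSES,
                observations=[Observation(t, c) for t, c in zip(ts, f)]))
        ds = Dataset(subjects=subs)
        init = PopulationModel(
            typical_values={"CL": 0.8, "V1": 25.0, "Q": 2.0, "V2": 80.0},
            covariate_effects=truth.covariate_effects,
            omega2={p: 1e-6 for p in TV}, sigma2_prop=1e-6)
        res = fit(ds, init, fixed=("omega2.CL", "omega2.V1", "omega2.Q",
                                   "omega2.V2", "sigma2", "beta.CL.GFR"),
                  **FAST_FIT)
        for name, truth_val in TV.items():
            assert res.model.typical_values[name] == pytest.approx(truth_val, rel=1e-3)

    def test_refit_from_truth_does_not_increase_ofv(self, published_model, small_cohort):
        start = ofv(published_model, small_cohort, exclude_blq=False)
        res = fit(small_cohort, published_model, **FAST_FIT)
        assert res.ofv <= start + 1e-6

    def test_eta_hat_aligned_with_subjects(self, published_model, small_cohort):
        res = fit(small_cohort, published_model, **FAST_FIT)
        assert len(res.eta_hat) == res.n_subjects
        assert set(res.eta_hat.columns) == {"ID", "eta_CL", "eta_V1", "eta_Q", "eta_V2"}

    def test_all_parameters_fixed_rejected(self, published_model, small_cohort):
        allnames = ("tv.CL", "tv.V1", "tv.Q", "tv.V2", "beta.CL.GFR",
                    "omega2.CL", "omega2.V1", "omega2.Q", "omega2.V2", "sigma2")
        with pytest.raises(ValueError):
            fit(small_cohort, published_model, fixed=allnames)


class TestCovariateStep:
    def test_strong_effect_selected_distractor_rejected(self, published_model):
        """Machinery check on a cohort with an unmistakable covariate signal.

        Statistical power at the study's own effect size is covered by the
        parameter-recovery acceptance test; here the renal effect is doubled
        and the variability halved so forward inclusion, the distractor
        rejection and backward retention are all clear-cut.
        """
        from teicopk import generate_dataset
        truth = PopulationModel(
            typical_values=TV,
            covariate_effects=(CovariateEffect("CL", "GFR", 0.9, 71.88, "power"),),
            omega2={"CL": 0.1, "V1": 0.15, "Q": 0.1, "V2": 0.05},
            sigma2_prop=0.02,
        )
        ds = generate_dataset(30, truth, np.random.default_rng(61))
        base = PopulationModel(typical_values=TV, omega2=truth.omega2,
                               sigma2_prop=truth.sigma2_prop)
        candidates = [
            CovariateEffect("CL", "GFR", 0.0, 71.88, "power"),
            CovariateEffect("CL", "ALB", 0.0, 29.5, "power"),  # distractor
        ]
        selected, audit = covariate_step(ds, base, candidates, **FAST_FIT)
        kept = {(e.parameter, e.covariate) for e in selected.covariate_effects}
        assert ("CL", "GFR") in kept
        assert ("CL", "ALB") not in kept
        forward = audit[(audit.phase == "forward") & (audit.covariate == "GFR")]
        assert (forward.dofv > 3.84).any() and forward.selected.any()

    def test_zero_signal_candidate_not_selected(self, published_model):
        # pure-noise covariate on a cohort with no covariate effect at all
        truth = PopulationModel(typical_values=TV, omega2=published_model.omega2,
                                sigma2_prop=published_model.sigma2_prop)
        from teicopk import generate_dataset
        ds = generate_dataset(20, truth, np.random.default_rng(88))
        base = truth
        selected, audit = covariate_step(
            ds, base, [CovariateEffect("CL", "WBC", 0.0, 11.5, "power")], **FAST_FIT)
        assert selected.covariate_effects == ()
        assert len(audit) == 1 and not audit.iloc[0]["selected"]


class TestBootstrap:
    def test_original_data_reproduces_original_fit(self, published_model, small_cohort):
        fitted = fit(small_cohort, published_model, **FAST_FIT)
        S = len(small_cohort.subjects)
        table = bootstrap(small_cohort, fitted.model, 1,
                          np.random.default_rng(0),
                          indices_list=[np.arange(S)], **FAST_FIT)
        assert table.attrs["n_success"] == 1
        for name, value in fitted.estimates().items():
            assert table.loc[name, "median"] == pytest.approx(value, rel=0.02, abs=1e-4)

    def test_percentile_table_shape(self, published_model, small_cohort):
        table = bootstrap(small_cohort, published_model, 3,
                          np.random.default_rng(5), maxiter=40, **{
                              k: v for k, v in FAST_FIT.items() if k != "maxiter"})
        assert list(table.columns) == ["median", "p2.5", "p97.5"]
        assert (table["p2.5"] <= table["p97.5"]).all()
        assert table.attrs["n_boot"] == 3

    def test_zero_replicates_rejected(self, published_model, small_cohort):
        with pytest.raises(ValueError):
            bootstrap(small_cohort, published_model, 0, np.random.default_rng(0))


class TestDiagnostics:
    def test_noise_free_residuals_vanish(self):
        truth = PopulationModel(typical_values=TV, omega2={p: 0.0 for p in TV},
                                sigma2_prop=0.0)
        p = StructuralParams(**TV)
        ts = np.array([24.0, 48.0, 72.0])
        f = np.asarray(conc_at(p, DOSES, ts))
        subs = [SubjectRecord(id=i + 1, covariates={}, doses=DOSES,
                              observations=[Observation(t, c) for t, c in zip(ts, f)])
                for i in range(3)]
        diag = compute_diagnostics(truth, Dataset(subjects=subs))
        assert np.allclose(diag.table.CWRES, 0.0, atol=1e-6)
        assert np.allclose(diag.table.PRED, diag.table.DV, rtol=1e-9)
        assert np.allclose(diag.table.IPRED, diag.table.DV, rtol=1e-9)

    def test_well_specified_cwres_standardized(self, published_model, small_cohort):
        diag = compute_diagnostics(published_model, small_cohort)
        assert len(diag.table) == small_cohort.without_blq().n_observations
        assert abs(diag.table.CWRES.mean()) < 0.4
        assert 0.5 < diag.table.CWRES.std() < 1.5


class TestPcVpc:
    def test_bands_ordered_and_calibrated(self, published_model, small_cohort):
        res = pcvpc(published_model, small_cohort, n_sim=150,
                    rng=np.random.default_rng(2))
        t = res.table
        assert (t["band_lo"] <= t["band_hi"]).all()
        assert (t["obs_p2.5"] <= t["obs_p50"]).all()
        assert (t["obs_p50"] <= t["obs_p97.5"]).all()
        assert 0.80 <= res.frac_in_band <= 1.0

    def test_misspecified_model_flagged(self, published_model, small_cohort):
        from dataclasses import replace
        halved = replace(
            published_model,
            typical_values={**published_model.typical_values, "CL": 1.03 / 2},
        )
        res = pcvpc(halved, small_cohort, n_sim=150, rng=np.random.default_rng(3))
        t = res.table
        outside = ((t["obs_p50"] < t["sim_p50_lo"]) | (t["obs_p50"] > t["sim_p50_hi"]))
        assert outside.any()


def test_laplace_matches_2d_grid_quadrature():
    """Two random effects (CL, V1): Laplace within 1 OFV unit of brute force."""
    from _oracles import grid_ofv_2d

    rng = np.random.default_rng(55)
    p = StructuralParams(TV["CL"] * 1.3, TV["V1"] * 0.8, TV["Q"], TV["V2"])
    f = np.asarray(conc_at(p, DOSES, np.asarray(TIMES)))
    y = f * (1 + rng.normal(0, 0.174, size=f.shape))
    sub = SubjectRecord(id=1, covariates={}, doses=DOSES,
                        observations=[Observation(t, c) for t, c in zip(TIMES, y)])
    m = PopulationModel(typical_values=TV,
                        omega2={"CL": 0.29, "V1": 0.37, "Q": 0, "V2": 0},
                        sigma2_prop=0.030276)
    lap = ofv(m, Dataset(subjects=[sub]))
    exact = grid_ofv_2d(TV, {"CL": 0.29, "V1": 0.37}, 0.030276, DOSES, TIMES, y)
    assert lap == pytest.approx(exact, abs=1.0)
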