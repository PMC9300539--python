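"""Synthetic trial generator: templates, determinism, noise structure."""

import dataclasses

import numpy as np
import pytest

from oralpax.errors import InputError
from oralpax.simulate import gut_doses_for, paclitaxel_concentrations
from oralpax.synthetic import (CAPSULE_DAILY_DOSES, TABLET_DAILY_DOSES,
                               TrialDesignSpec, generate_pd_observations,
                               generate_trial)
from oralpax.trial import RegimenDesign, write_dataset


class TestTemplates:
    def test_study3_design_structure(self, config):
        spec = TrialDesignSpec(template="study3", n_subjects=10, n_days=2,
                               pd_sampling_days=())
        ds, truth = generate_trial(spec, config, seed=3)
        for sid in ds.subjects:
            pac = ds.doses(sid, cmt="pac").sort_values("TIME")
            rtv = ds.doses(sid, cmt="rtv")
            # twice daily with a 7-h interval
            times = pac["TIME"].to_numpy()
            assert times[1] - times[0] == 7.0
            assert set(pac["DDI"]) == {"first", "second"}
            # ritonavir 200 mg/day, split 100 mg with each dose
            assert rtv["AMT"].sum() == 200.0 * 2
            daily = pac[pac["TIME"] < 24]["AMT"].sum()
            form = pac["FORM"].iloc[0]
            if form == "capsule":
                assert daily in CAPSULE_DAILY_DOSES
            else:
                assert daily in TABLET_DAILY_DOSES

    def test_study3_covers_all_dose_levels(self, config):
        spec = TrialDesignSpec(template="study3", n_subjects=9, n_days=1,
                               pd_sampling_days=())
        ds, _ = generate_trial(spec, config, seed=3)
        levels = set()
        for sid in ds.subjects:
            pac = ds.doses(sid, cmt="pac")
            levels.add((pac["FORM"].iloc[0], pac["AMT"].sum()))
        assert len(levels) == 9

    def test_study2_crossover(self, config):
        spec = TrialDesignSpec(template="study2", n_subjects=4,
                               pd_sampling_days=())
        ds, _ = generate_trial(spec, config, seed=3)
        orders = set()
        for sid in ds.subjects:
            pac = ds.doses(sid, cmt="pac").sort_values("TIME")
            assert len(pac) == 2
            assert pac["AMT"].tolist() == [30.0, 30.0]
            forms = tuple(pac["FORM"])
            assert set(forms) == {"solution", "capsule"}
            orders.add(forms)
        assert len(orders) == 2  # both randomization orders occur

    def test_study1_single_occasion(self, config):
        spec = TrialDesignSpec(template="study1", n_subjects=4,
                               pd_sampling_days=())
        ds, _ = generate_trial(spec, config, seed=3)
        rtv_doses = set()
        for sid in ds.subjects:
            pac = ds.doses(sid, cmt="pac")
            assert len(pac) == 1
            assert pac["AMT"].iloc[0] == 100.0
            assert pac["OCC"].iloc[0] == 1
            rtv = ds.doses(sid, cmt="rtv")
            # ritonavir 30 min before paclitaxel
            assert (pac["TIME"].iloc[0] - rtv["TIME"].iloc[0]) == 0.5
            rtv_doses.add(rtv["AMT"].iloc[0])
        assert rtv_doses == {100.0, 200.0}

    def test_unknown_template_rejected(self):
        with pytest.raises(InputError):
            TrialDesignSpec(template="study9")
        with pytest.raises(InputError):
            TrialDesignSpec(template="custom")


class TestGeneratedData:
    def test_datasets_pass_validation(self, config):
        spec = TrialDesignSpec(template="study3", n_subjects=4, n_days=8,
                               pd_sampling_days=(1, 2, 8))
        ds, _ = generate_trial(spec, config, seed=4)
        assert ds.validate() == []
        assert len(ds.observations(cmt="tsp1")) == 4 * 3

    def test_seed_determinism(self, config, tmp_path):
        spec = TrialDesignSpec(template="study3", n_subjects=3, n_days=1,
                               pd_sampling_days=(1,))
        a, truth_a = generate_trial(spec, config, seed=77)
        b, truth_b = generate_trial(spec, config, seed=77)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(a, pa)
        write_dataset(b, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert truth_a["subject_etas"] == truth_b["subject_etas"]
        c, _ = generate_trial(spec, config, seed=78)
        assert not a.records["DV"].equals(c.records["DV"])

    def test_zero_variability_gives_identical_subjects(self, config):
        re0 = dataclasses.replace(
            config.random_effects,
            bsv_cv={k: 0.0 for k in config.random_effects.bsv_cv},
            bov_cv_rf_gut=0.0, bsv_ebase_cv=0.0, sigma_prop_pk=0.0,
            sigma_prop_pd=0.0)
        cfg0 = config.replace(random_effects=re0)
        design = RegimenDesign(formulation="tablet", daily_dose_mg=40.0,
                               n_days=1, observation_times=(1, 2, 4, 8))
        spec = TrialDesignSpec(template="custom", n_subjects=3,
                               custom_designs=(design,),
                               pd_sampling_days=())
        ds, _ = generate_trial(spec, cfg0, seed=5)
        dv = [ds.observations(sid, cmt="pac")["DV"].to_numpy()
              for sid in ds.subjects]
        np.testing.assert_array_equal(dv[0], dv[1])
        np.testing.assert_array_equal(dv[0], dv[2])

    def test_truth_sidecar_reproduces_observations(self, config):
        """The sidecar etas regenerate each subject's PD trajectory."""
        spec = TrialDesignSpec(template="study3", n_subjects=2, n_days=2,
                               pd_sampling_days=(1, 2))
        ds, truth = generate_trial(spec, config, seed=6)
        rows = generate_pd_observations(
            ds, config, pd_sampling_days=(1, 2), seed=0,
            subject_etas=truth["subject_etas"])
        # same individuals -> same underlying trajectory; residuals differ
        assert len(rows) == len(ds.observations(cmt="tsp1"))

    def test_ritonavir_sampling_flag(self, config):
        spec = TrialDesignSpec(template="study1", n_subjects=6,
                               pd_sampling_days=(),
                               ritonavir_sampled_fraction=1.0)
        ds, _ = generate_trial(spec, config, seed=8)
        assert len(ds.observations(cmt="rtv")) > 0
        spec0 = dataclasses.replace(spec, ritonavir_sampled_fraction=0.0)
        ds0, _ = generate_trial(spec0, config, seed=8)
        assert len(ds0.observations(cmt="rtv")) == 0


class TestPDObservations:
    def test_baseline_scatter_matches_residual_cv(self, config):
        """Without dosing, TSP-1 samples scatter around E_BASE with
        CV ~ sigma_PD (baseline BSV switched off in the truth)."""
        re0 = dataclasses.replace(config.random_effects, bsv_ebase_cv=0.0)
        cfg0 = config.replace(random_effects=re0)
        design = RegimenDesign(daily_dose_mg=0.0)
        spec = TrialDesignSpec(template="custom", n_subjects=400,
                               custom_designs=(design,),
                               pd_sampling_days=(1,), pk_sampling_grid=())
        ds, _ = generate_trial(spec, cfg0, seed=10)
        dv = ds.observations(cmt="tsp1")["DV"].to_numpy()
        assert len(dv) == 400
        assert dv.mean() == pytest.approx(43.8, rel=0.02)
        assert dv.std(ddof=1) / dv.mean() == pytest.approx(0.138, rel=0.10)

    def test_sustained_exposure_bounded_by_double_baseline(self, config):
        """The implicit Emax of 1 caps TSP-1 below twice the baseline."""
        re0 = dataclasses.replace(
            config.random_effects,
            bsv_cv={k: 0.0 for k in config.random_effects.bsv_cv},
            bov_cv_rf_gut=0.0, bsv_ebase_cv=0.0, sigma_prop_pd=0.0)
        cfg0 = config.replace(random_effects=re0)
        design = RegimenDesign(formulation="tablet", daily_dose_mg=60.0,
                               n_days=43)
        spec = TrialDesignSpec(template="custom", n_subjects=1,
                               custom_designs=(design,),
                               pk_sampling_grid=(2.0,),
                               pd_sampling_days=(1, 8, 22, 43))
        ds, _ = generate_trial(spec, cfg0, seed=11)
        dv = ds.observations(cmt="tsp1")["DV"].to_numpy()
        assert np.all(dv <= 2.0 * 43.8)
        assert dv[-1] > 43.8  # stimulation visible

    def test_empty_pd_sampling_produces_no_records(self, config):
        spec = TrialDesignSpec(template="study3", n_subjects=2, n_days=1,
                               pd_sampling_days=())
        ds, _ = generate_trial(spec, config, seed=12)
        assert len(ds.observations(cmt="tsp1")) == 0


def test_auc_between_subject_cv_grows_with_omega(config):
    """Empirical CV of individual AUCs is monotone in the rF_gut and
    CLint0 variance components."""
    from oralpax.simulate import sample_individual
    from oralpax import pkmodels as pkm
    from oralpax.trial import build_regimen

    design = RegimenDesign(formulation="tablet", daily_dose_mg=40.0,
                           n_days=1)
    reg = build_regimen(design)
    rtv = pkm.solve_ritonavir(reg.ritonavir, config.ritonavir, 48.0)
    grid = np.arange(0.0, 48.01, 0.25)

    def auc_cv(bsv_cv, n=300, seed=13):
        re = dataclasses.replace(config.random_effects, bsv_cv=bsv_cv,
                                 bov_cv_rf_gut=0.0)
        cfg = config.replace(random_effects=re)
        rng = np.random.default_rng(seed)
        aucs = np.empty(n)
        for i in range(n):
            ind = sample_individual(cfg, [1, 2], rng)
            gd = gut_doses_for(reg.paclitaxel, ind)
            c = paclitaxel_concentrations(gd, ind, config.physio, rtv,
                                          grid)
            aucs[i] = np.trapezoid(c, grid)
        return aucs.std(ddof=1) / aucs.mean()

    base = {"alpha": 0.0, "clint0": 0.0, "vc": 0.0, "rf_gut": 0.0}
    cv_rf = [auc_cv({**base, "rf_gut": v}) for v in (0.0, 38.2, 70.0)]
    assert cv_rf[0] < cv_rf[1] < cv_rf[2]
    cv_cl = [auc_cv({**base, "clint0": v}) for v in (0.0, 25.1, 60.0)]
    assert cv_cl[0] < cv_cl[1] < cv_cl[2]
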