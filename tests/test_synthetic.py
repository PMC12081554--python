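"""Generator checks: seeded determinism, the location-scale batch-effect
model, censoring calibration, and survival-signal recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radstab.cox import fit_cox
from radstab.features import SEQUENCES
from radstab.synthetic import (CohortConfig, assign_batches,
                               generate_feature_cohort,
                               generate_phantom_volumes, simulate_survival)


def null_config(seed=0, **kw):
    """A cohort with no batch effects (gamma = 0, delta^2 ~ 1)."""
    kw.setdefault("batch_gamma_sd", 0.0)
    kw.setdefault("batch_delta_shape", 1e7)
    kw.setdefault("batch_delta_scale", 1e7 - 1.0)
    return CohortConfig(seed=seed, **kw)


class TestConfigValidation:
    def test_batch_sizes_must_sum_to_n(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(n_patients=10, batch_size_distribution=(4, 4),
                         n_batches_per_sequence=2)

    def test_censoring_fraction_bounds(self):
        with pytest.raises(ValueError, match="censoring"):
            CohortConfig(censoring_fraction_target=1.0)

    def test_one_hazard_ratio_per_prognostic_feature(self):
        with pytest.raises(ValueError, match="hazard ratio"):
            CohortConfig(true_log_hazard_ratios=(0.5,))


class TestBatchAssignment:
    def test_sizes_match_config_for_every_sequence(self):
        cfg = CohortConfig(seed=3)
        maps = assign_batches(cfg)
        for seq in SEQUENCES:
            assert sorted(maps[seq].sizes.to_list()) == \
                sorted(cfg.batch_size_distribution)

    def test_large_batches_shared_small_batches_differ(self):
        cfg = CohortConfig(seed=3)
        maps = assign_batches(cfg)
        a = maps[SEQUENCES[0]].assignments
        b = maps[SEQUENCES[1]].assignments
        sizes = dict(zip(cfg.batch_labels, cfg.batch_size_distribution))
        large = {lab for lab, sz in sizes.items()
                 if sz >= cfg.shared_batch_threshold}
        shared = a[a.isin(large)]
        assert (b.loc[shared.index] == shared).all()
        small = a[~a.isin(large)]
        assert (b.loc[small.index] != small).any()


class TestFeatureCohort:
    def test_seeded_determinism(self):
        out1 = generate_feature_cohort(CohortConfig(seed=9))
        out2 = generate_feature_cohort(CohortConfig(seed=9))
        assert out1[0].values.equals(out2[0].values)
        assert out1[3].equals(out2[3])
        pd.testing.assert_series_equal(out1[4].eta, out2[4].eta)

    def test_no_batch_effect_limit_feature_distributions_equal(self):
        # under gamma = 0, delta^2 = 1 a batch-association test must reject
        # at the nominal rate: p-values uniform over replicates
        pvals = []
        for rep in range(200):
            cfg = null_config(seed=rep, n_patients=60, n_features=1,
                              n_true_prognostic_features=0,
                              true_log_hazard_ratios=(),
                              batch_size_distribution=(20, 20, 20),
                              n_batches_per_sequence=3,
                              age_mean_by_batch=(60.0, 60.0, 60.0),
                              beta_age_sd=0.0)
            table, maps, _, _, _ = generate_feature_cohort(cfg)
            x = table.values.iloc[:, 0]
            groups = [x[maps[SEQUENCES[0]].assignments == b].to_numpy()
                      for b in maps[SEQUENCES[0]].batch_labels]
            pvals.append(stats.kruskal(*groups).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.asarray(pvals) < 0.05) == pytest.approx(0.05, abs=0.05)

    def test_batch_means_match_stored_gamma(self):
        cfg = CohortConfig(seed=21, n_patients=600,
                           batch_size_distribution=(200, 200, 200),
                           n_batches_per_sequence=3,
                           age_mean_by_batch=(60.0, 60.0, 60.0),
                           beta_age_sd=0.0, batch_gamma_sd=0.5,
                           shared_batch_threshold=1)
        table, maps, clin, _, truth = generate_feature_cohort(cfg)
        seq = SEQUENCES[0]
        block = table.sequence_block(seq).values
        labels = maps[seq].assignments
        for bi, lab in enumerate(cfg.batch_labels):
            rows = block.loc[labels == lab]
            observed = rows.mean(axis=0).to_numpy() - truth.alpha
            expected = truth.gamma[seq][bi]
            # Monte-Carlo error ~ sigma/sqrt(200) ~ 0.08; use 4x margin
            assert np.abs(observed - expected).max() < 0.35

    def test_cox_recovers_true_log_hazard_ratios_within_2_se(self):
        cfg = null_config(seed=5, n_patients=2000,
                          batch_size_distribution=(500, 500, 500, 500),
                          n_batches_per_sequence=4,
                          age_mean_by_batch=(60.0,) * 4,
                          age_log_hr=0.0, censoring_fraction_target=0.0)
        table, _, clin, surv, truth = generate_feature_cohort(cfg)
        # regress on the standardised biological signal: the observed
        # features equal alpha + eps here (no batch effects, no age slope)
        X = table.values[truth.prognostic_feature_ids].to_numpy()
        X = (X - truth.alpha[:4][None, :]) / truth.sigma[:4][None, :]
        m = fit_cox(X, surv["time"], surv["event"])
        se = np.sqrt(np.diag(np.linalg.inv(-_hessian(m, X, surv))))
        for est, true, s in zip(m.coefficients,
                                cfg.true_log_hazard_ratios, se):
            assert abs(est - true) < 2 * s


def _hessian(model, X, surv):
    from radstab.cox import _PartialLikelihood
    prob = _PartialLikelihood(X, surv["time"].to_numpy(),
                              surv["event"].to_numpy(float))
    _, _, h = prob(model.coefficients)
    return h


class TestSurvival:
    def test_exponential_mean_closed_form(self):
        cfg = CohortConfig(seed=2, weibull_shape=1.0, weibull_scale=10.0,
                           censoring_fraction_target=0.0)
        eta = pd.Series(np.zeros(5000))
        surv, _ = simulate_survival(eta, cfg,
                                    rng=np.random.default_rng(7))
        se = 10.0 / np.sqrt(5000)
        assert surv["time"].mean() == pytest.approx(10.0, abs=3 * se)

    def test_higher_eta_shortens_survival(self, rng):
        cfg = CohortConfig(seed=2, censoring_fraction_target=0.0)
        eta = pd.Series(rng.normal(size=500))
        surv, _ = simulate_survival(eta, cfg, rng=rng)
        # concordance of eta with event ordering beats chance
        r = stats.spearmanr(eta, surv["time"]).statistic
        assert r < -0.2

    def test_zero_censoring_target_gives_all_events(self):
        cfg = CohortConfig(seed=2, censoring_fraction_target=0.0)
        surv, bound = simulate_survival(pd.Series(np.zeros(100)), cfg,
                                        rng=np.random.default_rng(3))
        assert surv["event"].all() and np.isinf(bound)

    def test_censoring_calibrated_to_target(self):
        cfg = CohortConfig(seed=2, censoring_fraction_target=0.3)
        surv, _ = simulate_survival(pd.Series(np.zeros(4000)), cfg,
                                    rng=np.random.default_rng(3))
        assert (1 - surv["event"].mean()) == pytest.approx(0.3, abs=0.03)

    def test_non_finite_eta_rejected(self):
        cfg = CohortConfig(seed=2)
        with pytest.raises(ValueError, match="finite"):
            simulate_survival(pd.Series([0.0, np.inf]), cfg)


class TestPhantoms:
    def test_mask_nesting_and_determinism(self, phantom_cohort):
        cfg, vsets = phantom_cohort
        for vs in vsets:
            assert (vs.masks["core"] <= vs.masks["wtv"]).all()
            assert (vs.masks["wtv"] <= vs.masks["brain"]).all()
            assert not (vs.masks["nawm"] & vs.masks["wtv"]).any()
        again = generate_phantom_volumes(cfg)
        for a, b in zip(vsets, again):
            for seq in SEQUENCES:
                np.testing.assert_array_equal(a.volumes[seq], b.volumes[seq])

    def test_noiseless_limit_has_zero_compartment_variance(self):
        cfg = CohortConfig(n_patients=2, batch_size_distribution=(2,),
                           n_batches_per_sequence=1, age_mean_by_batch=(60.0,),
                           noise_sd=0.0, seed=8, shared_batch_threshold=1)
        vs = generate_phantom_volumes(cfg)[0]
        core = vs.masks["core"]
        assert vs.volumes["T1W"][core].var() < 1e-20

    def test_same_batch_same_gain_and_offset(self):
        cfg = CohortConfig(n_patients=4, batch_size_distribution=(4,),
                           n_batches_per_sequence=1, age_mean_by_batch=(60.0,),
                           noise_sd=0.0, seed=8, shared_batch_threshold=1)
        vsets = generate_phantom_volumes(cfg)
        # identical geometry is not guaranteed, but the intensity of a pure
        # compartment (noise-free core) reveals gain/offset directly
        vals = [np.unique(vs.volumes["T2W"][vs.masks["core"]])
                for vs in vsets]
        for v in vals[1:]:
            assert v == pytest.approx(vals[0])

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            generate_phantom_volumes(CohortConfig(grid_size=16, seed=1))

    def test_nifti_round_trip(self, phantom_cohort, tmp_path):
        import nibabel as nib
        _, vsets = phantom_cohort
        vsets[0].to_nifti(tmp_path)
        img = nib.load(tmp_path / f"{vsets[0].patient_id}_T1W.nii.gz")
        np.testing.assert_allclose(np.asanyarray(img.dataobj),
                                   vsets[0].volumes["T1W"], rtol=1e-6)
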