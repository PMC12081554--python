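"""ComBat harmonisation: cross-check against the reference R
implementation (sva::ComBat), batch-effect recovery, covariate
preservation, and the minimum-batch-size filter."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radstab.combat import (BatchMap, batch_covariate_screen, combat_adjust,
                            combat_adjust_by_sequence, filter_by_mbs)
from radstab.features import SEQUENCES, FeatureTable
from radstab.synthetic import CohortConfig, generate_feature_cohort


def make_batch_data(rng, n_per_batch=(20, 20, 20), G=10, gamma=(0.5, -0.3, 0.0),
                    scale=(1.4, 1.0, 1.0), age_slope=0.03):
    labels = np.repeat([f"b{i}" for i in range(len(n_per_batch))], n_per_batch)
    n = len(labels)
    age = rng.normal(60, 8, n)
    g_of = dict(zip([f"b{i}" for i in range(len(n_per_batch))], gamma))
    s_of = dict(zip([f"b{i}" for i in range(len(n_per_batch))], scale))
    X = np.empty((n, G))
    for g in range(G):
        X[:, g] = (2.0 + age_slope * age
                   + np.array([g_of[b] for b in labels])
                   + rng.normal(0, 0.7, n) * np.array([s_of[b] for b in labels]))
    ids = [f"p{i:03d}" for i in range(n)]
    table = FeatureTable(pd.DataFrame(
        X, index=ids, columns=[f"T1W_sim_f{g:02d}" for g in range(G)]))
    bm = BatchMap("T1W", pd.Series(labels, index=ids))
    cov = pd.DataFrame({"age": age}, index=ids)
    return table, bm, cov


class TestFilterByMbs:
    def _maps(self, sizes):
        labels = np.repeat([f"b{i}" for i in range(len(sizes))], sizes)
        ids = [f"p{i}" for i in range(len(labels))]
        return {s: BatchMap(s, pd.Series(labels, index=ids))
                for s in SEQUENCES}

    def test_arithmetic_8_6_3(self):
        maps = self._maps((8, 6, 3))
        retained, info = filter_by_mbs(maps, 5)
        assert len(retained) == 14
        assert info["overall"] == pytest.approx(14 / 17)

    def test_mbs_one_keeps_everyone(self):
        maps = self._maps((8, 6, 3))
        retained, info = filter_by_mbs(maps, 1)
        assert info["overall"] == 1.0

    def test_retention_monotone_in_mbs(self):
        cfg = CohortConfig(seed=13)
        _, maps, _, _, _ = generate_feature_cohort(cfg)
        fractions = [filter_by_mbs(maps, m)[1]["overall"] for m in (1, 5, 10, 15)]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_empty_cohort_raises(self):
        maps = self._maps((3, 2))
        with pytest.raises(ValueError, match="minimum batch size"):
            filter_by_mbs(maps, 10)

    def test_intersection_stricter_than_per_sequence(self):
        _, maps, _, _, _ = generate_feature_cohort(CohortConfig(seed=13))
        inter, _ = filter_by_mbs(maps, 10)
        per, _ = filter_by_mbs(maps, 10, mode="per_sequence")
        for seq in SEQUENCES:
            assert set(inter) <= set(per[seq])


class TestCombatAdjust:
    def test_matches_sva_reference(self, rng, tmp_path):
        """Oracle check: the R Bioconductor implementation on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: reference oracle cannot run")
        table, bm, cov = make_batch_data(rng)
        adj, _ = combat_adjust(table, bm, cov)
        np.savetxt(tmp_path / "dat.csv", table.values.to_numpy().T,
                   delimiter=",")
        meta = pd.DataFrame({"batch": bm.assignments.values,
                             "age": cov["age"].values})
        meta.to_csv(tmp_path / "meta.csv", index=False)
        rscript = f"""
        suppressMessages(library(sva))
        dat <- as.matrix(read.csv("{tmp_path}/dat.csv", header=FALSE))
        meta <- read.csv("{tmp_path}/meta.csv")
        mod <- model.matrix(~age, data=meta)
        res <- ComBat(dat=dat, batch=meta$batch, mod=mod, par.prior=TRUE)
        write.table(res, "{tmp_path}/r_adj.csv", sep=",",
                    row.names=FALSE, col.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", rscript], check=True,
                       capture_output=True)
        ref = np.loadtxt(tmp_path / "r_adj.csv", delimiter=",").T
        np.testing.assert_allclose(adj.values.to_numpy(), ref, atol=1e-3)

    def test_null_batch_effects_barely_adjust(self, rng):
        table, bm, cov = make_batch_data(
            rng, n_per_batch=(200, 200, 200), gamma=(0, 0, 0),
            scale=(1, 1, 1))
        adj, model = combat_adjust(table, bm, cov)
        delta = np.abs(adj.values.to_numpy() - table.values.to_numpy())
        assert delta.mean() < 0.05 * np.sqrt(model.sigma2_hat).mean()

    def test_known_shift_recovered(self, rng):
        table, bm, cov = make_batch_data(
            rng, n_per_batch=(100, 100), G=8, gamma=(0.0, 2.0),
            scale=(1.0, 1.0), age_slope=0.0)
        pre = table.values.groupby(bm.assignments).mean()
        pre_gap = (pre.iloc[0] - pre.iloc[1]).abs().mean()
        # without shrinkage the location-scale fit equalises batch means
        # exactly; with EB a sampling-noise-level residual remains by design
        adj_ls, _ = combat_adjust(table, bm, covariates=None, eb=False)
        means = adj_ls.values.groupby(bm.assignments).mean()
        assert (means.iloc[0] - means.iloc[1]).abs().max() < 1e-2
        adj_eb, _ = combat_adjust(table, bm, covariates=None)
        means_eb = adj_eb.values.groupby(bm.assignments).mean()
        eb_gap = (means_eb.iloc[0] - means_eb.iloc[1]).abs().max()
        assert eb_gap < 3.0 * 2 * 0.7 / np.sqrt(100)  # ~3 SE of a batch mean
        assert eb_gap < 0.1 * pre_gap

    def test_covariate_effect_preserved(self, rng):
        table, bm, cov = make_batch_data(rng)
        adj, model = combat_adjust(table, bm, cov)
        age = cov["age"].to_numpy()
        age_c = np.stack([np.ones_like(age), age], axis=1)
        for gi, name in enumerate(adj.feature_names):
            # batch effects removed, so OLS slope on age must equal beta_hat
            y = adj.values[name].to_numpy()
            slope = np.linalg.lstsq(age_c, y, rcond=None)[0][1]
            assert slope == pytest.approx(model.beta_hat[0, gi], abs=2e-2)

    def test_patient_order_and_feature_count_preserved(self, rng):
        table, bm, cov = make_batch_data(rng)
        adj, _ = combat_adjust(table, bm, cov)
        assert adj.patient_ids == table.patient_ids
        assert adj.feature_names == table.feature_names

    def test_fewer_than_two_batches_rejected(self, rng):
        table, bm, cov = make_batch_data(rng, n_per_batch=(30,), gamma=(0,),
                                         scale=(1,))
        with pytest.raises(ValueError, match="2 batches"):
            combat_adjust(table, bm, cov)

    def test_confounded_covariate_rejected(self, rng):
        table, bm, _ = make_batch_data(rng, n_per_batch=(20, 20),
                                       gamma=(0, 0), scale=(1, 1))
        confounded = pd.DataFrame(
            {"ind": (bm.assignments == "b0").astype(float)})
        with pytest.raises(ValueError, match="singular"):
            combat_adjust(table, bm, confounded)

    def test_idempotence_in_expectation(self, rng):
        table, bm, cov = make_batch_data(rng, n_per_batch=(60, 60, 60))
        adj1, m1 = combat_adjust(table, bm, cov)
        adj2, m2 = combat_adjust(adj1, bm, cov)
        assert np.abs(m2.gamma_star).mean() < 0.10 * np.abs(m1.gamma_star).mean()

    def test_per_sequence_blocks_and_shape_passthrough(self):
        cfg = CohortConfig(seed=17, n_features=6)
        table, maps, clin, _, _ = generate_feature_cohort(cfg)
        retained, _ = filter_by_mbs(maps, 5)
        sub = table.subset(patient_ids=retained)
        maps5 = {s: m.subset(retained) for s, m in maps.items()}
        cov = pd.DataFrame({"age": clin["age"].loc[retained]})
        adj, models = combat_adjust_by_sequence(sub, maps5, cov)
        assert adj.feature_names == sub.feature_names
        assert set(models) == set(SEQUENCES)


class TestParameterRecovery:
    def test_gamma_rmse_decreases_with_batch_size_class(self, rng):
        """Larger batches estimate their batch effects better — the
        mechanism behind the minimum-batch-size performance findings."""
        sizes = (5, 6, 7, 8, 10, 11, 13, 14, 15, 20, 30, 40)
        G = 120
        rmses = {"small": [], "mid": [], "large": []}
        for rep in range(5):
            r = np.random.default_rng(100 + rep)
            labels = np.repeat([f"b{i:02d}" for i in range(len(sizes))], sizes)
            n = len(labels)
            gamma = r.normal(0, 0.5, size=(len(sizes), G))
            delta2 = 1.0 / r.gamma(50.0, 1.0 / 49.0, size=(len(sizes), G))
            code = pd.Categorical(labels).codes
            X = (gamma[code] + np.sqrt(delta2)[code] * r.normal(0, 1, (n, G)))
            ids = [f"p{i}" for i in range(n)]
            table = FeatureTable(pd.DataFrame(
                X, index=ids, columns=[f"T1W_sim_f{g:03d}" for g in range(G)]))
            bm = BatchMap("T1W", pd.Series(labels, index=ids))
            adj, model = combat_adjust(table, bm)
            est = model.gamma_star * np.sqrt(model.sigma2_hat)[None, :]
            order = [int(b[1:]) for b in model.batch_labels]
            err = est - gamma[order]
            size_arr = np.array(sizes)[order]
            for cls, sel in (("small", size_arr < 10),
                             ("mid", (size_arr >= 10) & (size_arr < 15)),
                             ("large", size_arr >= 15)):
                rmses[cls].append(float(np.sqrt((err[sel] ** 2).mean())))
        assert np.mean(rmses["small"]) > np.mean(rmses["mid"]) \
            > np.mean(rmses["large"])


class TestCovariateScreen:
    def _bm(self, labels, ids):
        return BatchMap("T1W", pd.Series(labels, index=ids))

    def test_constant_covariate_reports_one_with_flag(self):
        ids = [f"p{i}" for i in range(20)]
        bm = self._bm(["a"] * 10 + ["b"] * 10, ids)
        p, flags = batch_covariate_screen(pd.Series(1.0, index=ids), bm)
        assert p == 1.0 and flags

    def test_strong_separation_tiny_p(self, rng):
        ids = [f"p{i}" for i in range(20)]
        bm = self._bm(["a"] * 10 + ["b"] * 10, ids)
        cov = pd.Series(np.r_[rng.normal(50, 1, 10), rng.normal(70, 1, 10)],
                        index=ids)
        p, _ = batch_covariate_screen(cov, bm)
        assert p < 1e-10

    def test_null_p_values_uniform(self):
        pvals = []
        for rep in range(200):
            r = np.random.default_rng(rep)
            ids = [f"p{i}" for i in range(30)]
            bm = self._bm(["a"] * 10 + ["b"] * 10 + ["c"] * 10, ids)
            cov = pd.Series(r.normal(size=30), index=ids)
            pvals.append(batch_covariate_screen(cov, bm)[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_singleton_batches_excluded_with_warning(self, rng):
        ids = [f"p{i}" for i in range(11)]
        bm = self._bm(["a"] * 5 + ["b"] * 5 + ["c"], ids)
        p, flags = batch_covariate_screen(
            pd.Series(rng.normal(size=11), index=ids), bm)
        assert any("excluded" in f for f in flags)
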