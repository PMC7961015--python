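"""Cluster profiles, Escore arithmetic, thresholding, metrics, LOOCV and
duplicate-core concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import dcisprofiler as dp
from dcisprofiler.errors import DataError, StatisticalError
from dcisprofiler.escore_model import (PUBLISHED_ESCORE, ClassificationMetrics,
                                       classify, cluster_profiles,
                                       core_concordance, escore, evaluate,
                                       fit_escore, loocv)

from conftest import profiles_frame


def profile_row(c1=0, c2=0, c3=0, c4=0, c5=0, c6=0, index=("P1",)):
    data = {f"cluster_{i}": v for i, v in
            enumerate((c1, c2, c3, c4, c5, c6), start=1)}
    return pd.DataFrame(data, index=list(index))


#: group-mean profiles reported for the event / no-event groups
#: (clusters 2, 4, 5, 6 as printed; 1 and 3 split the remainder)
BCE_MEAN = profile_row(c1=0.166, c2=0.030, c3=0.166, c4=0.063,
                       c5=0.245, c6=0.330)
NON_BCE_MEAN = profile_row(c1=0.230, c2=0.176, c3=0.230, c4=0.165,
                           c5=0.085, c6=0.114)


class TestClusterProfiles:
    def test_counting_example(self):
        assignments = pd.DataFrame({"patient_id": ["P1"] * 4,
                                    "cluster": [1, 1, 2, 3]})
        prof = cluster_profiles(assignments, k=6)
        expected = [0.5, 0.25, 0.25, 0.0, 0.0, 0.0]
        assert prof.loc["P1", [f"cluster_{i}" for i in range(1, 7)]
                        ].tolist() == expected
        assert prof.loc["P1", "n_cells"] == 4

    def test_single_cluster_patient(self):
        assignments = pd.DataFrame({"patient_id": ["P1"] * 3, "cluster": [6] * 3})
        prof = cluster_profiles(assignments, k=6)
        assert prof.loc["P1", "cluster_6"] == 1.0
        assert prof.loc["P1", "cluster_1"] == 0.0

    def test_proportions_sum_to_one(self, small_cohort):
        lab = small_cohort.truth.cell_clusters
        epi = lab[lab > 0]
        assignments = pd.DataFrame({
            "patient_id": small_cohort.cells.set_index("cell_id")
            .loc[epi.index, "patient_id"].to_numpy(),
            "cluster": epi.to_numpy()})
        prof = cluster_profiles(assignments, k=6)
        sums = prof[[f"cluster_{i}" for i in range(1, 7)]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_assignments_rejected(self):
        with pytest.raises(DataError):
            cluster_profiles(pd.DataFrame(columns=["patient_id", "cluster"]))


class TestEscoreArithmetic:
    def test_event_group_mean_profile_scores_high(self):
        score = escore(BCE_MEAN, PUBLISHED_ESCORE).iloc[0]
        assert score == pytest.approx(1.77 * 57.5 - 2.78 * 9.3, abs=1e-9)
        assert score == pytest.approx(75.921, abs=1e-3)
        assert classify([score], PUBLISHED_ESCORE)[0]

    def test_no_event_group_mean_profile_scores_low(self):
        score = escore(NON_BCE_MEAN, PUBLISHED_ESCORE).iloc[0]
        assert score == pytest.approx(1.77 * 19.9 - 2.78 * 34.1, abs=1e-9)
        assert score == pytest.approx(-59.575, abs=1e-3)
        assert not classify([score], PUBLISHED_ESCORE)[0]

    def test_zero_contribution_profile_scores_zero(self):
        prof = profile_row(c1=0.7, c3=0.3)
        assert escore(prof, PUBLISHED_ESCORE).iloc[0] == 0.0

    def test_threshold_is_strict(self):
        assert not classify([PUBLISHED_ESCORE.linear_threshold],
                            PUBLISHED_ESCORE)[0]
        assert classify([PUBLISHED_ESCORE.linear_threshold + 1e-9],
                        PUBLISHED_ESCORE)[0]

    def test_published_threshold_and_base_rate(self):
        assert PUBLISHED_ESCORE.linear_threshold == pytest.approx(13.0)
        assert PUBLISHED_ESCORE.base_rate == pytest.approx(13 / 51, abs=5e-4)

    def test_monotone_in_risk_clusters(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(6), size=1)
        prof = profiles_frame(base)
        bumped = base.copy()
        bumped[0, 4] += 0.05
        bumped[0, 0] -= 0.05
        assert escore(profiles_frame(bumped), PUBLISHED_ESCORE).iloc[0] > \
            escore(prof, PUBLISHED_ESCORE).iloc[0]


class TestFitEscore:
    def test_probability_and_linear_classification_agree(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            profiles = profiles_frame(rng.dirichlet(np.ones(6) * 2, size=60))
            y = pd.Series(rng.random(60) < 0.3, index=profiles.index)
            if y.all() or (~y).all():
                continue
            model = fit_escore(profiles, y)
            cov = dp.escore_covariates(profiles)
            p = model.predict_proba(cov["pct_c56"], cov["pct_c24"])
            s = model.linear_score(cov["pct_c56"], cov["pct_c24"])
            assert np.array_equal(p > model.base_rate,
                                  s > model.linear_threshold)

    def test_constant_covariates_reduce_to_intercept_only(self):
        profiles = profile_row(c1=0.5, c3=0.5,
                               index=[f"P{i}" for i in range(20)])
        y = pd.Series([True] * 5 + [False] * 15, index=profiles.index)
        model = fit_escore(profiles, y)
        assert model.slope_c56 == 0.0 and model.slope_c24 == 0.0
        assert model.intercept == pytest.approx(float(logit(0.25)), abs=1e-6)
        assert model.linear_threshold == pytest.approx(0.0, abs=1e-6)

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(2)
        profiles = profiles_frame(rng.dirichlet(np.ones(6), size=80))
        y = pd.Series(rng.random(80) < 0.4, index=profiles.index)
        m1 = fit_escore(profiles, y)
        perm = rng.permutation(80)
        m2 = fit_escore(profiles.iloc[perm], y.iloc[perm])
        assert m1.slope_c56 == pytest.approx(m2.slope_c56, rel=1e-8)
        assert m1.intercept == pytest.approx(m2.intercept, rel=1e-8)

    def test_single_class_rejected(self):
        profiles = profiles_frame(np.full((12, 6), 1 / 6))
        with pytest.raises(StatisticalError):
            fit_escore(profiles, pd.Series(True, index=profiles.index))


class TestEvaluate:
    def test_published_confusion_arithmetic(self):
        m = ClassificationMetrics.from_counts(tp=10, fn=3, tn=30, fp=8)
        assert m.sensitivity == pytest.approx(10 / 13)
        assert m.specificity == pytest.approx(30 / 38)
        assert m.error_rate == pytest.approx(11 / 51)
        assert 100 * m.error_rate == pytest.approx(21.6, abs=0.05)

    def test_perfect_separation_auc_one(self):
        y = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        scores = np.r_[np.full(5, 20.0), np.full(5, -5.0)]
        m = evaluate(scores, y, PUBLISHED_ESCORE)
        assert m.auc == 1.0
        assert m.tp == 5 and m.tn == 5

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(3)
        y = rng.random(1000) < 0.3
        scores = rng.standard_normal(1000)
        m = evaluate(scores, y, PUBLISHED_ESCORE)
        assert m.auc == pytest.approx(0.5, abs=0.05)


class TestLoocv:
    def separated_profiles(self, seed=4, n=20, conc=12.0):
        rng = np.random.default_rng(seed)
        gm = np.asarray(dp.SimulationConfig().group_profile_means)
        n_bce = n // 2
        profs = np.r_[rng.dirichlet(conc * gm[0], size=n_bce),
                      rng.dirichlet(conc * gm[1], size=n - n_bce)]
        y = np.r_[np.ones(n_bce, bool), np.zeros(n - n_bce, bool)]
        profiles = profiles_frame(profs)
        return profiles, pd.Series(y, index=profiles.index)

    def test_fold_count_at_n10(self):
        profiles, y = self.separated_profiles(n=10, conc=3.0)
        result = loocv(profiles, y)
        assert len(result.probabilities) + result.n_failed == 10

    def test_minimum_n_enforced(self):
        profiles, y = self.separated_profiles(n=10)
        with pytest.raises(StatisticalError):
            loocv(profiles.iloc[:8], y.iloc[:8])

    def test_separated_profiles_give_high_auc(self):
        profiles, y = self.separated_profiles(n=40, conc=12.0, seed=6)
        result = loocv(profiles, y)
        assert result.auc >= 0.95

    def test_shuffled_labels_give_chance_auc(self):
        # n large enough that the pessimistic small-sample bias of
        # leave-one-out under a null model is negligible
        aucs = []
        for seed in range(5):
            profiles, y = self.separated_profiles(n=200, conc=2.0, seed=seed)
            rng = np.random.default_rng(100 + seed)
            y_shuffled = pd.Series(rng.permutation(y.to_numpy()),
                                   index=y.index)
            try:
                aucs.append(loocv(profiles, y_shuffled).auc)
            except dp.EscoreFitError:
                continue
        assert abs(np.mean(aucs) - 0.5) <= 0.1


class TestCoreConcordance:
    def test_identical_cores_concordant(self):
        prof = pd.concat([BCE_MEAN, BCE_MEAN])
        prof["patient_id"] = "P1"
        prof["core_id"] = ["A", "B"]
        table, frac = core_concordance(prof, PUBLISHED_ESCORE)
        assert frac == 1.0 and table.loc["P1", "concordant"]

    def test_opposite_sides_discordant(self):
        prof = pd.concat([BCE_MEAN, NON_BCE_MEAN])
        prof["patient_id"] = "P1"
        prof["core_id"] = ["A", "B"]
        table, frac = core_concordance(prof, PUBLISHED_ESCORE)
        assert frac == 0.0

    def test_resampled_duplicate_cores_mostly_agree(self):
        # duplicate cores = two 1,000-cell multinomial draws from the same
        # patient profile; well-separated groups keep scores off-threshold
        rng = np.random.default_rng(7)
        gm = np.asarray(dp.SimulationConfig().group_profile_means)
        rows = []
        for i in range(40):
            mean = gm[0] if i < 20 else gm[1]
            profile = rng.dirichlet(8.0 * mean)
            for core in ("A", "B"):
                counts = rng.multinomial(1000, profile)
                rows.append({"patient_id": f"P{i}", "core_id": core,
                             **{f"cluster_{c + 1}": v / 1000
                                for c, v in enumerate(counts)}})
        table, frac = core_concordance(pd.DataFrame(rows), PUBLISHED_ESCORE)
        assert frac >= 0.9
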