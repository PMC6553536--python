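"""Trial mixed model: REML components, BLUPs, heritability, score conversion."""

import itertools

import numpy as np
import pandas as pd
import pytest

import structgs as sg
from structgs.blup import _MME, _term_design
from tests.conftest import dense_restricted_loglik


def balanced_records(n_fam=20, n_loc=2, n_blk=3, sd_fam=2.0, sd_eps=1.0,
                     seed=0, mu=10.0):
    rng = np.random.default_rng(seed)
    fam_eff = rng.normal(0, sd_fam, n_fam)
    rows = []
    for i, k, j in itertools.product(range(n_loc), range(n_blk), range(n_fam)):
        y = mu + fam_eff[j] + rng.normal(0, sd_eps)
        rows.append((f"loc{i}", f"blk{k}", f"fam{j}", y))
    return pd.DataFrame(rows, columns=["location", "block", "family", "score"])


class TestFitRandomModel:
    def test_no_shrinkage_limit_recovers_family_means(self):
        # residual variance ~ 0 -> family BLUPs -> family means - grand mean
        data = balanced_records(n_fam=20, sd_fam=3.0, sd_eps=1e-4, seed=1)
        fit = sg.fit_random_model(data, ["family"])
        fam_means = data.groupby("family", sort=False)["score"].mean()
        expected = fam_means - data["score"].mean()
        np.testing.assert_allclose(fit.blups["family"].reindex(fam_means.index),
                                   expected, atol=1e-3)

    def test_zero_signal_boundary(self):
        data = balanced_records(n_fam=25, sd_fam=0.0, sd_eps=1.0, seed=2)
        fit = sg.fit_random_model(data, ["family"])
        assert fit.varcomps["family"] < 0.05 * fit.varcomps["residual"]

    def test_loglik_beats_grid_oracle(self):
        data = balanced_records(n_fam=10, n_loc=1, n_blk=3, sd_fam=2.0,
                                sd_eps=1.0, seed=3)
        fit = sg.fit_random_model(data, ["family"])
        y = data["score"].to_numpy()
        Z, _ = _term_design(data, "family")
        best = -np.inf
        for sf in np.linspace(0.2, 8.0, 20):
            for se in np.linspace(0.2, 4.0, 20):
                V = sf * (Z @ Z.T) + se * np.eye(len(y))
                best = max(best, dense_restricted_loglik(y, V))
        assert fit.loglik >= best - 1e-6

    def test_mme_loglik_identity_matches_dense_form(self):
        data = balanced_records(n_fam=8, seed=4)
        y = data["score"].to_numpy()
        Z, _ = _term_design(data, "family")
        mme = _MME(y, [Z])
        for sf, se in [(1.0, 1.0), (3.0, 0.5), (0.2, 2.5)]:
            dense = dense_restricted_loglik(y, sf * (Z @ Z.T) + se * np.eye(len(y)))
            assert mme.reml_loglik(np.array([sf]), se) == pytest.approx(dense,
                                                                        abs=1e-8)

    def test_component_recovery_on_average(self):
        ests = []
        for rep in range(20):
            data = balanced_records(n_fam=100, sd_fam=2.0, sd_eps=1.5,
                                    seed=100 + rep)
            fit = sg.fit_random_model(data, ["family"])
            ests.append(fit.varcomps["family"])
        assert abs(np.mean(ests) - 4.0) < 0.6   # within 15% of truth

    def test_blup_shrinkage_never_exceeds_raw_variance(self):
        for seed in range(5):
            data = balanced_records(n_fam=30, sd_fam=1.0, sd_eps=2.0, seed=seed)
            fit = sg.fit_random_model(data, ["family"])
            raw = data.groupby("family")["score"].mean()
            assert fit.blups["family"].var() <= raw.var() + 1e-12

    def test_confounded_term_rejected(self):
        data = balanced_records(n_fam=5, n_loc=1, n_blk=1)
        with pytest.raises(ValueError, match="confounded"):
            sg.fit_random_model(data, ["family", "block:family"])

    def test_duplicate_grouping_rejected(self):
        data = balanced_records(n_fam=5)
        with pytest.raises(ValueError, match="confounded"):
            sg.fit_random_model(data, ["family", "family"])

    def test_deterministic_given_data(self):
        data = balanced_records(n_fam=12, seed=6)
        f1 = sg.fit_random_model(data, ["location", "family"])
        f2 = sg.fit_random_model(data, ["location", "family"])
        assert f1.varcomps == f2.varcomps
        assert f1.mu == f2.mu


class TestFamilyValues:
    def test_definition(self):
        fit = sg.MixedModelFit(
            varcomps={"family": 1.0, "residual": 1.0}, mu=10.0,
            blups={"family": pd.Series([-2.0, 0.0, 2.0],
                                       index=["a", "b", "c"])},
            loglik=0.0, converged=True, n_iter=1)
        vals = sg.family_values(fit)
        assert list(vals["value"]) == [8.0, 10.0, 12.0]
        assert vals["value"].mean() == pytest.approx(fit.mu)

    def test_shrinkage_decreases_with_noise(self):
        # |value - raw mean| shrinks as family/residual variance ratio grows
        gaps = []
        for sd_eps in (4.0, 1.0, 0.25):
            data = balanced_records(n_fam=15, sd_fam=1.0, sd_eps=sd_eps, seed=7)
            fit = sg.fit_random_model(data, ["family"])
            vals = sg.family_values(fit).set_index("family")["value"]
            raw = data.groupby("family")["score"].mean()
            gaps.append(float(np.mean(np.abs(vals - raw))))
        assert gaps[0] > gaps[1] > gaps[2]


class TestFamilyMeanH2:
    def test_pure_genetic(self):
        fit = sg.MixedModelFit(varcomps={"family": 3.0, "residual": 0.0},
                               mu=0, blups={}, loglik=0, converged=True,
                               n_iter=1)
        assert sg.family_mean_h2(fit, 2, 3) == 1.0

    def test_no_genetic(self):
        fit = sg.MixedModelFit(varcomps={"family": 0.0, "residual": 2.0},
                               mu=0, blups={}, loglik=0, converged=True,
                               n_iter=1)
        assert sg.family_mean_h2(fit, 2, 3) == 0.0

    def test_plug_in_arithmetic(self):
        fit = sg.MixedModelFit(
            varcomps={"family": 4.0, "location:family": 2.0, "residual": 6.0},
            mu=0, blups={}, loglik=0, converged=True, n_iter=1)
        h2 = sg.family_mean_h2(fit, 2, 3, fam_loc_term="location:family")
        assert h2 == pytest.approx(4.0 / 6.0)

    def test_all_zero_undefined(self):
        fit = sg.MixedModelFit(varcomps={"family": 0.0, "residual": 0.0},
                               mu=0, blups={}, loglik=0, converged=True,
                               n_iter=1)
        with pytest.raises(ValueError):
            sg.family_mean_h2(fit, 2, 3)


class TestSurvivalPercent:
    @pytest.mark.parametrize("scores,method,expected", [
        ([20, 20], "score_fraction", 100.0),
        ([0, 0, 0], "score_fraction", 0.0),
        ([0, 0], "plant_alive", 0.0),
        ([0, 10, 20], "score_fraction", 50.0),
        ([0, 10, 20], "plant_alive", pytest.approx(200 / 3)),
    ])
    def test_both_conventions(self, scores, method, expected):
        assert sg.survival_percent(scores, method) == expected

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            sg.survival_percent([1, 2], "nope")
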