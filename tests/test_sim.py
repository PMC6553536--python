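"""Synthetic-data generator: divergence, phenotypes, geography, read depths."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import structgs as sg
from structgs.sim import SimConfig


def hudson_fst(d1, d2):
    """Independent Hudson FST oracle (ratio of averages over markers)."""
    n1, n2 = d1.shape[0], d2.shape[0]
    p1, p2 = d1.mean(0) / 2, d2.mean(0) / 2
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


class TestStructuredGenotypes:
    def test_hudson_fst_matches_divergence_knob(self):
        cfg = SimConfig(n_subpops=3, n_per_subpop=100, n_markers=2000,
                        fst=0.3, missing_rate=0.0, seed=1)
        G, _ = sg.simulate_structured_genotypes(cfg)
        pops = G.populations
        ds = [G.dosage[pops == p] for p in ("pop1", "pop2", "pop3")]
        pairs = [(0, 1), (0, 2), (1, 2)]
        for a, b in pairs:
            assert abs(hudson_fst(ds[a], ds[b]) - 0.3) < 0.05

    def test_panmixia_limit(self):
        cfg = SimConfig(n_subpops=2, n_per_subpop=150, n_markers=2000,
                        fst=0.0, missing_rate=0.0, seed=2)
        G, _ = sg.simulate_structured_genotypes(cfg)
        p1 = G.dosage[G.populations == "pop1"].mean(0) / 2
        p2 = G.dosage[G.populations == "pop2"].mean(0) / 2
        # sampling noise only: mean |freq difference| ~ sqrt(2 p q / n)
        assert np.mean(np.abs(p1 - p2)) < 0.06

    def test_missingness_rate(self):
        cfg = SimConfig(n_subpops=2, n_per_subpop=100, n_markers=2000,
                        fst=0.1, missing_rate=0.1, seed=3)
        G, _ = sg.simulate_structured_genotypes(cfg)
        assert 0.08 < G.missing.mean() < 0.12

    def test_hwe_holds_within_subpops(self, small_panel):
        _, G, _ = small_panel
        for p in np.unique(G.populations):
            sub = G.dosage[G.populations == p]
            n_pass = 0
            for j in range(sub.shape[1]):
                col = sub[:, j]
                _, pv = sg.hwe_test(int((col == 0).sum()), int((col == 1).sum()),
                                    int((col == 2).sum()))
                n_pass += pv > 0.001
            assert n_pass / sub.shape[1] >= 0.99

    def test_wahlund_heterozygote_deficit_monotone_in_fst(self):
        deficits = []
        for f in (0.0, 0.1, 0.3):
            cfg = SimConfig(n_subpops=3, n_per_subpop=100, n_markers=2000,
                            fst=f, missing_rate=0.0, seed=4)
            G, _ = sg.simulate_structured_genotypes(cfg)
            p = G.dosage.mean(0) / 2
            het_obs = (G.dosage == 1).mean(0)
            het_exp = 2 * p * (1 - p)
            keep = het_exp > 0.05
            deficits.append(float(np.mean(1 - het_obs[keep] / het_exp[keep])))
        assert deficits[0] < deficits[1] < deficits[2]

    def test_bit_identical_under_fixed_seed(self):
        cfg = SimConfig(n_subpops=2, n_per_subpop=30, n_markers=200, seed=5)
        G1, t1 = sg.simulate_structured_genotypes(cfg)
        G2, t2 = sg.simulate_structured_genotypes(cfg)
        assert np.array_equal(G1.dosage, G2.dosage)
        assert np.array_equal(G1.missing, G2.missing)
        assert np.array_equal(t1.true_bv, t2.true_bv)

    @pytest.mark.parametrize("kwargs", [
        dict(n_subpops=0), dict(fst=1.0), dict(fst=-0.1),
        dict(missing_rate=0.5), dict(h2_target=1.5),
        dict(ancestral_maf_range=(0.0, 0.5)),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestTrialPhenotypes:
    def test_realized_family_mean_heritability(self):
        r2s = []
        for rep in range(20):
            cfg = SimConfig(n_subpops=3, n_per_subpop=100, n_markers=600,
                            fst=0.1, h2_target=0.6, missing_rate=0.0,
                            seed=100 + rep)
            G, truth = sg.simulate_structured_genotypes(cfg)
            rec = sg.simulate_trial_phenotypes(G, truth, cfg)
            fm = rec.groupby("family", sort=False)["score"].mean()
            bv = pd.Series(truth.true_bv, index=G.individual_ids)
            r, _ = stats.pearsonr(fm.reindex(bv.index), bv)
            r2s.append(r ** 2)
        assert abs(np.mean(r2s) - 0.6) < 0.1

    def test_zero_genetic_signal_gives_flat_family_means(self):
        cfg = SimConfig(n_subpops=1, n_per_subpop=80, n_markers=300,
                        h2_target=0.0, missing_rate=0.0, seed=6)
        G, truth = sg.simulate_structured_genotypes(cfg)
        rec = sg.simulate_trial_phenotypes(G, truth, cfg)
        fm = rec.groupby("family")["score"].mean()
        bv = pd.Series(truth.true_bv, index=G.individual_ids)
        r, _ = stats.pearsonr(fm.reindex(bv.index), bv)
        assert r ** 2 < 0.1

    def test_same_seed_identical_records(self):
        cfg = SimConfig(n_subpops=1, n_per_subpop=30, n_markers=200, seed=8)
        G, truth = sg.simulate_structured_genotypes(cfg)
        r1 = sg.simulate_trial_phenotypes(G, truth, cfg)
        r2 = sg.simulate_trial_phenotypes(G, truth, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_full_heritability_requires_zero_nongenetic_variance(self):
        cfg = SimConfig(n_subpops=1, n_per_subpop=30, n_markers=200,
                        h2_target=1.0, seed=9)
        G, truth = sg.simulate_structured_genotypes(cfg)
        with pytest.raises(ValueError):
            sg.simulate_trial_phenotypes(G, truth, cfg)
        rec = sg.simulate_trial_phenotypes(G, truth, cfg, loc_sd=0.0,
                                           block_sd=0.0)
        fm = rec.groupby("family", sort=False)["score"].mean()
        bv = pd.Series(truth.true_bv, index=G.individual_ids)
        assert stats.pearsonr(fm.reindex(bv.index), bv)[0] > 0.999

    def test_scores_stay_on_scale(self, small_panel):
        cfg, G, truth = small_panel
        rec = sg.simulate_trial_phenotypes(G, truth, cfg)
        assert rec["score"].between(0, 20).all()


class TestGeography:
    def test_positive_gradient_links_bv_to_latitude(self):
        cfg = SimConfig(n_subpops=10, n_per_subpop=20, n_markers=300,
                        fst=0.1, geo_gradient=(0.3, 0.0), missing_rate=0.0,
                        seed=10)
        G, truth = sg.simulate_structured_genotypes(cfg)
        meta = sg.assign_geography(G.populations, cfg, truth)
        pop_bv = pd.Series(truth.true_bv).groupby(G.populations).mean()
        merged = meta.set_index("population").join(pop_bv.rename("bv"))
        assert stats.pearsonr(merged["bv"], merged["latitude"])[0] > 0.5

    def test_zero_gradient_null(self):
        cfg = SimConfig(n_subpops=12, n_per_subpop=15, n_markers=300,
                        fst=0.1, geo_gradient=(0.0, 0.0), missing_rate=0.0,
                        seed=12)
        G, truth = sg.simulate_structured_genotypes(cfg)
        bv_before = truth.true_bv.copy()
        meta = sg.assign_geography(G.populations, cfg, truth)
        assert np.array_equal(bv_before, truth.true_bv)
        assert len(meta) == 12

    def test_min_temp_tracks_latitude(self):
        cfg = SimConfig(n_subpops=30, n_per_subpop=5, n_markers=50, seed=13)
        G, truth = sg.simulate_structured_genotypes(cfg)
        meta = sg.assign_geography(G.populations, cfg)
        r, _ = stats.pearsonr(meta["min_temp"], meta["latitude"])
        assert abs(r) >= 0.8 and r < 0


class TestAllelicDepths:
    def _hets(self, n_markers=3000, seed=14):
        cfg = SimConfig(n_subpops=1, n_per_subpop=4, n_markers=n_markers,
                        fst=0.0, missing_rate=0.0, seed=seed,
                        ancestral_maf_range=(0.4, 0.5))
        G, _ = sg.simulate_structured_genotypes(cfg)
        return G

    def test_tetraploid_concentrates_at_half(self):
        G = self._hets()
        ad = sg.simulate_allelic_depths(G, ["tetraploid"] * 4, mean_depth=200,
                                        seed=1)
        frac = ad["ref_depth"] / ad["total_depth"]
        assert np.mean(np.abs(frac - 0.5) < 0.1) > 0.99

    def test_octoploid_has_quarter_modes(self):
        G = self._hets()
        ad = sg.simulate_allelic_depths(G, ["octoploid"] * 4, mean_depth=60,
                                        seed=2)
        frac = (ad["ref_depth"] / ad["total_depth"]).to_numpy()
        near_25 = np.mean(np.abs(frac - 0.25) < 0.08)
        near_75 = np.mean(np.abs(frac - 0.75) < 0.08)
        assert near_25 > 0.15 and near_75 > 0.15

    def test_mean_depth_poisson(self):
        G = self._hets(n_markers=5000)
        ad = sg.simulate_allelic_depths(G, ["tetraploid"] * 4, mean_depth=20,
                                        seed=3)
        assert len(ad) > 5000
        assert 19 < ad["total_depth"].mean() < 21

    def test_unknown_ploidy_rejected(self):
        G = self._hets(n_markers=50)
        with pytest.raises(ValueError, match="ploidy"):
            sg.simulate_allelic_depths(G, ["hexaploid"] * 4, mean_depth=10)
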