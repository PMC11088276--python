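"""Generators: determinism, truth consistency and distributional sanity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyqhcs import synthdata
from polyqhcs.synthdata import (
    PlacementError,
    ScreenSimConfig,
    logistic_proportion,
    simulate_bends,
    simulate_competition,
    simulate_de_table,
    simulate_nuclei_image,
    simulate_reference_matrix,
    simulate_screen,
    simulate_survival,
)


# ---------------------------------------------------------------- screen sim

class TestSimulateScreen:
    def test_same_seed_reproduces_identical_plates_and_truth(self):
        cfg = ScreenSimConfig(n_compounds=100, n_active=3, seed=5)
        a, ta = simulate_screen(cfg)
        b, tb = simulate_screen(cfg)
        pd.testing.assert_frame_equal(a.wells, b.wells)
        assert ta == tb

    def test_truth_echoes_config(self):
        cfg = ScreenSimConfig(n_compounds=100, n_active=4, rescue_effects=(1.5,), seed=2)
        _, truth = simulate_screen(cfg)
        assert len(truth.active_ids) == 4
        assert all(truth.effect_by_compound[c] == 1.5 for c in truth.active_ids)

    def test_planted_ids_exist_in_generated_dataset(self):
        cfg = ScreenSimConfig(n_compounds=50, n_active=2, n_toxic=3, seed=3)
        plates, truth = simulate_screen(cfg)
        present = set(plates.wells.compound_id)
        assert set(truth.active_ids) <= present
        assert set(truth.toxic_ids) <= present

    def test_each_compound_once_per_replicate_plate(self):
        cfg = ScreenSimConfig(n_compounds=60, n_replicate_plates=3, seed=1)
        plates, _ = simulate_screen(cfg)
        comp = plates.wells[plates.wells.role == "compound"]
        per = comp.groupby("compound_id").size()
        assert (per == 3).all()

    def test_controls_scattered_and_at_least_eight_per_role(self):
        cfg = ScreenSimConfig(n_compounds=60, seed=4)
        plates, _ = simulate_screen(cfg)
        for _, g in plates.wells.groupby("plate_id"):
            counts = g.role.value_counts()
            assert counts["no_dox_control"] >= 8
            assert counts["dox_only_control"] >= 8
            ctrl = g[g.role != "compound"]
            assert not ctrl.is_edge.any()  # scattered interior placement

    def test_null_config_means_near_one_after_normalization(self):
        from polyqhcs import screen as scr
        cfg = ScreenSimConfig(n_compounds=300, dox_effect=1.0,
                              baseline_count=1000.0, seed=6)
        plates, _ = simulate_screen(cfg)
        norm = scr.normalize_plates(plates.wells)
        means = scr.summarize_compounds(norm).normalized_mean
        assert abs(means.mean() - 1.0) < 0.01

    @pytest.mark.parametrize("bad", [
        dict(baseline_count=-1.0),
        dict(dox_effect=0.0),
        dict(n_active=60, n_toxic=60, n_compounds=100),
        dict(toxic_effects=(1.5,), n_toxic=1),
        dict(rescue_effects=(-0.5,), n_active=1),
        dict(controls_per_plate=4),
        dict(noise="uniform"),
        dict(doses=()),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            ScreenSimConfig(**bad).validate()

    def test_gaussian_noise_matches_count_mean_and_cv(self):
        cfg = ScreenSimConfig(n_compounds=300, noise="gaussian",
                              baseline_count=200.0, dox_effect=0.5, seed=8)
        plates, _ = simulate_screen(cfg)
        dox = plates.wells[plates.wells.role == "dox_only_control"].nuclei_count
        assert abs(dox.mean() - 100) < 2
        assert abs(dox.std() / dox.mean() - 0.10) < 0.01

    def test_null_compounds_indistinguishable_from_controls(self):
        """With zero planted effects, compound wells and dox-only controls
        come from the same distribution (two-sample test at alpha=0.01)."""
        passed = 0
        for seed in range(10):
            cfg = ScreenSimConfig(n_compounds=120, seed=100 + seed)
            plates, _ = simulate_screen(cfg)
            comp = plates.wells[plates.wells.role == "compound"].nuclei_count
            ctrl = plates.wells[plates.wells.role == "dox_only_control"].nuclei_count
            if stats.mannwhitneyu(comp, ctrl).pvalue > 0.01:
                passed += 1
        assert passed >= 9


# -------------------------------------------------------------------- images

class TestSimulateNucleiImage:
    def test_zero_nuclei_gives_background_only(self):
        img, truth = simulate_nuclei_image(0, seed=1)
        assert truth.nuclei_centers == []
        assert img.max() < 300  # background + noise, far below nucleus amplitude

    def test_requested_count_disjoint_and_in_bounds(self):
        img, truth = simulate_nuclei_image(10, shape=(256, 256), seed=2)
        assert len(truth.nuclei_centers) == 10
        for r, c, rad in truth.nuclei_centers:
            assert rad <= r <= 255 - rad and rad <= c <= 255 - rad
        for i, (r1, c1, a1) in enumerate(truth.nuclei_centers):
            for r2, c2, a2 in truth.nuclei_centers[i + 1:]:
                assert np.hypot(r1 - r2, c1 - c2) > a1 + a2

    def test_fixed_seed_reproducible(self):
        a, _ = simulate_nuclei_image(7, seed=3)
        b, _ = simulate_nuclei_image(7, seed=3)
        assert np.array_equal(a, b)

    def test_impossible_placement_raises_not_truncates(self):
        with pytest.raises(PlacementError):
            simulate_nuclei_image(500, shape=(64, 64), seed=4)


# ------------------------------------------------------------------ DE table

class TestSimulateDeTable:
    def test_planted_genes_recorded_and_extreme(self):
        de, truth = simulate_de_table(500, 20, 20, lfc_magnitude=2.0, seed=5)
        up = set(truth.signature_truth["up"])
        down = set(truth.signature_truth["down"])
        assert len(up) == 20 and len(down) == 20
        assert (de.set_index("gene").loc[sorted(up), "lfc"] >= 2.0).all()
        assert (de.set_index("gene").loc[sorted(down), "lfc"] <= -2.0).all()

    def test_single_planted_gene_is_top_ranked_by_lfc(self):
        de, truth = simulate_de_table(100, 1, 0, seed=6)
        assert de.sort_values("lfc").gene.iloc[-1] == truth.signature_truth["up"][0]

    def test_null_tables_control_false_discoveries(self):
        """With nothing planted, BH at 0.05 yields ~<=5% FDR in expectation
        (here: expected false positives per table stays near the nominal
        level over 100 simulated tables)."""
        from polyqhcs.signatures import bh_adjust
        n_fp = 0
        n_tables = 100
        for seed in range(n_tables):
            de, _ = simulate_de_table(200, 0, 0, seed=1000 + seed)
            n_fp += int((bh_adjust(de.pvalue.to_numpy()) < 0.05).sum())
        # under the global null, P(any BH discovery) <= alpha per table
        assert n_fp / n_tables < 0.05 + 3 * np.sqrt(0.05 / n_tables) + 1e-9

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_de_table(10, 8, 8)


# ----------------------------------------------------------- reference matrix

class TestSimulateReferenceMatrix:
    def test_rankings_are_permutations(self):
        mat, _ = simulate_reference_matrix(10, 200, seed=7)
        mat.validate()

    def test_zero_concordance_uncorrelated_within_class(self):
        rhos = []
        for seed in range(10):
            mat, _ = simulate_reference_matrix(
                6, 500, class_labels=["A"] * 6, class_concordance=0.0, seed=seed)
            r = mat.ranks.to_numpy()
            for i in range(6):
                for j in range(i + 1, 6):
                    rhos.append(stats.spearmanr(r[:, i], r[:, j]).statistic)
        assert abs(np.mean(rhos)) < 3 * np.std(rhos) / np.sqrt(len(rhos)) + 0.02

    def test_high_concordance_correlates_within_class(self):
        mat, _ = simulate_reference_matrix(
            6, 500, class_labels=["A"] * 6, class_concordance=0.9, seed=8)
        r = mat.ranks.to_numpy()
        rho = stats.spearmanr(r[:, 0], r[:, 1]).statistic
        assert rho > 0.7

    def test_empty_matrix_is_valid(self):
        mat, _ = simulate_reference_matrix(0, 100, seed=9)
        assert mat.drugs == []
        mat.validate()

    def test_class_truth_recorded(self):
        labels = ["agonist"] * 3 + ["other"] * 4
        _, truth = simulate_reference_matrix(7, 100, class_labels=labels, seed=10)
        assert list(truth.class_truth.values()) == labels


# ------------------------------------------------------------------ phenotype

class TestPhenotypeGenerators:
    def test_logistic_formula_closed_form(self):
        # p0=0.5, s=0.2/day, t=5 -> e^-1 / (e^-1 + 1)
        expected = np.exp(-1) / (np.exp(-1) + 1)
        assert logistic_proportion(0.5, 0.2, 5) == pytest.approx(expected, abs=1e-12)

    def test_zero_fitness_deficit_keeps_proportion_flat(self):
        df, _ = simulate_competition(0.3, 0.0, [0, 5, 15], n_cells_sampled=200_000, seed=11)
        p = df.q94_count / (df.q94_count + df.control_count)
        assert np.allclose(p, 0.3, atol=0.01)

    def test_positive_deficit_declines_in_expectation(self):
        means = []
        for seed in range(20):
            df, _ = simulate_competition(0.5, 0.2, [0, 5, 15], 10_000, seed=seed)
            means.append((df.q94_count / (df.q94_count + df.control_count)).to_numpy())
        avg = np.mean(means, axis=0)
        assert avg[0] > avg[1] > avg[2]

    def test_competition_day_zero_required(self):
        with pytest.raises(ValueError):
            simulate_competition(0.5, 0.1, [1, 5, 15])

    def test_survival_extremes(self):
        all_dead, _ = simulate_survival({"a": 1.0}, n_eggs=50, n_replicates=3, seed=12)
        assert (all_dead.n_dead == 50).all()
        none_dead, _ = simulate_survival({"a": 0.0}, n_eggs=50, n_replicates=3, seed=12)
        assert (none_dead.n_dead == 0).all()

    def test_survival_triplicate_design_default(self):
        df, truth = simulate_survival(0.4, seed=13)
        assert df.replicate.nunique() == 3 and (df.n_total == 150).all()
        assert truth.survival_truth == {"arm": 0.4}

    def test_bends_zero_rate_and_clt(self):
        zeros, _ = simulate_bends({"a": 0.0}, n_worms=10, seed=14)
        assert (zeros.bends_30s == 0).all()
        big, _ = simulate_bends({"a": 9.0}, n_worms=2000, seed=15)
        se = np.sqrt(9.0 / 2000)
        assert abs(big.bends_30s.mean() - 9.0) <= 3 * se

    def test_generators_deterministic(self):
        for fn, args in [
            (simulate_competition, (0.5, 0.2, [0, 5, 15])),
            (simulate_survival, ({"a": 0.3},)),
            (simulate_bends, ({"a": 8.0},)),
        ]:
            a, _ = fn(*args, seed=16)
            b, _ = fn(*args, seed=16)
            pd.testing.assert_frame_equal(a, b)
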