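"""Normalization, hit calling, dose-response validation and QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_plate
from polyqhcs import synthdata
from polyqhcs.screen import (
    ControlStats,
    NormalizationError,
    call_hits,
    control_stats,
    normalize_plate,
    normalize_plates,
    qc_report,
    summarize_compounds,
    validate_dose_response,
    zprime,
)


class TestNormalizePlate:
    def test_ratio_to_dox_only_control_mean(self):
        plate = make_plate({"dox_only_control": [200, 200], "compound": [260]})
        out = normalize_plate(plate)
        assert out.loc[out.role == "compound", "normalized"].iloc[0] == pytest.approx(1.30)

    def test_scale_invariance(self):
        plate = make_plate({"dox_only_control": [180, 220], "compound": [150, 260, 300]})
        a = normalize_plate(plate)
        scaled = plate.assign(nuclei_count=plate.nuclei_count * 7.3)
        b = normalize_plate(scaled)
        assert np.allclose(a.normalized, b.normalized)

    def test_zero_control_mean_raises_naming_plate(self):
        plate = make_plate({"dox_only_control": [0, 0], "compound": [100]}, plate_id="P9")
        with pytest.raises(NormalizationError, match="P9"):
            normalize_plate(plate)

    def test_missing_controls_raise(self):
        plate = make_plate({"compound": [100, 120]})
        with pytest.raises(NormalizationError):
            normalize_plate(plate)

    def test_normalization_strictly_per_plate(self):
        p1 = make_plate({"dox_only_control": [100], "compound": [150]}, plate_id="P1")
        p2 = make_plate({"dox_only_control": [200], "compound": [150]}, plate_id="P2")
        out = normalize_plates(pd.concat([p1, p2], ignore_index=True))
        vals = out[out.role == "compound"].sort_values("plate_id").normalized.tolist()
        assert vals == [1.5, 0.75]

    def test_control_mean_normalizes_to_one_exactly(self, normalized_small_screen):
        ctrl = normalized_small_screen[normalized_small_screen.role == "dox_only_control"]
        for _, g in ctrl.groupby("plate_id"):
            assert g.normalized.mean() == pytest.approx(1.0, abs=1e-12)


class TestSummarizeCompounds:
    def test_triplicate_mean(self):
        frames = []
        for i, v in enumerate([1.2, 1.3, 1.4], start=1):
            p = make_plate({"dox_only_control": [100.0], "compound": [100.0 * v]},
                           plate_id=f"P{i}")
            frames.append(normalize_plate(p))
        out = summarize_compounds(pd.concat(frames, ignore_index=True))
        assert out.normalized_mean.iloc[0] == pytest.approx(1.3)
        assert out.n_replicates.iloc[0] == 3

    def test_single_replicate_kept_with_n_one(self):
        out = summarize_compounds(
            normalize_plate(make_plate({"dox_only_control": [100.0], "compound": [150.0]})))
        assert out.normalized_mean.iloc[0] == pytest.approx(1.5)
        assert out.n_replicates.iloc[0] == 1


class TestControlStats:
    def test_degenerate_controls_give_zero_sigma_with_flag(self):
        plate = normalize_plate(make_plate(
            {"dox_only_control": [100.0] * 10, "compound": [120.0]}))
        st = control_stats(plate, aggregate="well", self_norm_correction=False)
        assert st.mu == pytest.approx(1.0) and st.sigma == 0.0
        assert any("zero" in f for f in st.flags)

    def test_sample_sd_hand_value(self):
        # two control values 0.9, 1.1 -> mean 1.0, sample SD (n-1) ~ 0.1414
        df = pd.DataFrame({"plate_id": ["P1", "P1"], "role": ["dox_only_control"] * 2,
                           "normalized": [0.9, 1.1]})
        st = control_stats(df, aggregate="well", self_norm_correction=False)
        assert st.mu == pytest.approx(1.0)
        assert st.sigma == pytest.approx(0.141421356, abs=1e-6)

    def test_mad_resists_outlier_better_than_sd(self):
        vals = [0.95, 0.97, 1.0, 1.03, 1.05, 3.0]
        df = pd.DataFrame({"plate_id": "P1", "role": "dox_only_control",
                           "normalized": vals})
        sd = control_stats(df, estimator="sd", aggregate="well",
                           self_norm_correction=False).sigma
        mad = control_stats(df, estimator="mad", aggregate="well",
                            self_norm_correction=False).sigma
        assert mad < sd

    def test_replicate_mean_aggregation_shrinks_spread(self, normalized_small_screen):
        well = control_stats(normalized_small_screen, aggregate="well",
                             self_norm_correction=False)
        rep = control_stats(normalized_small_screen, aggregate="replicate_mean",
                            self_norm_correction=False)
        assert rep.sigma < well.sigma

    def test_too_few_controls_raise(self):
        df = pd.DataFrame({"plate_id": ["P1"], "role": ["dox_only_control"],
                           "normalized": [1.0]})
        with pytest.raises(ValueError):
            control_stats(df)


class TestCallHits:
    def test_threshold_arithmetic(self):
        st = ControlStats(mu=1.0, sigma=0.1, n=50, k=3.0)
        summaries = pd.DataFrame({"compound_id": ["A", "B"],
                                  "normalized_mean": [1.35, 1.25]})
        out = call_hits(summaries, st)
        assert out.threshold.iloc[0] == pytest.approx(1.30)
        assert out.set_index("compound_id").is_hit.to_dict() == {"A": True, "B": False}

    def test_boundary_is_strict(self):
        st = ControlStats(mu=1.0, sigma=0.1, n=50)
        out = call_hits(pd.DataFrame({"compound_id": ["A"], "normalized_mean": [1.30]}), st)
        assert not out.is_hit.iloc[0]

    def test_zero_sigma_threshold_is_control_mean(self):
        st = ControlStats(mu=1.0, sigma=0.0, n=50)
        out = call_hits(pd.DataFrame({"compound_id": ["A"], "normalized_mean": [1.0001]}), st)
        assert out.is_hit.iloc[0]

    def test_sorted_by_margin_then_compound_id(self):
        st = ControlStats(mu=1.0, sigma=0.1, n=50)
        summaries = pd.DataFrame({"compound_id": ["B", "A", "C"],
                                  "normalized_mean": [1.5, 1.5, 1.9]})
        out = call_hits(summaries, st)
        assert out.compound_id.tolist() == ["C", "A", "B"]

    def test_zero_count_wells_can_never_be_hits(self):
        st = ControlStats(mu=1.0, sigma=0.1, n=50)
        out = call_hits(pd.DataFrame({"compound_id": ["Z"], "normalized_mean": [0.0]}), st)
        assert not out.is_hit.iloc[0]

    def test_plate_factor_immunity(self):
        """Multiplying every count on a plate by an arbitrary factor leaves
        the hit set unchanged (normalization is per plate)."""
        cfg = synthdata.ScreenSimConfig(n_compounds=200, n_active=3,
                                        rescue_effects=(1.4,), seed=21)
        plates, _ = synthdata.simulate_screen(cfg)
        from polyqhcs.screen import normalize_plates as norm
        rng = np.random.default_rng(22)
        factors = {pid: f for pid, f in zip(
            plates.wells.plate_id.unique(),
            rng.lognormal(0, 0.5, plates.wells.plate_id.nunique()))}
        perturbed = plates.wells.assign(
            nuclei_count=plates.wells.nuclei_count * plates.wells.plate_id.map(factors))
        def hit_set(wells):
            n = norm(wells)
            return set(call_hits(summarize_compounds(n), control_stats(n))
                       .query("is_hit").compound_id)
        assert hit_set(plates.wells) == hit_set(perturbed)


class TestValidateDoseResponse:
    @staticmethod
    def _make_validation(effects_by_dose, n_rep=3, ctrl_n=24, seed=0):
        """One compound; normalized values ~ N(effect, 0.05) per dose."""
        rng = np.random.default_rng(seed)
        rows = [{"plate_id": "V1", "role": "dox_only_control", "compound_id": "",
                 "dose_uM": 0.0, "normalized": v}
                for v in rng.normal(1.0, 0.05, ctrl_n)]
        for dose, eff in effects_by_dose.items():
            for v in rng.normal(eff, 0.05, n_rep):
                rows.append({"plate_id": "V1", "role": "compound", "compound_id": "C0001",
                             "dose_uM": dose, "normalized": v})
        return pd.DataFrame(rows)

    def test_significant_increase_at_two_doses_validates(self):
        df = self._make_validation({0.5: 1.0, 1.0: 1.5, 3.0: 1.5, 10.0: 1.0}, seed=1)
        (res,) = validate_dose_response(df)
        assert res.validated and res.n_significant_doses == 2

    def test_single_significant_dose_fails(self):
        df = self._make_validation({0.5: 1.0, 1.0: 1.0, 3.0: 1.5, 10.0: 1.0}, seed=2)
        (res,) = validate_dose_response(df)
        assert not res.validated

    def test_significant_decrease_never_validates(self):
        df = self._make_validation({0.5: 0.5, 1.0: 0.5, 3.0: 0.5, 10.0: 0.5}, seed=3)
        (res,) = validate_dose_response(df)
        assert res.n_significant_doses == 0 and not res.validated

    def test_missing_control_arm_raises(self):
        df = self._make_validation({0.5: 1.0, 1.0: 1.2}, seed=4)
        with pytest.raises(ValueError):
            validate_dose_response(df[df.role == "compound"])

    def test_holm_fallback_agrees_on_clear_cases(self):
        df = self._make_validation({0.5: 1.6, 1.0: 1.6, 3.0: 1.0, 10.0: 1.0}, seed=5)
        (dunnett,) = validate_dose_response(df, method="dunnett")
        (holm,) = validate_dose_response(df, method="holm")
        assert dunnett.validated and holm.validated


class TestQc:
    def test_zprime_formula(self):
        # mu 2 vs 1, both sigma 0.1 -> Z' = 1 - 3*0.2/1 = 0.4
        df = pd.DataFrame({
            "plate_id": "P1",
            "role": ["no_dox_control"] * 2 + ["dox_only_control"] * 2,
            "nuclei_count": [1.9, 2.1, 0.9, 1.1]})
        sd = np.std([1.9, 2.1], ddof=1)
        expected = 1 - 3 * (2 * sd) / 1.0
        assert zprime(df) == pytest.approx(expected)

    def test_zprime_perfect_separation(self):
        df = pd.DataFrame({
            "plate_id": "P1",
            "role": ["no_dox_control"] * 2 + ["dox_only_control"] * 2,
            "nuclei_count": [2.0, 2.0, 1.0, 1.0]})
        assert zprime(df) == 1.0

    def test_zprime_identical_controls_undefined(self):
        df = pd.DataFrame({
            "plate_id": "P1",
            "role": ["no_dox_control"] * 2 + ["dox_only_control"] * 2,
            "nuclei_count": [1.0, 1.0, 1.0, 1.0]})
        assert zprime(df) is None

    def test_zprime_never_exceeds_one(self, small_screen):
        plates, _ = small_screen
        for _, g in plates.wells.groupby("plate_id"):
            z = zprime(g)
            assert z is None or z <= 1.0

    def test_qc_report_structure(self, small_screen):
        plates, _ = small_screen
        rep = qc_report(plates.wells)
        for entry in rep["plates"].values():
            assert {"zprime", "cv_no_dox", "cv_dox_only"} <= set(entry)
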