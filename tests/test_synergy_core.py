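"""Bliss scoring, hit calling, synthetic lethality, breadth, promiscuity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import synscape as syn
from synscape.synergy_core import (
    bliss_expected,
    bliss_matrix,
    bliss_score,
    call_synergy_hit,
    call_synthetic_lethal,
    promiscuity_index,
    score_dataset,
    synergy_breadth,
    synthetic_lethality_rate,
)

fractions = st.floats(min_value=0.0, max_value=1.2, allow_nan=False)


class TestBlissArithmetic:
    @pytest.mark.parametrize(
        "va,vb,expected",
        [(1.0, 0.6, 0.6), (1.0, 1.0, 1.0), (0.8, 0.5, 0.4), (1.2, 0.5, 0.5)],
    )
    def test_expected_product(self, va, vb, expected):
        assert bliss_expected(va, vb) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "va,vb,vab,expected",
        [(0.9, 0.9, 0.81, 0.0), (0.8, 0.9, 0.30, 42.0), (1.0, 0.5, 0.6, -10.0)],
    )
    def test_score_values(self, va, vb, vab, expected):
        assert bliss_score(va, vb, vab) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bliss_expected(-0.1, 0.5)
        with pytest.raises(ValueError):
            bliss_score(0.5, 0.5, -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(va=fractions, vb=fractions, vab=fractions)
    def test_score_symmetric_in_singles(self, va, vb, vab):
        assert bliss_score(va, vb, vab) == bliss_score(vb, va, vab)

    @settings(derandomize=True, max_examples=50)
    @given(va=fractions, vb=fractions, vab=fractions, dv=st.floats(0.01, 0.5))
    def test_score_strictly_decreases_with_combo_viability(self, va, vb, vab, dv):
        assert bliss_score(va, vb, vab + dv) < bliss_score(va, vb, vab)


class TestHitCalling:
    def test_threshold_is_strict(self):
        assert call_synergy_hit(42.0)
        assert not call_synergy_hit(40.0)
        assert call_synergy_hit(35.0, threshold_pct=30)

    @pytest.mark.parametrize(
        "va,vb,vab,expected",
        [
            (0.85, 0.9, 0.45, True),
            (0.80, 0.9, 0.45, False),  # boundary single, strict
            (0.9, 0.9, 0.55, False),  # combo not deep enough
            (0.9, 0.9, 0.50, False),  # boundary combo, strict
        ],
    )
    def test_synthetic_lethal_thresholds(self, va, vb, vab, expected):
        assert call_synthetic_lethal(va, vb, vab) is expected


class TestScoreDataset:
    def test_null_screen_scores_exactly_zero(self, null_screen):
        ds, _ = null_screen
        scores = score_dataset(ds)
        assert len(scores) == ds.n_combination_rows
        assert (scores["bliss_score"].to_numpy() == 0.0).all()
        for thr in (1e-9, 0.5, 40.0):
            assert not call_synergy_hit(scores["bliss_score"].to_numpy(), thr).any()

    def test_score_matches_fraction_formula(self, small_scores):
        s = small_scores
        recomputed = bliss_score(
            s["v_a"].to_numpy(), s["v_b"].to_numpy(), s["v_ab"].to_numpy()
        )
        np.testing.assert_allclose(s["bliss_score"], recomputed, atol=1e-9)

    def test_synthetic_lethal_implies_synergy_hit(self, small_scores):
        s = small_scores
        assert (s["is_synthetic_lethal"] <= s["is_synergy_hit"]).all()

    def test_incomplete_combinations_are_excluded(self, tmp_path):
        ds, _ = syn.generate_screen(syn.null_config(n_drugs=4, n_lines=2, seed=1))
        m = ds.measurements
        keep = ~((m["drug_a"] == "D001") & m["drug_b"].isna())
        ds2 = syn.ScreenDataset(
            panel=ds.panel, lines=ds.lines, measurements=m[keep]
        )
        scores = score_dataset(ds2)
        # all pairs containing D001 are unscorable
        assert not (
            (scores["drug_a"] == "D001") | (scores["drug_b"] == "D001")
        ).any()


class TestRecovery:
    def test_planted_breadth_recovered(self):
        pair = syn.PlantedSynergy(
            "D002", "D005", lines=("L01", "L03", "L06"), delta=0.4
        )
        # mild drug/line heterogeneity keeps every null combo viable enough
        # for the full planted delta to be realized
        ds, gt = syn.generate_screen(
            syn.SimulationConfig(
                n_drugs=8,
                n_lines=8,
                seed=13,
                noise_sd_viability=0.05,
                drug_effect_sd=0.25,
                line_effect_sd=0.2,
                planted_synergies=[pair],
                broad_sensitizer=None,
                planted_cparp_outliers=[],
            )
        )
        assert min(gt.realized_bliss.values()) >= 40.0
        scores = score_dataset(ds)
        breadth = synergy_breadth(scores, threshold_pct=30.0)
        row = breadth.per_pair.set_index(["drug_a", "drug_b"]).loc[("D002", "D005")]
        assert row["n_lines_synergistic"] == 3
        assert row["lines"] == ["L01", "L03", "L06"]

    def test_hit_recall_and_precision_on_planted_landscape(self):
        """Planted 40-point synergies vs a 25-point calling threshold: the
        15-point margin is ~3 score SDs (score noise pools the combination
        and both single-agent measurement errors, SD ~4.7 points at noise
        0.03), so recall and precision reach 0.95 over ~1000 pairs."""
        rng = np.random.default_rng(17)
        n_drugs, n_lines = 46, 4  # 1035 pairs
        pairs = [
            (f"D{i + 1:03d}", f"D{j + 1:03d}")
            for i in range(n_drugs)
            for j in range(i + 1, n_drugs)
        ]
        chosen = rng.choice(len(pairs), size=100, replace=False)
        plants = [
            syn.PlantedSynergy(*pairs[k], lines=("L01",), delta=0.4)
            for k in chosen
        ]
        ds, gt = syn.generate_screen(
            syn.SimulationConfig(
                n_drugs=n_drugs,
                n_lines=n_lines,
                seed=17,
                noise_sd_viability=0.03,
                planted_synergies=plants,
                broad_sensitizer=None,
                planted_cparp_outliers=[],
            )
        )
        scores = score_dataset(ds)
        std = scores[scores["tier"] == "standard"]
        hits = std[std["bliss_score"] > 25.0]
        hit_events = set(
            zip(hits["drug_a"], hits["drug_b"], hits["line_id"], hits["tier"])
        )
        all_planted = gt.synergy_events()
        # recall over events whose imprinted drop clears the threshold by
        # ~3 score SDs; precision against every planted event (a truncated
        # planted synergy detected at the threshold is still a true call)
        detectable = gt.detectable_events(40.0)
        assert len(detectable) >= 50
        recall = len(hit_events & detectable) / len(detectable)
        precision = len(hit_events & all_planted) / max(len(hit_events), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_breadth_fraction_matches_brute_force(self, small_scores):
        breadth = synergy_breadth(small_scores, threshold_pct=30.0)
        std = small_scores[small_scores["tier"] == "standard"]
        per_pair = (
            std[std["bliss_score"] > 30.0]
            .groupby(["drug_a", "drug_b"])["line_id"]
            .nunique()
        )
        for k in (1, 2, 3, 5):
            brute = (per_pair <= k).sum() / len(per_pair)
            assert breadth.fraction_le(k) == pytest.approx(brute)

    def test_no_hits_yields_empty_histogram(self, null_screen):
        ds, _ = null_screen
        breadth = synergy_breadth(score_dataset(ds), threshold_pct=5.0)
        assert breadth.histogram.empty
        assert np.isnan(breadth.fraction_le(3))


class TestSyntheticLethalityRate:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["is_synergy_hit", "is_synthetic_lethal"]
        ).assign(tier="standard")

    def test_all_hits_synthetic_lethal(self):
        rate = synthetic_lethality_rate(self._frame([[True, True]] * 4))
        assert rate.percent == 100.0 and rate.defined

    def test_no_hits_is_flagged_undefined(self):
        rate = synthetic_lethality_rate(self._frame([[False, False]] * 4))
        assert not rate.defined
        assert np.isnan(rate.percent)

    def test_matches_brute_force_filter(self, small_scores):
        rate = synthetic_lethality_rate(small_scores)
        hits = small_scores[small_scores["is_synergy_hit"]]
        brute = 100.0 * hits["is_synthetic_lethal"].sum() / len(hits)
        assert rate.percent == pytest.approx(brute)

    def test_planted_ratio_exact(self):
        # hand-built: 3 hits of which 1 synthetic lethal -> 33.33%
        rate = synthetic_lethality_rate(
            self._frame([[True, True], [True, False], [True, False], [False, False]])
        )
        assert rate.percent == pytest.approx(100.0 / 3.0)


class TestPromiscuity:
    def test_planted_sensitizer_ranks_first(self, small_screen, small_scores):
        _, gt = small_screen
        ranking = promiscuity_index(small_scores)
        assert ranking.iloc[0]["drug"] == gt.sensitizer.drug_id

    def test_null_screen_all_zero(self, null_screen):
        ds, _ = null_screen
        assert promiscuity_index(score_dataset(ds)).empty

    def test_symmetric_in_pair_order(self, small_scores):
        swapped = small_scores.rename(columns={"drug_a": "drug_b", "drug_b": "drug_a"})
        a = promiscuity_index(small_scores)
        b = promiscuity_index(swapped)
        pd.testing.assert_frame_equal(a, b)


def test_bliss_matrix_shape_and_values(small_scores):
    mat = bliss_matrix(small_scores, tier="standard")
    std = small_scores[small_scores["tier"] == "standard"]
    assert mat.shape == (std.groupby(["drug_a", "drug_b"]).ngroups, 8)
    row = std.iloc[0]
    assert mat.at[f"{row.drug_a}|{row.drug_b}", row.line_id] == pytest.approx(
        row.bliss_score
    )
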