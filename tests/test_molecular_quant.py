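"""qPCR quantification, ChIP enrichment, blot normalization, localization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuroquant.molecular_quant import (
    chip_fold_enrichment,
    fit_efficiency,
    genorm_stability,
    manders_coefficient,
    mean_ct,
    normalize_to_control,
    relative_difference,
    relative_expression,
)
from neuroquant.simulate import QpcrSimParams, simulate_ct_table


def _ct_rows(sample, group, gene, cts):
    return [{"sample_id": sample, "group": group, "gene": gene,
             "replicate": i, "ct": c} for i, c in enumerate(cts)]


class TestEfficiency:
    def test_perfect_doubling_chemistry(self):
        # Ct rises by log2(10) = 3.3219 cycles per 10-fold dilution
        logd = np.array([0.0, -1.0, -2.0, -3.0, -4.0])
        ct = 20.0 - np.log2(10.0) * logd
        fit = fit_efficiency(logd, ct)
        assert fit.efficiency == pytest.approx(2.0, abs=5e-4)
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_minus_3_6(self):
        logd = np.array([0.0, -1.0, -2.0, -3.0, -4.0])
        fit = fit_efficiency(logd, 20.0 - 3.6 * logd)
        assert fit.efficiency == pytest.approx(10 ** (1 / 3.6), rel=1e-9)
        assert fit.efficiency == pytest.approx(1.896, abs=5e-4)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_efficiency([0, -1, -2], [20.0, 19.0, 18.0])


class TestGenorm:
    def test_identical_patterns_give_zero_m(self):
        rows = []
        for s, offset in [("S1", 0.0), ("S2", 1.0), ("S3", -0.5)]:
            for gene in ("GAPDH", "ACTB", "HPRT1"):
                rows += _ct_rows(s, "G", gene, [20.0 + offset] * 3)
        m = genorm_stability(pd.DataFrame(rows), ["GAPDH", "ACTB", "HPRT1"],
                             {g: 2.0 for g in ("GAPDH", "ACTB", "HPRT1")})
        assert np.allclose(m.to_numpy(), 0.0, atol=1e-12)

    def test_planted_unstable_gene_ranks_last(self):
        """A reference with added log2 noise gets the highest M in >=95% of seeds."""
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            params = QpcrSimParams(
                target_folds={},
                ref_genes={"GAPDH": 0.05, "ACTB": 0.05, "HPRT1": 0.05,
                           "BAD": 0.5},
                replicate_sd=0.0, sample_sd_log2=0.0)
            ct, _ = simulate_ct_table(params, seed=seed)
            m = genorm_stability(ct, ["GAPDH", "ACTB", "HPRT1", "BAD"],
                                 params.efficiencies)
            wins += m.idxmax() == "BAD"
        assert wins / n_seeds >= 0.95

    def test_fewer_than_three_genes_rejected(self):
        rows = _ct_rows("S1", "G", "A", [20]) + _ct_rows("S1", "G", "B", [20])
        with pytest.raises(ValueError, match="3 candidate"):
            genorm_stability(pd.DataFrame(rows), ["A", "B"],
                             {"A": 2.0, "B": 2.0})

    def test_invariant_to_scaling_one_gene(self, rng):
        rows = []
        for s in ("S1", "S2", "S3", "S4"):
            for gene in ("A", "B", "C"):
                rows += _ct_rows(s, "G", gene, [20 + rng.normal(0, 0.3)])
        eff = {g: 2.0 for g in "ABC"}
        ct = pd.DataFrame(rows)
        m1 = genorm_stability(ct, list("ABC"), eff)
        shifted = ct.copy()  # multiplying Q of gene A <=> constant Ct shift
        shifted.loc[shifted.gene == "A", "ct"] += 3.0
        m2 = genorm_stability(shifted, list("ABC"), eff)
        np.testing.assert_allclose(m1.sort_index(), m2.sort_index(), atol=1e-12)


class TestRelativeExpression:
    REFS = ["GAPDH", "ACTB", "HPRT1"]

    def _table(self, target_delta_treated=0.0):
        rows = []
        for group, samples in [("WT_Ctrl", ["C1", "C2"]), ("Treated", ["T1", "T2"])]:
            for s in samples:
                for gene in self.REFS:
                    rows += _ct_rows(s, group, gene, [20.0] * 3)
                delta = target_delta_treated if group == "Treated" else 0.0
                rows += _ct_rows(s, group, "Itgb3", [25.0 + delta] * 3)
        return pd.DataFrame(rows)

    def test_identical_cts_give_unity(self):
        eff = {g: 2.0 for g in self.REFS + ["Itgb3"]}
        res = relative_expression(self._table(), self.REFS, "WT_Ctrl", eff)
        np.testing.assert_allclose(res["normalized"], 1.0, atol=1e-12)

    def test_one_cycle_lower_is_twofold(self):
        eff = {g: 2.0 for g in self.REFS + ["Itgb3"]}
        res = relative_expression(self._table(-1.0), self.REFS, "WT_Ctrl", eff)
        treated = res[res.group == "Treated"]["normalized"]
        np.testing.assert_allclose(treated, 2.0, atol=1e-12)

    def test_calibrator_mean_is_one(self):
        params = QpcrSimParams()
        ct, _ = simulate_ct_table(params, seed=11)
        res = relative_expression(ct, self.REFS, "WT_Ctrl", params.efficiencies)
        cal = res[res.group == "WT_Ctrl"].groupby("gene")["normalized"].mean()
        np.testing.assert_allclose(cal, 1.0, atol=1e-9)

    def test_matches_spreadsheet_oracle(self, rng):
        """4 genes x 6 samples with mixed efficiencies: the pipeline matches
        an independent spreadsheet-style evaluation of the ddCt algebra."""
        eff = {"Itgb3": 2.0, "GAPDH": 1.95, "ACTB": 1.9, "HPRT1": 1.92}
        rows = []
        cts = {}
        for group, samples in [("WT_Ctrl", ["C1", "C2", "C3"]),
                               ("Het", ["H1", "H2", "H3"])]:
            for s in samples:
                for gene in eff:
                    base = 25.0 if gene == "Itgb3" else 20.0
                    if gene == "Itgb3" and group == "Het":
                        base += 1.0  # planted 0.5x fold at E=2
                    ct_val = base + rng.normal(0.0, 0.2)
                    cts[(s, gene)] = ct_val
                    rows += _ct_rows(s, group, gene, [ct_val] * 3)
        res = relative_expression(pd.DataFrame(rows), self.REFS, "WT_Ctrl", eff)

        # independent oracle: explicit per-sample computation
        cal_samples = ["C1", "C2", "C3"]
        cal_mean = {g: np.mean([cts[(s, g)] for s in cal_samples]) for g in eff}
        expected = {}
        for s in ["C1", "C2", "C3", "H1", "H2", "H3"]:
            q = {g: eff[g] ** (cal_mean[g] - cts[(s, g)]) for g in eff}
            nf = (q["GAPDH"] * q["ACTB"] * q["HPRT1"]) ** (1.0 / 3.0)
            expected[s] = q["Itgb3"] / nf
        scale = np.mean([expected[s] for s in cal_samples])
        got = res.set_index("sample_id")["normalized"]
        for s, val in expected.items():
            assert got[s] == pytest.approx(val / scale, rel=1e-6)

    def test_missing_reference_drops_sample(self):
        table = self._table()
        table = table[~((table.sample_id == "T1") & (table.gene == "GAPDH"))]
        eff = {g: 2.0 for g in self.REFS + ["Itgb3"]}
        res = relative_expression(table, self.REFS, "WT_Ctrl", eff)
        assert "T1" not in set(res["sample_id"])
        assert res.attrs["dropped"][0][0] == "T1"

    def test_plate_offset_invariance(self):
        """Adding a constant to every Ct of one gene cancels in the ratios."""
        eff = {g: 2.0 for g in self.REFS + ["Itgb3"]}
        t1 = self._table(-1.0)
        t2 = t1.copy()
        t2.loc[t2.gene == "Itgb3", "ct"] += 2.5
        r1 = relative_expression(t1, self.REFS, "WT_Ctrl", eff)
        r2 = relative_expression(t2, self.REFS, "WT_Ctrl", eff)
        np.testing.assert_allclose(r1["normalized"], r2["normalized"],
                                   rtol=1e-12)

    def test_noisy_triplicates_flagged(self):
        rows = _ct_rows("S1", "G", "A", [20.0, 21.5, 20.2])
        out = mean_ct(pd.DataFrame(rows))
        assert bool(out.loc[0, "flagged"])


class TestChipEnrichment:
    def _table(self, ip_treat, ip_ctrl, inp=20.0):
        rows = []
        for group, ip in [("treatment", ip_treat), ("control", ip_ctrl)]:
            sid = f"{group}_1"
            rows.append({"sample_id": sid, "group": group, "fraction": "ip",
                         "ct": ip})
            rows.append({"sample_id": sid, "group": group, "fraction": "input",
                         "ct": inp})
        return pd.DataFrame(rows)

    def test_two_cycles_is_fourfold(self):
        res = chip_fold_enrichment(self._table(23.0, 25.0), input_dilution=100)
        fold = res.set_index("group")["fold_enrichment"]
        assert fold["treatment"] == pytest.approx(4.0, rel=1e-12)
        assert fold["control"] == pytest.approx(1.0)

    def test_equal_conditions_fold_one(self):
        res = chip_fold_enrichment(self._table(24.0, 24.0), input_dilution=100)
        np.testing.assert_allclose(res["fold_enrichment"], 1.0)

    def test_percent_input_hand_computation(self):
        # Ct_input == Ct_IP with 100x diluted input: %input = 100 * 2^-log2(100)
        res = chip_fold_enrichment(self._table(20.0, 20.0), input_dilution=100)
        np.testing.assert_allclose(res["percent_input"], 1.0, rtol=1e-12)

    def test_missing_input_rejected(self):
        table = self._table(23.0, 25.0)
        with pytest.raises(ValueError, match="input"):
            chip_fold_enrichment(table[table.fraction == "ip"],
                                 input_dilution=100)


class TestNormalizeToControl:
    def test_fold_over_control_mean(self):
        out = normalize_to_control({"c1": 2.0, "c2": 2.0, "s": 3.0},
                                   ["c1", "c2"])
        assert out["s"] == pytest.approx(1.5)

    def test_phospho_over_total_first(self):
        out = normalize_to_control(
            {"pA": 4.0, "tA": 2.0, "pC": 1.0, "tC": 1.0},
            ["pC"], phospho_total={"pA": "tA", "pC": "tC"})
        assert out["pA"] == pytest.approx(2.0)

    def test_order_invariance(self):
        v1 = {"a": 1.0, "b": 2.0, "c": 3.0}
        v2 = {"c": 3.0, "a": 1.0, "b": 2.0}
        o1 = normalize_to_control(v1, ["a"])
        o2 = normalize_to_control(v2, ["a"])
        for k in v1:
            assert o1[k] == o2[k]

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            normalize_to_control({"c": 0.0, "s": 1.0}, ["c"])


class TestRelativeDifference:
    def test_limits_and_symmetry(self):
        assert relative_difference(100.0, 0.0) == 1.0
        assert relative_difference(0.0, 100.0) == -1.0
        assert relative_difference(5.0, 5.0) == 0.0

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_antisymmetric_and_bounded(self, s, d):
        if s + d <= 0:
            with pytest.raises(ValueError):
                relative_difference(s, d)
            return
        rd = relative_difference(s, d)
        assert -1.0 <= rd <= 1.0
        assert rd == pytest.approx(-relative_difference(d, s), abs=1e-12)

    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4),
           st.floats(0.01, 1e3))
    def test_scale_invariant(self, s, d, c):
        assert relative_difference(c * s, c * d) == pytest.approx(
            relative_difference(s, d), rel=1e-9)

    def test_non_positive_total_excluded(self):
        with pytest.raises(ValueError):
            relative_difference(0.0, 0.0)


class TestManders:
    def test_identical_channels(self):
        a = np.array([0.0, 10.0, 20.0, 30.0])
        m_a, m_b = manders_coefficient(a, a, 5.0, 5.0)
        assert m_a == 1.0 and m_b == 1.0

    def test_disjoint_masks(self):
        a = np.array([10.0, 0.0, 0.0])
        b = np.array([0.0, 10.0, 0.0])
        m_a, m_b = manders_coefficient(a, b, 5.0, 5.0)
        assert m_a == 0.0 and m_b == 0.0

    def test_hand_computed_partial_overlap(self):
        a = np.array([10.0, 20.0, 30.0, 1.0])
        b = np.array([0.0, 50.0, 50.0, 0.0])
        m_a, _ = manders_coefficient(a, b, 5.0, 5.0)
        assert m_a == pytest.approx(50.0 / 60.0)

    def test_empty_mask_is_nan(self):
        a = np.array([1.0, 2.0])
        b = np.array([10.0, 20.0])
        m_a, m_b = manders_coefficient(a, b, 5.0, 5.0)
        assert np.isnan(m_a) and m_b == 0.0

    def test_invariant_to_partner_rescaling(self, rng):
        a = rng.uniform(0, 100, 500)
        b = rng.uniform(0, 100, 500)
        m_a1, _ = manders_coefficient(a, b, 30.0, 30.0)
        m_a2, _ = manders_coefficient(a, 10.0 * b, 30.0, 300.0)
        assert m_a1 == pytest.approx(m_a2, rel=1e-12)
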