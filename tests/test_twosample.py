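import numpy as np
import pandas as pd
import pytest

import proteomr as pm
from proteomr.twosample import harmonize


def _row(snp="rs1", ea="A", oa="G", eaf=0.3, beta=0.2, se=0.05, p=1e-4,
         n=4000, trait="X", chrom="1", pos=100):
    return {"snp_id": snp, "chrom": chrom, "pos": pos, "effect_allele": ea,
            "other_allele": oa, "eaf": eaf, "beta": beta, "se": se,
            "p": p, "n": n, "trait": trait}


class TestHarmonize:
    def test_identical_alleles_unchanged(self):
        exp = pd.DataFrame([_row()])
        out = pd.DataFrame([_row(beta=-0.1, trait="BMI")])
        pair = harmonize(exp, out)
        r = pair.table.iloc[0]
        assert r["beta_out"] == -0.1 and not r["flipped"]

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = pd.DataFrame([_row(ea="A", oa="G", eaf=0.3)])
        out = pd.DataFrame([_row(ea="G", oa="A", eaf=0.7, beta=-0.2)])
        r = harmonize(exp, out).table.iloc[0]
        assert r["beta_out"] == pytest.approx(0.2)
        assert r["eaf_out"] == pytest.approx(0.3)
        assert r["flipped"]

    def test_palindromic_ambiguous_dropped(self):
        exp = pd.DataFrame([_row(ea="A", oa="T", eaf=0.50),
                            _row(snp="rs2")])
        out = pd.DataFrame([_row(ea="A", oa="T", eaf=0.50),
                            _row(snp="rs2")])
        pair = harmonize(exp, out)
        assert pair.dropped == [("rs1", "palindromic-ambiguous")]
        assert list(pair.table["snp_id"]) == ["rs2"]

    def test_palindromic_unambiguous_kept(self):
        exp = pd.DataFrame([_row(ea="C", oa="G", eaf=0.10)])
        out = pd.DataFrame([_row(ea="C", oa="G", eaf=0.12, beta=0.3)])
        r = harmonize(exp, out).table.iloc[0]
        assert r["beta_out"] == pytest.approx(0.3)

    def test_allele_mismatch_dropped_with_reason(self):
        exp = pd.DataFrame([_row(ea="A", oa="G"),
                            _row(snp="rs2")])
        out = pd.DataFrame([_row(ea="C", oa="T"),
                            _row(snp="rs2")])
        pair = harmonize(exp, out)
        assert ("rs1", "allele-mismatch") in pair.dropped

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        p = pm.SimParams(n_subjects=200, n_variants=30, n_proteins=6,
                         n_reverse=2, seed=31)
        _, _, truth = pm.simulate_cohort(p)
        exp, out = pm.simulate_sumstats(truth, 4000, 170_000, seed=2)
        t = exp[exp["trait"] == exp["trait"].iloc[0]]
        pair1 = harmonize(t, out).table
        # re-harmonise the harmonised output against itself
        back_exp = pair1.rename(columns={
            "eaf_exp": "eaf", "beta_exp": "beta", "se_exp": "se",
            "p_exp": "p", "n_exp": "n"})[
            ["snp_id", "effect_allele", "other_allele", "eaf", "beta",
             "se", "p", "n"]]
        back_out = pair1.rename(columns={
            "eaf_out": "eaf", "beta_out": "beta", "se_out": "se",
            "p_out": "p", "n_out": "n"})[
            ["snp_id", "effect_allele", "other_allele", "eaf", "beta",
             "se", "p", "n"]]
        pair2 = harmonize(back_exp, back_out).table
        assert not pair2["flipped"].any()
        np.testing.assert_allclose(pair2["beta_out"], pair1["beta_out"])

    def test_empty_intersection_errors(self):
        exp = pd.DataFrame([_row(snp="rs1")])
        out = pd.DataFrame([_row(snp="rs2")])
        with pytest.raises(ValueError, match="no shared"):
            harmonize(exp, out)


class TestWaldRatio:
    def test_hand_computation(self):
        r = pm.wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert r["beta"] == pytest.approx(0.2)
        assert r["se"] == pytest.approx(0.04)

    def test_null_outcome(self):
        r = pm.wald_ratio(0.5, 0.05, 0.0, 0.02)
        assert r["beta"] == 0.0 and r["p"] == 1.0

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError):
            pm.wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_strong_cis_regime_consistency(self):
        """A strong cis-pQTL (0.73, SE 0.033) with the outcome effect
        implied by a reported ratio reproduces that ratio, -0.026 (SE
        0.006) -- a consistency check on the delta-method scaling."""
        b_out = -0.026 * 0.73         # back-computed outcome beta
        r = pm.wald_ratio(0.73, 0.033, b_out, 0.006 * 0.73)
        assert r["beta"] == pytest.approx(-0.026, abs=1e-12)
        assert r["se"] == pytest.approx(0.006, abs=1e-12)

    def test_second_order_se_larger(self):
        r1 = pm.wald_ratio(0.5, 0.1, 0.2, 0.02)
        r2 = pm.wald_ratio(0.5, 0.1, 0.2, 0.02, second_order=True)
        assert r2["se"] > r1["se"]


class TestSteiger:
    def test_tie_gives_no_direction(self):
        r = pm.steiger_filter(0.1, 0.02, 4000, 0.1, 0.02, 4000)
        assert r.z == pytest.approx(0.0)
        assert not r.direction_ok

    def test_forward_regime_accuracy(self):
        """Strong cis effect on the exposure, null outcome: the exposure ->
        outcome direction is supported in >=95% of replicates."""
        rng = np.random.default_rng(32)
        n_exp, n_out, r2 = 4000, 170_000, 0.10
        ok = []
        for _ in range(300):
            se_e = 1.0 / np.sqrt(n_exp)
            b_e = np.sqrt(r2 / (1 - r2) / n_exp) * np.sqrt(n_exp) + \
                se_e * rng.normal()
            se_o = 1.0 / np.sqrt(n_out)
            b_o = se_o * rng.normal()
            ok.append(pm.steiger_filter(b_e, se_e, n_exp, b_o, se_o,
                                        n_out).direction_ok)
        assert np.mean(ok) >= 0.95

    def test_reversed_regime_accuracy(self):
        """Variant drives the outcome, not the exposure: direction_ok is
        false in >=95% of replicates."""
        rng = np.random.default_rng(33)
        n_exp, n_out, r2 = 4000, 170_000, 0.05
        ok = []
        for _ in range(300):
            se_e = 1.0 / np.sqrt(n_exp)
            b_e = se_e * rng.normal()
            se_o = 1.0 / np.sqrt(n_out)
            b_o = np.sqrt(r2 / (1 - r2) / n_out) * np.sqrt(n_out) + \
                se_o * rng.normal()
            ok.append(pm.steiger_filter(b_e, se_e, n_exp, b_o, se_o,
                                        n_out).direction_ok)
        assert np.mean(ok) <= 0.05

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            pm.steiger_filter(0.1, 0.02, 5, 0.1, 0.02, 4000)


@pytest.fixture(scope="module")
def scan_inputs():
    p = pm.SimParams(n_subjects=600, n_variants=50, n_proteins=40,
                     n_reverse=4, seed=41)
    _, _, truth = pm.simulate_cohort(p)
    exp, out = pm.simulate_sumstats(truth, 4000, 170_000, seed=41)
    win = truth.cis_assignments.assign(
        start=lambda d: (d["gene_pos"] - 500_000).clip(lower=1),
        end=lambda d: d["gene_pos"] + 500_000)[
        ["protein", "chrom", "start", "end"]]
    tables = {pr: t for pr, t in exp.groupby("trait")}
    return truth, tables, out, win


class TestBidirectionalScan:

    def test_reverse_proteins_recovered(self, scan_inputs):
        truth, tables, out, win = scan_inputs
        scan = pm.bidirectional_scan(tables, out, win)
        fwd = scan[scan["direction"] == "protein_to_bmi"]
        hits = set(fwd.loc[fwd["significant"], "protein"])
        rev = set(truth.reverse_set)
        sensitivity = len(hits & rev) / len(rev)
        assert sensitivity >= 0.75
        false_pos = hits - rev
        assert len(false_pos) <= 2

    def test_steiger_supports_reverse_direction(self, scan_inputs):
        truth, tables, out, win = scan_inputs
        scan = pm.bidirectional_scan(tables, out, win)
        fwd = scan[(scan["direction"] == "protein_to_bmi")
                   & scan["protein"].isin(truth.reverse_set)]
        assert fwd["steiger_ok"].mean() >= 0.75

    def test_bmi_to_protein_direction_finds_forward_effects(self,
                                                            scan_inputs):
        truth, tables, out, win = scan_inputs
        scan = pm.bidirectional_scan(tables, out, win)
        rev_dir = scan[scan["direction"] == "bmi_to_protein"]
        sig = rev_dir[rev_dir["significant"]].set_index("protein")
        strong = truth.beta_bmi_to_protein[
            truth.beta_bmi_to_protein.abs() > 0.3].index
        found = len(set(strong) & set(sig.index)) / max(len(strong), 1)
        assert found >= 0.7

    def test_constructed_bidirectional_case(self):
        """A protein with both a forward and a reverse effect is flagged in
        both directions (the bi-directional feedback pattern)."""
        rows_exp, rows_out = [], []
        # cis instrument: strong on protein, real effect on BMI
        rows_exp.append(_row(snp="cisX", chrom="2", pos=500,
                             beta=0.5, se=0.016, p=1e-200, trait="PX"))
        rows_out.append(_row(snp="cisX", chrom="2", pos=500,
                             beta=-0.05, se=0.003, p=1e-60, trait="BMI"))
        # BMI instruments: strong on BMI, proportional effect on protein
        for i in range(3):
            rows_exp.append(_row(snp=f"g{i}", chrom="1", pos=10 + i,
                                 beta=0.02, se=0.002, p=1e-20, trait="PX"))
            rows_out.append(_row(snp=f"g{i}", chrom="1", pos=10 + i,
                                 beta=0.04, se=0.002, p=1e-80, trait="BMI"))
        win = pd.DataFrame([{"protein": "PX", "chrom": "2",
                             "start": 1, "end": 1000}])
        scan = pm.bidirectional_scan({"PX": pd.DataFrame(rows_exp)},
                                     pd.DataFrame(rows_out), win)
        assert scan["bidirectional"].all()
        assert set(scan["direction"]) == {"protein_to_bmi",
                                          "bmi_to_protein"}

    def test_protein_without_window_skipped(self, scan_inputs):
        truth, tables, out, win = scan_inputs
        scan = pm.bidirectional_scan(tables, out, win.iloc[:5])
        assert scan["protein"].nunique() <= 5
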