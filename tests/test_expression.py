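"""Normalisation, the NB exact test, DE calling and the qPCR helper."""

import numpy as np
import pandas as pd
import pytest

from mirwood import expression as expr


def matrix(data, columns=None, totals=None, lengths=None):
    df = pd.DataFrame(data, columns=columns)
    return expr.ExpressionMatrix(
        df,
        library_totals=pd.Series(totals) if totals is not None else None,
        feature_lengths=pd.Series(lengths) if lengths is not None else None)


class TestTPM:
    def test_worked_example(self):
        m = matrix({"L1": [1]}, totals={"L1": 1_000_000})
        assert expr.tpm_normalize(m).iloc[0, 0] == 1.0

    def test_zero_count(self):
        m = matrix({"L1": [0, 5]}, totals={"L1": 100})
        assert expr.tpm_normalize(m).iloc[0, 0] == 0.0

    def test_scale_invariance(self):
        m1 = matrix({"L1": [3, 7]})
        m2 = matrix({"L1": [6, 14]})
        pd.testing.assert_frame_equal(expr.tpm_normalize(m1), expr.tpm_normalize(m2))

    def test_column_sums_to_one_million_with_default_totals(self, rng):
        m = matrix({f"L{i}": rng.integers(0, 500, 50) for i in range(4)})
        tpm = expr.tpm_normalize(m)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_zero_total_library_rejected(self):
        with pytest.raises(ValueError, match="L1"):
            expr.tpm_normalize(matrix({"L1": [0, 0]}))


class TestFPKM:
    def test_worked_example(self):
        m = matrix({"L1": [100]}, totals={"L1": 1_000_000}, lengths={0: 1000})
        assert expr.fpkm_normalize(m).iloc[0, 0] == pytest.approx(100.0)

    def test_length_halves_fpkm(self):
        m = matrix({"L1": [100, 100]}, totals={"L1": 1_000_000},
                   lengths={0: 1000, 1: 2000})
        f = expr.fpkm_normalize(m)
        assert f.iloc[1, 0] == pytest.approx(f.iloc[0, 0] / 2)

    def test_missing_length_rejected(self):
        m = matrix({"L1": [1, 1]}, lengths={0: 1000})
        with pytest.raises(ValueError):
            expr.fpkm_normalize(m)


class TestNBExactTest:
    def test_identical_groups_give_p_one(self):
        assert expr.nb_exact_test([5, 5, 5], [5, 5, 5], 0.05) == 1.0

    def test_binomial_closed_form_at_zero_dispersion(self):
        p = expr.nb_exact_test([0], [20], 0.0)
        assert p == pytest.approx(2 * 0.5 ** 20, rel=1e-9)

    def test_all_zero_feature(self):
        assert expr.nb_exact_test([0, 0], [0, 0], 0.05) == 1.0

    def test_swapping_groups_preserves_p(self, rng):
        for _ in range(10):
            a = rng.integers(0, 200, 3)
            b = rng.integers(0, 200, 3)
            assert expr.nb_exact_test(a, b, 0.05) == pytest.approx(
                expr.nb_exact_test(b, a, 0.05), rel=1e-9)

    def test_dispersion_zero_matches_small_positive_limit(self):
        p0 = expr.nb_exact_test([10, 12, 9], [30, 28, 33], 0.0)
        p_eps = expr.nb_exact_test([10, 12, 9], [30, 28, 33], 1e-8)
        assert p0 == pytest.approx(p_eps, rel=1e-3)

    def test_uniform_null_p_at_zero_dispersion(self, rng):
        # conditional binomial null: p-values near-uniform despite discreteness
        pvals = []
        for _ in range(2000):
            mu = 80
            a = rng.poisson(mu, 3)
            b = rng.poisson(mu, 3)
            pvals.append(expr.nb_exact_test(a, b, 0.0))
        frac = np.mean(np.asarray(pvals) <= 0.05)
        assert abs(frac - 0.05) < 0.02


class TestDECalling:
    def build(self, rows, totals=None):
        # explicit library totals mirror the pipeline contract, where TPM uses
        # per-library clean-read totals rather than the matrix column sums
        libs = ["PS1", "PS2", "PS3", "TS1", "TS2", "TS3"]
        df = pd.DataFrame(rows, columns=libs)
        lt = pd.Series(totals if totals is not None else 10_000, index=libs)
        return expr.ExpressionMatrix(df, library_totals=lt), {l: l[:-1] for l in libs}

    def test_strong_effect_called_with_direction(self):
        m, groups = self.build([[50, 52, 48, 400, 410, 390],
                                [100, 100, 100, 100, 100, 100]])
        de = expr.call_de_mirnas(m, ("PS", "TS"), groups, dispersion=0.01)
        assert bool(de.iloc[0]["called"]) and de.iloc[0]["direction"] == "up"
        assert not de.iloc[1]["called"]

    def test_fold_change_below_threshold_not_called(self):
        m, groups = self.build([[1000, 1000, 1000, 1900, 1900, 1900],
                                [10, 10, 10, 10, 10, 10]])
        de = expr.call_de_mirnas(m, ("PS", "TS"), groups, dispersion=0.0)
        row = de.iloc[0]
        assert row["p"] < 0.05 and abs(row["log2fc"]) < 1 and not row["called"]

    def test_insignificant_p_not_called(self):
        m, groups = self.build([[1, 0, 1, 3, 2, 3],
                                [500, 500, 500, 500, 500, 500]])
        de = expr.call_de_mirnas(m, ("PS", "TS"), groups, dispersion=0.05)
        row = de.iloc[0]
        assert abs(row["log2fc"]) >= 1 and row["p"] > 0.05 and not row["called"]

    def test_swapping_comparison_flips_log2fc(self):
        m, groups = self.build([[50, 52, 48, 400, 410, 390]])
        fwd = expr.call_de_mirnas(m, ("PS", "TS"), groups, dispersion=0.01)
        rev = expr.call_de_mirnas(m, ("TS", "PS"), groups, dispersion=0.01)
        assert fwd.iloc[0]["log2fc"] == pytest.approx(-rev.iloc[0]["log2fc"])
        assert fwd.iloc[0]["p"] == pytest.approx(rev.iloc[0]["p"])

    def test_unknown_stage_rejected(self):
        m, groups = self.build([[1, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError):
            expr.call_de_mirnas(m, ("PS", "XX"), groups)

    def test_degs_use_fdr(self):
        libs = ["PS1", "PS2", "PS3", "TS1", "TS2", "TS3"]
        rows = [[50, 52, 48, 400, 410, 390]] + [[100] * 6] * 40
        df = pd.DataFrame(rows, columns=libs,
                          index=[f"G{i}" for i in range(41)])
        m = expr.ExpressionMatrix(df, feature_lengths=pd.Series(
            1000, index=df.index))
        degs = expr.call_degs(m, ("PS", "TS"), {l: l[:-1] for l in libs},
                              dispersion=0.01)
        assert bool(degs.loc["G0", "called"])
        assert degs.loc["G0", "fdr"] <= 0.05


class TestBH:
    def test_hand_computed_example(self):
        fdr = expr.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(fdr, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert expr.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        fdr = expr.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)


class TestDeltaDeltaCt:
    def table(self):
        rows = []
        for sample, tgt_ct in (("PS", 25.0), ("TS", 24.0), ("SS", 28.32)):
            for rep in range(3):
                rows.append({"sample": sample, "assay": "miR1", "replicate": rep,
                             "ct": tgt_ct})
                rows.append({"sample": sample, "assay": "5.8S", "replicate": rep,
                             "ct": 20.0})
        return expr.CtTable(data=pd.DataFrame(rows), reference_assay="5.8S",
                            calibrator_sample="PS")

    def test_calibrator_is_exactly_one(self):
        out = expr.delta_delta_ct(self.table())
        row = out[(out["sample"] == "PS")].iloc[0]
        assert row["relative_expression"] == 1.0

    def test_one_cycle_lower_doubles_expression(self):
        out = expr.delta_delta_ct(self.table())
        assert out[out["sample"] == "TS"].iloc[0]["relative_expression"] == \
            pytest.approx(2.0)

    def test_3_32_cycles_is_tenfold_down(self):
        out = expr.delta_delta_ct(self.table())
        assert out[out["sample"] == "SS"].iloc[0]["relative_expression"] == \
            pytest.approx(2 ** -3.32, rel=1e-6)

    def test_missing_reference_rejected(self):
        t = self.table()
        data = t.data[~((t.data["assay"] == "5.8S") & (t.data["sample"] == "TS"))]
        broken = expr.CtTable(data=data, reference_assay="5.8S",
                              calibrator_sample="PS")
        with pytest.raises(ValueError):
            expr.delta_delta_ct(broken)
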