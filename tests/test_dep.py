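import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ratioscreen.core_io import AbundanceMatrix, SampleInfo, ValidationError
from ratioscreen.dep import (
    DesignSpec,
    ModerationParams,
    bh_adjust,
    build_design,
    fit_models,
    moderate,
    nominal_dep_filter,
    run_dep,
)
from ratioscreen.dep import test_contrasts as moderated_contrasts


def _cohort(severities, pots, values, sample_ids=None):
    sample_ids = sample_ids or [f"S{i}" for i in range(len(severities))]
    info = SampleInfo(
        pd.DataFrame(
            {"severity": severities, "pots": pots},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    matrix = AbundanceMatrix(
        pd.DataFrame(
            np.atleast_2d(values),
            index=[f"P{i}" for i in range(np.atleast_2d(values).shape[0])],
            columns=sample_ids,
        )
    )
    return matrix, info


class TestFitModels:
    def test_two_group_log2fc_is_mean_difference(self):
        # mild vs severe only, no POTS variation: the severity coefficient
        # reduces to the difference of group means
        sev = ["mild"] * 4 + ["severe"] * 4
        vals = np.array([[1.0, 2.0, 1.5, 1.5, 3.0, 3.5, 2.5, 3.0]])
        matrix, info = _cohort(sev, [False] * 8, vals)
        fits = fit_models(matrix, info, DesignSpec(contrasts=("Severe_vs_Mild",)))
        expected = vals[0, 4:].mean() - vals[0, :4].mean()
        assert fits.fits[0].coef["sev_severe"] == pytest.approx(expected)

    def test_constant_protein_gives_zero_contrasts_and_s2(self):
        sev = ["mild"] * 3 + ["moderate"] * 3 + ["severe"] * 3
        pots = [False, True, False, True, False, True, False, True, False]
        matrix, info = _cohort(sev, pots, np.full((1, 9), 5.0))
        fits = fit_models(matrix, info)
        fit = fits.fits[0]
        assert fit.s2 == pytest.approx(0.0)
        assert fit.coef["pots"] == pytest.approx(0.0)
        assert fit.coef["sev_severe"] == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        """Hand-solved (XᵀX)⁻¹Xᵀy on an 8-sample fixture with both covariates."""
        sev = ["mild", "mild", "moderate", "moderate", "moderate", "severe",
               "severe", "severe"]
        pots = [False, True, False, True, False, True, False, True]
        rng = np.random.default_rng(5)
        y = rng.normal(10, 1, size=8)
        matrix, info = _cohort(sev, pots, y[None, :])
        fits = fit_models(matrix, info)
        x = build_design(info).to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        got = fits.fits[0]
        np.testing.assert_allclose(
            [got.coef["intercept"], got.coef["pots"],
             got.coef["sev_moderate"], got.coef["sev_severe"]],
            beta, atol=1e-10,
        )
        resid = y - x @ beta
        assert got.s2 == pytest.approx(resid @ resid / (8 - 4))
        assert got.df == 4 and got.n_used == 8

    def test_rank_deficient_protein_skipped_with_reason(self):
        sev = ["mild"] * 3 + ["moderate"] * 5 + ["severe"] * 3
        pots = [False] * 5 + [True] * 6
        vals = np.vstack(
            [np.arange(11.0), np.r_[[np.nan] * 3, np.arange(8.0)]]  # no mild obs
        )
        matrix, info = _cohort(sev, pots, vals)
        fits = fit_models(matrix, info)
        assert [f.protein_id for f in fits.fits] == ["P0"]
        assert fits.skipped and fits.skipped[0][0] == "P1"


class TestModeration:
    def test_equal_variances_give_infinite_d0(self):
        params = moderate([2.0] * 10, [5] * 10)
        assert math.isinf(params.d0)
        assert params.posterior_s2(2.0, 5) == pytest.approx(params.s0_sq)

    def test_d0_zero_override_is_ordinary_t(self, small_cohort):
        matrix, info, _ = small_cohort
        fits = fit_models(matrix, info)
        records = moderated_contrasts(fits, ModerationParams(d0=0.0, s0_sq=1.0))
        fit = fits.fits[0]
        row = records[
            (records.protein_id == fit.protein_id)
            & (records.contrast == "POTS_vs_NoPOTS")
        ].iloc[0]
        se = math.sqrt(fit.s2 * fit.cov_unscaled.loc["pots", "pots"])
        assert row.t_mod == pytest.approx(fit.coef["pots"] / se)
        assert row.df_total == fit.df

    def test_prior_recovery_from_conjugate_simulation(self):
        """Variances drawn from the scaled inverse-χ² hierarchy (d0=4, s0²=2)
        are recovered with d0 in [2, 8] and s0² within 25%, in the median
        over 50 repetitions of 50 proteins."""
        rng = np.random.default_rng(123)
        d0_true, s0_true, d = 4.0, 2.0, 10
        d0s, s0s = [], []
        for _ in range(50):
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=50)
            s2 = sigma2 * rng.chisquare(d, size=50) / d
            params = moderate(s2, [d] * 50)
            d0s.append(params.d0)
            s0s.append(params.s0_sq)
        assert 2.0 <= np.median(d0s) <= 8.0
        assert abs(np.median(s0s) - s0_true) / s0_true < 0.25

    def test_needs_two_positive_variances(self):
        with pytest.raises(ValidationError):
            moderate([0.0, 0.0], [3, 3])


class TestModeratedT:
    def test_limits_ordinary_t_and_normal(self, small_cohort):
        matrix, info, _ = small_cohort
        fits = fit_models(matrix, info)
        fit = fits.fits[0]
        se_unscaled = math.sqrt(fit.cov_unscaled.loc["pots", "pots"])

        small = moderated_contrasts(fits, ModerationParams(d0=1e-6, s0_sq=1.0))
        row = small[(small.protein_id == fit.protein_id)
                    & (small.contrast == "POTS_vs_NoPOTS")].iloc[0]
        t_ord = fit.coef["pots"] / (math.sqrt(fit.s2) * se_unscaled)
        assert row.t_mod == pytest.approx(t_ord, rel=1e-4)

        s0 = 1.7
        big = moderated_contrasts(fits, ModerationParams(d0=1e6, s0_sq=s0))
        row = big[(big.protein_id == fit.protein_id)
                  & (big.contrast == "POTS_vs_NoPOTS")].iloc[0]
        t_z = fit.coef["pots"] / (math.sqrt(s0) * se_unscaled)
        assert row.t_mod == pytest.approx(t_z, rel=1e-4)
        assert row.p == pytest.approx(2 * stats.norm.sf(abs(t_z)), rel=1e-3)

    def test_infinite_d0_gives_normal_quantiles(self, small_cohort):
        matrix, info, _ = small_cohort
        fits = fit_models(matrix, info)
        records = moderated_contrasts(fits, ModerationParams(d0=math.inf, s0_sq=0.5))
        np.testing.assert_allclose(
            records.p, 2 * stats.norm.sf(records.t_mod.abs()), atol=1e-12
        )

    def test_invariant_to_sample_permutation(self, study_cohort):
        matrix, info, _ = study_cohort
        rec1, _, _ = run_dep(matrix, info)
        perm = np.random.default_rng(1).permutation(matrix.sample_ids)
        matrix2 = AbundanceMatrix(matrix.data[perm], log2=True)
        rec2, _, _ = run_dep(matrix2, info)
        merged = rec1.merge(rec2, on=["protein_id", "contrast"], suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged.t_mod_1, merged.t_mod_2, atol=1e-9)

    def test_agrees_with_limma_oracle(self, tmp_path):
        """Dual-route check of the whole moderated pipeline (prior estimation,
        posterior variances, contrasts, p-values) against limma on a complete
        fixture."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable: cannot run the limma oracle")
        from ratioscreen.synthetic import SimConfig, generate_dataset

        cfg = SimConfig(
            n_proteins=40,
            group_sizes={"mild": 3, "moderate": 6, "severe": 3},
            n_pots=4, censor_quantile=0.0, seed=11,
        )
        matrix, info, _ = generate_dataset(cfg)
        records, params, _ = run_dep(matrix, info)
        matrix.data.to_csv(tmp_path / "mat.tsv", sep="\t")
        build_design(info).to_csv(tmp_path / "design.tsv", sep="\t")
        rcode = f"""
        suppressMessages(library(limma))
        mat <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1))
        design <- as.matrix(read.delim("{tmp_path}/design.tsv", row.names=1))
        fit <- lmFit(mat, design)
        cm <- cbind(POTS=c(0,1,0,0), SvMi=c(0,0,0,1))
        fit2 <- eBayes(contrasts.fit(fit, cm))
        out <- data.frame(protein_id=rownames(mat),
                          d0=fit2$df.prior, s0=fit2$s2.prior,
                          t_pots=fit2$t[,1], p_pots=fit2$p.value[,1],
                          t_svmi=fit2$t[,2])
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        r = pd.read_csv(tmp_path / "limma.tsv", sep="\t").set_index("protein_id")
        assert params.d0 == pytest.approx(r.d0.iloc[0], rel=1e-5)
        assert params.s0_sq == pytest.approx(r.s0.iloc[0], rel=1e-5)
        pots = records[records.contrast == "POTS_vs_NoPOTS"].set_index("protein_id")
        svmi = records[records.contrast == "Severe_vs_Mild"].set_index("protein_id")
        np.testing.assert_allclose(pots.t_mod, r.loc[pots.index, "t_pots"], rtol=1e-8)
        np.testing.assert_allclose(pots.p, r.loc[pots.index, "p_pots"], rtol=1e-8)
        np.testing.assert_allclose(svmi.t_mod, r.loc[svmi.index, "t_svmi"], rtol=1e-8)


class TestBhAdjust:
    def test_worked_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_idempotence(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # step-up output is already monotone in the step-up sense: re-adjusting
        # an adjusted monotone vector cannot lower it below itself
        again = bh_adjust(adj)
        assert np.all(again >= adj - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestNominalFilter:
    def test_strict_inequalities(self):
        records = pd.DataFrame(
            {
                "protein_id": ["A", "B", "C", "D"],
                "contrast": ["Severe_vs_Mild"] * 4,
                "log2fc": [math.log2(1.6), math.log2(1.5), 1.0, -1.0],
                "p": [0.04, 0.04, 0.05, 0.01],
            }
        )
        per_contrast, union = nominal_dep_filter(records)
        assert per_contrast["Severe_vs_Mild"] == ["A", "D"]
        assert union == ["A", "D"]

    def test_union_deduplicates_across_contrasts(self):
        records = pd.DataFrame(
            {
                "protein_id": ["A", "B", "A", "C"],
                "contrast": ["Severe_vs_Mild", "Severe_vs_Mild",
                             "Moderate_vs_Mild", "Moderate_vs_Mild"],
                "log2fc": [1.0, 1.0, -1.0, 1.0],
                "p": [0.01, 0.01, 0.01, 0.01],
            }
        )
        per_contrast, union = nominal_dep_filter(records)
        assert len(per_contrast["Severe_vs_Mild"]) == 2
        assert len(per_contrast["Moderate_vs_Mild"]) == 2
        assert sorted(union) == ["A", "B", "C"]
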