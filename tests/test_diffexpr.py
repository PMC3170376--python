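"""Linear-model scan, permutation-null and FDR tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxtemp_gxe import diffexpr as de
from toxtemp_gxe import preprocess as pp
from toxtemp_gxe import synthetic_data as sd

from conftest import channels_matrix


def _channel_sheet(n_reps=6):
    """Channel-level sheet for the default 3-treatment, 2-temp layout."""
    cfg = sd.SimulationConfig(
        n_genes=1,
        n_replicates=n_reps,
        gene_class_proportions={"null": 1.0},
        effect_model={"null": {}},
    )
    _, sheet, _ = sd.generate_experiment(cfg)
    return sheet


def _ratio_rank_oracle(sheet, terms):
    """Independent aliasing oracle: greedy elimination over distinct cells."""
    cells = sheet[["cpf", "dzn", "temp"]].drop_duplicates().to_numpy()
    cols = {}
    for term in terms:
        if term == "Intercept":
            cols[term] = np.ones(len(cells))
        else:
            col = np.ones(len(cells))
            for part in term.split(":"):
                col = col * cells[:, {"CPF": 0, "DZN": 1, "Temp": 2}[part]]
            cols[term] = col
    kept, aliased = [], []
    for term in terms:
        candidate = np.column_stack([cols[t] for t in kept] + [cols[term]])
        if np.linalg.matrix_rank(candidate) > len(kept):
            kept.append(term)
        else:
            aliased.append(term)
    return len(kept), tuple(aliased)


class TestBuildDesign:
    def test_channel_level_full_factorial_rank_8(self):
        sheet = _channel_sheet()
        dm = de.build_design(sheet, de.ModelSpec.full_factorial())
        assert dm.rank == 8
        assert dm.aliased == ()

    def test_ratio_level_design_rank_6_with_aliasing(self, ratio_sample_sheet):
        spec = de.ModelSpec.full_factorial()
        oracle_rank, oracle_aliased = _ratio_rank_oracle(ratio_sample_sheet, spec.terms)
        dm = de.build_design(ratio_sample_sheet, spec)
        assert dm.rank == oracle_rank == 6
        assert dm.aliased == oracle_aliased
        # the two-way CPF:DZN product is an exact linear combination of
        # the mains on a design without a toxicant-free cell, so it (and
        # the three-way term) can never be estimated
        assert set(dm.aliased) == {"CPF:DZN", "CPF:DZN:Temp"}

    def test_single_toxicant_design_rank_2(self):
        sheet = _channel_sheet()
        sub = sheet[(sheet["temp"] == 0) & (sheet["treatment"].isin(["CPF", "control"]))]
        dm = de.build_design(sub, de.ModelSpec.single_toxicant())
        assert dm.X.shape[1] == 2
        assert dm.rank == 2

    def test_empty_sheet_errors(self):
        with pytest.raises(ValueError, match="empty"):
            de.build_design(pd.DataFrame(columns=["cpf", "dzn", "temp"]), de.ModelSpec.full_factorial())

    def test_missing_factor_column_errors(self):
        sheet = pd.DataFrame({"cpf": [0, 1], "dzn": [0, 1]})
        with pytest.raises(ValueError, match="Temp"):
            de.build_design(sheet, de.ModelSpec.full_factorial())


class TestFitGeneModel:
    def test_zero_noise_exact_recovery(self):
        sheet = _channel_sheet()
        dm = de.build_design(sheet, de.ModelSpec.full_factorial())
        truth = np.array([10.0, 1.0, -0.5, 0.25, 0.8, -0.3, 0.1, 0.6])
        y = dm.X @ truth
        fit = de.fit_gene_model(y, None, dm)
        for term, expected in zip(dm.terms, truth):
            assert fit.estimates[term] == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_twelve_observation_normal_equations_oracle(self):
        # oracle: explicit normal equations + t CDF, computed here from
        # first principles on a fixed 12-observation example
        rng = np.random.default_rng(20)
        tox = np.repeat([0.0, 1.0], 6)
        X = np.column_stack([np.ones(12), tox])
        y = 5.0 + 0.8 * tox + rng.normal(0, 0.3, 12)
        beta_o = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_o
        s2 = resid @ resid / (12 - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se_o = np.sqrt(np.diag(cov))
        p_o = 2 * stats.t.sf(np.abs(beta_o / se_o), 12 - 2)

        sheet = pd.DataFrame({"toxicant": tox.astype(int)})
        sheet.index = pd.Index([f"o{i}" for i in range(12)], name="observation_id")
        dm = de.build_design(sheet, de.ModelSpec.single_toxicant())
        fit = de.fit_gene_model(y, None, dm)
        assert fit.estimates["Intercept"] == pytest.approx(beta_o[0], rel=1e-12)
        assert fit.estimates["Toxicant"] == pytest.approx(beta_o[1], rel=1e-12)
        assert fit.standard_errors["Toxicant"] == pytest.approx(se_o[1], rel=1e-12)
        assert fit.p_values["Toxicant"] == pytest.approx(p_o[1], rel=1e-12)
        assert fit.p_values["Intercept"] == pytest.approx(p_o[0], rel=1e-12)

    def test_orthogonal_response_gives_zero_estimate_p_one(self):
        tox = np.repeat([0.0, 1.0], 6)
        sheet = pd.DataFrame({"toxicant": tox.astype(int)})
        sheet.index = pd.Index([f"o{i}" for i in range(12)], name="observation_id")
        dm = de.build_design(sheet, de.ModelSpec.single_toxicant())
        y = np.tile([-1.0, 1.0], 6)  # sums to zero overall and within groups
        fit = de.fit_gene_model(y, None, dm)
        assert fit.estimates["Toxicant"] == pytest.approx(0.0, abs=1e-12)
        assert fit.p_values["Toxicant"] == pytest.approx(1.0)

    def test_insufficient_df_skipped(self):
        sheet = pd.DataFrame({"toxicant": [0, 1]})
        sheet.index = pd.Index(["o0", "o1"], name="observation_id")
        dm = de.build_design(sheet, de.ModelSpec.single_toxicant())
        assert de.fit_gene_model(np.array([1.0, 2.0]), None, dm) == "insufficient_df"

    def test_aliased_terms_reported_as_nan(self, ratio_sample_sheet):
        dm = de.build_design(ratio_sample_sheet, de.ModelSpec.full_factorial())
        rng = np.random.default_rng(21)
        y = rng.normal(0, 1, len(ratio_sample_sheet))
        fit = de.fit_gene_model(y, None, dm)
        for term in dm.aliased:
            assert np.isnan(fit.estimates[term])
            assert np.isnan(fit.p_values[term])


class TestGenomeScan:
    def test_empty_gene_set(self):
        sheet = _channel_sheet()
        empty = pp.ExpressionMatrix(
            pd.DataFrame(index=pd.Index([], name="gene_id"), columns=sheet.index, dtype=float),
            pd.DataFrame(index=pd.Index([], name="gene_id"), columns=sheet.index, dtype=bool),
            sheet,
        )
        results, skipped = de.genome_scan(empty, de.ModelSpec.full_factorial())
        assert len(results) == 0
        assert len(skipped) == 0

    def test_null_rejection_rate_near_nominal(self, null_run):
        results = null_run["results"]
        rates = results[results["term"] != "Intercept"].groupby("term")["significant"].mean()
        band = 3 * np.sqrt(0.01 * 0.99 / 2000)
        assert ((rates > 0.01 - band) & (rates < 0.01 + band)).all(), rates

    def test_planted_marginal_gene_detected(self, recovery_run):
        # power oracle: noncentral t at delta=1.0, sigma=0.25 exceeds 0.99
        results = recovery_run["results"]
        truth = recovery_run["truth"]
        marginal = truth.genes_of_class("marginal")
        sub = results[(results["term"] == "CPF") & results["gene_id"].isin(marginal)]
        assert sub["significant"].mean() >= 0.95

    def test_aliased_flagged_for_all_genes(self, ratio_sample_sheet):
        rng = np.random.default_rng(22)
        genes = pd.Index([f"g{i}" for i in range(40)], name="gene_id")
        values = pd.DataFrame(
            rng.normal(0, 1, (40, len(ratio_sample_sheet))),
            index=genes,
            columns=ratio_sample_sheet.index,
        )
        mask = pd.DataFrame(False, index=genes, columns=ratio_sample_sheet.index)
        matrix = pp.ExpressionMatrix(values, mask, ratio_sample_sheet)
        results, _ = de.genome_scan(matrix, de.ModelSpec.full_factorial())
        for term in ("CPF:DZN", "CPF:DZN:Temp"):
            sub = results[results["term"] == term]
            assert sub["aliased"].all()
            assert sub["estimate"].isna().all()
            assert not sub["significant"].any()


class TestPermutationNull:
    def test_n_perm_exceeding_transcripts_errors(self, recovery_run):
        with pytest.raises(ValueError, match="lower n_perm"):
            de.permutation_null(
                recovery_run["matrix"], de.ModelSpec.full_factorial(), n_perm=10**6, seed=0
            )

    def test_each_transcript_picked_once_at_full_n_perm(self, small_null_experiment):
        (raw, sheet, truth), cfg = small_null_experiment
        matrix = channels_matrix(raw, sheet)
        null = de.permutation_null(
            matrix, de.ModelSpec.full_factorial(), n_perm=cfg.n_genes, seed=3
        )
        assert len(null.p_values) == cfg.n_genes

    def test_fixed_seed_reproducible(self, small_null_experiment):
        (raw, sheet, truth), cfg = small_null_experiment
        matrix = channels_matrix(raw, sheet)
        a = de.permutation_null(matrix, de.ModelSpec.full_factorial(), n_perm=50, seed=9)
        b = de.permutation_null(matrix, de.ModelSpec.full_factorial(), n_perm=50, seed=9)
        pd.testing.assert_frame_equal(a.p_values, b.p_values)

    def test_null_pvalues_uniform_ks(self, null_run):
        # oracle: one-sample KS distance against the uniform CDF compared
        # with the alpha=0.01 asymptotic critical value at n = 2000
        null = null_run["null"]
        n = null.n_perm
        crit = np.sqrt(-np.log(0.01 / 2) / 2) / np.sqrt(n)
        for term in ("CPF", "DZN", "Temp", "CPF:DZN:Temp"):
            p = null.p_values[term].dropna().to_numpy()
            ks = stats.kstest(p, "uniform").statistic
            assert ks < crit, (term, ks, crit)


class TestEstimateFdr:
    def _observed(self, p_values, term="CPF"):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(p_values))],
                "term": term,
                "estimate": 0.0,
                "se": 1.0,
                "p_value": p_values,
            }
        )
        df["neglog10_p"] = -np.log10(df["p_value"])
        df["significant"] = df["neglog10_p"] > 2.0
        df["aliased"] = False
        return df

    def _null(self, p_values, term="CPF"):
        return de.NullDistribution(
            pd.DataFrame({term: p_values}), n_perm=len(p_values), threshold=2.0, spec_name="x"
        )

    def test_zero_rejections_reports_nan_with_note(self):
        observed = self._observed([0.5, 0.2, 0.9])
        null = self._null([0.001, 0.5])
        fdr = de.estimate_fdr(null, observed)
        assert np.isnan(fdr.loc[0, "fdr"])
        assert "no rejections" in fdr.loc[0, "note"]

    def test_no_null_exceedances_gives_zero(self):
        observed = self._observed([0.001, 0.5, 0.9])
        null = self._null([0.5, 0.6, 0.7])
        fdr = de.estimate_fdr(null, observed)
        assert fdr.loc[0, "fdr"] == 0.0

    def test_formula_plugin(self):
        observed = self._observed([0.001, 0.002, 0.5, 0.9])  # G=4, R=2
        null = self._null([0.005, 0.5, 0.2, 0.009])  # 2 of 4 below 0.01
        fdr = de.estimate_fdr(null, observed)
        assert fdr.loc[0, "fdr"] == pytest.approx((4 * 2 / 4) / 2)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            de.estimate_fdr(self._null([0.5]), self._observed([0.5]), threshold=0.0)

    def test_complete_null_fdr_near_one(self, null_run):
        fdr = de.estimate_fdr(null_run["null"], null_run["results"])
        sub = fdr[fdr["term"] != "Intercept"]
        assert sub["fdr"].between(0.3, 3.0).all(), sub
        assert 0.6 < sub["fdr"].mean() < 1.5


class TestSelectSignificant:
    def _results(self, p_values):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(p_values))],
                "term": "CPF",
                "p_value": p_values,
            }
        )
        df["neglog10_p"] = -np.log10(df["p_value"])
        df["aliased"] = False
        return df

    def test_exact_threshold_excluded(self):
        sets = de.select_significant(self._results([0.01]), threshold=2.0)
        assert sets["CPF"] == frozenset()

    def test_just_below_threshold_included(self):
        sets = de.select_significant(self._results([0.0099]), threshold=2.0)
        assert sets["CPF"] == frozenset({"g0"})

    def test_empty_results(self):
        assert de.select_significant(pd.DataFrame(), threshold=2.0) == {}


class TestParameterRecoveryInvariants:
    def test_interaction_only_genes(self, recovery_run):
        results = recovery_run["results"]
        truth = recovery_run["truth"]
        inter = truth.genes_of_class("interaction")
        assert len(inter) == 200
        hit = results[(results["term"] == "CPF:DZN") & results["gene_id"].isin(inter)]
        assert hit["significant"].mean() >= 0.90
        # marginal terms stay at the nominal rate for interaction-only genes
        rates = [
            results[(results["term"] == t) & results["gene_id"].isin(inter)][
                "significant"
            ].mean()
            for t in ("CPF", "DZN", "Temp")
        ]
        band = 3 * np.sqrt(0.01 * 0.99 / (3 * 200))
        assert np.mean(rates) < 0.01 + band
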