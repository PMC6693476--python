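"""Linear-model scanning engine, variability test and inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sadewas.core import ValidationError
from sadewas.ewas import (EwasModelSpec, build_design, fit_cpg_model,
                          genomic_inflation, levene_bf, qq_coordinates,
                          replicate_calls, residualize, run_dms_scan,
                          run_vms_scan, x_chromosome_scan)
from sadewas.simulate import SimConfig, simulate_cohort

from conftest import make_matrix, make_sheet


def _random_design(rng, n=20):
    sheet = make_sheet(n // 2, n - n // 2, rng)
    cells = pd.DataFrame(
        rng.dirichlet(np.ones(6), size=n),
        index=sheet.index,
        columns=["neutrophils", "monocytes", "B", "CD4", "CD8", "NK"])
    X, samples = build_design(sheet, cells, EwasModelSpec())
    return sheet, cells, X, samples


class TestFitCpgModel:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        _, _, X, _ = _random_design(rng, n=24)
        y = rng.random(len(X))
        fit = fit_cpg_model(y, X)
        # independent oracle: explicit normal equations
        A = X.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta
        df = len(y) - A.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(A.T @ A)
        ci = list(X.columns).index("diagnosis[MCTD]")
        se = np.sqrt(cov[ci, ci])
        p = 2 * stats.t.sf(abs(beta[ci] / se), df)
        assert fit["effect"] == pytest.approx(beta[ci], abs=1e-8)
        assert fit["se"] == pytest.approx(se, abs=1e-8)
        assert fit["p"] == pytest.approx(p, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        _, _, X, _ = _random_design(rng, n=30)
        y = rng.random(len(X))
        fit = fit_cpg_model(y, X)
        ref = sm.OLS(y, X.to_numpy()).fit()
        ci = list(X.columns).index("diagnosis[MCTD]")
        assert fit["effect"] == pytest.approx(ref.params[ci], abs=1e-10)
        assert fit["se"] == pytest.approx(ref.bse[ci], abs=1e-10)
        assert fit["p"] == pytest.approx(ref.pvalues[ci], abs=1e-10)

    def test_group_mean_difference_in_plain_design(self):
        # with no covariates the diagnosis coefficient is exactly the
        # difference of group means
        rng = np.random.default_rng(4)
        sheet = make_sheet(10, 10, rng, constant_covariates=True)
        X, samples = build_design(sheet, None, EwasModelSpec())
        case = (sheet["diagnosis"] == "MCTD").to_numpy()
        y = np.where(case, 0.35, 0.86) + 0.0
        fit = fit_cpg_model(y, X)
        assert fit["effect"] == pytest.approx(0.35 - 0.86, abs=1e-12)

    def test_zero_variance_probe(self):
        rng = np.random.default_rng(5)
        sheet = make_sheet(5, 5, rng)
        X, _ = build_design(sheet, None, EwasModelSpec())
        fit = fit_cpg_model(np.full(10, 0.5), X)
        assert fit["effect"] == 0.0 and fit["p"] == 1.0
        assert fit["zero_variance"]

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(6)
        sheet = make_sheet(8, 8, rng)
        cells = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=16), index=sheet.index,
            columns=["neutrophils", "monocytes", "B", "CD4", "CD8", "NK"])
        cells["CD8"] = cells["CD4"]   # aliased pair
        with pytest.raises(ValidationError, match=r"cell\[CD8\]"):
            build_design(sheet, cells, EwasModelSpec())


class TestResidualize:
    def test_covariate_free_design_centers(self):
        rng = np.random.default_rng(7)
        sheet = make_sheet(5, 5, rng, constant_covariates=True)
        m = make_matrix(rng.random((10, 3)),
                        sample_ids=list(sheet.index))
        res = residualize(m, sheet, None)
        expected = m.beta - m.beta.mean()
        np.testing.assert_allclose(res.to_numpy(), expected.to_numpy(),
                                   atol=1e-12)

    def test_exact_linear_age_signal_removed(self):
        rng = np.random.default_rng(8)
        sheet = make_sheet(6, 6, rng)
        y = 0.3 + 0.002 * sheet["age"].to_numpy()
        m = make_matrix(y[:, None], sample_ids=list(sheet.index))
        res = residualize(m, sheet, None)
        assert np.abs(res.to_numpy()).max() < 1e-10

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(9)
        sheet = make_sheet(15, 15, rng)
        m = make_matrix(rng.random((30, 4)), sample_ids=list(sheet.index))
        res = residualize(m, sheet, None)
        spec = EwasModelSpec(include_diagnosis=False)
        X, _ = build_design(sheet, None, spec)
        inner = X.to_numpy().T @ res.to_numpy()
        assert np.abs(inner).max() < 1e-8


class TestLeveneBrownForsythe:
    def test_equal_spread_gives_zero(self):
        res = levene_bf(np.array([-1.0, 1.0]), np.array([-1.0, 1.0]))
        assert res["levene_w"] == 0.0 and res["p"] == 1.0

    def test_matches_brute_force_oracle(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 4, 6, 8, 10])
        res = levene_bf(a, b)
        # brute force: |x - group median|, one-way F by hand
        da, db = np.abs(a - np.median(a)), np.abs(b - np.median(b))
        grand = np.concatenate([da, db]).mean()
        between = 5 * (da.mean() - grand) ** 2 + 5 * (db.mean() - grand) ** 2
        within = ((da - da.mean()) ** 2).sum() + ((db - db.mean()) ** 2).sum()
        W = (10 - 2) / (2 - 1) * between / within
        p = stats.f.sf(W, 1, 8)
        assert res["levene_w"] == pytest.approx(W, abs=1e-12)
        assert res["p"] == pytest.approx(p, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=12), rng.normal(scale=3, size=15)
        r1 = levene_bf(a, b)
        r2 = levene_bf(10 * a, 10 * b)
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-12)

    def test_degenerate_flagged(self):
        res = levene_bf(np.array([0.5, 0.5]), np.array([0.2, 0.2]))
        assert res["degenerate"]

    def test_needs_two_per_group(self):
        with pytest.raises(ValidationError):
            levene_bf(np.array([1.0]), np.array([1.0, 2.0]))


class TestScans:
    def test_sample_order_invariance(self, discovery):
        m, sheet, cells = discovery
        res1 = run_dms_scan(m, sheet, cells)
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(sheet))
        order = sheet.index[perm]
        res2 = run_dms_scan(m.subset_samples(order), sheet.loc[order],
                            cells.loc[order])
        pd.testing.assert_frame_equal(res1.records, res2.records)
        assert res1.calls == res2.calls

    def test_vms_finds_inflation_only_probes(self):
        cfg = SimConfig(n_probes=120, n_x_probes=0, n_ref_probes=30,
                        n_ifn_probes=0, n_vms_probes=20, vms_overlap_frac=0.0,
                        var_inflation=8.0, n_snps=8, n_meqtl_affected=0,
                        n_meqtl_unaffected=0, n_risk_snps=0,
                        mediated_meqtl_effect=0.0, n_specific_probes=0,
                        n_cases={"MCTD": 31}, n_controls=255,
                        n_extra_assoc_cases=0, n_extra_assoc_controls=0,
                        seed=23)
        res = simulate_cohort(cfg)
        sheet = res.sheet_for("discovery")
        cells = res.cell_props.loc[sheet.index]
        dms = run_dms_scan(res.discovery, sheet, cells)
        vms = run_vms_scan(res.discovery, sheet, cells, dms_calls=dms.calls)
        truth_vms = set(res.truth.vms_probes)
        assert len(set(vms.calls) & truth_vms) >= 0.6 * len(truth_vms)
        assert not set(dms.calls) & truth_vms
        # reported variances are valid
        assert (vms.records[["case_var", "control_var"]] >= 0).all().all()

    def test_replication_rules(self):
        disc = pd.DataFrame({"probe_id": ["a", "b", "c"],
                             "effect": [-0.3, -0.3, -0.2],
                             "p": [1e-9, 1e-9, 1e-9]})
        repl = pd.DataFrame({"probe_id": ["a", "b"],
                             "effect": [-0.1, 0.2],
                             "p": [0.01, 0.001]})
        table, summary = replicate_calls(disc, repl, ["a", "b", "c"])
        t = table.set_index("probe_id")
        assert bool(t.at["a", "replicated"])          # same sign, p<0.05
        assert not bool(t.at["b", "replicated"])      # direction flip
        assert not bool(t.at["c", "testable"])        # absent from platform
        assert summary == dict(n_calls=3, n_testable=2, n_replicated=1,
                               percent=50)

    def test_replication_percentage_rounding(self):
        disc = pd.DataFrame({"probe_id": [f"p{i}" for i in range(100)],
                             "effect": -0.3, "p": 1e-9})
        repl = disc.copy()
        repl.loc[0, "effect"] = 0.3   # one direction flip
        repl["p"] = 0.01
        _, summary = replicate_calls(disc, repl, list(disc["probe_id"]))
        assert summary["n_testable"] == 100
        assert summary["n_replicated"] == 99
        assert summary["percent"] == 99

    def test_x_scan_excludes_males(self, small_sim):
        sheet = small_sim.sheet_for("discovery")
        cells = small_sim.cell_props.loc[sheet.index]
        x_ids = [p for p in small_sim.discovery.probe_ids
                 if small_sim.discovery.probes.at[p, "chrom"] == "X"]
        mx = small_sim.discovery.subset_probes(x_ids)
        res = x_chromosome_scan(mx, sheet, cells)
        n_males = (sheet["sex"] == "male").sum()
        assert res.extra["excluded_males"] == n_males
        assert "sex[male]" not in res.extra["design_columns"]
        # X probes carry no disease effect in the simulation
        assert len(res.calls) == 0

    def test_x_scan_needs_female_cases(self):
        rng = np.random.default_rng(12)
        sheet = make_sheet(3, 10, rng)
        sheet.loc[sheet["diagnosis"] == "MCTD", "sex"] = "male"
        m = make_matrix(rng.random((13, 2)), sample_ids=list(sheet.index),
                        chrom=["X", "X"])
        with pytest.raises(ValidationError, match="female"):
            x_chromosome_scan(m, sheet, None)


class TestGenomicInflation:
    def test_null_median(self):
        assert genomic_inflation(np.full(101, 0.5)) == pytest.approx(1.0)

    def test_uniform_p_near_one(self):
        rng = np.random.default_rng(13)
        lam = genomic_inflation(rng.random(10_000))
        assert 0.95 < lam < 1.05

    def test_halved_p_inflates(self):
        rng = np.random.default_rng(14)
        p = rng.random(5000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            genomic_inflation(np.array([0.5, 1.5]))
        with pytest.raises(ValidationError):
            genomic_inflation(np.array([]))

    def test_qq_coordinates_monotone(self):
        rng = np.random.default_rng(15)
        qq = qq_coordinates(rng.random(100))
        assert (np.diff(qq["expected"]) <= 0).all()
        assert (np.diff(qq["observed"]) <= 1e-12).all()
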