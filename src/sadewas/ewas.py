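"""Per-CpG differential methylation (DMS) and variability (VMS) scanning.

The disease effect on methylation is estimated per probe with ordinary
least squares on the beta values themselves, so the coefficient of the
diagnosis indicator is directly the adjusted beta-value difference
(delta-beta) between cases and controls:

    beta_j ~ diagnosis + age + sex + batch + cell proportions

Batch enters one-hot with the first level dropped; one cell type
(neutrophils, the most abundant) is dropped to avoid collinearity with
the intercept.  Differential variability uses the Brown-Forsythe variant
of Levene's test (absolute deviations from the group median) on the
residuals of the covariate-only model, which accounts for mean
differences.  Two-sided t-tests throughout; no empirical-Bayes
moderation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (MethylationMatrix, ValidationError,
                   bonferroni_threshold)

logger = logging.getLogger("sadewas")

DROPPED_CELL_TYPE = "neutrophils"
_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.455936...


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass
class EwasModelSpec:
    """Design specification for a two-group methylation model."""

    case: str = "MCTD"
    control: str = "CTRL"
    include_diagnosis: bool = True
    include_sex: bool = True
    treatments: tuple[str, ...] = ()
    drop_cell_type: str = DROPPED_CELL_TYPE
    min_samples_margin: int = 2   # residual df required beyond parameters


def build_design(sheet: pd.DataFrame, cells: pd.DataFrame | None,
                 spec: EwasModelSpec) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix for the samples with the spec's two diagnoses.

    Returns the design (samples x columns, intercept first) and the list
    of sample ids used.  Raises on rank deficiency, naming the aliased
    columns.
    """
    keep = sheet.index[sheet["diagnosis"].isin([spec.case, spec.control])]
    sub = sheet.loc[keep]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    if spec.include_diagnosis:
        cols[f"diagnosis[{spec.case}]"] = (
            sub["diagnosis"] == spec.case).to_numpy(dtype=float)
    cols["age"] = sub["age"].to_numpy(dtype=float)
    if spec.include_sex:
        cols["sex[male]"] = (sub["sex"] == "male").to_numpy(dtype=float)
    batches = sorted(sub["batch"].unique())
    for b in batches[1:]:
        cols[f"batch[{b}]"] = (sub["batch"] == b).to_numpy(dtype=float)
    if cells is not None:
        missing = [s for s in keep if s not in cells.index]
        if missing:
            raise ValidationError(
                f"cell proportions missing for samples: {missing[:5]}")
        for ct in cells.columns:
            if ct == spec.drop_cell_type:
                continue
            cols[f"cell[{ct}]"] = cells.loc[keep, ct].to_numpy(dtype=float)
    for t in spec.treatments:
        if t not in sub.columns:
            raise ValidationError(f"treatment column {t!r} missing")
        v = sub[t].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.warning("treatment column %r is constant; dropped", t)
            continue
        cols[f"treatment[{t}]"] = v
    X = pd.DataFrame(cols, index=keep)
    # constant covariate columns carry no information and alias the
    # intercept; drop them (a constant diagnosis indicator is an error)
    for name in list(X.columns):
        if name == "intercept":
            continue
        if np.ptp(X[name].to_numpy()) == 0:
            if name.startswith("diagnosis["):
                raise ValidationError(
                    f"diagnosis indicator {name} is constant in the "
                    "selected samples")
            logger.warning("build_design: dropping constant column %r", name)
            X = X.drop(columns=name)
    _check_full_rank(X)
    return X, list(keep)


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify aliased columns by incremental rank
        aliased, kept = [], []
        for j, name in enumerate(X.columns):
            trial = A[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(name)
        raise ValidationError(
            f"design matrix rank deficient; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# OLS engines
# ---------------------------------------------------------------------------

def _batch_ols(Y: np.ndarray, X: np.ndarray, coef_idx: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized OLS of every column of Y on the shared design X.

    Returns (effect, se, p, residual_df) for the coefficient ``coef_idx``.
    """
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValidationError(f"zero residual degrees of freedom (n={n}, p={p})")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    betas = H @ Y                      # p x m
    resid = Y - X @ betas
    sigma2 = (resid ** 2).sum(axis=0) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * XtX_inv[coef_idx, coef_idx])
        t = betas[coef_idx] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return betas[coef_idx], se, pvals, df


def fit_cpg_model(y: np.ndarray | pd.Series, X: pd.DataFrame,
                  coef: str = None) -> dict:
    """OLS fit for a single probe; returns effect/se/p for one coefficient.

    ``coef`` defaults to the diagnosis indicator if present, otherwise the
    second column.  A zero-variance response returns effect 0, p = 1 (the
    scanners skip such probes with a warning).
    """
    y = np.asarray(y, dtype=float)
    if coef is None:
        cand = [c for c in X.columns if c.startswith("diagnosis[")]
        coef = cand[0] if cand else X.columns[1]
    ci = list(X.columns).index(coef)
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(
            f"too few samples (n={n}) for {p} parameters")
    if np.ptp(y) == 0:
        return dict(effect=0.0, se=np.nan, p=1.0, n=n, zero_variance=True)
    eff, se, pv, df = _batch_ols(y[:, None], X.to_numpy(dtype=float), ci)
    return dict(effect=float(eff[0]), se=float(se[0]), p=float(pv[0]),
                n=n, df=df, zero_variance=False)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Association records plus the Bonferroni call set for one scan."""

    records: pd.DataFrame
    threshold: float
    calls: list[str]
    skipped: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def m_tests(self) -> int:
        return len(self.records)


def _group_stats(beta: pd.DataFrame, case_mask: np.ndarray
                 ) -> tuple[np.ndarray, ...]:
    case = beta.to_numpy()[case_mask]
    ctrl = beta.to_numpy()[~case_mask]
    return (case.mean(axis=0), ctrl.mean(axis=0),
            case.var(axis=0, ddof=1), ctrl.var(axis=0, ddof=1))


def run_dms_scan(m: MethylationMatrix, sheet: pd.DataFrame,
                 cells: pd.DataFrame | None, alpha: float = 0.05,
                 spec: EwasModelSpec | None = None) -> ScanResult:
    """Differential-methylation scan: one OLS record per probe.

    Probes with zero variance (or too few complete cases) are skipped,
    never called, and listed in the result.  The call set is
    ``p < alpha / m`` with m = probes actually tested.
    """
    spec = spec or EwasModelSpec()
    present = set(m.sample_ids)
    sheet = sheet.loc[[s for s in sheet.index if s in present]]
    X, samples = build_design(sheet, cells, spec)
    beta = m.beta.loc[samples]
    coef = f"diagnosis[{spec.case}]"
    ci = list(X.columns).index(coef)
    Y = beta.to_numpy(dtype=float)

    variances = Y.var(axis=0)
    ok = variances > 0
    skipped = [p for p, o in zip(beta.columns, ok) if not o]
    if skipped:
        logger.warning("dms scan: skipping %d zero-variance probes",
                       len(skipped))
    eff = np.full(Y.shape[1], np.nan)
    se = np.full(Y.shape[1], np.nan)
    pv = np.full(Y.shape[1], np.nan)
    if ok.any():
        e, s, p_, _ = _batch_ols(Y[:, ok], X.to_numpy(dtype=float), ci)
        eff[ok], se[ok], pv[ok] = e, s, p_

    case_mask = (sheet.loc[samples, "diagnosis"] == spec.case).to_numpy()
    cm, km, cv, kv = _group_stats(beta, case_mask)
    records = pd.DataFrame(dict(
        probe_id=beta.columns, effect=eff, se=se, p=pv, n=len(samples),
        case_mean=cm, control_mean=km, case_var=cv, control_var=kv))
    tested = records[records["p"].notna()]
    thr = bonferroni_threshold(alpha, max(1, len(tested)))
    calls = list(tested.loc[tested["p"] < thr, "probe_id"])
    return ScanResult(records, thr, calls, skipped,
                      extra=dict(n_case=int(case_mask.sum()),
                                 n_control=int((~case_mask).sum()),
                                 design_columns=list(X.columns)))


def residualize(m: MethylationMatrix | pd.DataFrame, sheet: pd.DataFrame,
                cells: pd.DataFrame | None,
                spec: EwasModelSpec | None = None) -> pd.DataFrame:
    """Residuals of each probe on the covariate-only model (no diagnosis)."""
    spec = spec or EwasModelSpec()
    spec_cov = EwasModelSpec(case=spec.case, control=spec.control,
                             include_diagnosis=False,
                             include_sex=spec.include_sex,
                             treatments=spec.treatments,
                             drop_cell_type=spec.drop_cell_type)
    beta_all = m.beta if isinstance(m, MethylationMatrix) else m
    present = set(beta_all.index)
    sheet = sheet.loc[[s for s in sheet.index if s in present]]
    X, samples = build_design(sheet, cells, spec_cov)
    beta = beta_all.loc[samples]
    A = X.to_numpy(dtype=float)
    Y = beta.to_numpy(dtype=float)
    coefs, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coefs
    return pd.DataFrame(resid, index=beta.index, columns=beta.columns)


def levene_bf(*groups: np.ndarray) -> dict:
    """Brown-Forsythe test: one-way ANOVA on |x - group median|.

    Returns the W statistic, its F(k-1, N-k) p-value and the per-group
    variances.  Degenerate input (all deviations zero) yields
    ``degenerate=True`` and p = NaN; scanners skip such probes.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValidationError("each group needs at least 2 observations")
    gvars = [float(np.var(g, ddof=1)) for g in arrs]
    devs = [np.abs(g - np.median(g)) for g in arrs]
    within_ss = sum(float(((d - d.mean()) ** 2).sum()) for d in devs)
    if within_ss == 0:
        if all(np.all(d == 0) for d in devs):
            # every observation equals its group median: nothing to test
            return dict(levene_w=0.0, p=np.nan, degenerate=True,
                        group_vars=gvars)
        grand = np.concatenate(devs).mean()
        between_ss = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
        if between_ss == 0:  # equal constant spread in every group
            return dict(levene_w=0.0, p=1.0, degenerate=False,
                        group_vars=gvars)
        return dict(levene_w=np.inf, p=0.0, degenerate=False,
                    group_vars=gvars)
    w, p = stats.levene(*arrs, center="median")
    return dict(levene_w=float(w), p=float(p), degenerate=False,
                group_vars=gvars)


def run_vms_scan(m: MethylationMatrix, sheet: pd.DataFrame,
                 cells: pd.DataFrame | None, alpha: float = 0.05,
                 spec: EwasModelSpec | None = None,
                 dms_calls: list[str] | None = None) -> ScanResult:
    """Differential-variability scan on covariate residuals.

    Residualizes methylation on the covariates (which accounts for mean
    differences), then tests case-vs-control spread per probe with the
    Brown-Forsythe statistic.  Reports the overlap with a DMS call set if
    given.
    """
    spec = spec or EwasModelSpec()
    resid = residualize(m, sheet, cells, spec)
    case_mask = (sheet.loc[resid.index, "diagnosis"] == spec.case).to_numpy()
    rows, skipped = [], []
    R = resid.to_numpy()
    for j, pid in enumerate(resid.columns):
        res = levene_bf(R[case_mask, j], R[~case_mask, j])
        if res["degenerate"]:
            skipped.append(pid)
            continue
        rows.append((pid, res["levene_w"], res["p"],
                     res["group_vars"][0], res["group_vars"][1],
                     len(resid)))
    if skipped:
        logger.warning("vms scan: skipped %d degenerate probes", len(skipped))
    records = pd.DataFrame(rows, columns=["probe_id", "levene_w", "p",
                                          "case_var", "control_var", "n"])
    thr = bonferroni_threshold(alpha, max(1, len(records)))
    calls = list(records.loc[records["p"] < thr, "probe_id"])
    extra = {}
    if dms_calls is not None:
        extra["dms_overlap"] = len(set(calls) & set(dms_calls))
    return ScanResult(records, thr, calls, skipped, extra)


def replicate_calls(discovery: pd.DataFrame, replication: pd.DataFrame,
                    calls: list[str], effect_col: str = "effect",
                    p_threshold: float = 0.05,
                    id_col: str = "probe_id") -> tuple[pd.DataFrame, dict]:
    """Replication rule: consistent effect direction and p < 0.05.

    A call is *testable* if it appears in the replication records (i.e.,
    its probe exists on the replication platform and was not skipped).
    The summary percentage is replicated / testable x 100, rounded to an
    integer, as the study tables report it.
    """
    disc = discovery.set_index(id_col)
    repl = replication.set_index(id_col)
    rows = []
    for pid in calls:
        testable = pid in repl.index and np.isfinite(repl.at[pid, "p"])
        if not testable:
            rows.append((pid, False, False, np.nan, np.nan))
            continue
        d_eff = disc.at[pid, effect_col]
        r_eff = repl.at[pid, effect_col]
        r_p = repl.at[pid, "p"]
        ok = bool(np.sign(r_eff) == np.sign(d_eff) and r_p < p_threshold)
        rows.append((pid, True, ok, r_eff, r_p))
    table = pd.DataFrame(rows, columns=["probe_id", "testable", "replicated",
                                        "replication_effect", "replication_p"])
    n_testable = int(table["testable"].sum())
    n_repl = int(table["replicated"].sum())
    pct = int(round(100 * n_repl / n_testable)) if n_testable else 0
    summary = dict(n_calls=len(calls), n_testable=n_testable,
                   n_replicated=n_repl, percent=pct)
    return table, summary


def x_chromosome_scan(mX: MethylationMatrix, sheet: pd.DataFrame,
                      cells: pd.DataFrame | None, alpha: float = 0.05,
                      spec: EwasModelSpec | None = None) -> ScanResult:
    """X-chromosome scan restricted to females, sex dropped from the design."""
    spec = spec or EwasModelSpec()
    females = sheet.index[sheet["sex"] == "female"]
    excluded = len(sheet) - len(females)
    if excluded:
        logger.info("x scan: excluded %d male samples", excluded)
    sub_sheet = sheet.loc[females]
    n_case = (sub_sheet["diagnosis"] == spec.case).sum()
    n_ctrl = (sub_sheet["diagnosis"] == spec.control).sum()
    if n_case < 2 or n_ctrl < 2:
        raise ValidationError(
            f"too few female samples (cases={n_case}, controls={n_ctrl})")
    keep = [s for s in mX.sample_ids if s in set(females)]
    xspec = EwasModelSpec(case=spec.case, control=spec.control,
                          include_sex=False, treatments=spec.treatments,
                          drop_cell_type=spec.drop_cell_type)
    res = run_dms_scan(mX.subset_samples(keep), sub_sheet,
                       cells.loc[keep] if cells is not None else None,
                       alpha, xspec)
    res.extra["excluded_males"] = excluded
    return res


def genomic_inflation(p: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor lambda of a p-value vector.

    lambda = median(qchisq(1 - p, df=1)) / 0.455936...; ~1 under the null.
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


def qq_coordinates(p: np.ndarray | pd.Series) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(p, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return pd.DataFrame({"expected": expected, "observed": observed})
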