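"""Cross-disease comparison, case-vs-case scans and methylation biomarkers.

* cross-disease scan: the standard disease-vs-control model fitted per
  disease label at the disease-associated probe set; effect vectors are
  compared with the index disease by Pearson correlation, and the
  heat-map subset keeps probes whose index-disease |delta-beta| > 0.15;
* case-vs-case scan: the same covariate model with a diseaseA-vs-diseaseB
  indicator, Bonferroni-corrected at 0.05 / |call set|;
* ROC/AUC: Mann-Whitney U identity (ties count 1/2), equal to the
  trapezoidal area under the empirical ROC curve;
* panels: in-sample logistic regression on a probe list's betas (plus the
  standard covariates by default) scored by AUC;
* gene-set over-representation: one-sided hypergeometric tail with BH
  adjustment across sets (an in-repo stand-in for web enrichment tools).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylationMatrix, ValidationError, bh_fdr, \
    bonferroni_threshold
from .ewas import EwasModelSpec, ScanResult, build_design, run_dms_scan

__all__ = ["PanelSpec", "TOP10_PANEL", "IFI44L_PANEL", "cross_disease_scan",
           "case_vs_case_scan", "roc_auc", "evaluate_panel",
           "gene_set_enrichment"]

# Well-known discriminating panels for real-array input (probe ids on the
# EPIC/450K platforms); synthetic cohorts define their own panels.
TOP10_PANEL = ("cg22930808", "cg03607951", "cg13452062", "cg22862003",
               "cg06981309", "cg05552874", "cg07839457", "cg24678928",
               "cg00959259", "cg05696877")
IFI44L_PANEL = ("cg13452062", "cg05696877", "cg03607951", "cg13304609",
                "cg17980508", "cg00458211")


@dataclass
class PanelSpec:
    """A named list of CpG probes used jointly as a classifier."""

    name: str
    probes: tuple[str, ...]

    def validate_against(self, m: MethylationMatrix) -> None:
        missing = [p for p in self.probes if p not in m.beta.columns]
        if missing:
            raise ValidationError(
                f"panel {self.name!r}: probes absent from matrix: "
                f"{missing[:5]}")


def cross_disease_scan(m: MethylationMatrix, sheet: pd.DataFrame,
                       cells: pd.DataFrame | None, dms_calls: list[str],
                       diseases: tuple[str, ...] = ("SLE", "SjS", "RA", "SSc"),
                       index_disease: str = "MCTD",
                       heatmap_min_effect: float = 0.15,
                       alpha: float = 0.05) -> dict:
    """Disease-vs-control models per disease, restricted to the DMS set.

    Returns per-disease records, the Pearson correlation of each disease's
    effect vector with the index disease, and the heat-map subset (probes
    with index-disease |effect| above ``heatmap_min_effect``).
    """
    if not dms_calls:
        return dict(records={}, correlations={}, effect_matrix=pd.DataFrame(),
                    heatmap_probes=[])
    msub = m.subset_probes(dms_calls)
    records: dict[str, pd.DataFrame] = {}
    effects = {}
    all_dx = (index_disease,) + tuple(diseases)
    for dx in all_dx:
        if (sheet["diagnosis"] == dx).sum() == 0:
            import logging
            logging.getLogger("sadewas").warning(
                "cross-disease scan: no %s samples, skipped", dx)
            continue
        res = run_dms_scan(msub, sheet, cells, alpha,
                           EwasModelSpec(case=dx, control="CTRL"))
        records[dx] = res.records
        effects[dx] = res.records.set_index("probe_id")["effect"]
    eff_mat = pd.DataFrame(effects)
    correlations = {}
    for dx in diseases:
        if dx in eff_mat and index_disease in eff_mat:
            ok = eff_mat[[index_disease, dx]].dropna()
            correlations[dx] = float(
                np.corrcoef(ok[index_disease], ok[dx])[0, 1])
    idx_eff = eff_mat.get(index_disease)
    heatmap = (list(idx_eff.index[idx_eff.abs() > heatmap_min_effect])
               if idx_eff is not None else [])
    return dict(records=records, correlations=correlations,
                effect_matrix=eff_mat, heatmap_probes=heatmap)


def case_vs_case_scan(m: MethylationMatrix, sheet: pd.DataFrame,
                      cells: pd.DataFrame | None, dms_calls: list[str],
                      disease_a: str = "MCTD", disease_b: str = "SLE",
                      alpha: float = 0.05) -> ScanResult:
    """Direct case-vs-case differential methylation over the DMS set.

    Bonferroni threshold is alpha / |dms_calls| (the number of probes the
    comparison interrogates).
    """
    if not dms_calls:
        empty = pd.DataFrame(columns=["probe_id", "effect", "se", "p", "n"])
        return ScanResult(empty, np.nan, [], [])
    msub = m.subset_probes(dms_calls)
    spec = EwasModelSpec(case=disease_a, control=disease_b)
    res = run_dms_scan(msub, sheet, cells, alpha, spec)
    res.threshold = bonferroni_threshold(alpha, len(dms_calls))
    res.calls = list(res.records.loc[res.records["p"] < res.threshold,
                                     "probe_id"])
    return res


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    ``labels`` is a boolean/0-1 vector (1 = case).  Ties contribute 1/2;
    the result equals the trapezoidal area under the empirical ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes are required for an AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _panel_score(beta: pd.DataFrame, y: np.ndarray,
                 covariates: pd.DataFrame | None) -> tuple[np.ndarray, bool]:
    """In-sample logistic score for a probe panel; flags separation.

    On complete separation the IRLS likelihood diverges but the direction
    of the linear score converges; a lightly ridge-penalized fit supplies
    that score, flagged.
    """
    from .genetics import _logistic_fit

    cols = [beta.to_numpy(dtype=float)]
    if covariates is not None:
        cols.append(covariates.to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(beta))] + cols)
    fit = _logistic_fit(y, X)
    if not fit["separation"]:
        return X @ fit["coef"], False
    from sklearn.linear_model import LogisticRegression
    lr = LogisticRegression(C=1e3, max_iter=2000)
    lr.fit(X[:, 1:], y)
    return lr.decision_function(X[:, 1:]), True


def evaluate_panel(m: MethylationMatrix, sheet: pd.DataFrame,
                   panel: PanelSpec, comparator: str = "CTRL",
                   case: str = "MCTD",
                   cells: pd.DataFrame | None = None,
                   include_covariates: bool = True) -> dict:
    """Diagnostic value of a probe panel for case vs comparator.

    Fits an in-sample logistic regression of the case indicator on the
    panel's betas (plus the standard covariates when available and
    requested), scores samples by the fitted linear predictor and
    computes the AUC; per-probe single-CpG AUCs are reported alongside.
    """
    panel.validate_against(m)
    keep = sheet.index[sheet["diagnosis"].isin([case, comparator])]
    keep = [s for s in keep if s in m.beta.index]
    sub = sheet.loc[keep]
    y = (sub["diagnosis"] == case).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError(
            f"need both {case} and {comparator} samples for the panel AUC")
    beta = m.beta.loc[keep, list(panel.probes)]

    covs = None
    if include_covariates and cells is not None:
        X, _ = build_design(sub, cells.loc[keep],
                            EwasModelSpec(case=case, control=comparator,
                                          include_diagnosis=False))
        covs = X.drop(columns="intercept")
    score, separated = _panel_score(beta, y, covs)
    auc = roc_auc(score, y)
    single = {}
    for pid in panel.probes:
        b = beta[pid].to_numpy()
        a = roc_auc(b, y)
        single[pid] = max(a, 1 - a)   # orientation-free single-probe AUC
    return dict(panel=panel.name, comparator=comparator, auc=auc,
                n_case=int(y.sum()), n_comparator=int(len(y) - y.sum()),
                separation=separated, single_probe_auc=single,
                covariate_adjusted=covs is not None)


def gene_set_enrichment(hits: set[str] | list[str],
                        background: set[str] | list[str],
                        sets: dict[str, list[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    ``hits`` must be contained in ``background``; set members outside the
    background are ignored.  P-values are BH-adjusted across sets.
    """
    background = set(background)
    hits = set(hits)
    if not background:
        raise ValidationError("empty background gene universe")
    stray = hits - background
    if stray:
        raise ValidationError(
            f"hit genes outside the background: {sorted(stray)[:5]}")
    M, n_draw = len(background), len(hits)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        k = len(in_bg & hits)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_bg), n_draw))
        rows.append((name, len(in_bg), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    return out.sort_values("p").reset_index(drop=True)
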