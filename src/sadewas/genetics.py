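"""cis-meQTL scanning, case/control association and the mediation triangle.

* cis pairs: SNP and CpG on the same chromosome within a window
  (default 1 Mb, boundary inclusive).
* meQTL model: OLS of methylation on additive dosage, adjusting for sex,
  age, batch, cell proportions, disease status and the first genetic
  principal component; Benjamini-Hochberg FDR across all tested pairs
  jointly (Matrix-eQTL convention).
* genetic association: logistic regression of case status on dosage
  (additive model); odds ratio = exp(coefficient).
* mediation triangle: the SNP -> methylation -> disease intersection —
  SNPs in a significant meQTL whose CpG is disease-associated and which
  show at least suggestive case/control association.  The
  direction-consistency flag (does the risk allele move methylation
  toward the case profile?) is reported, not used as a filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import (GenotypeTable, MethylationMatrix, ValidationError, bh_fdr)
from .ewas import EwasModelSpec, build_design, genomic_inflation

logger = logging.getLogger("sadewas")

__all__ = ["enumerate_cis_pairs", "genotype_pc1", "genotype_pcs",
           "run_meqtl_scan", "meqtl_replication_filter",
           "top_meqtl_per_gene", "case_control_assoc", "mediation_triangle"]


def enumerate_cis_pairs(probes: pd.DataFrame, variants: pd.DataFrame,
                        window: int = 1_000_000) -> pd.DataFrame:
    """All (probe, SNP) pairs on the same chromosome within ``window`` bp.

    The boundary is inclusive: a SNP exactly ``window`` bp away is kept.
    Positions are 1-based on both sides.
    """
    rows = []
    for chrom, var_c in variants.groupby("chrom", sort=False):
        pro_c = probes[probes["chrom"] == str(chrom)]
        if pro_c.empty:
            continue
        ppos = pro_c["pos"].to_numpy()
        for sid, vrow in var_c.iterrows():
            dist = vrow["pos"] - ppos
            keep = np.abs(dist) <= window
            for pid, d in zip(pro_c.index[keep], dist[keep]):
                rows.append((pid, sid, int(d)))
    return pd.DataFrame(rows, columns=["probe_id", "snp_id", "distance"])


def genotype_pcs(g: GenotypeTable, k: int = 2) -> pd.DataFrame:
    """Leading principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed for the decomposition.  The sign of
    each component is fixed by making the loading of the first polymorphic
    variant non-negative.
    """
    D = g.dosage.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    sd = D.std(axis=0, ddof=1)
    poly = sd > 0
    if not poly.any():
        raise ValidationError("all variants are monomorphic")
    Z = (D[:, poly] - D[:, poly].mean(axis=0)) / sd[poly]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(S))
    scores = U[:, :k] * S[:k]
    for j in range(k):
        if Vt[j, 0] < 0:
            scores[:, j] = -scores[:, j]
    var_ratio = (S[:k] ** 2) / (S ** 2).sum()
    out = pd.DataFrame(scores, index=g.dosage.index,
                       columns=[f"PC{j+1}" for j in range(k)])
    out.attrs["explained_variance_ratio"] = var_ratio
    return out


def genotype_pc1(g: GenotypeTable) -> pd.Series:
    """Scores on the first genetic principal component."""
    return genotype_pcs(g, k=1)["PC1"]


def run_meqtl_scan(m: MethylationMatrix, g: GenotypeTable,
                   sheet: pd.DataFrame, cells: pd.DataFrame | None,
                   window: int = 1_000_000, maf_floor: float = 0.05,
                   q_level: float = 0.05,
                   probe_subset: list[str] | None = None,
                   spec: EwasModelSpec | None = None) -> dict:
    """cis-meQTL scan with joint BH correction across all tested pairs.

    Returns a dict with ``records`` (one AssociationRecord-style row per
    tested pair, plus q-values), ``significant`` (q < q_level),
    ``lambda_gc`` and per-rule skip counts.  Sub-MAF or monomorphic SNPs
    are skipped (MAF computed on the analysis cohort after complete-case
    reduction).
    """
    spec = spec or EwasModelSpec()
    shared = [s for s in m.sample_ids
              if s in g.dosage.index and s in sheet.index]
    if not shared:
        raise ValidationError("no overlapping samples between matrices")
    sub_sheet = sheet.loc[shared]
    gsub = GenotypeTable(g.dosage.loc[shared], g.variants)
    pc1 = genotype_pc1(gsub)
    X, samples = build_design(sub_sheet,
                              cells.loc[shared] if cells is not None else None,
                              spec)
    X = X.copy()
    X["genetic_PC1"] = pc1.loc[samples]
    A = X.to_numpy(dtype=float)
    n, p_cov = A.shape

    probes = m.probes if probe_subset is None else m.probes.loc[probe_subset]
    pairs = enumerate_cis_pairs(probes, gsub.variants, window)

    maf = gsub.dosage.loc[samples].pipe(
        lambda d: np.minimum(d.mean() / 2, 1 - d.mean() / 2))
    ok_snps = set(maf.index[(maf >= maf_floor) & (maf > 0)])
    skipped_maf = int(pairs["snp_id"].isin(
        set(pairs["snp_id"]) - ok_snps).sum())
    pairs = pairs[pairs["snp_id"].isin(ok_snps)].reset_index(drop=True)

    beta = m.beta.loc[samples]
    D = gsub.dosage.loc[samples]

    # Frisch-Waugh-Lovell: residualize probes and dosages on the
    # covariates once; the per-pair slope and SE then equal the full-model
    # OLS coefficient with n - p_cov - 1 residual df.
    Q, _ = np.linalg.qr(A)
    used_probes = pairs["probe_id"].unique()
    used_snps = pairs["snp_id"].unique()
    Y = beta[list(used_probes)].to_numpy(dtype=float)
    Yr = Y - Q @ (Q.T @ Y)
    pidx = {p: i for i, p in enumerate(used_probes)}
    Dmat = D[list(used_snps)].to_numpy(dtype=float)
    has_nan = np.isnan(Dmat).any(axis=0)
    Dr = np.where(np.isnan(Dmat), 0.0, Dmat)
    Dr = Dr - Q @ (Q.T @ Dr)
    sidx = {s: i for i, s in enumerate(used_snps)}

    df = n - p_cov - 1
    if df < 1:
        raise ValidationError("not enough samples for the meQTL model")
    eff = np.empty(len(pairs))
    se = np.empty(len(pairs))
    pv = np.empty(len(pairs))
    ns = np.full(len(pairs), n)
    for k, (pid, sid) in enumerate(zip(pairs["probe_id"], pairs["snp_id"])):
        si = sidx[sid]
        if has_nan[si]:
            mask = ~np.isnan(Dmat[:, si])
            nk = int(mask.sum())
            Xk = np.column_stack([A[mask], Dmat[mask, si]])
            yk = Y[mask, pidx[pid]]
            coef, _, rank, _ = np.linalg.lstsq(Xk, yk, rcond=None)
            resid = yk - Xk @ coef
            dfk = nk - Xk.shape[1]
            sig2 = resid @ resid / dfk
            XtXi = np.linalg.inv(Xk.T @ Xk)
            eff[k] = coef[-1]
            se[k] = np.sqrt(sig2 * XtXi[-1, -1])
            pv[k] = 2 * stats.t.sf(abs(eff[k] / se[k]), dfk)
            ns[k] = nk
            continue
        d = Dr[:, si]
        y = Yr[:, pidx[pid]]
        dd = d @ d
        slope = (d @ y) / dd
        rss = y @ y - slope ** 2 * dd
        sig2 = rss / df
        sek = np.sqrt(sig2 / dd)
        eff[k] = slope
        se[k] = sek
        pv[k] = 2 * stats.t.sf(abs(slope / sek), df)

    records = pairs.copy()
    records["effect"] = eff
    records["se"] = se
    records["p"] = pv
    records["n"] = ns
    records["q"] = bh_fdr(pv) if len(records) else np.array([])
    significant = records[records["q"] < q_level].copy()
    lam = genomic_inflation(records["p"]) if len(records) else np.nan
    return dict(records=records, significant=significant, lambda_gc=lam,
                skipped_sub_maf_pairs=skipped_maf,
                n_pairs_tested=len(records))


def meqtl_replication_filter(significant: pd.DataFrame,
                             replication_records: pd.DataFrame,
                             p_threshold: float = 0.001) -> pd.DataFrame:
    """Independent-cohort rule: p < 0.001 with consistent direction."""
    key = ["probe_id", "snp_id"]
    repl = replication_records.set_index(key)
    rows = []
    for _, row in significant.iterrows():
        k = (row["probe_id"], row["snp_id"])
        testable = k in repl.index
        ok = False
        if testable:
            r = repl.loc[k]
            ok = bool(r["p"] < p_threshold
                      and np.sign(r["effect"]) == np.sign(row["effect"]))
        rows.append((*k, testable, ok))
    return pd.DataFrame(rows, columns=[*key, "testable", "replicated"])


def top_meqtl_per_gene(records: pd.DataFrame,
                       annotation: pd.DataFrame) -> pd.DataFrame:
    """Best (smallest p) meQTL record per annotated gene.

    Ties on p are broken by larger |effect|, then lexicographic snp_id.
    """
    rec = records.copy()
    rec["gene"] = annotation.loc[rec["probe_id"], "gene"].to_numpy()
    rec["_abs_eff"] = -rec["effect"].abs()
    rec = rec.sort_values(["gene", "p", "_abs_eff", "snp_id"])
    best = rec.groupby("gene", as_index=False).head(1)
    return best.drop(columns="_abs_eff").reset_index(drop=True)


def _logistic_fit(y: np.ndarray, X: np.ndarray,
                  tol: float = 1e-8, maxiter: int = 100) -> dict:
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(method="newton", tol=tol,
                                     maxiter=maxiter, disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return dict(separation=True)
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 15:
        return dict(separation=True)
    return dict(separation=False, coef=params, se=np.asarray(fit.bse),
                p=np.asarray(fit.pvalues), llf=float(fit.llf))


def case_control_assoc(g: GenotypeTable, sheet: pd.DataFrame,
                       case: str = "MCTD", control: str = "CTRL",
                       ) -> pd.DataFrame:
    """Per-SNP additive logistic regression of case status on dosage.

    Returns one row per SNP with the log-odds coefficient, OR, SE, p,
    allele frequencies per group, and a separation flag (no OR reported
    for separated fits).  The genomic-control coefficient of the scan is
    attached as ``table.attrs["lambda_gc"]``.
    """
    keep = [s for s in g.dosage.index
            if s in sheet.index
            and sheet.at[s, "diagnosis"] in (case, control)]
    if not keep:
        raise ValidationError("no genotyped samples with the two diagnoses")
    y_all = (sheet.loc[keep, "diagnosis"] == case).to_numpy(dtype=float)
    if y_all.sum() == 0 or y_all.sum() == len(y_all):
        raise ValidationError("both case and control classes are required")
    D = g.dosage.loc[keep]
    rows = []
    for sid in D.columns:
        d = D[sid].to_numpy(dtype=float)
        mask = np.isfinite(d)
        d, y = d[mask], y_all[mask]
        n = int(mask.sum())
        af_case = float(d[y == 1].mean() / 2) if (y == 1).any() else np.nan
        af_ctrl = float(d[y == 0].mean() / 2) if (y == 0).any() else np.nan
        if np.ptp(d) == 0:
            rows.append((sid, np.nan, np.nan, np.nan, np.nan, n,
                         af_case, af_ctrl, "monomorphic"))
            continue
        X = np.column_stack([np.ones_like(d), d])
        fit = _logistic_fit(y, X)
        if fit["separation"]:
            rows.append((sid, np.nan, np.nan, np.nan, np.nan, n,
                         af_case, af_ctrl, "separation"))
            continue
        beta, se, p = fit["coef"][1], fit["se"][1], fit["p"][1]
        rows.append((sid, beta, float(np.exp(beta)), se, p, n,
                     af_case, af_ctrl, ""))
    out = pd.DataFrame(rows, columns=["snp_id", "log_or", "odds_ratio",
                                      "se", "p", "n", "af_case",
                                      "af_control", "flag"])
    ok = out["p"].notna()
    out.attrs["lambda_gc"] = (genomic_inflation(out.loc[ok, "p"])
                              if ok.any() else np.nan)
    return out


def mediation_triangle(meqtl_significant: pd.DataFrame,
                       dms_calls: list[str],
                       ewas_records: pd.DataFrame,
                       assoc_records: pd.DataFrame,
                       p_assoc: float = 0.05) -> pd.DataFrame:
    """SNP -> methylation -> disease intersection report.

    One row per (snp, probe) pair that is a significant meQTL, whose CpG
    is in the disease-associated call set, and whose SNP shows at least
    suggestive case/control association (p < ``p_assoc``).
    """
    dms = set(dms_calls)
    ewas = ewas_records.set_index("probe_id")
    assoc = assoc_records.set_index("snp_id")
    rows = []
    for _, r in meqtl_significant.iterrows():
        pid, sid = r["probe_id"], r["snp_id"]
        if pid not in dms or sid not in assoc.index:
            continue
        a = assoc.loc[sid]
        if not np.isfinite(a["p"]) or a["p"] >= p_assoc:
            continue
        ew_eff = ewas.at[pid, "effect"] if pid in ewas.index else np.nan
        ew_p = ewas.at[pid, "p"] if pid in ewas.index else np.nan
        consistent = bool(
            np.isfinite(ew_eff)
            and np.sign(r["effect"] * a["log_or"]) == np.sign(ew_eff)
            and ew_eff != 0)
        rows.append((sid, pid, r["effect"], r["p"], ew_eff, ew_p,
                     a["odds_ratio"], a["p"], consistent))
    return pd.DataFrame(rows, columns=[
        "snp_id", "probe_id", "meqtl_effect", "meqtl_p", "ewas_effect",
        "ewas_p", "odds_ratio", "assoc_p", "direction_consistent"])
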