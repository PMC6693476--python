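"""Treatment-adjusted and treatment-stratified differential methylation.

Three complementary views of how therapy interacts with the disease
signature:

* *adjusted scan* — the standard model with indicator covariates for each
  therapy; its effects are compared with the unadjusted scan by Pearson
  correlation over the disease-associated probe set;
* *stratified scan* — the model fitted separately in treated cases +
  controls and untreated cases + controls (controls are shared by both
  strata, matching the way group methylation profiles are illustrated);
* *specific-effect rule* — a probe is treatment-specific when it is
  Bonferroni-significant in one stratum but shows little evidence in the
  other (p above a floor), and the same directional pattern replicates at
  p < 0.05 in an independent cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MethylationMatrix, TREATMENTS, ValidationError, \
    bonferroni_threshold
from .ewas import EwasModelSpec, ScanResult, run_dms_scan

__all__ = ["ewas_treatment_adjusted", "stratified_scan",
           "call_treatment_specific"]


def ewas_treatment_adjusted(m: MethylationMatrix, sheet: pd.DataFrame,
                            cells: pd.DataFrame | None,
                            alpha: float = 0.05,
                            treatments: tuple[str, ...] = TREATMENTS,
                            spec: EwasModelSpec | None = None,
                            unadjusted: ScanResult | None = None,
                            dms_calls: list[str] | None = None,
                            ) -> tuple[ScanResult, float]:
    """Disease scan with therapy indicators as extra covariates.

    Returns the adjusted scan and the Pearson correlation between
    adjusted and unadjusted disease effects (over ``dms_calls`` when
    given, otherwise all shared probes).
    """
    spec = spec or EwasModelSpec()
    adj_spec = EwasModelSpec(case=spec.case, control=spec.control,
                             include_sex=spec.include_sex,
                             treatments=tuple(treatments),
                             drop_cell_type=spec.drop_cell_type)
    adjusted = run_dms_scan(m, sheet, cells, alpha, adj_spec)
    if unadjusted is None:
        unadjusted = run_dms_scan(m, sheet, cells, alpha, spec)
    a = adjusted.records.set_index("probe_id")["effect"]
    u = unadjusted.records.set_index("probe_id")["effect"]
    probes = dms_calls if dms_calls is not None else \
        [p for p in a.index if p in u.index]
    a, u = a.loc[probes], u.loc[probes]
    ok = a.notna() & u.notna()
    r = float(np.corrcoef(a[ok], u[ok])[0, 1]) if ok.sum() > 1 else np.nan
    adjusted.extra["effect_correlation_with_unadjusted"] = r
    return adjusted, r


def stratified_scan(m: MethylationMatrix, sheet: pd.DataFrame,
                    cells: pd.DataFrame | None, treatment: str,
                    call_set: list[str] | None = None,
                    alpha: float = 0.05,
                    spec: EwasModelSpec | None = None,
                    min_stratum: int = 3) -> pd.DataFrame:
    """Disease scan fitted separately in treated and untreated strata.

    Controls are shared by both strata; each stratum keeps cases with
    (respectively without) the given therapy flag.  Returns a per-probe
    table with treated/untreated effect and p.
    """
    spec = spec or EwasModelSpec()
    if treatment not in sheet.columns:
        raise ValidationError(f"unknown treatment column {treatment!r}")
    cases = sheet.index[(sheet["diagnosis"] == spec.case)]
    controls = sheet.index[sheet["diagnosis"] == spec.control]
    treated = [s for s in cases if sheet.at[s, treatment] == 1]
    untreated = [s for s in cases if sheet.at[s, treatment] == 0]
    counts = dict(treated=len(treated), untreated=len(untreated),
                  controls=len(controls))
    if len(treated) < min_stratum or len(untreated) < min_stratum:
        raise ValidationError(
            f"stratum too small for {treatment!r}: {counts} "
            f"(minimum {min_stratum} cases per stratum)")

    probes = call_set if call_set is not None else m.probe_ids
    msub = m.subset_probes(probes)
    out = {}
    for label, case_ids in (("treated", treated), ("untreated", untreated)):
        keep = list(case_ids) + list(controls)
        res = run_dms_scan(msub.subset_samples(keep), sheet.loc[keep],
                           cells.loc[keep] if cells is not None else None,
                           alpha, spec)
        rec = res.records.set_index("probe_id")
        out[f"{label}_effect"] = rec["effect"]
        out[f"{label}_p"] = rec["p"]
    table = pd.DataFrame(out)
    table.insert(0, "probe_id", table.index)
    table = table.reset_index(drop=True)
    table.attrs["counts"] = counts
    return table


def call_treatment_specific(discovery: pd.DataFrame,
                            replication: pd.DataFrame,
                            alpha_one: float | None = None,
                            p_other_floor: float = 0.01,
                            n_calls: int | None = None,
                            repl_p: float = 0.05) -> pd.DataFrame:
    """Treatment-specific effect decision rule.

    A probe is called specific in a stratum when, in the discovery
    stratified table, its p in that stratum is below ``alpha_one``
    (default 0.05 / number of probes scanned) while the other stratum
    shows little evidence (p above ``p_other_floor``); and the same
    stratum replicates with consistent direction at p < ``repl_p``.
    """
    m = n_calls if n_calls is not None else len(discovery)
    if alpha_one is None:
        alpha_one = bonferroni_threshold(0.05, max(1, m))
    disc = discovery.set_index("probe_id")
    repl = replication.set_index("probe_id")
    rows = []
    for pid, row in disc.iterrows():
        for stratum, other in (("treated", "untreated"),
                               ("untreated", "treated")):
            p_s, p_o = row[f"{stratum}_p"], row[f"{other}_p"]
            if not (np.isfinite(p_s) and np.isfinite(p_o)):
                continue
            if p_s < alpha_one and p_o > p_other_floor:
                replicated = False
                if pid in repl.index:
                    r = repl.loc[pid]
                    replicated = bool(
                        np.isfinite(r[f"{stratum}_p"])
                        and r[f"{stratum}_p"] < repl_p
                        and np.sign(r[f"{stratum}_effect"])
                        == np.sign(row[f"{stratum}_effect"]))
                if replicated:
                    rows.append((pid, stratum, row[f"{stratum}_effect"],
                                 p_s, row[f"{other}_effect"], p_o))
    out = pd.DataFrame(rows, columns=[
        "probe_id", "specific_stratum", "effect", "p",
        "other_effect", "other_p"])
    out.attrs["alpha_one"] = alpha_one
    return out
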