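"""Synthetic whole-blood methylation cohort generator.

Generates methylation, genotype, covariate and cell-composition data with
the statistical structure a blood EWAS of a rare systemic autoimmune
disease assumes, plus a ground-truth ledger for parameter-recovery tests:

* a small case group (default 31 MCTD) against a large shared healthy pool
  (default 255), with an independent replication cohort on a legacy
  platform covering ~55% of probes;
* pervasive case hypomethylation at a designated interferon-like probe
  set, with adjusted beta-scale differences drawn in [-0.5, -0.07];
* case-specific residual-variance inflation at variable-methylation probes;
* a six-cell-type mixture (neutrophils dominant) behind every beta value;
* batch, age and sex effects on the logit scale;
* cis-SNP effects on methylation within a 1 Mb window, disease-associated
  allele-frequency shifts, and one designated "mediated" locus wiring
  SNP -> methylation -> disease jointly;
* treatment-dependent attenuation of disease effects, with a few probes
  whose effect is fully specific to untreated patients;
* partially shared effect vectors across five disease labels.

The generative model per probe j and sample i is

    logit(beta_ij) = logit(sum_c w_ic B_jc) + batch + age + sex
                     + g_ij * gamma_j + case_i * shift_j + e_ij

with e_ij ~ N(0, sigma_j^2 * inflation) and betas clipped to (1e-6, 1-1e-6).
Disease and genotype effects are specified on the *beta* scale (the scale
the association tables report) and converted to logit-scale shifts by
numerically solving, per probe and sample group, for the shift whose
expected beta-scale difference (Gauss-Hermite integration over the noise)
equals the target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (CELL_TYPES, GenotypeTable, MethylationMatrix, TREATMENTS,
                   ValidationError, validate_sample_sheet)

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate_reference_profiles",
           "simulate_cohort", "truth_report"]

_EPS = 1e-6
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(25)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    return np.log(p / (1 - p))


def _expected_beta(mu: np.ndarray, sigma: float) -> float:
    """E[sigmoid(mu + sigma Z)], Z ~ N(0,1), averaged over the mu vector."""
    if sigma == 0:
        return float(np.mean(sigmoid(mu)))
    nodes = mu[:, None] + np.sqrt(2.0) * sigma * _GH_X[None, :]
    return float(np.mean(sigmoid(nodes) @ _GH_W) / np.sqrt(np.pi))


def solve_logit_shift(mu: np.ndarray, sigma: float, target: float) -> float:
    """Logit shift s with E[beta(mu+s)] - E[beta(mu)] = target.

    ``mu`` are the linear predictors (without noise) of the samples the
    shift will be applied to; monotonicity of the expected beta in s makes
    the root unique.
    """
    if target == 0:
        return 0.0
    base = _expected_beta(mu, sigma)
    lo, hi = -30.0, 30.0
    # achievable range is (-base, 1-base); clamp just inside
    target = float(np.clip(target, -base + 1e-4, 1 - base - 1e-4))
    return brentq(lambda s: _expected_beta(mu + s, sigma) - base - target,
                  lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# Configuration and truth ledger
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the discovery design the analyses assume: 31 cases vs
    255 shared controls on the full-resolution platform, a 21/103
    replication cohort on a legacy platform, disease effects up to
    |delta-beta| = 0.5, six-fold case variance inflation at variable
    probes, and cross-disease effect sharing of 1.0 / 1.0 / 0.15 / 0.2
    for SLE / SjS / RA / SSc.
    """

    # cohort sizes
    n_cases: Mapping[str, int] = field(default_factory=lambda: {
        "MCTD": 31, "SLE": 234, "SjS": 206, "RA": 217, "SSc": 177})
    n_controls: int = 255
    n_repl_cases: int = 21
    n_repl_controls: int = 103
    n_extra_assoc_cases: int = 58      # genotype-only MCTD (89 total genotyped)
    n_extra_assoc_controls: int = 295  # genotype-only CTRL (550 total genotyped)

    # probe panel
    n_probes: int = 2000               # autosomal, beyond the reference set
    n_x_probes: int = 120
    n_ref_probes: int = 120            # cell-type discriminating probes
    probe_spacing: int = 30_000
    legacy_platform_frac: float = 0.55

    # disease effects
    n_ifn_probes: int = 150
    delta_range: tuple[float, float] = (-0.5, -0.07)
    hyper_fraction: float = 0.06       # fraction of affected probes hypermethylated
    share_map: Mapping[str, float] = field(default_factory=lambda: {
        "SLE": 1.0, "SjS": 1.0, "RA": 0.15, "SSc": 0.2})
    share_jitter_sd: float = 0.016    # idiosyncratic per-disease effect (beta scale)

    # differential variability
    n_vms_probes: int = 80
    vms_overlap_frac: float = 0.85
    var_inflation: float = 6.0         # case residual-variance multiplier

    # genotypes
    n_snps: int = 300
    n_meqtl_affected: int = 8
    n_meqtl_unaffected: int = 8
    meqtl_effect_range: tuple[float, float] = (0.03, 0.15)  # |beta per allele|
    meqtl_window: int = 1_000_000
    n_risk_snps: int = 2
    risk_snp_freq_shift: float = 0.10
    mediated_maf: float = 0.30
    mediated_freq_shift: float = 0.18
    mediated_meqtl_effect: float = -0.10

    # treatments (fractions of the MCTD case group; 12/13/9 of 31)
    treatment_prevalence: Mapping[str, float] = field(default_factory=lambda: {
        "steroid": 12 / 31, "antimalarial": 13 / 31,
        "immunosuppressant": 9 / 31})
    treatment_attenuation: float = 0.25
    n_specific_probes: int = 6
    specific_treatment: str = "immunosuppressant"

    # nuisance structure
    n_batches: int = 4
    batch_sd: float = 0.12
    age_slope_sd: float = 0.004
    sex_effect_sd: float = 0.06
    x_sex_effect_sd: float = 0.30
    cell_dependent_frac: float = 0.30
    cell_dep_sd: float = 0.08
    dirichlet_alpha: tuple[float, ...] = (32.0, 5.0, 2.5, 6.0, 3.5, 2.5)
    noise_sd: float = 0.5              # logit-scale residual sd

    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.n_cases.values()) or self.n_controls < 0:
            raise ValidationError("cohort sizes must be non-negative")
        if self.var_inflation < 1:
            raise ValidationError("var_inflation must be >= 1")
        if not 0 <= self.treatment_attenuation <= 1:
            raise ValidationError("treatment_attenuation must be in [0,1]")
        if self.n_ifn_probes > self.n_probes:
            raise ValidationError("n_ifn_probes exceeds n_probes")
        if self.n_vms_probes > self.n_probes:
            raise ValidationError("n_vms_probes exceeds n_probes")
        needed = (self.n_meqtl_affected + self.n_meqtl_unaffected
                  + self.n_risk_snps + 1)
        if self.n_snps < needed:
            raise ValidationError(
                f"n_snps={self.n_snps} too small for wired loci ({needed})")
        if len(self.dirichlet_alpha) != len(CELL_TYPES):
            raise ValidationError("dirichlet_alpha must have 6 components")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def null(cls, **kw) -> "SimConfig":
        """A no-signal configuration (calibration runs)."""
        base = dict(n_ifn_probes=0, n_vms_probes=0, var_inflation=1.0,
                    n_meqtl_affected=0, n_meqtl_unaffected=0, n_risk_snps=0,
                    mediated_freq_shift=0.0, mediated_meqtl_effect=0.0,
                    n_specific_probes=0,
                    n_cases={"MCTD": 31})
        base.update(kw)
        return cls(**base)


@dataclass
class SimTruth:
    """Ground-truth effect ledger; the acceptance surface for recovery."""

    probes: pd.DataFrame          # per-probe truth (delta, flags, wiring)
    snps: pd.DataFrame            # per-SNP truth (AF, risk, meQTL wiring)
    reference_profiles: pd.DataFrame   # ref probes x cell types (betas)
    cell_props: pd.DataFrame      # realized proportions, methylation samples
    mediated: tuple[str, str] | None   # (snp_id, probe_id) wired triangle

    @property
    def affected_probes(self) -> list[str]:
        return list(self.probes.index[self.probes["delta"] != 0])

    @property
    def vms_probes(self) -> list[str]:
        return list(self.probes.index[self.probes["var_inflated"]])


@dataclass
class SimResult:
    discovery: MethylationMatrix
    replication: MethylationMatrix
    genotypes: GenotypeTable
    sheet: pd.DataFrame
    cell_props: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    def sheet_for(self, cohort: str) -> pd.DataFrame:
        return self.sheet[self.sheet["cohort"] == cohort]


# ---------------------------------------------------------------------------
# Reference profiles
# ---------------------------------------------------------------------------

def simulate_reference_profiles(k_celltypes: int = len(CELL_TYPES),
                                n_ref_probes: int = 120,
                                seed: int | np.random.Generator = 0,
                                separation: tuple[float, float] = (0.6, 0.95),
                                background: tuple[float, float] = (0.05, 0.30),
                                dirichlet_alpha: tuple[float, ...] | None = None,
                                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Cell-type reference beta profiles at discriminating probes.

    Each reference probe marks one cell type (assigned cyclically): the
    marked type draws a beta from ``separation`` and every other type from
    ``background`` (orientation flipped for half the probes).  Returns the
    reference matrix (probes x cell types) and a Dirichlet prior over
    proportions.
    """
    if k_celltypes < 2:
        raise ValidationError("need at least two cell types")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    names = (list(CELL_TYPES[:k_celltypes])
             if k_celltypes <= len(CELL_TYPES)
             else [f"cell{c}" for c in range(k_celltypes)])
    hi = rng.uniform(*separation, size=n_ref_probes)
    lo = rng.uniform(*background, size=(n_ref_probes, k_celltypes))
    flip = rng.random(n_ref_probes) < 0.5
    ref = lo
    marker = np.arange(n_ref_probes) % k_celltypes
    ref[np.arange(n_ref_probes), marker] = hi
    ref[flip] = 1.0 - ref[flip]
    probe_ids = [f"ref{j:05d}" for j in range(n_ref_probes)]
    ref_df = pd.DataFrame(ref, index=probe_ids, columns=names)
    if dirichlet_alpha is None:
        dirichlet_alpha = tuple(SimConfig().dirichlet_alpha[:k_celltypes])
    return ref_df, np.asarray(dirichlet_alpha, dtype=float)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _make_probe_annotation(cfg: SimConfig, rng: np.random.Generator
                           ) -> pd.DataFrame:
    """Main panel + X probes + reference probes, with gene blocks."""
    rows = []
    chrom_pos = {str(c): 1_000_000 for c in range(1, 23)}
    gene_counter = 0
    block_left = 0
    gene = "Intergenic"
    n_main = cfg.n_probes
    for j in range(n_main):
        chrom = str(1 + j % 22)
        pos = chrom_pos[chrom]
        chrom_pos[chrom] += cfg.probe_spacing
        if block_left == 0:
            block_left = int(rng.integers(2, 5))
            if rng.random() < 0.15:
                gene = "Intergenic"
            else:
                gene_counter += 1
                gene = f"G{gene_counter:05d}"
        block_left -= 1
        rows.append((f"cg{j:08d}", chrom, pos, gene))
    xpos = 1_000_000
    for j in range(cfg.n_x_probes):
        rows.append((f"cgX{j:06d}", "X", xpos, f"XG{j // 3:05d}"))
        xpos += cfg.probe_spacing
    refpos = 1_000_000
    for j in range(cfg.n_ref_probes):
        # reference probes live on autosomes, spread round-robin
        rows.append((f"ref{j:05d}", str(1 + j % 22), refpos + 17_000, "CellRef"))
        refpos += cfg.probe_spacing
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene"])
    return df.set_index("probe_id")


def _draw_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal methylation baselines typical of array data."""
    u = rng.random(n)
    out = np.empty(n)
    lo = u < 0.4
    hi = (u >= 0.4) & (u < 0.8)
    out[lo] = rng.uniform(0.03, 0.20, lo.sum())
    out[hi] = rng.uniform(0.80, 0.97, hi.sum())
    mid = ~(lo | hi)
    out[mid] = rng.uniform(0.20, 0.80, mid.sum())
    return out


def _draw_samples(rng: np.random.Generator, cfg: SimConfig, prefix: str,
                  counts: Mapping[str, int], n_controls: int,
                  cohort: str) -> pd.DataFrame:
    rows = []
    idx = 0

    def covariates():
        age = float(np.clip(rng.normal(45, 12), 18, 85))
        sex = "female" if rng.random() < 0.9 else "male"
        batch = f"b{int(rng.integers(cfg.n_batches))}"
        return age, sex, batch

    for dx, n in [("CTRL", n_controls)] + list(counts.items()):
        for _ in range(n):
            age, sex, batch = covariates()
            rows.append((f"{prefix}{idx:04d}", dx, age, sex, batch,
                         0, 0, 0, cohort))
            idx += 1
    df = pd.DataFrame(rows, columns=["sample_id", "diagnosis", "age", "sex",
                                     "batch", *TREATMENTS, "cohort"])
    df = df.set_index("sample_id")
    # treatment assignment among MCTD cases, exact counts per therapy
    mctd = df.index[df["diagnosis"] == "MCTD"]
    for t in TREATMENTS:
        n_t = int(round(cfg.treatment_prevalence.get(t, 0.0) * len(mctd)))
        chosen = rng.choice(mctd, size=min(n_t, len(mctd)), replace=False)
        df.loc[chosen, t] = 1
    return df


def _simulate_methylation(cfg: SimConfig, sheet: pd.DataFrame,
                          probe_truth: pd.DataFrame,
                          ref: pd.DataFrame, alpha: np.ndarray,
                          profiles_B: np.ndarray,
                          snp_truth: pd.DataFrame,
                          dosage: pd.DataFrame,
                          effects: dict[str, np.ndarray],
                          rng: np.random.Generator,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Betas for one cohort; returns (beta samples x probes, cell props)."""
    samples = sheet.index
    n, m = len(samples), len(probe_truth)
    w = rng.dirichlet(alpha, size=n)                       # n x 6
    mix = w @ profiles_B.T                                 # n x m, beta scale
    mu = logit(mix)

    batch_codes = pd.Categorical(sheet["batch"]).codes
    mu += effects["batch"][:, batch_codes].T               # probe x batch
    age_c = (sheet["age"].to_numpy() - 45.0) / 1.0
    mu += np.outer(age_c, effects["age_slope"])
    male = (sheet["sex"] == "male").to_numpy(dtype=float)
    mu += np.outer(male, effects["sex"])

    # genotype effects (gamma on the logit scale, solved upstream)
    probe_pos = {p: k for k, p in enumerate(probe_truth.index)}
    wired = snp_truth[snp_truth["target_probe"].notna()]
    for snp_id, row in wired.iterrows():
        j = probe_pos[row["target_probe"]]
        d = dosage.loc[samples, snp_id].to_numpy()
        mu[:, j] += row["logit_effect"] * np.nan_to_num(d)

    # residual sd per sample x probe (case variance inflation at VMS probes)
    sigma = np.full((n, m), cfg.noise_sd)
    is_mctd = (sheet["diagnosis"] == "MCTD").to_numpy()
    vms_mask = probe_truth["var_inflated"].to_numpy(dtype=bool)
    sigma[np.ix_(is_mctd, vms_mask)] *= np.sqrt(cfg.var_inflation)

    # mean-preserving variance inflation: widening the logit-scale noise
    # pulls the expected beta toward 0.5, so re-center the case group at
    # each variance-inflated probe before any disease shift is applied
    if cfg.var_inflation > 1 and is_mctd.any():
        sig_i = cfg.noise_sd * np.sqrt(cfg.var_inflation)
        for j in np.flatnonzero(vms_mask):
            mu_g = mu[is_mctd, j]
            base = _expected_beta(mu_g, cfg.noise_sd)
            mu[is_mctd, j] += brentq(
                lambda c: _expected_beta(mu_g + c, sig_i) - base,
                -30.0, 30.0, xtol=1e-10)

    # disease shifts: per affected probe, per sample group with a distinct
    # beta-scale target, solve the logit shift from the group's own mu
    dx = sheet["diagnosis"].to_numpy()
    treated_any = sheet[list(TREATMENTS)].to_numpy().sum(axis=1) > 0
    spec_t = cfg.specific_treatment
    treated_spec = sheet[spec_t].to_numpy() > 0 if spec_t in sheet else \
        np.zeros(n, dtype=bool)

    affected = probe_truth.index[probe_truth["delta"] != 0]
    for pid in affected:
        j = probe_pos[pid]
        delta = probe_truth.at[pid, "delta"]
        specific = probe_truth.at[pid, "specific_treatment"]
        groups: list[tuple[np.ndarray, float]] = []
        if specific == specific and specific:   # not NaN/empty
            t_mask = treated_spec if specific == spec_t else (
                sheet[specific].to_numpy() > 0)
            g1 = is_mctd & ~t_mask
            g2 = is_mctd & t_mask
            groups.append((g1, delta))
            groups.append((g2, 0.0))            # fully attenuated
        else:
            g1 = is_mctd & ~treated_any
            g2 = is_mctd & treated_any
            groups.append((g1, delta))
            groups.append((g2, delta * (1 - cfg.treatment_attenuation)))
        for disease in cfg.share_map:
            col = f"target_{disease}"
            target = probe_truth.at[pid, col] if col in probe_truth else 0.0
            groups.append((dx == disease, target))
        for mask, target in groups:
            if not mask.any() or target == 0:
                continue
            sig = float(sigma[mask, j].mean())
            shift = solve_logit_shift(mu[mask, j], sig, target)
            mu[mask, j] += shift

    noise = rng.standard_normal((n, m)) * sigma
    beta = sigmoid(mu + noise)
    beta = np.clip(beta, _EPS, 1 - _EPS)
    beta_df = pd.DataFrame(beta, index=samples, columns=probe_truth.index)
    w_df = pd.DataFrame(w, index=samples, columns=list(ref.columns))
    return beta_df, w_df


def simulate_cohort(cfg: SimConfig | None = None) -> SimResult:
    """Generate discovery + replication cohorts, genotypes and truth.

    Deterministic given ``cfg.seed``: all sub-streams are spawned from a
    single :class:`numpy.random.SeedSequence`.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(8)]
    (rng_probes, rng_ref, rng_geno, rng_disc, rng_repl,
     rng_extra, rng_truth, rng_misc) = streams

    # --- probes and truth scaffolding
    ann = _make_probe_annotation(cfg, rng_probes)
    main_ids = [p for p in ann.index if p.startswith("cg") and
                ann.at[p, "chrom"] != "X"]
    x_ids = [p for p in ann.index if ann.at[p, "chrom"] == "X"]
    ref_ids = [p for p in ann.index if p.startswith("ref")]

    truth = ann.copy()
    truth["baseline"] = 0.5
    truth["delta"] = 0.0
    truth["var_inflated"] = False
    truth["specific_treatment"] = ""
    truth["is_reference"] = truth.index.str.startswith("ref")
    truth["cell_dependent"] = False
    truth["cis_snp"] = None
    truth["meqtl_effect"] = 0.0

    # affected (interferon-like) probe set with beta-scale deltas
    affected = list(rng_truth.choice(main_ids, size=cfg.n_ifn_probes,
                                     replace=False))
    lo, hi = sorted(abs(d) for d in cfg.delta_range)
    mag = rng_truth.uniform(lo, hi, size=cfg.n_ifn_probes)
    sign = np.where(rng_truth.random(cfg.n_ifn_probes) < cfg.hyper_fraction,
                    1.0, -1.0)
    deltas = sign * mag
    truth.loc[affected, "delta"] = deltas

    # variance-inflated probes: mostly overlapping the affected set
    n_from_affected = min(int(round(cfg.vms_overlap_frac * cfg.n_vms_probes)),
                          len(affected))
    vms = list(rng_truth.choice(affected, size=n_from_affected,
                                replace=False)) if n_from_affected else []
    pool = [p for p in main_ids if p not in set(affected)]
    extra = cfg.n_vms_probes - len(vms)
    if extra > 0 and pool:
        vms += list(rng_truth.choice(pool, size=extra, replace=False))
    truth.loc[vms, "var_inflated"] = True

    # treatment-specific probes (fully attenuated under one therapy)
    if cfg.n_specific_probes:
        spec = rng_truth.choice(affected, size=min(cfg.n_specific_probes,
                                                   len(affected)),
                                replace=False)
        truth.loc[spec, "specific_treatment"] = cfg.specific_treatment

    # baselines; affected probes need headroom for the case shift
    truth.loc[main_ids + x_ids, "baseline"] = _draw_baseline(
        rng_truth, len(main_ids) + len(x_ids))
    for pid, d in zip(affected, deltas):
        if d < 0:
            truth.at[pid, "baseline"] = rng_truth.uniform(-d + 0.07, 0.95)
        else:
            truth.at[pid, "baseline"] = rng_truth.uniform(0.03, 0.93 - d)

    # per-disease effect targets: shared vector scaled by the share map,
    # plus a small idiosyncratic component (diseases are not exact copies)
    baselines = truth["baseline"]
    for disease, share in cfg.share_map.items():
        truth[f"target_{disease}"] = 0.0
        if affected:
            b = baselines.loc[affected].to_numpy()
            t = (share * truth.loc[affected, "delta"].to_numpy()
                 + rng_truth.normal(0, cfg.share_jitter_sd, len(affected)))
            t = np.clip(t, -(b - 0.02), 0.96 - b)
            truth.loc[affected, f"target_{disease}"] = t

    # cell-type structure
    ref_df, alpha = simulate_reference_profiles(
        len(CELL_TYPES), cfg.n_ref_probes, rng_ref,
        dirichlet_alpha=cfg.dirichlet_alpha)
    ref_df.index = ref_ids
    n_all = len(ann)
    B = np.tile(truth["baseline"].to_numpy()[:, None], (1, len(CELL_TYPES)))
    B[[ann.index.get_loc(p) for p in ref_ids]] = ref_df.to_numpy()
    celldep_pool = [p for p in main_ids if p not in set(affected)]
    n_cd = int(cfg.cell_dependent_frac * len(celldep_pool))
    celldep = rng_truth.choice(celldep_pool, size=n_cd, replace=False)
    truth.loc[celldep, "cell_dependent"] = True
    for pid in celldep:
        k = ann.index.get_loc(pid)
        B[k] = np.clip(B[k] + rng_truth.normal(0, cfg.cell_dep_sd,
                                               len(CELL_TYPES)), 0.02, 0.98)
    B = np.clip(B, 0.02, 0.98)

    # platform overlap mask for the replication (legacy) array
    truth["on_legacy_platform"] = rng_truth.random(n_all) < cfg.legacy_platform_frac

    # --- genotypes: wired meQTLs, risk SNPs, the mediated locus, nulls
    snp_rows = []
    used_probes: set[str] = set()

    def _place_near(pid: str, max_off: int) -> tuple[str, int]:
        chrom = ann.at[pid, "chrom"]
        off = int(rng_geno.integers(-max_off, max_off + 1))
        return chrom, max(1, int(ann.at[pid, "pos"]) + off)

    def _meqtl_gamma() -> float:
        g = rng_geno.uniform(*cfg.meqtl_effect_range)
        return g if rng_geno.random() < 0.5 else -g

    snp_idx = 0

    def _add_snp(chrom, pos, maf, shift=0.0, target=None, gamma=0.0,
                 mediated=False):
        nonlocal snp_idx
        sid = f"rs{snp_idx:06d}"
        snp_idx += 1
        snp_rows.append(dict(snp_id=sid, chrom=chrom, pos=pos, ref="A",
                             alt="G", maf=maf, case_freq_shift=shift,
                             is_risk=shift != 0, target_probe=target,
                             meqtl_beta=gamma, is_mediated=mediated))
        return sid

    mediated_pair = None
    if cfg.mediated_meqtl_effect != 0 and affected:
        pid = str(rng_geno.choice(affected))
        used_probes.add(pid)
        chrom, pos = _place_near(pid, cfg.meqtl_window // 2)
        sid = _add_snp(chrom, pos, cfg.mediated_maf, cfg.mediated_freq_shift,
                       pid, cfg.mediated_meqtl_effect, mediated=True)
        mediated_pair = (sid, pid)
    aff_pool = [p for p in affected if p not in used_probes]
    for pid in rng_geno.choice(aff_pool,
                               size=min(cfg.n_meqtl_affected, len(aff_pool)),
                               replace=False) if aff_pool else []:
        used_probes.add(pid)
        chrom, pos = _place_near(pid, cfg.meqtl_window // 2)
        _add_snp(chrom, pos, rng_geno.uniform(0.1, 0.45), 0.0, pid,
                 _meqtl_gamma())
    un_pool = [p for p in main_ids
               if p not in set(affected) and p not in used_probes]
    for pid in rng_geno.choice(un_pool,
                               size=min(cfg.n_meqtl_unaffected, len(un_pool)),
                               replace=False) if un_pool else []:
        used_probes.add(pid)
        chrom, pos = _place_near(pid, cfg.meqtl_window // 2)
        _add_snp(chrom, pos, rng_geno.uniform(0.1, 0.45), 0.0, pid,
                 _meqtl_gamma())
    for _ in range(cfg.n_risk_snps):
        pid = str(rng_geno.choice(main_ids))
        chrom, pos = _place_near(pid, cfg.meqtl_window - 100_000)
        _add_snp(chrom, pos, rng_geno.uniform(0.1, 0.45),
                 cfg.risk_snp_freq_shift)
    while snp_idx < cfg.n_snps:
        pid = str(rng_geno.choice(main_ids))
        chrom, pos = _place_near(pid, cfg.meqtl_window - 100_000)
        _add_snp(chrom, pos, rng_geno.uniform(0.05, 0.5))

    snp_truth = pd.DataFrame(snp_rows).set_index("snp_id")

    # --- sample sheets
    disc_sheet = _draw_samples(rng_disc, cfg, "D", dict(cfg.n_cases),
                               cfg.n_controls, "discovery")
    repl_sheet = _draw_samples(rng_repl, cfg, "R",
                               {"MCTD": cfg.n_repl_cases},
                               cfg.n_repl_controls, "replication")
    extra_sheet = _draw_samples(rng_extra, cfg, "E",
                                {"MCTD": cfg.n_extra_assoc_cases},
                                cfg.n_extra_assoc_controls, "genotype_only")
    frames = [f for f in (disc_sheet, repl_sheet, extra_sheet) if len(f)]
    sheet = pd.concat(frames)
    sheet = validate_sample_sheet(sheet.reset_index())

    # --- genotype dosages (HWE binomial with diagnosis-dependent AF)
    is_mctd_all = (sheet["diagnosis"] == "MCTD").to_numpy()
    n_total = len(sheet)
    dos = np.empty((n_total, len(snp_truth)))
    for k, (sid, row) in enumerate(snp_truth.iterrows()):
        af = np.full(n_total, row["maf"])
        af[is_mctd_all] = np.clip(row["maf"] + row["case_freq_shift"],
                                  0.01, 0.99)
        dos[:, k] = rng_geno.binomial(2, af)
    dosage = pd.DataFrame(dos, index=sheet.index, columns=snp_truth.index)
    genotypes = GenotypeTable(
        dosage, snp_truth[["chrom", "pos", "ref", "alt"]].copy())

    # convert wired meQTL beta-scale effects to logit shifts (per extra
    # alt allele, solved at the probe's own predictor distribution)
    snp_truth["logit_effect"] = 0.0
    meth_samples = list(disc_sheet.index)
    for sid, row in snp_truth[snp_truth["target_probe"].notna()].iterrows():
        pid = row["target_probe"]
        mu0 = np.full(len(meth_samples), float(logit(truth.at[pid, "baseline"])))
        shift = solve_logit_shift(mu0, cfg.noise_sd, row["meqtl_beta"])
        snp_truth.at[sid, "logit_effect"] = shift
        truth.at[pid, "cis_snp"] = sid
        truth.at[pid, "meqtl_effect"] = row["meqtl_beta"]

    # --- methylation matrices
    effects = dict(
        batch=rng_misc.normal(0, cfg.batch_sd, (n_all, cfg.n_batches)),
        age_slope=rng_misc.normal(0, cfg.age_slope_sd, n_all),
        sex=rng_misc.normal(0, cfg.sex_effect_sd, n_all),
    )
    # X probes respond to sex more strongly
    x_mask = np.array([ann.at[p, "chrom"] == "X" for p in ann.index])
    effects["sex"][x_mask] = rng_misc.normal(0, cfg.x_sex_effect_sd,
                                             x_mask.sum())

    disc_beta, disc_w = _simulate_methylation(
        cfg, disc_sheet, truth, ref_df, alpha, B, snp_truth, dosage,
        effects, rng_disc)
    repl_beta, repl_w = _simulate_methylation(
        cfg, repl_sheet, truth, ref_df, alpha, B, snp_truth, dosage,
        effects, rng_repl)
    legacy = truth.index[truth["on_legacy_platform"]]
    repl_beta = repl_beta[list(legacy)]

    discovery = MethylationMatrix(disc_beta, ann.loc[disc_beta.columns])
    replication = MethylationMatrix(repl_beta, ann.loc[repl_beta.columns])
    cell_props = pd.concat([disc_w, repl_w])

    sim_truth = SimTruth(
        probes=truth, snps=snp_truth, reference_profiles=ref_df,
        cell_props=cell_props, mediated=mediated_pair)
    return SimResult(discovery, replication, genotypes, sheet, cell_props,
                     sim_truth, cfg)


# ---------------------------------------------------------------------------
# Recovery reporting
# ---------------------------------------------------------------------------

def truth_report(truth: SimTruth, records: pd.DataFrame,
                 called: set[str] | list[str],
                 effect_class: str = "dms") -> dict:
    """Recovery metrics for a scan against the simulator's ledger.

    ``records`` must carry a ``unit_id`` (or probe_id/snp_id) column and,
    for effect classes with a quantitative truth, an ``effect`` column.
    Realized FDR = false discoveries / max(1, discoveries).
    """
    rec = records.copy()
    id_col = next((c for c in ("unit_id", "probe_id", "snp_id")
                   if c in rec.columns), None)
    if id_col is None:
        raise ValidationError("records need a unit_id/probe_id/snp_id column")
    rec = rec.set_index(id_col)

    if effect_class == "dms":
        truth_ids = truth.probes.index
        true_effects = truth.probes["delta"]
        positives = set(truth.affected_probes)
    elif effect_class == "vms":
        truth_ids = truth.probes.index
        true_effects = None
        positives = set(truth.vms_probes)
    elif effect_class == "meqtl":
        wired = truth.snps[truth.snps["target_probe"].notna()]
        truth_ids = pd.Index(
            [f"{p}:{s}" for s, p in wired["target_probe"].items()])
        true_effects = pd.Series(wired["meqtl_beta"].to_numpy(),
                                 index=truth_ids)
        positives = set(truth_ids)
    else:
        raise ValidationError(f"unknown effect class {effect_class!r}")

    unknown = [u for u in rec.index if u not in set(truth_ids)]
    if unknown and effect_class != "meqtl":
        raise ValidationError(
            f"records contain ids absent from truth: {unknown[:5]}")

    called = set(called)
    tp = len(called & positives)
    fp = len(called - positives)
    sensitivity = tp / len(positives) if positives else float("nan")
    realized_fdr = fp / max(1, len(called))

    out = dict(n_called=len(called), true_positives=tp, false_positives=fp,
               sensitivity=sensitivity, realized_fdr=realized_fdr)
    if true_effects is not None and "effect" in rec.columns:
        common = [u for u in rec.index if u in true_effects.index
                  and true_effects[u] != 0]
        if common:
            err = rec.loc[common, "effect"].to_numpy() - \
                true_effects[common].to_numpy()
            out["bias"] = float(np.mean(err))
            out["rmse"] = float(np.sqrt(np.mean(err ** 2)))
    return out
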