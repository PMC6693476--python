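"""Domain types, file I/O, probe filtering and multiple-testing utilities.

The central observable is a matrix of DNA-methylation beta values
(methylated fraction per CpG probe per sample, in [0, 1]) together with a
probe annotation (chromosome, 1-based position, gene label).  Everything
downstream — differential methylation and variability scans, meQTL mapping,
biomarker panels — consumes the containers defined here.

Conventions
-----------
* Genomic coordinates are 1-based and fully closed ("1:79088559" style).
  BED-style annotation (0-based, half-open) is converted at the reader
  boundary.
* Methylation files are TSV with probes as rows and samples as columns;
  in memory the beta matrix is samples x probes (a :class:`pandas.DataFrame`).
* All result tables are plain :class:`pandas.DataFrame` objects with stable
  column order, written as TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("sadewas")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

DIAGNOSES = ("CTRL", "MCTD", "SLE", "SjS", "RA", "SSc")
CASE_DIAGNOSES = ("MCTD", "SLE", "SjS", "RA", "SSc")
SEXES = ("female", "male")
TREATMENTS = ("steroid", "antimalarial", "immunosuppressant")
COHORTS = ("discovery", "replication", "genotype_only")
CELL_TYPES = ("neutrophils", "monocytes", "B", "CD4", "CD8", "NK")

SAMPLE_SHEET_COLUMNS = (
    "sample_id", "diagnosis", "age", "sex", "batch",
    "steroid", "antimalarial", "immunosuppressant", "cohort",
)

BETA_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def classify_chrom(chrom: str) -> str:
    """Classify a chromosome label as autosome / X / Y."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("X", "x"):
        return "X"
    if c in ("Y", "y"):
        return "Y"
    return "autosome"


@dataclass(frozen=True)
class CpGProbe:
    """A single CpG probe with its genomic annotation.

    ``gene`` may carry multiple labels ("PARP9; DTX3L") or "Intergenic".
    """

    probe_id: str
    chrom: str
    pos: int
    gene: str = "Intergenic"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(
                f"probe {self.probe_id}: position must be >= 1, got {self.pos}")

    @property
    def chrom_class(self) -> str:
        return classify_chrom(self.chrom)


def _annotation_frame(probes: Iterable[CpGProbe]) -> pd.DataFrame:
    rows = [(p.probe_id, str(p.chrom), int(p.pos), p.gene, p.chrom_class)
            for p in probes]
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene",
                                     "chrom_class"])
    return df.set_index("probe_id")


def validate_annotation(probes: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalize a probe annotation frame (index = probe_id)."""
    required = {"chrom", "pos", "gene"}
    missing = required - set(probes.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    if probes.index.duplicated().any():
        dupes = probes.index[probes.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated probe ids in annotation: {dupes[:5]}")
    if (probes["pos"] < 1).any():
        bad = probes.index[probes["pos"] < 1].tolist()
        raise ValidationError(f"probe positions must be >= 1: {bad[:5]}")
    out = probes.copy()
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(int)
    out["chrom_class"] = [classify_chrom(c) for c in out["chrom"]]
    return out


@dataclass
class MethylationMatrix:
    """Samples x probes beta values plus probe annotation.

    Parameters
    ----------
    beta
        DataFrame indexed by sample id with one column per probe id,
        values in [0, 1].
    probes
        Annotation frame indexed by probe_id with columns
        chrom, pos, gene (chrom_class is derived).
    detection_p
        Optional detection p-value matrix of the same shape as ``beta``.
    """

    beta: pd.DataFrame
    probes: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.probes = validate_annotation(self.probes)
        if self.beta.index.duplicated().any():
            raise ValidationError("duplicated sample ids in beta matrix")
        if list(self.beta.columns) != list(self.probes.index):
            # allow annotation supersets, but order must be resolvable
            missing = [p for p in self.beta.columns if p not in self.probes.index]
            if missing:
                raise ValidationError(
                    f"probes missing from annotation: {missing[:5]}")
            self.probes = self.probes.loc[list(self.beta.columns)]
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < -BETA_TOL) | (vals > 1 + BETA_TOL)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "beta outside [0,1] at sample "
                f"{self.beta.index[i]!r}, probe {self.beta.columns[j]!r}: "
                f"{vals[i, j]}")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise ValidationError("detection_p shape mismatch with beta")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        ids = [p for p in probe_ids if p in self.beta.columns]
        det = self.detection_p[ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta[ids], self.probes.loc[ids], det)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        det = (self.detection_p.loc[list(sample_ids)]
               if self.detection_p is not None else None)
        return MethylationMatrix(self.beta.loc[list(sample_ids)],
                                 self.probes, det)


@dataclass
class GenotypeTable:
    """Samples x variants additive alt-allele dosages.

    ``dosage`` values lie in [0, 2] (fractional allowed for imputed input);
    missing genotypes are NaN.  ``variants`` is indexed by snp_id with
    columns chrom, pos, ref, alt.
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValidationError(
                f"variant table missing columns: {sorted(missing)}")
        if (self.variants["pos"] < 1).any():
            raise ValidationError("variant positions must be >= 1")
        if list(self.dosage.columns) != list(self.variants.index):
            self.variants = self.variants.loc[list(self.dosage.columns)]
        vals = self.dosage.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < -1e-9) | (vals > 2 + 1e-9)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage outside [0,2] at sample {self.dosage.index[i]!r}, "
                f"variant {self.dosage.columns[j]!r}: {vals[i, j]}")
        self.variants = self.variants.copy()
        self.variants["chrom"] = self.variants["chrom"].astype(str)
        self.variants["pos"] = self.variants["pos"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    def maf(self) -> pd.Series:
        """Minor-allele frequency per variant (complete cases)."""
        af = self.dosage.mean(axis=0, skipna=True) / 2.0
        return np.minimum(af, 1.0 - af)


@dataclass
class MultipleTestingDecision:
    """Record of a multiple-testing correction applied to a scan."""

    method: str                 # "bonferroni" or "bh_fdr"
    alpha: float
    m: int
    threshold_or_q: float | np.ndarray

    def __post_init__(self) -> None:
        if self.method not in ("bonferroni", "bh_fdr"):
            raise ValidationError(f"unknown correction method {self.method!r}")


# Result tables use a fixed column schema rather than per-row objects;
# this is the AssociationRecord contract shared by every scan.
ASSOCIATION_COLUMNS = (
    "unit_id", "effect", "se", "p", "n",
    "case_mean", "control_mean", "case_var", "control_var",
)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and normalize dtypes.

    Expects the mandated columns (sample_id may be the index).  Treatment
    flags are coerced to 0/1 integers.
    """
    df = sheet.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValidationError("duplicated sample ids in sample sheet")
    missing = set(SAMPLE_SHEET_COLUMNS[1:]) - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    bad_dx = set(df["diagnosis"]) - set(DIAGNOSES)
    if bad_dx:
        raise ValidationError(f"unknown diagnosis labels: {sorted(bad_dx)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
    bad_cohort = set(df["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise ValidationError(f"unknown cohort labels: {sorted(bad_cohort)}")
    if (df["age"] <= 0).any():
        raise ValidationError("ages must be positive")
    for t in TREATMENTS:
        df[t] = df[t].astype(int)
    df["batch"] = df["batch"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_annotation(path: str | Path) -> pd.DataFrame:
    """Read probe annotation: native 4-column TSV or BED-like 5-column.

    Native format has a header ``probe_id  chrom  pos  gene`` with 1-based
    positions.  BED-like input (no header: chrom, start, end, probe_id,
    gene) is converted from 0-based half-open to 1-based closed.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.lower().startswith("probe_id"):
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("probe_id")
    else:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "probe_id", "gene"])
        df["pos"] = df["start"].astype(int) + 1  # BED start is 0-based
        df = df.set_index("probe_id")[["chrom", "pos", "gene"]]
    return validate_annotation(df)


def read_methylation(path: str | Path,
                     annotation: str | Path,
                     detection_p: str | Path | None = None,
                     ) -> MethylationMatrix:
    """Read a probes x samples beta TSV plus probe annotation.

    Probes absent from the annotation are dropped (count logged and stored
    on the returned matrix as ``dropped_unannotated``).  A malformed
    numeric cell or a beta outside [0, 1] raises :class:`ValidationError`
    naming the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        beta = raw.astype(float)
    except ValueError:
        for probe, row in raw.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path.name}: malformed numeric cell at probe "
                        f"{probe!r}, sample {sample!r}: {cell!r}") from None
        raise
    beta = beta.T  # file is probes x samples; in memory samples x probes
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)

    ann = _read_annotation(annotation)
    known = [p for p in beta.columns if p in ann.index]
    dropped = beta.shape[1] - len(known)
    if dropped:
        logger.warning("read_methylation: dropped %d probes lacking annotation",
                       dropped)
    beta = beta[known]

    det = None
    if detection_p is not None:
        det = pd.read_csv(detection_p, sep="\t", index_col=0).T
        det.index = det.index.astype(str)
        det = det[known].loc[beta.index]

    m = MethylationMatrix(beta, ann.loc[known], det)
    m.dropped_unannotated = dropped  # type: ignore[attr-defined]
    return m


def write_methylation(m: MethylationMatrix, path: str | Path,
                      annotation: str | Path | None = None,
                      float_format: str = "%.10g") -> None:
    """Write betas as a probes x samples TSV (and optionally the annotation)."""
    m.beta.T.to_csv(path, sep="\t", index_label="probe_id",
                    float_format=float_format)
    if annotation is not None:
        write_annotation(m.probes, annotation)


def write_annotation(probes: pd.DataFrame, path: str | Path) -> None:
    probes[["chrom", "pos", "gene"]].to_csv(path, sep="\t",
                                            index_label="probe_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return validate_sample_sheet(pd.read_csv(path, sep=sep))


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index_label="sample_id")


def _dosage_from_gt(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    out = np.full(gt_types.shape, np.nan)
    out[gt_types == 0] = 0.0
    out[gt_types == 1] = 1.0
    out[gt_types == 3] = 2.0
    return out


def read_genotypes(path: str | Path,
                   multiallelic: str = "reject") -> GenotypeTable:
    """Read genotypes from a VCF (GT or DS) or a dosage TSV.

    VCF records with a DS FORMAT field use the dosage directly; otherwise
    dosages are alt-allele counts from GT, with missing genotypes ("./.")
    preserved as NaN.  Multi-allelic records are rejected (default) or
    split into one pseudo-variant per alt allele (``multiallelic="split"``).
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, multiallelic)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValidationError(f"dosage table missing columns: {sorted(missing)}")
    variants = df[meta_cols].set_index("snp_id")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosage = df.set_index("snp_id")[sample_cols].astype(float).T
    dosage.index = dosage.index.astype(str)
    return GenotypeTable(dosage, variants)


def _read_vcf(path: Path, multiallelic: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows, meta = [], [], []
    for i, rec in enumerate(vcf):
        alts = rec.ALT or []
        if len(alts) > 1 and multiallelic == "reject":
            raise ValidationError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(set multiallelic='split' to keep)")
        rid = rec.ID if rec.ID not in (None, ".") else f"var{i}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None and len(alts) == 1:
            dosages = [np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]]
        elif len(alts) <= 1:
            dosages = [_dosage_from_gt(np.asarray(rec.gt_types))]
        else:  # split: alt-allele counts per alternative
            gt = np.asarray([g[:2] for g in rec.genotypes])
            dosages = []
            for k in range(len(alts)):
                d = np.where((gt < 0).any(axis=1), np.nan,
                             (gt == k + 1).sum(axis=1).astype(float))
                dosages.append(d)
        for k, d in enumerate(dosages):
            suffix = f"_{k+1}" if len(dosages) > 1 else ""
            snp_ids.append(f"{rid}{suffix}")
            rows.append(d)
            meta.append((str(rec.CHROM), int(rec.POS), rec.REF, alts[k] if alts else "."))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"],
                            index=pd.Index(snp_ids, name="snp_id"))
    dosage = pd.DataFrame(np.asarray(rows).T, index=samples,
                          columns=pd.Index(snp_ids, name="snp_id"))
    return GenotypeTable(dosage, variants)


def write_genotypes(g: GenotypeTable, path: str | Path) -> None:
    """Write a dosage TSV (variants as rows)."""
    out = g.variants.copy()
    out = pd.concat([out, g.dosage.T], axis=1)
    out.to_csv(path, sep="\t", index_label="snp_id")


def check_sample_overlap(g: GenotypeTable, sheet: pd.DataFrame) -> None:
    """Error if genotyped samples are absent from the sample sheet."""
    offenders = [s for s in g.sample_ids if s not in sheet.index]
    if offenders:
        raise ValidationError(
            f"genotyped samples missing from sample sheet: {offenders[:10]}")


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

@dataclass
class ProbeFilterRules:
    """Array-QC filtering rules.

    A probe is *kept* by the detection rule only if its detection p-value is
    <= ``detection_p_max`` in at least ``detection_sample_frac`` of samples
    (standard array-QC intent).  Probe-level SNP-overlap / multi-mapping
    exclusions are supplied as explicit probe-id lists.
    """

    detection_p_max: float = 0.01
    detection_sample_frac: float = 0.95
    exclusion_lists: tuple[tuple[str, frozenset[str]], ...] = ()
    apply_detection: bool = True
    drop_y: bool = True

    @staticmethod
    def load_exclusion_file(name: str, path: str | Path
                            ) -> tuple[str, frozenset[str]]:
        ids = frozenset(
            line.strip() for line in Path(path).read_text().splitlines()
            if line.strip())
        return (name, ids)


def filter_probes(m: MethylationMatrix,
                  rules: ProbeFilterRules | None = None,
                  ) -> tuple[MethylationMatrix, MethylationMatrix, dict]:
    """Apply QC filters and split autosomal from X-chromosome probes.

    Rules are applied in declared order (exclusion lists, then the
    detection rule, then chromosome routing) so the per-rule removal
    counts in the report sum, with the survivors, to the input count.

    Returns ``(autosomal, x_chromosome, report)``.
    """
    rules = rules or ProbeFilterRules()
    report: dict[str, int] = {"input": m.n_probes}
    surviving = list(m.probe_ids)

    for name, ids in rules.exclusion_lists:
        before = len(surviving)
        surviving = [p for p in surviving if p not in ids]
        report[f"excluded_{name}"] = before - len(surviving)

    if rules.apply_detection and m.detection_p is not None:
        det = m.detection_p[surviving]
        frac_ok = (det.to_numpy() <= rules.detection_p_max).mean(axis=0)
        keep = frac_ok >= rules.detection_sample_frac
        report["failed_detection"] = int((~keep).sum())
        surviving = [p for p, k in zip(surviving, keep) if k]
    else:
        report["failed_detection"] = 0

    cls = m.probes.loc[surviving, "chrom_class"]
    y_probes = [p for p in surviving if cls[p] == "Y"]
    x_probes = [p for p in surviving if cls[p] == "X"]
    auto = [p for p in surviving if cls[p] == "autosome"]
    report["routed_X"] = len(x_probes)
    report["dropped_Y" if rules.drop_y else "kept_Y"] = len(y_probes)
    report["autosomal_survivors"] = len(auto)

    if not auto:
        raise ValidationError("no autosomal probes survive filtering")
    logger.info("filter_probes: %s", report)
    return m.subset_probes(auto), m.subset_probes(x_probes), report


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m.

    Display rounding (two significant digits, "6.4 x 10^-08" style) happens
    only at the reporting layer via :func:`format_threshold`.
    """
    if m < 1:
        raise ValidationError(f"number of tests must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    return alpha / m


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant digits."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, digits - 1 - exponent)


def format_threshold(x: float, digits: int = 2) -> str:
    """Format a threshold as e.g. ``6.4 x 10^-08``."""
    r = round_sig(x, digits)
    exponent = math.floor(math.log10(abs(r)))
    mantissa = r / 10 ** exponent
    mantissa = round(mantissa, digits - 1)
    if mantissa >= 10:  # rounding spill-over (e.g. 9.99 -> 10)
        mantissa /= 10
        exponent += 1
    return f"{mantissa:g} x 10^{exponent:+03d}"


def bh_fdr(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def checksum(path: str | Path) -> str:
    """Short content checksum used in run logs / manifests."""
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
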