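import numpy as np
import pandas as pd
import pytest

from sadewas.core import MethylationMatrix
from sadewas.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A compact cohort with every kind of wired signal."""
    cfg = SimConfig(n_probes=300, n_x_probes=30, n_ref_probes=60,
                    n_ifn_probes=50, n_vms_probes=25, n_snps=50,
                    n_meqtl_affected=4, n_meqtl_unaffected=4, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def discovery(small_sim):
    sheet = small_sim.sheet_for("discovery")
    cells = small_sim.cell_props.loc[sheet.index]
    return small_sim.discovery, sheet, cells


def make_matrix(beta: np.ndarray, sample_ids=None, probe_ids=None,
                chrom="1", detection_p=None) -> MethylationMatrix:
    """Small hand-built methylation matrix for unit tests."""
    n, m = beta.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    probe_ids = probe_ids or [f"p{j}" for j in range(m)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    ann = pd.DataFrame({"chrom": chroms,
                        "pos": np.arange(1, m + 1) * 1000,
                        "gene": [f"gene{j}" for j in range(m)]},
                       index=pd.Index(probe_ids, name="probe_id"))
    det = None
    if detection_p is not None:
        det = pd.DataFrame(detection_p, index=sample_ids, columns=probe_ids)
    return MethylationMatrix(
        pd.DataFrame(beta, index=sample_ids, columns=probe_ids), ann, det)


def make_sheet(n_case: int, n_ctrl: int, rng: np.random.Generator,
               case: str = "MCTD", n_batches: int = 2,
               constant_covariates: bool = False) -> pd.DataFrame:
    rows = []
    for i in range(n_case + n_ctrl):
        dx = case if i < n_case else "CTRL"
        if constant_covariates:
            age, sex, batch = 50.0, "female", "b0"
        else:
            age = float(np.clip(rng.normal(45, 12), 18, 85))
            sex = "female" if rng.random() < 0.9 else "male"
            batch = f"b{int(rng.integers(n_batches))}"
        rows.append((f"s{i}", dx, age, sex, batch, 0, 0, 0, "discovery"))
    df = pd.DataFrame(rows, columns=["sample_id", "diagnosis", "age", "sex",
                                     "batch", "steroid", "antimalarial",
                                     "immunosuppressant", "cohort"])
    return df.set_index("sample_id")
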