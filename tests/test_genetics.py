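"""cis pairing, genetic PCs, meQTL scan, association and the triangle."""

import numpy as np
import pandas as pd
import pytest

from sadewas.core import GenotypeTable, ValidationError
from sadewas.ewas import run_dms_scan
from sadewas.genetics import (case_control_assoc, enumerate_cis_pairs,
                              genotype_pc1, genotype_pcs, mediation_triangle,
                              meqtl_replication_filter, run_meqtl_scan,
                              top_meqtl_per_gene)
from sadewas.simulate import SimConfig, simulate_cohort

from conftest import make_sheet


def _gt(dosage: np.ndarray, chrom=None, pos=None) -> GenotypeTable:
    n, v = dosage.shape
    ids = [f"rs{k}" for k in range(v)]
    var = pd.DataFrame({
        "chrom": chrom or ["1"] * v,
        "pos": pos or list(range(100, 100 + v)),
        "ref": "A", "alt": "G"}, index=pd.Index(ids, name="snp_id"))
    dos = pd.DataFrame(dosage, index=[f"s{i}" for i in range(n)],
                       columns=ids)
    return GenotypeTable(dos, var)


class TestCisPairs:
    def test_boundary_inclusive_at_window(self):
        probes = pd.DataFrame({"chrom": ["1"], "pos": [5_000_000],
                               "gene": ["g"]},
                              index=pd.Index(["p0"], name="probe_id"))
        variants = pd.DataFrame({"chrom": ["1", "1", "2"],
                                 "pos": [6_000_000, 6_000_001, 5_000_000],
                                 "ref": "A", "alt": "G"},
                                index=pd.Index(["at", "beyond", "otherchrom"],
                                               name="snp_id"))
        pairs = enumerate_cis_pairs(probes, variants, window=1_000_000)
        assert set(pairs["snp_id"]) == {"at"}   # inclusive; cross-chrom out
        assert pairs.iloc[0]["distance"] == 1_000_000

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        np_, nv = 8, 10
        probes = pd.DataFrame({
            "chrom": rng.choice(["1", "2"], np_),
            "pos": rng.integers(1, 4_000_000, np_),
            "gene": "g"}, index=pd.Index([f"p{i}" for i in range(np_)],
                                         name="probe_id"))
        variants = pd.DataFrame({
            "chrom": rng.choice(["1", "2"], nv),
            "pos": rng.integers(1, 4_000_000, nv),
            "ref": "A", "alt": "G"},
            index=pd.Index([f"r{i}" for i in range(nv)], name="snp_id"))
        w = 700_000
        got = set(map(tuple, enumerate_cis_pairs(probes, variants, w)
                      [["probe_id", "snp_id"]].to_numpy()))
        expect = {(p, s) for p in probes.index for s in variants.index
                  if probes.at[p, "chrom"] == variants.at[s, "chrom"]
                  and abs(int(probes.at[p, "pos"])
                          - int(variants.at[s, "pos"])) <= w}
        assert got == expect


class TestGenotypePCs:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, 40).astype(float)
        g = _gt(np.column_stack([d, d]))
        pcs = genotype_pcs(g, k=2)
        assert pcs.attrs["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_orthogonal_components(self):
        rng = np.random.default_rng(2)
        g = _gt(rng.integers(0, 3, (30, 6)).astype(float))
        pcs = genotype_pcs(g, k=2)
        assert abs(pcs["PC1"] @ pcs["PC2"]) < 1e-8

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        D = rng.integers(0, 3, (10, 6)).astype(float)
        g = _gt(D)
        scores = genotype_pc1(g)
        Z = (D - D.mean(axis=0)) / D.std(axis=0, ddof=1)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        v1 = evecs[:, -1]
        if v1[0] < 0:
            v1 = -v1
        np.testing.assert_allclose(scores.to_numpy(), Z @ v1, atol=1e-8)

    def test_monomorphic_table_errors(self):
        g = _gt(np.ones((5, 3)))
        with pytest.raises(ValidationError, match="monomorphic"):
            genotype_pc1(g)


class TestCaseControlAssoc:
    def test_two_by_two_closed_form(self):
        # carriers: 20 of 30 cases, 10 of 30 controls -> OR = (20*20)/(10*10)
        dosage = np.concatenate([np.ones(20), np.zeros(10),
                                 np.ones(10), np.zeros(20)])[:, None]
        g = _gt(dosage)
        sheet = make_sheet(30, 30, np.random.default_rng(4))
        out = case_control_assoc(g, sheet)
        assert out.iloc[0]["odds_ratio"] == pytest.approx(4.0, abs=1e-6)

    def test_matches_grid_search_likelihood(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, 60).astype(float)
        y = (rng.random(60) < 1 / (1 + np.exp(-(-0.5 + 0.8 * d)))).astype(float)
        g = _gt(d[:, None])
        sheet = make_sheet(int(y.sum()), int(60 - y.sum()),
                           np.random.default_rng(6))
        # order dosages so cases come first, matching the sheet layout
        order = np.argsort(-y, kind="stable")
        g = _gt(d[order][:, None])
        out = case_control_assoc(g, sheet)
        b_hat = out.iloc[0]["log_or"]

        ys = np.zeros(60)
        ys[:int(y.sum())] = 1.0

        def nll(b0, b1):
            eta = b0 + b1 * d[order]
            return -(ys @ eta - np.log1p(np.exp(eta)).sum())

        # nested grid search as an independent maximizer
        lo0, hi0, lo1, hi1 = -4, 4, -4, 4
        for _ in range(8):
            b0s = np.linspace(lo0, hi0, 21)
            b1s = np.linspace(lo1, hi1, 21)
            vals = np.array([[nll(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            w0, w1 = (hi0 - lo0) / 10, (hi1 - lo1) / 10
            lo0, hi0 = b0s[i] - w0, b0s[i] + w0
            lo1, hi1 = b1s[j] - w1, b1s[j] + w1
        assert b_hat == pytest.approx((lo1 + hi1) / 2, abs=1e-4)

    def test_null_snps_give_unit_or(self):
        rng = np.random.default_rng(7)
        g = _gt(rng.binomial(2, 0.3, (600, 5)).astype(float))
        sheet = make_sheet(300, 300, np.random.default_rng(8))
        out = case_control_assoc(g, sheet)
        assert np.abs(np.log(out["odds_ratio"])).max() < 0.5
        assert (out["p"] > 0.001).all()

    def test_complete_separation_flagged(self):
        dosage = np.concatenate([np.ones(10), np.zeros(10)])[:, None]
        g = _gt(dosage)
        sheet = make_sheet(10, 10, np.random.default_rng(9))
        out = case_control_assoc(g, sheet)
        assert out.iloc[0]["flag"] == "separation"
        assert np.isnan(out.iloc[0]["odds_ratio"])

    def test_monomorphic_flagged(self):
        g = _gt(np.ones((20, 1)))
        sheet = make_sheet(10, 10, np.random.default_rng(10))
        out = case_control_assoc(g, sheet)
        assert out.iloc[0]["flag"] == "monomorphic"


class TestTopPerGene:
    def _records(self):
        return pd.DataFrame({
            "probe_id": ["p0", "p1", "p2", "p3", "p4"],
            "snp_id": ["rsB", "rsA", "rsC", "rsB", "rsA"],
            "effect": [0.05, 0.02, 0.05, -0.1, 0.3],
            "p": [1e-10, 1e-10, 1e-4, 1e-6, 1e-3]})

    def test_tie_breaking(self):
        ann = pd.DataFrame({"chrom": "1", "pos": 1,
                            "gene": ["G1", "G1", "G2", "G2", "G3"]},
                           index=pd.Index([f"p{i}" for i in range(5)],
                                          name="probe_id"))
        best = top_meqtl_per_gene(self._records(), ann).set_index("gene")
        # G1: p tie 1e-10/1e-10 -> larger |effect| 0.05 wins
        assert best.at["G1", "probe_id"] == "p0"
        # G2: smallest p wins
        assert best.at["G2", "probe_id"] == "p3"
        assert len(best) == 3

    def test_exact_tie_on_effect_uses_snp_id(self):
        rec = pd.DataFrame({"probe_id": ["a", "b"],
                            "snp_id": ["rsZ", "rsA"],
                            "effect": [0.05, -0.05],
                            "p": [1e-8, 1e-8]})
        ann = pd.DataFrame({"chrom": "1", "pos": 1, "gene": ["G", "G"]},
                           index=pd.Index(["a", "b"], name="probe_id"))
        best = top_meqtl_per_gene(rec, ann)
        assert best.iloc[0]["snp_id"] == "rsA"


@pytest.fixture(scope="module")
def wired_sim():
    cfg = SimConfig(n_probes=150, n_x_probes=0, n_ref_probes=30,
                    n_ifn_probes=25, n_vms_probes=0, n_snps=20,
                    n_meqtl_affected=0, n_meqtl_unaffected=6,
                    meqtl_effect_range=(0.08, 0.15),
                    n_cases={"MCTD": 29}, n_controls=230,
                    treatment_attenuation=0.0, n_specific_probes=0,
                    seed=51)
    res = simulate_cohort(cfg)
    sheet = res.sheet_for("discovery")
    return res, sheet, res.cell_props.loc[sheet.index]


class TestMeqtlScan:
    def test_wired_effects_detected_and_recovered(self, wired_sim):
        res, sheet, cells = wired_sim
        scan = run_meqtl_scan(res.discovery, res.genotypes, sheet, cells)
        wired = res.truth.snps[res.truth.snps["target_probe"].notna()]
        sig = scan["significant"].set_index(["probe_id", "snp_id"])
        found = 0
        for sid, row in wired.iterrows():
            key = (row["target_probe"], sid)
            if key in sig.index:
                found += 1
                assert sig.loc[key, "effect"] == pytest.approx(
                    row["meqtl_beta"], abs=0.05)
        assert found >= len(wired) - 1

    def test_permuted_genotypes_destroy_signal(self, wired_sim):
        res, sheet, cells = wired_sim
        rng = np.random.default_rng(52)
        perm = rng.permutation(res.genotypes.dosage.index)
        shuffled = GenotypeTable(
            pd.DataFrame(res.genotypes.dosage.to_numpy(), index=perm,
                         columns=res.genotypes.dosage.columns),
            res.genotypes.variants)
        scan = run_meqtl_scan(res.discovery, shuffled, sheet, cells)
        assert len(scan["significant"]) == 0

    def test_missing_dosages_handled(self, wired_sim):
        res, sheet, cells = wired_sim
        dosage = res.genotypes.dosage.copy()
        rng = np.random.default_rng(53)
        mask = rng.random(dosage.shape) < 0.03
        dosage = dosage.mask(mask)
        g = GenotypeTable(dosage, res.genotypes.variants)
        scan = run_meqtl_scan(res.discovery, g, sheet, cells)
        assert (scan["records"]["n"] <= len(sheet)).all()
        assert len(scan["significant"]) > 0

    def test_sub_maf_snps_skipped(self, wired_sim):
        res, sheet, cells = wired_sim
        scan = run_meqtl_scan(res.discovery, res.genotypes, sheet, cells,
                              maf_floor=0.6)   # nothing can pass
        assert scan["n_pairs_tested"] == 0

    def test_replication_filter_direction(self):
        sig = pd.DataFrame({"probe_id": ["p"], "snp_id": ["r"],
                            "effect": [0.1]})
        repl_ok = pd.DataFrame({"probe_id": ["p"], "snp_id": ["r"],
                                "effect": [0.05], "p": [1e-5]})
        repl_flip = repl_ok.assign(effect=[-0.05])
        assert meqtl_replication_filter(sig, repl_ok)["replicated"].all()
        assert not meqtl_replication_filter(sig, repl_flip)["replicated"].any()


class TestMediationTriangle:
    def test_wired_locus_recovered(self):
        cfg = SimConfig(n_probes=120, n_x_probes=0, n_ref_probes=30,
                        n_ifn_probes=20, n_vms_probes=0, n_snps=12,
                        n_meqtl_affected=0, n_meqtl_unaffected=4,
                        treatment_attenuation=0.0, n_specific_probes=0,
                        seed=55)
        res = simulate_cohort(cfg)
        sheet = res.sheet_for("discovery")
        cells = res.cell_props.loc[sheet.index]
        dms = run_dms_scan(res.discovery, sheet, cells)
        mq = run_meqtl_scan(res.discovery, res.genotypes, sheet, cells)
        assoc = case_control_assoc(res.genotypes, res.sheet)
        tri = mediation_triangle(mq["significant"], dms.calls,
                                 dms.records, assoc)
        sid, pid = res.truth.mediated
        assert ((tri["snp_id"] == sid) & (tri["probe_id"] == pid)).any()
        row = tri[(tri["snp_id"] == sid) & (tri["probe_id"] == pid)].iloc[0]
        assert bool(row["direction_consistent"])
        # triangle SNPs are a subset of the significant meQTL SNPs
        assert set(tri["snp_id"]) <= set(mq["significant"]["snp_id"])

    def test_weak_association_excluded(self):
        sig = pd.DataFrame({"probe_id": ["p"], "snp_id": ["r"],
                            "effect": [0.1], "p": [1e-8], "q": [1e-6]})
        ewas = pd.DataFrame({"probe_id": ["p"], "effect": [-0.3],
                             "p": [1e-10]})
        assoc = pd.DataFrame({"snp_id": ["r"], "log_or": [0.5],
                              "odds_ratio": [1.65], "p": [0.4]})
        tri = mediation_triangle(sig, ["p"], ewas, assoc)
        assert tri.empty

    def test_empty_dms_set(self):
        sig = pd.DataFrame({"probe_id": ["p"], "snp_id": ["r"],
                            "effect": [0.1], "p": [1e-8]})
        ewas = pd.DataFrame({"probe_id": ["p"], "effect": [-0.3],
                             "p": [1e-10]})
        assoc = pd.DataFrame({"snp_id": ["r"], "log_or": [0.5],
                              "odds_ratio": [1.65], "p": [0.001]})
        assert mediation_triangle(sig, [], ewas, assoc).empty
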