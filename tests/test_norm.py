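"""TMM factors, CPM, Fisher DEG calling and the MDS QC ordination."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import homoeobias as hb
from homoeobias.io import DataModelError
from .conftest import random_count_matrix


# ---------------------------------------------------------------------------
# an independent, loop-based TMM reference (shares no code with the package)
# ---------------------------------------------------------------------------


def _avg_ranks(values):
    """1-based average ranks via sorting and tie-group averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_reference(x: np.ndarray) -> np.ndarray:
    """Step-by-step TMM: 30% M-trim, 5% A-trim, precision weights,
    upper-quartile reference choice, geometric-mean re-centring."""
    import math

    n_genes, n_samples = x.shape
    libs = x.sum(axis=0).astype(float)
    q75 = [np.quantile(x[:, j] / libs[j], 0.75) for j in range(n_samples)]
    ref = min(range(n_samples), key=lambda j: abs(q75[j] - sum(q75) / n_samples))
    factors = []
    for j in range(n_samples):
        ms, as_, vs = [], [], []
        for g in range(n_genes):
            o, r = x[g, j], x[g, ref]
            if o > 0 and r > 0:
                po, pr = o / libs[j], r / libs[ref]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                vs.append((libs[j] - o) / (libs[j] * o) + (libs[ref] - r) / (libs[ref] * r))
        if not ms:
            raise ValueError("no shared positive genes")
        if max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        rm, ra = _avg_ranks(ms), _avg_ranks(as_)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
        factors.append(2.0 ** (num / den) if den else 1.0)
    log_mean = sum(math.log(f) for f in factors) / n_samples
    return np.array([f / math.exp(log_mean) for f in factors])


class TestTmm:
    def test_identical_columns_give_exactly_one(self):
        col = np.array([10, 0, 55, 3, 200, 7])
        cm = hb.CountMatrix(pd.DataFrame({"a": col, "b": col, "c": col}))
        nf = hb.tmm_factors(cm)
        assert (nf.factors == 1.0).all()

    def test_pure_depth_change_gives_exactly_one(self):
        col = np.array([10, 1, 55, 3, 200, 7])
        cm = hb.CountMatrix(pd.DataFrame({"a": col, "b": 2 * col}))
        nf = hb.tmm_factors(cm)
        assert (nf.factors == 1.0).all()

    def test_matches_independent_reference_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            cm = random_count_matrix(rng)
            ours = hb.tmm_factors(cm).factors.to_numpy()
            ref = tmm_reference(cm.counts.to_numpy())
            assert np.abs(ours - ref).max() < 1e-10

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(11)
        cm = random_count_matrix(rng, n_samples=6)
        nf = hb.tmm_factors(cm)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_global_library_rescaling(self):
        rng = np.random.default_rng(12)
        cm = random_count_matrix(rng)
        scaled = hb.CountMatrix(cm.counts * 3)
        a = hb.tmm_factors(cm).factors.to_numpy()
        b = hb.tmm_factors(scaled).factors.to_numpy()
        assert a == pytest.approx(b, rel=1e-9)

    def test_disjoint_sample_named_in_error(self):
        df = pd.DataFrame({"a": [5, 0, 9, 0], "b": [4, 0, 10, 0], "weird": [0, 3, 0, 8]})
        with pytest.raises(DataModelError, match="weird"):
            hb.tmm_factors(hb.CountMatrix(df), ref_sample="a")

    def test_matches_edger_calcnormfactors(self, tmp_path):
        rng = np.random.default_rng(13)
        cm = random_count_matrix(rng, n_genes=300, n_samples=5)
        path = tmp_path / "m.tsv"
        hb.write_counts(cm, path)
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        ours = hb.tmm_factors(cm).factors.to_numpy()
        assert np.abs(ours - edger).max() < 1e-9


class TestCpm:
    def test_unit_factor_million_library(self):
        cm = hb.CountMatrix(pd.DataFrame({"s": [7, 10**6 - 7]}, index=["g1", "g2"]))
        nf = hb.NormFactors(pd.Series({"s": 1.0}), "s")
        assert hb.cpm(cm, nf).loc["g1", "s"] == pytest.approx(7.0)

    def test_doubling_factor_halves_cpm_and_conservation(self):
        rng = np.random.default_rng(14)
        cm = random_count_matrix(rng)
        nf = hb.tmm_factors(cm)
        c1 = hb.cpm(cm, nf)
        doubled = nf.factors.copy()
        doubled.iloc[0] *= 2
        nf2 = hb.NormFactors(doubled, nf.ref_sample)
        c2 = hb.cpm(cm, nf2)
        s0 = cm.sample_ids[0]
        assert c2[s0].to_numpy() == pytest.approx(c1[s0].to_numpy() / 2)
        # column sums: 1e6 / factor
        assert c2.sum(axis=0).to_numpy() == pytest.approx(
            (1e6 / nf2.factors.to_numpy()), rel=1e-12
        )


class TestFisherDeg:
    def test_all_zero_gene_is_null(self):
        rng = np.random.default_rng(15)
        cm = random_count_matrix(rng, n_genes=30, n_samples=6)
        df = cm.counts.copy()
        df.iloc[0] = 0
        cm = hb.CountMatrix(df)
        nf = hb.tmm_factors(cm)
        res = hb.fisher_deg(cm, nf, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_group_swap_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(16)
        cm = random_count_matrix(rng, n_genes=40, n_samples=6)
        nf = hb.tmm_factors(cm)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        r1 = hb.fisher_deg(cm, nf, a, b)
        r2 = hb.fisher_deg(cm, nf, b, a)
        assert r1["log2fc"].to_numpy() == pytest.approx(-r2["log2fc"].to_numpy())
        assert r1["pvalue"].to_numpy() == pytest.approx(r2["pvalue"].to_numpy(), rel=1e-9)

    def test_overlapping_groups_rejected(self):
        rng = np.random.default_rng(17)
        cm = random_count_matrix(rng)
        nf = hb.tmm_factors(cm)
        with pytest.raises(DataModelError, match="disjoint"):
            hb.fisher_deg(cm, nf, ["s0"], ["s0", "s1"])


class TestCallDeg:
    @pytest.mark.parametrize(
        "log2fc,fdr,expected",
        [
            (1.5, 0.01, "UP"),
            (1.5, 0.06, "NS"),
            (-1.0, 0.001, "NS"),   # strict at |log2FC| = 1
            (1.0, 0.001, "NS"),
            (-1.2, 0.04, "DOWN"),
            (0.0, 0.0, "NS"),
            (2.0, 0.05, "NS"),     # strict at FDR = alpha
        ],
    )
    def test_threshold_conventions(self, log2fc, fdr, expected):
        assert hb.call_deg([log2fc], [fdr])[0] == expected


class TestMds:
    def test_within_group_distance_zero(self):
        col_a = np.array([5, 1, 9, 2, 7], dtype=float)
        col_b = col_a * 4
        df = pd.DataFrame({"a1": col_a, "a2": col_a, "b1": col_b, "b2": col_b})
        d = hb.norm.leading_logfc_distance(np.log2(df + 1), n_top=5)
        assert d.loc["a1", "a2"] == 0
        assert d.loc["b1", "b2"] == 0
        assert d.loc["a1", "b1"] > 0

    def test_distance_matrix_axioms(self):
        rng = np.random.default_rng(18)
        df = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        d = hb.norm.leading_logfc_distance(df, n_top=20)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_classical_mds_reproduces_three_point_metric(self):
        # points 0, 3, 4 on a line -> pairwise distances 3, 4, 1
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 1], [4, 1, 0]], index=list("abc"), columns=list("abc"), dtype=float
        )
        coords = hb.norm.classical_mds(d)
        recon = np.sqrt(
            ((coords.to_numpy()[:, None, :] - coords.to_numpy()[None, :, :]) ** 2).sum(-1)
        )
        assert np.abs(recon - d.to_numpy()).max() < 1e-8

    def test_degenerate_all_equal_samples_warn_zero(self):
        df = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        with pytest.warns(UserWarning, match="degenerate"):
            coords = hb.mds_qc(df, n_top=5)
        assert (coords.to_numpy() == 0).all()

    def test_groups_separate_on_simulated_data(self, small_bundle):
        merged, msheet = hb.collapse_hybrid_replicates(small_bundle.counts, small_bundle.sheet)
        nf = hb.tmm_factors(merged)
        coords = hb.mds_qc(np.log2(hb.cpm(merged, nf) + 2.0), n_top=200)
        # parental groups land apart, replicates together
        pk = coords.loc[["PK_1", "PK_2", "PK_3"]].to_numpy()
        pt = coords.loc[["PT_1", "PT_2", "PT_3"]].to_numpy()
        within = max(np.linalg.norm(pk - pk.mean(0), axis=1).max(),
                     np.linalg.norm(pt - pt.mean(0), axis=1).max())
        between = np.linalg.norm(pk.mean(0) - pt.mean(0))
        assert between > 3 * within
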