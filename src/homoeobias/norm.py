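"""Between-sample normalization, differential-expression calling and QC.

Normalization uses the trimmed mean of M-values (TMM): for each sample a
scaling factor is estimated against a reference column from the
precision-weighted mean of per-gene log2 expression ratios, after discarding
the most extreme 30% of M-values and 5% of A-values (two-sided).  Factors are
re-centred to geometric mean 1, so CPM values computed with them stay on the
counts-per-million scale.

Differential expression between two sample groups is tested per gene with a
two-sided Fisher exact test on pooled, TMM-rescaled counts, and called
UP/DOWN at |log2FC| > 1 with BH FDR < 0.05 (both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, DataModelError
from .stats import bh_fdr, fisher_exact_rows

UP, DOWN, NS = "UP", "DOWN", "NS"


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean 1) + reference sample."""

    factors: pd.Series
    ref_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise DataModelError("normalization factors must be positive")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic variance of M (delta method, binomial sampling)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0:
        raise DataModelError("sample shares no positive genes with the reference")
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> NormFactors:
    """TMM normalization factors for every sample of a count matrix.

    The reference is the sample whose upper-quartile count proportion is
    closest to the mean of that proportion across samples (unless given).
    """
    if cm.counts.shape[1] < 2:
        raise DataModelError("TMM needs at least 2 samples")
    cm.require_positive_libraries()
    x = cm.counts.to_numpy(dtype=float)
    libs = x.sum(axis=0)
    q75 = np.quantile(x / libs, 0.75, axis=0)
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = int(cm.sample_ids.get_loc(ref_sample))
    ref = x[:, ref_idx]
    factors = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        try:
            factors[j] = _tmm_pair_factor(x[:, j], ref, libs[j], libs[ref_idx])
        except DataModelError as err:
            raise DataModelError(f"sample {cm.sample_ids[j]!r}: {err}") from None
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=cm.sample_ids), str(cm.sample_ids[ref_idx]))


def cpm(cm: CountMatrix, nf: NormFactors) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    missing = cm.sample_ids.difference(nf.factors.index)
    if len(missing) > 0:
        raise DataModelError(f"no normalization factor for samples: {missing.tolist()}")
    eff = cm.library_sizes() * nf.factors.reindex(cm.sample_ids)
    return cm.counts.div(eff, axis=1) * 1e6


def fisher_deg(
    cm: CountMatrix,
    nf: NormFactors,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudo_cpm: float = 0.5,
) -> pd.DataFrame:
    """Per-gene Fisher exact DEG test of group A over group B.

    Each sample is rescaled to the mean TMM-effective library size, counts are
    pooled (summed) within each group, and the gene is tested in the 2x2
    table ``[[g_A, L_A - g_A], [g_B, L_B - g_B]]`` (entries rounded to
    integers) where ``L_X`` is the pooled rescaled library size.  The reported
    log2 fold change is ``log2((meanCPM_A + c) / (meanCPM_B + c))`` with
    pseudo-count ``c`` (default 0.5 CPM).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise DataModelError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise DataModelError("groups must be disjoint")
    eff = (cm.library_sizes() * nf.factors.reindex(cm.sample_ids)).astype(float)
    nbar = eff[group_a + group_b].mean()
    scaled = cm.counts.astype(float).mul(nbar / eff, axis=1)
    g_a = scaled[group_a].sum(axis=1).round().astype(np.int64)
    g_b = scaled[group_b].sum(axis=1).round().astype(np.int64)
    l_a = int(round(len(group_a) * nbar))
    l_b = int(round(len(group_b) * nbar))
    if (g_a > l_a).any() or (g_b > l_b).any():
        raise DataModelError("internal error: pooled gene count exceeds pooled library")
    pvals = fisher_exact_rows(g_a, l_a - g_a, g_b, l_b - g_b)
    cpms = cpm(cm, nf)
    mean_a = cpms[group_a].mean(axis=1)
    mean_b = cpms[group_b].mean(axis=1)
    log2fc = np.log2((mean_a + pseudo_cpm) / (mean_b + pseudo_cpm))
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals}, index=cm.gene_ids
    )


def call_deg(log2fc, fdr, lfc_cut: float = 1.0, alpha: float = 0.05) -> np.ndarray:
    """Trinary call: UP if log2FC > cut and FDR < alpha, DOWN mirrored, else NS."""
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if not np.isfinite(log2fc).all():
        raise DataModelError("log2fc must be finite")
    if ((fdr < 0) | (fdr > 1)).any():
        raise DataModelError("fdr must lie in [0, 1]")
    out = np.full(log2fc.shape, NS, dtype=object)
    sig = fdr < alpha
    out[sig & (log2fc > lfc_cut)] = UP
    out[sig & (log2fc < -lfc_cut)] = DOWN
    return out


def deg_table(
    cm: CountMatrix,
    nf: NormFactors,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str,
    pseudo_cpm: float = 0.5,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full DEG table (log2fc, pvalue, BH fdr, call) for one contrast."""
    res = fisher_deg(cm, nf, group_a, group_b, pseudo_cpm=pseudo_cpm)
    res.insert(0, "contrast", contrast)
    res["fdr"] = bh_fdr(res["pvalue"].to_numpy())
    res["call"] = call_deg(res["log2fc"], res["fdr"], lfc_cut=lfc_cut, alpha=alpha)
    return res


# ---------------------------------------------------------------------------
# MDS QC ordination
# ---------------------------------------------------------------------------


def leading_logfc_distance(logexpr: pd.DataFrame, n_top: int = 500) -> pd.DataFrame:
    """Pairwise sample distance: RMS of the ``n_top`` largest |log2FC|.

    ``logexpr`` is a genes x samples matrix of log2 expression (e.g.
    log2(CPM + prior)).  For each sample pair only that pair's most divergent
    genes enter the distance, the "leading log-fold-change" convention.
    """
    x = logexpr.to_numpy(dtype=float)
    n = x.shape[1]
    k = min(n_top, x.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            top = np.partition(diff2, diff2.size - k)[diff2.size - k:]
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    return pd.DataFrame(d, index=logexpr.columns, columns=logexpr.columns)


def classical_mds(dist: pd.DataFrame, n_coords: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS: principal coordinates of a distance
    matrix via double-centring and eigendecomposition."""
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if n < 3:
        raise DataModelError("MDS needs at least 3 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0:
        warnings.warn("degenerate (all-equal) samples: MDS coordinates are zero")
        coords = np.zeros((n, n_coords))
    else:
        lam = np.clip(evals[:n_coords], 0, None)
        coords = evecs[:, :n_coords] * np.sqrt(lam)
    return pd.DataFrame(
        coords, index=dist.index, columns=[f"dim{i+1}" for i in range(n_coords)]
    )


def mds_qc(logexpr: pd.DataFrame, n_top: int = 500) -> pd.DataFrame:
    """Leading-logFC distances + classical MDS; first two coordinates."""
    return classical_mds(leading_logfc_distance(logexpr, n_top=n_top))
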