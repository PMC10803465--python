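"""Homoeolog expression bias (HEB): ratios, magnitude, tests, summaries.

For every single-copy gene pair the T-side over K-side expression ratio is
computed on pseudo-counted mean CPMs, in the parents (ortholog ratio) and in
each focal group (homoeolog ratio).  The "magnitude" of bias is the log2
ratio-of-ratios

    magnitude = log2( (focal_T / focal_K) / (parent_T / parent_K) )

so positive values mean the focal group over-expresses the T homoeolog
relative to the parental expectation.  A pair is called T-biased when
magnitude > 1 with Fisher-exact p < 0.05 and BH FDR < 0.05 (K-biased
mirrored); everything else is Non-bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DataModelError
from .stats import bh_fdr, fisher_exact_rows

T_BIAS, K_BIAS, NON_BIAS = "T_BIAS", "K_BIAS", "NON_BIAS"
HEB_LABELS = (T_BIAS, K_BIAS, NON_BIAS)


def homoeolog_log2_ratio(mean_cpm_t, mean_cpm_k, pseudo: float = 0.5) -> np.ndarray | float:
    """log2((T + pseudo) / (K + pseudo)) on mean CPMs; positive = T higher."""
    if pseudo <= 0:
        raise DataModelError("pseudo-count must be > 0")
    t = np.asarray(mean_cpm_t, dtype=float)
    k = np.asarray(mean_cpm_k, dtype=float)
    if (t < 0).any() or (k < 0).any():
        raise DataModelError("mean CPMs must be non-negative")
    out = np.log2((t + pseudo) / (k + pseudo))
    return out if out.ndim else float(out)


def magnitude(focal_ratio, parental_ratio) -> np.ndarray | float:
    """Bias magnitude: focal log2 ratio minus parental log2 ratio.

    Computed with a shared pseudo-count this equals the log2 of the
    ratio-of-ratios exactly.
    """
    f = np.asarray(focal_ratio, dtype=float)
    p = np.asarray(parental_ratio, dtype=float)
    if not (np.isfinite(f).all() and np.isfinite(p).all()):
        raise DataModelError("ratios must be finite")
    out = f - p
    return out if out.ndim else float(out)


def heb_test(focal_t, focal_k, parent_t, parent_k) -> np.ndarray:
    """Two-sided Fisher exact p on ``[[focal_T, focal_K], [parent_T, parent_K]]``.

    Mean CPMs are rounded to the nearest integer to form the count table; an
    all-zero table yields p = 1.
    """
    vals = [np.rint(np.asarray(v, dtype=float)).astype(np.int64)
            for v in (focal_t, focal_k, parent_t, parent_k)]
    if any((v < 0).any() for v in vals):
        raise DataModelError("mean CPMs must be non-negative")
    return fisher_exact_rows(*vals)


def call_heb(mag, pvalue, fdr, mag_cut: float = 1.0, alpha: float = 0.05) -> np.ndarray:
    """T_BIAS / K_BIAS / NON_BIAS per the magnitude + significance criteria."""
    mag = np.asarray(mag, dtype=float)
    pvalue = np.asarray(pvalue, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    if not np.isfinite(mag).all():
        raise DataModelError("magnitude must be finite")
    sig = (pvalue < alpha) & (fdr < alpha)
    out = np.full(mag.shape, NON_BIAS, dtype=object)
    out[sig & (mag > mag_cut)] = T_BIAS
    out[sig & (mag < -mag_cut)] = K_BIAS
    return out


def heb_records(
    mean_cpm: pd.DataFrame,
    group: str,
    pseudo: float = 0.5,
    mag_cut: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full HEB table for one focal group.

    ``mean_cpm`` must have columns ``focal_T``, ``focal_K``, ``parent_T``,
    ``parent_K`` (mean CPM over replicates), indexed by pair id.  FDR is
    BH-adjusted within this group's family of tests.
    """
    need = {"focal_T", "focal_K", "parent_T", "parent_K"}
    if not need.issubset(mean_cpm.columns):
        raise DataModelError(f"mean_cpm needs columns {sorted(need)}")
    focal_ratio = homoeolog_log2_ratio(mean_cpm["focal_T"], mean_cpm["focal_K"], pseudo)
    parent_ratio = homoeolog_log2_ratio(mean_cpm["parent_T"], mean_cpm["parent_K"], pseudo)
    mag = magnitude(focal_ratio, parent_ratio)
    pvals = heb_test(
        mean_cpm["focal_T"], mean_cpm["focal_K"], mean_cpm["parent_T"], mean_cpm["parent_K"]
    )
    fdr = bh_fdr(pvals)
    out = pd.DataFrame(index=mean_cpm.index)
    out["group"] = group
    out["log2_ratio"] = focal_ratio
    out["parental_log2_ratio"] = parent_ratio
    out["magnitude"] = mag
    out["pvalue"] = pvals
    out["fdr"] = fdr
    out["call"] = call_heb(mag, pvals, fdr, mag_cut=mag_cut, alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# distribution summaries (Table-1-style)
# ---------------------------------------------------------------------------


@dataclass
class DistributionSummary:
    group: str
    n: int
    mean: float
    median: float
    kurtosis: float
    t_pvalue: float
    t_fdr: float = float("nan")


def excess_kurtosis(values, convention: str = "excess") -> float:
    """Sample kurtosis m4/m2^2 - 3 (``"excess"``, normal = 0) or m4/m2^2
    (``"pearson"``, normal = 3)."""
    v = np.asarray(values, dtype=float)
    if np.var(v) == 0:
        return float("nan")
    k = float(sps.kurtosis(v, fisher=True, bias=True))
    if convention == "excess":
        return k
    if convention == "pearson":
        return k + 3.0
    raise DataModelError(f"unknown kurtosis convention {convention!r}")


def distribution_summary(
    log2_ratios, group: str, kurtosis_convention: str = "excess"
) -> DistributionSummary:
    """Mean / median / kurtosis of a log2-ratio vector plus a one-sample
    two-sided t-test against mean 0 (t undefined at zero variance)."""
    v = np.asarray(log2_ratios, dtype=float)
    if v.size < 3 or not np.isfinite(v).all():
        raise DataModelError("need >= 3 finite values")
    if np.var(v) == 0:
        t_p = float("nan")
    else:
        t_p = float(sps.ttest_1samp(v, 0.0).pvalue)
    return DistributionSummary(
        group=group,
        n=int(v.size),
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        kurtosis=excess_kurtosis(v, kurtosis_convention),
        t_pvalue=t_p,
    )


def summarize_distributions(
    ratios_by_group: dict[str, np.ndarray], kurtosis_convention: str = "excess"
) -> pd.DataFrame:
    """Table-1-style summary; the t-test p-values are BH-adjusted across the
    groups summarized together."""
    summaries = [
        distribution_summary(v, g, kurtosis_convention) for g, v in ratios_by_group.items()
    ]
    pvals = np.array([s.t_pvalue for s in summaries])
    ok = np.isfinite(pvals)
    fdr = np.full(pvals.shape, np.nan)
    if ok.any():
        fdr[ok] = bh_fdr(pvals[ok])
    rows = []
    for s, f in zip(summaries, fdr):
        s.t_fdr = float(f)
        rows.append(vars(s))
    return pd.DataFrame(rows).set_index("group")


def strong_bias_tally(records: pd.DataFrame, cutoff: float = 10.0) -> pd.DataFrame:
    """Strong-bias counts and per-direction magnitude summaries.

    Counts called T-biased pairs with magnitude > ``cutoff`` and K-biased
    pairs with magnitude < -``cutoff``; the mean/median magnitude columns
    summarize *all* called pairs of each direction (NaN when none).
    """
    if cutoff <= 0:
        raise DataModelError("cutoff must be > 0")
    rows = {}
    for label, sign in ((T_BIAS, 1), (K_BIAS, -1)):
        called = records.loc[records["call"] == label, "magnitude"]
        beyond = (called > cutoff).sum() if sign > 0 else (called < -cutoff).sum()
        rows[label] = {
            "n_called": int(called.size),
            f"n_beyond_{cutoff:g}": int(beyond),
            "mean_magnitude": float(called.mean()) if called.size else float("nan"),
            "median_magnitude": float(called.median()) if called.size else float("nan"),
        }
    return pd.DataFrame(rows).T.rename_axis("direction")


def heb_transition_table(src: pd.Series, dst: pd.Series) -> pd.DataFrame:
    """3x3 cross-tab of bias-call transitions between two focal groups."""
    from .eld import transition_table

    return transition_table(src, dst, labels=list(HEB_LABELS))
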