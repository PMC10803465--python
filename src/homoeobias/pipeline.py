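"""End-to-end pipeline: filters -> normalization -> DEG -> ELD -> HEB -> reports.

The pipeline consumes a homoeolog-resolved count matrix, a sample sheet, an
orthogroup table and per-gene effective lengths; it produces, per run:

- retained gene-pair lists for the TPM co-expression thresholds,
- per-contrast DEG tables (Fisher exact, TMM-normalized, BH FDR),
- per-focal-group ELD records with category counts and the F1K -> ALLO
  collapsed-category transition table,
- per-focal-group HEB records with distribution summaries, call counts,
  strong-bias tallies and the F1K -> ALLO bias transition table,
- MDS QC coordinates and a reproducible run manifest.

Everything is deterministic given the inputs; output writing is atomic (a
run directory either appears complete or not at all).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eld import AMBIGUOUS, COLLAPSED_LABELS, classify_records, category_counts, transition_table
from .heb import (
    HEB_LABELS,
    K_BIAS,
    NON_BIAS,
    T_BIAS,
    heb_records,
    heb_transition_table,
    strong_bias_tally,
    summarize_distributions,
)
from .io import (
    CountMatrix,
    DataModelError,
    GenePair,
    OrthogroupTable,
    collapse_hybrid_replicates,
    coexpression_filter,
    compute_tpm,
    filter_single_copy,
    group_pair_tpm,
    read_counts,
    read_lengths,
    read_orthogroups,
    read_sample_sheet,
    samples_of,
    validate_sample_sheet,
)
from .norm import cpm, deg_table, mds_qc, tmm_factors

FOCAL_GROUPS = ("F1K", "F1T", "ALLO")
SWEEP_THRESHOLDS = (0.0, 0.5, 1.0)


@dataclass
class PipelineConfig:
    """Paths plus the parameter surface of the analysis."""

    counts: str = ""
    samples: str = ""
    orthogroups: str = ""
    lengths: str = ""
    out_dir: str = "run"
    k_species: str = "K"
    t_species: str = "T"
    tpm_threshold: float = 0.5
    filter_mode: str = "sum"
    pseudo_cpm: float = 0.5
    alpha: float = 0.05
    lfc_cut: float = 1.0
    mag_cut: float = 1.0
    strong_cutoff: float = 10.0
    kurtosis_convention: str = "excess"
    ambiguous_mode: str = "strict"
    mds_top: int = 500
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise DataModelError("alpha must lie in (0, 1)")
        if self.tpm_threshold < 0 or self.lfc_cut <= 0 or self.mag_cut <= 0:
            raise DataModelError("thresholds must be positive where required")
        if self.strong_cutoff <= 0 or self.pseudo_cpm <= 0:
            raise DataModelError("strong_cutoff and pseudo_cpm must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise DataModelError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def analysis_params(self) -> dict:
        """Parameters that define the analysis (paths excluded)."""
        skip = {"counts", "samples", "orthogroups", "lengths", "out_dir"}
        return {
            k: v for k, v in dataclasses.asdict(self).items() if k not in skip
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    retained: dict            # threshold -> list of pair ids
    analysis_pairs: list      # pair ids analysed (configured threshold)
    deg: pd.DataFrame         # all contrasts stacked
    eld: dict                 # group -> records frame
    eld_counts: dict          # group -> counts frame (categories + collapsed)
    eld_transition: pd.DataFrame
    heb: dict                 # group -> records frame
    heb_distributions: pd.DataFrame
    heb_call_counts: pd.DataFrame
    heb_strong: dict          # group -> tally frame
    heb_transition: pd.DataFrame
    shared_heb_fraction: float
    mds: pd.DataFrame
    manifest: dict


def _pair_side_matrix(
    cm: CountMatrix, pairs: list[GenePair], columns: list[tuple[str, str]]
) -> CountMatrix:
    """Pair x sample matrix taking each column from one side of the pair.

    ``columns`` lists (sample_id, side) with side "K" or "T"; a parent sample
    uses its own species' gene, a homoeolog-resolved column the corresponding
    subgenome's gene.
    """
    k_rows = cm.counts.loc[[p.k_gene for p in pairs]].to_numpy()
    t_rows = cm.counts.loc[[p.t_gene for p in pairs]].to_numpy()
    data = {}
    for sample, side in columns:
        j = cm.sample_ids.get_loc(sample)
        data[sample] = (k_rows if side == "K" else t_rows)[:, j]
    idx = pd.Index([p.pair_id for p in pairs], name="pair_id")
    return CountMatrix(pd.DataFrame(data, index=idx))


def pair_total_matrix(
    collapsed: CountMatrix, pairs: list[GenePair]
) -> CountMatrix:
    """Pair totals per replicate column (K gene + T gene; parents contribute
    only their own gene because the other row is zero)."""
    k = collapsed.counts.loc[[p.k_gene for p in pairs]].to_numpy()
    t = collapsed.counts.loc[[p.t_gene for p in pairs]].to_numpy()
    idx = pd.Index([p.pair_id for p in pairs], name="pair_id")
    return CountMatrix(pd.DataFrame(k + t, index=idx, columns=collapsed.sample_ids))


def run_analysis(
    cm: CountMatrix,
    sheet: pd.DataFrame,
    og: OrthogroupTable,
    lengths: pd.Series,
    cfg: PipelineConfig,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    cfg.validate()
    sheet = validate_sample_sheet(sheet, cm)
    cm.require_positive_libraries()

    # ---- reference gene set: single-copy pairs present in the matrix ------
    pairs_all = filter_single_copy(og)
    pairs = [
        p for p in pairs_all
        if p.k_gene in cm.gene_ids and p.t_gene in cm.gene_ids
    ]
    n_dropped_missing = len(pairs_all) - len(pairs)
    if not pairs:
        raise DataModelError("no single-copy pairs with counts available")

    # ---- TPM co-expression filter ----------------------------------------
    collapsed, collapsed_sheet = collapse_hybrid_replicates(cm, sheet)
    tpm = compute_tpm(collapsed, lengths)
    tpm_k, tpm_t = group_pair_tpm(tpm, collapsed_sheet, pairs)
    thresholds = sorted(set(SWEEP_THRESHOLDS) | {cfg.tpm_threshold})
    retained = {
        thr: coexpression_filter(tpm_k, tpm_t, thr, mode=cfg.filter_mode)
        for thr in thresholds
    }
    analysis_ids = set(retained[cfg.tpm_threshold])
    pairs_kept = [p for p in pairs if p.pair_id in analysis_ids]
    if not pairs_kept:
        raise DataModelError(
            f"no pairs pass the TPM > {cfg.tpm_threshold} co-expression filter"
        )

    # ---- DEG contrasts on pair totals -------------------------------------
    totals = pair_total_matrix(collapsed, pairs_kept)
    nf_tot = tmm_factors(totals)
    groups_cols = {g: samples_of(collapsed_sheet, g) for g in ("PK", "PT") + FOCAL_GROUPS}
    contrasts = [("PKvsPT", groups_cols["PK"], groups_cols["PT"])]
    for grp in FOCAL_GROUPS:
        contrasts.append((f"{grp}vsPK", groups_cols[grp], groups_cols["PK"]))
        contrasts.append((f"{grp}vsPT", groups_cols[grp], groups_cols["PT"]))
    deg_by_contrast = {
        name: deg_table(
            totals, nf_tot, a, b, name,
            pseudo_cpm=cfg.pseudo_cpm, lfc_cut=cfg.lfc_cut, alpha=cfg.alpha,
        )
        for name, a, b in contrasts
    }
    deg = pd.concat(deg_by_contrast.values())

    # ---- ELD classification ------------------------------------------------
    eld_recs, eld_counts = {}, {}
    for grp in FOCAL_GROUPS:
        calls = pd.DataFrame(
            {
                "PvK": deg_by_contrast[f"{grp}vsPK"]["call"],
                "PvT": deg_by_contrast[f"{grp}vsPT"]["call"],
                "KvT": deg_by_contrast["PKvsPT"]["call"],
            }
        )
        recs = classify_records(calls, grp, ambiguous_mode=cfg.ambiguous_mode)
        eld_recs[grp] = recs
        eld_counts[grp] = {
            "category": category_counts(recs["category"]),
            "collapsed": category_counts(recs["collapsed"]),
        }
    eld_trans = transition_table(
        eld_recs["F1K"]["collapsed"], eld_recs["ALLO"]["collapsed"],
        labels=list(COLLAPSED_LABELS) + [AMBIGUOUS],
    )

    # ---- HEB ---------------------------------------------------------------
    parent_cols = [(s, "K") for s in samples_of(sheet, "PK")] + [
        (s, "T") for s in samples_of(sheet, "PT")
    ]
    heb_recs, heb_strong = {}, {}
    ratios_by_group: dict[str, np.ndarray] = {}
    for grp in FOCAL_GROUPS:
        focal_k = [(s, "K") for s in samples_of(sheet, grp, "K")]
        focal_t = [(s, "T") for s in samples_of(sheet, grp, "T")]
        side = _pair_side_matrix(cm, pairs_kept, parent_cols + focal_k + focal_t)
        nf = tmm_factors(side)
        c = cpm(side, nf)
        mean_cpm = pd.DataFrame(
            {
                "focal_T": c[[s for s, _ in focal_t]].mean(axis=1),
                "focal_K": c[[s for s, _ in focal_k]].mean(axis=1),
                "parent_T": c[samples_of(sheet, "PT")].mean(axis=1),
                "parent_K": c[samples_of(sheet, "PK")].mean(axis=1),
            }
        )
        recs = heb_records(
            mean_cpm, grp, pseudo=cfg.pseudo_cpm, mag_cut=cfg.mag_cut, alpha=cfg.alpha
        )
        heb_recs[grp] = recs
        heb_strong[grp] = strong_bias_tally(recs, cutoff=cfg.strong_cutoff)
        ratios_by_group[grp] = recs["log2_ratio"].to_numpy()

    # parents' ortholog ratio distribution from the parent-only matrix
    side_p = _pair_side_matrix(cm, pairs_kept, parent_cols)
    nf_p = tmm_factors(side_p)
    c_p = cpm(side_p, nf_p)
    parent_ratio = np.log2(
        (c_p[samples_of(sheet, "PT")].mean(axis=1) + cfg.pseudo_cpm)
        / (c_p[samples_of(sheet, "PK")].mean(axis=1) + cfg.pseudo_cpm)
    )
    dist_input = {"PARENTS": parent_ratio.to_numpy(), **ratios_by_group}
    heb_dists = summarize_distributions(dist_input, cfg.kurtosis_convention)

    heb_call_counts = pd.DataFrame(
        {
            grp: heb_recs[grp]["call"].value_counts().reindex(HEB_LABELS, fill_value=0)
            for grp in FOCAL_GROUPS
        }
    )
    heb_trans = heb_transition_table(heb_recs["F1K"]["call"], heb_recs["ALLO"]["call"])
    shared = shared_bias_fraction(heb_recs["F1K"]["call"], heb_recs["ALLO"]["call"])

    # ---- MDS QC ------------------------------------------------------------
    log_cpm = np.log2(cpm(totals, nf_tot) + 2.0)
    mds = mds_qc(log_cpm, n_top=cfg.mds_top)

    manifest = {
        "package": "homoeobias",
        "version": __version__,
        "parameters": cfg.analysis_params(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.analysis_params(), sort_keys=True).encode()
        ).hexdigest(),
        "n_genes": int(cm.counts.shape[0]),
        "n_samples": int(cm.counts.shape[1]),
        "n_orthogroups": len(og.members),
        "n_single_copy_pairs": len(pairs_all),
        "n_pairs_without_counts": n_dropped_missing,
        "retained_per_threshold": {f"{t:g}": len(v) for t, v in retained.items()},
        "n_analysis_pairs": len(pairs_kept),
        "tmm_reference_totals": nf_tot.ref_sample,
    }

    return PipelineResult(
        config=cfg,
        retained=retained,
        analysis_pairs=[p.pair_id for p in pairs_kept],
        deg=deg,
        eld=eld_recs,
        eld_counts=eld_counts,
        eld_transition=eld_trans,
        heb=heb_recs,
        heb_distributions=heb_dists,
        heb_call_counts=heb_call_counts,
        heb_strong=heb_strong,
        heb_transition=heb_trans,
        shared_heb_fraction=shared,
        mds=mds,
        manifest=manifest,
    )


def shared_bias_fraction(calls_src: pd.Series, calls_dst: pd.Series) -> float:
    """Fraction of source-biased pairs also biased in the destination group."""
    only = calls_src.index.difference(calls_dst.index)
    if len(only) or len(calls_dst.index.difference(calls_src.index)):
        raise DataModelError("call sets cover different gene universes")
    dst = calls_dst.reindex(calls_src.index)
    src_biased = calls_src != NON_BIAS
    if src_biased.sum() == 0:
        return 0.0
    both = src_biased & (dst != NON_BIAS)
    return float(both.sum() / src_biased.sum())


def compare_runs(
    eld_src: pd.Series, eld_dst: pd.Series, heb_src: pd.Series, heb_dst: pd.Series
) -> dict:
    """Transition reports between two focal groups over a shared universe."""
    return {
        "eld_transition": transition_table(
            eld_src, eld_dst, labels=list(COLLAPSED_LABELS) + [AMBIGUOUS]
        ),
        "heb_transition": heb_transition_table(heb_src, heb_dst),
        "shared_heb_fraction": shared_bias_fraction(heb_src, heb_dst),
    }


# ---------------------------------------------------------------------------
# file-level entry point and output writing
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Read the configured inputs, run the analysis and write the run
    directory (atomically)."""
    cm = read_counts(cfg.counts)
    sheet = read_sample_sheet(cfg.samples, cm)
    og = read_orthogroups(cfg.orthogroups, cfg.k_species, cfg.t_species)
    lengths = read_lengths(cfg.lengths)
    result = run_analysis(cm, sheet, og, lengths, cfg)
    write_result(result, cfg.out_dir)
    return result


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_result(result: PipelineResult, out_dir: str) -> None:
    """Write all result tables; the directory appears only on success."""
    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".homoeobias-", dir=parent)
    try:
        for thr, ids in result.retained.items():
            with open(os.path.join(tmp, f"retained_pairs_tpm{thr:g}.txt"), "w") as fh:
                fh.write("\n".join(ids) + ("\n" if ids else ""))
        result.deg.rename_axis("pair_id").to_csv(
            os.path.join(tmp, "deg.tsv"), sep="\t", lineterminator="\n"
        )
        for grp, recs in result.eld.items():
            recs.rename_axis("pair_id").to_csv(
                os.path.join(tmp, f"eld_{grp}.tsv"), sep="\t", lineterminator="\n"
            )
        counts_json = {
            grp: {
                kind: {
                    lab: {
                        "count": int(row["count"]),
                        "proportion": float(row["proportion"]),
                    }
                    for lab, row in frame.iterrows()
                }
                for kind, frame in kinds.items()
            }
            for grp, kinds in result.eld_counts.items()
        }
        _write_json(counts_json, os.path.join(tmp, "eld_counts.json"))
        result.eld_transition.to_csv(
            os.path.join(tmp, "eld_transition_F1K_to_ALLO.tsv"), sep="\t",
            lineterminator="\n",
        )
        for grp, recs in result.heb.items():
            recs.rename_axis("pair_id").to_csv(
                os.path.join(tmp, f"heb_{grp}.tsv"), sep="\t", lineterminator="\n"
            )
        result.heb_distributions.to_csv(
            os.path.join(tmp, "heb_distributions.tsv"), sep="\t", lineterminator="\n"
        )
        result.heb_call_counts.rename_axis("call").to_csv(
            os.path.join(tmp, "heb_call_counts.tsv"), sep="\t", lineterminator="\n"
        )
        strong_json = {
            grp: frame.to_dict(orient="index") for grp, frame in result.heb_strong.items()
        }
        _write_json(strong_json, os.path.join(tmp, "heb_strong_bias.json"))
        result.heb_transition.to_csv(
            os.path.join(tmp, "heb_transition_F1K_to_ALLO.tsv"), sep="\t",
            lineterminator="\n",
        )
        _write_json(
            {"shared_heb_fraction": result.shared_heb_fraction},
            os.path.join(tmp, "heb_shared.json"),
        )
        result.mds.rename_axis("sample_id").to_csv(
            os.path.join(tmp, "mds_coordinates.tsv"), sep="\t", lineterminator="\n"
        )
        _write_json(result.manifest, os.path.join(tmp, "manifest.json"))
    except BaseException:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if os.path.isdir(out_dir):
        shutil.rmtree(out_dir)
    os.replace(tmp, out_dir)
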