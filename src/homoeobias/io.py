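"""Data model and file I/O for homoeolog-resolved expression analysis.

The analysis operates on five sample groups: the two diploid parents (``PK``,
``PT``), the reciprocal F1 hybrids (``F1K``, ``F1T``; the letter names the
maternal parent) and the natural allotetraploid (``ALLO``).  Parents carry one
genome, so each parental sample is a single column of counts over that
parent's reference genes.  Hybrid and allotetraploid libraries are
homoeolog-resolved upstream: each biological replicate contributes *two*
columns, one per subgenome (K and T), over the corresponding parental
reference genes.

All tabular formats are plain UTF-8 TSV with no quoting; count matrices put
gene identifiers in a first column headed ``gene_id`` so that write→read
round-trips are byte-exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("PK", "PT", "F1K", "F1T", "ALLO")
#: groups whose samples are homoeolog-resolved (two columns per replicate)
HYBRID_GROUPS = ("F1K", "F1T", "ALLO")
SUBGENOMES = ("K", "T", "NONE")


class DataModelError(ValueError):
    """Raised when an input violates a data-model invariant."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples (non-negative integers).

    ``counts`` keeps the gene order of the source file; the index is named
    ``gene_id``.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataModelError(f"duplicate sample ids: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))
                g, s = bad[0]
                raise DataModelError(
                    f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
            df = df.astype(np.int64)
        arr = df.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise DataModelError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        df.index.name = "gene_id"
        self.counts = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def require_positive_libraries(self) -> None:
        libs = self.library_sizes()
        empty = libs.index[libs == 0].tolist()
        if empty:
            raise DataModelError(f"samples with zero library size: {empty}")


def read_counts(path) -> CountMatrix:
    """Read a gene x sample TSV count matrix (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    # reject non-numeric / non-integer cells with a precise message
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            gene = df.index[vals.isna().to_numpy().argmax()]
            raise DataModelError(
                f"non-numeric count at gene {gene!r}, sample {col!r} in {path}"
            )
        df[col] = vals
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    """Write a count matrix in the canonical TSV dialect (byte-stable)."""
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ("sample_id", "group", "replicate", "subgenome")


def validate_sample_sheet(sheet: pd.DataFrame, cm: CountMatrix | None = None) -> pd.DataFrame:
    """Validate a sample sheet; returns it with canonical column order.

    Diploid parents carry ``subgenome == NONE`` (their whole genome is one
    subgenome); hybrid/allotetraploid groups must provide both a K and a T
    column per replicate.
    """
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise DataModelError(f"sample sheet missing columns: {missing}")
    sheet = sheet.loc[:, list(SHEET_COLUMNS)].copy()
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataModelError(f"duplicate sample ids in sheet: {dups}")
    bad_group = set(sheet["group"]) - set(GROUPS)
    if bad_group:
        raise DataModelError(f"unknown groups: {sorted(bad_group)}")
    bad_sub = set(sheet["subgenome"]) - set(SUBGENOMES)
    if bad_sub:
        raise DataModelError(f"unknown subgenome labels: {sorted(bad_sub)}")
    for _, row in sheet.iterrows():
        parent = row["group"] in ("PK", "PT")
        if parent != (row["subgenome"] == "NONE"):
            raise DataModelError(
                f"sample {row['sample_id']!r}: group {row['group']} is incompatible "
                f"with subgenome {row['subgenome']}"
            )
    for grp in HYBRID_GROUPS:
        sub = sheet[sheet["group"] == grp]
        if len(sub) == 0:
            continue
        for rep, reprows in sub.groupby("replicate"):
            have = set(reprows["subgenome"])
            if have != {"K", "T"}:
                raise DataModelError(
                    f"group {grp} replicate {rep} must have exactly one K and one T "
                    f"sample, found subgenomes {sorted(have)}"
                )
    if cm is not None:
        sheet_ids = set(sheet["sample_id"])
        cm_ids = set(cm.sample_ids)
        if sheet_ids != cm_ids:
            raise DataModelError(
                f"sample sheet / count matrix mismatch: only in sheet "
                f"{sorted(sheet_ids - cm_ids)}, only in matrix {sorted(cm_ids - sheet_ids)}"
            )
    return sheet


def read_sample_sheet(path, cm: CountMatrix | None = None) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "subgenome": str})
    sheet["replicate"] = sheet["replicate"].astype(int)
    return validate_sample_sheet(sheet, cm)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.loc[:, list(SHEET_COLUMNS)].to_csv(path, sep="\t", index=False, lineterminator="\n")


def samples_of(sheet: pd.DataFrame, group: str, subgenome: str | None = None) -> list[str]:
    """Sample ids of a group (optionally one subgenome), ordered by replicate."""
    sub = sheet[sheet["group"] == group]
    if subgenome is not None:
        sub = sub[sub["subgenome"] == subgenome]
    sub = sub.sort_values(["replicate", "subgenome"])
    return sub["sample_id"].tolist()


# ---------------------------------------------------------------------------
# orthogroups and gene pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenePair:
    """A single-copy orthologous pair: one parent-K gene, one parent-T gene."""

    pair_id: str
    k_gene: str
    t_gene: str


@dataclass
class OrthogroupTable:
    """OrthoFinder-style orthogroup membership for the two parental species.

    ``members`` maps orthogroup id -> {species: [gene ids]} for the two
    species columns ``k_species`` and ``t_species``.
    """

    members: dict[str, dict[str, list[str]]]
    k_species: str
    t_species: str

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og, per_sp in self.members.items():
            for sp, genes in per_sp.items():
                for g in genes:
                    if g in seen:
                        raise DataModelError(
                            f"gene {g!r} appears in orthogroups {seen[g]!r} and {og!r}"
                        )
                    seen[g] = og


def read_orthogroups(path, k_species: str, t_species: str) -> OrthogroupTable:
    """Read an OrthoFinder ``Orthogroups.tsv``-dialect table.

    First column is the orthogroup id; each species column holds a
    comma-separated gene list (empty cell = no members).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    for sp in (k_species, t_species):
        if sp not in df.columns:
            raise DataModelError(f"orthogroup table lacks species column {sp!r}")
    members: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        members[row[og_col]] = {
            sp: [g.strip() for g in row[sp].split(",") if g.strip()]
            for sp in (k_species, t_species)
        }
    return OrthogroupTable(members, k_species, t_species)


def write_orthogroups(og: OrthogroupTable, path) -> None:
    rows = [
        {
            "Orthogroup": og_id,
            og.k_species: ", ".join(per_sp[og.k_species]),
            og.t_species: ", ".join(per_sp[og.t_species]),
        }
        for og_id, per_sp in og.members.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def filter_single_copy(og: OrthogroupTable) -> list[GenePair]:
    """Keep orthogroups with exactly one gene in each parental species.

    These single-copy one-to-one groups are the reference gene pairs on which
    every homoeolog-level comparison is defined.
    """
    pairs = []
    for og_id, per_sp in og.members.items():
        k = per_sp[og.k_species]
        t = per_sp[og.t_species]
        if len(k) == 1 and len(t) == 1:
            pairs.append(GenePair(og_id, k[0], t[0]))
    return pairs


# ---------------------------------------------------------------------------
# TPM and the co-expression filter
# ---------------------------------------------------------------------------


@dataclass
class TpmMatrix:
    """Transcripts-per-million, genes x samples; columns sum to 1e6."""

    tpm: pd.DataFrame


def read_lengths(path) -> pd.Series:
    """Read a two-column TSV (gene_id, length_kb) of effective lengths."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    s = df.set_index("gene_id")["length_kb"].astype(float)
    return s


def write_lengths(lengths: pd.Series, path) -> None:
    df = lengths.rename("length_kb").rename_axis("gene_id").reset_index()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def compute_tpm(cm: CountMatrix, lengths_kb: pd.Series) -> TpmMatrix:
    """Length-normalize counts to TPM: rate g = count/length, scaled to 1e6.

    An all-zero sample column yields an all-zero TPM column with a warning;
    zero or missing gene lengths are an error.
    """
    missing = cm.gene_ids.difference(lengths_kb.index)
    if len(missing) > 0:
        raise DataModelError(f"genes without effective length: {missing[:5].tolist()}")
    lens = lengths_kb.reindex(cm.gene_ids).astype(float)
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise DataModelError(f"non-positive effective length for genes: {bad[:5]}")
    rate = cm.counts.div(lens, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom.index[denom == 0].tolist()
    if zero_cols:
        warnings.warn(f"all-zero sample columns in TPM computation: {zero_cols}")
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1).fillna(0.0) * 1e6
    return TpmMatrix(tpm)


def collapse_hybrid_replicates(
    cm: CountMatrix, sheet: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame]:
    """Merge the two homoeolog columns of each hybrid replicate into one.

    A hybrid/allotetraploid replicate is a single sequencing library whose
    reads were split by subgenome upstream; its K column is non-zero only on
    parent-K genes and its T column only on parent-T genes, so summing the two
    columns reconstitutes the replicate's library over the full gene universe.
    Parental samples pass through unchanged.  Returns the replicate-level
    matrix and a matching sheet (one row per replicate, subgenome ``NONE``
    meaningless for hybrids and kept as ``BOTH``).
    """
    cols = {}
    rows = []
    for grp in GROUPS:
        sub = sheet[sheet["group"] == grp]
        if grp in HYBRID_GROUPS:
            for rep, reprows in sub.groupby("replicate"):
                ids = reprows.sort_values("subgenome")["sample_id"].tolist()
                name = f"{grp}_{rep}"
                cols[name] = cm.counts[ids].sum(axis=1)
                rows.append({"sample_id": name, "group": grp, "replicate": rep, "subgenome": "BOTH"})
        else:
            for _, r in sub.sort_values("replicate").iterrows():
                cols[r["sample_id"]] = cm.counts[r["sample_id"]]
                rows.append(dict(r))
    merged = CountMatrix(pd.DataFrame(cols, index=cm.gene_ids))
    return merged, pd.DataFrame(rows)


def group_pair_tpm(
    tpm: TpmMatrix, sheet: pd.DataFrame, pairs: Sequence[GenePair]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean TPM of each pair's K side and T side.

    ``tpm`` must be replicate-level (see :func:`collapse_hybrid_replicates`)
    so that hybrid TPMs are normalized over the replicate's whole library.
    Returns two pair x group frames (K side, T side); a parent contributes
    only its own side, the other side is NaN.
    """
    k_genes = pd.Index([p.k_gene for p in pairs])
    t_genes = pd.Index([p.t_gene for p in pairs])
    pair_ids = pd.Index([p.pair_id for p in pairs], name="pair_id")
    out_k = pd.DataFrame(index=pair_ids, columns=list(GROUPS), dtype=float)
    out_t = pd.DataFrame(index=pair_ids, columns=list(GROUPS), dtype=float)
    for grp in GROUPS:
        ids = sheet.loc[sheet["group"] == grp, "sample_id"].tolist()
        if not ids:
            raise DataModelError(f"sample sheet has no samples for group {grp}")
        gmean = tpm.tpm[ids].mean(axis=1)
        if grp != "PT":
            out_k[grp] = gmean.reindex(k_genes).to_numpy()
        if grp != "PK":
            out_t[grp] = gmean.reindex(t_genes).to_numpy()
    return out_k, out_t


def coexpression_filter(
    tpm_k: pd.DataFrame,
    tpm_t: pd.DataFrame,
    threshold: float,
    mode: str = "sum",
) -> list[str]:
    """Retain pairs whose expression strictly exceeds ``threshold`` in all
    five groups.

    For the diploid parents a pair's expression is its single ortholog's
    group-mean TPM.  For hybrid/allotetraploid groups the pair expresses two
    homoeologs; ``mode`` chooses how they enter the comparison:

    - ``"sum"``  — homoeolog TPMs are summed (default),
    - ``"either"`` — the larger homoeolog must pass,
    - ``"both"`` — both homoeologs must pass individually.
    """
    if threshold < 0:
        raise DataModelError("threshold must be >= 0")
    if mode not in ("sum", "either", "both"):
        raise DataModelError(f"unknown co-expression mode {mode!r}")
    missing = [g for g in GROUPS if g not in tpm_k.columns or g not in tpm_t.columns]
    if missing:
        raise DataModelError(f"missing groups in TPM tables: {missing}")
    ok = pd.Series(True, index=tpm_k.index)
    ok &= tpm_k["PK"] > threshold
    ok &= tpm_t["PT"] > threshold
    for grp in HYBRID_GROUPS:
        k, t = tpm_k[grp], tpm_t[grp]
        if mode == "sum":
            expr_ok = (k + t) > threshold
        elif mode == "either":
            expr_ok = np.maximum(k, t) > threshold
        else:
            expr_ok = (k > threshold) & (t > threshold)
        ok &= expr_ok
    return tpm_k.index[ok].tolist()
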