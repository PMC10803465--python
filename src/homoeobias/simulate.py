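"""Ground-truthed synthetic count data for the five-group design.

The generator emulates the study design downstream of read sorting: two
diploid parents (PK, PT), reciprocal F1 hybrids (F1K, F1T) and a natural
allotetraploid (ALLO), with homoeolog-resolved counts for the hybrid groups
and 3/3/3/2/3 biological replicates.  Per gene pair it plants

- an expression-level-dominance state (collapsed class + concrete category),
  realized through the parental log2 gap and the focal group's total
  expression level, and
- a homoeolog-expression-bias magnitude, realized through how the focal
  total is split between the K and T homoeologs,

then draws negative-binomial counts (variance mu + phi*mu^2) per replicate
with per-library depth factors.  Because the parents are the same
individuals in every focal comparison, the parental configuration (gap
direction and size) is a property of the pair: focal groups other than F1K
re-draw their state only among categories compatible with that
configuration, with a retention probability tying ALLO (and F1T) to the F1K
state.

All planted truth is returned alongside the matrices, so downstream
classification can be scored for recovery without any external data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .eld import ADD, AMBIGUOUS, COLLAPSE_MAP, K_DOM, NC, NO_CHANGE, T_DOM, TDR, TUR
from .heb import HEB_LABELS, K_BIAS, NON_BIAS, T_BIAS
from .io import (
    CountMatrix,
    GenePair,
    OrthogroupTable,
    validate_sample_sheet,
)

FOCAL_GROUPS = ("F1K", "F1T", "ALLO")

#: parental log2(T/K) gap, in units of eld_effect, required by each category
_RHO_UNITS = {
    "I": 2, "XII": -2,
    "II": 1, "IX": 1, "III": 1, "VIII": 1,
    "IV": -1, "XI": -1, "X": -1, "V": -1,
    "VI": 0, "VII": 0, NO_CHANGE: 0,
}
#: collapsed class -> concrete categories the generator may plant
_CLASS_CATEGORIES = {
    ADD: ("I", "XII"),
    T_DOM: ("II", "XI"),
    K_DOM: ("IV", "IX"),
    TUR: ("V", "VI", "VIII"),
    TDR: ("III", "VII", "X"),
    NC: (NO_CHANGE,),
}
#: categories compatible with each gap class (same parents, same gap)
_COMPATIBLE = {
    units: tuple(c for c, u in _RHO_UNITS.items() if u == units)
    for units in (-2, -1, 0, 1, 2)
}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator configuration; defaults are the package's study conditions.

    Expression levels are in CPM units at the nominal depth of 1e6 reads.
    ``eld_proportions`` / ``heb_proportions`` give the planted state mix for
    the F1K hybrids; other focal groups retain an F1K state with probability
    ``retention`` and otherwise re-draw among compatible states.  Planted
    HEB is restricted to pairs with baseline mean >= ``heb_min_cpm`` so that
    recovery measures classifier behaviour, not sequencing depth.
    """

    n_pairs: int = 5000
    replicates: dict = field(
        default_factory=lambda: {"PK": 3, "PT": 3, "F1K": 3, "F1T": 2, "ALLO": 3}
    )
    baseline_log_mean: float = math.log(50.0)
    baseline_log_sd: float = 1.2
    dispersion: float = 0.05
    eld_proportions: dict = field(
        default_factory=lambda: {NC: 0.70, ADD: 0.02, T_DOM: 0.05, K_DOM: 0.05, TUR: 0.08, TDR: 0.10}
    )
    eld_effect: float = 2.0
    heb_proportions: dict = field(
        default_factory=lambda: {NON_BIAS: 0.90, T_BIAS: 0.05, K_BIAS: 0.05}
    )
    heb_magnitude: float = 3.0
    heb_min_cpm: float = 20.0
    libsize_range: tuple = (0.7, 1.3)
    depth: float = 1e6
    length_kb_range: tuple = (0.5, 5.0)
    cyto_fraction: float = 0.0
    cyto_magnitude: float = 6.0
    retention: float = 0.7
    misassignment: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise SimulationError("n_pairs must be >= 1")
        for grp, n in self.replicates.items():
            if n < 2:
                raise SimulationError(f"group {grp} needs >= 2 replicates, got {n}")
        for name, props, keys in (
            ("eld_proportions", self.eld_proportions, set(_CLASS_CATEGORIES)),
            ("heb_proportions", self.heb_proportions, set(HEB_LABELS)),
        ):
            extra = set(props) - keys
            if extra:
                raise SimulationError(f"{name}: unknown labels {sorted(extra)}")
            if any(v < 0 for v in props.values()):
                raise SimulationError(f"{name}: negative proportion")
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise SimulationError(f"{name}: proportions must sum to 1")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.eld_effect <= 0 or self.heb_magnitude < 0:
            raise SimulationError("effect sizes must be positive")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise SimulationError("libsize_range must satisfy 0 < lo <= hi")
        lo, hi = self.length_kb_range
        if not (0 < lo <= hi):
            raise SimulationError("length_kb_range must satisfy 0 < lo <= hi")
        if not (0 <= self.retention <= 1 and 0 <= self.cyto_fraction <= 1):
            raise SimulationError("retention and cyto_fraction must lie in [0, 1]")
        if self.misassignment != 0:
            raise SimulationError("homoeolog misassignment mixing is not implemented")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise SimulationError(f"unknown config keys: {sorted(extra)}")
        for key in ("libsize_range", "length_kb_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def null_config(**overrides) -> SimConfig:
    """Configuration with no planted effects (all NC / NON_BIAS, no cyto)."""
    cfg = SimConfig(
        eld_proportions={NC: 1.0, ADD: 0.0, T_DOM: 0.0, K_DOM: 0.0, TUR: 0.0, TDR: 0.0},
        heb_proportions={NON_BIAS: 1.0, T_BIAS: 0.0, K_BIAS: 0.0},
        cyto_fraction=0.0,
        **overrides,
    )
    return cfg


@dataclass
class SimBundle:
    """Everything the downstream pipeline consumes, plus the planted truth."""

    counts: CountMatrix
    sheet: pd.DataFrame
    pairs: list
    orthogroups: OrthogroupTable
    lengths: pd.Series
    truth: pd.DataFrame
    config: SimConfig


def _category_weight(cfg: SimConfig, category: str) -> float:
    """Configured probability mass of one concrete category (class mass split
    uniformly over the class's categories)."""
    for cls, cats in _CLASS_CATEGORIES.items():
        if category in cats:
            return cfg.eld_proportions[cls] / len(cats)
    raise SimulationError(f"unknown category {category!r}")


def _draw_categories(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Planted ELD category per pair and focal group, parental-gap consistent.

    F1K draws from the configured class proportions.  F1T and ALLO keep the
    F1K category with probability ``retention`` and otherwise re-draw from
    the configured proportions restricted (and renormalized) to categories
    compatible with the pair's parental gap, so group-level category mixes
    stay close to the configured proportions.
    """
    classes = list(_CLASS_CATEGORIES)
    probs = np.array([cfg.eld_proportions[c] for c in classes])
    f1k_class = rng.choice(len(classes), size=cfg.n_pairs, p=probs)
    f1k = np.array(
        [rng.choice(_CLASS_CATEGORIES[classes[i]]) for i in f1k_class], dtype=object
    )
    out = {"F1K": f1k}
    units = np.array([_RHO_UNITS[c] for c in f1k])
    redraw_dist = {}
    for u, cats in _COMPATIBLE.items():
        w = np.array([_category_weight(cfg, c) for c in cats])
        redraw_dist[u] = (list(cats), w / w.sum()) if w.sum() > 0 else (list(cats), None)
    for grp in ("F1T", "ALLO"):
        keep = rng.random(cfg.n_pairs) < cfg.retention
        labels = f1k.copy()
        for i in np.nonzero(~keep)[0]:
            cats, w = redraw_dist[units[i]]
            labels[i] = rng.choice(cats, p=w) if w is not None else f1k[i]
        out[grp] = labels
    return out


def _draw_heb(
    cfg: SimConfig, rng: np.random.Generator, eligible: np.ndarray
) -> dict[str, np.ndarray]:
    """Planted HEB call per pair and focal group (NON_BIAS when ineligible).

    Bias is planted only on eligible pairs: baseline mean above the
    detectability floor and parentally balanced expression.  The latter keeps
    the planted magnitude identical to the focal homoeolog log-ratio and
    keeps planted bias a mid-scale broadening of the ratio distribution
    rather than an extension of its extreme tail (the mechanism behind the
    parents-over-allotetraploid kurtosis ordering).
    """
    labels = list(HEB_LABELS)
    probs = np.array([cfg.heb_proportions[l] for l in labels])
    f1k = np.array(rng.choice(labels, size=cfg.n_pairs, p=probs), dtype=object)
    f1k[~eligible] = NON_BIAS
    out = {"F1K": f1k}
    for grp in ("F1T", "ALLO"):
        keep = rng.random(cfg.n_pairs) < cfg.retention
        redraw = np.array(rng.choice(labels, size=cfg.n_pairs, p=probs), dtype=object)
        lab = np.where(keep, f1k, redraw)
        lab[~eligible] = NON_BIAS
        out[grp] = lab.astype(object)
    return out


def _focal_total(category: np.ndarray, base: np.ndarray, delta: float) -> np.ndarray:
    """Planted focal total expression (CPM) per pair given its category."""
    rho = np.array([_RHO_UNITS[c] for c in category]) * delta
    mu_k = base * 2.0 ** (-rho / 2)
    mu_t = base * 2.0 ** (rho / 2)
    total = np.empty_like(base)
    for i, cat in enumerate(category):
        if cat in (NO_CHANGE,):
            total[i] = 0.5 * (mu_k[i] + mu_t[i])
        elif cat in ("I", "XII"):
            total[i] = base[i]  # log-space midpoint of the parents
        elif cat in ("II", "XI"):
            total[i] = mu_t[i]
        elif cat in ("IV", "IX"):
            total[i] = mu_k[i]
        elif cat == "V":
            total[i] = mu_k[i] * 2.0**delta
        elif cat == "VIII":
            total[i] = mu_t[i] * 2.0**delta
        elif cat == "VI":
            total[i] = base[i] * 2.0**delta
        elif cat == "III":
            total[i] = mu_k[i] * 2.0**-delta
        elif cat == "X":
            total[i] = mu_t[i] * 2.0**-delta
        elif cat == "VII":
            total[i] = base[i] * 2.0**-delta
        else:  # pragma: no cover - guarded by _draw_categories
            raise SimulationError(f"cannot plant category {cat!r}")
    return total


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    n = 1.0 / phi
    p = 1.0 / (1.0 + phi * mean)
    return rng.negative_binomial(n, p)


def simulate(cfg: SimConfig) -> SimBundle:
    """Generate a ground-truthed dataset; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    width = max(4, len(str(n)))
    pair_ids = [f"OG{i+1:0{width}d}" for i in range(n)]
    k_genes = [f"K{i+1:0{width}d}" for i in range(n)]
    t_genes = [f"T{i+1:0{width}d}" for i in range(n)]
    pairs = [GenePair(p, k, t) for p, k, t in zip(pair_ids, k_genes, t_genes)]

    base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
    categories = _draw_categories(cfg, rng)
    # every focal group shares the pair's parental configuration (F1K-drawn)
    rho = np.array([_RHO_UNITS[c] for c in categories["F1K"]]) * cfg.eld_effect
    mu_k = base * 2.0 ** (-rho / 2)
    mu_t = base * 2.0 ** (rho / 2)

    eligible = (base >= cfg.heb_min_cpm) & (rho == 0)
    heb_calls = _draw_heb(cfg, rng, eligible)
    sign = {T_BIAS: 1.0, K_BIAS: -1.0, NON_BIAS: 0.0}
    n_cyto = int(round(cfg.cyto_fraction * n))
    cyto_idx = rng.choice(np.nonzero(eligible)[0], size=min(n_cyto, int(eligible.sum())),
                          replace=False) if n_cyto else np.array([], dtype=int)
    cyto = np.zeros(n, dtype=bool)
    cyto[cyto_idx] = True

    heb_mag = {}
    for grp in FOCAL_GROUPS:
        mag = np.array([sign[c] for c in heb_calls[grp]]) * cfg.heb_magnitude
        # maternal cytonuclear bias: K-ward where K is the maternal parent
        maternal_sign = 1.0 if grp == "F1T" else -1.0
        mag = mag + np.where(cyto, maternal_sign * cfg.cyto_magnitude, 0.0)
        heb_mag[grp] = mag

    # effective planted call follows the effective magnitude (cyto included)
    def effective_call(mag: np.ndarray) -> np.ndarray:
        out = np.full(n, NON_BIAS, dtype=object)
        out[mag > 1] = T_BIAS
        out[mag < -1] = K_BIAS
        return out

    # --- sample layout -----------------------------------------------------
    cols: dict[str, np.ndarray] = {}
    sheet_rows = []
    lib_factor = lambda: rng.uniform(*cfg.libsize_range)
    gene_index = pd.Index(k_genes + t_genes, name="gene_id")
    zeros = np.zeros(n)
    phi = cfg.dispersion

    for parent, mu, own in (("PK", mu_k, "K"), ("PT", mu_t, "T")):
        for r in range(1, cfg.replicates[parent] + 1):
            u = lib_factor()
            counts = _nb_draw(rng, mu * u * (cfg.depth / 1e6), phi)
            col = np.concatenate([counts, zeros]) if own == "K" else np.concatenate([zeros, counts])
            name = f"{parent}_{r}"
            cols[name] = col.astype(np.int64)
            sheet_rows.append(
                {"sample_id": name, "group": parent, "replicate": r, "subgenome": "NONE"}
            )

    for grp in FOCAL_GROUPS:
        total = _focal_total(categories[grp], base, cfg.eld_effect)
        ratio = 2.0 ** (rho + heb_mag[grp])
        t_h = total * ratio / (1.0 + ratio)
        k_h = total - t_h
        for r in range(1, cfg.replicates[grp] + 1):
            u = lib_factor()
            ck = _nb_draw(rng, k_h * u * (cfg.depth / 1e6), phi)
            ct = _nb_draw(rng, t_h * u * (cfg.depth / 1e6), phi)
            for sub, c in (("K", ck), ("T", ct)):
                col = np.concatenate([c, zeros]) if sub == "K" else np.concatenate([zeros, c])
                name = f"{grp}_{r}_{sub}"
                cols[name] = col.astype(np.int64)
                sheet_rows.append(
                    {"sample_id": name, "group": grp, "replicate": r, "subgenome": sub}
                )

    counts = CountMatrix(pd.DataFrame(cols, index=gene_index))
    sheet = validate_sample_sheet(pd.DataFrame(sheet_rows), counts)

    lo, hi = cfg.length_kb_range
    lengths = pd.Series(
        np.exp(rng.uniform(math.log(lo), math.log(hi), size=2 * n)),
        index=gene_index, name="length_kb",
    )

    og = OrthogroupTable(
        {p.pair_id: {"K": [p.k_gene], "T": [p.t_gene]} for p in pairs}, "K", "T"
    )

    truth = pd.DataFrame(index=pd.Index(pair_ids, name="pair_id"))
    truth["base_cpm"] = base
    truth["parental_log2_ratio"] = rho
    truth["cyto_flag"] = cyto
    truth["heb_eligible"] = eligible
    for grp in FOCAL_GROUPS:
        truth[f"eld_category_{grp}"] = categories[grp]
        truth[f"eld_collapsed_{grp}"] = [COLLAPSE_MAP[c] for c in categories[grp]]
        truth[f"heb_call_{grp}"] = effective_call(heb_mag[grp])
        truth[f"heb_magnitude_{grp}"] = heb_mag[grp]

    return SimBundle(counts, sheet, pairs, og, lengths, truth, cfg)


def write_bundle(bundle: SimBundle, out_dir) -> dict[str, str]:
    """Write the bundle in the exact formats the I/O layer consumes."""
    import os

    from .io import write_counts, write_lengths, write_orthogroups, write_sample_sheet

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts": os.path.join(out_dir, "counts.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "orthogroups": os.path.join(out_dir, "orthogroups.tsv"),
        "lengths": os.path.join(out_dir, "lengths.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_counts(bundle.counts, paths["counts"])
    write_sample_sheet(bundle.sheet, paths["samples"])
    write_orthogroups(bundle.orthogroups, paths["orthogroups"])
    write_lengths(bundle.lengths, paths["lengths"])
    bundle.truth.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    return paths
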