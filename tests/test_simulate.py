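"""The ground-truthed generator: determinism, concentration, truth mixes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import homoeobias as hb
from homoeobias.simulate import SimulationError


class TestConfigValidation:
    def test_bad_proportions_rejected(self):
        cfg = hb.SimConfig(eld_proportions={"NC": 0.5, "ADD": 0.1, "T_DOM": 0.1,
                                            "K_DOM": 0.1, "TUR": 0.1, "TDR": 0.2})
        with pytest.raises(SimulationError, match="sum to 1"):
            cfg.validate()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(SimulationError, match="dispersion"):
            hb.SimConfig(dispersion=-0.1).validate()

    def test_single_replicate_rejected(self):
        with pytest.raises(SimulationError, match="replicates"):
            hb.SimConfig(replicates={"PK": 1, "PT": 3, "F1K": 3, "F1T": 2, "ALLO": 3}).validate()

    def test_misassignment_stub(self):
        with pytest.raises(SimulationError, match="misassignment"):
            hb.SimConfig(misassignment=0.1).validate()

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_pairs: 123\nseed: 9\ndispersion: 0.01\n")
        cfg = hb.SimConfig.from_yaml(p)
        assert (cfg.n_pairs, cfg.seed, cfg.dispersion) == (123, 9, 0.01)
        p.write_text("not_a_key: 1\n")
        with pytest.raises(SimulationError, match="unknown config keys"):
            hb.SimConfig.from_yaml(p)


class TestDeterminismAndStructure:
    def test_same_seed_identical_output(self):
        a = hb.simulate(hb.SimConfig(n_pairs=100, seed=42))
        b = hb.simulate(hb.SimConfig(n_pairs=100, seed=42))
        assert a.counts.counts.equals(b.counts.counts)
        assert a.truth.equals(b.truth)
        assert a.lengths.equals(b.lengths)

    def test_different_seed_differs(self):
        a = hb.simulate(hb.SimConfig(n_pairs=100, seed=1))
        b = hb.simulate(hb.SimConfig(n_pairs=100, seed=2))
        assert not a.counts.counts.equals(b.counts.counts)

    def test_layout(self, small_bundle):
        cm, sheet = small_bundle.counts, small_bundle.sheet
        assert cm.counts.shape == (800, 22)  # 2 genes/pair, 6 parent + 16 hybrid cols
        hb.io.validate_sample_sheet(sheet, cm)
        # parental columns touch only their own species' genes
        k_rows = cm.counts.index.str.startswith("K")
        assert (cm.counts.loc[~k_rows, "PK_1"] == 0).all()
        assert (cm.counts.loc[k_rows, "PT_2"] == 0).all()

    def test_files_round_trip(self, small_bundle, tmp_path):
        paths = hb.write_bundle(small_bundle, tmp_path / "sim")
        cm = hb.read_counts(paths["counts"])
        sheet = hb.read_sample_sheet(paths["samples"], cm)
        og = hb.read_orthogroups(paths["orthogroups"], "K", "T")
        lens = hb.read_lengths(paths["lengths"])
        assert cm.counts.equals(small_bundle.counts.counts)
        assert len(hb.filter_single_copy(og)) == 400
        assert lens.to_numpy() == pytest.approx(small_bundle.lengths.to_numpy())


class TestPlantedSignal:
    def test_zero_dispersion_concentrates_on_planted_means(self):
        cfg = hb.SimConfig(
            n_pairs=2000, dispersion=0.0, libsize_range=(1.0, 1.0), seed=7,
            eld_proportions={"NC": 1.0, "ADD": 0, "T_DOM": 0, "K_DOM": 0, "TUR": 0, "TDR": 0},
            heb_proportions={"NON_BIAS": 1.0, "T_BIAS": 0, "K_BIAS": 0},
        )
        b = hb.simulate(cfg)
        # PK group mean counts vs planted parental means, well-expressed pairs
        k_means = b.counts.counts.loc[[p.k_gene for p in b.pairs], ["PK_1", "PK_2", "PK_3"]].mean(axis=1)
        planted = b.truth["base_cpm"].to_numpy()
        big = planted >= 50
        rel = np.abs(k_means.to_numpy()[big] - planted[big]) / planted[big]
        assert np.median(rel) < 0.1  # Poisson noise only
        # group-level mean over many pairs within 1%
        assert k_means.to_numpy()[big].mean() == pytest.approx(planted[big].mean(), rel=0.01)

    def test_non_bias_pairs_have_near_zero_empirical_magnitude(self):
        cfg = hb.SimConfig(n_pairs=1500, dispersion=0.0, libsize_range=(1.0, 1.0), seed=8)
        b = hb.simulate(cfg)
        cm = b.counts.counts
        kg = [p.k_gene for p in b.pairs]
        tg = [p.t_gene for p in b.pairs]
        f_t = cm.loc[tg, ["ALLO_1_T", "ALLO_2_T", "ALLO_3_T"]].mean(axis=1).to_numpy()
        f_k = cm.loc[kg, ["ALLO_1_K", "ALLO_2_K", "ALLO_3_K"]].mean(axis=1).to_numpy()
        p_t = cm.loc[tg, ["PT_1", "PT_2", "PT_3"]].mean(axis=1).to_numpy()
        p_k = cm.loc[kg, ["PK_1", "PK_2", "PK_3"]].mean(axis=1).to_numpy()
        mag = hb.magnitude(
            hb.homoeolog_log2_ratio(f_t, f_k), hb.homoeolog_log2_ratio(p_t, p_k)
        )
        null = (b.truth["heb_call_ALLO"] == "NON_BIAS").to_numpy() & (
            b.truth["base_cpm"].to_numpy() >= 50
        )
        assert np.quantile(np.abs(mag[null]), 0.9) < 0.5
        assert np.median(np.abs(mag[null])) < 0.15

    def test_truth_proportions_match_config(self):
        cfg = hb.SimConfig(n_pairs=8000, seed=9)
        b = hb.simulate(cfg)
        counts = b.truth["eld_collapsed_F1K"].value_counts()
        expected = {k: v * cfg.n_pairs for k, v in cfg.eld_proportions.items() if v > 0}
        obs = np.array([counts.get(k, 0) for k in expected])
        chi = sps.chisquare(obs, np.array(list(expected.values())))
        assert chi.pvalue > 0.001

    def test_nb_mean_variance_relationship(self):
        # many replicates of one group: moment check of var = mu + phi mu^2
        phi = 0.05
        cfg = hb.SimConfig(
            n_pairs=300, dispersion=phi, libsize_range=(1.0, 1.0), seed=10,
            replicates={"PK": 60, "PT": 2, "F1K": 2, "F1T": 2, "ALLO": 2},
            eld_proportions={"NC": 1.0, "ADD": 0, "T_DOM": 0, "K_DOM": 0, "TUR": 0, "TDR": 0},
            heb_proportions={"NON_BIAS": 1.0, "T_BIAS": 0, "K_BIAS": 0},
        )
        b = hb.simulate(cfg)
        pk_cols = [f"PK_{r}" for r in range(1, 61)]
        x = b.counts.counts.loc[[p.k_gene for p in b.pairs], pk_cols].to_numpy(float)
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        big = mu > 20
        ratio = var[big] / (mu[big] + phi * mu[big] ** 2)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.15)

    def test_retention_correlates_allo_with_f1k(self):
        b = hb.simulate(hb.SimConfig(n_pairs=4000, seed=11))
        t = b.truth
        same = (t["eld_category_F1K"] == t["eld_category_ALLO"]).mean()
        assert same > 0.7  # retention 0.7 plus compatible re-draw coincidences

    def test_null_config_truth_is_all_null(self):
        b = hb.simulate(hb.null_config(n_pairs=200, seed=12))
        assert (b.truth["eld_collapsed_F1K"] == "NC").all()
        assert (b.truth[["heb_call_F1K", "heb_call_F1T", "heb_call_ALLO"]] == "NON_BIAS").all().all()

    def test_cyto_bias_is_maternal(self):
        cfg = hb.SimConfig(n_pairs=1000, seed=13, cyto_fraction=0.05, cyto_magnitude=6.0)
        b = hb.simulate(cfg)
        cy = b.truth["cyto_flag"]
        assert cy.sum() == 50
        # K-ward (negative) in F1K/ALLO, T-ward (positive) in F1T
        assert (b.truth.loc[cy, "heb_magnitude_F1K"] < 0).all()
        assert (b.truth.loc[cy, "heb_magnitude_ALLO"] < 0).all()
        assert (b.truth.loc[cy, "heb_magnitude_F1T"] > 0).all()


class TestTruthConsistency:
    def test_heb_truth_call_matches_planted_magnitude_sign(self):
        b = hb.simulate(hb.SimConfig(n_pairs=600, seed=14))
        for grp in ("F1K", "F1T", "ALLO"):
            mag = b.truth[f"heb_magnitude_{grp}"]
            call = b.truth[f"heb_call_{grp}"]
            assert (call[mag > 1] == "T_BIAS").all()
            assert (call[mag < -1] == "K_BIAS").all()
            assert (call[mag.abs() <= 1] == "NON_BIAS").all()

    def test_parental_gap_shared_across_focal_groups(self):
        # focal groups never demand conflicting parental configurations
        from homoeobias.simulate import _RHO_UNITS

        b = hb.simulate(hb.SimConfig(n_pairs=800, seed=15))
        for grp in ("F1T", "ALLO"):
            units_f1k = b.truth["eld_category_F1K"].map(_RHO_UNITS)
            units_grp = b.truth[f"eld_category_{grp}"].map(_RHO_UNITS)
            assert (units_f1k == units_grp).all()
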