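import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from hltme.catalog import build_catalog, build_panel_layout, default_model_variables
from hltme.synthetic import (
    SimulationConfig,
    default_catalog,
    discovery_config,
    discovery_scaled_config,
    generate_cohort,
    make_signature_matrix,
    simulate_expression,
    simulate_fractions,
    simulate_survival,
    validation_config,
)


class TestConfig:
    def test_panel_budget_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(n_celltypes=13, n_markers_per_type=70,
                             n_housekeeping=40, total_genes=800)

    def test_unknown_adverse_type_rejected(self):
        with pytest.raises(ValueError, match="adverse_types"):
            SimulationConfig(adverse_types=("No such population",))

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            SimulationConfig(nb_dispersion=0.0)

    def test_yaml_round_trip(self, tmp_path, tiny_config):
        path = tmp_path / "config.yaml"
        tiny_config.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == tiny_config


class TestSignature:
    def test_two_type_fold_structure(self):
        cfg = SimulationConfig(
            n_favorable=1, n_unfavorable=1, n_celltypes=2, n_markers_per_type=1,
            n_housekeeping=3, total_genes=5, celltype_names=("A", "B"),
            adverse_types=("B",), marker_fold=8.0, baseline_expression=10.0,
            adverse_pathways=())
        sig = make_signature_matrix(cfg)
        markers = cfg.layout().markers
        np.testing.assert_allclose(sig.values.loc[markers["A"][0]], [80.0, 10.0])
        np.testing.assert_allclose(sig.values.loc[markers["B"][0]], [10.0, 80.0])

    def test_default_panel_has_800_genes(self):
        sig = make_signature_matrix(SimulationConfig())
        assert sig.values.shape == (800, 13)

    def test_housekeeping_flat_across_types(self):
        cfg = SimulationConfig()
        sig = make_signature_matrix(cfg)
        hk = sig.values.loc[list(cfg.layout().housekeeping)]
        assert (hk.nunique(axis=1) == 1).all()

    def test_deterministic_given_seed(self):
        a = make_signature_matrix(SimulationConfig(seed=5))
        b = make_signature_matrix(SimulationConfig(seed=5))
        pd.testing.assert_frame_equal(a.values, b.values)


class TestFractions:
    def test_columns_on_simplex(self, tiny_config):
        fr = simulate_fractions(tiny_config, tiny_config.labels())
        f = fr.fractions.to_numpy()
        assert (f >= 0).all()
        np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-9)

    def test_dirichlet_mean_of_shifted_type(self):
        """delta=9 on Dirichlet(1,1): shifted-type mean is 9/10."""
        cfg = SimulationConfig(
            n_favorable=0, n_unfavorable=10_000, n_celltypes=2,
            n_markers_per_type=1, n_housekeeping=3, total_genes=5,
            celltype_names=("t1", "t2"), dirichlet_base=(1.0, 1.0),
            adverse_types=("t2",), adverse_shift=9.0, adverse_pathways=(), seed=0)
        fr = simulate_fractions(cfg, cfg.labels())
        mean_t2 = fr.fractions.loc["t2"].mean()
        assert mean_t2 == pytest.approx(0.9, abs=0.01)

    def test_no_shift_makes_groups_exchangeable(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, adverse_shift=1.0,
                                  n_favorable=300, n_unfavorable=300)
        fr = simulate_fractions(cfg, cfg.labels())
        labels = cfg.labels()
        adverse = fr.fractions.loc["Type B"].to_numpy()
        p = ks_2samp(adverse[labels == "F"], adverse[labels == "U"]).pvalue
        assert p > 0.01

    def test_label_length_mismatch_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="labels length"):
            simulate_fractions(tiny_config, np.array(["F", "U"]))

    def test_adverse_shift_monotone_in_group_difference(self, tiny_config):
        diffs = []
        for delta in (1.0, 2.0, 4.0, 8.0):
            cfg = dataclasses.replace(tiny_config, adverse_shift=delta,
                                      n_favorable=200, n_unfavorable=200)
            fr = simulate_fractions(cfg, cfg.labels())
            labels = cfg.labels()
            b = fr.fractions.loc["Type B"].to_numpy()
            diffs.append(b[labels == "U"].mean() - b[labels == "F"].mean())
        assert all(b > a for a, b in zip(diffs, diffs[1:]))


class TestExpression:
    def test_pure_mixture_proportional_to_signature_column(self, tiny_config):
        sig = make_signature_matrix(tiny_config)
        n = tiny_config.n_samples
        f = pd.DataFrame(0.0, index=sig.values.columns,
                         columns=tiny_config.sample_ids())
        f.loc["Type B"] = 1.0
        from hltme.containers import FractionMatrix
        cfg = dataclasses.replace(tiny_config, nb_dispersion=1e-12,
                                  library_size_logsd=0.0, baseline_expression=5000.0)
        sig = make_signature_matrix(cfg)
        f = pd.DataFrame(0.0, index=sig.values.columns, columns=cfg.sample_ids())
        f.loc["Type B"] = 1.0
        expr = simulate_expression(sig, FractionMatrix(fractions=f), cfg)
        expected = sig.values["Type B"].to_numpy()
        for col in expr.sample_ids:
            np.testing.assert_allclose(expr.values[col], expected, rtol=0.1)

    def test_mean_over_replicates_matches_mixture(self):
        """Law of large numbers: replicate-mean counts approach S @ f."""
        cfg = SimulationConfig(
            n_favorable=2000, n_unfavorable=0, n_celltypes=2, n_markers_per_type=2,
            n_housekeeping=3, total_genes=10, celltype_names=("A", "B"),
            adverse_types=(), adverse_pathways=(), library_size_logsd=0.0,
            baseline_expression=50.0, seed=3)
        sig = make_signature_matrix(cfg)
        from hltme.containers import FractionMatrix
        f_col = np.array([0.25, 0.75])
        f = pd.DataFrame(np.tile(f_col[:, None], 2000), index=sig.values.columns,
                         columns=cfg.sample_ids())
        expr = simulate_expression(sig, FractionMatrix(fractions=f), cfg)
        expected = sig.values.to_numpy() @ f_col
        observed = expr.values.mean(axis=1).to_numpy()
        np.testing.assert_allclose(observed, expected, rtol=0.02)

    def test_dimension_mismatch_rejected(self, tiny_config):
        sig = make_signature_matrix(tiny_config)
        from hltme.containers import FractionMatrix
        f = pd.DataFrame([[0.5], [0.25], [0.25]], index=["A", "B", "C"],
                         columns=["S001"])
        with pytest.raises(ValueError, match="cell types"):
            simulate_expression(sig, FractionMatrix(fractions=f), tiny_config)


class TestSurvival:
    def test_all_unfavorable_progress_within_window(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_favorable=0, n_unfavorable=50)
        clin = simulate_survival(cfg.labels(), cfg, np.zeros(50))
        assert (clin.table["pfs_months"] <= 24.0).all()
        assert (clin.table["event"] == 1).all()

    def test_all_favorable_exceed_window(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_favorable=50, n_unfavorable=0)
        clin = simulate_survival(cfg.labels(), cfg, np.zeros(50))
        assert (clin.table["pfs_months"] > 24.0).all()
        assert (clin.table["outcome"] == "F").all()

    def test_zero_beta_makes_times_score_independent(self, tiny_config):
        """With beta=0 the within-group time distribution ignores the score."""
        cfg = dataclasses.replace(tiny_config, n_favorable=0, n_unfavorable=2000,
                                  log_hazard_per_sd=0.0)
        rng = np.random.default_rng(0)
        score = rng.normal(size=2000)
        clin = simulate_survival(cfg.labels(), cfg, score)
        t = clin.table["pfs_months"].to_numpy()
        hi, lo = t[score > 0], t[score <= 0]
        assert ks_2samp(hi, lo).pvalue > 0.01

    def test_positive_beta_accelerates_high_score_progression(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_favorable=0, n_unfavorable=2000,
                                  log_hazard_per_sd=1.0)
        rng = np.random.default_rng(0)
        score = rng.normal(size=2000)
        t = simulate_survival(cfg.labels(), cfg, score).table["pfs_months"].to_numpy()
        assert t[score > 1].mean() < t[score < -1].mean()

    def test_non_finite_scores_rejected(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, n_favorable=0, n_unfavorable=3)
        with pytest.raises(ValueError, match="finite"):
            simulate_survival(cfg.labels(), cfg, np.array([0.0, np.inf, 1.0]))

    def test_hazard_first_mode_derives_labels_from_times(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, survival_mode="hazard_first",
                                  n_favorable=0, n_unfavorable=200)
        clin = simulate_survival(np.array(["U"] * 200), cfg, np.zeros(200))
        t = clin.table
        derived_f = t["pfs_months"] > 24.0
        assert (t.loc[derived_f, "outcome"] == "F").all()
        assert (t.loc[~derived_f, "outcome"] == "U").all()


class TestGenerateCohort:
    def test_discovery_preset_counts(self, discovery_cohort):
        assert discovery_cohort.expression.n_samples == 25
        assert (discovery_cohort.clinical.table["outcome"] == "U").sum() == 14
        assert discovery_cohort.expression.n_genes == 800

    def test_validation_preset_size(self):
        cfg = validation_config(seed=2)
        assert cfg.n_samples == 103

    def test_counts_are_nonnegative_integers(self, discovery_cohort):
        v = discovery_cohort.expression.values.to_numpy()
        assert (v >= 0).all()
        np.testing.assert_array_equal(v, np.round(v))

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = discovery_config(seed=9)
        for sub in ("a", "b"):
            generate_cohort(cfg).write(tmp_path / sub)
        for name in ("expression.tsv", "true_fractions.tsv", "clinical.csv",
                      "signature.tsv", "simulation_config.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(discovery_config(seed=1))
        b = generate_cohort(discovery_config(seed=2))
        assert not a.expression.values.equals(b.expression.values)


class TestCatalog:
    def test_default_catalog_counts(self):
        cfg = SimulationConfig()
        cat = default_catalog(cfg)
        descriptions = [s.description for s in cat]
        assert descriptions.count("cell population") == 89
        assert descriptions.count("signaling pathway") >= 18

    def test_model_variable_list(self):
        variables = default_model_variables()
        assert len(variables) == 31
        for named in ("ROBO pathway", "VEGF pathway", "DAP12 pathway",
                      "M2-like macrophages", "Myeloid dendritic cells",
                      "Stromal cells"):
            assert named in variables

    def test_catalog_sets_resolve_in_panel(self):
        cfg = SimulationConfig()
        panel = set(cfg.layout().all_genes)
        cat = default_catalog(cfg)
        for s in cat:
            assert set(s.genes) <= panel

    def test_small_panel_gets_no_pathway_blocks(self):
        layout = build_panel_layout(["A", "B"], 2, 3, 10)
        assert layout.pathway_genes == {}
        assert len(layout.all_genes) == 10

    def test_catalog_deterministic(self):
        cfg = SimulationConfig(seed=4)
        a, b = default_catalog(cfg), default_catalog(cfg)
        assert [s.genes for s in a] == [s.genes for s in b]
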