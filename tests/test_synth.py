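"""Generator properties: determinism, planted structure, missingness, mixing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synaptomics import (
    ConfigurationError,
    SimulationConfig,
    fit_factorial_anova,
    impurity_correct,
    inject_missingness,
    mix_impurities,
    select_interaction,
    simulate_experiment,
    simulate_gene_sets,
)
from synaptomics.io import write_gmt
from synaptomics.quant import PurityMatrix


class TestSimulateExperiment:
    def test_dimensions_match_design(self):
        cfg = SimulationConfig(n_proteins=2554, n_per_group=4, seed=0,
                               spectra_per_protein=1.0)
        _, matrix, _, design = simulate_experiment(cfg)
        assert matrix.shape == (2554, 16)
        assert list(matrix.samples) == list(design.samples)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_proteins=120, seed=7, missing_rate=0.05)
        s1, m1, t1, _ = simulate_experiment(cfg)
        s2, m2, t2, _ = simulate_experiment(SimulationConfig(n_proteins=120, seed=7,
                                                             missing_rate=0.05))
        pd.testing.assert_frame_equal(m1.data, m2.data)
        pd.testing.assert_frame_equal(s1.intensities, s2.intensities)
        pd.testing.assert_series_equal(t1.rescue_direction, t2.rescue_direction)

    def test_global_null_flags_nothing(self):
        cfg = SimulationConfig(n_proteins=400, seed=3, frac_interaction=0.0,
                               frac_main_genotype=0.0, frac_main_treatment=0.0,
                               use_reference_names=False)
        _, matrix, truth, design = simulate_experiment(cfg)
        assert truth.interaction_true.sum() == 0
        stats_df = fit_factorial_anova(matrix, design)
        frac = len(select_interaction(stats_df, 0.05)) / len(stats_df)
        # binomial 99% interval around 0.05 for 400 trials
        lo, hi = stats.binom.ppf([0.005, 0.995], 400, 0.05) / 400
        assert lo <= frac <= hi

    def test_rescue_directions_split_and_realized(self):
        cfg = SimulationConfig(n_proteins=1000, seed=5, frac_interaction=0.2,
                               use_reference_names=False)
        _, matrix, truth, design = simulate_experiment(cfg)
        dirs = truth.rescue_direction[truth.interaction_true]
        frac_down = (dirs == "down").mean()
        assert 0.35 < frac_down < 0.65
        # planted cell means: TW shifted by ±delta, TF back at baseline
        # (restrict to proteins without composed main effects)
        cm = truth.cell_means
        pure = truth.interaction_true & ~truth.main_genotype_true & ~truth.main_treatment_true
        down = dirs.index[(dirs == "down") & pure[dirs.index]]
        assert len(down) > 20
        assert np.allclose(cm.loc[down, "EW"] - cm.loc[down, "TW"], 1.0)
        assert np.allclose(cm.loc[down, "TF"], cm.loc[down, "EW"])

    def test_empirical_cell_means_track_truth(self):
        cfg = SimulationConfig(n_proteins=500, seed=9, use_reference_names=False)
        _, matrix, truth, design = simulate_experiment(cfg)
        tw = list(design.samples_in("TW"))
        emp = matrix.data[tw].mean(axis=1)
        tol = 3 * cfg.sigma_log2 / np.sqrt(cfg.n_per_group)
        frac_within = (np.abs(emp - truth.cell_means["TW"]) <= tol).mean()
        assert frac_within >= 0.99

    def test_spectrum_medians_track_matrix(self):
        cfg = SimulationConfig(n_proteins=60, seed=13, spectra_per_protein=8.0,
                               frac_shared_spectra=0.0, use_reference_names=False)
        spectra, matrix, _, design = simulate_experiment(cfg)
        first = matrix.proteins[0]
        rows = spectra.protein_ids.map(lambda ids: ids[0] == first)
        sample0 = spectra.channels[0]
        med = np.median(np.log2(spectra.intensities.loc[rows.to_numpy(), sample0]))
        # median of spectrum offsets concentrates near 0
        assert abs(med - matrix.data.loc[first].iloc[0]) < 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(frac_interaction=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(missing_rate=1.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_per_group=1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(sigma_log2=np.inf)

    def test_reference_names_present(self):
        cfg = SimulationConfig(n_proteins=2000, seed=21)
        _, matrix, truth, _ = simulate_experiment(cfg)
        from synaptomics.io import default_markers
        assert all(m in matrix.proteins for m in default_markers())


class TestMixImpurities:
    def test_identity_purity_is_noop(self, small_experiment):
        spectra = small_experiment["spectra"]
        purity = PurityMatrix.identity(spectra.channels)
        mixed = mix_impurities(spectra, purity)
        pd.testing.assert_frame_equal(mixed.intensities, spectra.intensities)

    def test_two_channel_leak_by_hand(self):
        import synaptomics.containers as c

        table = pd.DataFrame({"ch1": [100.0, 0.0], "ch2": [0.0, 50.0]},
                             index=["s1", "s2"]).T
        spectra = c.SpectrumTable(
            pd.DataFrame([[100.0, 0.0], [0.0, 50.0]], index=["s1", "s2"],
                         columns=["ch1", "ch2"]),
            pd.Series([("A",), ("B",)], index=["s1", "s2"]),
            {"ch1": "x1", "ch2": "x2"},
        )
        purity = PurityMatrix(["ch1", "ch2"], np.array([[0.9, 0.0], [0.1, 1.0]]))
        mixed = mix_impurities(spectra, purity)
        # 10% of channel 1 leaks into channel 2: (100, 0) -> (90, 10)
        assert mixed.intensities.loc["s1"].tolist() == [90.0, 10.0]

    def test_mix_correct_round_trip(self, small_experiment, rng):
        spectra = small_experiment["spectra"]
        k = len(spectra.channels)
        base = np.eye(k) * 0.9
        for i in range(k - 1):
            base[i + 1, i] = 0.06
            base[i, i + 1] = 0.04
        purity = PurityMatrix(list(spectra.channels), base)
        mixed = mix_impurities(spectra, purity)
        recovered, _ = impurity_correct(mixed, purity)
        err = np.nanmax(
            np.abs(recovered.intensities.to_numpy() - spectra.intensities.to_numpy())
        )
        assert err < 1e-10 * max(1.0, np.nanmax(spectra.intensities.to_numpy()))


class TestGeneSets:
    def test_null_collection_uniform_and_deterministic(self, small_experiment, tmp_path):
        truth = small_experiment["truth"]
        c1 = simulate_gene_sets(truth, n_sets=10, size_range=(5, 20), seed=3)
        c2 = simulate_gene_sets(truth, n_sets=10, size_range=(5, 20), seed=3)
        assert c1.sets == c2.sets
        write_gmt(c1, tmp_path / "a.gmt")
        write_gmt(c2, tmp_path / "b.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_planted_set_oversamples_single_direction(self, small_experiment):
        truth = small_experiment["truth"]
        coll = simulate_gene_sets(
            truth, n_sets=5, size_range=(10, 10),
            enrichment_spec={"HOT": "interaction_true"}, seed=1,
        )
        members = coll.sets["HOT"]
        flagged = [m for m in members if truth.interaction_true.get(m, False)]
        assert len(flagged) >= 8  # 90% purity at size 10
        dirs = {truth.rescue_direction[m] for m in flagged}
        assert len(dirs) == 1  # direction-coherent

    def test_size_range_validation(self, small_experiment):
        with pytest.raises(ConfigurationError):
            simulate_gene_sets(small_experiment["truth"], n_sets=3,
                               size_range=(1, 10), seed=0)
        with pytest.raises(ConfigurationError):
            simulate_gene_sets(small_experiment["truth"], n_sets=3,
                               size_range=(10, 10_000), seed=0)


class TestInjectMissingness:
    def test_rate_zero_noop(self, small_experiment):
        m = small_experiment["matrix"]
        out = inject_missingness(m, 0.0, seed=0)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_rate_within_binomial_bounds(self, balanced_design, rng):
        from conftest import make_matrix

        m = make_matrix(rng.normal(10, 1, (2554, 16)), balanced_design)
        out = inject_missingness(m, 0.1, seed=5)
        n_missing = int(out.data.isna().sum().sum())
        n_cells = 2554 * 16
        lo, hi = stats.binom.ppf([0.005, 0.995], n_cells, 0.1)
        assert lo <= n_missing <= hi

    def test_mask_deterministic(self, small_experiment):
        m = small_experiment["matrix"]
        a = inject_missingness(m, 0.2, seed=11)
        b = inject_missingness(m, 0.2, seed=11)
        assert (a.data.isna() == b.data.isna()).all().all()

    def test_mnar_prefers_dim_cells(self, balanced_design, rng):
        from conftest import make_matrix

        vals = np.sort(rng.normal(10, 2, (4000, 16)), axis=None).reshape(4000, 16)
        m = make_matrix(vals, balanced_design)
        out = inject_missingness(m, 0.2, seed=2, mnar=True)
        mask = out.data.isna().to_numpy()
        dim_rate = mask[:2000].mean()
        bright_rate = mask[2000:].mean()
        assert dim_rate > bright_rate

    def test_rate_one_rejected(self, small_experiment):
        with pytest.raises(ConfigurationError):
            inject_missingness(small_experiment["matrix"], 1.0, seed=0)
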