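import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refstab.exceptions import DataError
from refstab.io import aggregate_replicates
from refstab.genorm import pairwise_stability_m, stepwise_exclusion
from refstab.normfinder import rank_by_stability, stability_single_group
from refstab.simulate import (
    STUDY_ASSAYS,
    STUDY_PANELS,
    SimConfig,
    study_design,
    simulate_cq,
    spike_target,
)
from refstab.transform import log_quantities, relative_quantities


class TestSimulateCq:
    def test_noiseless_limit_constant_per_gene_and_zero_m(self):
        cfg = SimConfig(
            n_genes=4, n_samples=6, sample_effect_sd=0.0,
            gene_noise_sd=0.0, replicate_sd=0.0, seed=0,
        )
        ds, _ = simulate_cq(cfg)
        m = aggregate_replicates(ds)
        assert (m.cq.nunique(axis=1) == 1).all()
        qm = relative_quantities(m)
        np.testing.assert_allclose(pairwise_stability_m(qm), 0.0, atol=1e-12)

    def test_same_seed_identical_datasets(self):
        cfg = SimConfig(n_genes=5, n_samples=8, seed=123)
        ds1, t1 = simulate_cq(cfg)
        ds2, t2 = simulate_cq(SimConfig(n_genes=5, n_samples=8, seed=123))
        pd.testing.assert_frame_equal(ds1.records, ds2.records)
        pd.testing.assert_series_equal(t1.sample_effects, t2.sample_effects)

    def test_different_seed_differs(self):
        ds1, _ = simulate_cq(SimConfig(n_genes=3, n_samples=4, seed=1))
        ds2, _ = simulate_cq(SimConfig(n_genes=3, n_samples=4, seed=2))
        assert not ds1.records["cq"].equals(ds2.records["cq"])

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(DataError):
            simulate_cq(SimConfig(n_genes=0, n_samples=5))
        with pytest.raises(DataError):
            simulate_cq(SimConfig(n_genes=3, n_samples=3, gene_noise_sd=[0.1, 0.2]))
        with pytest.raises(DataError):
            simulate_cq(SimConfig(n_genes=3, n_samples=3, sample_effect_sd=-1.0))

    def test_empirical_cq_sd_matches_configured_components(self):
        # aggregated Cq variance = sample_effect^2 + gene_noise^2 + rep^2/r
        cfg = SimConfig(
            n_genes=3, n_samples=4000, n_tech_replicates=3,
            sample_effect_sd=0.5, gene_noise_sd=0.3, replicate_sd=0.15, seed=9,
        )
        ds, _ = simulate_cq(cfg)
        m = aggregate_replicates(ds)
        expected = np.sqrt(0.5**2 + 0.3**2 + 0.15**2 / 3)
        observed = m.cq.std(axis=1, ddof=1)
        np.testing.assert_allclose(observed, expected, rtol=0.06)

    def test_truth_order_sorted_by_noise(self):
        cfg = SimConfig(
            n_genes=4, n_samples=5, gene_noise_sd=[0.4, 0.1, 0.3, 0.2], seed=0
        )
        _, truth = simulate_cq(cfg)
        assert truth.true_order == ["G02", "G04", "G03", "G01"]

    def test_sample_effect_magnitude_does_not_change_rankings(self):
        # shared loading cancels in both algorithms' statistics
        sds = np.linspace(0.05, 0.6, 6)
        agreements = 0
        n_runs = 30
        for i in range(n_runs):
            rankings = []
            for se_sd in (0.4, 0.8):
                cfg = SimConfig(
                    n_genes=6, n_samples=30, n_tech_replicates=1,
                    gene_noise_sd=sds, sample_effect_sd=se_sd,
                    replicate_sd=0.0, seed=4000 + i,
                )
                ds, _ = simulate_cq(cfg)
                qm = relative_quantities(aggregate_replicates(ds))
                rankings.append(stepwise_exclusion(qm).ranking)
            agreements += rankings[0] == rankings[1]
        # same gene-noise draws, only the cancelling loading differs
        assert agreements == n_runs

    def test_truth_order_correlates_with_estimates(self):
        sds = np.linspace(0.05, 0.6, 12)
        rhos = []
        for i in range(20):
            cfg = SimConfig(
                n_genes=12, n_samples=50, n_tech_replicates=1,
                gene_noise_sd=sds, replicate_sd=0.0, seed=6000 + i,
            )
            ds, truth = simulate_cq(cfg)
            qm = relative_quantities(aggregate_replicates(ds))
            ranking = stepwise_exclusion(qm).ranking
            rhos.append(
                stats.spearmanr(
                    [truth.true_order.index(g) for g in qm.genes],
                    [ranking.index(g) for g in qm.genes],
                ).statistic
            )
        assert np.mean(rhos) >= 0.8


class TestSpikeTarget:
    CONDITIONS = ["c0"] * 4 + ["c1"] * 4

    def cfg(self, seed=0, **kw):
        base = dict(
            n_genes=4, n_samples=8, gene_noise_sd=0.05,
            group_labels=self.CONDITIONS, replicate_sd=0.0,
            sample_effect_sd=0.3, seed=seed,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_fold_one_behaves_like_ordinary_gene(self):
        ds, truth = spike_target(
            self.cfg(), {"c0": 1.0, "c1": 1.0}, target_noise_sd=0.05
        )
        m = aggregate_replicates(ds)
        # remove the shared loading, then the target is flat across conditions
        centered = m.cq.loc["DlACO"] - truth.sample_effects
        by_cond = centered.groupby(m.meta["group"]).mean()
        assert abs(by_cond["c1"] - by_cond["c0"]) < 0.1

    def test_fold_four_at_perfect_efficiency_shifts_two_cycles(self):
        ds, truth = spike_target(
            self.cfg(), {"c0": 1.0, "c1": 4.0},
            target_efficiency=2.0, target_noise_sd=0.0,
        )
        m = aggregate_replicates(ds)
        centered = m.cq.loc["DlACO"] - truth.sample_effects
        by_cond = centered.groupby(m.meta["group"]).mean()
        assert by_cond["c1"] - by_cond["c0"] == pytest.approx(-2.0, abs=1e-9)

    def test_positive_fold_required(self):
        with pytest.raises(DataError, match="positive"):
            spike_target(self.cfg(), {"c0": 1.0, "c1": -2.0})

    def test_every_condition_needs_a_fold(self):
        with pytest.raises(DataError, match="missing condition"):
            spike_target(self.cfg(), {"c0": 1.0})


class TestPaperDesign:
    def test_total_samples_is_150(self, study_dataset):
        ds, _ = study_dataset
        assert len(ds.meta) == 150
        assert ds.records["sample_id"].nunique() == 150
        assert len(ds) == 12 * 150 * 3

    def test_set_partition_matches_design(self, study_dataset):
        ds, _ = study_dataset
        counts = ds.meta["experimental_set"].value_counts()
        assert counts["different_varieties"] == 36
        assert counts["developmental_stages"] == 36
        assert counts["different_organs"] == 18
        for s in ("NAA", "2,4-D", "ethephon", "bagging"):
            assert counts[s] == 9
        assert counts["temperature"] == 12
        assert counts["girdling_defoliation"] == 12

    def test_panel_definitions_cover_13_analyses(self, study_matrix):
        from refstab.io import subset_by_experiment

        assert len(STUDY_PANELS) == 13
        sizes = {
            name: subset_by_experiment(study_matrix, sel).n_samples
            for name, sel in STUDY_PANELS
        }
        assert sizes["varieties_pericarp"] == 18
        assert sizes["different_organs"] == 18
        assert sizes["NAA"] == 9
        assert sizes["cold_4C"] == 6
        assert sizes["girdling_fruitlets"] == 6

    def test_assays_attached_with_measured_efficiencies(self, study_dataset):
        ds, _ = study_dataset
        assert ds.assays is not None
        assert ds.assays.loc["CYP", "efficiency"] == 2.072
        assert ds.assays.loc["RPL", "efficiency"] == 1.914
        assert ((ds.assays["efficiency"] > 1.9) & (ds.assays["efficiency"] < 2.1)).all()

    def test_cq_within_plausible_qpcr_range(self, study_dataset):
        ds, _ = study_dataset
        assert ds.records["cq"].between(11, 35).all()

    def test_truth_roundtrip_json(self, study_dataset, tmp_path):
        import json

        _, truth = study_dataset
        truth.to_json(tmp_path / "truth.json")
        loaded = json.loads((tmp_path / "truth.json").read_text())
        assert loaded["config"]["seed"] == truth.config.seed
        assert loaded["true_order"] == truth.true_order
        assert len(loaded["sample_effects"]) == 150
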