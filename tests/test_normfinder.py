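import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refstab.exceptions import DataError
from refstab.normfinder import (
    rank_by_stability,
    stability_from_cq,
    stability_single_group,
    stability_with_groups,
)
from refstab.results import NormfinderResult


def two_way_sample(rng, g, n, sigmas, alpha_sd=2.0, beta_sd=1.0):
    """Draw from the additive model y_ij = alpha_i + beta_j + eps_ij."""
    alpha = rng.normal(0, alpha_sd, size=(g, 1))
    beta = rng.normal(0, beta_sd, size=(1, n))
    eps = rng.normal(0, 1.0, size=(g, n)) * np.asarray(sigmas)[:, None]
    y = alpha + beta + eps
    genes = [f"G{i+1:02d}" for i in range(g)]
    samples = [f"S{j+1:03d}" for j in range(n)]
    return pd.DataFrame(y, index=genes, columns=samples)


class TestSingleGroup:
    def test_zero_residual_gene_has_zero_stability_and_ranks_first(self):
        rng = np.random.default_rng(0)
        y = two_way_sample(rng, 5, 20, [0.3, 0.3, 0.3, 0.3, 0.3])
        # a gene equal to the mean pattern of the others has zero fitted
        # residuals, hence a clipped variance estimate and rho = 0
        y.loc["G01"] = y.drop(index="G01").mean(axis=0)
        res = stability_single_group(y)
        assert res.stability["G01"] == pytest.approx(0.0, abs=1e-9)
        assert rank_by_stability(res)[0] == "G01"

    def test_fewer_than_three_genes_rejected(self):
        y = two_way_sample(np.random.default_rng(1), 2, 10, [0.2, 0.2])
        with pytest.raises(DataError, match="3 genes"):
            stability_single_group(y)

    def test_invariant_to_sample_and_gene_constants(self):
        rng = np.random.default_rng(2)
        y = two_way_sample(rng, 6, 15, np.linspace(0.1, 0.6, 6))
        base = stability_single_group(y).stability
        shifted = y + rng.normal(0, 3, size=(1, 15))  # per-sample loading
        shifted = shifted + rng.normal(0, 3, size=(6, 1))  # per-gene abundance
        np.testing.assert_allclose(
            stability_single_group(shifted).stability, base, atol=1e-10
        )

    def test_variance_never_negative(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = two_way_sample(rng, 4, 5, [0.05, 0.05, 0.05, 0.05])
            res = stability_single_group(y)
            assert (res.variance >= 0).all()

    def test_variance_estimator_approximately_unbiased(self):
        # Monte-Carlo oracle: the variance estimate is unbiased, so the
        # root of its replicate average recovers each true sigma
        sigmas = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        rng = np.random.default_rng(3)
        var = np.zeros(6)
        n_rep = 60
        for _ in range(n_rep):
            y = two_way_sample(rng, 6, 200, sigmas)
            var += stability_single_group(y).variance.to_numpy()
        np.testing.assert_allclose(np.sqrt(var / n_rep), sigmas, rtol=0.10)

    def test_stability_decreases_with_noise(self):
        sigmas = np.linspace(0.1, 0.8, 6)
        rng = np.random.default_rng(4)
        est = np.zeros(6)
        for _ in range(40):
            y = two_way_sample(rng, 6, 100, sigmas)
            est += stability_single_group(y).stability.to_numpy()
        assert (np.diff(est) > 0).all()

    def test_neg_cq_path_gives_identical_ranking(self):
        rng = np.random.default_rng(5)
        cq = pd.DataFrame(
            rng.uniform(15, 30, size=(5, 12)),
            index=[f"G{i}" for i in range(5)],
        )
        from refstab.io import CqMatrix
        from refstab.transform import log_quantities, relative_quantities

        qm = relative_quantities(CqMatrix(cq=cq))
        via_q = stability_single_group(log_quantities(qm))
        via_cq = stability_from_cq(cq)
        np.testing.assert_allclose(via_cq.stability, via_q.stability, atol=1e-10)
        assert rank_by_stability(via_cq) == rank_by_stability(via_q)


class TestGrouped:
    @staticmethod
    def grouped_sample(rng, g, n_g, sigmas, shift_gene=None, shift=0.0):
        # gene abundances (alpha) are a property of the assay and must be
        # shared across groups; loadings and noise are drawn per group
        alpha = rng.normal(0, 2.0, size=(g, 1))
        y1 = two_way_sample(rng, g, n_g, sigmas, alpha_sd=0.0) + alpha
        y2 = two_way_sample(rng, g, n_g, sigmas, alpha_sd=0.0) + alpha
        y2.columns = [f"T{j+1:03d}" for j in range(n_g)]
        if shift_gene is not None:
            y2.loc[shift_gene] += shift
        y = pd.concat([y1, y2], axis=1)
        groups = pd.Series(
            ["A"] * n_g + ["B"] * n_g, index=y.columns
        )
        return y, groups

    def test_zero_residuals_give_zero_everything(self):
        g, n = 4, 6
        alpha = np.arange(g)[:, None].astype(float)
        beta = np.linspace(0, 2, 2 * n)[None, :]
        y = pd.DataFrame(
            alpha + beta,
            index=[f"G{i}" for i in range(g)],
            columns=[f"S{j}" for j in range(2 * n)],
        )
        groups = pd.Series(["A"] * n + ["B"] * n, index=y.columns)
        res = stability_with_groups(y, groups)
        np.testing.assert_allclose(res.stability, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.group_bias.to_numpy(), 0.0, atol=1e-10)

    def test_group_with_single_sample_rejected(self):
        rng = np.random.default_rng(6)
        y = two_way_sample(rng, 4, 5, [0.2] * 4)
        groups = pd.Series(["A", "A", "A", "A", "B"], index=y.columns)
        with pytest.raises(DataError, match=">= 2"):
            stability_with_groups(y, groups)

    def test_unlabeled_sample_rejected(self):
        rng = np.random.default_rng(7)
        y = two_way_sample(rng, 4, 4, [0.2] * 4)
        with pytest.raises(DataError, match="group label"):
            stability_with_groups(y, {"S001": "A", "S002": "A"})

    def test_spiked_between_group_gene_is_least_stable(self):
        sigmas = [0.2] * 6
        hits = 0
        n_runs = 50
        for i in range(n_runs):
            rng = np.random.default_rng(900 + i)
            y, groups = self.grouped_sample(
                rng, 6, 20, sigmas, shift_gene="G03", shift=1.0
            )
            res = stability_with_groups(y, groups)
            hits += res.stability.idxmax() == "G03"
        assert hits / n_runs >= 0.95

    def test_identical_groups_concord_with_pooled_ranking(self):
        # no true group shift: grouped and single-group orderings agree
        sigmas = np.linspace(0.1, 0.7, 6)
        agree = 0
        n_runs = 100
        for i in range(n_runs):
            rng = np.random.default_rng(2000 + i)
            y, groups = self.grouped_sample(rng, 6, 25, sigmas)
            grouped_rank = rank_by_stability(stability_with_groups(y, groups))
            pooled_rank = rank_by_stability(stability_single_group(y))
            rho = stats.spearmanr(
                [grouped_rank.index(g) for g in y.index],
                [pooled_rank.index(g) for g in y.index],
            ).statistic
            agree += rho >= 0.8
        assert agree / n_runs >= 0.90


class TestRanking:
    def test_ascending_order(self):
        res = NormfinderResult(
            stability=pd.Series({"A": 0.2, "B": 0.1, "C": 0.3}),
            variance=pd.Series({"A": 0.04, "B": 0.01, "C": 0.09}),
        )
        assert rank_by_stability(res) == ["B", "A", "C"]

    def test_tie_broken_by_gene_ordering(self):
        res = NormfinderResult(
            stability=pd.Series({"B": 0.2, "A": 0.2, "C": 0.1}),
            variance=pd.Series({"B": 0.04, "A": 0.04, "C": 0.01}),
        )
        assert rank_by_stability(res) == ["C", "B", "A"]

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(8)
        y = two_way_sample(rng, 7, 10, np.linspace(0.1, 0.7, 7))
        res = stability_single_group(y)
        assert sorted(rank_by_stability(res)) == sorted(y.index)
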