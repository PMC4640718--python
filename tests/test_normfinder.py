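import numpy as np
import pandas as pd
import pytest

import refstab as rs
from refstab.normfinder import (
    estimate_intergroup_difference,
    estimate_intragroup_variance,
    log_and_center,
)
from refstab.simulate import GeneSpec, SyntheticSpec

from conftest import random_lognormal_expr


def grouped_spec(noise_sds, n_per_group, shifts=None, seed=0, loading_sd=0.5):
    shifts = shifts or {}
    genes = [
        GeneSpec(g, 20.0, sd, group_shifts=shifts.get(g, {})) for g, sd in noise_sds.items()
    ]
    samples = [(f"c{i}", "control") for i in range(n_per_group)] + [
        (f"h{i}", "heat") for i in range(n_per_group)
    ]
    return SyntheticSpec(genes=genes, samples=samples, loading_sd=loading_sd, seed=seed)


def quantities(spec):
    ct, truth = rs.generate_ct_dataset(spec)
    return rs.ct_to_relative_quantity(ct), truth


class TestLogAndCenter:
    def test_identical_genes_center_to_zero(self):
        values = pd.DataFrame(np.full((3, 4), 5.0), index=list("abc"), columns=list("wxyz"))
        z = log_and_center(rs.ExpressionMatrix(values))
        assert (z.to_numpy() == 0).all()

    def test_column_sums_vanish(self, rng):
        z = log_and_center(random_lognormal_expr(rng))
        np.testing.assert_allclose(z.sum(axis=0).to_numpy(), 0.0, atol=1e-12)

    def test_per_sample_loading_removed_exactly(self, rng):
        expr = random_lognormal_expr(rng)
        factors = 2.0 ** rng.normal(0, 5, size=len(expr.sample_ids))
        scaled = rs.ExpressionMatrix(expr.values * factors)
        np.testing.assert_allclose(
            log_and_center(expr).to_numpy(), log_and_center(scaled).to_numpy(), atol=1e-9
        )

    def test_requires_three_genes(self):
        values = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]], index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match=">=3 genes"):
            log_and_center(rs.ExpressionMatrix(values))


class TestIntragroupVariance:
    def test_moment_equation_hand_solution(self):
        """k=3 and naive variances all 0.1: total 0.45, each corrected to 0.15."""
        # build z rows with exact sample variance 0.1 within one group
        row = np.array([-1.0, 0.0, 1.0]) * np.sqrt(0.1 / 1.0)  # var (ddof=1) = 0.1
        # cyclic shifts: every row has variance 0.1 and columns still sum to 0
        z = pd.DataFrame([row, np.roll(row, 1), np.roll(row, 2)], index=list("abc"), columns=list("xyz"))
        v = z.to_numpy().var(axis=1, ddof=1)
        np.testing.assert_allclose(v, 0.1)
        groups = pd.Series("g", index=list("xyz"))
        sigma2 = estimate_intragroup_variance(z, groups)
        np.testing.assert_allclose(sigma2["g"].to_numpy(), 0.15, rtol=1e-12)
        assert sigma2["g"].sum() == pytest.approx(0.45)

    def test_constant_group_gives_zero(self):
        z = pd.DataFrame(np.zeros((3, 4)), index=list("abc"), columns=list("wxyz"))
        groups = pd.Series("g", index=list("wxyz"))
        assert (estimate_intragroup_variance(z, groups).to_numpy() == 0).all()

    def test_group_of_one_rejected(self):
        z = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("xyz"))
        groups = pd.Series({"x": "g1", "y": "g1", "z": "solo"})
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_intragroup_variance(z, groups)

    def test_recovers_planted_variances(self):
        """k=8 genes, n=200: corrected estimates land near the planted sigma^2."""
        sds = np.linspace(0.1, 0.8, 8)
        spec = SyntheticSpec(
            genes=[GeneSpec(f"g{i}", 20.0, sd) for i, sd in enumerate(sds)],
            samples=[(f"s{j}", "all") for j in range(200)],
            loading_sd=0.5,
            seed=11,
        )
        expr, _ = quantities(spec)
        z = log_and_center(expr)
        sigma2 = estimate_intragroup_variance(z, pd.Series("all", index=z.columns))["all"]
        rel_err = np.abs(sigma2.to_numpy() - sds**2) / sds**2
        assert np.median(rel_err) < 0.2


class TestIntergroupDifference:
    def test_identical_group_means_give_zero(self):
        z = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0], [0.5, -0.5, 0.5, -0.5], [-1.5, 1.5, -1.5, 1.5]],
            index=list("abc"),
            columns=["c1", "c2", "h1", "h2"],
        )
        groups = pd.Series({"c1": "c", "c2": "c", "h1": "h", "h2": "h"})
        d_tilde, d_hat, ungrouped = estimate_intergroup_difference(z, groups)
        assert not ungrouped
        np.testing.assert_allclose(d_hat.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(d_tilde.to_numpy(), 0.0, atol=1e-12)

    def test_single_group_flags_ungrouped(self, rng):
        z = log_and_center(random_lognormal_expr(rng))
        groups = pd.Series("all", index=z.columns)
        d_tilde, d_hat, ungrouped = estimate_intergroup_difference(z, groups)
        assert ungrouped
        assert (d_tilde.to_numpy() == 0).all()

    def test_sum_to_zero_and_shrinkage_bound(self):
        spec = grouped_spec(
            {"a": 0.1, "b": 0.1, "c": 0.1, "d": 0.1, "e": 0.1},
            n_per_group=30,
            shifts={"e": {"heat": 1.0}},
            seed=5,
        )
        expr, _ = quantities(spec)
        z = log_and_center(expr)
        d_tilde, d_hat, _ = estimate_intergroup_difference(z, expr.groups)
        np.testing.assert_allclose(d_hat.sum(axis=0).to_numpy(), 0.0, atol=1e-9)
        assert (d_tilde.abs().to_numpy() <= d_hat.abs().to_numpy() + 1e-15).all()

    def test_noise_dominated_differences_fully_shrunk(self):
        """With no planted shift and tiny groups, gamma^2 can hit 0 -> d = 0."""
        rng = np.random.default_rng(2)
        z = pd.DataFrame(rng.normal(0, 1.0, size=(3, 4)), index=list("abc"),
                         columns=["c1", "c2", "h1", "h2"])
        z -= z.mean(axis=0)
        groups = pd.Series({"c1": "c", "c2": "c", "h1": "h", "h2": "h"})
        d_tilde, d_hat, _ = estimate_intergroup_difference(z, groups)
        assert (d_tilde.abs().to_numpy() <= d_hat.abs().to_numpy() + 1e-15).all()


class TestStabilityValues:
    def test_ideal_gene_ranks_first(self):
        """A noise-free, shift-free gene among noisy (unshifted) companions wins.

        Companions with group shifts would reflect a ±shift/k artifact onto
        every gene through the per-sample centering, so the clean limit case
        needs shift-free companions.
        """
        spec = grouped_spec(
            {"ideal": 0.01, "b": 0.3, "c": 0.4, "d": 0.5},
            n_per_group=50,
            seed=7,
        )
        expr, _ = quantities(spec)
        result = rs.stability_values(expr)
        assert result.ranking.entries[0][0] == "ideal"
        assert not result.ungrouped

    def test_shifted_gene_ranks_worse_than_equal_noise_twin(self):
        spec = grouped_spec(
            {"twin": 0.2, "shifted": 0.2, "c": 0.3, "d": 0.4, "e": 0.5},
            n_per_group=50,
            shifts={"shifted": {"heat": 1.0}},
            seed=21,
        )
        expr, _ = quantities(spec)
        ranks = {g: r for g, _, r in rs.stability_values(expr).ranking.entries}
        assert ranks["shifted"] > ranks["twin"]

    def test_ungrouped_order_recovery(self):
        """Well-separated planted noise is recovered up to rare adjacent swaps.

        Ungrouped NormFinder ranks by corrected within-set variance; the two
        quietest genes (SD 0.05 vs 0.1) differ by less than the sampling noise
        of a variance at n=50, so exact full-order recovery is not expected —
        rank correlation and worst-gene identification are.
        """
        from scipy.stats import spearmanr

        sds = {"g0": 0.05, "g1": 0.1, "g2": 0.2, "g3": 0.4, "g4": 0.8}
        order = list(sds)
        good_rho = worst_found = 0
        for seed in range(100):
            spec = SyntheticSpec(
                genes=[GeneSpec(g, 20.0, sd) for g, sd in sds.items()],
                samples=[(f"s{j}", "all") for j in range(50)],
                loading_sd=0.5,
                seed=seed,
            )
            expr, truth = quantities(spec)
            ranking = rs.stability_values(expr).ranking
            est = {g: i for i, g in enumerate(ranking.ordered_genes)}
            rho = spearmanr([est[g] for g in order], range(len(order))).statistic
            good_rho += rho >= 0.9 - 1e-9
            worst_found += ranking.ordered_genes[-1] == "g4"
        assert good_rho >= 90
        assert worst_found >= 99

    def test_consistency_at_large_n(self):
        """Estimates approach the planted parameters as groups grow."""
        sds = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.15}
        spec = grouped_spec(sds, n_per_group=1000, shifts={"c": {"heat": 0.8}}, seed=13)
        expr, truth = quantities(spec)
        z = log_and_center(expr)
        sigma2 = estimate_intragroup_variance(z, expr.groups)
        for g, sd in sds.items():
            est = sigma2.loc[g].mean()
            assert est == pytest.approx(sd**2, rel=0.15)
        d_tilde, _, _ = estimate_intergroup_difference(z, expr.groups, sigma2)
        # planted Ct shift +0.8 on c in heat -> centered log2 truth:
        k = len(sds)
        centered = -0.8 * (1 - 1 / k)
        expected_heat = centered / 2  # two equal groups
        assert d_tilde.loc["c", "heat"] == pytest.approx(expected_heat, abs=0.05)

    def test_loading_invariance_of_stability(self, rng):
        spec = grouped_spec({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}, 20, seed=3)
        expr, _ = quantities(spec)
        factors = 2.0 ** rng.normal(0, 5, size=len(expr.sample_ids))
        scaled = rs.ExpressionMatrix(expr.values * factors, expr.groups)
        r0, r1 = rs.stability_values(expr), rs.stability_values(scaled)
        np.testing.assert_allclose(r0.stability.to_numpy(), r1.stability.to_numpy(), atol=1e-9)


class TestRankGenes:
    def test_published_style_ranking_table(self):
        values = {"UBQ5": 0.338, "Fb15": 0.423, "17S_rRNA": 0.456, "beta-TUB": 1.036}
        ranking = rs.rank_genes(values, method="normfinder", condition="long-term")
        assert ranking.entries[0] == ("UBQ5", 0.338, 1)
        assert ranking.entries[-1] == ("beta-TUB", 1.036, 4)

    def test_single_gene(self):
        assert rs.rank_genes({"only": 0.5}).entries == [("only", 0.5, 1)]

    def test_ties_share_lower_rank_lexicographic(self):
        ranking = rs.rank_genes({"b": 0.1, "a": 0.1, "c": 0.2})
        assert ranking.entries == [("a", 0.1, 1), ("b", 0.1, 1), ("c", 0.2, 3)]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rs.rank_genes({"a": np.nan})
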