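"""Spearman statistics, permutation p, interaction filtering, pair tables."""

import numpy as np
import pandas as pd
import pytest

import fibermir as fm
from fibermir.expression_matrix import InputError
from fibermir.integration import (
    DegenerateCorrelation,
    nearest_attainable_rho,
)
from fibermir.study_data import (
    CORRELATION_N,
    HOST_GENE_CORRELATIONS,
    TARGET_CORRELATIONS,
)
from fibermir.synthetic_data import Coupling


def rank_pearson_oracle(x, y):
    """Brute-force Spearman: Pearson on average ranks, from definitions."""

    def avg_ranks(v):
        v = list(v)
        return [
            1 + sum(u < w for u in v) + (sum(u == w for u in v) - 1) / 2.0 for w in v
        ]

    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def _coupled_matrices(seed, sign=1, noise_sd=0.1, n=10, phi=0.05, base=50.0):
    # a large stable background keeps the coupled pair a small share of
    # the library, so compositional rescaling does not distort its ranks
    rng = np.random.default_rng(seed)
    feats = ["miR-A", "GENE-H"] + [f"bg{i}" for i in range(100)]
    levels = np.concatenate([[base, base], rng.lognormal(7, 0.5, 100)])
    design = fm.SimulationDesign(
        feature_ids=feats,
        e_slow=levels,
        e_fast=levels,
        slow_fractions=rng.uniform(0.2, 0.8, n),
        groups=["type1"] * (n // 2) + ["type2"] * (n - n // 2),
        library_sizes=np.full(n, 10_000_000),
        dispersions=phi,
        seed=seed,
        couplings=[Coupling("miR-A", "GENE-H", sign=sign, noise_sd=noise_sd)],
    )
    counts, _ = fm.sim_mixture_counts(design)
    mirna = counts.loc[["miR-A"]].astype(float)
    genes = counts.drop(index="miR-A").astype(float)
    return mirna, genes


class TestSpearman:
    def test_identity(self):
        assert fm.spearman(np.arange(1, 11), np.arange(1, 11)) == 1.0

    def test_reversal(self):
        assert fm.spearman([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_ties_match_rank_pearson_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            assert fm.spearman(x, y) == pytest.approx(
                rank_pearson_oracle(x, y), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert fm.spearman(x, y) == pytest.approx(fm.spearman(y, x), abs=1e-15)

    def test_joint_sample_permutation_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        assert fm.spearman(x[perm], y[perm]) == pytest.approx(
            fm.spearman(x, y), abs=1e-12
        )

    def test_degenerate_rank_variance_flagged(self):
        with pytest.raises(DegenerateCorrelation):
            fm.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestTApproxP:
    def test_zero_rho(self):
        assert fm.t_approx_p(0.0, 10) == 1.0

    def test_perfect_correlation_limit(self):
        assert fm.t_approx_p(1.0, 10) == 0.0
        assert fm.t_approx_p(-1.0, 10) == 0.0

    def test_monotone_in_abs_rho(self):
        rhos = np.linspace(0, 0.99, 40)
        ps = [fm.t_approx_p(r, 10) for r in rhos]
        assert np.all(np.diff(ps) < 0)

    @pytest.mark.parametrize(
        "rho,printed",
        [(0.903, "0.00034"), (-0.842, "0.00222"), (0.564, "0.090"), (0.442, "0.200")],
    )
    def test_reported_study_pvalues(self, rho, printed):
        exact = nearest_attainable_rho(rho, CORRELATION_N)
        decimals = len(printed.split(".")[1])
        assert round(fm.t_approx_p(exact, CORRELATION_N), decimals) == float(printed)

    def test_all_reported_pvalues_reproduced(self):
        rows = [
            (r.rho, r.p_two_sided)
            for r in pd.concat(
                [
                    HOST_GENE_CORRELATIONS.rename(columns={"host_gene": "gene"}),
                    TARGET_CORRELATIONS.rename(columns={"target_gene": "gene"}),
                ]
            ).itertuples()
            if not r.p_two_sided.startswith("<")
        ]
        for rho, printed in rows:
            exact = nearest_attainable_rho(rho, CORRELATION_N)
            decimals = len(printed.split(".")[1])
            assert round(fm.t_approx_p(exact, CORRELATION_N), decimals) == float(
                printed
            ), (rho, printed)


class TestPermutationP:
    def test_single_permutation_bounds(self):
        rng = np.random.default_rng(0)
        p = fm.permutation_p(rng.normal(size=8), rng.normal(size=8), B=1, seed=1)
        assert p in (0.5, 1.0)

    def test_exhaustive_perfect_correlation_n4(self):
        # of the 24 permutations of 4 distinct ranks exactly 2 reach |rho| = 1
        p = fm.permutation_p([1, 2, 3, 4], [1, 2, 3, 4], exhaustive=True)
        assert p == pytest.approx(2 / 24)

    def test_sampled_converges_to_exhaustive(self):
        rng = np.random.default_rng(3)
        for n in (4, 5):
            x, y = rng.normal(size=n), rng.normal(size=n)
            exact = fm.permutation_p(x, y, exhaustive=True)
            sampled = fm.permutation_p(x, y, B=40000, seed=11, add_one=False)
            assert sampled == pytest.approx(exact, abs=0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert fm.permutation_p(x, y, B=200, seed=9) == fm.permutation_p(
            x, y, B=200, seed=9
        )

    def test_lower_bound(self):
        p = fm.permutation_p(np.arange(10.0), np.arange(10.0), B=100, seed=2)
        assert p >= 1 / 101


class TestFilterInteractions:
    def _table(self, evidences):
        return pd.DataFrame(
            {
                "mirna": [f"m{i}" for i in range(len(evidences))],
                "target_gene": [f"g{i}" for i in range(len(evidences))],
                "evidence_methods": evidences,
            }
        )

    def test_all_three_methods_kept(self):
        t = self._table(["Luciferase reporter assay;Western blot;qRT-PCR"])
        assert len(fm.filter_interactions(t)) == 1

    def test_two_methods_dropped(self):
        t = self._table(["Luciferase reporter assay;Western blot"])
        assert len(fm.filter_interactions(t)) == 0

    def test_empty_table(self):
        t = self._table([])
        assert len(fm.filter_interactions(t)) == 0

    def test_any_mode_counts_distinct_methods(self):
        t = self._table(["Microarray;NGS;pSILAC", "Microarray;NGS"])
        kept = fm.filter_interactions(t, mode="any", min_methods=3)
        assert list(kept.mirna) == ["m0"]


class TestPairTables:
    def test_coupled_host_pair_recovered(self):
        mirna, genes = _coupled_matrices(seed=123, noise_sd=0.05)
        annot = pd.DataFrame({"mirna": ["miR-A"], "host_gene": ["GENE-H"]})
        table = fm.host_gene_correlations(mirna, genes, annot, B=200, seed=0)
        assert len(table) == 1
        assert table.loc[0, "rho"] >= 0.8
        assert table.loc[0, "p_perm"] <= 0.05
        assert table.loc[0, "kind"] == "host_gene"

    def test_uncoupled_host_pair_is_null(self):
        # unrelated miRNA/gene: p_t should exceed 0.05 in >= 90% of seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=10), rng.normal(size=10)
            if fm.t_approx_p(fm.spearman(x, y), 10) > 0.05:
                hits += 1
        assert hits >= 90

    def test_empty_annotation(self):
        mirna, genes = _coupled_matrices(seed=5)
        annot = pd.DataFrame({"mirna": [], "host_gene": []})
        assert len(fm.host_gene_correlations(mirna, genes, annot, B=10)) == 0

    def test_missing_gene_skipped_with_warning(self):
        mirna, genes = _coupled_matrices(seed=6)
        annot = pd.DataFrame({"mirna": ["miR-A"], "host_gene": ["ABSENT"]})
        with pytest.warns(UserWarning):
            table = fm.host_gene_correlations(mirna, genes, annot, B=10)
        assert len(table) == 0

    def test_strong_pair_counts_from_reported_coefficients(self):
        neg, pos = fm.strong_pairs(TARGET_CORRELATIONS["rho"])
        assert int(neg.sum()) == 11
        assert int(pos.sum()) == 18

    def test_boundary_rho_excluded(self):
        neg, pos = fm.strong_pairs(np.array([-0.8, 0.8, -0.81, 0.81]))
        assert list(neg) == [False, False, True, False]
        assert list(pos) == [False, False, False, True]

    def test_simulated_negative_couplings_all_strong(self):
        rng = np.random.default_rng(77)
        n = 10
        feats = (
            [f"miR-{i}" for i in range(5)]
            + [f"G{i}" for i in range(5)]
            + [f"bg{i}" for i in range(100)]
        )
        levels = np.concatenate([np.full(10, 50.0), rng.lognormal(7, 0.5, 100)])
        design = fm.SimulationDesign(
            feature_ids=feats,
            e_slow=levels,
            e_fast=levels,
            slow_fractions=rng.uniform(0.2, 0.8, n),
            groups=["type1"] * 5 + ["type2"] * 5,
            library_sizes=np.full(n, 10_000_000),
            dispersions=0.01,
            seed=77,
            couplings=[
                Coupling(f"miR-{i}", f"G{i}", sign=-1, noise_sd=0.02)
                for i in range(5)
            ],
        )
        counts, _ = fm.sim_mixture_counts(design)
        mirna = counts.loc[[f"miR-{i}" for i in range(5)]].astype(float)
        genes = counts.loc[[f"G{i}" for i in range(5)]].astype(float)
        inter = pd.DataFrame(
            {
                "mirna": [f"miR-{i}" for i in range(5)],
                "target_gene": [f"G{i}" for i in range(5)],
                "evidence_methods": ["reporter assay;Western blot;qPCR"] * 5,
            }
        )
        full, strong, n_neg, n_pos = fm.target_correlations(
            mirna, genes, inter, B=100, seed=0
        )
        assert n_neg == 5 and n_pos == 0
        assert set(zip(strong.feature_a, strong.feature_b)) == {
            (f"miR-{i}", f"G{i}") for i in range(5)
        }


class TestSharedTargetNetwork:
    def _interactions(self):
        return pd.DataFrame(
            {
                "mirna": ["miR-a", "miR-b", "miR-a"],
                "target_gene": ["T1", "T1", "T2"],
                "evidence_methods": ["x"] * 3,
            }
        )

    def test_min_shared_two(self):
        edges = fm.shared_target_network(["miR-a", "miR-b"], self._interactions())
        assert set(edges.target_gene) == {"T1"}
        assert len(edges) == 2

    def test_min_shared_one_is_identity(self):
        edges = fm.shared_target_network(
            ["miR-a", "miR-b"], self._interactions(), min_shared=1
        )
        assert len(edges) == 3

    def test_seed_prefix_fixture_yields_network(self):
        refs = [
            fm.MirnaReference("mir-x", "TAAGGCACGCGGTGAATGCCA"),
            fm.MirnaReference("mir-y", "TAAGGCAGTATCGATCGTACA"),
        ]
        table = fm.gen_interaction_table(refs, seed=1)
        edges = fm.shared_target_network(["mir-x", "mir-y"], table, min_shared=2)
        assert len(edges) > 0


class TestInputValidation:
    def test_short_vectors_rejected(self):
        with pytest.raises(InputError):
            fm.spearman([1, 2], [3, 4])

    def test_invalid_n_rejected(self):
        with pytest.raises(InputError):
            fm.t_approx_p(0.5, 2)
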