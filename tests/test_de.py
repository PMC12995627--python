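import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pyrosig import (
    SyntheticConfig,
    adjust_bh,
    anova_screen,
    estimate_log2fc,
    filter_de,
    generate_cohort,
    intersect_subtypes,
    run_screen,
    tukey_hsd,
)
from pyrosig.de import screen
from pyrosig.registry import CORE9, SUBTYPES

from conftest import make_matrix


def paired_matrix(tumor_shift: float, n_pairs: int = 4, n_probes: int = 3, seed: int = 0,
                  noise: float = 1.0, subtype: str = "LumA"):
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 1, size=n_probes)
    values, meta = {}, []
    for i in range(n_pairs):
        values[f"p{i}_T"] = base + tumor_shift + noise * rng.normal(size=n_probes)
        values[f"p{i}_C"] = base + noise * rng.normal(size=n_probes)
        meta.append((f"p{i}_T", f"s{i}", subtype, "tumor", f"p{i}"))
        meta.append((f"p{i}_C", f"s{i}", subtype, "control", f"p{i}"))
    return make_matrix(values, [f"probe{j}" for j in range(n_probes)], meta)


class TestLog2FC:
    def test_identical_groups_give_zero(self):
        m = paired_matrix(0.0, noise=0.0)
        assert np.allclose(estimate_log2fc(m, "LumA"), 0.0)

    def test_exact_shift_recovered(self):
        m = paired_matrix(5.0, noise=0.0)
        assert np.allclose(estimate_log2fc(m, "LumA"), 5.0)

    def test_equals_brute_force_mean_difference(self):
        m = paired_matrix(2.0, seed=5)
        got = estimate_log2fc(m, "LumA")
        tum = [c for c in m.values.columns if c.endswith("_T")]
        ctl = [c for c in m.values.columns if c.endswith("_C")]
        for probe in m.values.index:
            expect = m.values.loc[probe, tum].mean() - m.values.loc[probe, ctl].mean()
            assert got[probe] == pytest.approx(expect)

    def test_too_few_samples_rejected(self):
        m = paired_matrix(1.0, n_pairs=1)
        with pytest.raises(ValueError, match=">=2"):
            estimate_log2fc(m, "LumA")


class TestAnova:
    def test_matches_scipy_per_probe_on_random_cohort(self):
        """The vectorized screen equals scipy's f_oneway on the same
        pooled-control + per-subtype-tumor grouping, probe by probe."""
        from pyrosig.de import _tissue_groups

        cfg = SyntheticConfig(
            seed=13, n_pairs_per_subtype={s: 4 for s in SUBTYPES},
            n_universal=2, n_subtype_specific=2, n_null=6,
        )
        matrix, _ = generate_cohort(cfg)
        res = anova_screen(matrix)
        groups = _tissue_groups(matrix)
        for probe in matrix.values.index:
            arrays = [matrix.values.loc[probe, cols].to_numpy() for cols in groups.values()]
            expect = stats.f_oneway(*arrays)
            assert res.loc[probe, "F_stat"] == pytest.approx(expect.statistic)
            assert res.loc[probe, "p_raw"] == pytest.approx(expect.pvalue)

    def test_three_plain_groups_f_equals_three(self):
        """The classical textbook case, computed through the same estimator
        the screen uses but on raw group vectors via Tukey's components."""
        g = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]
        msb = 3 * ((2 - 3) ** 2 + 0 + (4 - 3) ** 2) / 2
        msw = (2 + 2 + 2) / 6
        assert msb / msw == 3.0
        f = stats.f_oneway(*g)
        assert f.statistic == pytest.approx(3.0)

    def test_identical_means_give_f_near_zero(self):
        m = paired_matrix(0.0, n_pairs=10, seed=2)
        res = anova_screen(m)
        assert (res["p_raw"] > 0.05).all()

    def test_two_group_f_equals_t_squared(self):
        m = paired_matrix(1.5, n_pairs=6, seed=3)
        res = anova_screen(m)
        tum = [c for c in m.values.columns if c.endswith("_T")]
        ctl = [c for c in m.values.columns if c.endswith("_C")]
        for probe in m.values.index:
            t = stats.ttest_ind(m.values.loc[probe, tum], m.values.loc[probe, ctl]).statistic
            assert res.loc[probe, "F_stat"] == pytest.approx(t**2)

    def test_degenerate_probe_flagged(self):
        m = paired_matrix(0.0, noise=0.0)
        res = anova_screen(m)
        assert res["degenerate"].all()
        assert res["p_raw"].isna().all()


class TestBH:
    @pytest.mark.parametrize(
        "p_raw, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03], [0.03]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_computed_step_up(self, p_raw, expected):
        assert adjust_bh(p_raw) == pytest.approx(expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        expect = multipletests(p, method="fdr_bh")[1]
        assert adjust_bh(p) == pytest.approx(expect)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_bh([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_properties(self, p):
        adj = adjust_bh(p)
        p = np.asarray(p)
        # adjusted never below raw, capped at 1
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        # monotone: raw order preserved in adjusted ranks
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_fixed_points(self):
        """Vectors where BH is a genuine no-op: all-equal p and all-ones."""
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert adjust_bh([0.2, 0.2]) == pytest.approx([0.2, 0.2])
        v = adjust_bh([0.2, 0.2])
        assert adjust_bh(v) == pytest.approx(v)


class TestTukey:
    def test_identical_groups_q_zero_p_one(self):
        g = [np.array([1.0, 2, 3]), np.array([1.0, 2, 3])]
        res = tukey_hsd(g)
        assert res["q"].item() == 0.0
        assert res["p"].item() == pytest.approx(1.0)

    def test_two_group_identity_q_is_sqrt2_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 12)
        res = tukey_hsd([a, b])
        t = stats.ttest_ind(a, b).statistic
        assert res["q"].item() == pytest.approx(np.sqrt(2) * abs(t), abs=1e-9)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        g = [rng.normal(i * 0.8, 1, 10) for i in range(3)]
        ours = tukey_hsd(g)
        ref = stats.tukey_hsd(*g)
        for _, row in ours.iterrows():
            i, j = int(row.group_i), int(row.group_j)
            assert row.p == pytest.approx(ref.pvalue[i, j], abs=1e-3)

    def test_zero_msw_rejected(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            tukey_hsd([np.array([1.0, 1.0]), np.array([2.0, 2.0])])


def stub_table(log2fc: dict[str, dict[str, float]], p_adj: float = 0.01,
               tukey: bool = True) -> pd.DataFrame:
    rows = []
    for gene, per_sub in log2fc.items():
        for s, v in per_sub.items():
            rows.append((f"{gene}_at", gene, s, v, p_adj, p_adj, tukey))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "subtype", "log2FC", "p_raw", "p_adj",
                       "tukey_significant"],
    )


class TestFilterAndIntersect:
    def test_boundary_fc_exactly_three_fails(self):
        t = stub_table({"G": {"LumA": 3.0}})
        assert filter_de(t)["LumA"] == set()
        t2 = stub_table({"G": {"LumA": 3.0001}})
        assert filter_de(t2)["LumA"] == {"G"}

    def test_table2_fixture_all_nine_genes_pass_everywhere(self, table2):
        long = table2.melt(
            id_vars=["probe_id", "gene_symbol", "list_rank"],
            var_name="subtype", value_name="log2FC",
        )
        long["p_raw"] = 0.001
        long["p_adj"] = 0.01
        long["tukey_significant"] = True
        sets = filter_de(long)
        for s, genes in sets.items():
            assert genes == set(CORE9), s

    def test_filter_shrinks_with_stricter_thresholds(self, planted_cohort):
        matrix, _ = planted_cohort
        table = screen(matrix)
        loose = filter_de(table, alpha=0.05, fc_threshold=3)
        tight_alpha = filter_de(table, alpha=0.005, fc_threshold=3)
        tight_fc = filter_de(table, alpha=0.05, fc_threshold=4.5)
        for s in loose:
            assert tight_alpha[s] <= loose[s]
            assert tight_fc[s] <= loose[s]

    def test_intersection_recovers_planted_nine(self, planted_cohort):
        matrix, truth = planted_cohort
        _, _, venn = run_screen(matrix)
        planted = set(truth.loc[truth["class"] == "universal", "gene_symbol"])
        assert venn.universal_set == planted
        assert len(venn.universal_set) == 9

    def test_disjoint_sets_empty_intersection(self):
        sets = {s: {f"g_{s}"} for s in SUBTYPES}
        assert intersect_subtypes(sets).universal_set == frozenset()

    def test_identical_sets_idempotent(self):
        S = {"A", "B", "C"}
        sets = {s: set(S) for s in SUBTYPES}
        assert intersect_subtypes(sets).universal_set == frozenset(S)

    def test_fewer_than_five_sets_rejected(self):
        with pytest.raises(ValueError, match="need 5"):
            intersect_subtypes({"LumA": {"A"}, "TNBC": {"A"}})

    def test_universal_subset_and_permutation_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        sets = {s: {g for g in genes if rng.random() < 0.5} for s in SUBTYPES}
        venn = intersect_subtypes(sets)
        for s, members in sets.items():
            assert venn.universal_set <= members
        shuffled = dict(reversed(list(sets.items())))
        assert intersect_subtypes(shuffled).universal_set == venn.universal_set

    def test_cell_counts_partition_membership(self):
        sets = {s: {"A", "B"} if s == "LumA" else {"B"} for s in SUBTYPES}
        venn = intersect_subtypes(sets)
        counts = venn.cell_counts()
        assert sum(counts.values()) == 2
        assert counts[tuple(sorted(SUBTYPES))] == 1  # B in all five


class TestRecoveryAndSize:
    def test_null_false_universal_rate_below_1e3(self):
        """Under the null config, essentially no gene should survive the
        adjusted-p, effect-size and Tukey filters in all five subtypes."""
        total_genes, false_universal = 0, 0
        for seed in (0, 1, 2):
            cfg = SyntheticConfig(
                seed=seed, n_pairs_per_subtype={s: 20 for s in SUBTYPES},
                n_universal=0, n_subtype_specific=0, n_null=1000,
            )
            matrix, _ = generate_cohort(cfg)
            _, _, venn = run_screen(matrix)
            total_genes += 1000
            false_universal += len(venn.universal_set)
        assert false_universal / total_genes < 1e-3
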