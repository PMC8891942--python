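import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pasym.inference import (
    StatMap,
    SummaryGroup,
    ancova_f_map,
    anova_from_summary,
    build_design,
    chi_square_independence,
    extract_clusters,
    fdr_bh,
    posthoc_t_map,
    summarize,
    table_one,
    ttest_from_summary,
)
from pasym.io_core import BrainMask, PasymError, SubjectTable, ValidationError

from oracles import bh_brute, flood_fill_components


def make_table(rng, n_per_group=(30, 20, 30)):
    groups = (["GI_MDD"] * n_per_group[0] + ["NGI_MDD"] * n_per_group[1]
              + ["HC"] * n_per_group[2])
    n = len(groups)
    return SubjectTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "age": rng.normal(30, 6, n),
        "gender": rng.choice(["male", "female"], n),
        "education": rng.normal(14, 3, n),
        "mean_fd": rng.uniform(0.02, 0.15, n),
    }))


class TestBuildDesign:
    def test_structure_80x7(self, rng):
        table = make_table(rng, (35, 17, 28))
        d = build_design(table)
        assert d.X.shape == (80, 7)
        assert d.X_reduced.shape == (80, 5)
        assert d.names[0] == "intercept"
        assert len(d.group_columns) == 2

    def test_covariates_centered(self, rng):
        d = build_design(make_table(rng))
        for i, name in enumerate(d.names):
            if name in ("age", "gender", "education", "mean_fd"):
                assert abs(d.X[:, i].sum()) < 1e-8

    def test_no_group_equals_reduced(self, rng):
        table = make_table(rng)
        d = build_design(table)
        d2 = build_design(table, groups=["HC"])  # single group: no indicators
        assert d2.X.shape[1] == d.X_reduced.shape[1]

    def test_reference_dropped(self, rng):
        d = build_design(make_table(rng))
        assert d.reference == "HC"
        assert "group[HC]" not in d.names

    def test_collinear_covariates_rejected(self, rng):
        table = make_table(rng)
        table.df["age2"] = table.df["age"]
        with pytest.raises(ValidationError, match="collinear"):
            build_design(table, covariates=("age", "age2"))

    def test_missing_covariate_rejected(self, rng):
        table = make_table(rng)
        table.df.loc[3, "education"] = np.nan
        with pytest.raises(ValidationError, match="education"):
            build_design(table)


class TestAncova:
    def test_constant_voxel(self, rng):
        table = make_table(rng)
        stack = np.column_stack([np.full(len(table), 1.7),
                                 rng.normal(size=len(table))])
        smap = ancova_f_map(stack, build_design(table))
        assert smap.stat[0] == 0
        assert smap.p[0] == 1

    def test_no_covariates_equals_classical_anova(self, rng):
        table = make_table(rng)
        stack = rng.normal(size=(len(table), 12))
        d = build_design(table, covariates=())
        smap = ancova_f_map(stack, d)
        g = table.groups.to_numpy()
        for v in range(12):
            f_ref, p_ref = stats.f_oneway(*[stack[g == lev, v]
                                            for lev in ("GI_MDD", "NGI_MDD", "HC")])
            assert smap.stat[v] == pytest.approx(f_ref, abs=1e-8)
            assert smap.p[v] == pytest.approx(p_ref, abs=1e-8)

    def test_injected_shift_detected(self, rng):
        table = make_table(rng)
        stack = rng.normal(0, 0.2, size=(len(table), 5))
        stack[(table.groups == "GI_MDD").to_numpy(), 2] += 0.5
        smap = ancova_f_map(stack, build_design(table))
        assert smap.p[2] < 1e-6
        assert smap.p[[0, 1, 3, 4]].min() > 1e-6


class TestPosthocT:
    def test_identical_groups_t_zero(self, rng):
        table = make_table(rng, (20, 20, 2)).subset(["GI_MDD", "NGI_MDD"])
        stack = rng.normal(size=(40, 6))
        d = build_design(table, groups=["GI_MDD", "NGI_MDD"], reference="NGI_MDD")
        t_obs = posthoc_t_map(stack, d).stat
        assert np.abs(t_obs).max() < 4  # no systematic effect

    def test_t_squared_equals_partial_f(self, rng):
        table = make_table(rng, (18, 14, 2)).subset(["GI_MDD", "NGI_MDD"])
        stack = rng.normal(size=(32, 8))
        d = build_design(table, groups=["GI_MDD", "NGI_MDD"], reference="NGI_MDD")
        tmap = posthoc_t_map(stack, d)
        fmap = ancova_f_map(stack, d)
        np.testing.assert_allclose(tmap.stat**2, fmap.stat, atol=1e-8)

    def test_sign_convention(self, rng):
        table = make_table(rng, (20, 20, 2)).subset(["GI_MDD", "NGI_MDD"])
        stack = rng.normal(0, 0.1, size=(40, 1))
        stack[(table.groups == "GI_MDD").to_numpy(), 0] += 1.0
        d = build_design(table, groups=["GI_MDD", "NGI_MDD"], reference="NGI_MDD")
        assert posthoc_t_map(stack, d).stat[0] > 0

    def test_requires_two_groups(self, rng):
        table = make_table(rng)
        d = build_design(table)
        with pytest.raises(PasymError):
            posthoc_t_map(np.zeros((len(table), 2)), d)


class TestFdrBh:
    def test_hand_example(self):
        q, rej = fdr_bh([0.01, 0.02, 0.03], 0.05)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        assert rej.all()

    def test_all_ones(self):
        q, rej = fdr_bh(np.ones(10), 0.05)
        assert not rej.any()
        np.testing.assert_allclose(q, 1.0)

    def test_single_p(self):
        q, rej = fdr_bh([0.04], 0.05)
        assert q[0] == pytest.approx(0.04)
        assert rej[0]

    def test_empty(self):
        q, rej = fdr_bh([], 0.05)
        assert q.size == 0 and rej.size == 0

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = np.round(rng.uniform(size=m), 3)  # rounding forces ties
            q, rej = fdr_bh(p, 0.05)
            q_ref, rej_ref = bh_brute(p, 0.05)
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_ref)

    def test_rejections_monotone_in_alpha(self, rng):
        p = rng.uniform(size=100)
        _, r1 = fdr_bh(p, 0.01)
        _, r2 = fdr_bh(p, 0.10)
        assert (r2 | ~r1).all()  # r1 subset of r2


def stat_map_from_flags(flags_1d, stats_1d):
    p = np.where(flags_1d, 0.001, 0.9)
    smap = StatMap(stat=np.asarray(stats_1d, float), p=p, df=(10,), kind="t")
    smap.significant = np.asarray(flags_1d, bool)
    smap.q = p
    return smap


class TestExtractClusters:
    def grid(self, shape=(4, 4, 4)):
        return BrainMask(np.ones(shape, dtype=bool), np.eye(4))

    def test_no_significant_voxels(self):
        mask = self.grid()
        smap = stat_map_from_flags(np.zeros(64, bool), np.ones(64))
        assert extract_clusters(smap, mask, np.arange(64)) == []

    def test_corner_touch_connectivity(self):
        mask = self.grid((2, 2, 2))
        flags = np.zeros(8, bool)
        stats_ = np.ones(8)
        # row-major: (0,0,0) -> 0 and (1,1,1) -> 7 touch only at a corner
        flags[[0, 7]] = True
        smap = stat_map_from_flags(flags, stats_)
        assert len(extract_clusters(smap, mask, np.arange(8), connectivity=26)) == 1
        assert len(extract_clusters(smap, mask, np.arange(8), connectivity=18)) == 2
        assert len(extract_clusters(smap, mask, np.arange(8), connectivity=6)) == 2

    def test_two_blobs_sizes(self):
        mask = self.grid((5, 5, 5))
        vol = np.zeros((5, 5, 5), bool)
        vol[0, 0, 0:5] = True  # size 5 line
        vol[3:4, 3, 1:4] = True  # size 3 line
        flags = vol[mask.data]
        stats_ = np.where(flags, 2.0, 0.0)
        recs = extract_clusters(stat_map_from_flags(flags, stats_), mask,
                                np.arange(125), connectivity=26)
        assert sorted(r.n_voxels for r in recs) == [3, 5]

    def test_min_extent(self):
        mask = self.grid((5, 5, 5))
        vol = np.zeros((5, 5, 5), bool)
        vol[0, 0, 0:5] = True
        vol[3, 3, 1:4] = True
        flags = vol[mask.data]
        recs = extract_clusters(stat_map_from_flags(flags, np.ones(125)), mask,
                                np.arange(125), connectivity=26, min_extent=4)
        assert [r.n_voxels for r in recs] == [5]

    def test_signs_split(self):
        mask = self.grid((4, 1, 1))
        flags = np.array([True, True, True, True])
        stats_ = np.array([2.0, 3.0, -2.0, -1.0])
        recs = extract_clusters(stat_map_from_flags(flags, stats_), mask,
                                np.arange(4), connectivity=6)
        assert len(recs) == 2
        assert {r.sign for r in recs} == {1, -1}
        pos = next(r for r in recs if r.sign == 1)
        assert pos.peak_stat == 3.0 and pos.peak_ijk == (1, 0, 0)

    def test_peak_and_world_coords(self):
        mask = BrainMask(np.ones((3, 3, 3), bool), np.diag([2.0, 2.0, 2.0, 1.0]))
        vol = np.zeros((3, 3, 3), bool)
        vol[1, 1, 1] = vol[1, 1, 2] = True
        flags = vol[mask.data]
        stats_ = np.zeros(27)
        stats_[np.flatnonzero(flags)] = [1.5, 4.0]
        recs = extract_clusters(stat_map_from_flags(flags, stats_), mask, np.arange(27))
        assert recs[0].peak_ijk == (1, 1, 2)
        assert recs[0].peak_mm == (2.0, 2.0, 4.0)

    def test_subject_means(self, rng):
        mask = self.grid((3, 3, 3))
        flags = np.zeros(27, bool)
        flags[[0, 1, 2]] = True
        stack = rng.normal(size=(5, 27))
        recs = extract_clusters(stat_map_from_flags(flags, np.ones(27)), mask,
                                np.arange(27), pas_stack=stack)
        np.testing.assert_allclose(recs[0].subject_means,
                                   stack[:, [0, 1, 2]].mean(axis=1))

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill(self, rng, connectivity):
        mask = self.grid((6, 6, 6))
        for _ in range(5):
            vol = rng.random((6, 6, 6)) < 0.25
            flags = vol[mask.data]
            recs = extract_clusters(
                stat_map_from_flags(flags, rng.random(216) + 0.5), mask,
                np.arange(216), connectivity=connectivity)
            ours = {frozenset(map(tuple, np.argwhere(
                np.isin(np.arange(216).reshape(6, 6, 6), r.voxel_members))))
                for r in recs}
            ref = set(flood_fill_components(vol, connectivity))
            assert ours == ref


class TestSummaryTests:
    def test_anova_identical_means(self):
        g = [SummaryGroup(10, 5.0, 1.0), SummaryGroup(12, 5.0, 2.0)]
        F, df1, df2 = anova_from_summary(g)
        assert F == 0 and df1 == 1 and df2 == 20

    def test_anova_raw_vs_summary_identity(self, rng):
        raw = [rng.normal(5, 2, 14), rng.normal(6, 1, 9), rng.normal(4, 3, 20)]
        F, df1, df2 = anova_from_summary([summarize(v) for v in raw])
        F_ref, _ = stats.f_oneway(*raw)
        assert F == pytest.approx(F_ref, rel=1e-12)

    def test_ttest_raw_vs_summary_identity(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1.4, 11)
        t, df = ttest_from_summary(summarize(a), summarize(b))
        t_ref, _ = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == 24

    def test_ttest_equal_means(self):
        t, _ = ttest_from_summary(SummaryGroup(5, 2.0, 1.0), SummaryGroup(8, 2.0, 3.0))
        assert t == 0

    def test_sd_validation(self):
        with pytest.raises(ValidationError):
            SummaryGroup(5, 1.0, -0.1)

    def test_chi2_hand_2x2(self):
        chi2, df = chi_square_independence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)
        assert df == 1

    def test_chi2_equal_proportions(self):
        chi2, _ = chi_square_independence([[10, 20, 30], [1, 2, 3]])
        assert chi2 == pytest.approx(0, abs=1e-12)

    def test_chi2_matches_scipy(self, rng):
        table = rng.integers(1, 30, size=(2, 3))
        chi2, df = chi_square_independence(table)
        ref = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert df == ref.dof

    def test_chi2_zero_marginal(self):
        with pytest.raises(ValidationError):
            chi_square_independence([[0, 0], [1, 2]])


class TestTableOne:
    def test_smoke(self, rng):
        from pasym.simulate import SimDesign, simulate_cohort

        cohort = simulate_cohort(SimDesign(shape=(4, 2, 2), n_timepoints=10,
                                           n_gi=8, n_ngi=6, n_hc=6, seed=1))
        frame = table_one(cohort.subjects)
        assert {"variable", "test", "statistic"} <= set(frame.columns)
        assert (frame["variable"] == "gender (male/female)").any()
        assert len(frame) >= 5
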