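"""Rarefaction, diversity, Bray-Curtis, NMDS, PERMANOVA and Mantel."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from hermetia import community as cm
from hermetia.community import AbundanceTable, DistanceMatrix


def table_from(counts: np.ndarray, meta: pd.DataFrame | None = None) -> AbundanceTable:
    frame = pd.DataFrame(counts, index=[f"s{i}" for i in range(len(counts))],
                         columns=[f"t{j}" for j in range(counts.shape[1])])
    return AbundanceTable(frame, metadata=meta)


class TestRarefy:
    def test_row_sums_equal_depth(self, gut_table):
        sub = cm.rarefy(gut_table, 500, seed=0)
        assert (sub.counts.sum(axis=1) == 500).all()

    def test_full_depth_unchanged(self):
        t = table_from(np.array([[5, 3, 2], [4, 4, 2]]))
        sub = cm.rarefy(t, 10, seed=0)
        pd.testing.assert_frame_equal(sub.counts, t.counts)

    def test_hypergeometric_expectation(self):
        # one taxon at 50%: mean subsampled proportion stays 0.5
        t = table_from(np.array([[5000, 3000, 2000]]))
        rng = np.random.default_rng(0)
        props = [cm.rarefy(t, 1000, rng).counts.iloc[0, 0] / 1000
                 for _ in range(200)]
        assert np.mean(props) == pytest.approx(0.5, abs=0.01)

    def test_shallow_samples_dropped(self):
        t = table_from(np.array([[50, 50], [2, 1]]))
        sub = cm.rarefy(t, 10, seed=0)
        assert sub.sample_ids == ["s0"]

    def test_bad_depth(self):
        t = table_from(np.array([[1, 1]]))
        with pytest.raises(ValueError):
            cm.rarefy(t, 0)


class TestPrevalenceFilter:
    def test_count_threshold_rule(self):
        # 10 samples; taxon 0 has count 4 in exactly one sample -> kept
        # (1 >= ceil(0.10 * 10)); taxon 1 has count 3 everywhere -> removed
        counts = np.zeros((10, 2), dtype=int)
        counts[0, 0] = 4
        counts[:, 1] = 3
        t = table_from(counts)
        kept = cm.prevalence_filter(t, min_count=4, min_sample_frac=0.10)
        assert kept.taxon_ids == ["t0"]

    def test_empty_table_passes_through(self):
        t = table_from(np.zeros((3, 0), dtype=int))
        out = cm.prevalence_filter(t)
        assert out.counts.shape == (3, 0)

    def test_sample_presence_mode(self):
        counts = np.array([[1, 0], [1, 0], [1, 0], [1, 1]])
        t = table_from(counts)
        kept = cm.prevalence_filter(t, min_count=4, mode="sample_presence")
        assert kept.taxon_ids == ["t0"]


class TestShannonEvenness:
    def test_uniform_four_taxa(self):
        h, j, s = cm.shannon_evenness([10, 10, 10, 10])
        assert h == pytest.approx(math.log(4))
        assert j == pytest.approx(1.0)
        assert s == 4

    def test_single_taxon_convention(self):
        h, j, s = cm.shannon_evenness([42])
        assert h == 0.0 and j == 0.0 and s == 1

    def test_two_taxon_hand_value(self):
        h, _, _ = cm.shannon_evenness([77, 23])
        assert h == pytest.approx(0.5393, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cm.shannon_evenness([0, 0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = table_from(np.array([[3, 3, 0], [3, 3, 0], [0, 0, 5]]))
        d = cm.bray_curtis(t)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_hand_value(self):
        t = table_from(np.array([[2, 0, 1], [1, 1, 0]]))
        d = cm.bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(0.6)

    def test_matches_scipy_oracle(self, gut_table):
        sub = gut_table.counts.iloc[:8]
        ours = cm.bray_curtis(AbundanceTable(sub)).condensed()
        oracle = pdist(sub.to_numpy(dtype=float), metric="braycurtis")
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_relative_equals_counts_at_equal_sums(self, gut_table):
        d1 = cm.bray_curtis(gut_table, input="counts")
        d2 = cm.bray_curtis(gut_table, input="relative")
        assert np.allclose(d1.values, d2.values, atol=1e-12)

    def test_zero_sample_named(self):
        t = table_from(np.array([[1, 1], [0, 0]]))
        with pytest.raises(ValueError, match="s1"):
            cm.bray_curtis(t)


def embeddable_distances(n=12, k=2, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, k))
    d = squareform(pdist(x))
    return DistanceMatrix(d, [f"s{i}" for i in range(n)])


class TestNmds:
    def test_exactly_embeddable_low_stress(self):
        res = cm.nmds(embeddable_distances(), k=2, n_starts=4, seed=0)
        assert res.stress < 1e-3

    def test_gut_data_stress_below_conventional_limit(self, gut_table):
        filt = cm.prevalence_filter(gut_table)
        res = cm.nmds(cm.bray_curtis(filt), k=2, n_starts=4, max_iter=300, seed=0)
        assert res.stress < 0.2

    def test_stress_descent(self):
        res = cm.nmds(embeddable_distances(seed=3), k=2, n_starts=1, seed=1)
        diffs = np.diff(res.stress_trace)
        assert (diffs <= 1e-9).all()

    def test_stress_invariant_under_rotation(self):
        d = embeddable_distances(seed=4)
        res = cm.nmds(d, k=2, n_starts=2, seed=0)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        rotated = res.coordinates @ rot
        # recomputing stress-1 on rotated coordinates gives the same value
        from sklearn.isotonic import IsotonicRegression
        for coords in (res.coordinates, rotated):
            dconf = pdist(coords)
            order = np.argsort(d.condensed(), kind="stable")
            iso = IsotonicRegression(increasing=True)
            dhat_sorted = iso.fit_transform(np.arange(dconf.size, dtype=float),
                                            dconf[order])
            dhat = np.empty_like(dhat_sorted)
            dhat[order] = dhat_sorted
            s = math.sqrt(((dhat - dconf) ** 2).sum() / (dconf ** 2).sum())
            assert s == pytest.approx(res.stress, abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cm.nmds(embeddable_distances(n=3), k=2)


def two_cluster_distance(n_per=3, within=0.1, between=0.9):
    n = 2 * n_per
    d = np.full((n, n), between)
    d[:n_per, :n_per] = within
    d[n_per:, n_per:] = within
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [f"s{i}" for i in range(n)])


class TestPermanova:
    def test_exhaustive_enumeration_p(self):
        """3+3 separated toy: 2 of the 20 assignments reach the observed F."""
        d = two_cluster_distance()
        labels = ["A"] * 3 + ["B"] * 3
        res = cm.permanova(d, labels, permutations="exhaustive")
        assert res.p_value == pytest.approx(0.1)
        assert res.n_permutations == 20

    def test_matches_skbio_oracle(self, gut_table):
        skbio = pytest.importorskip("skbio")
        filt = cm.prevalence_filter(gut_table)
        dist = cm.bray_curtis(filt)
        res = cm.permanova(dist, filt.metadata["diet"].astype(str), n_perm=99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.values, dist.ids),
            filt.metadata["diet"].astype(str).to_numpy(), permutations=99)
        assert res.statistic == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_sample_order_invariance(self):
        d = two_cluster_distance()
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=d.ids)
        perm = [3, 0, 4, 1, 5, 2]
        ids = [d.ids[i] for i in perm]
        d2 = DistanceMatrix(d.values[np.ix_(perm, perm)], ids)
        f1 = cm.permanova(d, labels, n_perm=9, seed=0).statistic
        f2 = cm.permanova(d2, labels, n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_r2_decomposition(self):
        d = two_cluster_distance()
        res = cm.permanova(d, ["A"] * 3 + ["B"] * 3, n_perm=9, seed=0)
        assert 0 <= res.r2 <= 1
        # R2 recomputed from the SS decomposition by hand
        d2 = d.values ** 2
        n = 6
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = (d2[:3, :3][np.triu_indices(3, 1)].sum()
                     + d2[3:, 3:][np.triu_indices(3, 1)].sum()) / 3
        assert res.r2 == pytest.approx((ss_total - ss_within) / ss_total, rel=1e-12)

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=0.05 over 400 label-shuffled datasets."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sims = 400
        labels = ["A"] * 6 + ["B"] * 6
        for _ in range(n_sims):
            x = rng.normal(size=(12, 5))
            d = DistanceMatrix(squareform(pdist(x)), [f"s{i}" for i in range(12)])
            res = cm.permanova(d, labels, n_perm=99,
                               seed=int(rng.integers(2 ** 31 - 1)))
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sims <= 0.08

    def test_pairwise_bonferroni(self, gut_table):
        filt = cm.prevalence_filter(gut_table)
        dist = cm.bray_curtis(filt)
        res = cm.permanova(dist, filt.metadata["diet"].astype(str), n_perm=49,
                           seed=0, pairwise=True)
        pw = res.pairwise
        assert len(pw) == 6  # 4 diets choose 2
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-15).all()

    def test_single_group_rejected(self):
        d = two_cluster_distance()
        with pytest.raises(ValueError):
            cm.permanova(d, ["A"] * 6)


class TestMantel:
    def test_linear_relation_r_one(self):
        d1 = embeddable_distances(seed=5)
        d2 = DistanceMatrix(2 * d1.values, d1.ids)
        res = cm.mantel(d1, d2, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_symmetric_in_argument_order(self):
        d1 = embeddable_distances(seed=6)
        d2 = embeddable_distances(seed=7)
        r12 = cm.mantel(d1, d2, n_perm=9, seed=0).statistic
        r21 = cm.mantel(d2, d1, n_perm=9, seed=0).statistic
        assert r12 == pytest.approx(r21, rel=1e-12)

    def test_independent_matrices_null(self):
        """|r| small and p large for unrelated matrices in most seeds."""
        ok = 0
        for seed in range(20):
            d1 = embeddable_distances(n=20, seed=100 + seed)
            d2 = embeddable_distances(n=20, seed=200 + seed)
            res = cm.mantel(d1, d2, n_perm=99, seed=seed)
            ok += (abs(res.statistic) < 0.3) and (res.p_value > 0.05)
        assert ok >= 18

    def test_matches_skbio_oracle(self, gut_table):
        skbio = pytest.importorskip("skbio")
        sub = gut_table.subset(gut_table.sample_ids[:10])
        d1 = cm.bray_curtis(sub)
        d2 = cm.bray_curtis(AbundanceTable(sub.counts.iloc[:, ::2]))
        ours = cm.mantel(d1, d2, n_perm=99, seed=0)
        r, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.values, d1.ids),
            skbio.DistanceMatrix(d2.values, d2.ids),
            method="pearson", permutations=0)
        assert ours.statistic == pytest.approx(float(r), rel=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cm.mantel(embeddable_distances(n=5), embeddable_distances(n=6))


class TestSubsamplingStability:
    def test_mantel_r_high_across_depths(self, gut_table):
        """Distance structure is stable across rarefaction depths."""
        rs = []
        for seed in range(5):
            depth_full = int(gut_table.depths.min())
            mats = [cm.bray_curtis(cm.rarefy(gut_table, depth, seed=seed))
                    for depth in (depth_full, depth_full // 2, depth_full // 4)]
            for i in range(3):
                for j in range(i + 1, 3):
                    rs.append(cm.mantel(mats[i], mats[j], n_perm=9,
                                        seed=seed).statistic)
        assert np.median(rs) > 0.9


class TestAlphaGroupTests:
    def test_planted_diversity_drop_detected(self):
        """A strong planted Shannon drop is flagged by ANOVA in nearly all seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            h_ctrl = rng.normal(3.0, 0.2, 9)
            h_drop = rng.normal(3.0 - 3 * 0.2, 0.2, 9)
            values = pd.Series(np.concatenate([h_ctrl, h_drop]))
            grouping = pd.Series(["ctrl"] * 9 + ["waste"] * 9)
            out = cm.alpha_group_tests(values, grouping, methods=("anova",))
            hits += out.loc[0, "p_value"] < 0.01
        assert hits >= 19

    def test_all_methods_report(self, gut_table):
        alpha = cm.alpha_diversity_table(gut_table)
        out = cm.alpha_group_tests(alpha["shannon"], alpha["diet"].astype(str))
        assert set(out["method"]) == {"anova", "pairwise_t_bonferroni",
                                      "tukey_hsd", "bartlett"}
        assert out["p_value"].between(0, 1).all()
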