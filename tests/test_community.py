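"""Aggregation, Bray-Curtis, PCoA, and PERMANOVA against independent oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import pdist, squareform

from smtz.community import (
    CountTable,
    DistanceMatrix,
    aggregate_to_rank,
    bray_curtis,
    pcoa,
    permanova,
    relative_abundance,
)
from smtz.synthetic import CommunityScenario, generate_count_table

from conftest import make_count_table


def two_group_metadata(n):
    ids = [f"S{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "bay": ["control"] * (n // 2) + ["heated"] * (n - n // 2),
            "season": ["summer"] * n,
            "depth": [float(i) for i in range(n)],
            "site": ["x"] * n,
        },
        index=ids,
    )


def group_permanova_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """One-way pseudo-F from the direct group-sum formula (independent of the
    hat-matrix route): SS_total = sum d^2 / n, SS_within = per-group sums."""
    n = len(labels)
    ss_total = (d**2).sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        ss_within += (d[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestAggregation:
    def test_single_family_collapses_to_one_row(self):
        t = make_count_table(np.array([[3, 4], [1, 2]]), families=["A1", "A2"])
        t.taxonomy = {"A1": "Ar;P;C;O;Fam", "A2": "Ar;P;C;O;Fam"}
        agg = aggregate_to_rank(t, "family")
        assert agg.asv_ids == ["Fam"]
        assert agg.counts[:, 0].tolist() == [7, 3]

    def test_two_asvs_same_family_sum(self):
        t = make_count_table(np.array([[3, 4, 5], [0, 1, 2]]), families=["A1", "A2", "B1"])
        t.taxonomy = {
            "A1": "Ar;P;C;O;FamA", "A2": "Ar;P;C;O;FamA", "B1": "Ar;P;C;O;FamB",
        }
        agg = aggregate_to_rank(t, "family")
        assert dict(zip(agg.asv_ids, agg.counts[0])) == {"FamA": 7, "FamB": 5}

    def test_lineage_short_of_rank_pools_unassigned(self):
        t = make_count_table(np.array([[2, 3]]), families=["A1", "A2"])
        t.taxonomy = {"A1": "Ar;P", "A2": "Ar;P;C;O;FamA"}
        agg = aggregate_to_rank(t, "family")
        assert "Unassigned" in agg.asv_ids

    @given(
        counts=hnp.arrays(
            np.int64, (4, 6), elements=st.integers(min_value=0, max_value=500)
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_totals_conserved_over_random_tables(self, counts):
        t = make_count_table(counts)
        t.taxonomy = {f: f"Ar;P;C;O;Fam{i % 3}" for i, f in enumerate(t.asv_ids)}
        agg = aggregate_to_rank(t, "family")
        np.testing.assert_array_equal(agg.totals(), t.totals())

    def test_unknown_rank_rejected(self, count_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_to_rank(count_table, "tribe")


class TestRelativeAbundance:
    def test_single_family_is_all_of_the_sample(self):
        t = make_count_table(np.array([[17], [3]]), families=["OnlyFam"])
        props = relative_abundance(t, top_k=None)
        assert (props["OnlyFam"] == 1.0).all()

    def test_simple_normalization(self):
        t = make_count_table(np.array([[3, 1]]))
        props = relative_abundance(t, top_k=None)
        assert props.iloc[0].tolist() == pytest.approx([0.75, 0.25])

    def test_rows_sum_to_one_with_pooling(self):
        rng = np.random.default_rng(0)
        t = make_count_table(rng.integers(0, 50, size=(6, 20)) + 1)
        props = relative_abundance(t, top_k=5)
        assert props.shape[1] == 6  # top 5 + Other_Families
        assert "Other_Families" in props.columns
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named_in_error(self):
        t = make_count_table(np.array([[1, 2], [0, 0]]))
        with pytest.raises(ValueError, match="S1"):
            relative_abundance(t)


class TestBrayCurtis:
    def test_identical_samples_have_zero_distance(self):
        t = make_count_table(np.array([[2, 1, 0], [2, 1, 0]]))
        assert bray_curtis(t, use_relative=False).values[0, 1] == 0.0

    def test_disjoint_support_gives_one(self):
        t = make_count_table(np.array([[5, 0, 0], [0, 3, 2]]))
        assert bray_curtis(t, use_relative=False).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # |2-1|+|1-1|+|0-1| over (2+1)+(1+1)+(0+1) = 2/6
        t = make_count_table(np.array([[2, 1, 0], [1, 1, 1]]))
        d = bray_curtis(t, use_relative=False).values[0, 1]
        assert d == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 40, size=(7, 11)) + 1
        t = make_count_table(counts)
        ours = bray_curtis(t, use_relative=False).values
        ref = squareform(pdist(counts.astype(float), metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_relative_mode_invariant_to_library_size(self):
        t1 = make_count_table(np.array([[2, 1, 0], [1, 1, 1]]))
        t2 = make_count_table(np.array([[20, 10, 0], [5, 5, 5]]))
        np.testing.assert_allclose(
            bray_curtis(t1).values, bray_curtis(t2).values, atol=1e-12
        )

    def test_all_zero_pair_rejected(self):
        t = make_count_table(np.array([[0, 0], [0, 0], [1, 1]]))
        with pytest.raises(ValueError):
            bray_curtis(t, use_relative=False)

    @given(
        counts=hnp.arrays(
            np.int64, (5, 8), elements=st.integers(min_value=1, max_value=200)
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_metric_properties(self, counts):
        d = bray_curtis(make_count_table(counts)).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 1.0 + 1e-12


class TestPCoA:
    def test_two_point_embedding(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        res = pcoa(d)
        coords = np.sort(res.coordinates["PC1"].to_numpy())
        np.testing.assert_allclose(coords, [-0.5, 0.5], atol=1e-12)

    def test_euclidean_distances_reproduced_exactly(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(9, 3))
        dist = squareform(pdist(points))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(9)], dist))
        embedded = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(embedded, dist, atol=1e-9)

    def test_eigenvalue_sum_equals_gower_trace(self):
        rng = np.random.default_rng(6)
        points = rng.normal(size=(6, 2))
        dist = squareform(pdist(points))
        d2 = dist**2
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(n)], dist))
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g), rel=1e-10)

    def test_matches_skbio_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 60, size=(8, 12))
        d = bray_curtis(make_count_table(counts))
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.sample_ids)
        )
        k = min(5, ours.coordinates.shape[1])
        np.testing.assert_allclose(
            ours.eigenvalues[:k], ref.eigvals.to_numpy()[:k], atol=1e-9
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()[:, :k]),
            np.abs(ref.samples.to_numpy()[:, :k]),
            atol=1e-8,
        )

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 60, size=(6, 9))
        res = pcoa(bray_curtis(make_count_table(counts)))
        assert res.proportion_explained.sum() == pytest.approx(1.0)


class TestPermanova:
    @pytest.fixture
    def separated(self):
        """Two groups of 3 with clear between-group separation."""
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, size=(3, 4))
        b = rng.normal(2.5, 1.0, size=(3, 4))
        d = squareform(pdist(np.vstack([a, b])))
        return DistanceMatrix([f"S{i}" for i in range(6)], d)

    def test_observed_f_matches_group_formula_oracle(self, separated):
        labels = np.array(["control"] * 3 + ["heated"] * 3)
        res = permanova(separated, two_group_metadata(6), ["bay"], 999, seed=0)
        f_ours = res.terms.loc[0, "pseudo_F"]
        f_oracle = group_permanova_oracle(separated.values, labels)
        assert f_ours == pytest.approx(f_oracle, rel=1e-9)

    def test_p_agrees_with_exhaustive_enumeration(self, separated):
        labels = np.array(["control"] * 3 + ["heated"] * 3)
        f_obs = group_permanova_oracle(separated.values, labels)
        fs = []
        for idx in combinations(range(6), 3):
            lab = np.array(["heated"] * 6)
            lab[list(idx)] = "control"
            fs.append(group_permanova_oracle(separated.values, lab))
        p_exact = np.mean(np.array(fs) >= f_obs - 1e-12)
        res = permanova(separated, two_group_metadata(6), ["bay"], 999, seed=3)
        assert abs(res.terms.loc[0, "p_value"] - p_exact) <= 0.02

    def test_matches_skbio_pseudo_f(self, separated):
        skbio = pytest.importorskip("skbio")
        res = permanova(separated, two_group_metadata(6), ["bay"], 999, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(separated.values, ids=separated.sample_ids),
            grouping=["c"] * 3 + ["h"] * 3,
            permutations=99,
        )
        assert res.terms.loc[0, "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-9
        )

    def test_ss_decomposition_and_r_squared(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(1, 80, size=(12, 10))
        meta = two_group_metadata(12)
        d = bray_curtis(make_count_table(counts, metadata=meta))
        res = permanova(d, meta, ["bay", "depth", "bay:depth"], 99, seed=1)
        ss_sum = res.terms["sum_of_squares"].sum() + res.ss_residual
        assert ss_sum == pytest.approx(res.ss_total, rel=1e-9)
        assert res.terms["r_squared"].sum() <= 1.0
        assert (res.terms["p_value"] >= 1.0 / 100.0).all()

    def test_stronger_separation_raises_f_and_lowers_p(self, separated):
        meta = two_group_metadata(6)
        weak = DistanceMatrix(separated.sample_ids, separated.values / 1.0)
        rng = np.random.default_rng(13)
        noise_pts = rng.normal(0, 1, size=(6, 4))
        d_null = DistanceMatrix(separated.sample_ids, squareform(pdist(noise_pts)))
        res_sep = permanova(weak, meta, ["bay"], 999, seed=0)
        res_null = permanova(d_null, meta, ["bay"], 999, seed=0)
        assert res_sep.terms.loc[0, "pseudo_F"] > res_null.terms.loc[0, "pseudo_F"]
        assert res_sep.terms.loc[0, "p_value"] <= res_null.terms.loc[0, "p_value"]

    def test_power_monotone_in_planted_bay_effect(self):
        f_stats = []
        for effect in (0.0, 1.0, 2.5):
            scenario = CommunityScenario(
                families=("A", "B", "C", "D"),
                base_log_abundance=(1.0, 1.0, 0.0, 0.0),
                depth_slope=(0.0, 0.0, 0.0, 0.0),
                bay_effect=(effect, 0.0, -effect, 0.0),
                dirichlet_concentration=200.0,
                library_size=5000,
            )
            samples = [("control", "summer", 5.0)] * 6 + [("heated", "summer", 5.0)] * 6
            table = generate_count_table(scenario, samples, seed=21)
            res = permanova(bray_curtis(table), table.metadata, ["bay"], 99, seed=0)
            f_stats.append(res.terms.loc[0, "pseudo_F"])
        assert f_stats[0] < f_stats[1] < f_stats[2]

    def test_planted_strong_bay_effect_detected_at_n12(self):
        scenario = CommunityScenario(
            families=("ANME-1", "TCS64", "UBA233", "BA1"),
            base_log_abundance=(0.0, 2.0, 2.0, 0.0),
            depth_slope=(0.0, 0.0, 0.0, 0.0),
            bay_effect=(2.0, 0.0, 0.0, 0.0),
            dirichlet_concentration=100.0,
            library_size=10_000,
        )
        samples = [("control", "summer", 5.0)] * 6 + [("heated", "summer", 5.0)] * 6
        table = generate_count_table(scenario, samples, seed=42)
        res = permanova(bray_curtis(table), table.metadata, ["bay"], 999, seed=7)
        assert res.terms.loc[0, "p_value"] <= 0.05

    def test_seed_reproducibility(self, separated):
        meta = two_group_metadata(6)
        p1 = permanova(separated, meta, ["bay"], 999, seed=5).terms["p_value"]
        p2 = permanova(separated, meta, ["bay"], 999, seed=5).terms["p_value"]
        pd.testing.assert_series_equal(p1, p2)

    def test_aliased_term_rejected(self, separated):
        meta = two_group_metadata(6)
        meta["bay_copy"] = meta["bay"]
        with pytest.raises(ValueError, match="aliased"):
            permanova(separated, meta, ["bay", "bay_copy"], 99, seed=0)

    def test_too_few_permutations_rejected(self, separated):
        with pytest.raises(ValueError):
            permanova(separated, two_group_metadata(6), ["bay"], 10, seed=0)
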