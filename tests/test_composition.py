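import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ampliquant import (
    GenotypeCountTable,
    TaxonomyTable,
    alpha_compare,
    bray_curtis,
    choose_rarefaction_depth,
    decontaminate,
    genus_aggregate,
    pcoa,
    per_line_beta_report,
    permanova,
    permdisp,
    rarefy,
    shannon,
)
from ampliquant.composition import DistanceMatrix, centroid_distances

from conftest import random_count_table


def _table(columns: dict, index=None) -> GenotypeCountTable:
    return GenotypeCountTable(pd.DataFrame(columns, index=index))


class TestRarefactionDepth:
    def test_equal_libraries(self):
        t = _table({"a": [50, 50], "b": [60, 40], "c": [30, 70]})
        assert choose_rarefaction_depth(t, 0.8).depth == 100

    def test_four_of_five_at_fraction_080(self):
        t = _table({"a": [10], "b": [100], "c": [100], "d": [100], "e": [100]})
        plan = choose_rarefaction_depth(t, 0.8)
        assert plan.depth == 100
        assert plan.samples_lost == ["a"]

    def test_fraction_one_forces_minimum(self):
        t = _table({"a": [10], "b": [100], "c": [55]})
        assert choose_rarefaction_depth(t, 1.0).depth == 10

    def test_empty_table_errors(self):
        t = GenotypeCountTable(pd.DataFrame(index=["g1"], dtype=int))
        with pytest.raises(ValueError):
            choose_rarefaction_depth(t)


class TestRarefy:
    def test_columns_sum_to_depth_and_never_exceed_original(self):
        rng = np.random.default_rng(0)
        t = random_count_table(rng, 10, 6)
        depth = int(t.library_sizes.min())
        out = rarefy(t, depth, seed=1)
        assert (out.library_sizes == depth).all()
        assert (out.counts <= t.counts[out.sample_ids]).all().all()

    def test_exhaustive_draw_is_identity(self):
        t = _table({"a": [7, 3, 5]})
        out = rarefy(t, 15, seed=0)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        t = random_count_table(rng, 12, 4)
        a = rarefy(t, 50, seed=99)
        b = rarefy(t, 50, seed=99)
        assert a == b

    def test_shallow_samples_dropped(self):
        t = _table({"a": [100, 100], "b": [3, 2]})
        out = rarefy(t, 50, seed=0)
        assert out.sample_ids == ["a"]

    def test_depth_beyond_all_warns_empty(self):
        t = _table({"a": [5]})
        with pytest.warns(UserWarning):
            out = rarefy(t, 10, seed=0)
        assert out.shape[1] == 0

    def test_hypergeometric_mean(self):
        """Empirical mean matches d*c/N (spot check; the larger Monte-Carlo
        comparison runs in the acceptance suite)."""
        t = _table({"a": [50, 30, 20]})
        depth = 40
        draws = np.array([rarefy(t, depth, seed=s).counts["a"].to_numpy()
                          for s in range(1000)])
        expected = depth * np.array([50, 30, 20]) / 100
        assert np.allclose(draws.mean(axis=0), expected, atol=0.3)


class TestShannon:
    @pytest.mark.parametrize("vec,expected", [
        ([10, 0, 0], 0.0),
        ([5, 5, 5, 5], 2.0),
        ([6, 2], -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
    ])
    def test_known_values_bits(self, vec, expected):
        assert shannon(vec, base=2) == pytest.approx(expected, abs=1e-12)

    def test_natural_log_base(self):
        assert shannon([1, 1], base=np.e) == pytest.approx(np.log(2))

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_uniform_is_maximal(self):
        rng = np.random.default_rng(5)
        for k in (2, 5, 16):
            v = rng.integers(1, 100, size=k)
            assert shannon(v, base=2) <= np.log2(k) + 1e-12
            assert shannon(np.full(k, 7), base=2) == pytest.approx(np.log2(k))


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_case(self):
        t = _table({"a": [6, 2], "b": [2, 2], "c": [6, 2], "d": [0, 9]},
                   index=["g1", "g2"])
        dm = bray_curtis(t).to_frame()
        assert dm.loc["a", "c"] == pytest.approx(0.0)
        assert dm.loc["a", "b"] == pytest.approx(1 / 3)
        t2 = _table({"x": [5, 0], "y": [0, 7]}, index=["g1", "g2"])
        assert bray_curtis(t2).data[0, 1] == pytest.approx(1.0)

    def test_zero_total_sample_named(self):
        t = _table({"a": [5, 1], "bad": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="bad"):
            bray_curtis(t)

    def test_invariants_and_min_identity(self):
        rng = np.random.default_rng(7)
        t = random_count_table(rng, 9, 6)
        dm = bray_curtis(t)
        assert (dm.data >= -1e-12).all() and (dm.data <= 1 + 1e-12).all()
        # 1 - 2*sum(min)/sum(x+y) identity
        x = t.counts.to_numpy(dtype=float)
        for i, j in itertools.combinations(range(6), 2):
            xi, xj = x[:, i], x[:, j]
            alt = 1 - 2 * np.minimum(xi, xj).sum() / (xi + xj).sum()
            assert dm.data[i, j] == pytest.approx(alt, abs=1e-12)
        # genotype reordering leaves distances unchanged
        perm = rng.permutation(t.counts.index)
        dm2 = bray_curtis(GenotypeCountTable(t.counts.loc[perm]))
        assert np.allclose(dm.data, dm2.data)


class TestPCoA:
    def test_two_samples_at_distance_d(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        res = pcoa(dm)
        coords = res.coordinates[:, 0]
        assert sorted(coords) == pytest.approx([-0.2, 0.2])
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_distance_recovery(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        dm = DistanceMatrix(list(range(10)), squareform(pdist(pts)))
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, dm.data, atol=1e-8)
        assert res.n_negative_eigenvalues == 0

    def test_three_equidistant_samples(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_matches_skbio_on_bray_curtis(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        t = random_count_table(rng, 12, 7)
        dm = bray_curtis(t)
        ours = pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=[str(s) for s in dm.sample_ids]))
        k = ours.coordinates.shape[1]
        their_eig = theirs.eigvals.to_numpy()[:k]
        assert np.allclose(ours.eigenvalues[:k], their_eig, atol=1e-8)
        # embeddings agree up to axis sign
        ref = theirs.samples.to_numpy()[:, :k]
        for axis in range(k):
            c = ours.coordinates[:, axis]
            assert (np.allclose(c, ref[:, axis], atol=1e-6)
                    or np.allclose(c, -ref[:, axis], atol=1e-6))


def brute_force_permanova(dm: np.ndarray, labels: list):
    """Independent pseudo-F over every distinct relabeling (test-side oracle)."""
    labels = np.array(labels)
    n = len(labels)

    def pseudo_f(lab):
        groups = set(lab)
        ss_total = (dm ** 2).sum() / (2 * n)
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            ss_within += (dm[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
        a = len(groups)
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    seen = set()
    fs = []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        fs.append(pseudo_f(np.array(perm)))
    fs = np.array(fs)
    return f_obs, fs, (fs >= f_obs - 1e-12).mean()


class TestPermanova:
    def _clustered_dm(self, rng, spread=0.05):
        pts = np.vstack([rng.normal(0, spread, size=(3, 2)),
                         rng.normal(5, spread, size=(3, 2))])
        return DistanceMatrix(list(range(6)), squareform(pdist(pts)))

    def test_exhaustive_equals_brute_force_3v3(self):
        rng = np.random.default_rng(8)
        dm = self._clustered_dm(rng, spread=1.5)
        labels = ["x", "x", "x", "y", "y", "y"]
        result = permanova(dm, labels, mode="exhaustive")
        f_obs, fs, p = brute_force_permanova(dm.data, labels)
        assert result.permutations == 20
        assert result.statistic == pytest.approx(f_obs, rel=1e-12)
        assert result.p_value == pytest.approx(p, abs=1e-12)

    def test_matches_skbio_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        t = random_count_table(rng, 10, 8)
        dm = bray_curtis(t)
        labels = ["u"] * 4 + ["v"] * 4
        ours = permanova(dm, labels, permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=[str(s) for s in dm.sample_ids]),
            grouping=labels, permutations=0)
        assert ours.statistic == pytest.approx(theirs["test statistic"],
                                               rel=1e-10)

    def test_separated_clusters_hit_permutation_floor(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 0.05, size=(8, 2)),
                         rng.normal(5, 0.05, size=(8, 2))])
        dm = DistanceMatrix(list(range(16)), squareform(pdist(pts)))
        labels = ["a"] * 8 + ["b"] * 8
        res = permanova(dm, labels, permutations=199, seed=3)
        assert res.p_value == pytest.approx(1 / 200)
        # at 3+3 the exact null has exactly 2 cluster-respecting relabelings
        small = self._clustered_dm(rng)
        exact = permanova(small, ["a", "a", "a", "b", "b", "b"],
                          mode="exhaustive")
        assert exact.p_value == pytest.approx(2 / 20)

    def test_single_group_and_tiny_group_rejected(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            squareform(pdist(np.arange(3)[:, None])))
        with pytest.raises(ValueError):
            permanova(dm, ["g", "g", "g"])
        with pytest.raises(ValueError):
            permanova(dm, ["g", "g", "h"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        t = random_count_table(rng, 8, 8)
        dm = bray_curtis(t)
        labels = ["a"] * 4 + ["b"] * 4
        p1 = permanova(dm, labels, permutations=199, seed=5).p_value
        p2 = permanova(dm, labels, permutations=199, seed=5).p_value
        assert p1 == p2


class TestPermdisp:
    def test_mirror_groups_equal_dispersion(self):
        pts = np.array([[0, 0], [1, 0], [0, 1],
                        [10, 10], [11, 10], [10, 11]], dtype=float)
        dm = DistanceMatrix(list(range(6)), squareform(pdist(pts)))
        labels = ["a"] * 3 + ["b"] * 3
        res = permdisp(dm, labels, permutations=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value > 0.9

    def test_centroid_distances_euclidean_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(9, 3))
        labels = ["a"] * 4 + ["b"] * 5
        dm = DistanceMatrix(list(range(9)), squareform(pdist(pts)))
        dists = centroid_distances(dm, labels)
        expected = np.empty(9)
        expected[:4] = np.linalg.norm(pts[:4] - pts[:4].mean(axis=0), axis=1)
        expected[4:] = np.linalg.norm(pts[4:] - pts[4:].mean(axis=0), axis=1)
        assert np.allclose(dists, expected, atol=1e-8)

    def test_identical_samples_have_zero_centroid_distance(self):
        t = _table({"a": [5, 5], "b": [5, 5], "c": [9, 1], "d": [1, 9]},
                   index=["g1", "g2"])
        dm = bray_curtis(t)
        dists = centroid_distances(dm, ["u", "u", "v", "v"])
        assert dists[0] == pytest.approx(0.0, abs=1e-10)
        assert dists[1] == pytest.approx(0.0, abs=1e-10)

    def test_tight_vs_diffuse_detected(self):
        rng = np.random.default_rng(14)
        pts = np.vstack([rng.normal(0, 0.01, size=(8, 2)),
                         rng.normal(0, 5.0, size=(8, 2))])
        dm = DistanceMatrix(list(range(16)), squareform(pdist(pts)))
        labels = ["tight"] * 8 + ["diffuse"] * 8
        res = permdisp(dm, labels, permutations=199, seed=1)
        assert res.p_value <= 0.01


class TestGenusAggregate:
    def _taxonomy(self):
        return TaxonomyTable(pd.DataFrame.from_dict({
            "g1": {"genus": "Wolbachia"}, "g2": {"genus": "Wolbachia"},
            "g3": {"genus": "Serratia"}, "g4": {"genus": ""},
        }, orient="index"))

    def test_same_genus_zotus_are_additive(self):
        t = _table({"s": [30, 70, 60, 40]}, index=["g1", "g2", "g3", "g4"])
        rel = genus_aggregate(t, self._taxonomy(), 0.0)
        assert rel.loc["Wolbachia", "s"] == pytest.approx(0.5)
        assert rel.loc["unclassified", "s"] == pytest.approx(0.2)

    def test_below_threshold_goes_to_other(self):
        t = _table({"s": [96, 0, 4, 0]}, index=["g1", "g2", "g3", "g4"])
        rel = genus_aggregate(t, self._taxonomy(), 0.05)
        assert "Serratia" not in rel.index
        assert rel.loc["other", "s"] == pytest.approx(0.04)

    def test_all_above_threshold_other_is_zero(self):
        t = _table({"s": [50, 0, 50, 0]}, index=["g1", "g2", "g3", "g4"])
        rel = genus_aggregate(t, self._taxonomy(), 0.05)
        assert rel.loc["other", "s"] == 0.0
        assert rel["s"].sum() == pytest.approx(1.0)


class TestAlphaCompare:
    def test_identical_arms(self):
        # duplicate samples across arms -> identical Shannon sets
        t = _table({"c1": [5, 5], "c2": [8, 2], "t1": [5, 5], "t2": [8, 2]},
                   index=["g1", "g2"])
        from ampliquant.containers import SampleMetadata
        meta = [
            SampleMetadata("c1", species="x", line="x1", treatment="control"),
            SampleMetadata("c2", species="x", line="x1", treatment="control"),
            SampleMetadata("t1", species="x", line="x1", treatment="hotshot"),
            SampleMetadata("t2", species="x", line="x1", treatment="hotshot"),
        ]
        results, _ = alpha_compare(t, meta)
        assert results[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert results[0].p_value == pytest.approx(1.0)


class TestPerLineBetaReport:
    def test_structure_and_skips(self, small_sim):
        _, bundle, _ = small_sim
        res = decontaminate(bundle)
        results, skipped = per_line_beta_report(
            res.decontaminated, bundle.metadata,
            sample_ids=res.kept_samples, permutations=99, seed=11)
        lines = {m.line for m in bundle.experimental_samples()}
        assert {r.line for r in results} | {s[0] for s in skipped} == lines
        for r in results:
            assert r.n_control >= 2 and r.n_hotshot >= 2
            assert 0 < r.permanova.p_value <= 1
            assert len(r.ordination.proportion_explained) >= 1

    def test_deterministic(self, small_sim):
        _, bundle, _ = small_sim
        res = decontaminate(bundle)
        kwargs = dict(sample_ids=res.kept_samples, permutations=49, seed=21)
        a, _ = per_line_beta_report(res.decontaminated, bundle.metadata, **kwargs)
        b, _ = per_line_beta_report(res.decontaminated, bundle.metadata, **kwargs)
        assert [(r.line, r.permanova.p_value, r.permdisp.p_value)
                for r in a] == [(r.line, r.permanova.p_value,
                                 r.permdisp.p_value) for r in b]

    def test_dominant_swap_hits_floor(self):
        rng = np.random.default_rng(31)
        from ampliquant.containers import SampleMetadata
        cols, meta = {}, []
        for i in range(6):
            arm = "control" if i < 3 else "hotshot"
            dominant = 0 if arm == "control" else 1
            v = rng.integers(0, 10, size=3)
            v[dominant] += 1000
            cols[f"s{i}"] = v
            meta.append(SampleMetadata(f"s{i}", species="x", line="x1",
                                       treatment=arm))
        t = _table(cols, index=["gA", "gB", "gC"])
        dm = bray_curtis(t)
        res = permanova(dm, [m.treatment for m in meta], mode="exhaustive")
        assert res.p_value == pytest.approx(2 / 20)
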