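import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from elsanet import (
    AbundanceTable,
    ValidationError,
    aggregate_families,
    bray_curtis,
    heatmap_filter,
    pcoa,
    permanova,
    rarefy,
    shannon,
)


def _table(values, meta=None, units="counts", otus=None):
    data = pd.DataFrame(values, index=[f"s{i}" for i in range(len(values))],
                        columns=otus)
    meta = pd.DataFrame(
        meta
        or {
            "treatment": ["x"] * len(data),
            "generation": list(range(1, len(data) + 1)),
            "replicate": [1] * len(data),
        },
        index=data.index,
    )
    return AbundanceTable(data, meta, units=units)


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = _table([[60, 40], [70, 30]])
        out = rarefy(t, 100, seed=1)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_row_sums_equal_depth(self, rng):
        t = _table(rng.integers(50, 200, size=(6, 5)))
        out = rarefy(t, 100, seed=2)
        assert (out.data.sum(axis=1) == 100).all()

    def test_shallow_sample_is_error(self):
        t = _table([[60, 39]])
        with pytest.raises(ValidationError, match="s0"):
            rarefy(t, 100)

    def test_hypergeometric_expectation(self):
        # (900, 100) subsampled to 100 reads: E[count of OTU 1] = 90
        t = _table([[900, 100]])
        draws = np.array([rarefy(t, 100, seed=s).data.iloc[0, 0] for s in range(1000)])
        var = 100 * 0.9 * 0.1 * (900 / 999)
        assert abs(draws.mean() - 90) < 3 * math.sqrt(var / 1000)

    def test_deterministic_under_seed(self, rng):
        t = _table(rng.integers(50, 200, size=(4, 6)))
        a = rarefy(t, 120, seed=9)
        b = rarefy(t, 120, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert math.isclose(shannon([10, 10, 10, 10]), math.log(4), rel_tol=1e-12)

    def test_single_taxon_is_zero(self):
        assert shannon([100]) == 0.0

    def test_direct_formula_value(self):
        assert math.isclose(shannon([1, 2, 3, 4]), 1.2799, abs_tol=5e-5)

    def test_uniform_maximizes(self, rng):
        s = 6
        h_max = shannon(np.ones(s))
        for _ in range(50):
            assert shannon(rng.random(s) + 1e-9) <= h_max + 1e-12

    def test_all_zero_error(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_hand_example(self):
        d = bray_curtis(_table([[6, 2], [2, 2]], units="counts"))
        assert math.isclose(d[("s0", "s1")], 1 / 3)

    def test_identity_and_disjoint_bounds(self):
        d = bray_curtis(_table([[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 3, 7]]))
        assert d[("s0", "s1")] == 0.0
        assert math.isclose(d[("s0", "s2")], 1.0)

    def test_range_and_symmetry(self, rng):
        t = _table(rng.random((8, 10)) + 1e-6)
        d = bray_curtis(t).data
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        np.testing.assert_allclose(d, d.T)

    def test_all_zero_sample_error(self):
        with pytest.raises(ValidationError, match="s1"):
            bray_curtis(_table([[1, 2], [0, 0]]))


class TestPcoa:
    def test_collinear_points_recover_distances(self):
        d = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        res = pcoa(d)
        assert res.proportion_explained[0] > 1 - 1e-9
        coords = res.coordinates["PCo1"]
        assert math.isclose(abs(coords["a"] - coords["c"]), 2, abs_tol=1e-9)

    def test_equidistant_simplex_has_equal_eigenvalues(self):
        n = 4
        d = DistanceMatrix(np.ones((n, n)) - np.eye(n), ids=list("abcd"))
        res = pcoa(d)
        np.testing.assert_allclose(res.eigenvalues, res.eigenvalues[0], rtol=1e-9)

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.standard_normal((10, 4))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rec, d.data, atol=1e-9)

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.standard_normal((8, 3))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(8)])
        mine = pcoa(d)
        ref = skbio_pcoa(d, number_of_dimensions=len(mine.eigenvalues))
        np.testing.assert_allclose(
            mine.eigenvalues, ref.eigvals.to_numpy()[: len(mine.eigenvalues)], atol=1e-8
        )

    def test_sample_permutation_invariance(self, rng):
        pts = rng.standard_normal((6, 3))
        ids = [str(i) for i in range(6)]
        d = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        perm = [3, 1, 5, 0, 2, 4]
        dp = DistanceMatrix(d.data[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        np.testing.assert_allclose(pcoa(d).eigenvalues, pcoa(dp).eigenvalues, atol=1e-9)


def _oneway_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Independent one-way pseudo-F via within-group distance sums."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(np.unique(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _meta(self, labels, gens=None):
        n = len(labels)
        return pd.DataFrame(
            {"treatment": labels, "generation": gens or [1] * n,
             "replicate": list(range(1, n + 1))},
            index=[f"s{i}" for i in range(n)],
        )

    def test_exhaustive_enumeration_oracle_n4(self, rng):
        """Monte-Carlo p agrees with the full 4! relabeling distribution."""
        pts = rng.standard_normal((4, 3))
        pts[:2] += 2.0
        d2 = squareform(pdist(pts)) ** 2
        labels = np.array(["a", "a", "b", "b"])
        f_obs = _oneway_f(d2, labels)
        count = sum(
            _oneway_f(d2, labels[list(perm)]) >= f_obs - 1e-12
            for perm in itertools.permutations(range(4))
        )
        p_exact = count / 24
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(4)])
        res = permanova(d, self._meta(list(labels)), ["treatment"], n_perm=999, seed=3,
                        interaction=False)
        p_mc = res["treatment"]["p_value"]
        se = math.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_mc - p_exact) < 3 * se + 1 / 1000
        assert math.isclose(res["treatment"]["pseudo_F"], f_obs, rel_tol=1e-9)

    def test_perfect_separation_minimal_p(self):
        # duplicated identical samples per group: zero within, positive between
        pts = np.array([[0, 0], [0, 0], [0, 0], [5, 5], [5, 5], [5, 5]], dtype=float)
        pts += np.arange(6)[:, None] * 1e-9  # break exact zero distances
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        res = permanova(d, self._meta(["a"] * 3 + ["b"] * 3), ["treatment"],
                        n_perm=199, seed=1, interaction=False)
        # every relabeling preserving the 3+3 partition attains the observed F,
        # so the attainable floor is the atom 3!*3!*2/6! = 0.1, not 1/(n_perm+1)
        assert res["treatment"]["p_value"] == pytest.approx(0.1, abs=0.06)
        assert res["treatment"]["p_value"] >= 1 / 200

    def test_matches_skbio_oneway_statistic(self, rng):
        pts = rng.standard_normal((12, 4))
        labels = ["a", "b", "c"] * 4
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
        mine = permanova(d, self._meta(labels), ["treatment"], n_perm=99, seed=0,
                        interaction=False)
        ref = skbio_permanova(d, grouping=labels, permutations=99)
        assert math.isclose(mine["treatment"]["pseudo_F"], ref["test statistic"],
                            rel_tol=1e-9)

    def test_dfs_sum_to_n_minus_one(self, rng):
        pts = rng.standard_normal((12, 3))
        labels = ["a", "b"] * 6
        gens = [1, 1, 2, 2, 3, 3] * 2
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)])
        res = permanova(d, self._meta(labels, gens), ["generation", "treatment"],
                        n_perm=99, seed=0)
        assert res.table["df"].drop("Total").sum() == 11
        assert res.table["sum_sq"].drop("Total").sum() == pytest.approx(
            res.table.loc["Total", "sum_sq"]
        )

    def test_null_rejection_rate_calibrated(self):
        """Shuffled labels on unstructured distances reject at ~alpha."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_data = 1000
        for k in range(n_data):
            pts = rng.standard_normal((9, 3))
            d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(9)])
            labels = list(rng.permutation(["a", "b", "c"] * 3))
            res = permanova(d, self._meta(labels), ["treatment"], n_perm=199,
                            seed=int(rng.integers(2**31)), interaction=False)
            rejections += res["treatment"]["p_value"] <= 0.05
        assert 0.03 <= rejections / n_data <= 0.07

    def test_single_level_factor_error(self, rng):
        pts = rng.standard_normal((6, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(6)])
        with pytest.raises(ValidationError, match="single level"):
            permanova(d, self._meta(["a"] * 6), ["treatment"], n_perm=99)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestVeganCrossCheck:
    def test_sequential_f_matches_adonis2(self, rng, tmp_path):
        """The sequential two-factor partition matches vegan's adonis2 by-terms F."""
        n = 18
        pts = rng.standard_normal((n, 4))
        gens = np.tile([1, 2, 3], 6)
        treats = np.repeat(["a", "b", "c"], 6)
        pts[treats == "a"] += 0.8
        ids = [f"s{i}" for i in range(n)]
        d = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        meta = pd.DataFrame({"treatment": treats, "generation": gens,
                             "replicate": 1}, index=ids)
        mine = permanova(d, meta, ["generation", "treatment"], n_perm=99, seed=0,
                         interaction=True)
        dm_path, meta_path = tmp_path / "d.tsv", tmp_path / "m.tsv"
        pd.DataFrame(d.data, index=ids, columns=ids).to_csv(dm_path, sep="\t")
        meta.to_csv(meta_path, sep="\t")
        script = f"""
        suppressMessages(library(vegan))
        d <- as.dist(as.matrix(read.table("{dm_path}", sep="\\t", header=TRUE, row.names=1)))
        m <- read.table("{meta_path}", sep="\\t", header=TRUE, row.names=1)
        m$generation <- factor(m$generation); m$treatment <- factor(m$treatment)
        fit <- adonis2(d ~ generation * treatment, data=m, permutations=99, by="terms")
        cat(fit$F[1:3], sep="\\n")
        """
        r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                           timeout=120)
        assert r.returncode == 0, r.stderr
        f_ref = [float(v) for v in r.stdout.split()]
        f_mine = mine.table["pseudo_F"].to_numpy()[:3]
        np.testing.assert_allclose(f_mine, f_ref, rtol=1e-6)


class TestAggregation:
    def test_top_k_ranking_matches_hand_sort(self):
        rel = _table(
            [[0.5, 0.2, 0.2, 0.1], [0.4, 0.2, 0.2, 0.2]],
            units="relative", otus=["o1", "o2", "o3", "o4"],
        )
        tax = {"o1": "F1", "o2": "F2", "o3": "F2", "o4": "F3"}
        out = aggregate_families(rel, tax, top_k=2)
        # grand means: F1 0.45, F2 0.40, F3 0.15 -> top two are F1, F2
        assert list(out.data.columns) == ["F1", "F2", "Other"]
        np.testing.assert_allclose(out.data["Other"], [0.1, 0.2])
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0)

    def test_single_family_collapses_to_row_sums(self):
        rel = _table([[0.6, 0.4]], units="relative", otus=["o1", "o2"])
        out = aggregate_families(rel, {"o1": "F", "o2": "F"}, top_k=3)
        assert list(out.data.columns) == ["F"]
        np.testing.assert_allclose(out.data["F"], 1.0)

    def test_unclassified_pooling(self):
        rel = _table([[0.7, 0.3]], units="relative", otus=["o1", "o2"])
        out = aggregate_families(rel, {"o1": "F"}, top_k=5)
        assert "unclassified" in out.data.columns


class TestHeatmapFilter:
    def test_strict_below_boundary(self):
        rel = _table([[0.074, 0.075, 0.851]], units="relative", otus=["lo", "at", "hi"])
        out = heatmap_filter(rel, 0.075)
        assert out.otu_ids == ["at", "hi"]

    def test_threshold_bounds(self):
        rel = _table([[1.0]], units="relative", otus=["o"])
        with pytest.raises(ValidationError):
            heatmap_filter(rel, 0)
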