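import numpy as np
import pandas as pd
import pytest

from cladepath.niche import (
    EnvGrid,
    NicheError,
    build_niche_table,
    extract_env,
    filter_min_occurrences,
    jaccard_distances,
    pca,
    pcoa,
    shannon_breadth,
    summarize_categorical,
    summarize_env,
    annualize,
)


def incidence(rows, species=None):
    rows = np.atleast_2d(rows)
    species = species or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=species, columns=[f"f{j}" for j in range(rows.shape[1])])


class TestJaccard:
    def test_known_values(self):
        m = incidence([[1, 1, 0], [1, 0, 1], [1, 1, 0], [0, 0, 1]])
        d = jaccard_distances(m)
        assert d.iloc[0, 2] == 0  # identical rows
        assert d.iloc[0, 1] == pytest.approx(2 / 3)  # 1 - 1/3
        assert d.iloc[0, 3] == 1  # disjoint

    def test_all_zero_row_raises(self):
        with pytest.raises(NicheError):
            jaccard_distances(incidence([[1, 0], [0, 0]]))

    def test_triangle_inequality_random(self, rng):
        """Jaccard distance is a metric: triangle inequality on 100 random
        incidence matrices."""
        for _ in range(100):
            m = (rng.random((6, 8)) < 0.5).astype(int)
            m[m.sum(axis=1) == 0, 0] = 1
            d = jaccard_distances(incidence(m)).to_numpy()
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPcoa:
    def test_collinear_points(self):
        pts = np.array([0.0, 1.0, 2.0])
        D = np.abs(pts[:, None] - pts[None, :])
        ord_ = pcoa(pd.DataFrame(D), k=1)
        c = ord_.coords.to_numpy()[:, 0]
        # spacing recovered up to an overall sign
        assert np.abs(np.diff(c)) == pytest.approx([1.0, 1.0], abs=1e-9)
        assert np.sign(np.diff(c)[0]) == np.sign(np.diff(c)[1])
        assert ord_.proportion_explained[0] == pytest.approx(1.0)

    def test_identical_points_identical_coords(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        ord_ = pcoa(pd.DataFrame(D), k=1)
        assert ord_.coords.iloc[0, 0] == pytest.approx(ord_.coords.iloc[1, 0])

    def test_distance_reconstruction_2d(self, rng):
        """Classical scaling of Euclidean distances from a planar cloud
        reproduces the distances with 2 axes."""
        pts = rng.normal(size=(12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ord_ = pcoa(pd.DataFrame(D), k=2)
        c = ord_.coords.to_numpy()
        D2 = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        assert np.abs(D - D2).max() < 1e-8

    def test_matches_skbio(self, rng):
        """Independent cross-check against scikit-bio's PCoA."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        pts = rng.normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = pcoa(pd.DataFrame(D), k=2)
        theirs = skbio_ord.pcoa(D, number_of_dimensions=2)
        ref = theirs.samples.to_numpy()[:, :2]
        got = ours.coords.to_numpy()
        for k in range(2):
            assert np.allclose(np.abs(got[:, k]), np.abs(ref[:, k]), atol=1e-8)

    def test_too_many_axes_raises(self):
        D = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(NicheError):
            pcoa(pd.DataFrame(D), k=2)


class TestShannon:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ([5], 0.0),
            ([1, 1, 1], np.log(3)),
            ([2, 1, 1], 1.0397207708399179),
        ],
    )
    def test_values(self, x, expected):
        assert shannon_breadth(x) == pytest.approx(expected, abs=1e-10)

    def test_all_zero_raises(self):
        with pytest.raises(NicheError):
            shannon_breadth([0, 0])

    def test_maximized_at_equal_usage(self):
        """For fixed family count k, H is maximal at equal usage (small
        enumeration over count vectors)."""
        for k in (2, 3):
            hmax = shannon_breadth([1] * k)
            for counts in np.ndindex(*(4,) * k):
                if min(counts) == 0:
                    continue
                assert shannon_breadth(list(counts)) <= hmax + 1e-12


class TestOccurrenceFilter:
    def test_inclusive_threshold(self):
        occ = pd.DataFrame(
            {
                "species": ["a"] * 9 + ["b"] * 10 + ["c"] * 50,
                "lon": 0.0,
                "lat": 0.0,
            }
        )
        kept = filter_min_occurrences(occ, 10)
        assert set(kept["species"]) == {"b", "c"}

    def test_nmin_one_is_identity(self):
        occ = pd.DataFrame({"species": ["a", "b"], "lon": [0.0, 1.0], "lat": [0.0, 1.0]})
        assert filter_min_occurrences(occ, 1).equals(occ)

    def test_against_count_oracle(self, rng):
        sp = rng.choice([f"s{i}" for i in range(20)], size=400)
        occ = pd.DataFrame({"species": sp, "lon": 0.0, "lat": 0.0})
        kept = set(filter_min_occurrences(occ, 15)["species"])
        # brute-force count oracle
        from collections import Counter

        oracle = {s for s, c in Counter(sp).items() if c >= 15}
        assert kept == oracle


class TestEnvGrid:
    def grid(self, values, **kw):
        return EnvGrid("g", values, lon_min=0.0, lat_min=0.0, cell_size=1.0, **kw)

    def test_single_point_cell_center(self):
        g = self.grid(np.arange(12, dtype=float).reshape(3, 4))
        occ = pd.DataFrame({"species": ["a"], "lon": [1.5], "lat": [2.5]})
        vals = extract_env(occ, g)
        # row 0 is the northern edge: lat 2.5 -> row 0, lon 1.5 -> col 1
        assert vals["a"].tolist() == [1.0]

    def test_constant_grid(self):
        g = self.grid(np.full((3, 3), 7.0))
        occ = pd.DataFrame({"species": ["a"] * 4, "lon": [0.5, 1.5, 2.5, 0.5], "lat": [0.5, 1.5, 2.5, 1.5]})
        assert np.all(extract_env(occ, g)["a"] == 7.0)

    def test_random_points_match_bruteforce_lookup(self, rng):
        vals = rng.normal(size=(8, 10))
        g = self.grid(vals)
        lon = rng.uniform(0, 10, 50)
        lat = rng.uniform(0, 8, 50)
        occ = pd.DataFrame({"species": "a", "lon": lon, "lat": lat})
        got = extract_env(occ, g)["a"]
        oracle = [vals[int(np.floor(8 - la)), int(np.floor(lo))] for lo, la in zip(lon, lat)]
        assert np.allclose(got, oracle)

    def test_no_overlap_raises(self):
        g = self.grid(np.zeros((3, 3)))
        occ = pd.DataFrame({"species": ["a"], "lon": [100.0], "lat": [100.0]})
        with pytest.raises(NicheError):
            extract_env(occ, g)

    def test_roundtrip_io(self, tmp_path, rng):
        g = self.grid(rng.normal(size=(4, 5)))
        g.write(tmp_path)
        g2 = EnvGrid.read(tmp_path, "g")
        assert np.allclose(g.values, g2.values)
        assert g2.cell_size == g.cell_size

    def test_annualize(self):
        layers = [self.grid(np.full((2, 2), float(m))) for m in range(1, 13)]
        assert annualize(layers, "mean").values[0, 0] == pytest.approx(6.5)
        assert annualize(layers, "sum").values[0, 0] == pytest.approx(78.0)


class TestSummaries:
    def test_constant_list(self):
        assert summarize_env([3.0, 3.0, 3.0]) == (3.0, 0.0)

    def test_mean_and_quantile_oracle(self):
        mean, iqr = summarize_env(np.arange(1, 6))
        assert mean == 3.0
        v = np.arange(1, 101, dtype=float)
        mean, iqr = summarize_env(v)
        # type-7 oracle
        assert iqr == pytest.approx(np.percentile(v, 75) - np.percentile(v, 25))

    def test_categorical(self):
        mode, rich = summarize_categorical([1, 2, 2, 3])
        assert (mode, rich) == (2.0, 3)

    def test_empty_raises(self):
        with pytest.raises(NicheError):
            summarize_env([])


class TestPca:
    def test_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=30)
        f = pd.DataFrame({"a": x, "b": 2 * x + 1})
        ord_ = pca(f, k=1)
        assert ord_.proportion_explained[0] == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(40, 3)) @ np.diag([3.0, 1.0, 0.3])
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        # rotation invariance holds for covariance-PCA of already unit-scaled data
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        v1 = pca(pd.DataFrame(X), k=2).proportion_explained
        v2 = pca(pd.DataFrame(X @ R), k=2).proportion_explained
        # variance ordering is preserved up to standardization effects
        assert v1[0] > v1[1] and v2[0] > v2[1]

    def test_scores_match_eigh_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)))
        ord_ = pca(X, k=4)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        C = np.cov(Z, rowvar=False)
        vals, vecs = np.linalg.eigh(C)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        oracle = Z @ vecs
        got = ord_.coords.to_numpy()
        for k in range(4):
            assert np.allclose(np.abs(got[:, k]), np.abs(oracle[:, k]), atol=1e-8)
        assert ord_.proportion_explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        f = pd.DataFrame({"a": rng.normal(size=10), "b": 1.0})
        with pytest.warns(UserWarning):
            ord_ = pca(f, k=1)
        assert list(ord_.coords.columns) == ["PC1"]


class TestBuildNicheTable:
    def test_assembles_complete_table(self, rng):
        n_sp = 8
        species = [f"s{i}" for i in range(n_sp)]
        inc = incidence((rng.random((n_sp, 6)) < 0.5).astype(int), species)
        inc.iloc[:, 0] = 1
        rows = []
        for i, s in enumerate(species):
            for _ in range(12):
                rows.append({"species": s, "lon": rng.uniform(0, 10), "lat": rng.uniform(0, 8)})
        occ = pd.DataFrame(rows)
        grids = [
            EnvGrid(f"env{k}", rng.normal(size=(8, 10)), 0.0, 0.0, 1.0)
            for k in range(3)
        ]
        t = build_niche_table(inc, occ, grids, n_min=10, k_axes=2)
        assert len(t) == n_sp
        assert {"host_pco1", "host_pco2", "host_breadth", "env_pc1", "env_pc2"} <= set(t.columns)
        assert not t.isna().any().any()
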