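"""Binary-profile distances, PCoA, Ward clustering, heatmap ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import holophylo as hp
from holophylo.formats import TraitMatrix
from holophylo.profiles import (
    DistanceMatrix,
    heatmap_order,
    pcoa,
    profile_distance,
    ward_cluster,
)


def tm(rows, species=None, traits=None):
    rows = np.asarray(rows)
    species = species or [f"s{i}" for i in range(rows.shape[0])]
    traits = traits or [f"g{j}" for j in range(rows.shape[1])]
    return TraitMatrix(pd.DataFrame(rows, index=species, columns=traits))


@pytest.mark.parametrize("metric", ["jaccard", "simple_matching", "pearson_complement"])
def test_identical_profiles_distance_zero(metric):
    m = tm([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0]])
    d = profile_distance(m, metric)
    assert d.values[0, 1] == 0.0
    assert np.allclose(np.diag(d.values), 0.0)
    assert np.allclose(d.values, d.values.T)


def test_hand_counted_distances():
    m = tm([[1, 1, 0, 0], [0, 0, 1, 1]])
    assert profile_distance(m, "jaccard").values[0, 1] == pytest.approx(1.0)
    # phi = -1, complement unclamped: distance 2
    assert profile_distance(m, "pearson_complement").values[0, 1] == pytest.approx(2.0)

    m2 = tm([[1, 1, 0], [1, 0, 0]])
    assert profile_distance(m2, "jaccard").values[0, 1] == pytest.approx(0.5)
    assert profile_distance(m2, "simple_matching").values[0, 1] == pytest.approx(1 / 3)


def test_constant_profile_warns_and_uses_convention():
    m = tm([[1, 1, 1], [1, 1, 1], [1, 0, 1]])
    with pytest.warns(UserWarning, match="constant"):
        d = profile_distance(m, "pearson_complement")
    assert d.values[0, 1] == 0.0  # identical constant profiles
    assert d.values[0, 2] == 1.0  # constant vs anything else


def test_triangle_inequality_binary_metrics():
    rng = np.random.default_rng(11)
    for _ in range(30):
        m = tm(rng.integers(0, 2, size=(6, 15)))
        for metric in ("jaccard", "simple_matching"):
            d = profile_distance(m, metric).values
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_pcoa_right_triangle_exact():
    d = DistanceMatrix(["x", "y", "z"], np.array(
        [[0.0, 3, 4], [3, 0, 5], [4, 5, 0]]), "euclid")
    ord_ = pcoa(d, n_axes=3)
    assert len(ord_.eigenvalues) == 2  # only two positive axes
    rebuilt = squareform(pdist(ord_.coordinates))
    assert np.abs(rebuilt - d.values).max() < 1e-9
    # axes orthogonal, sign convention: first nonzero loading positive
    gram = ord_.coordinates.T @ ord_.coordinates
    assert np.abs(gram - np.diag(np.diag(gram))).max() < 1e-9
    for a in range(ord_.coordinates.shape[1]):
        col = ord_.coordinates[:, a]
        assert col[np.flatnonzero(np.abs(col) > 1e-12)[0]] > 0


def test_pcoa_planar_points_and_duplicates():
    pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [0.3, 0.7]])
    d = squareform(pdist(pts))
    ord_ = pcoa(DistanceMatrix([f"p{i}" for i in range(5)], d, "euclid"), n_axes=4)
    assert len(ord_.eigenvalues) == 2  # intrinsically 2-D
    dup = np.vstack([pts, pts[0]])
    d2 = squareform(pdist(dup))
    ord2 = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], d2, "euclid"), n_axes=2)
    assert np.allclose(ord2.coordinates[0], ord2.coordinates[5], atol=1e-9)


def test_pcoa_fully_euclidean_reproduces_all_distances():
    rng = np.random.default_rng(21)
    m = tm(rng.integers(0, 2, size=(8, 30)))
    x = m.data.to_numpy(dtype=float)
    d = squareform(pdist(x))  # Euclidean-embeddable by construction
    ord_ = pcoa(DistanceMatrix(m.species, d, "euclid"), n_axes=8)
    rebuilt = squareform(pdist(ord_.coordinates))
    assert np.abs(rebuilt - d).max() < 1e-9
    assert ord_.negative_eigenvalue_mass < 1e-9


def test_pcoa_agrees_with_skbio_reference():
    from skbio.stats.ordination import pcoa as skbio_pcoa
    import skbio

    rng = np.random.default_rng(31)
    m = tm(rng.integers(0, 2, size=(7, 25)))
    d = profile_distance(m, "jaccard")
    ours = pcoa(d, n_axes=4)
    ref = skbio_pcoa(skbio.DistanceMatrix(d.values, ids=d.labels))
    ref_vals = np.sort(np.asarray(ref.eigvals))[::-1]
    k = len(ours.eigenvalues)
    assert np.allclose(ours.eigenvalues, ref_vals[:k], atol=1e-9)
    ref_coords = np.asarray(ref.samples)[:, :k]
    assert np.allclose(np.abs(ours.coordinates), np.abs(ref_coords), atol=1e-8)


def test_pcoa_degenerate_error():
    with pytest.raises(ValueError, match="degenerate|positive"):
        pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "zero"), 1)


def test_ward_recovers_planted_blocks():
    rng = np.random.default_rng(41)
    proto = np.zeros((2, 40), dtype=int)
    proto[0, :20] = 1
    proto[1, 20:] = 1
    rows, labels = [], []
    for b in range(2):
        for i in range(5):
            noisy = proto[b].copy()
            flip = rng.random(40) < 0.05
            noisy[flip] = 1 - noisy[flip]
            rows.append(noisy)
            labels.append(f"b{b}_s{i}")
    m = TraitMatrix(pd.DataFrame(rows, index=labels, columns=[f"g{j}" for j in range(40)]))
    res = ward_cluster(m, "species_pearson")
    clusters = res.flat_clusters(2)
    assert len(set(clusters[clusters.index.str.startswith("b0")])) == 1
    assert len(set(clusters[clusters.index.str.startswith("b1")])) == 1
    assert set(clusters) == {1, 2}
    # merge heights weakly increase
    assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)


def test_ward_deterministic_on_ties():
    m = tm([[1, 0, 0], [0, 1, 0], [0, 0, 1]], species=["c", "a", "b"])
    r1 = ward_cluster(m, "species_pearson")
    r2 = ward_cluster(m, "species_pearson")
    assert r1.labels == ["a", "b", "c"]  # sorted label order feeds the linkage
    assert np.array_equal(r1.linkage, r2.linkage)
    assert r1.to_newick() == r2.to_newick()
    # equidistant items: the first merge joins the two smallest labels
    assert set(r1.linkage[0, :2].astype(int)) == {0, 1}


def test_ortholog_mode_clusters_duplicate_traits_together():
    rng = np.random.default_rng(51)
    col = rng.integers(0, 2, size=8)
    data = pd.DataFrame(
        {"gA": col, "gB": col, "gC": 1 - col, "gD": 1 - col},
        index=[f"s{i}" for i in range(8)],
    )
    res = ward_cluster(TraitMatrix(data), "orthologs_euclidean")
    clusters = res.flat_clusters(2)
    assert clusters["gA"] == clusters["gB"]
    assert clusters["gC"] == clusters["gD"]
    assert clusters["gA"] != clusters["gC"]


def test_heatmap_order_identity_reversal_blocks():
    rng = np.random.default_rng(61)
    m = tm(rng.integers(0, 2, size=(5, 6)))
    assert heatmap_order(m).equals(m.data)

    rows = ward_cluster(m, "species_pearson")
    cols = ward_cluster(m, "orthologs_euclidean")
    ordered = heatmap_order(m, rows, cols)
    assert sorted(ordered.index) == sorted(m.data.index)
    assert sorted(ordered.columns) == sorted(m.data.columns)
    assert ordered.loc[m.species, m.traits].equals(m.data)  # values untouched

    other = tm(rng.integers(0, 2, size=(4, 6)), species=list("wxyz"))
    with pytest.raises(ValueError, match="row"):
        heatmap_order(m, ward_cluster(other, "species_pearson"), None)


def test_planted_lineage_profiles_cluster_at_k3():
    """Species sharing a planted repertoire profile co-cluster at k=3."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        proto = np.zeros((3, 60), dtype=int)
        proto[0, :20] = 1
        proto[1, 20:40] = 1
        proto[2, 40:] = 1
        rows, labels = [], []
        for b in range(3):
            for i in range(4):
                noisy = proto[b].copy()
                flip = rng.random(60) < 0.05
                noisy[flip] = 1 - noisy[flip]
                rows.append(noisy)
                labels.append(f"L{b}_{i}")
        m = TraitMatrix(
            pd.DataFrame(rows, index=labels, columns=[f"g{j}" for j in range(60)])
        )
        clusters = ward_cluster(m, "species_pearson").flat_clusters(3)
        ok = all(
            len(set(clusters[clusters.index.str.startswith(f"L{b}")])) == 1
            for b in range(3)
        ) and len(set(clusters)) == 3
        hits += ok
    assert hits >= 9
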