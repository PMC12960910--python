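"""IO and preprocessing chain: readers, filtering, HVG, normalization, affine."""

import numpy as np
import pytest

import spatialmix as sm
from spatialmix.data import AffineTransform, SpatialDataset, load_dataset


def make_ds(X, coords=None, **kw):
    X = np.asarray(X, dtype=float)
    if coords is None:
        coords = np.column_stack([np.arange(len(X)), np.zeros(len(X))])
    return SpatialDataset(X=X, coords=coords, **kw)


# -- load_dataset -------------------------------------------------------------


def test_load_delimited_matrix_and_coords(tmp_path):
    m = tmp_path / "X.tsv"
    c = tmp_path / "coords.tsv"
    m.write_text("1\t0\t2\n0\t1\t0\n3\t0\t0\n0\t0\t4\n")
    c.write_text("0.0\t0.0\n1.0\t0.0\n0.0\t1.0\n1.0\t1.0\n")
    ds = load_dataset(m, c)
    assert (ds.n_units, ds.n_features) == (4, 3)
    np.testing.assert_allclose(ds.X[0], [1, 0, 2])


def test_load_mismatched_coords_mentions_both_counts(tmp_path):
    m = tmp_path / "X.tsv"
    c = tmp_path / "coords.tsv"
    m.write_text("1\t2\n3\t4\n5\t6\n7\t8\n")
    c.write_text("0\t0\n1\t0\n2\t0\n")
    with pytest.raises(ValueError, match=r"coordinate rows \(3\) != units \(4\)"):
        load_dataset(m, c)


def test_matrix_market_matches_dense_reader(tmp_path):
    import scipy.io
    import scipy.sparse as sp

    rng = np.random.default_rng(0)
    X = rng.poisson(1.0, size=(6, 4)).astype(float)
    X[0, 0] = 0.0  # explicit zero entry in the triplet file
    mm = tmp_path / "X.mtx"
    coo = sp.coo_matrix(X)
    scipy.io.mmwrite(mm, coo)
    dense = tmp_path / "X.tsv"
    np.savetxt(dense, X, delimiter="\t")
    coords = tmp_path / "coords.tsv"
    np.savetxt(coords, np.zeros((6, 2)), delimiter="\t")
    ds_mm = load_dataset(mm, coords)
    ds_tsv = load_dataset(dense, coords)
    np.testing.assert_allclose(ds_mm.X, ds_tsv.X)


def test_h5ad_roundtrip(tmp_path):
    ds = sm.generate(sm.SyntheticSpec(n_units=50, k_domains=2, m_features=10, seed=0))
    sm.data.save_dataset(ds, tmp_path / "f.h5ad", tmp_path / "f.tif")
    back = load_dataset(tmp_path / "f.h5ad", _coords_file(tmp_path, ds), tmp_path / "f.tif")
    np.testing.assert_allclose(back.X, ds.X, rtol=1e-6)
    assert back.image.shape == ds.image.shape


def _coords_file(tmp_path, ds):
    p = tmp_path / "coords.tsv"
    np.savetxt(p, ds.coords, delimiter="\t")
    return p


def test_unreadable_image_names_path(tmp_path):
    with pytest.raises(FileNotFoundError, match="nope.tif"):
        sm.read_image(tmp_path / "nope.tif")


# -- filtering ----------------------------------------------------------------


def test_filter_removes_empty_unit_then_empty_feature():
    ds = make_ds([[1, 0], [0, 0]])
    out = sm.filter_units_and_features(ds)
    assert out.X.shape == (1, 1)
    np.testing.assert_allclose(out.X, [[1.0]])


def test_filter_identity_when_nothing_empty():
    ds = make_ds([[1, 2], [3, 4]])
    out = sm.filter_units_and_features(ds)
    np.testing.assert_allclose(out.X, ds.X)
    assert list(out.unit_ids) == list(ds.unit_ids)


def test_filter_matches_brute_force_on_sparse_fixture(rng):
    X = rng.poisson(0.15, size=(50, 20)).astype(float)
    ds = make_ds(X, labels=rng.integers(0, 3, 50))
    out = sm.filter_units_and_features(ds)
    unit_keep = X.sum(axis=1) >= 1
    feat_keep = X[unit_keep].sum(axis=0) >= 1
    np.testing.assert_allclose(out.X, X[np.ix_(unit_keep, feat_keep)])
    np.testing.assert_array_equal(out.labels, ds.labels[unit_keep])


def test_filter_is_idempotent(rng):
    X = rng.poisson(0.3, size=(30, 10)).astype(float)
    once = sm.filter_units_and_features(make_ds(X))
    twice = sm.filter_units_and_features(once)
    np.testing.assert_allclose(once.X, twice.X)


def test_filter_all_units_removed_raises():
    with pytest.raises(ValueError, match="no units survive"):
        sm.filter_units_and_features(make_ds([[0, 0], [0, 0]]))


def test_exclude_prefix_drops_named_features():
    from spatialmix.preprocess import exclude_feature_prefixes

    ds = make_ds(
        np.ones((3, 3)),
        feature_names=np.array(["NegPrb1", "GeneA", "NegPrb2"]),
    )
    out = exclude_feature_prefixes(ds, ["NegPrb"])
    assert list(out.feature_names) == ["GeneA"]


# -- HVG ----------------------------------------------------------------------


def test_hvg_small_panel_passes_through(rng):
    X = rng.poisson(2.0, size=(30, 47)).astype(float) + 1
    out = sm.select_hvg(make_ds(X), n_top=3000)
    assert out.n_features == 47


def test_hvg_prefers_variable_over_constant():
    rng = np.random.default_rng(1)
    const = np.full(40, 5.0)
    var = rng.poisson(5.0, 40).astype(float)
    var[0] += 30
    X = np.column_stack([const, var]) + 1
    out = sm.select_hvg(make_ds(X), n_top=1)
    assert list(out.feature_names) == ["feature_1"]


def test_hvg_matches_binned_dispersion_oracle(rng):
    X = (rng.poisson(rng.uniform(0.5, 20, size=(1, 100)), size=(80, 100))).astype(float)
    X += 1  # avoid empty features
    out = sm.select_hvg(make_ds(X), n_top=10)

    # independent Seurat-flavor oracle: library-size normalize, per-gene
    # mean/dispersion on the de-logged scale, z-score dispersion within
    # 20 mean bins, take the top by normalized dispersion
    import pandas as pd

    Xn = X / X.sum(axis=1, keepdims=True) * np.median(X.sum(axis=1))
    mean = Xn.mean(axis=0)
    var = Xn.var(axis=0, ddof=1)
    disp = var / mean
    df = pd.DataFrame({"mean": np.log1p(mean), "disp": np.log(disp)})
    df["bin"] = pd.cut(df["mean"], bins=20)
    grouped = df.groupby("bin", observed=True)["disp"]
    z = (df["disp"] - grouped.transform("mean")) / grouped.transform("std")
    expected = set(np.argsort(-z.fillna(0).to_numpy(), kind="stable")[:10])
    got = {int(n.split("_")[1]) for n in out.feature_names}
    assert got == expected


def test_hvg_rejects_bad_n_top():
    with pytest.raises(ValueError):
        sm.select_hvg(make_ds(np.ones((3, 3))), n_top=0)


# -- normalization ------------------------------------------------------------


def test_normalize_zscores_columns(rng):
    X = rng.poisson(3.0, size=(40, 8)).astype(float) + 1
    out = sm.normalize_log_scale(make_ds(X))
    np.testing.assert_allclose(out.X.mean(axis=0), 0.0, atol=1e-6)
    np.testing.assert_allclose(out.X.std(axis=0), 1.0, atol=1e-6)


def test_normalize_constant_feature_maps_to_zero():
    # equal library sizes keep column 0 constant through normalization
    X = np.array([[2.0, 1.0, 3.0], [2.0, 2.0, 2.0], [2.0, 3.0, 1.0]])
    out = sm.normalize_log_scale(make_ds(X))
    np.testing.assert_allclose(out.X[:, 0], 0.0)
    assert np.isfinite(out.X).all()


def test_normalize_matches_step_by_step_oracle(rng):
    X = rng.poisson(4.0, size=(10, 5)).astype(float) + 1
    out = sm.normalize_log_scale(make_ds(X))
    # three independently written steps
    tot = X.sum(axis=1)
    step1 = X * (np.median(tot) / tot)[:, None]
    step2 = np.log1p(step1)
    step3 = (step2 - step2.mean(axis=0)) / step2.std(axis=0)
    np.testing.assert_allclose(out.X, step3, atol=1e-12)


def test_chained_preprocessing_matches_reference_on_counts(rng):
    """Filter -> (HVG passthrough) -> normalize on a 50x20 fixture equals
    independently composed reference steps elementwise."""
    X = rng.poisson(1.0, size=(50, 20)).astype(float)
    X[0] = 0  # one empty unit
    ds = make_ds(X)
    out = sm.preprocess(ds, n_top=3000)

    keep_u = X.sum(axis=1) >= 1
    Xf = X[keep_u]
    keep_f = Xf.sum(axis=0) >= 1
    Xf = Xf[:, keep_f]
    tot = Xf.sum(axis=1)
    ref = Xf * (np.median(tot) / tot)[:, None]
    ref = np.log1p(ref)
    sd = ref.std(axis=0)
    ref = np.where(sd > 0, (ref - ref.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    np.testing.assert_allclose(out.X, ref, atol=1e-6)


# -- affine alignment ---------------------------------------------------------


def test_affine_identity_translation_rotation():
    coords = np.array([[1.0, 0.0], [2.0, 3.0]])
    ident = AffineTransform.identity()
    np.testing.assert_allclose(sm.apply_affine(coords, ident), coords)

    shift = AffineTransform([[1, 0, 5], [0, 1, -2], [0, 0, 1]])
    np.testing.assert_allclose(sm.apply_affine(coords, shift), coords + [5, -2])

    rot90 = AffineTransform([[0, -1, 0], [1, 0, 0], [0, 0, 1]])
    np.testing.assert_allclose(
        sm.apply_affine(np.array([[1.0, 0.0]]), rot90), [[0.0, 1.0]], atol=1e-9
    )


def test_affine_roundtrip_recovers_coordinates(rng):
    theta = 0.7
    T = AffineTransform(
        [
            [2.0 * np.cos(theta), -np.sin(theta), 3.0],
            [2.0 * np.sin(theta), np.cos(theta), -1.0],
            [0, 0, 1],
        ]
    )
    coords = rng.normal(size=(20, 2))
    back = sm.apply_affine(sm.apply_affine(coords, T), T.inverse())
    np.testing.assert_allclose(back, coords, atol=1e-6)


def test_affine_rejects_singular_and_bad_bottom_row():
    with pytest.raises(ValueError, match="singular"):
        AffineTransform([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
    with pytest.raises(ValueError, match="bottom row"):
        AffineTransform([[1, 0, 0], [0, 1, 0], [0, 1, 1]])


def test_units_outside_image_are_removed_after_alignment():
    ds = make_ds(
        np.ones((3, 2)),
        coords=np.array([[1.0, 1.0], [5.0, 1.0], [20.0, 1.0]]),
    )
    ds.image = np.zeros((10, 10))
    out = sm.remove_units_outside_image(ds)
    assert out.n_units == 2
    assert list(out.unit_ids) == ["unit_0", "unit_1"]


def test_preprocess_preserves_unit_order_and_alignment(rng):
    ds = sm.generate(sm.SyntheticSpec(n_units=100, k_domains=2, m_features=15, seed=2))
    out = sm.preprocess(ds)
    # id round-trip: retained units keep their original relative order
    orig = {u: i for i, u in enumerate(ds.unit_ids)}
    positions = [orig[u] for u in out.unit_ids]
    assert positions == sorted(positions)
    kept = np.array(positions)
    np.testing.assert_allclose(out.coords, ds.coords[kept])
    np.testing.assert_array_equal(out.labels, ds.labels[kept])
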