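"""Raster preparation: resampling, gap filling, masking, pruning,
extraction and standardisation."""

import numpy as np
import pandas as pd
import pytest

from reefscape.env_stack import (EnvStack, Layer, SiteEnv, depth_mask,
                                 extract_site_values, fill_gaps,
                                 prune_correlated, read_ascii_grid,
                                 resample_nn, standardize_env,
                                 write_ascii_grid)
from reefscape.grids import Grid, haversine_km


def grid(nrows, ncols, lon0=113.0, lat0=-12.0, d=0.5):
    return Grid(lon0=lon0, lat0=lat0, dlon=d, dlat=d, nrows=nrows, ncols=ncols)


# ---------------------------------------------------------------------------
# resample_nn


def test_resample_identity():
    g = grid(5, 5)
    layer = Layer(np.arange(25, dtype=float).reshape(5, 5))
    out = resample_nn(layer, g, g)
    np.testing.assert_array_equal(out.values, layer.values)


def test_resample_upsample_blocks():
    src = grid(2, 2, d=1.0)
    tgt = Grid(lon0=src.lon0 - 0.25, lat0=src.lat0 + 0.25, dlon=0.5, dlat=0.5,
               nrows=4, ncols=4)
    layer = Layer(np.array([[1.0, 2.0], [3.0, 4.0]]))
    out = resample_nn(layer, src, tgt)
    for i in range(2):
        for j in range(2):
            block = out.values[2 * i: 2 * i + 2, 2 * j: 2 * j + 2]
            np.testing.assert_array_equal(block, layer.values[i, j])


def test_resample_matches_exhaustive_oracle():
    rng = np.random.default_rng(0)
    src = grid(10, 10, d=0.31)
    tgt = grid(25, 25, lon0=113.05, lat0=-12.04, d=0.119)
    vals = rng.standard_normal((10, 10))
    out = resample_nn(Layer(vals), src, tgt).values
    slon, slat = src.meshgrid()
    for i, lat in enumerate(tgt.lats()):
        for j, lon in enumerate(tgt.lons()):
            k = np.argmin((slon.ravel() - lon) ** 2 + (slat.ravel() - lat) ** 2)
            assert out[i, j] == vals.ravel()[k]


def test_resample_disjoint_extents_error():
    src = grid(4, 4, lon0=113.0)
    tgt = grid(4, 4, lon0=150.0)
    with pytest.raises(ValueError, match="disjoint"):
        resample_nn(Layer(np.zeros((4, 4))), src, tgt)


# ---------------------------------------------------------------------------
# fill_gaps


def test_fill_constant_field():
    g = grid(6, 6, d=0.1)
    vals = np.full((6, 6), 7.5)
    vals[2, 3] = np.nan
    vals[4, 1] = np.nan
    out = fill_gaps(Layer(vals), g)
    assert not np.isnan(out.values).any()
    assert out.values[2, 3] == pytest.approx(7.5)


def test_fill_single_neighbour_copies_value():
    g = grid(3, 3, d=0.1)
    vals = np.full((3, 3), np.nan)
    vals[0, 0] = 3.0
    out = fill_gaps(Layer(vals), g, k=1)
    assert out.values[2, 2] == pytest.approx(3.0)


def test_fill_linear_ramp_hole():
    g = grid(9, 9, d=0.05)
    lons, _ = g.meshgrid()
    vals = (lons - lons.min()) * 10.0
    truth = vals[4, 4]
    vals = vals.copy()
    vals[4, 4] = np.nan
    out = fill_gaps(Layer(vals), g)
    assert out.values[4, 4] == pytest.approx(truth, rel=0.05)


def test_fill_beyond_radius_stays_masked():
    g = grid(40, 40, d=0.5)  # ~55 km cells
    vals = np.full((40, 40), np.nan)
    vals[0, 0] = 1.0
    out = fill_gaps(Layer(vals), g, max_radius_km=60.0)
    assert np.isnan(out.values[39, 39])
    assert not np.isnan(out.values[0, 1])


def test_fill_all_masked_error():
    with pytest.raises(ValueError):
        fill_gaps(Layer(np.full((3, 3), np.nan)), grid(3, 3))


# ---------------------------------------------------------------------------
# depth_mask


def test_depth_mask_boundaries_and_count():
    g = grid(1, 4)
    depth = Layer(np.array([[-1.0, 0.0, 40.0, 41.0]]))
    stack = EnvStack(g, {"v": Layer(np.ones((1, 4)))})
    out = depth_mask(stack, depth)
    np.testing.assert_array_equal(np.isnan(out["v"].values),
                                  [[True, False, False, True]])
    # idempotent
    out2 = depth_mask(out, depth)
    np.testing.assert_array_equal(np.isnan(out2["v"].values),
                                  np.isnan(out["v"].values))


def test_depth_mask_synthetic_shelf_count():
    g = grid(10, 10)
    depth = np.linspace(-5, 90, 100).reshape(10, 10)
    expected = int(((depth >= 0) & (depth <= 40)).sum())
    stack = EnvStack(g, {"v": Layer(np.ones((10, 10)))})
    out = depth_mask(stack, Layer(depth))
    assert int((~np.isnan(out["v"].values)).sum()) == expected


# ---------------------------------------------------------------------------
# prune_correlated


def _site_env(df, classes):
    prov = pd.DataFrame("exact", index=df.index, columns=df.columns)
    return SiteEnv(df, prov, classes)


def test_prune_perfect_pair_keeps_one():
    x = np.linspace(0, 1, 10)
    df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.cos(9 * x)})
    se = _site_env(df, {"a": "SST", "b": "SST", "c": "optical"})
    kept = prune_correlated(se, r_max=0.8)
    assert ("a" in kept) != ("b" in kept)
    assert "c" in kept


def test_prune_uncorrelated_identity():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list("abcd"))
    se = _site_env(df, {c: "physical" for c in "abcd"})
    assert prune_correlated(se, r_max=0.8) == list("abcd")


def test_prune_thirteen_to_nine():
    """13 candidate variables with 4 redundant pairs prune to 9."""
    rng = np.random.default_rng(2)
    base = rng.standard_normal((26, 9))
    cols = {f"v{i}": base[:, i] for i in range(9)}
    # four near-duplicates of distinct originals
    for k, src in enumerate([0, 2, 4, 6]):
        cols[f"dup{k}"] = base[:, src] + 0.05 * rng.standard_normal(26)
    df = pd.DataFrame(cols)
    classes = {c: ("SST" if i < 5 else "optical") for i, c in enumerate(df.columns)}
    kept = prune_correlated(_site_env(df, classes), r_max=0.8)
    assert len(kept) == 9


def test_prune_protects_sole_class_member():
    x = np.linspace(0, 1, 20)
    df = pd.DataFrame({"a": x, "b": x + 1e-9})
    se = _site_env(df, {"a": "SST", "b": "optical"})
    # both are sole members of their class: neither can be dropped
    assert prune_correlated(se, r_max=0.8) == ["a", "b"]


def test_prune_never_leaves_removable_high_pairs():
    rng = np.random.default_rng(3)
    z = rng.standard_normal(30)
    df = pd.DataFrame({f"v{i}": z + 0.1 * rng.standard_normal(30) for i in range(5)})
    df["w"] = rng.standard_normal(30)
    classes = {c: "SST" for c in df.columns}
    kept = prune_correlated(_site_env(df, classes), r_max=0.8)
    corr = df[kept].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0)
    assert corr.max() < 0.8


# ---------------------------------------------------------------------------
# extract_site_values


def test_extract_exact_and_fallback():
    g = grid(3, 3, d=0.5)
    vals = np.arange(9, dtype=float).reshape(3, 3)
    vals[1, 1] = np.nan
    stack = EnvStack(g, {"v": Layer(vals)})
    lons, lats = g.meshgrid()
    sites = pd.DataFrame({"lon": [lons[0, 0], lons[1, 1]],
                          "lat": [lats[0, 0], lats[1, 1]]}, index=["s1", "s2"])
    se = extract_site_values(stack, sites)
    assert se.values.loc["s1", "v"] == 0.0
    assert se.provenance.loc["s1", "v"] == "exact"
    assert se.provenance.loc["s2", "v"] == "nearest_fallback"
    # fallback takes some neighbouring valid cell's value
    assert se.values.loc["s2", "v"] in set(np.delete(vals.ravel(), 4))


def test_extract_matches_bruteforce_nearest_valid():
    rng = np.random.default_rng(4)
    g = grid(8, 8, d=0.2)
    vals = rng.standard_normal((8, 8))
    vals[rng.random((8, 8)) < 0.4] = np.nan
    stack = EnvStack(g, {"v": Layer(vals)})
    lons = rng.uniform(g.lons()[0], g.lons()[-1], 10)
    lats = rng.uniform(g.lats()[-1], g.lats()[0], 10)
    sites = pd.DataFrame({"lon": lons, "lat": lats},
                         index=[f"s{i}" for i in range(10)])
    se = extract_site_values(stack, sites)
    glon, glat = g.meshgrid()
    valid = ~np.isnan(vals)
    for i in range(10):
        r, c = g.cell_of(lons[i], lats[i])
        if r >= 0 and valid[r, c]:
            assert se.values.iloc[i, 0] == vals[r, c]
        else:
            d = haversine_km(lons[i], lats[i], glon[valid], glat[valid])
            assert se.values.iloc[i, 0] == vals[valid][np.argmin(d)]


def test_extract_no_valid_cell_errors_with_site_name():
    g = grid(3, 3, d=0.01)
    stack = EnvStack(g, {"v": Layer(np.full((3, 3), np.nan))})
    sites = pd.DataFrame({"lon": [113.0], "lat": [-12.0]}, index=["lonely"])
    with pytest.raises(ValueError):
        extract_site_values(stack, sites)


# ---------------------------------------------------------------------------
# standardize_env


def test_standardize_median_reference():
    df = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
    se = _site_env(df, {"v": "SST"})
    out = standardize_env(se, reference="median")
    np.testing.assert_allclose(out.standardized["v"].to_numpy(), [1.0, 0.0, 1.0])


def test_standardize_reference_site_zero_and_max_one():
    df = pd.DataFrame({"v": [2.0, 5.0, 11.0]}, index=list("abc"))
    out = standardize_env(_site_env(df, {"v": "SST"}), reference=5.0)
    std = out.standardized["v"]
    assert std["b"] == 0.0
    assert std.max() == 1.0


def test_standardize_constant_variable_errors():
    df = pd.DataFrame({"v": [2.0, 2.0, 2.0]}, index=list("abc"))
    with pytest.raises(ValueError, match="constant"):
        standardize_env(_site_env(df, {"v": "SST"}))


# ---------------------------------------------------------------------------
# ASCII grid I/O


def test_ascii_grid_roundtrip(tmp_path):
    g = grid(4, 6, d=0.25)
    vals = np.arange(24, dtype=float).reshape(4, 6)
    vals[1, 2] = np.nan
    write_ascii_grid(tmp_path / "x.asc", Layer(vals), g)
    vals2, g2 = read_ascii_grid(tmp_path / "x.asc")
    np.testing.assert_allclose(vals, vals2, equal_nan=True)
    assert g2.shape == g.shape
    assert g2.lon0 == pytest.approx(g.lon0)
    assert g2.lat0 == pytest.approx(g.lat0)
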