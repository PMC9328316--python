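"""Genetic offset surfaces, buffers, scenario substitution and system tests."""

import numpy as np
import pandas as pd
import pytest

from reefscape.env_stack import EnvStack, Layer
from reefscape.gdm import GDM
from reefscape.genotypes import SampleHierarchy
from reefscape.gradient_forest import GradientForest
from reefscape.grids import Grid, haversine_km
from reefscape.offset import (OffsetConfig, OffsetSurface, buffer_membership,
                              compare_systems, future_env, gdm_offset,
                              gf_offset, pca_rgb, _dunn_posthoc)


def _grid(nrows=12, ncols=12, d=0.2):
    return Grid(lon0=113.0, lat0=-12.0, dlon=d, dlat=d, nrows=nrows, ncols=ncols)


def _hier(sites):
    df = pd.DataFrame(sites).set_index("sample")
    return SampleHierarchy(df)


def _simple_hierarchy():
    return _hier([
        {"sample": "a1", "site": "sA", "reef": "rA", "system": "North",
         "lon": 113.4, "lat": -12.4, "replicate_group": np.nan},
        {"sample": "b1", "site": "sB", "reef": "rB", "system": "South",
         "lon": 114.6, "lat": -13.8, "replicate_group": np.nan},
    ])


# ---------------------------------------------------------------------------
# buffers


def test_buffer_membership_matches_exhaustive_oracle():
    g = _grid()
    stack = EnvStack(g, {"v": Layer(np.zeros(g.shape))})
    h = _simple_hierarchy()
    labels = buffer_membership(h, stack, radius_km=50.0)
    glon, glat = g.meshgrid()
    sites = h.site_table()
    for i in range(g.nrows):
        for j in range(g.ncols):
            d = haversine_km(glon[i, j], glat[i, j],
                             sites["lon"].to_numpy(), sites["lat"].to_numpy())
            if d.min() <= 50.0:
                assert labels[i, j] == sites["system"].iloc[int(np.argmin(d))]
            else:
                assert labels[i, j] is None


def test_cell_at_site_and_beyond_radius():
    g = _grid()
    stack = EnvStack(g, {"v": Layer(np.zeros(g.shape))})
    h = _hier([{"sample": "a", "site": "s", "reef": "r", "system": "Only",
                "lon": 113.1, "lat": -12.1, "replicate_group": np.nan}])
    labels = b = buffer_membership(h, stack, radius_km=50.0)
    r, c = g.cell_of(113.1, -12.1)
    assert labels[r, c] == "Only"
    glon, glat = g.meshgrid()
    far = haversine_km(glon, glat, 113.1, -12.1) > 50.0
    assert all(l is None for l in labels[far])


# ---------------------------------------------------------------------------
# future_env


def _stack_with(vals_by_name, g=None):
    g = g or _grid(4, 4)
    return EnvStack(g, {k: Layer(np.asarray(v, dtype=float), "SST", "degC")
                        for k, v in vals_by_name.items()})


def test_future_env_member_average_and_untouched_layers():
    g = _grid(4, 4)
    present = _stack_with({"SSTmax": np.full((4, 4), 28.0),
                           "SSTrange": np.full((4, 4), 4.0),
                           "Tidal": np.full((4, 4), 2.0)}, g)
    cfg = OffsetConfig(scenario="test", replace_variables=("SSTmax",))
    members = {"SSTmax": [Layer(np.full((4, 4), 29.0)),
                          Layer(np.full((4, 4), 30.0)),
                          Layer(np.full((4, 4), 31.0))]}
    fut = future_env(present, members, cfg)
    np.testing.assert_allclose(fut["SSTmax"].values, 30.0)
    np.testing.assert_array_equal(fut["Tidal"].values, present["Tidal"].values)
    np.testing.assert_array_equal(fut["SSTrange"].values, present["SSTrange"].values)


def test_future_env_missing_member_errors():
    present = _stack_with({"SSTmax": np.zeros((4, 4))})
    cfg = OffsetConfig(scenario="x", replace_variables=("SSTmax",))
    with pytest.raises(ValueError, match="no member layers"):
        future_env(present, {}, cfg)


# ---------------------------------------------------------------------------
# GF / GDM offsets


def _fitted_gf(seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"SSTmax": np.linspace(26, 32, 30),
                      "Tidal": rng.uniform(1, 8, 30)})
    Y = pd.DataFrame({"s1": (X["SSTmax"] - 26) / 6 + 0.02 * rng.standard_normal(30),
                      "s2": (X["SSTmax"] > 29).astype(float)})
    return GradientForest(n_trees=120, random_state=seed).fit(X, Y)


def test_gf_offset_identity_is_zero():
    gf = _fitted_gf()
    g = _grid(6, 6)
    vals = {"SSTmax": np.linspace(26, 32, 36).reshape(6, 6),
            "Tidal": np.full((6, 6), 4.0)}
    present = _stack_with(vals, g)
    membership = np.full((6, 6), "S", dtype=object)
    surf = gf_offset(gf, present, present.copy(), membership)
    np.testing.assert_allclose(surf.values, 0.0)


def test_gf_offset_ignores_zero_importance_predictors():
    gf = _fitted_gf()
    assert "SSTmax" in gf.active_predictors_
    g = _grid(6, 6)
    base = {"SSTmax": np.full((6, 6), 28.0), "Tidal": np.full((6, 6), 4.0)}
    present = _stack_with(base, g)
    future = present.copy()
    if "Tidal" not in gf.active_predictors_:
        future.layers["Tidal"].values += 5.0
        membership = np.full((6, 6), "S", dtype=object)
        surf = gf_offset(gf, present, future, membership)
        np.testing.assert_allclose(surf.values, 0.0)


def test_gf_offset_matches_hand_computation():
    gf = _fitted_gf()
    g = Grid(lon0=113.0, lat0=-12.0, dlon=0.2, dlat=0.2, nrows=1, ncols=2)
    present = _stack_with({"SSTmax": [[27.0, 30.0]], "Tidal": [[4.0, 4.0]]}, g)
    future = _stack_with({"SSTmax": [[29.0, 32.0]], "Tidal": [[4.0, 4.0]]}, g)
    membership = np.array([["S", "S"]], dtype=object)
    surf = gf_offset(gf, present, future, membership)
    pres_pts = gf.transform(pd.DataFrame({"SSTmax": [27.0, 30.0], "Tidal": [4.0, 4.0]}))
    fut_pts = gf.transform(pd.DataFrame({"SSTmax": [29.0, 32.0], "Tidal": [4.0, 4.0]}))
    expected = np.sqrt(((pres_pts - fut_pts) ** 2).sum(axis=1))
    np.testing.assert_allclose(surf.values[0], expected)


def _fitted_gdm(seed=0):
    rng = np.random.default_rng(seed)
    n = 20
    env = pd.DataFrame({"SSTmax": np.linspace(26, 32, n)},
                       index=[f"s{i}" for i in range(n)])
    ia, ib = np.triu_indices(n, 1)
    from reefscape.gdm import ispline_basis
    gdm = GDM()
    knots = gdm._knots(env["SSTmax"].to_numpy())
    eta = 0.05 + np.abs(ispline_basis(env["SSTmax"].to_numpy()[ia], knots)
                        - ispline_basis(env["SSTmax"].to_numpy()[ib], knots)) @ [0.4, 0.3, 0.3]
    D = np.zeros((n, n))
    D[ia, ib] = 1 - np.exp(-eta)
    D += D.T
    return GDM().fit(env, pd.DataFrame(D, index=env.index, columns=env.index))


def test_gdm_offset_identity_zero_and_monotone():
    model = _fitted_gdm()
    g = _grid(4, 4)
    present = _stack_with({"SSTmax": np.full((4, 4), 28.0)}, g)
    membership = np.full((4, 4), "S", dtype=object)
    surf0 = gdm_offset(model, present, present.copy(), membership)
    np.testing.assert_allclose(surf0.values, 0.0, atol=1e-12)
    last = -1.0
    for delta in (0.5, 1.0, 2.0, 4.0):
        future = present.copy()
        future.layers["SSTmax"].values += delta
        s = gdm_offset(model, present, future, membership)
        val = s.values[0, 0]
        assert val >= last - 1e-12
        last = val


# ---------------------------------------------------------------------------
# PCA/RGB


def test_pca_rgb_orthogonal_scores_and_range():
    gf = _fitted_gf()
    g = _grid(8, 8)
    rng = np.random.default_rng(1)
    present = _stack_with({"SSTmax": rng.uniform(26, 32, (8, 8)),
                           "Tidal": rng.uniform(1, 8, (8, 8))}, g)
    bands, loadings, evr = pca_rgb(gf, present)
    ok = ~np.isnan(bands[:, :, 0])
    vals = bands[ok]
    assert vals.min() >= -1e-9 and vals.max() <= 255.0 + 1e-9


def test_pca_rgb_degenerate_field_is_uniform():
    gf = _fitted_gf()
    g = _grid(5, 5)
    present = _stack_with({"SSTmax": np.full((5, 5), 28.0),
                           "Tidal": np.full((5, 5), 4.0)}, g)
    with pytest.warns(UserWarning):
        bands, _, _ = pca_rgb(gf, present)
    ok = ~np.isnan(bands[:, :, 0])
    # existing-but-degenerate components render mid-grey; all bands uniform
    assert np.allclose(bands[ok][:, 0], 127.5)
    assert np.allclose(bands[ok].std(axis=0), 0.0)


# ---------------------------------------------------------------------------
# system comparisons


def kruskal_oracle(groups):
    """Textbook Kruskal-Wallis H with tie correction."""
    from scipy.stats import rankdata
    all_vals = np.concatenate(groups)
    N = len(all_vals)
    ranks = rankdata(all_vals)
    start = 0
    H = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - ((counts ** 3 - counts).sum()) / (N ** 3 - N)
    return H / tie


def _surface_from_groups(groups):
    vals = np.concatenate(groups).astype(float)
    systems = np.concatenate([[f"G{i}"] * len(g) for i, g in enumerate(groups)])
    n = len(vals)
    values = np.full((1, n), np.nan)
    values[0] = vals
    system = np.empty((1, n), dtype=object)
    system[0] = systems
    return OffsetSurface(values, system, "scen", "GF")


def test_kruskal_h_matches_textbook_formula():
    groups = [np.array([1, 2, 2, 3, 5, 5, 3, 1, 2, 6]),
              np.array([2, 4, 4, 6, 7, 7, 8, 8, 9, 9]),
              np.array([5, 6, 8, 9, 10, 10, 11, 12, 12, 13])]
    surf = _surface_from_groups(groups)
    rep = compare_systems(surf, method="kruskal_dunn", seed=0)
    assert rep["statistic"] == pytest.approx(kruskal_oracle(groups), abs=1e-9)


def test_shifted_systems_detected():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 300)
    b = rng.normal(3, 1, 300)  # 3 SD shift
    rep = compare_systems(_surface_from_groups([a, b]), method="kruskal_dunn", seed=0)
    assert rep["p_value"] < 1e-3
    post = rep["posthoc"]
    assert (post["p_bonferroni"] < 1e-3).all()


def test_null_systems_rarely_rejected():
    rng = np.random.default_rng(3)
    rejections = 0
    reps = 40
    for r in range(reps):
        a = rng.normal(0, 1, 120)
        b = rng.normal(0, 1, 120)
        rep = compare_systems(_surface_from_groups([a, b]),
                              method="kruskal_dunn", seed=r)
        rejections += rep["p_value"] < 0.05
    assert rejections / reps <= 0.10


def test_anova_tukey_two_way():
    rng = np.random.default_rng(4)
    surfaces = []
    for s, shift in (("scenA", 0.0), ("scenB", 1.0)):
        a = rng.normal(0 + shift, 1, 200)
        b = rng.normal(2 + shift, 1, 200)
        surf = _surface_from_groups([a, b])
        surf.scenario = s
        surfaces.append(surf)
    rep = compare_systems(surfaces, method="anova_tukey", seed=0)
    assert rep["p_value"] < 1e-6
    assert "anova" in rep


def test_single_system_errors():
    rng = np.random.default_rng(5)
    surf = _surface_from_groups([rng.normal(0, 1, 50)])
    with pytest.raises(ValueError):
        compare_systems(surf, method="kruskal_dunn")
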