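"""Spatial genetic-offset prediction and reef-system comparisons.

Builds 50 km dispersal buffers around sampled sites, substitutes future
sea-surface-temperature layers into the present-day environmental stack,
maps every buffered grid cell through a fitted gradient-forest or GDM
gene-environment model, and measures the genetic offset: for GF the
Euclidean distance between present and future positions in biological
space; for GDM the predicted present-vs-future dissimilarity minus the
model's identical-environment baseline. Offsets are compared between
reef systems with Kruskal-Wallis + Dunn (Bonferroni) or two-way
ANOVA + Tukey tests on (subsampled) buffer cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .env_stack import EnvStack, Layer
from .gdm import GDM
from .genotypes import SampleHierarchy
from .gradient_forest import GradientForest
from .grids import SphereIndex


@dataclass
class OffsetConfig:
    buffer_radius_km: float = 50.0
    scenario: str = "RCP8.5-2090s"
    replace_variables: tuple[str, ...] = ("SSTmax", "SSTrange")

    def __post_init__(self):
        if self.buffer_radius_km <= 0:
            raise ValueError("buffer radius must be positive")


@dataclass
class OffsetSurface:
    """Per-cell genetic offset within site buffers, labelled by system."""

    values: np.ndarray            # grid of offsets, NaN outside buffers
    system: np.ndarray            # object array of system labels, None outside
    scenario: str
    model_tag: str                # "GF" or "GDM"

    def cells(self) -> pd.DataFrame:
        ok = ~np.isnan(self.values)
        return pd.DataFrame({
            "system": self.system[ok],
            "offset": self.values[ok],
        })

    def per_system_summary(self) -> pd.DataFrame:
        df = self.cells()
        return df.groupby("system")["offset"].agg(["mean", "std", "count"])


def buffer_membership(h: SampleHierarchy, stack: EnvStack,
                      radius_km: float = 50.0) -> np.ndarray:
    """Label each grid cell with the system of its nearest site, or None.

    A cell belongs to the buffer iff its centre lies within ``radius_km``
    (haversine) of any site; overlaps resolve to the nearest site.
    """
    sites = h.site_table()
    glon, glat = stack.grid.meshgrid()
    index = SphereIndex(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    idx, km = index.query(glon.ravel(), glat.ravel(), k=1)
    labels = np.full(glon.size, None, dtype=object)
    inside = km[:, 0] <= radius_km
    systems = sites["system"].to_numpy()
    labels[inside] = systems[idx[inside, 0]]
    return labels.reshape(stack.grid.shape)


def future_env(stack: EnvStack, scenario_layers: dict[str, list[Layer]],
               cfg: OffsetConfig) -> EnvStack:
    """Substitute future layers for the configured variables.

    ``scenario_layers`` maps each replaced variable to its AOGCM-member
    layers (already co-registered); members are averaged cell-wise. All
    other layers are copied unchanged.
    """
    out = stack.copy()
    for var in cfg.replace_variables:
        if var not in stack:
            raise ValueError(f"variable {var!r} not in the present-day stack")
        members = scenario_layers.get(var)
        if not members:
            raise ValueError(
                f"scenario {cfg.scenario!r}: no member layers for {var!r}; "
                f"found layers for {sorted(scenario_layers)}")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            vals = np.nanmean(np.stack([m.values for m in members]), axis=0)
        vals[np.isnan(stack[var].values)] = np.nan  # keep the present-day mask
        out.layers[var] = Layer(vals, stack[var].var_class, stack[var].units)
    return out


def _stack_points(stack: EnvStack, predictors, mask: np.ndarray) -> pd.DataFrame:
    missing = [p for p in predictors if p not in stack]
    if missing:
        raise ValueError(f"predictors missing from stack: {missing}")
    data = {p: stack[p].values[mask] for p in predictors}
    return pd.DataFrame(data)


def gf_offset(model: GradientForest, present: EnvStack, future: EnvStack,
              membership: np.ndarray, scenario: str = "") -> OffsetSurface:
    """Per-cell Euclidean distance between present and future biological space."""
    predictors = model.active_predictors_
    valid = membership != None  # noqa: E711 (object array)
    for p in predictors:
        valid &= ~np.isnan(present[p].values) & ~np.isnan(future[p].values)
    pres = model.transform(_stack_points(present, predictors, valid))
    fut = model.transform(_stack_points(future, predictors, valid))
    off = np.sqrt(((pres - fut) ** 2).sum(axis=1))
    values = np.full(membership.shape, np.nan)
    values[valid] = off
    system = np.where(valid, membership, None)
    return OffsetSurface(values, system, scenario, "GF")


def gdm_offset(model: GDM, present: EnvStack, future: EnvStack,
               membership: np.ndarray, scenario: str = "") -> OffsetSurface:
    """Baseline-subtracted GDM dissimilarity between present and future."""
    predictors = model.predictors_
    valid = membership != None  # noqa: E711
    for p in predictors:
        valid &= ~np.isnan(present[p].values) & ~np.isnan(future[p].values)
    env_a = _stack_points(present, predictors, valid)
    env_b = _stack_points(future, predictors, valid)
    off = model.predict(env_a, env_b) - model.baseline_
    values = np.full(membership.shape, np.nan)
    values[valid] = np.maximum(off, 0.0)
    system = np.where(valid, membership, None)
    return OffsetSurface(values, system, scenario, "GDM")


def pca_rgb(model: GradientForest, stack: EnvStack,
            membership: np.ndarray | None = None):
    """PCA of the transformed stack rendered as three 0-255 bands.

    Returns (bands: (nrows, ncols, 3) float array with NaN outside the
    valid region, loadings DataFrame, explained variance ratios). The
    sign convention makes each component's largest-magnitude loading
    positive. Degenerate (zero-variance) components render mid-grey.
    """
    from sklearn.decomposition import PCA

    predictors = model.active_predictors_
    valid = np.ones(stack.grid.shape, dtype=bool)
    if membership is not None:
        valid &= membership != None  # noqa: E711
    for p in predictors:
        valid &= ~np.isnan(stack[p].values)
    pts = model.transform(_stack_points(stack, predictors, valid))
    n_comp = min(3, pts.shape[1], max(pts.shape[0] - 1, 1))
    bands = np.full(stack.grid.shape + (3,), np.nan)
    if pts.shape[0] == 0:
        return bands, pd.DataFrame(), np.zeros(3)
    if n_comp < 3:
        import warnings
        warnings.warn("fewer than 3 informative predictors; RGB bands padded with zeros")
    pca = PCA(n_components=max(n_comp, 1))
    scores = pca.fit_transform(pts)
    # deterministic sign: largest-|loading| positive
    for c in range(scores.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[c] *= -1
            scores[:, c] *= -1
    rgb = np.zeros((pts.shape[0], 3))  # absent components stay zero
    for c in range(min(3, scores.shape[1])):
        lo, hi = scores[:, c].min(), scores[:, c].max()
        if hi > lo:
            rgb[:, c] = 255.0 * (scores[:, c] - lo) / (hi - lo)
        else:  # degenerate variance renders mid-grey
            rgb[:, c] = 127.5
    for c in range(3):
        band = np.full(stack.grid.shape, np.nan)
        band[valid] = rgb[:, c]
        bands[:, :, c] = band
    loadings = pd.DataFrame(pca.components_[: min(3, scores.shape[1])],
                            columns=predictors,
                            index=[f"PC{i+1}" for i in range(min(3, scores.shape[1]))])
    evr = np.zeros(3)
    evr[: min(3, len(pca.explained_variance_ratio_))] = \
        pca.explained_variance_ratio_[:3]
    return bands, loadings, evr


# ---------------------------------------------------------------------------
# reef-system comparisons


def _dunn_posthoc(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Dunn's z test on rank sums with Bonferroni-adjusted p-values."""
    ranks = stats.rankdata(values)
    N = len(values)
    labels = pd.unique(groups)
    ties = pd.Series(values).value_counts()
    tie_term = float(((ties ** 3 - ties).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups.to_numpy() == g].mean() for g in labels}
    n = {g: int((groups == g).sum()) for g in labels}
    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ga, gb = labels[a], labels[b]
            se = np.sqrt(var_base * (1.0 / n[ga] + 1.0 / n[gb]))
            z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": ga, "group_b": gb, "z": z,
                         "p": p, "p_bonferroni": min(p * m, 1.0)})
    return pd.DataFrame(rows)


def compare_systems(surfaces, method: str = "kruskal_dunn", alpha: float = 0.05,
                    max_cells_per_system: int = 5000,
                    seed: int | None = None) -> dict:
    """Test for offset differences between reef systems.

    ``surfaces`` is one :class:`OffsetSurface` or a list (multiple
    scenarios enable the two-way ANOVA). Cells are subsampled per system
    (seeded) to limit spatial pseudo-replication.
    """
    if isinstance(surfaces, OffsetSurface):
        surfaces = [surfaces]
    rng = np.random.default_rng(seed)
    frames = []
    for s in surfaces:
        df = s.cells()
        df["scenario"] = s.scenario
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    sub = []
    for (_, _), grp in data.groupby(["system", "scenario"]):
        if len(grp) > max_cells_per_system:
            grp = grp.iloc[rng.choice(len(grp), max_cells_per_system, replace=False)]
        sub.append(grp)
    data = pd.concat(sub, ignore_index=True)
    systems = pd.unique(data["system"])
    if len(systems) < 2:
        raise ValueError("need at least two systems to compare")
    counts = data.groupby("system")["offset"].count()
    if (counts < 10).any():
        raise ValueError("every system needs at least 10 buffer cells")

    summary = (data.groupby(["system", "scenario"])["offset"]
                   .agg(["mean", "std", "count"]).reset_index())
    report = {"method": method, "alpha": alpha, "summary": summary}

    if method == "kruskal_dunn":
        groups = [data.loc[data["system"] == g, "offset"].to_numpy() for g in systems]
        H, p = stats.kruskal(*groups)
        report.update({"statistic": float(H), "p_value": float(p),
                       "posthoc": _dunn_posthoc(data["offset"], data["system"])})
    elif method == "anova_tukey":
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        if data["scenario"].nunique() > 1:
            model = ols("offset ~ C(system) * C(scenario)", data=data).fit()
        else:
            model = ols("offset ~ C(system)", data=data).fit()
        report["anova"] = sm.stats.anova_lm(model, typ=2)
        tk = pairwise_tukeyhsd(data["offset"], data["system"], alpha=alpha)
        report["posthoc"] = pd.DataFrame(tk.summary().data[1:],
                                         columns=tk.summary().data[0])
        report["p_value"] = float(report["anova"]["PR(>F)"].iloc[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return report
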