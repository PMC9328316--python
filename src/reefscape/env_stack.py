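"""Environmental raster stacks and site-level environmental tables.

Prepares co-registered environmental layers for seascape analysis:
nearest-neighbour resampling onto a common grid, inverse-distance gap
filling, clipping to the photic depth band, collinearity pruning of the
candidate variable set, site-value extraction with nearest-valid-pixel
fallback, and standardisation to absolute environmental distances.

Layers are numpy arrays with NaN as nodata, co-registered on one
:class:`~reefscape.grids.Grid`. Text I/O uses the ESRI ASCII grid format
(with DX/DY keywords for non-square cells) plus a YAML manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import Grid, SphereIndex, haversine_km

VAR_CLASSES = ("SST", "anomaly", "optical", "physical", "geomorphological")

KELVIN_OFFSET = 273.15


@dataclass
class Layer:
    """One named environmental raster. NaN marks nodata."""

    values: np.ndarray
    var_class: str = "physical"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("layer values must be 2-D")

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "Layer":
        return Layer(self.values.copy(), self.var_class, self.units)


@dataclass
class EnvStack:
    """Named, co-registered environmental layers on a shared grid."""

    grid: Grid
    layers: dict[str, Layer] = field(default_factory=dict)

    def __post_init__(self):
        for name, layer in self.layers.items():
            if layer.values.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {layer.values.shape} != grid {self.grid.shape}")

    def __contains__(self, name):
        return name in self.layers

    def __getitem__(self, name) -> Layer:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def add(self, name: str, values, var_class="physical", units="", kelvin=False):
        """Add a layer; Kelvin temperature layers are converted to Celsius."""
        values = np.asarray(values, dtype=float)
        if kelvin:
            values = values - KELVIN_OFFSET
            units = "degC"
        if values.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} shape mismatch")
        self.layers[name] = Layer(values, var_class, units)
        return self

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, {k: v.copy() for k, v in self.layers.items()})

    def as_matrix(self, names=None) -> np.ndarray:
        """Cells x variables matrix (row-major flattened grid)."""
        names = list(names) if names is not None else self.names
        return np.column_stack([self.layers[n].values.ravel() for n in names])


@dataclass
class SiteEnv:
    """Site x variable table of extracted (and standardised) values."""

    values: pd.DataFrame
    provenance: pd.DataFrame  # same shape; "exact" or "nearest_fallback"
    var_class: dict[str, str] = field(default_factory=dict)
    standardized: pd.DataFrame | None = None

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, variables) -> "SiteEnv":
        variables = list(variables)
        return SiteEnv(
            self.values[variables].copy(),
            self.provenance[variables].copy(),
            {v: self.var_class.get(v, "physical") for v in variables},
            None if self.standardized is None else self.standardized[variables].copy(),
        )


# ---------------------------------------------------------------------------
# raster operations


def resample_nn(layer: Layer, source_grid: Grid, target_grid: Grid) -> Layer:
    """Nearest-neighbour resample onto ``target_grid``.

    Each target cell takes the value of the source cell whose centre is
    nearest in lon/lat degree space; nodata propagates. Raises if the grid
    footprints are disjoint.
    """
    if not source_grid.overlaps(target_grid):
        raise ValueError("source and target grid extents are disjoint")
    src_lons, src_lats = source_grid.lons(), source_grid.lats()
    # nearest source centre separately per axis (exact for rectilinear grids)
    cols = np.abs(target_grid.lons()[:, None] - src_lons[None, :]).argmin(axis=1)
    rows = np.abs(target_grid.lats()[:, None] - src_lats[None, :]).argmin(axis=1)
    out = layer.values[np.ix_(rows, cols)]
    return Layer(out.copy(), layer.var_class, layer.units)


def fill_gaps(layer: Layer, grid: Grid, k: int = 12, power: float = 2.0,
              max_radius_km: float = 100.0) -> Layer:
    """Fill nodata cells by inverse-distance weighting of nearby valid cells.

    Each nodata cell within ``max_radius_km`` of valid data receives the
    IDW (haversine distances, ``k`` nearest valid cells, exponent
    ``power``) interpolated value; cells with no valid neighbour within
    the radius stay masked.
    """
    vals = layer.values
    valid = ~np.isnan(vals)
    if not valid.any():
        raise ValueError("cannot fill an all-nodata layer")
    if valid.all():
        return layer.copy()
    glon, glat = grid.meshgrid()
    index = SphereIndex(glon[valid], glat[valid])
    holes = ~valid
    idx, km = index.query(glon[holes], glat[holes], k=min(k, int(valid.sum())),
                          max_km=max_radius_km)
    vsrc = vals[valid]
    out = vals.copy()
    filled = np.full(int(holes.sum()), np.nan)
    reachable = np.isfinite(km).any(axis=1)
    for i in np.nonzero(reachable)[0]:
        ok = np.isfinite(km[i])
        d = km[i][ok]
        v = vsrc[idx[i][ok]]
        if np.any(d <= 1e-9):
            filled[i] = v[np.argmin(d)]
        else:
            w = d ** (-power)
            filled[i] = np.sum(w * v) / np.sum(w)
    out[holes] = filled
    return Layer(out, layer.var_class, layer.units)


def depth_mask(stack: EnvStack, bathymetry: Layer, zmin: float = 0.0,
               zmax: float = 40.0) -> EnvStack:
    """Mask every layer outside the closed depth interval [zmin, zmax] m.

    Depths are positive-down; cells where bathymetry is nodata are masked
    too. Idempotent.
    """
    depth = bathymetry.values
    keep = (depth >= zmin) & (depth <= zmax)
    out = stack.copy()
    for layer in out.layers.values():
        layer.values[~keep] = np.nan
    return out


# ---------------------------------------------------------------------------
# site-level operations


def extract_site_values(stack: EnvStack, sites: pd.DataFrame,
                        max_fallback_km: float = 100.0) -> SiteEnv:
    """Extract layer values at site coordinates.

    ``sites`` must have columns ``lon`` and ``lat`` indexed by site ID.
    A site falling on a masked (or out-of-grid) cell takes the value of
    the nearest valid cell (haversine), with provenance flagged
    ``nearest_fallback``; no valid cell within ``max_fallback_km`` is an
    error naming the site.
    """
    grid = stack.grid
    glon, glat = grid.meshgrid()
    rows, cols = grid.cell_of(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    values = {}
    prov = {}
    for name in stack.names:
        vals = stack[name].values
        valid = ~np.isnan(vals)
        if not valid.any():
            raise ValueError(f"layer {name!r} has no valid cells")
        index = SphereIndex(glon[valid], glat[valid])
        vsrc = vals[valid]
        col_out = np.empty(len(sites))
        flag = np.empty(len(sites), dtype=object)
        for i, site in enumerate(sites.index):
            r, c = rows[i], cols[i]
            if r >= 0 and not np.isnan(vals[r, c]):
                col_out[i] = vals[r, c]
                flag[i] = "exact"
            else:
                idx, km = index.query(sites["lon"].iloc[i], sites["lat"].iloc[i],
                                      k=1, max_km=max_fallback_km)
                if not np.isfinite(km[0, 0]):
                    raise ValueError(
                        f"site {site!r}: no valid {name!r} cell within {max_fallback_km} km")
                col_out[i] = vsrc[idx[0, 0]]
                flag[i] = "nearest_fallback"
        values[name] = col_out
        prov[name] = flag
    var_class = {n: stack[n].var_class for n in stack.names}
    return SiteEnv(pd.DataFrame(values, index=sites.index),
                   pd.DataFrame(prov, index=sites.index), var_class)


def prune_correlated(site_env: SiteEnv, r_max: float = 0.80,
                     never_drop: tuple[str, ...] = ()) -> list[str]:
    """Greedy collinearity pruning of the variable set at site locations.

    Repeatedly drops the variable with the largest number of partners at
    |Pearson r| >= ``r_max`` (ties: larger mean |r|, then later in input
    order), but never drops the last remaining member of a variable class
    nor any variable in ``never_drop``. Zero-variance variables are dropped
    first with a warning. Returns retained variable names in input order.
    """
    df = site_env.values
    if len(df) < 2:
        raise ValueError("need at least 2 sites to compute correlations")
    names = list(df.columns)
    keep = list(names)
    for v in names:
        if df[v].std(ddof=0) == 0:
            warnings.warn(f"variable {v!r} has zero variance at sites; dropped")
            keep.remove(v)
    while True:
        if len(keep) < 2:
            break
        corr = df[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        high = corr >= r_max
        counts = high.sum(axis=1)
        if counts.max() == 0:
            break
        cls_counts = {}
        for v in keep:
            cls_counts.setdefault(site_env.var_class.get(v, "physical"), 0)
            cls_counts[site_env.var_class.get(v, "physical")] += 1
        mean_r = np.where(high, corr, 0.0).sum(axis=1) / np.maximum(counts, 1)
        order = sorted(
            range(len(keep)),
            key=lambda i: (counts[i], mean_r[i], i),
            reverse=True,
        )
        dropped = False
        for i in order:
            if counts[i] == 0:
                break
            v = keep[i]
            if v in never_drop:
                continue
            if cls_counts[site_env.var_class.get(v, "physical")] <= 1:
                continue  # sole class representative is protected
            keep.remove(v)
            dropped = True
            break
        if not dropped:
            break
    return keep


def standardize_env(site_env: SiteEnv, reference: str | float = "median") -> SiteEnv:
    """Standardise site values to absolute environmental distances.

    For each variable, d_j = |e_j - ref| / max_j |e_j - ref| so values lie
    in [0, 1] with at least one exact 1. ``reference`` is ``"median"``,
    ``"mean"`` or a number applied to every variable. Constant variables
    cannot be standardised and raise.
    """
    df = site_env.values
    out = {}
    for v in df.columns:
        col = df[v].to_numpy(dtype=float)
        if np.nanmax(col) == np.nanmin(col):
            raise ValueError(f"variable {v!r} is constant across sites; cannot standardize")
        if reference == "median":
            ref = np.median(col)
        elif reference == "mean":
            ref = np.mean(col)
        else:
            ref = float(reference)
        d = np.abs(col - ref)
        m = d.max()
        if m == 0:
            raise ValueError(f"variable {v!r}: all sites equal the reference")
        out[v] = d / m
    result = SiteEnv(site_env.values.copy(), site_env.provenance.copy(),
                     dict(site_env.var_class))
    result.standardized = pd.DataFrame(out, index=df.index)
    return result


# ---------------------------------------------------------------------------
# text I/O (ESRI ASCII grid + YAML manifest)


def write_ascii_grid(path, layer: Layer, grid: Grid, nodata: float = -9999.0):
    vals = np.where(np.isnan(layer.values), nodata, layer.values)
    lon_ll = grid.lon0 - grid.dlon / 2.0
    lat_ll = grid.lats()[-1] - grid.dlat / 2.0
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {lon_ll:.10g}\n")
        fh.write(f"yllcorner {lat_ll:.10g}\n")
        fh.write(f"dx {grid.dlon:.10g}\n")
        fh.write(f"dy {grid.dlat:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    dx = header.get("dx", header.get("cellsize"))
    dy = header.get("dy", header.get("cellsize"))
    nodata = header.get("nodata_value", -9999.0)
    lon0 = header["xllcorner"] + dx / 2.0
    lat0 = header["yllcorner"] + dy / 2.0 + (nrows - 1) * dy
    vals = np.where(vals == nodata, np.nan, vals)
    return vals, Grid(lon0, lat0, dx, dy, nrows, ncols)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def save_stack(stack: EnvStack, directory, bathymetry: Layer | None = None):
    """Write each layer as .asc plus a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, layer in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", layer, stack.grid)
        manifest[name] = {"class": layer.var_class, "units": layer.units, "kelvin": False}
    if bathymetry is not None:
        write_ascii_grid(directory / "bathymetry.asc", bathymetry, stack.grid)
        manifest["bathymetry"] = {"class": "geomorphological", "units": "m", "kelvin": False}
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_stack(directory) -> tuple[EnvStack, Layer | None]:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    stack = None
    bathy = None
    for name, meta in manifest.items():
        vals, grid = read_ascii_grid(directory / f"{name}.asc")
        if meta.get("kelvin"):
            vals = vals - KELVIN_OFFSET
        layer = Layer(vals, meta.get("class", "physical"), meta.get("units", ""))
        if name == "bathymetry":
            bathy = layer
            if stack is None:
                stack = EnvStack(grid, {})
            continue
        if stack is None:
            stack = EnvStack(grid, {})
        stack.layers[name] = layer
    return stack, bathy
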