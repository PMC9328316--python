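"""Synthetic seascape generator with known ground truth.

Emulates the study system the pipeline targets: ~26 sampling sites nested
in 4 reef systems along a ~12-degree latitudinal gradient on a shallow
shelf, ~10^3 biallelic GBS loci with hierarchical neutral structure
(nested Balding-Nichols) plus a minority of loci whose allele frequencies
follow logistic clines in an SST-like variable, spatially smooth
environmental fields with a latitudinal temperature gradient and
engineered collinearity, technical replicates with genotyping error,
planted clones, and decade-averaged future-SST deltas that grow toward
the poleward ("Ningaloo-like") end of the domain.

Every dataset is fully determined by its :class:`TruthManifest` and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .env_stack import EnvStack, Layer
from .genotypes import MISSING, GenotypeMatrix, SampleHierarchy
from .grids import Grid

# latitudinal trend (per unit standardised latitude, south = -1) and noise
# scales loosely shaped after the North West Shelf variable ranges
_DEFAULT_VARS = {
    # name: (class, mean, lat_slope, field_amp, noise_sd, units)
    "SSTmax": ("SST", 29.5, 2.0, 0.5, 0.05, "degC"),  # cool poleward end
    "SSTrange": ("SST", 4.0, 1.2, 0.4, 0.05, "degC"),
    "SSTA": ("anomaly", 0.6, 0.25, 0.15, 0.03, "degC"),
    "TSA": ("anomaly", 1.0, 0.0, 0.3, 0.03, "degC"),  # built anti-correlated with SSTrange
    "TSM": ("optical", 2.0, -0.6, 0.5, 0.08, "mg/m3"),
    "Chla": ("optical", 0.4, -0.1, 0.12, 0.02, "g/m3"),
    "Light": ("optical", 40.0, -4.0, 2.0, 0.3, "einstein/m2/day"),
    "Tidal": ("physical", 4.0, 2.5, 0.8, 0.08, "m"),
    "Roughness": ("geomorphological", 5.0, 0.0, 2.0, 0.3, "degrees"),
}

SCENARIOS = {
    # scenario: (delta at southern end, delta at northern end) for SSTmax;
    # SSTrange shifts by 40% of the local SSTmax delta
    "RCP2.6-2040s": (1.0, 0.5),
    "RCP2.6-2090s": (1.6, 0.9),
    "RCP8.5-2040s": (2.2, 1.2),
    "RCP8.5-2090s": (4.0, 2.0),
}


@dataclass
class TruthManifest:
    """Ground truth that, with the seed, fully determines a dataset."""

    seed: int
    n_loci: int = 1200
    frac_selected: float = 0.05
    cline_slope: float = 2.0
    driving_variable: str = "SSTmax"
    f_system: float = 0.10
    f_reef: float = 0.02
    f_site: float = 0.01
    n_per_site: int = 20
    missing_rate: float = 0.02
    replicate_error: float = 0.01
    n_replicate_pairs: int = 5
    n_clone_pairs: int = 2
    corr_targets: dict = field(default_factory=lambda: {"TSA": ("SSTrange", -0.83)})
    selected_loci: list = field(default_factory=list)
    clone_pairs: list = field(default_factory=list)
    replicate_pairs: list = field(default_factory=list)
    scenario_deltas: dict = field(default_factory=lambda: dict(SCENARIOS))

    def validate(self):
        for name in ("f_system", "f_reef", "f_site"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# environment


def _smooth_field(rng, shape, length_scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field via Gaussian-kernel smoothing."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=length_scale, mode="nearest")
    sd = z.std()
    return z / sd if sd > 0 else z


def simulate_env(nrows: int = 120, ncols: int = 120,
                 lon_min: float = 113.0, lat_min: float = -23.0,
                 lat_max: float = -11.0, lon_span: float = 6.0,
                 variables: dict | None = None,
                 corr_targets: dict | None = None,
                 length_scale: float = 8.0,
                 n_holes: int = 40,
                 seed: int | None = None) -> tuple[EnvStack, Layer]:
    """Simulate an environmental stack plus bathymetry.

    Each variable is a linear latitudinal trend plus a smooth Gaussian
    random field plus white noise; ``corr_targets`` maps a variable name
    to ``(companion, rho)`` and rebuilds its standardised anomaly as a
    mixture sharing the companion's, pushing the realised Pearson
    correlation toward rho. Bathymetry is a west-deepening shelf so the
    0-40 m mask keeps a contiguous north-south band; ``n_holes`` nodata
    cells are planted per variable for gap-filling exercises.
    """
    if nrows < 20 or ncols < 20:
        raise ValueError("grid must be at least 20x20")
    rng = np.random.default_rng(seed)
    variables = dict(_DEFAULT_VARS) if variables is None else variables
    corr_targets = {"TSA": ("SSTrange", -0.83)} if corr_targets is None else corr_targets
    for var, (comp, rho) in corr_targets.items():
        if abs(rho) >= 1.0:
            raise ValueError(f"infeasible correlation target {rho} for {var!r}")
    dlat = (lat_max - lat_min) / nrows
    dlon = lon_span / ncols
    grid = Grid(lon0=lon_min + dlon / 2, lat0=lat_max - dlat / 2,
                dlon=dlon, dlat=dlat, nrows=nrows, ncols=ncols)
    _, glat = grid.meshgrid()
    lat_std = (glat - glat.mean()) / (glat.max() - glat.min()) * 2.0  # south ~ -1

    # standardised anomaly fields (trend + GRF + noise), then cross-correlated
    z = {}
    for name in variables:
        z[name] = _smooth_field(rng, grid.shape, length_scale)
    for var, (comp, rho) in corr_targets.items():
        if var in z and comp in z:
            z[var] = rho * z[comp] + np.sqrt(1 - rho ** 2) * z[var]

    stack = EnvStack(grid, {})
    for name, (cls, mean, slope, amp, noise_sd, units) in variables.items():
        vals = (mean + slope * lat_std + amp * z[name]
                + noise_sd * rng.standard_normal(grid.shape))
        # correlated pairs share the *total* anomaly: add the companion trend
        if name in corr_targets:
            comp, rho = corr_targets[name]
            c_cls, c_mean, c_slope, c_amp, _, _ = variables[comp]
            vals = mean + rho * c_slope * lat_std + amp * z[name] \
                + noise_sd * rng.standard_normal(grid.shape)
        stack.add(name, vals, var_class=cls, units=units)

    # shelf: shallow band along the eastern third, deepening westward
    glon, _ = grid.meshgrid()
    coast = glon.max() + dlon
    depth = (coast - glon) / lon_span * 220.0 - 8.0
    depth += 3.0 * _smooth_field(rng, grid.shape, length_scale)
    bathy = Layer(depth, "geomorphological", "m")

    # planted nodata holes (not in bathymetry)
    flat_idx = rng.choice(nrows * ncols, size=min(n_holes, nrows * ncols), replace=False)
    for layer in stack.layers.values():
        layer.values.ravel()[flat_idx] = np.nan
    return stack, bathy


def place_sites(stack: EnvStack, bathy: Layer,
                reefs_per_system=(3, 2, 3, 2),
                sites_per_reef=(3, 3, 2, 3, 2, 3, 3, 2, 3, 2),
                seed: int | None = None) -> pd.DataFrame:
    """Place nested site/reef/system locations inside the 0-40 m band.

    Systems occupy latitudinal bands ordered south to north (system S1 is
    the poleward, "Ningaloo-like" end). Returns a site table with
    columns reef, system, lon, lat.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    glon, glat = grid.meshgrid()
    shallow = (bathy.values >= 0) & (bathy.values <= 40)
    if not shallow.any():
        raise ValueError("no shallow cells to place sites on")
    lats = grid.lats()
    lat_lo, lat_hi = lats.min(), lats.max()
    n_sys = len(reefs_per_system)
    edges = np.linspace(lat_lo, lat_hi, n_sys + 1)
    rows = []
    reef_i = 0
    site_i = 0
    for s in range(n_sys):
        sys_name = f"S{s + 1}"
        band = np.linspace(edges[s], edges[s + 1], reefs_per_system[s] + 2)[1:-1]
        for r in range(reefs_per_system[s]):
            reef_name = f"{sys_name}R{r + 1}"
            n_sites = sites_per_reef[reef_i % len(sites_per_reef)]
            reef_i += 1
            for k in range(n_sites):
                lat = band[r] + rng.uniform(-0.25, 0.25)
                # nearest shallow cell at this latitude
                row = int(np.clip(np.rint((grid.lat0 - lat) / grid.dlat), 0, grid.nrows - 1))
                cols = np.nonzero(shallow[row])[0]
                if cols.size == 0:
                    cand = np.argwhere(shallow)
                    best = cand[np.abs(cand[:, 0] - row).argmin()]
                    row, col = int(best[0]), int(best[1])
                else:
                    col = int(rng.choice(cols))
                site_i += 1
                rows.append({"site": f"{reef_name}P{k + 1}", "reef": reef_name,
                             "system": sys_name,
                             "lon": float(glon[row, col]), "lat": float(glat[row, col])})
    return pd.DataFrame(rows).set_index("site")


# ---------------------------------------------------------------------------
# genotypes


def _beta_draw(rng, p, f):
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def simulate_genotypes(manifest: TruthManifest, sites: pd.DataFrame,
                       site_env: pd.DataFrame,
                       seed: int | None = None
                       ) -> tuple[GenotypeMatrix, SampleHierarchy]:
    """Draw genotypes for every site under the manifest's ground truth.

    Neutral loci follow nested Balding-Nichols sampling of site
    frequencies around a Uniform(0.05, 0.95) ancestral frequency with F
    values per hierarchy level; selected loci have site frequency
    inverse-logit(a + b * z) where z is the standardised driving
    variable at the site. Technical replicates are re-drawn with
    per-allele error; clones are exact row copies. The manifest's
    ``selected_loci``, ``replicate_pairs`` and ``clone_pairs`` fields are
    filled in.
    """
    manifest.validate()
    rng = np.random.default_rng(manifest.seed if seed is None else seed)
    n_loci = manifest.n_loci
    site_ids = list(sites.index)
    systems = pd.unique(sites["system"])
    reefs = pd.unique(sites["reef"])

    n_sel = int(round(manifest.frac_selected * n_loci))
    sel_idx = rng.choice(n_loci, size=n_sel, replace=False)
    is_sel = np.zeros(n_loci, dtype=bool)
    is_sel[sel_idx] = True

    anc = rng.uniform(0.05, 0.95, size=n_loci)
    sys_p = {s: _beta_draw(rng, anc, manifest.f_system) for s in systems}
    reef_p = {}
    for r in reefs:
        parent = sites.loc[sites["reef"] == r, "system"].iloc[0]
        reef_p[r] = _beta_draw(rng, sys_p[parent], manifest.f_reef)
    site_p = np.empty((len(site_ids), n_loci))
    for i, s in enumerate(site_ids):
        site_p[i] = _beta_draw(rng, reef_p[sites.loc[s, "reef"]], manifest.f_site)

    # overwrite selected loci with logistic clines in the driving variable
    drv = site_env[manifest.driving_variable].to_numpy(dtype=float)
    zdrv = (drv - drv.mean()) / (drv.std() if drv.std() > 0 else 1.0)
    a = rng.uniform(-1.0, 1.0, size=n_sel)
    for k, li in enumerate(sel_idx):
        site_p[:, li] = expit(a[k] + manifest.cline_slope * zdrv)

    samples, rows, meta_rows = [], [], []
    for i, s in enumerate(site_ids):
        for k in range(manifest.n_per_site):
            samples.append(f"{s}_{k + 1:02d}")
            rows.append(rng.binomial(2, site_p[i]).astype(np.int16))
            meta_rows.append({"site": s, "reef": sites.loc[s, "reef"],
                              "system": sites.loc[s, "system"],
                              "lon": sites.loc[s, "lon"], "lat": sites.loc[s, "lat"],
                              "replicate_group": np.nan})
    codes = np.vstack(rows)

    # MCAR missingness
    miss = rng.random(codes.shape) < manifest.missing_rate
    codes[miss] = MISSING

    # technical replicates: re-genotype with per-allele error
    rep_pairs = []
    rep_src = rng.choice(len(samples), size=manifest.n_replicate_pairs, replace=False)
    extra_rows, extra_meta, extra_names = [], [], []
    for gi, si in enumerate(rep_src):
        src = codes[si].copy()
        rep = src.copy()
        obs = rep != MISSING
        # each of the two alleles flips independently with the error rate
        flips = rng.random((2, n_loci)) < manifest.replicate_error
        alleles = np.stack([(src > 0).astype(np.int16), (src == 2).astype(np.int16)])
        alleles = np.where(flips, 1 - alleles, alleles)
        rep = np.where(obs, alleles.sum(axis=0), MISSING).astype(np.int16)
        name = samples[si] + "_rep"
        group = f"RG{gi + 1}"
        meta_rows[si]["replicate_group"] = group
        extra_rows.append(rep)
        extra_meta.append({**{k: meta_rows[si][k] for k in ("site", "reef", "system", "lon", "lat")},
                           "replicate_group": group})
        extra_names.append(name)
        rep_pairs.append([samples[si], name])

    # clones: exact copies of non-replicate samples
    clone_pairs = []
    pool = [i for i in range(len(samples)) if i not in set(rep_src)]
    clone_src = rng.choice(pool, size=manifest.n_clone_pairs, replace=False)
    for gi, si in enumerate(clone_src):
        name = samples[si] + "_cl"
        extra_rows.append(codes[si].copy())
        extra_meta.append({**{k: meta_rows[si][k] for k in ("site", "reef", "system", "lon", "lat")},
                           "replicate_group": np.nan})
        extra_names.append(name)
        clone_pairs.append([samples[si], name])

    all_codes = np.vstack([codes] + [r[None, :] for r in extra_rows])
    all_samples = samples + extra_names
    all_meta = meta_rows + extra_meta

    loci = pd.DataFrame({
        "locus_id": [f"L{j + 1:05d}" for j in range(n_loci)],
        "fragment_id": [f"F{j + 1:05d}" for j in range(n_loci)],
        "position": np.full(n_loci, 1),
        "call_rate": (all_codes != MISSING).mean(axis=0),
        "repeatability": rng.uniform(0.95, 1.0, size=n_loci),
        "coverage": rng.lognormal(np.log(30), 0.3, size=n_loci),
        "contaminant_flag": np.zeros(n_loci, dtype=bool),
    }).set_index("locus_id")

    manifest.selected_loci = [f"L{j + 1:05d}" for j in sorted(sel_idx)]
    manifest.replicate_pairs = rep_pairs
    manifest.clone_pairs = clone_pairs

    g = GenotypeMatrix(all_samples, loci, all_codes)
    h = SampleHierarchy(pd.DataFrame(all_meta, index=all_samples))
    return g, h


# ---------------------------------------------------------------------------
# future scenarios


def simulate_future(stack: EnvStack, scenario: str = "RCP8.5-2090s",
                    deltas: tuple[float, float] | None = None,
                    n_members: int = 3, member_sd: float = 0.15,
                    range_fraction: float = 0.4,
                    seed: int | None = None) -> dict[str, list[Layer]]:
    """Pseudo-AOGCM future SST layers for one scenario.

    The SSTmax delta interpolates linearly from the southern-end value to
    the northern-end value of ``deltas`` (defaults from the scenario
    table — warming is larger toward the poleward end); SSTrange shifts
    by ``range_fraction`` of the local delta. Each of ``n_members``
    members adds mean-zero noise.
    """
    if deltas is None:
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        deltas = SCENARIOS[scenario]
    d_south, d_north = deltas
    rng = np.random.default_rng(seed)
    grid = stack.grid
    _, glat = grid.meshgrid()
    lat_frac = (glat - glat.min()) / (glat.max() - glat.min())  # 0 at south
    delta = d_south + (d_north - d_south) * lat_frac
    out = {"SSTmax": [], "SSTrange": []}
    for _ in range(n_members):
        noise = member_sd * rng.standard_normal(grid.shape)
        out["SSTmax"].append(Layer(stack["SSTmax"].values + delta + noise,
                                   "SST", stack["SSTmax"].units))
        noise2 = member_sd * range_fraction * rng.standard_normal(grid.shape)
        out["SSTrange"].append(Layer(stack["SSTrange"].values + range_fraction * delta + noise2,
                                     "SST", stack["SSTrange"].units))
    return out


def delta_field(stack: EnvStack, scenario: str) -> np.ndarray:
    """Deterministic SSTmax warming field for a named scenario."""
    d_south, d_north = SCENARIOS[scenario]
    _, glat = stack.grid.meshgrid()
    lat_frac = (glat - glat.min()) / (glat.max() - glat.min())
    return d_south + (d_north - d_south) * lat_frac


# ---------------------------------------------------------------------------
# presets


def paper_scale_dataset(seed: int = 0, nrows: int = 120, ncols: int = 120,
                        n_loci: int = 1200, n_per_site: int = 20,
                        **manifest_kwargs):
    """One-call synthetic dataset at the default study scale.

    Returns a dict with the env stack, bathymetry, site table, raw site
    environments, genotypes, hierarchy and the filled-in manifest.
    """
    rng = np.random.default_rng(seed)
    s_env, s_sites, s_geno = (int(x) for x in rng.integers(0, 2 ** 31 - 1, 3))
    stack, bathy = simulate_env(nrows=nrows, ncols=ncols, seed=s_env)
    sites = place_sites(stack, bathy, seed=s_sites)
    from .env_stack import depth_mask, extract_site_values, fill_gaps

    filled = EnvStack(stack.grid, {})
    for name, layer in stack.layers.items():
        filled.layers[name] = fill_gaps(layer, stack.grid)
    masked = depth_mask(filled, bathy)
    site_env = extract_site_values(masked, sites)
    manifest = TruthManifest(seed=s_geno, n_loci=n_loci, n_per_site=n_per_site,
                             **manifest_kwargs)
    g, h = simulate_genotypes(manifest, sites, site_env.values)
    return {"stack": masked, "raw_stack": filled, "bathymetry": bathy,
            "sites": sites, "site_env": site_env, "genotypes": g,
            "hierarchy": h, "manifest": manifest}
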