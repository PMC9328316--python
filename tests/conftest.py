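"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pandas as pd
import pytest

from reefscape.env_stack import (EnvStack, depth_mask, extract_site_values,
                                 fill_gaps, prune_correlated, standardize_env)
from reefscape.genotypes import GenotypeMatrix, SampleHierarchy
from reefscape.synthetic import (TruthManifest, place_sites, simulate_env,
                                 simulate_genotypes)


def make_genotypes(codes, locus_meta=None, samples=None):
    """Build a GenotypeMatrix from a plain code array with default metadata."""
    codes = np.asarray(codes, dtype=np.int16)
    n, L = codes.shape
    samples = samples or [f"s{i}" for i in range(n)]
    meta = {
        "locus_id": [f"L{j}" for j in range(L)],
        "fragment_id": [f"F{j}" for j in range(L)],
        "position": [1] * L,
        "call_rate": (codes != -1).mean(axis=0),
        "repeatability": [1.0] * L,
        "coverage": [30.0] * L,
        "contaminant_flag": [False] * L,
    }
    if locus_meta:
        meta.update(locus_meta)
    return GenotypeMatrix(samples, pd.DataFrame(meta).set_index("locus_id"), codes)


def make_hierarchy(samples, sites, reefs=None, systems=None, lon=None, lat=None,
                   replicate_group=None):
    n = len(samples)
    sites = list(sites)
    reefs = list(reefs) if reefs is not None else [f"r_{s}" for s in sites]
    systems = list(systems) if systems is not None else [f"g_{r}" for r in reefs]
    return SampleHierarchy(pd.DataFrame({
        "site": sites, "reef": reefs, "system": systems,
        "lon": lon if lon is not None else np.linspace(113, 115, n),
        "lat": lat if lat is not None else np.linspace(-20, -15, n),
        "replicate_group": replicate_group if replicate_group is not None else [np.nan] * n,
    }, index=list(samples)))


@pytest.fixture(scope="session")
def small_seascape():
    """A 40x40 seascape with 26 sites, prepared env, and one genotype draw."""
    stack, bathy = simulate_env(nrows=40, ncols=40, seed=11)
    sites = place_sites(stack, bathy, seed=12)
    filled = EnvStack(stack.grid, {})
    for name, layer in stack.layers.items():
        filled.layers[name] = fill_gaps(layer, stack.grid)
    masked = depth_mask(filled, bathy)
    site_env = extract_site_values(masked, sites)
    kept = prune_correlated(site_env, never_drop=("SSTrange",))
    site_env_kept = standardize_env(site_env.subset(kept))
    manifest = TruthManifest(seed=13, n_loci=300, frac_selected=0.05,
                             driving_variable="SSTrange", n_per_site=12)
    g, h = simulate_genotypes(manifest, sites, site_env.values)
    return {
        "stack": masked, "bathymetry": bathy, "sites": sites,
        "site_env": site_env_kept, "genotypes": g, "hierarchy": h,
        "manifest": manifest,
    }
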