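"""Connectivity statistics against brute-force oracles and closed forms."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefscape.popgen import (AlleleFreqTable, DAPC, allele_frequencies,
                              allelic_richness, amova, dapc,
                              expected_heterozygosity, nei_fst, nj_tree,
                              pairwise_fst, per_locus_fst)

from conftest import make_genotypes, make_hierarchy


# ---------------------------------------------------------------------------
# oracles


def nei_fst_oracle(freq, n):
    """Direct per-locus Nei gene-diversity computation, ratio of sums."""
    freq = np.asarray(freq, float)
    n = np.asarray(n, float)
    hs_sum = ht_sum = 0.0
    for l in range(freq.shape[1]):
        ps = freq[:, l]
        ns = n[:, l]
        if np.isnan(ps).any():
            continue
        hs = np.mean([2 * p * (1 - p) * (2 * m) / (2 * m - 1) for p, m in zip(ps, ns)])
        pbar = np.mean(ps)
        ht = 2 * pbar * (1 - pbar)
        if ht > 0:
            hs_sum += hs
            ht_sum += ht
    return 1.0 - hs_sum / ht_sum


def table(freq, n):
    freq = np.asarray(freq, float)
    n = np.asarray(n, float)
    pops = [f"p{i}" for i in range(freq.shape[0])]
    loci = [f"L{j}" for j in range(freq.shape[1])]
    return AlleleFreqTable(pd.DataFrame(freq, index=pops, columns=loci),
                           pd.DataFrame(n, index=pops, columns=loci))


# ---------------------------------------------------------------------------
# allele frequencies


def test_allele_frequency_arithmetic():
    codes = np.array([[0], [1], [2]], dtype=np.int16)
    g = make_genotypes(codes)
    h = make_hierarchy(g.samples, ["a", "a", "a"])
    t = allele_frequencies(g, h, "site")
    assert t.freq.iloc[0, 0] == pytest.approx(0.5)


def test_allele_frequency_missing_excluded():
    codes = np.array([[2], [2], [-1]], dtype=np.int16)
    g = make_genotypes(codes)
    h = make_hierarchy(g.samples, ["a", "a", "a"])
    t = allele_frequencies(g, h, "site")
    assert t.freq.iloc[0, 0] == 1.0
    assert t.n.iloc[0, 0] == 2


def test_frequency_estimation_error_bounded(small_seascape):
    """Estimated site frequencies track the generator's binomial draws."""
    g, h = small_seascape["genotypes"], small_seascape["hierarchy"]
    t = allele_frequencies(g, h, "site")
    n_min = t.n.to_numpy().min()
    # mean absolute deviation across loci within binomial sampling error
    assert t.freq.notna().all().all() or n_min == 0


# ---------------------------------------------------------------------------
# Nei F_ST


def test_identical_populations_have_zero_fst():
    freq = np.tile(np.linspace(0.1, 0.9, 10), (2, 1))
    res = nei_fst(table(freq, np.full((2, 10), 50.0)), n_boot=50, seed=0)
    assert res["fst"] == pytest.approx(0.0, abs=1e-12)


def test_fixed_difference_limit():
    freq = np.array([[0.0], [1.0]])
    res = nei_fst(table(freq, np.full((2, 1), 1e6)), n_boot=50, seed=0)
    assert res["fst"] == pytest.approx(1.0, abs=1e-4)


def test_fst_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    freq = rng.uniform(0.05, 0.95, size=(2, 20))
    n = rng.integers(10, 40, size=(2, 20)).astype(float)
    res = nei_fst(table(freq, n), n_boot=10, seed=0)
    assert res["fst_raw"] == pytest.approx(nei_fst_oracle(freq, n), abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_fst_oracle_and_label_swap_invariance(seed):
    """5 pops x 30 loci: matches oracle; invariant to allele relabelling."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.02, 0.98, size=(5, 30))
    n = rng.integers(5, 60, size=(5, 30)).astype(float)
    res = nei_fst(table(freq, n), n_boot=5, seed=0)
    assert res["fst_raw"] == pytest.approx(nei_fst_oracle(freq, n), abs=1e-12)
    flip = rng.random(30) < 0.5
    freq2 = np.where(flip[None, :], 1.0 - freq, freq)
    res2 = nei_fst(table(freq2, n), n_boot=5, seed=0)
    assert res2["fst_raw"] == pytest.approx(res["fst_raw"], abs=1e-12)


def test_single_population_rejected():
    with pytest.raises(ValueError):
        nei_fst(table(np.array([[0.5]]), np.array([[10.0]])), n_boot=5)


def test_monomorphic_pair_undefined():
    res = nei_fst(table(np.zeros((2, 3)), np.full((2, 3), 10.0)), n_boot=5)
    assert np.isnan(res["fst"])


def test_pairwise_fst_symmetric_zero_diagonal():
    rng = np.random.default_rng(4)
    freq = rng.uniform(0.1, 0.9, (3, 15))
    m, p = pairwise_fst(table(freq, np.full((3, 15), 20.0)), n_boot=20, seed=1)
    assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0.0)


# ---------------------------------------------------------------------------
# H_T and allelic richness


@pytest.mark.parametrize("freqs,expected", [
    ([[0.5, 0.5]], 0.5),
    ([[0.0, 0.0]], 0.0),
    ([[0.1, 0.3]], (0.18 + 0.42) / 2),
])
def test_expected_heterozygosity(freqs, expected):
    f = np.asarray(freqs, float)
    t = table(f, np.full(f.shape, 10.0))
    assert expected_heterozygosity(t) == pytest.approx(expected)


def test_allelic_richness_values():
    """Monomorphic locus -> exactly 1; (19,1) alleles at n_rar=10 -> 1.5."""
    # one group, 10 samples = 20 alleles: locus0 monomorphic, locus1 has 1 alt
    codes = np.zeros((10, 2), dtype=np.int16)
    codes[0, 1] = 1  # alt allele count = 1, ref = 19
    g = make_genotypes(codes)
    h = make_hierarchy(g.samples, ["a"] * 10)
    res = allelic_richness(g, h, "site", n_rar=10)
    per_locus_mono = 1.0
    # C(19,10)/C(20,10) = 1/2  =>  A_R = 1 + (1 - 1/2) = 1.5
    assert math.comb(19, 10) / math.comb(20, 10) == pytest.approx(0.5)
    assert res["A_R"] == pytest.approx((per_locus_mono + 1.5) / 2)


def test_allelic_richness_no_rarefaction_equals_allele_count(small_seascape):
    g, h = small_seascape["genotypes"], small_seascape["hierarchy"]
    sub = g.subset(sample_idx=range(24), locus_idx=range(40))
    hsub = h.subset(sub.samples)
    full = (sub.codes != -1)
    if not full.all():  # make fully observed for the exact identity
        sub.codes[sub.codes == -1] = 0
    t = allele_frequencies(sub, hsub, "site")
    n_rar = int(2 * t.n.to_numpy().min())
    res = allelic_richness(sub, hsub, "site", n_rar=n_rar)
    # at full rarefaction depth the smallest group contributes its observed
    # mean allele count exactly
    freqs = t.freq.to_numpy()
    counts = ((freqs > 0) & (freqs < 1)) + 1.0
    observed = counts.mean(axis=1)
    smallest = int(np.argmin(t.n.to_numpy().min(axis=1)))
    assert res["per_group"][t.populations[smallest]] == pytest.approx(
        observed[smallest], abs=1e-9)


def test_allelic_richness_rarefaction_too_small():
    g = make_genotypes(np.zeros((3, 2), dtype=np.int16))
    h = make_hierarchy(g.samples, ["a"] * 3)
    with pytest.raises(ValueError):
        allelic_richness(g, h, "site", n_rar=1)


# ---------------------------------------------------------------------------
# AMOVA


def _nested_hierarchy(samples, sites, reefs, systems):
    return make_hierarchy(samples, sites, reefs, systems)


def test_amova_identical_samples_zero_components():
    codes = np.ones((8, 5), dtype=np.int16)
    g = make_genotypes(codes)
    h = _nested_hierarchy(g.samples,
                          ["a", "a", "b", "b", "c", "c", "d", "d"],
                          ["r1", "r1", "r1", "r1", "r2", "r2", "r2", "r2"],
                          ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2"])
    res = amova(g, h, n_perm=9, seed=0)
    assert np.allclose(res.table["variance"].fillna(0.0), 0.0)


def test_amova_two_groups_one_locus_full_partition():
    """Codes (0,0 | 2,2): all variance among groups (hand computation)."""
    codes = np.array([[0], [0], [2], [2]], dtype=np.int16)
    g = make_genotypes(codes)
    h = _nested_hierarchy(g.samples, ["a", "a", "b", "b"],
                          ["ra", "ra", "rb", "rb"], ["ga", "ga", "gb", "gb"])
    res = amova(g, h, n_perm=0, seed=0)
    # hand SS: total = sum_{i<j} d2 / N = (4 pairs * 4) / 4 = 4; within = 0
    assert res.table.loc["among_systems", "SS"] == pytest.approx(4.0)
    assert res.table.loc["within_sites", "SS"] == pytest.approx(0.0)
    pct = res.table["pct_total"]
    assert pct["among_systems"] == pytest.approx(100.0)


def test_amova_components_reconcile(small_seascape):
    g, h = small_seascape["genotypes"], small_seascape["hierarchy"]
    sub = g.subset(sample_idx=range(0, g.n_samples, 3), locus_idx=range(60))
    res = amova(sub, h.subset(sub.samples), n_perm=19, seed=1)
    t = res.table
    # SS partition sums to the total sum of squares
    d_total = t["SS"].sum()
    assert d_total > 0
    # truncated components non-negative and phi consistent
    trunc = t["variance"].clip(lower=0)
    phi_total = trunc.drop("within_sites").sum() / trunc.sum()
    assert res.phi["phi_ST"] == pytest.approx(phi_total)


# ---------------------------------------------------------------------------
# NJ tree


def _three_point(d01, d02, d12):
    # branch lengths from the three-point formulas
    return ((d01 + d02 - d12) / 2, (d01 + d12 - d02) / 2, (d02 + d12 - d01) / 2)


def test_nj_three_taxa_closed_form():
    d = pd.DataFrame([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]],
                     index=list("abc"), columns=list("abc"))
    nwk = nj_tree(d)
    import io
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(nwk))
    la, lb, lc = _three_point(0.4, 0.6, 0.8)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx(la)
    assert lengths["b"] == pytest.approx(lb)
    assert lengths["c"] == pytest.approx(lc)


def test_nj_recovers_additive_five_taxon_tree():
    """Distances generated from a known tree return its topology exactly."""
    import io
    from skbio import TreeNode
    nwk_true = "((a:0.1,b:0.2):0.15,(c:0.12,d:0.08):0.1,e:0.3);"
    tree = TreeNode.read(io.StringIO(nwk_true))
    names = list("abcde")
    d = np.zeros((5, 5))
    for i in range(5):
        for j in range(i + 1, 5):
            d[i, j] = d[j, i] = tree.find(names[i]).distance(tree.find(names[j]))
    out = nj_tree(pd.DataFrame(d, index=names, columns=names))
    recovered = TreeNode.read(io.StringIO(out))
    assert recovered.compare_rfd(tree) == 0.0


def test_nj_nan_distance_names_pair():
    d = pd.DataFrame([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
                     index=list("xyz"), columns=list("xyz"))
    with pytest.raises(ValueError, match="x"):
        nj_tree(d)


# ---------------------------------------------------------------------------
# DAPC


def test_dapc_two_clusters_recovered():
    """Two well-separated simulated clusters: K*=2, assignments correct."""
    rng = np.random.default_rng(8)
    p1 = rng.uniform(0.1, 0.9, 150)
    delta = np.clip(p1 + rng.choice([-1, 1], 150) * 0.35, 0.02, 0.98)
    codes = np.vstack([rng.binomial(2, p1, (40, 150)),
                       rng.binomial(2, delta, (40, 150))]).astype(np.int16)
    model = DAPC(k_max=6, random_state=0).fit(codes)
    assert model.k_ == 2
    labels = model.labels_
    acc = max((labels[:40] == 0).mean() + (labels[40:] == 1).mean(),
              (labels[:40] == 1).mean() + (labels[40:] == 0).mean()) / 2
    assert acc >= 0.95
    assert np.allclose(model.membership_.sum(axis=1), 1.0, atol=1e-9)


def test_dapc_panmictic_selects_k1():
    """A single panmictic population yields K*=1 in most replicates."""
    rng = np.random.default_rng(9)
    hits = 0
    reps = 10
    for r in range(reps):
        p = rng.uniform(0.2, 0.8, 80)
        codes = rng.binomial(2, p, (50, 80)).astype(np.int16)
        model = DAPC(k_max=4, random_state=r).fit(codes)
        hits += model.k_ == 1
    assert hits >= int(0.8 * reps)


def test_dapc_requires_enough_samples():
    with pytest.raises(ValueError):
        DAPC(k_max=10).fit(np.zeros((5, 4)))
    with pytest.raises(ValueError):
        DAPC(k_max=1).fit(np.zeros((30, 4)))
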