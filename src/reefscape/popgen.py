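"""Connectivity statistics: allele frequencies, Nei F_ST with bootstrap
significance, expected heterozygosity, rarefied allelic richness,
hierarchical AMOVA and a DAPC estimator.

F_ST follows Nei's gene-diversity formulation: per locus
H_S = mean over populations of 2p(1-p) * 2n/(2n-1) (small-sample
correction), H_T = 2 p_bar (1 - p_bar) from the unweighted mean of
population frequencies, and the multilocus estimate is the ratio of sums
F_ST = 1 - sum_l H_S,l / sum_l H_T,l. Significance and confidence
intervals come from bootstrapping loci.

The AMOVA partitions squared Euclidean distances between genotype code
vectors across the sample -> site -> reef -> system nesting, with
variance components by the method of moments for unbalanced nested
designs and permutation p-values at each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import MISSING, GenotypeMatrix, SampleHierarchy


@dataclass
class AlleleFreqTable:
    """Population x locus alternate-allele frequencies with per-cell n."""

    freq: pd.DataFrame   # populations x loci, NaN when n == 0
    n: pd.DataFrame      # genotyped sample counts, same shape

    @property
    def populations(self) -> list:
        return list(self.freq.index)

    @property
    def loci(self) -> list:
        return list(self.freq.columns)


def allele_frequencies(g: GenotypeMatrix, h: SampleHierarchy,
                       level: str = "site") -> AlleleFreqTable:
    """Alternate-allele frequency per hierarchy group and locus."""
    groups = h.loc(g.samples).reset_index()[level].to_numpy()
    labels = pd.unique(groups)
    obs = g.observed
    alt = np.where(obs, g.codes, 0).astype(float)
    freq_rows, n_rows, kept = [], [], []
    for lab in labels:
        rows = groups == lab
        if not rows.any():
            continue
        n = obs[rows].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, alt[rows].sum(axis=0) / (2 * n), np.nan)
        freq_rows.append(f)
        n_rows.append(n)
        kept.append(lab)
    loci = list(g.loci.index)
    return AlleleFreqTable(
        pd.DataFrame(freq_rows, index=kept, columns=loci),
        pd.DataFrame(n_rows, index=kept, columns=loci),
    )


# ---------------------------------------------------------------------------
# Nei F_ST


def _nei_components(freq: np.ndarray, n: np.ndarray):
    """Per-locus (H_S, H_T) over populations; NaN-frequency cells ignored."""
    with np.errstate(invalid="ignore"):
        corr = np.where(n > 0.5, 2 * n / np.maximum(2 * n - 1, 1), np.nan)
        hs_cells = 2 * freq * (1 - freq) * corr
        hs = np.nanmean(np.where(np.isnan(freq), np.nan, hs_cells), axis=0)
        pbar = np.nanmean(freq, axis=0)
        ht = 2 * pbar * (1 - pbar)
    return hs, ht


def nei_fst(freqs: AlleleFreqTable, pops=None, n_boot: int = 1000,
            seed: int | None = None) -> dict:
    """Multilocus Nei F_ST (ratio of sums) with bootstrap CI and p-value.

    ``pops`` selects a subset of populations (default: all). The p-value
    is the fraction of over-loci bootstrap replicates with F_ST <= 0;
    the CI is the percentile 2.5/97.5 interval. Negative estimates are
    truncated to 0 in ``fst`` and kept in ``fst_raw``.
    """
    f = freqs.freq if pops is None else freqs.freq.loc[list(pops)]
    n = freqs.n if pops is None else freqs.n.loc[list(pops)]
    if len(f) < 2:
        raise ValueError("need at least two populations")
    hs, ht = _nei_components(f.to_numpy(dtype=float), n.to_numpy(dtype=float))
    usable = np.isfinite(hs) & np.isfinite(ht) & (ht > 0)
    if not usable.any():
        return {"fst": np.nan, "fst_raw": np.nan, "ci": (np.nan, np.nan),
                "p_value": np.nan, "n_loci": 0}
    hs, ht = hs[usable], ht[usable]
    fst_raw = 1.0 - hs.sum() / ht.sum()
    rng = np.random.default_rng(seed)
    L = hs.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, L, L)
        boots[b] = 1.0 - hs[idx].sum() / ht[idx].sum()
    return {
        "fst": max(fst_raw, 0.0),
        "fst_raw": float(fst_raw),
        "ci": (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
        "p_value": float(np.mean(boots <= 0.0)),
        "n_loci": int(L),
    }


def pairwise_fst(freqs: AlleleFreqTable, n_boot: int = 1000,
                 seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric pairwise F_ST matrix and bootstrap p-values."""
    pops = freqs.populations
    k = len(pops)
    fst = np.zeros((k, k))
    pval = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            res = nei_fst(freqs, pops=[pops[a], pops[b]], n_boot=n_boot,
                          seed=int(rng.integers(2 ** 31)))
            fst[a, b] = fst[b, a] = res["fst"]
            pval[a, b] = pval[b, a] = res["p_value"]
    return (pd.DataFrame(fst, index=pops, columns=pops),
            pd.DataFrame(pval, index=pops, columns=pops))


def per_locus_fst(freq: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-locus Nei F_ST; NaN for monomorphic (H_T = 0) loci."""
    hs, ht = _nei_components(freq, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ht > 0, 1.0 - hs / ht, np.nan)


def expected_heterozygosity(freqs: AlleleFreqTable) -> float:
    """H_T: gene diversity from pooled mean frequencies, averaged over loci."""
    pbar = np.nanmean(freqs.freq.to_numpy(dtype=float), axis=0)
    ht = 2 * pbar * (1 - pbar)
    return float(np.nanmean(ht))


# ---------------------------------------------------------------------------
# allelic richness (El Mousadik & Petit rarefaction)


def allelic_richness(g: GenotypeMatrix, h: SampleHierarchy, level: str = "site",
                     n_rar: int | None = None) -> dict:
    """Rarefied allele count per locus, averaged over loci then groups.

    The rarefaction size defaults to the smallest per-group, per-locus
    allele count 2n (must be >= 2). For a biallelic locus the value lies
    in [1, 2]; a monomorphic locus contributes exactly 1.
    """
    from scipy.special import gammaln

    freqs = allele_frequencies(g, h, level=level)
    n = freqs.n.to_numpy(dtype=float)
    f = freqs.freq.to_numpy(dtype=float)
    alleles = 2 * n
    if n_rar is None:
        pos = alleles[alleles > 0]
        if pos.size == 0:
            raise ValueError("no genotyped samples")
        n_rar = int(pos.min())
    if n_rar < 2:
        raise ValueError(f"rarefaction size must be >= 2, got {n_rar}")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    per_group = {}
    for gi, grp in enumerate(freqs.populations):
        vals = []
        for li in range(f.shape[1]):
            tot = alleles[gi, li]
            if tot < n_rar or np.isnan(f[gi, li]):
                continue
            n_alt = round(f[gi, li] * tot)
            a_r = 0.0
            for count in (n_alt, tot - n_alt):
                if count > 0:
                    if tot - count >= n_rar:
                        miss = np.exp(log_comb(tot - count, n_rar) - log_comb(tot, n_rar))
                    else:
                        miss = 0.0
                    a_r += 1.0 - miss
            vals.append(a_r)
        if vals:
            per_group[grp] = float(np.mean(vals))
    if not per_group:
        raise ValueError("no locus/group combination reaches the rarefaction size")
    return {"A_R": float(np.mean(list(per_group.values()))),
            "per_group": per_group, "n_rar": int(n_rar)}


# ---------------------------------------------------------------------------
# hierarchical AMOVA


@dataclass
class AmovaResult:
    table: pd.DataFrame            # df, SS, MS, variance component, % total
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        import json
        payload = json.dumps({
            "table": self.table.reset_index().to_dict(orient="records"),
            "phi": self.phi, "p_values": self.p_values,
        }, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _squared_distance_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise-complete mean squared code difference, scaled by locus count."""
    obs = g.observed.astype(np.float64)
    x = np.where(g.observed, g.codes, 0).astype(np.float64)
    sq = x ** 2
    cross = x @ x.T
    ss = sq @ obs.T + obs @ sq.T - 2 * cross
    comparable = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(comparable > 0, ss / comparable, 0.0) * g.n_loci
    np.fill_diagonal(d2, 0.0)
    return d2


def _within_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in pd.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * idx.size)
    return total


def _amova_components(d2, sites, reefs, systems):
    """Sums of squares, df and method-of-moments variance components."""
    N = d2.shape[0]
    ss_total = d2.sum() / (2.0 * N)
    w_site = _within_ss(d2, sites)
    w_reef = _within_ss(d2, reefs)
    w_sys = _within_ss(d2, systems)

    site_ids = pd.unique(sites)
    reef_ids = pd.unique(reefs)
    sys_ids = pd.unique(systems)
    S, R, G = len(site_ids), len(reef_ids), len(sys_ids)

    ss = {
        "among_systems": ss_total - w_sys,
        "among_reefs": w_sys - w_reef,
        "among_sites": w_reef - w_site,
        "within_sites": w_site,
    }
    df = {
        "among_systems": G - 1,
        "among_reefs": R - G,
        "among_sites": S - R,
        "within_sites": N - S,
    }

    n_site = pd.Series(sites).value_counts()
    n_reef = pd.Series(reefs).value_counts()
    n_sys = pd.Series(systems).value_counts()
    site_info = pd.DataFrame({"site": sites, "reef": reefs, "system": systems}).drop_duplicates("site")
    site_n = n_site.rename("n")
    site_info = site_info.set_index("site").join(site_n)
    reef_sys = site_info.groupby("reef")["system"].first()

    def sum_sq_over(parent_level):
        # sum over parents of (sum of child n^2) / parent n
        if parent_level == "reef":
            return sum(
                (site_info.loc[site_info["reef"] == r, "n"] ** 2).sum() / n_reef[r]
                for r in reef_ids)
        if parent_level == "system_site":
            return sum(
                (site_info.loc[site_info["system"] == s, "n"] ** 2).sum() / n_sys[s]
                for s in sys_ids)
        if parent_level == "system_reef":
            return sum(
                sum(n_reef[r] ** 2 for r in reef_ids if reef_sys[r] == s) / n_sys[s]
                for s in sys_ids)
        raise ValueError(parent_level)

    sum_nsite_sq = float((site_info["n"] ** 2).sum())
    sum_nreef_sq = float((n_reef ** 2).sum())
    sum_nsys_sq = float((n_sys ** 2).sum())

    # expected-mean-square coefficients for the unbalanced nested design
    k3 = (N - sum_sq_over("reef")) / df["among_sites"] if df["among_sites"] > 0 else 0.0
    if df["among_reefs"] > 0:
        k2a = (sum_sq_over("reef") - sum_sq_over("system_site")) / df["among_reefs"]
        k2b = (N - sum_sq_over("system_reef")) / df["among_reefs"]
    else:
        k2a = k2b = 0.0
    if df["among_systems"] > 0:
        k1a = (sum_sq_over("system_site") - sum_nsite_sq / N) / df["among_systems"]
        k1b = (sum_sq_over("system_reef") - sum_nreef_sq / N) / df["among_systems"]
        k1c = (N - sum_nsys_sq / N) / df["among_systems"]
    else:
        k1a = k1b = k1c = 0.0

    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}
    sigma_w = ms["within_sites"]
    sigma_s = (ms["among_sites"] - sigma_w) / k3 if k3 > 0 else 0.0
    sigma_r = ((ms["among_reefs"] - sigma_w - k2a * sigma_s) / k2b) if k2b > 0 else 0.0
    sigma_g = ((ms["among_systems"] - sigma_w - k1a * sigma_s - k1b * sigma_r) / k1c) if k1c > 0 else 0.0
    comps = {"among_systems": sigma_g, "among_reefs": sigma_r,
             "among_sites": sigma_s, "within_sites": sigma_w}
    return ss, df, ms, comps


def amova(g: GenotypeMatrix, h: SampleHierarchy, n_perm: int = 999,
          seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA across system / reef / site / sample levels.

    Permutation tests move units at the appropriate level: samples among
    sites (within reefs), sites among reefs (within systems), reefs among
    systems; one-sided p-values on the variance component.
    """
    tab = h.loc(g.samples)
    sites = tab["site"].to_numpy()
    reefs = tab["reef"].to_numpy()
    systems = tab["system"].to_numpy()
    if len(pd.unique(systems)) < 2:
        raise ValueError("need at least two systems")
    d2 = _squared_distance_matrix(g)
    ss, df, ms, comps = _amova_components(d2, sites, reefs, systems)

    total_var = sum(max(v, 0.0) for v in comps.values())
    trunc = {k: max(v, 0.0) for k, v in comps.items()}
    pct = {k: (100.0 * trunc[k] / total_var if total_var > 0 else np.nan) for k in comps}
    phi = {
        "phi_ST": (trunc["among_systems"] + trunc["among_reefs"] + trunc["among_sites"]) / total_var
        if total_var > 0 else np.nan,
        "phi_CT": trunc["among_systems"] / total_var if total_var > 0 else np.nan,
        "phi_SC": (trunc["among_reefs"] / (trunc["among_reefs"] + trunc["among_sites"] + trunc["within_sites"]))
        if (trunc["among_reefs"] + trunc["among_sites"] + trunc["within_sites"]) > 0 else np.nan,
        "phi_RS": (trunc["among_sites"] / (trunc["among_sites"] + trunc["within_sites"]))
        if (trunc["among_sites"] + trunc["within_sites"]) > 0 else np.nan,
    }

    rng = np.random.default_rng(seed)
    pvals = {}
    # sample hierarchy lookup tables
    site_info = pd.DataFrame({"site": sites, "reef": reefs, "system": systems}).drop_duplicates("site")
    reef_info = site_info.drop_duplicates("reef")[["reef", "system"]]

    def comp_of(sites_p, reefs_p, systems_p, key):
        try:
            return _amova_components(d2, sites_p, reefs_p, systems_p)[3][key]
        except Exception:
            return np.nan

    # samples among sites (shuffle site labels of samples, keep site->reef map)
    if df["among_sites"] > 0 and n_perm > 0:
        obs = comps["among_sites"]
        count = 0
        site_to_reef = site_info.set_index("site")["reef"].to_dict()
        site_to_sys = site_info.set_index("site")["system"].to_dict()
        for _ in range(n_perm):
            perm_sites = rng.permutation(sites)
            perm_reefs = np.array([site_to_reef[s] for s in perm_sites])
            perm_sys = np.array([site_to_sys[s] for s in perm_sites])
            if comp_of(perm_sites, perm_reefs, perm_sys, "among_sites") >= obs:
                count += 1
        pvals["among_sites"] = (count + 1) / (n_perm + 1)
    else:
        pvals["among_sites"] = np.nan

    # sites among reefs (reassign whole sites to reefs, within nothing)
    if df["among_reefs"] > 0 and n_perm > 0:
        obs = comps["among_reefs"]
        count = 0
        site_ids = site_info["site"].to_numpy()
        site_reefs = site_info["reef"].to_numpy()
        reef_to_sys = reef_info.set_index("reef")["system"].to_dict()
        for _ in range(n_perm):
            perm = rng.permutation(site_reefs)
            site_to_reef_p = dict(zip(site_ids, perm))
            perm_reefs = np.array([site_to_reef_p[s] for s in sites])
            perm_sys = np.array([reef_to_sys[r] for r in perm_reefs])
            if comp_of(sites, perm_reefs, perm_sys, "among_reefs") >= obs:
                count += 1
        pvals["among_reefs"] = (count + 1) / (n_perm + 1)
    else:
        pvals["among_reefs"] = np.nan

    # reefs among systems
    if df["among_systems"] > 0 and n_perm > 0:
        obs = comps["among_systems"]
        count = 0
        reef_ids = reef_info["reef"].to_numpy()
        reef_systems = reef_info["system"].to_numpy()
        for _ in range(n_perm):
            perm = rng.permutation(reef_systems)
            reef_to_sys_p = dict(zip(reef_ids, perm))
            perm_sys = np.array([reef_to_sys_p[r] for r in reefs])
            if comp_of(sites, reefs, perm_sys, "among_systems") >= obs:
                count += 1
        pvals["among_systems"] = (count + 1) / (n_perm + 1)
    else:
        pvals["among_systems"] = np.nan

    table = pd.DataFrame({
        "df": pd.Series(df), "SS": pd.Series(ss), "MS": pd.Series(ms),
        "variance": pd.Series(comps), "pct_total": pd.Series(pct),
    })
    return AmovaResult(table, phi, pvals)


# ---------------------------------------------------------------------------
# NJ tree


def fst_linearized_distance(fst: pd.DataFrame) -> pd.DataFrame:
    """Slatkin-linearised distance F_ST / (1 - F_ST)."""
    f = fst.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        d = f / (1.0 - f)
    return pd.DataFrame(d, index=fst.index, columns=fst.columns)


def nj_tree(dist: pd.DataFrame) -> str:
    """Saitou-Nei neighbour joining; returns a Newick string.

    Negative branch lengths are clamped to zero; requires a symmetric
    matrix with zero diagonal and at least three taxa.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = dist.to_numpy(dtype=float)
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(d).any():
        i, j = map(int, np.argwhere(np.isnan(d))[0])
        raise ValueError(f"NaN distance between {dist.index[i]!r} and {dist.columns[j]!r}")
    dm = DistanceMatrix((d + d.T) / 2.0, ids=[str(x) for x in dist.index])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


# ---------------------------------------------------------------------------
# DAPC


class DAPC(BaseEstimator):
    """Discriminant analysis of principal components with BIC model choice.

    The genotype code matrix is mean-imputed, centred/scaled and projected
    onto principal components; k-means over K = 1..k_max (BIC =
    n log(WSS/n) + K log n) picks the cluster count, and linear
    discriminant axes on the retained PCs give membership probabilities.
    ``n_pcs="auto"`` retains min(n_samples - 1, #components reaching >= 95%
    cumulative variance).

    Attributes (after fit): ``k_``, ``bic_``, ``n_pcs_``, ``membership_``,
    ``labels_``, ``coords_``.
    """

    def __init__(self, k_max: int = 10, n_pcs="auto", n_init: int = 20,
                 var_explained: float = 0.95, random_state: int | None = None):
        self.k_max = k_max
        self.n_pcs = n_pcs
        self.n_init = n_init
        self.var_explained = var_explained
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        X = self._prepare(np.asarray(X, dtype=float))
        n = X.shape[0]
        if n < self.k_max:
            raise ValueError("need at least k_max samples")
        pca = PCA(n_components=min(n - 1, X.shape[1]), random_state=self.random_state)
        scores = pca.fit_transform(X)
        if self.n_pcs == "auto":
            cum = np.cumsum(pca.explained_variance_ratio_)
            n_pcs = int(np.searchsorted(cum, self.var_explained) + 1)
            n_pcs = min(n_pcs, n - 1, scores.shape[1])
        else:
            n_pcs = int(min(self.n_pcs, scores.shape[1]))
        Z = scores[:, :n_pcs]

        bics = {}
        labels_by_k = {}
        rng = np.random.default_rng(self.random_state)
        for k in range(1, self.k_max + 1):
            if k == 1:
                labels = np.zeros(n, dtype=int)
                wss = float(((Z - Z.mean(axis=0)) ** 2).sum())
            else:
                km = KMeans(n_clusters=k, n_init=self.n_init,
                            random_state=int(rng.integers(2 ** 31)))
                labels = km.fit_predict(Z)
                wss = float(km.inertia_)
            bics[k] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
            labels_by_k[k] = labels
        k_best = min(bics, key=bics.get)
        labels = labels_by_k[k_best]

        if k_best == 1:
            membership = np.ones((n, 1))
            coords = np.zeros((n, 0))
            self.lda_ = None
        else:
            lda = LinearDiscriminantAnalysis()  # all discriminant axes kept
            coords = lda.fit_transform(Z, labels)
            membership = lda.predict_proba(Z)
            self.lda_ = lda

        self.pca_ = pca
        self.k_ = int(k_best)
        self.bic_ = bics
        self.n_pcs_ = n_pcs
        self.labels_ = labels
        self.membership_ = membership
        self.coords_ = coords
        return self

    def _prepare(self, X):
        X = X.copy()
        miss = (X == MISSING) | np.isnan(X)
        col_mean = np.where(miss, np.nan, X).astype(float)
        mu = np.nanmean(col_mean, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        X = np.where(miss, mu[None, :], X).astype(float)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._mu, self._sd = X.mean(axis=0), sd
        return (X - X.mean(axis=0)) / sd


def dapc(g: GenotypeMatrix, k_max: int = 10, n_pcs="auto",
         seed: int | None = None) -> DAPC:
    """Fit a DAPC on a genotype matrix (thin wrapper over :class:`DAPC`)."""
    model = DAPC(k_max=k_max, n_pcs=n_pcs, random_state=seed)
    return model.fit(g.codes.astype(float))
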