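"""Outlier and gene-environment association scans.

Two complementary scans partition loci into putatively neutral and
selection-candidate sets:

* a permutation F_ST outlier scan — per-locus Nei F_ST against a null
  distribution built by permuting individuals among populations, with
  Benjamini-Hochberg FDR control;
* a Samβada-style logistic gene-environment scan — for each locus and
  environmental variable, a logistic model of individual allele presence
  on the (standardised) variable, judged significant only when BOTH the
  likelihood-ratio (G) and Wald statistics pass the corrected threshold.
  The population-corrected mode adds DAPC cluster-membership covariates.

Individuals sampled from the same site share that site's allele
frequency, which overdisperses classical per-individual logistic tests
under hierarchical structure. Both statistics are therefore made
structure-aware: the G (likelihood-ratio) statistic is scaled by a
per-locus quasi-binomial dispersion estimated from site-level Pearson
residuals and referred to F(1, n_sites - d), and the Wald statistic uses
a reef-clustered sandwich (CR1) variance with an F(1, n_reefs - 1)
reference. The dual G-and-Wald decision then controls the family-wise
error under nested population structure while keeping power against
genuine environmental clines.

The logistic fits are batched: all loci share the per-variable design
matrix, so Newton-Raphson iterations run vectorised across loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, f as fdist

from .genotypes import MISSING, GenotypeMatrix, SampleHierarchy
from .popgen import AlleleFreqTable, allele_frequencies, per_locus_fst

_MAX_ABS_BETA = 15.0  # |beta| beyond this on a [0,1] covariate signals separation


# ---------------------------------------------------------------------------
# batched logistic regression


def _batched_logistic(X: np.ndarray, Y: np.ndarray, W: np.ndarray,
                      max_iter: int = 30, tol: float = 1e-8):
    """Weighted logistic regression fit independently for each row of Y.

    X: (n, d) shared design; Y, W: (L, n) responses and 0/1 weights.
    Returns (beta (L, d), loglik (L,), cov (L, d, d), ok (L,)).
    """
    L, n = Y.shape
    d = X.shape[1]
    beta = np.zeros((L, d))
    ok = np.ones(L, dtype=bool)
    ridge = 1e-9 * np.eye(d)
    for _ in range(max_iter):
        eta = beta @ X.T
        p = expit(eta)
        grad = ((Y - p) * W) @ X
        wpq = W * p * (1.0 - p)
        H = np.einsum("ln,ni,nj->lij", wpq, X, X, optimize=True) + ridge
        try:
            delta = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = np.einsum("lij,lj->li", np.linalg.pinv(H), grad)
        np.clip(delta, -5.0, 5.0, out=delta)
        beta += delta
        if np.abs(delta).max() < tol:
            break
    eta = beta @ X.T
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    loglik = (W * (Y * np.log(p) + (1 - Y) * np.log(1 - p))).sum(axis=1)
    wpq = W * p * (1.0 - p)
    H = np.einsum("ln,ni,nj->lij", wpq, X, X, optimize=True) + ridge
    Hinv = np.linalg.pinv(H)
    ok &= np.abs(beta).max(axis=1) <= _MAX_ABS_BETA
    ok &= np.isfinite(loglik)
    return beta, loglik, Hinv, ok, (p, W)


def _cluster_robust_cov(X, Y, W, p, Hinv, clusters):
    """CR1 sandwich covariance with cluster-summed scores.

    clusters: (n,) integer labels. Returns (L, d, d) covariances scaled
    by the m/(m-1) small-sample factor.
    """
    resid = W * (Y - p)  # (L, n)
    labels = np.unique(clusters)
    m = labels.size
    d = X.shape[1]
    meat = np.zeros((Y.shape[0], d, d))
    for c in labels:
        idx = clusters == c
        g = resid[:, idx] @ X[idx]  # (L, d)
        meat += g[:, :, None] * g[:, None, :]
    factor = m / max(m - 1, 1)
    return factor * np.einsum("lij,ljk,lkm->lim", Hinv, meat, Hinv, optimize=True), m


def _site_dispersion(Y, W, p, clusters, n_params):
    """Per-locus quasi-binomial dispersion from site-aggregated residuals.

    phi_l = X^2_l / (m - d) with X^2 the Pearson chi-square of site-level
    allele-presence counts against the fitted probabilities, floored at 1.
    """
    resid = W * (Y - p)
    var = W * p * (1.0 - p)
    labels = np.unique(clusters)
    x2 = np.zeros(Y.shape[0])
    for c in labels:
        idx = clusters == c
        r = resid[:, idx].sum(axis=1)
        v = var[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            x2 += np.where(v > 0, r * r / v, 0.0)
    df = max(labels.size - n_params, 1)
    return np.maximum(x2 / df, 1.0), df


@dataclass
class GEAResult:
    """Tidy locus x variable association table plus per-locus locus sets."""

    associations: pd.DataFrame  # locus, variable, orientation, G, wald, p, q, significant
    per_locus: pd.DataFrame     # fst, fst_outlier, gea_significant, outlier, polymorphic_pops
    mode: str
    correction: str
    alpha: float
    gf_set: list = field(default_factory=list)
    gdm_set: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# F_ST outlier scan


def fst_outlier_scan(g: GenotypeMatrix, h: SampleHierarchy, level: str = "site",
                     n_perm: int = 2000, fdr: float = 0.05,
                     center: bool = False,
                     seed: int | None = None) -> pd.DataFrame:
    """Per-locus F_ST outlier calls against an individual-permutation null.

    With ``center=False`` the test statistic is the raw per-locus F_ST:
    the null is panmixia, so under genome-wide background structure most
    loci exceed it. ``center=True`` subtracts the across-locus mean F_ST
    (in the observed data and in every permutation alike), testing for
    *excess* differentiation over the genome-wide background — the
    variant a neutral-panel construction should use when the organism is
    genuinely structured.

    Returns a DataFrame indexed by locus with columns ``fst``, ``p``,
    ``q``, ``outlier``. Monomorphic loci are untestable and labelled
    neutral with p = q = NaN.
    """
    groups = h.loc(g.samples)[level].to_numpy()
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    P = (groups[:, None] == labels[None, :]).T.astype(np.float64)  # (npop, n)
    O = g.observed.astype(np.float64)
    A = np.where(g.observed, g.codes, 0).astype(np.float64)

    def scan(P_, raw: bool = False):
        n = P_ @ O
        alt = P_ @ A
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, alt / (2 * n), np.nan)
        f = per_locus_fst(freq, n)
        if center and not raw:
            f = f - np.nanmean(f)
        return f

    raw_fst = scan(P, raw=True)
    obs_fst = raw_fst - np.nanmean(raw_fst) if center else raw_fst
    testable = np.isfinite(obs_fst)
    rng = np.random.default_rng(seed)
    count = np.zeros(g.n_loci)
    n_samples = g.n_samples
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        f = scan(P[:, perm])
        count += np.where(np.isfinite(f), f, -np.inf) >= np.nan_to_num(obs_fst, nan=np.inf)
    p = np.full(g.n_loci, np.nan)
    p[testable] = (1.0 + count[testable]) / (n_perm + 1.0)
    from .qc import _bh_reject
    reject = _bh_reject(p, fdr)
    q = _bh_qvalues(p)
    return pd.DataFrame({
        "fst": raw_fst, "p": p, "q": q, "outlier": reject,
    }, index=g.loci.index)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    idx = np.nonzero(ok)[0]
    order = np.argsort(p[idx], kind="stable")
    ranked = p[idx][order]
    raw = ranked * m / np.arange(1, m + 1)
    qvals = np.minimum.accumulate(raw[::-1])[::-1]
    q[idx[order]] = np.minimum(qvals, 1.0)
    return q


# ---------------------------------------------------------------------------
# logistic GEA scan


def logistic_gea(g: GenotypeMatrix, h: SampleHierarchy, site_env_std: pd.DataFrame,
                 mode: str = "univariate", alpha: float = 0.05,
                 correction: str = "bonferroni",
                 membership: np.ndarray | None = None) -> GEAResult:
    """Samβada-style logistic GEA scan across loci and variables.

    ``site_env_std`` is the standardised site x variable table; samples
    map to rows via their site. In ``pop_corrected`` mode,
    ``membership`` (samples x K cluster probabilities, e.g. from DAPC)
    enters the model as covariates. A locus x variable pair is significant
    only if both the G (likelihood-ratio) and Wald tests pass the
    ``correction``-adjusted alpha; non-estimable (separated) fits are
    never significant.
    """
    if mode not in ("univariate", "pop_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pop_corrected":
        if membership is None:
            raise ValueError("pop_corrected mode needs cluster membership probabilities")
        membership = np.asarray(membership, dtype=float)
        covar = membership[:, :-1] if membership.shape[1] > 1 else np.zeros((len(g.samples), 0))
    else:
        covar = np.zeros((len(g.samples), 0))

    sites = h.loc(g.samples)["site"].to_numpy()
    env_by_sample = site_env_std.loc[sites].to_numpy(dtype=float)  # (n, V)
    variables = list(site_env_std.columns)
    n, L = g.n_samples, g.n_loci
    obs = g.observed
    W = obs.T.astype(np.float64)  # (L, n)
    _, site_clusters = np.unique(sites, return_inverse=True)
    reefs = h.loc(g.samples)["reef"].to_numpy()
    _, reef_clusters = np.unique(reefs, return_inverse=True)

    # two response orientations: presence of alt allele, alt homozygosity
    Y_dom = ((g.codes > 0) & obs).T.astype(np.float64)
    Y_rec = ((g.codes == 2) & obs).T.astype(np.float64)

    ones = np.ones((n, 1))
    X_red = np.hstack([ones, covar])
    records = []
    for orient, Y in (("dominant", Y_dom), ("recessive", Y_rec)):
        _, ll_red, _, ok_red, _ = _batched_logistic(X_red, Y, W)
        for vi, var in enumerate(variables):
            x = env_by_sample[:, vi:vi + 1]
            if np.ptp(x) == 0:
                records.append(pd.DataFrame({
                    "locus": g.loci.index, "variable": var, "orientation": orient,
                    "G": 0.0, "wald": 0.0, "p_g": 1.0, "p_wald": 1.0,
                    "estimable": False, "beta": 0.0,
                }))
                continue
            X_full = np.hstack([ones, covar, x])
            beta, ll_full, Hinv, ok_full, (p_hat, _) = _batched_logistic(X_full, Y, W)
            Graw = np.maximum(2.0 * (ll_full - ll_red), 0.0)
            env_ix = X_full.shape[1] - 1
            phi, df_disp = _site_dispersion(Y, W, p_hat, site_clusters,
                                            X_full.shape[1])
            Gstat = Graw / phi
            cov_cr, m_clust = _cluster_robust_cov(X_full, Y, W, p_hat, Hinv,
                                                  reef_clusters)
            se2 = cov_cr[:, env_ix, env_ix]
            with np.errstate(invalid="ignore", divide="ignore"):
                wald = np.where(se2 > 0, beta[:, env_ix] ** 2 / se2, 0.0)
            estimable = ok_full & ok_red
            records.append(pd.DataFrame({
                "locus": g.loci.index, "variable": var, "orientation": orient,
                "G": Gstat, "wald": wald,
                "p_g": fdist.sf(Gstat, 1, df_disp),
                "p_wald": fdist.sf(wald, 1, max(m_clust - 1, 1)),
                "estimable": estimable, "beta": beta[:, env_ix],
            }))
    tidy = pd.concat(records, ignore_index=True)
    # the multiplicity count covers every fitted model (both orientations)
    m_tests = int(tidy["estimable"].sum())
    # keep the better orientation per locus x variable (larger G)
    tidy = (tidy.sort_values(["locus", "variable", "G"], ascending=[True, True, False])
                .drop_duplicates(["locus", "variable"], keep="first")
                .reset_index(drop=True))
    tidy["p"] = np.maximum(tidy["p_g"], tidy["p_wald"])  # both tests must pass
    if correction == "bonferroni":
        thresh = alpha / max(m_tests, 1)
        tidy["significant"] = tidy["estimable"] & (tidy["p_g"] <= thresh) & (tidy["p_wald"] <= thresh)
    elif correction == "bh":
        p_for_bh = np.where(tidy["estimable"], tidy["p"], np.nan)
        from .qc import _bh_reject
        tidy["significant"] = _bh_reject(p_for_bh, alpha)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    tidy["q"] = _bh_qvalues(np.where(tidy["estimable"], tidy["p"].to_numpy(), np.nan))

    sig_by_locus = tidy.groupby("locus")["significant"].any()
    per_locus = pd.DataFrame(index=g.loci.index)
    per_locus["gea_significant"] = sig_by_locus.reindex(g.loci.index).fillna(False)
    return GEAResult(tidy, per_locus, mode=mode, correction=correction, alpha=alpha)


# ---------------------------------------------------------------------------
# adaptive-locus selection


def select_adaptive_loci(gea: GEAResult, freqs: AlleleFreqTable,
                         min_poly_frac: float = 0.20,
                         fst_outliers: pd.DataFrame | None = None,
                         ) -> tuple[list, list]:
    """Select the GF and GDM locus sets from the association results.

    ``gdm_set`` holds every locus with at least one significant
    association; ``gf_set`` restricts it to loci polymorphic
    (0 < p < 1) in more than ``min_poly_frac`` of populations. The
    per-locus table is annotated with the union outlier flag
    (F_ST outlier or GEA-significant) and the polymorphic-population
    count.
    """
    sig = gea.per_locus["gea_significant"]
    gdm_set = list(sig[sig].index)

    f = freqs.freq
    poly = ((f > 0) & (f < 1)).sum(axis=0)
    poly_frac = poly / len(f.index)
    gea.per_locus["polymorphic_pops"] = poly.reindex(gea.per_locus.index).fillna(0).astype(int)
    gea.per_locus["poly_frac"] = poly_frac.reindex(gea.per_locus.index).fillna(0.0)
    if fst_outliers is not None:
        gea.per_locus["fst_outlier"] = (
            fst_outliers["outlier"].reindex(gea.per_locus.index).fillna(False))
    else:
        gea.per_locus["fst_outlier"] = False
    gea.per_locus["outlier"] = gea.per_locus["fst_outlier"] | gea.per_locus["gea_significant"]

    gf_set = [l for l in gdm_set if gea.per_locus.loc[l, "poly_frac"] > min_poly_frac]
    gea.gf_set = gf_set
    gea.gdm_set = gdm_set
    if not gdm_set:
        import warnings
        warnings.warn("no significant gene-environment associations; "
                      "downstream GF/GDM models cannot be fitted")
    return gf_set, gdm_set
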