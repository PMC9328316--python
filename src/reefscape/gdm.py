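"""Generalized dissimilarity modelling of genetic turnover.

GDM regresses pairwise genetic dissimilarity d_ij in [0, 1) on
between-site differences of monotone I-spline transforms of the
environmental predictors:

    eta_ij = a0 + sum_p sum_k c_pk |I_pk(x_pi) - I_pk(x_pj)|,
    dhat_ij = 1 - exp(-eta_ij),

with all coefficients (including the intercept) constrained
non-negative, fitted by iteratively reweighted least squares with an
inner non-negative least-squares step under a binomial deviance
objective. Three order-2 I-splines per predictor with knots at the
min / median / max of the observed values are used; a predictor's
relative importance is the sum of its I-spline coefficients.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .grids import haversine_km
from .popgen import AlleleFreqTable

_EPS = 1e-9


# ---------------------------------------------------------------------------
# genetic dissimilarity


def genetic_dissimilarity(freqs: AlleleFreqTable, metric: str = "euclidean",
                          fst: pd.DataFrame | None = None) -> pd.DataFrame:
    """Site-pair genetic dissimilarity matrix on [0, 1].

    ``euclidean``: Euclidean distance between site allele-frequency
    vectors over pairwise-complete loci, rescaled by its maximum.
    ``fst``: Slatkin-linearised F_ST / (1 - F_ST), also max-rescaled
    (requires a precomputed pairwise ``fst`` matrix).
    """
    if metric == "fst":
        if fst is None:
            raise ValueError("metric='fst' requires a pairwise fst matrix")
        d = fst.to_numpy(dtype=float)
        d = d / np.maximum(1.0 - d, _EPS)
    elif metric == "euclidean":
        f = freqs.freq.to_numpy(dtype=float)
        keep = ~np.all(np.isnan(f), axis=1)
        if not keep.all():
            warnings.warn("sites with all-missing frequencies excluded")
            f = f[keep]
        k = f.shape[0]
        if k < 3:
            raise ValueError("need at least 3 sites")
        d = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                both = ~np.isnan(f[a]) & ~np.isnan(f[b])
                if not both.any():
                    d[a, b] = d[b, a] = np.nan
                else:
                    d[a, b] = d[b, a] = float(np.sqrt(np.sum((f[a, both] - f[b, both]) ** 2)))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = np.nanmax(d)
    if m > 0:
        d = d / m
    idx = freqs.freq.index if metric == "euclidean" else fst.index
    return pd.DataFrame(d, index=idx[: d.shape[0]], columns=idx[: d.shape[0]])


# ---------------------------------------------------------------------------
# I-spline basis


def ispline_basis(values, knots) -> np.ndarray:
    """Three order-2 (piecewise-quadratic) I-spline basis columns.

    ``knots`` = (min, median, max), strictly increasing. Each basis
    function is a monotone non-decreasing integral of an M-spline, 0 at
    the lower knot and 1 at and beyond the upper knot. Built as partial
    sums of the degree-2 B-spline basis on the augmented knot vector.
    """
    q1, q2, q3 = (float(k) for k in knots)
    if not (q1 < q2 < q3):
        raise ValueError("knots must be strictly increasing (min < median < max)")
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("NaN values cannot be spline-transformed")
    span = q3 - q1
    xc = np.clip(x, q1, q3 - 1e-9 * span)  # keep strictly inside the base interval
    t = np.array([q1, q1, q1, q2, q3, q3, q3])
    design = BSpline.design_matrix(xc.ravel(), t, 2).toarray()  # (n, 4)
    # I_i = sum of B-splines with index > i (partition of unity makes these
    # the monotone integrated M-splines)
    basis = np.column_stack([
        design[:, 1:].sum(axis=1),
        design[:, 2:].sum(axis=1),
        design[:, 3],
    ])
    basis[x.ravel() >= q3] = 1.0
    basis[x.ravel() <= q1] = 0.0
    return basis.reshape(x.shape + (3,)) if x.ndim > 1 else basis


class GDM(BaseEstimator):
    """Generalized dissimilarity model with non-negative I-spline fit.

    Attributes (after fit): ``intercept_``, ``coefs_`` (predictor ->
    3-vector), ``knots_``, ``deviance_explained_``, ``importance_``.
    """

    def __init__(self, n_splines: int = 3, include_geo: bool = False,
                 max_iter: int = 500, tol: float = 1e-8):
        if n_splines != 3:
            raise ValueError("only the default 3 I-splines per predictor are supported")
        self.n_splines = n_splines
        self.include_geo = include_geo
        self.max_iter = max_iter
        self.tol = tol

    # -- design ----------------------------------------------------------

    def _knots(self, col: np.ndarray) -> tuple[float, float, float]:
        lo, med, hi = float(np.min(col)), float(np.median(col)), float(np.max(col))
        if not lo < med < hi:  # degenerate medians collapse onto a bound
            med = (lo + hi) / 2.0
        return lo, med, hi

    def _pair_design(self, env_a: pd.DataFrame, env_b: pd.DataFrame) -> np.ndarray:
        blocks = []
        for p in self.predictors_:
            I_a = ispline_basis(env_a[p].to_numpy(dtype=float), self.knots_[p])
            I_b = ispline_basis(env_b[p].to_numpy(dtype=float), self.knots_[p])
            blocks.append(np.abs(I_a - I_b))
        if self.include_geo:
            d = haversine_km(env_a["lon"].to_numpy(), env_a["lat"].to_numpy(),
                             env_b["lon"].to_numpy(), env_b["lat"].to_numpy())
            blocks.append(np.abs(ispline_basis(d, self.knots_["_geo"])
                                 - ispline_basis(np.zeros_like(d), self.knots_["_geo"])))
        return np.hstack(blocks)

    # -- fitting ----------------------------------------------------------

    def fit(self, site_env: pd.DataFrame, D: pd.DataFrame,
            coords: pd.DataFrame | None = None):
        """Fit to a site x site dissimilarity matrix ``D`` and raw site
        environments (rows aligned with D's index)."""
        site_env = site_env.loc[D.index]
        self.predictors_ = [str(c) for c in site_env.columns]
        if len(D) < 3:
            raise ValueError("need at least 3 sites")
        self.knots_ = {p: self._knots(site_env[p].to_numpy(dtype=float))
                       for p in self.predictors_}
        k = len(D)
        ia, ib = np.triu_indices(k, 1)
        env_a = site_env.iloc[ia].reset_index(drop=True)
        env_b = site_env.iloc[ib].reset_index(drop=True)
        if self.include_geo:
            if coords is None:
                raise ValueError("include_geo requires site coordinates")
            coords = coords.loc[D.index]
            dists = haversine_km(coords["lon"].to_numpy()[ia], coords["lat"].to_numpy()[ia],
                                 coords["lon"].to_numpy()[ib], coords["lat"].to_numpy()[ib])
            self.knots_["_geo"] = self._knots(np.concatenate([[0.0], dists]))
            env_a = env_a.assign(lon=coords["lon"].to_numpy()[ia], lat=coords["lat"].to_numpy()[ia])
            env_b = env_b.assign(lon=coords["lon"].to_numpy()[ib], lat=coords["lat"].to_numpy()[ib])
        A = self._pair_design(env_a, env_b)
        d_obs = D.to_numpy(dtype=float)[ia, ib]
        if np.isnan(d_obs).any():
            raise ValueError("NaN dissimilarities in the pair table")

        beta = self._irls(np.hstack([np.ones((len(d_obs), 1)), A]), d_obs)
        self.intercept_ = float(beta[0])
        coefs = beta[1:]
        self.coefs_ = {}
        pred_names = list(self.predictors_) + (["_geo"] if self.include_geo else [])
        for i, p in enumerate(pred_names):
            self.coefs_[p] = coefs[3 * i: 3 * i + 3].copy()
        self.importance_ = pd.Series({p: float(self.coefs_[p].sum()) for p in pred_names})

        d_hat = self._predict_from_design(A)
        self.deviance_ = _binomial_deviance(d_obs, d_hat)
        null_mu = np.clip(np.full_like(d_obs, d_obs.mean()), 1e-6, 1 - 1e-6)
        self.null_deviance_ = _binomial_deviance(d_obs, null_mu)
        self.deviance_explained_ = (
            100.0 * (1.0 - self.deviance_ / self.null_deviance_)
            if self.null_deviance_ > 0 else 0.0)
        self._train_pairs = (ia, ib)
        return self

    def _irls(self, X: np.ndarray, d: np.ndarray) -> np.ndarray:
        n, m = X.shape
        beta = np.zeros(m)
        beta[0] = -np.log(max(1.0 - np.clip(d.mean(), 1e-4, 1 - 1e-4), _EPS))
        self.n_iter_ = 0
        for it in range(self.max_iter):
            eta = X @ beta
            mu = np.clip(1.0 - np.exp(-eta), 1e-6, 1.0 - 1e-6)
            dmu = 1.0 - mu  # d mu / d eta = exp(-eta)
            w = dmu * dmu / (mu * (1.0 - mu))
            z = eta + (d - mu) / np.maximum(dmu, _EPS)
            sw = np.sqrt(np.maximum(w, _EPS))
            coef, _ = nnls(X * sw[:, None], z * sw)
            delta = np.abs(coef - beta).max()
            beta = coef
            self.n_iter_ = it + 1
            if delta < self.tol:
                break
        else:
            warnings.warn(f"GDM IRLS did not converge in {self.max_iter} iterations")
        return beta

    # -- prediction --------------------------------------------------------

    def _predict_from_design(self, A: np.ndarray) -> np.ndarray:
        coef = np.concatenate([self.coefs_[p] for p in
                               (list(self.predictors_) + (["_geo"] if self.include_geo else []))])
        eta = self.intercept_ + A @ coef
        return 1.0 - np.exp(-eta)

    def predict(self, env_a, env_b) -> np.ndarray:
        """Predicted dissimilarity between environment vectors (row-wise)."""
        env_a = pd.DataFrame(env_a)
        env_b = pd.DataFrame(env_b)
        A = self._pair_design(env_a.reset_index(drop=True), env_b.reset_index(drop=True))
        return self._predict_from_design(A)

    @property
    def baseline_(self) -> float:
        """Predicted dissimilarity of identical environments, 1 - exp(-a0)."""
        return float(1.0 - np.exp(-self.intercept_))

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept_,
            "knots": {p: list(map(float, k)) for p, k in self.knots_.items()},
            "coefs": {p: list(map(float, c)) for p, c in self.coefs_.items()},
            "deviance_explained": float(self.deviance_explained_),
            "include_geo": self.include_geo,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _binomial_deviance(d, mu) -> float:
    d = np.asarray(d, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-9, 1 - 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1 - d) * np.log((1 - d) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def fit_gdm(D: pd.DataFrame, site_env: pd.DataFrame, include_geo: bool = False,
            coords: pd.DataFrame | None = None, seed: int | None = None) -> GDM:
    """Functional wrapper over :class:`GDM` (the fit is deterministic;
    ``seed`` is accepted for interface symmetry)."""
    return GDM(include_geo=include_geo).fit(site_env, D, coords=coords)


def gdm_significance(model: GDM, D: pd.DataFrame, site_env: pd.DataFrame,
                     n_perm: int = 100, seed: int | None = None) -> pd.Series:
    """Per-predictor permutation p-values.

    Each predictor's site values are permuted (others fixed), the model
    refitted, and p = (1 + #{permuted deviance explained >= observed}) /
    (n_perm + 1).
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives unstable permutation p-values")
    rng = np.random.default_rng(seed)
    obs = model.deviance_explained_
    out = {}
    for p in model.predictors_:
        count = 0
        for _ in range(n_perm):
            env_p = site_env.copy()
            env_p[p] = rng.permutation(env_p[p].to_numpy())
            try:
                m = GDM(include_geo=False).fit(env_p, D)
                if m.deviance_explained_ >= obs:
                    count += 1
            except ValueError:
                count += 1
        out[p] = (count + 1) / (n_perm + 1)
    return pd.Series(out)


def gdm_predict(model: GDM, env_a, env_b) -> np.ndarray:
    return model.predict(env_a, env_b)
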