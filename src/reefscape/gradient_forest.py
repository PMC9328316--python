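"""Gradient forest: turning per-SNP random-forest fits into monotone
cumulative-importance curves that define an environment -> biological-space
transform.

For every SNP a random-forest regression of site allele frequency on the
environmental predictors is fitted (bootstrapped rows, sqrt(p) candidate
predictors per split). SNPs with non-positive out-of-bag R^2 are dropped.
Each split's impurity reduction is accumulated in bins along the split
predictor's observed range; per-SNP bin profiles are rescaled to that
predictor's (conditional) permutation importance, standardised by the
binned density of observed predictor values, and averaged across SNPs
weighted by R^2. Cumulative sums give non-decreasing step functions whose
final values are the overall predictor importances; evaluating them maps
raw environments into the common biological space in which genetic offset
is a Euclidean distance.

Conditional permutation: when a predictor has a companion correlated
beyond ``r_threshold``, its permutation runs within quantile strata of the
most-correlated companion, discounting importance it merely shares.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor


class GradientForest(BaseEstimator):
    """R^2-weighted gradient forest over per-SNP random-forest regressions.

    Parameters
    ----------
    n_trees : trees per SNP forest (2000 reproduces the reference scale;
        smaller values are fine for the ~26-site regime).
    n_bins : bins per predictor axis for split-importance accumulation.
    r_threshold : |Pearson r| beyond which a predictor's permutation
        importance is computed conditionally on its companion.
    n_strata : quantile strata used for conditional permutation.
    density_floor : lower bound on binned predictor density.

    Attributes (after fit)
    ----------------------
    predictors_, r2_ (per-SNP OOB R^2, all SNPs), kept_snps_,
    importance_ (per-predictor overall importance),
    curves_ : dict predictor -> (bin_edges, cumulative_importance).
    """

    def __init__(self, n_trees: int = 2000, n_bins: int = 201,
                 r_threshold: float = 0.8, n_strata: int = 4,
                 density_floor: float = 1e-6, random_state: int | None = None):
        self.n_trees = n_trees
        self.n_bins = n_bins
        self.r_threshold = r_threshold
        self.n_strata = n_strata
        self.density_floor = density_floor
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, Y):
        """Fit per-SNP forests. X: sites x predictors (DataFrame or array);
        Y: sites x SNPs allele frequencies."""
        X = pd.DataFrame(X)
        Y = pd.DataFrame(Y)
        if len(X) < 5:
            raise ValueError("need at least 5 sites")
        if Y.shape[1] < 1:
            raise ValueError("need at least one SNP")
        self.predictors_ = [str(c) for c in X.columns]
        self.snps_ = [str(c) for c in Y.columns]
        Xv = X.to_numpy(dtype=float)
        n_sites, P = Xv.shape

        constant = np.ptp(Xv, axis=0) == 0
        self._ranges = [(Xv[:, j].min(), Xv[:, j].max()) for j in range(P)]
        edges = []
        for j in range(P):
            lo, hi = self._ranges[j]
            if hi == lo:
                hi = lo + 1.0
            edges.append(np.linspace(lo, hi, self.n_bins + 1))
        self._edges = edges

        # binned density of observed predictor values
        density = np.empty((P, self.n_bins))
        for j in range(P):
            cnt, _ = np.histogram(Xv[:, j], bins=edges[j])
            density[j] = np.maximum(cnt / cnt.sum(), self.density_floor)

        companions = self._companions(Xv, constant)
        master = np.random.default_rng(self.random_state)
        seed_pool = master.integers(0, 2 ** 31 - 1, size=Y.shape[1])

        r2 = np.full(Y.shape[1], np.nan)
        split_acc = []   # per kept SNP: (P, n_bins) raw impurity sums
        perm_imp = []    # per kept SNP: (P,) conditional permutation importance
        kept = []
        for s in range(Y.shape[1]):
            y = Y.iloc[:, s].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                r2[s] = -np.inf
                continue
            forest = RandomForestRegressor(
                n_estimators=self.n_trees, max_features="sqrt", bootstrap=True,
                oob_score=True, random_state=int(seed_pool[s]), n_jobs=1)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # tiny forests may miss OOB coverage
                forest.fit(Xv, y)
            r2[s] = forest.oob_score_
            if not np.isfinite(r2[s]) or r2[s] <= 0:
                continue
            split_acc.append(self._split_profile(forest, Xv))
            perm_imp.append(self._conditional_importance(
                forest, Xv, y, companions, np.random.default_rng(int(seed_pool[s]))))
            kept.append(s)

        self.r2_ = pd.Series(r2, index=self.snps_)
        self.kept_snps_ = [self.snps_[s] for s in kept]
        cum = {p: np.zeros(self.n_bins) for p in self.predictors_}
        importance = np.zeros(P)
        if kept:
            w = self.r2_.iloc[kept].to_numpy()
            w = w / w.sum()
            profile = np.zeros((P, self.n_bins))
            for wi, (raw, imp) in enumerate(zip(split_acc, perm_imp)):
                imp = np.where(constant, 0.0, np.maximum(imp, 0.0))
                snp_profile = np.zeros_like(raw)
                for j in range(P):
                    tot = raw[j].sum()
                    if tot <= 0 or imp[j] <= 0:
                        continue
                    prof = raw[j] / tot            # split-importance distribution
                    prof = prof / density[j]        # density standardisation
                    prof = prof / prof.sum() * imp[j]
                    snp_profile[j] = prof
                profile += w[wi] * snp_profile
                importance += w[wi] * imp
            for j, p in enumerate(self.predictors_):
                cum[p] = np.cumsum(profile[j])
        self.importance_ = pd.Series(importance, index=self.predictors_)
        self.curves_ = {p: (self._edges[j], cum[p])
                        for j, p in enumerate(self.predictors_)}
        return self

    def _companions(self, Xv, constant):
        P = Xv.shape[1]
        if P < 2:
            return [None] * P
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(Xv.T)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        out = []
        for j in range(P):
            if constant[j]:
                out.append(None)
                continue
            k = int(np.argmax(np.abs(corr[j])))
            out.append(k if abs(corr[j, k]) > self.r_threshold and not constant[k] else None)
        return out

    def _split_profile(self, forest, Xv):
        """Accumulate per-split impurity reduction into predictor bins."""
        P = Xv.shape[1]
        acc = np.zeros((P, self.n_bins))
        for est in forest.estimators_:
            t = est.tree_
            internal = t.children_left != -1
            if not internal.any():
                continue
            node = np.nonzero(internal)[0]
            feat = t.feature[node]
            thr = t.threshold[node]
            w = t.weighted_n_node_samples
            imp = t.impurity
            red = (w[node] * imp[node]
                   - w[t.children_left[node]] * imp[t.children_left[node]]
                   - w[t.children_right[node]] * imp[t.children_right[node]]) / w[0]
            for j in range(P):
                sel = feat == j
                if not sel.any():
                    continue
                lo, hi = self._edges[j][0], self._edges[j][-1]
                width = (hi - lo) / self.n_bins
                b = np.clip(((thr[sel] - lo) / width).astype(int), 0, self.n_bins - 1)
                np.add.at(acc[j], b, red[sel])
        return acc / len(forest.estimators_)

    def _conditional_importance(self, forest, Xv, y, companions, rng):
        """OOB permutation importance; within-stratum permutation for
        predictors with a highly correlated companion."""
        n, P = Xv.shape
        n_trees = len(forest.estimators_)
        imp = np.zeros(P)
        strata = []
        for j in range(P):
            c = companions[j]
            if c is None:
                strata.append(None)
            else:
                qs = np.quantile(Xv[:, c], np.linspace(0, 1, self.n_strata + 1)[1:-1])
                strata.append(np.searchsorted(qs, Xv[:, c]))
        # one permuted copy of each column, reused across trees
        Xperm = [None] * P
        for j in range(P):
            col = Xv[:, j].copy()
            if strata[j] is None:
                rng.shuffle(col)
            else:
                for s in np.unique(strata[j]):
                    idx = np.nonzero(strata[j] == s)[0]
                    col[idx] = col[idx[rng.permutation(idx.size)]]
            Xp = Xv.copy()
            Xp[:, j] = col
            Xperm[j] = Xp
        from sklearn.ensemble._forest import _generate_unsampled_indices

        try:  # sklearn >= 1.9 takes sample_weight
            _unsampled = lambda rs: _generate_unsampled_indices(rs, n, n, None)
            _unsampled(forest.estimators_[0].random_state)
        except TypeError:
            _unsampled = lambda rs: _generate_unsampled_indices(rs, n, n)

        # one stacked predict per tree: [original | perm_0 | ... | perm_{P-1}]
        stacked = np.ascontiguousarray(
            np.vstack([Xv] + Xperm), dtype=np.float32)
        for est in forest.estimators_:
            oob_idx = _unsampled(est.random_state)
            if oob_idx.size == 0:
                continue
            pred = est.tree_.predict(stacked).ravel()
            base = np.mean((y[oob_idx] - pred[oob_idx]) ** 2)
            for j in range(P):
                pj = pred[(j + 1) * n:][oob_idx]
                imp[j] += (np.mean((y[oob_idx] - pj) ** 2) - base) / n_trees
        return imp

    # -- transform / summaries -------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Map raw predictor values through the cumulative-importance curves.

        Accepts a DataFrame (columns matched by name) or an array in
        ``predictors_`` order. Output columns correspond to predictors
        with positive overall importance, in that order.
        """
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.active_predictors_ if p not in X.columns]
            if missing:
                raise ValueError(f"unknown/missing predictors: {missing}")
            cols = {p: X[p].to_numpy(dtype=float)
                    for p in self.predictors_ if p in X.columns}
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.predictors_):
                raise ValueError("array input must have one column per fitted predictor")
            cols = {p: X[:, j] for j, p in enumerate(self.predictors_)}
        out = []
        for p in self.active_predictors_:
            edges, cum = self.curves_[p]
            v = cols[p]
            width = edges[1] - edges[0]
            idx = np.floor((v - edges[0]) / width).astype(int)
            res = np.where(idx < 0, 0.0,
                           cum[np.clip(idx, 0, len(cum) - 1)])
            res = np.where(idx >= len(cum), cum[-1], res)
            out.append(res)
        return np.column_stack(out) if out else np.zeros((len(next(iter(cols.values()))), 0))

    @property
    def active_predictors_(self) -> list[str]:
        return [p for p in self.predictors_ if self.importance_[p] > 0]

    def goodness(self) -> dict:
        """Mean/SD of positive R^2 and the overall importance ranking."""
        pos = self.r2_[self.r2_ > 0]
        ranking = self.importance_.sort_values(ascending=False)
        return {
            "n_snps_kept": len(self.kept_snps_),
            "n_snps_total": len(self.snps_),
            "mean_r2": float(pos.mean()) if len(pos) else np.nan,
            "sd_r2": float(pos.std(ddof=1)) if len(pos) > 1 else np.nan,
            "importance_ranking": {k: float(v) for k, v in ranking.items()},
        }

    def to_json(self, path=None) -> str:
        payload = {
            "config": {"n_trees": self.n_trees, "n_bins": self.n_bins,
                       "r_threshold": self.r_threshold,
                       "random_state": self.random_state},
            "predictors": self.predictors_,
            "importance": {k: float(v) for k, v in self.importance_.items()},
            "r2": {k: (None if not np.isfinite(v) else float(v))
                   for k, v in self.r2_.items()},
            "curves": {p: {"edges": list(map(float, e)), "cumulative": list(map(float, c))}
                       for p, (e, c) in self.curves_.items()},
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_gradient_forest(site_freqs, site_env, n_trees: int = 2000,
                        n_bins: int = 201, r_threshold: float = 0.8,
                        seed: int | None = None) -> GradientForest:
    """Functional wrapper over :class:`GradientForest`."""
    model = GradientForest(n_trees=n_trees, n_bins=n_bins,
                           r_threshold=r_threshold, random_state=seed)
    return model.fit(site_env, site_freqs)


def gf_transform(model: GradientForest, env_points) -> np.ndarray:
    return model.transform(env_points)


def gf_goodness(model: GradientForest) -> dict:
    return model.goodness()
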