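"""Locus and sample quality control for GBS SNP panels.

Filters are applied in a fixed order — contaminant flag, locus call rate,
sample call rate, repeatability, coverage, minor allele frequency,
per-site exact Hardy–Weinberg test — followed by collapse of secondary
SNPs on shared sequencing fragments and removal of clonal genotypes
detected from technical-replicate distances. Thresholds are strict
(a locus must *exceed* the call-rate / repeatability / MAF / coverage
cut-offs to be kept). Re-applying the filter chain to its own output is a
fixed point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import MISSING, GenotypeMatrix, SampleHierarchy


@dataclass
class QCConfig:
    call_rate_min: float = 0.70
    sample_call_rate_min: float = 0.70
    repeatability_min: float = 0.70
    maf_min: float = 0.05
    coverage_min: float = 10.0
    hwe_alpha: float = 0.05
    hwe_min_samples: int = 10
    clone_metric: str = "hamming"  # or "euclidean"
    clone_threshold: float | None = None  # derived from replicates when None

    def validate(self):
        for name in ("call_rate_min", "sample_call_rate_min", "repeatability_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_min < 0:
            raise ValueError("coverage_min must be >= 0")
        if not 0.0 < self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in (0, 1]")


@dataclass
class QCReport:
    """Per-stage removal counts; reconciles input and output dimensions."""

    stages: list[dict] = field(default_factory=list)
    clones_removed: list[str] = field(default_factory=list)
    clone_threshold: float | None = None

    def record(self, stage: str, loci_removed: int = 0, samples_removed: int = 0,
               detail=None):
        self.stages.append({
            "stage": stage,
            "loci_removed": int(loci_removed),
            "samples_removed": int(samples_removed),
            "detail": detail,
        })

    def totals(self) -> tuple[int, int]:
        return (sum(s["loci_removed"] for s in self.stages),
                sum(s["samples_removed"] for s in self.stages))

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "stages": self.stages,
            "clones_removed": self.clones_removed,
            "clone_threshold": self.clone_threshold,
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Wigginton, Cutler & Abecasis 2005)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact two-sided HWE p-value for one biallelic locus.

    Probability, under Hardy-Weinberg proportions conditional on the
    allele counts, of a heterozygote count at most as probable as the one
    observed.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence
    h, rh, ch = mid, (rare - mid) // 2, (2 * n - rare - mid) // 2
    while h > 1:
        het_probs[h - 2] = het_probs[h] * h * (h - 1.0) / (4.0 * (rh + 1.0) * (ch + 1.0))
        h -= 2
        rh += 1
        ch += 1
    # upward recurrence
    h, rh, ch = mid, (rare - mid) // 2, (2 * n - rare - mid) // 2
    while h <= rare - 2:
        het_probs[h + 2] = het_probs[h] * 4.0 * rh * ch / ((h + 2.0) * (h + 1.0))
        h += 2
        rh -= 1
        ch -= 1
    het_probs /= het_probs.sum()
    return float(min(1.0, het_probs[het_probs <= het_probs[n_het] * (1 + 1e-12)].sum()))


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR alpha (NaNs never rejected)."""
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    m = int(ok.sum())
    reject = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return reject
    idx = np.nonzero(ok)[0]
    order = np.argsort(p[idx], kind="stable")
    ranked = p[idx][order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    below = np.nonzero(ranked <= thresh)[0]
    if below.size:
        k = below.max()
        reject[idx[order[: k + 1]]] = True
    return reject


def hwe_site_filter(g: GenotypeMatrix, h: SampleHierarchy, alpha: float = 0.05,
                    min_samples: int = 10) -> np.ndarray:
    """Mask of loci to REMOVE by the per-site exact HWE rule.

    Within each site with >= ``min_samples`` genotyped samples at a locus,
    the exact test is computed; p-values are BH-adjusted per site across
    loci, and a locus is removed when rejected in more than half of its
    testable sites.
    """
    sites = h.loc(g.samples)["site"].to_numpy()
    n_loci = g.n_loci
    testable = np.zeros(n_loci, dtype=int)
    rejected = np.zeros(n_loci, dtype=int)
    for site in pd.unique(sites):
        rows = np.nonzero(sites == site)[0]
        codes = g.codes[rows]
        obs = codes != MISSING
        n_obs = obs.sum(axis=0)
        use = n_obs >= min_samples
        if not use.any():
            continue
        pvals = np.full(n_loci, np.nan)
        for j in np.nonzero(use)[0]:
            col = codes[obs[:, j], j]
            n_het = int((col == 1).sum())
            n_hom_ref = int((col == 0).sum())
            n_hom_alt = int((col == 2).sum())
            pvals[j] = hwe_exact_pvalue(n_het, n_hom_ref, n_hom_alt)
        rej = _bh_reject(pvals, alpha)
        testable += use.astype(int)
        rejected += rej.astype(int)
    remove = np.zeros(n_loci, dtype=bool)
    has_tests = testable > 0
    remove[has_tests] = rejected[has_tests] > testable[has_tests] / 2.0
    return remove


# ---------------------------------------------------------------------------
# filter chain


def apply_locus_filters(g: GenotypeMatrix, h: SampleHierarchy,
                        config: QCConfig | None = None,
                        collapse_secondary: bool = True,
                        ) -> tuple[GenotypeMatrix, SampleHierarchy, QCReport]:
    """Run the fixed-order QC filter chain and report per-stage removals."""
    config = config or QCConfig()
    config.validate()
    if g.n_loci == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport()
    cur = g

    # 1. contaminant flag
    keep = ~cur.loci["contaminant_flag"].to_numpy(dtype=bool)
    report.record("contaminant_flag", loci_removed=int((~keep).sum()))
    cur = cur.subset(locus_idx=np.nonzero(keep)[0])

    # 2. locus call rate (metadata value, strict >)
    keep = cur.loci["call_rate"].to_numpy(dtype=float) > config.call_rate_min
    report.record("locus_call_rate", loci_removed=int((~keep).sum()))
    cur = cur.subset(locus_idx=np.nonzero(keep)[0])

    # 3. sample call rate (observed, strict >)
    scr = cur.observed_call_rates(axis="sample")
    keep_s = scr > config.sample_call_rate_min
    report.record("sample_call_rate", samples_removed=int((~keep_s).sum()))
    cur = cur.subset(sample_idx=np.nonzero(keep_s)[0])

    # 4. repeatability
    keep = cur.loci["repeatability"].to_numpy(dtype=float) > config.repeatability_min
    report.record("repeatability", loci_removed=int((~keep).sum()))
    cur = cur.subset(locus_idx=np.nonzero(keep)[0])

    # 5. coverage
    keep = cur.loci["coverage"].to_numpy(dtype=float) > config.coverage_min
    report.record("coverage", loci_removed=int((~keep).sum()))
    cur = cur.subset(locus_idx=np.nonzero(keep)[0])

    # 6. MAF on pooled genotypes
    maf = cur.pooled_maf()
    keep = np.nan_to_num(maf, nan=0.0) > config.maf_min
    report.record("maf", loci_removed=int((~keep).sum()))
    cur = cur.subset(locus_idx=np.nonzero(keep)[0])

    # 7. HWE per site
    h_cur = h.subset(cur.samples)
    remove = hwe_site_filter(cur, h_cur, config.hwe_alpha, config.hwe_min_samples)
    report.record("hwe", loci_removed=int(remove.sum()))
    cur = cur.subset(locus_idx=np.nonzero(~remove)[0])

    # 8. secondary-SNP collapse
    if collapse_secondary:
        before = cur.n_loci
        cur = collapse_secondary_snps(cur)
        report.record("secondary_collapse", loci_removed=before - cur.n_loci)

    return cur, h.subset(cur.samples), report


def collapse_secondary_snps(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep exactly one SNP per sequencing fragment.

    The locus with the highest call rate wins; ties break to the lowest
    position in the fragment, then to the lexicographically smallest
    locus ID.
    """
    loci = g.loci
    order = pd.DataFrame({
        "fragment_id": loci["fragment_id"].to_numpy(),
        "call_rate": loci["call_rate"].to_numpy(dtype=float),
        "position": loci["position"].to_numpy(),
        "locus_id": loci.index.to_numpy(),
        "idx": np.arange(len(loci)),
    })
    order = order.sort_values(
        ["fragment_id", "call_rate", "position", "locus_id"],
        ascending=[True, False, True, True], kind="stable")
    winners = order.groupby("fragment_id", sort=False).head(1)["idx"].to_numpy()
    winners.sort()
    return g.subset(locus_idx=winners)


# ---------------------------------------------------------------------------
# clone detection


def pairwise_genotype_distance(g: GenotypeMatrix, metric: str = "hamming") -> np.ndarray:
    """All-pairs genotype distance over pairwise-complete loci.

    ``hamming``: proportion of loci, non-missing in both samples, with
    unequal codes. ``euclidean``: root mean squared code difference over
    the same loci (kept on a comparable per-locus scale).
    Pairs with no comparable locus get NaN.
    """
    obs = g.observed.astype(np.float64)
    comparable = obs @ obs.T
    if metric == "hamming":
        matches = np.zeros_like(comparable)
        for c in (0, 1, 2):
            m = ((g.codes == c) & g.observed).astype(np.float64)
            matches += m @ m.T
        mism = comparable - matches
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comparable > 0, mism / comparable, np.nan)
    elif metric == "euclidean":
        x = np.where(g.observed, g.codes, 0).astype(np.float64)
        sq = x ** 2
        cross = x @ x.T
        ss = sq @ obs.T + obs @ sq.T - 2 * cross
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comparable > 0, np.sqrt(np.maximum(ss, 0) / comparable), np.nan)
    else:
        raise ValueError(f"unknown clone metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return d


def detect_clones(g: GenotypeMatrix, h: SampleHierarchy,
                  metric: str = "hamming",
                  threshold: float | None = None,
                  ) -> tuple[list[list[str]], float]:
    """Find clonal multilocus genotypes via the technical-replicate threshold.

    The clone distance threshold is the maximum pairwise distance observed
    within any technical-replicate group (unless supplied); samples joined
    by distance <= threshold form clone sets by transitive closure. Returns
    the clone sets (size >= 2) and the threshold used.
    """
    d = pairwise_genotype_distance(g, metric=metric)
    if threshold is None:
        groups = h.subset([s for s in g.samples if s in h.table.index]).replicate_groups()
        dists = []
        pos = {s: i for i, s in enumerate(g.samples)}
        for members in groups.values():
            idx = [pos[m] for m in members if m in pos]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    v = d[idx[a], idx[b]]
                    if np.isfinite(v):
                        dists.append(v)
        if not dists:
            raise ValueError(
                "no technical replicate pairs found; supply clone_threshold in the QC config")
        threshold = float(max(dists))
    adj = np.nan_to_num(d, nan=np.inf) <= threshold
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sets = []
    for c in range(n_comp):
        members = [g.samples[i] for i in np.nonzero(labels == c)[0]]
        if len(members) >= 2:
            sets.append(members)
    return sets, float(threshold)


def remove_clones(g: GenotypeMatrix, h: SampleHierarchy, clone_sets,
                  ) -> tuple[GenotypeMatrix, SampleHierarchy, list[str]]:
    """Keep the highest-call-rate member of each clone set; drop the rest."""
    call = g.observed_call_rates(axis="sample")
    pos = {s: i for i, s in enumerate(g.samples)}
    drop = set()
    for members in clone_sets:
        ranked = sorted(members, key=lambda s: (-call[pos[s]], s))
        drop.update(ranked[1:])
    keep_idx = [i for i, s in enumerate(g.samples) if s not in drop]
    g2 = g.subset(sample_idx=keep_idx)
    return g2, h.subset(g2.samples), sorted(drop)
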