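"""Genotype containers and file I/O for biallelic SNP data.

A :class:`GenotypeMatrix` holds a sample x locus matrix of alternate-allele
counts (0/1/2, ``MISSING`` = -1) together with per-locus quality metadata
as produced by DArT-style genotyping-by-sequencing (call rate,
repeatability, coverage, fragment membership, contaminant flag).

Two dialects are read: plain VCF (biallelic records with GT) via pysam,
and a DArT-like transposed CSV where the first seven rows carry the locus
metadata fields and each subsequent row is one sample's codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_LOCUS_META_FIELDS = ("locus_id", "fragment_id", "position", "call_rate",
                      "repeatability", "coverage", "contaminant_flag")


@dataclass
class GenotypeMatrix:
    """Sample x locus biallelic genotype codes with per-locus QC metadata.

    ``loci`` is a DataFrame indexed by locus ID with columns fragment_id,
    position, call_rate, repeatability, coverage, contaminant_flag.
    """

    samples: list[str]
    loci: pd.DataFrame
    codes: np.ndarray  # int16, values {0,1,2,MISSING}

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} != ({len(self.samples)}, {len(self.loci)})")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample IDs")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def observed(self) -> np.ndarray:
        return self.codes != MISSING

    def observed_call_rates(self, axis: str = "locus") -> np.ndarray:
        """Fraction of non-missing codes per locus column or sample row."""
        obs = self.observed
        return obs.mean(axis=0) if axis == "locus" else obs.mean(axis=1)

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        l = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in s],
            self.loci.iloc[l].copy(),
            self.codes[np.ix_(s, l)].copy(),
        )

    def pooled_maf(self) -> np.ndarray:
        """Minor allele frequency per locus over pooled non-missing genotypes."""
        obs = self.observed
        alt = np.where(obs, self.codes, 0).sum(axis=0)
        n2 = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(n2 > 0, alt / n2, np.nan)
        return np.minimum(p, 1.0 - p)


@dataclass
class SampleHierarchy:
    """sample -> site -> reef -> system nesting with WGS84 coordinates.

    ``table`` is indexed by sample ID with columns site, reef, system, lon,
    lat, replicate_group (NaN when the sample has no technical replicate).
    """

    table: pd.DataFrame

    REQUIRED = ("site", "reef", "system", "lon", "lat")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"hierarchy missing column {col!r}")
        if "replicate_group" not in self.table.columns:
            self.table = self.table.assign(replicate_group=np.nan)
        if self.table.index.duplicated().any():
            raise ValueError("duplicated sample IDs in hierarchy")
        lat = self.table["lat"].to_numpy(dtype=float)
        lon = self.table["lon"].to_numpy(dtype=float)
        if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
            raise ValueError("non-finite coordinates")
        if (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        # site -> reef -> system must be functions
        for child, parent in (("site", "reef"), ("reef", "system")):
            mapping = self.table.groupby(child)[parent].nunique()
            if (mapping > 1).any():
                bad = mapping[mapping > 1].index.tolist()
                raise ValueError(f"{child}(s) {bad} belong to more than one {parent}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def loc(self, samples) -> pd.DataFrame:
        return self.table.loc[samples]

    def groups(self, level: str) -> pd.Series:
        if level not in ("site", "reef", "system"):
            raise ValueError(f"unknown hierarchy level {level!r}")
        return self.table[level]

    def site_table(self) -> pd.DataFrame:
        """One row per site: reef, system and mean sample coordinates."""
        return self.table.groupby("site").agg(
            reef=("reef", "first"), system=("system", "first"),
            lon=("lon", "mean"), lat=("lat", "mean"))

    def replicate_groups(self) -> dict[str, list[str]]:
        out = {}
        col = self.table["replicate_group"]
        for g, sub in self.table[col.notna()].groupby(col):
            if len(sub) >= 2:
                out[str(g)] = list(sub.index)
        return out

    def subset(self, samples) -> "SampleHierarchy":
        return SampleHierarchy(self.table.loc[samples].copy())


def read_hierarchy(path) -> SampleHierarchy:
    df = pd.read_csv(path, dtype={"sample": str, "site": str, "reef": str, "system": str})
    if "sample" not in df.columns:
        raise ValueError("hierarchy CSV must have a 'sample' column")
    return SampleHierarchy(df.set_index("sample"))


def write_hierarchy(h: SampleHierarchy, path):
    h.table.rename_axis("sample").to_csv(path)


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, dialect: str = "dart_csv") -> GenotypeMatrix:
    """Read a genotype file in the ``vcf`` or ``dart_csv`` dialect."""
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "dart_csv":
        return _read_dart_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path) -> GenotypeMatrix:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicated sample IDs in VCF header")
    cols = []
    meta = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            locus = rec.id or f"{rec.chrom}:{rec.pos}"
            raise ValueError(f"multi-allelic record at locus {locus}")
        col = np.full(len(samples), MISSING, dtype=np.int16)
        depths = []
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is not None and None not in gt:
                col[i] = int(sum(1 for a in gt if a != 0))
            dp = rec.samples[s].get("DP")
            if dp is not None:
                depths.append(dp)
        call_rate = float((col != MISSING).mean())
        if depths:
            coverage = float(np.mean(depths))
        else:
            try:
                coverage = float(rec.info.get("DP", 0) or 0)
            except (KeyError, ValueError):
                coverage = 0.0
        meta.append({
            "locus_id": rec.id or f"{rec.chrom}:{rec.pos}",
            "fragment_id": rec.chrom,
            "position": rec.pos,
            "call_rate": call_rate,
            "repeatability": 1.0,
            "coverage": coverage,
            "contaminant_flag": "CONTAM" in (rec.info.keys() or ()),
        })
        cols.append(col)
    if not cols:
        raise ValueError("no records in VCF")
    loci = pd.DataFrame(meta).set_index("locus_id")
    return GenotypeMatrix(samples, loci, np.column_stack(cols))


def _read_dart_csv(path) -> GenotypeMatrix:
    try:
        raw = pd.read_csv(path, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError("no records in dart_csv file") from None
    if raw.empty:
        raise ValueError("no records in dart_csv file")
    labels = raw.iloc[:, 0].tolist()
    meta_rows = {}
    row = 0
    while row < len(raw) and labels[row] in _LOCUS_META_FIELDS:
        meta_rows[labels[row]] = raw.iloc[row, 1:].tolist()
        row += 1
    missing = [f for f in _LOCUS_META_FIELDS if f not in meta_rows]
    if missing:
        raise ValueError(f"dart_csv missing metadata rows: {missing}")
    loci = pd.DataFrame({
        "locus_id": meta_rows["locus_id"],
        "fragment_id": meta_rows["fragment_id"],
        "position": [int(x) for x in meta_rows["position"]],
        "call_rate": [float(x) for x in meta_rows["call_rate"]],
        "repeatability": [float(x) for x in meta_rows["repeatability"]],
        "coverage": [float(x) for x in meta_rows["coverage"]],
        "contaminant_flag": [_parse_bool(x) for x in meta_rows["contaminant_flag"]],
    }).set_index("locus_id")
    body = raw.iloc[row:]
    if body.empty:
        raise ValueError("no sample rows in dart_csv file")
    samples = body.iloc[:, 0].tolist()
    codes = np.full((len(samples), len(loci)), MISSING, dtype=np.int16)
    for j in range(len(loci)):
        col = body.iloc[:, j + 1]
        for i, x in enumerate(col):
            if isinstance(x, str) and x.strip().upper() not in ("NA", ""):
                codes[i, j] = int(x)
    return GenotypeMatrix(samples, loci, codes)


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in ("1", "true", "t", "yes")


# ---------------------------------------------------------------------------
# writers


def write_dart_csv(g: GenotypeMatrix, path):
    path = Path(path)
    with open(path, "w") as fh:
        loci = g.loci
        fh.write("locus_id," + ",".join(map(str, loci.index)) + "\n")
        fh.write("fragment_id," + ",".join(map(str, loci["fragment_id"])) + "\n")
        fh.write("position," + ",".join(str(int(x)) for x in loci["position"]) + "\n")
        fh.write("call_rate," + ",".join(f"{x:.6g}" for x in loci["call_rate"]) + "\n")
        fh.write("repeatability," + ",".join(f"{x:.6g}" for x in loci["repeatability"]) + "\n")
        fh.write("coverage," + ",".join(f"{x:.6g}" for x in loci["coverage"]) + "\n")
        fh.write("contaminant_flag," + ",".join(str(int(bool(x))) for x in loci["contaminant_flag"]) + "\n")
        for i, s in enumerate(g.samples):
            row = ["NA" if c == MISSING else str(int(c)) for c in g.codes[i]]
            fh.write(str(s) + "," + ",".join(row) + "\n")


def write_vcf(g: GenotypeMatrix, path):
    """Write a minimal uncompressed VCF 4.2 with GT and per-sample DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        frags = pd.unique(g.loci["fragment_id"])
        for f in frags:
            fh.write(f"##contig=<ID={f}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, (locus, row) in enumerate(g.loci.iterrows()):
            gts = "\t".join(gt_map[int(c)] for c in g.codes[:, j])
            fh.write(f"{row['fragment_id']}\t{int(row['position'])}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
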