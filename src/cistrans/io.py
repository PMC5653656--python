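"""File formats and in-memory containers shared by all pipeline stages.

The central container is :class:`SiteTable`: one row per SNV-anchored site
with replicate count columns for each library.  The TSV interchange format is

    site_id  chrom  pos  assay  F0_A_rep1 .. F0_B_rep1 .. F1_A_rep1 .. F1_B_rep1 ..

with ``pos`` 1-based for human readability.  Internally all coordinates are
0-based (half-open for intervals, point coordinates for SNVs); the +/-1 shift
happens only at the read/write boundary.  Genomic intervals use BED and paired
interactions BEDPE, both 0-based half-open as native.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cistrans")

__all__ = [
    "SiteTable",
    "GenomicFeatureSet",
    "read_site_table",
    "write_site_table",
    "read_intervals",
    "write_intervals",
    "ratio_difference_diagnostic",
]

_META_COLS = ["site_id", "chrom", "pos", "assay"]
_GROUPS = ("F0_A", "F0_B", "F1_A", "F1_B")


def _group_cols(columns, group):
    pat = re.compile(rf"^{group}_rep(\d+)$")
    hits = [(int(pat.match(c).group(1)), c) for c in columns if pat.match(c)]
    return [c for _, c in sorted(hits)]


@dataclass
class SiteTable:
    """Ordered collection of allele-specific count sites.

    ``data`` holds one row per site; ``pos`` is a 0-based SNV coordinate.
    Count columns may be real-valued after normalization; raw input must be
    non-negative integers.
    """

    data: pd.DataFrame
    size_factors: pd.Series | None = None  # per library column, set by preprocess

    def __post_init__(self):
        cols = list(self.data.columns)
        missing = [c for c in _META_COLS if c not in cols]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        self.group_cols = {g: _group_cols(cols, g) for g in _GROUPS}
        for g in _GROUPS:
            if not self.group_cols[g]:
                raise ValueError(f"site table has no {g}_rep* columns")
        if self.data["site_id"].duplicated().any():
            dups = self.data.loc[self.data["site_id"].duplicated(), "site_id"]
            raise ValueError(f"duplicate site_id: {sorted(set(dups))[:5]}")
        counts = self.data[self.count_cols]
        if (counts.to_numpy() < 0).any():
            bad = np.where((counts.to_numpy() < 0).any(axis=1))[0][0]
            raise ValueError(f"negative count at row {bad} "
                             f"(site_id={self.data.iloc[bad]['site_id']})")

    @property
    def count_cols(self) -> list[str]:
        return [c for g in _GROUPS for c in self.group_cols[g]]

    @property
    def site_ids(self) -> np.ndarray:
        return self.data["site_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def matrix(self, group: str) -> np.ndarray:
        """(n_sites, n_replicates) count matrix for one library group."""
        return self.data[self.group_cols[group]].to_numpy(dtype=float)

    def f1_totals(self) -> np.ndarray:
        return self.matrix("F1_A") + self.matrix("F1_B")

    def iter_sites(self):
        """Yield per-site mappings consumed by the model-fitting stages."""
        mats = {g: self.matrix(g) for g in _GROUPS}
        ids = self.site_ids
        for i in range(len(self.data)):
            yield {
                "site_id": ids[i],
                "f0_a": mats["F0_A"][i],
                "f0_b": mats["F0_B"][i],
                "f1_a": mats["F1_A"][i],
                "f1_b": mats["F1_B"][i],
            }

    def subset(self, mask_or_ids) -> "SiteTable":
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and \
                np.asarray(mask_or_ids).dtype == bool:
            sub = self.data.loc[np.asarray(mask_or_ids)]
        else:
            sub = self.data[self.data["site_id"].isin(list(mask_or_ids))]
        return SiteTable(sub.reset_index(drop=True), size_factors=self.size_factors)

    def copy(self) -> "SiteTable":
        return SiteTable(self.data.copy(), size_factors=None if
                         self.size_factors is None else self.size_factors.copy())


@dataclass
class GenomicFeatureSet:
    """Genomic context consumed by the coordination and integration stages.

    genes : gene_id, chrom, tss (0-based), strand, expression columns and an
        (optional) expression regulatory class.
    promoters / enhancers : BED-style interval frames (chrom, start, end).
    interactions : BEDPE-style frame (chrom1, start1, end1, chrom2, start2, end2).
    """

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoters: pd.DataFrame = field(default_factory=pd.DataFrame)
    enhancers: pd.DataFrame = field(default_factory=pd.DataFrame)
    interactions: pd.DataFrame = field(default_factory=pd.DataFrame)
    chrom_sizes: dict = field(default_factory=dict)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)  # site_id, chrom, pos, class


def read_site_table(path) -> SiteTable:
    """Read the TSV site table, converting ``pos`` to the internal 0-based
    convention and validating counts."""
    df = pd.read_csv(path, sep="\t")
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise ValueError(f"{path}: pos < 1 at row {bad + 2}")  # header + 1-based
    count_cols = [c for g in _GROUPS for c in _group_cols(df.columns, g)]
    neg = df[count_cols].lt(0)
    if neg.to_numpy().any():
        row = int(np.where(neg.to_numpy().any(axis=1))[0][0])
        raise ValueError(f"{path}: negative count at line {row + 2}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    return SiteTable(df)


def write_site_table(table: SiteTable, path) -> None:
    out = table.data.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
               "name", "score", "strand1", "strand2"]


def read_intervals(path, kind: str = "intervals") -> pd.DataFrame:
    """Read BED (``kind="intervals"``) or BEDPE (``kind="interactions"``).

    Coordinates are 0-based half-open, as in the file.  Returns a sorted frame;
    optional columns (name/score/strand) are kept when present.
    """
    if kind not in ("intervals", "interactions"):
        raise ValueError(f"unknown kind {kind!r}")
    names = _BED_COLS if kind == "intervals" else _BEDPE_COLS
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if kind == "intervals":
        if (df["end"] <= df["start"]).any():
            bad = df.index[df["end"] <= df["start"]][0]
            raise ValueError(f"{path}: end <= start at line {bad + 1}")
        return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    for a, b in (("start1", "end1"), ("start2", "end2")):
        if (df[b] <= df[a]).any():
            bad = df.index[df[b] <= df[a]][0]
            raise ValueError(f"{path}: {b} <= {a} at line {bad + 1}")
    return df.sort_values(["chrom1", "start1"]).reset_index(drop=True)


def write_intervals(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def ratio_difference_diagnostic(table: SiteTable, calls: pd.DataFrame | None = None
                                ) -> pd.DataFrame:
    """Per-site difference between the F0 strain ratio and the F1 allelic ratio.

    Both ratios are proportions ``A / (A + B)`` of replicate-mean counts; the
    difference is near zero for conserved and cis sites (where the F1 alleles
    recapitulate the parental ratio) and appreciable for trans / cis-trans
    sites on well-powered data.  Sites with a zero total in F0 or F1 are
    excluded (logged).
    """
    f0a = table.matrix("F0_A").mean(axis=1)
    f0b = table.matrix("F0_B").mean(axis=1)
    f1a = table.matrix("F1_A").mean(axis=1)
    f1b = table.matrix("F1_B").mean(axis=1)
    ok = (f0a + f0b > 0) & (f1a + f1b > 0)
    if (~ok).sum():
        logger.info("ratio_difference_diagnostic: excluded %d/%d sites with a "
                    "zero F0 or F1 total", int((~ok).sum()), len(table))
    with np.errstate(invalid="ignore"):
        f0_ratio = f0a / (f0a + f0b)
        f1_ratio = f1a / (f1a + f1b)
    out = pd.DataFrame({
        "site_id": table.site_ids,
        "f0_ratio": f0_ratio,
        "f1_ratio": f1_ratio,
        "ratio_difference": f0_ratio - f1_ratio,
    })[ok]
    if calls is not None:
        out = out.merge(calls[["site_id", "class"]], on="site_id", how="left")
    return out.reset_index(drop=True)
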