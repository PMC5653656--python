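"""Depth normalization, site filtering, SNV thinning and dispersion estimation.

Library depth is normalized with the median-of-ratios estimator: for each
library, the size factor is the median over sites of the count divided by the
site's geometric mean across libraries, computed only on sites with no zero
count anywhere.  Size factors are estimated jointly across all F0 and F1
libraries of an assay, using the F1 per-replicate allele totals (A + B) as the
F1 library signal, and each F1 factor is applied identically to both alleles
so allelic proportions are untouched.

Filters follow the allele-specific read-count rules: an F0 strain must reach a
minimum summed depth, and enough F1 replicates must individually reach a
minimum allele-resolved depth.  Clustered SNVs within a minimum spacing are
thinned to a single representative, and histone-mark SNVs within a shared peak
are summed into one aggregate site.

Site-level overdispersion of the parental negative-binomial counts is
estimated by method of moments, ``d = (var - mean) / mean**2``, with a fitted
mean-dispersion trend ``d(m) = a0 + a1 / m`` and a floor; the NB size used by
the likelihood stages is ``r = 1 / d``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SiteTable

logger = logging.getLogger("cistrans")

__all__ = [
    "SizeFactors",
    "DispersionModel",
    "median_ratio_size_factors",
    "normalize_counts",
    "filter_sites",
    "thin_sites_by_distance",
    "aggregate_histone_snvs",
    "estimate_dispersion",
]


@dataclass
class SizeFactors:
    """Per-library multiplicative depth factors."""

    factors: pd.Series          # index = library label
    n_sites_used: int

    def __getitem__(self, lib):
        return float(self.factors[lib])


def median_ratio_size_factors(count_matrix: pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors from a sites x libraries count frame.

    Only sites with strictly positive counts in every library contribute (the
    geometric mean is undefined otherwise).
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least two libraries")
    counts = count_matrix.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no site has positive counts in every library; cannot compute "
            "median-of-ratios size factors (pseudo-reference fallback is "
            "deliberately not provided)")
    sub = counts[all_pos]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    factors = pd.Series(np.median(ratios, axis=0), index=count_matrix.columns)
    logger.info("size factors: %d/%d all-positive sites used",
                int(all_pos.sum()), len(count_matrix))
    return SizeFactors(factors=factors, n_sites_used=int(all_pos.sum()))


def _library_signal(table: SiteTable) -> pd.DataFrame:
    """F0 replicate columns plus F1 per-replicate totals, one column each."""
    sig = {}
    for g in ("F0_A", "F0_B"):
        for c in table.group_cols[g]:
            sig[c] = table.data[c].to_numpy(dtype=float)
    a_cols = table.group_cols["F1_A"]
    b_cols = table.group_cols["F1_B"]
    for ca, cb in zip(a_cols, b_cols):
        lib = ca.replace("F1_A", "F1")
        sig[lib] = (table.data[ca].to_numpy(dtype=float)
                    + table.data[cb].to_numpy(dtype=float))
    return pd.DataFrame(sig)


def normalize_counts(table: SiteTable, size_factors: SizeFactors | None = None
                     ) -> SiteTable:
    """Divide each library's counts by its size factor.

    When ``size_factors`` is None they are estimated from the table itself.
    F1 factors (estimated on allele totals) divide both allele columns of the
    corresponding replicate.
    """
    if size_factors is None:
        size_factors = median_ratio_size_factors(_library_signal(table))
    out = table.data.copy()
    for g in ("F0_A", "F0_B"):
        for c in table.group_cols[g]:
            out[c] = out[c] / size_factors[c]
    for ca, cb in zip(table.group_cols["F1_A"], table.group_cols["F1_B"]):
        f = size_factors[ca.replace("F1_A", "F1")]
        out[ca] = out[ca] / f
        out[cb] = out[cb] / f
    return SiteTable(out, size_factors=size_factors.factors)


def filter_sites(table: SiteTable, min_f0: int = 10, min_f1_reads: int = 10,
                 min_f1_reps: int = 10, f0_per_replicate: bool = False
                 ) -> SiteTable:
    """Apply the minimum-depth site filters to raw counts.

    A site is kept when (a) the summed F0 depth reaches ``min_f0`` in at least
    one strain (or every replicate reaches it, with ``f0_per_replicate``), and
    (b) at least ``min_f1_reps`` F1 replicates have an allele-resolved total of
    at least ``min_f1_reads`` reads.
    """
    f0a, f0b = table.matrix("F0_A"), table.matrix("F0_B")
    if f0_per_replicate:
        ok_f0 = (f0a >= min_f0).all(axis=1) | (f0b >= min_f0).all(axis=1)
    else:
        ok_f0 = (f0a.sum(axis=1) >= min_f0) | (f0b.sum(axis=1) >= min_f0)
    ok_f1 = (table.f1_totals() >= min_f1_reads).sum(axis=1) >= min_f1_reps
    keep = ok_f0 & ok_f1
    logger.info("filter_sites: %d -> %d (min_f0=%d, >=%d reads in >=%d F1 reps)",
                len(table), int(keep.sum()), min_f0, min_f1_reads, min_f1_reps)
    return table.subset(keep)


def thin_sites_by_distance(table: SiteTable, min_spacing: int = 250) -> SiteTable:
    """Retain at most one site per ``min_spacing`` window.

    Sites are considered in order of decreasing total (F0 + F1) coverage, ties
    broken toward the smaller coordinate; a site is kept when no already-kept
    site on the same chromosome lies closer than ``min_spacing``.  The kept set
    is therefore pairwise separated and the operation is idempotent.
    """
    df = table.data
    coverage = df[table.count_cols].sum(axis=1).to_numpy()
    order = np.lexsort((df["pos"].to_numpy(), -coverage))
    kept_by_chrom: dict[str, list[int]] = {}
    keep = np.zeros(len(df), dtype=bool)
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for i in order:
        kept = kept_by_chrom.setdefault(chroms[i], [])
        if all(abs(pos[i] - p) >= min_spacing for p in kept):
            keep[i] = True
            kept.append(pos[i])
    logger.info("thin_sites_by_distance: %d -> %d (spacing %d bp)",
                len(df), int(keep.sum()), min_spacing)
    return table.subset(keep)


def aggregate_histone_snvs(table: SiteTable, peaks: pd.DataFrame) -> SiteTable:
    """Sum counts of all SNVs that fall in the same peak interval.

    ``peaks`` is a BED-style frame (chrom, start, end, optional name), 0-based
    half-open.  SNVs overlapping no peak are dropped (logged); SNVs in more
    than one overlapping peak go to the peak with the nearest midpoint.
    The aggregate site sits at the peak midpoint and records its members.
    """
    df = table.data
    assignments = np.full(len(df), -1)
    for ci, chrom_sites in df.groupby("chrom").groups.items():
        p = peaks[peaks["chrom"] == ci]
        if p.empty:
            continue
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        mids = (starts + ends) / 2.0
        idx = p.index.to_numpy()
        for row in chrom_sites:
            x = df.at[row, "pos"]
            hit = np.where((starts <= x) & (x < ends))[0]
            if hit.size == 0:
                continue
            if hit.size > 1:
                hit = hit[np.argsort(np.abs(mids[hit] - x), kind="stable")][:1]
                logger.info("aggregate_histone_snvs: site %s in overlapping "
                            "peaks, assigned to nearest midpoint",
                            df.at[row, "site_id"])
            assignments[df.index.get_loc(row)] = idx[hit[0]]

    dropped = int((assignments < 0).sum())
    if dropped:
        logger.info("aggregate_histone_snvs: dropped %d/%d SNVs outside all "
                    "peaks", dropped, len(df))
    rows = []
    for peak_idx in sorted(set(assignments[assignments >= 0])):
        members = df[assignments == peak_idx]
        peak = peaks.loc[peak_idx]
        name = peak.get("name") if "name" in peaks.columns else None
        if not isinstance(name, str):
            name = f"peak_{peak['chrom']}_{peak['start']}_{peak['end']}"
        row = {"site_id": name, "chrom": peak["chrom"],
               "pos": int((peak["start"] + peak["end"]) // 2),
               "assay": members["assay"].iloc[0],
               "members": ",".join(members["site_id"].astype(str))}
        for c in table.count_cols:
            row[c] = members[c].sum()
        rows.append(row)
    out = pd.DataFrame(rows, columns=list(df.columns) + ["members"] if rows
                       else list(df.columns) + ["members"])
    return SiteTable(out)


@dataclass
class DispersionModel:
    """Per-site dispersion with a fitted mean-dispersion trend."""

    table: pd.DataFrame         # site_id, mean, raw_dispersion, dispersion, r
    a0: float
    a1: float
    floor: float
    r_by_site: dict = field(default_factory=dict)

    def trend(self, mean):
        mean = np.asarray(mean, dtype=float)
        return np.maximum(self.a0 + self.a1 / np.maximum(mean, 1e-12), self.floor)


def estimate_dispersion(table: SiteTable, floor: float = 1e-4) -> DispersionModel:
    """Method-of-moments dispersion with an ``a0 + a1/m`` trend and a floor.

    For each site the raw estimate pools the two parental strains (each
    contributes ``(var - mean) / mean**2`` weighted by its residual degrees of
    freedom).  The trend is least squares on sites with a positive raw
    estimate; the final per-site dispersion is ``max(trend(mean), floor)`` and
    ``r = 1 / dispersion``.
    """
    f0a, f0b = table.matrix("F0_A"), table.matrix("F0_B")
    if f0a.shape[1] < 3 or f0b.shape[1] < 3:
        raise ValueError("need >= 3 F0 replicates per strain")

    def strain_d(x):
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        return d

    wa, wb = f0a.shape[1] - 1, f0b.shape[1] - 1
    raw = (wa * strain_d(f0a) + wb * strain_d(f0b)) / (wa + wb)
    mean = np.concatenate([f0a, f0b], axis=1).mean(axis=1)

    use = raw > 0
    if use.sum() >= 2:
        X = np.column_stack([np.ones(int(use.sum())), 1.0 / np.maximum(mean[use], 1e-12)])
        coef, *_ = np.linalg.lstsq(X, raw[use], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        logger.warning("estimate_dispersion: no site with positive raw "
                       "dispersion; all dispersions set to the floor %g", floor)
        a0, a1 = floor, 0.0

    disp = np.maximum(a0 + a1 / np.maximum(mean, 1e-12), floor)
    r = 1.0 / disp
    frame = pd.DataFrame({
        "site_id": table.site_ids, "mean": mean, "raw_dispersion": raw,
        "dispersion": disp, "r": r,
    })
    return DispersionModel(table=frame, a0=a0, a1=a1, floor=floor,
                           r_by_site=dict(zip(frame["site_id"], frame["r"])))
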