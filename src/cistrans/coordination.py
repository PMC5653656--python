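"""Distance decay of cis-effect coordination between neighboring sites.

Sites whose allelic imbalance is driven by the same cis-acting variant should
show correlated allelic proportions, and the correlation should fall off with
genomic distance.  Around each cis-class "anchor" site, partner sites are
binned by absolute distance (1 kb bins starting 400 bp from the anchor SNV,
both directions pooled) and Spearman's rho between anchor and partner allelic
proportions is computed per bin.  A resampling null keeps the anchors fixed
and redraws partners genome-wide, matched in number per bin.  The decay is
summarized by a least-squares fit of rho against log distance, and the
characteristic distance where the fitted curve bends is located by the
perpendicular-distance ("knee point") method on a 1-50 kb chord with both
axes min-max normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cistrans")

__all__ = [
    "allelic_proportion",
    "site_proportions",
    "CoordinationProfile",
    "correlation_profile",
    "null_profile",
    "fit_log_decay",
    "find_elbow",
    "contact_enrichment",
]


def allelic_proportion(site) -> float:
    """Mean across replicates of strain-A reads over the replicate total.

    Replicates with a zero total are skipped; returns NaN when no replicate
    has reads (the site is excluded upstream).
    """
    a = np.asarray(site["f1_a"], dtype=float)
    b = np.asarray(site["f1_b"], dtype=float)
    tot = a + b
    ok = tot > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(a[ok] / tot[ok]))


def site_proportions(site_table) -> pd.DataFrame:
    """Per-site frame: site_id, chrom, pos, allelic proportion."""
    props = [allelic_proportion(s) for s in site_table.iter_sites()]
    df = pd.DataFrame({
        "site_id": site_table.site_ids,
        "chrom": site_table.data["chrom"].to_numpy(),
        "pos": site_table.data["pos"].to_numpy(),
        "prop": props,
    })
    n_bad = int(df["prop"].isna().sum())
    if n_bad:
        logger.info("site_proportions: excluded %d/%d zero-total sites",
                    n_bad, len(df))
    return df.dropna(subset=["prop"]).reset_index(drop=True)


def _bin_edges(start: int, width: int, max_distance: int, growing: bool):
    """Mutually exclusive distance-bin edges from ``start`` to ``max``."""
    edges = [start]
    w = width
    while edges[-1] < max_distance:
        edges.append(min(edges[-1] + w, max_distance))
        if growing:
            w += width
    return np.asarray(edges, dtype=float)


@dataclass
class CoordinationProfile:
    """Per-bin Spearman profile with optional null envelope and fit."""

    bins: pd.DataFrame           # bin_idx, d_lo, d_hi, d_mid, n_pairs, rho
    pairs: pd.DataFrame          # anchor_id, site_id, distance, bin_idx, props
    start: int
    width: int
    max_distance: int
    min_pairs: int
    growing: bool = False
    null: pd.DataFrame | None = None     # bin_idx, null_mean, lo, hi
    fit: dict | None = None
    elbow: float | None = None


def correlation_profile(anchors: pd.DataFrame, sites: pd.DataFrame,
                        start: int = 400, width: int = 1000,
                        max_distance: int = 400_000, min_pairs: int = 20,
                        growing: bool = False) -> CoordinationProfile:
    """Binned Spearman correlation of allelic proportions around anchors.

    ``anchors`` and ``sites`` are frames with ``site_id``, ``chrom``, ``pos``,
    ``prop`` (see :func:`site_proportions`); anchors are typically the
    cis-class sites.  Pairs are formed within each chromosome by absolute
    distance in ``[start, max_distance]``, both directions pooled; a site
    never pairs with itself.  Bins with fewer than ``min_pairs`` pairs report
    ``rho = NaN``.
    """
    edges = _bin_edges(start, width, max_distance, growing)
    pair_rows = []
    for chrom, anc in anchors.groupby("chrom"):
        s = sites[sites["chrom"] == chrom]
        if s.empty:
            continue
        spos = s["pos"].to_numpy()
        order = np.argsort(spos)
        spos_sorted = spos[order]
        sprop = s["prop"].to_numpy()[order]
        sid = s["site_id"].to_numpy()[order]
        for _, a in anc.iterrows():
            lo = np.searchsorted(spos_sorted, a["pos"] - max_distance, "left")
            hi = np.searchsorted(spos_sorted, a["pos"] + max_distance, "right")
            d = np.abs(spos_sorted[lo:hi] - a["pos"])
            keep = (d >= start) & (sid[lo:hi] != a["site_id"])
            if not keep.any():
                continue
            dd = d[keep]
            bins = np.searchsorted(edges, dd, side="right") - 1
            inside = bins < len(edges) - 1
            for di, bi, pp, pid in zip(dd[inside], bins[inside],
                                       sprop[lo:hi][keep][inside],
                                       sid[lo:hi][keep][inside]):
                pair_rows.append((a["site_id"], pid, int(di), int(bi),
                                  a["prop"], pp))
    pairs = pd.DataFrame(pair_rows, columns=["anchor_id", "site_id", "distance",
                                             "bin_idx", "anchor_prop", "prop"])

    rows = []
    for bi in range(len(edges) - 1):
        sub = pairs[pairs["bin_idx"] == bi]
        n = len(sub)
        if n >= max(min_pairs, 3):
            rho = stats.spearmanr(sub["anchor_prop"], sub["prop"]).statistic
        else:
            rho = float("nan")
        rows.append({"bin_idx": bi, "d_lo": edges[bi], "d_hi": edges[bi + 1],
                     "d_mid": (edges[bi] + edges[bi + 1]) / 2.0,
                     "n_pairs": n, "rho": rho})
    return CoordinationProfile(bins=pd.DataFrame(rows), pairs=pairs,
                               start=start, width=width,
                               max_distance=max_distance, min_pairs=min_pairs,
                               growing=growing)


def null_profile(profile: CoordinationProfile, sites: pd.DataFrame,
                 n_resamples: int = 100, seed: int = 0) -> pd.DataFrame:
    """Resampling null for a profile: anchors kept, partners redrawn.

    For every populated observed bin, the same number of partner sites is
    drawn from the genome-wide pool without replacement (with replacement and
    a warning when the pool is smaller than the bin) and rho is recomputed
    against the observed anchor values.  Returns per-bin null mean and
    2.5/97.5 percentiles, and attaches the result to ``profile.null``.
    """
    rng = np.random.default_rng(seed)
    pool = sites["prop"].to_numpy()
    out = []
    for bi in profile.bins["bin_idx"]:
        sub = profile.pairs[profile.pairs["bin_idx"] == bi]
        n = len(sub)
        if n < max(profile.min_pairs, 3):
            out.append({"bin_idx": bi, "null_mean": float("nan"),
                        "null_lo": float("nan"), "null_hi": float("nan")})
            continue
        anchor_vals = sub["anchor_prop"].to_numpy()
        replace = n > len(pool)
        if replace:
            logger.warning("null_profile: pool (%d) smaller than bin (%d); "
                           "resampling with replacement", len(pool), n)
        rhos = np.empty(n_resamples)
        for t in range(n_resamples):
            partner = rng.choice(pool, size=n, replace=replace)
            rhos[t] = stats.spearmanr(anchor_vals, partner).statistic
        out.append({"bin_idx": bi, "null_mean": float(np.mean(rhos)),
                    "null_lo": float(np.percentile(rhos, 2.5)),
                    "null_hi": float(np.percentile(rhos, 97.5))})
    null = pd.DataFrame(out)
    profile.null = null
    return null


def fit_log_decay(profile: CoordinationProfile, ci: float = 0.90) -> dict:
    """Least-squares fit of rho against log distance over populated bins.

    Returns slope, intercept and the ``ci`` (default 90%) confidence interval
    of the slope; attaches the result to ``profile.fit``.
    """
    import statsmodels.api as sm

    bins = profile.bins.dropna(subset=["rho"])
    if len(bins) < 3:
        raise ValueError(f"need >= 3 populated bins, have {len(bins)}")
    X = sm.add_constant(np.log(bins["d_mid"].to_numpy()))
    model = sm.OLS(bins["rho"].to_numpy(), X).fit()
    lo, hi = model.conf_int(alpha=1.0 - ci)[1]
    fit = {"intercept": float(model.params[0]), "slope": float(model.params[1]),
           "slope_ci": (float(lo), float(hi)), "n_bins": int(len(bins)),
           "ci_level": ci}
    profile.fit = fit
    return fit


def find_elbow(fit: dict, lo: float = 1_000.0, hi: float = 50_000.0,
               n_grid: int = 200, tol: float = 1e-9) -> float | None:
    """Knee of the fitted decay curve by maximal perpendicular chord distance.

    The fitted curve ``rho(d) = intercept + slope * ln d`` is evaluated on a
    uniform grid over ``[lo, hi]``; a chord joins the two endpoints, both axes
    are min-max normalized to [0, 1], and the grid point farthest
    (perpendicularly) from the chord is the elbow.  Returns ``None`` for an
    effectively straight curve (max distance below ``tol``).
    """
    a, b = fit["intercept"], fit["slope"]
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("non-finite regression fit")
    x = np.linspace(lo, hi, n_grid)
    y = a + b * np.log(x)
    return _elbow_of_curve(x, y, tol=tol)


def _elbow_of_curve(x, y, tol: float = 1e-9) -> float | None:
    """Perpendicular-distance elbow of an arbitrary sampled curve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return None
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    x0, y0 = xn[0], yn[0]
    x1, y1 = xn[-1], yn[-1]
    norm = math.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * xn - (x1 - x0) * yn + x1 * y0 - y1 * x0) / norm
    if float(dist.max()) < tol:
        return None
    return float(x[int(np.argmax(dist))])


def _endpoint_classes(sites_by_class: pd.DataFrame, endpoints: pd.DataFrame):
    """For each interaction, the set of site classes overlapping each end."""
    classes = {}
    for chrom, sub in sites_by_class.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        order = np.argsort(sub["pos"].to_numpy())
        cls = sub["class"].to_numpy()[order]
        classes[chrom] = (pos, cls)

    def classes_in(chrom, start, end):
        if chrom not in classes:
            return set()
        pos, cls = classes[chrom]
        lo = np.searchsorted(pos, start, "left")
        hi = np.searchsorted(pos, end, "left")
        return set(cls[lo:hi])

    end1, end2 = [], []
    for _, row in endpoints.iterrows():
        end1.append(classes_in(row["chrom1"], row["start1"], row["end1"]))
        end2.append(classes_in(row["chrom2"], row["start2"], row["end2"]))
    return end1, end2


def contact_enrichment(sites_by_class: pd.DataFrame, endpoints: pd.DataFrame
                       ) -> pd.DataFrame:
    """Class-pair enrichment of chromatin-contact endpoints.

    ``sites_by_class``: frame with site_id, chrom, pos, class (point sites;
    overlap with an endpoint interval means >= 1 bp, i.e. the point falls in
    the half-open interval).  For each ordered class pair (A, B): observed =
    number of interactions whose first end overlaps an A site and second end a
    B site; expected = n * p_A * p_B with p_X the marginal endpoint-overlap
    rate of class X over all 2n endpoints; exact binomial test against the
    expected proportion.  Empty endpoint set -> empty result.
    """
    cols = ["class_a", "class_b", "observed", "expected", "enrichment", "p_value"]
    if endpoints.empty:
        logger.info("contact_enrichment: no interactions supplied")
        return pd.DataFrame(columns=cols)
    end1, end2 = _endpoint_classes(sites_by_class, endpoints)
    n = len(endpoints)
    all_classes = sorted(sites_by_class["class"].unique())
    marginal = {c: sum(c in s for s in end1 + end2) / (2 * n)
                for c in all_classes}
    rows = []
    for ca in all_classes:
        for cb in all_classes:
            obs = sum((ca in s1) and (cb in s2) for s1, s2 in zip(end1, end2))
            p_exp = marginal[ca] * marginal[cb]
            expected = n * p_exp
            if expected == 0:
                rows.append({"class_a": ca, "class_b": cb, "observed": obs,
                             "expected": 0.0, "enrichment": float("nan"),
                             "p_value": float("nan")})
                continue
            p = stats.binomtest(obs, n, p_exp).pvalue
            rows.append({"class_a": ca, "class_b": cb, "observed": obs,
                         "expected": expected, "enrichment": obs / expected,
                         "p_value": float(p)})
    return pd.DataFrame(rows, columns=cols)
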