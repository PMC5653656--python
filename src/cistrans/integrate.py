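"""Integration of regulatory-class calls across TF binding, chromatin and
expression layers.

Sites, histone marks and genes each carry one of the four regulatory classes
(conserved / cis / trans / cis_trans); genes additionally carry allele-level
expression.  The operations here relate the layers: strand-aware assignment
of sites to TSS windows (20 kb upstream / 10 kb downstream by default),
logistic-regression enrichment of layer classes on per-class site counts,
exact binomial concordance and co-location tests, Shannon diversity of the
mechanisms around each gene, expression-matched subsampling, and the summary
statistics of cis extent (F0-vs-F1 Pearson correlation and the random-pair
effect-magnitude comparison).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cistrans")

CLASSES = ("conserved", "cis", "trans", "cis_trans")

__all__ = [
    "assign_sites_to_genes",
    "logistic_enrichment",
    "chromatin_tf_enrichment",
    "promoter_mark_gene_concordance",
    "shannon_diversity",
    "diversity_by_expression_class",
    "expression_matched_subsample",
    "colocation_shared_class_test",
    "region_class_enrichment",
    "cis_extent_correlation",
    "compare_cis_effect_magnitude",
    "direction_concordance",
]


def _window(tss: int, strand: str, up: int, down: int):
    """Strand-aware inclusive TSS window (upstream `up`, downstream `down`)."""
    if strand == "+":
        return tss - up, tss + down
    return tss - down, tss + up


def assign_sites_to_genes(sites: pd.DataFrame, genes: pd.DataFrame,
                          up: int = 20_000, down: int = 10_000) -> pd.DataFrame:
    """Count classified sites per regulatory class in each gene's TSS window.

    ``sites``: site_id, chrom, pos, class.  ``genes``: gene_id, chrom, tss,
    strand.  Window bounds are inclusive on both ends; windows running off the
    chromosome start are truncated at 0 (logged).  Returns the gene frame with
    one ``n_<class>`` column per class and ``n_sites``.
    """
    out = genes.copy()
    for c in CLASSES:
        out[f"n_{c}"] = 0
    by_chrom = {}
    for chrom, sub in sites.groupby("chrom"):
        order = np.argsort(sub["pos"].to_numpy())
        by_chrom[chrom] = (sub["pos"].to_numpy()[order],
                           sub["class"].to_numpy()[order])
    n_trunc = 0
    for i, gene in genes.iterrows():
        if gene["chrom"] not in by_chrom:
            continue
        pos, cls = by_chrom[gene["chrom"]]
        lo, hi = _window(int(gene["tss"]), gene["strand"], up, down)
        if lo < 0:
            lo, n_trunc = 0, n_trunc + 1
        a = np.searchsorted(pos, lo, "left")
        b = np.searchsorted(pos, hi, "right")   # inclusive upper bound
        vals, counts = np.unique(cls[a:b], return_counts=True)
        for v, k in zip(vals, counts):
            out.at[i, f"n_{v}"] = int(k)
    if n_trunc:
        logger.info("assign_sites_to_genes: %d windows truncated at "
                    "chromosome start", n_trunc)
    out["n_sites"] = out[[f"n_{c}" for c in CLASSES]].sum(axis=1)
    return out


def logistic_enrichment(gene_table: pd.DataFrame, response_class: str,
                        class_col: str = "expr_class") -> pd.DataFrame:
    """Logistic regression of one layer class on per-class site counts.

    The binary response is membership of ``response_class`` (vs all other
    classes); the four predictors are the ``n_<class>`` count columns.
    Returns one row per predictor with the odds ratio, Z-score and a
    significance flag at |Z| > 2; zero-variance predictors are reported as
    non-estimable.
    """
    import statsmodels.api as sm

    y = (gene_table[class_col] == response_class).astype(float).to_numpy()
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(f"need >= 2 genes on each side of class "
                         f"{response_class!r}")
    pred_cols = [f"n_{c}" for c in CLASSES]
    X = gene_table[pred_cols].to_numpy(dtype=float)
    estimable = X.std(axis=0) > 0
    rows = []
    Xs = sm.add_constant(X[:, estimable])
    try:
        fit = sm.Logit(y, Xs).fit(disp=0, maxiter=200)
        params = fit.params[1:]
        zs = fit.tvalues[1:]
        ok = np.isfinite(fit.bse[1:])
    except Exception as exc:  # perfect separation and friends
        logger.warning("logistic_enrichment(%s): %s", response_class, exc)
        params = np.full(int(estimable.sum()), np.nan)
        zs = np.full(int(estimable.sum()), np.nan)
        ok = np.zeros(int(estimable.sum()), dtype=bool)
    j = 0
    for i, col in enumerate(pred_cols):
        if not estimable[i]:
            rows.append({"response": response_class, "predictor": col,
                         "log_odds": np.nan, "odds_ratio": np.nan,
                         "z": np.nan, "significant": False,
                         "estimable": False})
            continue
        rows.append({"response": response_class, "predictor": col,
                     "log_odds": float(params[j]),
                     "odds_ratio": float(np.exp(params[j])),
                     "z": float(zs[j]),
                     "significant": bool(ok[j] and abs(zs[j]) > 2),
                     "estimable": bool(ok[j])})
        j += 1
    return pd.DataFrame(rows)


def enrichment_panel(gene_table: pd.DataFrame, class_col: str = "expr_class",
                     mean_center: bool = True) -> pd.DataFrame:
    """All four response-class regressions; optionally mean-centered odds
    ratios (per predictor, across the four fits) for display."""
    frames = [logistic_enrichment(gene_table, c, class_col=class_col)
              for c in CLASSES if (gene_table[class_col] == c).sum() >= 2
              and (gene_table[class_col] != c).sum() >= 2]
    panel = pd.concat(frames, ignore_index=True)
    if mean_center:
        centered = panel["log_odds"] - panel.groupby("predictor")[
            "log_odds"].transform("mean")
        panel["centered_odds_ratio"] = np.exp(centered)
    return panel


def chromatin_tf_enrichment(marks: pd.DataFrame, sites: pd.DataFrame,
                            window: int = 2_000) -> pd.DataFrame:
    """Same regression machinery with histone marks as the observations.

    ``marks``: mark_id, chrom, pos, class.  Site counts per class are taken
    in a +/- ``window`` bp interval (inclusive) around each mark.
    """
    m = marks.rename(columns={"mark_id": "gene_id"}).copy()
    m["tss"] = m["pos"]
    m["strand"] = "+"
    counted = assign_sites_to_genes(sites, m, up=window, down=window)
    return enrichment_panel(counted, class_col="class")


def promoter_mark_gene_concordance(marks: pd.DataFrame, genes: pd.DataFrame,
                                   upstream: int = 5_000) -> pd.DataFrame:
    """Per-class binomial test of shared mark/gene regulatory mechanism.

    A mark is assigned to a gene when it lies within ``upstream`` bp upstream
    of the TSS (strand-aware, inclusive).  For each class c, tests whether
    P(gene class = c and assigned mark class = c) exceeds the product of the
    marginal frequencies among assigned pairs (one-sided exact binomial).
    """
    pairs = []
    by_chrom = {chrom: sub for chrom, sub in marks.groupby("chrom")}
    for _, gene in genes.iterrows():
        sub = by_chrom.get(gene["chrom"])
        if sub is None:
            continue
        if gene["strand"] == "+":
            lo, hi = gene["tss"] - upstream, gene["tss"]
        else:
            lo, hi = gene["tss"], gene["tss"] + upstream
        hit = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
        for _, mk in hit.iterrows():
            pairs.append((gene["expr_class"], mk["class"]))
    cols = ["class", "n_pairs", "observed", "expected_p", "p_value"]
    if not pairs:
        logger.info("promoter_mark_gene_concordance: no assignable pairs")
        return pd.DataFrame(columns=cols)
    pairs = pd.DataFrame(pairs, columns=["gene_class", "mark_class"])
    n = len(pairs)
    rows = []
    for c in CLASSES:
        p_exp = ((pairs["gene_class"] == c).mean()
                 * (pairs["mark_class"] == c).mean())
        k = int(((pairs["gene_class"] == c) & (pairs["mark_class"] == c)).sum())
        if p_exp in (0.0, 1.0):
            pv = 1.0
        else:
            pv = float(stats.binomtest(k, n, p_exp, alternative="greater").pvalue)
        rows.append({"class": c, "n_pairs": n, "observed": k,
                     "expected_p": p_exp, "p_value": pv})
    return pd.DataFrame(rows, columns=cols)


def shannon_diversity(proportions) -> float:
    """Shannon diversity H' = -sum a_i ln a_i over class proportions.

    Zero proportions contribute zero; the result lies in [0, ln(n_classes)].
    """
    a = np.asarray(proportions, dtype=float)
    if (a < 0).any():
        raise ValueError("negative proportion")
    s = a.sum()
    if s <= 0:
        raise ValueError("proportions sum to zero")
    a = a / s
    nz = a[a > 0]
    return float(-(nz * np.log(nz)).sum()) + 0.0  # avoid -0.0


def diversity_by_expression_class(gene_table: pd.DataFrame,
                                  class_col: str = "expr_class") -> dict:
    """Per-gene mechanistic diversity, compared between expression classes.

    Each gene's H' is computed over the class composition of the sites in its
    TSS window (``n_<class>`` columns; genes with no sites are dropped).
    Returns ``{"diversity": frame, "tests": frame}`` with two-sided
    Mann-Whitney U tests between all expression-class pairs having >= 2 genes.
    """
    counts = gene_table[[f"n_{c}" for c in CLASSES]].to_numpy(dtype=float)
    has = counts.sum(axis=1) > 0
    sub = gene_table[has]
    hvals = np.array([shannon_diversity(row) for row in counts[has]])
    div = pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(),
                        "class": sub[class_col].to_numpy(), "H": hvals})
    rows = []
    present = [c for c in CLASSES if (div["class"] == c).sum() >= 2]
    for i, ca in enumerate(present):
        for cb in present[i + 1:]:
            a = div.loc[div["class"] == ca, "H"]
            b = div.loc[div["class"] == cb, "H"]
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"class_a": ca, "class_b": cb,
                         "median_a": float(a.median()),
                         "median_b": float(b.median()),
                         "p_value": float(res.pvalue)})
    return {"diversity": div,
            "tests": pd.DataFrame(rows, columns=["class_a", "class_b",
                                                 "median_a", "median_b",
                                                 "p_value"])}


def expression_matched_subsample(gene_table: pd.DataFrame, target_class: str,
                                 reference_class: str, seed: int = 0,
                                 n_bins: int = 20,
                                 class_col: str = "expr_class") -> dict:
    """Match reference-class genes to target-class genes by expression level.

    Expression is the log of the more highly expressed parent's mean level
    (columns ``expr_f0_a`` / ``expr_f0_b``), cut into ``n_bins`` equal-width
    bins over its range.  Each target gene draws a reference gene from its
    own bin, with replacement; target genes whose bin holds no reference gene
    are dropped (logged).
    """
    rng = np.random.default_rng(seed)
    expr = np.log(np.maximum(gene_table[["expr_f0_a", "expr_f0_b"]].max(axis=1),
                             1e-12))
    edges = np.linspace(expr.min(), expr.max(), n_bins + 1)
    bins = np.clip(np.digitize(expr, edges) - 1, 0, n_bins - 1)
    gt = gene_table.assign(_bin=bins)
    targets = gt[gt[class_col] == target_class]
    refs = gt[gt[class_col] == reference_class]
    ref_by_bin = {b: sub.index.to_numpy() for b, sub in refs.groupby("_bin")}
    matched_idx, kept_idx = [], []
    dropped = 0
    for idx, b in zip(targets.index, targets["_bin"]):
        if b not in ref_by_bin:
            dropped += 1
            continue
        kept_idx.append(idx)
        matched_idx.append(rng.choice(ref_by_bin[b]))
    if dropped:
        logger.warning("expression_matched_subsample: dropped %d target genes "
                       "with an empty reference bin", dropped)
    return {"target": gt.loc[kept_idx].drop(columns="_bin"),
            "matched": gt.loc[matched_idx].drop(columns="_bin"),
            "n_dropped": dropped, "bin_edges": edges}


def colocation_shared_class_test(per_tf_calls: pd.DataFrame) -> pd.DataFrame:
    """Shared-class excess at SNVs bound by all assays.

    ``per_tf_calls``: one row per triple-bound SNV, one class column per
    assay.  For each class i the expected Bernoulli success is the product of
    the per-assay class-i proportions; the observed successes are SNVs where
    all assays share class i (one-sided exact binomial for excess sharing).
    """
    cols = ["class", "n", "observed", "expected_p", "p_value"]
    if per_tf_calls.empty:
        logger.info("colocation_shared_class_test: no triple-bound SNVs")
        return pd.DataFrame(columns=cols)
    assays = list(per_tf_calls.columns)
    n = len(per_tf_calls)
    rows = []
    for c in CLASSES:
        p_exp = float(np.prod([(per_tf_calls[a] == c).mean() for a in assays]))
        k = int((per_tf_calls.eq(c).all(axis=1)).sum())
        if p_exp in (0.0, 1.0):
            pv = 1.0
        else:
            pv = float(stats.binomtest(k, n, p_exp, alternative="greater").pvalue)
        rows.append({"class": c, "n": n, "observed": k, "expected_p": p_exp,
                     "p_value": pv})
    return pd.DataFrame(rows, columns=cols)


def region_class_enrichment(sites: pd.DataFrame, regions: pd.DataFrame,
                            overall_props: dict) -> pd.DataFrame:
    """Exact binomial enrichment of site classes inside genomic regions.

    A site co-locates with a region on a >= 1 bp overlap (the point coordinate
    falls inside the half-open interval).  For each class: ``k`` sites of the
    class among the ``n`` region-overlapping sites, two-sided exact binomial
    against the overall class proportion ``p``, odds ratio
    ``(k/(n-k)) / (p/(1-p))``.
    """
    cols = ["class", "n_in_regions", "k", "p_overall", "odds_ratio", "p_value"]
    in_region = np.zeros(len(sites), dtype=bool)
    for chrom, sub in regions.groupby("chrom"):
        mask = sites["chrom"] == chrom
        if not mask.any():
            continue
        pos = sites.loc[mask, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for _, reg in sub.iterrows():
            hit |= (pos >= reg["start"]) & (pos < reg["end"])
        in_region[np.where(mask)[0]] = hit
    n = int(in_region.sum())
    if n == 0:
        logger.info("region_class_enrichment: no site overlaps any region")
        return pd.DataFrame(columns=cols)
    inside = sites[in_region]
    rows = []
    for c, p in overall_props.items():
        k = int((inside["class"] == c).sum())
        if not 0 < p < 1:
            rows.append({"class": c, "n_in_regions": n, "k": k,
                         "p_overall": p, "odds_ratio": float("nan"),
                         "p_value": float("nan")})
            continue
        if k == n:
            orr = float("inf")
        else:
            orr = (k / (n - k)) / (p / (1 - p))
        pv = float(stats.binomtest(k, n, p).pvalue)
        rows.append({"class": c, "n_in_regions": n, "k": k, "p_overall": p,
                     "odds_ratio": orr, "p_value": pv})
    return pd.DataFrame(rows, columns=cols)


def cis_extent_correlation(f0_log_ratio, f1_log_ratio, ci: float = 0.95) -> dict:
    """Pearson correlation of F0 strain ratios against F1 allelic ratios.

    Under a purely cis architecture the F1 alleles recapitulate the parental
    ratio (r -> 1); equal cis and trans contributions drive r toward 0.
    Returns r, the Fisher-z confidence interval, and the p-value.
    """
    x = np.asarray(f0_log_ratio, dtype=float)
    y = np.asarray(f1_log_ratio, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 units")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / math.sqrt(len(x) - 3)
    zc = stats.norm.ppf(0.5 + ci / 2.0)
    return {"r": r, "ci": (float(np.tanh(z - zc * se)),
                           float(np.tanh(z + zc * se))),
            "p_value": float(res.pvalue), "n": int(len(x))}


def compare_cis_effect_magnitude(site_magnitudes, gene_magnitudes,
                                 n_draws: int = 10_000, seed: int = 0) -> float:
    """Fraction of random (site, gene) pairs where the site's allelic-effect
    magnitude (|log2 F1 allelic ratio|) exceeds the gene's; ties count 1/2."""
    s = np.asarray(site_magnitudes, dtype=float)
    g = np.asarray(gene_magnitudes, dtype=float)
    if s.size == 0 or g.size == 0:
        raise ValueError("empty magnitude input")
    rng = np.random.default_rng(seed)
    si = rng.integers(0, s.size, size=n_draws)
    gi = rng.integers(0, g.size, size=n_draws)
    wins = (s[si] > g[gi]).sum() + 0.5 * (s[si] == g[gi]).sum()
    return float(wins / n_draws)


def direction_concordance(site_changes, gene_changes) -> dict:
    """Sign agreement and rank correlation of paired allelic changes.

    ``site_changes`` and ``gene_changes`` are paired signed log2 allelic
    changes (one entry per site-gene pair).  Returns the exact binomial test
    of sign agreement against 0.5 (pairs with a zero on either side are
    dropped) and Spearman's rho of the signed values.
    """
    s = np.asarray(site_changes, dtype=float)
    g = np.asarray(gene_changes, dtype=float)
    if s.size == 0 or s.size != g.size:
        raise ValueError("need equal-length, non-empty paired changes")
    nz = (s != 0) & (g != 0)
    agree = int((np.sign(s[nz]) == np.sign(g[nz])).sum())
    n = int(nz.sum())
    pv = float(stats.binomtest(agree, n, 0.5).pvalue) if n else float("nan")
    rho = stats.spearmanr(s, g)
    return {"n": n, "agreement": agree / n if n else float("nan"),
            "sign_p": pv, "rho": float(rho.statistic),
            "rho_p": float(rho.pvalue)}
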