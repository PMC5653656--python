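"""Synthetic allele-specific count data with known ground truth.

The generator mirrors the hierarchy used by the classification model:

* F0 replicate counts are Poisson with Gamma-distributed means (shape
  ``r = 1/dispersion``, scale chosen so the marginal mean hits the target
  depth) — i.e. negative-binomial marginals.
* F1 per-replicate totals are drawn from the same family at diploid scale
  (midparent mean by default).
* F1 strain-A allele counts are beta-binomial given the totals, with the
  allelic mean set by the regulatory class: ``cis`` ties it to the F0 odds,
  ``trans`` and ``conserved`` keep it at 1/2, ``cis_trans`` uses an
  independent mean.

Library-size variation is multiplicative and log-normal; the same F1 factor
scales both alleles so allelic proportions are unaffected.  One root seed
drives everything through named sub-streams (``sites``, ``library``,
``genome``, ``landscape``), so partial re-runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicFeatureSet, SiteTable

__all__ = [
    "SimConfig",
    "simulate_site",
    "simulate_dataset",
    "simulate_genome_context",
    "simulate_coordination_landscape",
    "simulate_lineage_dataset",
    "CoordinationLandscape",
    "CLASSES",
]

CLASSES = ("conserved", "cis", "trans", "cis_trans")

_STREAMS = {"sites": 1, "library": 2, "genome": 3, "landscape": 4, "lineage": 5}


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults reproduce the reference design: six F0 replicates per strain,
    twelve allele-resolved F1 replicates, mean depth 100 reads per site,
    NB dispersion 0.1, a 4:1 strain-A:strain-B intensity odds for divergent
    classes (hence a cis allelic mean of 0.8), and an independent allelic mean
    of 0.65 for cis-trans sites.
    """

    n_sites_per_class: int = 100
    n_f0_reps: int = 6
    n_f1_reps: int = 12
    mean_depth: float = 100.0
    dispersion: float = 0.1
    f0_odds: float = 4.0
    f1_allelic_mean: dict = field(default_factory=dict)  # per-class overrides
    concentration: float = 50.0
    library_size_cv: float = 0.1
    f1_depth_scale: float = 1.0     # F1 total depth relative to the midparent
    cis_trans_mean: float = 0.65
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sites_per_class, self.n_f0_reps, self.n_f1_reps) <= 0:
            raise ValueError("replicate and site counts must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.cis_trans_mean < 1:
            raise ValueError("cis_trans_mean must lie in (0, 1)")
        for v in self.f1_allelic_mean.values():
            if not 0 < v < 1:
                raise ValueError("f1_allelic_mean values must lie in (0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def class_allelic_mean(self, label: str) -> float:
        if label in self.f1_allelic_mean:
            return float(self.f1_allelic_mean[label])
        if label in ("conserved", "trans"):
            return 0.5
        if label == "cis":
            return self.f0_odds / (1.0 + self.f0_odds)
        if label == "cis_trans":
            return self.cis_trans_mean
        raise ValueError(f"unknown class label {label!r}")


def _nb_draw(rng, mean, r, size):
    """Poisson-Gamma draw with marginal mean ``mean`` and size ``r``;
    degenerates to Poisson when the dispersion is zero (r = inf)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if not np.isfinite(r):
        return rng.poisson(mean)
    lam = rng.gamma(shape=r, scale=mean / r, size=size)
    return rng.poisson(lam)


def simulate_site(class_label: str, config: SimConfig, rng: np.random.Generator,
                  f1_total_mode: str = "midparent",
                  lib_factors: dict | None = None,
                  direction: int | None = None) -> dict:
    """Draw one site's replicate counts under a regulatory class.

    ``f1_total_mode`` plants the inheritance mode of the F1 total occupancy:
    ``midparent`` (additive), ``high_parent`` or ``low_parent`` (dominant).
    ``lib_factors`` optionally supplies per-library multiplicative factors
    (keys ``f0_a``, ``f0_b``, ``f1`` mapping to arrays).  ``direction`` (+1:
    strain A carries the higher intensity, -1: strain B) defaults to a fair
    coin per site — strain divergence has no preferred direction, and a
    direction-balanced mix is what the median-of-ratios normalization
    assumption (most sites unaffected in any one library) requires.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    if config.mean_depth <= 0:
        raise ValueError("non-positive depth")

    r = math.inf if config.dispersion == 0 else 1.0 / config.dispersion
    if direction is None:
        direction = 1 if rng.integers(0, 2) else -1
    if class_label == "conserved":
        mu_a = mu_b = config.mean_depth
    else:
        f = config.f0_odds if direction > 0 else 1.0 / config.f0_odds
        mu_a = config.mean_depth * 2.0 * f / (1.0 + f)
        mu_b = config.mean_depth * 2.0 / (1.0 + f)

    nf0, nf1 = config.n_f0_reps, config.n_f1_reps
    ones = np.ones
    lf = lib_factors or {"f0_a": ones(nf0), "f0_b": ones(nf0), "f1": ones(nf1)}

    x_a = _nb_draw(rng, mu_a * lf["f0_a"], r, nf0)
    x_b = _nb_draw(rng, mu_b * lf["f0_b"], r, nf0)

    if f1_total_mode == "midparent":
        mu_f1 = (mu_a + mu_b) / 2.0
    elif f1_total_mode == "high_parent":
        mu_f1 = max(mu_a, mu_b)
    elif f1_total_mode == "low_parent":
        mu_f1 = min(mu_a, mu_b)
    else:
        raise ValueError(f"unknown f1_total_mode {f1_total_mode!r}")
    mu_f1 *= config.f1_depth_scale

    n = _nb_draw(rng, mu_f1 * lf["f1"], r, nf1)
    m = config.class_allelic_mean(class_label)
    if direction < 0 and class_label in ("cis", "cis_trans"):
        m = 1.0 - m
    if config.dispersion == 0 and config.concentration >= 1e6:
        z = rng.binomial(n, m)
    else:
        p = rng.beta(m * config.concentration, (1.0 - m) * config.concentration,
                     size=nf1)
        z = rng.binomial(n, p)

    site = {"true_class": class_label, "direction": direction}
    site.update({f"F0_A_rep{i+1}": int(x_a[i]) for i in range(nf0)})
    site.update({f"F0_B_rep{i+1}": int(x_b[i]) for i in range(nf0)})
    site.update({f"F1_A_rep{j+1}": int(z[j]) for j in range(nf1)})
    site.update({f"F1_B_rep{j+1}": int(n[j] - z[j]) for j in range(nf1)})
    return site


def _library_factors(config: SimConfig):
    """Log-normal per-library scale factors with the configured CV."""
    rng = config.rng("library")
    cv = config.library_size_cv
    if cv <= 0:
        return {"f0_a": np.ones(config.n_f0_reps),
                "f0_b": np.ones(config.n_f0_reps),
                "f1": np.ones(config.n_f1_reps)}
    sigma = math.sqrt(math.log(1.0 + cv ** 2))
    mu = -sigma ** 2 / 2.0  # unit mean
    return {"f0_a": rng.lognormal(mu, sigma, config.n_f0_reps),
            "f0_b": rng.lognormal(mu, sigma, config.n_f0_reps),
            "f1": rng.lognormal(mu, sigma, config.n_f1_reps)}


def simulate_dataset(config: SimConfig, class_weights: dict | None = None,
                     f1_total_modes: dict | None = None,
                     site_spacing: int = 1000, assay: str = "TF1",
                     lib_factors: dict | None = None
                     ) -> tuple[SiteTable, pd.DataFrame]:
    """Simulate a balanced (or weighted) multi-class dataset.

    Returns the site table and a truth table (site_id, true_class,
    true_inheritance, outgroup_present).  Sites are laid on ``chr1`` with a
    fixed spacing so downstream positional operations have coordinates to
    work with.
    """
    rng = config.rng("sites")
    if lib_factors is None:
        lib_factors = _library_factors(config)
    weights = class_weights or {c: 1.0 for c in CLASSES}
    modes = f1_total_modes or {}

    rows, truth = [], []
    pos = 1000
    i = 0
    for label in CLASSES:
        n_sites = int(round(config.n_sites_per_class * weights.get(label, 0)))
        mode = modes.get(label, "midparent")
        for _ in range(n_sites):
            site = simulate_site(label, config, rng, f1_total_mode=mode,
                                 lib_factors=lib_factors)
            sid = f"site_{i:05d}"
            row = {"site_id": sid, "chrom": "chr1", "pos": pos, "assay": assay}
            row.update({k: v for k, v in site.items()
                        if k not in ("true_class", "direction")})
            rows.append(row)
            truth.append({"site_id": sid, "true_class": label,
                          "direction": site["direction"],
                          "true_inheritance":
                              {"midparent": "additive",
                               "high_parent": "dominant_high_parent",
                               "low_parent": "dominant_low_parent"}[mode],
                          "outgroup_present": bool(rng.integers(0, 2))})
            pos += site_spacing
            i += 1
    table = SiteTable(pd.DataFrame(rows))
    table.lib_factors = lib_factors  # recorded for tests / reporting
    return table, pd.DataFrame(truth)


def simulate_lineage_dataset(config: SimConfig, mechanism: str,
                             n_sites: int | None = None,
                             trans_factor: float = 2.0
                             ) -> tuple[SiteTable, pd.DataFrame]:
    """Simulate lineage-specific sites (bound in one strain only).

    Under a purely cis mechanism the F1 carries a single bound allele, so its
    total is half the bound parent's level (``2y = x``); under cis-trans the
    F1 level deviates from that 2:1 ratio by ``trans_factor``.
    """
    if mechanism not in ("cis", "cis_trans"):
        raise ValueError(f"unknown lineage mechanism {mechanism!r}")
    rng = config.rng("lineage")
    n_sites = n_sites or config.n_sites_per_class
    r = math.inf if config.dispersion == 0 else 1.0 / config.dispersion
    mu = config.mean_depth
    mu_f1 = mu / 2.0 * (1.0 if mechanism == "cis" else trans_factor)

    rows, truth = [], []
    for i in range(n_sites):
        x = _nb_draw(rng, mu, r, config.n_f0_reps)
        n = _nb_draw(rng, mu_f1, r, config.n_f1_reps)
        # essentially all F1 reads fall on the bound (strain A) allele
        z = rng.binomial(n, 0.985)
        row = {"site_id": f"ls_{i:05d}", "chrom": "chr1", "pos": 1000 + i * 1000,
               "assay": "TF1"}
        row.update({f"F0_A_rep{j+1}": int(x[j]) for j in range(config.n_f0_reps)})
        row.update({f"F0_B_rep{j+1}": 0 for j in range(config.n_f0_reps)})
        row.update({f"F1_A_rep{j+1}": int(z[j]) for j in range(config.n_f1_reps)})
        row.update({f"F1_B_rep{j+1}": int(n[j] - z[j])
                    for j in range(config.n_f1_reps)})
        rows.append(row)
        truth.append({"site_id": row["site_id"], "true_mechanism": mechanism,
                      "outgroup_present": bool(rng.integers(0, 2))})
    return SiteTable(pd.DataFrame(rows)), pd.DataFrame(truth)


def simulate_genome_context(config: SimConfig, n_genes: int = 200,
                            chrom_length: int = 50_000_000,
                            n_sites: int = 1000,
                            n_interactions: int = 100,
                            planted_extra: dict | None = None,
                            upstream: int = 20_000, downstream: int = 10_000
                            ) -> GenomicFeatureSet:
    """Generate genes, intervals, interactions and classified site positions.

    ``planted_extra`` maps a regulatory class to the expected number of extra
    sites of that same class placed in the TSS window of genes whose
    expression class matches (e.g. ``{"cis": 3}``); without it, site classes
    are independent of gene classes.
    """
    if min(n_genes, chrom_length, n_sites) <= 0:
        raise ValueError("gene count, chromosome length and site count must be > 0")
    if upstream + downstream >= chrom_length:
        raise ValueError("TSS window exceeds chromosome bounds")
    rng = config.rng("genome")
    margin = upstream + downstream

    # genes: TSS, strand, expression class and allele-level expression
    tss = np.sort(rng.integers(margin, chrom_length - margin, size=n_genes))
    strand = rng.choice(["+", "-"], size=n_genes)
    expr_class = rng.choice(CLASSES, size=n_genes)
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    f = config.f0_odds
    genes = []
    for g in range(n_genes):
        cls = expr_class[g]
        ratio_f0 = 1.0 if cls == "conserved" else f
        m = config.class_allelic_mean(cls)
        genes.append({
            "gene_id": f"gene_{g:04d}", "chrom": "chr1", "tss": int(tss[g]),
            "strand": strand[g], "expr_class": cls,
            "expr_f0_a": base[g] * 2 * ratio_f0 / (1 + ratio_f0),
            "expr_f0_b": base[g] * 2 / (1 + ratio_f0),
            "expr_f1_a": base[g] * m, "expr_f1_b": base[g] * (1 - m),
        })
    genes = pd.DataFrame(genes)

    # background sites, classes independent of genes
    spos = np.sort(rng.integers(0, chrom_length, size=n_sites))
    sites = pd.DataFrame({
        "site_id": [f"ctx_{i:05d}" for i in range(n_sites)],
        "chrom": "chr1", "pos": spos,
        "class": rng.choice(CLASSES, size=n_sites),
    })
    if planted_extra:
        extra_rows = []
        for _, gene in genes.iterrows():
            cls = gene["expr_class"]
            lam = planted_extra.get(cls, 0)
            if lam <= 0:
                continue
            k = rng.poisson(lam)
            for _ in range(k):
                if gene["strand"] == "+":
                    lo, hi = gene["tss"] - upstream, gene["tss"] + downstream
                else:
                    lo, hi = gene["tss"] - downstream, gene["tss"] + upstream
                extra_rows.append({
                    "site_id": f"ctx_p{len(extra_rows):05d}", "chrom": "chr1",
                    "pos": int(rng.integers(max(lo, 0), hi)), "class": cls})
        if extra_rows:
            sites = pd.concat([sites, pd.DataFrame(extra_rows)],
                              ignore_index=True)

    promoters = pd.DataFrame({
        "chrom": "chr1",
        "start": np.maximum(genes["tss"] - 1000, 0),
        "end": genes["tss"] + 1000,
        "name": genes["gene_id"] + "_prom",
    })
    n_enh = max(n_genes // 2, 1)
    estart = np.sort(rng.integers(0, chrom_length - 2000, size=n_enh))
    enhancers = pd.DataFrame({"chrom": "chr1", "start": estart,
                              "end": estart + 2000,
                              "name": [f"enh_{i:04d}" for i in range(n_enh)]})

    if n_interactions > 0:
        a = rng.integers(0, chrom_length - 5000, size=n_interactions)
        off = rng.integers(50_000, 2_000_000, size=n_interactions)
        b = np.minimum(a + off, chrom_length - 5000)
        interactions = pd.DataFrame({
            "chrom1": "chr1", "start1": a, "end1": a + 5000,
            "chrom2": "chr1", "start2": b, "end2": b + 5000,
        })
    else:
        interactions = pd.DataFrame(
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])

    fs = GenomicFeatureSet(genes=genes, promoters=promoters,
                           enhancers=enhancers, interactions=interactions,
                           chrom_sizes={"chr1": chrom_length})
    fs.sites = sites
    return fs


@dataclass
class CoordinationLandscape:
    """Simulated sites sharing attenuated anchor allelic shifts."""

    table: SiteTable
    anchor_ids: list
    truth: pd.DataFrame          # site_id, anchor_id, distance, true_mean
    decay_scale: float


def simulate_coordination_landscape(decay_scale: float, n_anchors: int,
                                    config: SimConfig,
                                    n_satellites: int = 10,
                                    max_distance: int = 400_000,
                                    min_distance: int = 500,
                                    shift_sd: float = 0.2,
                                    noise_sd: float = 0.05,
                                    independent: bool = False
                                    ) -> CoordinationLandscape:
    """Plant a distance-decaying shared cis effect around anchor sites.

    Each anchor carries a latent allelic shift; satellites at distance ``d``
    inherit it attenuated by ``exp(-d / decay_scale)`` plus independent noise.
    With ``independent=True`` satellites ignore the anchor shift entirely
    (a null landscape).  Satellite distances are log-uniform on
    ``[min_distance, max_distance]``, both directions.
    """
    if decay_scale <= 0:
        raise ValueError("decay_scale must be > 0 (use independent=True for a null)")
    rng = config.rng("landscape")
    spacing = 2 * max_distance + 100_000
    rows, truth = [], []

    def draw_counts(m):
        n = rng.poisson(config.mean_depth, size=config.n_f1_reps)
        p = rng.beta(m * config.concentration, (1 - m) * config.concentration,
                     size=config.n_f1_reps)
        z = rng.binomial(n, p)
        return n, z

    def add_site(sid, pos, m):
        m = float(np.clip(m, 0.02, 0.98))
        n, z = draw_counts(m)
        row = {"site_id": sid, "chrom": "chr1", "pos": int(pos), "assay": "TF1"}
        odds = m / (1 - m)
        mu_a = config.mean_depth * 2 * odds / (1 + odds)
        mu_b = config.mean_depth * 2 / (1 + odds)
        row.update({f"F0_A_rep{i+1}": int(rng.poisson(mu_a))
                    for i in range(config.n_f0_reps)})
        row.update({f"F0_B_rep{i+1}": int(rng.poisson(mu_b))
                    for i in range(config.n_f0_reps)})
        row.update({f"F1_A_rep{j+1}": int(z[j]) for j in range(config.n_f1_reps)})
        row.update({f"F1_B_rep{j+1}": int(n[j] - z[j])
                    for j in range(config.n_f1_reps)})
        rows.append(row)
        return m

    anchor_ids = []
    for a in range(n_anchors):
        center = max_distance + a * spacing
        delta = float(np.clip(rng.normal(0.0, shift_sd), -0.4, 0.4))
        aid = f"anchor_{a:04d}"
        anchor_ids.append(aid)
        m_a = add_site(aid, center, 0.5 + delta)
        truth.append({"site_id": aid, "anchor_id": aid, "distance": 0,
                      "true_mean": m_a})
        log_lo, log_hi = math.log(min_distance), math.log(max_distance)
        for s in range(n_satellites):
            d = int(math.exp(rng.uniform(log_lo, log_hi)))
            sign = 1 if rng.integers(0, 2) else -1
            shift = 0.0 if independent else delta * math.exp(-d / decay_scale)
            m_s = add_site(f"sat_{a:04d}_{s:02d}", center + sign * d,
                           0.5 + shift + rng.normal(0.0, noise_sd))
            truth.append({"site_id": f"sat_{a:04d}_{s:02d}", "anchor_id": aid,
                          "distance": d, "true_mean": m_s})

    table = SiteTable(pd.DataFrame(rows).sort_values("pos").reset_index(drop=True))
    return CoordinationLandscape(table=table, anchor_ids=anchor_ids,
                                 truth=pd.DataFrame(truth),
                                 decay_scale=decay_scale)
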