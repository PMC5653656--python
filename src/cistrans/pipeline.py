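"""Stage orchestration: preprocess -> classify -> {inheritance, lineage}
-> coordination -> integrate, with a reproducible report bundle.

The pipeline is a pure function of (inputs, config, seed): identical inputs
produce byte-identical stage tables, which the bundle exposes as SHA-256
hashes for regression checking.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coordination as coord
from . import integrate as integ
from .inheritance import classify_inheritance
from .io import SiteTable, read_site_table, write_site_table
from .lineage import classify_lineage
from .preprocess import (estimate_dispersion, filter_sites, normalize_counts,
                         thin_sites_by_distance)
from .regclass import classify_sites

logger = logging.getLogger("cistrans")

ALL_STAGES = ("preprocess", "regclass", "inheritance", "lineage",
              "coordination", "integrate")


@dataclass
class ReportBundle:
    """Per-stage result tables plus run metadata."""

    tables: dict = field(default_factory=dict)       # name -> DataFrame
    summaries: dict = field(default_factory=dict)    # name -> JSON-able dict
    metadata: dict = field(default_factory=dict)

    def hashes(self) -> dict:
        out = {}
        for name, df in self.tables.items():
            csv = df.to_csv(index=False, float_format="%.10g").encode()
            out[name] = hashlib.sha256(csv).hexdigest()
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        report = {"metadata": self.metadata, "hashes": self.hashes(),
                  "summaries": self.summaries}
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, tuple)):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: dict) -> ReportBundle:
    """Run enabled stages in dependency order.

    ``config`` keys (all optional unless noted):

    counts : SiteTable or path to a site-table TSV (required)
    stages : iterable of stage names (default: all)
    seed : int, drives every stochastic step (default 0)
    genome : GenomicFeatureSet for the integrate stage
    outgroup : mapping site_id -> bool outgroup presence (lineage stage)
    preprocess : dict of filter/thinning overrides
    coordination : dict of binning/resampling overrides
    """
    counts = config["counts"]
    table = read_site_table(counts) if not isinstance(counts, SiteTable) else counts
    stages = tuple(config.get("stages", ALL_STAGES))
    seed = int(config.get("seed", 0))
    bundle = ReportBundle(metadata={"seed": seed, "stages": list(stages),
                                    "n_sites_in": len(table)})

    norm, disp, calls = table, None, None

    if "preprocess" in stages:
        p = config.get("preprocess", {})
        filtered = filter_sites(table,
                                min_f0=p.get("min_f0", 10),
                                min_f1_reads=p.get("min_f1_reads", 10),
                                min_f1_reps=p.get("min_f1_reps", 10))
        thinned = thin_sites_by_distance(filtered,
                                         min_spacing=p.get("spacing", 250))
        norm = normalize_counts(thinned)
        disp = estimate_dispersion(norm)
        bundle.tables["normalized_counts"] = norm.data
        bundle.tables["dispersions"] = disp.table
        bundle.summaries["preprocess"] = {
            "n_after_filter": len(filtered), "n_after_thinning": len(thinned),
            "size_factors": dict(norm.size_factors.round(6)),
            "dispersion_trend": {"a0": disp.a0, "a1": disp.a1},
        }

    if "regclass" in stages:
        if disp is None:
            raise ValueError("regclass stage requires preprocess")
        calls = classify_sites(norm, disp)
        bundle.tables["regulatory_calls"] = calls
        bundle.summaries["regclass"] = {
            "class_counts": calls["class"].value_counts().to_dict(),
            "median_delta_bic": float(calls["delta_bic"].median()),
        }

    if "inheritance" in stages:
        if calls is None:
            raise ValueError("inheritance stage requires regclass")
        inh = classify_inheritance(norm, calls, disp)
        bundle.tables["inheritance"] = inh
        if len(inh):
            bundle.summaries["inheritance"] = {
                "mode_counts": inh["mode"].value_counts().to_dict()}

    if "lineage" in stages:
        if calls is None:
            raise ValueError("lineage stage requires regclass")
        lin = classify_lineage(norm, disp, outgroup=config.get("outgroup"),
                               calls=calls)
        bundle.tables["lineage"] = lin
        bundle.summaries["lineage"] = {
            "n_lineage_specific": int((lin["lineage"] != "shared").sum()),
            "mechanism_counts":
                lin.loc[lin["mechanism"] != "", "mechanism"]
                .value_counts().to_dict(),
        }

    if "coordination" in stages:
        if calls is None:
            raise ValueError("coordination stage requires regclass")
        c = config.get("coordination", {})
        props = coord.site_proportions(norm)
        anchor_ids = set(calls.loc[calls["class"] == "cis", "site_id"])
        anchors = props[props["site_id"].isin(anchor_ids)]
        profile = coord.correlation_profile(
            anchors, props, start=c.get("start", 400),
            width=c.get("width", 1000),
            max_distance=c.get("max_distance", 400_000),
            min_pairs=c.get("min_pairs", 20))
        coord.null_profile(profile, props,
                           n_resamples=c.get("resamples", 50), seed=seed)
        bins = profile.bins.merge(profile.null, on="bin_idx")
        bundle.tables["coordination_profile"] = bins
        summary = {"n_anchors": int(len(anchors)),
                   "n_pairs": int(len(profile.pairs))}
        if profile.bins["rho"].notna().sum() >= 3:
            fit = coord.fit_log_decay(profile)
            summary["decay_fit"] = fit
            summary["elbow_bp"] = coord.find_elbow(fit)
        else:
            logger.info("coordination: fewer than 3 populated bins; decay "
                        "fit skipped")
        bundle.summaries["coordination"] = summary

    if "integrate" in stages:
        if calls is None:
            raise ValueError("integrate stage requires regclass")
        genome = config.get("genome")
        classified = norm.data[["site_id", "chrom", "pos"]].merge(
            calls[["site_id", "class"]], on="site_id")
        classified = classified[classified["class"].isin(integ.CLASSES)]
        # cis-extent summary over classified sites
        f0a = norm.matrix("F0_A").mean(axis=1)
        f0b = norm.matrix("F0_B").mean(axis=1)
        f1a = norm.matrix("F1_A").mean(axis=1)
        f1b = norm.matrix("F1_B").mean(axis=1)
        lr0 = np.log2((f0a + 0.5) / (f0b + 0.5))
        lr1 = np.log2((f1a + 0.5) / (f1b + 0.5))
        summary = {"cis_extent": integ.cis_extent_correlation(lr0, lr1)}
        if genome is not None and len(genome.genes):
            gene_table = integ.assign_sites_to_genes(classified, genome.genes)
            bundle.tables["gene_site_counts"] = gene_table
            if "expr_class" in gene_table.columns:
                panel = integ.enrichment_panel(gene_table)
                bundle.tables["expression_enrichment"] = panel
                div = integ.diversity_by_expression_class(gene_table)
                bundle.tables["diversity_tests"] = div["tests"]
            props = classified["class"].value_counts(normalize=True).to_dict()
            for name, regions in (("promoters", genome.promoters),
                                  ("enhancers", genome.enhancers)):
                if len(regions):
                    bundle.tables[f"{name}_enrichment"] = \
                        integ.region_class_enrichment(classified, regions, props)
            if len(genome.interactions):
                bundle.tables["contact_enrichment"] = coord.contact_enrichment(
                    classified, genome.interactions)
        bundle.summaries["integrate"] = summary

    return bundle
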