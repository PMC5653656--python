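"""Cross-layer integration statistics: windows, regressions, exact tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cistrans.integrate as integ
from cistrans.integrate import CLASSES


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestWindowAssignment:
    def test_boundaries_and_strand_mirroring(self):
        sites = pd.DataFrame({
            "site_id": ["in_up", "out_up", "in_minus"],
            "chrom": "chr1",
            "pos": [85_000, 79_999, 115_000],
            "class": ["cis", "cis", "cis"],
        })
        plus = _genes([("g+", "chr1", 100_000, "+")])
        res = integ.assign_sites_to_genes(sites.iloc[:2], plus)
        assert res.loc[0, "n_cis"] == 1          # 15 kb upstream in, 20,001 out
        minus = _genes([("g-", "chr1", 100_000, "-")])
        res = integ.assign_sites_to_genes(sites.iloc[[2]], minus)
        assert res.loc[0, "n_cis"] == 1          # 15 kb upstream on the - strand

    def test_exact_boundary_inclusive(self):
        sites = pd.DataFrame({"site_id": ["edge"], "chrom": "chr1",
                              "pos": [80_000], "class": ["trans"]})
        res = integ.assign_sites_to_genes(sites, _genes([("g", "chr1",
                                                          100_000, "+")]))
        assert res.loc[0, "n_trans"] == 1


class TestLogisticEnrichment:
    def _null_genes(self, rng, n=2000):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "expr_class": rng.choice(CLASSES, n),
            **{f"n_{c}": rng.poisson(2.0, n) for c in CLASSES}})

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(1)
        genes = self._null_genes(rng)
        extra = rng.poisson(3.0, (genes["expr_class"] == "cis").sum())
        genes.loc[genes["expr_class"] == "cis", "n_cis"] += extra
        res = integ.logistic_enrichment(genes, "cis")
        row = res.set_index("predictor").loc["n_cis"]
        assert row["odds_ratio"] > 1 and row["z"] > 2

    def test_constant_predictor_flagged(self):
        rng = np.random.default_rng(2)
        genes = self._null_genes(rng, 200)
        genes["n_trans"] = 1
        res = integ.logistic_enrichment(genes, "cis").set_index("predictor")
        assert not res.loc["n_trans", "estimable"]
        assert res.loc["n_cis", "estimable"]

    def test_mean_centered_panel(self):
        rng = np.random.default_rng(3)
        panel = integ.enrichment_panel(self._null_genes(rng, 400))
        # mean-centered log odds average to 0 per predictor
        centered = np.log(panel.groupby("predictor")["centered_odds_ratio"]
                          .apply(lambda s: np.exp(np.log(s).mean())))
        assert np.allclose(centered, 0.0, atol=1e-10)


class TestChromatinEnrichment:
    def test_planted_mark_site_association(self):
        rng = np.random.default_rng(0)
        n = 400
        pos = np.arange(n) * 50_000
        marks = pd.DataFrame({"mark_id": [f"m{i}" for i in range(n)],
                              "chrom": "chr1", "pos": pos,
                              "class": rng.choice(CLASSES, n)})
        # each +/-2 kb window holds two random-class background sites plus
        # Poisson(2) extra sites of the mark's own class
        rows = []
        for i in range(n):
            rows.append((f"b{i}a", pos[i] - 1_500, rng.choice(CLASSES)))
            rows.append((f"b{i}b", pos[i] + 1_500, rng.choice(CLASSES)))
            for j in range(rng.poisson(2.0)):
                rows.append((f"p{i}_{j}", pos[i] + 300 + j, marks.loc[i, "class"]))
        sites = pd.DataFrame(rows, columns=["site_id", "pos", "class"])
        sites["chrom"] = "chr1"
        panel = integ.chromatin_tf_enrichment(marks, sites)
        diag = panel[panel.apply(
            lambda r: r["predictor"] == f"n_{r['response']}", axis=1)]
        assert (diag["z"] > 2).all()
        assert (diag["odds_ratio"] > 1).all()


class TestConcordance:
    def _layout(self, n, rng):
        tss = np.arange(n) * 100_000 + 50_000
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "chrom": "chr1", "tss": tss,
                              "strand": "+",
                              "expr_class": rng.choice(CLASSES, n)})
        marks = pd.DataFrame({"mark_id": [f"m{i}" for i in range(n)],
                              "chrom": "chr1", "pos": tss - 2_000})
        return genes, marks

    def test_perfect_concordance_small_p(self):
        rng = np.random.default_rng(4)
        genes, marks = self._layout(300, rng)
        marks["class"] = genes["expr_class"].to_numpy()
        res = integ.promoter_mark_gene_concordance(marks, genes)
        pop = res[res["observed"] > 0]
        assert (pop["p_value"] < 1e-6).all()

    def test_independent_labels_uniform_p(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(120):
            genes, marks = self._layout(60, rng)
            marks["class"] = rng.choice(CLASSES, len(marks))
            res = integ.promoter_mark_gene_concordance(marks, genes)
            pvals.extend(res["p_value"].tolist())
        # discrete one-sided p-values: conservative, but not anti-conservative
        assert np.mean(np.asarray(pvals) < 0.05) < 0.08

    def test_single_pair(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": "chr1",
                              "tss": [10_000], "strand": "+",
                              "expr_class": ["cis"]})
        marks = pd.DataFrame({"mark_id": ["m"], "chrom": "chr1",
                              "pos": [8_000], "class": ["cis"]})
        res = integ.promoter_mark_gene_concordance(marks, genes)
        row = res.set_index("class").loc["cis"]
        assert row["n_pairs"] == 1 and row["observed"] == 1
        assert row["p_value"] == pytest.approx(row["expected_p"])


class TestShannon:
    @pytest.mark.parametrize("props,expect", [
        ((1, 0, 0, 0), 0.0),
        ((0.25, 0.25, 0.25, 0.25), math.log(4)),
        ((0.5, 0.5, 0, 0), math.log(2)),
    ])
    def test_identities(self, props, expect):
        assert integ.shannon_diversity(props) == pytest.approx(expect, abs=1e-12)

    def test_bounds_and_max_only_at_uniform(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.dirichlet(np.ones(4))
            h = integ.shannon_diversity(p)
            assert 0 <= h <= math.log(4) + 1e-12
            if h > math.log(4) - 1e-9:
                assert np.allclose(p, 0.25, atol=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            integ.shannon_diversity([-0.1, 0.6, 0.5, 0.0])


class TestDiversityByClass:
    def _gene_table(self, rng, n=400, planted=False):
        gt = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                           "expr_class": rng.choice(CLASSES, n)})
        for c in CLASSES:
            gt[f"n_{c}"] = rng.poisson(1.0, n)
        if planted:
            ct = gt["expr_class"] == "cis_trans"
            for c in CLASSES:
                gt.loc[ct, f"n_{c}"] = rng.poisson(3.0, int(ct.sum()))
            cons = gt["expr_class"] == "conserved"
            gt.loc[cons, [f"n_{c}" for c in CLASSES]] = 0
            gt.loc[cons, "n_conserved"] = rng.poisson(4.0, int(cons.sum())) + 1
        return gt

    def test_single_site_gene_has_zero_diversity(self):
        gt = pd.DataFrame({"gene_id": ["g"], "expr_class": ["cis"],
                           "n_conserved": [0], "n_cis": [1], "n_trans": [0],
                           "n_cis_trans": [0]})
        res = integ.diversity_by_expression_class(gt)
        assert res["diversity"]["H"].iloc[0] == 0.0

    def test_planted_high_diversity_detected(self):
        rng = np.random.default_rng(7)
        res = integ.diversity_by_expression_class(
            self._gene_table(rng, 500, planted=True))
        row = res["tests"]
        hit = row[((row["class_a"] == "conserved") & (row["class_b"] == "cis_trans"))
                  | ((row["class_a"] == "cis_trans") & (row["class_b"] == "conserved"))]
        assert (hit["p_value"] < 0.05).all()


class TestExpressionMatching:
    def _genes(self, rng, n=500):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "expr_class": rng.choice(["cis", "conserved"], n),
            "expr_f0_a": rng.lognormal(3, 1, n),
            "expr_f0_b": rng.lognormal(3, 1, n)})

    def test_bin_histograms_match_and_deterministic(self):
        rng = np.random.default_rng(8)
        genes = self._genes(rng)
        r1 = integ.expression_matched_subsample(genes, "cis", "conserved", seed=5)
        r2 = integ.expression_matched_subsample(genes, "cis", "conserved", seed=5)
        pd.testing.assert_frame_equal(r1["matched"], r2["matched"])
        expr = lambda df: np.log(df[["expr_f0_a", "expr_f0_b"]].max(axis=1))
        h_t = np.histogram(expr(r1["target"]), bins=r1["bin_edges"])[0]
        h_m = np.histogram(expr(r1["matched"]), bins=r1["bin_edges"])[0]
        assert (h_t == h_m).all()

    def test_empty_reference_bin_drops_targets(self):
        rng = np.random.default_rng(9)
        genes = self._genes(rng, 300)
        # remove reference genes from the top half of the expression range
        expr = np.log(genes[["expr_f0_a", "expr_f0_b"]].max(axis=1))
        drop = (genes["expr_class"] == "conserved") & (expr > expr.median())
        res = integ.expression_matched_subsample(genes[~drop], "cis",
                                                 "conserved", seed=0)
        assert res["n_dropped"] > 0


class TestColocation:
    def test_product_formula(self):
        rng = np.random.default_rng(10)
        calls = pd.DataFrame({a: rng.choice(["cis", "trans"], 400, p=[0.5, 0.5])
                              for a in ("TF1", "TF2", "TF3")})
        res = integ.colocation_shared_class_test(calls).set_index("class")
        assert res.loc["cis", "expected_p"] == pytest.approx(
            np.prod([(calls[a] == "cis").mean() for a in calls]), rel=1e-12)

    def test_always_agreeing_assays_tiny_p(self):
        rng = np.random.default_rng(11)
        shared = rng.choice(CLASSES, 300)
        calls = pd.DataFrame({a: shared for a in ("TF1", "TF2", "TF3")})
        res = integ.colocation_shared_class_test(calls)
        pop = res[(res["expected_p"] > 0) & (res["expected_p"] < 1)]
        assert (pop["p_value"] < 1e-10).all()

    def test_permutation_null_calibrated(self):
        rng = np.random.default_rng(12)
        hits = total = 0
        for _ in range(200):
            calls = pd.DataFrame({a: rng.choice(CLASSES, 150)
                                  for a in ("TF1", "TF2", "TF3")})
            res = integ.colocation_shared_class_test(calls)
            hits += int((res["p_value"] < 0.05).sum())
            total += len(res)
        assert hits / total < 0.08   # one-sided discrete test: conservative


class TestRegionEnrichment:
    def _sites(self, classes, pos):
        return pd.DataFrame({"site_id": range(len(classes)), "chrom": "chr1",
                             "pos": pos, "class": classes})

    def test_or_formula_hand_example(self):
        sites = self._sites(["cis"] * 50 + ["trans"] * 50, np.arange(100) * 10)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        res = integ.region_class_enrichment(sites, regions, {"cis": 0.25})
        row = res.set_index("class").loc["cis"]
        assert row["k"] == 50 and row["n_in_regions"] == 100
        assert row["odds_ratio"] == pytest.approx(3.0)

    def test_expectation_met_gives_or_one(self):
        sites = self._sites(["cis"] * 25 + ["trans"] * 75, np.arange(100) * 10)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        res = integ.region_class_enrichment(sites, regions, {"cis": 0.25})
        row = res.set_index("class").loc["cis"]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_zero_hits_binomial_tail(self):
        sites = self._sites(["trans"] * 100, np.arange(100) * 10)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        res = integ.region_class_enrichment(sites, regions, {"cis": 0.25})
        row = res.set_index("class").loc["cis"]
        expect = float(stats.binomtest(0, 100, 0.25).pvalue)
        assert row["p_value"] == pytest.approx(expect, rel=1e-9)

    def test_agrees_with_enumeration_oracle_small_n(self):
        # brute-force two-sided exact binomial for n <= 30
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(5, 31))
            p = float(rng.uniform(0.1, 0.9))
            k = int(rng.integers(0, n + 1))
            pmf = np.array([math.comb(n, i) * p ** i * (1 - p) ** (n - i)
                            for i in range(n + 1)])
            brute = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
            sites = self._sites(["cis"] * k + ["trans"] * (n - k),
                                np.arange(n) * 10)
            regions = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                    "end": [10 * n]})
            res = integ.region_class_enrichment(sites, regions, {"cis": p})
            row = res.set_index("class").loc["cis"]
            assert row["p_value"] == pytest.approx(min(brute, 1.0), rel=1e-6)


class TestCisExtent:
    def test_identity_and_permutation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 500)
        res = integ.cis_extent_correlation(x, x)
        assert res["r"] == pytest.approx(1.0)
        perm = integ.cis_extent_correlation(x, rng.permutation(x))
        assert abs(perm["r"]) < 3 / math.sqrt(500)

    def test_cis_fraction_monotonicity(self):
        rng = np.random.default_rng(15)

        def mixture(frac_cis, n=800):
            f0 = rng.normal(0, 1, n)
            cis = rng.random(n) < frac_cis
            f1 = np.where(cis, f0 + rng.normal(0, 0.2, n),
                          rng.normal(0, 0.2, n))
            return integ.cis_extent_correlation(f0, f1)["r"]

        assert mixture(0.9) > mixture(0.5)


class TestMagnitudeComparison:
    def test_extremes_and_determinism(self):
        assert integ.compare_cis_effect_magnitude([1.0] * 5, [0.0] * 5,
                                                  1000, seed=0) == 1.0
        rng = np.random.default_rng(16)
        m = rng.exponential(1, 300)
        f1 = integ.compare_cis_effect_magnitude(m, m, 10_000, seed=3)
        f2 = integ.compare_cis_effect_magnitude(m, m, 10_000, seed=3)
        assert f1 == f2
        assert abs(f1 - 0.5) < 3 / math.sqrt(10_000) + 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            integ.compare_cis_effect_magnitude([], [1.0])


class TestDirectionConcordance:
    def test_concordant_and_anticoncordant(self):
        x = np.linspace(-2, 2, 40)
        x = x[x != 0]
        res = integ.direction_concordance(x, x)
        assert res["agreement"] == 1.0 and res["rho"] == pytest.approx(1.0)
        anti = integ.direction_concordance(x, -x)
        assert anti["agreement"] == 0.0 and anti["rho"] == pytest.approx(-1.0)

    def test_independent_signs_near_half(self):
        rng = np.random.default_rng(17)
        res = integ.direction_concordance(rng.normal(0, 1, 2000),
                                          rng.normal(0, 1, 2000))
        assert abs(res["agreement"] - 0.5) < 0.05
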