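"""Distance-decay profiles, nulls, regression, elbow and contact enrichment."""

import numpy as np
import pandas as pd
import pytest

from cistrans import coordination as coord
from conftest import make_site


class TestAllelicProportion:
    def test_extremes_and_mean_of_replicates(self):
        assert coord.allelic_proportion(
            make_site([1], [1], [10, 10], [0, 0])) == 1.0
        assert coord.allelic_proportion(
            make_site([1], [1], [5, 5], [5, 5])) == 0.5
        # replicates (3/10, 7/10) -> mean of proportions = 0.5
        assert coord.allelic_proportion(
            make_site([1], [1], [3, 7], [7, 3])) == pytest.approx(0.5)

    def test_zero_total_is_nan(self):
        assert np.isnan(coord.allelic_proportion(
            make_site([1], [1], [0, 0], [0, 0])))


def _frame(ids, pos, props, chrom="chr1"):
    return pd.DataFrame({"site_id": ids, "chrom": chrom, "pos": pos,
                         "prop": props})


class TestProfile:
    def test_duplicated_anchors_give_rho_one(self):
        rng = np.random.default_rng(0)
        n = 60
        props = rng.uniform(0.2, 0.8, n)
        anchors = _frame([f"a{i}" for i in range(n)],
                         np.arange(n) * 1_000_000, props)
        # partner sites: copies of each anchor at offsets within a few bins
        sats = _frame([f"s{i}" for i in range(n)],
                      np.arange(n) * 1_000_000 + 1500, props)
        prof = coord.correlation_profile(anchors, sats, min_pairs=10)
        pop = prof.bins.dropna(subset=["rho"])
        assert len(pop) >= 1
        assert np.allclose(pop["rho"], 1.0)

    def test_bin_partition_is_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(1)
        anchors = _frame(["a0"], [1_000_000], [0.5])
        offs = rng.integers(400, 50_000, 500)
        sats = _frame([f"s{i}" for i in range(500)], 1_000_000 + offs,
                      rng.uniform(0, 1, 500))
        prof = coord.correlation_profile(anchors, sats, min_pairs=1)
        # every pair within range lands in exactly one bin
        assert len(prof.pairs) == 500
        assert prof.pairs["bin_idx"].between(0, len(prof.bins) - 1).all()
        for _, row in prof.pairs.iterrows():
            b = prof.bins.iloc[row["bin_idx"]]
            assert b["d_lo"] <= row["distance"] < b["d_hi"]

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        n = 80
        props = rng.uniform(0.1, 0.9, n)
        anchors = _frame([f"a{i}" for i in range(n)],
                         np.arange(n) * 500_000, props)
        sats = _frame([f"s{i}" for i in range(n)],
                      np.arange(n) * 500_000 + 2_000,
                      np.clip(props + rng.normal(0, 0.05, n), 0, 1))
        p1 = coord.correlation_profile(anchors, sats, min_pairs=10)
        flip = lambda df: df.assign(prop=1 - df["prop"])
        p2 = coord.correlation_profile(flip(anchors), flip(sats), min_pairs=10)
        pd.testing.assert_series_equal(p1.bins["rho"], p2.bins["rho"])

    def test_no_anchors_empty_profile(self):
        sites = _frame(["s0"], [100], [0.5])
        prof = coord.correlation_profile(sites.iloc[:0], sites)
        assert prof.pairs.empty
        assert prof.bins["rho"].isna().all()


class TestNull:
    def test_null_centered_at_zero_and_deterministic(self):
        rng = np.random.default_rng(3)
        n = 100
        anchors = _frame([f"a{i}" for i in range(n)],
                         np.arange(n) * 500_000, rng.uniform(0, 1, n))
        sats = _frame([f"s{i}" for i in range(n)],
                      np.arange(n) * 500_000 + 1_000, rng.uniform(0, 1, n))
        prof = coord.correlation_profile(anchors, sats, min_pairs=10)
        null1 = coord.null_profile(prof, sats, n_resamples=50, seed=7)
        pop = null1.dropna(subset=["null_mean"])
        assert (pop["null_mean"].abs() < 0.15).all()
        null2 = coord.null_profile(prof, sats, n_resamples=50, seed=7)
        pd.testing.assert_frame_equal(null1, null2)

    def test_empty_observed_bin_gives_empty_null_bin(self):
        anchors = _frame(["a0"], [1_000_000], [0.5])
        sats = _frame(["s0"], [1_000_500], [0.5])
        prof = coord.correlation_profile(anchors, sats, min_pairs=1)
        null = coord.null_profile(prof, sats, n_resamples=5, seed=0)
        empty_bins = prof.bins.loc[prof.bins["n_pairs"] == 0, "bin_idx"]
        assert null.set_index("bin_idx").loc[empty_bins, "null_mean"].isna().all()


class TestDecayFit:
    def _profile_from(self, d, rho):
        bins = pd.DataFrame({"bin_idx": range(len(d)), "d_lo": d, "d_hi": d,
                             "d_mid": d, "n_pairs": 100, "rho": rho})
        return coord.CoordinationProfile(bins=bins, pairs=pd.DataFrame(),
                                         start=400, width=1000,
                                         max_distance=400_000, min_pairs=20)

    def test_exact_log_linear_recovery(self):
        d = np.array([1e3, 2e3, 5e3, 1e4, 5e4, 1e5])
        rho = 0.8 - 0.07 * np.log(d)
        fit = coord.fit_log_decay(self._profile_from(d, rho))
        assert fit["slope"] == pytest.approx(-0.07, abs=1e-12)
        assert fit["intercept"] == pytest.approx(0.8, abs=1e-10)

    def test_flat_profile_ci_contains_zero(self):
        rng = np.random.default_rng(4)
        d = np.geomspace(1e3, 4e5, 30)
        fit = coord.fit_log_decay(self._profile_from(d, 0.1 + rng.normal(0, 0.01, 30)))
        lo, hi = fit["slope_ci"]
        assert lo < 0 < hi

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError, match="3 populated bins"):
            coord.fit_log_decay(self._profile_from(np.array([1e3, 2e3]),
                                                   np.array([0.5, 0.4])))


class TestElbow:
    def test_straight_line_returns_none(self):
        x = np.linspace(1e3, 5e4, 100)
        assert coord._elbow_of_curve(x, 2.0 - 1e-5 * x) is None

    def test_piecewise_knee_near_break(self):
        x = np.linspace(1e3, 5e4, 491)  # 100 bp grid
        y = np.where(x < 10_000, 1.0 - (x - 1e3) / 9e3 * 0.9, 0.1)
        elbow = coord._elbow_of_curve(x, y)
        assert abs(elbow - 10_000) <= 200

    def test_matches_bruteforce_on_curve_suite(self):
        """Oracle equivalence: independent perpendicular-distance scan."""
        def brute(x, y):
            xn = (x - x.min()) / np.ptp(x)
            yn = (y - y.min()) / np.ptp(y)
            best_i, best_d = None, -1.0
            for i in range(len(x)):
                # distance from point to the chord through first/last points
                num = abs((yn[-1] - yn[0]) * xn[i] - (xn[-1] - xn[0]) * yn[i]
                          + xn[-1] * yn[0] - yn[-1] * xn[0])
                den = np.hypot(xn[-1] - xn[0], yn[-1] - yn[0])
                d = num / den
                if d > best_d:
                    best_i, best_d = i, d
            return None if best_d < 1e-9 else float(x[best_i])

        rng = np.random.default_rng(5)
        x = np.linspace(1e3, 5e4, 200)
        curves = [0.9 - 0.08 * np.log(x)]
        for k in range(19):
            a = rng.uniform(0.2, 1.0)
            b = rng.uniform(0.01, 0.2)
            scale = rng.uniform(2e3, 3e4)
            curves.append(a * np.exp(-x / scale) + b * rng.standard_normal(len(x)) * 0.01)
        for y in curves:
            assert coord._elbow_of_curve(x, y) == brute(x, y)


class TestContactEnrichment:
    def _sites(self, classes, pos0=0, step=10_000):
        return pd.DataFrame({
            "site_id": [f"s{i}" for i in range(len(classes))],
            "chrom": "chr1",
            "pos": pos0 + np.arange(len(classes)) * step,
            "class": classes,
        })

    def test_no_overlap_reports_no_test(self):
        sites = self._sites(["cis"] * 5)
        ends = pd.DataFrame({"chrom1": ["chr2"], "start1": [0], "end1": [100],
                             "chrom2": ["chr2"], "start2": [500], "end2": [600]})
        res = coord.contact_enrichment(sites, ends)
        assert (res["observed"] == 0).all()
        assert res["p_value"].isna().all()

    def test_planted_cis_anchors_enriched(self):
        rng = np.random.default_rng(6)
        sites = self._sites(list(rng.choice(["conserved", "trans"], 200)))
        cis = pd.DataFrame({"site_id": [f"c{i}" for i in range(40)],
                            "chrom": "chr1",
                            "pos": 5_000_000 + np.arange(40) * 10_000,
                            "class": "cis"})
        all_sites = pd.concat([sites, cis], ignore_index=True)
        # 40 interactions planted exactly on cis sites at both ends, plus 80
        # on empty genomic background so the cis marginal rate stays < 1
        bg = 20_000_000 + np.arange(160) * 7_000
        ends = pd.DataFrame({
            "chrom1": "chr1",
            "start1": np.r_[cis["pos"] - 50, bg[:80] - 50],
            "end1": np.r_[cis["pos"] + 50, bg[:80] + 50],
            "chrom2": "chr1",
            "start2": np.r_[cis["pos"].iloc[::-1].to_numpy() - 50, bg[80:] - 50],
            "end2": np.r_[cis["pos"].iloc[::-1].to_numpy() + 50, bg[80:] + 50]})
        res = coord.contact_enrichment(all_sites, ends)
        row = res[(res["class_a"] == "cis") & (res["class_b"] == "cis")].iloc[0]
        assert row["enrichment"] > 1
        assert row["p_value"] < 0.01

    def test_permuted_labels_near_unit_enrichment(self):
        rng = np.random.default_rng(7)
        n = 400
        sites = self._sites(list(rng.choice(["cis", "conserved"], n)), step=5_000)
        a = rng.integers(0, n // 2, 150) * 5_000
        b = rng.integers(n // 2, n, 150) * 5_000
        ends = pd.DataFrame({"chrom1": "chr1", "start1": a - 100, "end1": a + 100,
                             "chrom2": "chr1", "start2": b - 100, "end2": b + 100})
        res = coord.contact_enrichment(sites, ends)
        ok = res.dropna(subset=["enrichment"])
        assert ((ok["enrichment"] > 0.5) & (ok["enrichment"] < 2.0)).mean() >= 0.75
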