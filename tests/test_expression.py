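import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netspread as ns
from netspread.expression import SEGMENT_QC_THRESHOLDS, qc_genes


def seg_row(trimmed=85, stitched=85, aligned=80, saturation=60, loq=5):
    return dict(
        trimmed_pct=trimmed, stitched_pct=stitched, aligned_pct=aligned,
        saturation_pct=saturation, pct_genes_above_loq=loq,
    )


class TestSegmentQC:
    def test_all_above_thresholds_kept(self):
        kept, removed = ns.qc_segments(pd.DataFrame([seg_row()]))
        assert len(kept) == 1 and len(removed) == 0

    def test_trimmed_below_80_removed_with_reason(self):
        kept, removed = ns.qc_segments(pd.DataFrame([seg_row(trimmed=79)]))
        assert len(kept) == 0
        assert removed["reason"].iloc[0] == "trimmed"

    def test_exactly_at_threshold_kept(self):
        row = seg_row(trimmed=80, stitched=80, aligned=75, saturation=50, loq=3)
        kept, removed = ns.qc_segments(pd.DataFrame([row]))
        assert len(kept) == 1

    def test_one_violation_per_rule(self):
        """Five segments, each failing exactly one rule, in evaluation order."""
        table = pd.DataFrame([
            seg_row(trimmed=79),
            seg_row(stitched=79),
            seg_row(aligned=74),
            seg_row(saturation=49),
            seg_row(loq=2),
        ])
        kept, removed = ns.qc_segments(table)
        assert len(kept) == 0 and len(removed) == 5
        assert list(removed["reason"]) == [
            "trimmed", "stitched", "aligned", "saturation", "loq",
        ]

    def test_first_failing_reason_wins(self):
        kept, removed = ns.qc_segments(pd.DataFrame([seg_row(trimmed=10, loq=0)]))
        assert removed["reason"].iloc[0] == "trimmed"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing metric"):
            ns.qc_segments(pd.DataFrame([{"trimmed_pct": 90}]))

    def test_removal_count_equals_union_of_failures(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame([
            seg_row(*rng.uniform(40, 100, 4), rng.uniform(0, 10)) for _ in range(50)
        ])
        kept, removed = ns.qc_segments(table)
        fails = np.zeros(len(table), dtype=bool)
        for c, thr in SEGMENT_QC_THRESHOLDS.items():
            fails |= table[c].to_numpy() < thr
        assert len(removed) == fails.sum()
        assert len(kept) + len(removed) == len(table)


class TestGrubbs:
    def grubbs_expected(self, x, alpha):
        """Direct evaluation of the stated critical-value formula."""
        n = len(x)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))

    def test_constant_vector_degenerate(self):
        res = ns.grubbs_test(np.ones(5))
        assert res.outlier_index is None and res.degenerate

    def test_symmetric_three_point_no_outlier(self):
        x = np.array([-1.0, 0.0, 1.0])
        res = ns.grubbs_test(x, alpha=0.01)
        assert res.G == pytest.approx(1.0)  # max deviation / sample sd
        assert res.G_critical == pytest.approx(self.grubbs_expected(x, 0.01))
        assert res.outlier_index is None

    def test_planted_extreme_flagged(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 50.0])
        res = ns.grubbs_test(x, alpha=0.01)
        expected_G = np.abs(x - x.mean()).max() / x.std(ddof=1)
        assert res.G == pytest.approx(expected_G)
        assert res.G_critical == pytest.approx(self.grubbs_expected(x, 0.01))
        assert res.outlier_index == 4

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ns.grubbs_test(np.array([1.0, 2.0]))


class TestGeneQC:
    def build_counts(self, rng, n_genes=30, n_seg=200):
        counts = pd.DataFrame(
            rng.poisson(100, size=(n_genes, n_seg)).astype(float),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_seg)],
        )
        for k in range(3):
            counts.loc[f"NEG{k}"] = rng.poisson(10, size=n_seg).astype(float)
        return counts

    def test_undetected_gene_removed_as_loq(self):
        rng = np.random.default_rng(1)
        counts = self.build_counts(rng)
        counts.loc["G0"] = 0.0
        kept, ledger = qc_genes(counts, [f"NEG{k}" for k in range(3)])
        assert "G0" not in kept
        assert ledger.set_index("gene").loc["G0", "reason"] == "LOQ"

    def test_boundary_detection_fraction_kept(self):
        """Detected in exactly ceil(1% of segments) -> kept by the LOQ rule."""
        rng = np.random.default_rng(2)
        counts = self.build_counts(rng, n_seg=200)
        counts.loc["G1"] = 0.0
        counts.loc["G1", ["s0", "s1"]] = 1e6  # 2/200 = exactly 1%
        kept, ledger = qc_genes(counts, [f"NEG{k}" for k in range(3)])
        reasons = dict(zip(ledger["gene"], ledger["reason"]))
        assert reasons.get("G1") != "LOQ"

    def test_planted_global_outlier_removed(self):
        rng = np.random.default_rng(3)
        counts = self.build_counts(rng)
        counts.loc["G5"] = 1e7  # extreme pooled expression across all segments
        kept, ledger = qc_genes(counts, [f"NEG{k}" for k in range(3)])
        assert "G5" not in kept
        assert ledger.set_index("gene").loc["G5", "reason"] == "global_grubbs"

    def test_keep_list_exempts_gene_from_qc(self):
        """A-priori genes are retained regardless of QC performance."""
        rng = np.random.default_rng(11)
        counts = self.build_counts(rng)
        counts.loc["G0"] = 0.0
        kept, ledger = qc_genes(counts, [f"NEG{k}" for k in range(3)],
                                keep_genes=["G0"])
        assert "G0" in kept
        assert "G0" not in set(ledger["gene"])

    def test_negative_counts_rejected(self):
        rng = np.random.default_rng(4)
        counts = self.build_counts(rng)
        counts.iloc[0, 0] = -1
        with pytest.raises(ValueError, match="negative"):
            qc_genes(counts, [f"NEG{k}" for k in range(3)])

    def test_no_negative_probes_rejected(self):
        with pytest.raises(ValueError, match="negative-probe"):
            qc_genes(pd.DataFrame(np.ones((2, 2))), [])


class TestSigmoidScale:
    def test_min_zero_max_one(self):
        out = ns.sigmoid_scale(np.array([3.0, -1.0, 7.0, 2.0]))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_strictly_order_preserving(self):
        x = np.array([0.0, 0.5, 2.0, 10.0])
        out = ns.sigmoid_scale(x)
        assert np.all(np.diff(out) > 0)

    def test_symmetric_three_point_midpoint_half(self):
        out = ns.sigmoid_scale(np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0], atol=1e-12)

    def test_constant_returns_half(self):
        np.testing.assert_array_equal(ns.sigmoid_scale(np.full(4, 2.0)), 0.5)


class TestRankInverseNormal:
    def test_middle_of_three_is_zero(self):
        z = ns.rank_inverse_normal(np.array([5.0, 1.0, 9.0]))
        assert z[0] == pytest.approx(0.0, abs=1e-12)

    def test_blom_extremes_for_n3(self):
        z = ns.rank_inverse_normal(np.array([1.0, 2.0, 3.0]))
        expected = stats.norm.ppf((3 - 3 / 8) / 3.25)
        assert z[2] == pytest.approx(expected)
        assert z[0] == pytest.approx(-expected)
        assert abs(expected) == pytest.approx(0.8694, abs=5e-4)

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        z = ns.rank_inverse_normal(x)
        assert np.array_equal(np.argsort(x), np.argsort(z))

    def test_mean_near_zero_sd_near_one(self):
        rng = np.random.default_rng(6)
        z = ns.rank_inverse_normal(rng.standard_normal(200))
        assert abs(z.mean()) < 1e-8
        assert z.std(ddof=1) == pytest.approx(1.0, rel=0.05)

    def test_all_tied_maps_to_zeros(self):
        np.testing.assert_array_equal(ns.rank_inverse_normal(np.full(5, 3.0)), 0.0)

    def test_sigmoid_then_rint_equals_rint_alone(self):
        """Both are rank functions: the sigmoid is order-irrelevant."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        a = ns.rank_inverse_normal(ns.sigmoid_scale(x))
        b = ns.rank_inverse_normal(x)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestGeneVulnerabilityCorrelation:
    def make_inputs(self, n_regions=30, seed=8):
        rng = np.random.default_rng(seed)
        regions = [f"r{i}" for i in range(n_regions)]
        vuln = pd.Series(rng.standard_normal(n_regions), index=regions)
        atlas = pd.DataFrame(
            rng.standard_normal((5, n_regions)), columns=regions,
            index=[f"g{i}" for i in range(5)],
        )
        return atlas, vuln

    def test_gene_equal_to_vulnerability_r_one(self):
        atlas, vuln = self.make_inputs()
        atlas.loc["g0"] = vuln.values
        out = ns.gene_vulnerability_correlation(atlas, vuln)
        assert out.loc["g0", "r"] == pytest.approx(1.0)
        assert out.loc["g0", "p"] < 1e-20

    def test_constant_gene_flagged_excluded(self):
        atlas, vuln = self.make_inputs()
        atlas.loc["g1"] = 5.0
        out = ns.gene_vulnerability_correlation(atlas, vuln)
        assert out.loc["g1", "constant"]
        assert np.isnan(out.loc["g1", "r"]) and np.isnan(out.loc["g1", "q"])

    def test_bh_hand_computation(self):
        """BH on [0.01, 0.02, 0.03, 0.5] gives [0.04, 0.04, 0.04, 0.5]."""
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_q_monotone_in_p_rank(self):
        atlas, vuln = self.make_inputs(seed=9)
        out = ns.gene_vulnerability_correlation(atlas, vuln).dropna(subset=["q"])
        s = out.sort_values("p")
        assert np.all(np.diff(s["q"].to_numpy()) >= -1e-15)
        assert ((out["q"] >= 0) & (out["q"] <= 1)).all()

    def test_too_few_shared_regions_rejected(self):
        atlas, vuln = self.make_inputs()
        with pytest.raises(ValueError, match="shared"):
            ns.gene_vulnerability_correlation(atlas[atlas.columns[:3]], vuln)

    def test_matches_scipy_pearson(self):
        atlas, vuln = self.make_inputs(seed=10)
        out = ns.gene_vulnerability_correlation(atlas, vuln)
        g = ns.rank_inverse_normal(ns.sigmoid_scale(atlas.loc["g2"].to_numpy()))
        v = ns.rank_inverse_normal(vuln.to_numpy())
        r, p = stats.pearsonr(g, v)
        assert out.loc["g2", "r"] == pytest.approx(r, abs=1e-12)
        assert out.loc["g2", "p"] == pytest.approx(p, rel=1e-9)


class TestKinaseFilter:
    def make_assoc(self):
        return pd.DataFrame(
            {
                "r": [0.8, 0.7, -0.6, 0.5, 0.9],
                "q": [0.01, 0.01, 0.01, 0.20, 0.01],
            },
            index=["K1", "K2", "K3", "K4", "NOTKIN"],
        )

    def test_significant_positive_de_kinase_retained(self):
        hits = ns.kinase_filter(self.make_assoc(), ["K1", "K2", "K3", "K4"], ["K1"])
        assert hits == ["K1"]

    def test_not_in_de_list_dropped(self):
        hits = ns.kinase_filter(self.make_assoc(), ["K2"], ["K1"])
        assert hits == []

    def test_ordering_by_r_descending(self):
        hits = ns.kinase_filter(
            self.make_assoc(), ["K1", "K2"], ["K1", "K2"]
        )
        assert hits == ["K1", "K2"]

    def test_negative_direction(self):
        hits = ns.kinase_filter(
            self.make_assoc(), ["K1", "K3"], ["K1", "K3"], direction="negative"
        )
        assert hits == ["K3"]

    def test_empty_intersection_no_error(self):
        assert ns.kinase_filter(self.make_assoc(), ["ZZZ"], ["K1"]) == []
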