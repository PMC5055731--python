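import math

import numpy as np
import pandas as pd
import pytest

from metharray.dhs import (
    PROBE_POSITIONING,
    TECHNICAL_ARTIFACT,
    UNCLASSIFIED,
    classify_disagreements,
    cross_platform_concordance,
    methylation_status,
    methylation_vs_dhs,
    region_methylation_array,
    region_methylation_wgbs,
    select_regions,
)
from metharray.errors import IntegrityError
from metharray.manifest import Manifest, ProbeRecord


def regions_df(rows):
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def counts_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "methylated", "total"])


def probe_at(pid, chrom, pos):
    return ProbeRecord(pid, "II", chrom, pos, "+", "A" * 49 + "R", None)


class TestStatus:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, "low"), (0.3, "low"), (0.30001, "mid"), (0.6, "mid"), (0.61, "high"), (1.0, "high")],
    )
    def test_thresholds(self, beta, expected):
        assert methylation_status(beta) == expected


class TestSelectRegions:
    def test_two_cpgs_excluded_at_default(self):
        regs = regions_df([("r1", "chr1", 100, 200)])
        cpgs = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [110, 120]})
        assert len(select_regions(regs, cpgs)) == 0

    def test_three_cpgs_retained(self):
        regs = regions_df([("r1", "chr1", 100, 200)])
        cpgs = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [110, 120, 130]})
        out = select_regions(regs, cpgs)
        assert list(out["region_id"]) == ["r1"]
        assert out["n_cpgs"].iloc[0] == 3

    def test_min_zero_retains_catalog(self, dataset):
        regs = dataset.annotation["dhs_distal"]
        out = select_regions(regs, dataset.cpg_positions, min_cpgs=0)
        assert len(out) == len(regs)

    def test_equals_brute_force_counting(self, dataset):
        regs = dataset.annotation["dhs_distal"]
        out = select_regions(regs, dataset.cpg_positions, min_cpgs=3)
        cpg = dataset.cpg_positions
        brute = set()
        for r in regs.itertuples(index=False):
            n = sum(
                1
                for row in cpg.itertuples(index=False)
                if row.chrom == r.chrom and r.start <= row.start < r.end
            )
            if n >= 3:
                brute.add(r.region_id)
        assert set(out["region_id"]) == brute


class TestWgbsRegions:
    def test_pooled_ratio_not_mean_of_ratios(self):
        counts = counts_df(
            [("chr1", 110, 112, 3, 4), ("chr1", 150, 152, 1, 4)]
        )
        regs = regions_df([("r1", "chr1", 100, 200)])
        out = region_methylation_wgbs(counts, regs, min_region_cov=5)
        assert out.loc["r1", "mean_beta"] == pytest.approx(0.5)
        assert out.loc["r1", "total_coverage"] == 8

    def test_fully_methylated_is_high(self):
        counts = counts_df([("chr1", 110, 112, 60, 60)])
        regs = regions_df([("r1", "chr1", 100, 200)])
        out = region_methylation_wgbs(counts, regs)
        assert out.loc["r1", "mean_beta"] == 1.0
        assert out.loc["r1", "status"] == "high"
        assert bool(out.loc["r1", "informative"])

    def test_zero_observations_no_division_error(self):
        regs = regions_df([("r1", "chr1", 100, 200)])
        out = region_methylation_wgbs(counts_df([]), regs)
        assert not bool(out.loc["r1", "informative"])
        assert math.isnan(out.loc["r1", "mean_beta"])

    def test_pooled_equals_coverage_weighted_mean(self):
        """Algebraic identity on random counts."""
        rng = np.random.default_rng(0)
        total = rng.integers(1, 40, size=30)
        meth = rng.binomial(total, 0.4)
        counts = counts_df(
            [("chr1", 100 + 2 * i, 102 + 2 * i, int(m), int(t))
             for i, (m, t) in enumerate(zip(meth, total))]
        )
        regs = regions_df([("r1", "chr1", 0, 1000)])
        out = region_methylation_wgbs(counts, regs)
        weighted = np.sum((meth / total) * total) / total.sum()
        assert out.loc["r1", "mean_beta"] == pytest.approx(weighted, abs=1e-12)

    def test_binomial_interval_on_synthetic_region(self):
        """true_m = 0.2 at pooled coverage 200: estimate within the 99 %
        closed-form binomial interval."""
        rng = np.random.default_rng(1)
        total = np.full(10, 20)
        meth = rng.binomial(total, 0.2)
        counts = counts_df(
            [("chr1", 100 + 2 * i, 102 + 2 * i, int(m), int(t))
             for i, (m, t) in enumerate(zip(meth, total))]
        )
        regs = regions_df([("r1", "chr1", 0, 1000)])
        out = region_methylation_wgbs(counts, regs)
        half_width = 2.576 * math.sqrt(0.2 * 0.8 / 200)
        assert abs(out.loc["r1", "mean_beta"] - 0.2) < half_width

    def test_raising_min_cov_shrinks_informative_set(self, dataset):
        regs = select_regions(
            dataset.annotation["dhs_distal"], dataset.cpg_positions, min_cpgs=3
        )
        informative = [
            set(
                region_methylation_wgbs(dataset.wgbs, regs, min_region_cov=c)
                .query("informative")
                .index
            )
            for c in (10, 50, 200, 1000)
        ]
        for bigger, smaller in zip(informative, informative[1:]):
            assert smaller <= bigger


class TestArrayRegions:
    def test_single_probe_low(self):
        m = Manifest("t", {"cg1": probe_at("cg1", "chr1", 150)})
        beta = pd.Series({"cg1": 0.25})
        regs = regions_df([("r1", "chr1", 100, 300)])
        out = region_methylation_array(beta, m, regs)
        assert out.loc["r1", "mean_beta"] == pytest.approx(0.25)
        assert out.loc["r1", "status"] == "low"

    def test_two_probes_average_to_mid(self):
        m = Manifest(
            "t",
            {"cg1": probe_at("cg1", "chr1", 150), "cg2": probe_at("cg2", "chr1", 160)},
        )
        beta = pd.Series({"cg1": 0.2, "cg2": 0.8})
        regs = regions_df([("r1", "chr1", 100, 300)])
        out = region_methylation_array(beta, m, regs)
        assert out.loc["r1", "mean_beta"] == pytest.approx(0.5)
        assert out.loc["r1", "status"] == "mid"

    def test_failing_detection_probe_excluded(self):
        m = Manifest(
            "t",
            {"cg1": probe_at("cg1", "chr1", 150), "cg2": probe_at("cg2", "chr1", 160)},
        )
        beta = pd.Series({"cg1": 0.2, "cg2": 0.8})
        detection = pd.Series({"cg1": 0.001, "cg2": 0.5})
        regs = regions_df([("r1", "chr1", 100, 300)])
        out = region_methylation_array(beta, m, regs, detection_p=detection)
        assert out.loc["r1", "mean_beta"] == pytest.approx(0.2)
        assert out.loc["r1", "n_used"] == 1

    def test_no_probe_not_informative(self):
        m = Manifest("t", {"cg1": probe_at("cg1", "chr1", 999_000)})
        beta = pd.Series({"cg1": 0.2})
        regs = regions_df([("r1", "chr1", 100, 300)])
        out = region_methylation_array(beta, m, regs)
        assert not bool(out.loc["r1", "informative"])

    def test_matches_hand_computed_means_on_dataset(self, dataset, beta_matrix):
        regs = select_regions(
            dataset.annotation["dhs_distal"], dataset.cpg_positions, min_cpgs=0
        )
        out = region_methylation_array(
            beta_matrix.beta["A1"], dataset.manifest, regs,
            detection_p=beta_matrix.detection_p["A1"],
        )
        for r in regs.itertuples(index=False):
            vals = [
                beta_matrix.beta.loc[pid, "A1"]
                for pid, p in dataset.manifest.probes.items()
                if p.chrom == r.chrom and r.start <= p.target_pos < r.end
                and beta_matrix.detection_p.loc[pid, "A1"] < 0.01
            ]
            if vals:
                assert out.loc[r.region_id, "mean_beta"] == pytest.approx(
                    np.mean(vals)
                )


class TestAssociation:
    def test_fixed_table_log_or_ln36(self):
        meth = pd.DataFrame(
            {
                "mean_beta": [0.1] * 110 + [0.9] * 90,
                "status": ["low"] * 110 + ["high"] * 90,
                "informative": [True] * 200,
            },
            index=[f"r{i}" for i in range(200)],
        )
        # presence arranged to yield the 2x2 table (90, 10, 20, 80)
        presence = pd.Series(
            [True] * 90 + [False] * 20 + [True] * 10 + [False] * 80,
            index=meth.index,
        )
        assoc = methylation_vs_dhs(meth, presence)
        assert assoc.table == (90, 10, 20, 80)
        assert assoc.log_odds_ratio == pytest.approx(math.log(36), abs=1e-12)
        assert not assoc.haldane_corrected

    def test_anticorrelated_fixture_large_positive(self, dataset, beta_matrix):
        regs = select_regions(
            dataset.annotation["dhs_distal"], dataset.cpg_positions, min_cpgs=3
        )
        w = region_methylation_wgbs(dataset.wgbs, regs)
        presence = dataset.annotation["dhs_presence"]["cellA"].reindex(w.index)
        assoc = methylation_vs_dhs(w, presence)
        assert assoc.log_odds_ratio > 1.0
        # construction is perfectly anti-correlated: off cells are empty
        assert assoc.table[1] == 0 and assoc.table[2] == 0

    def test_independent_fixture_log_or_near_zero(self):
        rng = np.random.default_rng(1)
        n = 600
        low = rng.random(n) < 0.4
        present = rng.random(n) < 0.5
        meth = pd.DataFrame(
            {
                "mean_beta": np.where(low, 0.1, 0.9),
                "status": np.where(low, "low", "high"),
                "informative": True,
            },
            index=[f"r{i}" for i in range(n)],
        )
        assoc = methylation_vs_dhs(meth, pd.Series(present, index=meth.index))
        assert assoc.ci_low <= 0.0 <= assoc.ci_high

    def test_zero_margin_flagged(self):
        meth = pd.DataFrame(
            {
                "mean_beta": [0.1, 0.1, 0.9],
                "status": ["low", "low", "high"],
                "informative": True,
            },
            index=["r1", "r2", "r3"],
        )
        presence = pd.Series([True, True, True], index=meth.index)
        assoc = methylation_vs_dhs(meth, presence)
        assert assoc.haldane_corrected


def region_meth(values, informative=None):
    idx = [f"r{i}" for i in range(len(values))]
    informative = informative or [True] * len(values)
    return pd.DataFrame(
        {
            "mean_beta": values,
            "status": [methylation_status(v) for v in values],
            "informative": informative,
        },
        index=idx,
    )


class TestConcordance:
    def test_identical_inputs_perfect(self):
        w = region_meth([0.1, 0.2, 0.5, 0.8, 0.9])
        res = cross_platform_concordance(w, w.copy())
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.agreement_fractions[0.05] == 1.0
        assert res.disagreements.empty

    def test_opposed_region_flagged(self):
        w = region_meth([0.1, 0.2, 0.5, 0.1])
        a = region_meth([0.1, 0.2, 0.5, 0.9])
        res = cross_platform_concordance(w, a)
        assert list(res.disagreements.index) == ["r3"]

    def test_fractions_nested(self, dataset, beta_matrix):
        regs = select_regions(
            dataset.annotation["dhs_distal"], dataset.cpg_positions, min_cpgs=3
        )
        w = region_methylation_wgbs(dataset.wgbs, regs)
        a = region_methylation_array(
            beta_matrix.beta["A1"], dataset.manifest, regs,
            detection_p=beta_matrix.detection_p["A1"],
        )
        res = cross_platform_concordance(w, a)
        f = res.agreement_fractions
        assert f[0.05] <= f[0.10] <= f[0.20]

    def test_only_jointly_informative_regions_used(self):
        w = region_meth([0.1, 0.2, 0.3, 0.4], informative=[True, True, True, False])
        a = region_meth([0.1, 0.2, 0.3, 0.9], informative=[True, True, True, True])
        res = cross_platform_concordance(w, a)
        assert res.n_common_regions == 3
        assert res.disagreements.empty

    def test_insufficient_regions_rejected(self):
        w = region_meth([0.1, 0.2])
        with pytest.raises(IntegrityError):
            cross_platform_concordance(w, w.copy())


class TestDisagreementTyping:
    def _setup(self, own_beta_counts, region_beta=0.2, array_beta=0.9):
        m = Manifest("t", {"cg1": probe_at("cg1", "chr1", 150)})
        regs = regions_df([("r1", "chr1", 100, 300)])
        counts = counts_df([("chr1", 150, 152, *own_beta_counts)])
        disagreements = pd.DataFrame(
            {"beta_wgbs": [region_beta], "beta_array": [array_beta]}, index=["r1"]
        )
        return disagreements, counts, m, regs

    def test_consistent_own_cpg_is_probe_positioning(self):
        # array 0.9, own CpG 17/20 = 0.85, region 0.2
        d, counts, m, regs = self._setup((17, 20))
        types = classify_disagreements(d, counts, m, regs)
        assert types.loc["r1"] == PROBE_POSITIONING

    def test_contradicting_own_cpg_is_artifact(self):
        # array 0.9, own CpG 2/20 = 0.1
        d, counts, m, regs = self._setup((2, 20))
        types = classify_disagreements(d, counts, m, regs)
        assert types.loc["r1"] == TECHNICAL_ARTIFACT

    def test_low_coverage_unclassified(self):
        d, counts, m, regs = self._setup((4, 5))
        types = classify_disagreements(d, counts, m, regs, min_single_cov=10)
        assert types.loc["r1"] == UNCLASSIFIED

    def test_planted_fault_types_recovered(self, dataset, beta_matrix):
        regs = select_regions(
            dataset.annotation["dhs_distal"], dataset.cpg_positions, min_cpgs=3
        )
        w = region_methylation_wgbs(dataset.wgbs, regs)
        a = region_methylation_array(
            beta_matrix.beta["A1"], dataset.manifest, regs,
            detection_p=beta_matrix.detection_p["A1"],
        )
        res = cross_platform_concordance(w, a)
        types = classify_disagreements(res.disagreements, dataset.wgbs,
                                       dataset.manifest, regs, tau=0.2)
        assert dict(types) == dataset.ground_truth.dhs_fault_types
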