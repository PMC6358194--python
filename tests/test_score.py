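"""Score formula, missingness rescaling, exclusion, categorisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wgrs import (
    ConfigError,
    GenotypeMatrix,
    WeightEntry,
    WeightPanel,
    assign_category,
    categorize_scores,
    category_thresholds,
    compute_wgrs,
    filter_low_genotyping,
    score_distribution_report,
    score_matrix,
    simulate_genotypes,
)


def brute_force_score(counts: dict, panel: WeightPanel) -> tuple[float, int, float]:
    """Independent loop-based oracle for the score formula."""
    raw, n = 0.0, 0
    for entry in panel.entries:
        x = counts.get(entry.snp_id)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            continue
        raw += entry.weight * x
        n += 1
    return raw, n, raw / n * panel.panel_size


class TestComputeWgrs:
    def test_all_zero_counts(self, panel3):
        res = compute_wgrs(pd.Series({"rs1": 0, "rs2": 0, "rs3": 0}), panel3)
        assert res.raw_sum == 0.0 and res.scaled_score == 0.0
        assert res.n_genotyped == 3

    def test_hand_computed_weighted_sum(self, panel3):
        res = compute_wgrs(pd.Series({"rs1": 1, "rs2": 2, "rs3": 0}), panel3)
        expected = math.log(1.5) + 2 * math.log(2.0)
        assert res.raw_sum == pytest.approx(expected, abs=1e-12)
        assert res.scaled_score == pytest.approx(expected, abs=1e-12)  # complete data
        assert res.scaled_score == pytest.approx(1.7918, abs=5e-5)

    def test_rescaling_26_over_22(self):
        # a sample genotyped at 22 of 26 SNPs with raw sum 5.0 scales to 5.0/22*26
        entries = tuple(
            WeightEntry(f"s{i}", "1", i + 1, "A", "G", math.exp(5.0 / 22.0))
            for i in range(26)
        )
        panel = WeightPanel(entries)
        counts = pd.Series({f"s{i}": (1.0 if i < 22 else np.nan) for i in range(26)})
        res = compute_wgrs(counts, panel)
        assert res.n_genotyped == 22
        assert res.raw_sum == pytest.approx(5.0, rel=1e-12)
        assert res.scaled_score == pytest.approx(5.0 / 22 * 26, rel=1e-12)
        assert res.scaled_score == pytest.approx(5.9091, abs=5e-5)

    def test_zero_genotyped_is_error(self, panel3):
        with pytest.raises(ConfigError, match="zero genotyped"):
            compute_wgrs(pd.Series({"rs1": np.nan, "rs2": np.nan, "rs3": np.nan}), panel3)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            panel = WeightPanel(
                tuple(
                    WeightEntry(f"v{j}", "1", j + 1, "A", "G", float(rng.uniform(0.5, 3.0)))
                    for j in range(k)
                )
            )
            counts = {
                f"v{j}": (np.nan if rng.random() < 0.3 else float(rng.integers(0, 3)))
                for j in range(k)
            }
            if all(isinstance(v, float) and math.isnan(v) for v in counts.values()):
                counts["v0"] = 1.0
            res = compute_wgrs(pd.Series(counts), panel)
            raw, n, scaled = brute_force_score(counts, panel)
            assert res.raw_sum == pytest.approx(raw, abs=1e-12)
            assert res.n_genotyped == n
            assert res.scaled_score == pytest.approx(scaled, abs=1e-12)
            # the rescaling identity holds exactly
            assert res.scaled_score * n == pytest.approx(res.raw_sum * k, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.5, 3.0), min_size=2, max_size=8), st.data())
    def test_doubling_weights_doubles_scores(self, ors, data):
        base = WeightPanel(
            tuple(WeightEntry(f"v{j}", "1", j + 1, "A", "G", o) for j, o in enumerate(ors))
        )
        doubled = WeightPanel(
            tuple(WeightEntry(f"v{j}", "1", j + 1, "A", "G", o * o) for j, o in enumerate(ors))
        )
        counts = pd.Series(
            {f"v{j}": float(data.draw(st.integers(0, 2))) for j in range(len(ors))}
        )
        a = compute_wgrs(counts, base)
        b = compute_wgrs(counts, doubled)
        assert b.raw_sum == pytest.approx(2 * a.raw_sum, abs=1e-10)
        assert b.scaled_score == pytest.approx(2 * a.scaled_score, abs=1e-10)

    def test_masking_mean_contribution_snps_keeps_scaled_score(self, panel26, freqs26):
        gm = simulate_genotypes(1, freqs26, seed=5)
        counts = gm.counts.iloc[0]
        full = compute_wgrs(counts, panel26)
        per_snp = counts.to_numpy() * panel26.weights
        # mask one SNP whose contribution is replaced by the remaining mean:
        # engineer it by setting that SNP's contribution to the mean exactly
        target = per_snp.mean()
        # choose weights so snp01 contributes exactly the sample mean
        adjusted = counts.copy()
        rest = per_snp[1:]
        entry0 = panel26.entries[0]
        if counts.iloc[0] > 0:
            new_or = math.exp(rest.mean() / counts.iloc[0])
            entries = (WeightEntry("snp01", entry0.chrom, entry0.pos, "A", "G", new_or),) + panel26.entries[1:]
            panel = WeightPanel(entries)
            before = compute_wgrs(adjusted, panel)
            adjusted.iloc[0] = np.nan
            after = compute_wgrs(adjusted, panel)
            assert after.scaled_score == pytest.approx(before.scaled_score, abs=1e-9)

    def test_matrix_scoring_matches_per_sample(self, panel26, freqs26):
        gm = simulate_genotypes(50, freqs26, seed=3)
        masked = gm.counts.copy()
        masked.iloc[::3, ::4] = np.nan
        gm = GenotypeMatrix(masked)
        table = score_matrix(gm, panel26)
        for sid in gm.sample_ids[:10]:
            res = compute_wgrs(gm.counts.loc[sid], panel26, sample_id=sid)
            assert table.loc[sid, "raw_sum"] == pytest.approx(res.raw_sum, abs=1e-12)
            assert table.loc[sid, "scaled_score"] == pytest.approx(res.scaled_score, abs=1e-12)


class TestFilterLowGenotyping:
    def test_single_snp_sample_excluded(self, panel3):
        counts = pd.DataFrame(
            [[1.0, np.nan, np.nan], [1.0, 2.0, np.nan]],
            index=pd.Index(["one_snp", "two_snps"], name="sample_id"),
            columns=panel3.snp_ids,
        )
        retained, excluded = filter_low_genotyping(GenotypeMatrix(counts))
        assert excluded == ["one_snp"]
        assert retained.sample_ids == ["two_snps"]

    def test_known_counts_excluded_exactly(self, panel26, freqs26):
        gm = simulate_genotypes(10, freqs26, seed=9)
        counts = gm.counts.copy()
        genotyped = [1, 1, 1, 2, 5, 26, 26, 26, 3, 2]
        for i, g in enumerate(genotyped):
            counts.iloc[i, g:] = np.nan
        retained, excluded = filter_low_genotyping(GenotypeMatrix(counts), min_genotyped=2)
        assert len(excluded) == 3
        assert len(retained.sample_ids) == 7

    def test_exclusion_count_logged(self, panel26, freqs26, caplog):
        gm = simulate_genotypes(4, freqs26, seed=9)
        counts = gm.counts.copy()
        counts.iloc[0, 1:] = np.nan
        with caplog.at_level("INFO", logger="wgrs.score"):
            filter_low_genotyping(GenotypeMatrix(counts))
        assert any("excluded 1" in r.getMessage() for r in caplog.records)

    def test_fully_genotyped_retained(self, small_genotypes):
        retained, excluded = filter_low_genotyping(small_genotypes, min_genotyped=1)
        assert excluded == []


class TestCategorisation:
    def test_worked_reference(self):
        thr = category_thresholds([4, 5, 6, 7])
        assert thr[1] == pytest.approx(5.5)
        assert thr[0] == pytest.approx(5.5 - 1.2909944, abs=1e-6)
        cats = [assign_category(v, thr) for v in (4, 5, 6, 7)]
        assert cats == [1, 2, 3, 4]

    def test_score_at_mean_goes_to_upper_interval(self):
        thr = (1.0, 2.0, 3.0)
        assert assign_category(2.0, thr) == 3
        assert assign_category(1.0, thr) == 2
        assert assign_category(3.0, thr) == 4

    def test_normal_proportions(self):
        rng = np.random.default_rng(1234)
        scores = pd.Series(rng.standard_normal(100_000))
        cats = categorize_scores(scores, scores.to_numpy())
        counts = np.bincount([c.category for c in cats], minlength=5)[1:]
        props = counts / counts.sum() * 100
        expected = np.array([15.87, 34.13, 34.13, 15.87])
        assert np.all(np.abs(props - expected) < 0.5)

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(6, 1, 500))
        cats = categorize_scores(scores, scores.to_numpy())
        assert len(cats) == 500
        assert set(c.category for c in cats) <= {1, 2, 3, 4}

    def test_zero_sd_reference_rejected(self):
        with pytest.raises(ConfigError, match="zero standard deviation"):
            category_thresholds([5.0, 5.0, 5.0])


class TestDistributionReport:
    def test_identical_groups(self):
        rep = score_distribution_report([1, 2, 3], [1, 2, 3])
        assert rep.t_stat == pytest.approx(0.0)
        assert rep.t_p == pytest.approx(1.0)
        assert rep.levene_stat == pytest.approx(0.0)

    def test_textbook_pooled_t(self):
        rep = score_distribution_report([1, 2, 3], [4, 5, 6])
        assert rep.equal_var
        assert rep.t_stat == pytest.approx(-3.6742, abs=1e-4)
        assert rep.t_p == pytest.approx(0.0213, abs=1e-3)
        # cross-check against scipy's pooled t-test directly
        t, p = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert rep.t_stat == pytest.approx(t)
        assert rep.t_p == pytest.approx(p)

    def test_qq_points_monotone(self):
        rng = np.random.default_rng(3)
        rep = score_distribution_report(rng.normal(6, 1, 50), rng.normal(5.5, 1, 50))
        qq = np.asarray(rep.qq_points)
        assert np.all(np.diff(qq[:, 0]) >= 0)
        assert np.all(np.diff(qq[:, 1]) >= 0)

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError):
            score_distribution_report([1.0], [1, 2, 3])
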