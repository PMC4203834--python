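import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from platesort import (
    PlateScenario,
    correlation_matrix,
    dose_response_all_traits,
    dose_response_table,
    edge_effect_test,
    fill_wells,
    generate_summarized_plate,
    wilcoxon_rank_sum,
)
from platesort.errors import InsufficientDataError, InvalidMetadataError
from platesort.summarize import SummarizedPlate
from platesort.wells import ALL_WELL_LABELS


def exact_p_by_enumeration(x, y):
    """Brute-force two-sided p: every C(n, n1) assignment of pooled ranks."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free by construction
    w_obs = sum(ranks[v] for v in x)
    n1 = len(x)
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n1)]
    total = len(sums)
    p_low = sum(s <= w_obs for s in sums) / total
    p_high = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxonRankSum:
    def test_textbook_example(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.w_statistic == 6
        assert r.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]).p_value == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 2), (6, 6), (1, 7)])
    def test_exact_mode_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, n1 + n2 + 1) * 1.0)
            x, y = pooled[:n1], pooled[n1:]
            r = wilcoxon_rank_sum(x, y)
            assert r.method == "exact"
            assert r.p_value == pytest.approx(exact_p_by_enumeration(x, y), abs=1e-12)

    def test_complete_sweep_small_samples(self):
        # every tie-free configuration with n1+n2 <= 9: the observed W fully
        # determines the exact p, so sweep all rank subsets
        for n in range(2, 10):
            for n1 in range(1, n):
                for combo in itertools.combinations(range(1, n + 1), n1):
                    x = [float(c) for c in combo]
                    y = [float(v) for v in range(1, n + 1) if v not in combo]
                    r = wilcoxon_rank_sum(x, y)
                    assert r.p_value == pytest.approx(
                        exact_p_by_enumeration(x, y), abs=1e-12
                    )

    def test_label_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(size=9)
            assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                wilcoxon_rank_sum(y, x).p_value, abs=1e-12
            )

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=5), rng.normal(size=6)
        base = wilcoxon_rank_sum(x, y).p_value
        assert wilcoxon_rank_sum(x + 7.5, y + 7.5).p_value == base
        assert wilcoxon_rank_sum(x * 3.25, y * 3.25).p_value == base

    def test_w_statistic_within_attainable_range(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n1, n2 = rng.integers(1, 15, size=2)
            r = wilcoxon_rank_sum(rng.normal(size=n1), rng.normal(size=n2))
            assert n1 * (n1 + 1) / 2 <= r.w_statistic <= n1 * (n1 + 2 * n2 + 1) / 2

    def test_normal_approximation_close_to_exact_at_10v10(self):
        # pooled size 20 sits at the exact-mode limit; force the comparison by
        # computing both on the same data
        from platesort.stats import _null_ranksum_counts

        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            r = wilcoxon_rank_sum(x, y)
            assert r.method == "exact"
            big = wilcoxon_rank_sum(np.concatenate([x, [100.0]]), y)  # n=21 -> approx
            assert big.method == "normal-approximation"
        # direct check: approx vs exact on identical rank data
        counts = _null_ranksum_counts(10, 20)
        total = counts.sum()
        for w in range(55, 156, 10):
            p_exact = min(1.0, 2 * min(counts[: w + 1].sum() / total, counts[w:].sum() / total))
            mean_w = 10 * 21 / 2
            var_w = 10 * 10 * 21 / 12
            diff = w - mean_w
            cc = 0.5 * math.copysign(1.0, diff) if diff else 0.0
            from scipy.stats import norm

            p_approx = min(1.0, 2 * norm.sf(abs((diff - cc) / math.sqrt(var_w))))
            assert abs(p_approx - p_exact) < 0.01

    def test_agrees_with_scipy_mannwhitneyu(self):
        # independent cross-check: scipy's U statistic relates to W by
        # U = W - n1(n1+1)/2; p-values must agree in both regimes
        rng = np.random.default_rng(4)
        for n1, n2 in [(4, 5), (8, 8), (15, 20), (30, 25)]:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            r = wilcoxon_rank_sum(x, y)
            method = "exact" if r.method == "exact" else "asymptotic"
            ref = mannwhitneyu(x, y, alternative="two-sided", method=method)
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_rank_sum([], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            wilcoxon_rank_sum([1.0], [np.nan])


class TestEdgeEffect:
    def test_partition_sizes(self, summarized_plate):
        report = edge_effect_test(summarized_plate, trait="tof")
        assert len(report.edge_wells) == 36
        assert len(report.center_wells) == 60
        assert set(report.edge_wells).isdisjoint(report.center_wells)

    def test_strong_gradient_detected(self):
        s = generate_summarized_plate(PlateScenario(seed=606, edge_effect_sd=5.0))
        report = edge_effect_test(s, trait="tof")
        assert report.results["tof"].p_value < 0.01

    def test_null_plate_not_significant_typically(self):
        rng = np.random.default_rng(707)
        pvals = [
            edge_effect_test(
                generate_summarized_plate(PlateScenario(seed=0), rng=rng), trait="tof"
            ).results["tof"].p_value
            for _ in range(50)
        ]
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_all_traits_mode_reports_untestable(self, summarized_plate):
        df = summarized_plate.data.copy()
        df["mean_red"] = np.nan
        crippled = SummarizedPlate(data=df, source="x")
        report = edge_effect_test(crippled, trait="all")
        assert "red" in report.untestable
        assert "tof" in report.results

    def test_single_all_missing_trait_errors(self, summarized_plate):
        df = summarized_plate.data.copy()
        df["mean_red"] = np.nan
        with pytest.raises(InsufficientDataError):
            edge_effect_test(SummarizedPlate(data=df, source="x"), trait="red")

    def test_bh_adjustment_monotone_and_bounded(self, summarized_plate):
        report = edge_effect_test(summarized_plate, trait="all", bh_adjust=True)
        raw = report.p_values()
        for t, padj in report.adjusted_p.items():
            assert padj >= raw[t] - 1e-12
            assert padj <= 1.0


def naive_pearson(u, v):
    pairs = [(a, b) for a, b in zip(u, v) if not (math.isnan(a) or math.isnan(b))]
    if len(pairs) < 3:
        return math.nan
    n = len(pairs)
    mu = sum(a for a, _ in pairs) / n
    mv = sum(b for _, b in pairs) / n
    num = sum((a - mu) * (b - mv) for a, b in pairs)
    den = math.sqrt(sum((a - mu) ** 2 for a, _ in pairs) * sum((b - mv) ** 2 for _, b in pairs))
    return num / den if den else math.nan


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, summarized_plate):
        m = correlation_matrix(summarized_plate)
        vals = m.values
        np.testing.assert_allclose(np.diag(vals), 1.0, atol=1e-12)
        np.testing.assert_allclose(vals, vals.T, atol=1e-12, equal_nan=True)

    def test_affine_transform_gives_exactly_minus_one(self, summarized_plate):
        df = summarized_plate.data[["well", "mean_tof"]].copy()
        df["derived"] = -2.0 * df["mean_tof"] + 3.0
        m = correlation_matrix(SummarizedPlate(data=df, source="x"))
        assert m.values.loc["mean_tof", "derived"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_naive_pairwise_complete_oracle(self, summarized_plate):
        df = summarized_plate.data.copy()
        # punch holes so pairwise-complete logic actually matters
        rng = np.random.default_rng(5)
        for col in ("mean_tof", "mean_ext", "mean_green"):
            idx = rng.choice(len(df), size=10, replace=False)
            df.loc[idx, col] = np.nan
        m = correlation_matrix(SummarizedPlate(data=df, source="x"))
        cols = ["n", "mean_tof", "mean_ext", "mean_green", "var_tof"]
        for a in cols:
            for b in cols:
                expected = naive_pearson(df[a].tolist(), df[b].tolist())
                got = m.values.loc[a, b]
                if math.isnan(expected):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, rel=1e-9)

    def test_between_plates_matched_by_well(self, summarized_plate):
        # second plate = first with wells reversed; matching by well must
        # undo the reversal and give corr 1 on the diagonal block
        df2 = summarized_plate.data.iloc[::-1].reset_index(drop=True)
        b = SummarizedPlate(data=df2, source="plate_b")
        m = correlation_matrix(summarized_plate, b, traits=["mean_tof", "mean_ext"])
        assert not m.within_plate
        assert m.values.shape == (2, 2)
        assert m.values.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_pairs_raises(self):
        df = pd.DataFrame({"well": ["A1", "A2"], "mean_tof": [1.0, 2.0], "mean_ext": [2.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            correlation_matrix(SummarizedPlate(data=df, source="x"))


class TestDoseResponse:
    @staticmethod
    def _layout_summary(value_fn):
        rows = [{"well": w, "n": 10, "mean_tof": value_fn(i, w)} for i, w in enumerate(ALL_WELL_LABELS)]
        return SummarizedPlate(data=pd.DataFrame(rows), source="dr")

    def test_constant_trait_gives_constant_group_means(self):
        summary = self._layout_summary(lambda i, w: 7.25)
        strains = ["s1"] * 96
        doses = [float(i % 4) for i in range(96)]
        table = dose_response_table(summary, strains, doses, "tof")
        assert (table.groups["mean"] == 7.25).all()
        assert table.groups["well_count"].sum() == 96

    def test_known_per_group_constants_recovered(self):
        # four strains x five doses with distinct constants per group
        strains = [f"s{(i // 12) % 4}" for i in range(96)]
        doses = [float((i % 12) // 3) for i in range(96)]  # doses 0..3 (4 doses here)
        const = {(s, d): 10.0 * int(s[1]) + d for s in set(strains) for d in set(doses)}
        lookup = dict(zip(ALL_WELL_LABELS, zip(strains, doses)))
        summary = self._layout_summary(lambda i, w: const[lookup[w]])
        table = dose_response_table(summary, strains, doses, "tof")
        for g in table.groups.itertuples(index=False):
            assert g.mean == const[(g.strain, g.dose)]

    def test_group_mean_equals_mean_of_points(self):
        rng = np.random.default_rng(6)
        summary = self._layout_summary(lambda i, w: float(rng.normal(100, 10)))
        strains = [f"s{i % 3}" for i in range(96)]
        doses = [float(i % 2) for i in range(96)]
        table = dose_response_table(summary, strains, doses, "tof")
        for g in table.groups.itertuples(index=False):
            pts = table.points[
                (table.points["strain"] == g.strain) & (table.points["dose"] == g.dose)
            ]["value"]
            assert g.mean == pytest.approx(pts.mean(), rel=1e-12)
            assert g.well_count == len(pts)

    def test_all_missing_group_present_with_zero_count(self):
        summary = self._layout_summary(lambda i, w: np.nan if i < 12 else 5.0)
        strains = ["dead" if i < 12 else "alive" for i in range(96)]
        doses = [0.0] * 96
        table = dose_response_table(summary, strains, doses, "tof")
        dead = table.groups[table.groups["strain"] == "dead"].iloc[0]
        assert dead.well_count == 0
        assert math.isnan(dead["mean"])

    def test_metadata_length_validated(self, summarized_plate):
        with pytest.raises(InvalidMetadataError):
            dose_response_table(summarized_plate, ["s"] * 95, [0.0] * 96, "tof")
        with pytest.raises(InvalidMetadataError):
            dose_response_table(summarized_plate, ["s"] * 96, [0.0] * 95, "tof")

    def test_all_traits_map_matches_individual_tables(self, summarized_plate):
        strains = [f"s{i % 4}" for i in range(96)]
        doses = [float(i % 5) for i in range(96)]
        tables = dose_response_all_traits(summarized_plate, strains, doses)
        assert set(tables) == {
            "tof", "ext", "green", "yellow", "red",
            "norm_ext", "norm_green", "norm_yellow", "norm_red",
        }
        single = dose_response_table(summarized_plate, strains, doses, "ext")
        pd.testing.assert_frame_equal(tables["ext"].groups, single.groups)

    def test_missing_trait_skipped_in_all_traits_map(self, summarized_plate):
        df = summarized_plate.data.copy()
        df["mean_red"] = np.nan
        tables = dose_response_all_traits(
            SummarizedPlate(data=df, source="x"),
            ["s"] * 96,
            [0.0] * 96,
        )
        assert "red" not in tables
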