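"""Quality filters: blank ratio, QC dilution linearity, prevalence, CV, t-test."""

import math

import numpy as np
import pytest

from lipidtraffic.qc import (
    QCError,
    blank_ratio_filter,
    compare_total_signal,
    cv_summary,
    cv_table,
    passing_ids,
    prevalence_filter,
    qc_linearity_filter,
    run_filter_chain,
)

from conftest import analytical, blank, feat, make_sheet, qc


def _blank_sheet(analytical_vals, blank_vals):
    """One feature per row of analytical_vals, with paired blank intensities."""
    n = len(analytical_vals)
    features = [feat(f"f{i}") for i in range(n)]
    samples = [analytical("a1"), analytical("a2"), blank("b1"), blank("b2")]
    matrix = [
        [a, a, b, b] for a, b in zip(analytical_vals, blank_vals)
    ]
    return make_sheet(features, samples, matrix)


class TestBlankRatio:
    @pytest.mark.parametrize(
        "a_mean, b_mean, factor, expected",
        [
            (400_000, 100_000, 3.0, True),  # ratio 4 > 3
            (250_000, 100_000, 3.0, False),  # ratio 2.5
            (300_000, 100_000, 3.0, False),  # exactly 3x: strict inequality
            (0, 0, 3.0, False),  # no signal at all
            (100, 0, 3.0, True),  # zero blank, any analytical signal
            (600_000, 100_000, 5.0, True),  # unmatched-chain factor
            (500_000, 100_000, 5.0, False),  # exactly 5x fails
        ],
    )
    def test_boundary_cases(self, a_mean, b_mean, factor, expected):
        sheet = _blank_sheet([a_mean], [b_mean])
        (res,) = blank_ratio_filter(sheet, factor=factor)
        assert res.passed is expected

    def test_no_blanks_is_instructive_error(self):
        sheet = make_sheet([feat("f1")], [analytical("a1")], [[1.0]])
        with pytest.raises(QCError, match="blank"):
            blank_ratio_filter(sheet)

    def test_raising_factor_shrinks_passing_set(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1e6, size=20)
        sheet = _blank_sheet(vals.tolist(), (vals / rng.uniform(1, 10, 20)).tolist())
        sets = [passing_ids(blank_ratio_filter(sheet, factor=f)) for f in (2, 3, 5, 8)]
        for small, big in zip(sets[1:], sets):
            assert small <= big


def _qc_sheet(stock1_by_level, stock2_by_level=None):
    """One feature; QC wells for 2 stocks x 3 levels x 3 replicates."""
    samples, row = [], []
    for stock, by_level in (("stock1", stock1_by_level), ("stock2", stock2_by_level)):
        if by_level is None:
            continue
        for level in (0.25, 0.5, 1.0):
            for r in range(1, 4):
                samples.append(qc(f"{stock}_L{level}_{r}", stock, level, r))
                row.append(by_level[level])
    samples.append(analytical("a1"))
    row.append(1.0)
    return make_sheet([feat("f1")], samples, [row])


class TestQCLinearity:
    def test_proportional_intensities_pass(self):
        sheet = _qc_sheet({0.25: 100.0, 0.5: 200.0, 1.0: 400.0})
        (res,) = qc_linearity_filter(sheet)
        assert res.passed and res.statistic == pytest.approx(1.0)

    def test_constant_intensity_fails_with_undefined_r(self):
        sheet = _qc_sheet({0.25: 5.0, 0.5: 5.0, 1.0: 5.0})
        (res,) = qc_linearity_filter(sheet)
        assert not res.passed and math.isnan(res.statistic)

    def test_decreasing_intensity_fails(self):
        sheet = _qc_sheet({0.25: 400.0, 0.5: 200.0, 1.0: 100.0})
        (res,) = qc_linearity_filter(sheet)
        assert not res.passed and res.statistic < 0

    def test_one_good_stock_suffices(self):
        sheet = _qc_sheet(
            {0.25: 400.0, 0.5: 200.0, 1.0: 100.0},  # anticorrelated
            {0.25: 100.0, 0.5: 200.0, 1.0: 400.0},  # perfectly linear
        )
        (res,) = qc_linearity_filter(sheet)
        assert res.passed

    def test_no_qc_samples_errors(self):
        sheet = make_sheet([feat("f1")], [analytical("a1")], [[1.0]])
        with pytest.raises(QCError, match="QC"):
            qc_linearity_filter(sheet)


def _prevalence_sheet(present_per_type):
    """present_per_type: {type: (n_present, n_total)}; one feature."""
    samples, row = [], []
    for comp, (n_present, n_total) in present_per_type.items():
        for i in range(n_total):
            samples.append(analytical(f"{comp}_{i}", compartment=comp))
            row.append(100.0 if i < n_present else 0.0)
    return make_sheet([feat("f1")], samples, [row])


class TestPrevalence:
    @pytest.mark.parametrize(
        "design, min_frac, expected",
        [
            ({"t1": (9, 10), "t2": (0, 10)}, 0.9, True),  # 90% in one type
            ({"t1": (8, 10), "t2": (8, 10)}, 0.9, False),
            ({"t1": (10, 10)}, 1.0, True),  # boundary: min_frac 1
            ({"t1": (9, 10)}, 1.0, False),
        ],
    )
    def test_boundary_cases(self, design, min_frac, expected):
        sheet = _prevalence_sheet(design)
        (res,) = prevalence_filter(sheet, min_frac=min_frac)
        assert res.passed is expected

    def test_empty_group_warned_and_ignored(self):
        sheet = _prevalence_sheet({"t1": (9, 10)})
        # append an analytical sample with empty compartment
        sheet.samples.append(analytical("stray", compartment=""))
        sheet = make_sheet(
            sheet.features, sheet.samples, np.hstack([sheet.intensities, [[0.0]]])
        )
        with pytest.warns(UserWarning, match="stray"):
            (res,) = prevalence_filter(sheet, min_frac=0.9)
        assert res.passed


class TestCV:
    def test_cv_value(self):
        sheet = make_sheet(
            [feat("f1")],
            [analytical(f"a{i}") for i in range(3)],
            [[90.0, 100.0, 110.0]],
        )
        table = cv_table(sheet)
        assert table["cv"].iloc[0] == pytest.approx(10.0)

    def test_equal_values_cv_zero_and_n1_missing(self):
        sheet = make_sheet(
            [feat("f1")],
            [
                analytical("a1", compartment="x"),
                analytical("a2", compartment="x"),
                analytical("a3", compartment="y"),
            ],
            [[5.0, 5.0, 7.0]],
        )
        table = cv_table(sheet)
        by_stratum = table.set_index("stratum")["cv"]
        assert by_stratum["x"] == 0.0
        assert math.isnan(by_stratum["y"])  # n = 1: undefined, not 0
        summary = cv_summary(table)
        assert summary.set_index("stratum").loc["y", "n_defined"] == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 100, size=(4, 5))
        sheet = make_sheet(
            [feat(f"f{i}") for i in range(4)],
            [analytical(f"a{j}") for j in range(5)],
            vals,
        )
        scaled = make_sheet(sheet.features, sheet.samples, vals * 7.5)
        t1, t2 = cv_table(sheet), cv_table(scaled)
        assert np.allclose(t1["cv"], t2["cv"])


class TestTotalSignalComparison:
    def test_identical_groups(self):
        sheet = make_sheet(
            [feat("f1")],
            [analytical(f"a{i}") for i in range(4)],
            [[10.0, 20.0, 10.0, 20.0]],
        )
        t, p = compare_total_signal(sheet, ["a0", "a1"], ["a2", "a3"])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        sheet = make_sheet(
            [feat("f1")],
            [analytical(f"a{i}") for i in range(6)],
            [[1.0, 2.0, 3.0, 101.0, 102.0, 103.0]],
        )
        t, p = compare_total_signal(sheet, ["a0", "a1", "a2"], ["a3", "a4", "a5"])
        # independent check from the t formula: pooled sd 1, se = sqrt(2/3)
        from scipy import stats as ss

        t_expected = -100.0 / math.sqrt(2.0 / 3.0)
        assert t == pytest.approx(t_expected)
        assert p == pytest.approx(2 * ss.t.sf(abs(t_expected), df=4))
        assert p < 0.01

    def test_label_swap_negates_t(self):
        sheet = make_sheet(
            [feat("f1")],
            [analytical(f"a{i}") for i in range(4)],
            [[1.0, 2.0, 5.0, 7.0]],
        )
        t1, p1 = compare_total_signal(sheet, ["a0", "a1"], ["a2", "a3"])
        t2, p2 = compare_total_signal(sheet, ["a2", "a3"], ["a0", "a1"])
        assert t1 == -t2 and p1 == p2

    def test_degenerate_variance(self):
        sheet = make_sheet(
            [feat("f1")],
            [analytical(f"a{i}") for i in range(4)],
            [[1.0, 1.0, 9.0, 9.0]],
        )
        t, p = compare_total_signal(sheet, ["a0", "a1"], ["a2", "a3"])
        assert t == -math.inf and p == 0.0


class TestChains:
    def test_unmatched_chain_skips_qc_correlation(self):
        vals = [1e6, 1e6]
        features = [feat("f1"), feat("f2")]
        samples = [
            analytical("a1", compartment="x"),
            analytical("a2", compartment="x"),
            blank("b1"),
        ]
        sheet = make_sheet(features, samples, [[v, v, 10.0] for v in vals])
        filtered, results = run_filter_chain(sheet, chain="unmatched")
        assert set(results) == {"blank_ratio", "prevalence"}
        assert len(filtered.features) == 2

    def test_filters_idempotent_on_passing_set(self):
        sheet = _blank_sheet([4e5, 2e5, 1e6], [1e5, 1e5, 0.0])
        first = passing_ids(blank_ratio_filter(sheet))
        filtered = sheet.subset(feature_ids=sorted(first))
        second = passing_ids(blank_ratio_filter(filtered))
        assert second == first
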