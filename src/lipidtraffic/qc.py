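"""Signal-quality filters: blank ratio, QC dilution linearity, prevalence, CV.

Two preset filter chains mirror the two processing routes for LCMS feature
tables.  The *matched* chain (ID-matched data) keeps features whose mean
analytical signal exceeds 3x the blank mean (S/N test) and whose intensity
correlates with the QC dilution level (r > 0.75 for at least one of the two
QC stocks).  The *unmatched* chain keeps features exceeding 5x the blank
mean and present in at least 90% of samples of at least one sample type.
All thresholds use strict inequality except the prevalence fraction, which
is inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_sheet import SignalSheet, total_signal

__all__ = [
    "FilterResult",
    "QCError",
    "blank_ratio_filter",
    "qc_linearity_filter",
    "prevalence_filter",
    "cv_table",
    "cv_summary",
    "compare_total_signal",
    "passing_ids",
    "run_filter_chain",
    "CHAIN_PRESETS",
]


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class FilterResult:
    """Outcome of one test for one feature."""

    feature_id: str
    passed: bool
    statistic: float  # ratio, r, fraction or CV as appropriate (nan if undefined)
    threshold: float
    test_name: str


def passing_ids(results: Iterable[FilterResult]) -> set[str]:
    return {r.feature_id for r in results if r.passed}


def results_frame(results: Sequence[FilterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "test_name": [r.test_name for r in results],
            "statistic": [r.statistic for r in results],
            "threshold": [r.threshold for r in results],
            "passed": [r.passed for r in results],
        }
    )


def blank_ratio_filter(sheet: SignalSheet, factor: float = 3.0) -> list[FilterResult]:
    """S/N test: mean analytical signal must strictly exceed factor x blank mean.

    A feature with zero blank mean passes iff it has any analytical signal.
    """
    if factor <= 0:
        raise QCError("factor must be > 0")
    analytical = [s.sample_id for s in sheet.samples if s.role == "analytical"]
    blanks = [s.sample_id for s in sheet.samples if s.role == "blank"]
    if not blanks:
        raise QCError(
            "no blank samples in sheet; blank_ratio_filter requires role='blank' wells"
        )
    if not analytical:
        raise QCError("no analytical samples in sheet")
    a_idx = [sheet.sample_index(s) for s in analytical]
    b_idx = [sheet.sample_index(s) for s in blanks]
    a_mean = sheet.intensities[:, a_idx].mean(axis=1)
    b_mean = sheet.intensities[:, b_idx].mean(axis=1)
    out = []
    for i, feat in enumerate(sheet.features):
        if b_mean[i] > 0:
            ratio = a_mean[i] / b_mean[i]
        else:
            ratio = math.inf if a_mean[i] > 0 else 0.0
        out.append(
            FilterResult(
                feature_id=feat.feature_id,
                passed=bool(a_mean[i] > factor * b_mean[i] and a_mean[i] > 0),
                statistic=float(ratio),
                threshold=factor,
                test_name=f"blank_ratio>{factor:g}",
            )
        )
    return out


def qc_linearity_filter(
    sheet: SignalSheet,
    r_min: float = 0.75,
    method: str = "pearson",
    log_scale: bool = False,
) -> list[FilterResult]:
    """QC test: intensity must correlate with dilution level for >= 1 QC stock.

    Per feature and per QC stock, the correlation between raw intensity and
    the numeric dilution fraction (0.25/0.5/1.0) is computed across all QC
    replicates of that stock; the feature passes iff r > ``r_min`` for at
    least one stock.  Zero-variance intensity vectors have undefined r and
    fail.  ``log_scale`` correlates log10 intensity against log10 level.
    """
    qcs = [s for s in sheet.samples if s.role == "qc"]
    if not qcs:
        raise QCError("no QC samples in sheet; qc_linearity_filter requires them")
    stocks = sorted({s.qc_stock for s in qcs})
    stock_cols: dict[str, tuple[list[int], np.ndarray]] = {}
    for stock in stocks:
        members = [s for s in qcs if s.qc_stock == stock]
        levels = np.array([s.qc_level for s in members], dtype=float)
        if len(set(levels.tolist())) < 2:
            raise QCError(
                f"QC stock {stock!r} has fewer than 2 distinct dilution levels"
            )
        stock_cols[stock] = (
            [sheet.sample_index(s.sample_id) for s in members],
            np.log10(levels) if log_scale else levels,
        )

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    out = []
    for i, feat in enumerate(sheet.features):
        best = math.nan
        for stock, (cols, levels) in stock_cols.items():
            y = sheet.intensities[i, cols]
            if log_scale:
                y = np.log10(np.maximum(y, 1e-12))
            if np.ptp(y) == 0:  # zero variance: r undefined
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(corr(levels, y).statistic)
            if math.isnan(best) or r > best:
                best = r
        out.append(
            FilterResult(
                feature_id=feat.feature_id,
                passed=bool(not math.isnan(best) and best > r_min),
                statistic=best,
                threshold=r_min,
                test_name=f"qc_r>{r_min:g}",
            )
        )
    return out


def prevalence_filter(
    sheet: SignalSheet, min_frac: float = 0.9, scope: str = "compartment"
) -> list[FilterResult]:
    """Presence in >= ``min_frac`` of analytical samples of >= 1 scope group.

    ``scope`` names the metadata field whose values partition the analytical
    samples (sample type by default).  Empty groups are ignored with a
    warning.
    """
    if not 0 < min_frac <= 1:
        raise QCError("min_frac must be in (0, 1]")
    analytical = [s for s in sheet.samples if s.role == "analytical"]
    if not analytical:
        raise QCError("no analytical samples in sheet")
    groups: dict[str, list[int]] = {}
    for s in analytical:
        key = getattr(s, scope)
        if key == "":
            warnings.warn(
                f"sample {s.sample_id!r} has empty {scope!r}; ignored by "
                "prevalence_filter"
            )
            continue
        groups.setdefault(key, []).append(sheet.sample_index(s.sample_id))
    if not groups:
        raise QCError(f"no non-empty {scope!r} groups among analytical samples")
    out = []
    for i, feat in enumerate(sheet.features):
        best = 0.0
        for cols in groups.values():
            frac = float((sheet.intensities[i, cols] > 0).mean())
            best = max(best, frac)
        out.append(
            FilterResult(
                feature_id=feat.feature_id,
                passed=bool(best >= min_frac),
                statistic=best,
                threshold=min_frac,
                test_name=f"prevalence>={min_frac:g}",
            )
        )
    return out


def cv_table(
    sheet: SignalSheet, strata: Sequence[str] = ("compartment",)
) -> pd.DataFrame:
    """Coefficient of variation (percent) per feature per stratum.

    CV = 100 * sd / mean using the sample standard deviation, over the
    analytical samples of each stratum (the cartesian key over the given
    metadata fields).  Undefined entries (mean 0 or n < 2) are recorded as
    NaN, never as 0.
    """
    analytical = [s for s in sheet.samples if s.role == "analytical"]
    groups: dict[tuple, list[int]] = {}
    for s in analytical:
        key = tuple(getattr(s, f) for f in strata)
        groups.setdefault(key, []).append(sheet.sample_index(s.sample_id))
    rows = []
    for key, cols in sorted(groups.items()):
        sub = sheet.intensities[:, cols]
        n = len(cols)
        for i, feat in enumerate(sheet.features):
            vals = sub[i]
            mean = vals.mean()
            if n < 2 or mean == 0:
                cv = math.nan
            else:
                cv = 100.0 * vals.std(ddof=1) / mean
            rows.append(
                {
                    "feature_id": feat.feature_id,
                    "stratum": "|".join(key),
                    "cv": cv,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["feature_id", "stratum", "cv", "n"])


def cv_summary(
    table: pd.DataFrame, thresholds: Sequence[float] = (15.0, 20.0)
) -> pd.DataFrame:
    """Per stratum: counts and fractions of features with CV below each threshold.

    NaN (undefined) entries are excluded from the denominators.
    """
    rows = []
    for stratum, grp in table.groupby("stratum"):
        defined = grp["cv"].dropna()
        row = {"stratum": stratum, "n_defined": len(defined)}
        for t in thresholds:
            n_below = int((defined < t).sum())
            row[f"n_cv_below_{t:g}"] = n_below
            row[f"frac_cv_below_{t:g}"] = (
                n_below / len(defined) if len(defined) else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_total_signal(
    sheet: SignalSheet, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[float, float]:
    """Two-sample Student's t-test on per-sample total signal.

    Returns (t, p); t > 0 means group_a totals are larger.  With zero pooled
    variance the test degenerates: identical means give (0, 1), different
    means give (+-inf, 0).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise QCError("both groups need n >= 2 samples")
    a = np.array([total_signal(sheet, s) for s in group_a])
    b = np.array([total_signal(sheet, s) for s in group_b])
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (math.inf if a.mean() > b.mean() else -math.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


#: Preset filter chains: (blank factor, use QC correlation, prevalence fraction).
CHAIN_PRESETS = {
    "matched": {"blank_factor": 3.0, "qc_r_min": 0.75, "prevalence": None},
    "unmatched": {"blank_factor": 5.0, "qc_r_min": None, "prevalence": 0.9},
}


def run_filter_chain(
    sheet: SignalSheet,
    chain: str = "matched",
    blank_factor: float | None = None,
    qc_r_min: float | None = None,
    prevalence: float | None = None,
) -> tuple[SignalSheet, dict[str, list[FilterResult]]]:
    """Apply a preset filter chain; returns the filtered sheet and per-test results.

    Explicit threshold arguments override the preset.  The filtered sheet
    keeps only features passing every test in the chain.
    """
    if chain not in CHAIN_PRESETS:
        raise QCError(f"unknown chain {chain!r}; choose from {sorted(CHAIN_PRESETS)}")
    preset = dict(CHAIN_PRESETS[chain])
    if blank_factor is not None:
        preset["blank_factor"] = blank_factor
    if qc_r_min is not None:
        preset["qc_r_min"] = qc_r_min
    if prevalence is not None:
        preset["prevalence"] = prevalence

    results: dict[str, list[FilterResult]] = {}
    keep = {f.feature_id for f in sheet.features}
    results["blank_ratio"] = blank_ratio_filter(sheet, factor=preset["blank_factor"])
    keep &= passing_ids(results["blank_ratio"])
    if preset["qc_r_min"] is not None:
        results["qc_linearity"] = qc_linearity_filter(sheet, r_min=preset["qc_r_min"])
        keep &= passing_ids(results["qc_linearity"])
    if preset["prevalence"] is not None:
        results["prevalence"] = prevalence_filter(sheet, min_frac=preset["prevalence"])
        keep &= passing_ids(results["prevalence"])
    ordered = [f.feature_id for f in sheet.features if f.feature_id in keep]
    return sheet.subset(feature_ids=ordered), results
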