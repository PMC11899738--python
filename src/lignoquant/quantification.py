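"""Exposed-vs-control comparison of lignin-peak heights.

For each selected peak the two cohorts are compared with a tiered test:
Shapiro-Wilk and a Lilliefors-corrected Kolmogorov-Smirnov test screen both
groups for normality (either test rejecting in either group routes the
comparison to Kruskal-Wallis); otherwise Levene's test decides between the
pooled-variance Student t-test and Welch's t-test.  All p-values are
two-sided and significance is called per peak at alpha (no multiplicity
correction by default, matching the per-peak reporting convention; a
Bonferroni switch exists).

The relative lignin change is the unit-free ratio of group-mean heights,
``100 * (mean_exposed / mean_control - 1)``.  Alternatively heights can be
mapped through the standard-curve slope first; because that map is affine,
the two readings differ only through the curve's intercept.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .calibration import PeakDefinition, SelectedPeakSet, StandardCurve, peak_height
from .errors import EmptyInputError, InsufficientDataError
from .spectra import GROUP_CONTROL, GROUP_EXPOSED, SpectrumSet


class TestUsed(str, enum.Enum):
    STUDENT_T = "student_t"
    WELCH_T = "welch_t"
    KRUSKAL_WALLIS = "kruskal_wallis"


def compute_peak_heights(
    samples: SpectrumSet, peaks: SelectedPeakSet | list[PeakDefinition]
) -> pd.DataFrame:
    """One height per (sample, peak).

    Returns columns ``sample_id, group, peak_center, height, flagged``;
    ``flagged`` marks windows without a negative derivative minimum (height
    reported as 0).
    """
    peak_list = peaks.peaks if isinstance(peaks, SelectedPeakSet) else peaks
    if not peak_list:
        raise EmptyInputError("no peaks to measure")
    rows = []
    for s in samples:
        for peak in peak_list:
            h, flagged = peak_height(s, peak)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "peak_center": peak.center,
                    "height": h,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def _ks_lilliefors_p(x: np.ndarray, method: str, rng: np.random.Generator | None) -> float:
    """Kolmogorov-Smirnov normality p with estimated mean/sd.

    ``method='table'`` uses the statsmodels Lilliefors table (itself built
    from large-scale simulation); ``method='mc'`` runs a seeded Monte-Carlo
    null of 10^4 draws, which is exact in distribution but far slower.
    Groups of n < 4 (below the test's minimum) fall back to the
    Shapiro-Wilk screen alone.
    """
    if x.size < 4:
        return 1.0
    if method == "mc":
        n = x.size
        stat = lilliefors(x, dist="norm", pvalmethod="table")[0]
        reps = 10_000
        rng = rng or np.random.default_rng(0)
        null = np.empty(reps)
        for i in range(reps):
            null[i] = lilliefors(rng.standard_normal(n), dist="norm",
                                 pvalmethod="table")[0]
        return float((null >= stat).mean())
    return float(lilliefors(x, dist="norm", pvalmethod="table")[1])


def _normality_p(x: np.ndarray, ks_method: str, rng) -> tuple[float, float]:
    """(KS-Lilliefors p, Shapiro-Wilk p); zero-variance data counts as a
    hard rejection of normality."""
    if np.ptp(x) == 0.0:
        return 0.0, 0.0
    p_ks = _ks_lilliefors_p(x, ks_method, rng)
    p_sw = float(stats.shapiro(x).pvalue)
    return p_ks, p_sw


@dataclass(frozen=True)
class GroupComparisonResult:
    peak: PeakDefinition
    mean_exposed: float
    mean_control: float
    sd_exposed: float
    sd_control: float
    relative_change_percent: float
    test_used: TestUsed
    levene_p: float
    normality_p_ks: float  # min over the two groups
    normality_p_sw: float  # min over the two groups
    test_p: float
    significant: bool
    n_exposed: int
    n_control: int


@dataclass
class LigninChangeEstimate:
    """Per-peak relative change results plus the significant-peak summary."""

    per_peak: list[GroupComparisonResult] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant_peaks(self) -> list[GroupComparisonResult]:
        return [r for r in self.per_peak if r.significant]

    @property
    def summary_range(self) -> tuple[float, float] | None:
        """(min %, max %) of relative change over significant peaks."""
        sig = self.significant_peaks
        if not sig:
            return None
        changes = [r.relative_change_percent for r in sig]
        return (min(changes), max(changes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peak_center": r.peak.center,
                    "mean_exposed": r.mean_exposed,
                    "mean_control": r.mean_control,
                    "sd_exposed": r.sd_exposed,
                    "sd_control": r.sd_control,
                    "relative_change_percent": r.relative_change_percent,
                    "test_used": r.test_used.value,
                    "levene_p": r.levene_p,
                    "normality_p_ks": r.normality_p_ks,
                    "normality_p_sw": r.normality_p_sw,
                    "test_p": r.test_p,
                    "significant": r.significant,
                    "n_exposed": r.n_exposed,
                    "n_control": r.n_control,
                }
                for r in self.per_peak
            ]
        )


def compare_two_samples(
    exposed: np.ndarray,
    control: np.ndarray,
    alpha: float = 0.05,
    ks_method: str = "table",
    rng: np.random.Generator | None = None,
) -> tuple[TestUsed, float, float, float, float]:
    """Tiered two-group comparison.

    Returns (test_used, test_p, levene_p, min KS p, min SW p).
    """
    e = np.asarray(exposed, float)
    c = np.asarray(control, float)
    if e.size < 3 or c.size < 3:
        raise InsufficientDataError("each group needs n >= 3")
    ks_e, sw_e = _normality_p(e, ks_method, rng)
    ks_c, sw_c = _normality_p(c, ks_method, rng)
    p_ks, p_sw = min(ks_e, ks_c), min(sw_e, sw_c)

    if min(p_ks, p_sw) < alpha:
        stat_p = float(stats.kruskal(e, c).pvalue)
        return TestUsed.KRUSKAL_WALLIS, stat_p, float("nan"), p_ks, p_sw

    levene_p = float(stats.levene(e, c, center="mean").pvalue)
    if levene_p < alpha:
        stat_p = float(stats.ttest_ind(e, c, equal_var=False).pvalue)
        return TestUsed.WELCH_T, stat_p, levene_p, p_ks, p_sw
    stat_p = float(stats.ttest_ind(e, c, equal_var=True).pvalue)
    return TestUsed.STUDENT_T, stat_p, levene_p, p_ks, p_sw


def compare_groups(
    heights: pd.DataFrame,
    alpha: float = 0.05,
    ks_method: str = "table",
    seed: int | None = None,
    bonferroni: bool = False,
    curves: list[StandardCurve] | None = None,
    use_curve_mapping: bool = False,
) -> LigninChangeEstimate:
    """Per-peak exposed-vs-control comparison of a heights table.

    ``heights`` comes from :func:`compute_peak_heights`.  When
    ``use_curve_mapping`` is set, heights are first mapped through the
    matching standard curve (``(h - intercept) / slope``) before the group
    means are compared; the test p-values are unaffected because the map is
    monotone affine.
    """
    rng = np.random.default_rng(seed) if ks_method == "mc" else None
    slope_map: dict[float, StandardCurve] = {}
    if use_curve_mapping:
        if not curves:
            raise EmptyInputError("curve mapping requested but no curves given")
        slope_map = {c.peak.center: c for c in curves}

    results = []
    peak_centers = sorted(heights["peak_center"].unique())
    n_peaks = len(peak_centers)
    for center in peak_centers:
        sub = heights[heights["peak_center"] == center]
        e = sub.loc[sub["group"] == GROUP_EXPOSED, "height"].to_numpy()
        c = sub.loc[sub["group"] == GROUP_CONTROL, "height"].to_numpy()
        test_used, test_p, levene_p, p_ks, p_sw = compare_two_samples(
            e, c, alpha=alpha, ks_method=ks_method, rng=rng
        )
        if bonferroni:
            test_p = min(1.0, test_p * n_peaks)

        if use_curve_mapping:
            curve = slope_map.get(center)
            if curve is None or curve.slope == 0:
                raise EmptyInputError(f"no usable standard curve for peak {center}")
            e = (e - curve.intercept) / curve.slope
            c = (c - curve.intercept) / curve.slope

        mean_e, mean_c = float(e.mean()), float(c.mean())
        rel = 100.0 * (mean_e / mean_c - 1.0) if mean_c > 0 else float("nan")
        results.append(
            GroupComparisonResult(
                peak=PeakDefinition(center=float(center)),
                mean_exposed=mean_e,
                mean_control=mean_c,
                sd_exposed=float(e.std(ddof=1)),
                sd_control=float(c.std(ddof=1)),
                relative_change_percent=rel,
                test_used=test_used,
                levene_p=levene_p,
                normality_p_ks=p_ks,
                normality_p_sw=p_sw,
                test_p=test_p,
                significant=bool(test_p < alpha),
                n_exposed=int(e.size),
                n_control=int(c.size),
            )
        )
    return LigninChangeEstimate(per_peak=results, alpha=alpha)
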