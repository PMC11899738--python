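"""Lignin-peak discovery and standard-curve selection.

Works on preprocessed second-derivative spectra: absorbance maxima appear as
derivative *minima*, so a peak's height is defined as the negated minimum of
the derivative inside the peak window, clipped at zero.  Candidate peaks are
those present in the pure-lignin standard, absent from the pure-cellulose
standard, and matched by a sample-side peak; each candidate gets an ordinary
least-squares standard curve (height versus lignin weight fraction), and
peaks pass the selection gate when Pearson's r >= 0.75 with p < 0.05
(exact t-transform p-value, two-sided).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    InvalidDesignError,
    WindowError,
)
from .spectra import Spectrum, SpectrumSet, Stage

#: Default half-width of a peak window and peak-match tolerance (cm^-1);
#: peaks cannot be localized better than the 4 cm^-1 instrument resolution.
DEFAULT_MATCH_TOLERANCE = 4.0

DERIVATIVE_STAGES = (Stage.SECOND_DERIVATIVE, Stage.EMSC_CORRECTED)


class PeakSource(str, enum.Enum):
    STANDARDS = "standards"
    SAMPLES = "samples"
    MATCHED = "matched"


@dataclass(frozen=True)
class PeakDefinition:
    """A candidate peak: sub-grid center plus its extraction window."""

    center: float
    window_halfwidth: float = DEFAULT_MATCH_TOLERANCE
    source: PeakSource = PeakSource.STANDARDS

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise InvalidDesignError("peak window halfwidth must be > 0")
        if not isinstance(self.source, PeakSource):
            object.__setattr__(self, "source", PeakSource(self.source))


def peak_height(s: Spectrum, peak: PeakDefinition) -> tuple[float, bool]:
    """Height = -(minimum of the second derivative inside the window),
    clipped at 0.  Returns (height, flagged); flagged means no negative
    minimum existed in the window."""
    mask = np.abs(s.grid - peak.center) <= peak.window_halfwidth
    if not mask.any():
        raise WindowError(
            f"peak window {peak.center}±{peak.window_halfwidth} cm^-1 "
            "contains no grid points"
        )
    minimum = float(s.values[mask].min())
    if minimum >= 0.0:
        return 0.0, True
    return -minimum, False


def _parabolic_refine(grid: np.ndarray, values: np.ndarray, i: int) -> float:
    """Sub-grid vertex of the parabola through points i-1, i, i+1."""
    if i == 0 or i == values.size - 1:
        return float(grid[i])
    y0, y1, y2 = values[i - 1 : i + 2]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(grid[i])
    shift = 0.5 * (y0 - y2) / denom
    spacing = grid[min(i + 1, grid.size - 1)] - grid[i]
    return float(grid[i] + np.clip(shift, -1.0, 1.0) * spacing)


def detect_peaks(
    second_derivative: Spectrum,
    prominence_floor: float = 0.05,
    window_halfwidth: float = DEFAULT_MATCH_TOLERANCE,
    source: PeakSource = PeakSource.STANDARDS,
) -> list[PeakDefinition]:
    """Local minima of the second derivative whose magnitude reaches
    ``prominence_floor`` times the global maximum magnitude.

    Centers are refined by a 3-point parabola; results are ordered by
    wavenumber.  A flat (or nowhere-negative) spectrum yields an empty list.
    """
    second_derivative.require_stage(DERIVATIVE_STAGES, "detect_peaks")
    v = second_derivative.values
    magnitude = -v
    max_mag = float(magnitude.max(initial=0.0))
    if max_mag <= 0.0:
        return []
    threshold = prominence_floor * max_mag
    # interior local maxima of the magnitude; the prominence requirement
    # prunes noise ripples riding on the flank of a larger band
    from scipy.signal import find_peaks

    idx, _ = find_peaks(magnitude, height=threshold, prominence=threshold)
    peaks = [
        PeakDefinition(
            center=_parabolic_refine(second_derivative.grid, magnitude * -1.0, i),
            window_halfwidth=window_halfwidth,
            source=source,
        )
        for i in idx
    ]
    return sorted(peaks, key=lambda p: p.center)


def _endpoint(standards: SpectrumSet, fraction: float, tol: float = 1e-9) -> Spectrum:
    for s in standards:
        if s.lignin_fraction is not None and abs(s.lignin_fraction - fraction) <= tol:
            return s
    raise InvalidDesignError(
        f"standards must include a pure endpoint at fraction {fraction:g}"
    )


def _mean_spectrum(sset: SpectrumSet) -> Spectrum:
    first = sset[0]
    return Spectrum(
        grid=first.grid,
        values=sset.values_matrix().mean(axis=0),
        stage=first.stage,
        sample_id="<mean>",
        group=first.group,
    )


def find_lignin_specific_peaks(
    standards: SpectrumSet,
    samples: SpectrumSet,
    match_tolerance: float = DEFAULT_MATCH_TOLERANCE,
    prominence_floor: float = 0.05,
    veto_prominence_floor: float = 0.2,
) -> list[PeakDefinition]:
    """Peaks present in pure lignin, absent from pure cellulose, and matched
    in the samples.

    Both sets must be preprocessed second-derivative spectra; standards must
    include the fraction-0 and fraction-1 endpoints.  The returned centers
    are the sample-side centers.  The cellulose veto uses its own (higher)
    prominence floor: only a substantive cellulose band disqualifies a
    candidate, not a noise wiggle in an otherwise featureless region.
    """
    lignin_end = _endpoint(standards, 1.0)
    cellulose_end = _endpoint(standards, 0.0)
    lignin_peaks = detect_peaks(lignin_end, prominence_floor, match_tolerance)
    cellulose_centers = np.array(
        [
            p.center
            for p in detect_peaks(cellulose_end, veto_prominence_floor, match_tolerance)
        ]
    )
    sample_peaks = detect_peaks(
        _mean_spectrum(samples), prominence_floor, match_tolerance,
        source=PeakSource.SAMPLES,
    )
    sample_centers = np.array([p.center for p in sample_peaks])

    matched: list[PeakDefinition] = []
    used_sample_idx: set[int] = set()
    for lp in lignin_peaks:
        if cellulose_centers.size and np.min(
            np.abs(cellulose_centers - lp.center)
        ) <= match_tolerance:
            continue  # not lignin-specific
        if not sample_centers.size:
            continue
        j = int(np.argmin(np.abs(sample_centers - lp.center)))
        if abs(sample_centers[j] - lp.center) > match_tolerance or j in used_sample_idx:
            continue
        used_sample_idx.add(j)
        matched.append(
            PeakDefinition(
                center=float(sample_centers[j]),
                window_halfwidth=match_tolerance,
                source=PeakSource.MATCHED,
            )
        )
    return sorted(matched, key=lambda p: p.center)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of peak height versus lignin weight fraction."""

    peak: PeakDefinition
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    @property
    def informative(self) -> bool:
        return np.isfinite(self.pearson_r)


def build_standard_curves(
    peaks: list[PeakDefinition], standards: SpectrumSet
) -> list[StandardCurve]:
    """One OLS standard curve per candidate peak.

    Pearson's r carries a two-sided p-value from the exact t-transform with
    n - 2 degrees of freedom.  A peak whose heights do not vary across the
    standards gets ``pearson_r = nan`` / ``p_value = 1`` and is flagged
    non-informative (it can never be selected).
    """
    if not peaks:
        raise EmptyInputError("no candidate peaks to calibrate")
    fractions = np.array([s.lignin_fraction for s in standards], dtype=float)
    if np.any(np.isnan(fractions)):
        raise InvalidDesignError("every standard needs a known lignin fraction")
    if np.unique(fractions).size < 3:
        raise DegenerateInputError(
            "need >= 3 standards with distinct lignin fractions"
        )
    curves = []
    for peak in peaks:
        heights = np.array([peak_height(s, peak)[0] for s in standards])
        n = heights.size
        if np.ptp(heights) == 0.0:
            curves.append(
                StandardCurve(peak, 0.0, float(heights[0]), float("nan"), 1.0, n)
            )
            continue
        fit = stats.linregress(fractions, heights)
        curves.append(
            StandardCurve(
                peak=peak,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                pearson_r=float(fit.rvalue),
                p_value=float(fit.pvalue),
                n=n,
            )
        )
    return curves


@dataclass
class SelectedPeakSet:
    """Peaks whose standard curves pass the correlation gate."""

    peaks: list[PeakDefinition] = field(default_factory=list)
    curves: list[StandardCurve] = field(default_factory=list)
    r_min: float = 0.75
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.peaks)

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])


def select_peaks(
    curves: list[StandardCurve], r_min: float = 0.75, alpha: float = 0.05
) -> SelectedPeakSet:
    """Keep curves with ``pearson_r >= r_min`` and ``p_value < alpha``.

    The gate is inclusive on r (r == r_min passes) and exclusive on alpha.
    An empty selection is allowed but warned about.
    """
    if not curves:
        raise EmptyInputError("no standard curves to select from")
    kept = [
        c
        for c in curves
        if c.informative and c.pearson_r >= r_min and c.p_value < alpha
    ]
    kept.sort(key=lambda c: c.peak.center)
    if not kept:
        warnings.warn("no peaks passed the selection gate", stacklevel=2)
    return SelectedPeakSet(
        peaks=[c.peak for c in kept], curves=kept, r_min=r_min, alpha=alpha
    )


def calibration_report(curves: list[StandardCurve], selected: SelectedPeakSet):
    """Tabular calibration report (one row per candidate peak)."""
    import pandas as pd

    chosen = {id(c) for c in selected.curves}
    return pd.DataFrame(
        [
            {
                "peak_center_cm-1": c.peak.center,
                "window_halfwidth_cm-1": c.peak.window_halfwidth,
                "slope": c.slope,
                "intercept": c.intercept,
                "pearson_r": c.pearson_r,
                "p_value": c.p_value,
                "n": c.n,
                "selected": id(c) in chosen,
            }
            for c in curves
        ]
    )
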