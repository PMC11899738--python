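"""Spectral pretreatment chain.

Replicate averaging, ATR penetration-depth compensation, unit vector
normalization (UVN), Savitzky-Golay second-derivative filtering, and
extended multiplicative scatter correction (EMSC), composed in that order by
:func:`run_pretreatment` and windowed to the 800-1800 cm^-1 fingerprint
region.

Notes on the defaults:

* "Basic" ATR correction is the minimal pointwise ``wavenumber / reference``
  rescaling that undoes the 1/wavenumber penetration-depth weighting of ATR
  absorbance; it can be disabled.
* EMSC is applied *after* the derivative by default, with the reference
  computed from the derivative spectra; a switch restores the conventional
  pre-derivative order.
* In the composed pipeline the EMSC reference is rescaled to unit Euclidean
  norm, which makes the pipeline output invariant to per-spectrum affine
  scatter (the standalone operation keeps the plain mean reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateFitError,
    DegenerateInputError,
    DomainError,
    EmptyInputError,
    ParameterError,
    ResampleRequiredError,
)
from .spectra import (
    DEFAULT_ATR_REFERENCE,
    FINGERPRINT_WINDOW,
    Spectrum,
    SpectrumSet,
    Stage,
)

__all__ = [
    "average_replicates",
    "atr_correct",
    "unit_vector_normalize",
    "savgol_second_derivative",
    "emsc_correct",
    "resample",
    "run_pretreatment",
    "PretreatmentConfig",
    "PretreatmentResult",
]


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Pointwise mean of the replicate scans of each sample.

    Returns one spectrum per sample id, in order of first appearance, with
    the sample's metadata preserved.  The shared-grid requirement is
    enforced by :class:`SpectrumSet` itself.
    """
    averaged = []
    for sample_id, scans in sset.by_sample().items():
        mean_values = np.mean([s.values for s in scans], axis=0)
        first = scans[0]
        averaged.append(
            Spectrum(
                grid=first.grid,
                values=mean_values,
                stage=Stage.AVERAGED,
                sample_id=sample_id,
                group=first.group,
                lignin_fraction=first.lignin_fraction,
                scan_index=None,
            )
        )
    return SpectrumSet(averaged)


def atr_correct(
    s: Spectrum, reference_wavenumber: float = DEFAULT_ATR_REFERENCE
) -> Spectrum:
    """Rescale intensities by ``wavenumber / reference_wavenumber``.

    Compensates the 1/wavenumber effective-path-length weighting of ATR
    absorbance; the value at the reference wavenumber is unchanged.
    """
    s.require_stage((Stage.RAW, Stage.AVERAGED), "atr_correct")
    if reference_wavenumber <= 0:
        raise DomainError("reference wavenumber must be positive")
    if np.any(s.grid <= 0):
        raise DomainError("ATR correction requires positive wavenumbers")
    return s.evolve(s.values * (s.grid / reference_wavenumber), Stage.ATR_CORRECTED)


def unit_vector_normalize(s: Spectrum) -> Spectrum:
    """Scale the spectrum to unit Euclidean norm over its current window."""
    s.require_stage(
        (Stage.RAW, Stage.AVERAGED, Stage.ATR_CORRECTED), "unit_vector_normalize"
    )
    norm = float(np.linalg.norm(s.values))
    if norm == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    return s.evolve(s.values / norm, Stage.NORMALIZED)


def savgol_second_derivative(
    s: Spectrum, window_points: int = 15, poly_order: int = 2
) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavenumber.

    Values are scaled by the squared grid spacing so units are
    absorbance / cm^2.  The first and last ``(window_points - 1) // 2``
    points, where the filter window would extend past the data, are dropped
    rather than flagged: the returned spectrum contains interior points
    only, so nothing invalid can leak into downstream peak work.
    """
    s.require_stage(
        (Stage.RAW, Stage.AVERAGED, Stage.ATR_CORRECTED, Stage.NORMALIZED),
        "savgol_second_derivative",
    )
    if window_points % 2 == 0:
        raise ParameterError("SG window must be odd")
    if window_points <= poly_order:
        raise ParameterError("SG window must exceed the polynomial order")
    if len(s) < window_points:
        raise ParameterError(
            f"series length {len(s)} shorter than SG window {window_points}"
        )
    if not s.has_uniform_grid():
        raise ResampleRequiredError(
            "SG derivative requires a uniform grid; call resample() first"
        )
    spacing = float(s.grid[1] - s.grid[0])
    deriv = savgol_filter(
        s.values, window_length=window_points, polyorder=poly_order, deriv=2,
        delta=spacing,
    )
    half = (window_points - 1) // 2
    return s.evolve(
        deriv[half:-half], Stage.SECOND_DERIVATIVE, grid=s.grid[half:-half]
    )


def resample(s: Spectrum, new_grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``new_grid`` (stage is preserved)."""
    new_grid = np.asarray(new_grid, dtype=float)
    if new_grid.min() < s.grid.min() or new_grid.max() > s.grid.max():
        raise DomainError("resample target grid extends beyond the data")
    return replace(s, grid=new_grid, values=np.interp(new_grid, s.grid, s.values))


def _emsc_basis(grid: np.ndarray, reference: np.ndarray, poly_order: int) -> np.ndarray:
    """Design matrix [1, p_1..p_k, reference] with orthogonalized polynomial
    columns (Legendre on the grid rescaled to [-1, 1])."""
    x = (2.0 * grid - grid[0] - grid[-1]) / (grid[-1] - grid[0])
    cols = [np.ones_like(x)]
    for k in range(1, poly_order + 1):
        coeffs = np.zeros(k + 1)
        coeffs[k] = 1.0
        cols.append(np.polynomial.legendre.legval(x, coeffs))
    cols.append(reference)
    return np.column_stack(cols)


def emsc_correct(
    sset: SpectrumSet,
    poly_order: int = 2,
    reference: np.ndarray | None = None,
    normalize_reference: bool = False,
    b_floor: float = 1e-6,
) -> SpectrumSet:
    """Extended multiplicative scatter correction against a common reference.

    Each spectrum ``x`` is least-squares decomposed as
    ``x = a*1 + b*ref + sum_k d_k p_k + e`` with polynomial baseline terms
    ``p_k`` up to ``poly_order``, and replaced by ``ref + e/b``.  The default
    reference is the pointwise mean of the set; pass ``reference`` to pin it,
    or ``normalize_reference=True`` to rescale it to unit norm (making the
    output invariant to a common intensity scale).
    """
    if len(sset) < 2 and reference is None:
        raise DegenerateInputError("EMSC needs >= 2 spectra to form a reference")
    X = sset.values_matrix()
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != sset.grid.size:
        raise DomainError("EMSC reference length does not match the grid")
    if normalize_reference:
        nrm = float(np.linalg.norm(ref))
        if nrm == 0.0:
            raise DegenerateInputError("EMSC reference is identically zero")
        ref = ref / nrm
    basis = _emsc_basis(sset.grid, ref, poly_order)
    coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    fitted = basis @ coef
    residual = X.T - fitted
    b = coef[-1]
    corrected = []
    for j, s in enumerate(sset):
        if abs(b[j]) < b_floor:
            raise DegenerateFitError(
                f"EMSC: spectrum '{s.sample_id}' unrelated to the reference "
                f"(|b| = {abs(b[j]):.2e})"
            )
        corrected.append(s.evolve(ref + residual[:, j] / b[j], Stage.EMSC_CORRECTED))
    return SpectrumSet(corrected)


def _scale_free_reference(sset: SpectrumSet) -> np.ndarray:
    """Mean of the per-spectrum unit-normalized values.

    Unlike the plain mean, this reference is invariant to per-spectrum
    intensity scaling, which makes the composed pipeline exactly invariant
    to affine scatter distortions of the raw scans.
    """
    X = sset.values_matrix()
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateInputError("cannot form a reference from a zero spectrum")
    return (X / norms).mean(axis=0)


@dataclass(frozen=True)
class PretreatmentConfig:
    """Every knob of the composed pretreatment chain."""

    atr_enabled: bool = True
    atr_reference: float = DEFAULT_ATR_REFERENCE
    sg_window: int = 15
    sg_poly_order: int = 2
    emsc_poly_order: int = 2
    emsc_before_derivative: bool = False
    emsc_normalize_reference: bool = True
    window: tuple[float, float] = FINGERPRINT_WINDOW


@dataclass
class PretreatmentResult:
    spectra: SpectrumSet
    log: list[str] = field(default_factory=list)


def run_pretreatment(
    sset: SpectrumSet | list[Spectrum],
    config: PretreatmentConfig | None = None,
) -> PretreatmentResult:
    """Average replicates, correct, differentiate, scatter-correct, window.

    Order: average -> ATR -> UVN -> SG second derivative -> EMSC (EMSC moves
    before the derivative when ``emsc_before_derivative`` is set), then
    restriction to the fingerprint window.  A line-oriented log records each
    stage applied.
    """
    if isinstance(sset, list):
        if not sset:
            raise EmptyInputError("run_pretreatment received an empty set")
        sset = SpectrumSet(sset)
    cfg = config or PretreatmentConfig()
    log: list[str] = []

    out = average_replicates(sset)
    log.append(f"average_replicates: {len(sset)} scans -> {len(out)} samples")

    if cfg.atr_enabled:
        out = SpectrumSet([atr_correct(s, cfg.atr_reference) for s in out])
        log.append(f"atr_correct: reference {cfg.atr_reference:g} cm^-1")
    out = SpectrumSet([unit_vector_normalize(s) for s in out])
    log.append("unit_vector_normalize")

    if cfg.emsc_before_derivative:
        out = emsc_correct(
            out,
            poly_order=cfg.emsc_poly_order,
            reference=_scale_free_reference(out)
            if cfg.emsc_normalize_reference
            else None,
            normalize_reference=cfg.emsc_normalize_reference,
        )
        # evolve() forbids revisiting earlier stages, so rebuild at the
        # pre-derivative stage for the SG step that follows.
        out = SpectrumSet(
            [replace(s, stage=Stage.NORMALIZED) for s in out]
        )
        log.append(f"emsc_correct (pre-derivative): poly order {cfg.emsc_poly_order}")

    out = SpectrumSet(
        [
            savgol_second_derivative(s, cfg.sg_window, cfg.sg_poly_order)
            for s in out
        ]
    )
    log.append(
        f"savgol_second_derivative: window {cfg.sg_window}, order {cfg.sg_poly_order}"
    )

    if not cfg.emsc_before_derivative:
        out = emsc_correct(
            out,
            poly_order=cfg.emsc_poly_order,
            reference=_scale_free_reference(out)
            if cfg.emsc_normalize_reference
            else None,
            normalize_reference=cfg.emsc_normalize_reference,
        )
        log.append(f"emsc_correct: poly order {cfg.emsc_poly_order}")

    lo, hi = cfg.window
    out = out.window(lo, hi)
    log.append(f"window: {lo:g}-{hi:g} cm^-1 ({out.grid.size} points)")
    return PretreatmentResult(spectra=out, log=log)
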