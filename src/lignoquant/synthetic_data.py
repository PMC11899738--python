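"""Synthetic ground-truth generators for every pipeline input.

Generates binary lignin/cellulose mixture spectra, plant cohort spectra with
a configurable relative lignin difference, four-parameter-logistic
dose-response tables, and gene-universe draws with planted category
enrichment.  All randomness flows through a single seeded
``numpy.random.Generator`` per call, so a fixed seed reproduces the output
bit for bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dose_response import four_parameter_logistic
from .errors import InvalidDesignError
from .spectra import (
    DEFAULT_ATR_REFERENCE,
    GROUP_CONTROL,
    GROUP_EXPOSED,
    GROUP_STANDARD,
    Spectrum,
    SpectrumSet,
    Stage,
    write_spectrum_set,
)


class BandShape(str, enum.Enum):
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"


@dataclass(frozen=True)
class Band:
    """A single vibrational band.

    ``width`` is the Gaussian sigma (or Lorentzian half-width at half
    maximum) in cm^-1; ``amplitude`` is the peak absorbance.
    """

    center: float
    width: float
    amplitude: float
    shape: BandShape = BandShape.GAUSSIAN

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidDesignError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise InvalidDesignError(
                f"band amplitude must be >= 0, got {self.amplitude}"
            )
        if not isinstance(self.shape, BandShape):
            object.__setattr__(self, "shape", BandShape(self.shape))

    def profile(self, grid: np.ndarray) -> np.ndarray:
        d = grid - self.center
        if self.shape is BandShape.GAUSSIAN:
            return self.amplitude * np.exp(-0.5 * (d / self.width) ** 2)
        return self.amplitude * self.width**2 / (d**2 + self.width**2)


@dataclass(frozen=True)
class ComponentProfile:
    """A pure-component spectrum model: a named sum of bands."""

    name: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise InvalidDesignError("a component profile needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))

    def spectrum(self, grid: np.ndarray) -> np.ndarray:
        out = np.zeros_like(grid, dtype=float)
        for band in self.bands:
            out += band.profile(grid)
        return out

    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])


# Lignin aromatic-band doublets; widths chosen so neighbouring doublet
# members (6-8 cm^-1 apart) remain resolvable in the second derivative.
DEFAULT_LIGNIN_PROFILE = ComponentProfile(
    "lignin",
    (
        Band(1417.0, 3.0, 0.90),
        Band(1423.0, 3.0, 0.80),
        Band(1464.0, 3.0, 0.55),
        Band(1472.0, 3.0, 0.50),
        Band(1515.0, 3.0, 1.00),
        Band(1521.0, 3.0, 0.70),
        Band(1617.0, 3.0, 0.85),
        Band(1623.0, 3.0, 0.60),
    ),
)

# Polysaccharide bands (cellulose backbone / C-O stretching region);
# broader than the lignin bands and separated from every lignin band by far
# more than the 4 cm^-1 match tolerance, so "lignin-specific" is decidable
# by construction.  Widths are set so the two pure components carry
# comparable weight in second-derivative space, which keeps the composed
# pretreatment chain close to affine in the mixture fraction.
DEFAULT_CELLULOSE_PROFILE = ComponentProfile(
    "cellulose",
    (
        Band(898.0, 6.0, 0.45),
        Band(1030.0, 6.0, 1.10),
        Band(1060.0, 6.0, 0.90),
        Band(1110.0, 6.0, 0.60),
        Band(1160.0, 6.0, 0.45),
        Band(1315.0, 6.0, 0.40),
        Band(1370.0, 6.0, 0.50),
    ),
)


def validate_profiles(
    lignin: ComponentProfile,
    cellulose: ComponentProfile,
    min_separation: float = 4.0,
) -> None:
    """Reject profile pairs whose band centers are closer than the peak-match
    tolerance (those bands would not be component-specific)."""
    lc = lignin.centers()[:, None]
    cc = cellulose.centers()[None, :]
    gap = np.abs(lc - cc).min()
    if gap < min_separation:
        raise InvalidDesignError(
            f"lignin and cellulose band centers separated by {gap:.2f} cm^-1 "
            f"(< {min_separation}); component-specific peaks are undefined"
        )


@dataclass(frozen=True)
class InstrumentModel:
    """Wavenumber grid plus scan-level distortion magnitudes.

    Distortions: a lognormal multiplicative scatter factor, an additive
    polynomial baseline with per-order Gaussian coefficients, iid Gaussian
    noise, and an optional 1/wavenumber ATR intensity weighting -- exactly
    the effects the pretreatment chain is designed to remove.
    """

    grid_start: float = 800.0
    grid_stop: float = 1800.0
    spacing: float = 0.5
    scatter_multiplier_sd: float = 0.05
    baseline_poly_coeffs_sd: tuple[float, ...] = (0.01, 0.01, 0.01)
    noise_sd: float = 0.001
    atr_distortion: bool = True
    atr_reference: float = DEFAULT_ATR_REFERENCE

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise InvalidDesignError("grid spacing must be > 0")
        if self.grid_start > 800.0 or self.grid_stop < 1800.0:
            raise InvalidDesignError(
                "grid must cover at least the 800-1800 cm^-1 fingerprint window"
            )
        for sd in (self.scatter_multiplier_sd, self.noise_sd, *self.baseline_poly_coeffs_sd):
            if sd < 0:
                raise InvalidDesignError("distortion sds must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.spacing)) + 1
        return self.grid_start + self.spacing * np.arange(n)

    def is_noiseless(self) -> bool:
        return (
            self.scatter_multiplier_sd == 0
            and self.noise_sd == 0
            and all(sd == 0 for sd in self.baseline_poly_coeffs_sd)
        )

    def distort(
        self, ideal: np.ndarray, grid: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Apply one scan's worth of instrument distortions to an ideal
        absorbance spectrum.  Draws from ``rng`` in a fixed order."""
        values = ideal.copy()
        if self.atr_distortion:
            values = values * (self.atr_reference / grid)
        multiplier = (
            np.exp(rng.normal(0.0, self.scatter_multiplier_sd))
            if self.scatter_multiplier_sd > 0
            else 1.0
        )
        x = (grid - grid.mean()) / (0.5 * (grid[-1] - grid[0]))  # scaled to [-1, 1]
        baseline = np.zeros_like(grid)
        for order, sd in enumerate(self.baseline_poly_coeffs_sd):
            coeff = rng.normal(0.0, sd) if sd > 0 else 0.0
            baseline += coeff * x**order
        noise = rng.normal(0.0, self.noise_sd, grid.size) if self.noise_sd > 0 else 0.0
        return multiplier * values + baseline + noise


def noiseless_instrument(**overrides) -> InstrumentModel:
    """An instrument with every distortion switched off (ATR weighting too)."""
    defaults = dict(
        scatter_multiplier_sd=0.0,
        baseline_poly_coeffs_sd=(0.0,),
        noise_sd=0.0,
        atr_distortion=False,
    )
    defaults.update(overrides)
    return InstrumentModel(**defaults)


# ---------------------------------------------------------------------------
# Mixture standards
# ---------------------------------------------------------------------------


def generate_mixture_series(
    lignin_profile: ComponentProfile = DEFAULT_LIGNIN_PROFILE,
    cellulose_profile: ComponentProfile = DEFAULT_CELLULOSE_PROFILE,
    n_mixtures: int = 13,
    instrument: InstrumentModel | None = None,
    seed: int = 0,
    n_scans: int = 1,
) -> SpectrumSet:
    """Binary mixture standards with evenly spaced lignin fractions on [0, 1].

    Each mixture's ideal absorbance is the convex combination
    ``fraction * lignin + (1 - fraction) * cellulose`` of the pure component
    spectra, subsequently passed through the instrument distortion model.
    The true fraction rides along on every emitted spectrum.
    """
    if n_mixtures < 3:
        raise InvalidDesignError(
            f"need at least 3 mixtures to correlate afterwards, got {n_mixtures}"
        )
    validate_profiles(lignin_profile, cellulose_profile)
    instrument = instrument or InstrumentModel()
    grid = instrument.grid()
    rng = np.random.default_rng(seed)
    lignin = lignin_profile.spectrum(grid)
    cellulose = cellulose_profile.spectrum(grid)
    fractions = np.linspace(0.0, 1.0, n_mixtures)
    spectra = []
    for i, f in enumerate(fractions):
        ideal = f * lignin + (1.0 - f) * cellulose
        for scan in range(n_scans):
            spectra.append(
                Spectrum(
                    grid=grid,
                    values=instrument.distort(ideal, grid, rng),
                    stage=Stage.RAW,
                    sample_id=f"std{i:02d}",
                    group=GROUP_STANDARD,
                    lignin_fraction=float(f),
                    scan_index=scan,
                )
            )
    return SpectrumSet(spectra)


# ---------------------------------------------------------------------------
# Plant cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of an exposed-vs-control cohort with replicate scans."""

    n_exposed: int = 16
    n_control: int = 33
    n_scans_per_sample: int = 3
    lignin_fraction_control: float = 0.2
    lignin_change_percent: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exposed, self.n_control, self.n_scans_per_sample) < 1:
            raise InvalidDesignError("cohort counts must all be >= 1")
        if not 0.0 <= self.lignin_fraction_control <= 1.0:
            raise InvalidDesignError("control lignin fraction must be in [0, 1]")
        f = self.lignin_fraction_exposed
        if not 0.0 <= f <= 1.0:
            raise InvalidDesignError(
                f"exposed lignin fraction {f:.3f} falls outside [0, 1]"
            )

    @property
    def lignin_fraction_exposed(self) -> float:
        return self.lignin_fraction_control * (1.0 + self.lignin_change_percent / 100.0)


def generate_cohort(
    spec: CohortSpec,
    lignin_profile: ComponentProfile = DEFAULT_LIGNIN_PROFILE,
    cellulose_profile: ComponentProfile = DEFAULT_CELLULOSE_PROFILE,
    instrument: InstrumentModel | None = None,
) -> SpectrumSet:
    """Exposed and control plant spectra with replicate scans per sample.

    Every scan of a sample shares the sample's composition; distortions and
    noise are drawn independently per scan.
    """
    validate_profiles(lignin_profile, cellulose_profile)
    instrument = instrument or InstrumentModel()
    grid = instrument.grid()
    rng = np.random.default_rng(spec.seed)
    lignin = lignin_profile.spectrum(grid)
    cellulose = cellulose_profile.spectrum(grid)

    def make(sample_id: str, group: str, fraction: float) -> list[Spectrum]:
        ideal = fraction * lignin + (1.0 - fraction) * cellulose
        return [
            Spectrum(
                grid=grid,
                values=instrument.distort(ideal, grid, rng),
                stage=Stage.RAW,
                sample_id=sample_id,
                group=group,
                lignin_fraction=fraction,
                scan_index=scan,
            )
            for scan in range(spec.n_scans_per_sample)
        ]

    spectra: list[Spectrum] = []
    for i in range(spec.n_exposed):
        spectra.extend(make(f"exp{i:02d}", GROUP_EXPOSED, spec.lignin_fraction_exposed))
    for i in range(spec.n_control):
        spectra.extend(make(f"ctl{i:02d}", GROUP_CONTROL, spec.lignin_fraction_control))
    return SpectrumSet(spectra)


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseTruth:
    """Ground-truth parameters of a four-parameter logistic response."""

    bottom: float = 0.0
    top: float = 100.0
    ec50: float = 8.1
    hill: float = 1.5
    noise_sd: float = 0.0
    doses: tuple[float, ...] = (0.0, 1.0, 2.5, 5.0, 10.0, 25.0)

    def __post_init__(self) -> None:
        if self.top == self.bottom:
            raise InvalidDesignError("top and bottom responses must differ")
        if self.ec50 <= 0:
            raise InvalidDesignError("ec50 must be > 0")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        if len(set(self.doses)) < 4:
            raise InvalidDesignError(
                "need at least 4 distinct doses for a 4-parameter model"
            )
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))


def generate_dose_response(
    truth: DoseResponseTruth, seed: int = 0, replicates: int = 1
) -> pd.DataFrame:
    """Dose/response table from the 4PL model plus Gaussian noise.

    Dose-0 rows carry the asymptotic control response (``top`` for a
    positive Hill slope).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for dose in truth.doses:
        clean = four_parameter_logistic(
            np.array([dose]), truth.bottom, truth.top, truth.ec50, truth.hill
        )[0]
        for rep in range(replicates):
            noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
            rows.append({"dose": dose, "replicate": rep, "response": clean + noise})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Enrichment universes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategorySpec:
    label: str
    size: int
    planted_enrichment: float = 1.0


@dataclass
class EnrichmentUniverse:
    """A gene/category membership draw with its planted ground truth."""

    genes: pd.DataFrame  # columns: gene_id, category, is_deg
    categories: pd.DataFrame  # columns: term, size, observed, planted_enrichment
    universe_size: int
    n_deg: int


def generate_enrichment_universe(
    universe_size: int,
    n_deg: int,
    categories: Sequence[CategorySpec | tuple],
    seed: int = 0,
) -> EnrichmentUniverse:
    """Draw a DEG set over disjoint gene categories with planted enrichment.

    Each category's expected DEG count is
    ``size * (n_deg / universe_size) * planted_enrichment`` (clipped to what
    is feasible given the total DEG budget).
    """
    cats = [c if isinstance(c, CategorySpec) else CategorySpec(*c) for c in categories]
    if n_deg > universe_size:
        raise InvalidDesignError("n_deg cannot exceed the universe size")
    if sum(c.size for c in cats) > universe_size:
        raise InvalidDesignError("category sizes exceed the universe")
    base_rate = n_deg / universe_size
    for c in cats:
        if c.size > universe_size:
            raise InvalidDesignError(f"category {c.label} larger than universe")
        if c.planted_enrichment < 0:
            raise InvalidDesignError("planted enrichment must be >= 0")
        if c.size * base_rate * c.planted_enrichment > c.size + 1e-12:
            raise InvalidDesignError(
                f"category {c.label}: expected DEG count exceeds category size"
            )

    rng = np.random.default_rng(seed)
    order = rng.permutation(universe_size)
    gene_ids = np.array([f"g{i:06d}" for i in range(universe_size)])
    membership = np.full(universe_size, "", dtype=object)
    pos = 0
    blocks: dict[str, np.ndarray] = {}
    for c in cats:
        idx = order[pos : pos + c.size]
        membership[idx] = c.label
        blocks[c.label] = idx
        pos += c.size
    background = order[pos:]

    is_deg = np.zeros(universe_size, dtype=bool)
    remaining = n_deg
    observed: dict[str, int] = {}
    for c in cats:
        p = min(1.0, base_rate * c.planted_enrichment)
        count = int(rng.binomial(c.size, p)) if p > 0 else 0
        count = min(count, remaining)
        chosen = rng.choice(blocks[c.label], size=count, replace=False)
        is_deg[chosen] = True
        observed[c.label] = count
        remaining -= count
    if remaining > background.size:
        raise InvalidDesignError(
            "too few background genes to place the remaining DEGs"
        )
    if remaining > 0:
        chosen = rng.choice(background, size=remaining, replace=False)
        is_deg[chosen] = True

    genes = pd.DataFrame(
        {"gene_id": gene_ids, "category": membership, "is_deg": is_deg}
    )
    cat_table = pd.DataFrame(
        {
            "term": [c.label for c in cats],
            "size": [c.size for c in cats],
            "observed": [observed[c.label] for c in cats],
            "planted_enrichment": [c.planted_enrichment for c in cats],
            "expected_null": [c.size * base_rate for c in cats],
        }
    )
    return EnrichmentUniverse(
        genes=genes, categories=cat_table, universe_size=universe_size, n_deg=n_deg
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def write_cohort_with_truth(
    sset: SpectrumSet, spec: CohortSpec, directory: str | Path
) -> Path:
    """Write scan CSVs, manifest, and a ground-truth sidecar."""
    directory = Path(directory)
    manifest = write_spectrum_set(sset, directory)
    write_ground_truth(
        {
            "n_exposed": spec.n_exposed,
            "n_control": spec.n_control,
            "n_scans_per_sample": spec.n_scans_per_sample,
            "lignin_fraction_control": spec.lignin_fraction_control,
            "lignin_fraction_exposed": spec.lignin_fraction_exposed,
            "lignin_change_percent": spec.lignin_change_percent,
            "seed": spec.seed,
        },
        directory / "ground_truth.yaml",
    )
    return manifest
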