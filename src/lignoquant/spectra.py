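"""Spectral containers and plain-text I/O.

A :class:`Spectrum` couples a strictly monotone wavenumber grid (cm^-1) with
absorbance (or derivative) values and carries sample metadata plus a *stage*
tag.  Stages advance in a fixed order so that a correction cannot be applied
twice or out of sequence.  A :class:`SpectrumSet` is a non-empty collection of
spectra sharing one grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GridMismatchError, StageError

#: Wavenumber at which the ATR penetration-depth weighting is anchored.
DEFAULT_ATR_REFERENCE = 2000.0

#: Fingerprint window bounds (cm^-1) used for peak work.
FINGERPRINT_WINDOW = (800.0, 1800.0)

GROUP_STANDARD = "standard"
GROUP_EXPOSED = "exposed"
GROUP_CONTROL = "control"


class Stage(str, enum.Enum):
    """Processing stages in their only admissible order."""

    RAW = "raw"
    AVERAGED = "averaged"
    ATR_CORRECTED = "atr_corrected"
    NORMALIZED = "normalized"
    SECOND_DERIVATIVE = "second_derivative"
    EMSC_CORRECTED = "emsc_corrected"

    @property
    def index(self) -> int:
        return _STAGE_ORDER.index(self)


_STAGE_ORDER = list(Stage)


@dataclass(frozen=True)
class Spectrum:
    """One scan (or derived spectrum) on a wavenumber grid.

    Parameters
    ----------
    grid:
        Strictly monotone increasing wavenumbers in cm^-1.
    values:
        Absorbance (or second-derivative) values, same length as ``grid``.
    stage:
        Current processing stage; transitions are forward-only.
    sample_id, group:
        Sample metadata.  ``group`` is one of ``standard``, ``exposed``,
        ``control`` (or empty).
    lignin_fraction:
        Known lignin weight fraction, for standards and synthetic truth.
    scan_index:
        Replicate scan number within a sample, if applicable.
    """

    grid: np.ndarray
    values: np.ndarray
    stage: Stage = Stage.RAW
    sample_id: str = ""
    group: str = ""
    lignin_fraction: float | None = None
    scan_index: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or values.ndim != 1:
            raise ValueError("grid and values must be one-dimensional")
        if grid.size != values.size:
            raise ValueError(
                f"grid length {grid.size} != values length {values.size}"
            )
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly monotone increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if not isinstance(self.stage, Stage):
            object.__setattr__(self, "stage", Stage(self.stage))

    def __len__(self) -> int:
        return self.grid.size

    @property
    def spacing(self) -> float:
        """Median grid spacing in cm^-1."""
        return float(np.median(np.diff(self.grid)))

    def has_uniform_grid(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.grid)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))

    def require_stage(self, allowed: Sequence[Stage], op: str) -> None:
        if self.stage not in allowed:
            names = ", ".join(s.value for s in allowed)
            raise StageError(
                f"{op}: spectrum at stage '{self.stage.value}', requires one of [{names}]"
            )

    def evolve(
        self,
        values: np.ndarray,
        stage: Stage,
        grid: np.ndarray | None = None,
    ) -> "Spectrum":
        """Return a copy with new values at a strictly later stage."""
        if stage.index <= self.stage.index:
            raise StageError(
                f"stage may only advance: {self.stage.value} -> {stage.value}"
            )
        return replace(
            self,
            grid=self.grid if grid is None else grid,
            values=np.asarray(values, dtype=float),
            stage=stage,
        )

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to grid points with ``lo <= wavenumber <= hi``."""
        mask = (self.grid >= lo) & (self.grid <= hi)
        if not mask.any():
            raise GridMismatchError(
                f"window [{lo}, {hi}] contains no grid points"
            )
        return replace(self, grid=self.grid[mask], values=self.values[mask])


@dataclass
class SpectrumSet:
    """Non-empty list of spectra sharing a single grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise EmptyInputError("SpectrumSet must contain at least one spectrum")
        ref = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid.size != ref.size or not np.array_equal(s.grid, ref):
                raise GridMismatchError("all spectra in a set must share one grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].grid

    def values_matrix(self) -> np.ndarray:
        """Stack values into an (n_spectra, n_points) matrix."""
        return np.vstack([s.values for s in self.spectra])

    def subset(self, group: str) -> "SpectrumSet":
        picked = [s for s in self.spectra if s.group == group]
        if not picked:
            raise EmptyInputError(f"no spectra with group '{group}'")
        return SpectrumSet(picked)

    def sample_ids(self) -> list[str]:
        """Unique sample ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.sample_id, None)
        return list(seen)

    def by_sample(self) -> dict[str, list[Spectrum]]:
        out: dict[str, list[Spectrum]] = {}
        for s in self.spectra:
            out.setdefault(s.sample_id, []).append(s)
        return out

    def window(self, lo: float, hi: float) -> "SpectrumSet":
        return SpectrumSet([s.window(lo, hi) for s in self.spectra])


# ---------------------------------------------------------------------------
# Plain-text I/O: one two-column CSV per scan plus a samples manifest.
# ---------------------------------------------------------------------------

MANIFEST_NAME = "samples_manifest.csv"


def _scan_filename(s: Spectrum) -> str:
    scan = 0 if s.scan_index is None else s.scan_index
    return f"{s.sample_id}_scan{scan}.csv"


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber_cm-1": s.grid, "absorbance": s.values}
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, **meta) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        grid=df["wavenumber_cm-1"].to_numpy(),
        values=df["absorbance"].to_numpy(),
        **meta,
    )


def write_spectrum_set(sset: SpectrumSet, directory: str | Path) -> Path:
    """Write one CSV per scan plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sset:
        fname = _scan_filename(s)
        write_spectrum_csv(s, directory / fname)
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "scan_file": fname,
                "scan_index": -1 if s.scan_index is None else s.scan_index,
                "true_fraction": np.nan
                if s.lignin_fraction is None
                else s.lignin_fraction,
                "stage": s.stage.value,
            }
        )
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_spectrum_set(directory: str | Path) -> SpectrumSet:
    """Read a set previously written by :func:`write_spectrum_set`."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest file: {manifest}")
    table = pd.read_csv(manifest)
    spectra = []
    for row in table.itertuples(index=False):
        frac = None if pd.isna(row.true_fraction) else float(row.true_fraction)
        scan = None if row.scan_index < 0 else int(row.scan_index)
        spectra.append(
            read_spectrum_csv(
                directory / row.scan_file,
                stage=Stage(row.stage),
                sample_id=str(row.sample_id),
                group=str(row.group),
                lignin_fraction=frac,
                scan_index=scan,
            )
        )
    return SpectrumSet(spectra)
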