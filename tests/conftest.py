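"""Shared fixtures: noiseless instruments, small synthetic sets."""

import numpy as np
import pytest

from lignoquant import preprocessing as pre
from lignoquant import synthetic_data as syn
from lignoquant.spectra import Spectrum, SpectrumSet, Stage


@pytest.fixture(scope="session")
def noiseless_instrument() -> syn.InstrumentModel:
    return syn.noiseless_instrument()


@pytest.fixture(scope="session")
def default_instrument() -> syn.InstrumentModel:
    return syn.InstrumentModel()


@pytest.fixture(scope="session")
def noiseless_standards(noiseless_instrument) -> SpectrumSet:
    return syn.generate_mixture_series(instrument=noiseless_instrument, seed=11)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_instrument) -> SpectrumSet:
    spec = syn.CohortSpec(seed=12, lignin_change_percent=25.0)
    return syn.generate_cohort(spec, instrument=noiseless_instrument)


@pytest.fixture(scope="session")
def processed_standards(noiseless_standards) -> SpectrumSet:
    return pre.run_pretreatment(noiseless_standards).spectra


@pytest.fixture(scope="session")
def processed_cohort(noiseless_cohort) -> SpectrumSet:
    return pre.run_pretreatment(noiseless_cohort).spectra


def make_spectrum(values, spacing=2.0, start=800.0, stage=Stage.RAW, **meta):
    values = np.asarray(values, dtype=float)
    grid = start + spacing * np.arange(values.size)
    meta.setdefault("sample_id", "s0")
    return Spectrum(grid=grid, values=values, stage=stage, **meta)


@pytest.fixture
def small_grid() -> np.ndarray:
    return 800.0 + 2.0 * np.arange(501)
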