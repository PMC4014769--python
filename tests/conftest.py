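"""Shared fixtures: nominal model, synthetic study, tabulated forward model."""

from __future__ import annotations

import numpy as np
import pytest

from tcekin.forward import DirectStrainModel, TabulatedStrainModel
from tcekin.params import DoseRegimen, default_metabolism, default_physiology
from tcekin.synthetic import SyntheticDesign, generate_study


@pytest.fixture(scope="session")
def physiology():
    return default_physiology()


@pytest.fixture(scope="session")
def metabolism(physiology):
    return default_metabolism(physiology.body_weight)


@pytest.fixture(scope="session")
def regimen():
    return DoseRegimen()


@pytest.fixture(scope="session")
def default_study():
    """The default 17-strain synthetic study (seed 42) with its truth."""
    return generate_study(SyntheticDesign(seed=42))


@pytest.fixture(scope="session")
def tabulated_default(default_study, physiology, metabolism, regimen):
    """Tabulated forward model over (VMax, VMaxDCVG) for the default design."""
    data, _ = default_study
    direct = DirectStrainModel(
        physiology, metabolism, regimen,
        times=data.times, scaled_parameters=("VMax", "VMaxDCVG"),
    )
    return TabulatedStrainModel(direct)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
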