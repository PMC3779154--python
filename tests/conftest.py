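"""Shared fixtures: desk-scale synthetic screens with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from qhtscreen.classify import CurveClassifier
from qhtscreen.config import mini_config
from qhtscreen.doseresponse import fit_table
from qhtscreen.normalize import PatternCorrector, normalize_stack
from qhtscreen.plates import make_series
from qhtscreen.simulate import NoiseModel, generate_library, generate_sample_screen

MINI_SEED = 11


@pytest.fixture(scope="session")
def series8():
    return make_series(57.0, 5.0, 8)


@pytest.fixture(scope="session")
def mini_truth():
    """64-compound library over the full 6 CLL + 5 normal manifest."""
    cfg = mini_config(seed=MINI_SEED)
    return generate_library(
        cfg.generator.n_compounds,
        fractions=cfg.generator.fractions,
        cll_samples=cfg.cll_samples,
        normal_samples=cfg.normal_samples,
        seed=MINI_SEED,
    )


@pytest.fixture(scope="session")
def mini_stack(mini_truth):
    """One CLL sample's raw stack at default noise."""
    return generate_sample_screen(mini_truth, "CLL-1", noise=NoiseModel(), seed=MINI_SEED)


@pytest.fixture(scope="session")
def noiseless_stack(mini_truth):
    return generate_sample_screen(
        mini_truth, "CLL-1", noise=NoiseModel(well_cv=0.0, spatial_amplitude=0.0), seed=MINI_SEED
    )


def analyze_stack(stack) -> pd.DataFrame:
    """Correct, normalize, fit and classify one stack; returns the fit table."""
    corrected = PatternCorrector().fit(stack).transform(stack)
    norm = normalize_stack(corrected)
    curves = curves_from_normalized(norm)
    fits = fit_table(curves)
    return CurveClassifier().predict(fits, curves)


def curves_from_normalized(norm: pd.DataFrame) -> pd.DataFrame:
    sub = norm[norm["role"] == "compound"]
    return (
        sub.loc[:, ["compound_id", "sample_id", "conc_uM", "value_norm"]]
        .rename(columns={"value_norm": "response"})
        .reset_index(drop=True)
    )


@pytest.fixture(scope="session")
def mini_classified(mini_stack):
    """Classified fit table for the noisy CLL-1 mini stack."""
    return analyze_stack(mini_stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
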