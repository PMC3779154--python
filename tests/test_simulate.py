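"""Synthetic screen generator: determinism, planted truth, signal model."""

import numpy as np
import pandas as pd
import pytest

from conftest import analyze_stack
from qhtscreen.errors import InvalidArgumentError, LookupFailure
from qhtscreen.simulate import (
    DEFAULT_FRACTIONS,
    NoiseModel,
    generate_library,
    generate_sample_screen,
    spatial_field,
)


class TestGenerateLibrary:
    def test_all_inactive_mix_respects_invariant(self):
        truth = generate_library(10, fractions={"inactive": 1.0}, seed=1)
        assert (truth.table["archetype"] == "inactive").all()
        assert (truth.table["yinf"] - truth.table["y0"]).abs().max() < 5

    def test_seed_determinism(self):
        a = generate_library(200, seed=7).table
        b = generate_library(200, seed=7).table
        pd.testing.assert_frame_equal(a, b)
        c = generate_library(200, seed=8).table
        assert not a["ac50_uM"].equals(c["ac50_uM"])

    def test_exact_archetype_counts(self):
        fr = {"inactive": 0.9, "selective": 5 / 50, "pan_cytotoxic": 0.0}
        truth = generate_library(50, fractions=fr, seed=42)
        per_compound = truth.table.groupby("compound_id")["archetype"].first()
        assert (per_compound == "selective").sum() == 5

    def test_selective_separation_planted(self):
        truth = generate_library(40, fractions={"selective": 1.0}, seed=3)
        t = truth.table
        gm = (
            t.groupby(["compound_id", "group"])["ac50_uM"]
            .apply(lambda v: np.exp(np.log(v).mean()))
            .unstack()
        )
        eff = t.groupby(["compound_id", "group"])["yinf"].mean().unstack()
        ratio = gm["normal"] / gm["cll"]
        eff_gap = eff["normal"] - eff["cll"]  # normals killed less -> positive gap
        assert ((ratio > 5) | (eff_gap > 40)).all()

    def test_invalid_fractions(self):
        with pytest.raises(InvalidArgumentError):
            generate_library(10, fractions={"inactive": 0.5})
        with pytest.raises(InvalidArgumentError):
            generate_library(10, fractions={"nonsense": 1.0})

    def test_per_sample_potency_spread(self):
        truth = generate_library(60, fractions={"pan_cytotoxic": 1.0}, seed=9, sigma_log10=0.3)
        spread = (
            truth.table.groupby("compound_id")["ac50_uM"]
            .apply(lambda v: np.std(np.log10(v), ddof=1))
        )
        assert 0.15 < spread.mean() < 0.45


class TestGenerateSampleScreen:
    def test_unknown_sample_rejected(self, mini_truth):
        with pytest.raises(LookupFailure):
            generate_sample_screen(mini_truth, "NOT-A-SAMPLE")

    def test_stack_architecture(self, mini_stack):
        ids = mini_stack.plate_ids
        # 8 concentration plates bracketed by DMSO-only plates
        assert len(ids) == 10
        assert mini_stack.dmso_plate_ids() == [ids[0], ids[-1]]
        counts = mini_stack.wells.groupby("plate_id").size()
        assert (counts == 1536).all()

    def test_zero_noise_anchor_values(self, mini_truth, noiseless_stack):
        noise = NoiseModel()
        wells = noiseless_stack.wells
        # inactive compounds drift by < 5 points, so their wells sit within
        # 5% of the basal signal; control anchors are exact
        inactive_ids = set(
            mini_truth.table.query("archetype == 'inactive'")["compound_id"]
        )
        inact = wells[wells["compound_id"].isin(inactive_ids)]["value"]
        assert np.allclose(inact, noise.plate_baseline, rtol=0.05)
        pos = wells[wells["role"] == "pos_top"]["value"]
        assert np.allclose(pos, noise.plate_baseline / noise.sb_ratio, rtol=1e-9)
        dmso = wells[wells["role"] == "dmso_control"]["value"]
        assert np.allclose(dmso, noise.plate_baseline, rtol=1e-9)

    def test_truly_flat_compound_wells_equal_baseline(self):
        truth = generate_library(4, fractions={"inactive": 1.0}, seed=2,
                                 cll_samples=("CLL-1",), normal_samples=())
        truth.table.loc[:, ["y0", "yinf"]] = 0.0
        noise = NoiseModel(well_cv=0.0, spatial_amplitude=0.0)
        stack = generate_sample_screen(truth, "CLL-1", noise=noise)
        comp = stack.wells[stack.wells["role"] == "compound"]["value"]
        assert np.allclose(comp, noise.plate_baseline, rtol=1e-12)

    def test_midpoint_well_signal(self):
        # a compound at c = ac50 kills half its cells: the surviving-cell
        # fraction is 0.5 and the signal sits midway between floor and basal
        truth = generate_library(1, fractions={"pan_cytotoxic": 1.0}, seed=0,
                                 cll_samples=("CLL-1",), normal_samples=(),
                                 sigma_log10=0.0)
        truth.table.loc[:, ["y0", "yinf", "ac50_uM", "hill"]] = [0.0, -100.0, 1.0, 1.0]
        noise = NoiseModel(well_cv=0.0, spatial_amplitude=0.0)
        stack = generate_sample_screen(truth, "CLL-1", noise=noise)
        cells = stack.wells.query("compound_id == 'C0001'")
        at_mid = cells[np.isclose(cells["conc_uM"], 1.0, rtol=0.02)]
        # no tested concentration is exactly 1 uM in the 57/5^k series; check the model directly
        sb = noise.sb_ratio
        expected_mid = noise.plate_baseline * (1 / sb + (1 - 1 / sb) * 0.5)
        if len(at_mid):
            assert np.allclose(at_mid["value"], expected_mid, rtol=0.05)
        # exact check at the tested concentration closest to ac50
        conc = cells["conc_uM"].to_numpy()
        c_star = conc[np.argmin(np.abs(np.log(conc) - 0.0))]
        frac = 1.0 / (1.0 + 1.0 / c_star)
        expected = noise.plate_baseline * (1 / sb + (1 - 1 / sb) * (1 - frac))
        got = cells[np.isclose(cells["conc_uM"], c_star)]["value"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_spatial_field_mean_one(self):
        fld = spatial_field(0.1)
        assert fld.mean() == pytest.approx(1.0, abs=1e-12)
        assert fld.std() > 0.01

    def test_noise_model_validation(self):
        with pytest.raises(InvalidArgumentError):
            NoiseModel(sb_ratio=0.9)
        with pytest.raises(InvalidArgumentError):
            NoiseModel(well_cv=-0.1)


class TestRoundTrip:
    def test_noiseless_pipeline_recovers_truth(self, mini_truth, noiseless_stack):
        fits = analyze_stack(noiseless_stack)
        truth = mini_truth.table.query("sample_id == 'CLL-1'")
        merged = fits.merge(truth, on=["compound_id", "sample_id"], suffixes=("", "_true"))
        complete = merged[merged["curve_class"].isin(["1.1", "1.2"])]
        assert len(complete) >= 10
        rel_err = (complete["ac50_uM"] / complete["ac50_uM_true"] - 1).abs()
        assert rel_err.max() < 0.01
        assert (complete["yinf"] - complete["yinf_true"]).abs().max() < 1.0

    def test_ac50_rmse_under_default_noise(self):
        truth = generate_library(
            128, fractions={"pan_cytotoxic": 1.0}, seed=21,
            cll_samples=("CLL-1",), normal_samples=(),
        )
        stack = generate_sample_screen(truth, "CLL-1", noise=NoiseModel(well_cv=0.05))
        fits = analyze_stack(stack)
        merged = fits.merge(truth.table, on=["compound_id", "sample_id"], suffixes=("", "_true"))
        err = np.log10(merged["ac50_uM"]) - np.log10(merged["ac50_uM_true"])
        assert np.sqrt((err**2).mean()) < 0.15
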