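"""Generative model: planted truth, plates, colonies, titrations, CFSE."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_dummy_library
from hipscreen.pools import group_superpools, partition_pools
from hipscreen.simulate import (
    NoiseModel,
    draw_colonies,
    headline_scenario,
    hill,
    plant_reactivity,
    simulate_cfse_cohort,
    simulate_dose_response,
    simulate_plate,
)


@pytest.fixture(scope="module")
def small_manifest():
    lib = make_dummy_library(40)
    return group_superpools(partition_pools(lib, pool_size=5, seed=1), group_size=2)


NOISELESS = NoiseModel(lognormal_sigma=0.0)


class TestPlantReactivity:
    def test_empty_and_small(self):
        lib = make_dummy_library(20)
        truth = plant_reactivity(["a1"], lib.member_ids(), [])
        assert truth.entries == {}
        truth = plant_reactivity(
            ["a1"], lib.member_ids(), [("a1", "m00000", 1e-6), ("a1", "m00001", 1e-7), ("a1", "m00002", 1e-8)]
        )
        assert len(truth.entries) == 3

    def test_unknown_sequence_rejected(self):
        with pytest.raises(KeyError):
            plant_reactivity(["a1"], ["m1"], [("a1", "nope", 1e-6)])

    def test_headline_scenario_shape(self):
        lib = make_dummy_library(200)
        avatars, truth = headline_scenario(lib.member_ids(), n_avatars=109, seed=5)
        assert len(avatars) == 109
        assert len(truth.reactive_avatars()) == 9
        assert len(truth.reactive_members()) == 13
        lo, hi = min(truth.entries.values()), max(truth.entries.values())
        assert lo == pytest.approx(20e-9) and hi == pytest.approx(20e-6)


class TestSimulatePlate:
    def test_noiseless_null_is_exact_background(self, small_manifest):
        truth = plant_reactivity(["a1"], list(small_manifest.sequences), [])
        plate = simulate_plate(
            truth, small_manifest, "superpool", small_manifest.superpool_ids,
            ["a1"], dose=1e-3, noise=NOISELESS, seed=0,
        )
        assert (plate["rlu"] == NOISELESS.background_mean).all()

    def test_noiseless_saturating_dose(self, small_manifest):
        member = small_manifest.members_of_pool("pool0001")[0]
        truth = plant_reactivity(["a1"], [member], [("a1", member, 1e-9)])
        plate = simulate_plate(
            truth, small_manifest, "peptide", [member], ["a1"],
            dose=1.0, noise=NOISELESS, seed=0,
        )
        test = plate[plate["antigen_kind"] == "peptide"]["rlu"]
        assert np.allclose(test, NOISELESS.background_mean + NOISELESS.signal_max, rtol=1e-8)

    def test_seed_determinism(self, small_manifest):
        truth = plant_reactivity(["a1"], list(small_manifest.sequences), [])
        kw = dict(
            truth=truth, manifest=small_manifest, antigen_kind="superpool",
            antigens=small_manifest.superpool_ids, avatar_ids=["a1"],
            dose=1e-3, noise=NoiseModel(), seed=7,
        )
        pd.testing.assert_frame_equal(simulate_plate(**kw), simulate_plate(**kw))

    def test_signal_monotone_in_dose(self, small_manifest):
        member = small_manifest.members_of_pool("pool0001")[0]
        truth = plant_reactivity(["a1"], [member], [("a1", member, 1e-6)])
        rlus = []
        for dose in (1e-9, 1e-8, 1e-7, 1e-6, 1e-5):
            plate = simulate_plate(
                truth, small_manifest, "peptide", [member], ["a1"],
                dose=dose, noise=NOISELESS, seed=0,
            )
            rlus.append(plate[plate["antigen_kind"] == "peptide"]["rlu"].iloc[0])
        assert rlus == sorted(rlus)

    def test_unknown_kind_rejected(self, small_manifest):
        truth = plant_reactivity(["a1"], list(small_manifest.sequences), [])
        with pytest.raises(ValueError):
            simulate_plate(truth, small_manifest, "mystery", ["x"], ["a1"], 1e-3, NOISELESS)


class TestDrawColonies:
    def test_single_draw_and_single_member(self):
        assert len(draw_colonies(["m1", "m2"], n=1, seed=0)) == 1
        colonies = draw_colonies(["only"], n=5, seed=0)
        assert {m for _, m in colonies} == {"only"}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            draw_colonies([], n=3)

    def test_coupon_collector_mean_distinct(self):
        """44 uniform colonies from 33 members: E[distinct] = 33*(1-(32/33)^44)."""
        members = [f"m{i}" for i in range(33)]
        expected = 33 * (1 - (32 / 33) ** 44)
        distinct = [
            len({m for _, m in draw_colonies(members, n=44, seed=s)})
            for s in range(10_000)
        ]
        assert abs(np.mean(distinct) - expected) < 0.5

    def test_infinite_skew_is_uniform(self):
        members = [f"m{i}" for i in range(10)]
        colonies = draw_colonies(members, n=20_000, skew=1e9, seed=3)
        freqs = pd.Series([m for _, m in colonies]).value_counts(normalize=True)
        assert (freqs - 0.1).abs().max() < 0.01


class TestDoseResponse:
    def test_hill_midpoint(self):
        assert hill(1e-6, 1e-6, 1.0) == pytest.approx(0.5)
        plate = simulate_dose_response(1e-6, [1e-8, 1e-7, 1e-6, 1e-5], noise=NOISELESS)
        mid = plate[plate["dose_molar"] == 1e-6]["rlu"].iloc[0]
        assert mid == pytest.approx(NOISELESS.background_mean + NOISELESS.signal_max / 2)

    def test_low_dose_approaches_background(self):
        plate = simulate_dose_response(1e-6, [1e-15, 1e-9, 1e-8, 1e-7], noise=NOISELESS)
        lowest = plate[plate["dose_molar"] == 1e-15]["rlu"].iloc[0]
        assert lowest == pytest.approx(NOISELESS.background_mean, rel=1e-6)

    def test_non_reactive_flat(self):
        plate = simulate_dose_response(None, [1e-9, 1e-8, 1e-7, 1e-6], noise=NOISELESS)
        assert (plate["rlu"] == NOISELESS.background_mean).all()

    def test_needs_four_positive_doses(self):
        with pytest.raises(ValueError):
            simulate_dose_response(1e-6, [1e-8, 1e-7, 1e-6])


class TestCfseCohort:
    def test_null_cohort_centred_at_one(self):
        df = simulate_cfse_cohort({"ctrl": 0.0}, n_subjects=300, lam=50.0, seed=2)
        cdi = df["dim_with"] / df["dim_without"].clip(lower=1)
        assert abs(cdi.mean() - 1.0) < 0.1

    def test_effect_size_recovery(self):
        df = simulate_cfse_cohort({"t1d": 1.0}, effect_size=10.0, lam=20.0, n_subjects=1000, seed=4)
        cdi = df["dim_with"] / df["dim_without"].clip(lower=1)
        assert abs(cdi.mean() - 10.0) / 10.0 < 0.15

    def test_determinism(self):
        kw = dict(group_probs={"a": 0.5}, n_subjects=20, seed=9)
        pd.testing.assert_frame_equal(simulate_cfse_cohort(**kw), simulate_cfse_cohort(**kw))

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            simulate_cfse_cohort({"a": 1.5})
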