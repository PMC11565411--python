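"""Delta-luciferase, hit calling, Dunnett comparisons, staged deconvolution."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_dummy_library
from hipscreen.deconvolution import (
    ScreenPolicy,
    call_hits,
    delta_luciferase,
    dunnett_compare,
    paired_comparison,
    run_deconvolution,
)
from hipscreen.pools import group_superpools, partition_pools
from hipscreen.simulate import NoiseModel, SimulatedScreen, plant_reactivity


def make_readout(rows):
    data = []
    for antigen_id, kind, rlus in rows:
        for i, rlu in enumerate(rlus, start=1):
            data.append(
                {
                    "plate_id": "p1",
                    "well_id": f"w{len(data):03d}",
                    "avatar_id": "a1",
                    "antigen_id": antigen_id,
                    "antigen_kind": kind,
                    "replicate": i,
                    "rlu": float(rlu),
                }
            )
    return pd.DataFrame(data)


class TestDeltaLuciferase:
    def test_subtracts_control_mean(self):
        r = make_readout([("GST", "GST_control", [100, 100, 100]), ("sp1", "superpool", [150])])
        d = delta_luciferase(r)
        assert d.loc[d["antigen_id"] == "sp1", "delta"].iloc[0] == 50

    def test_control_deltas_average_zero(self):
        r = make_readout([("GST", "GST_control", [90, 100, 110]), ("sp1", "superpool", [80])])
        d = delta_luciferase(r)
        assert d.loc[d["antigen_kind"] == "GST_control", "delta"].mean() == pytest.approx(0)
        assert d.loc[d["antigen_id"] == "sp1", "delta"].iloc[0] == pytest.approx(-20)

    def test_missing_controls_named(self):
        r = make_readout([("sp1", "superpool", [100, 100])])
        with pytest.raises(ValueError, match="p1"):
            delta_luciferase(r)


class TestCallHits:
    def _delta(self, control_rlus, test_rlus):
        return delta_luciferase(
            make_readout(
                [("GST", "GST_control", control_rlus), ("sp1", "superpool", test_rlus)]
            )
        )

    def test_positive_above_threshold(self):
        d = self._delta([90, 100, 110], [150, 150, 150])
        (call,) = [c for c in call_hits(d) if c.antigen_kind == "superpool"]
        assert call.positive and call.delta_rlu == pytest.approx(50)
        assert call.threshold == pytest.approx(2 * 10.0)

    def test_negative_below_threshold(self):
        d = self._delta([90, 100, 110], [115, 115, 115])
        (call,) = [c for c in call_hits(d) if c.antigen_kind == "superpool"]
        assert not call.positive

    def test_zero_sd_guarded_by_floor(self):
        d = self._delta([100, 100, 100], [100.5, 100.5])
        (call,) = [c for c in call_hits(d, sd_floor=1.0) if c.antigen_kind == "superpool"]
        assert not call.positive  # 0.5 < 2 * floor

    def test_too_few_controls_rejected(self):
        d = delta_luciferase(
            make_readout([("GST", "GST_control", [100, 100]), ("sp1", "superpool", [500])])
        )
        with pytest.raises(ValueError, match="control SD"):
            call_hits(d)


class TestDunnett:
    def test_null_groups_not_significant(self):
        groups = {"a": [10.0, 10.0, 10.1], "b": [10.0, 10.1, 9.9]}
        res = dunnett_compare(groups, [10.0, 10.1, 9.9])
        assert (res.adjusted_p > 0.05).all()

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 1, 3)
        groups = {"shift": rng.normal(10, 1, 3), "null": rng.normal(0, 1, 3)}
        res = dunnett_compare(groups, ctrl)
        assert res.adjusted_p["shift"] < 0.01
        assert res.adjusted_p["null"] > 0.05

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_quadrature_matches_scipy(self, alternative):
        """Independent oracle: the balanced quadrature path agrees with
        scipy's Dunnett implementation on small families."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            arrs = [rng.normal(rng.normal(0, 1), 1, 4) for _ in range(3)]
            ctrl = rng.normal(0, 1, 4)
            mine = dunnett_compare(
                {f"g{i}": a for i, a in enumerate(arrs)}, ctrl, alternative=alternative
            )
            ref = stats.dunnett(*arrs, control=ctrl, alternative=alternative)
            for i in range(3):
                assert mine.adjusted_p[f"g{i}"] == pytest.approx(ref.pvalue[i], abs=0.01)

    def test_family_wise_error_under_global_null(self):
        """Simulated global null: the fraction of families with any
        adjusted p < alpha matches alpha within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        alpha, reps = 0.05, 4000
        false_families = 0
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0, 1, 3) for i in range(3)}
            res = dunnett_compare(groups, rng.normal(0, 1, 3), alpha=alpha)
            false_families += bool((res.adjusted_p < alpha).any())
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(false_families / reps - alpha) < 4 * se

    def test_single_group_with_one_replicate_rejected(self):
        with pytest.raises(ValueError):
            dunnett_compare({"a": [1.0]}, [0.0, 0.0])


@pytest.fixture(scope="module")
def small_screen_setup():
    lib = make_dummy_library(40)
    manifest = group_superpools(partition_pools(lib, pool_size=5, seed=1), group_size=2)
    avatars = [f"a{i}" for i in range(6)]
    members = lib.member_ids()
    planted = [
        ("a0", members[3], 1e-7),
        ("a0", members[17], 1e-6),
        ("a2", members[17], 2e-8),
        ("a5", members[31], 1e-5),
    ]
    truth = plant_reactivity(avatars, members, planted)
    return lib, manifest, avatars, truth


class TestRunDeconvolution:
    def test_noiseless_equals_planted_truth(self, small_screen_setup):
        lib, manifest, avatars, truth = small_screen_setup
        screen = SimulatedScreen(truth, manifest, NoiseModel(lognormal_sigma=0.0), seed=0)
        result = run_deconvolution(screen, manifest, avatars)
        found = {
            (a, h.member_id) for a, hips in result.identifications.items() for h in hips
        }
        assert found == set(truth.entries)
        result.validate_chains(manifest)

    def test_no_reactivity_empty_everywhere(self, small_screen_setup):
        lib, manifest, avatars, _ = small_screen_setup
        truth = plant_reactivity(avatars, lib.member_ids(), [])
        screen = SimulatedScreen(truth, manifest, NoiseModel(lognormal_sigma=0.0), seed=0)
        result = run_deconvolution(screen, manifest, avatars)
        assert result.positive_avatars() == []
        assert result.distinct_sequences() == set()

    def test_noisy_default_recovers_truth(self, small_screen_setup):
        lib, manifest, avatars, truth = small_screen_setup
        screen = SimulatedScreen(truth, manifest, NoiseModel(), seed=12)
        result = run_deconvolution(screen, manifest, avatars)
        found = {
            (a, h.member_id) for a, hips in result.identifications.items() for h in hips
        }
        assert found == set(truth.entries)

    def test_colony_recall_matches_coupon_collector(self, small_screen_setup):
        """With n sampled colonies from a 33-member pool, per-member recall
        is 1 - (32/33)^n; checked by Monte-Carlo over 1,000 colony draws."""
        from hipscreen.simulate import draw_colonies

        members = [f"m{i}" for i in range(33)]
        target = members[5]
        n = 44
        hits = sum(
            target in {m for _, m in draw_colonies(members, n=n, seed=s)}
            for s in range(1000)
        )
        expected = 1 - (32 / 33) ** n
        assert expected == pytest.approx(0.741, abs=0.005)
        assert abs(hits / 1000 - expected) < 0.02

    def test_recall_monotone_in_colony_count(self):
        from hipscreen.simulate import draw_colonies

        members = [f"m{i}" for i in range(33)]
        coverage = []
        for n in (10, 30, 60):
            distinct = np.mean(
                [len({m for _, m in draw_colonies(members, n=n, seed=s)}) for s in range(300)]
            )
            coverage.append(distinct)
        assert coverage == sorted(coverage)


class TestPairedComparison:
    def test_identical_pairs(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_difference_degenerate(self):
        res = paired_comparison([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])
        assert res.degenerate and res.p_value == 0.0 and res.mean_difference == 1.0

    def test_unequal_pairing_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_against_sign_permutation_oracle(self):
        """t-based p agrees with the exact sign-flip permutation null on a
        small fixture."""
        rng = np.random.default_rng(3)
        islet = rng.normal(1.0, 1.0, 8)
        spleen = rng.normal(0.0, 1.0, 8)
        res = paired_comparison(islet, spleen)
        diffs = islet - spleen
        obs = abs(diffs.mean())
        perms = [
            abs(np.mean(diffs * signs))
            for signs in itertools.product([1, -1], repeat=len(diffs))
        ]
        p_perm = np.mean([p >= obs - 1e-12 for p in perms])
        assert res.p_value == pytest.approx(p_perm, abs=0.05)
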