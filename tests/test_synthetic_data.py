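import numpy as np
import pytest
from scipy import ndimage

from segconcord import (
    PhantomSpec,
    PerturbationParams,
    generate_phantom,
    perturb_mask,
    calibrate_perturbation,
    generate_cohort,
    evaluate_pair,
    mask_volume_mm3,
)


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(
        PhantomSpec(grid_shape=(48, 48, 48), target_volume_mm3=8000, seed=21)
    )


class TestGeneratePhantom:
    def test_volume_within_ten_percent_and_connected(self):
        spec = PhantomSpec(target_volume_mm3=1000.0, seed=3)
        m = generate_phantom(spec)
        assert 900 <= m.foreground_count <= 1100
        _, n_components = ndimage.label(m.voxels)
        assert n_components == 1

    def test_deterministic_per_seed(self):
        spec = PhantomSpec(target_volume_mm3=2000.0, seed=9)
        a, b = generate_phantom(spec), generate_phantom(spec)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        c = generate_phantom(PhantomSpec(target_volume_mm3=2000.0, seed=10))
        assert (a.voxels != c.voxels).any()

    def test_respects_anisotropic_spacing(self):
        spec = PhantomSpec(
            grid_shape=(24, 48, 48), spacing=(2.0, 1.0, 1.0),
            target_volume_mm3=4000.0, seed=5,
        )
        m = generate_phantom(spec)
        assert abs(mask_volume_mm3(m) - 4000.0) <= 400.0

    def test_volume_spread_recovers_target_median(self):
        # lognormal volume spread around a target median
        rng = np.random.default_rng(0)
        target = 8000.0
        vols = []
        for seed in range(30):
            draw = float(np.clip(target * rng.lognormal(0.0, 0.4), 500, 40_000))
            m = generate_phantom(PhantomSpec(target_volume_mm3=draw, seed=seed))
            vols.append(mask_volume_mm3(m))
        assert abs(np.median(vols) - target) / target < 0.2

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_phantom(
                PhantomSpec(grid_shape=(8, 8, 8), target_volume_mm3=1e6)
            )


class TestPerturbMask:
    def test_zero_params_identity(self, phantom):
        out = perturb_mask(phantom, PerturbationParams(), seed=0)
        np.testing.assert_array_equal(out.voxels, phantom.voxels)
        assert evaluate_pair(phantom, out).dsc == 1.0

    def test_deterministic_per_seed(self, phantom):
        p = PerturbationParams(boundary_flip_rate=0.3, miss_fraction=0.1)
        a = perturb_mask(phantom, p, seed=4)
        b = perturb_mask(phantom, p, seed=4)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_grid_geometry_never_changes(self, phantom):
        p = PerturbationParams(
            boundary_flip_rate=0.5, dilation_bias=1,
            satellite_count=2, satellite_volume_voxels=30,
        )
        out = perturb_mask(phantom, p, seed=1)
        assert out.shape == phantom.shape
        assert out.spacing == phantom.spacing

    def test_empty_output_failure(self, phantom):
        out = perturb_mask(
            phantom, PerturbationParams(failure_mode="empty_output"), seed=0
        )
        assert out.foreground_count == 0
        assert evaluate_pair(phantom, out).dsc == 0.0

    def test_wrong_structure_scores_near_zero(self, phantom):
        out = perturb_mask(
            phantom, PerturbationParams(failure_mode="wrong_structure"), seed=2
        )
        assert out.foreground_count > 0
        assert evaluate_pair(phantom, out).dsc < 0.01

    def test_satellite_only_failure_disjoint(self, phantom):
        out = perturb_mask(
            phantom, PerturbationParams(failure_mode="satellite_only"), seed=3
        )
        assert out.foreground_count > 0
        overlap = (out.voxels.astype(bool) & phantom.voxels.astype(bool)).sum()
        assert overlap == 0

    def test_satellites_disjoint_and_near_tumor(self, phantom):
        p = PerturbationParams(satellite_count=3, satellite_volume_voxels=25)
        out = perturb_mask(phantom, p, seed=6)
        added = out.voxels.astype(bool) & ~phantom.voxels.astype(bool)
        assert added.sum() > 0
        # disjoint from the tumor but inside a 10-voxel neighborhood
        assert not (added & phantom.voxels.astype(bool)).any()
        shell = ndimage.binary_dilation(phantom.voxels.astype(bool), iterations=10)
        assert (added & ~shell).sum() == 0

    def test_dsc_monotone_in_miss_fraction(self, phantom):
        prev = 1.0
        for frac in (0.0, 0.2, 0.4, 0.6, 0.8):
            out = perturb_mask(
                phantom, PerturbationParams(miss_fraction=frac), seed=8
            )
            d = evaluate_pair(phantom, out).dsc
            assert d <= prev + 1e-12
            prev = d

    def test_miss_fraction_dsc_matches_closed_form(self, phantom):
        # removal only: tp = (1-m)V, fn = mV, fp = 0
        v = phantom.foreground_count
        for frac in (0.3, 0.5, 0.82):
            out = perturb_mask(
                phantom, PerturbationParams(miss_fraction=frac), seed=9
            )
            removed = v - out.foreground_count
            expected = 2 * (v - removed) / (2 * v - removed)
            assert evaluate_pair(phantom, out).dsc == pytest.approx(expected)
            assert removed == pytest.approx(frac * v, abs=1.0)

    def test_empty_ground_truth_rejected(self, phantom):
        empty = phantom.copy_with(np.zeros_like(phantom.voxels))
        with pytest.raises(ValueError, match="empty"):
            perturb_mask(empty, PerturbationParams(), seed=0)


class TestCalibration:
    def test_target_one_returns_zero_perturbation(self, phantom):
        p, achieved = calibrate_perturbation(phantom, 1.0, seeds=(0,))
        assert p.boundary_flip_rate == 0.0
        assert achieved == 1.0

    def test_hits_mid_range_target(self, phantom):
        p, achieved = calibrate_perturbation(
            phantom, 0.92, seeds=(0, 1, 2, 3, 4)
        )
        assert 0.90 <= achieved <= 0.94
        vals = [
            evaluate_pair(phantom, perturb_mask(phantom, p, seed=s)).dsc
            for s in (0, 1, 2, 3, 4)
        ]
        assert abs(np.mean(vals) - 0.92) <= 0.02

    def test_dsc_decreases_with_flip_rate(self, phantom):
        dscs = []
        for rate in (0.0, 0.2, 0.4, 0.6, 0.8):
            out = perturb_mask(
                phantom, PerturbationParams(boundary_flip_rate=rate), seed=12
            )
            dscs.append(evaluate_pair(phantom, out).dsc)
        assert all(a >= b for a, b in zip(dscs, dscs[1:]))
        assert dscs[0] > dscs[-1]

    def test_unreachable_target_rejected(self, phantom):
        # boundary flips alone cannot drive the overlap to 0.1
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_perturbation(phantom, 0.1, seeds=(0,))

    def test_non_monotone_knob_rejected(self, phantom):
        with pytest.raises(ValueError):
            calibrate_perturbation(phantom, 0.9, free_param="dilation_bias")


class TestGenerateCohort:
    def test_default_composition_quotas(self):
        recs = generate_cohort(132, seed=0)
        assert sum(r.location == "abdominopelvic" for r in recs) == 105
        assert sum(r.location == "cervicothoracic" for r in recs) == 27
        assert sum(r.vendor == "Siemens" for r in recs) == 54
        assert sum(r.vendor == "GE" for r in recs) == 51
        assert sum(r.vendor == "Philips" for r in recs) == 27
        assert sum(r.field_strength == 1.5 for r in recs) == 116
        assert sum(r.sequence == "T2w" for r in recs) == 84

    def test_single_level_covariates(self):
        recs = generate_cohort(
            10,
            composition={
                "vendor": {"GE": 1.0},
                "field_strength": {3.0: 1.0},
                "location": {"cervicothoracic": 1.0},
                "sequence": {"T2w-fat-sat": 1.0},
            },
            seed=4,
        )
        assert len(recs) == 10
        assert all(r.vendor == "GE" and r.sequence == "T2w-fat-sat" for r in recs)

    def test_quota_counts_match_brute_force_tally(self):
        comp = {
            "vendor": {"Siemens": 0.41, "GE": 0.39, "Philips": 0.2},
            "field_strength": {1.5: 0.88, 3.0: 0.12},
            "location": {"abdominopelvic": 0.8, "cervicothoracic": 0.2},
            "sequence": {"T2w": 0.64, "T2w-fat-sat": 0.36},
        }
        n = 97
        recs = generate_cohort(n, composition=comp, seed=11)
        for cov, props in comp.items():
            tally: dict = {}
            for r in recs:
                lev = getattr(r, cov)
                tally[lev] = tally.get(lev, 0) + 1
            for lev, p in props.items():
                assert abs(tally.get(lev, 0) - p * n) < 1.0

    def test_age_distribution_scale(self):
        recs = generate_cohort(2000, seed=5)
        ages = np.array([r.age_months for r in recs])
        assert (ages >= 0).all() and (ages <= 252).all()
        assert 18 < np.median(ages) < 32

    def test_deterministic_and_invalid_proportions_rejected(self):
        a = generate_cohort(40, seed=8)
        b = generate_cohort(40, seed=8)
        assert a == b
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(10, composition={"vendor": {"GE": 0.5}})
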