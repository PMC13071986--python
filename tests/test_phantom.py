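from dataclasses import replace

import numpy as np
import pytest

from bonemorph import (
    PhantomSpec,
    add_noise,
    apply_fixation_model,
    ethanol_like,
    formalin_like,
    generate_bone_phantom,
    simulate_series,
)
from bonemorph.phantom import ConfigurationError, GT_TRABECULAR


def test_zero_fill_fraction_yields_no_trabecular_voxels():
    spec = PhantomSpec(length_vox=60, outer_radius_vox=24.0,
                       cortical_thickness_vox=5.0, trabecular_fill_fraction=0.0,
                       seed=3)
    _, truth = generate_bone_phantom(spec)
    assert not np.any(truth.label_map == GT_TRABECULAR)


def test_plain_tube_matches_analytic_annulus_volume():
    spec = PhantomSpec(
        length_vox=100, outer_radius_vox=40.0, cortical_thickness_vox=8.0,
        trabecular_fill_fraction=0.0, shaft_radius_fraction=1.0,
        end_cap_fraction=0.0, seed=0,
    )
    _, truth = generate_bone_phantom(spec)
    ct_bv = (truth.label_map == 2).sum() * spec.voxel_size_mm**3
    analytic = np.pi * (40.0**2 - 32.0**2) * 100 * spec.voxel_size_mm**3
    assert ct_bv == pytest.approx(analytic, rel=0.02)


def test_generation_is_deterministic(small_spec):
    v1, t1 = generate_bone_phantom(small_spec)
    v2, t2 = generate_bone_phantom(small_spec)
    np.testing.assert_array_equal(v1.grid, v2.grid)
    np.testing.assert_array_equal(t1.label_map, t2.label_map)


def test_labels_partition_the_grid(small_phantom):
    _, truth = small_phantom
    counts = np.bincount(truth.label_map.ravel(), minlength=4)
    assert counts.sum() == truth.label_map.size


def test_noiseless_class_medians_equal_spec(clean_small_phantom):
    vol, truth = clean_small_phantom
    spec = truth.spec
    for lab, mu in ((1, spec.mu_marrow), (2, spec.mu_cortical),
                    (3, spec.mu_trabecular)):
        assert float(np.median(vol.grid[truth.label_map == lab])) == mu


def test_geometry_must_fit_grid():
    with pytest.raises(ConfigurationError):
        PhantomSpec(outer_radius_vox=60.0, grid_width=100)


@pytest.mark.parametrize("bad", [
    dict(cortical_thickness_vox=60.0),
    dict(trabecular_fill_fraction=1.0),
    dict(diaphysis_fraction=0.0),
    dict(noise_sigma=-0.1),
])
def test_spec_invariants(bad):
    with pytest.raises(ValueError):
        PhantomSpec(**bad)


def test_ethanol_preset_is_the_identity(small_phantom):
    vol, truth = small_phantom
    out, out_truth = apply_fixation_model(truth, vol, ethanol_like(), 900)
    np.testing.assert_array_equal(out.grid, vol.grid)
    assert out.day == 900
    np.testing.assert_array_equal(out_truth.label_map, truth.label_map)


def test_day_zero_is_the_identity(small_phantom):
    vol, truth = small_phantom
    out, _ = apply_fixation_model(truth, vol, formalin_like(), 0)
    np.testing.assert_array_equal(out.grid, vol.grid)


def test_day_out_of_range_rejected(small_phantom):
    vol, truth = small_phantom
    model = formalin_like(duration_days=100)
    for day in (-1, 101):
        with pytest.raises(ValueError):
            apply_fixation_model(truth, vol, model, day)


def test_schedule_is_monotone_saturating():
    model = formalin_like()
    days = np.linspace(0, model.duration_days, 25)
    vals = [model.schedule(d) for d in days]
    assert vals[0] == 0.0
    assert vals[-1] == pytest.approx(1.0)
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_programmed_volume_change_is_reached_in_the_labels(clean_small_phantom):
    vol, truth = clean_small_phantom
    model = formalin_like(delta_volume_max=8.6)
    _, evolved = apply_fixation_model(truth, vol, model, model.duration_days)
    for lab in (2, 3):
        before = (truth.label_map == lab).sum()
        after = (evolved.label_map == lab).sum()
        change = 100 * (after - before) / before
        assert change == pytest.approx(8.6, abs=1.0)
    bone0 = (truth.label_map >= 2).sum()
    bone1 = (evolved.label_map >= 2).sum()
    assert 100 * (bone1 - bone0) / bone0 == pytest.approx(8.6, abs=0.5)


def test_attenuation_drift_is_exact_in_the_labels(clean_small_phantom):
    vol, truth = clean_small_phantom
    model = formalin_like(delta_mu_ct_max=-5.3, delta_mu_tb_max=-2.9)
    evolved_vol, evolved = apply_fixation_model(truth, vol, model,
                                                model.duration_days)
    mu_ct = np.median(evolved_vol.grid[evolved.label_map == 2])
    assert mu_ct == pytest.approx(truth.spec.mu_cortical * (1 - 0.053), rel=1e-12)


def test_add_noise_properties(small_phantom):
    vol, _ = small_phantom
    assert add_noise(vol, 0.0, 1) is vol
    a = add_noise(vol, 0.05, 42)
    b = add_noise(vol, 0.05, 42)
    np.testing.assert_array_equal(a.grid, b.grid)
    with pytest.raises(ValueError):
        add_noise(vol, -0.01, 1)


def test_noise_is_zero_mean_at_large_n():
    from bonemorph import Volume

    vol = Volume(np.zeros((102, 102, 102)), 0.009)
    sigma = 0.05
    noisy = add_noise(vol, sigma, 99)
    diff = noisy.grid - vol.grid
    n = diff.size
    assert n >= 1_000_000
    assert abs(diff.mean()) <= 3 * sigma / np.sqrt(n)


def test_series_starts_at_baseline(small_spec):
    with pytest.raises(ValueError):
        simulate_series(small_spec, ethanol_like(), [35, 70])


def test_diaphyseal_residual_is_a_small_fraction(small_phantom):
    _, truth = small_phantom
    z1, z2 = truth.region_boundaries
    trab = truth.label_map == GT_TRABECULAR
    dia = trab[z1:z2].sum()
    assert 0 < dia / trab.sum() < 0.02
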