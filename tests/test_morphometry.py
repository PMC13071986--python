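import numpy as np
import pytest

from bonemorph import (
    MorphometryRecord,
    Volume,
    apply_trabecular_exclusion,
    bone_volume_fraction,
    compute_morphometry,
)
from bonemorph.compartments import LabelMap, RegionPartition
from bonemorph.morphometry import WHOLE_SAMPLE


@pytest.mark.parametrize(
    "bv, tv, expected",
    [
        (0.01076, 0.01365, 78.8),  # formalin-stored phalanx
        (0.00916, 0.01225, 74.8),  # ethanol-stored phalanx
        (1.0, 1.0, 100.0),
    ],
)
def test_bone_volume_fraction(bv, tv, expected):
    assert round(bone_volume_fraction(bv, tv), 1) == expected


@pytest.mark.parametrize("bv, tv", [(1.0, 0.0), (2.0, 1.0), (-0.1, 1.0)])
def test_bone_volume_fraction_domain(bv, tv):
    with pytest.raises(ValueError):
        bone_volume_fraction(bv, tv)


def _random_scene(rng, shape=(24, 16, 16)):
    labels = rng.integers(0, 3, size=shape).astype(np.uint8)
    envelope = rng.uniform(size=shape) < 0.7
    envelope |= labels > 0  # envelope must cover the bone
    grid = rng.uniform(0.0, 1.5, size=shape)
    lm = LabelMap(labels=labels, envelope=envelope)
    part = RegionPartition(z1=8, z2=17, n_slices=shape[0])
    vol = Volume(grid, voxel_size_mm=0.01, day=0, sample_id="fixture")
    return vol, lm, part


def brute_force_records(vol, lm, part):
    """Oracle: per-voxel Python counting, no vectorization shared with the unit."""
    vv = vol.voxel_size_mm**3
    slabs = {WHOLE_SAMPLE: range(vol.shape[0])}
    slabs.update(
        {name: range(s.start or 0, s.stop if s.stop is not None else vol.shape[0])
         for name, s in part.region_slices().items()}
    )
    out = {}
    for name, zs in slabs.items():
        env = cort = trab = 0
        mus = {"b": [], "c": [], "t": []}
        for z in zs:
            for y in range(vol.shape[1]):
                for x in range(vol.shape[2]):
                    if lm.envelope[z, y, x]:
                        env += 1
                    lab = lm.labels[z, y, x]
                    if lab == 1:
                        cort += 1
                        mus["c"].append(vol.grid[z, y, x])
                        mus["b"].append(vol.grid[z, y, x])
                    elif lab == 2:
                        trab += 1
                        mus["t"].append(vol.grid[z, y, x])
                        mus["b"].append(vol.grid[z, y, x])
        out[name] = {
            "TV": env * vv, "Ct": cort * vv, "Tb": trab * vv,
            "mu_Ct": np.median(mus["c"]) if mus["c"] else None,
            "mu_Tb": np.median(mus["t"]) if mus["t"] else None,
            "mu_B": np.median(mus["b"]) if mus["b"] else None,
        }
    return out


def test_counts_and_medians_match_per_voxel_oracle(rng):
    vol, lm, part = _random_scene(rng)
    oracle = brute_force_records(vol, lm, part)
    for rec in compute_morphometry(vol, lm, part):
        ref = oracle[rec.region]
        assert rec.TV == pytest.approx(ref["TV"], abs=1e-12)
        assert rec.Ct_BV == pytest.approx(ref["Ct"], abs=1e-12)
        assert rec.Tb_BV == pytest.approx(ref["Tb"], abs=1e-12)
        assert rec.BV == pytest.approx(ref["Ct"] + ref["Tb"], abs=1e-12)
        for got, want in ((rec.mu_Ct, ref["mu_Ct"]), (rec.mu_Tb, ref["mu_Tb"]),
                          (rec.mu_B, ref["mu_B"])):
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)


def test_regional_volumes_are_additive(rng):
    vol, lm, part = _random_scene(rng)
    recs = {r.region: r for r in compute_morphometry(vol, lm, part)}
    whole = recs.pop(WHOLE_SAMPLE)
    assert sum(r.TV for r in recs.values()) == pytest.approx(whole.TV, abs=1e-12)
    assert sum(r.BV for r in recs.values()) == pytest.approx(whole.BV, abs=1e-12)


def test_noiseless_phantom_medians_are_exact(clean_small_phantom):
    vol, truth = clean_small_phantom
    spec = truth.spec
    recs = compute_morphometry(vol, truth.as_label_map(), truth.partition)
    for r in recs:
        assert r.mu_Ct == spec.mu_cortical
        if r.Tb_BV:
            assert r.mu_Tb == spec.mu_trabecular
        assert r.BV == pytest.approx(r.Ct_BV + r.Tb_BV, abs=1e-12)


def test_median_error_bound_under_gaussian_noise(small_phantom):
    vol, truth = small_phantom
    sigma = truth.spec.noise_sigma
    recs = compute_morphometry(vol, truth.as_label_map(), truth.partition)
    whole = next(r for r in recs if r.region == WHOLE_SAMPLE)
    n_ct = (truth.label_map == 2).sum()
    bound = 3 * 1.2533 * sigma / np.sqrt(n_ct)  # asymptotic sd of the median
    assert abs(whole.mu_Ct - truth.spec.mu_cortical) <= bound


def test_empty_trabecular_region_reports_zero_volume_absent_mu():
    labels = np.zeros((10, 8, 8), dtype=np.uint8)
    labels[:, 2:6, 2:6] = 1  # cortical only
    lm = LabelMap(labels=labels, envelope=labels > 0)
    part = RegionPartition(z1=3, z2=7, n_slices=10)
    vol = Volume(np.full(labels.shape, 1.2), 0.009)
    for r in compute_morphometry(vol, lm, part):
        assert r.Tb_BV == 0.0
        assert r.mu_Tb is None


def _series_records(dia_fraction):
    base = dict(sample_id="s", day=0, TV=10.0, BV=5.0, BV_TV=50.0,
                mu_B=1.1, mu_Ct=1.2)
    whole = MorphometryRecord(region=WHOLE_SAMPLE, Ct_BV=4.0, Tb_BV=1.0,
                              mu_Tb=0.86, **base)
    dia = MorphometryRecord(region="diaphysis", Ct_BV=4.9,
                            Tb_BV=dia_fraction * 1.0, mu_Tb=0.86, **base)
    prox = MorphometryRecord(region="proximal EM-zone", Ct_BV=4.2, Tb_BV=0.8,
                             mu_Tb=0.86, **base)
    return [whole, dia, prox]


def test_low_trabecular_regions_are_excluded():
    out = apply_trabecular_exclusion(_series_records(0.01), threshold_fraction=0.02)
    dia = next(r for r in out if r.region == "diaphysis")
    assert dia.Tb_BV is None and dia.mu_Tb is None
    # other fields and other regions untouched
    assert dia.TV == 10.0 and dia.Ct_BV == 4.9
    prox = next(r for r in out if r.region == "proximal EM-zone")
    assert prox.Tb_BV == 0.8
    whole = next(r for r in out if r.region == WHOLE_SAMPLE)
    assert whole.Tb_BV == 1.0


def test_zero_threshold_excludes_nothing():
    out = apply_trabecular_exclusion(_series_records(0.01), threshold_fraction=0.0)
    assert all(r.Tb_BV is not None for r in out)


def test_mismatched_shapes_rejected(rng):
    vol, lm, part = _random_scene(rng)
    bad = Volume(np.zeros((5, 5, 5)), 0.009)
    with pytest.raises(ValueError):
        compute_morphometry(bad, lm, part)
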