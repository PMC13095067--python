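"""Radial binning, profiling, normalization, morphometrics and group stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardionuc.radial import (
    NuclearMask,
    compare_radial_distributions,
    compute_distance_bins,
    normalize_profiles,
    normalized_boundary_distance,
    peripherality_index,
    profile_intensity,
    shape_descriptors,
)
from conftest import (
    brute_force_bins,
    noiseless_group_profiles,
    random_mask,
    two_group_per_nucleus,
)


@pytest.mark.parametrize("mode", ["equal_width", "equal_area"])
def test_binning_matches_brute_force_oracle(mode):
    for seed in range(12):
        mask = random_mask(seed)
        got = compute_distance_bins(mask, mode=mode).raster
        want = brute_force_bins(mask.raster, mode=mode)
        assert np.array_equal(got, want), (seed, mode)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), mode=st.sampled_from(["equal_width", "equal_area"]))
def test_partition_conservation(seed, mode):
    """Per-bin pixel counts always sum to the mask area; all bins indexed 1..10."""
    mask = random_mask(seed)
    binmap = compute_distance_bins(mask, mode=mode)
    counts = binmap.pixel_counts()
    assert counts.sum() == mask.area_px
    assert np.array_equal(binmap.raster > 0, mask.raster)
    if mode == "equal_width":
        assert binmap.raster.max() == 10
    else:
        # a boundary tie block larger than area/10 may legally absorb the
        # outermost bin; occupied bins still form a contiguous range from 1
        occupied = np.nonzero(counts)[0]
        assert occupied[0] == 0 and np.all(np.diff(occupied) == 1)


def test_disk_extremes_equal_width(disk_mask):
    """Deepest pixel lands in bin 1, boundary-adjacent pixels in bin 10."""
    from scipy import ndimage

    binmap = compute_distance_bins(disk_mask, mode="equal_width")
    dist = ndimage.distance_transform_edt(disk_mask.raster)
    assert binmap.raster[np.unravel_index(np.argmax(dist), dist.shape)] == 1
    boundary = disk_mask.raster & (dist == 1)
    assert np.all(binmap.raster[boundary] == 10)


def test_disk_equal_area_counts_within_tie_blocks(disk_mask):
    """Equal-area bins deviate from area/10 only by unsplittable tie blocks."""
    binmap = compute_distance_bins(disk_mask, mode="equal_area")
    r = normalized_boundary_distance(disk_mask.raster)[disk_mask.raster]
    area, n = r.size, 10
    counts = binmap.pixel_counts()
    cum = np.cumsum(counts)
    order = np.sort(r)
    for k in range(1, n):
        ideal = k * area / n
        # the cut may only move to the end of the tie block containing it
        v = order[min(int(np.ceil(ideal)) - 1, area - 1)]
        block = int((order == v).sum())
        assert abs(cum[k - 1] - ideal) <= block, (k, cum[k - 1], ideal, block)


def test_binning_rejects_bad_masks():
    with pytest.raises(ValueError):
        compute_distance_bins(np.zeros((10, 10), bool))
    two = np.zeros((20, 20), bool)
    two[2:6, 2:6] = True
    two[12:16, 12:16] = True
    with pytest.raises(ValueError, match="component"):
        compute_distance_bins(two)


def test_profile_constant_image(disk_mask):
    binmap = compute_distance_bins(disk_mask)
    prof = profile_intensity(np.full(disk_mask.raster.shape, 3.5), binmap)
    assert np.allclose(prof.mean_intensity, 3.5)
    assert prof.pixel_count.sum() == disk_mask.area_px


def test_profile_of_radius_image_is_monotone(disk_mask):
    """An image equal to its pixel's r gives strictly increasing bin means."""
    binmap = compute_distance_bins(disk_mask, mode="equal_width")
    r = np.nan_to_num(normalized_boundary_distance(disk_mask.raster))
    prof = profile_intensity(r, binmap)
    assert np.all(np.diff(prof.mean_intensity) > 0)


def test_profile_shape_mismatch_rejected(disk_mask):
    binmap = compute_distance_bins(disk_mask)
    with pytest.raises(ValueError, match="mismatch"):
        profile_intensity(np.zeros((10, 10)), binmap)


# --------------------------------------------------------------------------
# normalization


def _toy_profiles(values):
    from cardionuc.radial import RadialProfile

    return [
        RadialProfile(
            mean_intensity=np.asarray(v, float),
            pixel_count=np.ones(len(v), int),
            nucleus_id=f"n{i}",
            probe_id="p",
            group_label="A" if i % 2 == 0 else "B",
        )
        for i, v in enumerate(values)
    ]


def test_normalization_endpoints_map_to_zero_and_one():
    profiles = _toy_profiles([np.arange(2, 12), np.arange(3, 13)])
    matrix = normalize_profiles(profiles)
    assert matrix.v_min == 2 and matrix.v_max == 12
    flat = matrix.per_nucleus.filter(like="bin").to_numpy()
    assert flat.min() == 0.0 and flat.max() == 1.0
    assert np.all((flat >= 0) & (flat <= 1))


def test_normalization_degenerate_flag():
    profiles = _toy_profiles([np.full(10, 4.0), np.full(10, 4.0)])
    with pytest.warns(UserWarning, match="degenerate"):
        matrix = normalize_profiles(profiles)
    assert matrix.degenerate
    assert np.all(matrix.values.to_numpy() == 0.0)


def test_normalization_affine_invariant():
    rng = np.random.default_rng(0)
    base = [rng.uniform(10, 50, 10) for _ in range(6)]
    m1 = normalize_profiles(_toy_profiles(base))
    m2 = normalize_profiles(_toy_profiles([3.0 * v + 7.0 for v in base]))
    assert np.allclose(m1.values.to_numpy(), m2.values.to_numpy())


def test_per_bin_scope_differs_but_stays_in_unit_interval():
    rng = np.random.default_rng(1)
    profiles = _toy_profiles([rng.uniform(0, 10, 10) for _ in range(4)])
    m = normalize_profiles(profiles, scope="per_bin")
    flat = m.per_nucleus.filter(like="bin").to_numpy()
    assert np.all((flat >= 0) & (flat <= 1))


# --------------------------------------------------------------------------
# peripherality


def test_peripherality_uniform_and_extreme():
    assert peripherality_index(np.ones(10)) == pytest.approx(0.5)
    only_last = np.zeros(10)
    only_last[9] = 3.0
    assert peripherality_index(only_last) == 1.0
    with pytest.raises(ValueError, match="all-zero"):
        peripherality_index(np.zeros(10))


def test_peripherality_recovers_radial_position():
    """Peripheral territories (mu=0.9) score above central ones (mu=0.1)."""
    hi = noiseless_group_profiles(0.9, 5, seed0=0, group="hi")
    lo = noiseless_group_profiles(0.1, 5, seed0=0, group="lo")
    hi_idx = np.mean([peripherality_index(p) for p in hi])
    lo_idx = np.mean([peripherality_index(p) for p in lo])
    assert hi_idx > 0.5 > lo_idx


# --------------------------------------------------------------------------
# shape descriptors


def test_disk_shape_descriptors(disk_mask):
    sd = shape_descriptors(disk_mask)
    assert abs(sd.circularity - 1.0) < 0.05
    assert abs(sd.solidity - 1.0) < 0.02
    assert sd.max_diameter >= 2 * np.sqrt(sd.area / np.pi) * 0.98
    assert sd.area == pytest.approx(np.pi * (40 * 0.11) ** 2, rel=0.02)


def test_rectangle_feret_diagonal():
    raster = np.zeros((40, 120), bool)
    raster[10:30, 10:110] = True  # 100 x 20 px rectangle
    sd = shape_descriptors(NuclearMask(raster, pixel_size=0.11))
    assert abs(sd.solidity - 1.0) < 0.02
    assert sd.max_diameter == pytest.approx(np.hypot(100, 20) * 0.11, rel=0.02)


def test_circularity_decreases_with_aspect_ratio():
    from cardionuc.synthetic import SceneParams, make_nucleus_mask

    circ = []
    for aspect in (1.0, 2.0, 3.0, 4.0):
        b = 12.0
        sp = SceneParams(nucleus_semiaxes=(b * aspect, b), image_size=(40, 128),
                         boundary_wobble=0.0)
        sd = shape_descriptors(make_nucleus_mask(sp))
        circ.append(sd.circularity)
    assert np.all(np.diff(circ) < 0)


# --------------------------------------------------------------------------
# group comparison


def test_separated_groups_yield_significant_interaction():
    per_nucleus = two_group_per_nucleus(0.4, 0.7, n=15, seed0=0)
    result = compare_radial_distributions(per_nucleus)
    assert result.interaction_p < 0.05
    assert set(result.per_bin.columns) >= {"p_raw", "p_adj", "significant"}
    assert ((result.per_bin["p_adj"].dropna() >= 0) &
            (result.per_bin["p_adj"].dropna() <= 1)).all()


def test_bin_main_effect_invariant_under_group_relabeling():
    per_nucleus = two_group_per_nucleus(0.4, 0.7, n=8, seed0=5)
    res1 = compare_radial_distributions(per_nucleus)
    swapped = per_nucleus.copy()
    swapped["group"] = swapped["group"].map({"A": "B", "B": "A"})
    res2 = compare_radial_distributions(swapped)
    assert res1.bin_p == pytest.approx(res2.bin_p)
    assert res1.anova.loc["C(bin)", "F"] == pytest.approx(res2.anova.loc["C(bin)", "F"])


def test_comparison_requires_two_nuclei_per_group():
    per_nucleus = two_group_per_nucleus(0.4, 0.7, n=2, seed0=1)
    short = per_nucleus.drop(per_nucleus[per_nucleus.group == "B"].index[0])
    with pytest.raises(ValueError, match="fewer than 2"):
        compare_radial_distributions(short)
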