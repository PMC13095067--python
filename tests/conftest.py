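"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cardionuc.radial import (
    NuclearMask,
    RadialProfile,
    compute_distance_bins,
    normalize_profiles,
    profile_intensity,
)
from cardionuc.synthetic import SceneParams, make_nucleus_mask, render_territory_scene


def brute_force_bins(raster: np.ndarray, n_bins: int = 10, mode: str = "equal_width"):
    """Independent per-pixel oracle for the radial binning.

    Nearest-background distances by direct pairwise search and a direct
    decile split; shares no code with the implementation under test.
    """
    raster = np.asarray(raster, bool)
    fg = np.argwhere(raster)
    bg = np.argwhere(~raster)
    d = cdist(fg.astype(float), bg.astype(float)).min(axis=1)
    r = 1.0 - d / d.max()
    out = np.zeros(raster.shape, dtype=np.int32)
    if mode == "equal_width":
        idx = np.minimum(np.floor(r * n_bins).astype(int) + 1, n_bins)
    else:
        area = r.size
        idx = np.empty(area, dtype=int)
        for i, v in enumerate(r):
            rank = int((r < v).sum())
            idx[i] = (rank * n_bins) // area + 1
    out[fg[:, 0], fg[:, 1]] = idx
    return out


def random_mask(seed: int, max_size: int = 64) -> NuclearMask:
    """A random valid elliptical mask fitting in a max_size x max_size image."""
    rng = np.random.default_rng(seed)
    # deep enough for 10 distinct bins, small enough to fit with wobble margin
    a = rng.uniform(13, 25)
    b = rng.uniform(13, 25)
    sp = SceneParams(
        nucleus_semiaxes=(a, b),
        image_size=(max_size, max_size),
        boundary_wobble=rng.uniform(0.0, 0.12),
        seed=seed,
    )
    return make_nucleus_mask(sp)


def noiseless_group_profiles(
    mu: float, n: int, seed0: int, group: str, sigma: float = 0.05,
    mode: str = "equal_width",
) -> list[RadialProfile]:
    """Noiseless probe profiles (expected image, background removed) at radius mu."""
    profiles = []
    for i in range(n):
        sp = SceneParams(
            territory_radial_mu=mu,
            territory_radial_sigma=sigma,
            read_noise_sd=0.0,
            seed=seed0 + i,
        )
        mask = make_nucleus_mask(sp)
        scene = render_territory_scene(mask, sp)
        binmap = compute_distance_bins(mask, mode=mode)
        profiles.append(
            profile_intensity(
                scene.expected[1] - sp.background, binmap,
                nucleus_id=f"{group}_{i}", probe_id="p", group_label=group,
            )
        )
    return profiles


def two_group_per_nucleus(mu_a: float, mu_b: float, n: int, seed0: int):
    """Normalized per-nucleus profile table for a two-group comparison."""
    profiles = noiseless_group_profiles(mu_a, n, seed0, "A")
    profiles += noiseless_group_profiles(mu_b, n, seed0 + 10_000, "B")
    return normalize_profiles(profiles).per_nucleus


@pytest.fixture(scope="session")
def disk_mask() -> NuclearMask:
    """Rasterized disk of radius 40 px in a 96x96 image."""
    yy, xx = np.mgrid[0:96, 0:96]
    raster = (yy - 47.5) ** 2 + (xx - 47.5) ** 2 <= 40.0**2
    return NuclearMask(raster=raster, pixel_size=0.11)
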