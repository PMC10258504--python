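"""Shared fixtures and independent oracles used across the suite."""

from collections import deque

import numpy as np
import pytest

from siderseg import BandSpec, PhantomSpec, generate_phantom


def bfs_flood_fill(candidate: np.ndarray, seeds) -> set:
    """Independent brute-force 6-neighborhood flood fill (pure-Python BFS)."""
    shape = candidate.shape
    visited = set()
    queue = deque()
    for s in seeds:
        s = tuple(s)
        if candidate[s] and s not in visited:
            visited.add(s)
            queue.append(s)
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = (i + di, j + dj, k + dk)
            if any(c < 0 or c >= m for c, m in zip(n, shape)):
                continue
            if candidate[n] and n not in visited:
                visited.add(n)
                queue.append(n)
    return visited


def make_tube_volume(shape=(48, 48, 3), width=1.0, depth=60.0, background=100.0,
                     angle_deg=0.0, spacing=(0.6, 0.6, 1.0)):
    """A straight dark tube with a Gaussian cross-section profile.

    The tube runs in-plane through the slice centre at ``angle_deg`` from
    the first axis; the smooth profile makes the image (up to rasterisation)
    rotation invariant, which the discrete filter should approximately
    respect.
    """
    from siderseg import SwiVolume

    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    # signed distance from the line through (cx, cy) at angle theta
    d = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    plane = background - depth * np.exp(-(d**2) / (2.0 * width**2))
    data = np.repeat(plane[:, :, None], nz, axis=2)
    return SwiVolume(data=data, spacing=spacing, slice_axis=2)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic noisy phantom with a single thickness-2 band."""
    spec = PhantomSpec(
        shape=(64, 64, 16),
        n_sulci=3,
        css_bands=(BandSpec(sulcus=1, thickness=2),),
        rng_seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free counterpart for exact-recovery checks."""
    spec = PhantomSpec(
        shape=(64, 64, 16),
        n_sulci=3,
        css_bands=(BandSpec(sulcus=1, thickness=2),),
        noise_sigma=0.0,
        rng_seed=11,
    )
    return generate_phantom(spec)
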