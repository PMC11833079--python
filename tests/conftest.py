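"""Shared fixtures.

The expensive study-condition runs (default 400x400x800-um volumes,
three seeds) are computed once per session and shared by every test
that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

from paleocanal.io import BONE, CANAL, LabelVolume
from paleocanal.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_runs():
    """Three default-condition pipeline runs (morphometry; FE stage off)."""
    return {seed: run_pipeline({"fe": {"enabled": False}}, seed=seed) for seed in (1, 2, 3)}


@pytest.fixture(scope="session")
def small_run():
    """One small, fast end-to-end run (reduced domain, no FE)."""
    cfg = {
        "generator": {"domain_size": (160.0, 160.0, 320.0)},
        "fe": {"enabled": False},
    }
    return run_pipeline(cfg, seed=7)


def make_cylinder_label(
    shape=(41, 41, 80), spacing=2.0, radius_um=10.0, center=None
) -> LabelVolume:
    """Straight axial cylinder phantom.

    Uses an odd transverse grid so the axis passes through voxel centers:
    3D thinning needs an on-grid medial voxel to anchor the centerline.
    """
    nx, ny, nz = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = ((x - center[0]) * spacing) ** 2 + ((y - center[1]) * spacing) ** 2
    arr = np.full(shape, BONE, dtype=np.uint8)
    arr[r2 <= radius_um**2] = CANAL
    return LabelVolume(arr, (spacing,) * 3)
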