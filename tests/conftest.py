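"""Shared fixtures: analytic phantom nuclei and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from nucpos.geometry import NucleusModel


def make_sphere_nucleus(
    radius_um: float = 5.0,
    voxel_size=(0.2, 0.2, 0.2),
    chromocenters=(),
    pad_um: float = 0.6,
    nucleus_id: str = "sphere",
) -> NucleusModel:
    """Spherical phantom nucleus with optional chromocenter spheres.

    ``chromocenters`` is a sequence of ((dx, dy, dz) offset from the nucleus
    center in um, radius_um) pairs.
    """
    sx, sy, sz = voxel_size
    nx = int(np.ceil(2 * (radius_um + pad_um) / sx))
    ny = int(np.ceil(2 * (radius_um + pad_um) / sy))
    nz = int(np.ceil(2 * (radius_um + pad_um) / sz))
    cx, cy, cz = nx * sx / 2, ny * sy / 2, nz * sz / 2
    xc = (np.arange(nx) + 0.5) * sx - cx
    yc = (np.arange(ny) + 0.5) * sy - cy
    zc = (np.arange(nz) + 0.5) * sz - cz
    r2 = zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
    mask = r2 <= radius_um**2
    labels = np.zeros(mask.shape, dtype=np.int32)
    for i, (offset, r) in enumerate(chromocenters, start=1):
        ox, oy, oz = offset
        d2 = (
            (zc - oz)[:, None, None] ** 2
            + (yc - oy)[None, :, None] ** 2
            + (xc - ox)[None, None, :] ** 2
        )
        labels[d2 <= r**2] = i
    return NucleusModel(
        nucleus_id=nucleus_id, mask=mask, chromocenters=labels, voxel_size=voxel_size
    )


def center_of(nucleus: NucleusModel) -> tuple[float, float, float]:
    nz, ny, nx = nucleus.mask.shape
    sx, sy, sz = nucleus.voxel_size
    return (nx * sx / 2, ny * sy / 2, nz * sz / 2)


@pytest.fixture(scope="session")
def sphere_nucleus() -> NucleusModel:
    """Radius-5 um sphere with a radius-1 um chromocenter offset 2.5 um in x."""
    return make_sphere_nucleus(radius_um=5.0, chromocenters=(((2.5, 0.0, 0.0), 1.0),))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_901)
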