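"""Nuclear geometry: segmentation, FISH spot detection and anisotropic 3D distances.

Image stacks are confocal-like z-stacks stored in ZYX axis order on an
anisotropic voxel grid (default 0.08 x 0.08 x 0.2 um in xyz).  Physical
coordinates are always expressed as (x, y, z) in micrometres.  The voxel with
index (iz, iy, ix) spans the half-open physical box
``[i*s, (i+1)*s)`` per axis and its centre sits at ``(i + 0.5) * s``.

Distances are computed with exact anisotropic Euclidean distance transforms on
the voxel grid (distance between voxel centres), so the sub-voxel error of any
reported distance is bounded by half a voxel diagonal (~0.12 um at the default
voxel size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

#: default physical voxel size in xyz order (um)
DEFAULT_VOXEL_SIZE = (0.08, 0.08, 0.2)

SPOT_COLUMNS = ["locus_id", "gene_id", "nucleus_id", "condition", "x_um", "y_um", "z_um"]


class SegmentationError(RuntimeError):
    """Raised when no nuclear foreground can be segmented from a stack."""


class OutOfNucleusError(ValueError):
    """Raised when a query point falls outside the nuclear mask."""


class ChromocenterPlacementError(RuntimeError):
    """Raised by the synthetic generator when chromocenters cannot be placed."""


@dataclass
class NucleusModel:
    """A single nucleus: voxel mask, chromocenter labels and voxel geometry.

    Parameters
    ----------
    nucleus_id:
        Stable identifier of the nucleus.
    mask:
        Boolean nuclear mask, ZYX order.  Must be a single connected
        component (the edge of the DAPI-like signal defines the periphery).
    chromocenters:
        Integer label mask of chromocenters on the same grid, 0 = background.
        Must be contained in ``mask``.  May be empty (no chromocenters).
    voxel_size:
        Physical voxel size as an (x, y, z) triple in micrometres.
    """

    nucleus_id: str
    mask: np.ndarray
    chromocenters: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    condition: str | None = None

    _edt_periphery: np.ndarray | None = field(default=None, repr=False, compare=False)
    _edt_chromocenter: np.ndarray | None = field(default=None, repr=False, compare=False)
    _in_mask_flat: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.chromocenters is None:
            self.chromocenters = np.zeros(self.mask.shape, dtype=np.int32)
        self.chromocenters = np.asarray(self.chromocenters)
        if self.chromocenters.shape != self.mask.shape:
            raise ValueError("chromocenter mask shape differs from nuclear mask")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive lengths (um)")
        if not self.mask.any():
            raise ValueError(f"nucleus {self.nucleus_id}: empty nuclear mask")
        if ((self.chromocenters > 0) & ~self.mask).any():
            raise ValueError(
                f"nucleus {self.nucleus_id}: chromocenter mask extends outside the nuclear mask"
            )

    # -- geometry helpers ---------------------------------------------------

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Voxel size reordered to match the ZYX array axes."""
        sx, sy, sz = self.voxel_size
        return (sz, sy, sx)

    @property
    def n_chromocenters(self) -> int:
        labels = np.unique(self.chromocenters)
        return int((labels > 0).sum())

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum() * np.prod(self.voxel_size))

    def point_to_voxel(self, point_xyz_um) -> tuple[int, int, int]:
        """Map a physical (x, y, z) point in um to the containing voxel (iz, iy, ix)."""
        x, y, z = (float(v) for v in point_xyz_um)
        sx, sy, sz = self.voxel_size
        return (int(np.floor(z / sz)), int(np.floor(y / sy)), int(np.floor(x / sx)))

    def contains(self, point_xyz_um) -> bool:
        iz, iy, ix = self.point_to_voxel(point_xyz_um)
        nz, ny, nx = self.mask.shape
        if not (0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx):
            return False
        return bool(self.mask[iz, iy, ix])

    # -- cached distance transforms ----------------------------------------

    def edt_periphery(self) -> np.ndarray:
        """Distance (um) from each in-mask voxel to the nearest out-of-mask voxel."""
        if self._edt_periphery is None:
            self._edt_periphery = ndimage.distance_transform_edt(
                self.mask, sampling=self.sampling_zyx
            )
        return self._edt_periphery

    def edt_chromocenter(self) -> np.ndarray | None:
        """Distance (um) to the nearest chromocenter voxel; None if there are none."""
        if self.n_chromocenters == 0:
            return None
        if self._edt_chromocenter is None:
            self._edt_chromocenter = ndimage.distance_transform_edt(
                self.chromocenters == 0, sampling=self.sampling_zyx
            )
        return self._edt_chromocenter

    def in_mask_indices(self) -> np.ndarray:
        """Flat indices of in-mask voxels (cached; used for uniform sampling)."""
        if self._in_mask_flat is None:
            self._in_mask_flat = np.flatnonzero(self.mask.ravel())
        return self._in_mask_flat


@dataclass(frozen=True)
class DistanceRecord:
    """Shortest 3D distances of one locus to the two heterochromatin compartments.

    ``d_chromocenter`` is 0.0 for a locus inside a chromocenter and NaN
    (missing) when the nucleus has no chromocenters at all.
    """

    locus_id: str
    d_periphery: float
    d_chromocenter: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_nucleus(
    stack: np.ndarray,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    sigma_um: float = 0.25,
    nucleus_id: str = "nucleus",
) -> NucleusModel:
    """Segment the dominant nucleus from a DAPI-like intensity stack.

    Gaussian smoothing, global Otsu threshold, per-plane-independent 3D hole
    filling, then the largest connected component is retained (ties broken by
    the first label, which is deterministic in scan order).
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.size == 0:
        raise SegmentationError("expected a non-empty 3D ZYX stack")
    if np.ptp(stack) == 0:
        raise SegmentationError("stack has constant intensity; no foreground")
    sx, sy, sz = voxel_size
    sigma_voxels = (sigma_um / sz, sigma_um / sy, sigma_um / sx)
    smoothed = ndimage.gaussian_filter(stack, sigma=sigma_voxels)
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        raise SegmentationError("empty foreground after Otsu threshold")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1  # argmax -> first maximal label
        fg = labels == keep
    return NucleusModel(
        nucleus_id=nucleus_id,
        mask=fg,
        chromocenters=np.zeros(fg.shape, dtype=np.int32),
        voxel_size=voxel_size,
    )


def segment_chromocenters(
    stack: np.ndarray,
    nucleus: NucleusModel,
    k: float = 2.0,
    alt_channel: np.ndarray | None = None,
    sigma_um: float = 0.15,
) -> np.ndarray:
    """Label chromocenters as high-intensity regions inside the nuclear mask.

    Voxels whose smoothed intensity exceeds ``mean + k * SD`` (statistics taken
    within the nuclear mask) are marked; connected components become labels.
    If ``alt_channel`` is given (e.g., an MeCP2-like immunofluorescence
    channel) thresholding is applied to it instead of the DAPI-like stack.
    An empty result is permitted (downstream chromocenter distances are then
    reported missing).
    """
    if k <= 0:
        raise ValueError("k (SD multiplier) must be > 0")
    channel = np.asarray(alt_channel if alt_channel is not None else stack, dtype=np.float64)
    if channel.shape != nucleus.mask.shape:
        raise ValueError("channel shape differs from the nuclear mask")
    sx, sy, sz = nucleus.voxel_size
    smoothed = ndimage.gaussian_filter(channel, sigma=(sigma_um / sz, sigma_um / sy, sigma_um / sx))
    inside = smoothed[nucleus.mask]
    thr = inside.mean() + k * inside.std()
    cc = (smoothed > thr) & nucleus.mask
    labels, n = ndimage.label(cc)
    logger.debug(
        "nucleus %s: chromocenter threshold mean+%.2f*SD = %.3f -> %d components",
        nucleus.nucleus_id, k, thr, n,
    )
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------


def detect_spots(
    spot_stack: np.ndarray,
    nucleus: NucleusModel,
    min_separation_um: float = 1.0,
    mad_multiplier: float = 6.0,
    sigma_um: float = 0.1,
    gene_id: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """Detect FISH-like spots inside the nucleus and localize them sub-voxel.

    Local maxima of the lightly smoothed spot channel above a robust
    background threshold (median + ``mad_multiplier`` * scaled MAD, computed
    within the nuclear mask) are detected; each spot centroid is refined by an
    intensity-weighted mean over its local neighborhood.  Spots outside the
    nuclear mask are discarded.  An empty table is a valid result.
    """
    spot_stack = np.asarray(spot_stack, dtype=np.float64)
    if spot_stack.shape != nucleus.mask.shape:
        raise ValueError("spot stack shape differs from the nuclear mask")
    sx, sy, sz = nucleus.voxel_size
    smoothed = ndimage.gaussian_filter(
        spot_stack, sigma=(sigma_um / sz, sigma_um / sy, sigma_um / sx)
    )
    inside = smoothed[nucleus.mask]
    med = np.median(inside)
    mad = np.median(np.abs(inside - med))
    thr = med + mad_multiplier * 1.4826 * mad
    # min separation expressed in voxels on the finest axis is conservative on
    # the coarser axes; fine for sparse FISH-like signals
    min_dist_vox = max(1, int(round(min_separation_um / max(nucleus.voxel_size))))
    peaks = peak_local_max(
        smoothed,
        min_distance=min_dist_vox,
        threshold_abs=thr,
        labels=nucleus.mask,
        exclude_border=False,
    )
    rows = []
    half = np.maximum(1, np.round(0.2 / np.array(nucleus.sampling_zyx)).astype(int))
    for i, (pz, py, px) in enumerate(peaks):
        sl = tuple(
            slice(max(0, c - h), min(s, c + h + 1))
            for c, h, s in zip((pz, py, px), half, spot_stack.shape)
        )
        patch = smoothed[sl]
        weights = np.clip(patch - med, 0, None)
        if weights.sum() == 0:
            continue
        grid = np.mgrid[sl].astype(float)
        cz, cy, cx = (np.sum(g * weights) / weights.sum() for g in grid)
        x_um = (cx + 0.5) * sx
        y_um = (cy + 0.5) * sy
        z_um = (cz + 0.5) * sz
        if not nucleus.contains((x_um, y_um, z_um)):
            continue
        rows.append(
            {
                "locus_id": f"{nucleus.nucleus_id}:spot{i}",
                "gene_id": gene_id,
                "nucleus_id": nucleus.nucleus_id,
                "condition": condition or (nucleus.condition or ""),
                "x_um": x_um,
                "y_um": y_um,
                "z_um": z_um,
            }
        )
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def measure_distances(point_xyz_um, nucleus: NucleusModel, locus_id: str = "") -> DistanceRecord:
    """Shortest 3D distances (um) from a point to the periphery and chromocenters.

    The point must lie inside the nuclear mask.  ``d_chromocenter`` is NaN when
    the nucleus has no chromocenters (missing, not zero).
    """
    d_per, d_cc = measure_distances_batch(np.asarray(point_xyz_um, float)[None, :], nucleus)
    return DistanceRecord(locus_id=locus_id, d_periphery=float(d_per[0]), d_chromocenter=float(d_cc[0]))


def measure_distances_batch(points_xyz_um: np.ndarray, nucleus: NucleusModel):
    """Vectorized :func:`measure_distances` for an (n, 3) array of xyz points (um)."""
    pts = np.asarray(points_xyz_um, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of xyz coordinates in um")
    sx, sy, sz = nucleus.voxel_size
    iz = np.floor(pts[:, 2] / sz).astype(np.intp)
    iy = np.floor(pts[:, 1] / sy).astype(np.intp)
    ix = np.floor(pts[:, 0] / sx).astype(np.intp)
    nz, ny, nx = nucleus.mask.shape
    inside_grid = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    if not inside_grid.all():
        bad = pts[~inside_grid][0]
        raise OutOfNucleusError(f"point {tuple(bad)} um lies outside the image grid")
    if not nucleus.mask[iz, iy, ix].all():
        bad = pts[~nucleus.mask[iz, iy, ix]][0]
        raise OutOfNucleusError(
            f"point {tuple(bad)} um lies outside the nuclear mask of {nucleus.nucleus_id}"
        )
    # trilinear interpolation of the transforms at the continuous point keeps
    # sub-voxel variation (voxel-center sampling would tie all points sharing
    # a voxel) while agreeing exactly with the grid values at voxel centers
    coords = np.vstack([
        pts[:, 2] / sz - 0.5,
        pts[:, 1] / sy - 0.5,
        pts[:, 0] / sx - 0.5,
    ])
    d_per = ndimage.map_coordinates(nucleus.edt_periphery(), coords, order=1, mode="nearest")
    edt_cc = nucleus.edt_chromocenter()
    if edt_cc is None:
        logger.debug("nucleus %s has no chromocenters; d_chromocenter missing", nucleus.nucleus_id)
        d_cc = np.full(len(pts), np.nan)
    else:
        d_cc = ndimage.map_coordinates(edt_cc, coords, order=1, mode="nearest")
        # exact zero inside a chromocenter (interpolation at its rim can leak
        # a small positive value)
        d_cc[nucleus.chromocenters[iz, iy, ix] > 0] = 0.0
    np.maximum(d_per, 0.0, out=d_per)
    np.maximum(d_cc, 0.0, out=d_cc)
    return d_per, d_cc


def sample_uniform_points(nucleus: NucleusModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n points uniformly over the in-mask physical volume, as (n, 3) xyz um.

    All voxels share one volume on the regular grid, so a uniform voxel choice
    plus a uniform jitter within the voxel is uniform over the mask volume and
    avoids lattice artifacts.
    """
    if n <= 0:
        raise ValueError("n must be a positive count")
    flat = nucleus.in_mask_indices()
    if flat.size == 0:
        raise ValueError(f"nucleus {nucleus.nucleus_id}: empty mask")
    choice = rng.integers(0, flat.size, size=n)
    iz, iy, ix = np.unravel_index(flat[choice], nucleus.mask.shape)
    jitter = rng.random((n, 3))
    sx, sy, sz = nucleus.voxel_size
    x = (ix + jitter[:, 0]) * sx
    y = (iy + jitter[:, 1]) * sy
    z = (iz + jitter[:, 2]) * sz
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a ZYX stack."""
    return tifffile.imread(str(path))


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def write_spot_table(path, spots: pd.DataFrame) -> None:
    spots.to_csv(path, index=False, columns=SPOT_COLUMNS)


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot table {path} lacks columns: {sorted(missing)}")
    return df
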