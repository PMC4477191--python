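"""Voxel-wise regional homogeneity (ReHo) via Kendall's coefficient of
concordance.

ReHo quantifies how synchronized a voxel's BOLD time series is with its
immediate spatial neighbors. For a cluster of K voxels observed at n time
points, each voxel's series is converted to within-voxel temporal ranks
(midranks on ties) and Kendall's W is

    W = 12 * sum_i (R_i - Rbar)^2 / (K^2 * (n^3 - n))

where R_i is the rank sum across the K voxels at time point i and
Rbar = K*(n+1)/2. W lies in [0, 1]; 1 means all K series rank the time
points identically. The conventional cluster is the 27-voxel cube centered
on the target voxel; 7 (face neighbors) and 19 (faces + edges) are also
supported. Each voxel's series is linearly detrended before ranking, and
the finished map may be smoothed with a masked, renormalized Gaussian
kernel specified by its FWHM in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import signal
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

__all__ = [
    "Volume4D",
    "GreyMask",
    "ReHoMap",
    "MotionTrace",
    "QCReport",
    "detrend_linear",
    "kendalls_w",
    "compute_reho_map",
    "smooth_gaussian",
    "qc_motion",
    "cluster_offsets",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _affine_from_voxel_size(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class Volume4D:
    """A subject's 4D BOLD volume: 3 spatial axes x time, plus voxel size."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D.data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 10:
            raise ValueError(
                f"Volume4D needs at least 10 time points, got {self.data.shape[3]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"Volume4D for {self.subject_id!r} contains non-finite values")
        if self.affine is None:
            self.affine = _affine_from_voxel_size(self.voxel_size_mm)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(self.voxel_size_mm) + (1.0,))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, subject_id: str | None = None) -> "Volume4D":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if not np.all(np.isfinite(data)):
            raise ValueError(f"volume {path} contains non-finite values")
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
        return cls(data=data, voxel_size_mm=vox, subject_id=sid, affine=np.asarray(img.affine))


@dataclass
class GreyMask:
    """Binary 3D grey-matter mask restricting every analysis stage."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"GreyMask.data must be 3D, got shape {self.data.shape}")
        if not self.data.any():
            raise ValueError("GreyMask has no in-mask voxels")
        if self.affine is None:
            self.affine = _affine_from_voxel_size(self.voxel_size_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "GreyMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj) > 0
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, voxel_size_mm=vox, affine=np.asarray(img.affine))


@dataclass
class ReHoMap:
    """3D map of Kendall's W values; NaN marks no-data (out of mask or too
    few in-mask neighbors), never a silent zero."""

    data: np.ndarray
    mask: GreyMask
    cluster_size: int
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.mask.data.shape:
            raise ValueError(
                f"map shape {self.data.shape} != mask shape {self.mask.data.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.data)

    def save(self, path) -> None:
        # on disk NaN becomes 0; the mask disambiguates background from data
        out = np.nan_to_num(self.data, nan=0.0).astype(np.float32)
        img = nib.Nifti1Image(out, self.mask.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, mask: GreyMask, cluster_size: int = 27,
             subject_id: str = "") -> "ReHoMap":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        data[~mask.data] = np.nan
        return cls(data=data, mask=mask, cluster_size=cluster_size,
                   subject_id=subject_id)


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume: 3 translations (mm)
    followed by 3 rotations (degrees)."""

    values: np.ndarray

    COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(
                f"motion trace must have 6 columns, got shape {self.values.shape}"
            )

    def save(self, path) -> None:
        np.savetxt(str(path), self.values, fmt="%.6f")

    @classmethod
    def load(cls, path) -> "MotionTrace":
        vals = np.loadtxt(str(path))
        if vals.ndim == 1:
            vals = vals.reshape(1, -1)
        if vals.shape[1] != 6:
            raise ValueError(
                f"motion trace {path} must have 6 columns, got {vals.shape[1]}"
            )
        return cls(values=vals)


@dataclass
class QCReport:
    passed: bool
    offending: list[tuple[str, float]] = field(default_factory=list)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the best-fit line (slope and mean) from a 1D series.

    A constant series returns all zeros.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("detrend_linear expects a 1D series")
    if series.size < 3:
        raise ValueError("detrend_linear needs at least 3 samples")
    return signal.detrend(series, type="linear")


def kendalls_w(block: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K series of length n.

    `block` is (K, n): K voxels (judges) ranking n time points. Ranks are
    midranks within each series; the denominator is the tie-uncorrected
    K^2*(n^3 - n), the convention of the original ReHo formulation. A
    constant series gets equal midranks, which can only lower W.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2:
        raise ValueError("kendalls_w expects a (K, n) array")
    k, n = block.shape
    if k < 2 or n < 2:
        raise ValueError(f"kendalls_w needs K >= 2 and n >= 2, got K={k}, n={n}")
    ranks = rankdata(block, axis=1)
    r_i = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2.0
    s = float(np.sum((r_i - rbar) ** 2))
    return 12.0 * s / (k * k * (n**3 - n))


# cluster geometries: 7 = face neighbors, 19 = faces + edges, 27 = full cube
def cluster_offsets(cluster_size: int) -> list[tuple[int, int, int]]:
    if cluster_size not in (7, 19, 27):
        raise ValueError(f"cluster_size must be one of 7, 19, 27; got {cluster_size}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if cluster_size == 7 and manhattan > 1:
                    continue
                if cluster_size == 19 and manhattan > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def compute_reho_map(
    volume: Volume4D,
    mask: GreyMask,
    cluster_size: int = 27,
    detrend: bool = True,
    edge_policy: str = "intersect",
) -> ReHoMap:
    """Compute the ReHo map: Kendall's W over each in-mask voxel's
    neighborhood.

    The neighborhood is the `cluster_size` stencil centered on the voxel,
    intersected with the mask. With ``edge_policy="intersect"`` W is computed
    over however many in-mask neighbors remain (at least 2; fewer gives
    no-data). ``edge_policy="full"`` requires the complete stencil in-mask
    and marks everything else no-data. Each voxel's series is linearly
    detrended first when `detrend` is true.
    """
    if volume.spatial_shape != mask.data.shape:
        raise ValueError(
            f"volume spatial shape {volume.spatial_shape} != mask shape {mask.data.shape}"
        )
    if edge_policy not in ("intersect", "full"):
        raise ValueError(f"edge_policy must be 'intersect' or 'full', got {edge_policy!r}")
    offsets = cluster_offsets(cluster_size)

    data = volume.data
    n = volume.n_timepoints
    if detrend:
        data = signal.detrend(data, axis=-1, type="linear")

    m = mask.data
    ranks = rankdata(data, axis=-1)
    ranks = np.where(m[..., None], ranks, 0.0)

    # accumulate neighbor rank-sums and neighbor counts by shifting through
    # a zero-padded copy; padding handles volume edges, masking handles the rim
    rp = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    mp = np.pad(m.astype(np.float64), 1)
    sx, sy, sz = m.shape
    rank_sum = np.zeros(m.shape + (n,), dtype=np.float64)
    count = np.zeros(m.shape, dtype=np.float64)
    for dx, dy, dz in offsets:
        rank_sum += rp[1 + dx:1 + dx + sx, 1 + dy:1 + dy + sy, 1 + dz:1 + dz + sz, :]
        count += mp[1 + dx:1 + dx + sx, 1 + dy:1 + dy + sy, 1 + dz:1 + dz + sz]

    rbar = count * (n + 1) / 2.0
    ss = np.sum((rank_sum - rbar[..., None]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * ss / (count**2 * (n**3 - n))

    if edge_policy == "full":
        valid = m & (count == cluster_size)
    else:
        valid = m & (count >= 2)
    out = np.full(m.shape, np.nan)
    out[valid] = w[valid]
    return ReHoMap(data=out, mask=mask, cluster_size=cluster_size,
                   subject_id=volume.subject_id)


def smooth_gaussian(
    reho_map: ReHoMap,
    fwhm_mm: float,
    masked: bool = True,
    truncate: float = 4.0,
) -> ReHoMap:
    """Smooth a ReHo map with a Gaussian kernel of the given FWHM (mm).

    sigma per axis = fwhm / (2*sqrt(2*ln 2)) / voxel_size. By default the
    convolution is restricted to voxels carrying data and renormalized by the
    smoothed data-mask, so values never bleed in from background and a
    constant map is a fixed point. ``masked=False`` smooths the whole volume
    with background treated as zero. fwhm 0 returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return reho_map
    sigma = [
        fwhm_mm * _FWHM_TO_SIGMA / vs for vs in reho_map.mask.voxel_size_mm
    ]
    valid = reho_map.valid
    filled = np.where(valid, reho_map.data, 0.0)
    num = gaussian_filter(filled, sigma=sigma, mode="constant", truncate=truncate)
    if masked:
        den = gaussian_filter(valid.astype(np.float64), sigma=sigma,
                              mode="constant", truncate=truncate)
        with np.errstate(divide="ignore", invalid="ignore"):
            sm = num / den
    else:
        sm = num
    out = np.full(reho_map.data.shape, np.nan)
    out[valid] = sm[valid]
    return ReHoMap(data=out, mask=reho_map.mask, cluster_size=reho_map.cluster_size,
                   subject_id=reho_map.subject_id)


def qc_motion(
    trace: MotionTrace,
    translation_limit_mm: float = 1.5,
    rotation_limit_deg: float = 1.5,
) -> QCReport:
    """Head-motion QC: fail if any translation exceeds the mm limit or any
    rotation exceeds the degree limit in absolute value. Limits are
    inclusive: an extremum exactly at the threshold passes."""
    vals = trace.values
    offending: list[tuple[str, float]] = []
    for j, name in enumerate(MotionTrace.COLUMNS):
        col = vals[:, j]
        extremum = col[np.argmax(np.abs(col))] if col.size else 0.0
        limit = translation_limit_mm if j < 3 else rotation_limit_deg
        if abs(extremum) > limit:
            offending.append((name, float(extremum)))
    return QCReport(passed=not offending, offending=offending)
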