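"""Labelled voxel volumes: layered skin with cylindrical vessels, two-layer phantoms.

Coordinate convention (fixed for reproducibility): voxel indices are 0-based
with voxel ``k`` covering the half-open physical slab ``[k*h, (k+1)*h)`` mm;
a voxel belongs to the region containing its *center*.  The ``z = 0`` face of
the grid is the air-tissue surface; +Z points into the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chromophores import BLOOD_ID, DERMIS_ID, EPIDERMIS_ID, PHANTOM_BOTTOM_ID, PHANTOM_TOP_ID

__all__ = [
    "TissueVolume",
    "SkinSpec",
    "PhantomSpec",
    "DEFAULT_SKIN_EXTENT",
    "build_skin_volume",
    "build_phantom_volume",
    "sample_vessel_centers",
    "resolve_centers",
    "dilate_vessels",
    "save_volume",
    "load_volume",
]

#: the simulated skin tissue block, mm (X, Y, Z)
DEFAULT_SKIN_EXTENT = (2.0, 4.7, 1.1)


@dataclass(frozen=True)
class TissueVolume:
    """3-D medium-id grid (X, Y, Z) with isotropic voxels of ``voxel_size`` mm."""

    labels: np.ndarray
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3 or min(self.labels.shape) == 0:
            raise ValueError("labels must be a non-empty 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if np.any(self.labels == 0):
            raise ValueError("ambient label 0 must not appear below the surface")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def extent(self):
        return tuple(s * self.voxel_size for s in self.labels.shape)

    def label_counts(self) -> dict:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def volume_fraction(self, medium_id: int) -> float:
        return float(np.count_nonzero(self.labels == medium_id)) / self.labels.size


@dataclass(frozen=True)
class SkinSpec:
    """Epidermis slab over dermis with parallel cylindrical vessels.

    Vessels run along ``vessel_axis`` ('x' or 'y'); their cross-sectional
    density (vessels per mm^2) is taken over the plane perpendicular to that
    axis.  ``depth_band`` (mm, below the surface) bounds the vessel material;
    if None it defaults to [D + 0.05 mm, extent_z - diameter].  ``centers``
    may pin explicit cross-sectional centers (mm pairs in the perpendicular
    plane); otherwise they are sampled from ``placement_seed``.
    """

    epidermal_thickness_um: float
    vessel_diameter_um: float = 117.0
    vessel_density_per_mm2: float = 33.75
    vessel_axis: str = "y"
    depth_band: "tuple | None" = None
    placement: str = "random"  # or "grid"
    placement_seed: int = 0
    centers: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if self.epidermal_thickness_um <= 0:
            raise ValueError("epidermal thickness must be positive")
        if self.vessel_diameter_um <= 0:
            raise ValueError("vessel diameter must be positive")
        if self.vessel_density_per_mm2 < 0:
            raise ValueError("vessel density must be non-negative")
        if self.vessel_axis not in ("x", "y"):
            raise ValueError("vessel_axis must be 'x' or 'y'")
        if self.placement not in ("random", "grid"):
            raise ValueError("placement must be 'random' or 'grid'")

    @property
    def d_mm(self) -> float:
        return self.epidermal_thickness_um * 1e-3

    @property
    def diameter_mm(self) -> float:
        return self.vessel_diameter_um * 1e-3


@dataclass(frozen=True)
class PhantomSpec:
    """Top absorber layer of thickness D (mm) over a deep bottom layer."""

    top_thickness_mm: float
    top_medium: int = PHANTOM_TOP_ID
    bottom_medium: int = PHANTOM_BOTTOM_ID

    def __post_init__(self) -> None:
        if self.top_thickness_mm < 0:
            raise ValueError("top thickness must be non-negative")


def _cross_axes(extent, axis: str):
    """Lateral extents of the plane perpendicular to the vessel axis."""
    ex, ey, ez = extent
    return (ey, ez) if axis == "x" else (ex, ez)


def _depth_band(spec: SkinSpec, extent) -> tuple:
    if spec.depth_band is not None:
        lo, hi = spec.depth_band
    else:
        lo, hi = spec.d_mm + 0.05, extent[2] - spec.diameter_mm
    if not (spec.d_mm <= lo < hi <= extent[2]):
        raise ValueError(f"vessel depth band [{lo}, {hi}] does not fit the dermis")
    return lo, hi


def vessel_count(spec: SkinSpec, extent) -> int:
    """round(density x cross-sectional area), the realized cylinder count."""
    lat, dep = _cross_axes(extent, spec.vessel_axis)
    return int(round(spec.vessel_density_per_mm2 * lat * dep))


def sample_vessel_centers(spec: SkinSpec, extent=DEFAULT_SKIN_EXTENT) -> np.ndarray:
    """Cross-sectional vessel centers (lateral_mm, depth_mm), shape (N, 2).

    Random placement is sequential rejection of overlapping circles
    (centers at least one diameter apart) inside the admissible box;
    grid placement lays a near-square lattice.  Both are deterministic
    for a fixed spec.
    """
    n = vessel_count(spec, extent)
    if n == 0:
        return np.empty((0, 2))
    r = spec.diameter_mm / 2.0
    lat_ext, _ = _cross_axes(extent, spec.vessel_axis)
    band_lo, band_hi = _depth_band(spec, extent)
    lo = np.array([r, band_lo + r])
    hi = np.array([lat_ext - r, band_hi - r])
    if np.any(hi <= lo):
        raise ValueError("vessels do not fit the volume")
    if spec.placement == "grid":
        spacing = np.sqrt((hi[0] - lo[0]) * (hi[1] - lo[1]) / n)
        nx = max(1, int(np.ceil((hi[0] - lo[0]) / spacing)))
        nz = max(1, int(np.ceil(n / nx)))
        gx = np.linspace(lo[0], hi[0], nx)
        gz = np.linspace(lo[1], hi[1], nz)
        pts = np.stack(np.meshgrid(gx, gz, indexing="ij"), axis=-1).reshape(-1, 2)
        return pts[:n]
    rng = np.random.default_rng(spec.placement_seed)
    centers = np.empty((n, 2))
    placed = 0
    min_d = 2 * r
    # sequential rejection first; at the dense default vasculature the packing
    # fraction sits near the sequential-adsorption jamming limit, so finish
    # with a deterministic pairwise-repulsion relaxation if it stalls
    for _ in range(2000 * n):
        c = lo + rng.random(2) * (hi - lo)
        if placed and np.min(np.sum((centers[:placed] - c) ** 2, axis=1)) < min_d ** 2:
            continue
        centers[placed] = c
        placed += 1
        if placed == n:
            return centers
    centers[placed:] = lo + rng.random((n - placed, 2)) * (hi - lo)
    for _ in range(5000):
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.sqrt(np.sum(diff ** 2, axis=-1))
        np.fill_diagonal(dist, np.inf)
        ii, jj = np.where(np.triu(dist < min_d))
        if ii.size == 0:
            return centers
        push = np.zeros_like(centers)
        for i, j in zip(ii, jj):
            v = centers[i] - centers[j]
            norm = np.sqrt(v @ v)
            u = v / norm if norm > 0 else rng.standard_normal(2)
            shift = 0.5 * (min_d - dist[i, j] + 1e-6) * u
            push[i] += shift
            push[j] -= shift
        centers = np.clip(centers + push, lo, hi)
    raise ValueError(
        f"could not place {n} non-overlapping vessels of diameter "
        f"{spec.vessel_diameter_um} um"
    )


def resolve_centers(spec: SkinSpec, extent=DEFAULT_SKIN_EXTENT) -> SkinSpec:
    """Materialize vessel centers into the spec so later edits preserve them."""
    if spec.centers is not None:
        return spec
    return replace(spec, centers=sample_vessel_centers(spec, extent))


def dilate_vessels(spec: SkinSpec, new_diameter_um: float,
                   extent=DEFAULT_SKIN_EXTENT) -> SkinSpec:
    """Change the vessel diameter at fixed centers (systole <-> diastole).

    The vessel count and center positions are preserved so that pulsatile
    pairs differ only in blood volume.  Dilation that would push any vessel
    into the epidermis or out of the volume raises.
    """
    if new_diameter_um <= 0:
        raise ValueError("new diameter must be positive")
    spec = resolve_centers(spec, extent)
    new = replace(spec, vessel_diameter_um=float(new_diameter_um))
    r = new.diameter_mm / 2.0
    depth = spec.centers[:, 1]
    if np.any(depth - r < spec.d_mm) or np.any(depth + r > extent[2]):
        raise ValueError("dilated vessels would leave the dermis")
    return new


def build_skin_volume(spec: SkinSpec, extent=DEFAULT_SKIN_EXTENT,
                      voxel_size: float = 0.010) -> TissueVolume:
    """Voxelize epidermis [0, D), dermis below, and the vessel cylinders."""
    if voxel_size > spec.diameter_mm / 5.0:
        raise ValueError("voxel_size must be at most vessel_diameter / 5")
    spec = resolve_centers(spec, extent)
    shape = tuple(int(round(e / voxel_size)) for e in extent)
    nx, ny, nz = shape
    zc = (np.arange(nz) + 0.5) * voxel_size
    labels = np.full(shape, DERMIS_ID, dtype=np.uint8)
    labels[:, :, zc < spec.d_mm] = EPIDERMIS_ID
    if spec.centers.shape[0]:
        r = spec.diameter_mm / 2.0
        if np.any(spec.centers[:, 1] - r < spec.d_mm - 1e-12) or \
           np.any(spec.centers[:, 1] + r > extent[2] + 1e-12):
            raise ValueError("vessels protrude into the epidermis or out of the volume")
        n_lat = nx if spec.vessel_axis == "y" else ny
        lat_c = (np.arange(n_lat) + 0.5) * voxel_size
        mask = np.zeros((n_lat, nz), dtype=bool)
        for cx, cz in spec.centers:
            i0, i1 = np.searchsorted(lat_c, [cx - r, cx + r])
            k0, k1 = np.searchsorted(zc, [cz - r, cz + r])
            sub = (lat_c[i0:i1, None] - cx) ** 2 + (zc[None, k0:k1] - cz) ** 2 <= r * r
            mask[i0:i1, k0:k1] |= sub
        if spec.vessel_axis == "y":
            labels[mask[:, None, :] & (labels == DERMIS_ID)] = BLOOD_ID
        else:
            labels[mask[None, :, :] & (labels == DERMIS_ID)] = BLOOD_ID
    return TissueVolume(labels, voxel_size)


def build_phantom_volume(spec: PhantomSpec, extent=(6.0, 6.0, 4.0),
                         voxel_size: float = 0.020) -> TissueVolume:
    """Slab of top medium for z in [0, D), bottom medium below (D = 0: homogeneous)."""
    if spec.top_thickness_mm >= extent[2]:
        raise ValueError("top layer thickness must be smaller than the volume depth")
    shape = tuple(int(round(e / voxel_size)) for e in extent)
    labels = np.full(shape, spec.bottom_medium, dtype=np.uint8)
    zc = (np.arange(shape[2]) + 0.5) * voxel_size
    labels[:, :, zc < spec.top_thickness_mm] = spec.top_medium
    return TissueVolume(labels, voxel_size)


def save_volume(path: "str | Path", volume: TissueVolume, attrs: "dict | None" = None) -> None:
    """Persist to HDF5 (chunked, compressed) with voxel size and origin as attrs."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("labels", data=volume.labels,
                               chunks=True, compression="gzip")
        ds.attrs["voxel_size_mm"] = volume.voxel_size
        ds.attrs["origin_mm"] = volume.origin
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def load_volume(path: "str | Path") -> TissueVolume:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["labels"]
        return TissueVolume(ds[...], float(ds.attrs["voxel_size_mm"]),
                            tuple(ds.attrs["origin_mm"]))
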