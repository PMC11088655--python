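"""Template construction: densities from atomic models, resampling, masks and
shape descriptors.

A template is a density map plus an alignment mask (values in [0, 1], usually
a sphere or cylinder with a cosine-tapered edge) and optionally a binary
density mask that marks the voxels occupied by the structure itself. The
density mask drives the overlap-fraction analysis and the solidity descriptor:
hollow or elongated shapes have low solidity and need finer angular sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import scipy.fft as sfft
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label

from .errors import (
    DomainError,
    HullError,
    MaskError,
    ShapeError,
    ThresholdError,
)
from .io import Volume

__all__ = [
    "Template",
    "ShapeDescriptors",
    "density_from_atoms",
    "atoms_from_structure",
    "resample_volume",
    "make_mask",
    "density_mask_from_threshold",
    "shape_descriptors",
]

#: Gaussian width as a fraction of the stated resolution, sigma = k * res.
#: This is the default of the ChimeraX molmap convention.
SIGMA_PER_RESOLUTION = 0.225


@dataclass
class Template:
    """Density map + alignment mask (+ optional binary density mask)."""

    map: Volume
    mask: Volume
    density_mask: Volume | None = None
    symmetry: int = 1

    def __post_init__(self):
        if self.map.shape != self.mask.shape:
            raise ShapeError(
                f"map shape {self.map.shape} != mask shape {self.mask.shape}"
            )
        m = self.mask.data
        if m.min() < -1e-6 or m.max() > 1 + 1e-6:
            raise MaskError("mask values must lie in [0, 1]")
        if self.density_mask is not None:
            if self.density_mask.shape != self.map.shape:
                raise ShapeError("density_mask shape differs from map")
            d = self.density_mask.data > 0.5
            outside = d & ~(m > 1e-6)
            if outside.any():
                raise MaskError(
                    f"{int(outside.sum())} density-mask voxels fall outside "
                    "the support of the alignment mask"
                )
        if int(self.symmetry) < 1:
            raise DomainError("symmetry order must be >= 1")

    @property
    def boxsize(self) -> int:
        return self.map.shape[0]

    @property
    def voxel_size(self) -> float:
        return self.map.voxel_size

    def diameter_voxels(self) -> float:
        """Diameter of the density (or mask) support, in voxels."""
        src = self.density_mask if self.density_mask is not None else self.mask
        occ = np.argwhere(src.data > 0.5)
        if len(occ) == 0:
            raise MaskError("template has empty support")
        return float(np.linalg.norm(occ.max(axis=0) - occ.min(axis=0)))


@dataclass
class ShapeDescriptors:
    """Size and compactness of a density mask."""

    dims: tuple
    density_voxels: int
    solidity: float

    def __post_init__(self):
        if not 0 < self.solidity <= 1 + 1e-9:
            raise DomainError(f"solidity {self.solidity} outside (0, 1]")
        self.solidity = min(float(self.solidity), 1.0)


def atoms_from_structure(path) -> list:
    """Read atoms from a PDB/mmCIF file as (element, x, y, z [A]) tuples."""
    st = gemmi.read_structure(str(path))
    out = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    out.append(
                        (atom.element.name, atom.pos.x, atom.pos.y, atom.pos.z)
                    )
        break  # first model only
    return out


def density_from_atoms(
    atoms,
    resolution: float,
    voxel_size: float,
    boxsize: int | None = None,
    center: bool = True,
) -> Volume:
    """Sum-of-Gaussians density from an atomic model.

    Each atom contributes an isotropic 3D Gaussian of width
    ``sigma = SIGMA_PER_RESOLUTION * resolution`` whose amplitude is its
    atomic number (so the integral is proportional to Z). ``atoms`` is an
    iterable of ``(element, x, y, z)`` with coordinates in Angstrom.

    If ``boxsize`` is omitted the grid is the cubic bounding box of the model
    plus 4 sigma of padding; if ``center`` is true the model's bounding-box
    midpoint is moved to the grid center voxel ``n // 2``.
    """
    if not resolution > 0:
        raise DomainError("resolution must be > 0")
    if not voxel_size > 0:
        raise DomainError("voxel_size must be > 0")
    atoms = list(atoms)
    if not atoms:
        raise DomainError("no atoms given")
    numbers, coords = [], []
    for el, x, y, z in atoms:
        try:
            zn = gemmi.Element(str(el)).atomic_number
        except (ValueError, RuntimeError) as exc:  # pragma: no cover
            raise LookupError(f"unknown element symbol {el!r}") from exc
        if zn == 0:
            raise LookupError(f"unknown element symbol {el!r}")
        numbers.append(zn)
        coords.append((x, y, z))
    numbers = np.asarray(numbers, dtype=float)
    coords = np.asarray(coords, dtype=float)

    sigma = SIGMA_PER_RESOLUTION * resolution  # Angstrom
    pad = 4.0 * sigma
    if boxsize is None:
        extent = (coords.max(axis=0) - coords.min(axis=0)).max() + 2 * pad
        boxsize = max(8, int(np.ceil(extent / voxel_size)))
    if center:
        mid = 0.5 * (coords.max(axis=0) + coords.min(axis=0))
        coords = coords - mid + (boxsize // 2) * voxel_size

    grid = np.zeros((boxsize,) * 3, dtype=np.float64)
    cut = int(np.ceil(4.0 * sigma / voxel_size))
    axes = np.arange(boxsize)
    for zn, (x, y, z) in zip(numbers, coords):
        vx = np.array([x, y, z]) / voxel_size
        lo = np.maximum(np.floor(vx).astype(int) - cut, 0)
        hi = np.minimum(np.floor(vx).astype(int) + cut + 2, boxsize)
        if np.any(lo >= hi):
            continue  # atom outside the grid
        gx = np.exp(-((axes[lo[0]:hi[0]] - vx[0]) * voxel_size) ** 2
                    / (2 * sigma**2))
        gy = np.exp(-((axes[lo[1]:hi[1]] - vx[1]) * voxel_size) ** 2
                    / (2 * sigma**2))
        gz = np.exp(-((axes[lo[2]:hi[2]] - vx[2]) * voxel_size) ** 2
                    / (2 * sigma**2))
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            zn * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return Volume(grid.astype(np.float32), voxel_size)


def resample_volume(vol: Volume, new_voxel: float) -> Volume:
    """Resample to a new voxel size by Fourier cropping/padding.

    The physical extent of the box is preserved (the grid size becomes
    ``round(n * old_voxel / new_voxel)`` per axis) and so is the mean value.
    """
    if not new_voxel > 0:
        raise DomainError("new_voxel must be > 0")
    old = vol.data.astype(np.float64)
    new_shape = tuple(
        int(round(s * vol.voxel_size / new_voxel)) for s in old.shape
    )
    if min(new_shape) < 4:
        raise DomainError(
            f"resampling to {new_voxel} A gives degenerate shape {new_shape}"
        )
    if new_shape == old.shape:
        return vol.copy()
    spec = sfft.fftshift(sfft.fftn(old))
    out = np.zeros(new_shape, dtype=complex)
    src, dst = [], []
    for n_old, n_new in zip(old.shape, new_shape):
        n = min(n_old, n_new)
        c_old, c_new = n_old // 2, n_new // 2
        src.append(slice(c_old - n // 2, c_old - n // 2 + n))
        dst.append(slice(c_new - n // 2, c_new - n // 2 + n))
    out[tuple(dst)] = spec[tuple(src)]
    data = sfft.ifftn(sfft.ifftshift(out)).real
    data *= np.prod(new_shape) / np.prod(old.shape)
    true_voxel = old.shape[0] * vol.voxel_size / new_shape[0]
    return Volume(data.astype(np.float32), float(true_voxel))


def make_mask(
    shape: str,
    diameter: float,
    voxel_size: float,
    boxsize: int,
    height: float | None = None,
    taper: float = 3.0,
) -> Volume:
    """Spherical or cylindrical alignment mask, centered on voxel ``n // 2``.

    ``diameter`` and ``height`` are in Angstrom; ``taper`` is the width of the
    cosine edge in voxels (0 gives a strictly binary mask). Cylinders have
    their axis along z; ``height`` defaults to the box height.
    """
    if shape not in ("sphere", "cylinder"):
        raise DomainError(f"unknown mask shape {shape!r}")
    if not diameter > 0:
        raise DomainError("diameter must be > 0")
    r_vox = 0.5 * diameter / voxel_size
    if 2 * r_vox > boxsize:
        raise DomainError(
            f"diameter {diameter} A exceeds the {boxsize}-voxel box"
        )
    c = boxsize // 2
    ax = np.arange(boxsize, dtype=float) - c
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    if shape == "sphere":
        dist = np.sqrt(X**2 + Y**2 + Z**2) - r_vox
    else:
        radial = np.sqrt(X**2 + Y**2) - r_vox
        if height is None:
            axial = np.full_like(radial, -np.inf)
        else:
            h_vox = 0.5 * height / voxel_size
            axial = np.abs(Z) - h_vox
        dist = np.maximum(radial, axial)
    if taper > 0:
        mask = np.clip(0.5 * (1 + np.cos(np.pi * dist / taper)), 0, 1)
        mask[dist <= 0] = 1.0
        mask[dist >= taper] = 0.0
    else:
        mask = (dist <= 0).astype(float)
    return Volume(mask.astype(np.float32), voxel_size)


def density_mask_from_threshold(
    vol: Volume, threshold: float, largest_component: bool = False
) -> Volume:
    """Binary mask of voxels >= threshold; optionally keep only the largest
    connected component."""
    binary = vol.data >= threshold
    if not binary.any():
        raise ThresholdError(
            f"threshold {threshold} is above the map maximum "
            f"({vol.data.max():.6g}); empty mask"
        )
    if largest_component:
        lab = label(binary, connectivity=3)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        binary = lab == sizes.argmax()
    return vol.with_data(binary.astype(np.float32))


def shape_descriptors(density_mask: Volume) -> ShapeDescriptors:
    """Dims, voxel count and solidity of a binary density mask.

    Solidity = occupied voxel count / convex-hull volume, with the hull built
    over the voxel centers and its volume measured in voxels. Because the
    center hull slightly underestimates the volume of the voxel union, the
    raw ratio can exceed 1 for filled convex bodies; it is clipped to 1.
    """
    binary = density_mask.data > 0.5
    n_vox = int(binary.sum())
    if n_vox == 0:
        raise MaskError("density mask is empty")
    occ = np.argwhere(binary)
    try:
        hull = ConvexHull(occ.astype(float))
    except QhullError as exc:
        raise HullError(f"cannot build convex hull: {exc}") from exc
    return ShapeDescriptors(
        dims=tuple(int(x) for x in (occ.max(axis=0) - occ.min(axis=0) + 1)),
        density_voxels=n_vox,
        solidity=min(n_vox / hull.volume, 1.0),
    )


def soften_edges(vol: Volume, sigma_voxels: float = 0.8) -> Volume:
    """Gaussian-smooth a (typically binary) map; used by the phantom builder."""
    return vol.with_data(
        gaussian_filter(vol.data.astype(np.float32), sigma_voxels)
    )
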