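"""Synthetic phantoms and planted-particle tomograms.

Every stage of the pipeline is testable without downloads: parametric phantom
templates (ball, hollow barrel, rod, bilayer slab, two-lobe "ribosome"),
tomograms with rotated copies planted at known positions, white Gaussian
noise at a requested SNR followed by binary missing-wedge filtering, and
labeled draws from the two-component score-ratio mixture.

The generator realizes the noise model under which the matching statistic is
the maximum-likelihood solution: white Gaussian noise added in real space,
then the wedge applied in Fourier space. What it does NOT emulate: CTF
oscillations in the data (tomograms are assumed CTF-corrected), structural
noise from neighboring molecules, or per-tilt alignment errors.

SNR is defined as var(signal volume) / var(noise), both over the full box,
measured before wedge filtering.

The two-lobe phantom approximates a ribosome: a large and a small sphere plus
a small off-axis knob. The knob matters — two spheres alone are rotationally
symmetric about their common axis, so the in-plane angle would be
unrecoverable and angular-error statistics meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.ndimage import gaussian_filter

from .errors import DomainError, PackingError
from .geometry import AngleList, Orientation, generate_angle_list, rotate_array
from .io import ParticleList, Volume, WedgeList
from .matching import build_fourier_weight
from .templates import Template, make_mask

__all__ = [
    "PhantomSpec",
    "PlantedTruth",
    "make_phantom",
    "make_wedge_list",
    "plant_particles",
    "corrupt",
    "simulate_ratios",
]

PHANTOM_KINDS = ("ball", "hollow_barrel", "rod", "bilayer_slab", "two_lobe")


@dataclass
class PhantomSpec:
    """Parametric phantom template.

    dims is the cubic box side in voxels; intensity the peak value; binary
    phantoms have strictly {0, intensity} voxels, otherwise edges are softened
    with a 0.8-voxel Gaussian. wall is the hollow-barrel wall thickness in
    voxels.
    """

    kind: str = "ball"
    dims: int = 32
    intensity: float = 1.0
    binary: bool = False
    voxel_size: float = 8.704
    wall: float = 2.0

    def __post_init__(self):
        if self.kind not in PHANTOM_KINDS:
            raise DomainError(
                f"unknown phantom kind {self.kind!r}; pick from {PHANTOM_KINDS}"
            )
        if self.dims < 8:
            raise DomainError("phantom box must be >= 8 voxels")
        if self.kind == "hollow_barrel" and self.wall < 1:
            raise DomainError("hollow_barrel wall thickness must be >= 1 voxel")


def _coords(n: int):
    c = n // 2
    ax = np.arange(n, dtype=float) - c
    return np.meshgrid(ax, ax, ax, indexing="ij")


def make_phantom(spec: PhantomSpec) -> Template:
    """Deterministic phantom template with density mask and spherical
    alignment mask (tapered 2 voxels)."""
    n = spec.dims
    X, Y, Z = _coords(n)
    R = np.sqrt(X**2 + Y**2 + Z**2)
    Rxy = np.sqrt(X**2 + Y**2)

    if spec.kind == "ball":
        solid = R <= 0.30 * n
    elif spec.kind == "hollow_barrel":
        r_out = 0.32 * n
        solid = (
            (Rxy <= r_out) & (Rxy >= r_out - spec.wall) & (np.abs(Z) <= 0.32 * n)
        )
    elif spec.kind == "rod":
        solid = (Rxy <= 0.12 * n) & (np.abs(Z) <= 0.40 * n)
    elif spec.kind == "bilayer_slab":
        gap = 0.06 * n
        leaf = 0.05 * n
        solid = (np.abs(np.abs(Z) - (gap / 2 + leaf / 2)) <= leaf / 2) & (
            np.abs(X) <= 0.40 * n
        ) & (np.abs(Y) <= 0.40 * n)
    else:  # two_lobe
        big = (
            np.sqrt(X**2 + Y**2 + (Z + 0.10 * n) ** 2) <= 0.24 * n
        )
        small = (
            np.sqrt(X**2 + Y**2 + (Z - 0.17 * n) ** 2) <= 0.165 * n
        )
        knob = (
            np.sqrt((X - 0.20 * n) ** 2 + Y**2 + (Z - 0.10 * n) ** 2)
            <= 0.09 * n
        )
        solid = big | small | knob

    data = solid.astype(np.float32) * spec.intensity
    if not spec.binary:
        data = gaussian_filter(data, 0.8)
    vol = Volume(data, spec.voxel_size)

    occ = np.argwhere(solid)
    # tight alignment mask: template fully contained, little surrounding
    # background (mask tightness beyond containment barely affects the CC);
    # radius from the farthest density voxel so anisotropic shapes keep
    # their corners inside
    r_max = float(np.linalg.norm(occ - np.array([n // 2] * 3), axis=1).max())
    mask_diam = min(2.0 * (r_max + 1.5), float(n)) * spec.voxel_size
    mask = make_mask("sphere", mask_diam, spec.voxel_size, n, taper=2.0)
    density = Volume(solid.astype(np.float32), spec.voxel_size)
    return Template(map=vol, mask=mask, density_mask=density)


def make_wedge_list(
    tilt_min: float = -60.0,
    tilt_max: float = 60.0,
    tilt_step: float = 3.0,
    pixel_size: float = 8.704,
    defocus_um: float = 3.0,
    dose_per_tilt: float = 3.0,
    tomogram_id: str = "synthetic",
) -> WedgeList:
    """Wedge list for a single-axis scheme: ±60° in 3° steps by default
    (41 tilts), constant defocus, dose accumulating in tilt order."""
    tilts = np.arange(tilt_min, tilt_max + 1e-9, tilt_step)
    df = pd.DataFrame(
        {
            "tilt_angle": tilts,
            "defocus": defocus_um,
            "exposure": dose_per_tilt * np.arange(1, len(tilts) + 1),
            "pixel_size": pixel_size,
        }
    )
    return WedgeList(df, tomogram_id=tomogram_id)


@dataclass
class PlantedTruth:
    """Ground truth for a planted-particle volume."""

    positions: np.ndarray  # (n, 3) voxel centers
    orientations: np.ndarray  # (n, 3) ZXZ eulers, degrees
    template_id: str = "phantom"
    snr: float | None = None
    wedge_applied: bool = False

    def to_particle_list(self) -> ParticleList:
        df = pd.DataFrame(
            np.hstack([self.positions, self.orientations]),
            columns=["x", "y", "z", "phi", "theta", "psi"],
        )
        df["class_label"] = self.template_id
        return ParticleList(df)

    def __len__(self) -> int:
        return len(self.positions)


def plant_particles(
    boxsize: int,
    tpl: Template,
    n: int,
    seed: int = 0,
    min_separation: float | None = None,
    orientation_grid: AngleList | None = None,
    max_tries: int = 10_000,
) -> tuple:
    """Plant n rotated template copies at non-overlapping random positions.

    Orientations are drawn uniformly from ``orientation_grid`` (default the
    10° grid); positions are rejection-sampled with center distance
    > ``min_separation`` (default the template diameter) and at least half a
    template box away from every face. Returns ``(Volume, PlantedTruth)``.
    """
    rng = np.random.default_rng(seed)
    L = tpl.boxsize
    if boxsize < L:
        raise DomainError("box smaller than the template")
    if orientation_grid is None:
        orientation_grid = generate_angle_list(10.0)
    if min_separation is None:
        min_separation = tpl.diameter_voxels()

    margin = L // 2
    lo, hi = margin, boxsize - margin
    if hi <= lo:
        raise DomainError("box leaves no room for particle centers")

    centers = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"placed only {len(centers)}/{n} particles after "
                f"{max_tries} tries; box too small for this separation"
            )
        p = rng.integers(lo, hi, size=3)
        if all(np.sum((p - q) ** 2) > min_separation**2 for q in centers):
            centers.append(p)
    centers = np.array(centers, dtype=int)

    idx = rng.integers(0, len(orientation_grid), size=n)
    eulers = orientation_grid.eulers[idx]

    vol = np.zeros((boxsize,) * 3, dtype=np.float32)
    c = L // 2
    for (x, y, z), eul in zip(centers, eulers):
        t_rot = rotate_array(tpl.map.data.astype(np.float32),
                             Orientation(*eul))
        vol[x - c:x - c + L, y - c:y - c + L, z - c:z - c + L] += t_rot
    truth = PlantedTruth(
        positions=centers.astype(float), orientations=eulers
    )
    return Volume(vol, tpl.voxel_size), truth


def corrupt(
    vol: Volume,
    snr: float,
    wl: WedgeList | None = None,
    seed: int = 0,
) -> Volume:
    """Add white Gaussian noise at the requested SNR, then apply the binary
    missing wedge of the wedge list in Fourier space.

    ``snr = numpy.inf`` skips the noise; ``wl = None`` skips the wedge.
    """
    if not snr > 0:
        raise DomainError("snr must be > 0")
    data = vol.data.astype(np.float64)
    if np.isfinite(snr):
        sig_var = data.var()
        if sig_var <= 0:
            raise DomainError("signal volume has zero variance")
        rng = np.random.default_rng(seed)
        data = data + rng.normal(
            scale=np.sqrt(sig_var / snr), size=data.shape
        )
    if wl is not None:
        span = float(wl.tilt_angles.max() - wl.tilt_angles.min())
        if span < 179.0:  # full coverage needs no filtering
            wedge = build_fourier_weight(
                wl, boxsize=data.shape[0], wedge_on=True,
                ctf=False, exposure=False,
            )
            if len(set(data.shape)) != 1:
                raise DomainError("wedge filtering requires a cubic volume")
            spec = sfft.rfftn(data) * wedge.half()
            data = sfft.irfftn(spec, s=data.shape)
    return vol.with_data(data.astype(np.float32))


def simulate_ratios(
    n: int,
    pi_rot: float,
    mu_rot: float,
    sigma_rot: float,
    mu_unrot: float,
    sigma_unrot: float,
    seed: int = 0,
):
    """Labeled draws from the two-component score-ratio mixture.

    Returns ``(ScoreRatioSet, labels)`` with labels "rotated"/"unrotated".
    """
    from .substates import ScoreRatioSet

    if not 0 <= pi_rot <= 1:
        raise DomainError("pi_rot must be in [0, 1]")
    if sigma_rot <= 0 or sigma_unrot <= 0:
        raise DomainError("component sigmas must be > 0")
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    is_rot = rng.random(n) < pi_rot
    x = np.where(
        is_rot,
        rng.normal(mu_rot, sigma_rot, size=n),
        rng.normal(mu_unrot, sigma_unrot, size=n),
    )
    x = np.clip(x, 1e-6, None)  # ratios of positive scores stay positive
    labels = np.where(is_rot, "rotated", "unrotated")
    return ScoreRatioSet(x), labels
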