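"""Constrained cross-correlation template matching.

The statistic is the masked, locally normalized cross-correlation (the "fast
local correlation function"): for every voxel x of the tomogram f and every
trial orientation R of the template t with alignment mask m,

    CC(x, R) = sum_y m_R(y) (f(x+y) - mu_f(x)) (t_R(y) - mu_t)
               / sqrt( N sigma_f(x)^2 * sum_y m_R(y) (t_R(y) - mu_t)^2 )

where mu_t is the template mean under the rotated mask, N = sum m_R, and
mu_f(x), sigma_f(x) are the local mean and standard deviation of the tomogram
under the mask, all computed by FFT convolutions. Before normalization the
rotated template is multiplied in Fourier space by a per-tomogram weight that
models the acquisition: the missing wedge of the tilt range, the CTF of each
tilt's defocus, and the dose-dependent exposure envelope. The per-voxel
maximum of CC over orientations, the index of the best orientation, and the
z-score map (CC standardized by its global mean and standard deviation) are
returned.

For white Gaussian noise of width sigma the unnormalized correlation
sum f * (RT) is the log-likelihood that the template, rotated and shifted,
explains the map, scaled by sigma^2 (the squared terms being constants); the
argmax-CC solution is therefore the maximum-likelihood solution.

Boundary handling: the FFT correlation is circular, so every voxel within half
a template box of a face mixes data from opposite faces; those voxels are
flagged invalid for peak calling but still enter the global z-score statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import scipy.fft as sfft

from .errors import (
    DegenerateMapError,
    DomainError,
    MaskError,
    ShapeError,
)
from .geometry import AngleList, Orientation, rotate_array
from .io import Volume, WedgeList
from .templates import Template

__all__ = [
    "BandpassSpec",
    "FourierWeight",
    "ScoreMaps",
    "build_fourier_weight",
    "bandpass_mask",
    "tm_scan",
    "zscore_transform",
    "cc_to_loglik",
    "correlate_raw",
    "apply_fourier_weight",
    "ctf_magnitude",
    "dose_envelope",
]

#: variance floor, relative to the global tomogram variance; local windows
#: flatter than this get CC = 0 instead of a division blow-up
VARIANCE_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class BandpassSpec:
    """Spherical Fourier band limits, in Fourier voxels of the template box.

    ``highpass_radius = 0`` disables the high-pass; ``lowpass_radius = None``
    means Nyquist (no low-pass).
    """

    highpass_radius: float = 0.0
    lowpass_radius: float | None = None

    def __post_init__(self):
        if self.highpass_radius < 0:
            raise DomainError("highpass_radius must be >= 0")
        if self.lowpass_radius is not None:
            if self.highpass_radius >= self.lowpass_radius:
                raise DomainError(
                    f"highpass {self.highpass_radius} must be below lowpass "
                    f"{self.lowpass_radius}"
                )


@dataclass
class FourierWeight:
    """Non-negative weights over the full Fourier grid of the template box.

    ``weights`` follows numpy fftn frequency ordering (DC at index 0) and is
    Hermitian-symmetric by construction, so multiplying the rfftn half-spectrum
    with a slice of it keeps the template real.
    """

    weights: np.ndarray
    wedge_on: bool = True

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 3:
            raise ShapeError("Fourier weight must be a 3D grid")
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise DomainError("Fourier weights must lie in [0, 1]")
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def boxsize(self) -> int:
        return self.weights.shape[0]

    def half(self) -> np.ndarray:
        """Slice matching the rfftn half-spectrum layout."""
        n = self.weights.shape[-1]
        return self.weights[..., : n // 2 + 1]


def _freq_grids(boxsize: int):
    """fftn-ordered frequency grids in cycles/voxel."""
    f = sfft.fftfreq(boxsize)
    return np.meshgrid(f, f, f, indexing="ij")


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_magnitude(
    k_inv_angstrom: np.ndarray,
    defocus_um: float,
    voltage_kv: float = 300.0,
    cs_mm: float = 2.7,
    amplitude_contrast: float = 0.07,
) -> np.ndarray:
    """|CTF| for an unastigmatic phase-contrast transfer function.

    chi(k) = pi lambda dz k^2 - (pi/2) Cs lambda^3 k^4, underfocus positive;
    CTF = -(sqrt(1 - A^2) sin chi + A cos chi).
    """
    lam = electron_wavelength(voltage_kv)
    dz = defocus_um * 1e4  # A
    cs = cs_mm * 1e7  # A
    k = np.asarray(k_inv_angstrom, dtype=float)
    chi = np.pi * lam * dz * k**2 - 0.5 * np.pi * cs * lam**3 * k**4
    a = amplitude_contrast
    return np.abs(np.sqrt(1.0 - a**2) * np.sin(chi) + a * np.cos(chi))


def dose_envelope(k_inv_angstrom: np.ndarray, dose: float) -> np.ndarray:
    """Dose-dependent exposure low-pass, exp(-d / (2 d_e(k))) with the
    standard empirical critical exposure d_e(k) = 0.245 k^-1.665 + 2.81."""
    k = np.maximum(np.asarray(k_inv_angstrom, dtype=float), 1e-6)
    d_e = 0.245 * k ** (-1.665) + 2.81
    return np.exp(-dose / (2.0 * d_e))


def build_fourier_weight(
    wl: WedgeList,
    boxsize: int,
    voltage_kv: float = 300.0,
    wedge_on: bool = True,
    ctf: bool = True,
    exposure: bool = True,
    cs_mm: float = 2.7,
    amplitude_contrast: float = 0.07,
) -> FourierWeight:
    """Acquisition weight for the template box from a wedge list.

    The tilt axis is y and the beam at zero tilt is along z, so a voxel with
    Fourier coordinates (kx, ky, kz) is sampled iff the angle
    atan2(kx, kz), folded to (-90, 90], lies within the tilt span. Each
    sampled voxel carries the |CTF| (of the nearest tilt's defocus) times the
    dose envelope of that tilt's accumulated exposure. ``wedge_on=False``
    returns the all-pass weight.
    """
    if len(wl) == 0:
        raise DomainError("empty wedge list")
    if not wedge_on:
        return FourierWeight(np.ones((boxsize,) * 3), wedge_on=False)

    tilts = wl.tilt_angles
    fx, fy, fz = _freq_grids(boxsize)
    beta = np.degrees(np.arctan2(fx, fz))
    # fold to (-90, 90]: a Fourier plane at tilt a equals the one at a+180
    beta = np.where(beta > 90.0, beta - 180.0, beta)
    beta = np.where(beta <= -90.0, beta + 180.0, beta)
    on_axis = (np.abs(fx) < 1e-12) & (np.abs(fz) < 1e-12)

    covered = (beta >= tilts.min() - 1e-9) & (beta <= tilts.max() + 1e-9)
    covered |= on_axis  # the tilt-axis line is in every section

    nearest = np.abs(beta[..., None] - tilts[None, None, None, :]).argmin(-1)

    weights = covered.astype(np.float64)
    if ctf or exposure:
        k_abs = np.sqrt(fx**2 + fy**2 + fz**2) / wl.pixel_size  # 1/A
        env = np.ones_like(k_abs)
        for i in range(len(tilts)):
            rec = wl.records.iloc[i]
            sel = nearest == i
            if not sel.any():
                continue
            e = np.ones(int(sel.sum()))
            if ctf:
                e = e * ctf_magnitude(
                    k_abs[sel], float(rec["defocus"]), voltage_kv,
                    cs_mm=cs_mm, amplitude_contrast=amplitude_contrast,
                )
            if exposure:
                e = e * dose_envelope(k_abs[sel], float(rec["exposure"]))
            env[sel] = e
        env[0, 0, 0] = 1.0  # DC untouched
        weights *= env
    return FourierWeight(weights, wedge_on=True)


def bandpass_mask(
    boxsize: int, spec: BandpassSpec, taper: float = 0.0
) -> FourierWeight:
    """Annular Fourier mask between the band radii (in Fourier voxels)."""
    fx, fy, fz = _freq_grids(boxsize)
    r = np.sqrt(fx**2 + fy**2 + fz**2) * boxsize
    w = np.ones_like(r)
    lo, hi = spec.highpass_radius, spec.lowpass_radius

    def _edge(dist):
        # 1 inside (dist <= 0), cosine falloff to 0 over `taper`
        if taper > 0:
            return np.clip(0.5 * (1 + np.cos(np.pi * np.clip(dist, 0, taper)
                                             / taper)), 0.0, 1.0)
        return (dist <= 0).astype(float)

    if lo > 0:
        w *= _edge(lo - r)
    if hi is not None:
        w *= _edge(r - hi)
    return FourierWeight(w, wedge_on=False)


@dataclass
class ScoreMaps:
    """Voxelwise results of a template-matching scan."""

    cc_max: Volume
    zscore: Volume
    angle_index: np.ndarray
    mu: float
    sigma: float
    valid: np.ndarray
    n_orientations: int = 0

    def __post_init__(self):
        if self.angle_index.shape != self.cc_max.shape:
            raise ShapeError("angle_index shape differs from cc_max")


def zscore_transform(cc: Volume | np.ndarray):
    """Standardize a CC map by its global mean and standard deviation.

    Returns ``(z, mu, sigma)``; raises :class:`DegenerateMapError` when the
    map is constant.
    """
    data = cc.data if isinstance(cc, Volume) else np.asarray(cc)
    mu = float(data.mean(dtype=np.float64))
    sigma = float(data.std(dtype=np.float64))
    scale = max(abs(mu), float(np.abs(data).max()), 1.0)
    if sigma <= 1e-14 * scale:
        raise DegenerateMapError("constant map: z-scores undefined")
    z = (data.astype(np.float64) - mu) / sigma
    if isinstance(cc, Volume):
        z = cc.with_data(z.astype(np.float32))
    return z, mu, sigma


def cc_to_loglik(cc, noise_sigma: float):
    """Scaled log-likelihood cc / noise_sigma^2 (additive constants dropped).

    For Gaussian noise the unnormalized correlation between map and rotated
    template is the log of the likelihood that the feature matches the
    template, times the squared noise amplitude.
    """
    if not noise_sigma > 0:
        raise DomainError("noise_sigma must be > 0")
    return np.asarray(cc, dtype=float) / noise_sigma**2


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def _center_embed(small: np.ndarray, shape: tuple) -> np.ndarray:
    """Embed a template-box array into the tomogram box with the template
    CENTER voxel (L//2 per axis) at index (0,0,0), for circular correlation."""
    out = np.zeros(shape, dtype=small.dtype)
    sl = tuple(slice(0, s) for s in small.shape)
    out[sl] = small
    shift = tuple(-(s // 2) for s in small.shape)
    return np.roll(out, shift, axis=(0, 1, 2))


def _prepare_oriented_template(
    tpl: Template,
    o: Orientation,
    weight_half: np.ndarray | None,
    mask_rotated: np.ndarray | None,
    dtype,
):
    """Rotate, Fourier-weight and mask-normalize the template for one
    orientation. Returns (t_norm, mask, n_mask)."""
    t_rot = rotate_array(tpl.map.data.astype(dtype), o)
    m_rot = (
        mask_rotated
        if mask_rotated is not None
        else np.clip(rotate_array(tpl.mask.data.astype(dtype), o), 0, 1)
    )
    n_mask = float(m_rot.sum(dtype=np.float64))
    if n_mask < 1.0:
        raise MaskError("alignment mask is empty after rotation")
    if weight_half is not None:
        t_rot = sfft.irfftn(
            sfft.rfftn(t_rot) * weight_half, s=t_rot.shape
        ).astype(dtype)
    mu_t = float((t_rot * m_rot).sum(dtype=np.float64)) / n_mask
    # mask-weighted norm (mask applied ONCE) keeps the statistic consistent
    # with the mask-weighted local variance below, so a perfect match gives 1
    # even for tapered masks
    s = float(
        np.sqrt((m_rot.astype(np.float64)
                 * (t_rot.astype(np.float64) - mu_t) ** 2).sum())
    )
    if s <= 0:
        raise MaskError("template is constant under the mask")
    t_norm = (m_rot * (t_rot - mu_t) / s).astype(dtype)
    return t_norm, m_rot, n_mask


def _combined_weight_half(
    boxsize: int,
    weight: FourierWeight | None,
    bp: BandpassSpec | None,
    dtype,
) -> np.ndarray | None:
    parts = []
    if weight is not None:
        if weight.boxsize != boxsize:
            raise ShapeError(
                f"Fourier weight box {weight.boxsize} != template box {boxsize}"
            )
        parts.append(weight.half())
    if bp is not None:
        parts.append(bandpass_mask(boxsize, bp).half())
    if not parts:
        return None
    out = parts[0]
    for p in parts[1:]:
        out = out * p
    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    return out.astype(cdtype)


def _mask_is_rotation_invariant(mask: np.ndarray) -> bool:
    probe = Orientation(33.0, 41.0, 17.0)
    rot = rotate_array(mask.astype(np.float32), probe)
    scale = max(float(np.abs(mask).max()), 1e-12)
    return float(np.abs(rot - mask).max()) <= 1e-3 * scale


def orientation_cc_maps(
    tomo: Volume,
    tpl: Template,
    angles: AngleList,
    weight: FourierWeight | None = None,
    bp: BandpassSpec | None = None,
    dtype=np.float32,
) -> Iterator[tuple]:
    """Yield ``(index, cc_map)`` for each orientation in the list.

    This is the engine under :func:`tm_scan` and the in-silico peak analysis;
    cc_map is the masked, locally normalized CC of the template at that
    orientation against every (circularly valid) position of the tomogram.
    """
    if tomo.shape != tpl.map.shape and min(
        ts - ls for ts, ls in zip(tomo.shape, tpl.map.shape)
    ) < 0:
        raise ShapeError(
            f"template box {tpl.map.shape} exceeds tomogram {tomo.shape}"
        )
    L = tpl.map.shape
    if len(set(L)) != 1:
        raise ShapeError("template box must be cubic")

    f = tomo.data.astype(dtype)
    global_var = float(f.var(dtype=np.float64))
    if global_var <= 0:
        raise DegenerateMapError("tomogram has zero variance")
    var_floor = VARIANCE_FLOOR_REL * global_var

    F = sfft.rfftn(f)
    F2 = sfft.rfftn(f * f)
    w_half = _combined_weight_half(L[0], weight, bp, dtype)

    mask = tpl.mask.data
    static_mask = _mask_is_rotation_invariant(mask)
    m_static = np.clip(mask.astype(dtype), 0, 1) if static_mask else None

    denom = None  # cached when the mask is rotation-invariant

    for idx in range(len(angles)):
        o = angles[idx]
        t_norm, m_rot, n_mask = _prepare_oriented_template(
            tpl, o, w_half, m_static, dtype
        )
        T = sfft.rfftn(_center_embed(t_norm, tomo.shape))
        num = sfft.irfftn(F * np.conj(T), s=tomo.shape)

        if denom is None or not static_mask:
            M = sfft.rfftn(_center_embed(m_rot, tomo.shape))
            m1 = sfft.irfftn(F * np.conj(M), s=tomo.shape) / n_mask
            m2 = sfft.irfftn(F2 * np.conj(M), s=tomo.shape) / n_mask
            local_var = m2 - m1 * m1
            flat = local_var < var_floor
            denom = np.sqrt(np.maximum(local_var, var_floor) * n_mask)
            denom_flat = flat

        cc = num / denom
        cc[denom_flat] = 0.0
        yield idx, cc


def tm_scan(
    tomo: Volume,
    tpl: Template,
    angles: AngleList,
    weight: FourierWeight | None = None,
    bp: BandpassSpec | None = None,
    dtype=np.float32,
    progress: bool = False,
) -> ScoreMaps:
    """Scan a tomogram with a template over an angle list.

    Returns per-voxel maximum CC, the argmax orientation index (ties broken
    toward the lowest index), the z-score map (global statistics over the
    whole map), and a validity mask that excludes the circular-wraparound
    border of half a template box from peak calling.
    """
    best = None
    best_idx = None
    it = orientation_cc_maps(tomo, tpl, angles, weight, bp, dtype)
    if progress:  # pragma: no cover - cosmetic
        from tqdm.auto import tqdm  # type: ignore

        it = tqdm(it, total=len(angles), desc="tm_scan")
    for idx, cc in it:
        if best is None:
            best = cc.copy()
            best_idx = np.zeros(cc.shape, dtype=np.int32)
        else:
            better = cc > best
            best[better] = cc[better]
            best_idx[better] = idx
    if best is None:
        raise DomainError("empty angle list")

    z, mu, sigma = zscore_transform(best)
    valid = np.zeros(tomo.shape, dtype=bool)
    h = tpl.map.shape[0] // 2
    inner = tuple(slice(h, s - h) for s in tomo.shape)
    valid[inner] = True
    return ScoreMaps(
        cc_max=tomo.with_data(best.astype(np.float32)),
        zscore=tomo.with_data(np.asarray(z, dtype=np.float32)),
        angle_index=best_idx,
        mu=mu,
        sigma=sigma,
        valid=valid,
        n_orientations=len(angles),
    )


def correlate_raw(
    tomo: Volume,
    template_map: Volume,
    o: Orientation = Orientation.identity(),
    dtype=np.float64,
) -> np.ndarray:
    """Unnormalized circular correlation sum_y f(x+y) (RT)(y) by FFT.

    This is the raw overlap score of the rotated template centered at each
    voxel — for Gaussian noise, the scaled log-likelihood surface (see
    :func:`cc_to_loglik`). For a strictly binary template correlated against a
    binary map it counts overlapping voxels exactly.
    """
    t_rot = rotate_array(template_map.data.astype(dtype), o)
    F = sfft.rfftn(tomo.data.astype(dtype))
    T = sfft.rfftn(_center_embed(t_rot, tomo.shape))
    return sfft.irfftn(F * np.conj(T), s=tomo.shape)


def apply_fourier_weight(
    vol: Volume,
    weight: FourierWeight | None = None,
    bp: BandpassSpec | None = None,
) -> Volume:
    """Filter a volume by a Fourier weight and/or bandpass (template box)."""
    w = _combined_weight_half(vol.shape[0], weight, bp, np.float64)
    if w is None:
        return vol.copy()
    data = sfft.irfftn(sfft.rfftn(vol.data.astype(np.float64)) * w,
                       s=vol.shape)
    return vol.with_data(data.astype(np.float32))
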