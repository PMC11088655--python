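"""Orientations, angular grids, volume rotation and angular distances.

Euler convention
----------------
ZXZ, intrinsic, in degrees, written ``(phi, theta, psi)``:

* ``phi``   — in-plane pre-rotation about the template z axis,
* ``theta`` — tilt about the (new) x axis,
* ``psi``   — azimuthal rotation about the (new) z axis.

The rotation matrix acting on column vectors ``v = (x, y, z)`` is::

    R(phi, theta, psi) = Rz(psi) @ Rx(theta) @ Rz(phi)

so the template z axis maps to a cone direction fixed by (theta, psi) alone,
while phi spins the template about its own axis. This is the convention of the
TOM/STOPGAP lineage of subtomogram-averaging packages.

Angular grid
------------
:func:`generate_angle_list` samples cone directions on latitude rings at
multiples of the angular step, widening the azimuth spacing by 1/sin(theta)
(ceil rounding of the ring count; a single point at each pole), and crosses
them with in-plane angles in steps of the same step over [0, 360/n) for Cn
symmetry. With ceil rounding the grid sizes at 30/20/10/5 degrees (C1) are
576, 1944, 15192 and 119952 orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .errors import DomainError, ShapeError
from .io import Volume

__all__ = [
    "Orientation",
    "AngleList",
    "generate_angle_list",
    "rotate_volume",
    "rotate_array",
    "angular_distance_full",
    "cone_inplane_distance",
]


@dataclass(frozen=True)
class Orientation:
    """A rigid rotation, stored as a ZXZ Euler triplet in degrees."""

    phi: float = 0.0
    theta: float = 0.0
    psi: float = 0.0

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def from_rotation(cls, rot: Rotation) -> "Orientation":
        import warnings

        with warnings.catch_warnings():
            # at theta in {0, 180} phi/psi are degenerate; the phi=0
            # representative scipy picks is a valid choice, not a problem
            warnings.filterwarnings("ignore", message="Gimbal lock")
            psi, theta, phi = rot.as_euler("ZXZ", degrees=True)
        return cls(float(phi), float(theta), float(psi))

    @classmethod
    def from_quat(cls, quat) -> "Orientation":
        """From a unit quaternion in (x, y, z, w) order."""
        q = np.asarray(quat, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise DomainError(f"quaternion norm {n} is not 1")
        return cls.from_rotation(Rotation.from_quat(q / n))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler(
            "ZXZ", [self.psi, self.theta, self.phi], degrees=True
        )

    @property
    def quat(self) -> np.ndarray:
        """Unit quaternion (x, y, z, w), canonicalized to w >= 0."""
        q = self.rotation.as_quat()
        return q if q[3] >= 0 else -q

    @property
    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    @property
    def euler(self) -> tuple:
        return (self.phi, self.theta, self.psi)

    def compose(self, other: "Orientation") -> "Orientation":
        """Rotation that applies ``other`` first, then ``self``."""
        return Orientation.from_rotation(self.rotation * other.rotation)

    def inverse(self) -> "Orientation":
        return Orientation.from_rotation(self.rotation.inv())

    def isclose(self, other: "Orientation", atol_deg: float = 1e-6) -> bool:
        return angular_distance_full(self, other) <= atol_deg


@dataclass
class AngleList:
    """An ordered set of orientations sampled on a uniform grid.

    ``eulers`` is an (N, 3) array of (phi, theta, psi) in degrees.
    """

    eulers: np.ndarray
    step: float
    symmetry: int = 1

    def __post_init__(self):
        self.eulers = np.atleast_2d(np.asarray(self.eulers, dtype=float))
        if self.eulers.shape[1] != 3:
            raise ShapeError("eulers must be (N, 3)")

    def __len__(self) -> int:
        return len(self.eulers)

    def __getitem__(self, i: int) -> Orientation:
        phi, theta, psi = self.eulers[i]
        return Orientation(phi, theta, psi)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def as_rotations(self) -> Rotation:
        """All orientations as a single vectorized scipy Rotation."""
        zxz = self.eulers[:, [2, 1, 0]]  # (psi, theta, phi)
        return Rotation.from_euler("ZXZ", zxz, degrees=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.eulers, columns=["phi", "theta", "psi"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_angle_list(step: float, symmetry: int = 1) -> AngleList:
    """Uniform grid over SO(3) at the given angular step (degrees), reduced
    for Cn in-plane symmetry.

    Cone directions lie on latitude rings theta = 0, step, 2*step, ... <= 180
    with ceil((360/step) sin theta) azimuth samples per ring (one sample at
    each pole); each direction is crossed with in-plane angles
    phi = 0, step, ... < 360/n.
    """
    if not 0 < step <= 360:
        raise DomainError(f"step must be in (0, 360], got {step}")
    symmetry = int(symmetry)
    if symmetry < 1:
        raise DomainError(f"Cn order must be >= 1, got {symmetry}")

    # in-plane angles over the symmetry-reduced range
    inplane = np.arange(0.0, 360.0 / symmetry - 1e-9, step)
    if len(inplane) == 0:
        inplane = np.array([0.0])

    cone = []  # (theta, psi) pairs
    n_theta = int(np.floor(180.0 / step + 1e-9))
    for i in range(n_theta + 1):
        theta = i * step
        if theta < 1e-9 or abs(theta - 180.0) < 1e-9:
            cone.append((theta, 0.0))
            continue
        n_az = int(np.ceil((360.0 / step) * np.sin(np.radians(theta)) - 1e-9))
        n_az = max(n_az, 1)
        for j in range(n_az):
            cone.append((theta, 360.0 * j / n_az))
    if not cone:
        cone = [(0.0, 0.0)]

    eulers = np.array(
        [(phi, theta, psi) for theta, psi in cone for phi in inplane]
    )
    return AngleList(eulers, step=step, symmetry=symmetry)


def rotate_array(data: np.ndarray, o: Orientation, order: int = 1) -> np.ndarray:
    """Rotate a cubic 3D array about its center voxel ``n // 2``.

    Trilinear interpolation (order=1) by default, zero fill outside. The
    identity orientation returns the input values exactly.
    """
    data = np.asarray(data)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ShapeError(f"rotation requires a cubic grid, got {data.shape}")
    R = o.matrix
    if np.allclose(R, np.eye(3), atol=1e-12):
        return data.copy()
    c = np.array([s // 2 for s in data.shape], dtype=float)
    # output[x] = input[R^-1 (x - c) + c]
    Rinv = R.T.copy()
    # snap numerical dust (cos 90 deg ~ 6e-17) so lattice-commensurate
    # rotations map the grid onto itself exactly
    Rinv[np.abs(Rinv) < 1e-12] = 0.0
    Rinv[np.abs(Rinv - 1) < 1e-12] = 1.0
    Rinv[np.abs(Rinv + 1) < 1e-12] = -1.0
    offset = c - Rinv @ c
    return affine_transform(
        data, Rinv, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def rotate_volume(vol: Volume, o: Orientation, order: int = 1) -> Volume:
    """Rotate a :class:`Volume` about its center voxel (see rotate_array)."""
    return vol.with_data(rotate_array(vol.data, o, order=order))


def angular_distance_full(o1: Orientation, o2: Orientation) -> float:
    """Geodesic rotation angle between two orientations, in [0, 180] degrees.

    Computed from the relative quaternion; zero iff the rotations are equal
    (up to quaternion sign), symmetric in its arguments.
    """
    rel = o1.rotation.inv() * o2.rotation
    return float(np.degrees(rel.magnitude()))


def cone_inplane_distance(o1: Orientation, o2: Orientation) -> tuple:
    """Split the difference of two orientations into cone and in-plane parts.

    cone    — angle between the two rotated z axes (the template normals),
    inplane — angle between the rotated in-plane reference (x) vectors after
              parallel transport of the first frame's x axis onto the second
              frame's cone direction by the minimal rotation.

    Both in [0, 180] degrees.
    """
    R1, R2 = o1.matrix, o2.matrix
    z1, z2 = R1[:, 2], R2[:, 2]
    x1, x2 = R1[:, 0], R2[:, 0]
    cone = _vec_angle(z1, z2)
    # minimal rotation taking z1 onto z2
    U = _minimal_rotation(z1, z2)
    inplane = _vec_angle(U @ x1, x2)
    return float(cone), float(inplane)


def _vec_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees, via the stable atan2 form."""
    cross = np.linalg.norm(np.cross(a, b))
    dot = float(np.dot(a, b))
    return float(np.degrees(np.arctan2(cross, dot)))


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix with the smallest angle mapping unit vector a to b."""
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    K = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )
    return np.eye(3) + K + K @ K * ((1 - c) / s**2)
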