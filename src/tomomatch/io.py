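"""Volume and table I/O.

Conventions
-----------
* Volumes are MRC2014 on disk (read/written through gemmi) and dense numpy
  arrays in memory, indexed ``data[x, y, z]`` with x the fastest axis of the
  file. Axis permutations declared in the MRC header are normalized on read.
* Voxel size is isotropic and carried in Angstrom. Nanometres appear only at
  the evaluation/reporting boundary; :func:`angstrom_to_nm` /
  :func:`nm_to_angstrom` own the factor 10.
* Particle positions are 0-based voxel indices of the voxel where the CENTER
  of the template sits. Orientations are ZXZ Euler triplets in degrees
  (see :mod:`tomomatch.geometry`).
* Tabular data (wedge lists, particle lists) are loop_-based STAR or CSV,
  chosen by file suffix. Column names are fixed:

  wedge list:    tilt_angle [deg], defocus [um], exposure [e-/A^2,
                 accumulated], pixel_size [A]   (+ optional tomogram_id)
  particle list: x, y, z [voxel], phi, theta, psi [deg]
                 (+ optional score, zscore, class_label)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import DimensionalityError, DomainError, FormatError, SchemaError

__all__ = [
    "Volume",
    "WedgeList",
    "ParticleList",
    "read_volume",
    "write_volume",
    "read_wedge_list",
    "write_wedge_list",
    "read_particle_list",
    "write_particle_list",
    "angstrom_to_nm",
    "nm_to_angstrom",
]

_A_PER_NM = 10.0


def angstrom_to_nm(x):
    """Convert Angstrom to nanometres (the single owner of the factor 10)."""
    return np.asarray(x, dtype=float) / _A_PER_NM


def nm_to_angstrom(x):
    """Convert nanometres to Angstrom."""
    return np.asarray(x, dtype=float) * _A_PER_NM


@dataclass
class Volume:
    """A 3D intensity grid with an isotropic voxel size in Angstrom.

    ``data`` is indexed ``[x, y, z]``; ``origin`` tags the index convention
    (always ``"corner0"``: index (0,0,0) is the first voxel, 0-based).
    """

    data: np.ndarray
    voxel_size: float
    origin: str = "corner0"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume data must be 3D, got {self.data.ndim}D"
            )
        if any(s < 1 for s in self.data.shape):
            raise DimensionalityError(f"invalid shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise DomainError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("Volume contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin)

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same metadata, new grid."""
        return Volume(data, self.voxel_size, self.origin)


def read_volume(path) -> Volume:
    """Read an MRC2014 volume.

    The grid is returned with the header's axis permutation normalized so that
    ``data[x, y, z]`` always has x fastest on file; voxel size is taken from
    the header cell (mean of the three spacings, which must agree to 0.1%).
    """
    path = str(path)
    try:
        m = gemmi.read_ccp4_map(path, setup=True)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC volume {path!r}: {exc}") from exc
    data = np.array(m.grid, copy=True)
    if data.ndim != 3 or min(data.shape) < 2:
        raise DimensionalityError(
            f"{path!r} does not contain a 3D volume (shape {data.shape})"
        )
    sp = np.array(m.grid.spacing, dtype=float)
    if not np.all(sp > 0):
        raise FormatError(f"{path!r}: non-positive voxel size in header")
    if (sp.max() - sp.min()) > 1e-3 * sp.mean():
        warnings.warn(
            f"{path!r}: anisotropic voxel size {sp}; using the mean",
            stacklevel=2,
        )
    return Volume(data.astype(np.float32), float(sp.mean()))


def write_volume(vol: Volume, path) -> None:
    """Write a volume as MRC2014 mode-2 (float32); bit-exact on round-trip."""
    if not isinstance(vol, Volume):
        vol = Volume(np.asarray(vol), 1.0)  # validates
    # __post_init__ already rejects NaN at construction; re-check in case the
    # array was mutated in place since.
    if not np.all(np.isfinite(vol.data)):
        raise DomainError("refusing to write volume with non-finite values")
    nx, ny, nz = vol.data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.array(grid, copy=False)[...] = vol.data.astype(np.float32)
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * vol.voxel_size, ny * vol.voxel_size, nz * vol.voxel_size,
            90.0, 90.0, 90.0,
        )
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# tabular records
# ---------------------------------------------------------------------------

WEDGE_COLUMNS = ["tilt_angle", "defocus", "exposure", "pixel_size"]
PARTICLE_COLUMNS = ["x", "y", "z", "phi", "theta", "psi"]
PARTICLE_OPTIONAL = ["score", "zscore", "class_label"]


@dataclass
class WedgeList:
    """Per-tilt acquisition records for one tomogram.

    Columns: tilt_angle (deg), defocus (um), exposure (accumulated e-/A^2),
    pixel_size (A). Records are kept sorted by tilt angle.
    """

    records: pd.DataFrame
    tomogram_id: str = "tomo"

    def __post_init__(self):
        df = pd.DataFrame(self.records).reset_index(drop=True)
        missing = [c for c in WEDGE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"wedge list missing column(s): {missing}")
        if len(df) == 0:
            raise SchemaError("wedge list is empty")
        tilts = df["tilt_angle"].to_numpy(float)
        if not np.all(np.diff(tilts) > 0):
            if len(np.unique(tilts)) != len(tilts):
                raise SchemaError("duplicate tilt angles in wedge list")
            warnings.warn(
                "wedge list tilt angles not sorted; sorting by tilt angle",
                stacklevel=2,
            )
            df = df.sort_values("tilt_angle").reset_index(drop=True)
        px = df["pixel_size"].to_numpy(float)
        if not np.allclose(px, px[0]):
            raise SchemaError("pixel_size differs between tilts")
        if not px[0] > 0:
            raise DomainError("pixel_size must be > 0")
        expo = df["exposure"].to_numpy(float)
        if np.any(expo < 0):
            raise DomainError("exposure must be non-negative")
        # accumulated exposure is monotone in ACQUISITION order, which for
        # dose-symmetric schemes is not tilt order; no ordering is enforced
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def tilt_angles(self) -> np.ndarray:
        return self.records["tilt_angle"].to_numpy(float)

    @property
    def pixel_size(self) -> float:
        return float(self.records["pixel_size"].iloc[0])


@dataclass
class ParticleList:
    """Particle positions (template-center voxel, 0-based) and orientations."""

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        df = pd.DataFrame(self.entries).reset_index(drop=True)
        if len(df):
            missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
            if missing:
                raise SchemaError(f"particle list missing column(s): {missing}")
            num = df[PARTICLE_COLUMNS + [c for c in ("score", "zscore")
                                         if c in df.columns]]
            if not np.all(np.isfinite(num.to_numpy(float))):
                raise DomainError("particle list contains non-finite values")
        else:
            df = pd.DataFrame(columns=PARTICLE_COLUMNS)
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) voxel coordinates."""
        return self.entries[["x", "y", "z"]].to_numpy(float)

    @property
    def eulers(self) -> np.ndarray:
        """(n, 3) ZXZ Euler angles (phi, theta, psi) in degrees."""
        return self.entries[["phi", "theta", "psi"]].to_numpy(float)


# ---------------------------------------------------------------------------
# STAR / CSV plumbing
# ---------------------------------------------------------------------------

def _read_star_table(path) -> pd.DataFrame:
    """Parse the first loop_ block of a (single-block) STAR file."""
    tags, rows = [], []
    in_loop = in_header = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            if in_loop and rows:
                break
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop, in_header = True, True
            continue
        if in_loop and line.startswith("_"):
            if not in_header:
                break
            tags.append(line.split()[0].lstrip("_"))
            continue
        if in_loop:
            in_header = False
            vals = line.split()
            if len(vals) != len(tags):
                raise FormatError(
                    f"{path}: row has {len(vals)} fields, expected {len(tags)}"
                )
            rows.append(vals)
    if not tags:
        raise FormatError(f"{path}: no loop_ block found")
    df = pd.DataFrame(rows, columns=tags)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df


def _write_star_table(df: pd.DataFrame, path, block: str) -> None:
    lines = [f"data_{block}", "", "loop_"]
    lines += [f"_{c} #{i + 1}" for i, c in enumerate(df.columns)]
    for _, row in df.iterrows():
        lines.append("  ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6f}"
    return str(v)


def _read_table(path) -> pd.DataFrame:
    suffix = Path(path).suffix.lower()
    if suffix == ".star":
        return _read_star_table(path)
    if suffix in (".csv", ".txt"):
        return pd.read_csv(path)
    raise FormatError(f"unsupported table format {suffix!r} (use .star or .csv)")


def _write_table(df: pd.DataFrame, path, block: str) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".star":
        _write_star_table(df, path, block)
    elif suffix in (".csv", ".txt"):
        df.to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported table format {suffix!r}")


def read_wedge_list(path, tomogram_id: str | None = None) -> WedgeList:
    df = _read_table(path)
    if tomogram_id is None:
        tomogram_id = (
            str(df["tomogram_id"].iloc[0])
            if "tomogram_id" in df.columns and len(df)
            else Path(path).stem
        )
    return WedgeList(df, tomogram_id=tomogram_id)


def write_wedge_list(wl: WedgeList, path) -> None:
    df = wl.records.copy()
    df.insert(0, "tomogram_id", wl.tomogram_id)
    _write_table(df, path, "wedge")


def read_particle_list(path) -> ParticleList:
    return ParticleList(_read_table(path))


def write_particle_list(pl: ParticleList, path) -> None:
    _write_table(pl.entries, path, "particles")
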