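"""Voxel-volume domain types and standard-format I/O.

Three value types share one grid description: binary occupancy masks,
per-voxel probabilities in [0, 1] and signed distances in mm.  Physical
position of voxel (i, j, k) is ``origin + index * spacing`` (voxel centers);
volumes and distances are always reported in mm^3 / mm.

Supported on-disk formats: NIfTI (.nii/.nii.gz, via nibabel), MetaImage
(.mha/.mhd) and NRRD (.nrrd) with raw little-endian encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np

from .errors import ContentError, DomainError, FormatError, FrameError

__all__ = [
    "VolumeGrid",
    "BinaryVolume",
    "ProbabilityVolume",
    "SignedDistanceVolume",
    "AnyVolume",
    "read_volume",
    "write_volume",
    "threshold_atlas",
    "assert_common_frame",
]

_REL_TOL = 1e-5


def _as_triple(x, cast) -> tuple:
    t = tuple(cast(v) for v in x)
    if len(t) != 3:
        raise DomainError(f"expected a length-3 sequence, got {x!r}")
    return t


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3D voxel lattice: dimensions, spacing (mm) and origin (mm)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "dims", _as_triple(self.dims, int))
        object.__setattr__(self, "spacing", _as_triple(self.spacing, float))
        object.__setattr__(self, "origin", _as_triple(self.origin, float))
        if any(d < 1 for d in self.dims):
            raise DomainError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise DomainError(f"all spacing must be > 0, got {self.spacing}")

    # -- geometry helpers -------------------------------------------------

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def center(self) -> np.ndarray:
        """Physical center of the voxel window (mm)."""
        return np.asarray(self.origin) + (np.asarray(self.dims) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_grid_physical(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape dims + (3,)."""
        axes = [
            self.origin[a] + np.arange(self.dims[a]) * self.spacing[a] for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def compatible(self, other: "VolumeGrid") -> bool:
        if self.dims != other.dims:
            return False
        return all(
            math.isclose(a, b, rel_tol=_REL_TOL, abs_tol=1e-9)
            for a, b in zip(self.spacing + self.origin, other.spacing + other.origin)
        )


@dataclass
class BinaryVolume:
    """A realization of a random compact set: {0,1} occupancy on a grid."""

    grid: VolumeGrid
    occupancy: np.ndarray

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.dims:
            raise FrameError(
                f"occupancy shape {occ.shape} != grid dims {self.grid.dims}"
            )
        vals = np.unique(occ)
        if not np.isin(vals, (0, 1)).all():
            raise ContentError(f"occupancy must be strictly binary, found {vals[:10]}")
        self.occupancy = occ.astype(np.uint8)

    def volume(self) -> float:
        """V(S) in mm^3."""
        return float(np.count_nonzero(self.occupancy)) * self.grid.voxel_volume

    def count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    @property
    def empty(self) -> bool:
        return self.count() == 0

    @property
    def full(self) -> bool:
        return self.count() == int(np.prod(self.grid.dims))


@dataclass
class ProbabilityVolume:
    """Per-voxel probability of belonging to the organ (the atlas)."""

    grid: VolumeGrid
    prob: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.prob, dtype=np.float32)
        if p.shape != self.grid.dims:
            raise FrameError(f"prob shape {p.shape} != grid dims {self.grid.dims}")
        if not np.isfinite(p).all():
            raise ContentError("probabilities must be finite")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ContentError(
                f"probabilities outside [0,1]: range [{p.min()}, {p.max()}]"
            )
        self.prob = np.clip(p, 0.0, 1.0)


@dataclass
class SignedDistanceVolume:
    """Per-voxel signed distance (mm): negative inside, positive outside."""

    grid: VolumeGrid
    distance: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distance, dtype=np.float32)
        if d.shape != self.grid.dims:
            raise FrameError(f"distance shape {d.shape} != grid dims {self.grid.dims}")
        if not np.isfinite(d).all():
            raise ContentError("distances must be finite")
        self.distance = d


AnyVolume = Union[BinaryVolume, ProbabilityVolume, SignedDistanceVolume]

# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

Mode = Literal["binary", "probability", "distance"]


def _wrap(grid: VolumeGrid, data: np.ndarray, mode: Mode) -> AnyVolume:
    if mode == "binary":
        if np.min(data) < 0:
            raise ContentError("binary mode: negative voxel values present")
        return BinaryVolume(grid, (data > 0).astype(np.uint8))
    if mode == "probability":
        return ProbabilityVolume(grid, data)
    if mode == "distance":
        return SignedDistanceVolume(grid, data)
    raise DomainError(f"unknown mode {mode!r}")


def _check_3d(data: np.ndarray, path) -> np.ndarray:
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data


# -- NIfTI ------------------------------------------------------------------


def _read_nifti(path: Path):
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as e:  # nibabel raises several types
        raise FormatError(f"{path}: not a readable NIfTI file ({e})") from e
    data = _check_3d(np.asanyarray(img.dataobj), path)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    grid = VolumeGrid(data.shape, tuple(float(z) for z in zooms), origin)
    return grid, np.asarray(data)


def _write_nifti(path: Path, grid: VolumeGrid, data: np.ndarray):
    import nibabel as nib

    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


# -- MetaImage --------------------------------------------------------------

_MET_TYPES = {"MET_UCHAR": np.uint8, "MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
              "MET_SHORT": np.int16, "MET_USHORT": np.uint16, "MET_INT": np.int32}


def _read_metaimage(path: Path):
    raw_bytes = path.read_bytes()
    # header is ASCII lines until ElementDataFile
    header: dict[str, str] = {}
    offset = 0
    for line in raw_bytes.split(b"\n"):
        offset += len(line) + 1
        text = line.decode("ascii", errors="replace").strip()
        if "=" not in text:
            raise FormatError(f"{path}: malformed MetaImage header line {text!r}")
        key, val = (s.strip() for s in text.split("=", 1))
        header[key] = val
        if key == "ElementDataFile":
            break
    else:
        raise FormatError(f"{path}: no ElementDataFile key in MetaImage header")

    if int(header.get("NDims", "0")) != 3:
        raise FormatError(f"{path}: only 3D MetaImage supported")
    dims = tuple(int(v) for v in header["DimSize"].split())
    spacing = tuple(float(v) for v in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in header.get("Offset", "0 0 0").split())
    try:
        dtype = _MET_TYPES[header["ElementType"]]
    except KeyError:
        raise FormatError(f"{path}: unsupported ElementType {header.get('ElementType')}")
    if header.get("CompressedData", "False").lower() == "true":
        raise FormatError(f"{path}: compressed MetaImage not supported")

    datafile = header["ElementDataFile"]
    if datafile == "LOCAL":
        payload = raw_bytes[offset:]
    else:
        payload = (path.parent / datafile).read_bytes()
    n = int(np.prod(dims))
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"), count=n)
    # MetaImage raster order: x fastest
    data = arr.reshape(dims, order="F")
    return VolumeGrid(dims, spacing, origin), np.asarray(data)


def _write_metaimage(path: Path, grid: VolumeGrid, data: np.ndarray):
    met_type = {np.uint8: "MET_UCHAR", np.float32: "MET_FLOAT"}[data.dtype.type]
    local = path.suffix == ".mha"
    datafile = "LOCAL" if local else path.with_suffix(".raw").name
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            "CompressedData = False",
            "TransformMatrix = 1 0 0 0 1 0 0 0 1",
            "Offset = " + " ".join(repr(v) for v in grid.origin),
            "ElementSpacing = " + " ".join(repr(v) for v in grid.spacing),
            "DimSize = " + " ".join(str(v) for v in grid.dims),
            f"ElementType = {met_type}",
            f"ElementDataFile = {datafile}",
        ]
    ) + "\n"
    payload = np.asfortranarray(data).tobytes(order="F")
    if local:
        path.write_bytes(header.encode("ascii") + payload)
    else:
        path.write_text(header)
        (path.parent / datafile).write_bytes(payload)


# -- NRRD -------------------------------------------------------------------

_NRRD_TYPES = {"uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8,
               "float": np.float32, "double": np.float64, "short": np.int16,
               "int": np.int32}


def _read_nrrd(path: Path):
    raw_bytes = path.read_bytes()
    try:
        head, payload = raw_bytes.split(b"\n\n", 1)
    except ValueError:
        raise FormatError(f"{path}: missing NRRD header terminator")
    lines = head.decode("ascii", errors="replace").splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise FormatError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise FormatError(f"{path}: malformed NRRD field {line!r}")
        key, val = line.split(":", 1)
        fields[key.strip().lower()] = val.lstrip("= ").strip()

    if int(fields.get("dimension", "0")) != 3:
        raise FormatError(f"{path}: only 3D NRRD supported")
    if fields.get("encoding", "raw") != "raw":
        raise FormatError(f"{path}: only raw NRRD encoding supported")
    dims = tuple(int(v) for v in fields["sizes"].split())
    if "space directions" in fields:
        vecs = [
            [float(x) for x in v.strip("()").split(",")]
            for v in fields["space directions"].split()
        ]
        spacing = tuple(float(np.linalg.norm(v)) for v in vecs)
    elif "spacings" in fields:
        spacing = tuple(float(v) for v in fields["spacings"].split())
    else:
        spacing = (1.0, 1.0, 1.0)
    if "space origin" in fields:
        origin = tuple(float(x) for x in fields["space origin"].strip("()").split(","))
    else:
        origin = (0.0, 0.0, 0.0)
    try:
        dtype = _NRRD_TYPES[fields["type"]]
    except KeyError:
        raise FormatError(f"{path}: unsupported NRRD type {fields.get('type')}")
    n = int(np.prod(dims))
    arr = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"), count=n)
    data = arr.reshape(dims, order="F")  # NRRD sizes are fastest-first
    return VolumeGrid(dims, spacing, origin), np.asarray(data)


def _write_nrrd(path: Path, grid: VolumeGrid, data: np.ndarray):
    nrrd_type = {np.uint8: "uchar", np.float32: "float"}[data.dtype.type]
    sx, sy, sz = grid.spacing
    header = "\n".join(
        [
            "NRRD0004",
            f"type: {nrrd_type}",
            "dimension: 3",
            "space: left-posterior-superior",
            "sizes: " + " ".join(str(v) for v in grid.dims),
            f"space directions: ({sx!r},0,0) (0,{sy!r},0) (0,0,{sz!r})",
            "space origin: ({},{},{})".format(*(repr(v) for v in grid.origin)),
            "kinds: domain domain domain",
            "endian: little",
            "encoding: raw",
        ]
    ) + "\n\n"
    path.write_bytes(header.encode("ascii") + np.asfortranarray(data).tobytes(order="F"))


_READERS = {".nii": _read_nifti, ".gz": _read_nifti, ".mha": _read_metaimage,
             ".mhd": _read_metaimage, ".nrrd": _read_nrrd}
_WRITERS = {".nii": _write_nifti, ".gz": _write_nifti, ".mha": _write_metaimage,
             ".mhd": _write_metaimage, ".nrrd": _write_nrrd}


def _dispatch(path: Path, table):
    suffix = path.suffix.lower()
    if suffix == ".gz" and not path.name.lower().endswith(".nii.gz"):
        raise FormatError(f"{path}: unrecognized volume format")
    try:
        return table[suffix]
    except KeyError:
        raise FormatError(f"{path}: unrecognized volume format {suffix!r}")


def read_volume(path, mode: Mode = "binary") -> AnyVolume:
    """Read a 3D volume file as the requested domain type.

    In ``binary`` mode any strictly positive voxel maps to occupancy 1.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    grid, data = _dispatch(path, _READERS)(path)
    return _wrap(grid, data, mode)


def write_volume(vol: AnyVolume, path) -> None:
    """Write a volume; the format is chosen from the file extension."""
    path = Path(path)
    if isinstance(vol, BinaryVolume):
        data = vol.occupancy.astype(np.uint8)
    elif isinstance(vol, ProbabilityVolume):
        data = vol.prob.astype(np.float32)
    elif isinstance(vol, SignedDistanceVolume):
        data = vol.distance.astype(np.float32)
    else:
        raise DomainError(f"cannot write object of type {type(vol).__name__}")
    writer = _dispatch(path, _WRITERS)
    try:
        writer(path, vol.grid, data)
    except OSError:
        raise
    except FileNotFoundError:
        raise


# ---------------------------------------------------------------------------
# Thresholding & frames
# ---------------------------------------------------------------------------


def threshold_atlas(atlas: ProbabilityVolume, t: float) -> BinaryVolume:
    """Binary shape {x : p(x) > t}.

    Strict inequality so t = 0 selects the support of the atlas rather than
    the whole window.
    """
    if not (0.0 <= t < 1.0):
        raise DomainError(f"threshold must be in [0, 1), got {t}")
    return BinaryVolume(atlas.grid, (atlas.prob > t).astype(np.uint8))


def assert_common_frame(vols: Sequence[AnyVolume | VolumeGrid]) -> None:
    """Raise FrameError unless every volume shares one grid."""
    if len(vols) == 0:
        raise DomainError("assert_common_frame requires a non-empty list")
    grids = [v if isinstance(v, VolumeGrid) else v.grid for v in vols]
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.dims != ref.dims:
            raise FrameError(f"volume {i}: dims {g.dims} != {ref.dims}")
        for name in ("spacing", "origin"):
            a, b = getattr(g, name), getattr(ref, name)
            if not all(
                math.isclose(x, y, rel_tol=_REL_TOL, abs_tol=1e-9)
                for x, y in zip(a, b)
            ):
                raise FrameError(f"volume {i}: {name} {a} != {b}")
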