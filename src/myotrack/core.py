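"""Shared spatial data model and file I/O.

All imaging stages exchange data through a small set of typed volumes that
carry their voxel geometry explicitly.  Conventions:

* voxel indexing is 0-based ``(i, j, k)`` with ``k`` the slice axis;
* world coordinates (mm) follow the 4x4 affine, NIfTI style;
* segmentations live on the Dixon grid and are transferred to the T2/DWI
  grids by nearest-neighbour lookup through world coordinates;
* complex echo series are stored on disk as real/imaginary NIfTI pairs with
  a JSON sidecar holding the echo times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MUSCLES",
    "LOW_FAT_MUSCLES",
    "MUSCLE_GROUPS",
    "GEOMETRY_TOL_MM",
    "VolumeGeometry",
    "ScalarVolume",
    "ComplexEchoSeries",
    "MagnitudeEchoTrain",
    "DWISeries",
    "MuscleLabelMap",
    "GeometryMismatchError",
    "read_volume",
    "write_volume",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "write_summary_table",
    "read_summary_table",
    "resample_labels_to_grid",
]

#: The 12 thigh muscles analysed per side.
MUSCLES = (
    "adductor_longus",
    "adductor_magnus",
    "biceps_femoris_long",
    "biceps_femoris_short",
    "gracilis",
    "rectus_femoris",
    "sartorius",
    "semimembranosus",
    "semitendinosus",
    "vastus_intermedius",
    "vastus_lateralis",
    "vastus_medialis",
)

#: Muscles that remain mildly fat-infiltrated (<~30% FF) in SMA thighs.
LOW_FAT_MUSCLES = ("adductor_longus", "biceps_femoris_short")

#: Functional muscle-group mapping used for the random intercepts and HHD.
#: Sartorius belongs to none of the dynamometry groups but keeps its own
#: group label for the mixed model.
MUSCLE_GROUPS = {
    "adductor_longus": "adductors",
    "adductor_magnus": "adductors",
    "gracilis": "adductors",
    "biceps_femoris_long": "hamstrings",
    "biceps_femoris_short": "hamstrings",
    "semimembranosus": "hamstrings",
    "semitendinosus": "hamstrings",
    "rectus_femoris": "quadriceps",
    "vastus_intermedius": "quadriceps",
    "vastus_lateralis": "quadriceps",
    "vastus_medialis": "quadriceps",
    "sartorius": "sartorius",
}

#: Geometry agreement tolerance between volumes that must share a grid.
GEOMETRY_TOL_MM = 0.01

SUMMARY_COLUMNS = [
    "subject",
    "time_point",
    "muscle",
    "side",
    "n_voxels",
    "FF",
    "CSA",
    "cCSA",
    "T2",
    "MD",
    "FA",
    "SNR",
]


class GeometryMismatchError(ValueError):
    """Raised when two volumes that must share a grid disagree."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid description: shape, affine and slice packing.

    ``affine`` maps 0-based voxel indices to world mm.  ``slice_gap`` is the
    gap between imaged slabs; slice *spacing* along the affine equals
    thickness + gap.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    slice_gap: float = 0.0

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @classmethod
    def from_params(
        cls,
        voxel_size: tuple[float, float, float],
        shape: tuple[int, int, int],
        slice_gap: float = 0.0,
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VolumeGeometry":
        """Axis-aligned geometry; the slice axis pitch includes the gap."""
        dx, dy, dz = voxel_size
        affine = np.diag([dx, dy, dz + slice_gap, 1.0])
        affine[:3, 3] = origin
        return cls(shape=tuple(shape), affine=affine, slice_gap=slice_gap)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Physical voxel edge lengths (mm); slice axis excludes the gap."""
        lengths = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        return (float(lengths[0]), float(lengths[1]), float(lengths[2] - self.slice_gap))

    @property
    def slice_spacing(self) -> float:
        return float(np.sqrt((self.affine[:3, 2] ** 2).sum()))

    @property
    def n_slices(self) -> int:
        return self.shape[2]

    @property
    def in_plane_matrix(self) -> tuple[int, int]:
        return (self.shape[0], self.shape[1])

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def allclose(self, other: "VolumeGeometry", tol: float = GEOMETRY_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=tol)
            and abs(self.slice_gap - other.slice_gap) <= tol
        )

    def require_match(self, other: "VolumeGeometry", what: str = "volumes") -> None:
        if not self.allclose(other):
            raise GeometryMismatchError(f"geometry mismatch between {what}")


@dataclass
class ScalarVolume:
    """A single quantitative map (FF, T2, psi, T2*, MD, FA, ...)."""

    geometry: VolumeGeometry
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape disagrees with geometry")


@dataclass
class ComplexEchoSeries:
    """Complex multi-echo gradient-echo series (Dixon input)."""

    geometry: VolumeGeometry
    echo_times: np.ndarray  # ms
    data: np.ndarray  # (X, Y, Z, n_echo) complex

    def __post_init__(self):
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.data = np.asarray(self.data, dtype=complex)
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.data.shape != self.geometry.shape + (len(self.echo_times),):
            raise ValueError("data shape disagrees with geometry/echoes")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)


@dataclass
class MagnitudeEchoTrain:
    """Multi-echo spin-echo magnitude train (T2 mapping input)."""

    geometry: VolumeGeometry
    echo_spacing: float  # ms
    data: np.ndarray  # (X, Y, Z, n_echo) >= 0
    excitation_deg: float = 90.0
    refocus_deg: float = 180.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be >= 0")
        if self.data.ndim != 4 or self.data.shape[:3] != self.geometry.shape:
            raise ValueError("data shape disagrees with geometry")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]

    @property
    def echo_times(self) -> np.ndarray:
        """TE_n = n * echo spacing (CPMG timing)."""
        return self.echo_spacing * np.arange(1, self.n_echoes + 1)


@dataclass
class DWISeries:
    """Diffusion-weighted magnitude series with its b-table."""

    geometry: VolumeGeometry
    data: np.ndarray  # (X, Y, Z, n_vol)
    bvals: np.ndarray  # s/mm^2
    bvecs: np.ndarray  # (n_vol, 3), unit norm where b > 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        n = self.data.shape[-1] if self.data.ndim == 4 else -1
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                "scheme length mismatch: b-table rows must equal DWI volumes"
            )
        if self.data.shape[:3] != self.geometry.shape:
            raise ValueError("data shape disagrees with geometry")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MuscleLabelMap:
    """Integer per-voxel muscle labels with a name dictionary."""

    geometry: VolumeGeometry
    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.shape != self.geometry.shape:
            raise ValueError("labels shape disagrees with geometry")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_names)
        if unknown:
            raise ValueError(f"label values outside dictionary: {sorted(unknown)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _geometry_from_nifti(img: nib.Nifti1Image, slice_gap: float = 0.0) -> VolumeGeometry:
    return VolumeGeometry(shape=img.shape[:3], affine=np.asarray(img.affine), slice_gap=slice_gap)


def _nifti_from(values: np.ndarray, geometry: VolumeGeometry) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(values), geometry.affine)


def write_volume(volume, path) -> None:
    """Write a typed volume to NIfTI (plus sidecars where needed).

    Complex echo series become ``<stem>_real.nii`` / ``<stem>_imag.nii``
    4D volumes plus ``<stem>.json`` (echo times, slice gap).  DWI series
    write FSL-style ``.bval``/``.bvec`` next to the image.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    ext = path.name[len(stem):] or ".nii.gz"
    base = path.parent / stem

    if isinstance(volume, ComplexEchoSeries):
        nib.save(_nifti_from(volume.data.real, volume.geometry), str(base) + "_real" + ext)
        nib.save(_nifti_from(volume.data.imag, volume.geometry), str(base) + "_imag" + ext)
        sidecar = {
            "echo_times_ms": list(map(float, volume.echo_times)),
            "slice_gap_mm": volume.geometry.slice_gap,
            "storage": "real_imag_pair",
        }
        (base.with_suffix(".json")).write_text(json.dumps(sidecar, indent=2))
    elif isinstance(volume, MagnitudeEchoTrain):
        nib.save(_nifti_from(volume.data, volume.geometry), str(base) + ext)
        sidecar = {
            "echo_spacing_ms": volume.echo_spacing,
            "n_echoes": volume.n_echoes,
            "excitation_deg": volume.excitation_deg,
            "refocus_deg": volume.refocus_deg,
            "slice_gap_mm": volume.geometry.slice_gap,
        }
        (base.with_suffix(".json")).write_text(json.dumps(sidecar, indent=2))
    elif isinstance(volume, DWISeries):
        nib.save(_nifti_from(volume.data, volume.geometry), str(base) + ext)
        write_bvals_bvecs(volume.bvals, volume.bvecs, base.with_suffix(".bval"), base.with_suffix(".bvec"))
    elif isinstance(volume, MuscleLabelMap):
        nib.save(_nifti_from(volume.labels.astype(np.int16), volume.geometry), str(base) + ext)
        names = {str(k): v for k, v in volume.label_names.items()}
        (base.with_suffix(".json")).write_text(json.dumps({"labels": names}, indent=2))
    elif isinstance(volume, ScalarVolume):
        nib.save(_nifti_from(volume.values, volume.geometry), str(base) + ext)
    else:
        raise TypeError(f"unsupported volume type {type(volume)!r}")


def read_volume(path, expected_kind: str):
    """Read a typed volume written by :func:`write_volume`.

    ``expected_kind`` is one of ``scalar``, ``complex_echoes``, ``echo_train``,
    ``dwi``, ``labels``.
    """
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    ext = path.name[len(stem):] or ".nii.gz"
    base = path.parent / stem

    def _load(p):
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(str(p))
        return nib.load(str(p))

    def _sidecar():
        sc = base.with_suffix(".json")
        if not sc.exists():
            raise FileNotFoundError(f"missing sidecar {sc}")
        return json.loads(sc.read_text())

    if expected_kind == "scalar":
        img = _load(path)
        return ScalarVolume(_geometry_from_nifti(img), np.asarray(img.dataobj, dtype=float), name=stem)
    if expected_kind == "complex_echoes":
        sc = _sidecar()
        real = _load(str(base) + "_real" + ext)
        imag = _load(str(base) + "_imag" + ext)
        if real.shape != imag.shape:
            raise GeometryMismatchError("real/imag parts disagree in shape")
        if not np.allclose(real.affine, imag.affine, atol=GEOMETRY_TOL_MM):
            raise GeometryMismatchError("real/imag parts disagree in affine")
        geom = _geometry_from_nifti(real, sc.get("slice_gap_mm", 0.0))
        data = np.asarray(real.dataobj, dtype=float) + 1j * np.asarray(imag.dataobj, dtype=float)
        return ComplexEchoSeries(geom, np.asarray(sc["echo_times_ms"]), data)
    if expected_kind == "echo_train":
        sc = _sidecar()
        img = _load(path)
        geom = _geometry_from_nifti(img, sc.get("slice_gap_mm", 0.0))
        return MagnitudeEchoTrain(
            geom,
            echo_spacing=float(sc["echo_spacing_ms"]),
            data=np.asarray(img.dataobj, dtype=float),
            excitation_deg=float(sc.get("excitation_deg", 90.0)),
            refocus_deg=float(sc.get("refocus_deg", 180.0)),
        )
    if expected_kind == "dwi":
        img = _load(path)
        bvals, bvecs = read_bvals_bvecs(base.with_suffix(".bval"), base.with_suffix(".bvec"))
        return DWISeries(_geometry_from_nifti(img), np.asarray(img.dataobj, dtype=float), bvals, bvecs)
    if expected_kind == "labels":
        img = _load(path)
        sc = _sidecar()
        names = {int(k): v for k, v in sc["labels"].items()}
        return MuscleLabelMap(_geometry_from_nifti(img), np.asarray(img.dataobj).astype(np.int32), names)
    raise ValueError(f"unknown kind {expected_kind!r}")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style b-table: one row of b-values; three rows of components."""
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise ValueError("scheme length mismatch: bval/bvec tables disagree")
    return bvals, bvecs


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, np.atleast_2d(np.asarray(bvals, dtype=float)), fmt="%.1f")
    np.savetxt(bvec_path, np.asarray(bvecs, dtype=float).T, fmt="%.8f")


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------


def write_summary_table(records, path) -> pd.DataFrame:
    """Write per-muscle summary records to CSV in a deterministic row order.

    ``records`` may be a DataFrame or an iterable of dataclasses/dicts with
    the summary fields (subject, time_point, muscle, side, n_voxels, FF, CSA,
    cCSA, T2, MD, FA, SNR).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append({k: getattr(r, k) for k in SUMMARY_COLUMNS})
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SUMMARY_COLUMNS]
    if len(df):
        df = df.sort_values(["subject", "time_point", "muscle", "side"], kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def read_summary_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Grid transfer
# ---------------------------------------------------------------------------


def resample_labels_to_grid(labels: MuscleLabelMap, target: VolumeGeometry) -> MuscleLabelMap:
    """Nearest-neighbour transfer of a label map to another voxel grid.

    Segmentations are drawn once on the Dixon grid and moved to the T2/DWI
    grids through world coordinates; voxels falling outside the source
    field of view become background.
    """
    ii, jj, kk = np.meshgrid(
        np.arange(target.shape[0]), np.arange(target.shape[1]), np.arange(target.shape[2]),
        indexing="ij",
    )
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = target.voxel_to_world(pts)
    src = labels.geometry.world_to_voxel(world)
    idx = np.rint(src).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(labels.geometry.shape)), axis=1)
    out = np.zeros(len(pts), dtype=labels.labels.dtype)
    sel = idx[inside]
    out[inside] = labels.labels[sel[:, 0], sel[:, 1], sel[:, 2]]
    return MuscleLabelMap(target, out.reshape(target.shape), dict(labels.label_names))
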