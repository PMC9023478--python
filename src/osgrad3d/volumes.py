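"""Volume data model and I/O.

All grids are ordered (z, y, x) with 0-based indices. Physical coordinates
are voxel centers at ``(index + 0.5) * voxel_size_um``. Voxels are isotropic;
anisotropic containers are rejected rather than resampled silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

#: Canonical material classes, in fixed code order.
CLASS_NAMES = ("exterior", "pore", "POM", "matrix", "dense")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}
EXTERIOR, PORE, POM, MATRIX, DENSE = range(5)

STAGES = ("pre_stain", "post_stain", "difference", "registered")


@dataclass
class ScalarVolume:
    """A 3D grayscale volume with isotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Grayscale values. Stored as floating point internally; ``difference``
        volumes may be negative, all other stages are non-negative.
    voxel_size_um : float
        Edge length of the (isotropic) cubic voxel in micrometers.
    stage : str
        One of ``pre_stain``, ``post_stain``, ``difference``, ``registered``.
    """

    data: np.ndarray
    voxel_size_um: float
    stage: str = "pre_stain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D grid with all dimensions >= 1")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3


@dataclass
class LabelVolume:
    """A 3D categorical volume sharing geometry with a :class:`ScalarVolume`.

    Every voxel carries exactly one class from :data:`CLASS_NAMES`.
    """

    data: np.ndarray
    voxel_size_um: float
    classes: tuple[str, ...] = field(default=CLASS_NAMES)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        if self.data.min() < 0 or self.data.max() >= len(self.classes):
            raise ValueError("label codes outside class range")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one class."""
        return self.data == self.classes.index(name)

    def volume_fractions(self) -> dict[str, float]:
        """Class volume fractions over non-exterior voxels (sum to 1)."""
        interior = self.data != CLASS_CODES["exterior"]
        n = int(interior.sum())
        if n == 0:
            raise ValueError("no non-exterior voxels")
        counts = np.bincount(self.data[interior], minlength=len(self.classes))
        return {
            name: counts[code] / n
            for code, name in enumerate(self.classes)
            if name != "exterior"
        }


def _check_isotropic(spacing: tuple[float, ...]) -> float:
    s = np.asarray(spacing, dtype=float)
    if not np.allclose(s, s[0], rtol=1e-6, atol=0):
        raise ValueError(f"anisotropic voxel spacing {tuple(s)}; pipeline assumes isotropic voxels")
    return float(s[0])


def read_volume(path: str | Path, voxel_size_um: float | None = None, stage: str = "pre_stain") -> ScalarVolume:
    """Read a TIFF stack or NRRD file into a :class:`ScalarVolume`.

    Integer grids are preserved bit-exactly (then widened to float).
    TIFF stacks carry no 3D spacing, so ``voxel_size_um`` must be supplied
    for them; NRRD spacing is honored and must be isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if voxel_size_um is None:
            raise ValueError("TIFF stacks carry no 3D spacing; supply voxel_size_um")
        spacing = float(voxel_size_um)
    elif suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = _check_isotropic(img.GetSpacing())
        if voxel_size_um is not None:
            spacing = float(voxel_size_um)
    else:
        raise ValueError(f"unsupported volume format {suffix!r}; expected .tif/.tiff/.nrrd")
    return ScalarVolume(data=data, voxel_size_um=spacing, stage=stage)


def read_labels(path: str | Path, voxel_size_um: float | None = None) -> LabelVolume:
    """Read a label volume written by :func:`write_volume` (with JSON sidecar)."""
    vol = read_volume(path, voxel_size_um=voxel_size_um, stage="pre_stain")
    sidecar = Path(str(path) + ".classes.json")
    classes = CLASS_NAMES
    if sidecar.exists():
        mapping = json.loads(sidecar.read_text())
        classes = tuple(mapping[str(i)] for i in range(len(mapping)))
    return LabelVolume(data=vol.data.astype(np.uint8), voxel_size_um=vol.voxel_size_um, classes=classes)


def write_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume so that it round-trips exactly through the readers.

    Scalar volumes are stored as float (difference maps keep their negative
    values); label volumes as unsigned 8-bit with a JSON class-map sidecar.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    is_label = isinstance(vol, LabelVolume)
    data = vol.data if not is_label else vol.data.astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif suffix == ".nrrd":
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((vol.voxel_size_um,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    if is_label:
        sidecar = Path(str(path) + ".classes.json")
        sidecar.write_text(json.dumps({str(i): c for i, c in enumerate(vol.classes)}, indent=1))
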