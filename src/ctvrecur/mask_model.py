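"""Domain types, validation, volumetric I/O and volume arithmetic.

The analysis operates on co-registered binary masks on a shared 3D voxel
lattice: the clinical target volume (CTV), the gross tumor volume (GTV),
gross nodal disease (GTVnd), an optional recurrence region, and the 16
mediastinal/hilar lymph-node stations of the IASLC map (labels 1R..11L,
indexed LN1..LN16).  Masks are stored one NIfTI volume per structure with a
JSON sidecar carrying grid metadata and the clinical record.

Conventions: 0-based voxel indices, axis order (x, y, z); a voxel belongs to
a structure iff its mask value is 1; volumes are voxel counts times the
voxel volume (no partial-volume weighting).  All masks must already live on
the shared grid — no resampling is performed here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Optional

import nibabel as nib
import numpy as np

__all__ = [
    "N_STATIONS",
    "STATION_LABELS",
    "STATION_INDEX",
    "station_label",
    "station_index",
    "VoxelGrid",
    "PatientRecord",
    "StructureSet",
    "StructureSetError",
    "volume_mm3",
    "validate_structure_set",
    "save_structure_set",
    "load_structure_set",
    "DEFAULT_MANIFEST",
]

# ---------------------------------------------------------------------------
# Station nomenclature
# ---------------------------------------------------------------------------

N_STATIONS = 16

#: IASLC station label for each internal index LN1..LN16.
STATION_LABELS: tuple[str, ...] = (
    "1R", "1L", "2R", "2L", "3A", "3P", "4R", "4L",
    "5", "6", "7", "8", "10R", "10L", "11R", "11L",
)

#: Inverse map, station label -> 1-based LN index.
STATION_INDEX: dict[str, int] = {lab: i + 1 for i, lab in enumerate(STATION_LABELS)}


def station_label(ln_index: int) -> str:
    """IASLC label for a 1-based LN index (LN7 -> '4R')."""
    if not 1 <= ln_index <= N_STATIONS:
        raise ValueError(f"LN index must be in [1, {N_STATIONS}], got {ln_index}")
    return STATION_LABELS[ln_index - 1]


def station_index(label: str) -> int:
    """1-based LN index for an IASLC station label ('4R' -> 7)."""
    try:
        return STATION_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown station label {label!r}") from None


# ---------------------------------------------------------------------------
# Grid and clinical record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of the shared voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry >= 1.
    spacing
        Voxel edge lengths in mm along (x, y, z); each entry > 0.
    origin
        mm coordinate of the voxel with index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three entries > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the lattice along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (axis-aligned)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """mm coordinates of voxel centers as three broadcastable axes."""
        ax = [
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        ]
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing),
                "origin": list(self.origin)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "VoxelGrid":
        return cls(tuple(d["shape"]), tuple(d["spacing"]), tuple(d["origin"]))


@dataclass
class PatientRecord:
    """Clinical covariates and outcome for one patient.

    ``smoking_index`` is the cumulative pack-based exposure score (the study
    cohort stratified it as 0, 0-400, >400).  ``lung_area_code`` encodes the
    lung quadrant holding the GTV centroid: 1=right-upper, 2=right-lower,
    3=left-upper, 4=left-lower.  ``relapse`` is the local-failure label and
    ``followup_months`` the observed (possibly censored) follow-up time.
    """

    id: str
    age_years: float = 60.0
    sex: str = "male"
    t_stage: str = "T2"
    n_stage: str = "N2"
    tnm_stage: str = "III"
    smoking_index: float = 0.0
    tumor_diameter_cm: float = 4.0
    tumor_location: str = "central"
    chemo: str = "synchronous"
    followup_months: float = 0.0
    relapse: int = 0
    lung_area_code: int = 1

    _SEX = ("male", "female")
    _T = ("T1", "T2", "T3", "T4")
    _N = ("N0", "N1", "N2", "N3")
    _TNM = ("I", "II", "III", "IV")
    _LOC = ("central", "peripheral")
    _CHEMO = ("synchronous", "sequential")

    def __post_init__(self) -> None:
        if self.sex not in self._SEX:
            raise ValueError(f"sex must be one of {self._SEX}, got {self.sex!r}")
        if self.t_stage not in self._T:
            raise ValueError(f"t_stage must be one of {self._T}")
        if self.n_stage not in self._N:
            raise ValueError(f"n_stage must be one of {self._N}")
        if self.tnm_stage not in self._TNM:
            raise ValueError(f"tnm_stage must be one of {self._TNM}")
        if self.tumor_location not in self._LOC:
            raise ValueError(f"tumor_location must be one of {self._LOC}")
        if self.chemo not in self._CHEMO:
            raise ValueError(f"chemo must be one of {self._CHEMO}")
        if self.smoking_index < 0:
            raise ValueError("smoking_index must be >= 0")
        if self.tumor_diameter_cm <= 0:
            raise ValueError("tumor_diameter_cm must be > 0")
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if self.relapse not in (0, 1):
            raise ValueError("relapse must be 0 or 1")
        if self.lung_area_code not in (1, 2, 3, 4):
            raise ValueError("lung_area_code must be in {1,2,3,4}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatientRecord":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


# ---------------------------------------------------------------------------
# Structure set
# ---------------------------------------------------------------------------


class StructureSetError(ValueError):
    """Raised for malformed or inconsistent structure sets."""


def _as_mask(arr: np.ndarray, name: str, shape: tuple[int, int, int]) -> np.ndarray:
    a = np.asarray(arr)
    if a.shape != shape:
        raise StructureSetError(
            f"mask {name!r} has shape {a.shape}, expected grid shape {shape}"
        )
    return a.astype(bool, copy=False)


@dataclass
class StructureSet:
    """Co-registered binary masks for one patient on a shared grid.

    ``ln`` maps the 1-based LN index (1..16) to that station's mask.  The
    recurrence mask is optional; ``None`` means no recurrence imaging is
    attached.  Construction coerces every mask to boolean and checks shapes;
    the set-level invariants (station disjointness, CTV containment) are
    checked by :func:`validate_structure_set`.
    """

    grid: VoxelGrid
    ctv: np.ndarray
    gtv: np.ndarray
    gtvnd: np.ndarray
    ln: dict[int, np.ndarray]
    recurrence: Optional[np.ndarray] = None
    patient: Optional[PatientRecord] = None

    def __post_init__(self) -> None:
        shape = self.grid.shape
        self.ctv = _as_mask(self.ctv, "CTV", shape)
        self.gtv = _as_mask(self.gtv, "GTV", shape)
        self.gtvnd = _as_mask(self.gtvnd, "GTVnd", shape)
        if self.recurrence is not None:
            self.recurrence = _as_mask(self.recurrence, "recurrence", shape)
        if set(self.ln) != set(range(1, N_STATIONS + 1)):
            raise StructureSetError(
                f"ln must map indices 1..{N_STATIONS}, got {sorted(self.ln)}"
            )
        self.ln = {
            i: _as_mask(self.ln[i], f"LN{i}", shape)
            for i in range(1, N_STATIONS + 1)
        }

    def stations(self) -> Iterator[tuple[int, str, np.ndarray]]:
        """Yield (ln_index, station_label, mask) in LN1..LN16 order."""
        for i in range(1, N_STATIONS + 1):
            yield i, STATION_LABELS[i - 1], self.ln[i]

    @property
    def has_recurrence(self) -> bool:
        return self.recurrence is not None and bool(self.recurrence.any())


def volume_mm3(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Physical volume of a binary mask: set-voxel count times voxel volume."""
    m = np.asarray(mask)
    if m.shape != grid.shape:
        raise StructureSetError(
            f"mask shape {m.shape} does not match grid shape {grid.shape}"
        )
    return float(np.count_nonzero(m)) * grid.voxel_volume_mm3


def validate_structure_set(ss: StructureSet) -> list[str]:
    """Check StructureSet invariants; return a list of violation messages.

    An empty list means the set is valid.  Checked: pairwise disjointness of
    the 16 station masks (the ratio formulas double-count under overlap, so
    this is a hard requirement, never auto-repaired) and containment of
    gross disease in the CTV.
    """
    report: list[str] = []
    for i in range(1, N_STATIONS + 1):
        for j in range(i + 1, N_STATIONS + 1):
            n = int(np.count_nonzero(ss.ln[i] & ss.ln[j]))
            if n:
                report.append(
                    f"stations (LN{i}, LN{j}) = ({station_label(i)}, "
                    f"{station_label(j)}) overlap in {n} voxel(s)"
                )
    n_out = int(np.count_nonzero(ss.gtv & ~ss.ctv))
    if n_out:
        report.append(f"GTV not contained in CTV: {n_out} voxel(s) outside")
    n_out = int(np.count_nonzero(ss.gtvnd & ~ss.ctv))
    if n_out:
        report.append(f"GTVnd not contained in CTV: {n_out} voxel(s) outside")
    return report


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# ---------------------------------------------------------------------------

DEFAULT_MANIFEST: dict[str, str] = {
    "ctv": "ctv.nii.gz",
    "gtv": "gtv.nii.gz",
    "gtvnd": "gtvnd.nii.gz",
    "recurrence": "recurrence.nii.gz",
    **{f"ln{i:02d}": f"ln{i:02d}.nii.gz" for i in range(1, N_STATIONS + 1)},
}

_SIDECAR = "patient.json"


def _write_mask(mask: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def _read_mask(path: Path) -> tuple[np.ndarray, tuple[int, ...]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data > 0, data.shape


def save_structure_set(
    ss: StructureSet,
    path: str | Path,
    manifest: Mapping[str, str] = DEFAULT_MANIFEST,
) -> Path:
    """Write one NIfTI volume per structure plus a ``patient.json`` sidecar.

    The sidecar stores grid geometry to full precision (NIfTI headers are
    float32, so spacing/origin are authoritative in the sidecar), the LN
    index -> station label map, and the clinical record if attached.  An
    empty/absent recurrence mask writes no recurrence file.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_mask(ss.ctv, ss.grid, path / manifest["ctv"])
    _write_mask(ss.gtv, ss.grid, path / manifest["gtv"])
    _write_mask(ss.gtvnd, ss.grid, path / manifest["gtvnd"])
    if ss.has_recurrence:
        _write_mask(ss.recurrence, ss.grid, path / manifest["recurrence"])
    for i, _lab, mask in ss.stations():
        _write_mask(mask, ss.grid, path / manifest[f"ln{i:02d}"])
    sidecar = {
        "grid": ss.grid.to_dict(),
        "stations": {str(i): lab for i, lab in enumerate(STATION_LABELS, start=1)},
        "patient": ss.patient.to_dict() if ss.patient is not None else None,
    }
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_structure_set(
    path: str | Path,
    manifest: Mapping[str, str] = DEFAULT_MANIFEST,
) -> StructureSet:
    """Load a structure set written by :func:`save_structure_set`.

    Raises :class:`StructureSetError` naming the structure if a mandatory
    file is missing, or listing the offending files on a grid-shape
    mismatch.  A missing recurrence file yields ``recurrence=None``.
    """
    path = Path(path)
    sidecar_path = path / _SIDECAR
    if not sidecar_path.exists():
        raise StructureSetError(f"missing sidecar: {_SIDECAR} in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    grid = VoxelGrid.from_dict(sidecar["grid"])

    masks: dict[str, np.ndarray] = {}
    shapes: dict[str, tuple[int, ...]] = {}
    mandatory = ["ctv", "gtv", "gtvnd"] + [f"ln{i:02d}" for i in range(1, N_STATIONS + 1)]
    for key in mandatory:
        f = path / manifest[key]
        if not f.exists():
            raise StructureSetError(f"missing structure: {key.upper()} ({f.name})")
        masks[key], shapes[key] = _read_mask(f)
    rec_file = path / manifest["recurrence"]
    recurrence = None
    if rec_file.exists():
        recurrence, shapes["recurrence"] = _read_mask(rec_file)

    bad = {k: s for k, s in shapes.items() if s != grid.shape}
    if bad:
        details = ", ".join(f"{manifest[k]}: {s}" for k, s in sorted(bad.items()))
        raise StructureSetError(
            f"grid shape mismatch (sidecar says {grid.shape}): {details}"
        )

    patient = (
        PatientRecord.from_dict(sidecar["patient"])
        if sidecar.get("patient") is not None
        else None
    )
    return StructureSet(
        grid=grid,
        ctv=masks["ctv"],
        gtv=masks["gtv"],
        gtvnd=masks["gtvnd"],
        ln={i: masks[f"ln{i:02d}"] for i in range(1, N_STATIONS + 1)},
        recurrence=recurrence,
        patient=patient,
    )
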