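"""Partition parameters of the CTV against the 16 lymph-node stations.

The central construct is the *ideal CTV* (``ideaCTV``): the union of every
full station volume that the delineated CTV touches at all.  A CTV that
clips one corner of station 4R "violates" 4R, and the ideal target would
have covered the whole station — so ideaCTV is the natural normalizer for
asking how much of the ideal coverage the actual delineation achieved.

Six ratio families (16 stations each, 96 values) plus 14 scalar parameters
give the 110-entry feature vector used by the recurrence model:

=======  ==========================================================
RctvLNi   |CTV ∩ LNi| / |LNi|          station coverage by the CTV
RIctvLNi  |CTV ∩ LNi| / |ideaCTV|      CTV-in-station share of ideaCTV
RgtvLNi   |G ∩ LNi| / |LNi|            station involvement by gross disease
RIgtvLNi  |G ∩ LNi| / |ideaCTV|
RcmgLNi   |(CTV−G) ∩ LNi| / |LNi|      elective (CTV minus gross) coverage
RIcmgLNi  |(CTV−G) ∩ LNi| / |ideaCTV|
=======  ==========================================================

where G is the gross-disease mask — by default GTV ∪ GTVnd, switchable to
the primary GTV alone.  All ratios are voxel-count ratios (the voxel volume
cancels).  Mask-comparison metrics (Dice, Hausdorff) live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .mask_model import (
    N_STATIONS,
    PatientRecord,
    StructureSet,
    StructureSetError,
    VoxelGrid,
    station_index,
    validate_structure_set,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "OVERLAP_FLAG_STATIONS",
    "FeatureVector",
    "gross_disease_mask",
    "idea_ctv",
    "ratio_families",
    "scalar_features",
    "extract_features",
    "feature_table",
    "dice",
    "hausdorff_mm",
]

# ---------------------------------------------------------------------------
# Canonical 110-name schema
# ---------------------------------------------------------------------------

#: Stations whose CTV-overlap status enters the feature vector as a flag,
#: in schema order (rows 103-109).
OVERLAP_FLAG_STATIONS: tuple[str, ...] = ("4L", "4R", "5", "6", "7", "11L", "11R")

_RATIO_FAMILIES = ("Rctv", "RIctv", "Rgtv", "RIgtv", "Rcmg", "RIcmg")

_SCALAR_NAMES = (
    "ctv_volume",          # row 97, mm^3
    "gtvnd_volume",        # row 98, mm^3
    "image_resolution",    # row 99, in-plane spacing in mm
    "n_ln_ctv",            # row 100
    "n_ln_gtvnd",          # row 101
    "lung_area_code",      # row 102
    *(f"overlap_{s}" for s in OVERLAP_FLAG_STATIONS),  # rows 103-109
    "gtv_size",            # row 110, pre-treatment tumor size (cm)
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{fam}LN{i}" for fam in _RATIO_FAMILIES for i in range(1, N_STATIONS + 1)
) + _SCALAR_NAMES

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 110


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 110-parameter record for one patient."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.names != FEATURE_NAMES:
            raise ValueError("feature names must match the canonical schema")
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {self.values.shape}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


# ---------------------------------------------------------------------------
# ideaCTV and ratio families
# ---------------------------------------------------------------------------


def gross_disease_mask(ss: StructureSet, gross_disease: str = "union") -> np.ndarray:
    """Resolve the gross-disease mask G used by the ratio formulas.

    ``"union"`` (default) takes GTV ∪ GTVnd so that nodal gross disease
    contributes to the station ratios; ``"primary_only"`` restricts G to the
    primary GTV.
    """
    if gross_disease == "union":
        return ss.gtv | ss.gtvnd
    if gross_disease == "primary_only":
        return ss.gtv
    raise ValueError(f"gross_disease must be 'union' or 'primary_only', got {gross_disease!r}")


def idea_ctv(ss: StructureSet, min_overlap_voxels: int = 1) -> np.ndarray:
    """Union of every full station mask the CTV intersects.

    A station counts as violated as soon as the CTV covers at least
    ``min_overlap_voxels`` of its voxels (default 1, i.e. any contact); the
    *entire* station then enters the union, not just the touched part.
    Returns an all-False mask when the CTV touches no station.
    """
    out = np.zeros(ss.grid.shape, dtype=bool)
    for _i, _lab, mask in ss.stations():
        if int(np.count_nonzero(ss.ctv & mask)) >= min_overlap_voxels:
            out |= mask
    return out


@dataclass(frozen=True)
class _StationCounts:
    """Per-station voxel counts shared by the ratio and scalar features."""

    n_ln: np.ndarray      # |LNi|
    n_ctv: np.ndarray     # |CTV ∩ LNi|
    n_g: np.ndarray       # |G ∩ LNi|
    n_cmg: np.ndarray     # |(CTV−G) ∩ LNi|
    n_gtvnd: np.ndarray   # |GTVnd ∩ LNi|
    n_idea: int           # |ideaCTV| (sum of violated station sizes)


def _station_counts(
    ss: StructureSet,
    gross_disease: str = "union",
    min_overlap_voxels: int = 1,
) -> _StationCounts:
    """One pass of flat gathers per station.

    Station disjointness makes |ideaCTV| the plain sum of the violated
    stations' sizes, so the ideal-CTV mask never needs materializing here.
    """
    g = gross_disease_mask(ss, gross_disease).ravel()
    ctv = ss.ctv.ravel()
    gtvnd = ss.gtvnd.ravel()
    n_ln = np.zeros(N_STATIONS, dtype=int)
    n_ctv = np.zeros(N_STATIONS, dtype=int)
    n_g = np.zeros(N_STATIONS, dtype=int)
    n_cmg = np.zeros(N_STATIONS, dtype=int)
    n_nd = np.zeros(N_STATIONS, dtype=int)
    for i, _lab, ln in ss.stations():
        idx = np.flatnonzero(ln.ravel())
        if idx.size == 0:
            raise StructureSetError(f"station LN{i} is empty; ratios undefined")
        ctv_in = ctv[idx]
        g_in = g[idx]
        n_ln[i - 1] = idx.size
        n_ctv[i - 1] = int(ctv_in.sum())
        n_g[i - 1] = int(g_in.sum())
        n_cmg[i - 1] = int((ctv_in & ~g_in).sum())
        n_nd[i - 1] = int(gtvnd[idx].sum())
    violated = n_ctv >= min_overlap_voxels
    return _StationCounts(
        n_ln=n_ln, n_ctv=n_ctv, n_g=n_g, n_cmg=n_cmg, n_gtvnd=n_nd,
        n_idea=int(n_ln[violated].sum()),
    )


def ratio_families(
    ss: StructureSet,
    gross_disease: str = "union",
    min_overlap_voxels: int = 1,
) -> dict[str, float]:
    """Compute the 96 station ratios, keyed by canonical name.

    Station masks must be non-empty (an empty station makes its per-station
    ratios undefined, a hard error).  When the CTV touches no station,
    ``|ideaCTV| = 0`` and all RI* ratios are defined as 0 with a warning —
    a CTV clear of every station is a legal degenerate case.
    """
    c = _station_counts(ss, gross_disease, min_overlap_voxels)
    if c.n_idea == 0:
        logger.warning(
            "ideaCTV is empty (CTV touches no station); RI* ratios set to 0"
        )
    out: dict[str, float] = {}
    for i in range(1, N_STATIONS + 1):
        k = i - 1
        out[f"RctvLN{i}"] = c.n_ctv[k] / c.n_ln[k]
        out[f"RIctvLN{i}"] = c.n_ctv[k] / c.n_idea if c.n_idea else 0.0
        out[f"RgtvLN{i}"] = c.n_g[k] / c.n_ln[k]
        out[f"RIgtvLN{i}"] = c.n_g[k] / c.n_idea if c.n_idea else 0.0
        out[f"RcmgLN{i}"] = c.n_cmg[k] / c.n_ln[k]
        out[f"RIcmgLN{i}"] = c.n_cmg[k] / c.n_idea if c.n_idea else 0.0
    return {
        f"{fam}LN{i}": out[f"{fam}LN{i}"]
        for fam in _RATIO_FAMILIES
        for i in range(1, N_STATIONS + 1)
    }


def scalar_features(
    ss: StructureSet,
    rec: PatientRecord,
    min_overlap_voxels: int = 1,
) -> dict[str, float]:
    """The 14 scalar parameters (schema rows 97-110), keyed by name."""
    vol = ss.grid.voxel_volume_mm3
    c = _station_counts(ss, min_overlap_voxels=min_overlap_voxels)
    touched = c.n_ctv >= min_overlap_voxels
    return {
        "ctv_volume": float(np.count_nonzero(ss.ctv)) * vol,
        "gtvnd_volume": float(np.count_nonzero(ss.gtvnd)) * vol,
        "image_resolution": float(ss.grid.spacing[0]),
        "n_ln_ctv": float(touched.sum()),
        "n_ln_gtvnd": float((c.n_gtvnd >= min_overlap_voxels).sum()),
        "lung_area_code": float(rec.lung_area_code),
        **{
            f"overlap_{s}": float(touched[station_index(s) - 1])
            for s in OVERLAP_FLAG_STATIONS
        },
        "gtv_size": float(rec.tumor_diameter_cm),
    }


def extract_features(
    ss: StructureSet,
    rec: Optional[PatientRecord] = None,
    gross_disease: str = "union",
    min_overlap_voxels: int = 1,
    validate: bool = False,
) -> FeatureVector:
    """Assemble the full 110-entry feature vector in canonical order."""
    if rec is None:
        rec = ss.patient
    if rec is None:
        raise ValueError("a PatientRecord is required (pass rec= or attach to ss)")
    if validate:
        report = validate_structure_set(ss)
        if report:
            raise StructureSetError("; ".join(report))
    vals = ratio_families(ss, gross_disease, min_overlap_voxels)
    vals.update(scalar_features(ss, rec, min_overlap_voxels))
    arr = np.array([vals[name] for name in FEATURE_NAMES], dtype=float)
    return FeatureVector(names=FEATURE_NAMES, values=arr)


def feature_table(
    cohort: Iterable[tuple[StructureSet, PatientRecord]],
    gross_disease: str = "union",
    min_overlap_voxels: int = 1,
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per patient, id index,
    110 canonical columns plus the ``relapse`` label."""
    rows = []
    ids = []
    for ss, rec in cohort:
        fv = extract_features(ss, rec, gross_disease, min_overlap_voxels)
        row = dict(zip(fv.names, fv.values))
        row["relapse"] = rec.relapse
        rows.append(row)
        ids.append(rec.id)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    return df[list(FEATURE_NAMES) + ["relapse"]]


# ---------------------------------------------------------------------------
# Mask-comparison metrics
# ---------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 if both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise StructureSetError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary_points_mm(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """mm coordinates of boundary-voxel centers (6-connected erosion residue)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    idx = np.argwhere(mask & ~eroded)
    return np.asarray(grid.origin) + idx * np.asarray(grid.spacing)


def hausdorff_mm(mask_a: np.ndarray, mask_b: np.ndarray, grid: VoxelGrid) -> float:
    """Symmetric Hausdorff distance (mm) between mask boundaries."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape or a.shape != grid.shape:
        raise StructureSetError("masks and grid must share one shape")
    if not a.any() or not b.any():
        raise StructureSetError("Hausdorff distance undefined for an empty mask")
    pa = _boundary_points_mm(a, grid)
    pb = _boundary_points_mm(b, grid)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
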