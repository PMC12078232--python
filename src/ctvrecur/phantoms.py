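"""Synthetic voxel phantoms: cohorts with known generative ground truth.

No per-patient imaging is publicly available for the clinical cohort this
pipeline mirrors, so every downstream stage is exercised on synthetic
structure sets.  The generator emulates the statistical structure the
analysis relies on, not anatomy:

* a stylized mediastinal atlas of 16 disjoint ellipsoidal stations
  (superior 1R/1L above 2R/2L, subcarinal 7 central, hilar/interlobar
  10R/10L/11R/11L lateral-inferior);
* a spherical primary GTV placed in a sampled lung quadrant with a sampled
  diameter, nodal gross disease (GTVnd) as sub-regions of the sampled
  involved stations;
* the CTV as a morphological expansion of GTV ∪ GTVnd unioned with the full
  masks of involved stations — so nearby stations get partial coverage and
  the station ratios land strictly between 0 and 1;
* a relapse label drawn from a planted logistic model on the patient's own
  extracted partition features, an exponential time-to-event with
  covariate-dependent hazard, independent exponential censoring, and a
  recurrence ellipsoid seeded in a station drawn from configurable weights.

Identical seeds give byte-identical cohorts; per-patient substreams are
derived by counter so the cohort is reproducible regardless of generation
order.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .mask_model import (
    N_STATIONS,
    PatientRecord,
    STATION_LABELS,
    StructureSet,
    StructureSetError,
    VoxelGrid,
    station_index,
)
from .features import FEATURE_NAMES, extract_features
from .recurrence import REFERENCE_STATION_EVENTS

__all__ = [
    "DEFAULT_GRID",
    "AtlasSpec",
    "EffectSpec",
    "TruthRecord",
    "Cohort",
    "rasterize_ellipsoid",
    "dilate_mm",
    "generate_atlas",
    "generate_patient",
    "generate_cohort",
]

# Default phantom lattice: 96^3 voxels at 1.5 mm isotropic (a desk-scale
# stand-in for the clinical 512 x 512 x 5 mm planning grid; the geometry of
# the ratio formulas is resolution-independent).
DEFAULT_GRID = VoxelGrid(shape=(96, 96, 96), spacing=(1.5, 1.5, 1.5))

# Station layout in normalized coordinates (fractions of the grid's physical
# extent): x runs patient-right (0) to patient-left (1), z inferior (0) to
# superior (1).  Radii are fractions of extent too, so the same layout stays
# pairwise disjoint at any resolution (minimum center separation 0.166 vs
# a diameter of 0.11).
_LAYOUT: dict[str, tuple[float, float, float]] = {
    "1R": (0.35, 0.45, 0.88), "1L": (0.65, 0.45, 0.88),
    "2R": (0.35, 0.42, 0.72), "2L": (0.65, 0.42, 0.72),
    "3A": (0.50, 0.22, 0.60), "3P": (0.50, 0.78, 0.60),
    "4R": (0.35, 0.45, 0.55), "4L": (0.65, 0.45, 0.55),
    "5":  (0.78, 0.35, 0.52), "6":  (0.80, 0.20, 0.62),
    "7":  (0.50, 0.50, 0.42), "8":  (0.50, 0.55, 0.25),
    "10R": (0.22, 0.50, 0.40), "10L": (0.78, 0.52, 0.40),
    "11R": (0.15, 0.50, 0.25), "11L": (0.85, 0.52, 0.25),
}
_NORM_RADIUS = 0.055

# Lung-quadrant anchors for the primary GTV (normalized coordinates);
# code 1=right-upper, 2=right-lower, 3=left-upper, 4=left-lower.
_LUNG_AREAS = {
    1: (0.22, 0.50, 0.68), 2: (0.22, 0.50, 0.32),
    3: (0.78, 0.50, 0.68), 4: (0.78, 0.50, 0.32),
}


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry of the synthetic station atlas (mm units)."""

    grid: VoxelGrid
    station_centers: tuple[tuple[float, float, float], ...]
    station_radii: tuple[tuple[float, float, float], ...]

    @classmethod
    def default(cls, grid: VoxelGrid = DEFAULT_GRID) -> "AtlasSpec":
        ext = np.asarray(grid.extent_mm)
        origin = np.asarray(grid.origin)
        centers = tuple(
            tuple(origin + np.asarray(_LAYOUT[lab]) * ext) for lab in STATION_LABELS
        )
        radii = tuple(tuple(_NORM_RADIUS * ext) for _ in STATION_LABELS)
        return cls(grid=grid, station_centers=centers, station_radii=radii)


@dataclass(frozen=True)
class EffectSpec:
    """Planted statistical structure of a synthetic cohort.

    ``logit_coefficients`` act on the patient's *extracted* feature values
    (canonical names), so the recurrence label genuinely depends on the
    partition geometry the downstream model sees.  ``hazard_ratio_per_unit``
    multiplies the event hazard per unit of the named covariate
    (``large_tumor``, ``male`` and ``age_ge60`` are derived binaries).
    ``censoring_window_months`` is the administrative follow-up horizon for
    patients who never relapse.
    """

    involved_station_probs: dict[str, float] = field(default_factory=lambda: {
        "1R": 0.08, "1L": 0.08, "2R": 0.15, "2L": 0.03, "3A": 0.08, "3P": 0.03,
        "4R": 0.35, "4L": 0.12, "5": 0.10, "6": 0.12, "7": 0.30, "8": 0.06,
        "10R": 0.45, "10L": 0.35, "11R": 0.18, "11L": 0.15,
    })
    logit_intercept: float = -4.2
    logit_coefficients: dict[str, float] = field(default_factory=lambda: {
        "RctvLN13": 3.0,   # station 10R coverage
        "RctvLN14": 2.5,   # station 10L coverage
        "RctvLN7": 2.0,    # station 4R coverage
        "RgtvLN11": 2.5,   # gross-disease fraction of station 7
        "RgtvLN13": 2.5,   # gross-disease fraction of station 10R
    })
    baseline_hazard: float = 0.02          # events / month
    hazard_ratio_per_unit: dict[str, float] = field(
        default_factory=lambda: {"large_tumor": 2.0}
    )
    censoring_rate: float = 0.003          # events / month
    censoring_window_months: float = 72.0
    ctv_margin_mm: float = 8.0
    recurrence_station_weights: dict[str, float] = field(
        default_factory=lambda: {k: float(v) for k, v in REFERENCE_STATION_EVENTS.items()}
    )
    p_recurrence_in_gross: float = 0.6
    tumor_diameter_mean_cm: float = 4.8
    tumor_diameter_sd_cm: float = 1.8

    def __post_init__(self) -> None:
        for lab, p in self.involved_station_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"involvement probability for {lab} not in [0,1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        unknown = set(self.logit_coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names in logit_coefficients: {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Planted parameters and per-patient latent values of one cohort."""

    effect: EffectSpec
    seed: int
    linear_predictor: list[float] = field(default_factory=list)
    relapse_probability: list[float] = field(default_factory=list)
    latent_relapse: list[int] = field(default_factory=list)
    involved_stations: list[list[str]] = field(default_factory=list)
    recurrence_station: list[Optional[str]] = field(default_factory=list)
    event_time: list[Optional[float]] = field(default_factory=list)
    censor_time: list[Optional[float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"] = dataclasses.asdict(self.effect)
        return d


@dataclass
class Cohort:
    patients: list[tuple[StructureSet, PatientRecord]]
    truth: TruthRecord
    #: 110 canonical feature columns + relapse label, id index — the same
    #: values extract_features would recompute from the masks.
    features: "pd.DataFrame" = None

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def rasterize_ellipsoid(
    grid: VoxelGrid,
    center_mm: Sequence[float],
    radii_mm: Sequence[float] | float,
) -> np.ndarray:
    """Binary mask of voxels whose centers lie inside the ellipsoid.

    Only the bounding box is evaluated, so rasterization cost scales with
    the structure, not the grid.  Parts of the ellipsoid outside the lattice
    are clipped.
    """
    if np.isscalar(radii_mm):
        radii_mm = (float(radii_mm),) * 3
    c = np.asarray(center_mm, dtype=float)
    r = np.asarray(radii_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ellipsoid radii must be positive")
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1,
                    np.asarray(grid.shape))
    mask = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    ax = [
        (origin[k] + spacing[k] * np.arange(lo[k], hi[k]) - c[k]) / r[k]
        for k in range(3)
    ]
    inside = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    ) <= 1.0
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    return mask


def dilate_mm(mask: np.ndarray, grid: VoxelGrid, margin_mm: float) -> np.ndarray:
    """Isotropic morphological dilation by a physical margin.

    Implemented with a Euclidean distance transform of the background so
    anisotropic spacings are honored exactly.
    """
    if margin_mm <= 0 or not mask.any():
        return mask.copy()
    # restrict the distance transform to the dilated bounding box
    idx = np.argwhere(mask)
    pad = np.ceil(margin_mm / np.asarray(grid.spacing)).astype(int) + 1
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(grid.shape))
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    dist = ndimage.distance_transform_edt(~mask[box], sampling=grid.spacing)
    out = np.zeros_like(mask)
    out[box] = dist <= margin_mm
    return out


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


def generate_atlas(spec: AtlasSpec | None = None) -> tuple[AtlasSpec, dict[int, np.ndarray]]:
    """Rasterize the 16 station ellipsoids; error on collision or emptiness."""
    if spec is None:
        spec = AtlasSpec.default()
    masks: dict[int, np.ndarray] = {}
    for i, lab in enumerate(STATION_LABELS, start=1):
        m = rasterize_ellipsoid(spec.grid, spec.station_centers[i - 1],
                                spec.station_radii[i - 1])
        if not m.any():
            raise StructureSetError(
                f"station {lab} rasterizes to an empty mask on grid {spec.grid.shape}"
            )
        masks[i] = m
    for i in range(1, N_STATIONS + 1):
        for j in range(i + 1, N_STATIONS + 1):
            if np.any(masks[i] & masks[j]):
                raise StructureSetError(
                    f"station ellipsoids collide: ({STATION_LABELS[i-1]}, "
                    f"{STATION_LABELS[j-1]})"
                )
    return spec, masks


# ---------------------------------------------------------------------------
# Patients and cohorts
# ---------------------------------------------------------------------------

_T_PROBS = (0.156, 0.261, 0.117, 0.466)
_N_PROBS = (0.033, 0.044, 0.456, 0.467)
_TNM_PROBS = (0.022, 0.022, 0.878, 0.078)


def _choice(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    p = np.asarray(probs, dtype=float)
    return items[int(rng.choice(len(items), p=p / p.sum()))]


def _sample_record(rng: np.random.Generator, pid: str, effect: EffectSpec) -> PatientRecord:
    """Clinical covariates drawn from marginals shaped like the study cohort
    (median age ~60, ~72% male, ~76% central tumors, near-even tumor-size split)."""
    u = rng.random()
    if u < 0.328:
        smoking = 0.0
    elif u < 0.395:
        smoking = float(rng.uniform(1, 400))
    else:
        smoking = float(rng.uniform(400, 1600))
    diameter = float(np.clip(
        rng.normal(effect.tumor_diameter_mean_cm, effect.tumor_diameter_sd_cm),
        1.5, 11.0,
    ))
    return PatientRecord(
        id=pid,
        age_years=float(np.clip(rng.normal(62, 9), 35, 88)),
        sex="male" if rng.random() < 0.722 else "female",
        t_stage=_choice(rng, PatientRecord._T, _T_PROBS),
        n_stage=_choice(rng, PatientRecord._N, _N_PROBS),
        tnm_stage=_choice(rng, PatientRecord._TNM, _TNM_PROBS),
        smoking_index=smoking,
        tumor_diameter_cm=diameter,
        tumor_location="central" if rng.random() < 0.756 else "peripheral",
        chemo="synchronous" if rng.random() < 0.661 else "sequential",
        lung_area_code=int(rng.integers(1, 5)),
    )


def generate_patient(
    atlas: tuple[AtlasSpec, dict[int, np.ndarray]],
    effect: EffectSpec,
    rng: np.random.Generator,
    patient_id: str = "P0",
) -> tuple[StructureSet, PatientRecord]:
    """One synthetic structure set + clinical record (no outcome yet).

    GTV: sphere of the sampled diameter anchored in the sampled lung
    quadrant (center clamped so the sphere stays on the lattice where
    possible).  GTVnd: one ellipsoidal sub-region per sampled involved
    station, confined to that station.  CTV: GTV ∪ GTVnd dilated by the
    margin, unioned with the full masks of involved stations.
    """
    spec, ln_masks = atlas
    grid = spec.grid
    rec = _sample_record(rng, patient_id, effect)

    ext = np.asarray(grid.extent_mm)
    origin = np.asarray(grid.origin)
    anchor = origin + np.asarray(_LUNG_AREAS[rec.lung_area_code]) * ext
    jitter = rng.uniform(-0.05, 0.05, size=3) * ext
    radius = rec.tumor_diameter_cm * 10.0 / 2.0
    center = np.clip(anchor + jitter, origin + radius, origin + ext - radius)
    # if the tumor is larger than the lattice allows, fall back to centering
    center = np.where(origin + radius > origin + ext - radius,
                      origin + ext / 2, center)
    gtv = rasterize_ellipsoid(grid, center, radius)

    involved = [
        i for i, lab in enumerate(STATION_LABELS, start=1)
        if rng.random() < effect.involved_station_probs.get(lab, 0.0)
    ]
    gtvnd = np.zeros(grid.shape, dtype=bool)
    for i in involved:
        c = np.asarray(spec.station_centers[i - 1])
        r = np.asarray(spec.station_radii[i - 1])
        sub_c = c + rng.uniform(-0.3, 0.3, size=3) * r
        sub_r = r * rng.uniform(0.45, 0.8, size=3)
        sub = rasterize_ellipsoid(grid, sub_c, sub_r) & ln_masks[i]
        if not sub.any():
            # degenerate jitter: fall back to the station voxel nearest its center
            idx = np.argwhere(ln_masks[i])
            mm = origin + idx * np.asarray(grid.spacing)
            k = int(np.argmin(((mm - c) ** 2).sum(axis=1)))
            sub = np.zeros(grid.shape, dtype=bool)
            sub[tuple(idx[k])] = True
        gtvnd |= sub

    ctv = dilate_mm(gtv | gtvnd, grid, effect.ctv_margin_mm)
    for i in involved:
        ctv |= ln_masks[i]

    ss = StructureSet(
        grid=grid, ctv=ctv, gtv=gtv, gtvnd=gtvnd,
        ln={i: ln_masks[i] for i in range(1, N_STATIONS + 1)},
        patient=rec,
    )
    return ss, rec


def _synthesize_recurrence(
    ss: StructureSet,
    effect: EffectSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str]:
    """One connected recurrence ellipsoid, seeded inside a weighted station.

    With probability ``p_recurrence_in_gross`` (and where gross disease
    exists in the chosen station) the center sits inside gross disease, so
    the event classifies as GTV-affected; otherwise anywhere in the station.
    A generous radius lets the ellipsoid straddle station boundaries, which
    is how multi-station events arise.
    """
    labels = list(effect.recurrence_station_weights)
    w = np.asarray([effect.recurrence_station_weights[l] for l in labels], dtype=float)
    lab = labels[int(rng.choice(len(labels), p=w / w.sum()))]
    i = station_index(lab)
    ln = ss.ln[i]
    g = ss.gtv | ss.gtvnd
    pool = ln & g if (rng.random() < effect.p_recurrence_in_gross and (ln & g).any()) else ln
    idx = np.argwhere(pool)
    vox = idx[int(rng.integers(len(idx)))]
    center = np.asarray(ss.grid.origin) + vox * np.asarray(ss.grid.spacing)
    radius = rng.uniform(4.0, 10.0)
    return rasterize_ellipsoid(ss.grid, center, radius), lab


_DERIVED_COVARIATES = {
    "large_tumor": lambda r: float(r.tumor_diameter_cm >= 5.0),
    "male": lambda r: float(r.sex == "male"),
    "age_ge60": lambda r: float(r.age_years >= 60.0),
}


def _covariate_value(rec: PatientRecord, name: str) -> float:
    if name in _DERIVED_COVARIATES:
        return _DERIVED_COVARIATES[name](rec)
    v = getattr(rec, name)
    return float(v)


def patient_hazard(rec: PatientRecord, effect: EffectSpec) -> float:
    """Event hazard (per month) for one patient under the planted model."""
    h = effect.baseline_hazard
    for name, hr in effect.hazard_ratio_per_unit.items():
        h *= hr ** _covariate_value(rec, name)
    return h


def generate_cohort(
    n: int,
    effect: EffectSpec | None = None,
    atlas_spec: AtlasSpec | None = None,
    seed: int = 0,
    gross_disease: str = "union",
) -> Cohort:
    """Generate ``n`` patients with planted outcome structure.

    The latent relapse label is Bernoulli in the planted logistic
    probability sigma(intercept + sum coef_j * feature_j) evaluated on the
    patient's own extracted 110-feature vector.  Latent relapsers receive an
    exponential event time at their covariate-dependent hazard; censoring is
    exponential at ``censoring_rate`` (none when 0); the *observed* relapse
    status — what the clinical record and every downstream stage see — is 1
    only when the event precedes censoring, and only then is a recurrence
    mask synthesized.  Patients who never relapse are censored at
    min(censoring draw, administrative window).  With ``censoring_rate=0``
    the observed status equals the latent label exactly.
    """
    if n < 2:
        raise ValueError("cohort size must be >= 2")
    effect = effect or EffectSpec()
    spec, ln_masks = generate_atlas(atlas_spec or AtlasSpec.default())
    truth = TruthRecord(effect=effect, seed=seed)
    patients: list[tuple[StructureSet, PatientRecord]] = []
    feature_rows: list[dict] = []
    for k in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        ss, rec = generate_patient((spec, ln_masks), effect, rng, patient_id=f"P{k:04d}")

        fv = extract_features(ss, rec, gross_disease=gross_disease)
        eta = effect.logit_intercept + sum(
            coef * fv[name] for name, coef in effect.logit_coefficients.items()
        )
        p = 1.0 / (1.0 + math.exp(-eta))
        latent = int(rng.random() < p)

        t_cens = (
            float(rng.exponential(1.0 / effect.censoring_rate))
            if effect.censoring_rate > 0 else math.inf
        )
        rec_station: Optional[str] = None
        t_event: Optional[float] = None
        if latent:
            t_event = float(rng.exponential(1.0 / patient_hazard(rec, effect)))
            rec.relapse = int(t_event <= t_cens)
            rec.followup_months = min(t_event, t_cens)
            if rec.relapse:
                rec_mask, rec_station = _synthesize_recurrence(ss, effect, rng)
                ss.recurrence = rec_mask
        else:
            rec.relapse = 0
            rec.followup_months = min(t_cens, effect.censoring_window_months)
        ss.patient = rec

        truth.linear_predictor.append(float(eta))
        truth.relapse_probability.append(float(p))
        truth.latent_relapse.append(latent)
        truth.involved_stations.append(
            [lab for _i, lab, m in ss.stations() if np.any(ss.gtvnd & m)]
        )
        truth.recurrence_station.append(rec_station)
        truth.event_time.append(t_event)
        truth.censor_time.append(None if math.isinf(t_cens) else t_cens)
        patients.append((ss, rec))
        row = dict(zip(fv.names, fv.values))
        row["relapse"] = rec.relapse
        feature_rows.append(row)
    features = pd.DataFrame(
        feature_rows, index=pd.Index([rec.id for _ss, rec in patients], name="id")
    )
    return Cohort(patients=patients, truth=truth, features=features)
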