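"""Shared fixtures: hand-built structure sets and reusable phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ctvrecur.mask_model import (
    N_STATIONS,
    PatientRecord,
    StructureSet,
    VoxelGrid,
)
from ctvrecur.phantoms import AtlasSpec, generate_atlas, generate_cohort

GRID48 = VoxelGrid((48, 48, 48), (1.5, 1.5, 1.5))
GRID64 = VoxelGrid((64, 64, 64), (1.5, 1.5, 1.5))

# Hand-laid station geometry for exact-value tests: sixteen 2x2x2 cubes on a
# 24^3 unit-spacing grid, arranged 4x4 in the (x, y) plane at z in [2, 4).
BOX_GRID = VoxelGrid((24, 24, 24), (1.0, 1.0, 1.0))


def station_box(i: int) -> tuple[slice, slice, slice]:
    """Index-space box of hand-laid station LN``i`` (1-based)."""
    row, col = divmod(i - 1, 4)
    x0, y0 = 2 + 5 * col, 2 + 5 * row
    return (slice(x0, x0 + 2), slice(y0, y0 + 2), slice(2, 4))


def build_box_ss(
    ctv: np.ndarray | None = None,
    gtv: np.ndarray | None = None,
    gtvnd: np.ndarray | None = None,
    recurrence: np.ndarray | None = None,
    patient: PatientRecord | None = None,
) -> StructureSet:
    """StructureSet on the hand-laid 16-cube atlas; omitted masks are empty."""
    def blank():
        return np.zeros(BOX_GRID.shape, dtype=bool)

    ln = {}
    for i in range(1, N_STATIONS + 1):
        m = blank()
        m[station_box(i)] = True
        ln[i] = m
    gtv = blank() if gtv is None else gtv
    gtvnd = blank() if gtvnd is None else gtvnd
    if ctv is None:
        ctv = gtv | gtvnd
    return StructureSet(
        grid=BOX_GRID, ctv=ctv, gtv=gtv, gtvnd=gtvnd, ln=ln,
        recurrence=recurrence,
        patient=patient or PatientRecord(id="T1", tumor_diameter_cm=4.0),
    )


def blank_box() -> np.ndarray:
    return np.zeros(BOX_GRID.shape, dtype=bool)


@pytest.fixture(scope="session")
def atlas48():
    return generate_atlas(AtlasSpec.default(GRID48))


@pytest.fixture(scope="session")
def atlas64():
    return generate_atlas(AtlasSpec.default(GRID64))


@pytest.fixture(scope="session")
def cohort64():
    """Sixty default-effect patients on a 64^3 lattice, reused read-only."""
    return generate_cohort(60, atlas_spec=AtlasSpec.default(GRID64), seed=7)
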