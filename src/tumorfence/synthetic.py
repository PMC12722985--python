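"""Synthetic slides and cohorts with known planted ground truth.

The generator emulates a ~1 mm² tumor microarray core: a disc-shaped tumor
region filled with tumor cells, non-tumor background cells scattered
uniformly outside the tumor, and a configurable number of planted *fences*
— tight arcs of one non-tumor phenotype hugging the tumor boundary (about
50 μm across, 20 per mm² by default, matching the size and density scale of
fences seen in tissue).  Fence cells are labelled ``fence`` in their
cell_id so tests can assert recovery of the planted structure.

Cohorts couple outcomes to fencing strength: responders receive many
planted fences, non-responders few, and survival times are exponential
with a configurable hazard ratio between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .data import CellRecord, Cohort, PatientOutcome, Slide

__all__ = [
    "SyntheticSlideConfig",
    "SyntheticCohortConfig",
    "generate_slide",
    "generate_null_slide",
    "generate_cohort",
    "generate_ics_slide",
    "planted_fence_ids",
]

TUMOR_LABEL = "Tumor"


@dataclass(frozen=True)
class SyntheticSlideConfig:
    """Geometry and intensities of one synthetic slide.

    Densities are homogeneous-Poisson intensities in cells per mm².  The
    tumor region is a disc centered in the slide; fences are arcs of
    ``fence_phenotype`` cells placed tangent to the tumor boundary at
    jittered angles, with one tumor cell anchored just inside the boundary
    beneath each fence so planted fences meet the fencing definition by
    construction.
    """

    extent: tuple[float, float] = (1000.0, 1000.0)
    tumor_radius: float = 300.0  # μm
    tumor_density: float = 1500.0  # cells per mm² inside the disc
    background_densities: Mapping[str, float] = field(
        default_factory=lambda: {"g": 300.0, "other": 700.0}
    )
    fence_phenotype: str = "g"
    n_fences: int = 20
    fence_diameter: float = 50.0  # μm arc span
    cells_per_fence: int = 8

    def __post_init__(self) -> None:
        if self.fence_phenotype == TUMOR_LABEL:
            raise ValueError("fence cells must be non-tumor")
        if self.n_fences > 0 and self.fence_phenotype not in self.background_densities:
            raise ValueError(
                "fence phenotype must be part of the background label set"
            )
        if any(d < 0 for d in self.background_densities.values()):
            raise ValueError("densities must be non-negative")


def _poisson_disc(rng, center, radius, density_mm2, extent):
    """Uniform points in a disc (homogeneous Poisson number)."""
    area_mm2 = np.pi * (radius / 1000.0) ** 2
    n = rng.poisson(density_mm2 * area_mm2)
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    pts = np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])
    return _clip(pts, extent)


def _poisson_outside_disc(rng, center, radius, density_mm2, extent):
    """Uniform points in the slide rectangle excluding the tumor disc."""
    w, h = extent
    area_mm2 = (w / 1000.0) * (h / 1000.0)
    n = rng.poisson(density_mm2 * area_mm2)
    pts = np.column_stack([rng.random(n) * w, rng.random(n) * h])
    d2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return pts[d2 > radius**2]


def _clip(pts, extent):
    w, h = extent
    keep = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
    return pts[keep]


def _fence_arcs(rng, cfg: SyntheticSlideConfig):
    """Fence-cell positions (list of arrays, one per fence) and the anchor
    tumor positions placed just inside the boundary under each fence."""
    cx = cfg.extent[0] / 2.0
    cy = cfg.extent[1] / 2.0
    R = cfg.tumor_radius
    arcs, anchors = [], []
    angles = rng.random(cfg.n_fences) * 2 * np.pi
    half_arc = (cfg.fence_diameter / 2.0) / R  # radians
    for th0 in angles:
        ths = np.linspace(th0 - half_arc, th0 + half_arc, cfg.cells_per_fence)
        rr = R + 10.0 + rng.normal(0.0, 2.0, cfg.cells_per_fence)
        pts = np.column_stack([cx + rr * np.cos(ths), cy + rr * np.sin(ths)])
        arcs.append(pts)
        anchors.append([cx + (R - 5.0) * np.cos(th0), cy + (R - 5.0) * np.sin(th0)])
    return arcs, np.array(anchors).reshape(-1, 2)


def generate_slide(
    cfg: SyntheticSlideConfig,
    seed: int,
    slide_id: str = "synthetic",
    patient_id: str | None = None,
) -> Slide:
    """Slide with planted boundary fences (ground truth in the cell ids)."""
    rng = np.random.default_rng(seed)
    center = (cfg.extent[0] / 2.0, cfg.extent[1] / 2.0)
    cells: list[CellRecord] = []

    arcs, anchors = (
        _fence_arcs(rng, cfg) if cfg.n_fences > 0 else ([], np.empty((0, 2)))
    )

    tum = _poisson_disc(rng, center, cfg.tumor_radius, cfg.tumor_density, cfg.extent)
    tum = np.vstack([tum, _clip(anchors, cfg.extent)])
    for i, (x, y) in enumerate(tum):
        cells.append(CellRecord(f"tum{i:05d}", x, y, TUMOR_LABEL, True))

    for label, dens in cfg.background_densities.items():
        pts = _poisson_outside_disc(rng, center, cfg.tumor_radius, dens, cfg.extent)
        for i, (x, y) in enumerate(pts):
            cells.append(CellRecord(f"bg_{label}_{i:05d}", x, y, label, False))

    k = 0
    for pts in arcs:
        for x, y in _clip(pts, cfg.extent):
            cells.append(
                CellRecord(f"fence{k:05d}", x, y, cfg.fence_phenotype, False)
            )
            k += 1

    return Slide(
        slide_id=slide_id,
        patient_id=patient_id if patient_id is not None else slide_id,
        cells=cells,
        extent=cfg.extent,
    )


def generate_null_slide(
    cfg: SyntheticSlideConfig,
    seed: int,
    slide_id: str = "null",
    patient_id: str | None = None,
) -> Slide:
    """Matched slide with NO planted structure: the would-be fence cells are
    scattered uniformly outside the tumor like any background cell.  Used
    for type-I-error calibration of the permutation test."""
    rng = np.random.default_rng(seed)
    center = (cfg.extent[0] / 2.0, cfg.extent[1] / 2.0)
    cells: list[CellRecord] = []

    tum = _poisson_disc(rng, center, cfg.tumor_radius, cfg.tumor_density, cfg.extent)
    for i, (x, y) in enumerate(tum):
        cells.append(CellRecord(f"tum{i:05d}", x, y, TUMOR_LABEL, True))

    # background plus the fence-cell budget, all unstructured
    extra = cfg.n_fences * cfg.cells_per_fence
    area_out = (cfg.extent[0] / 1000.0) * (cfg.extent[1] / 1000.0) - np.pi * (
        cfg.tumor_radius / 1000.0
    ) ** 2
    for label, dens in cfg.background_densities.items():
        eff = dens + (extra / area_out if label == cfg.fence_phenotype else 0.0)
        pts = _poisson_outside_disc(rng, center, cfg.tumor_radius, eff, cfg.extent)
        for i, (x, y) in enumerate(pts):
            cells.append(CellRecord(f"bg_{label}_{i:05d}", x, y, label, False))

    return Slide(
        slide_id=slide_id,
        patient_id=patient_id if patient_id is not None else slide_id,
        cells=cells,
        extent=cfg.extent,
    )


def planted_fence_ids(slide: Slide) -> set[str]:
    """cell_ids of planted fence cells (ground-truth recovery helper)."""
    return {c.cell_id for c in slide.cells if c.cell_id.startswith("fence")}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Two-group cohort with outcome coupled to planted fencing strength.

    Responders get ``fences_strong`` planted fences per slide and hazard
    ``hazard_ratio`` relative to non-responders (``fences_weak`` fences,
    baseline hazard 1/``mean_survival``).  Administrative censoring at
    ``censor_time``.
    """

    n_per_group: int = 40
    slide: SyntheticSlideConfig = SyntheticSlideConfig()
    fences_strong: int = 20
    fences_weak: int = 2
    hazard_ratio: float = 0.3
    mean_survival: float = 500.0  # time units, non-responder mean
    censor_time: float = 1500.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need >= 1 patient per group")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def generate_cohort(cfg: SyntheticCohortConfig, seed: int) -> Cohort:
    """Cohort of one slide per patient with coupled response and survival."""
    rng = np.random.default_rng(seed)
    slides: list[Slide] = []
    outcomes: dict[str, PatientOutcome] = {}
    groups = [("responder", cfg.fences_strong, cfg.hazard_ratio), (
        "non_responder", cfg.fences_weak, 1.0,
    )]
    pid = 0
    for name, n_fences, hr in groups:
        base = replace(cfg.slide, n_fences=n_fences)
        for _ in range(cfg.n_per_group):
            pid += 1
            patient = f"P{pid:03d}"
            s = generate_slide(
                base,
                seed=int(rng.integers(2**31 - 1)),
                slide_id=f"S{pid:03d}",
                patient_id=patient,
            )
            slides.append(s)
            hazard = hr / cfg.mean_survival
            t = rng.exponential(1.0 / hazard)
            event = t <= cfg.censor_time
            outcomes[patient] = PatientOutcome(
                patient_id=patient,
                group=name,
                survival_time=float(min(t, cfg.censor_time)),
                event=bool(event),
            )
    return Cohort(slides=slides, outcomes=outcomes)


def generate_ics_slide(
    n_tumor: int = 300,
    n_cd8: int = 30,
    tumor_radius: float = 250.0,
    cd8_band: tuple[float, float] = (265.0, 325.0),
    seed: int = 0,
) -> Slide:
    """Initial condition for the agent-based fence-implantation experiment:
    a tumor disc with cytotoxic CD8 cells scattered in an annulus just
    outside the boundary, where implanted fences will intercept them."""
    rng = np.random.default_rng(seed)
    cells: list[CellRecord] = []
    for i in range(n_tumor):
        r = tumor_radius * np.sqrt(rng.random())
        th = rng.random() * 2 * np.pi
        cells.append(
            CellRecord(
                f"tum{i:05d}",
                500.0 + r * np.cos(th),
                500.0 + r * np.sin(th),
                TUMOR_LABEL,
                True,
            )
        )
    lo, hi = cd8_band
    for i in range(n_cd8):
        r = lo + (hi - lo) * rng.random()
        th = rng.random() * 2 * np.pi
        x = float(np.clip(500.0 + r * np.cos(th), 0.0, 1000.0))
        y = float(np.clip(500.0 + r * np.sin(th), 0.0, 1000.0))
        cells.append(CellRecord(f"cd8_{i:05d}", x, y, "CD8", False))
    return Slide("ics_synthetic", "ics_synthetic", cells)
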