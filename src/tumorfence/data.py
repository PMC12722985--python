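"""Domain containers and I/O for spatial single-cell slide data.

A *slide* is a table of cell-nucleus centroids (μm) with per-cell phenotype
labels, typically a ~1 mm² tumor microarray core imaged at single-cell
resolution.  Coordinates use a bottom-left origin with y increasing upward;
every computation downstream is translation/rotation invariant, so the
choice is purely a documentation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "Slide",
    "PatientOutcome",
    "Cohort",
    "SlideFormat",
    "read_slide",
    "write_slide",
    "read_outcomes",
    "write_outcomes",
    "filter_eligible",
]


class SlideFormatError(ValueError):
    """Raised when a slide file does not match the expected column layout."""


@dataclass(frozen=True)
class CellRecord:
    """One cell: identifier, centroid position in μm, phenotype label."""

    cell_id: str
    x: float
    y: float
    phenotype: str
    is_tumor: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.x) or not np.isfinite(self.y):
            raise ValueError(f"cell {self.cell_id!r}: non-finite coordinates")
        if not self.phenotype:
            raise ValueError(f"cell {self.cell_id!r}: empty phenotype")


@dataclass
class Slide:
    """A single tissue region: a collection of cells within a known extent."""

    slide_id: str
    patient_id: str
    cells: list[CellRecord]
    extent: tuple[float, float] = (1000.0, 1000.0)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError(f"slide {self.slide_id!r}: duplicate cell_ids")
        w, h = self.extent
        for c in self.cells:
            if not (0.0 <= c.x <= w and 0.0 <= c.y <= h):
                raise ValueError(
                    f"slide {self.slide_id!r}: cell {c.cell_id!r} at "
                    f"({c.x}, {c.y}) outside extent {self.extent}"
                )

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def area_mm2(self) -> float:
        w, h = self.extent
        return (w / 1000.0) * (h / 1000.0)

    def positions(self) -> np.ndarray:
        """(n, 2) float array of centroid coordinates in μm."""
        return np.array([[c.x, c.y] for c in self.cells], dtype=float).reshape(-1, 2)

    def phenotypes(self) -> np.ndarray:
        return np.array([c.phenotype for c in self.cells], dtype=object)

    def tumor_mask(self) -> np.ndarray:
        return np.array([c.is_tumor for c in self.cells], dtype=bool)

    def n_phenotype(self, phenotype: str) -> int:
        return sum(c.phenotype == phenotype for c in self.cells)

    @property
    def n_tumor(self) -> int:
        return int(self.tumor_mask().sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "x": [c.x for c in self.cells],
                "y": [c.y for c in self.cells],
                "phenotype": [c.phenotype for c in self.cells],
                "is_tumor": [c.is_tumor for c in self.cells],
            }
        )


@dataclass(frozen=True)
class PatientOutcome:
    """Clinical outcome for one patient.

    ``group`` is a categorical outcome (e.g. responder / non-responder, or
    primary / metastasis).  ``survival_time`` and ``event`` travel together:
    either both present or both absent.
    """

    patient_id: str
    group: str
    survival_time: float | None = None
    event: bool | None = None

    def __post_init__(self) -> None:
        if (self.survival_time is None) != (self.event is None):
            raise ValueError(
                f"patient {self.patient_id!r}: survival_time and event must "
                "be present together"
            )
        if self.survival_time is not None and self.survival_time < 0:
            raise ValueError(f"patient {self.patient_id!r}: negative survival_time")


@dataclass
class Cohort:
    """Slides plus per-patient outcomes."""

    slides: list[Slide]
    outcomes: dict[str, PatientOutcome] = field(default_factory=dict)

    def require_outcomes(self) -> None:
        missing = {s.patient_id for s in self.slides} - set(self.outcomes)
        if missing:
            raise KeyError(f"patients without outcomes: {sorted(missing)}")


@dataclass(frozen=True)
class SlideFormat:
    """Column-name mapping for slide CSV files."""

    cell_id: str = "cell_id"
    x: str = "x"
    y: str = "y"
    phenotype: str = "phenotype"


def _tumor_labels(tumor_label: str | Sequence[str]) -> set[str]:
    if isinstance(tumor_label, str):
        return {tumor_label}
    return set(tumor_label)


def read_slide(
    path,
    *,
    tumor_label: str | Sequence[str] = "Tumor",
    fmt: SlideFormat = SlideFormat(),
    slide_id: str | None = None,
    patient_id: str | None = None,
    extent: tuple[float, float] = (1000.0, 1000.0),
) -> Slide:
    """Read a slide from a delimited text file with a header row.

    ``tumor_label`` may be a single label or a list of labels; a cell is a
    tumor cell iff its phenotype is in that set.
    """
    df = pd.read_csv(path)
    required = [fmt.cell_id, fmt.x, fmt.y, fmt.phenotype]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SlideFormatError(f"{path}: missing column(s) {missing}")
    tumor = _tumor_labels(tumor_label)
    cells = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            x = float(raw[fmt.x])
            y = float(raw[fmt.y])
        except (TypeError, ValueError) as exc:
            raise SlideFormatError(f"{path}: non-numeric coordinate at row {i}") from exc
        ph = str(raw[fmt.phenotype])
        cells.append(
            CellRecord(
                cell_id=str(raw[fmt.cell_id]),
                x=x,
                y=y,
                phenotype=ph,
                is_tumor=ph in tumor,
            )
        )
    name = slide_id if slide_id is not None else _stem(path)
    return Slide(
        slide_id=name,
        patient_id=patient_id if patient_id is not None else name,
        cells=cells,
        extent=extent,
    )


def write_slide(slide: Slide, path, fmt: SlideFormat = SlideFormat()) -> None:
    df = slide.to_frame().rename(
        columns={
            "cell_id": fmt.cell_id,
            "x": fmt.x,
            "y": fmt.y,
            "phenotype": fmt.phenotype,
        }
    )
    df.drop(columns=["is_tumor"]).to_csv(path, index=False)


def read_outcomes(path) -> dict[str, PatientOutcome]:
    """Read an outcome table: patient_id, group, optional survival_time/event."""
    df = pd.read_csv(path)
    for col in ("patient_id", "group"):
        if col not in df.columns:
            raise SlideFormatError(f"{path}: missing column {col!r}")
    has_surv = "survival_time" in df.columns and "event" in df.columns
    out: dict[str, PatientOutcome] = {}
    for row in df.itertuples(index=False):
        raw = dict(zip(df.columns, row))
        pid = str(raw["patient_id"])
        st, ev = None, None
        if has_surv and pd.notna(raw["survival_time"]):
            st = float(raw["survival_time"])
            ev = bool(int(raw["event"]))
        out[pid] = PatientOutcome(pid, str(raw["group"]), st, ev)
    return out


def write_outcomes(outcomes: Mapping[str, PatientOutcome], path) -> None:
    rows = []
    for o in outcomes.values():
        rows.append(
            {
                "patient_id": o.patient_id,
                "group": o.group,
                "survival_time": o.survival_time,
                "event": int(o.event) if o.event is not None else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_eligible(
    slide: Slide,
    phenotype: str,
    min_g: int = 50,
    min_tumor: int = 50,
) -> bool:
    """Slide eligibility for a fencing analysis of ``phenotype``.

    A slide qualifies when it carries at least ``min_g`` cells of the queried
    (non-tumor) phenotype and at least ``min_tumor`` tumor cells; slides below
    either floor give too-noisy enrichment statistics and are skipped.
    """
    tumor_phenos = {c.phenotype for c in slide.cells if c.is_tumor}
    if phenotype in tumor_phenos:
        raise ValueError(f"{phenotype!r} is a tumor label, not a fencing phenotype")
    return slide.n_phenotype(phenotype) >= min_g and slide.n_tumor >= min_tumor


def _stem(path) -> str:
    import os

    base = os.path.basename(str(path))
    return os.path.splitext(base)[0]
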