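"""Cohort tables, summary statistics and per-cell infiltration frequency maps.

The cohort CSV schema follows the source study's per-patient table: one row
per patient with gender, age, histology (A astrocytoma / O oligodendroglioma),
WHO grade (2/3), side (R/L/B), local radiological anatomy (free text,
carried as an input annotation), margin phenotype (B bulky / D diffuse),
tumor volume in cm^3, infiltrated grid-voxel count, onset, procedure
(R resection / B biopsy) and number of MRI studies.  An optional ``cells``
column (semicolon-separated labels) attaches explicit per-patient cell sets
for frequency mapping.

Frequency maps bin per-cell infiltration frequency on the published color
scale: white 0-5%, then light and medium shades, intense orange from the
50% high-frequency cut-off, dark red above 80%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import GridLabel

__all__ = [
    "CohortRecord",
    "FrequencyMap",
    "load_cohort_table",
    "default_cohort_table",
    "cohort_summary",
    "frequency_map",
    "frequency_bin",
    "FREQUENCY_BINS",
]

#: (low, high, low_closed, high_closed, bin name) in percent; edges tile [0, 100].
FREQUENCY_BINS = (
    (0.0, 5.0, True, True, "white (0-5%)"),
    (5.0, 25.0, False, True, "light (5-25%)"),
    (25.0, 50.0, False, False, "medium (25-50%)"),
    (50.0, 80.0, True, True, "intense orange (50-80%)"),
    (80.0, 100.0, False, True, "dark red (>80%)"),
)

HIGH_FREQUENCY_CUTOFF = 0.50

_CODES = {
    "gender": {"M", "F"},
    "histology": {"A", "O"},
    "side": {"R", "L", "B"},
    "margins": {"B", "D"},
    "procedure": {"R", "B"},
}

_REQUIRED_COLUMNS = [
    "patient_id", "gender", "age", "histology", "who_grade", "side",
    "local_anatomy", "margins", "volume_cm3", "bg_voxels", "onset",
    "procedure", "n_mri",
]


@dataclass
class CohortRecord:
    patient_id: str
    gender: str
    age: float
    histology: str
    who_grade: int
    side: str
    local_anatomy: str
    margins: str
    volume_cm3: float
    bg_voxels: int
    onset: str
    procedure: str
    n_mri: int
    cells: Optional[frozenset[GridLabel]] = None
    row: Optional[int] = None  # 1-based data row for error reporting

    def __post_init__(self) -> None:
        where = f"row {self.row}" if self.row is not None else f"patient {self.patient_id}"
        for col, valid in _CODES.items():
            if getattr(self, col) not in valid:
                raise ValueError(
                    f"{where}, column {col}: invalid code {getattr(self, col)!r} "
                    f"(valid: {sorted(valid)})"
                )
        if self.who_grade not in (2, 3):
            raise ValueError(f"{where}, column who_grade: {self.who_grade!r} not in (2, 3)")
        if not np.isfinite(self.volume_cm3) or self.volume_cm3 <= 0:
            raise ValueError(f"{where}, column volume_cm3: must be a positive number")
        if not 1 <= self.bg_voxels <= 48:
            raise ValueError(f"{where}, column bg_voxels: {self.bg_voxels} outside 1..48")
        if self.cells is not None and len(self.cells) != self.bg_voxels:
            raise ValueError(
                f"{where}: cells lists {len(self.cells)} labels but bg_voxels is "
                f"{self.bg_voxels}"
            )


def load_cohort_table(path) -> list[CohortRecord]:
    """Parse and validate a cohort CSV; errors name the row and column."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for i, r in df.iterrows():
        row = i + 1
        def num(col, cast, r=r, row=row):
            try:
                return cast(r[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name} row {row}, column {col}: non-numeric value {r[col]!r}"
                ) from None
        cells = None
        if "cells" in df.columns and r.get("cells", "").strip():
            cells = frozenset(
                GridLabel.parse(tok) for tok in r["cells"].split(";") if tok.strip()
            )
        records.append(
            CohortRecord(
                patient_id=str(r["patient_id"]).strip(),
                gender=r["gender"].strip(),
                age=num("age", float),
                histology=r["histology"].strip(),
                who_grade=num("who_grade", int),
                side=r["side"].strip(),
                local_anatomy=r["local_anatomy"].strip(),
                margins=r["margins"].strip(),
                volume_cm3=num("volume_cm3", float),
                bg_voxels=num("bg_voxels", int),
                onset=r["onset"].strip(),
                procedure=r["procedure"].strip(),
                n_mri=num("n_mri", int),
                cells=cells,
                row=row,
            )
        )
    return records


def default_cohort_table() -> list[CohortRecord]:
    """The shipped transcription of the source study's 39-patient table."""
    with resources.as_file(
        resources.files("braingrid.data").joinpath("cohort_table1.csv")
    ) as p:
        return load_cohort_table(p)


def _stats(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean_display": round(float(arr.mean()), 1),
    }


def cohort_summary(records: Sequence[CohortRecord]) -> dict:
    """Counts and means over a cohort, raw values plus one-decimal display.

    Subgroup means are reported for bulky/diffuse margins and WHO grade
    II/III; counts cover histology x grade, margins, side and procedure.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")

    def count(pred: Callable[[CohortRecord], bool]) -> int:
        return sum(1 for r in records if pred(r))

    def subgroup(pred: Callable[[CohortRecord], bool]) -> dict:
        sub = [r for r in records if pred(r)]
        if not sub:
            return {"n": 0}
        return {
            "n": len(sub),
            "bg_voxels": _stats([r.bg_voxels for r in sub]),
            "volume_cm3": _stats([r.volume_cm3 for r in sub]),
        }

    return {
        "n_patients": len(records),
        "histology": {
            "A": count(lambda r: r.histology == "A"),
            "O": count(lambda r: r.histology == "O"),
            "A_grade2": count(lambda r: r.histology == "A" and r.who_grade == 2),
            "A_grade3": count(lambda r: r.histology == "A" and r.who_grade == 3),
            "O_grade2": count(lambda r: r.histology == "O" and r.who_grade == 2),
            "O_grade3": count(lambda r: r.histology == "O" and r.who_grade == 3),
        },
        "margins": {
            "bulky": count(lambda r: r.margins == "B"),
            "diffuse": count(lambda r: r.margins == "D"),
        },
        "side": {
            "L": count(lambda r: r.side == "L"),
            "R": count(lambda r: r.side == "R"),
            "B": count(lambda r: r.side == "B"),
        },
        "procedure": {
            "resection": count(lambda r: r.procedure == "R"),
            "biopsy": count(lambda r: r.procedure == "B"),
        },
        "age": _stats([r.age for r in records]),
        "volume_cm3": _stats([r.volume_cm3 for r in records]),
        "bg_voxels": _stats([r.bg_voxels for r in records]),
        "total_infiltrated_voxels": int(sum(r.bg_voxels for r in records)),
        "n_mri_total": int(sum(r.n_mri for r in records)),
        "subgroups": {
            "bulky": subgroup(lambda r: r.margins == "B"),
            "diffuse": subgroup(lambda r: r.margins == "D"),
            "grade2": subgroup(lambda r: r.who_grade == 2),
            "grade3": subgroup(lambda r: r.who_grade == 3),
        },
    }


def frequency_bin(frequency: float) -> str:
    """Bin name on the published color scale for a frequency in [0, 1]."""
    pct = frequency * 100.0
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"frequency {frequency!r} outside [0, 1]")
    for lo, hi, lo_closed, hi_closed, name in FREQUENCY_BINS:
        above = pct >= lo if lo_closed else pct > lo
        below = pct <= hi if hi_closed else pct < hi
        if above and below:
            return name
    raise AssertionError("bins do not cover [0, 100]")  # pragma: no cover


@dataclass
class FrequencyMap:
    """Per-cell infiltration frequency for one cohort stratum."""

    frequencies: dict[GridLabel, float]
    stratum: str
    n_records: int
    bins: dict[GridLabel, str] = field(init=False)
    high_frequency: frozenset[GridLabel] = field(init=False)

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.frequencies.values()):
            raise ValueError("frequencies must lie in [0, 1]")
        self.bins = {lb: frequency_bin(f) for lb, f in self.frequencies.items()}
        self.high_frequency = frozenset(
            lb for lb, f in self.frequencies.items() if f >= HIGH_FREQUENCY_CUTOFF
        )

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n_records": self.n_records,
            "cells": {
                str(lb): {
                    "frequency": self.frequencies[lb],
                    "bin": self.bins[lb],
                    "high_frequency": lb in self.high_frequency,
                }
                for lb in sorted(self.frequencies, key=lambda x: x.id)
            },
        }

    def plot(self, ax=None):
        """Render the axial C2-slab view of the map with the color gradient."""
        import matplotlib.pyplot as plt
        from matplotlib import colors

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        img = np.zeros((4, 4))  # rows: S1..S4, cols: A1..A4
        for lb, f in self.frequencies.items():
            if lb.c == 2:
                img[lb.s - 1, lb.a - 1] = f
        cmap = colors.LinearSegmentedColormap.from_list(
            "braingrid", ["white", "orange", "darkred"]
        )
        im = ax.imshow(img, cmap=cmap, vmin=0, vmax=1)
        ax.set_xticks(range(4), [f"A{i}" for i in range(1, 5)])
        ax.set_yticks(range(4), [f"S{i}" for i in range(1, 5)])
        ax.set_title(f"Infiltration frequency, C2 slab ({self.stratum})")
        plt.colorbar(im, ax=ax, label="frequency")
        return ax


def frequency_map(
    records: Sequence[CohortRecord],
    stratum: str = "all",
    predicate: Optional[Callable[[CohortRecord], bool]] = None,
) -> FrequencyMap:
    """Per-cell frequency over the records matching ``predicate``.

    Every selected record must carry an explicit cell set; frequency(cell) =
    share of selected records whose cells contain it, over all 48 cells.
    """
    selected = [r for r in records if predicate is None or predicate(r)]
    if not selected:
        raise ValueError(f"stratum {stratum!r} selects no records")
    missing = [r.patient_id for r in selected if r.cells is None]
    if missing:
        raise ValueError(
            f"records without explicit cell sets cannot enter a frequency map: "
            f"patients {', '.join(missing)}"
        )
    n = len(selected)
    freqs = {
        GridLabel.from_id(i): sum(1 for r in selected if GridLabel.from_id(i) in r.cells) / n
        for i in range(1, 49)
    }
    return FrequencyMap(frequencies=freqs, stratum=stratum, n_records=n)
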