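"""White-matter tract <-> grid-cell association table.

The shipped default table summarizes, per structure, which of the 48 grid
cells the tract traverses in MNI space.  The inventory holds 34 entries:
the corpus callosum split into genu/body/splenium, the anterior commissure
and fornix at the midline, fourteen bilateral tract names, and the vertical
SLF segment encoded once with hemisphere-pooled cells (a bookkeeping device
recorded in the provenance column).  Queries answer "which structures are at
risk given these infiltrated cells"; :func:`build_table_from_masks` rebuilds
a table from any per-tract mask atlas.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .classify import classify_mask
from .grid import BrainGrid, GridLabel
from .image_io import VolumeMask

__all__ = [
    "TractEntry",
    "TractTable",
    "load_tract_table",
    "default_tract_table",
    "tracts_in_cells",
    "cells_of_tract",
    "build_table_from_masks",
]

_HEMISPHERES = ("L", "R", "midline")
_CATEGORIES = ("commissural", "projection", "associative")
_COLUMNS = ["name", "hemisphere", "category", "cells", "provenance"]


@dataclass(frozen=True)
class TractEntry:
    """One white-matter structure and the grid cells it traverses."""

    name: str
    hemisphere: str
    category: str
    cells: frozenset[GridLabel]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.hemisphere not in _HEMISPHERES:
            raise ValueError(
                f"{self.name}: hemisphere {self.hemisphere!r} not in {_HEMISPHERES}"
            )
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"{self.name}: unknown category {self.category!r}; valid: {_CATEGORIES}"
            )
        if not self.cells:
            raise ValueError(f"{self.name} ({self.hemisphere}): empty cell set")
        object.__setattr__(self, "cells", frozenset(self.cells))

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.hemisphere)

    @property
    def display_name(self) -> str:
        return self.name if self.hemisphere == "midline" else f"{self.name}-{self.hemisphere}"


@dataclass
class TractTable:
    entries: list[TractEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.key in seen:
                raise ValueError(f"duplicate structure entry {e.display_name}")
            seen.add(e.key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str, hemisphere: str | None = None) -> TractEntry:
        matches = [
            e for e in self.entries
            if e.name == name and (hemisphere is None or e.hemisphere == hemisphere)
        ]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise KeyError(
                f"{name!r} is ambiguous without a hemisphere; "
                f"candidates: {', '.join(e.display_name for e in matches)}"
            )
        known = sorted({e.name for e in self.entries})
        near = difflib.get_close_matches(name, known, n=3)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise KeyError(f"unknown structure {name!r}{hint}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": e.name,
                "hemisphere": e.hemisphere,
                "category": e.category,
                "cells": ";".join(str(lb) for lb in sorted(e.cells, key=lambda x: x.id)),
                "provenance": e.provenance,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _parse_cells(text: str, where: str) -> frozenset[GridLabel]:
    labels = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            labels.append(GridLabel.parse(token))
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
    return frozenset(labels)


def load_tract_table(path, provenance: str | None = None) -> TractTable:
    """Load a TSV table (columns: name, hemisphere, category, cells[, provenance])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    entries = []
    for i, row in df.iterrows():
        where = f"{path.name} line {i + 2}"  # 1-based + header
        try:
            entries.append(
                TractEntry(
                    name=row["name"].strip(),
                    hemisphere=row["hemisphere"].strip(),
                    category=row["category"].strip(),
                    cells=_parse_cells(row["cells"], where),
                    provenance=str(row.get("provenance", "")).strip(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
    try:
        return TractTable(entries=entries, provenance=provenance or str(path))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def default_tract_table() -> TractTable:
    """The shipped 34-structure table (HCP-template atlas summarized per cell)."""
    with resources.as_file(
        resources.files("braingrid.data").joinpath("tract_table.tsv")
    ) as p:
        return load_tract_table(p, provenance="literature-encoded")


def tracts_in_cells(
    cells: Iterable[GridLabel | str],
    table: TractTable | None = None,
) -> list[tuple[TractEntry, int]]:
    """Structures whose cell sets intersect the query, ranked by overlap.

    Returns (entry, n_shared_cells) pairs sorted by decreasing overlap,
    ties broken by canonical display name.
    """
    if table is None:
        table = default_tract_table()
    query = {c if isinstance(c, GridLabel) else GridLabel.parse(c) for c in cells}
    hits = [
        (e, len(e.cells & query)) for e in table.entries if e.cells & query
    ]
    hits.sort(key=lambda pair: (-pair[1], pair[0].display_name))
    return hits


def cells_of_tract(
    name: str,
    hemisphere: str | None = None,
    table: TractTable | None = None,
) -> frozenset[GridLabel]:
    """Grid cells traversed by one structure; unknown names get suggestions."""
    if table is None:
        table = default_tract_table()
    return table.get(name, hemisphere).cells


def build_table_from_masks(
    tract_masks: Mapping[tuple[str, str] | str, VolumeMask],
    grid: BrainGrid,
    min_overlap_mm3: float = 0.0,
    category: str | Mapping = "associative",
) -> TractTable:
    """Summarize per-tract masks into a table for any user atlas.

    Keys are ``(name, hemisphere)`` pairs (a bare name implies midline); a
    cell joins an entry when the mask's overlap volume exceeds the threshold.
    Empty masks are rejected with the offending name.
    """
    entries = []
    for key, mask in tract_masks.items():
        name, hemi = key if isinstance(key, tuple) else (key, "midline")
        report = classify_mask(mask, grid, min_overlap_mm3=min_overlap_mm3)
        if report.n_cells == 0:
            raise ValueError(f"tract mask {name} ({hemi}): no cells above threshold")
        cat = category[key] if isinstance(category, Mapping) else category
        entries.append(
            TractEntry(
                name=name,
                hemisphere=hemi,
                category=cat,
                cells=report.cells,
                provenance=f"mask-derived (min_overlap_mm3={min_overlap_mm3:g})",
            )
        )
    return TractTable(
        entries=entries,
        provenance=f"built from {len(entries)} tract masks in {grid.space_tag} space",
    )
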