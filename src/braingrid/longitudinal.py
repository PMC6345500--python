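"""Serial-study comparison: progression deltas and white-matter spread routes.

Comparing two infiltration reports of the same patient gives the cells
gained, lost and stable plus the volume change.  For each newly infiltrated
cell, candidate spread routes pair it with every face-adjacent baseline cell
and list the structures whose cell sets contain both endpoints — the
tract-informed reading of "the tumor crossed into this cell along these
fibers".  Gained cells with no infiltrated neighbor are flagged as
non-contiguous appearances rather than assigned a route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .classify import InfiltrationReport
from .grid import GridLabel
from .tracts import TractTable, default_tract_table

__all__ = [
    "ProgressionDelta",
    "SpreadRoute",
    "RouteAnalysis",
    "compare_reports",
    "progression_routes",
]


@dataclass(frozen=True)
class SpreadRoute:
    """One proposed spread step: baseline cell -> gained cell along tracts."""

    from_cell: GridLabel
    to_cell: GridLabel
    shared_structures: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.from_cell not in self.to_cell.neighbors():
            raise ValueError(
                f"route {self.from_cell}->{self.to_cell} is not face-adjacent"
            )


@dataclass
class ProgressionDelta:
    """Cell-set and volume differences between two serial studies."""

    gained: frozenset[GridLabel]
    lost: frozenset[GridLabel]
    stable: frozenset[GridLabel]
    volume_change_cm3: float
    interval: tuple[str, str]
    cell_volume_changes_mm3: dict[GridLabel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.gained & self.lost) or (self.gained & self.stable) or (self.lost & self.stable):
            raise ValueError("gained, lost and stable must be disjoint")

    def to_dict(self) -> dict:
        key = lambda lb: lb.id
        return {
            "interval": list(self.interval),
            "gained": [str(lb) for lb in sorted(self.gained, key=key)],
            "lost": [str(lb) for lb in sorted(self.lost, key=key)],
            "stable": [str(lb) for lb in sorted(self.stable, key=key)],
            "volume_change_cm3": self.volume_change_cm3,
            "cell_volume_changes_mm3": {
                str(lb): v for lb, v in sorted(
                    self.cell_volume_changes_mm3.items(), key=lambda kv: kv[0].id
                )
            },
        }


@dataclass
class RouteAnalysis:
    """Spread routes for the gained cells of one progression step."""

    routes: list[SpreadRoute]
    non_contiguous: frozenset[GridLabel]

    def to_dict(self) -> dict:
        return {
            "routes": [
                {
                    "from": str(r.from_cell),
                    "to": str(r.to_cell),
                    "shared_structures": list(r.shared_structures),
                }
                for r in self.routes
            ],
            "non_contiguous": [str(lb) for lb in sorted(self.non_contiguous, key=lambda x: x.id)],
        }


def compare_reports(
    earlier: InfiltrationReport, later: InfiltrationReport
) -> ProgressionDelta:
    """Set differences and volume change between two serial reports.

    Both reports must be classified in the same space; when both carry
    acquisition dates the earlier report must not post-date the later one.
    """
    if earlier.space_tag != later.space_tag:
        raise ValueError(
            f"cannot compare reports across spaces "
            f"({earlier.space_tag} vs {later.space_tag})"
        )
    if (
        earlier.acquisition_date
        and later.acquisition_date
        and earlier.acquisition_date > later.acquisition_date
    ):
        raise ValueError("earlier report post-dates the later report")
    before, after = earlier.cells, later.cells
    stable = before & after
    return ProgressionDelta(
        gained=frozenset(after - before),
        lost=frozenset(before - after),
        stable=frozenset(stable),
        volume_change_cm3=later.total_volume_cm3 - earlier.total_volume_cm3,
        interval=(earlier.study_id, later.study_id),
        cell_volume_changes_mm3={
            lb: later.cell_volumes[lb] - earlier.cell_volumes[lb] for lb in stable
        },
    )


def progression_routes(
    delta: ProgressionDelta,
    baseline_cells: Iterable[GridLabel] | None = None,
    table: Optional[TractTable] = None,
) -> RouteAnalysis:
    """Propose white-matter spread routes for the gained cells.

    Routes run only along face adjacency (including the trans-callosal
    A2<->A3 step); each (baseline cell, gained cell) pair carries the
    structures whose stored cell sets contain both endpoints.  By default
    the baseline is the delta's stable set.
    """
    if table is None:
        table = default_tract_table()
    baseline = frozenset(baseline_cells) if baseline_cells is not None else delta.stable
    routes: list[SpreadRoute] = []
    non_contiguous: set[GridLabel] = set()
    for gained in sorted(delta.gained, key=lambda lb: lb.id):
        sources = sorted(gained.neighbors() & baseline, key=lambda lb: lb.id)
        if not sources:
            non_contiguous.add(gained)
            continue
        for src in sources:
            shared = sorted(
                e.display_name
                for e in table.entries
                if gained in e.cells and src in e.cells
            )
            routes.append(
                SpreadRoute(
                    from_cell=src, to_cell=gained, shared_structures=tuple(shared)
                )
            )
    return RouteAnalysis(routes=routes, non_contiguous=frozenset(non_contiguous))
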