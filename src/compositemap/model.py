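"""Domain model for component and composite genetic linkage maps.

A *component map* is an independently constructed linkage map: a set of
linkage groups (LGs), each an ordered list of markers at centiMorgan (cM)
positions.  A *composite map* integrates several component maps by merging
markers onto a fixed seed backbone via anchor-marker regression; every
composite locus carries provenance (which component maps support it and in
which merge round it was placed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "MarkerType",
    "MarkerLocus",
    "ComponentMap",
    "LGComparison",
    "Projection",
    "CompositeLocus",
    "CompositeMap",
    "MergeRound",
    "ChiSquareResult",
    "MapFormatError",
]

# Marker technologies seen on these maps.  DArT (Diversity Arrays Technology)
# dominates; SSR = microsatellite; "gene" = gene-based marker.
MARKER_TYPES = ("DArT", "SSR", "gene", "other")


class MapFormatError(ValueError):
    """Raised when an input map violates the format or its invariants."""


def normalize_marker_type(value: str | None) -> str:
    if value is None or value == "":
        return "DArT"
    for t in MARKER_TYPES:
        if value.lower() == t.lower():
            return t
    return "other"


@dataclass(frozen=True)
class MarkerLocus:
    """One marker at one map position on one linkage group."""

    name: str
    linkage_group: str
    position: float  # cM
    marker_type: str = "DArT"

    def __post_init__(self) -> None:
        if not self.name:
            raise MapFormatError("marker name must be non-empty")
        if not math.isfinite(self.position) or self.position < 0:
            raise MapFormatError(
                f"marker {self.name!r}: position must be a finite non-negative "
                f"number of cM, got {self.position!r}"
            )


@dataclass
class ComponentMap:
    """An input linkage map: ordered marker lists per linkage group.

    ``linkage_groups`` maps LG identifier -> loci sorted by non-decreasing
    position.  ``family_size`` is the number of progeny in the mapping
    pedigree (used only for seed-map tie-breaking and reporting).
    """

    map_id: str
    linkage_groups: dict[str, list[MarkerLocus]]
    family_size: int | None = None

    def __post_init__(self) -> None:
        if not self.linkage_groups:
            raise MapFormatError(f"map {self.map_id!r}: at least one linkage group required")
        for lg, loci in self.linkage_groups.items():
            seen: set[str] = set()
            for a, b in zip(loci, loci[1:]):
                if b.position < a.position:
                    raise MapFormatError(
                        f"map {self.map_id!r} LG {lg!r}: loci not sorted by position"
                    )
            for locus in loci:
                if locus.name in seen:
                    raise MapFormatError(
                        f"map {self.map_id!r} LG {lg!r}: duplicate locus {locus.name!r}"
                    )
                seen.add(locus.name)

    def loci(self) -> Iterator[MarkerLocus]:
        for loci in self.linkage_groups.values():
            yield from loci

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.linkage_groups.values())

    @property
    def marker_names(self) -> set[str]:
        return {locus.name for locus in self.loci()}

    def lg_length(self, lg: str) -> float:
        loci = self.linkage_groups[lg]
        return loci[-1].position - loci[0].position if loci else 0.0

    def normalize_lg_starts(self) -> "ComponentMap":
        """Return a copy with each LG rigidly shifted so its minimum position is 0."""
        groups = {}
        for lg, loci in self.linkage_groups.items():
            shift = loci[0].position if loci else 0.0
            groups[lg] = [
                MarkerLocus(l.name, l.linkage_group, l.position - shift, l.marker_type)
                for l in loci
            ]
        return ComponentMap(self.map_id, groups, self.family_size)


@dataclass
class LGComparison:
    """Shared-marker statistics for one building-LG vs component-LG pair.

    ``fit_value`` is the selection heuristic |rho| x log(n_common): the
    correlation term rewards order agreement, the log term rewards anchor
    count with diminishing returns.  It is 0 for a single shared marker and
    undefined (None) when nothing is shared or rho cannot be computed.
    """

    building_lg: str
    component_map_id: str
    component_lg: str
    n_common: int
    rho: float | None
    orientation: str  # "forward" | "reversed"
    fit_value: float | None

    def __post_init__(self) -> None:
        if self.n_common < 0:
            raise ValueError("n_common must be >= 0")
        if self.rho is not None and abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")


@dataclass
class Projection:
    """Least-squares line pc = m * pi + c mapping component positions (pi)
    onto building-composite positions (pc)."""

    slope: float
    intercept: float
    residual_rmse: float
    n_anchors: int

    def __post_init__(self) -> None:
        if self.n_anchors < 2:
            raise ValueError("a defined projection needs >= 2 anchors")
        if self.residual_rmse < 0:
            raise ValueError("residual_rmse must be >= 0")

    def predict(self, pi: float) -> float:
        return self.slope * pi + self.intercept


@dataclass
class CompositeLocus:
    """A marker placed on the composite map, with provenance."""

    name: str
    linkage_group: str
    position: float  # cM; may be negative transiently during building
    marker_type: str = "DArT"
    support: set[str] = field(default_factory=set)  # component map ids
    added_in_round: int = 0  # 0 = seed backbone
    is_multicopy: bool = False  # occupies >= 2 LGs in the composite

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError(f"composite locus {self.name!r} has empty support")


@dataclass
class MergeRound:
    """Audit record of one merge round on one building linkage group."""

    building_lg: str
    round_index: int
    component_map_id: str
    component_lg: str
    n_common: int
    rho: float
    orientation: str
    fit_value: float
    slope: float
    intercept: float
    residual_rmse: float
    markers_added: int
    markers_skipped: int

    def __post_init__(self) -> None:
        if self.markers_added < 0 or self.markers_skipped < 0:
            raise ValueError("marker counts must be >= 0")


@dataclass
class CompositeMap:
    """The merged map: composite loci per LG plus the merge audit trail."""

    linkage_groups: dict[str, list[CompositeLocus]]
    merge_log: list[MergeRound] = field(default_factory=list)
    seed_map_id: str | None = None

    def loci(self) -> Iterator[CompositeLocus]:
        for loci in self.linkage_groups.values():
            yield from loci

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.linkage_groups.values())

    @property
    def distinct_markers(self) -> set[str]:
        return {locus.name for locus in self.loci()}

    def copies_per_marker(self) -> dict[str, int]:
        """Number of distinct LGs each marker occupies."""
        lgs: dict[str, set[str]] = {}
        for lg, loci in self.linkage_groups.items():
            for locus in loci:
                lgs.setdefault(locus.name, set()).add(lg)
        return {name: len(s) for name, s in lgs.items()}

    def annotate_multicopy(self) -> None:
        copies = self.copies_per_marker()
        for locus in self.loci():
            locus.is_multicopy = copies[locus.name] >= 2

    def check_position_accounting(self) -> None:
        """positions == distinct markers + sum(copies - 1) over multicopy markers."""
        copies = self.copies_per_marker()
        expected = len(copies) + sum(c - 1 for c in copies.values() if c >= 2)
        if expected != self.n_positions:
            raise AssertionError(
                f"position accounting violated: {self.n_positions} positions vs "
                f"{expected} = distinct + extra copies"
            )


@dataclass
class ChiSquareResult:
    """Goodness-of-fit test of observed vs expected per-LG counts."""

    statistic: float
    df: int
    p_value: float
    observed: list[float]
    expected: list[float]

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")
        if self.df != len(self.observed) - 1:
            raise ValueError("df must equal number of LGs - 1")
        if abs(sum(self.observed) - sum(self.expected)) > 1e-6 * max(1.0, sum(self.observed)):
            raise ValueError("expected counts must sum to the observed total")
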