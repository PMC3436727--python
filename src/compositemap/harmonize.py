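"""Cross-map harmonization: name standardization, linkage-group homology,
marker classification and colinearity pre-screening.

Before any merging, component maps must speak the same language: marker names
are standardized via an optional alias table, homologous linkage groups are
identified from shared (anchor) loci, and each component LG is screened for
gross order discordance against the reference map.  Marker placements are
classified as *bridging* (mapped on homologous LGs in >= 2 maps), *unique*
(one map only) or *multicopy* (mapped to >= 2 distinct homologous LG classes,
indicating a putatively duplicated locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ComponentMap, MarkerLocus
from .stats import spearman_rho

__all__ = [
    "AnchorSet",
    "LGAssignment",
    "MarkerClassification",
    "ColinearityRecord",
    "standardize_names",
    "find_shared_markers",
    "match_linkage_groups",
    "classify_markers",
    "screen_colinearity",
    "screen_map",
]


@dataclass
class AnchorSet:
    """Markers shared by one LG pair, with their paired positions."""

    names: list[str]
    positions_a: np.ndarray
    positions_b: np.ndarray

    @property
    def n(self) -> int:
        return len(self.names)


@dataclass
class LGAssignment:
    """Homology assignment of one component LG to a reference LG."""

    component_lg: str
    reference_lg: str | None  # None when unassigned
    n_shared: int
    tie: bool = False


@dataclass
class MarkerClassification:
    """Per-marker placements and the bridging/unique/multicopy breakdown.

    A *position* is one (marker, homologous-LG class) pair.  The accounting
    identity ``total positions == bridging + unique`` always holds; multicopy
    markers are counted separately (a marker can be both bridging and
    multicopy through different copies).
    """

    placements: dict[str, set[tuple[str, str]]]  # marker -> {(map_id, lg)}
    position_class: dict[tuple[str, str], set[str]]  # (marker, class) -> map_ids
    multicopy_markers: set[str]

    @property
    def n_positions(self) -> int:
        return len(self.position_class)

    @property
    def n_bridging(self) -> int:
        return sum(1 for maps in self.position_class.values() if len(maps) >= 2)

    @property
    def n_unique(self) -> int:
        return sum(1 for maps in self.position_class.values() if len(maps) == 1)

    def category(self, marker: str, lg_class: str) -> str:
        return "bridging" if len(self.position_class[(marker, lg_class)]) >= 2 else "unique"


def standardize_names(
    maps: list[ComponentMap], alias_table: dict[str, str] | None = None
) -> list[ComponentMap]:
    """Apply raw -> canonical marker-name aliases across all maps.

    Raises ``ValueError`` when two distinct raw names on the same LG of the
    same map collapse onto one canonical name (naming both raw names).
    """
    if not alias_table:
        return maps
    out = []
    for cmap in maps:
        groups: dict[str, list[MarkerLocus]] = {}
        for lg, loci in cmap.linkage_groups.items():
            renamed = []
            canon_from: dict[str, str] = {}
            for locus in loci:
                canon = alias_table.get(locus.name, locus.name)
                if canon in canon_from and canon_from[canon] != locus.name:
                    raise ValueError(
                        f"alias collision on {cmap.map_id}:{lg}: raw names "
                        f"{canon_from[canon]!r} and {locus.name!r} both map to {canon!r}"
                    )
                canon_from[canon] = locus.name
                renamed.append(MarkerLocus(canon, lg, locus.position, locus.marker_type))
            groups[lg] = renamed
        out.append(ComponentMap(cmap.map_id, groups, cmap.family_size))
    return out


def find_shared_markers(
    lg_a: list[MarkerLocus], lg_b: list[MarkerLocus]
) -> AnchorSet:
    """Intersect two LGs by marker name, returning paired positions."""
    pos_b = {l.name: l.position for l in lg_b}
    names, pa, pb = [], [], []
    for locus in lg_a:
        if locus.name in pos_b:
            names.append(locus.name)
            pa.append(locus.position)
            pb.append(pos_b[locus.name])
    return AnchorSet(names, np.asarray(pa, dtype=float), np.asarray(pb, dtype=float))


def match_linkage_groups(
    reference_map: ComponentMap,
    other_map: ComponentMap,
    min_anchors: int = 3,
) -> dict[str, LGAssignment]:
    """Assign each LG of ``other_map`` to the reference LG sharing the most
    markers.  Assignments below ``min_anchors`` shared markers, or tied
    between reference LGs, are flagged unassigned."""
    ref_names = {
        lg: {l.name for l in loci} for lg, loci in reference_map.linkage_groups.items()
    }
    out: dict[str, LGAssignment] = {}
    for lg, loci in other_map.linkage_groups.items():
        names = {l.name for l in loci}
        counts = {ref_lg: len(names & ref) for ref_lg, ref in ref_names.items()}
        best = max(counts.values(), default=0)
        winners = [ref_lg for ref_lg, c in counts.items() if c == best and c > 0]
        if best < min_anchors:
            out[lg] = LGAssignment(lg, None, best)
        elif len(winners) > 1:
            out[lg] = LGAssignment(lg, None, best, tie=True)
        else:
            out[lg] = LGAssignment(lg, winners[0], best)
    return out


def classify_markers(
    maps: list[ComponentMap],
    homology: dict[str, dict[str, LGAssignment]],
    reference_map_id: str,
) -> MarkerClassification:
    """Classify every (marker, map, LG) placement.

    ``homology`` maps non-reference map ids to their LG assignments against
    the reference map (whose LGs are their own homology classes).  A
    placement on an unassigned LG forms its own singleton class keyed by
    (map_id, lg) so that totals stay conserved.
    """
    placements: dict[str, set[tuple[str, str]]] = {}
    position_class: dict[tuple[str, str], set[str]] = {}
    marker_classes: dict[str, set[str]] = {}

    for cmap in maps:
        for lg, loci in cmap.linkage_groups.items():
            if cmap.map_id == reference_map_id:
                lg_class = lg
            else:
                assign = homology[cmap.map_id].get(lg)
                lg_class = (
                    assign.reference_lg
                    if assign is not None and assign.reference_lg is not None
                    else f"?{cmap.map_id}:{lg}"
                )
            for locus in loci:
                placements.setdefault(locus.name, set()).add((cmap.map_id, lg))
                position_class.setdefault((locus.name, lg_class), set()).add(cmap.map_id)
                marker_classes.setdefault(locus.name, set()).add(lg_class)

    multicopy = {m for m, classes in marker_classes.items() if len(classes) >= 2}
    return MarkerClassification(placements, position_class, multicopy)


@dataclass
class ColinearityRecord:
    """One pairwise order-correlation between a component LG and a reference LG."""

    map_id: str
    component_lg: str
    reference_lg: str
    n_common: int
    rho: float | None
    decision: str = "pass"  # "pass" | "excluded" | "unassessed"


def screen_colinearity(
    component_lg: list[MarkerLocus],
    reference_lgs: dict[str, list[MarkerLocus]],
    min_rho: float = 0.90,
    min_anchors: int = 3,
    map_id: str = "",
    component_lg_id: str = "",
) -> tuple[bool, list[ColinearityRecord]]:
    """Pre-screen one component LG for gross order discordance.

    Returns ``(excluded, records)``: the LG is flagged excluded when, over all
    reference LGs with >= ``min_anchors`` shared markers, the best |rho| falls
    below ``min_rho``.  Orientation is arbitrary across independently built
    maps, so the magnitude of rho is what is screened (a perfectly reversed LG
    passes).  When no reference comparison reaches ``min_anchors`` the LG is
    unassessed and passes by default — screening is advisory, mirroring a
    visual colinearity inspection, unless the caller auto-applies exclusions.
    """
    records: list[ColinearityRecord] = []
    best: float | None = None
    for ref_lg, ref_loci in reference_lgs.items():
        anchors = find_shared_markers(component_lg, ref_loci)
        if anchors.n == 0:
            continue
        rho = spearman_rho(anchors.positions_a, anchors.positions_b)
        records.append(
            ColinearityRecord(map_id, component_lg_id, ref_lg, anchors.n, rho)
        )
        if anchors.n >= min_anchors and rho is not None:
            best = abs(rho) if best is None else max(best, abs(rho))
    if best is None:
        for r in records:
            r.decision = "unassessed"
        return False, records
    excluded = best < min_rho
    for r in records:
        r.decision = "excluded" if excluded else "pass"
    return excluded, records


def screen_map(
    component_maps: list[ComponentMap],
    reference_map: ComponentMap,
    min_rho: float = 0.90,
    min_anchors: int = 3,
) -> tuple[set[tuple[str, str]], list[ColinearityRecord]]:
    """Screen every LG of every non-reference map against the reference.

    Returns the set of (map_id, lg) flagged for exclusion plus the full
    pairwise report for human review.
    """
    excluded: set[tuple[str, str]] = set()
    report: list[ColinearityRecord] = []
    for cmap in component_maps:
        if cmap.map_id == reference_map.map_id:
            continue
        for lg, loci in cmap.linkage_groups.items():
            is_excluded, records = screen_colinearity(
                loci,
                reference_map.linkage_groups,
                min_rho=min_rho,
                min_anchors=min_anchors,
                map_id=cmap.map_id,
                component_lg_id=lg,
            )
            report.extend(records)
            if is_excluded:
                excluded.add((cmap.map_id, lg))
    return excluded, report
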