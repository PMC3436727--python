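"""The composite-map merge engine.

The algorithm treats one component map as a *seed* (fixed backbone) and
iteratively merges the remaining component linkage groups into each seed LG:

1. For every candidate component LG homologous to the building LG, count
   shared (anchor) markers and compute the Spearman order correlation rho of
   their positions; score each candidate by fit value = |rho| x log(n_common).
2. Select the eligible candidate with the highest fit value (eligible means
   >= 3 anchors and |rho| >= 0.50 by default).
3. Fit the least-squares line pc = m * pi + c through the anchor positions
   (component positions pi flipped to max(pi) - pi first when the orientation
   is reversed) and place every component marker not yet on the building LG
   at m * pi + c.  Markers already present only gain provenance.
4. Repeat with the grown building LG — later rounds anchor on previously
   projected markers too — until no candidate is eligible.

Seed marker positions are never re-estimated; the final per-LG shift to a
minimum position of 0 is a rigid translation.  Distal markers separated from
the map body by a large gap (>= 5 cM) and supported by a single component map
are trimmed afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .harmonize import LGAssignment, match_linkage_groups
from .model import (
    ComponentMap,
    CompositeLocus,
    CompositeMap,
    LGComparison,
    MarkerLocus,
    MergeRound,
    Projection,
)
from .stats import fit_projection, fit_value, spearman_rho

__all__ = [
    "MergeConfig",
    "spearman_rho",
    "fit_value",
    "fit_projection",
    "compare_lgs",
    "select_best_component",
    "project_unique_markers",
    "build_linkage_group",
    "trim_ends",
    "select_seed_map",
    "build_composite",
]

logger = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    """Tunable thresholds of the merge procedure (defaults are the reference
    behavior: 3 anchors, |rho| >= 0.50, 5 cM distal trim)."""

    min_anchors: int = 3
    min_rho: float = 0.50
    log_base: float = 10.0
    trim_gap_cm: float = 5.0
    trim_min_support: int = 2
    screen_rho: float = 0.90
    auto_exclude: bool = False
    seed_map_id: str | None = None


@dataclass
class _Candidate:
    """A component LG not yet consumed for the current building LG."""

    map_id: str
    lg: str
    loci: list[MarkerLocus]
    order: int  # input order, for deterministic tie-breaking


def compare_lgs(
    building: list[CompositeLocus],
    candidate: _Candidate,
    log_base: float = 10.0,
    building_lg: str = "",
) -> LGComparison:
    """Shared-marker count, signed rho, orientation and fit value for one
    building-LG vs component-LG pair."""
    pos_b = {l.name: l.position for l in building}
    names = [l.name for l in candidate.loci if l.name in pos_b]
    pc = np.array([pos_b[n] for n in names])
    pi_map = {l.name: l.position for l in candidate.loci}
    pi = np.array([pi_map[n] for n in names])
    rho = spearman_rho(pc, pi) if len(names) >= 2 else None
    orientation = "reversed" if (rho is not None and rho < 0) else "forward"
    return LGComparison(
        building_lg=building_lg,
        component_map_id=candidate.map_id,
        component_lg=candidate.lg,
        n_common=len(names),
        rho=rho,
        orientation=orientation,
        fit_value=fit_value(rho, len(names), log_base),
    )


def select_best_component(
    building: list[CompositeLocus],
    candidates: list[_Candidate],
    min_anchors: int = 3,
    min_rho: float = 0.50,
    log_base: float = 10.0,
    building_lg: str = "",
) -> tuple[LGComparison, _Candidate] | None:
    """Among eligible candidates (n_common >= min_anchors, |rho| >= min_rho),
    return the one with the highest fit value; None when nothing is eligible.

    Ties are broken by larger n_common, then candidate input order, so the
    selection is deterministic.
    """
    best: tuple[float, int, int, LGComparison, _Candidate] | None = None
    for cand in candidates:
        cmp_ = compare_lgs(building, cand, log_base, building_lg)
        if cmp_.n_common < min_anchors or cmp_.rho is None or abs(cmp_.rho) < min_rho:
            continue
        key = (cmp_.fit_value, cmp_.n_common, -cand.order)
        if best is None or key > (best[0], best[1], best[2]):
            best = (cmp_.fit_value, cmp_.n_common, -cand.order, cmp_, cand)
    if best is None:
        return None
    return best[3], best[4]


def project_unique_markers(
    candidate_loci: list[MarkerLocus],
    building_index: dict[str, CompositeLocus],
    projection: Projection,
    map_id: str,
    round_index: int,
    building_lg: str,
    flip_max: float | None = None,
) -> tuple[list[CompositeLocus], int]:
    """Place component markers absent from the building LG at m*pi + c.

    ``flip_max`` reverses component positions (pi <- flip_max - pi) first when
    the component LG's orientation is opposite to the building LG.  Markers
    already on the building LG are skipped but gain ``map_id`` in their
    support set; returns (new loci, number skipped).  Projected positions may
    fall below 0 or beyond the current LG ends — a later rigid shift
    renormalizes the LG start.
    """
    added: list[CompositeLocus] = []
    skipped = 0
    for locus in candidate_loci:
        if locus.name in building_index:
            building_index[locus.name].support.add(map_id)
            skipped += 1
            continue
        pi = locus.position if flip_max is None else flip_max - locus.position
        added.append(
            CompositeLocus(
                name=locus.name,
                linkage_group=building_lg,
                position=projection.predict(pi),
                marker_type=locus.marker_type,
                support={map_id},
                added_in_round=round_index,
            )
        )
    return added, skipped


def build_linkage_group(
    building_lg: str,
    seed_loci: list[MarkerLocus],
    candidates: list[tuple[str, str, list[MarkerLocus]]],
    seed_map_id: str,
    config: MergeConfig | None = None,
) -> tuple[list[CompositeLocus], list[MergeRound]]:
    """Merge candidate component LGs into one seed LG.

    Each candidate LG is consumed at most once.  Anchors in later rounds
    include markers projected in earlier rounds, at their composite
    positions.  Returns the sorted composite LG (rigidly shifted to start at
    0) and the per-round audit records.
    """
    config = config or MergeConfig()
    building = [
        CompositeLocus(l.name, building_lg, l.position, l.marker_type, {seed_map_id}, 0)
        for l in seed_loci
    ]
    index = {l.name: l for l in building}
    pool = [_Candidate(m, lg, loci, i) for i, (m, lg, loci) in enumerate(candidates)]
    log: list[MergeRound] = []
    round_index = 0
    while pool:
        selected = select_best_component(
            building, pool, config.min_anchors, config.min_rho, config.log_base, building_lg
        )
        if selected is None:
            break
        cmp_, cand = selected
        round_index += 1
        flip_max = None
        if cmp_.orientation == "reversed":
            flip_max = max(l.position for l in cand.loci)
        pos_b = {l.name: l.position for l in building}
        anchor_names = [l.name for l in cand.loci if l.name in pos_b]
        pc = np.array([pos_b[n] for n in anchor_names])
        pi_raw = {l.name: l.position for l in cand.loci}
        pi = np.array(
            [pi_raw[n] if flip_max is None else flip_max - pi_raw[n] for n in anchor_names]
        )
        projection = fit_projection(pc, pi)
        added, skipped = project_unique_markers(
            cand.loci, index, projection, cand.map_id, round_index, building_lg, flip_max
        )
        building.extend(added)
        index.update({l.name: l for l in added})
        log.append(
            MergeRound(
                building_lg=building_lg,
                round_index=round_index,
                component_map_id=cand.map_id,
                component_lg=cand.lg,
                n_common=cmp_.n_common,
                rho=cmp_.rho,
                orientation=cmp_.orientation,
                fit_value=cmp_.fit_value,
                slope=projection.slope,
                intercept=projection.intercept,
                residual_rmse=projection.residual_rmse,
                markers_added=len(added),
                markers_skipped=skipped,
            )
        )
        pool = [c for c in pool if not (c.map_id == cand.map_id and c.lg == cand.lg)]

    building.sort(key=lambda l: (l.position, l.name))
    if building:
        shift = building[0].position
        for locus in building:
            locus.position -= shift
    return building, log


def trim_ends(
    loci: list[CompositeLocus],
    gap_threshold: float = 5.0,
    min_support: int = 2,
) -> tuple[list[CompositeLocus], list[CompositeLocus]]:
    """Remove poorly supported distal markers.

    A terminal marker is removed while its gap to the nearest neighbour is
    >= ``gap_threshold`` cM AND it is supported by fewer than ``min_support``
    component maps.  Applied repeatedly from both ends until stable (hence
    idempotent); the kept LG is rigidly shifted back to start at 0.
    Returns (kept, removed).
    """
    kept = sorted(loci, key=lambda l: (l.position, l.name))
    removed: list[CompositeLocus] = []
    changed = True
    while changed and len(kept) >= 2:
        changed = False
        first = kept[0]
        if kept[1].position - first.position >= gap_threshold and len(first.support) < min_support:
            removed.append(first)
            kept = kept[1:]
            changed = True
            continue
        last = kept[-1]
        if last.position - kept[-2].position >= gap_threshold and len(last.support) < min_support:
            removed.append(last)
            kept = kept[:-1]
            changed = True
    if kept:
        shift = kept[0].position
        for locus in kept:
            locus.position -= shift
    return kept, removed


def select_seed_map(maps: list[ComponentMap]) -> ComponentMap:
    """Pick the seed (backbone) map: most mapped markers, then largest
    pedigree family size, then lexical map id."""
    return sorted(
        maps, key=lambda m: (-m.n_positions, -(m.family_size or 0), m.map_id)
    )[0]


def build_composite(
    component_maps: list[ComponentMap],
    config: MergeConfig | None = None,
    excluded_lgs: set[tuple[str, str]] | None = None,
    homology: dict[str, dict[str, LGAssignment]] | None = None,
) -> CompositeMap:
    """Build the full composite map from harmonized component maps.

    The seed map contributes the fixed backbone for every one of its LGs;
    every other map's LGs are routed to their homologous seed LG (by shared
    anchor count) and merged by :func:`build_linkage_group`, then distal ends
    are trimmed and multicopy flags (markers on >= 2 composite LGs) are
    annotated.  ``excluded_lgs`` holds (map_id, lg) pairs ruled out by the
    colinearity pre-screen.
    """
    if len(component_maps) < 2:
        raise ValueError("composite map construction needs >= 2 component maps")
    config = config or MergeConfig()
    excluded_lgs = excluded_lgs or set()

    if config.seed_map_id is not None:
        try:
            seed = next(m for m in component_maps if m.map_id == config.seed_map_id)
        except StopIteration:
            raise ValueError(f"seed map {config.seed_map_id!r} not among inputs") from None
    else:
        seed = select_seed_map(component_maps)
    others = [m for m in component_maps if m.map_id != seed.map_id]

    if homology is None:
        homology = {
            m.map_id: match_linkage_groups(seed, m, config.min_anchors) for m in others
        }
    for m in others:
        for lg, assign in homology[m.map_id].items():
            if assign.reference_lg is None and (m.map_id, lg) not in excluded_lgs:
                logger.warning(
                    "map %s LG %s: no homologous seed LG (%d shared markers%s)",
                    m.map_id,
                    lg,
                    assign.n_shared,
                    ", tie" if assign.tie else "",
                )

    groups: dict[str, list[CompositeLocus]] = {}
    merge_log: list[MergeRound] = []
    for seed_lg, seed_loci in seed.linkage_groups.items():
        candidates: list[tuple[str, str, list[MarkerLocus]]] = []
        for m in others:
            for lg, assign in homology[m.map_id].items():
                if assign.reference_lg != seed_lg:
                    continue
                if (m.map_id, lg) in excluded_lgs:
                    continue
                candidates.append((m.map_id, lg, m.linkage_groups[lg]))
        built, log = build_linkage_group(seed_lg, seed_loci, candidates, seed.map_id, config)
        kept, removed = trim_ends(built, config.trim_gap_cm, config.trim_min_support)
        if removed:
            logger.info(
                "LG %s: trimmed %d poorly supported distal marker(s): %s",
                seed_lg,
                len(removed),
                ", ".join(l.name for l in removed),
            )
        groups[seed_lg] = kept
        merge_log.extend(log)

    composite = CompositeMap(linkage_groups=groups, merge_log=merge_log, seed_map_id=seed.map_id)
    composite.annotate_multicopy()
    return composite
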